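"""Tetramer interface analysis: ion pairs, hydrogen bonds, surfaces.

A dimer-of-dimers tetramer (chains A+B and C+D forming the two dimers)
has three classes of chain-chain interface, each the sum of two
disjoint chain pairs:

* ``m`` — the intra-dimer interfaces, A-B plus D-C;
* ``d`` and ``c`` — the two cross-dimer pairings (A-D/B-C and
  A-C/B-D); which pairing carries which label is a convention fixed by
  the tetramer geometry, so it is configurable rather than hard-coded.

Per interface the module counts interdomain ion pairs (basic
side-chain N against acidic carboxylate O) and hydrogen bonds
(geometric donor/acceptor criterion), tracks their per-frame timelines
and occupancies, classifies the interfacial surface into
hydrophobic/hydrophilic/mixed area fractions from the Voronoi facets
separating the two sides, and assembles occupancy-weighted ion-pair
networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Structure, Trajectory

__all__ = [
    "InterfaceSpec",
    "Contact",
    "ContactTimelineSet",
    "SurfaceClassification",
    "define_interfaces",
    "detect_ion_pairs",
    "detect_hydrogen_bonds",
    "contact_timelines",
    "classify_interface_surface",
    "build_ip_network",
    "hydrophobic_proximity_census",
]

BASIC_SIDECHAIN_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "HSP": ("ND1", "NE2"),
}
ACIDIC_SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# donor heavy atom -> antecedent atom used for the heavy-atom angle proxy
HB_DONORS: dict[str, dict[str, str]] = {
    "*": {"N": "CA"},  # backbone amide on every residue
    "ARG": {"NE": "CZ", "NH1": "CZ", "NH2": "CZ"},
    "LYS": {"NZ": "CE"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "TRP": {"NE1": "CD1"},
}
HB_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O", "OXT"),  # backbone carbonyl
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

HYDROPHOBIC_RESNAMES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
)


@dataclass(frozen=True)
class InterfaceSpec:
    """One interface class: a label plus the two chain pairs it sums."""

    label: str
    pairs: tuple[tuple[str, str], tuple[str, str]]

    def __post_init__(self) -> None:
        chains = [c for p in self.pairs for c in p]
        if len(set(chains)) != 4:
            raise ValueError(
                f"interface {self.label}: the two pairs must cover 4 distinct chains"
            )

    def spans(self, chain_a: str, chain_b: str) -> bool:
        return (chain_a, chain_b) in self.pairs or (chain_b, chain_a) in self.pairs


def define_interfaces(
    structure: Structure,
    d_pairs: tuple[tuple[str, str], tuple[str, str]] = (("A", "D"), ("B", "C")),
) -> dict[str, InterfaceSpec]:
    """The m/d/c interface decomposition of a 4-chain tetramer.

    ``m`` is always the intra-dimer sum A-B + D-C.  The cross-dimer
    pairing assigned to ``d`` is configurable (default A-D/B-C); the
    remaining pairing becomes ``c``.
    """
    chains = structure.chains
    if len(chains) != 4 or set(chains) != {"A", "B", "C", "D"}:
        raise ValueError(f"expected exactly chains A,B,C,D; found {chains}")
    cross = [(("A", "D"), ("B", "C")), (("A", "C"), ("B", "D"))]
    d_norm = tuple(tuple(sorted(p)) for p in d_pairs)
    options = [tuple(tuple(sorted(p)) for p in o) for o in cross]
    if sorted(d_norm) not in [sorted(o) for o in options]:
        raise ValueError(f"d_pairs must be one of the cross-dimer pairings, got {d_pairs}")
    c_pairs = cross[1] if sorted(d_norm) == sorted(options[0]) else cross[0]
    return {
        "m": InterfaceSpec("m", (("A", "B"), ("D", "C"))),
        "d": InterfaceSpec("d", tuple(d_pairs)),  # type: ignore[arg-type]
        "c": InterfaceSpec("c", c_pairs),
    }


@dataclass(frozen=True)
class Contact:
    """A cross-chain residue-pair contact (counted once per pair)."""

    kind: str  # "IP" | "HB"
    chain_a: str
    resid_a: int
    resname_a: str
    chain_b: str
    resid_b: int
    resname_b: str

    @property
    def key(self) -> tuple:
        return (self.chain_a, self.resid_a, self.chain_b, self.resid_b)


def _atoms_with_names(structure: Structure, table: dict[str, tuple[str, ...]]):
    """Indices of atoms whose (resname -> names) entry matches."""
    out = []
    for i, a in enumerate(structure.atoms):
        names = table.get(a.resname, ())
        if a.name in names:
            out.append(i)
    return np.array(out, dtype=int)


def detect_ion_pairs(
    frame: np.ndarray,
    structure: Structure,
    interface: InterfaceSpec,
    cutoff: float = 4.0,
    include_his: bool = False,
) -> list[Contact]:
    """Interdomain ion pairs at one frame.

    An ion pair exists when any basic side-chain nitrogen (Arg NE/NH*,
    Lys NZ, His if ``include_his``) lies within ``cutoff`` Å of any
    acidic carboxylate oxygen (Asp OD*, Glu OE*) on a chain paired by
    the interface.  Each residue pair counts once per frame.
    """
    frame = np.asarray(frame, dtype=float)
    basic_table = dict(BASIC_SIDECHAIN_N)
    if not include_his:
        basic_table.pop("HIS", None)
        basic_table.pop("HSP", None)
    basic = _atoms_with_names(structure, basic_table)
    acidic = _atoms_with_names(structure, ACIDIC_SIDECHAIN_O)
    if basic.size == 0 or acidic.size == 0:
        return []
    tree = cKDTree(frame[acidic])
    found: dict[tuple, Contact] = {}
    for bi in basic:
        ab = structure.atoms[bi]
        near = tree.query_ball_point(frame[bi], cutoff)
        for k in near:
            ai = int(acidic[k])
            aa = structure.atoms[ai]
            if not interface.spans(ab.chain, aa.chain):
                continue
            c = Contact("IP", ab.chain, ab.resid, ab.resname, aa.chain, aa.resid, aa.resname)
            found.setdefault(c.key, c)
    return list(found.values())


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _donor_entries(structure: Structure):
    """(donor idx, antecedent idx or -1, hydrogens attached) per donor."""
    loc: dict[tuple[str, int, str], int] = {
        (a.chain, a.resid, a.name): i for i, a in enumerate(structure.atoms)
    }
    hydro_by_res: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.element == "H":
            hydro_by_res.setdefault((a.chain, a.resid), []).append(i)
    entries = []
    unknown: set[str] = set()
    for i, a in enumerate(structure.atoms):
        if a.element == "H":
            continue
        templ = {}
        templ.update(HB_DONORS.get("*", {}))
        res_t = HB_DONORS.get(a.resname)
        if res_t is None and a.resname not in HB_ACCEPTORS and a.resname not in {
            "GLY", "ALA", "LEU", "ILE", "VAL", "PRO", "PHE", "MET", "CYS", "ASP", "GLU", "LYS", "ARG", "TRP", "HIS", "SER", "THR", "TYR", "ASN", "GLN",
        }:
            unknown.add(a.resname)
        templ.update(res_t or {})
        ant_name = templ.get(a.name)
        if ant_name is None:
            continue
        ant = loc.get((a.chain, a.resid, ant_name), -1)
        hs = [
            h
            for h in hydro_by_res.get((a.chain, a.resid), [])
            if np.linalg.norm(structure.coords[h] - structure.coords[i]) < 1.25
        ]
        entries.append((i, ant, hs))
    for rn in unknown:
        warnings.warn(f"unknown residue type {rn!r}: skipped in H-bond templates")
    return entries


def _acceptor_indices(structure: Structure) -> np.ndarray:
    out = []
    for i, a in enumerate(structure.atoms):
        if a.name in HB_ACCEPTORS.get("*", ()) or a.name in HB_ACCEPTORS.get(a.resname, ()):
            out.append(i)
    return np.array(out, dtype=int)


def detect_hydrogen_bonds(
    frame: np.ndarray,
    structure: Structure,
    interface: InterfaceSpec,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 150.0,
    proxy_angle_cutoff: float = 120.0,
) -> list[Contact]:
    """Interdomain hydrogen bonds at one frame (geometric criterion).

    Donor-acceptor heavy-atom distance <= 3.5 Å and, when the donor
    carries explicit hydrogens, D-H...A angle >= 150° for at least one
    of them; without hydrogens a heavy-atom proxy requires the
    antecedent-D...A angle >= 120°.  One bond per residue pair per
    frame.
    """
    frame = np.asarray(frame, dtype=float)
    donors = _donor_entries(structure)
    acceptors = _acceptor_indices(structure)
    if not donors or acceptors.size == 0:
        return []
    tree = cKDTree(frame[acceptors])
    found: dict[tuple, Contact] = {}
    for di, ant, hs in donors:
        da = structure.atoms[di]
        for k in tree.query_ball_point(frame[di], distance_cutoff):
            ai = int(acceptors[k])
            aa = structure.atoms[ai]
            if ai == di or not interface.spans(da.chain, aa.chain):
                continue
            if hs:
                ok = any(
                    _angle_deg(frame[di], frame[h], frame[ai]) >= angle_cutoff for h in hs
                )
            elif ant >= 0:
                ok = _angle_deg(frame[ant], frame[di], frame[ai]) >= proxy_angle_cutoff
            else:
                ok = True
            if ok:
                c = Contact("HB", da.chain, da.resid, da.resname, aa.chain, aa.resid, aa.resname)
                found.setdefault(c.key, c)
    return list(found.values())


@dataclass
class ContactTimelineSet:
    """Per-frame contact counts and per-pair occupancy over a trajectory."""

    kind: str
    interface: InterfaceSpec
    times: np.ndarray
    counts: np.ndarray  # per-frame number of distinct residue-pair contacts
    presence: dict[tuple, np.ndarray]  # pair key -> boolean per-frame
    contacts: dict[tuple, Contact]

    @property
    def occupancy(self) -> dict[tuple, float]:
        return {k: float(v.mean()) for k, v in self.presence.items()}

    @property
    def mean_count(self) -> float:
        return float(self.counts.mean())

    @property
    def std_count(self) -> float:
        return float(self.counts.std())

    def distinct_pairs(self) -> int:
        return len(self.presence)


def contact_timelines(
    traj: Trajectory,
    interface: InterfaceSpec,
    kind: str = "ip",
    **criteria,
) -> ContactTimelineSet:
    """Track interdomain IP or HB contacts over every frame."""
    detect = {"ip": detect_ion_pairs, "hb": detect_hydrogen_bonds}[kind.lower()]
    presence: dict[tuple, list[int]] = {}
    contacts: dict[tuple, Contact] = {}
    counts = np.zeros(traj.n_frames, dtype=int)
    per_frame: list[list[tuple]] = []
    for t in range(traj.n_frames):
        found = detect(traj.frames[t], traj.topology, interface, **criteria)
        counts[t] = len(found)
        keys = []
        for c in found:
            contacts.setdefault(c.key, c)
            keys.append(c.key)
        per_frame.append(keys)
    pres = {k: np.zeros(traj.n_frames, dtype=bool) for k in contacts}
    for t, keys in enumerate(per_frame):
        for k in keys:
            pres[k][t] = True
    return ContactTimelineSet(kind.upper(), interface, traj.times, counts, pres, contacts)


# ---------------------------------------------------------------------------
# Interfacial surface classification
# ---------------------------------------------------------------------------

HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})
HYDROPHILIC_ELEMENTS = frozenset({"N", "O"})


@dataclass
class SurfaceClassification:
    """Hydrophobic / hydrophilic / mixed interfacial area split."""

    interface: str
    fractions: tuple[float, float, float]  # phobic-phobic, philic-philic, mixed
    areas: tuple[float, float, float]  # Å^2
    method: str = "voronoi-facets"

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-6:
            raise ValueError("surface fractions must sum to 1")


def _facet_area(vertices: np.ndarray) -> float:
    """Area of a planar convex polygon given its 3D vertices (fan sum)."""
    if vertices.shape[0] < 3:
        return 0.0
    v0 = vertices[0]
    area = 0.0
    for i in range(1, vertices.shape[0] - 1):
        area += 0.5 * np.linalg.norm(np.cross(vertices[i] - v0, vertices[i + 1] - v0))
    return float(area)


def _atom_class(element: str) -> str | None:
    if element in HYDROPHOBIC_ELEMENTS:
        return "phobic"
    if element in HYDROPHILIC_ELEMENTS:
        return "philic"
    return None


def classify_interface_surface(
    frame: np.ndarray,
    structure: Structure,
    interface: InterfaceSpec,
    contact_cutoff: float = 7.0,
) -> SurfaceClassification:
    """Split the interfacial contact surface by the chemistry of its sides.

    The space around the complex is tessellated (Voronoi diagram over
    heavy atoms, closed by a probe shell); every facet separating two
    atoms that belong to the two chains of an interface pair, with the
    atoms within ``contact_cutoff`` of each other, contributes its area
    to one of three classes by the elements of the facing atoms: both
    carbon/sulfur = hydrophobic-hydrophobic, both nitrogen/oxygen =
    hydrophilic-hydrophilic, otherwise mixed.  Fractions are
    normalized to sum to 1 per interface.
    """
    from .volumetrics import _probe_shell  # shared boundary construction

    frame = np.asarray(frame, dtype=float)
    heavy = np.array(
        [i for i, a in enumerate(structure.atoms) if a.element != "H"], dtype=int
    )
    pts = frame[heavy]
    shell = _probe_shell(pts)
    allpts = np.vstack([pts, shell])
    from scipy.spatial import Voronoi

    vor = Voronoi(allpts)
    n_protein = pts.shape[0]
    areas = {"phobic": 0.0, "philic": 0.0, "mixed": 0.0}
    chains = [structure.atoms[i].chain for i in heavy]
    elements = [structure.atoms[i].element for i in heavy]
    for (p, q), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_protein or q >= n_protein:
            continue
        if not interface.spans(chains[p], chains[q]):
            continue
        if np.linalg.norm(pts[p] - pts[q]) > contact_cutoff:
            continue
        if -1 in ridge:
            continue
        area = _facet_area(vor.vertices[np.array(ridge)])
        cp, cq = _atom_class(elements[p]), _atom_class(elements[q])
        if cp is None or cq is None:
            continue
        key = cp if cp == cq else "mixed"
        areas[key] += area
    total = sum(areas.values())
    if total <= 0:
        raise ValueError(f"interface {interface.label} empty: no interfacial facets found")
    fr = (areas["phobic"] / total, areas["philic"] / total, areas["mixed"] / total)
    return SurfaceClassification(
        interface.label, fr, (areas["phobic"], areas["philic"], areas["mixed"])
    )


# ---------------------------------------------------------------------------
# Ion-pair occupancy networks
# ---------------------------------------------------------------------------


def build_ip_network(timelines: list[ContactTimelineSet], display_threshold: float = 0.05):
    """Occupancy-weighted graph of interchain ion pairs.

    Nodes are charged residues (labelled ``chain:resid:resname``) with
    weight = fraction of frames in which the residue forms at least one
    interdomain ion pair; edges carry pair occupancies.  Edges below
    ``display_threshold`` stay in the graph flagged ``display=False``.
    """
    import networkx as nx

    if not timelines:
        raise ValueError("need at least one timeline set")
    g = nx.Graph()
    node_presence: dict[str, np.ndarray] = {}
    for tl in timelines:
        for key, pres in tl.presence.items():
            c = tl.contacts[key]
            na = f"{c.chain_a}:{c.resid_a}:{c.resname_a}"
            nb = f"{c.chain_b}:{c.resid_b}:{c.resname_b}"
            for n, ch in ((na, c.chain_a), (nb, c.chain_b)):
                if n not in node_presence:
                    node_presence[n] = np.zeros(pres.size, dtype=bool)
                    g.add_node(n, chain=ch, weight=0.0)
                node_presence[n] = node_presence[n] | pres
            occ = float(pres.mean())
            if g.has_edge(na, nb):
                g[na][nb]["weight"] = max(g[na][nb]["weight"], occ)
            else:
                g.add_edge(
                    na, nb, weight=occ, interface=tl.interface.label,
                    display=occ >= display_threshold,
                )
    for n, pres in node_presence.items():
        g.nodes[n]["weight"] = float(pres.mean())
    return g


def hydrophobic_proximity_census(
    structure: Structure,
    interface: InterfaceSpec,
    cutoff: float = 4.5,
) -> dict[str, int]:
    """Hydrophobic residues near hydrophobic residues across the interface.

    Counts, per chain, the hydrophobic residues having any side-chain
    heavy atom within ``cutoff`` Å of a side-chain heavy atom of a
    hydrophobic residue on the opposite side of the interface.
    """
    sc = structure.select("sidechain-heavy")
    info = [(i, structure.atoms[i]) for i in sc if structure.atoms[i].resname in HYDROPHOBIC_RESNAMES]
    if not info:
        return {c: 0 for p in interface.pairs for c in p}
    idx = np.array([i for i, _ in info])
    coords = structure.coords[idx]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    hits: dict[str, set[tuple[str, int]]] = {}
    for a, b in pairs:
        aa, ab = info[a][1], info[b][1]
        if interface.spans(aa.chain, ab.chain):
            hits.setdefault(aa.chain, set()).add((aa.chain, aa.resid))
            hits.setdefault(ab.chain, set()).add((ab.chain, ab.resid))
    out = {c: 0 for p in interface.pairs for c in p}
    for c, residues in hits.items():
        out[c] = len(residues)
    return out
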