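"""Collective variables on trajectory frames.

Four scalar descriptors of a protein conformation, evaluated per frame:

* radius of gyration ``Rg`` about the unweighted mean position,
* ``RMSD`` to a crystallographic reference after optimal rigid-body
  superposition,
* fraction of native side-chain heavy-atom contacts ``Q``,
* fraction of native backbone torsion angles ``A`` (phi and psi).

``Q`` and ``A`` compare a frame against a reference state built once
from the crystal structure; both lie in [0, 1] and are invariant under
rigid-body motion of the frame.  The module also provides the
catalytic-pocket RMSD of a trajectory against apo and holo reference
conformers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_io import SelectionSpec, Structure, Trajectory, resolve_selection

__all__ = [
    "CVSeries",
    "ContactReference",
    "TorsionReference",
    "Transform",
    "radius_of_gyration",
    "superpose",
    "rmsd",
    "rmsd_series",
    "build_contact_reference",
    "fraction_native_contacts",
    "native_contacts_series",
    "build_torsion_reference",
    "fraction_native_torsions",
    "native_torsions_series",
    "pocket_rmsd_to_references",
]


@dataclass
class CVSeries:
    """A scalar collective variable xi(t)."""

    name: str
    values: np.ndarray
    times: np.ndarray  # ps
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")


def _as_indices(structure: Structure, selection) -> np.ndarray:
    if selection is None:
        return np.arange(structure.n_atoms)
    if isinstance(selection, (str, SelectionSpec)):
        return resolve_selection(structure, selection)
    return np.asarray(selection, dtype=int)


# ---------------------------------------------------------------------------
# Rg and superposition
# ---------------------------------------------------------------------------


def radius_of_gyration(coords: np.ndarray, selection: np.ndarray | None = None) -> float:
    """Unweighted radius of gyration, sqrt(mean |r_i - rbar|^2), in Å."""
    coords = np.asarray(coords, dtype=float)
    if selection is not None:
        coords = coords[np.asarray(selection, dtype=int)]
    if coords.shape[0] == 0:
        raise ValueError("empty selection for radius of gyration")
    center = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=1))))


def rg_series(traj: Trajectory, selection=None) -> CVSeries:
    idx = _as_indices(traj.topology, selection)
    vals = [radius_of_gyration(f, idx) for f in traj.frames]
    return CVSeries("Rg", np.array(vals), traj.times, "Å")


@dataclass
class Transform:
    """A proper rigid-body transform x -> R @ (x - mobile_center) + ref_center."""

    rotation: np.ndarray
    mobile_center: np.ndarray
    ref_center: np.ndarray
    rmsd: float  # post-fit RMSD over the fit selection, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return (coords - self.mobile_center) @ self.rotation.T + self.ref_center


def superpose(
    mobile: np.ndarray, reference: np.ndarray, fit: np.ndarray | None = None
) -> Transform:
    """Least-squares optimal proper rigid-body fit of mobile onto reference.

    Kabsch superposition (SVD with reflection correction) via
    :func:`scipy.spatial.transform.Rotation.align_vectors`.  Raises on
    fewer than 3 fit points or degenerate (collinear) geometry.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    m = mobile if fit is None else mobile[np.asarray(fit, dtype=int)]
    r = reference if fit is None else reference[np.asarray(fit, dtype=int)]
    if m.shape != r.shape:
        raise ValueError("fit selections have unequal atom counts")
    n = m.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    dm, dr = m - mc, r - rc
    # collinearity check: second singular value of the centered cloud
    sv = np.linalg.svd(dm, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) geometry: fit is ill-defined")
    rot, rssd = Rotation.align_vectors(dr, dm)
    fitted_rmsd = float(rssd / np.sqrt(n))
    return Transform(rot.as_matrix(), mc, rc, fitted_rmsd)


def superpose_batch(
    frames: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch-superpose a stack of frames onto one reference at once.

    Vectorized over the batch via stacked SVDs (with reflection
    correction); numerically identical to calling :func:`superpose`
    frame by frame, but orders of magnitude faster for long
    trajectories.  Returns (aligned frames, per-frame RMSD).
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frames.ndim != 3 or frames.shape[1:] != reference.shape:
        raise ValueError("frames must be (B, N, 3) matching the reference (N, 3)")
    rc = reference.mean(axis=0)
    ref_c = reference - rc
    centers = frames.mean(axis=1, keepdims=True)
    fc = frames - centers
    h = np.einsum("bni,nj->bij", fc, ref_c)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, :, -1] *= d[:, None]
    rot = u @ vt  # row-vector convention: aligned = fc @ rot
    aligned = fc @ rot + rc
    rmsds = np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=2), axis=1))
    return aligned, rmsds


def rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit: np.ndarray | None = None,
    measure: np.ndarray | None = None,
) -> float:
    """RMSD after superposition; measured over ``measure`` (default: fit set)."""
    t = superpose(mobile, reference, fit)
    if measure is None:
        return t.rmsd
    idx = np.asarray(measure, dtype=int)
    moved = t.apply(np.asarray(mobile, dtype=float)[idx])
    ref = np.asarray(reference, dtype=float)[idx]
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, reference: Structure, selection=None) -> CVSeries:
    """Per-frame RMSD to a reference after superposition on the same selection."""
    idx = _as_indices(traj.topology, selection)
    ref_idx = _as_indices(reference, selection) if isinstance(selection, (str, SelectionSpec)) else idx
    ref = reference.coords[ref_idx]
    _, vals = superpose_batch(traj.frames[:, idx], ref)
    return CVSeries("RMSD", vals, traj.times, "Å")


# ---------------------------------------------------------------------------
# Native contacts (Q)
# ---------------------------------------------------------------------------


@dataclass
class ContactReference:
    """Native side-chain heavy-atom contact map of a reference structure.

    ``partners[k]`` lists, for the k-th side-chain heavy atom, the
    side-chain heavy atoms (as positions into ``atom_indices``) within
    ``cutoff`` in the reference and more than ``min_sep`` residues apart
    in sequence (same chain), or on another chain if built interchain.
    """

    atom_indices: np.ndarray  # structure-level indices of side-chain heavy atoms
    partners: list[np.ndarray]
    cutoff: float  # Å
    min_sep: int  # residues
    interchain: bool = False

    @property
    def n_counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.partners])

    def __post_init__(self) -> None:
        if len(self.partners) != len(self.atom_indices):
            raise ValueError("partners and atom_indices length mismatch")


def build_contact_reference(
    structure: Structure,
    cutoff: float = 5.0,
    min_sep: int = 3,
    interchain: bool = False,
    selection: str = "sidechain-heavy",
) -> ContactReference:
    """Build the native contact map from a crystallographic structure.

    A contact pairs two side-chain heavy atoms within ``cutoff`` Å whose
    residues are more than ``min_sep`` apart in sequence.  By default
    only intrachain contacts count; ``interchain=True`` additionally
    admits cross-chain pairs (no sequence-separation rule applies
    across chains).
    """
    idx = _as_indices(structure, selection)
    if idx.size == 0:
        warnings.warn("no side-chain heavy atoms: empty contact reference")
        return ContactReference(idx, [], cutoff, min_sep, interchain)
    coords = structure.coords[idx]
    resids = np.array([structure.atoms[i].resid for i in idx])
    chains = np.array([structure.atoms[i].chain for i in idx])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    partners: list[list[int]] = [[] for _ in range(idx.size)]
    for a, b in pairs:
        same_chain = chains[a] == chains[b]
        if same_chain:
            if abs(int(resids[a]) - int(resids[b])) <= min_sep:
                continue
        elif not interchain:
            continue
        partners[a].append(b)
        partners[b].append(a)
    return ContactReference(
        idx,
        [np.array(sorted(p), dtype=int) for p in partners],
        cutoff,
        min_sep,
        interchain,
    )


def fraction_native_contacts(frame: np.ndarray, reference: ContactReference) -> float:
    """Q(t): mean over atoms (with n_i > 0) of the retained-partner fraction."""
    n_counts = reference.n_counts
    active = np.flatnonzero(n_counts > 0)
    if active.size == 0:
        raise ValueError("contact reference is empty (no atom has native partners)")
    coords = np.asarray(frame, dtype=float)[reference.atom_indices]
    tree = cKDTree(coords)
    fractions = np.empty(active.size)
    for out_i, k in enumerate(active):
        near = tree.query_ball_point(coords[k], reference.cutoff)
        kept = np.intersect1d(reference.partners[k], np.array(near, dtype=int)).size
        fractions[out_i] = kept / n_counts[k]
    return float(fractions.mean())


def native_contacts_series(traj: Trajectory, reference: ContactReference) -> CVSeries:
    vals = [fraction_native_contacts(f, reference) for f in traj.frames]
    return CVSeries("Q", np.array(vals), traj.times, "")


# ---------------------------------------------------------------------------
# Native torsions (A)
# ---------------------------------------------------------------------------


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


@dataclass
class TorsionReference:
    """Native phi/psi torsion values with a circular tolerance window."""

    torsions: list[tuple[str, int, str, tuple[int, int, int, int]]]  # chain, resid, kind, atom idx quad
    native: np.ndarray  # degrees
    tolerance: float = 60.0  # degrees

    def __post_init__(self) -> None:
        if not 0 < self.tolerance < 180:
            raise ValueError("tolerance must lie in (0, 180) degrees")
        self.native = np.asarray(self.native, dtype=float)


def _backbone_quads(structure: Structure):
    """Yield (chain, resid, 'phi'|'psi', (i,j,k,l)) for consecutive residues."""
    bb: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.name in {"N", "CA", "C"}:
            bb.setdefault((a.chain, a.resid), {})[a.name] = i
    residues = [
        (c, r) for (c, r, _rn) in structure.residues() if (c, r) in bb and len(bb[(c, r)]) == 3
    ]
    for (c1, r1), (c2, r2) in zip(residues, residues[1:]):
        if c1 != c2 or r2 != r1 + 1:
            continue
        a, b = bb[(c1, r1)], bb[(c2, r2)]
        yield (c2, r2, "phi", (a["C"], b["N"], b["CA"], b["C"]))
        yield (c1, r1, "psi", (a["N"], a["CA"], a["C"], b["N"]))


def build_torsion_reference(structure: Structure, tolerance: float = 60.0) -> TorsionReference:
    """Native phi/psi angles of every consecutive backbone pair."""
    quads = list(_backbone_quads(structure))
    native = np.array(
        [dihedral_angle(*(structure.coords[i] for i in q[3])) for q in quads]
    )
    if not quads:
        warnings.warn("structure has no resolvable phi/psi torsions")
    return TorsionReference(quads, native, tolerance)


def circular_deviation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shorter-arc angular deviation |a - b| in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)


def fraction_native_torsions(frame: np.ndarray, reference: TorsionReference) -> float:
    """A(t): fraction of phi/psi angles within the native tolerance window."""
    if not reference.torsions:
        raise ValueError("torsion reference is empty")
    frame = np.asarray(frame, dtype=float)
    current = np.array(
        [dihedral_angle(*(frame[i] for i in q[3])) for q in reference.torsions]
    )
    dev = circular_deviation(current, reference.native)
    return float(np.mean(dev <= reference.tolerance))


def native_torsions_series(traj: Trajectory, reference: TorsionReference) -> CVSeries:
    vals = [fraction_native_torsions(f, reference) for f in traj.frames]
    return CVSeries("A", np.array(vals), traj.times, "")


# ---------------------------------------------------------------------------
# Catalytic-pocket RMSD against apo/holo references
# ---------------------------------------------------------------------------


def _map_selection(struct: Structure, labels: list[tuple[str, int, str]]) -> np.ndarray:
    table = {
        (a.chain, a.resid, a.name): i for i, a in enumerate(struct.atoms)
    }
    missing = [lab for lab in labels if lab not in table]
    if missing:
        raise ValueError(f"residue/atom labels not mappable onto reference: {missing[:10]}")
    return np.array([table[lab] for lab in labels], dtype=int)


def pocket_rmsd_to_references(
    traj: Trajectory,
    apo_ref: Structure,
    holo_ref: Structure,
    pocket_selection: str = "backbone",
) -> tuple[CVSeries, CVSeries]:
    """Per-frame pocket-backbone RMSD to apo and holo reference conformers.

    The pocket selection is resolved on the trajectory topology and
    mapped onto each reference by (chain, resid, atom name); residues
    that do not map raise an error listing them.
    """
    idx = _as_indices(traj.topology, pocket_selection)
    if idx.size < 3:
        raise ValueError("pocket selection must contain at least 3 atoms")
    labels = [
        (traj.topology.atoms[i].chain, traj.topology.atoms[i].resid, traj.topology.atoms[i].name)
        for i in idx
    ]
    apo_idx = _map_selection(apo_ref, labels)
    holo_idx = _map_selection(holo_ref, labels)
    out = []
    for ref, ref_idx, name in ((apo_ref, apo_idx, "RMSD_apo"), (holo_ref, holo_idx, "RMSD_holo")):
        ref_xyz = ref.coords[ref_idx]
        vals = np.array([superpose(f[idx], ref_xyz).rmsd for f in traj.frames])
        out.append(CVSeries(name, vals, traj.times, "Å"))
    return out[0], out[1]
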