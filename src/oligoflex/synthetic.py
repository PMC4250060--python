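"""Synthetic structures and trajectories with known ground truth.

Real multi-hundred-nanosecond trajectories of solvated tetramers are
far beyond desk scale, so every analysis stage in this package is
validated against generators whose statistical properties are known in
closed form:

* toy protein chains (helical backbone, minimal side chains) whose
  atom naming resolves under the selection grammar, contributes
  phi/psi torsions, and carries charged / hydrophobic / polar residues;
* stationary Ornstein-Uhlenbeck (OU) per-atom dynamics with exact
  discretization — ground truth for windowed RMSF and for the
  fluctuation/decorrelation/diffusion chain;
* discrete Markov hopping among K well-separated conformers — ground
  truth for leader clustering and state occupancies;
* telegraph (two-state Markov) interfacial contacts — ground truth for
  ion-pair / hydrogen-bond occupancy timelines.

All randomness flows from a single seeded generator per trajectory, so
a fixed seed reproduces outputs bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, Structure, Trajectory

__all__ = [
    "GeneratorSpec",
    "make_chain",
    "make_toy_structure",
    "make_tetramer",
    "make_interface_dimer",
    "make_ou_trajectory",
    "make_hopping_trajectory",
    "make_contact_telegraph",
]

# Minimal side-chain templates: local offsets (Å) from CA, chosen so that
# each residue class carries the atoms its detector needs (charged-group
# nitrogens/oxygens, hydrophobic carbons, one polar hydroxyl).
_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", (0.6, 1.2, 0.6))],
    "LEU": [
        ("CB", "C", (0.6, 1.2, 0.6)),
        ("CG", "C", (1.0, 2.4, 0.8)),
        ("CD1", "C", (0.4, 3.5, 1.2)),
        ("CD2", "C", (1.9, 3.2, 0.2)),
    ],
    "SER": [("CB", "C", (0.6, 1.2, 0.6)), ("OG", "O", (1.0, 2.4, 0.8))],
    "ARG": [
        ("CB", "C", (0.6, 1.2, 0.6)),
        ("CZ", "C", (1.2, 3.2, 1.0)),
        ("NH1", "N", (0.8, 4.4, 1.4)),
        ("NH2", "N", (2.4, 3.6, 0.8)),
    ],
    "LYS": [
        ("CB", "C", (0.6, 1.2, 0.6)),
        ("CE", "C", (1.2, 3.2, 1.0)),
        ("NZ", "N", (1.6, 4.4, 1.4)),
    ],
    "ASP": [
        ("CB", "C", (0.6, 1.2, 0.6)),
        ("CG", "C", (1.0, 2.4, 0.8)),
        ("OD1", "O", (0.6, 3.5, 1.2)),
        ("OD2", "O", (2.1, 2.8, 0.4)),
    ],
    "GLU": [
        ("CB", "C", (0.6, 1.2, 0.6)),
        ("CD", "C", (1.2, 3.2, 1.0)),
        ("OE1", "O", (0.8, 4.3, 1.4)),
        ("OE2", "O", (2.3, 3.6, 0.6)),
    ],
}

CHARGED_BASIC = ("ARG", "LYS")
CHARGED_ACIDIC = ("ASP", "GLU")
HYDROPHOBIC = ("LEU", "ALA")
POLAR = ("SER", "GLY")


@dataclass
class GeneratorSpec:
    """Declarative recipe for a toy system.

    Composition fractions refer to the per-chain residue makeup; the
    remainder after charged and hydrophobic fractions is polar.
    """

    seed: int = 0
    n_chains: int = 1
    chain_length: int = 30
    charged_fraction: float = 0.25
    hydrophobic_fraction: float = 0.35
    n_frames: int = 100
    dt: float = 4.0  # ps, matching a typical trajectory dump interval
    chain_spacing: float = 16.0  # Å between chain axes in a multimer

    def __post_init__(self) -> None:
        if self.charged_fraction + self.hydrophobic_fraction > 1.0 + 1e-9:
            raise ValueError("composition fractions exceed 1")
        if self.n_chains < 1 or self.chain_length < 2:
            raise ValueError("need at least 1 chain of 2 residues")


def _helix_backbone(n_res: int, rise: float = 0.9, twist_deg: float = 100.0, radius: float = 2.3):
    """CA positions on a helix; N and C flank CA along the helix path.

    The compact helix brings residues i and i±4 within native-contact
    range of each other, so toy chains have a non-trivial contact map.
    """
    out = []
    twist = np.radians(twist_deg)
    for i in range(n_res):
        th = i * twist
        ca = np.array([radius * np.cos(th), radius * np.sin(th), i * rise])
        thn = th - 0.4 * twist
        thc = th + 0.4 * twist
        n = np.array([radius * np.cos(thn) * 0.8, radius * np.sin(thn) * 0.8, i * rise - 0.45])
        c = np.array([radius * np.cos(thc) * 0.8, radius * np.sin(thc) * 0.8, i * rise + 0.45])
        o = c + np.array([0.0, 0.0, 1.23]) * (1 if i % 2 else -1) + np.array([0.4, -0.3, 0.0])
        out.append((n, ca, c, o))
    return out


def _sequence(spec: GeneratorSpec, rng: np.random.Generator) -> list[str]:
    n = spec.chain_length
    n_charged = int(round(spec.charged_fraction * n))
    n_phobic = int(round(spec.hydrophobic_fraction * n))
    n_polar = n - n_charged - n_phobic
    seq = []
    for k in range(n_charged):
        # alternate basic/acidic so ion-pair partners exist in-chain
        pool = CHARGED_BASIC if k % 2 == 0 else CHARGED_ACIDIC
        seq.append(pool[k // 2 % len(pool)])
    seq += [HYDROPHOBIC[k % len(HYDROPHOBIC)] for k in range(n_phobic)]
    seq += [POLAR[k % len(POLAR)] for k in range(max(n_polar, 0))]
    perm = rng.permutation(len(seq))
    return [seq[i] for i in perm]


def make_chain(
    sequence: list[str],
    chain_id: str = "A",
    origin: np.ndarray | None = None,
    first_resid: int = 1,
) -> tuple[list[Atom], np.ndarray]:
    """Build one helical chain; returns (atoms, coords)."""
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    backbone = _helix_backbone(len(sequence))
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for i, resname in enumerate(sequence):
        if resname not in _SIDE_CHAINS:
            raise ValueError(f"unsupported toy residue {resname!r}")
        n, ca, c, o = backbone[i]
        resid = first_resid + i
        for name, el, xyz in (("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)):
            atoms.append(Atom(name, el, resname, resid, chain_id))
            coords.append(xyz + origin)
        th = np.arctan2(ca[1], ca[0])
        outward = np.array([np.cos(th), np.sin(th), 0.0])
        up = np.array([0.0, 0.0, 1.0])
        side = np.cross(up, outward)
        for name, el, (dx, dy, dz) in _SIDE_CHAINS[resname]:
            pos = ca + dy * outward + dx * side + dz * up
            atoms.append(Atom(name, el, resname, resid, chain_id))
            coords.append(pos + origin)
    return atoms, np.array(coords)


_GRID = {  # chain axis positions in the xy plane (units of chain_spacing)
    "A": (0.0, 0.0),
    "B": (1.0, 0.0),
    "D": (0.0, 1.0),
    "C": (1.0, 1.0),
}


def make_toy_structure(spec: GeneratorSpec) -> Structure:
    """Toy protein per the spec: chains A.. on a square grid.

    With four chains the layout places A|B and D|C side by side and
    A|D, B|C across, mimicking a dimer-of-dimers tetramer.
    """
    rng = np.random.default_rng(spec.seed)
    chain_ids = ["A", "B", "C", "D"][: spec.n_chains]
    atoms: list[Atom] = []
    coords_parts = []
    for cid in chain_ids:
        gx, gy = _GRID.get(cid, (ord(cid) - 65, 0))
        origin = np.array([gx * spec.chain_spacing, gy * spec.chain_spacing, 0.0])
        seq = _sequence(spec, rng)
        a, c = make_chain(seq, cid, origin)
        atoms += a
        coords_parts.append(c)
    return Structure(atoms, np.vstack(coords_parts), {"source": "synthetic", "seed": spec.seed})


def make_tetramer(
    seed: int = 0,
    chain_length: int = 30,
    charged_fraction: float = 0.25,
    hydrophobic_fraction: float = 0.35,
    chain_spacing: float = 16.0,
) -> Structure:
    return make_toy_structure(
        GeneratorSpec(
            seed=seed,
            n_chains=4,
            chain_length=chain_length,
            charged_fraction=charged_fraction,
            hydrophobic_fraction=hydrophobic_fraction,
            chain_spacing=chain_spacing,
        )
    )


# ---------------------------------------------------------------------------
# Designed interfaces
# ---------------------------------------------------------------------------


def _place_contact(
    structure: Structure,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    atom_a: str,
    atom_b: str,
    distance: float,
) -> tuple[int, int]:
    """Move two designated side-chain atoms to exactly ``distance`` apart.

    The two atoms are pulled onto the line joining the two residues'
    CA atoms, symmetric about its midpoint.  Returns their indices.
    """
    loc = {(a.chain, a.resid, a.name): i for i, a in enumerate(structure.atoms)}
    try:
        ia = loc[(res_a[0], res_a[1], atom_a)]
        ib = loc[(res_b[0], res_b[1], atom_b)]
        ca_a = loc[(res_a[0], res_a[1], "CA")]
        ca_b = loc[(res_b[0], res_b[1], "CA")]
    except KeyError as exc:
        raise ValueError(f"contact references a missing atom: {exc}") from exc
    mid = 0.5 * (structure.coords[ca_a] + structure.coords[ca_b])
    direction = structure.coords[ca_b] - structure.coords[ca_a]
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        raise ValueError("contact residues coincide; geometric conflict")
    u = direction / nrm
    structure.coords[ia] = mid - 0.5 * distance * u
    structure.coords[ib] = mid + 0.5 * distance * u
    return ia, ib


@dataclass
class DesignedContact:
    """One designed cross-chain contact with its moved atom indices."""

    kind: str  # "IP" | "HB" | "phobic"
    res_a: tuple[str, int, str]  # chain, resid, resname
    res_b: tuple[str, int, str]
    atom_a: int
    atom_b: int
    distance: float


def make_interface_dimer(
    n_ip: int = 3,
    n_hb: int = 2,
    n_phobic: int = 0,
    chain_ids: tuple[str, str] = ("A", "B"),
    chain_length: int | None = None,
    spacing: float = 14.0,
    ip_distance: float = 3.0,
    hb_distance: float = 2.9,
    phobic_distance: float = 4.0,
    seed: int = 0,
) -> tuple[Structure, list[DesignedContact]]:
    """Two facing chains with designed interfacial IPs, HBs and hydrophobic pairs.

    Ion pairs place an ARG guanidinium nitrogen (NH1) against a GLU
    carboxylate oxygen (OE1); hydrogen bonds place a SER hydroxyl (OG,
    donor) against a backbone carbonyl oxygen; hydrophobic pairs place
    LEU CD1 atoms at van-der-Waals range.
    """
    n_design = n_ip + n_hb + n_phobic
    length = chain_length or max(5 * n_design + 4, 10)
    if 5 * n_design > length:
        raise ValueError("chain too short for the requested number of contacts")
    # designed residues every 5th position: far enough apart on the helix
    # that neighbouring designed contacts cannot cross-react
    seq_a = ["GLY"] * length
    seq_b = ["GLY"] * length
    slots = [1 + 5 * k for k in range(n_design)]
    kinds: list[str] = ["IP"] * n_ip + ["HB"] * n_hb + ["phobic"] * n_phobic
    for slot, kind in zip(slots, kinds):
        if kind == "IP":
            seq_a[slot], seq_b[slot] = "ARG", "GLU"
        elif kind == "HB":
            seq_a[slot], seq_b[slot] = "SER", "SER"
        else:
            seq_a[slot], seq_b[slot] = "LEU", "LEU"
    ca_id, cb_id = chain_ids
    atoms_a, xa = make_chain(seq_a, ca_id)
    atoms_b, xb = make_chain(seq_b, cb_id, origin=np.array([spacing, 0.0, 0.0]))
    structure = Structure(atoms_a + atoms_b, np.vstack([xa, xb]), {"source": "synthetic"})
    contacts: list[DesignedContact] = []
    for slot, kind in zip(slots, kinds):
        resid = slot + 1
        if kind == "IP":
            pair_atoms, dist = ("NH1", "OE1"), ip_distance
        elif kind == "HB":
            pair_atoms, dist = ("OG", "O"), hb_distance
        else:
            pair_atoms, dist = ("CD1", "CD1"), phobic_distance
        ia, ib = _place_contact(
            structure, (ca_id, resid), (cb_id, resid), pair_atoms[0], pair_atoms[1], dist
        )
        contacts.append(
            DesignedContact(
                kind,
                (ca_id, resid, seq_a[slot]),
                (cb_id, resid, seq_b[slot]),
                ia,
                ib,
                dist,
            )
        )
    return structure, contacts


# ---------------------------------------------------------------------------
# Dynamics generators
# ---------------------------------------------------------------------------


def make_ou_trajectory(
    structure: Structure,
    sigma: float | np.ndarray = 0.5,
    tau_c: float = 20.0,
    n_frames: int = 1000,
    dt: float = 1.0,
    seed: int = 0,
    temperature: float | None = None,
) -> Trajectory:
    """Stationary OU fluctuations about the reference coordinates.

    Each coordinate follows the exact discretization
    ``x(t+dt) = x(t) e^(-dt/tau_c) + eta`` with
    ``eta ~ N(0, s^2 (1 - e^(-2 dt/tau_c)))``, initialized from the
    stationary law.  ``sigma`` is the stationary per-atom 3D RMSF
    sqrt(<|dr|^2>) in Å, so the per-coordinate standard deviation is
    ``s = sigma / sqrt(3)`` and a long-window RMSF analysis recovers
    ``sigma`` directly.  ``sigma`` may be a scalar or per-atom array;
    ``tau_c`` and ``dt`` share one time unit (ps).
    """
    if tau_c <= 0 or dt <= 0:
        raise ValueError("tau_c and dt must be positive")
    rng = np.random.default_rng(seed)
    n_atoms = structure.n_atoms
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (n_atoms,)).reshape(n_atoms, 1) / np.sqrt(3.0)
    if np.any(sig < 0):
        raise ValueError("sigma must be nonnegative")
    rho = np.exp(-dt / tau_c)
    innov_sd = sig * np.sqrt(1.0 - rho**2)
    x = rng.standard_normal((n_atoms, 3)) * sig
    frames = np.empty((n_frames, n_atoms, 3))
    frames[0] = structure.coords + x
    for t in range(1, n_frames):
        x = x * rho + rng.standard_normal((n_atoms, 3)) * innov_sd
        frames[t] = structure.coords + x
    return Trajectory(structure, frames, dt, temperature)


def _markov_path(P: np.ndarray, n_steps: int, rng: np.random.Generator, start: int = 0) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_steps, dtype=int)
    s = start
    for t in range(n_steps):
        states[t] = s
        s = int(np.searchsorted(cum[s], rng.random()))
    return states


def make_hopping_trajectory(
    conformers: list[Structure],
    transition_matrix: np.ndarray,
    jitter_sigma: float = 0.1,
    n_frames: int = 500,
    dt: float = 4.0,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Discrete Markov hopping among K conformers plus Gaussian jitter.

    Conformers must be well separated (pairwise heavy-atom RMSD more
    than 3x the jitter), otherwise the generated states are not
    recoverable and an error is raised.  Returns the trajectory and the
    hidden state path.
    """
    from .collective_variables import superpose

    K = len(conformers)
    if K < 2:
        raise ValueError("need at least 2 conformers")
    n_atoms = conformers[0].n_atoms
    for c in conformers[1:]:
        if c.n_atoms != n_atoms:
            raise ValueError("conformers differ in atom count")
    for i in range(K):
        for j in range(i + 1, K):
            sep = superpose(conformers[j].coords, conformers[i].coords).rmsd
            if sep <= 3.0 * jitter_sigma:
                raise ValueError(
                    f"conformers {i} and {j} are degenerate: RMSD {sep:.3f} Å "
                    f"<= 3 x jitter {jitter_sigma:.3f} Å"
                )
    rng = np.random.default_rng(seed)
    states = _markov_path(transition_matrix, n_frames, rng)
    frames = np.empty((n_frames, n_atoms, 3))
    for t, s in enumerate(states):
        frames[t] = conformers[s].coords + rng.standard_normal((n_atoms, 3)) * jitter_sigma
    return Trajectory(conformers[0], frames, dt), states


def displaced_conformers(
    base: Structure, K: int, separation: float = 5.0, seed: int = 0
) -> list[Structure]:
    """K conformers: the base plus internal random distortions of set size.

    Each non-base conformer displaces every atom by an independent
    random direction scaled so the all-atom RMSD to the base is
    ``separation`` (superposition changes this only marginally for
    incoherent displacements).
    """
    rng = np.random.default_rng(seed)
    out = [base]
    for _ in range(K - 1):
        d = rng.standard_normal((base.n_atoms, 3))
        d *= separation / np.sqrt(np.mean(np.sum(d**2, axis=1)))
        out.append(base.with_coords(base.coords + d))
    return out


def make_contact_telegraph(
    structure: Structure,
    contacts: list[DesignedContact],
    rates: list[tuple[float, float]] | tuple[float, float],
    n_frames: int = 2000,
    dt: float = 4.0,
    seed: int = 0,
    unbound_distance: float = 9.0,
) -> tuple[Trajectory, np.ndarray]:
    """Toggle designed contacts on/off as independent two-state chains.

    ``rates`` gives per-frame switching probabilities (p_on, p_off) for
    each contact (or one pair for all); the stationary bound
    probability is p_on / (p_on + p_off).  In the unbound state the
    second atom of the pair is pushed out to ``unbound_distance`` along
    the contact axis.  Returns the trajectory and the (n_frames,
    n_contacts) boolean bound-state matrix.
    """
    if isinstance(rates, tuple):
        rates = [rates] * len(contacts)
    if len(rates) != len(contacts):
        raise ValueError("one (p_on, p_off) pair per contact required")
    rng = np.random.default_rng(seed)
    n_c = len(contacts)
    bound = np.empty((n_frames, n_c), dtype=bool)
    for j, (p_on, p_off) in enumerate(rates):
        if not (0 <= p_on <= 1 and 0 <= p_off <= 1):
            raise ValueError("rates are per-frame probabilities in [0, 1]")
        # start from the stationary law so occupancy estimates are unbiased
        p_stat = p_on / (p_on + p_off) if (p_on + p_off) > 0 else 1.0
        state = rng.random() < p_stat
        for t in range(n_frames):
            bound[t, j] = state
            state = (rng.random() < p_on) if not state else (rng.random() >= p_off)
    base = structure.coords
    frames = np.tile(base, (n_frames, 1, 1))
    for j, c in enumerate(contacts):
        a, b = base[c.atom_a], base[c.atom_b]
        axis = b - a
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            raise ValueError("degenerate contact geometry")
        u = axis / nrm
        far = a + unbound_distance * u
        off_frames = ~bound[:, j]
        frames[off_frames, c.atom_b] = far
    return Trajectory(structure, frames, dt), bound
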