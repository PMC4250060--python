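"""Multi-timescale RMSF and rigidity-pattern extraction.

The windowed RMSF uses a double time average: within each
non-overlapping block of length ``tau_w`` the trajectory is superposed
onto the block's own mean structure and the per-atom mean squared
deviation is taken; the outer average runs over blocks.  Sweeping
``tau_w`` (0.1–5 ns by default) probes fluctuations at different
timescales, and the block-to-block spread measures the slow
variability of the profile.

Rigidity patterns compare the RMSF of a chain simulated in isolation
with the same chain inside an oligomer: residues whose fluctuations
drop by more than a threshold fraction upon assembly are the ones
stiffened by oligomerization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .collective_variables import superpose_batch
from .structure_io import SelectionSpec, Trajectory, resolve_selection

__all__ = [
    "RMSFProfile",
    "RigidityPattern",
    "rmsf_windowed",
    "rmsf_average",
    "rmsf_temperature_derivative",
    "rigidity_pattern",
    "DEFAULT_WINDOWS_PS",
]

# Window sweep covering 0.1 to 5 ns.
DEFAULT_WINDOWS_PS = (100.0, 200.0, 500.0, 1000.0, 2000.0, 5000.0)


@dataclass
class RMSFProfile:
    """Per-atom windowed RMSF with block-to-block variability."""

    window_ps: float
    rmsf: np.ndarray  # Å, per selected atom
    variability: np.ndarray  # Å, std of per-block RMSF over blocks
    atom_indices: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    selection: str = ""
    temperature: float | None = None
    n_blocks: int = 0

    def __post_init__(self) -> None:
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF must be nonnegative")

    def residue_profile(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chains, resids, mean RMSF per residue) in order of appearance."""
        keys: list[tuple[str, int]] = []
        sums: dict[tuple[str, int], list[float]] = {}
        for c, r, v in zip(self.chains, self.resids, self.rmsf):
            k = (str(c), int(r))
            if k not in sums:
                sums[k] = []
                keys.append(k)
            sums[k].append(float(v))
        ch = np.array([k[0] for k in keys])
        rs = np.array([k[1] for k in keys])
        vals = np.array([np.mean(sums[k]) for k in keys])
        return ch, rs, vals


def _resolve(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return np.arange(traj.topology.n_atoms)
    if isinstance(selection, (str, SelectionSpec)):
        return resolve_selection(traj.topology, selection)
    return np.asarray(selection, dtype=int)


def rmsf_windowed(
    traj: Trajectory,
    selection="ca",
    window_ps: float = 1000.0,
    superpose_blocks: bool = True,
) -> RMSFProfile:
    """Windowed per-atom RMSF (double time average).

    Blocks are non-overlapping stretches of ``window_ps``; each block
    is rigid-body superposed onto its own mean structure (using the
    analysis selection) before deviations are measured, so uniform
    rigid motion contributes nothing.  Requires the trajectory to span
    at least two full windows.
    """
    idx = _resolve(traj, selection)
    if idx.size == 0:
        raise ValueError("empty selection for RMSF")
    block_len = int(round(window_ps / traj.dt))
    if block_len < 2:
        raise ValueError(f"window {window_ps} ps is shorter than 2 frames (dt={traj.dt} ps)")
    n_blocks = traj.n_frames // block_len
    if n_blocks < 2:
        raise ValueError(
            f"trajectory ({traj.n_frames * traj.dt:g} ps) must span >= 2 windows "
            f"of {window_ps:g} ps"
        )
    sub = traj.frames[:, idx]
    msf_blocks = np.empty((n_blocks, idx.size))
    for b in range(n_blocks):
        block = sub[b * block_len : (b + 1) * block_len]
        if superpose_blocks:
            # one alignment pass to the running mean: align to first frame,
            # take the mean, then re-align every frame onto that mean
            aligned, _ = superpose_batch(block, block[0])
            aligned, _ = superpose_batch(aligned, aligned.mean(axis=0))
        else:
            aligned = block
        mean = aligned.mean(axis=0)
        msf_blocks[b] = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)
    rmsf_blocks = np.sqrt(msf_blocks)
    atoms = traj.topology.atoms
    return RMSFProfile(
        window_ps=float(window_ps),
        rmsf=np.sqrt(msf_blocks.mean(axis=0)),
        variability=rmsf_blocks.std(axis=0),
        atom_indices=idx,
        resids=np.array([atoms[i].resid for i in idx]),
        chains=np.array([atoms[i].chain for i in idx]),
        selection=str(selection),
        temperature=traj.temperature,
        n_blocks=n_blocks,
    )


def rmsf_average(profile: RMSFProfile | list[RMSFProfile]) -> float:
    """Mean RMSF over all selected atoms (all chains pooled)."""
    profiles = profile if isinstance(profile, list) else [profile]
    if not profiles or any(p.rmsf.size == 0 for p in profiles):
        raise ValueError("empty RMSF profile")
    return float(np.concatenate([p.rmsf for p in profiles]).mean())


def rmsf_temperature_derivative(
    profile_t1: RMSFProfile,
    profile_t2: RMSFProfile,
    t1: float | None = None,
    t2: float | None = None,
) -> np.ndarray:
    """Finite-difference d(RMSF)/dT per atom, Å/K."""
    t1 = profile_t1.temperature if t1 is None else t1
    t2 = profile_t2.temperature if t2 is None else t2
    if t1 is None or t2 is None:
        raise ValueError("temperatures not set on profiles nor given")
    if not t2 > t1:
        raise ValueError("requires T2 > T1")
    if profile_t1.rmsf.shape != profile_t2.rmsf.shape or not np.array_equal(
        profile_t1.atom_indices, profile_t2.atom_indices
    ):
        raise ValueError("profiles cover different atoms")
    return (profile_t2.rmsf - profile_t1.rmsf) / (t2 - t1)


@dataclass
class RigidityPattern:
    """Residues stiffened upon oligomerization beyond a threshold."""

    chains: np.ndarray
    resids: np.ndarray
    relative_change: np.ndarray  # (mono - tetra) / mono, only listed residues
    threshold: float
    all_resids: np.ndarray | None = None
    all_changes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.relative_change <= self.threshold):
            raise ValueError("pattern lists residues at or below threshold")


def rigidity_pattern(
    rmsf_monomer: RMSFProfile,
    rmsf_oligomer: RMSFProfile,
    threshold: float = 0.30,
) -> RigidityPattern:
    """Residues whose RMSF drops by more than ``threshold`` upon assembly.

    Relative change is (RMSF_mono - RMSF_oligo) / RMSF_mono per
    residue, positive = stiffening.  Residues are matched by residue
    number (the chain id may differ between the two simulations);
    residues with zero monomer RMSF are skipped with a warning.
    """
    _, rm, vm = rmsf_monomer.residue_profile()
    _, ro, vo = rmsf_oligomer.residue_profile()
    mono = dict(zip(rm.tolist(), vm.tolist()))
    olig = dict(zip(ro.tolist(), vo.tolist()))
    common = [r for r in rm.tolist() if r in olig]
    if not common:
        raise ValueError("no common residues between monomer and oligomer profiles")
    chains_kept, res_kept, chg_kept = [], [], []
    all_res, all_chg = [], []
    oc, orr, _ = rmsf_oligomer.residue_profile()
    chain_of = dict(zip(orr.tolist(), oc.tolist()))
    for r in common:
        if mono[r] <= 0:
            warnings.warn(f"residue {r}: zero monomer RMSF, skipped")
            continue
        change = (mono[r] - olig[r]) / mono[r]
        all_res.append(r)
        all_chg.append(change)
        if change > threshold:
            chains_kept.append(chain_of.get(r, ""))
            res_kept.append(r)
            chg_kept.append(change)
    return RigidityPattern(
        np.array(chains_kept),
        np.array(res_kept, dtype=int),
        np.array(chg_kept),
        threshold,
        np.array(all_res, dtype=int),
        np.array(all_chg),
    )
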