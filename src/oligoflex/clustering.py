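"""Leader-algorithm conformational clustering and saturation fitting.

Frames are scanned in time order; each frame joins the first existing
cluster whose leader lies within an RMSD cutoff (after rigid-body
superposition), otherwise it founds a new cluster.  The cumulative
number of distinct clusters n(t) grows toward saturation as the
trajectory exhausts the accessible conformational substates; fitting
n(t) = N_inf (1 - exp(-t/tau)) yields the estimated maximum number of
substates and the characteristic time to visit them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .collective_variables import superpose
from .structure_io import SelectionSpec, Trajectory, resolve_selection

__all__ = [
    "ClusterGrowth",
    "SaturationFit",
    "leader_cluster",
    "fit_saturation",
    "cutoff_sweep",
    "cluster_leaders_export",
]


@dataclass
class ClusterGrowth:
    """Result of a leader clustering pass."""

    assignments: np.ndarray  # per-frame cluster id (creation order)
    leader_frames: np.ndarray  # frame index that founded each cluster
    n_t: np.ndarray  # cumulative distinct clusters after each frame
    times: np.ndarray  # ps
    cutoff: float  # Å
    selection: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n_t) < 0):
            raise ValueError("n(t) must be nondecreasing")
        if self.n_t[0] != 1:
            raise ValueError("first frame must found the first cluster")

    @property
    def n_clusters(self) -> int:
        return int(self.n_t[-1])


def leader_cluster(
    traj: Trajectory,
    selection="heavy",
    cutoff: float = 1.3,
) -> ClusterGrowth:
    """Single-pass leader clustering on superposed-RMSD distance.

    Ties break toward the earliest-created leader (classic leader
    algorithm), making the assignment deterministic.  The default
    metric uses all heavy atoms; pass ``"ca"`` or any selection for
    reduced metrics, or cluster a single chain by selecting it.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(selection, (str, SelectionSpec)):
        idx = resolve_selection(traj.topology, selection)
    elif selection is None:
        idx = np.arange(traj.topology.n_atoms)
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection for clustering")
    coords = traj.frames[:, idx]
    leaders: list[np.ndarray] = []
    leader_frames: list[int] = []
    assignments = np.empty(traj.n_frames, dtype=int)
    n_t = np.empty(traj.n_frames, dtype=int)
    for t in range(traj.n_frames):
        frame = coords[t]
        hit = -1
        for c, lead in enumerate(leaders):
            if superpose(frame, lead).rmsd <= cutoff:
                hit = c
                break
        if hit < 0:
            hit = len(leaders)
            leaders.append(frame)
            leader_frames.append(t)
        assignments[t] = hit
        n_t[t] = len(leaders)
    return ClusterGrowth(
        assignments,
        np.array(leader_frames, dtype=int),
        n_t,
        traj.times,
        float(cutoff),
        str(selection),
    )


@dataclass
class SaturationFit:
    """Exponential-saturation fit n(t) = N_inf (1 - exp(-t/tau))."""

    n_inf: float
    tau: float  # same unit as the input times
    residual_norm: float
    ok: bool = True
    message: str = ""


def fit_saturation(times: np.ndarray, n_t: np.ndarray) -> SaturationFit:
    """Nonlinear least squares of the cluster-growth curve.

    Initialization: N_inf0 = max n(t), tau0 = time at which n(t) first
    reaches half of N_inf0.  A constant n(t) has no defined timescale
    and is returned flagged (``ok=False``) with N_inf = n.  Noisy
    growth samples need not be strictly nondecreasing; monotonicity is
    an invariant of :class:`ClusterGrowth`, not of the fit.
    """
    times = np.asarray(times, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    if times.size != n_t.size or times.size < 5:
        raise ValueError("need >= 5 (t, n) points")
    if n_t[-1] == n_t[0]:
        return SaturationFit(float(n_t[-1]), float("nan"), 0.0, False, "constant n(t): tau undefined")

    def model(t, n_inf, tau):
        return n_inf * (1.0 - np.exp(-t / tau))

    n0 = float(n_t.max())
    half_idx = int(np.searchsorted(n_t, n0 / 2.0))
    tau0 = float(times[min(half_idx, times.size - 1)]) or float(times[-1]) / 10.0
    try:
        popt, _ = curve_fit(
            model,
            times,
            n_t,
            p0=(n0, tau0),
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"saturation fit did not converge (p0=({n0:g}, {tau0:g})): {exc}"
        ) from exc
    resid = float(np.linalg.norm(model(times, *popt) - n_t))
    return SaturationFit(float(popt[0]), float(popt[1]), resid)


def cutoff_sweep(
    traj: Trajectory, selection="heavy", cutoffs=(1.0, 1.3, 1.6, 2.0)
) -> dict[float, int]:
    """Final cluster counts across a cutoff sweep (robustness check)."""
    return {
        float(c): leader_cluster(traj, selection, c).n_clusters for c in cutoffs
    }


def cluster_leaders_export(growth: ClusterGrowth, traj: Trajectory, path) -> int:
    """Write each cluster-leader frame as a model of a multi-model PDB."""
    from .structure_io import Trajectory as _T
    from .structure_io import write_trajectory

    frames = traj.frames[growth.leader_frames]
    write_trajectory(_T(traj.topology, frames, traj.dt, traj.temperature), path)
    return len(growth.leader_frames)
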