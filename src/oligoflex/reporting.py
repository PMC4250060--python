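"""Pipeline orchestration and comparative reporting.

``run_pipeline`` drives the full analysis battery over one system
(topology + trajectory + temperature) from a declarative
:class:`RunConfig`, writing per-stage CSV/JSON artifacts and a summary
dictionary.  ``compare_systems`` aligns two or more summaries into a
side-by-side comparison table with differences and ratios — the
layout used when contrasting a mesophilic and a thermophilic system,
or a monomer against its tetramer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, collective_variables as cv, diffusion, fluctuations, interfaces, volumetrics
from .structure_io import Structure, Trajectory, read_structure, read_trajectory

__all__ = ["SystemEntry", "RunConfig", "run_pipeline", "compare_systems", "load_config"]

log = logging.getLogger("oligoflex")

SCHEMA_VERSION = 1


@dataclass
class SystemEntry:
    """One system to analyse."""

    label: str
    topology: str
    trajectory: str
    temperature: float = 300.0
    form: str = "tetramer"  # or "monomer"
    dt: float | None = None  # ps override for timeless formats


@dataclass
class RunConfig:
    """Declarative pipeline configuration (round-trips through YAML)."""

    systems: list[SystemEntry] = field(default_factory=list)
    output_dir: str = "oligoflex_out"
    seed: int = 0
    selection_rmsf: str = "ca"
    rmsf_windows_ps: list[float] = field(default_factory=lambda: [100.0, 1000.0])
    cluster_cutoff: float = 1.3
    cluster_selection: str = "heavy"
    diffusion_skip_ns: float = 0.0
    contact_cutoff_ip: float = 4.0
    native_contact_cutoff: float = 5.0
    torsion_tolerance_deg: float = 60.0
    enable: dict = field(
        default_factory=lambda: {
            "cv": True,
            "rmsf": True,
            "cluster": True,
            "diffusion": True,
            "interfaces": True,
            "volumetrics": True,
        }
    )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        required = {"systems"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"config missing required keys: {sorted(missing)}")
        systems = [SystemEntry(**s) for s in d.pop("systems")]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(systems=systems, **d)
        labels = [s.label for s in cfg.systems]
        if len(set(labels)) != len(labels):
            raise ValueError("system labels must be unique")
        return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError("config file must hold a mapping")
    return RunConfig.from_dict(d)


def _analyse_system(
    entry: SystemEntry, cfg: RunConfig, outdir: Path
) -> dict:
    structure = read_structure(entry.topology)
    traj = read_trajectory(
        entry.trajectory, structure, dt=entry.dt, temperature=entry.temperature
    )
    return analyse(traj, structure, entry.label, cfg, outdir, form=entry.form)


def analyse(
    traj: Trajectory,
    reference: Structure,
    label: str,
    cfg: RunConfig,
    outdir: Path,
    form: str = "tetramer",
) -> dict:
    """Run every enabled stage on one in-memory system; write artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "label": label,
        "form": form,
        "temperature_K": traj.temperature,
        "n_frames": traj.n_frames,
        "dt_ps": traj.dt,
        "parameters": {
            "cluster_cutoff_A": cfg.cluster_cutoff,
            "cluster_selection": cfg.cluster_selection,
            "rmsf_windows_ps": list(cfg.rmsf_windows_ps),
            "diffusion_skip_ns": cfg.diffusion_skip_ns,
            "native_contact_cutoff_A": cfg.native_contact_cutoff,
            "torsion_tolerance_deg": cfg.torsion_tolerance_deg,
            "ion_pair_cutoff_A": cfg.contact_cutoff_ip,
        },
    }
    stage_error: list[str] = []

    def run_stage(name: str, fn):
        if not cfg.enable.get(name, True):
            log.info("[%s] stage %s disabled", label, name)
            return
        log.info("[%s] stage %s", label, name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed for system {label!r}: {exc}") from exc

    def stage_cv():
        series = {}
        series["Rg"] = cv.rg_series(traj, "ca")
        series["RMSD"] = cv.rmsd_series(traj, reference, "ca")
        contact_ref = cv.build_contact_reference(reference, cfg.native_contact_cutoff)
        if np.any(contact_ref.n_counts > 0):
            series["Q"] = cv.native_contacts_series(traj, contact_ref)
        torsion_ref = cv.build_torsion_reference(reference, cfg.torsion_tolerance_deg)
        if torsion_ref.torsions:
            series["A"] = cv.native_torsions_series(traj, torsion_ref)
        df = pd.DataFrame({"time_ps": traj.times})
        for name, s in series.items():
            unit = f" ({s.units})" if s.units else ""
            df[f"{name}{unit}"] = s.values
        df.to_csv(outdir / f"{label}_cv.csv", index=False)
        summary["cv"] = {
            name: {"mean": float(s.values.mean()), "std": float(s.values.std())}
            for name, s in series.items()
        }
        summary["_cv_series"] = series  # in-memory handoff to diffusion stage

    def stage_rmsf():
        rows = []
        out = {}
        for w in cfg.rmsf_windows_ps:
            prof = fluctuations.rmsf_windowed(traj, cfg.selection_rmsf, w)
            out[f"window_{w:g}ps"] = fluctuations.rmsf_average(prof)
            for i in range(prof.rmsf.size):
                rows.append(
                    {
                        "window_ps": w,
                        "atom_index": int(prof.atom_indices[i]),
                        "chain": str(prof.chains[i]),
                        "resid": int(prof.resids[i]),
                        "rmsf_A": float(prof.rmsf[i]),
                        "variability_A": float(prof.variability[i]),
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / f"{label}_rmsf.csv", index=False)
        summary["rmsf_mean_A"] = out

    def stage_cluster():
        growth = clustering.leader_cluster(traj, cfg.cluster_selection, cfg.cluster_cutoff)
        pd.DataFrame(
            {"time_ps": growth.times, "cluster": growth.assignments, "n_clusters": growth.n_t}
        ).to_csv(outdir / f"{label}_clusters.csv", index=False)
        res: dict = {"n_clusters": growth.n_clusters, "cutoff_A": growth.cutoff}
        if growth.times.size >= 5 and growth.n_clusters > 1:
            fit = clustering.fit_saturation(growth.times, growth.n_t)
            res["n_inf"] = fit.n_inf
            res["tau_ps"] = fit.tau
            res["fit_ok"] = fit.ok
        summary["clustering"] = res

    def stage_diffusion():
        series = summary.pop("_cv_series", None)
        if series is None:
            return
        out = {}
        for name in ("Q", "A"):
            if name not in series:
                continue
            try:
                est = diffusion.diffusion_coefficient(series[name], cfg.diffusion_skip_ns)
            except ValueError as exc:
                out[name] = {"error": str(exc)}
                continue
            out[name] = est.as_dict()
        summary["diffusion"] = out
        (outdir / f"{label}_diffusion.json").write_text(json.dumps(out, indent=2))

    def stage_interfaces():
        if form != "tetramer" or len(reference.chains) != 4:
            log.info("[%s] interface stage skipped: not a 4-chain system", label)
            return
        specs = interfaces.define_interfaces(reference)
        out = {}
        for lab, spec in specs.items():
            ip = interfaces.contact_timelines(traj, spec, "ip", cutoff=cfg.contact_cutoff_ip)
            hb = interfaces.contact_timelines(traj, spec, "hb")
            entry = {
                "ip_mean": ip.mean_count,
                "ip_std": ip.std_count,
                "ip_distinct_pairs": ip.distinct_pairs(),
                "hb_mean": hb.mean_count,
                "hb_std": hb.std_count,
            }
            try:
                surf = interfaces.classify_interface_surface(
                    traj.frames[0], reference, spec
                )
                entry["surface_fractions"] = {
                    "hydrophobic": surf.fractions[0],
                    "hydrophilic": surf.fractions[1],
                    "mixed": surf.fractions[2],
                }
            except ValueError:
                entry["surface_fractions"] = None
            out[lab] = entry
            pd.DataFrame({"time_ps": ip.times, "n_ip": ip.counts, "n_hb": hb.counts}).to_csv(
                outdir / f"{label}_interface_{lab}.csv", index=False
            )
        summary["interfaces"] = out

    def stage_volumetrics():
        stride = max(traj.n_frames // 50, 1)  # tessellation is the slow stage
        series = volumetrics.volume_series(traj, stride=stride)
        mean, sd = volumetrics.volume_per_atom(series)
        res = {"volume_per_atom_A3": mean, "volume_per_atom_sd_A3": sd}
        if traj.temperature:
            res["compressibility_1e-2_GPa"] = volumetrics.intrinsic_compressibility(series)
        summary["volumetrics"] = res

    run_stage("cv", stage_cv)
    run_stage("rmsf", stage_rmsf)
    run_stage("cluster", stage_cluster)
    run_stage("diffusion", stage_diffusion)
    run_stage("interfaces", stage_interfaces)
    run_stage("volumetrics", stage_volumetrics)
    summary.pop("_cv_series", None)
    if stage_error:
        raise RuntimeError("; ".join(stage_error))
    (outdir / f"{label}_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def run_pipeline(cfg: RunConfig) -> dict[str, dict]:
    """Analyse every configured system; returns label -> summary."""
    if not cfg.systems:
        raise ValueError("config lists no systems (required keys: systems[].label/topology/trajectory)")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("pipeline start: %d systems, seed %d", len(cfg.systems), cfg.seed)
        log.info("parameters: %s", json.dumps(asdict(cfg), default=str))
        reports = {}
        for entry in cfg.systems:
            reports[entry.label] = _analyse_system(entry, cfg, outdir)
        if len(reports) >= 2:
            table = compare_systems(reports)
            table.to_csv(outdir / "comparison.csv")
        return reports
    finally:
        log.removeHandler(handler)
        handler.close()


def _flatten(d: dict, prefix: str = "") -> dict[str, float]:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (int, float)) and not isinstance(v, bool):
            out[key] = float(v)
    return out


def compare_systems(reports: dict[str, dict]) -> pd.DataFrame:
    """Side-by-side metric table with differences and ratios.

    Rows are flattened metric names shared by all systems; for exactly
    two systems, absolute difference and ratio columns are appended.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 system reports to compare")
    flat = {label: _flatten({k: v for k, v in rep.items() if k != "parameters"}) for label, rep in reports.items()}
    labels = list(flat)
    shared = set(flat[labels[0]])
    for lab in labels[1:]:
        shared &= set(flat[lab])
    if not shared:
        raise ValueError("reports share no analysis stages/metrics")
    rows = sorted(shared)
    df = pd.DataFrame({lab: [flat[lab][r] for r in rows] for lab in labels}, index=rows)
    if len(labels) == 2:
        a, b = labels
        df["difference"] = df[a] - df[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ratio"] = np.where(df[b] != 0, df[a] / df[b], np.nan)
    return df
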