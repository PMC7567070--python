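"""Comparative analysis pipeline: several systems, one reference.

Mirrors the study design this package serves: a wild-type system compared
against point-mutant systems (e.g. WT vs G12D vs G12D/K104A vs G12D/K104Q),
each with a trajectory stage (RMSD, RMSF/B-factor, pseudo-dihedral
distribution), pairwise distribution shifts against the reference, and an
optional free-energy stage producing a ddG table.  Everything is driven by
a flat INI-style config and is deterministic given config + seeds.
"""

from __future__ import annotations

import configparser
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import free_energy as fe
from . import io as tio
from . import metrics, synthetic
from .core import Trajectory, select
from .errors import TrajmetricsError

__all__ = ["SystemConfig", "ComparativeReport", "run_pipeline", "load_config"]

logger = logging.getLogger("trajmetrics.pipeline")


@dataclass
class SystemConfig:
    """One system of the comparative run."""

    label: str
    trajectory: str | None = None  # PDB or XYZ-table path
    selection: str = "backbone"
    rmsf_selection: str = "calpha"
    quadruple: metrics.QuadrupleSpec = field(default_factory=metrics.QuadrupleSpec)
    rmsd_mean_window: tuple[float, float] | None = None
    rmsf_window: tuple[float, float] | None = None
    angle_window: tuple[float, float] | None = None
    bin_width: float = 1.0
    # synthetic angle ensemble (used when no trajectory is given)
    angle_mu: float | None = None
    angle_kappa: float = 50.0
    angle_n_frames: int = 3000
    angle_dt: float = 10.0
    # free-energy stage (optional)
    work_file: str | None = None
    work_dialect: str = "two_column"
    work_dg_true: float | None = None
    work_dissipation: float = 3.0
    n_boot: int = 200
    temperature: float = fe.DEFAULT_TEMPERATURE_K
    seed: int = 0


@dataclass
class ComparativeReport:
    """Aggregated machine-readable result of a pipeline run."""

    reference_label: str
    systems: dict
    shifts: dict
    ddg_table: list
    failures: dict
    artifacts: dict

    def to_json(self) -> str:
        payload = {
            "reference": self.reference_label,
            "systems": self.systems,
            "shifts": self.shifts,
            "ddg_table": self.ddg_table,
            "failures": self.failures,
            "artifacts": self.artifacts,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_trajectory(path: str) -> Trajectory:
    p = Path(path)
    if p.suffix.lower() in (".pdb", ".ent"):
        obj = tio.read_pdb(p, model_policy="all")
        return obj
    return tio.read_xyz_table(p)


def _angle_stage(cfg: SystemConfig, traj: Trajectory | None) -> metrics.AngleDistribution:
    if traj is not None:
        series = metrics.compute_pseudo_dihedral(traj, cfg.quadruple)
    elif cfg.angle_mu is not None:
        series = synthetic.simulate_angle_trajectory(
            mu=cfg.angle_mu,
            kappa=cfg.angle_kappa,
            n_frames=cfg.angle_n_frames,
            dt=cfg.angle_dt,
            seed=cfg.seed,
            quadruple=cfg.quadruple,
        )
    else:
        raise TrajmetricsError(
            f"system {cfg.label!r}: no trajectory and no synthetic angle spec"
        )
    return metrics.summarize_angles(series, window=cfg.angle_window, bin_width=cfg.bin_width)


def _work_stage(cfg: SystemConfig) -> fe.DoubleDifference | None:
    if cfg.work_file is not None:
        ws = fe.read_work_file(cfg.work_file, dialect=cfg.work_dialect)
        ws.temperature = cfg.temperature
    elif cfg.work_dg_true is not None:
        ws = synthetic.simulate_work(
            synthetic.WorkSpec(
                dg_true=cfg.work_dg_true,
                dissipation=cfg.work_dissipation,
                temperature=cfg.temperature,
                seed=cfg.seed,
                label=cfg.label,
            )
        )
    else:
        return None
    return fe.double_difference(ws, n_boot=cfg.n_boot, seed=cfg.seed, label=cfg.label)


def run_pipeline(
    configs: list[SystemConfig],
    reference_label: str,
    outdir: str | Path | None = None,
) -> ComparativeReport:
    """Run all configured systems and compare them against the reference.

    Writes per-system TSV artifacts (RMSD series, RMSF/B-factor profile,
    angle histogram) and a run-level JSON report under ``outdir`` when given.
    A stage error aborts only that system and is collected in ``failures``.
    """
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("system labels must be unique")
    if reference_label not in labels:
        raise ValueError(f"reference label {reference_label!r} not among systems")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    systems: dict = {}
    distributions: dict = {}
    ddg_table: list = []
    failures: dict = {}
    artifacts: dict = {}

    for cfg in configs:
        logger.info("system %s: starting", cfg.label)
        try:
            entry: dict = {"seed": cfg.seed, "temperature": cfg.temperature}
            traj = _load_trajectory(cfg.trajectory) if cfg.trajectory else None

            if traj is not None:
                sel = select(traj, cfg.selection)
                rmsd = metrics.compute_rmsd(
                    traj, sel, fit=True, mass_weighted=True, mean_window=cfg.rmsd_mean_window
                )
                entry["rmsd_mean_A"] = rmsd.mean_value
                entry["rmsd_mean_window_ps"] = list(rmsd.mean_window)
                rsel = select(traj, cfg.rmsf_selection)
                rmsf = metrics.compute_rmsf(traj, rsel, window=cfg.rmsf_window)
                bfac = metrics.rmsf_to_bfactor(rmsf)
                entry["rmsf_mean_A"] = float(np.mean(rmsf.rmsf))
                entry["bfactor_max_A2"] = float(np.max(bfac.b))
                if outdir is not None:
                    rmsd_path = outdir / f"{cfg.label}_rmsd.tsv"
                    pd.DataFrame(
                        {"time_ps": rmsd.times, "rmsd_A": rmsd.values}
                    ).to_csv(rmsd_path, sep="\t", index=False)
                    prof_path = outdir / f"{cfg.label}_rmsf_bfactor.tsv"
                    pd.DataFrame(
                        {
                            "atom_index": rsel.indices,
                            "rmsf_A": rmsf.rmsf,
                            "bfactor_A2": bfac.b,
                        }
                    ).to_csv(prof_path, sep="\t", index=False)
                    artifacts.setdefault(cfg.label, []).extend(
                        [rmsd_path.name, prof_path.name]
                    )

            dist = _angle_stage(cfg, traj)
            distributions[cfg.label] = dist
            entry["angle"] = {
                "circular_mean_deg": dist.circular_mean,
                "arithmetic_mean_deg": dist.arithmetic_mean,
                "circular_std_deg": dist.circular_std,
                "mode_bin_center_deg": dist.mode_bin_center,
                "n_frames": dist.n_frames,
                "window_ps": list(dist.window),
            }
            if outdir is not None:
                hist_path = outdir / f"{cfg.label}_angle_hist.tsv"
                pd.DataFrame(
                    {
                        "bin_center_deg": dist.bin_centers,
                        "count": dist.counts,
                        "density": dist.density,
                    }
                ).to_csv(hist_path, sep="\t", index=False)
                artifacts.setdefault(cfg.label, []).append(hist_path.name)

            ddg = _work_stage(cfg)
            if ddg is not None:
                row = {
                    "label": cfg.label,
                    "ddg_kj_mol": ddg.ddg,
                    "stderr_kj_mol": ddg.stderr,
                    "interpretation": ddg.interpretation,
                    "mode": ddg.mode,
                }
                entry["ddg"] = row
                ddg_table.append(row)

            systems[cfg.label] = entry
        except TrajmetricsError as exc:
            logger.error("system %s: %s", cfg.label, exc)
            failures[cfg.label] = str(exc)

    shifts: dict = {}
    ref_dist = distributions.get(reference_label)
    if ref_dist is not None:
        for label, dist in distributions.items():
            if label == reference_label or label in failures:
                continue
            shift = metrics.compare_distributions(dist, ref_dist)
            shifts[label] = {
                "delta_circular_mean_deg": shift.delta_circular_mean,
                "delta_mode_deg": shift.delta_mode,
                "circular_std_ratio": shift.circular_std_ratio,
                "overlap": shift.overlap,
                "left_shifted": shift.left_shifted,
            }

    report = ComparativeReport(
        reference_label=reference_label,
        systems=systems,
        shifts=shifts,
        ddg_table=ddg_table,
        failures=failures,
        artifacts=artifacts,
    )
    if outdir is not None:
        (outdir / "report.json").write_text(report.to_json() + "\n")
    return report


def _parse_window(text: str) -> tuple[float, float]:
    lo, hi = text.replace(":", " ").split()
    return float(lo), float(hi)


def load_config(path: str | Path) -> tuple[list[SystemConfig], str]:
    """Parse the flat INI config: a [run] section naming the reference, plus
    one section per system with key=value lines."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise TrajmetricsError(f"config file {path} not found or unreadable")
    if "run" not in parser:
        raise TrajmetricsError("config needs a [run] section with 'reference ='")
    reference = parser["run"].get("reference", "")
    configs = []
    for section in parser.sections():
        if section == "run":
            continue
        s = parser[section]
        cfg = SystemConfig(
            label=section,
            trajectory=s.get("trajectory"),
            selection=s.get("selection", "backbone"),
            rmsf_selection=s.get("rmsf_selection", "calpha"),
            bin_width=s.getfloat("bin_width", 1.0),
            angle_kappa=s.getfloat("angle_kappa", 50.0),
            angle_n_frames=s.getint("angle_n_frames", 3000),
            angle_dt=s.getfloat("angle_dt", 10.0),
            work_file=s.get("work_file"),
            work_dialect=s.get("work_dialect", "two_column"),
            work_dissipation=s.getfloat("work_dissipation", 3.0),
            n_boot=s.getint("n_boot", 200),
            temperature=s.getfloat("temperature", fe.DEFAULT_TEMPERATURE_K),
            seed=s.getint("seed", 0),
        )
        if s.get("angle_mu") is not None:
            cfg.angle_mu = s.getfloat("angle_mu")
        if s.get("work_dg_true") is not None:
            cfg.work_dg_true = s.getfloat("work_dg_true")
        if s.get("quadruple") is not None:
            cfg.quadruple = metrics.QuadrupleSpec.parse(s.get("quadruple"))
        for key, attr in (
            ("rmsd_mean_window", "rmsd_mean_window"),
            ("rmsf_window", "rmsf_window"),
            ("angle_window", "angle_window"),
        ):
            if s.get(key) is not None:
                setattr(cfg, attr, _parse_window(s.get(key)))
        configs.append(cfg)
    if not configs:
        raise TrajmetricsError("config defines no systems")
    if not reference:
        reference = configs[0].label
    return configs, reference


def _setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("trajmetrics")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(logging.INFO if verbose else logging.WARNING)
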