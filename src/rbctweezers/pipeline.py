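"""Stage orchestration: simulate -> (track) -> estimate -> summarize.

Each stage reads and writes only documented CSV/JSON artifacts, so
third-party data in the same layout can enter at any stage. Ground
truth is written to a separate file (``truth.csv``) that no downstream
stage reads. A run manifest records the config hash, seed and outputs;
re-running with the same config reproduces identical data files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    build_report,
    ros_percent_positive,
    rank_sum_test,
    summarize_by_day,
)
from .config import RunConfig
from .errors import RBCTweezersError
from .estimation import (
    ElongationSweep,
    ZetaSweep,
    estimate_elasticity,
    estimate_zeta,
)
from .physics import CellGeometry
from .synthetic import draw_cohort, simulate_elongation_sweep, simulate_ros, simulate_zeta_sweep

log = logging.getLogger("rbctweezers")

#: per-cell fit-quality warning threshold (the instrument's published
#: velocity-voltage fits all exceeded |r| = 0.98)
R_WARN = 0.98


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_simulate(config: RunConfig, out_dir: Path) -> list[Path]:
    """Draw the cohort and simulate all sweeps; write cohort/truth/sweeps CSVs."""
    design = config.cohort.build(config.seed)
    schedule = config.schedule()
    medium = config.medium.build()
    chamber = config.chamber.build()
    noise = config.noise.build()
    records = draw_cohort(design, schedule)

    cohort_rows, truth_rows, sweep_rows = [], [], []
    for cell in records:
        cohort_rows.append(
            {"cell_id": cell.cell_id, "day": cell.day, "arm": cell.arm, "kind": cell.kind}
        )
        truth_rows.append(
            {
                "cell_id": cell.cell_id,
                "day": cell.day,
                "arm": cell.arm,
                "kind": cell.kind,
                "true_zeta_V": cell.true_zeta,
                "true_mu_N_m": cell.true_mu,
                "rest_length_m": cell.rest_length,
            }
        )
        if cell.kind == "zeta":
            sweep = simulate_zeta_sweep(cell, chamber, medium, noise, root_seed=config.seed)
            for step, (volt, vel) in enumerate(zip(sweep.voltages, sweep.velocities)):
                sweep_rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "day": cell.day,
                        "arm": cell.arm,
                        "stimulus_kind": "voltage_V",
                        "step": step,
                        "stimulus_value": volt,
                        "response_value": vel,
                        "l0_m": np.nan,
                    }
                )
        else:
            sweep = simulate_elongation_sweep(cell, chamber, medium, noise, root_seed=config.seed)
            for step, (vel, length) in enumerate(zip(sweep.velocities, sweep.lengths)):
                sweep_rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "day": cell.day,
                        "arm": cell.arm,
                        "stimulus_kind": "velocity_m_s",
                        "step": step,
                        "stimulus_value": vel,
                        "response_value": length,
                        "l0_m": cell.rest_length,
                    }
                )

    paths = []
    for name, rows in [("cohort", cohort_rows), ("truth", truth_rows), ("sweeps", sweep_rows)]:
        p = out_dir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths.append(p)
    log.info("simulate: %d cells, %d sweep rows", len(records), len(sweep_rows))
    return paths


def stage_estimate(config: RunConfig, out_dir: Path) -> list[Path]:
    """Reduce sweeps.csv to per-cell zeta/elasticity estimates."""
    medium = config.medium.build()
    chamber = config.chamber.build()
    sweeps = pd.read_csv(out_dir / "sweeps.csv", dtype={"cell_id": str})
    rows = []
    for cell_id, grp in sweeps.groupby("cell_id", sort=True):
        grp = grp.sort_values("step")
        kind = grp["stimulus_kind"].iloc[0]
        day, arm = int(grp["day"].iloc[0]), grp["arm"].iloc[0]
        row = {"cell_id": cell_id, "day": day, "arm": arm,
               "zeta_mV": np.nan, "mu_dyne_cm": np.nan}
        if kind == "voltage_V":
            est = estimate_zeta(
                ZetaSweep(
                    cell_id=cell_id,
                    voltages=grp["stimulus_value"].to_numpy(),
                    velocities=grp["response_value"].to_numpy(),
                    chamber=chamber,
                    medium=medium,
                )
            )
            row.update(kind="zeta", zeta_mV=est.zeta_mV, r=est.pearson_r, n=est.n_points)
            if abs(est.pearson_r) < R_WARN:
                log.warning(
                    "estimate: cell %s velocity-voltage fit |r|=%.3f below %.2f",
                    cell_id, abs(est.pearson_r), R_WARN,
                )
        else:
            l0 = float(grp["l0_m"].iloc[0])
            est = estimate_elasticity(
                ElongationSweep(
                    cell_id=cell_id,
                    velocities=grp["stimulus_value"].to_numpy(),
                    lengths=grp["response_value"].to_numpy(),
                    rest_length=l0,
                    geometry=CellGeometry(rest_length=l0),
                    z_bottom=chamber.z_bottom,
                    z_top=chamber.z_top,
                    medium=medium,
                )
            )
            row.update(kind="elastic", mu_dyne_cm=est.mu_dyne_cm, r=est.pearson_r, n=est.n_points)
        rows.append(row)
    p = out_dir / "estimates.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    log.info("estimate: %d cells", len(rows))
    return [p]


def stage_summarize(config: RunConfig, out_dir: Path) -> list[Path]:
    """Cohort summaries, Wilcoxon comparisons, ROS kinetics, headlines."""
    est = pd.read_csv(out_dir / "estimates.csv", dtype={"cell_id": str})
    zeta = est[est["kind"] == "zeta"]
    elastic = est[est["kind"] == "elastic"]
    days = sorted(zeta["day"].unique())

    pooled = {}
    if {8, 15, 22} <= set(days):
        pooled["Day 8 to Day 22"] = (8, 15, 22)
    if {29, 36} <= set(days):
        pooled["Day 29 to Day 36"] = (29, 36)
    summaries = summarize_by_day(zeta, "zeta_mV", "mV", pooled=pooled)
    if len(elastic):
        summaries += summarize_by_day(elastic, "mu_dyne_cm", "dyne/cm")

    def values(df, day):
        return df[df["day"] == day]

    comparisons = []
    if 1 in days:
        base = values(zeta, 1)["zeta_mV"]
        for d in days:
            if d != 1:
                comparisons.append(rank_sum_test(base, values(zeta, d)["zeta_mV"],
                                                 "zeta Day 1", f"zeta Day {d}"))
    if {8, 15, 22} <= set(days) and {29, 36} <= set(days):
        comparisons.append(
            rank_sum_test(
                zeta[zeta["day"].isin([8, 15, 22])]["zeta_mV"],
                zeta[zeta["day"].isin([29, 36])]["zeta_mV"],
                "zeta Day 8 to Day 22",
                "zeta Day 29 to Day 36",
            )
        )
    edays = sorted(elastic["day"].unique())
    if 8 in edays:
        base = values(elastic, 8)["mu_dyne_cm"]
        for d in edays:
            if d != 8:
                comparisons.append(rank_sum_test(base, values(elastic, d)["mu_dyne_cm"],
                                                 "elasticity Day 8", f"elasticity Day {d}"))

    ros_series: dict[int, float] = {}
    if config.ros.enabled and config.cohort.arm == "standard":
        schedule = config.schedule()
        for d in config.cohort.days:
            events = simulate_ros(d, schedule, n_events=config.ros.n_events, seed=config.seed)
            ros_series[d] = ros_percent_positive(events)

    paths = build_report(summaries, comparisons, ros_series, out_dir)
    return list(paths.values())


STAGES = {
    "simulate": stage_simulate,
    "estimate": stage_estimate,
    "summarize": stage_summarize,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ("simulate", "estimate", "summarize")) -> dict:
    """Run the requested stages in order and write ``manifest.json``.

    On a stage failure the manifest is still written, with the failed
    stage and error recorded, and the exception re-raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "config": config.model_dump(),
        "seed": config.seed,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "stages": [],
        "outputs": [],
    }
    try:
        for name in stages:
            if name not in STAGES:
                raise RBCTweezersError(f"unknown stage {name!r}")
            try:
                outputs = STAGES[name](config, out_dir)
            except RBCTweezersError as exc:
                manifest["stages"].append(
                    {"name": name, "status": "failed", "error": f"{type(exc).__name__}: {exc}"}
                )
                raise
            manifest["stages"].append({"name": name, "status": "ok"})
            manifest["outputs"] += [p.name for p in outputs]
    finally:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
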