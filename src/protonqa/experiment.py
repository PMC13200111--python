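"""End-to-end orchestration: simulate -> compare -> stats -> train -> dose.

One call (or ``protonqa run --config experiment.yaml``) reproduces the whole
synthetic QA experiment: generate the campaign logs, compute spot deviations,
summarise distributions and run the factor analyses, flag tolerance
exceedances, train and evaluate the per-axis position predictors on the
temporal split, and quantify the dose impact of the predictions on one
held-out session.  All randomness flows from a single global seed; a
manifest recording the seed, configuration and package version makes re-runs
exact.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compute_deviations, match_spots
from .dose import BeamModel, GridSpec, compare_dose, compute_dose, spots_to_plan
from .errors import ConfigurationError
from .log_io import read_log
from .plan_io import write_ion_plan
from .predict import (
    FEATURES,
    ModelConfig,
    build_features,
    evaluate,
    feature_importance,
    temporal_split,
    train_axis_model,
)
from .qa_stats import ToleranceConfig, factor_analysis, moving_window_flags, summarize
from .simulator import CampaignSpec, default_campaign_spec, simulate_campaign

log = logging.getLogger("protonqa")


@dataclass
class PipelineConfig:
    """Everything one experiment run needs."""

    campaign: CampaignSpec
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    out_dir: str = "protonqa-run"
    seed: int = 0
    dose_spacing_mm: float = 2.0
    dose_session_limit_spots: int = 5000
    make_plots: bool = True


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Schema (all keys optional; defaults are the study-shaped campaign)::

        seed: 1
        out_dir: runs/demo
        campaign:
          spots_per_layer: 100
          faults: [[G2, 2025-05-20, 1.1, 0.0]]
        tolerances: {annual_mm: 1.0, daily_mm: 2.0, window: 50}
        model: {n_trees: 500, learning_rate: 0.1}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    camp = raw.get("campaign", {}) or {}
    faults = None
    if "faults" in camp:
        faults = [
            (str(r), dt.date.fromisoformat(str(d)), float(fx), float(fy))
            for r, d, fx, fy in camp["faults"]
        ]
    try:
        campaign = default_campaign_spec(
            spots_per_layer=int(camp.get("spots_per_layer", 725)),
            seed=seed,
            faults=faults,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid campaign block: {exc}") from exc
    tol = ToleranceConfig(**(raw.get("tolerances", {}) or {}))
    model = ModelConfig(seed=seed, **(raw.get("model", {}) or {}))
    return PipelineConfig(
        campaign=campaign,
        tolerances=tol,
        model=model,
        out_dir=str(raw.get("out_dir", "protonqa-run")),
        seed=seed,
        dose_spacing_mm=float(raw.get("dose_spacing_mm", 2.0)),
        make_plots=bool(raw.get("make_plots", True)),
    )


def _plot_reports(out: Path, dev: pd.DataFrame, flags):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for ax, col, label in zip(axes, ("dx", "dy", "dmu"), ("Δx (mm)", "Δy (mm)", "ΔMU (MU)")):
        v = dev[col].to_numpy()
        ax.hist(v, bins=80, density=True, alpha=0.6)
        g = np.linspace(v.min(), v.max(), 200)
        ax.plot(g, sps.norm.pdf(g, v.mean(), v.std(ddof=1)), "r-", lw=1)
        ax.set_xlabel(label)
    fig.tight_layout()
    fig.savefig(out / "deviation_histograms.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(9, 3.2))
    for (room, date), sf in list(flags.sessions.items())[:8]:
        ax.plot(sf.window_means["end"], sf.window_means["mean_x"], lw=0.7,
                label=f"{room} {date}")
    ax.axhline(1.0, color="b", ls="--", lw=0.8)
    ax.axhline(-1.0, color="b", ls="--", lw=0.8)
    ax.set_xlabel("spot index")
    ax.set_ylabel("running mean Δx (mm)")
    ax.legend(fontsize=6, ncol=4)
    fig.tight_layout()
    fig.savefig(out / "running_means.png", dpi=120)
    plt.close(fig)


def run_experiment(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the structured summary (also written as
    ``summary.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "version": __version__}
    stage_t0 = time.perf_counter()

    def _stage(name):
        nonlocal stage_t0
        now = time.perf_counter()
        log.info("stage %-10s done in %.1fs", name, now - stage_t0)
        stage_t0 = now

    # 1. simulate ------------------------------------------------------------
    plan = config.campaign.plan
    plan_path = out / "plan.dcm"
    write_ion_plan(plan, plan_path)
    log_dir = out / "logs"
    paths = simulate_campaign(config.campaign, log_dir)
    summary["n_sessions"] = len(paths)
    _stage("simulate")

    # 2. compare -------------------------------------------------------------
    sessions = [read_log(p) for p in paths]
    factors = config.campaign.factors
    matched = [match_spots(plan, s) for s in sessions]
    dev = compute_deviations(matched, factors)
    dev.to_csv(out / "deviations.csv", index=False)
    summary["n_spots"] = int(len(dev))
    summary["deviation_summary"] = {
        col: vars(summarize(dev[col])) | {"gaussian_fit": list(summarize(dev[col]).gaussian_fit)}
        for col in ("dx", "dy", "d2", "dmu")
    }
    _stage("compare")

    # 3. stats + flags -------------------------------------------------------
    flags = moving_window_flags(dev, config.tolerances)
    summary["flags"] = {
        "annual_union": flags.counts("annual", "union"),
        "annual_x": flags.counts("annual", "x"),
        "annual_y": flags.counts("annual", "y"),
        "daily_union": flags.counts("daily", "union"),
        "flagged_sessions": [
            [room, str(date)] for room, date in flags.flagged_sessions
        ],
    }
    fa = {}
    for factor in ("energy", "date", "room"):
        res = factor_analysis(dev, factor, "dx")
        fa[factor] = {
            "skipped": res.skipped,
            "levene_p": res.levene[1] if res.levene else None,
            "welch_F": res.welch[0] if res.welch else None,
            "welch_p": res.welch[3] if res.welch else None,
        }
    summary["factor_analysis_dx"] = fa
    _stage("stats")

    # 4. train + evaluate ----------------------------------------------------
    rows = build_features(plan, sessions, factors)
    train_rows, test_rows = temporal_split(rows)
    summary["split"] = {"train_rows": int(len(train_rows)), "test_rows": int(len(test_rows))}
    model_x = train_axis_model(train_rows, "x", config.model)
    model_y = train_axis_model(train_rows, "y", config.model)
    report = evaluate(model_x, model_y, test_rows)
    summary["evaluation"] = report.to_dict()
    summary["feature_importance"] = {
        "x": feature_importance(model_x),
        "y": feature_importance(model_y),
    }
    report.by_room_date.to_csv(out / "eval_by_room_date.csv", index=False)
    report.by_energy_band.to_csv(out / "eval_by_energy_band.csv", index=False)
    _stage("train")

    # 5. dose impact on one held-out session ---------------------------------
    test_sessions = [
        s for s in sessions if pd.Timestamp(s.date) in set(test_rows["date"])
    ]
    if test_sessions and plan.n_spots <= config.dose_session_limit_spots:
        session = test_sessions[0]
        mask = (test_rows["room"] == session.room) & (
            test_rows["date"] == pd.Timestamp(session.date)
        )
        srows = test_rows[mask]
        pred = np.column_stack(
            [model_x.predict(srows[FEATURES]), model_y.predict(srows[FEATURES])]
        )
        beam_model = BeamModel.analytic(plan.energies)
        grid = GridSpec.covering(plan, spacing=config.dose_spacing_mm)
        planned_dose = compute_dose(plan, beam_model, grid)
        predicted_plan = spots_to_plan((pred, None), plan, plan_id_suffix="-PREDICTED")
        predicted_dose = compute_dose(predicted_plan, beam_model, grid)
        cmp = compare_dose(planned_dose, predicted_dose)
        summary["dose"] = {
            "session": [session.room, session.date.isoformat()],
            "planned": cmp.stats_a,
            "predicted": cmp.stats_b,
            "mean_dose_diff": cmp.mean_dose_diff,
            "max_abs_voxel_diff": cmp.max_abs_voxel_diff,
            "sd_voxel_diff": cmp.sd_voxel_diff,
        }
    else:
        summary["dose"] = None
    _stage("dose")

    if config.make_plots:
        try:
            _plot_reports(out, dev, flags)
        except Exception as exc:  # plotting must never sink the run
            log.warning("plotting failed: %s", exc)

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "n_sessions": len(paths),
        "spots_per_layer": plan.layers[0].n_spots,
        "model": vars(config.model),
        "tolerances": vars(config.tolerances),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
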