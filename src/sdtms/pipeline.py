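"""End-to-end orchestration: simulate -> fit-io -> fit-sd -> stats -> report.

Each stage reads its predecessor's tabular artifact and writes its own,
so any stage can be re-run in isolation; all randomness flows from the
simulation config's seed, making re-runs byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import SdtmsError
from . import io_curve, sd_fit, stats
from .membrane import waveform_family
from .synthetic import SimulationConfig, simulate_study

__all__ = ["RunConfig", "run_pipeline", "fit_io_stage", "fit_sd_stage", "stats_stage"]

log = logging.getLogger("sdtms")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    trials_csv: Path | None = None  # None -> simulate
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    shared_sdtc: bool = False
    waveform_shape: str = "ctms_pseudorect"
    df_method: str = "residual"
    single_width_us: int = 60  # width for the single-threshold analysis

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)


def simulate_stage(cfg: RunConfig) -> pd.DataFrame:
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    trials, truth = simulate_study(cfg.sim)
    trials.to_csv(out / "trials.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    (out / "simulation_config.yaml").write_text(cfg.sim.to_yaml())
    log.info("simulated %d trials -> %s", len(trials), out / "trials.csv")
    return trials


def fit_io_stage(cfg: RunConfig, trials: pd.DataFrame | None = None) -> pd.DataFrame:
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if trials is None:
        src = cfg.trials_csv or out / "trials.csv"
        trials = io_curve.read_trials(src)
    fits = io_curve.fit_all_io_curves(trials)
    (out / "io_curve_fits.json").write_text(
        json.dumps([f.to_dict() for f in fits], indent=1)
    )
    rmt = pd.DataFrame(
        [
            {
                "subject_id": f.subject_id,
                "condition": f.condition,
                "pulse_width_us": f.pulse_width_us,
                "rmt_io": f.rmt_io,
            }
            for f in fits
        ]
    )
    rmt.to_csv(out / "rmt_io.csv", index=False)
    log.info("fitted %d I-O curves -> %s", len(fits), out / "rmt_io.csv")
    return rmt


def fit_sd_stage(cfg: RunConfig, rmt: pd.DataFrame | None = None) -> pd.DataFrame:
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if rmt is None:
        rmt = pd.read_csv(out / "rmt_io.csv")
    widths = sorted(rmt["pulse_width_us"].unique())
    fam = waveform_family(widths, shape=cfg.waveform_shape)
    tsets = sd_fit.threshold_sets_from_frame(rmt)
    fits = [sd_fit.fit_sd_individual(t, fam) for t in tsets]
    frame = pd.DataFrame([f.to_dict() for f in fits])
    frame.to_csv(out / "sd_fits.csv", index=False)
    log.info("fitted %d strength-duration curves -> %s", len(fits), out / "sd_fits.csv")
    if cfg.shared_sdtc:
        shared = []
        for cond in sorted(rmt["condition"].unique()):
            sub = [t for t in tsets if t.condition == cond]
            shared.append(sd_fit.fit_sd_shared(sub, fam).to_dict())
        (out / "sd_fits_shared.json").write_text(json.dumps(shared, indent=1))
        log.info("shared-SDTC sensitivity fits -> %s", out / "sd_fits_shared.json")
    return frame


def stats_stage(
    cfg: RunConfig,
    rmt: pd.DataFrame | None = None,
    sd: pd.DataFrame | None = None,
) -> dict:
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    if rmt is None:
        rmt = pd.read_csv(out / "rmt_io.csv")
    if sd is None:
        sd = pd.read_csv(out / "sd_fits.csv")
    ref = cfg.sim.reference_condition
    bundle: dict = {}

    single = rmt[rmt["pulse_width_us"] == cfg.single_width_us].rename(
        columns={"rmt_io": "rmt"}
    )
    bundle["single_threshold"] = stats.fit_lme_scalar(single, "rmt", reference=ref).to_dict()
    rmt_model = stats.fit_lme_rmt(rmt, reference=ref, df_method=cfg.df_method)
    bundle["rmt_model"] = rmt_model.to_dict()
    diffs, diff_model = stats.placebo_differences(rmt, reference=ref)
    bundle["placebo_differences"] = {
        "per_width_mean": diffs.groupby(["condition", "pulse_width_us"])["diff_rmt_io"]
        .mean()
        .reset_index()
        .to_dict(orient="records"),
        "model": diff_model.to_dict(),
    }
    bundle["sdtc_model"] = stats.fit_lme_scalar(sd, "sdtc_us", reference=ref).to_dict()
    bundle["rheobase_model"] = stats.fit_lme_scalar(
        sd, "rheobase_pct_mso", reference=ref
    ).to_dict()
    slopes, rel_model = stats.sdtc_rheobase_relationship(sd, reference=ref)
    bundle["sdtc_rheobase"] = {
        "per_condition": slopes.to_dict(orient="records"),
        "model": rel_model.to_dict(),
    }
    (out / "stats.json").write_text(json.dumps(bundle, indent=1))
    log.info("statistics bundle -> %s", out / "stats.json")
    return bundle


def report_stage(cfg: RunConfig, bundle: dict | None = None) -> str:
    out = cfg.out_dir
    if bundle is None:
        bundle = json.loads((out / "stats.json").read_text())
    lines = ["sdtms pipeline report", "=" * 21, ""]

    def model_block(title, d):
        lines.append(title)
        for a in d.get("anova", []):
            lines.append(
                f"  {a['effect']}: F[{a['df_num']},{a['df_den']}] = {a['F']:.2f}, p = {a['p']:.3g}"
            )
        for e in d.get("effects", []):
            lines.append(
                f"  {e['term']}: estimate = {e['estimate']:.3g}, SE = {e['se']:.3g}, "
                f"t[{e['df']}] = {e['t']:.2f}, p = {e['p']:.3g}, d = {e['cohen_d']:.2f}"
            )
        lines.append("")

    model_block(
        f"Single-threshold model (RMT_I-O at {cfg.single_width_us} us)",
        bundle["single_threshold"],
    )
    model_block("RMT_I-O ~ condition x pulse width", bundle["rmt_model"])
    model_block("Drug-minus-placebo differences", bundle["placebo_differences"]["model"])
    model_block("SDTC ~ condition", bundle["sdtc_model"])
    model_block("Rheobase ~ condition", bundle["rheobase_model"])
    lines.append("SDTC-rheobase regressions (per condition):")
    for row in bundle["sdtc_rheobase"]["per_condition"]:
        lines.append(
            f"  {row['condition']}: slope = {row['slope_us_per_pct']:.1f} us/%MSO, "
            f"R^2 = {row['r_squared']:.3f}, p = {row['p']:.3g}"
        )
    lines.append("")
    model_block("SDTC ~ rheobase x condition", bundle["sdtc_rheobase"]["model"])
    text = "\n".join(lines)
    (out / "report.txt").write_text(text)
    log.info("report -> %s", out / "report.txt")
    return text


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the statistics bundle."""
    try:
        if cfg.trials_csv is None:
            trials = simulate_stage(cfg)
        else:
            trials = io_curve.read_trials(cfg.trials_csv)
        rmt = fit_io_stage(cfg, trials)
        sd = fit_sd_stage(cfg, rmt)
        bundle = stats_stage(cfg, rmt, sd)
        report_stage(cfg, bundle)
    except SdtmsError:
        log.exception("pipeline stage failed; partial outputs preserved in %s", cfg.out_dir)
        raise
    return bundle
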