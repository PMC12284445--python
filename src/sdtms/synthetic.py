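"""Synthetic trial-level cohorts with known ground truth.

The generator emulates a placebo-controlled crossover pulse-width study:
each subject has a latent (rheobase, SDTC) pair; each drug condition
perturbs them (additive shifts and/or multiplicative threshold scaling);
true thresholds follow the first-order membrane model across pulse
widths; and each session yields sigmoid I-O responses — lognormal trial
variability around the population curve with an EMG noise floor applied
as a max() against an independent background draw (so sub-threshold
trials record background peak-to-peak, which is what makes the
10th/90th-percentile asymptote rule meaningful).

Study design constants: 13 subjects x 3 conditions x 3 pulse widths
{30, 60, 120} us x 11 intensities (80-164% of the preliminary RMT) x 10
trials.  Stimulus intensities are rounded to 1 %MSO (device resolution)
and capped at the per-width stimulator ceilings (100/73/50 %MSO).

One master seed drives everything; per-subject/per-session RNG streams
are derived deterministically so any subset is reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SpecValidationError
from .io_curve import MEP_CRITERION_MV, NOMINAL_LEVELS_PCT_RMT, sigmoid
from .membrane import MSO_CEILING_PCT, SampledWaveform, depolarization_factors, waveform_family

__all__ = [
    "DrugEffect",
    "SimulationConfig",
    "SubjectLatents",
    "draw_population",
    "condition_latents",
    "simulate_session",
    "simulate_study",
    "simulate_rmt_table",
]


@dataclass(frozen=True)
class DrugEffect:
    """Condition-level perturbation of the latent excitability parameters.

    ``threshold_scale`` multiplies all thresholds (a rheobase-like,
    pulse-width-proportional action); ``rheobase_additive`` and
    ``sdtc_additive`` shift the parameters directly.

    ``threshold_additive_pct_mso`` adds the same absolute amount to the
    threshold at every pulse width and is then projected back onto the
    membrane model: the subject's perturbed thresholds are refitted to
    yield a subject-specific (rheobase up, SDTC down) pair that
    reproduces the flat shift.  This indirection is necessary because in
    the tau >> tp regime no *fixed* parameter shift produces a
    width-independent threshold change - both rheobase and SDTC move
    thresholds near-proportionally across widths - yet the flat pattern
    is exactly what distinguishes a lacosamide-like action from a
    carbamazepine-like one.
    """

    rheobase_additive_pct_mso: float = 0.0
    sdtc_additive_us: float = 0.0
    threshold_scale: float = 1.0
    threshold_additive_pct_mso: float = 0.0


def _default_drug_effects() -> dict[str, DrugEffect]:
    return {
        "placebo": DrugEffect(),
        # width-proportional threshold elevation (~15%), SDTC untouched
        "carbamazepine": DrugEffect(threshold_scale=1.15),
        # flat +2 %MSO threshold elevation at every width, realized per
        # subject as a rheobase increase plus SDTC reduction
        "lacosamide": DrugEffect(threshold_additive_pct_mso=2.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort, excitability and noise parameters of the simulated study.

    Defaults reproduce the study design (13 subjects, 3 conditions,
    widths {30, 60, 120} us, 11 intensity levels, 10 trials each) with a
    population whose thresholds sit in the device's working range: mean
    rheobase 3.5 %MSO and mean SDTC 550 us give thresholds of roughly
    66/34/18 %MSO at 30/60/120 us, under the respective stimulator
    ceilings of 100/73/50 %MSO.
    """

    n_subjects: int = 13
    conditions: tuple[str, ...] = ("placebo", "carbamazepine", "lacosamide")
    reference_condition: str = "placebo"
    pulse_widths_us: tuple[int, ...] = (30, 60, 120)
    mean_rheobase_pct_mso: float = 3.5
    sd_rheobase_pct_mso: float = 0.7
    mean_sdtc_us: float = 550.0
    sd_sdtc_us: float = 120.0
    rheobase_sdtc_correlation: float = 0.0
    drug_effects: Mapping[str, DrugEffect] = field(default_factory=_default_drug_effects)
    io_spread_s_pct_mso: float = 5.0
    io_spread_between_sd: float = 1.0
    trial_noise_sd_log10: float = 0.25
    noise_floor_median_mv: float = 0.01
    noise_floor_gsd: float = 1.3
    upper_plateau_median_mv: float = 2.0
    upper_plateau_gsd: float = 1.4
    n_trials_per_intensity: int = 10
    nominal_levels_pct_rmt: tuple[int, ...] = NOMINAL_LEVELS_PCT_RMT
    prelim_jitter_pct_mso: float = 2.0
    waveform_shape: str = "ctms_pseudorect"
    seed: int = 0

    def __post_init__(self):
        for name in (
            "mean_rheobase_pct_mso",
            "sd_rheobase_pct_mso",
            "mean_sdtc_us",
            "sd_sdtc_us",
            "io_spread_s_pct_mso",
            "trial_noise_sd_log10",
            "noise_floor_median_mv",
            "upper_plateau_median_mv",
        ):
            if getattr(self, name) < 0 or (
                name.startswith("mean") and getattr(self, name) <= 0
            ):
                raise SpecValidationError(name, "must be positive")
        if abs(self.rheobase_sdtc_correlation) >= 1:
            raise SpecValidationError("rheobase_sdtc_correlation", "must satisfy |rho| < 1")
        if tuple(sorted(self.nominal_levels_pct_rmt)) != tuple(self.nominal_levels_pct_rmt):
            raise SpecValidationError("nominal_levels_pct_rmt", "must be sorted ascending")
        if self.reference_condition not in self.conditions:
            raise SpecValidationError("reference_condition", "must be one of conditions")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drug_effects"] = {k: asdict(v) for k, v in self.drug_effects.items()}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "drug_effects" in d:
            d["drug_effects"] = {
                k: v if isinstance(v, DrugEffect) else DrugEffect(**v)
                for k, v in d["drug_effects"].items()
            }
        for key in ("conditions", "pulse_widths_us", "nominal_levels_pct_rmt"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))

    def waveforms(self) -> dict[float, SampledWaveform]:
        return waveform_family(self.pulse_widths_us, shape=self.waveform_shape)


@dataclass(frozen=True)
class SubjectLatents:
    subject_id: str
    rheobase_pct_mso: float
    sdtc_us: float
    io_spread_s: float
    plateau_mv: float


def _session_rng(config: SimulationConfig, subj_idx: int, cond_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(subj_idx, cond_idx))
    )


def draw_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SubjectLatents]:
    """Draw per-subject latent parameters from the configured population.

    (rheobase, SDTC) come from a bivariate normal with the configured
    correlation, redrawn per subject until physiologically valid
    (rheobase > 0.5 %MSO, SDTC within the fitting bounds with margin) and
    measurable: thresholds must sit below the stimulator ceiling at every
    pulse width in every condition, mirroring the device-limited
    recruitment of a real pulse-width study.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(config.seed), spawn_key=(999,))
        )
    fam = config.waveforms()
    margin = config.prelim_jitter_pct_mso + 1.0
    rho = config.rheobase_sdtc_correlation
    cov = np.array(
        [
            [config.sd_rheobase_pct_mso**2, rho * config.sd_rheobase_pct_mso * config.sd_sdtc_us],
            [rho * config.sd_rheobase_pct_mso * config.sd_sdtc_us, config.sd_sdtc_us**2],
        ]
    )
    mean = np.array([config.mean_rheobase_pct_mso, config.mean_sdtc_us])
    latents = []
    for i in range(config.n_subjects):
        for _ in range(1000):
            rb, tau = rng.multivariate_normal(mean, cov, method="svd")
            if not (rb > 0.5 and 60.0 < tau < 1900.0):
                continue
            lat = SubjectLatents(f"S{i + 1:02d}", float(rb), float(tau), 1.0, 1.0)
            feasible = True
            for cond in config.conditions:
                try:
                    rb_c, tau_c = condition_latents(lat, cond, config, fam)
                except SpecValidationError:
                    feasible = False
                    break
                for w, thr in true_thresholds(rb_c, tau_c, config, fam).items():
                    if thr > MSO_CEILING_PCT[int(w)] - margin:
                        feasible = False
            if feasible:
                break
        else:  # pragma: no cover - pathological config
            raise SpecValidationError("population", "cannot draw valid latents")
        s = max(config.io_spread_s_pct_mso + config.io_spread_between_sd * rng.standard_normal(), 1.0)
        plateau = config.upper_plateau_median_mv * math.exp(
            math.log(config.upper_plateau_gsd) * rng.standard_normal()
        )
        latents.append(
            SubjectLatents(
                subject_id=f"S{i + 1:02d}",
                rheobase_pct_mso=float(rb),
                sdtc_us=float(tau),
                io_spread_s=float(s),
                plateau_mv=float(plateau),
            )
        )
    return latents


def condition_latents(
    latents: SubjectLatents,
    condition: str,
    config: SimulationConfig,
    wf_family=None,
) -> tuple[float, float]:
    """Apply the condition's drug effect to one subject's latent pair.

    Returns (rheobase', sdtc') with rheobase' = (rheobase + additive) *
    scale and sdtc' = sdtc + sdtc_additive; the reference condition is
    the identity.  A flat ``threshold_additive_pct_mso`` is applied by
    shifting the subject's model thresholds at every width and projecting
    the shifted curve back onto the membrane model (least-squares refit),
    which yields the subject-specific rheobase/SDTC pair generating the
    flat shift.
    """
    if condition not in config.drug_effects:
        raise SpecValidationError("condition", f"{condition!r} has no configured drug effect")
    eff = config.drug_effects[condition]
    rb = (latents.rheobase_pct_mso + eff.rheobase_additive_pct_mso) * eff.threshold_scale
    tau = latents.sdtc_us + eff.sdtc_additive_us
    if rb <= 0 or tau <= 0:
        raise SpecValidationError(
            "drug_effects", f"{condition}: resulting parameters non-positive ({rb:.3g}, {tau:.3g})"
        )
    if eff.threshold_additive_pct_mso != 0.0:
        from .sd_fit import ThresholdSet, fit_sd_individual

        fam = wf_family if wf_family is not None else config.waveforms()
        shifted = {
            w: thr + eff.threshold_additive_pct_mso
            for w, thr in true_thresholds(rb, tau, config, fam).items()
        }
        if any(v <= 0 for v in shifted.values()):
            raise SpecValidationError(
                "drug_effects", f"{condition}: flat shift drives a threshold non-positive"
            )
        proj = fit_sd_individual(
            ThresholdSet(latents.subject_id, condition, shifted), fam
        )
        rb, tau = proj.rheobase_pct_mso, proj.sdtc_us
    return float(rb), float(tau)


def _noise_floor(rng, config, size) -> np.ndarray:
    return config.noise_floor_median_mv * np.exp(
        math.log(config.noise_floor_gsd) * rng.standard_normal(size)
    )


def true_thresholds(
    rheobase: float, sdtc: float, config: SimulationConfig, wf_family=None
) -> dict[int, float]:
    """Membrane-model thresholds at each configured pulse width."""
    fam = wf_family if wf_family is not None else config.waveforms()
    out = {}
    for w in config.pulse_widths_us:
        r = float(depolarization_factors(fam[float(w)], sdtc)[0])
        out[int(w)] = rheobase / r
    return out


def simulate_session(
    latents: SubjectLatents,
    condition: str,
    config: SimulationConfig,
    wf_family=None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one subject x condition session.

    Returns the trial table plus a per-width truth/bookkeeping dict
    (true threshold, preliminary RMT, whether levels were truncated at
    the stimulator ceiling).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed)))
    fam = wf_family if wf_family is not None else config.waveforms()
    rb, tau = condition_latents(latents, condition, config, fam)
    thresholds = true_thresholds(rb, tau, config, fam)

    y_low_gen = math.log10(config.noise_floor_median_mv)
    y_high_gen = math.log10(latents.plateau_mv)
    y_star = math.log10(MEP_CRITERION_MV)
    ln_k = math.log((y_high_gen - y_low_gen) / (y_star - y_low_gen) - 1.0)

    n = config.n_trials_per_intensity
    levels = np.array(config.nominal_levels_pct_rmt, dtype=float)
    rows = []
    truth = {"subject_id": latents.subject_id, "condition": condition, "widths": {}}
    for w in config.pulse_widths_us:
        thr = thresholds[int(w)]
        jitter = rng.uniform(-config.prelim_jitter_pct_mso, config.prelim_jitter_pct_mso)
        prelim = round(thr + jitter)
        ceiling = MSO_CEILING_PCT[int(w)]
        truncated = prelim > ceiling
        intensities = np.minimum(np.round(levels / 100.0 * prelim), ceiling)
        xm = thr + latents.io_spread_s * ln_k
        mean_y = sigmoid(intensities, xm, latents.io_spread_s, y_low_gen, y_high_gen)
        x_rep = np.repeat(intensities, n)
        level_rep = np.repeat(levels, n)
        y_rep = np.repeat(mean_y, n) + config.trial_noise_sd_log10 * rng.standard_normal(
            len(x_rep)
        )
        sig_amp = np.power(10.0, y_rep)
        floor = _noise_floor(rng, config, len(x_rep))
        mep = np.maximum(sig_amp, floor)
        noise_pp = _noise_floor(rng, config, len(x_rep))
        for x, lev, m, np_ in zip(x_rep, level_rep, mep, noise_pp):
            rows.append(
                {
                    "subject_id": latents.subject_id,
                    "condition": condition,
                    "pulse_width_us": int(w),
                    "intensity_pct_mso": float(x),
                    "nominal_level_pct_rmt": float(lev),
                    "mep_pp_mv": float(m),
                    "noise_pp_mv": float(np_),
                }
            )
        truth["widths"][int(w)] = {
            "true_threshold_pct_mso": float(thr),
            "preliminary_rmt_pct_mso": float(prelim),
            "truncated": bool(truncated),
        }
    truth["rheobase_true_pct_mso"] = rb
    truth["sdtc_true_us"] = tau
    return pd.DataFrame(rows), truth


def simulate_study(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full crossover study.

    Returns ``(trials, truth)``: the trial-level table in the mandated
    CSV schema and a tidy ground-truth table with the generating
    rheobase/SDTC and per-width true thresholds for recovery testing.
    Fully reproducible from ``config.seed``.
    """
    config = config or SimulationConfig()
    fam = config.waveforms()
    latents = draw_population(config)
    trial_frames = []
    truth_rows = []
    for si, lat in enumerate(latents):
        for ci, cond in enumerate(config.conditions):
            rng = _session_rng(config, si, ci)
            trials, truth = simulate_session(lat, cond, config, fam, rng)
            trial_frames.append(trials)
            for w, info in truth["widths"].items():
                truth_rows.append(
                    {
                        "subject_id": truth["subject_id"],
                        "condition": cond,
                        "pulse_width_us": int(w),
                        "rheobase_true_pct_mso": truth["rheobase_true_pct_mso"],
                        "sdtc_true_us": truth["sdtc_true_us"],
                        "true_threshold_pct_mso": info["true_threshold_pct_mso"],
                        "preliminary_rmt_pct_mso": info["preliminary_rmt_pct_mso"],
                        "truncated": info["truncated"],
                    }
                )
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def simulate_rmt_table(
    config: SimulationConfig | None = None,
    measurement_sd_pct_mso: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Threshold-level shortcut: true thresholds plus measurement noise.

    Skips the trial level entirely; useful for statistics calibration
    runs (e.g. null-rejection rates) where only the rmt_io table matters.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed if seed is not None else config.seed))
    )
    fam = config.waveforms()
    latents = draw_population(
        config,
        rng=np.random.default_rng(
            np.random.SeedSequence(
                entropy=int(seed if seed is not None else config.seed), spawn_key=(999,)
            )
        ),
    )
    rows = []
    for lat in latents:
        for cond in config.conditions:
            rb, tau = condition_latents(lat, cond, config, fam)
            for w, thr in true_thresholds(rb, tau, config, fam).items():
                rows.append(
                    {
                        "subject_id": lat.subject_id,
                        "condition": cond,
                        "pulse_width_us": int(w),
                        "rmt_io": thr + measurement_sd_pct_mso * rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)
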