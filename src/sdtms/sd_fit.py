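"""Rheobase and strength-duration time constant estimation.

Given motor thresholds ``Vth(tp)`` measured at two or more pulse widths,
the first-order membrane model predicts

    Vth'(tp) = Vth_inf / r(tau_m, tp)

and the parameters (rheobase ``Vth_inf``, SDTC ``tau_m``) are chosen to
minimize the normalized least-squares criterion

    J = sum_p ( Vth'(tp) / Vth(tp) - 1 )^2 .

For fixed ``tau_m`` the optimal rheobase has a closed form: with
``a_p = 1 / (r_p * Vth(tp))`` the inner minimizer of ``sum (V*a_p - 1)^2``
is ``V* = sum(a_p) / sum(a_p^2)`` (:func:`profile_rheobase`).  The outer
1-D problem in ``tau_m`` is solved by a dense log-spaced grid followed by
bounded local refinement, which is deterministic and globally robust for
this cheap objective.

Two modes mirror the analysis variants: per-subject fits
(:func:`fit_sd_individual`) and a shared-SDTC sensitivity mode in which
one time constant is common to all subjects of a condition while each
keeps an individual rheobase (:func:`fit_sd_shared`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import DataQualityError, SdtmsError
from .membrane import SampledWaveform, depolarization_factors

__all__ = [
    "TAU_BOUNDS_US",
    "ThresholdSet",
    "SDFit",
    "SharedSDFit",
    "StrengthDurationModel",
    "sd_objective",
    "profile_rheobase",
    "fit_sd_individual",
    "fit_sd_shared",
    "threshold_sets_from_frame",
]

#: SDTC search bounds in microseconds; brackets reported cortical and
#: peripheral values with wide margin.  Optima pinned at a bound are
#: flagged, not silently accepted.
TAU_BOUNDS_US = (50.0, 2000.0)

N_GRID = 400


@dataclass(frozen=True)
class ThresholdSet:
    """RMT_I-O thresholds (%MSO) across pulse widths for one session."""

    subject_id: str
    condition: str
    thresholds: Mapping[float, float]

    def __post_init__(self):
        th = {float(k): float(v) for k, v in self.thresholds.items()}
        if len(th) < 1:
            raise DataQualityError("need thresholds at >= 1 pulse width")
        if any(v <= 0 for v in th.values()):
            raise DataQualityError("thresholds must be > 0 %MSO")
        object.__setattr__(self, "thresholds", th)

    @property
    def widths(self) -> np.ndarray:
        return np.array(sorted(self.thresholds), dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([self.thresholds[w] for w in sorted(self.thresholds)], dtype=float)


@dataclass(frozen=True)
class SDFit:
    """Fitted rheobase/SDTC pair with the criterion value at the optimum."""

    subject_id: str
    condition: str
    rheobase_pct_mso: float
    sdtc_us: float
    objective: float
    mode: str = "individual"
    at_bound: bool = False
    residual_dof: int = 1

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "rheobase_pct_mso": self.rheobase_pct_mso,
            "sdtc_us": self.sdtc_us,
            "objective": self.objective,
            "mode": self.mode,
            "at_bound": self.at_bound,
            "residual_dof": self.residual_dof,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def summary(self) -> str:
        flag = "  [SDTC at search bound]" if self.at_bound else ""
        return (
            f"Strength-duration fit ({self.mode}): subject {self.subject_id}, "
            f"{self.condition}\n"
            f"  rheobase Vth_inf = {self.rheobase_pct_mso:8.3f} %MSO\n"
            f"  SDTC tau_m       = {self.sdtc_us:8.1f} us{flag}\n"
            f"  objective        = {self.objective:.3e} ({self.residual_dof} residual dof)"
        )


@dataclass(frozen=True)
class SharedSDFit:
    """Shared-SDTC fit: one time constant, per-subject rheobases."""

    condition: str
    sdtc_us: float
    rheobases: Mapping[str, float]
    objective: float
    at_bound: bool = False

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "sdtc_us": self.sdtc_us,
            "rheobases": dict(self.rheobases),
            "objective": self.objective,
            "at_bound": self.at_bound,
            "mode": "shared",
        }


def _factors(wf_family: Mapping[float, SampledWaveform], widths: np.ndarray, taus) -> np.ndarray:
    """Depolarization factors, shape (n_tau, n_width)."""
    missing = [w for w in widths if float(w) not in wf_family]
    if missing:
        raise SdtmsError(f"no waveform configured for pulse width(s) {missing}")
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    out = np.empty((taus.size, widths.size))
    for j, w in enumerate(widths):
        out[:, j] = depolarization_factors(wf_family[float(w)], taus)
    return out


def sd_objective(
    candidate: tuple[float, float],
    tset: ThresholdSet,
    wf_family: Mapping[float, SampledWaveform],
) -> float:
    """Normalized least-squares criterion at ``candidate = (rheobase, sdtc)``."""
    rheobase, sdtc = candidate
    if rheobase <= 0 or sdtc <= 0:
        raise DataQualityError("candidate parameters must be > 0")
    r = _factors(wf_family, tset.widths, sdtc)[0]
    pred = rheobase / r
    return float(np.sum((pred / tset.values - 1.0) ** 2))


def profile_rheobase(
    sdtc_us: float,
    tset: ThresholdSet,
    wf_family: Mapping[float, SampledWaveform],
) -> float:
    """Closed-form inner minimizer of the criterion in the rheobase.

    With ``a_p = 1/(r_p Vth_p)`` the objective is a quadratic in the
    rheobase whose unique minimizer is ``sum(a_p)/sum(a_p^2)``.
    """
    if sdtc_us <= 0:
        raise DataQualityError("sdtc_us must be > 0")
    r = _factors(wf_family, tset.widths, sdtc_us)[0]
    a = 1.0 / (r * tset.values)
    denom = float(np.sum(a * a))
    if denom <= 0 or not np.isfinite(denom):
        raise FloatingPointError("degenerate profile: all a_p vanish")
    return float(np.sum(a) / denom)


class StrengthDurationModel:
    """Strength-duration model of thresholds across pulse widths.

    Parameters
    ----------
    tsets : ThresholdSet or sequence of ThresholdSet
        One set per subject (sequence for the shared-SDTC mode).
    wf_family : mapping pulse width (us) -> SampledWaveform
        Pulse shapes used to evaluate the depolarization factor.
    tau_bounds_us, n_grid
        SDTC search interval and density of the log-spaced scan.
    """

    def __init__(
        self,
        tsets: ThresholdSet | Sequence[ThresholdSet],
        wf_family: Mapping[float, SampledWaveform],
        tau_bounds_us: tuple[float, float] = TAU_BOUNDS_US,
        n_grid: int = N_GRID,
    ):
        if isinstance(tsets, ThresholdSet):
            tsets = [tsets]
        if len(tsets) == 0:
            raise DataQualityError("no threshold sets supplied")
        self.tsets = list(tsets)
        self.wf_family = wf_family
        self.tau_bounds_us = (float(tau_bounds_us[0]), float(tau_bounds_us[1]))
        self.n_grid = max(int(n_grid), 400)
        self._grid = np.geomspace(*self.tau_bounds_us, self.n_grid)

    # -- profiled objectives -------------------------------------------------

    def _profiled(self, tset: ThresholdSet, taus) -> tuple[np.ndarray, np.ndarray]:
        """(objective, rheobase) profiles over an array of taus."""
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        r = _factors(self.wf_family, tset.widths, taus)  # (n_tau, n_w)
        a = 1.0 / (r * tset.values[None, :])
        v = a.sum(axis=1) / (a * a).sum(axis=1)
        obj = ((v[:, None] * a - 1.0) ** 2).sum(axis=1)
        return obj, v

    def _total_objective(self, taus) -> np.ndarray:
        total = 0.0
        for tset in self.tsets:
            obj, _ = self._profiled(tset, taus)
            total = total + obj
        return total

    def _minimize_tau(self, objective_fn) -> tuple[float, float, bool]:
        """Grid scan + bounded local refinement of a 1-D objective in tau."""
        obj = objective_fn(self._grid)
        i = int(np.argmin(obj))
        lo = self._grid[max(i - 1, 0)]
        hi = self._grid[min(i + 1, self.n_grid - 1)]
        res = minimize_scalar(
            lambda t: float(objective_fn(np.array([t]))[0]),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        tau = float(res.x)
        val = float(res.fun)
        # the refinement must not exceed the best grid node
        if obj[i] < val:
            tau, val = float(self._grid[i]), float(obj[i])
        at_bound = (i == 0 and tau < self.tau_bounds_us[0] * 1.001) or (
            i == self.n_grid - 1 and tau > self.tau_bounds_us[1] * 0.999
        )
        return tau, val, at_bound

    # -- fitting -------------------------------------------------------------

    def fit(self, mode: str = "individual"):
        if mode == "individual":
            fits = [self._fit_one(t) for t in self.tsets]
            return fits[0] if len(fits) == 1 else fits
        if mode == "shared":
            return self._fit_shared()
        raise ValueError(f"unknown mode {mode!r}")

    def _fit_one(self, tset: ThresholdSet) -> SDFit:
        if len(tset.thresholds) < 2:
            raise DataQualityError(
                "fitting (rheobase, SDTC) needs thresholds at >= 2 distinct pulse widths"
            )
        tau, val, at_bound = self._minimize_tau(lambda ts: self._profiled(tset, ts)[0])
        rheobase = profile_rheobase(tau, tset, self.wf_family)
        return SDFit(
            subject_id=tset.subject_id,
            condition=tset.condition,
            rheobase_pct_mso=rheobase,
            sdtc_us=tau,
            objective=val,
            mode="individual",
            at_bound=at_bound,
            residual_dof=len(tset.thresholds) - 2,
        )

    def _fit_shared(self) -> SharedSDFit:
        tau, val, at_bound = self._minimize_tau(self._total_objective)
        rheobases = {
            t.subject_id: profile_rheobase(tau, t, self.wf_family) for t in self.tsets
        }
        cond = self.tsets[0].condition
        return SharedSDFit(
            condition=cond,
            sdtc_us=tau,
            rheobases=rheobases,
            objective=val,
            at_bound=at_bound,
        )


def fit_sd_individual(
    tset: ThresholdSet,
    wf_family: Mapping[float, SampledWaveform],
    tau_bounds_us: tuple[float, float] = TAU_BOUNDS_US,
    n_grid: int = N_GRID,
) -> SDFit:
    """Per-subject (rheobase, SDTC) fit by grid-then-refine profiling."""
    return StrengthDurationModel(tset, wf_family, tau_bounds_us, n_grid).fit("individual")


def fit_sd_shared(
    tsets: Sequence[ThresholdSet],
    wf_family: Mapping[float, SampledWaveform],
    tau_bounds_us: tuple[float, float] = TAU_BOUNDS_US,
    n_grid: int = N_GRID,
) -> SharedSDFit:
    """Common SDTC across subjects of one condition, individual rheobases."""
    return StrengthDurationModel(tsets, wf_family, tau_bounds_us, n_grid).fit("shared")


def threshold_sets_from_frame(rmt: pd.DataFrame) -> list[ThresholdSet]:
    """Build ThresholdSets from a tidy (subject, condition, width, rmt_io) frame."""
    required = {"subject_id", "condition", "pulse_width_us", "rmt_io"}
    missing = required - set(rmt.columns)
    if missing:
        raise DataQualityError(f"threshold table missing column(s): {sorted(missing)}")
    out = []
    for (subj, cond), grp in rmt.groupby(["subject_id", "condition"], sort=True):
        th = dict(zip(grp["pulse_width_us"].astype(float), grp["rmt_io"].astype(float)))
        out.append(ThresholdSet(subject_id=str(subj), condition=str(cond), thresholds=th))
    return out


def sd_fits_to_frame(fits: Iterable[SDFit]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits])
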