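"""Sigmoid input-output curves and resting-motor-threshold estimation.

The input-output (I-O) relation between TMS intensity ``x`` (% maximum
stimulator output, %MSO) and log10 MEP amplitude ``y`` is modelled as a
Boltzmann sigmoid with session-fixed asymptotes:

    y(x) = yl + (yh - yl) / (1 + exp((xm - x) / s))

``yl``/``yh`` are the lower/upper saturation levels on the log10(mV)
scale, fixed per session (subject x drug condition) at the 10th percentile
of pre-stimulus noise amplitudes and the 90th percentile of MEP
amplitudes; only the midpoint ``xm`` and spread ``s`` are fitted, per
pulse width, to the median log response at each intensity.  The resting
motor threshold RMT_I-O is the intensity at which the fitted curve crosses
log10(0.05 mV), obtained by inverting the sigmoid in closed form.

The module follows a Model/Results layout: :class:`IOCurveModel` holds the
median points and asymptotes, ``fit()`` returns an :class:`IOCurveFit`
with estimates, R^2 and the inverted threshold.  The flat functions
(`session_asymptotes`, `median_log_response`, `fit_io_curve`,
`invert_rmt`, `preliminary_rmt`) expose the same steps individually.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DataQualityError,
    FitError,
    InversionError,
    SchemaError,
    ThresholdNotFoundError,
)
from .membrane import MSO_CEILING_PCT

__all__ = [
    "TRIAL_COLUMNS",
    "CONDITIONS",
    "MEP_CRITERION_MV",
    "TrialRecord",
    "SessionAsymptotes",
    "IOCurveFit",
    "IOCurveModel",
    "sigmoid",
    "read_trials",
    "validate_trials",
    "session_asymptotes",
    "median_log_response",
    "fit_io_curve",
    "invert_rmt",
    "preliminary_rmt",
    "fit_all_io_curves",
]

#: Mandated trial CSV schema (UTF-8, "." decimal).
TRIAL_COLUMNS = (
    "subject_id",
    "condition",
    "pulse_width_us",
    "intensity_pct_mso",
    "nominal_level_pct_rmt",
    "mep_pp_mv",
    "noise_pp_mv",
)

CONDITIONS = ("placebo", "carbamazepine", "lacosamide")

#: MEP amplitude (mV) defining the motor threshold.
MEP_CRITERION_MV = 0.05

#: Floor applied to non-positive recorded amplitudes before log transform.
AMPLITUDE_CLIP_MV = 1e-4

NOMINAL_LEVELS_PCT_RMT = (80, 90, 100, 108, 116, 124, 132, 140, 148, 156, 164)


@dataclass(frozen=True)
class TrialRecord:
    """One TMS stimulus with its MEP and pre-stimulus noise amplitudes."""

    subject_id: str
    condition: str
    pulse_width_us: int
    intensity_pct_mso: float
    mep_pp_mv: float
    noise_pp_mv: float
    nominal_level_pct_rmt: float | None = None

    def __post_init__(self):
        if self.mep_pp_mv <= 0 or self.noise_pp_mv <= 0:
            raise DataQualityError("trial amplitudes must be > 0")
        ceiling = MSO_CEILING_PCT.get(int(self.pulse_width_us))
        if ceiling is not None and self.intensity_pct_mso > ceiling + 1e-9:
            raise DataQualityError(
                f"intensity {self.intensity_pct_mso} %MSO exceeds the "
                f"{ceiling} %MSO ceiling for {self.pulse_width_us} us pulses"
            )


@dataclass(frozen=True)
class SessionAsymptotes:
    """Session-fixed sigmoid saturation levels on the log10(mV) scale."""

    y_low: float
    y_high: float

    def __post_init__(self):
        crit = math.log10(MEP_CRITERION_MV)
        if not self.y_low < self.y_high:
            raise DataQualityError("y_low must be below y_high")
        if not (self.y_low < crit < self.y_high):
            raise DataQualityError(
                f"threshold criterion log10({MEP_CRITERION_MV}) = {crit:.4f} must lie "
                f"strictly between y_low = {self.y_low:.4f} and y_high = {self.y_high:.4f}"
            )


def sigmoid(x, xm: float, s: float, y_low: float, y_high: float):
    """Boltzmann sigmoid on log10 amplitude."""
    x = np.asarray(x, dtype=float)
    return y_low + (y_high - y_low) / (1.0 + np.exp((xm - x) / s))


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the mandated trial schema; clip non-positive amplitudes.

    Zero or negative recorded amplitudes are physically impossible for
    peak-to-peak EMG and break the log transform; they are clipped at
    ``AMPLITUDE_CLIP_MV`` with a warning.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns and c != "nominal_level_pct_rmt"]
    if missing:
        raise SchemaError(f"trial table is missing mandated column(s): {', '.join(missing)}")
    out = trials.copy()
    for col in ("mep_pp_mv", "noise_pp_mv"):
        bad = out[col] <= 0
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} non-positive {col} value(s) clipped at {AMPLITUDE_CLIP_MV} mV",
                stacklevel=2,
            )
            out.loc[bad, col] = AMPLITUDE_CLIP_MV
    return out


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV (mandated header, UTF-8, '.' decimal)."""
    df = pd.read_csv(path, encoding="utf-8")
    return validate_trials(df)


def session_asymptotes(
    trials: pd.DataFrame, percentile_method: str = "linear"
) -> SessionAsymptotes:
    """Session-fixed asymptotes from pooled amplitude percentiles.

    ``y_low`` is the log10 of the 10th percentile of pre-stimulus noise
    amplitudes and ``y_high`` the log10 of the 90th percentile of MEP
    amplitudes, pooled across all pulse widths and intensities of one
    subject x condition session.  Percentiles interpolate linearly between
    order statistics by default (configurable via ``percentile_method``).
    """
    if len(trials) < 10:
        raise DataQualityError("need at least 10 trials to fix session asymptotes")
    noise = np.asarray(trials["noise_pp_mv"], dtype=float)
    mep = np.asarray(trials["mep_pp_mv"], dtype=float)
    if np.any(noise <= 0) or np.any(mep <= 0):
        raise DataQualityError("amplitudes must be > 0 (run validate_trials first)")
    p10 = float(np.percentile(noise, 10, method=percentile_method))
    p90 = float(np.percentile(mep, 90, method=percentile_method))
    try:
        return SessionAsymptotes(y_low=math.log10(p10), y_high=math.log10(p90))
    except DataQualityError as exc:
        ids = trials[["subject_id", "condition"]].iloc[0].tolist() if {
            "subject_id",
            "condition",
        }.issubset(trials.columns) else ["?", "?"]
        raise DataQualityError(f"session {ids[0]}/{ids[1]}: {exc}") from exc


def median_log_response(trials: pd.DataFrame) -> pd.DataFrame:
    """Median log10 MEP amplitude per distinct stimulus intensity.

    Returns a frame with columns ``intensity_pct_mso`` and ``y`` (median
    log10 amplitude), sorted by intensity.
    """
    if len(trials) == 0:
        raise DataQualityError("no trials supplied")
    logs = np.log10(np.asarray(trials["mep_pp_mv"], dtype=float))
    df = pd.DataFrame(
        {"intensity_pct_mso": trials["intensity_pct_mso"].to_numpy(dtype=float), "y": logs}
    )
    out = (
        df.groupby("intensity_pct_mso", as_index=False)["y"]
        .median()
        .sort_values("intensity_pct_mso", ignore_index=True)
    )
    return out


@dataclass(frozen=True)
class IOCurveFit:
    """Fitted sigmoid for one subject/condition/pulse width.

    Carries the session-fixed asymptotes, the fitted midpoint ``x_mid``
    and spread, the inverted threshold ``rmt_io`` and fit diagnostics.
    """

    subject_id: str
    condition: str
    pulse_width_us: int
    y_low: float
    y_high: float
    x_mid: float
    spread: float
    rmt_io: float
    r_squared: float
    n_points: int
    ss_res: float
    spread_at_bound: bool = False

    def predict(self, x):
        return sigmoid(x, self.x_mid, self.spread, self.y_low, self.y_high)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "pulse_width_us": int(self.pulse_width_us),
            "y_low": self.y_low,
            "y_high": self.y_high,
            "x_mid": self.x_mid,
            "spread": self.spread,
            "rmt_io": self.rmt_io,
            "r_squared": self.r_squared,
            "n_points": int(self.n_points),
            "ss_res": self.ss_res,
            "spread_at_bound": self.spread_at_bound,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def plot(self, points: pd.DataFrame | None = None, ax=None):
        """Diagnostic plot: fitted sigmoid, asymptotes and RMT_I-O marker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo = self.rmt_io - 6 * self.spread
        hi = self.rmt_io + 6 * self.spread
        if points is not None:
            ax.plot(points["intensity_pct_mso"], points["y"], "ko", ms=4, label="median log MEP")
            lo = min(lo, points["intensity_pct_mso"].min())
            hi = max(hi, points["intensity_pct_mso"].max())
        x = np.linspace(lo, hi, 200)
        ax.plot(x, self.predict(x), "-", label="fitted sigmoid")
        for y, lab in ((self.y_low, "y_low"), (self.y_high, "y_high")):
            ax.axhline(y, ls=":", color="gray", lw=0.8)
        ax.axvline(self.rmt_io, ls="--", color="C3", lw=0.8, label="RMT_I-O")
        ax.set_xlabel("stimulus intensity (%MSO)")
        ax.set_ylabel("log10 MEP amplitude (mV)")
        ax.set_title(f"{self.subject_id} {self.condition} {self.pulse_width_us} us")
        ax.legend(fontsize=8)
        return ax

    def summary(self) -> str:
        lines = [
            f"I-O curve fit: subject {self.subject_id}, {self.condition}, "
            f"{self.pulse_width_us} us",
            f"  asymptotes (fixed): y_low = {self.y_low:.4f}, y_high = {self.y_high:.4f} log10(mV)",
            f"  midpoint x_mid     = {self.x_mid:8.3f} %MSO",
            f"  spread s           = {self.spread:8.3f} %MSO"
            + ("  [at bound]" if self.spread_at_bound else ""),
            f"  RMT_I-O            = {self.rmt_io:8.3f} %MSO (criterion {MEP_CRITERION_MV} mV)",
            f"  R^2 = {self.r_squared:.4f} on {self.n_points} median points",
        ]
        return "\n".join(lines)


class IOCurveModel:
    """Boltzmann sigmoid model of one I-O curve with fixed asymptotes.

    Parameters
    ----------
    points : DataFrame with columns ``intensity_pct_mso`` and ``y``
        Median log10 amplitude per intensity (see :func:`median_log_response`).
    asymptotes : SessionAsymptotes
        Session-fixed saturation levels; only (xm, s) are estimated.
    """

    #: spread search bounds and multi-start values, in %MSO
    S_BOUNDS = (0.5, 50.0)
    S_STARTS = (2.0, 5.0, 10.0)

    def __init__(
        self,
        points: pd.DataFrame,
        asymptotes: SessionAsymptotes,
        subject_id: str = "",
        condition: str = "",
        pulse_width_us: int = 0,
    ):
        if len(points) < 3:
            raise DataQualityError("need at least 3 median points to fit an I-O curve")
        self.x = points["intensity_pct_mso"].to_numpy(dtype=float)
        self.y = points["y"].to_numpy(dtype=float)
        self.asymptotes = asymptotes
        self.subject_id = subject_id
        self.condition = condition
        self.pulse_width_us = int(pulse_width_us)

    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        asymptotes: SessionAsymptotes | None = None,
        **ids,
    ) -> "IOCurveModel":
        """Build from raw trials of one subject x condition x pulse width."""
        if asymptotes is None:
            asymptotes = session_asymptotes(trials)
        pts = median_log_response(trials)
        return cls(pts, asymptotes, **ids)

    def _residuals(self, params):
        xm, s = params
        return sigmoid(self.x, xm, s, self.asymptotes.y_low, self.asymptotes.y_high) - self.y

    def _jacobian(self, params):
        xm, s = params
        yl, yh = self.asymptotes.y_low, self.asymptotes.y_high
        z = (xm - self.x) / s
        ez = np.exp(z)
        denom = (1.0 + ez) ** 2
        common = -(yh - yl) * ez / denom
        d_xm = common / s
        d_s = common * (-(xm - self.x) / s**2)
        return np.column_stack([d_xm, d_s])

    def fit(self) -> IOCurveFit:
        """Bounded deterministic least squares with multi-start.

        ``xm`` starts at the intensity whose median response is nearest the
        mid-level between the asymptotes; ``s`` is multi-started.  The best
        of the converged starts is kept; ties cannot arise because the
        objective comparison is strict and the starts are processed in a
        fixed order.
        """
        yl, yh = self.asymptotes.y_low, self.asymptotes.y_high
        mid = 0.5 * (yl + yh)
        xm0 = float(self.x[np.argmin(np.abs(self.y - mid))])
        lo = (float(np.min(self.x)) - 50.0, self.S_BOUNDS[0])
        hi = (float(np.max(self.x)) + 50.0, self.S_BOUNDS[1])
        best = None
        diagnostics = []
        for s0 in self.S_STARTS:
            try:
                res = least_squares(
                    self._residuals,
                    x0=[xm0, s0],
                    jac=self._jacobian,
                    bounds=(lo, hi),
                    ftol=1e-12,
                    xtol=1e-12,
                    gtol=1e-12,
                )
            except Exception as exc:  # pragma: no cover - scipy internal failure
                diagnostics.append({"s0": s0, "error": str(exc)})
                continue
            diagnostics.append({"s0": s0, "cost": res.cost, "status": res.status})
            if res.status > 0 and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitError(
                "I-O curve fit failed to converge from all starts",
                diagnostics={"starts": diagnostics},
            )
        xm, s = best.x
        ss_res = float(2.0 * best.cost)
        ss_tot = float(np.sum((self.y - np.mean(self.y)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        at_bound = bool(
            abs(s - self.S_BOUNDS[0]) < 1e-8 or abs(s - self.S_BOUNDS[1]) < 1e-8
        )
        rmt = _invert(xm, s, yl, yh, MEP_CRITERION_MV)
        return IOCurveFit(
            subject_id=self.subject_id,
            condition=self.condition,
            pulse_width_us=self.pulse_width_us,
            y_low=yl,
            y_high=yh,
            x_mid=float(xm),
            spread=float(s),
            rmt_io=float(rmt),
            r_squared=float(r2),
            n_points=len(self.x),
            ss_res=ss_res,
            spread_at_bound=at_bound,
        )


def fit_io_curve(points: pd.DataFrame, asymptotes: SessionAsymptotes, **ids) -> IOCurveFit:
    """Functional wrapper around :class:`IOCurveModel` + ``fit``."""
    return IOCurveModel(points, asymptotes, **ids).fit()


def _invert(xm, s, yl, yh, criterion_mv):
    y_star = math.log10(criterion_mv)
    if not (yl < y_star < yh):
        raise InversionError(
            f"criterion log10({criterion_mv}) = {y_star:.4f} lies outside the "
            f"asymptote interval ({yl:.4f}, {yh:.4f})"
        )
    return xm - s * math.log((yh - yl) / (y_star - yl) - 1.0)


def invert_rmt(fit: IOCurveFit, criterion_mv: float = MEP_CRITERION_MV) -> float:
    """Intensity at which the fitted sigmoid crosses ``criterion_mv``."""
    return _invert(fit.x_mid, fit.spread, fit.y_low, fit.y_high, criterion_mv)


def preliminary_rmt(
    responder: Callable[[float], Sequence[float]],
    start_pct_mso: int = 20,
    ceiling_pct_mso: float = 100.0,
    n_trials: int = 10,
    n_required: int = 5,
    criterion_mv: float = MEP_CRITERION_MV,
) -> int:
    """Relative-frequency threshold by an ascending 1-%MSO sweep.

    ``responder(intensity)`` returns the MEP amplitudes (mV) of
    ``n_trials`` stimuli at that intensity.  The preliminary RMT is the
    lowest integer intensity at which at least ``n_required`` of them
    exceed ``criterion_mv``.
    """
    for intensity in range(int(start_pct_mso), int(math.floor(ceiling_pct_mso)) + 1):
        amps = list(responder(float(intensity)))
        if len(amps) < n_trials:
            raise DataQualityError(
                f"responder returned {len(amps)} trials at {intensity} %MSO, expected {n_trials}"
            )
        if sum(a > criterion_mv for a in amps[:n_trials]) >= n_required:
            return intensity
    raise ThresholdNotFoundError(
        f"no intensity <= {ceiling_pct_mso} %MSO evoked >= {n_required}/{n_trials} "
        f"MEPs above {criterion_mv} mV"
    )


def fit_all_io_curves(trials: pd.DataFrame) -> list[IOCurveFit]:
    """Fit every subject x condition x pulse width curve in a trial table.

    Asymptotes are fixed per session (subject x condition) and shared by
    that session's pulse widths.  Widths whose levels collapsed to fewer
    than 3 distinct intensities (e.g. through stimulator-ceiling capping)
    are skipped with a warning rather than aborting the whole table.
    """
    trials = validate_trials(trials)
    fits = []
    for (subj, cond), session in trials.groupby(["subject_id", "condition"], sort=True):
        asym = session_asymptotes(session)
        for width, sub in session.groupby("pulse_width_us", sort=True):
            if sub["intensity_pct_mso"].nunique() < 3:
                warnings.warn(
                    f"skipping {subj}/{cond}/{width} us: fewer than 3 distinct intensities",
                    stacklevel=2,
                )
                continue
            model = IOCurveModel.from_trials(
                sub,
                asymptotes=asym,
                subject_id=str(subj),
                condition=str(cond),
                pulse_width_us=int(width),
            )
            fits.append(model.fit())
    return fits
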