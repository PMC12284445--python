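"""First-order membrane response to cTMS electric-field pulses.

The neural element is modelled as a leaky first-order (RC) membrane driven
by the induced electric field ``e(t)``:

    tau_m * dy/dt + y = e(t),   y(0) = 0

The *depolarization factor* ``r(tau_m, pulse)`` is the peak of ``y`` for a
pulse whose initial-phase amplitude is normalized to 1; it lies in (0, 1]
and tends to 1 for an infinitely long plateau.  The modelled resting motor
threshold at pulse width ``tp`` is then

    Vth'(tp) = Vth_inf / r(tau_m, tp)

where ``Vth_inf`` is the rheobase (the infinite-duration threshold) and
``tau_m`` the strength-duration time constant (SDTC).  For a rectangular
pulse this reduces to the classical Lapicque form
``Vth' = Vth_inf / (1 - exp(-tp/tau_m))``.

Waveforms are piecewise linear; the membrane ODE is propagated exactly on
each linear segment (piecewise-exponential closed form), so the factor
carries no step-size bias.  A trapezoidal integrator is provided as an
independent numerical oracle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

from .errors import SpecValidationError

__all__ = [
    "MSO_CEILING_PCT",
    "WaveformSpec",
    "SampledWaveform",
    "MembraneConfig",
    "generate_waveform",
    "waveform_family",
    "depolarization_factor",
    "depolarization_factors",
    "depolarization_factor_rect",
    "depolarization_factor_trapezoid",
    "model_threshold",
]

#: Device amplitude ceilings (% maximum stimulator output) per pulse width.
#: Used by the synthetic generator and input validation, not by the
#: membrane math itself.
MSO_CEILING_PCT: Mapping[int, float] = {30: 100.0, 60: 73.0, 120: 50.0}

_SHAPES = ("rectangular", "ctms_pseudorect")


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric description of the induced electric-field pulse.

    The cTMS pulse is idealized as a near-rectangular initial phase of
    width ``tp_us`` (optionally drooping linearly by ``droop_fraction``
    of its amplitude), followed by a longer opposite-sign phase of
    constant relative amplitude ``m_ratio`` (the M-ratio, defined here as
    smaller-phase over larger-phase amplitude, so it lies in [0, 1)).
    """

    shape: str = "ctms_pseudorect"
    tp_us: float = 60.0
    m_ratio: float = 0.2
    second_phase_width_us: float | None = None
    droop_fraction: float = 0.0
    dt_us: float = 0.5

    def __post_init__(self):
        if self.shape not in _SHAPES:
            raise SpecValidationError("shape", f"must be one of {_SHAPES}")
        if not self.tp_us > 0:
            raise SpecValidationError("tp_us", "must be > 0")
        if self.shape == "rectangular":
            if self.m_ratio != 0.0:
                object.__setattr__(self, "m_ratio", 0.0)
            if self.droop_fraction != 0.0:
                object.__setattr__(self, "droop_fraction", 0.0)
            if self.second_phase_width_us is None:
                object.__setattr__(self, "second_phase_width_us", 0.0)
        if self.second_phase_width_us is None:
            # default: second phase five times the initial phase
            object.__setattr__(self, "second_phase_width_us", 5.0 * self.tp_us)
        if not 0.0 <= self.m_ratio < 1.0:
            raise SpecValidationError("m_ratio", "must be in [0, 1)")
        if not 0.0 <= self.droop_fraction < 1.0:
            raise SpecValidationError("droop_fraction", "must be in [0, 1)")
        if self.second_phase_width_us < 0:
            raise SpecValidationError("second_phase_width_us", "must be >= 0")
        if not self.dt_us > 0:
            raise SpecValidationError("dt_us", "must be > 0")
        if self.dt_us > self.tp_us / 30.0:
            raise SpecValidationError(
                "dt_us", f"must be <= tp_us/30 = {self.tp_us / 30.0:g} us for adequate sampling"
            )

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "tp_us": self.tp_us,
            "m_ratio": self.m_ratio,
            "second_phase_width_us": self.second_phase_width_us,
            "droop_fraction": self.droop_fraction,
            "dt_us": self.dt_us,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WaveformSpec":
        return cls(**dict(d))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "WaveformSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class SampledWaveform:
    """Sampled electric-field pulse, normalized to unit initial-phase peak.

    ``segments`` is the exact piecewise-linear description
    ``(t0, t1, e0, e1)`` used by the closed-form membrane propagation;
    ``t_us``/``e_norm`` are the sampled rendering of the same pulse (for
    export, plotting and numerical oracles).
    """

    t_us: np.ndarray
    e_norm: np.ndarray
    segments: tuple[tuple[float, float, float, float], ...] = field(default=())

    def __post_init__(self):
        t = np.asarray(self.t_us, dtype=float)
        e = np.asarray(self.e_norm, dtype=float)
        if t.ndim != 1 or t.shape != e.shape:
            raise SpecValidationError("t_us", "t_us and e_norm must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise SpecValidationError("t_us", "time grid must be strictly increasing")
        object.__setattr__(self, "t_us", t)
        object.__setattr__(self, "e_norm", e)
        if not self.segments:
            # reconstruct a piecewise-linear description from the samples
            segs = tuple(
                (float(t[i]), float(t[i + 1]), float(e[i]), float(e[i + 1]))
                for i in range(len(t) - 1)
            )
            object.__setattr__(self, "segments", segs)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("t_us,e_norm\n")
        for t, e in zip(self.t_us, self.e_norm):
            buf.write(f"{t:.6g},{e:.9g}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "SampledWaveform":
        rows = [line.split(",") for line in text.strip().splitlines()[1:]]
        t = np.array([float(r[0]) for r in rows])
        e = np.array([float(r[1]) for r in rows])
        return cls(t_us=t, e_norm=e)


@dataclass(frozen=True)
class MembraneConfig:
    """Membrane (strength-duration) time constant in microseconds."""

    tau_m_us: float

    def __post_init__(self):
        if not 10.0 <= self.tau_m_us <= 5000.0:
            raise SpecValidationError("tau_m_us", "must lie in [10, 5000] us")


def _analytic_segments(spec: WaveformSpec) -> tuple[tuple[float, float, float, float], ...]:
    tp = spec.tp_us
    segs: list[tuple[float, float, float, float]] = []
    if spec.shape == "rectangular":
        segs.append((0.0, tp, 1.0, 1.0))
    else:
        segs.append((0.0, tp, 1.0, 1.0 - spec.droop_fraction))
        if spec.second_phase_width_us > 0:
            t1 = tp + spec.second_phase_width_us
            segs.append((tp, t1, -spec.m_ratio, -spec.m_ratio))
    return tuple(segs)


def _eval_segments(segs, t: np.ndarray) -> np.ndarray:
    """Evaluate the piecewise-linear pulse at times t (left-continuous holds;
    0 after the pulse ends)."""
    e = np.zeros_like(t, dtype=float)
    for t0, t1, e0, e1 in segs:
        mask = (t >= t0) & (t < t1)
        if t1 > t0:
            e[mask] = e0 + (e1 - e0) * (t[mask] - t0) / (t1 - t0)
    return e


def generate_waveform(spec: WaveformSpec) -> SampledWaveform:
    """Render a :class:`WaveformSpec` as a sampled, unit-peak pulse.

    The sampled grid covers the pulse plus a short zero tail; the exact
    piecewise-linear segments travel with the samples so that the
    membrane propagation is independent of ``dt_us``.
    """
    segs = _analytic_segments(spec)
    t_end = segs[-1][1]
    n_tail = 2
    t = np.arange(0.0, t_end + (n_tail + 0.5) * spec.dt_us, spec.dt_us)
    e = _eval_segments(segs, t)
    return SampledWaveform(t_us=t, e_norm=e, segments=segs)


def waveform_family(
    pulse_widths_us: Iterable[float],
    shape: str = "ctms_pseudorect",
    **kwargs,
) -> dict[float, SampledWaveform]:
    """Build one waveform per pulse width with shared shape parameters."""
    fam = {}
    for tp in pulse_widths_us:
        spec = WaveformSpec(shape=shape, tp_us=float(tp), **kwargs)
        fam[float(tp)] = generate_waveform(spec)
    return fam


def depolarization_factors(wf: SampledWaveform, tau_m_us) -> np.ndarray:
    """Vectorized depolarization factor over an array of time constants.

    Propagates ``tau*dy/dt + y = e(t)`` exactly across each linear segment
    of the pulse and returns ``max_t y(t)`` per tau.  Interior maxima
    (where the response crosses the drive within a segment) are located in
    closed form.
    """
    taus = np.atleast_1d(np.asarray(tau_m_us, dtype=float))
    if np.any(taus <= 0):
        raise SpecValidationError("tau_m_us", "must be > 0")
    y = np.zeros_like(taus)
    best = np.zeros_like(taus)
    for t0, t1, e0, e1 in wf.segments:
        L = t1 - t0
        if L <= 0:
            continue
        b = (e1 - e0) / L
        # y(s) = A*exp(-s/tau) + e0 + b*s - b*tau,  A = y0 - e0 + b*tau
        A = y - e0 + b * taus
        decay = np.exp(-L / taus)
        y_end = A * decay + e0 + b * L - b * taus
        # interior stationary point: exp(-s/tau) = b*tau/A  ->  y(s*) = e(s*)
        if b != 0.0:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = A / (b * taus)
                s_star = np.where(ratio > 1.0, taus * np.log(ratio), np.nan)
            inside = (s_star > 0) & (s_star < L)
            if np.any(inside):
                y_star = e0 + b * s_star[inside]
                best[inside] = np.maximum(best[inside], y_star)
        best = np.maximum(best, y_end)
        y = y_end
    # after the pulse the response only decays toward 0: no new maximum
    return best


def depolarization_factor(membrane: MembraneConfig, wf: SampledWaveform) -> float:
    """Peak normalized membrane depolarization for a unit-amplitude pulse."""
    return float(depolarization_factors(wf, membrane.tau_m_us)[0])


def depolarization_factor_rect(tau_m_us: float, tp_us: float) -> float:
    """Closed-form rectangular-pulse (Lapicque) limit ``1 - exp(-tp/tau)``."""
    if tau_m_us <= 0:
        raise SpecValidationError("tau_m_us", "must be > 0")
    if tp_us <= 0:
        raise SpecValidationError("tp_us", "must be > 0")
    return float(-np.expm1(-tp_us / tau_m_us))


def depolarization_factor_trapezoid(
    membrane: MembraneConfig, wf: SampledWaveform, dt_us: float = 0.01
) -> float:
    """Independent numerical oracle: trapezoidal integration of the
    convolution ``y(t) = (1/tau) * integral exp(-(t-u)/tau) e(u) du`` on a
    dense grid.  Slower and step-size biased; kept for cross-checks only.
    """
    tau = membrane.tau_m_us
    if tau <= 0:
        raise SpecValidationError("tau_m_us", "must be > 0")
    t_end = wf.segments[-1][1]
    t = np.arange(0.0, t_end + dt_us, dt_us)
    e = _eval_segments(wf.segments, t)
    # cumulative trapezoid of exp(u/tau)*e(u), then scale by exp(-t/tau)/tau.
    # Work with increments to avoid overflow for long pulses / small tau.
    y = np.zeros_like(t)
    decay = np.exp(-dt_us / tau)
    for i in range(1, len(t)):
        y[i] = y[i - 1] * decay + 0.5 * dt_us / tau * (e[i] + e[i - 1] * decay)
    return float(np.max(y))


def model_threshold(
    rheobase_pct_mso: float, membrane: MembraneConfig, wf: SampledWaveform
) -> float:
    """Modelled RMT: rheobase divided by the depolarization factor."""
    if rheobase_pct_mso <= 0:
        raise SpecValidationError("rheobase_pct_mso", "must be > 0")
    r = depolarization_factor(membrane, wf)
    if r <= 0:
        raise FloatingPointError("depolarization factor is non-positive")
    return rheobase_pct_mso / r
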