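# Methods

This note documents the models, conventions and design choices behind
`sdtms`, and what the synthetic-cohort tests do and do not establish
about real data.

## Membrane model and depolarization factor

The neural element is a first-order membrane, `tau_m·dy/dt + y = e(t)`
with `y(0) = 0`, driven by the normalized induced electric field. The
depolarization factor `r(tau_m, pulse) = max_t y(t)` is computed by exact
piecewise-exponential propagation across the pulse's linear segments
(interior maxima located in closed form), so it carries no integration
step-size bias; a trapezoidal integrator is retained purely as an
independent numerical cross-check. For rectangular pulses the factor
reduces to the Lapicque form `1 − exp(−t_p/tau_m)`, which serves as the
analytic oracle in the tests.

The cTMS pulse is idealized as a pseudorectangular waveform: a unit
plateau of width `t_p` with an optional linear droop, followed by a
constant reversed phase of relative amplitude `m_ratio` (default 0.2,
second phase 5·t_p long, sampling step 0.5 μs). Published descriptions of
the M-ratio are ambiguous about its orientation (initial/second vs
second/initial); here `m_ratio` is defined as the smaller phase over the
larger, constrained to [0, 1). With no droop, the membrane response peaks
at the end of the initial phase, so the reversed phase never affects the
factor and the rectangular closed form remains exact for the default
shape. Whether the factor is a function of `tau_m` and `t_p` jointly or
of their ratio alone is moot here: it is evaluated through the waveform,
which subsumes the ratio form in the rectangular case.

Device amplitude ceilings (100/73/50 %MSO at 30/60/120 μs) are stored as
constants used by the generator and input validation; they play no role
in the membrane math.

## I-O curves and RMT_I-O

Per subject × condition ("session") × pulse width, trials are reduced to
the median log10 MEP amplitude at each distinct intensity, and a
Boltzmann sigmoid `y = y_l + (y_h − y_l)/(1 + exp((x_m − x)/s))` is
fitted with the saturation levels fixed across the session: `y_l` =
log10 of the 10th percentile of pre-stimulus noise amplitudes, `y_h` =
log10 of the 90th percentile of MEP amplitudes, both pooled over all
widths and intensities of the session. Percentiles interpolate linearly
between order statistics (the common "type 7" convention; configurable)
— the percentile-then-log and log-then-percentile orders agree exactly
whenever the percentile position lands on an order statistic.

Only `(x_m, s)` are estimated: bounded trust-region least squares with an
analytic Jacobian, `x_m` initialized at the intensity whose median
response is nearest the mid-level, `s` multi-started from {2, 5, 10} %MSO
within bounds [0.5, 50] %MSO (bound hits are flagged), tolerances 1e−12.
The fit is deterministic given identical inputs. R² is computed on the
median points — the quantity the optimizer actually sees — not on raw
trials. RMT_I-O is the closed-form inversion of the fitted sigmoid at
0.05 mV, `x_m − s·ln((y_h−y_l)/(y*−y_l) − 1)` with `y* = log10(0.05)`;
it requires `y_l < y* < y_h`, which is also enforced as a data-quality
gate on the asymptotes (a noise floor at or above 0.05 mV makes the
criterion meaningless).

The preliminary relative-frequency threshold (5 of 10 trials above
0.05 mV) is implemented as an ascending integer-%MSO sweep from a
configurable start — the search strategy is this package's choice, as
only the acceptance rule itself is standard.

Ingest clips non-positive recorded amplitudes at 1e−4 mV with a warning
(peak-to-peak EMG is never exactly zero; the log transform requires
positivity). Nominal intensity levels (80–164 %RMT) are carried as
metadata only; all fitting treats intensity as continuous %MSO.

## Strength–duration fitting

Given thresholds at ≥ 2 widths, the criterion
`J(V, tau) = Σ_p (V/(r_p·V_p) − 1)²` is minimized. For fixed `tau` the
optimal rheobase is the closed form `Σa_p / Σa_p²` with
`a_p = 1/(r_p V_p)`; the 1-D profile over `tau` is scanned on a 400-point
log grid over [50, 2000] μs and refined by bounded scalar minimization
(absolute tolerance 1e−8), which is deterministic and — verified against
exhaustive 2-D grids — globally correct for this objective. Optima pinned
at a `tau` bound are flagged rather than silently accepted. Three-width
fits leave a single residual degree of freedom, reported with each fit.
The criterion is scale-equivariant in the thresholds: scaling all
thresholds by c scales the rheobase by c and leaves the SDTC unchanged.

The shared-SDTC sensitivity mode minimizes the sum of per-subject
profiled objectives over one `tau` (inner rheobases still closed-form),
reducing exactly to the individual fit for a single subject.

A structural property worth knowing: with `tau` several times the longest
pulse width, the three factors respond almost proportionally to any
parameter change, so threshold noise moves the estimates along a strongly
anti-correlated (SDTC, rheobase) ridge. Per-subject scatter plots of
fitted SDTC against rheobase therefore show a steep negative relation
even when the generating parameters are uncorrelated; the package's tests
assert this artifact so that users do not over-interpret such plots as
physiology.

## Statistics

All mixed models are REML fits (statsmodels `MixedLM`) with subject
random intercepts; the threshold model offers random pulse-width slopes
(`random_slope=True`), falling back to intercepts with a flag if the
slope fit is singular. Fixed-effect contrasts use treatment coding with
placebo as reference; omnibus tests are Type III Wald F on sum-to-zero
coded terms. Denominator df follow the residual rule
`N_obs − rank(fixed design)` — 36 for the 13×3 scalar models, 108 for the
full threshold model, 72 for the difference model, 33 for the
SDTC–rheobase model. A Satterthwaite option was considered and not
implemented: the residual rule is the convention this design family's
reported df follow, and `MixedLM` does not expose the variance-parameter
information a principled small-sample correction needs. Cohen d is the
fixed-effect estimate divided by the model's residual SD. No
multiple-testing correction is applied.

Calibration (measured in the test suite): under the null, the condition
F-test with random intercepts *and width slopes* rejects at ≈ 5–6% at
nominal 5%. With intercepts only — the simpler default — subject × width
heterogeneity inflates the residual and the same test becomes extremely
conservative (essentially 0% rejections) while contrast estimates remain
unbiased; use `random_slope=True` whenever the omnibus F on thresholds
matters.

Drug-minus-placebo differences are computed per subject × width and
modelled in the same framework (condition × width fixed effects, subject
intercepts); the interaction term distinguishes a width-proportional
(multiplicative, rheobase-like) drug action from a width-flat one. The
SDTC–rheobase relationship is reported as per-condition OLS slopes plus a
combined mixed model with a condition × rheobase interaction.

## Synthetic cohorts

The generator emulates the study design: 13 subjects × 3 conditions ×
3 pulse widths × 11 intensity levels (80–164% of a preliminary RMT,
rounded to 1 %MSO, capped at the width's ceiling) × 10 trials. Subject
latents are drawn from a bivariate normal — rheobase 3.5 ± 0.7 %MSO,
SDTC 550 ± 120 μs, correlation 0 by default — chosen so that model
thresholds (≈ 66/34/18 %MSO at 30/60/120 μs) sit inside the device's
working range with the reported strength–duration profile. Subjects whose
thresholds would exceed a stimulator ceiling in any condition are
redrawn, mirroring device-limited recruitment; this mildly truncates the
upper rheobase tail. Each session: the true threshold comes from the
membrane model; a preliminary RMT adds ±2 %MSO uniform jitter (rounded to
the 1-%MSO device resolution); the generating sigmoid passes through
log10(0.05) exactly at the true threshold with subject-specific spread
(5 ± 1 %MSO) and asymptotes at the noise-floor median (0.01 mV,
geometric SD 1.3) and the subject's plateau (median 2 mV, geometric SD
1.4); trials add Gaussian noise (SD 0.25) on log10 amplitude, and the
recorded MEP is the max of the sigmoid draw and an independent
noise-floor draw — sub-threshold trials record background EMG, which is
what gives the P10/P90 asymptote rule its meaning. One master seed fans
out into per-session streams, so any subset is reproducible in
isolation and identical seeds give byte-identical tables.

Drug effects perturb the latents per condition: additive rheobase/SDTC
shifts, multiplicative threshold scaling, and a width-flat threshold
shift. The flat shift needs a word of explanation. In the `tau ≫ t_p`
regime both rheobase and SDTC move thresholds near-proportionally across
widths, so *no fixed* parameter shift produces a width-independent
threshold change — yet the flat pattern is precisely the lacosamide-like
signature the analysis must distinguish from carbamazepine-like
proportional scaling. The generator therefore applies the flat shift to
the subject's model thresholds and projects back onto the membrane model
by least squares (residuals ~1e−6), giving each subject their own
rheobase-increase/SDTC-reduction pair that generates the shift exactly.
Defaults: carbamazepine = ×1.15 threshold scaling (SDTC untouched);
lacosamide = flat +2 %MSO (at the mean subject this projects to roughly
rheobase +3.5 %MSO, SDTC −275 μs); placebo = identity.

What the generator does **not** emulate: raw EMG traces and their
windowing, MEP latencies, intensity-order effects and hysteresis,
within-session drift or fatigue, pharmacokinetic time courses, hotspot
relocation error, and any trial-to-trial correlation. Trial variability
is lognormal by assumption — the real distribution is unspecified in the
literature this emulates — and is configurable. Passing recovery tests
therefore show the estimation chain is correct and well-calibrated for
data with this statistical structure; they do not certify accuracy under
EMG artifacts or non-lognormal MEP variability.

## Accuracy of 3-width SDTC estimation

Measured across 50 seeded default cohorts (1950 subject × condition
fits), the median absolute estimation error is ≈ 16–17% for the SDTC and
≈ 16% for the rheobase, with errors strongly anti-correlated
(r ≈ −0.8) along the estimation ridge. Roughly decomposed: intensity
rounding/ceiling capping alone contributes ~1%, the noise-floor ×
percentile-asymptote convention ~5% (the P10-of-noise lower asymptote
sits below the effective floor of max(signal, noise) data, a bias
inherent to the published estimation convention, not to this
implementation), trial noise alone ~9%, and their interaction the rest.
Noise-free cohorts recover both parameters to < 1e−6 relative error, so
the error is a property of the measurement design (3 widths, 10 trials,
EMG floor close to the 0.05 mV criterion), not of the optimizer.
Condition *contrasts* are far better behaved than per-subject estimates,
because the bias components are shared across conditions.

## Degenerate inputs and tie-breaking

Sessions whose intensity levels collapse below 3 distinct values (ceiling
capping) are skipped with a warning rather than aborting the table.
Sigmoid fits hitting the spread bounds and SDTC fits pinned at the τ
bounds are flagged in their result objects. The grid-then-refine
optimizer accepts the refinement only if it does not exceed the best grid
node, making results independent of optimizer internals; multi-starts
are evaluated in a fixed order with strict improvement, so ties resolve
deterministically.
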