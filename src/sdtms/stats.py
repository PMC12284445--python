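"""Mixed-effects statistics for the crossover pharmaco-TMS design.

Linear mixed-effects models (REML, via statsmodels ``MixedLM``) with
subject random intercepts quantify drug effects on motor thresholds,
SDTC and rheobase.  The layer reports:

* placebo-referenced fixed-effect contrasts (estimate, SE, t, df, p and
  Cohen d = estimate / residual SD),
* omnibus Type III F-tests per fixed-effect term (Wald F on sum-to-zero
  coded terms),
* per-pulse-width drug-minus-placebo threshold differences with the
  condition x width interaction tested on the differences, and
* the SDTC-rheobase relationship: per-condition OLS regressions plus a
  combined mixed model with a condition x rheobase interaction.

Denominator degrees of freedom use the residual rule
``df = N_obs - rank(fixed design)`` (39 - 3 = 36 for scalar outcomes,
117 - 9 = 108 for the threshold model in the full balanced design),
the convention the reported df of this design family follow.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import DataQualityError

__all__ = [
    "EffectEstimate",
    "AnovaRow",
    "MixedModelResult",
    "cohen_d",
    "fit_lme_rmt",
    "fit_lme_scalar",
    "placebo_differences",
    "sdtc_rheobase_relationship",
]


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect contrast (estimate, SE, t, df, p, Cohen d)."""

    term: str
    estimate: float
    se: float
    t: float
    df: int
    p: float
    cohen_d: float

    def __post_init__(self):
        if self.se <= 0:
            raise DataQualityError(f"{self.term}: SE must be > 0")

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "estimate": self.estimate,
            "se": self.se,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "cohen_d": self.cohen_d,
        }

    def format(self) -> str:
        return (
            f"{self.term}: estimate = {self.estimate:.3g}, SE = {self.se:.3g}, "
            f"t[{self.df}] = {self.t:.2f}, p = {self.p:.3g}, Cohen d = {self.cohen_d:.2f}"
        )


@dataclass(frozen=True)
class AnovaRow:
    """One omnibus F-test on a fixed-effect term."""

    effect: str
    df_num: int
    df_den: int
    F: float
    p: float

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "F": self.F,
            "p": self.p,
        }

    def format(self) -> str:
        return f"{self.effect}: F[{self.df_num},{self.df_den}] = {self.F:.2f}, p = {self.p:.3g}"


@dataclass
class MixedModelResult:
    """Bundle of contrasts, ANOVA rows and diagnostics from one model."""

    effects: list[EffectEstimate]
    anova: list[AnovaRow]
    residual_sd: float
    n_obs: int
    description: str = ""
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "description": self.description,
            "n_obs": self.n_obs,
            "residual_sd": self.residual_sd,
            "effects": [e.to_dict() for e in self.effects],
            "anova": [a.to_dict() for a in self.anova],
            "flags": list(self.flags),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def effect(self, substring: str) -> EffectEstimate:
        """First contrast whose term label contains ``substring``."""
        for e in self.effects:
            if substring in e.term:
                return e
        raise KeyError(substring)

    def anova_row(self, substring: str) -> AnovaRow:
        for a in self.anova:
            if substring in a.effect:
                return a
        raise KeyError(substring)

    def summary(self) -> str:
        lines = [self.description, "-" * len(self.description)]
        lines += ["ANOVA (Type III, residual-df denominator):"]
        lines += ["  " + a.format() for a in self.anova]
        lines += ["Fixed-effect contrasts:"]
        lines += ["  " + e.format() for e in self.effects]
        lines += [f"Residual SD = {self.residual_sd:.4g} on {self.n_obs} observations"]
        if self.flags:
            lines += ["Flags: " + "; ".join(self.flags)]
        return "\n".join(lines)


def cohen_d(estimate: float, residual_sd: float) -> float:
    """Effect size: fixed-effect estimate over the model's residual SD."""
    if residual_sd <= 0:
        raise DataQualityError("residual SD must be > 0")
    return estimate / residual_sd


def _fit_mixedlm(formula, data, re_formula=None, groups="subject_id"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
        try:
            res = model.fit(reml=True, method="lbfgs")
        except Exception:
            res = model.fit(reml=True)
    return res


def _singular_re(res) -> bool:
    try:
        cov = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        return (not np.all(np.isfinite(cov))) or np.linalg.cond(cov) > 1e10 or np.any(
            np.diag(cov) < 1e-12 * res.scale
        )
    except Exception:
        return True


def _residual_df(data, fixed_formula) -> int:
    X = patsy.dmatrix(fixed_formula, data, return_type="dataframe")
    return len(data) - int(np.linalg.matrix_rank(np.asarray(X)))


def _wald_anova(res, term_slices, df_den) -> list[AnovaRow]:
    """Type III Wald F per term from the fixed-effects covariance."""
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(params), : len(params)]
    rows = []
    for name, idx in term_slices:
        L = np.zeros((len(idx), len(params)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        lb = L @ params
        lcov = L @ cov @ L.T
        stat = float(lb @ np.linalg.solve(lcov, lb))
        q = len(idx)
        F = stat / q
        p = float(sps.f.sf(F, q, df_den))
        rows.append(AnovaRow(effect=name, df_num=q, df_den=df_den, F=max(F, 0.0), p=p))
    return rows


def _term_slices(design_info, skip_intercept=True):
    out = []
    for term, sl in design_info.term_name_slices.items():
        if skip_intercept and term == "Intercept":
            continue
        out.append((term, list(range(sl.start, sl.stop))))
    return out


def _contrasts(res, df_den, residual_sd, keep=None) -> list[EffectEstimate]:
    effects = []
    fe = res.fe_params
    se = np.sqrt(np.diag(np.asarray(res.cov_params())[: len(fe), : len(fe)]))
    for i, name in enumerate(fe.index):
        if keep is not None and not keep(name):
            continue
        est = float(fe.iloc[i])
        s = float(se[i])
        t = est / s
        p = float(2.0 * sps.t.sf(abs(t), df_den))
        effects.append(
            EffectEstimate(
                term=name,
                estimate=est,
                se=s,
                t=t,
                df=df_den,
                p=p,
                cohen_d=cohen_d(est, residual_sd),
            )
        )
    return effects


def _clean_labels(effects: list[EffectEstimate]) -> list[EffectEstimate]:
    def clean(term: str) -> str:
        return (
            term.replace("C(condition, Treatment('placebo'))", "condition")
            .replace("C(condition, Sum)", "condition")
            .replace("C(pulse_width_us, Sum)", "pulse_width")
            .replace("C(pulse_width_us)", "pulse_width")
            .replace("[T.", "[")
        )

    return [
        EffectEstimate(
            term=clean(e.term),
            estimate=e.estimate,
            se=e.se,
            t=e.t,
            df=e.df,
            p=e.p,
            cohen_d=e.cohen_d,
        )
        for e in effects
    ]


def _clean_anova(rows: list[AnovaRow]) -> list[AnovaRow]:
    def clean(name: str) -> str:
        return (
            name.replace("C(condition, Sum)", "condition")
            .replace("C(pulse_width_us, Sum)", "pulse_width")
            .replace(":", " x ")
        )

    return [
        AnovaRow(effect=clean(r.effect), df_num=r.df_num, df_den=r.df_den, F=r.F, p=r.p)
        for r in rows
    ]


def _check_design(data: pd.DataFrame, cols: list[str], min_subjects: int = 5):
    if data["subject_id"].nunique() < min_subjects:
        raise DataQualityError(f"need >= {min_subjects} subjects")
    counts = data.groupby(cols).size()
    if (counts == 0).any():
        raise DataQualityError("design has empty cells")


def fit_lme_rmt(
    table: pd.DataFrame,
    reference: str = "placebo",
    random_slope: bool = False,
    df_method: str = "residual",
) -> MixedModelResult:
    """Mixed model of RMT_I-O on condition x pulse width.

    ``table`` is tidy with columns subject_id, condition, pulse_width_us,
    rmt_io.  Fixed effects: condition, pulse width and their interaction;
    random effects: subject intercepts (optionally width slopes, refit
    without them if singular).  Returns Type III omnibus F-tests and
    treatment-coded contrasts against ``reference``.
    """
    if df_method != "residual":
        raise ValueError("df_method: only the residual rule is implemented")
    data = table.copy()
    required = {"subject_id", "condition", "pulse_width_us", "rmt_io"}
    if not required.issubset(data.columns):
        raise DataQualityError(f"rmt table missing column(s): {sorted(required - set(data.columns))}")
    _check_design(data, ["condition", "pulse_width_us"])
    flags = []

    treat = f"rmt_io ~ C(condition, Treatment('{reference}')) * C(pulse_width_us)"
    sum_f = "rmt_io ~ C(condition, Sum) * C(pulse_width_us, Sum)"
    re_formula = "~C(pulse_width_us)" if random_slope else None
    res_t = _fit_mixedlm(treat, data, re_formula=re_formula)
    if random_slope and _singular_re(res_t):
        flags.append("random-slope fit singular; refit with intercept-only random effects")
        re_formula = None
        res_t = _fit_mixedlm(treat, data)
    res_s = _fit_mixedlm(sum_f, data, re_formula=re_formula)

    fixed_rhs = treat.split("~", 1)[1]
    df_den = _residual_df(data, fixed_rhs)
    residual_sd = float(np.sqrt(res_t.scale))
    X_s = patsy.dmatrix(sum_f.split("~", 1)[1], data, return_type="dataframe")
    anova = _wald_anova(res_s, _term_slices(X_s.design_info), df_den)
    keep = lambda name: name != "Intercept" and "Group" not in name
    effects = _contrasts(res_t, df_den, residual_sd, keep=keep)
    return MixedModelResult(
        effects=_clean_labels(effects),
        anova=_clean_anova(anova),
        residual_sd=residual_sd,
        n_obs=len(data),
        description=f"RMT_I-O ~ condition * pulse width (+ subject random "
        f"{'intercept+slope' if re_formula else 'intercept'}), reference = {reference}",
        flags=flags,
    )


def fit_lme_scalar(
    values: pd.DataFrame,
    outcome: str,
    reference: str = "placebo",
) -> MixedModelResult:
    """Mixed model of one scalar per subject x condition (SDTC or rheobase).

    Condition fixed effect with subject random intercepts; placebo-
    referenced contrasts with Cohen d, plus the omnibus condition F-test.
    Subjects with missing cells are dropped listwise with a warning.
    """
    required = {"subject_id", "condition", outcome}
    if not required.issubset(values.columns):
        raise DataQualityError(
            f"table missing column(s): {sorted(required - set(values.columns))}"
        )
    data = values.dropna(subset=[outcome]).copy()
    n_cond = data["condition"].nunique()
    complete = data.groupby("subject_id")["condition"].nunique() == n_cond
    if not complete.all():
        dropped = complete.index[~complete].tolist()
        warnings.warn(f"dropping subject(s) with missing cells: {dropped}", stacklevel=2)
        data = data[data["subject_id"].isin(complete.index[complete])]
    if data["subject_id"].nunique() < 2:
        raise DataQualityError("need >= 2 complete subjects")

    treat = f"{outcome} ~ C(condition, Treatment('{reference}'))"
    sum_f = f"{outcome} ~ C(condition, Sum)"
    res_t = _fit_mixedlm(treat, data)
    res_s = _fit_mixedlm(sum_f, data)
    df_den = _residual_df(data, treat.split("~", 1)[1])
    residual_sd = float(np.sqrt(res_t.scale))
    X_s = patsy.dmatrix(sum_f.split("~", 1)[1], data, return_type="dataframe")
    anova = _wald_anova(res_s, _term_slices(X_s.design_info), df_den)
    keep = lambda name: name != "Intercept" and "Group" not in name
    effects = _contrasts(res_t, df_den, residual_sd, keep=keep)
    return MixedModelResult(
        effects=_clean_labels(effects),
        anova=_clean_anova(anova),
        residual_sd=residual_sd,
        n_obs=len(data),
        description=f"{outcome} ~ condition (+ subject random intercept), "
        f"reference = {reference}",
    )


def placebo_differences(
    table: pd.DataFrame, reference: str = "placebo"
) -> tuple[pd.DataFrame, MixedModelResult]:
    """Per-subject drug-minus-placebo threshold differences by pulse width.

    Returns the tidy difference table (subject_id, condition,
    pulse_width_us, diff_rmt_io) and a mixed model of the differences with
    condition, width and their interaction as fixed effects — the
    interaction tests whether a drug's threshold shift scales with pulse
    width (multiplicative, rheobase-like action) or is flat across widths.
    """
    required = {"subject_id", "condition", "pulse_width_us", "rmt_io"}
    if not required.issubset(table.columns):
        raise DataQualityError(f"rmt table missing column(s): {sorted(required - set(table.columns))}")
    wide = table.pivot_table(
        index=["subject_id", "pulse_width_us"], columns="condition", values="rmt_io"
    )
    if reference not in wide.columns:
        raise DataQualityError(f"reference condition {reference!r} absent")
    incomplete = wide[reference].isna()
    if incomplete.any():
        warnings.warn(
            f"excluding {int(incomplete.sum())} subject x width cell(s) lacking {reference}",
            stacklevel=2,
        )
        wide = wide[~incomplete]
    drugs = [c for c in wide.columns if c != reference]
    rows = []
    for drug in drugs:
        d = wide[drug] - wide[reference]
        for (subj, width), val in d.dropna().items():
            rows.append(
                {
                    "subject_id": subj,
                    "condition": drug,
                    "pulse_width_us": width,
                    "diff_rmt_io": val,
                }
            )
    diffs = pd.DataFrame(rows)

    sum_f = "diff_rmt_io ~ C(condition, Sum) * C(pulse_width_us, Sum)"
    treat = f"diff_rmt_io ~ C(condition, Treatment('{drugs[0]}')) * C(pulse_width_us)"
    res_s = _fit_mixedlm(sum_f, diffs)
    res_t = _fit_mixedlm(treat, diffs)
    df_den = _residual_df(diffs, sum_f.split("~", 1)[1])
    residual_sd = float(np.sqrt(res_s.scale))
    X_s = patsy.dmatrix(sum_f.split("~", 1)[1], diffs, return_type="dataframe")
    anova = _wald_anova(res_s, _term_slices(X_s.design_info), df_den)
    keep = lambda name: name != "Intercept" and "Group" not in name
    effects = _contrasts(res_t, df_den, residual_sd, keep=keep)
    result = MixedModelResult(
        effects=_clean_labels(effects),
        anova=_clean_anova(anova),
        residual_sd=residual_sd,
        n_obs=len(diffs),
        description="drug-minus-placebo RMT_I-O differences ~ condition * pulse width "
        "(+ subject random intercept)",
    )
    return diffs, result


def sdtc_rheobase_relationship(
    fits: pd.DataFrame, reference: str = "placebo"
) -> tuple[pd.DataFrame, MixedModelResult]:
    """SDTC as a function of rheobase, per condition and combined.

    ``fits`` is tidy with columns subject_id, condition, sdtc_us,
    rheobase_pct_mso.  Returns per-condition OLS slopes (with R^2) and a
    combined mixed model ``sdtc ~ rheobase * condition`` with subject
    random intercepts; the interaction terms test condition-specific
    slopes.
    """
    required = {"subject_id", "condition", "sdtc_us", "rheobase_pct_mso"}
    if not required.issubset(fits.columns):
        raise DataQualityError(f"fit table missing column(s): {sorted(required - set(fits.columns))}")
    data = fits.copy()
    slopes = []
    for cond, grp in data.groupby("condition", sort=True):
        if grp["rheobase_pct_mso"].nunique() < 2:
            raise DataQualityError(f"degenerate rheobase variance in condition {cond}")
        ols = smf.ols("sdtc_us ~ rheobase_pct_mso", grp).fit()
        slopes.append(
            {
                "condition": cond,
                "slope_us_per_pct": float(ols.params["rheobase_pct_mso"]),
                "intercept_us": float(ols.params["Intercept"]),
                "r_squared": float(ols.rsquared),
                "p": float(ols.pvalues["rheobase_pct_mso"]),
                "n": int(ols.nobs),
            }
        )
    slopes = pd.DataFrame(slopes)

    formula = f"sdtc_us ~ rheobase_pct_mso * C(condition, Treatment('{reference}'))"
    res = _fit_mixedlm(formula, data)
    df_den = _residual_df(data, formula.split("~", 1)[1])
    residual_sd = float(np.sqrt(res.scale))
    keep = lambda name: "Group" not in name  # keep the intercept: placebo SDTC at rheobase 0
    effects = _contrasts(res, df_den, residual_sd, keep=keep)
    result = MixedModelResult(
        effects=_clean_labels(effects),
        anova=[],
        residual_sd=residual_sd,
        n_obs=len(data),
        description="SDTC ~ rheobase * condition (+ subject random intercept), "
        f"reference = {reference}",
    )
    return slopes, result
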