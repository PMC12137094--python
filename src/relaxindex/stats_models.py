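"""Linear mixed-effects analysis of RI and BCVA.

The displacement response is analyzed with the timepoint pair as a discrete
fixed effect and nested random intercepts — one per eye and one per marker
within eye — to absorb the correlation of repeated measurements on the same
eye and the same vessel crossing:

    d ~ pair + (1 | eye) + (1 | eye:marker)

BCVA (decimal units) uses the same structure with only the per-eye random
intercept, and the RI-BCVA association model treats RI as a continuous
fixed effect.  Fits are REML by default (statsmodels ``MixedLM``, with the
marker-in-eye intercept expressed as a variance component inside the eye
group).  Fixed-effect inference uses Wald z statistics: with 9 eyes the
residual degrees of freedom are large enough that the normal approximation
is the pragmatic choice, and boundary (singular) fits are reported as
states rather than raised.

Post-hoc pairwise comparisons between levels are Wald contrasts of the
fitted level means with step-down Bonferroni-Holm adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import ModelSpecError, ParameterError

__all__ = [
    "MixedModelResult",
    "PairwiseComparison",
    "fit_ri_model",
    "fit_bcva_model",
    "pairwise_posthoc",
    "holm_adjust",
    "ri_bcva_association",
    "decimal_to_logmar",
]


@dataclass
class FixedEffect:
    level: str
    estimate: float
    se: float
    df: float
    p: float


@dataclass
class PairwiseComparison:
    level_a: str
    level_b: str
    estimate: float
    se: float
    raw_p: float
    adjusted_p: float | None = None


@dataclass
class MixedModelResult:
    """Fitted mixed model: level means, variance components, post-hoc."""

    fixed_effects: dict[str, FixedEffect]
    variance_components: dict[str, float]
    pairwise: list[PairwiseComparison]
    converged: bool
    singular: bool
    n_obs: int
    # internals for contrast computation
    _levels: list[str] = field(default_factory=list, repr=False)
    _level_means: np.ndarray | None = field(default=None, repr=False)
    _level_cov: np.ndarray | None = field(default=None, repr=False)
    _df_contrast: float = field(default=np.inf, repr=False)


def holm_adjust(p_values) -> list[float]:
    """Step-down Bonferroni-Holm adjustment, returned in input order.

    For sorted p-values p(1) <= ... <= p(m), the adjusted value is the
    running maximum of (m - i + 1) * p(i), capped at 1; the running maximum
    enforces monotonicity.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj.tolist()


def _validate_design(table: pd.DataFrame, factor: str, require_marker: bool) -> None:
    if table[factor].nunique() < 2:
        raise ModelSpecError(f"need >= 2 levels of {factor!r}, "
                             f"got {sorted(table[factor].unique())}")
    if table["eye_id"].nunique() < 2:
        raise ModelSpecError("need >= 2 eyes")
    if require_marker:
        per_eye = table.groupby("eye_id")["marker_id"].nunique()
        if (per_eye < 2).any():
            raise ModelSpecError("need >= 2 markers per eye")


def _wald_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * sps.norm.sf(np.abs(z))


def _satterthwaite_level_df(vcs: dict[str, float], n_eyes: int, n_units: int,
                            n_obs: int, n_levels: int) -> tuple[float, float]:
    """Approximate df for level means and level contrasts.

    Treats the design as (near-)balanced: the variance of a level mean
    decomposes into eye, unit-in-eye (marker) and residual contributions
    with classical ANOVA degrees of freedom, combined Satterthwaite-style.
    Random intercepts cancel in level differences, so contrasts carry the
    residual df.  ``n_units`` is the number of (eye, marker) cells (equals
    ``n_eyes`` when there is no marker term).
    """
    df_eye = max(n_eyes - 1, 1)
    df_unit = max(n_units - n_eyes, 1)
    df_resid = max(n_obs - n_units - (n_levels - 1), 1)
    a_eye = vcs.get("eye", 0.0) / n_eyes
    a_unit = vcs.get("marker_in_eye", 0.0) / max(n_units, 1)
    a_resid = vcs.get("residual", 0.0) / max(n_units, 1)
    num = (a_eye + a_unit + a_resid) ** 2
    den = (a_eye ** 2 / df_eye + a_unit ** 2 / df_unit + a_resid ** 2 / df_resid)
    df_mean = num / den if den > 0 else np.inf
    return float(df_mean), float(df_resid)


def _level_design(levels: list[str], fe_names: list[str], factor: str) -> np.ndarray:
    """Rows mapping the fixed-effect parameter vector to level means."""
    L = np.zeros((len(levels), len(fe_names)))
    for i, lev in enumerate(levels):
        for j, name in enumerate(fe_names):
            if name == "Intercept":
                L[i, j] = 1.0
            elif name == f"C({factor})[T.{lev}]":
                L[i, j] = 1.0
    return L


def _degenerate_result(table: pd.DataFrame, response: str, factor: str,
                       vc_names: tuple[str, ...]) -> MixedModelResult:
    """Boundary fallback: per-level means with zero variance components.

    Used when the mixed fit is numerically impossible (e.g. an exactly
    noise-free response); the level means remain the least-squares answer.
    """
    levels = sorted(table[factor].astype(str).unique())
    means = table.groupby(factor)[response].mean()
    resid = table[response] - table[factor].map(means)
    sigma2 = float((resid ** 2).mean())
    fe = {lev: FixedEffect(lev, float(means[lev]), 0.0, np.inf,
                           0.0 if means[lev] != 0 else 1.0)
          for lev in levels}
    vcs = {name: 0.0 for name in vc_names}
    vcs["residual"] = sigma2
    result = MixedModelResult(
        fixed_effects=fe, variance_components=vcs, pairwise=[],
        converged=True, singular=True, n_obs=len(table),
        _levels=levels,
        _level_means=means.loc[levels].to_numpy(float),
        _level_cov=np.zeros((len(levels), len(levels))),
    )
    result.pairwise = pairwise_posthoc(result)
    return result


def _fit_factor_model(
    table: pd.DataFrame,
    response: str,
    factor: str,
    nested_marker: bool,
    reml: bool = True,
) -> MixedModelResult:
    table = table.copy()
    table[factor] = table[factor].astype(str)
    vc_names = ("eye", "marker_in_eye") if nested_marker else ("eye",)
    levels = sorted(table[factor].unique())

    vc = {"marker": "0 + C(marker_id)"} if nested_marker else None
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(
                f"{response} ~ C({factor})",
                data=table,
                groups=table["eye_id"],
                re_formula="1",
                vc_formula=vc,
            )
            res = model.fit(reml=reml)
        singular = any("singular" in str(w.message).lower() for w in caught)
        converged = bool(res.converged)
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        return _degenerate_result(table, response, factor, vc_names)

    fe_names = list(res.fe_params.index)
    fe_params = res.fe_params.to_numpy(float)
    cov_fe = np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)]
    L = _level_design(levels, fe_names, factor)
    means = L @ fe_params
    cov_means = L @ cov_fe @ L.T
    ses = np.sqrt(np.clip(np.diag(cov_means), 0.0, None))

    vcs = {"eye": float(max(res.cov_re.iloc[0, 0], 0.0))}
    if nested_marker:
        vcs["marker_in_eye"] = float(max(res.vcomp[0], 0.0)) if len(res.vcomp) else 0.0
    vcs["residual"] = float(res.scale)
    # a variance component estimated at (numerically) zero is a boundary fit
    singular = singular or any(v < 1e-10 * max(vcs["residual"], 1e-300)
                               for k, v in vcs.items() if k != "residual")

    n_eyes = table["eye_id"].nunique()
    n_units = (table.groupby("eye_id")["marker_id"].nunique().sum()
               if nested_marker else n_eyes)
    df_mean, df_contrast = _satterthwaite_level_df(
        vcs, n_eyes, int(n_units), len(table), len(levels))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ses > 0, means / ses, np.inf)
    ps = 2.0 * sps.t.sf(np.abs(t), df_mean)

    fixed = {
        lev: FixedEffect(lev, float(means[i]), float(ses[i]), df_mean, float(ps[i]))
        for i, lev in enumerate(levels)
    }

    result = MixedModelResult(
        fixed_effects=fixed, variance_components=vcs, pairwise=[],
        converged=converged, singular=singular, n_obs=len(table),
        _levels=levels, _level_means=means, _level_cov=cov_means,
        _df_contrast=df_contrast,
    )
    result.pairwise = pairwise_posthoc(result)
    return result


def fit_ri_model(table: pd.DataFrame, response: str = "d_total_mm",
                 factor: str = "pair", reml: bool = True) -> MixedModelResult:
    """REML fit of ``response ~ pair + (1|eye) + (1|eye:marker)``.

    ``table`` is the tidy per-marker displacement table (columns ``eye_id``,
    ``marker_id``, ``pair``, ``d_total_mm``).  Returns level means (not
    treatment contrasts), variance components for eye, marker-in-eye and
    residual, and Holm-adjusted pairwise level comparisons.  Singular or
    non-converged fits are flagged on the result, not raised.
    """
    _validate_design(table, factor, require_marker=True)
    return _fit_factor_model(table, response, factor, nested_marker=True, reml=reml)


def fit_bcva_model(bcva_table: pd.DataFrame, response: str = "bcva_decimal",
                   factor: str = "timepoint", reml: bool = True) -> MixedModelResult:
    """REML fit of ``bcva ~ timepoint + (1|eye)`` on the decimal-BCVA table."""
    _validate_design(bcva_table, factor, require_marker=False)
    return _fit_factor_model(bcva_table, response, factor, nested_marker=False, reml=reml)


def pairwise_posthoc(result: MixedModelResult) -> list[PairwiseComparison]:
    """All pairwise level contrasts with Holm-adjusted Wald p-values."""
    levels = result._levels
    if len(levels) < 2:
        raise ModelSpecError("post-hoc requires >= 2 fixed-effect levels")
    if result._level_means is None or result._level_cov is None:
        raise ModelSpecError("model result lacks a level-mean covariance")
    means, cov = result._level_means, result._level_cov
    comps: list[PairwiseComparison] = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        est = float(means[i] - means[j])
        var = float(cov[i, i] + cov[j, j] - 2 * cov[i, j])
        se = float(np.sqrt(max(var, 0.0)))
        if se > 0:
            p = float(2.0 * sps.t.sf(abs(est / se), result._df_contrast))
        else:
            p = 1.0 if est == 0 else 0.0
        comps.append(PairwiseComparison(levels[i], levels[j], est, se, p))
    adjusted = holm_adjust([c.raw_p for c in comps])
    for c, a in zip(comps, adjusted):
        c.adjusted_p = float(a)
    return comps


@dataclass
class AssociationResult:
    """Slope of BCVA on RI from the continuous-fixed-effect mixed model."""

    slope: float
    se: float
    p: float
    n_obs: int
    converged: bool
    preop_only: bool


def ri_bcva_association(joint_table: pd.DataFrame, preop_only: bool = False,
                        reml: bool = True) -> AssociationResult:
    """Mixed model ``bcva ~ ri_mm + (1|eye)`` testing the RI-BCVA link.

    ``preop_only`` restricts to the pre-operative timepoints (T1, T2),
    mirroring the subgroup analysis of the clinical question.
    """
    df = joint_table.copy()
    if preop_only:
        df = df[df["timepoint"].isin(["T1", "T2"])]
    if df["ri_mm"].nunique() < 3:
        raise ModelSpecError("need >= 3 distinct RI values for the association model")
    if np.isclose(df["bcva_decimal"].var(ddof=0), 0.0):
        # no response variance: the slope is exactly zero, with no evidence
        return AssociationResult(0.0, 0.0, 1.0, len(df), True, preop_only)
    try:
        model = smf.mixedlm("bcva_decimal ~ ri_mm", data=df,
                            groups=df["eye_id"], re_formula="1")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=reml)
        slope = float(res.fe_params["ri_mm"])
        se = float(res.bse_fe["ri_mm"])
        p = float(_wald_p(np.array([slope / se]))[0]) if se > 0 else 1.0
        return AssociationResult(slope, se, p, len(df), bool(res.converged), preop_only)
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        ols = smf.ols("bcva_decimal ~ ri_mm", data=df).fit()
        slope = float(ols.params["ri_mm"])
        se = float(ols.bse["ri_mm"])
        p = float(ols.pvalues["ri_mm"]) if np.isfinite(ols.pvalues["ri_mm"]) else 1.0
        return AssociationResult(slope, se, p, len(df), False, preop_only)


def decimal_to_logmar(bcva_decimal) -> np.ndarray:
    """Convert decimal visual acuity to logMAR (= -log10 decimal)."""
    v = np.asarray(bcva_decimal, dtype=float)
    if np.any(v <= 0):
        raise ParameterError("decimal BCVA must be strictly positive")
    return -np.log10(v)


def result_to_dict(result: MixedModelResult) -> dict:
    """JSON-serializable report of a fitted mixed model."""
    return {
        "fixed_effects": {
            lev: {"estimate": fe.estimate, "se": fe.se, "p": fe.p}
            for lev, fe in result.fixed_effects.items()
        },
        "variance_components": result.variance_components,
        "pairwise": [
            {"levels": [c.level_a, c.level_b], "estimate": c.estimate,
             "se": c.se, "raw_p": c.raw_p, "adjusted_p": c.adjusted_p}
            for c in result.pairwise
        ],
        "converged": result.converged,
        "singular": result.singular,
        "n_obs": result.n_obs,
    }
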