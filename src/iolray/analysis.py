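"""Refractive prediction-error computation and the cohort-level
statistical comparison of IOL power calculation methods.

The prediction error (PE) of a formula for one eye is the predicted
minus the observed postoperative spherical-equivalent refraction; the
absolute error (AE) is its magnitude.  Formulas are compared with a
linear mixed model on AE (formula as fixed effect, patient-level random
intercept, Bonferroni-corrected pairwise contrasts), Levene's test for
variance heterogeneity of the PE, and GEE logistic models for the
within-threshold proportions, clustered on patient to respect the
correlation between fellow eyes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, EmptyGroupError

AL_BIN_LABELS = ["<22", "22-24", "24-26", "26-30", ">30"]
THRESHOLDS = (0.25, 0.50, 1.00)


def compute_pe(predicted_se: float, actual_se: float) -> float:
    """Prediction error: predicted minus actual postoperative SE, D."""
    if not (math.isfinite(predicted_se) and math.isfinite(actual_se)):
        raise ValueError("refractions must be finite")
    return predicted_se - actual_se


def assign_al_bin(al: float) -> str:
    """Axial-length subgroup: half-open bins [22,24), [24,26), [26,30)
    with open ends below 22 and at/above 30 mm."""
    if al < 22:
        return "<22"
    if al < 24:
        return "22-24"
    if al < 26:
        return "24-26"
    if al < 30:
        return "26-30"
    return ">30"


@dataclass(frozen=True)
class ErrorSummary:
    """Per-formula distribution summary of PE and AE plus the share of
    eyes within each refraction threshold."""

    n: int
    mean_pe: float
    sd_pe: float
    median_pe: float
    range_pe: tuple[float, float]
    mean_ae: float
    sd_ae: float
    median_ae: float
    range_ae: tuple[float, float]
    pct_within: dict[float, float]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["range_pe"] = list(d["range_pe"])
        d["range_ae"] = list(d["range_ae"])
        d["pct_within"] = {f"{t:.2f}": v for t, v in d["pct_within"].items()}
        return d


def summarize_errors(pe: Sequence[float],
                     thresholds: Iterable[float] = THRESHOLDS
                     ) -> ErrorSummary:
    """Summarize one formula's prediction errors.

    Standard deviations use the n-1 denominator; the within-threshold
    counts are inclusive (``ae <= t``) and reported as percentages
    rounded to 2 decimals.
    """
    pe = np.asarray(list(pe), dtype=float)
    if pe.size == 0:
        raise EmptyGroupError("cannot summarize an empty error group")
    ae = np.abs(pe)
    sd = float(pe.std(ddof=1)) if pe.size > 1 else 0.0
    sd_ae = float(ae.std(ddof=1)) if pe.size > 1 else 0.0
    pct = {float(t): round(float((ae <= t).mean() * 100.0), 2)
           for t in thresholds}
    return ErrorSummary(
        n=int(pe.size),
        mean_pe=float(pe.mean()), sd_pe=sd, median_pe=float(np.median(pe)),
        range_pe=(float(pe.min()), float(pe.max())),
        mean_ae=float(ae.mean()), sd_ae=sd_ae,
        median_ae=float(np.median(ae)),
        range_ae=(float(ae.min()), float(ae.max())),
        pct_within=pct)


def _containment_df(n_obs: int, n_groups: int, k_fixed: int) -> float:
    """Denominator degrees of freedom for mixed-model contrasts: the
    between-within (containment) rule ``N - n_groups - rank(X) + 1``,
    which reduces to the paired-t df for a balanced two-condition
    within-subject design."""
    return max(float(n_obs - n_groups - k_fixed + 1), 1.0)


def compare_mae_mixed(errors: pd.DataFrame, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """All pairwise formula contrasts of the absolute error from a linear
    mixed model with a patient-level random intercept.

    ``errors`` is a long table with columns ``patient_id``, ``formula``
    and ``ae``; every eye must be evaluated by every formula.  Returns a
    contrast table with the estimate (row formula minus column formula),
    SE, t, df, raw and Bonferroni-adjusted p (family = all C(k,2) pairs)
    and the confidence interval.
    """
    import statsmodels.formula.api as smf

    required = {"patient_id", "formula", "ae"}
    if not required.issubset(errors.columns):
        raise ContractError(f"errors table needs columns {sorted(required)}")
    formulas = sorted(errors["formula"].unique())
    k = len(formulas)
    if k < 2:
        raise ContractError("need at least two formulas to compare")
    counts = errors.groupby("formula").size()
    if counts.nunique() != 1:
        raise ContractError(
            "non-crossed design: every eye must be evaluated by every "
            f"formula (group sizes {counts.to_dict()})")

    m = k * (k - 1) // 2
    n_obs = len(errors)
    n_groups = errors["patient_id"].nunique()
    df_den = _containment_df(n_obs, n_groups, k)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("ae ~ C(formula)", errors,
                            groups=errors["patient_id"])
        fit = model.fit(reml=True)

    names = list(fit.fe_params.index)
    beta = fit.fe_params.to_numpy()
    cov = fit.cov_params().loc[names, names].to_numpy()

    def coef_vector(f: str) -> np.ndarray:
        c = np.zeros(len(names))
        term = f"C(formula)[T.{f}]"
        if term in names:
            c[names.index(term)] = 1.0
        return c

    rows = []
    for fa, fb in combinations(formulas, 2):
        c = coef_vector(fa) - coef_vector(fb)
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ cov @ c, 0.0)))
        if se < 1e-12:
            tval, p_raw = (0.0, 1.0) if abs(est) < 1e-12 else \
                (math.inf, 0.0)
        else:
            tval = est / se
            p_raw = 2.0 * stats.t.sf(abs(tval), df_den)
        p_adj = min(1.0, p_raw * m)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df_den)
        rows.append({
            "formula_a": fa, "formula_b": fb, "estimate": est, "se": se,
            "t": tval, "df": df_den, "p_raw": p_raw, "p_bonferroni": p_adj,
            "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
            "m_comparisons": m})
    return pd.DataFrame(rows)


def levene_heterogeneity(groups: Sequence[Sequence[float]]
                         ) -> tuple[float, float]:
    """Classic (mean-centered) Levene test for heterogeneity of variances
    across formulas: one-way ANOVA F on absolute deviations from each
    group mean, with (k-1, N-k) degrees of freedom."""
    if len(groups) < 2:
        raise ContractError("Levene needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise EmptyGroupError("each Levene group needs n >= 2")
    stat, p = stats.levene(*arrays, center="mean")
    return float(stat), float(p)


def gee_threshold_comparison(indicators: pd.DataFrame,
                             thresholds: Iterable[float] = THRESHOLDS
                             ) -> dict[str, dict]:
    """Within-threshold success proportions per formula and pairwise
    GEE contrasts.

    ``indicators`` is a long table with columns ``patient_id``,
    ``formula``, ``ae``.  For each threshold ``t`` the binary outcome
    ``ae <= t`` is modeled with a binomial GEE (logit link, exchangeable
    working correlation clustered on patient, robust sandwich
    covariance); pairwise log-odds contrasts are Bonferroni-adjusted.
    Formulas with all-0 or all-1 outcomes (complete separation) keep
    their proportions but their contrast p-values are reported as NaN.
    """
    import statsmodels.api as sm

    required = {"patient_id", "formula", "ae"}
    if not required.issubset(indicators.columns):
        raise ContractError(
            f"indicators table needs columns {sorted(required)}")
    formulas = sorted(indicators["formula"].unique())
    out: dict[str, dict] = {}
    for t in thresholds:
        df = indicators.copy()
        df["success"] = (df["ae"] <= t).astype(float)
        props = {f: float(df.loc[df["formula"] == f, "success"].mean())
                 for f in formulas}
        separated = {f for f in formulas if props[f] in (0.0, 1.0)}
        usable = [f for f in formulas if f not in separated]
        contrasts = []
        beta = cov = names = None
        if len(usable) >= 2:
            sub = df[df["formula"].isin(usable)]
            X = pd.get_dummies(sub["formula"], drop_first=True, dtype=float)
            X.insert(0, "const", 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GEE(sub["success"].to_numpy(), X.to_numpy(),
                               groups=sub["patient_id"].to_numpy(),
                               family=sm.families.Binomial(),
                               cov_struct=sm.cov_struct.Exchangeable())
                fit = model.fit()
            names = list(X.columns)
            beta = fit.params
            cov = fit.cov_params()
        m = len(formulas) * (len(formulas) - 1) // 2
        for fa, fb in combinations(formulas, 2):
            if fa in separated or fb in separated or beta is None:
                contrasts.append({
                    "formula_a": fa, "formula_b": fb,
                    "estimate": props[fa] - props[fb],
                    "p_raw": float("nan"), "p_bonferroni": float("nan"),
                    "undefined": True})
                continue
            c = np.zeros(len(names))
            if fa in names:
                c[names.index(fa)] = 1.0
            if fb in names:
                c[names.index(fb)] -= 1.0
            est = float(c @ beta)
            se = float(np.sqrt(max(c @ cov @ c, 0.0)))
            if se < 1e-12:
                z, p_raw = (0.0, 1.0) if abs(est) < 1e-12 else (math.inf, 0.0)
            else:
                z = est / se
                p_raw = 2.0 * stats.norm.sf(abs(z))
            contrasts.append({
                "formula_a": fa, "formula_b": fb, "estimate": est, "se": se,
                "z": z, "p_raw": p_raw,
                "p_bonferroni": min(1.0, p_raw * m), "undefined": False})
        out[f"{t:.2f}"] = {"proportions": props, "contrasts": contrasts,
                           "m_comparisons": m}
    return out


def subgroup_report(errors: pd.DataFrame, min_contrast_n: int = 3
                    ) -> dict[str, dict]:
    """Axial-length subgroup analysis.

    ``errors`` is a long table with columns ``patient_id``, ``formula``,
    ``pe``, ``ae`` and ``al_bin``.  For every populated bin a
    per-formula summary, the pairwise mixed-model contrasts (when the
    bin holds enough eyes), and the PE variability profile (SD of PE per
    formula) are reported; empty bins are absent from the result.
    """
    out: dict[str, dict] = {}
    for label in AL_BIN_LABELS:
        sub = errors[errors["al_bin"] == label]
        if sub.empty:
            continue
        block: dict = {"summaries": {}, "pe_sd": {}}
        for f, grp in sub.groupby("formula"):
            block["summaries"][f] = summarize_errors(grp["pe"]).to_dict()
            block["pe_sd"][f] = (float(grp["pe"].std(ddof=1))
                                 if len(grp) > 1 else 0.0)
        n_eyes = sub.groupby("formula").size().min()
        if n_eyes >= min_contrast_n and sub["formula"].nunique() >= 2 \
                and sub.groupby("formula").size().nunique() == 1:
            try:
                block["contrasts"] = compare_mae_mixed(sub).to_dict("records")
            except (ContractError, np.linalg.LinAlgError):
                block["contrasts"] = []
        else:
            block["contrasts"] = []
        out[label] = block
    return out
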