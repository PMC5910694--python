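"""Compartment-level aggregation and mixed-model statistics.

Input records carry one row per subject x compartment x condition with the
mean architecture of that compartment's accepted fascicles: columns
``subject_id, compartment, condition, volume_cm3, pcsa_cm2,
fascicle_length_mm, pennation_deg, curvature_per_m`` (plus optional
``n_fascicles``). Conditions are ``short`` and ``long``.

Whole-muscle summaries are computed per subject first (volume and PCSA summed
over compartments; fascicle length, pennation and curvature averaged), then
averaged across subjects; change rows are within-subject long - short
differences, then averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "METRICS", "CONDITIONS", "WHOLE",
    "round_half_up", "compartment_table", "posterior_fraction", "per_cm_change",
    "ModelResult", "lmm_compartment", "lmm_lengthening", "holm_adjust",
]

METRICS = ["volume_cm3", "pcsa_cm2", "fascicle_length_mm", "pennation_deg", "curvature_per_m"]
SUMMED_METRICS = {"volume_cm3", "pcsa_cm2"}  # summed (not averaged) for the whole muscle
CONDITIONS = ["short", "long"]
WHOLE = "whole-muscle"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (report-table convention; numpy rounds half-even)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _validate_records(records: pd.DataFrame, metrics) -> pd.DataFrame:
    df = records.copy()
    required = {"subject_id", "compartment", "condition", *metrics}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    return df


def _complete_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Drop subject/compartment cells lacking either condition (with a warning)."""
    counts = df.groupby(["subject_id", "compartment"])["condition"].nunique()
    incomplete = counts[counts < 2]
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} subject/compartment cells missing a condition: "
            f"{list(incomplete.index)}",
            stacklevel=3,
        )
        keep = counts[counts == 2].index
        df = df.set_index(["subject_id", "compartment"]).loc[keep].reset_index()
    return df


def _per_subject_rows(df: pd.DataFrame, metrics) -> pd.DataFrame:
    """Per-subject cells: each compartment at each condition, the whole-muscle
    summary at each condition, and within-subject change rows."""
    rows = []
    for (subject, condition), grp in df.groupby(["subject_id", "condition"]):
        for _, r in grp.iterrows():
            rows.append({"subject_id": subject, "compartment": r["compartment"],
                         "condition": condition, **{m: r[m] for m in metrics}})
        whole = {
            m: grp[m].sum() if m in SUMMED_METRICS else grp[m].mean() for m in metrics
        }
        rows.append({"subject_id": subject, "compartment": WHOLE, "condition": condition, **whole})
    out = pd.DataFrame(rows)
    pivots = out.pivot_table(index=["subject_id", "compartment"], columns="condition",
                             values=metrics, sort=False)
    change = []
    for (subject, comp), r in pivots.iterrows():
        change.append({"subject_id": subject, "compartment": comp, "condition": "change",
                       **{m: r[(m, "long")] - r[(m, "short")] for m in metrics}})
    return pd.concat([out, pd.DataFrame(change)], ignore_index=True)


def compartment_table(records: pd.DataFrame, metrics=METRICS) -> pd.DataFrame:
    """Mean +/- SD across subjects per compartment x condition, plus change rows
    (within-subject long - short) and the whole-muscle rows.

    Returns a frame indexed by (compartment, condition) with ``<metric>_mean``
    and ``<metric>_sd`` columns. SD is NaN with a single subject.
    """
    df = _complete_pairs(_validate_records(records, metrics))
    if df.empty:
        raise ValueError("no complete subject/compartment pairs")
    cells = _per_subject_rows(df, metrics)
    comp_order = list(dict.fromkeys(df["compartment"])) + [WHOLE]
    cond_order = ["short", "long", "change"]
    grouped = cells.groupby(["compartment", "condition"])
    table = grouped[metrics].mean()
    sds = grouped[metrics].std(ddof=1)
    table.columns = [f"{m}_mean" for m in metrics]
    for m in metrics:
        table[f"{m}_sd"] = sds[m]
    idx = pd.MultiIndex.from_product([comp_order, cond_order], names=["compartment", "condition"])
    return table.reindex(idx)


def posterior_fraction(records: pd.DataFrame,
                       posterior=("MP", "LP")) -> tuple[pd.Series, float, float]:
    """Percentage of total muscle volume in the posterior compartments.

    Per subject, a compartment's volume is the mean of its short- and
    long-condition volumes; the fraction is 100 * (posterior sum)/(total sum).
    Returns (per-subject series, mean, sd).
    """
    df = _validate_records(records, ["volume_cm3"])
    mean_vol = df.groupby(["subject_id", "compartment"])["volume_cm3"].mean().unstack()
    missing = set(posterior) - set(mean_vol.columns)
    if missing or mean_vol.isna().any().any():
        raise ValueError(f"missing compartment volumes (need all compartments; missing {sorted(missing)})")
    frac = 100.0 * mean_vol[list(posterior)].sum(axis=1) / mean_vol.sum(axis=1)
    sd = float(frac.std(ddof=1)) if len(frac) > 1 else float("nan")
    return frac, float(frac.mean()), sd


def per_cm_change(records: pd.DataFrame, mtu_change_mm: dict,
                  metrics=("fascicle_length_mm", "pennation_deg", "curvature_per_m")
                  ) -> pd.DataFrame:
    """Within-subject architecture change per centimetre of muscle-tendon
    lengthening, summarised as mean +/- SD across subjects.

    ``mtu_change_mm`` maps subject_id to the long - short muscle-tendon length
    change in mm (an input; subjects with zero change are excluded with a
    warning). Rows cover each compartment and the whole muscle.
    """
    metrics = list(metrics)
    df = _complete_pairs(_validate_records(records, metrics))
    zero = [s for s in df["subject_id"].unique() if mtu_change_mm.get(s, 0.0) == 0.0]
    if zero:
        warnings.warn(f"excluding subjects with zero MTU length change: {zero}", stacklevel=2)
        df = df[~df["subject_id"].isin(zero)]
    missing = set(df["subject_id"].unique()) - set(mtu_change_mm)
    if missing:
        raise ValueError(f"no MTU length change supplied for subjects: {sorted(missing)}")
    cells = _per_subject_rows(df, metrics)
    change = cells[cells["condition"] == "change"].copy()
    cm = change["subject_id"].map(lambda s: mtu_change_mm[s] / 10.0)
    for m in metrics:
        change[m] = change[m] / cm
    grouped = change.groupby("compartment", sort=False)
    out = grouped[metrics].mean()
    sds = grouped[metrics].std(ddof=1)
    out.columns = [f"{m}_per_cm_mean" for m in metrics]
    for m in metrics:
        out[f"{m}_per_cm_sd"] = sds[m]
    return out


# ---------------------------------------------------------------------------
# linear mixed models


@dataclass
class ModelResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    var_subject: float
    var_residual: float
    contrasts: pd.DataFrame
    singular: bool
    method: str  # 'reml' or 'ols-fallback'
    group_means: pd.Series


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def _pairwise_contrasts(levels, cell_mean_l, params, cov):
    """Wald z-tests for all pairwise differences of cell means."""
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            l_vec = cell_mean_l[levels[i]] - cell_mean_l[levels[j]]
            est = float(l_vec @ params)
            se = float(np.sqrt(l_vec @ cov @ l_vec))
            z = est / se if se > 0 else np.inf * np.sign(est)
            p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else 0.0
            rows.append({"contrast": f"{levels[i]} - {levels[j]}", "estimate": est,
                         "se": se, "z": z, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p"].to_numpy())  # non-paper, clearly labelled
    return out


def _cell_mean_vectors(design_info, levels, factor: str, fixed: dict):
    """L-vectors mapping fixed-effect params to cell means of one factor."""
    import patsy

    vectors = {}
    for lev in levels:
        row = {factor: [lev], **{k: [v] for k, v in fixed.items()}}
        (mat,) = patsy.build_design_matrices([design_info], pd.DataFrame(row))
        vectors[lev] = np.asarray(mat)[0]
    return vectors


def _fit_fixed_effects(formula: str, data: pd.DataFrame):
    """REML random-intercept fit; falls back to OLS when the mixed fit is
    degenerate (e.g. zero residual variance, where the balanced-design fixed
    effects coincide with OLS). Returns (params, cov, bse, pvalues,
    var_subject, var_residual, method, design_info)."""
    ols = smf.ols(formula, data=data).fit()
    design_info = ols.model.data.design_info
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data=data, groups=data["subject_id"]).fit(reml=True)
            params = fit.fe_params
            if not np.all(np.isfinite(np.asarray(params))):
                raise ValueError("non-finite mixed-model fit")
            k = len(params)
            cov = np.asarray(fit.cov_params())[:k, :k]
            bse, pvalues = fit.bse_fe, fit.pvalues[:k]
            if not np.all(np.isfinite(np.asarray(bse))):
                raise ValueError("degenerate mixed-model covariance")
        return (params, cov, bse, pvalues,
                float(np.asarray(fit.cov_re)[0, 0]), float(fit.scale), "reml", design_info)
    except Exception:
        var_res = float(ols.scale) if np.isfinite(ols.scale) else 0.0
        return (ols.params, np.asarray(ols.cov_params()), ols.bse, ols.pvalues,
                0.0, var_res, "ols-fallback", design_info)


def _build_result(formula, data, levels, l_vectors) -> ModelResult:
    (params, cov, bse, pvalues, var_subject, var_residual,
     method, _) = _fit_fixed_effects(formula, data)
    p = np.asarray(params)
    contrasts = _pairwise_contrasts(levels, l_vectors, p, cov)
    group_means = pd.Series({lev: float(l_vectors[lev] @ p) for lev in levels})
    singular = (method == "ols-fallback"
                or var_subject <= 1e-10 * max(var_residual, 1e-30)
                or var_residual <= 1e-12)
    return ModelResult(params=params, bse=bse, pvalues=pvalues, var_subject=var_subject,
                       var_residual=var_residual, contrasts=contrasts, singular=singular,
                       method=method, group_means=group_means)


def lmm_compartment(records: pd.DataFrame, metric: str, condition: str = "short") -> ModelResult:
    """REML random-intercept model ``metric ~ compartment + (1 | subject)`` at
    one muscle length, with pairwise compartment Wald contrasts."""
    df = _validate_records(records, [metric])
    df = df[df["condition"] == condition].copy()
    levels = list(dict.fromkeys(df["compartment"]))
    if df["subject_id"].nunique() < 2 or len(levels) < 2:
        raise ValueError("need at least 2 subjects and 2 compartments")
    formula = f"{metric} ~ C(compartment)"
    design_info = smf.ols(formula, data=df).fit().model.data.design_info
    l_vecs = _cell_mean_vectors(design_info, levels, "compartment", {})
    return _build_result(formula, df, levels, l_vecs)


def lmm_lengthening(records: pd.DataFrame, metric: str) -> ModelResult:
    """REML model ``metric ~ compartment * condition + (1 | subject)``; the
    reported contrasts compare the compartments' long - short changes
    (interaction contrasts), and ``group_means`` holds each compartment's
    estimated change."""
    import patsy

    df = _complete_pairs(_validate_records(records, [metric]))
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    levels = list(dict.fromkeys(df["compartment"]))
    formula = f"{metric} ~ C(compartment) * C(condition)"
    design_info = smf.ols(formula, data=df).fit().model.data.design_info
    l_change = {}
    for lev in levels:
        rows = pd.DataFrame({"compartment": [lev, lev], "condition": ["long", "short"]})
        (mat,) = patsy.build_design_matrices([design_info], rows)
        mat = np.asarray(mat)
        l_change[lev] = mat[0] - mat[1]
    return _build_result(formula, df, levels, l_change)
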