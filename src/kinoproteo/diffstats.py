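"""Moderated differential expression and effect sizes.

The differential test is an empirical-Bayes moderated t with a
PSM-count-dependent variance prior: per-protein residual variances from the
group-means model are shrunk toward a smooth trend of log-variance versus
log-PSM-count, the idea being that proteins quantified from more spectra are
measured more precisely. The prior degrees of freedom are estimated from the
scatter of the trend-standardised variances (moment matching on the log-F
distribution, the canonical moderation machinery).

Effect sizes are Cohen's d with Hedges' small-sample bias correction
J = 1 - 3/(4(n1+n2) - 9), g = d*J, classified by magnitude:
|g| < 0.8 small, [0.8, 1.5) notable, [1.5, 3.0) strong, >= 3.0 definitive.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from kinoproteo.errors import ValidationError
from kinoproteo.io_formats import SampleDesign
from kinoproteo.preprocess import QuantMatrix

#: |log2FC| threshold corresponding to a 1.5-fold change
FC_THRESHOLD = 0.585

MAGNITUDE_BINS = ((0.8, "small"), (1.5, "notable"), (3.0, "strong"))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone in p-value ranks)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior_df(s2: np.ndarray, s2_prior: np.ndarray, df: float) -> float:
    """Moment-matching estimate of the prior degrees of freedom d0.

    Under the hierarchical model, z = log(s2/s2_prior) follows a shifted
    log-F(df, d0) distribution with Var(z) = trigamma(df/2) + trigamma(d0/2);
    the excess of the empirical variance over trigamma(df/2) identifies d0.
    Returns inf when the variances scatter no more than sampling alone
    explains (complete shrinkage).
    """
    ok = (s2 > 0) & (s2_prior > 0) & np.isfinite(s2) & np.isfinite(s2_prior)
    z = np.log(s2[ok] / s2_prior[ok])
    if z.size < 2:
        return np.inf
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf
    return 2.0 * _trigamma_inverse(evar)


def _variance_trend(s2: np.ndarray, psm_counts: np.ndarray, df: float,
                    frac: float = 0.5) -> np.ndarray:
    """Lowess trend of log residual variance against log PSM count.

    E[log s2] = log sigma2 + digamma(df/2) - log(df/2) under chi-square
    sampling, so the fitted curve is shifted by the negative of that bias
    before exponentiating; otherwise the prior variance would be
    systematically understated (badly so at small df).
    """
    floor = 1e-12
    logs2 = np.log(np.maximum(s2, floor))
    logn = np.log(psm_counts.astype(float))
    bias = float(special.digamma(df / 2.0) - np.log(df / 2.0))
    if np.ptp(logn) == 0:
        # all proteins share one PSM count: flat trend at the mean
        return np.full_like(s2, np.exp(logs2.mean() - bias))
    fitted = lowess(logs2, logn, frac=frac, return_sorted=False)
    return np.exp(fitted - bias)


def fit_moderated_de(
    m: QuantMatrix,
    design: SampleDesign | None = None,
    contrasts: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    fc_threshold: float = FC_THRESHOLD,
    trend_frac: float = 0.5,
    prior_df: float | None = None,
) -> dict[str, pd.DataFrame]:
    """PSM-count-aware moderated differential expression, one table per contrast.

    Group means are ordinary least squares under the group-means model; the
    pooled residual variance (df = n_samples - n_groups) is shrunk toward the
    PSM-count trend with estimated prior df d0 (overridable via ``prior_df``;
    0 recovers the classical equal-variance t test). Moderated
    t = log2FC / (s_tilde * sqrt(1/n1 + 1/n2)) on df_residual + d0 degrees of
    freedom, with BH-FDR per contrast and the conjunction significance call
    (FDR < alpha AND |log2FC| > fc_threshold).
    """
    design = design or m.design
    if not m.is_log2 or m.values.isna().any().any():
        raise ValidationError("fit_moderated_de expects an imputed log2 matrix")
    groups = design.group_labels
    if contrasts is None:
        ref = groups[0]
        contrasts = [(g, ref) for g in groups[1:]]
    for g1, g2 in contrasts:
        for g in (g1, g2):
            if g not in groups:
                raise ValidationError(f"contrast names unknown group '{g}'")
            if len(design.channels_of(g)) < 2:
                raise ValidationError(f"group '{g}' has fewer than 2 samples")

    X = m.values
    n_total = X.shape[1]
    k = len(groups)
    df_resid = n_total - k
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")

    means = {g: X[design.channels_of(g)].mean(axis=1) for g in groups}
    rss = np.zeros(len(X))
    for g in groups:
        sub = X[design.channels_of(g)]
        rss += ((sub.sub(means[g], axis=0)) ** 2).sum(axis=1).to_numpy()
    s2 = rss / df_resid

    counts = m.psm_counts.reindex(X.index).to_numpy()
    s2_prior = _variance_trend(s2, counts, df_resid, frac=trend_frac)
    d0 = estimate_prior_df(s2, s2_prior, df_resid) if prior_df is None \
        else float(prior_df)

    if np.isinf(d0):
        s2_post = s2_prior.copy()
    else:
        s2_post = (d0 * s2_prior + df_resid * s2) / (d0 + df_resid)
    df_total = df_resid + d0

    results = {}
    for g1, g2 in contrasts:
        n1 = len(design.channels_of(g1))
        n2 = len(design.channels_of(g2))
        lfc = (means[g1] - means[g2]).to_numpy()
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf))
        df_p = min(df_total, 1e6)  # t_1e6 is numerically normal
        p = 2.0 * stats.t.sf(np.abs(t), df_p)
        fdr = bh_fdr(p)
        res = pd.DataFrame({
            "protein": X.index,
            "log2fc": lfc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "psm_count": counts,
        }).set_index("protein")
        res["significant"] = (res["fdr"] < alpha) & \
            (res["log2fc"].abs() > fc_threshold)
        res.attrs["prior_df"] = d0
        res.attrs["df_residual"] = df_resid
        results[f"{g1}_vs_{g2}"] = res
    return results


def call_significance(res: pd.DataFrame, alpha: float = 0.05,
                      fc_threshold: float = FC_THRESHOLD) -> dict:
    """Apply the conjunction rule and summarise counts for one contrast.

    Returns both the conjunction count (FDR < alpha AND |log2FC| >
    fc_threshold) and the FDR-only count, since published protein tallies
    use either rule.
    """
    sig = (res["fdr"] < alpha) & (res["log2fc"].abs() > fc_threshold)
    res = res.copy()
    res["significant"] = sig
    return {
        "result": res,
        "n_significant": int(sig.sum()),
        "n_fdr_only": int((res["fdr"] < alpha).sum()),
        "n_up": int((sig & (res["log2fc"] > 0)).sum()),
        "n_down": int((sig & (res["log2fc"] < 0)).sum()),
    }


def hedges_j(n1: int, n2: int) -> float:
    """Small-sample bias correction J = 1 - 3/(4(n1+n2) - 9)."""
    return 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)


def classify_magnitude(g: float) -> str:
    if np.isnan(g):
        return "undefined"
    a = abs(g)
    for bound, label in MAGNITUDE_BINS:
        if a < bound:
            return label
    return "definitive"


def effect_size_from_groups(x1, x2) -> dict:
    """Cohen's d, Hedges' g, J and magnitude class for two sample vectors.

    d = (mean1 - mean2) / s_pooled with the (n1-1, n2-1)-weighted pooled SD;
    a zero pooled SD yields an undefined (NaN) effect size rather than an
    infinite one.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("effect sizes need group sizes >= 2")
    s_pooled = np.sqrt(((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1))
                       / (n1 + n2 - 2))
    j = hedges_j(n1, n2)
    if s_pooled == 0:
        d = g = np.nan
    else:
        d = (x1.mean() - x2.mean()) / s_pooled
        g = d * j
    return {"d": d, "g": g, "J": j, "n1": n1, "n2": n2,
            "s_pooled": float(s_pooled), "magnitude_class": classify_magnitude(g)}


def effect_sizes(m: QuantMatrix, design: SampleDesign | None = None,
                 contrast: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-protein effect sizes for one contrast (treated, reference)."""
    design = design or m.design
    if contrast is None:
        groups = design.group_labels
        contrast = (groups[-1], groups[0])
    g1, g2 = contrast
    a = m.values[design.channels_of(g1)].to_numpy()
    b = m.values[design.channels_of(g2)].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("effect sizes need group sizes >= 2")
    s_pooled = np.sqrt(((n1 - 1) * a.var(axis=1, ddof=1)
                        + (n2 - 1) * b.var(axis=1, ddof=1)) / (n1 + n2 - 2))
    j = hedges_j(n1, n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(s_pooled > 0,
                     (a.mean(axis=1) - b.mean(axis=1)) / s_pooled, np.nan)
    g = d * j
    out = pd.DataFrame({
        "d": d, "g": g, "J": j, "n1": n1, "n2": n2, "s_pooled": s_pooled,
    }, index=m.values.index)
    out["magnitude_class"] = [classify_magnitude(v) for v in g]
    return out


def dose_fate(log2fc_by_dose: pd.DataFrame,
              fc_threshold: float = FC_THRESHOLD) -> tuple[pd.DataFrame, dict]:
    """Categorise each protein per dose and count state transitions.

    States: 'up' (log2FC > threshold), 'stable' (|log2FC| <= threshold),
    'down' (log2FC < -threshold). Columns of ``log2fc_by_dose`` must be in
    increasing dose order; transition counts are Counter((state_i, state_j))
    per consecutive column pair and always sum to the protein universe size.
    """
    states = pd.DataFrame(index=log2fc_by_dose.index)
    for col in log2fc_by_dose.columns:
        lfc = log2fc_by_dose[col]
        states[col] = np.select(
            [lfc > fc_threshold, lfc < -fc_threshold], ["up", "down"], "stable")
    transitions = {}
    cols = list(states.columns)
    for a, b in zip(cols, cols[1:]):
        transitions[(a, b)] = Counter(zip(states[a], states[b]))
    return states, transitions


def intersection_summary(sets_by_label: dict[str, set]) -> dict:
    """Exclusive intersection sizes over labelled sets (UpSet-style counts).

    Returns every non-empty exclusive membership combination (elements in
    exactly that combination of sets) plus the count of elements consistent
    across >= 2 sets.
    """
    labels = list(sets_by_label)
    universe = set().union(*sets_by_label.values()) if sets_by_label else set()
    exclusive: dict[frozenset, int] = {}
    for element in universe:
        member = frozenset(l for l in labels if element in sets_by_label[l])
        exclusive[member] = exclusive.get(member, 0) + 1
    consistent = sum(n for combo, n in exclusive.items() if len(combo) >= 2)
    return {"exclusive": exclusive, "consistent_ge2": consistent,
            "universe_size": len(universe)}
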