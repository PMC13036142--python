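"""PSM table -> analysis-ready log2 protein matrix.

Stages: channel-completeness filtering, protein roll-up (sum of reporter
intensities over a protein's PSMs), log2 transform, QRILC imputation of
left-censored missing values, and QC metrics (within-group CV, missing rate,
replicate correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from kinoproteo.errors import ValidationError
from kinoproteo.io_formats import PsmTable, SampleDesign

logger = logging.getLogger(__name__)


@dataclass
class QuantMatrix:
    """Proteins x samples abundance matrix with per-protein PSM counts.

    ``values`` is indexed by protein accession with one column per design
    channel; NaN marks a missing (censored) cell. ``observed`` is a boolean
    mask of cells observed before imputation — imputation must never change
    an observed cell. ``is_log2`` records the current scale.
    """

    values: pd.DataFrame
    psm_counts: pd.Series
    design: SampleDesign
    observed: pd.DataFrame = field(default=None)
    is_log2: bool = False

    def __post_init__(self):
        if (self.psm_counts < 1).any():
            raise ValidationError("psm_counts must be >= 1")
        if self.observed is None:
            self.observed = self.values.notna()

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def missing_rate(self) -> float:
        return float(self.values.isna().to_numpy().mean())


def filter_psms(psms: PsmTable, fdr_max: float = 0.01,
                min_nonzero_channels: int = 6) -> PsmTable:
    """Retain PSMs with psm_fdr <= fdr_max and enough non-zero channels.

    The completeness rule requires a strictly positive reporter intensity in
    at least ``min_nonzero_channels`` of the design's channels (default 6 of
    11). Removal counts per criterion are logged.
    """
    if not 0 < fdr_max <= 1:
        raise ValidationError("fdr_max must be in (0,1]")
    n_ch = psms.design.n_channels
    if not 1 <= min_nonzero_channels <= n_ch:
        raise ValidationError("min_nonzero_channels out of range")
    frame = psms.frame
    pass_fdr = frame["psm_fdr"] <= fdr_max
    nonzero = psms.intensities.gt(0).sum(axis=1)
    pass_channels = nonzero >= min_nonzero_channels
    keep = pass_fdr & pass_channels
    logger.info(
        "filter_psms: %d/%d retained (%d failed FDR<=%g, %d failed >=%d non-zero channels)",
        int(keep.sum()), len(frame), int((~pass_fdr).sum()), fdr_max,
        int((~pass_channels).sum()), min_nonzero_channels)
    return PsmTable(frame=frame[keep].reset_index(drop=True),
                    design=psms.design)


def rollup_proteins(psms: PsmTable) -> QuantMatrix:
    """Sum reporter intensities over each protein's PSMs (linear scale).

    The per-protein PSM count is the number of contributing PSM rows; a
    summed channel value of 0 (all contributing PSMs censored) becomes a
    missing cell, preserving the left-censoring interpretation.
    """
    channels = list(psms.design.channels)
    grouped = psms.frame.groupby("protein", sort=True)
    values = grouped[channels].sum()
    counts = grouped.size().rename("psm_count")
    values = values.mask(values == 0.0)
    return QuantMatrix(values=values, psm_counts=counts, design=psms.design,
                       is_log2=False)


def log2_transform(m: QuantMatrix) -> QuantMatrix:
    """Elementwise log2; missing cells stay missing."""
    if m.is_log2:
        raise ValidationError("matrix is already log2-scale")
    if (m.values <= 0).any().any():
        raise ValidationError("observed values must be positive for log2")
    return QuantMatrix(values=np.log2(m.values), psm_counts=m.psm_counts,
                       design=m.design, observed=m.observed.copy(),
                       is_log2=True)


def _qrilc_fit_column(obs: np.ndarray, n_total: int) -> tuple[float, float]:
    """Estimate the complete-distribution mean/SD of one sample column.

    The observed values are treated as the upper (1 - missing_rate) portion
    of a normal distribution: sorted observations are regressed against the
    standard-normal quantiles of plotting positions confined to
    (missing_rate, 1), giving intercept = mean and slope = SD.
    """
    n_obs = obs.size
    r = 1.0 - n_obs / n_total  # observed missing rate
    order = np.sort(obs)
    p = r + (1.0 - r) * (np.arange(1, n_obs + 1) - 0.5) / n_obs
    q = stats.norm.ppf(p)
    slope, intercept = np.polyfit(q, order, 1)
    return float(intercept), float(abs(slope))


def impute_qrilc(m: QuantMatrix, tail_quantile: float = 0.01,
                 seed: int = 0, tune_sigma: float = 1.0) -> QuantMatrix:
    """Quantile-regression imputation of left-censored (QRILC) missing cells.

    Per sample column: the complete-distribution mean and SD are estimated by
    regressing observed order statistics against standard-normal quantiles
    restricted to the upper observed portion; missing cells are then drawn
    from that normal truncated above at its ``tail_quantile`` quantile (so
    imputed values fall in the left tail, below the detection limit).
    Observed cells are never touched. Deterministic given ``seed``.
    """
    if not m.is_log2:
        raise ValidationError("QRILC expects a log2-scale matrix")
    miss = m.values.isna()
    if not miss.any().any():
        return QuantMatrix(values=m.values.copy(), psm_counts=m.psm_counts,
                           design=m.design, observed=m.observed.copy(),
                           is_log2=True)
    rng = np.random.default_rng(seed)
    out = m.values.copy()
    for col in out.columns:
        colvals = out[col].to_numpy()
        missing = np.isnan(colvals)
        n_miss = int(missing.sum())
        if n_miss == 0:
            continue
        if n_miss == colvals.size:
            raise ValidationError(f"sample '{col}' has all values missing")
        if n_miss / colvals.size >= 0.5:
            raise ValidationError(
                f"sample '{col}' has >=50% missing; QRILC not applicable")
        mean, sd = _qrilc_fit_column(colvals[~missing], colvals.size)
        sd *= tune_sigma
        upper = mean + sd * stats.norm.ppf(tail_quantile)
        draws = stats.truncnorm.rvs(
            a=-np.inf, b=(upper - mean) / sd, loc=mean, scale=sd,
            size=n_miss, random_state=rng)
        colvals[missing] = draws
        out[col] = colvals
    result = QuantMatrix(values=out, psm_counts=m.psm_counts, design=m.design,
                         observed=m.observed.copy(), is_log2=True)
    assert not result.values.isna().any().any()
    return result


def qc_metrics(m: QuantMatrix, design: SampleDesign | None = None) -> dict:
    """Per-group median CV, pre-imputation missing rate, replicate correlation.

    CV is SD/mean per protein per group on the linear scale (log2 values are
    back-transformed first), summarised as the median over proteins. The
    missing rate counts NaN cells in the current matrix; run before
    imputation to report censoring.
    """
    design = design or m.design
    linear = np.exp2(m.values) if m.is_log2 else m.values
    median_cv = {}
    replicate_r = {}
    for g in design.group_labels:
        cols = design.channels_of(g)
        sub = linear[cols]
        cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
        median_cv[g] = float(cv.median())
        corr = sub.corr(method="pearson")
        pairs = corr.to_numpy()[np.triu_indices(len(cols), k=1)]
        replicate_r[g] = (float(np.nanmean(pairs))
                          if np.isfinite(pairs).any() else float("nan"))
    return {
        "median_cv": median_cv,
        "missing_rate": m.missing_rate(),
        "replicate_correlation": replicate_r,
    }


def preprocess_pipeline(psms: PsmTable, fdr_max: float = 0.01,
                        min_nonzero_channels: int = 6,
                        tail_quantile: float = 0.01,
                        seed: int = 0) -> tuple[QuantMatrix, dict]:
    """Filter -> roll up -> log2 -> QRILC. Returns (imputed matrix, QC dict)."""
    filtered = filter_psms(psms, fdr_max=fdr_max,
                           min_nonzero_channels=min_nonzero_channels)
    mat = log2_transform(rollup_proteins(filtered))
    qc = qc_metrics(mat)
    imputed = impute_qrilc(mat, tail_quantile=tail_quantile, seed=seed)
    return imputed, qc
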