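"""In-vivo and immunohistochemistry arithmetic.

Caliper tumor volume (L x W^2 / 2, with L the longer dimension), percent
reduction between group means, conversion of a log2 fold change to a percent
reduction, and Spearman correlation with a Fisher-z confidence interval
(exact permutation p-value at small n).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from kinoproteo.errors import ValidationError

logger = logging.getLogger(__name__)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper volume in mm^3: L x W^2 / 2 after orienting L >= W.

    If the inputs arrive swapped (width > length) they are reoriented with a
    warning, since length is defined as the longer dimension.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValidationError("tumor dimensions must be non-negative")
    if width_mm > length_mm:
        logger.warning("width %.3g > length %.3g; swapping", width_mm, length_mm)
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm ** 2 / 2.0


def volumes_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add a ``volume`` column to a (animal, day, length, width, ...) table."""
    out = measurements.copy()
    out["volume"] = [tumor_volume(r.length, r.width)
                     for r in measurements.itertuples()]
    return out


def percent_reduction(mean_control: float, mean_treated: float) -> float:
    """100 * (control - treated) / control, reported at one decimal."""
    if mean_control <= 0:
        raise ValidationError("mean_control must be positive")
    return round(100.0 * (mean_control - mean_treated) / mean_control, 1)


def log2fc_to_percent_reduction(log2fc: float) -> float:
    """Convert a (negative) log2 fold change to its percent reduction.

    100 * (1 - 2^log2fc): e.g. log2FC = -1 is a 50% reduction.
    """
    return 100.0 * (1.0 - 2.0 ** log2fc)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for Spearman's rho by full enumeration.

    Enumerates all n! assignments of y ranks (feasible for n <= 9); the
    p-value is the fraction of permutations with |rho| >= |rho observed|.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c ** 2).sum())
    count = total = 0
    for perm in itertools.permutations(ry):
        py = np.asarray(perm)
        py_c = py - py.mean()
        denom = denom_x * np.sqrt((py_c ** 2).sum())
        rho = (rx_c * py_c).sum() / denom
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_ci(x, y, conf: float = 0.95) -> dict:
    """Spearman rho with two-sided p and a Fisher-z confidence interval.

    Average ranks for ties. The CI transforms rho to z = atanh(rho) with
    SE = 1/sqrt(n-3) and back. For n <= 9 the p-value is exact (full
    permutation enumeration); otherwise the t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValidationError("x and y must have equal length")
    if n < 4:
        raise ValidationError("spearman_ci needs n >= 4")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if n <= 9:
        p = _exact_spearman_p(x, y, rho)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(1 - (1 - conf) / 2)
    return {
        "rho": rho,
        "p": float(p),
        "ci_low": float(np.tanh(z - zcrit * se)),
        "ci_high": float(np.tanh(z + zcrit * se)),
        "n": n,
    }


def group_summary(measurements: pd.DataFrame,
                  day: int | None = None) -> pd.DataFrame:
    """Mean final-day volume per group plus pairwise percent reductions.

    ``measurements`` columns: animal, day, length, width, group. When ``day``
    is None each animal's last measured day is used. Group means are
    arithmetic means of those final volumes.
    """
    vols = volumes_table(measurements)
    if day is not None:
        vols = vols[vols["day"] == day]
    else:
        last = vols.groupby("animal")["day"].transform("max")
        vols = vols[vols["day"] == last]
    means = vols.groupby("group")["volume"].agg(["mean", "count"])
    rows = []
    for ctrl, trt in itertools.permutations(means.index, 2):
        rows.append({
            "control": ctrl, "treated": trt,
            "mean_control": means.loc[ctrl, "mean"],
            "mean_treated": means.loc[trt, "mean"],
            "percent_reduction": percent_reduction(means.loc[ctrl, "mean"],
                                                   means.loc[trt, "mean"]),
        })
    out = pd.DataFrame(rows)
    out.attrs["group_means"] = means
    return out
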