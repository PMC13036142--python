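"""Kinome panel preprocessing and kinome-proteomics integration.

The kinome panel reports percent-control per kinase (100 = uninhibited);
inhibition = 100 - percent_control. Kinases are classified strong (> 50%),
moderate (30-50%) or weak (< 30%) and merged with the proteomic effect sizes
by symbol. Concordance quadrants ask whether enzymatic inhibition agrees
with proteome-level downregulation; RRHO (rank-rank hypergeometric overlap)
maps agreement between the two rankings across top-k thresholds; and
kinase-substrate enrichment asks whose known substrates are over-represented
among downregulated proteins (one-sided Fisher exact).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from kinoproteo.errors import ValidationError
from kinoproteo.diffstats import bh_fdr
from kinoproteo.io_formats import SubstrateMap, normalize_symbol
from kinoproteo.pathways import fisher_table


def classify_inhibition(inhibition: float) -> str:
    """strong (>50), moderate [30, 50], weak (<30)."""
    if inhibition > 50:
        return "strong"
    if inhibition >= 30:
        return "moderate"
    return "weak"


def preprocess_kinome(panel: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate the panel to one record per kinase, keeping max inhibition.

    Adds ``inhibition`` (100 - percent_control) and ``inhibition_class``
    columns. Idempotent: re-running on its own output changes nothing.
    """
    df = panel.copy()
    df["kinase"] = df["kinase"].map(normalize_symbol)
    df["inhibition"] = 100.0 - df["percent_control"]
    df = (df.sort_values(["kinase", "inhibition"], ascending=[True, False])
            .drop_duplicates(subset="kinase", keep="first")
            .reset_index(drop=True))
    df["percent_control"] = 100.0 - df["inhibition"]
    df["inhibition_class"] = df["inhibition"].map(classify_inhibition)
    return df


def pathway_mean_inhibition(profile: pd.DataFrame) -> pd.Series:
    """Mean inhibition per pathway label over the deduplicated profile."""
    return profile.groupby("pathway")["inhibition"].mean()


def assign_quadrant(inhibition: float, g_signed: float) -> str:
    """Concordance quadrant for one merged kinase.

    ConcordantHigh: inhibition > 30 and strictly negative g (enzymatic
    inhibition matched by proteome downregulation). ConcordantLow:
    inhibition < 30 and stable/positive g. Everything else — including g
    exactly 0 at high inhibition, and the boundary inhibition == 30 —
    is Discordant.
    """
    if inhibition > 30 and g_signed < 0:
        return "ConcordantHigh"
    if inhibition < 30 and g_signed >= 0:
        return "ConcordantLow"
    return "Discordant"


def merge_kinome_proteomics(profile: pd.DataFrame,
                            effects: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Inner-join the kinome profile with per-protein effect sizes by symbol.

    ``effects`` is indexed by protein symbol with columns ``g`` and ``fdr``
    (e.g. the effect-size table joined with the differential FDR at one
    dose). Returns the merged records with quadrants plus the list of
    panel kinases not quantified in the proteome.
    """
    eff = effects.copy()
    eff.index = [normalize_symbol(s) for s in eff.index]
    merged_rows, unmatched = [], []
    for rec in profile.itertuples():
        sym = normalize_symbol(rec.kinase)
        if sym not in eff.index:
            unmatched.append(sym)
            continue
        row = eff.loc[sym]
        g_signed = float(row["g"])
        merged_rows.append({
            "symbol": sym,
            "inhibition": float(rec.inhibition),
            "g_signed": g_signed,
            "g_abs": abs(g_signed),
            "fdr": float(row["fdr"]) if "fdr" in row else np.nan,
            "quadrant": assign_quadrant(float(rec.inhibition), g_signed),
        })
    return pd.DataFrame(merged_rows), unmatched


def concordance_correlation(records: pd.DataFrame,
                            use_signed: bool = True) -> dict:
    """Spearman rank correlation between inhibition and Hedges' g.

    ``use_signed`` selects signed g (the loss-of-function direction test,
    negative rho expected) versus |g| (unsigned magnitude concordance).
    Average ranks for ties; two-sided p.
    """
    if len(records) < 3:
        raise ValidationError("concordance needs n >= 3 merged kinases")
    y = records["g_signed"] if use_signed else records["g_abs"]
    rho, p = stats.spearmanr(records["inhibition"], y)
    return {"rho": float(rho), "p": float(p), "n": int(len(records))}


def rrho_map(ranking_a: list[str], ranking_b: list[str],
             step: int | None = None) -> pd.DataFrame:
    """Rank-rank hypergeometric overlap map between two rankings.

    Both rankings must order the same symbol universe (best first). For each
    grid point (i, j) the overlap of the top-i of A with the top-j of B is
    tested against the upper-tail hypergeometric P(X >= overlap) with
    population N, i successes, j draws. Default step is max(1, N // 20).
    """
    a = [normalize_symbol(s) for s in ranking_a]
    b = [normalize_symbol(s) for s in ranking_b]
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise ValidationError(f"ranking universes differ: {diff}")
    if len(set(a)) != len(a):
        raise ValidationError("rankings contain duplicate symbols")
    n = len(a)
    if step is None:
        step = max(1, n // 20)
    if step < 1:
        raise ValidationError("step must be >= 1")
    pos_b = {s: idx for idx, s in enumerate(b)}
    thresholds = list(range(step, n + 1, step))
    if thresholds[-1] != n:
        thresholds.append(n)
    rows = []
    for i in thresholds:
        in_top_a = np.zeros(n, dtype=bool)
        for s in a[:i]:
            in_top_a[pos_b[s]] = True
        cum = np.cumsum(in_top_a)
        for j in thresholds:
            overlap = int(cum[j - 1])
            p = float(stats.hypergeom.sf(overlap - 1, n, i, j))
            rows.append({"threshold_a": i, "threshold_b": j,
                         "overlap": overlap, "p_hyper": min(p, 1.0),
                         "neglog10p": float(-np.log10(max(p, 1e-300)))})
    return pd.DataFrame(rows)


def substrate_enrichment(substrate_map: SubstrateMap, downregulated: set,
                         universe: set) -> pd.DataFrame:
    """Per-kinase Fisher enrichment of substrates among downregulated proteins.

    The 2x2 is (substrate vs not) x (downregulated vs not) over the quantified
    universe; one-sided (enrichment) Fisher exact with BH across kinases. The
    odds ratio is the plain sample OR; the Haldane-Anscombe +0.5 correction is
    applied only when a zero cell occurs. Kinases with no substrate in the
    universe are skipped (reported in the ``skipped`` attr).
    """
    universe = {normalize_symbol(s) for s in universe}
    downregulated = {normalize_symbol(s) for s in downregulated} & universe
    rows, skipped = [], []
    for kinase in substrate_map.kinases:
        subs = substrate_map.substrates_of(kinase) & universe
        if not subs:
            skipped.append(kinase)
            continue
        table = fisher_table(downregulated, subs, universe)
        (a, b), (c, d) = table
        _, p = stats.fisher_exact(table, alternative="greater")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append({"kinase": kinase, "odds_ratio": float(odds), "p": float(p),
                     "n_substrates": len(subs), "a": a, "b": b, "c": c, "d": d})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    out.attrs["skipped"] = skipped
    return out


def odds_ratio_ci(a: int, b: int, c: int, d: int,
                  conf: float = 0.95) -> tuple[float, float, float]:
    """Sample odds ratio with a Woolf (log-normal) confidence interval.

    Haldane-Anscombe +0.5 on every cell when any cell is zero.
    """
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    return (float(odds), float(odds * np.exp(-z * se)),
            float(odds * np.exp(z * se)))


def top_substrate_selection(kinase: str, substrate_map: SubstrateMap,
                            effects: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k quantified substrates of a kinase with largest |log2FC|.

    ``effects`` is indexed by symbol with a ``log2fc`` column. Descending by
    |log2FC|; ties broken lexicographically by symbol; fewer than k returned
    when fewer substrates are quantified.
    """
    eff = effects.copy()
    eff.index = [normalize_symbol(s) for s in eff.index]
    subs = sorted(substrate_map.substrates_of(kinase) & set(eff.index))
    if not subs:
        raise ValidationError(f"kinase '{kinase}' has no quantified substrate")
    sub = eff.loc[subs, ["log2fc"]].copy()
    sub["abs_log2fc"] = sub["log2fc"].abs()
    sub = (sub.reset_index(names="substrate")
              .sort_values(["abs_log2fc", "substrate"],
                           ascending=[False, True], kind="stable")
              .reset_index(drop=True))
    return sub.head(k)
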