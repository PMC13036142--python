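"""Weighted pathway activity scoring, Fisher enrichment, dose-response curves.

The activity score summarises a pathway's response at one dose as a weighted
average of its members' log2 fold changes, where each member's weight couples
its pathway position (upstream 1.5x, central 1.0x, downstream 0.5x — upstream
changes propagate), statistical confidence (-log10 FDR) and effect magnitude
(|log2FC|):

    W_i = position_i * (-log10 FDR_i) * |log2FC_i|
    activity = sum(log2FC_i * W_i) / sum(W_i)

The score is scale-invariant in the weights and always lies within the range
of member log2FC values when sum(W) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from kinoproteo.errors import ValidationError
from kinoproteo.diffstats import bh_fdr
from kinoproteo.io_formats import GeneSetCollection, normalize_symbol

POSITION_WEIGHTS = {"upstream": 1.5, "central": 1.0, "downstream": 0.5}

#: FDR floor before the log term, preventing unbounded weights as FDR -> 0
FDR_FLOOR = 1e-16


@dataclass
class PathwayScore:
    """Weighted activity of one pathway at one dose."""

    pathway: str
    dose: str
    weighted_activity: float
    n_members_quantified: int
    degenerate: bool = False  # all weights zero -> unweighted mean used
    member_weights: pd.DataFrame = field(default=None, repr=False)
    #: standard error of the weighted mean over members
    se: float = float("nan")


def member_weight(log2fc: float, fdr: float, position: str) -> float:
    """W = position * (-log10 fdr) * |log2fc| (fdr floored at 1e-16)."""
    if not 0 < fdr <= 1:
        raise ValidationError("fdr must be in (0,1]")
    pos = POSITION_WEIGHTS[position]
    return pos * (-np.log10(max(fdr, FDR_FLOOR))) * abs(log2fc)


def weighted_activity(members: pd.DataFrame, pathway: str = "",
                      dose: str = "") -> PathwayScore:
    """Score one pathway from its quantified members.

    ``members`` needs columns ``log2fc``, ``fdr`` and ``position``. When all
    weights vanish (every member at FDR 1 or log2FC 0) the unweighted mean of
    log2FC is reported with the degenerate flag set.
    """
    if len(members) == 0:
        raise ValidationError("weighted_activity: empty member list")
    w = np.array([member_weight(r.log2fc, r.fdr, r.position)
                  for r in members.itertuples()])
    lfc = members["log2fc"].to_numpy(dtype=float)
    total = w.sum()
    if total == 0:
        activity = float(lfc.mean())
        se = float(lfc.std(ddof=1) / np.sqrt(len(lfc))) if len(lfc) > 1 else np.nan
        degenerate = True
    else:
        wn = w / total
        activity = float((lfc * wn).sum())
        se = float(np.sqrt((wn ** 2 * (lfc - activity) ** 2).sum()))
        degenerate = False
    detail = members.assign(W=w)
    return PathwayScore(pathway=pathway, dose=dose, weighted_activity=activity,
                        n_members_quantified=len(members), degenerate=degenerate,
                        member_weights=detail, se=se)


def score_collection(de_result: pd.DataFrame, gene_sets: GeneSetCollection,
                     dose: str = "") -> list[PathwayScore]:
    """Score every pathway with >= 1 quantified member at one dose.

    ``de_result`` is a per-protein table (indexed by symbol) with ``log2fc``
    and ``fdr`` columns; pathway positions come from the collection and
    default to central.
    """
    index = {normalize_symbol(p) for p in de_result.index}
    scores = []
    for name, genes in gene_sets.sets.items():
        quantified = [g for g in genes if g in index]
        if not quantified:
            continue
        sub = de_result.loc[quantified, ["log2fc", "fdr"]].copy()
        sub["position"] = [gene_sets.position_of(g) for g in quantified]
        sub["fdr"] = sub["fdr"].clip(lower=FDR_FLOOR, upper=1.0)
        scores.append(weighted_activity(sub, pathway=name, dose=dose))
    return scores


def fisher_table(selected: set, members: set, universe: set) -> list[list[int]]:
    """2x2 table [[in&sel, in&not], [out&sel, out&not]] over the universe."""
    members = members & universe
    selected = selected & universe
    a = len(members & selected)
    b = len(members - selected)
    c = len(selected - members)
    d = len(universe) - a - b - c
    return [[a, b], [c, d]]


def pathway_enrichment(significant: set, gene_sets: GeneSetCollection,
                       universe: set) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of the significant set per pathway.

    Odds ratio is the sample OR (ad/bc, inf when bc = 0); BH adjustment
    across pathways.
    """
    universe = {normalize_symbol(g) for g in universe}
    significant = {normalize_symbol(g) for g in significant} & universe
    rows = []
    for name, genes in gene_sets.sets.items():
        table = fisher_table(significant, set(genes), universe)
        (a, b), (c, d) = table
        _, p = stats.fisher_exact(table, alternative="greater")
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append({"pathway": name, "odds_ratio": odds, "p": p,
                     "n_in_sig": a, "n_in": a + b})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def dose_response_curves(de_by_dose: dict[str, pd.DataFrame],
                         gene_sets: GeneSetCollection) -> pd.DataFrame:
    """Per-pathway weighted activity across doses with member-level SE.

    ``de_by_dose`` maps dose label (in increasing order) to a per-protein
    differential table. Returns a long-format frame: pathway, dose,
    weighted_activity, se, n_members, degenerate.
    """
    if len(de_by_dose) < 2:
        raise ValidationError("dose-response needs >= 2 doses")
    rows = []
    for dose, de_result in de_by_dose.items():
        for score in score_collection(de_result, gene_sets, dose=dose):
            rows.append({
                "pathway": score.pathway,
                "dose": dose,
                "weighted_activity": score.weighted_activity,
                "se": score.se,
                "n_members": score.n_members_quantified,
                "degenerate": score.degenerate,
            })
    return pd.DataFrame(rows)
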