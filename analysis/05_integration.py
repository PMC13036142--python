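#!/usr/bin/env python
"""Kinome-proteomics integration: quadrants, Spearman, RRHO, substrates.

Deduplicates the kinome panel to the strongest inhibition per kinase, merges
it with the top-dose effect sizes, classifies concordance quadrants, runs
the signed and unsigned Spearman concordance tests, computes the RRHO map
between the inhibition and |g| rankings, and asks which kinases' substrates
are enriched among downregulated proteins (expecting the planted hub at
odds ratio ~5).

Writes results/analysis/integration.tsv, rrho.tsv, substrate_enrichment.tsv
and top_substrates.tsv.
"""

from pathlib import Path

import pandas as pd

from kinoproteo.diffstats import FC_THRESHOLD
from kinoproteo.integration import (
    concordance_correlation,
    merge_kinome_proteomics,
    pathway_mean_inhibition,
    preprocess_kinome,
    rrho_map,
    substrate_enrichment,
    top_substrate_selection,
)
from kinoproteo.io_formats import (
    read_kinome_panel,
    read_substrate_map,
    write_results_table,
)

IN = Path("results/analysis")


def main() -> None:
    profile = preprocess_kinome(read_kinome_panel(IN / "inputs" /
                                                  "kinome_panel.tsv"))
    strong = profile[profile["inhibition_class"] == "strong"]
    print(f"kinome panel: {len(profile)} kinases after dedup; "
          f"{len(strong)} strongly inhibited (>50%)")
    print("mean inhibition by pathway (top 3):")
    print(pathway_mean_inhibition(profile).sort_values(
        ascending=False).head(3).to_string())

    de_top = pd.read_csv(IN / "de_10uM.tsv", sep="\t", index_col=0)
    merged, unmatched = merge_kinome_proteomics(profile, de_top)
    write_results_table(merged, IN / "integration.tsv")
    print(f"\nmerged {len(merged)} kinases with the proteome "
          f"({len(unmatched)} panel kinases not quantified)")
    print(merged["quadrant"].value_counts().to_string())
    for signed, label in ((True, "signed g"), (False, "|g|")):
        st = concordance_correlation(merged, use_signed=signed)
        print(f"Spearman inhibition vs {label}: rho {st['rho']:+.3f} "
              f"(p {st['p']:.3f}, n {st['n']})")

    rank_inh = list(merged.sort_values("inhibition", ascending=False)["symbol"])
    rank_g = list(merged.sort_values("g_abs", ascending=False)["symbol"])
    rrho = rrho_map(rank_inh, rank_g)
    write_results_table(rrho, IN / "rrho.tsv")
    peak = rrho.loc[rrho["neglog10p"].idxmax()]
    print(f"RRHO peak: top-{int(peak['threshold_a'])} x "
          f"top-{int(peak['threshold_b'])}, overlap {int(peak['overlap'])}, "
          f"p {peak['p_hyper']:.3g}")

    smap = read_substrate_map(IN / "inputs" / "substrates.tsv")
    down = set(de_top.index[(de_top["fdr"] < 0.05) &
                            (de_top["log2fc"] < -FC_THRESHOLD)])
    enr = substrate_enrichment(smap, down, set(de_top.index))
    write_results_table(enr, IN / "substrate_enrichment.tsv")
    best = enr.sort_values("p").iloc[0]
    print(f"\nstrongest substrate enrichment: {best['kinase']} "
          f"(OR {best['odds_ratio']:.2f}, p {best['p']:.2e})")

    tops = []
    for kinase in enr.sort_values("p").head(3)["kinase"]:
        sel = top_substrate_selection(kinase, smap, de_top, k=5)
        sel.insert(0, "kinase", kinase)
        tops.append(sel)
    write_results_table(pd.concat(tops, ignore_index=True),
                        IN / "top_substrates.tsv")


if __name__ == "__main__":
    main()
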