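#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Emulates the 11-sample TMT design (vehicle/1/2.5/10 µM at n = 3,3,3,2):
a PSM-level quantification table with planted dose-linear effects and
left-censored missingness, a 97-kinase inhibition panel overlapping the
proteome at 28 symbols, a 13-pathway gene-set collection whose first pathway
carries the planted coherent downregulation, and a kinase-substrate map with
a planted enrichment odds ratio of 5.

Writes everything under results/analysis/inputs/.
"""

from pathlib import Path

import numpy as np

from kinoproteo.io_formats import (
    SampleDesign,
    write_gene_sets_gmt,
    write_position_table,
)
from kinoproteo.synthetic import (
    generate_gene_sets,
    generate_kinome_panel,
    generate_psm_dataset,
    generate_substrate_map,
)

SEED = 42
OUT = Path("results/analysis/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(SEED).spawn(4)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]

    design = SampleDesign.default_tmt11()
    psms, truth = generate_psm_dataset(n_proteins=2000, design=design,
                                       frac_de=0.05, effect_log2fc=2.0,
                                       missing_rate=0.02, seed=seeds[0])
    with open(OUT / "psms.tsv", "w") as fh:
        fh.write(f"# seed={seeds[0]}\n")
        psms.frame.to_csv(fh, sep="\t", index=False)
    design.to_table(OUT / "design.tsv")
    truth.per_protein.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    proteins = sorted(psms.frame["protein"].unique())
    # plant 8 strongly inhibited kinases (5 quantified in the proteome)
    strong = tuple(proteins[:5]) + ("KINS01", "KINS02", "KINS03")
    panel, panel_truth = generate_kinome_panel(
        n_kinases=97, n_overlap_with_proteome=23, planted_strong=strong,
        seed=seeds[1], proteome_symbols=tuple(proteins))
    panel.to_csv(OUT / "kinome_panel.tsv", sep="\t", index=False)
    panel_truth.to_csv(OUT / "kinome_truth.tsv", sep="\t", index=False)

    down = truth.planted_down(design.top_dose_group)
    gene_sets = generate_gene_sets(proteins, planted_proteins=down,
                                   background_exclude=truth.planted,
                                   seed=seeds[2])
    write_gene_sets_gmt(gene_sets, OUT / "pathways.gmt")
    write_position_table(gene_sets.positions, OUT / "positions.tsv")

    kinases = list(panel["kinase"].unique())
    smap, sub_truth = generate_substrate_map(
        kinases[:20], proteins, enriched_kinase=kinases[0],
        enrichment_or=5.0, seed=seeds[3], downregulated=down)
    smap.pairs.to_csv(OUT / "substrates.tsv", sep="\t", index=False)

    print(f"wrote inputs to {OUT}")
    print(f"  {len(psms)} PSMs over {len(proteins)} proteins, "
          f"{len(truth.planted)} planted differential "
          f"({len(down)} down at top dose)")
    print(f"  kinome panel: {len(panel)} kinases, 28 overlapping proteome")
    print(f"  substrate map: {len(smap.pairs)} pairs; enriched kinase "
          f"{sub_truth['enriched_kinase']} (target OR 5)")


if __name__ == "__main__":
    main()
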