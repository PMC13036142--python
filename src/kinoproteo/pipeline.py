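"""End-to-end orchestration: simulate -> preprocess -> DE -> pathways -> integration.

A single global seed fans out deterministically to per-stage child seeds
(simulation, imputation, ...) so each stage is individually reproducible;
identical config + seed yields identical outputs. Every stage writes its
table under the output directory and the run ends with a machine-readable
``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from kinoproteo import diffstats, integration, pathways, preprocess, synthetic
from kinoproteo.errors import ValidationError
from kinoproteo.io_formats import (
    GeneSetCollection,
    SampleDesign,
    read_gene_sets_gmt,
    read_kinome_panel,
    read_position_table,
    read_psm_table,
    read_substrate_map,
    write_results_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, input paths and seed for one pipeline run.

    Defaults are the pipeline's canonical thresholds: FDR alpha 0.05,
    |log2FC| > 0.585 (1.5-fold), kinome inhibition cutoffs 30/50, QRILC tail
    quantile 0.01, PSM filter FDR 0.01 with >= 6 non-zero channels.
    """

    out_dir: str = "results/run"
    seed: int = 42
    # input paths; None means "simulate this input"
    psm_path: str | None = None
    design_path: str | None = None
    gene_sets_path: str | None = None
    positions_path: str | None = None
    kinome_path: str | None = None
    substrate_path: str | None = None
    # thresholds
    alpha: float = 0.05
    fc_threshold: float = diffstats.FC_THRESHOLD
    fdr_max: float = 0.01
    min_nonzero_channels: int = 6
    tail_quantile: float = 0.01
    rrho_step: int | None = None
    dose_of_interest: str | None = None  # default: top dose group
    # simulation parameters (used when paths above are None)
    n_proteins: int = 2000
    frac_de: float = 0.05
    effect_log2fc: float = 2.0
    missing_rate: float = 0.02
    psm_count_min: int = 1
    psm_count_max: int = 40
    n_kinases: int = 97
    n_overlap_kinases: int = 28
    enrichment_or: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        stages = ("simulate", "impute", "kinome", "substrates", "genesets")
        if stage not in stages:
            raise KeyError(stage)
        children = np.random.SeedSequence(self.seed).spawn(len(stages))
        return int(children[stages.index(stage)].generate_state(1)[0] % (2**31))


def _load_or_simulate_inputs(config: RunConfig, out: Path):
    """Resolve every pipeline input, simulating whatever has no path."""
    design = (SampleDesign.from_table(config.design_path)
              if config.design_path else SampleDesign.default_tmt11())
    truth = None
    if config.psm_path:
        psms = read_psm_table(config.psm_path, design)
    else:
        psms, truth = synthetic.generate_psm_dataset(
            n_proteins=config.n_proteins, design=design,
            frac_de=config.frac_de, effect_log2fc=config.effect_log2fc,
            missing_rate=config.missing_rate,
            psm_count_range=(config.psm_count_min, config.psm_count_max),
            seed=config.child_seed("simulate"))
        truth.per_protein.to_csv(out / "truth.tsv", sep="\t", index=False)
    proteins = sorted(psms.frame["protein"].unique())

    if config.gene_sets_path:
        gene_sets = read_gene_sets_gmt(config.gene_sets_path)
        if config.positions_path:
            gene_sets.positions.update(read_position_table(config.positions_path))
    else:
        top = design.top_dose_group
        planted_down = truth.planted_down(top) if truth is not None else set()
        all_planted = truth.planted if truth is not None else set()
        gene_sets = synthetic.generate_gene_sets(
            proteins, planted_proteins=planted_down,
            background_exclude=all_planted,
            seed=config.child_seed("genesets"))

    if config.kinome_path:
        panel = read_kinome_panel(config.kinome_path)
    else:
        panel, _ = synthetic.generate_kinome_panel(
            n_kinases=config.n_kinases,
            n_overlap_with_proteome=config.n_overlap_kinases,
            seed=config.child_seed("kinome"), proteome_symbols=tuple(proteins))

    if config.substrate_path:
        smap = read_substrate_map(config.substrate_path)
    else:
        top = design.top_dose_group
        down = (truth.planted_down(top) if truth is not None else set())
        kinases = list(panel["kinase"].unique())
        enriched = kinases[0]
        smap, _ = synthetic.generate_substrate_map(
            kinases, proteins, enriched_kinase=enriched,
            enrichment_or=config.enrichment_or,
            seed=config.child_seed("substrates"), downregulated=down)
    return design, psms, truth, gene_sets, panel, smap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all outputs under ``config.out_dir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    design, psms, truth, gene_sets, panel, smap = \
        _load_or_simulate_inputs(config, out)

    # preprocess
    matrix, qc = preprocess.preprocess_pipeline(
        psms, fdr_max=config.fdr_max,
        min_nonzero_channels=config.min_nonzero_channels,
        tail_quantile=config.tail_quantile, seed=config.child_seed("impute"))
    write_results_table(matrix.values.reset_index(), out / "protein_matrix.tsv")
    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2)

    # differential expression + effect sizes
    de = diffstats.fit_moderated_de(matrix, design, alpha=config.alpha,
                                    fc_threshold=config.fc_threshold)
    ref = design.group_labels[0]
    sig_counts, de_by_dose = {}, {}
    for name, res in de.items():
        treated = name.split("_vs_")[0]
        eff = diffstats.effect_sizes(matrix, design, contrast=(treated, ref))
        merged = res.join(eff[["d", "g", "J", "s_pooled", "magnitude_class"]])
        write_results_table(merged.reset_index(), out / f"de_{treated}.tsv")
        calls = diffstats.call_significance(res, alpha=config.alpha,
                                            fc_threshold=config.fc_threshold)
        sig_counts[treated] = {k: v for k, v in calls.items() if k != "result"}
        de_by_dose[treated] = merged

    dose_order = sorted(de_by_dose, key=design.dose_of)
    lfc = pd.DataFrame({d: de_by_dose[d]["log2fc"] for d in dose_order})
    states, transitions = diffstats.dose_fate(lfc, config.fc_threshold)
    sig_sets = {d: set(de_by_dose[d].index[de_by_dose[d]["significant"]])
                for d in dose_order}
    upset = diffstats.intersection_summary(sig_sets)

    # pathway scoring
    curves = pathways.dose_response_curves(
        {d: de_by_dose[d] for d in dose_order}, gene_sets)
    write_results_table(curves, out / "pathway_scores.tsv")
    dose = config.dose_of_interest or design.top_dose_group
    universe = set(matrix.proteins)
    enr = pathways.pathway_enrichment(sig_sets[dose], gene_sets, universe)
    write_results_table(enr, out / "pathway_enrichment.tsv")

    # kinome integration
    profile = integration.preprocess_kinome(panel)
    eff_dose = de_by_dose[dose]
    merged, unmatched = integration.merge_kinome_proteomics(profile, eff_dose)
    write_results_table(merged, out / "integration.tsv")
    summary_int = {}
    if len(merged) >= 3:
        summary_int["spearman_signed"] = integration.concordance_correlation(
            merged, use_signed=True)
        summary_int["spearman_abs"] = integration.concordance_correlation(
            merged, use_signed=False)
        rank_inh = list(merged.sort_values("inhibition",
                                           ascending=False)["symbol"])
        rank_g = list(merged.sort_values("g_abs", ascending=False)["symbol"])
        rrho = integration.rrho_map(rank_inh, rank_g, step=config.rrho_step)
        write_results_table(rrho, out / "rrho.tsv")
    down = {p for p, r in eff_dose.iterrows()
            if r["fdr"] < config.alpha and r["log2fc"] < -config.fc_threshold}
    sub_enr = integration.substrate_enrichment(smap, down, universe)
    write_results_table(sub_enr, out / "substrate_enrichment.tsv")

    top_paths = (curves[curves["dose"] == dose]
                 .assign(absact=lambda d: d["weighted_activity"].abs())
                 .sort_values("absact", ascending=False))
    summary = {
        "seed": config.seed,
        "n_proteins_quantified": int(len(matrix.proteins)),
        "qc": qc,
        "significant_counts": sig_counts,
        "consistent_ge2": upset["consistent_ge2"],
        "dose_fates": {f"{a}->{b}": {f"{s1}->{s2}": n
                                     for (s1, s2), n in cnt.items()}
                       for (a, b), cnt in transitions.items()},
        "top_pathways": top_paths.head(5)[
            ["pathway", "weighted_activity"]].to_dict("records"),
        "quadrant_counts": (merged["quadrant"].value_counts().to_dict()
                            if len(merged) else {}),
        "unmatched_kinases": len(unmatched),
        "top_substrate_kinases": (sub_enr.sort_values("p").head(5)[
            ["kinase", "odds_ratio", "p"]].to_dict("records")
            if len(sub_enr) else []),
        **summary_int,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary
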