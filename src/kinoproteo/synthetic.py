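"""Synthetic-data generators with emitted ground truth.

These generators emulate the statistical structure of the study design the
pipeline targets — an 11-sample, 4-dose-group TMT experiment — so that every
downstream stage can be exercised and benchmarked without any raw
mass-spectrometry data:

* protein base abundances are log-normal;
* planted differential proteins shift linearly in log2 space with dose,
  reaching their full effect at the top dose;
* each protein carries a random PSM count, and protein-level measurement
  noise decreases with PSM count (the variance-count relationship the
  moderated differential test exploits);
* missingness is left-censored (MNAR): the lowest-intensity observations in
  each sample are removed first;
* a kinome panel and a kinase->substrate map can be planted with known
  inhibition values and a known substrate-enrichment odds ratio.

Every generator is a pure function of its seed and returns the ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from kinoproteo.errors import ValidationError
from kinoproteo.io_formats import (
    PsmTable,
    SampleDesign,
    SubstrateMap,
    GeneSetCollection,
    normalize_symbol,
)

#: 12 signalling-pathway families used to label synthetic kinome panels.
KINOME_PATHWAYS = (
    "JAK/STAT", "PAK", "MAPK/ERK", "PI3K/AKT/mTOR", "RTK", "Cell Cycle",
    "Aurora", "PKC", "IKK/NF-kB", "PIM", "SRC Family", "Autophagy",
)

#: set-size profile of the 13 curated signalling pathways used in tests
PATHWAY_SET_SIZES = (30, 25, 21, 17, 27, 26, 15, 17, 19, 23, 13, 16, 13)

PATHWAY_NAMES = (
    "JAK/STAT", "PAK/Rho GTPase", "PI3K/AKT", "MAPK", "Apoptosis",
    "Cell Cycle", "Ribosome Biogenesis", "RNA Processing", "TCR Signaling",
    "Nuclear Transport", "Immune Checkpoint", "NF-kB", "mTOR",
)


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every generated PSM dataset."""

    per_protein: pd.DataFrame  # protein, is_planted_de, true_log2fc_<group>...
    seed: int

    @property
    def planted(self) -> set[str]:
        mask = self.per_protein["is_planted_de"]
        return set(self.per_protein.loc[mask, "protein"])

    def planted_down(self, group: str) -> set[str]:
        col = f"true_log2fc_{group}"
        mask = self.per_protein["is_planted_de"] & (self.per_protein[col] < 0)
        return set(self.per_protein.loc[mask, "protein"])


def generate_psm_dataset(
    n_proteins: int = 2000,
    design: SampleDesign | None = None,
    frac_de: float = 0.05,
    effect_log2fc: float = 2.0,
    missing_rate: float = 0.02,
    psm_count_range: tuple[int, int] = (1, 40),
    seed: int = 0,
    base_log2_mean: float = 20.0,
    base_log2_sd: float = 1.5,
    within_group_sd: float = 0.25,
    psm_noise_sd: float = 0.5,
) -> tuple[PsmTable, SyntheticTruth]:
    """Generate a PSM-level quantification table with known ground truth.

    Planted proteins (a ``frac_de`` fraction, random sign) shift linearly in
    log2 space with dose, reaching ±``effect_log2fc`` at the top dose. Each
    protein gets a PSM count drawn uniformly from ``psm_count_range``; its
    channel intensity is split across PSMs with per-PSM multiplicative noise
    (sd ``psm_noise_sd`` in log2 units), so protein-level noise after roll-up
    shrinks with PSM count. Left-censoring then zeroes the lowest-intensity
    PSM observations per sample at an overall rate ≈ ``missing_rate``.
    """
    if not 0 <= frac_de <= 1:
        raise ValidationError("frac_de must be in [0,1]")
    if not 0 <= missing_rate < 0.1:
        raise ValidationError("missing_rate must be in [0, 0.1)")
    if psm_count_range[0] < 1 or psm_count_range[1] < psm_count_range[0]:
        raise ValidationError("psm_count_range must be >= 1 and ordered")
    design = design or SampleDesign.default_tmt11()

    rng = np.random.default_rng(seed)
    proteins = np.array([f"P{i:05d}" for i in range(1, n_proteins + 1)])
    n_planted = int(round(frac_de * n_proteins))
    planted_idx = rng.choice(n_proteins, size=n_planted, replace=False)
    is_planted = np.zeros(n_proteins, dtype=bool)
    is_planted[planted_idx] = True
    signs = rng.choice([-1.0, 1.0], size=n_proteins)
    top_lfc = np.where(is_planted, signs * effect_log2fc, 0.0)

    doses = np.asarray(design.doses)
    top_dose = doses.max()
    # per-channel planted shift: linear in dose, full effect at top dose
    shift = np.outer(top_lfc, doses / top_dose)  # proteins x channels

    base = rng.normal(base_log2_mean, base_log2_sd, size=n_proteins)
    bio = rng.normal(0.0, within_group_sd, size=(n_proteins, design.n_channels))
    true_log2 = base[:, None] + shift + bio  # proteins x channels

    counts = rng.integers(psm_count_range[0], psm_count_range[1] + 1,
                          size=n_proteins)

    rows_protein = np.repeat(np.arange(n_proteins), counts)
    n_psms = rows_protein.size
    # split each protein's linear intensity evenly across its PSMs, then
    # perturb each PSM cell with multiplicative log-normal noise
    share_log2 = true_log2[rows_protein] - np.log2(counts[rows_protein])[:, None]
    eps = rng.normal(0.0, psm_noise_sd, size=(n_psms, design.n_channels))
    intens = np.exp2(share_log2 + eps)

    # left-censoring: per sample, zero the lowest-intensity PSM cells
    n_censor = int(round(missing_rate * n_psms))
    censored = np.zeros_like(intens, dtype=bool)
    if n_censor > 0:
        for j in range(design.n_channels):
            order = np.argsort(intens[:, j], kind="stable")[:n_censor]
            censored[order, j] = True
        intens[censored] = 0.0

    frame = pd.DataFrame(intens, columns=list(design.channels))
    frame.insert(0, "psm_id", [f"PSM{i:07d}" for i in range(1, n_psms + 1)])
    frame.insert(1, "protein", proteins[rows_protein])
    frame.insert(2, "psm_fdr", rng.uniform(0.0, 0.01, size=n_psms))

    truth_cols = {"protein": proteins, "is_planted_de": is_planted}
    for g in design.group_labels:
        truth_cols[f"true_log2fc_{g}"] = top_lfc * design.dose_of(g) / top_dose
    truth = SyntheticTruth(per_protein=pd.DataFrame(truth_cols), seed=seed)
    return PsmTable(frame=frame, design=design), truth


def generate_kinome_panel(
    n_kinases: int = 97,
    n_overlap_with_proteome: int = 0,
    planted_strong: tuple[str, ...] = (),
    seed: int = 0,
    proteome_symbols: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a kinome panel (kinase, percent_control, pathway) plus truth.

    ``planted_strong`` kinases receive inhibition > 50% (strong class).
    When ``proteome_symbols`` is given, the first ``n_overlap_with_proteome``
    non-planted kinases take symbols from it so a downstream merge with the
    proteome succeeds for exactly those kinases (plus any planted symbol that
    also appears in the proteome).
    """
    rng = np.random.default_rng(seed)
    planted = [normalize_symbol(k) for k in planted_strong]
    if len(planted) > n_kinases:
        raise ValidationError("more planted kinases than panel size")
    symbols = list(planted)
    overlap_pool = [normalize_symbol(s) for s in proteome_symbols
                    if normalize_symbol(s) not in set(planted)]
    n_overlap = min(n_overlap_with_proteome, len(overlap_pool))
    symbols += list(rng.choice(overlap_pool, size=n_overlap, replace=False))
    i = 1
    while len(symbols) < n_kinases:
        cand = f"KIN{i:03d}"
        if cand not in symbols:
            symbols.append(cand)
        i += 1

    inhibition = rng.uniform(0.0, 50.0, size=n_kinases)
    inhibition[: len(planted)] = rng.uniform(55.0, 85.0, size=len(planted))
    pathways = [KINOME_PATHWAYS[i % len(KINOME_PATHWAYS)]
                for i in range(n_kinases)]
    panel = pd.DataFrame({
        "kinase": symbols,
        "percent_control": 100.0 - inhibition,
        "pathway": pathways,
    })
    truth = pd.DataFrame({"kinase": symbols, "true_inhibition": inhibition,
                          "planted_strong": [s in set(planted) for s in symbols]})
    return panel, truth


def generate_substrate_map(
    kinases: list[str],
    proteins: list[str],
    enriched_kinase: str,
    enrichment_or: float = 5.0,
    seed: int = 0,
    downregulated: set[str] | None = None,
    n_substrates: int = 50,
) -> tuple[SubstrateMap, dict]:
    """Generate a kinase->substrate map with a planted enrichment.

    Substrates of ``enriched_kinase`` are drawn preferentially from the
    ``downregulated`` protein set so that the expected 2x2 odds ratio of
    (substrate vs not) x (downregulated vs not) equals ``enrichment_or``;
    all other kinases draw substrates uniformly (odds ratio 1 in
    expectation).
    """
    if enrichment_or < 1:
        raise ValidationError("enrichment_or must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = [normalize_symbol(p) for p in proteins]
    downregulated = {normalize_symbol(p) for p in (downregulated or set())}
    enriched_kinase = normalize_symbol(enriched_kinase)
    down = sorted(downregulated & set(proteins))
    other = sorted(set(proteins) - set(down))
    n_total, m = len(proteins), len(down)
    if m == 0 and enrichment_or > 1:
        raise ValidationError("cannot plant enrichment without downregulated proteins")

    pairs = []
    for kin in kinases:
        kin = normalize_symbol(kin)
        s = min(n_substrates, n_total)
        if kin == enriched_kinase and enrichment_or > 1:
            # choose the expected substrate/downregulated overlap a so the
            # 2x2 odds ratio a*d/(b*c) with b = s-a, c = m-a, d = N-m-s+a
            # equals the target exactly: quadratic in a
            R = enrichment_or
            A = 1.0 - R
            B = n_total - m - s + R * (s + m)
            C = -R * s * m
            a_star = (-B + np.sqrt(B * B - 4 * A * C)) / (2 * A)
            f = min(max(a_star / s, 0.0), 1.0)
            k_down = min(int(rng.binomial(s, f)), m)
            subs = list(rng.choice(down, size=k_down, replace=False))
            subs += list(rng.choice(other, size=min(s - k_down, len(other)),
                                    replace=False))
        else:
            subs = list(rng.choice(proteins, size=s, replace=False))
        pairs += [(kin, sub) for sub in subs]

    smap = SubstrateMap(pairs=pd.DataFrame(pairs, columns=["kinase", "substrate"]))
    truth = {"enriched_kinase": enriched_kinase,
             "enrichment_or": float(enrichment_or), "seed": seed}
    return smap, truth


def generate_gene_sets(
    proteins: list[str],
    planted_proteins: set[str] | None = None,
    planted_pathway: str = PATHWAY_NAMES[0],
    set_sizes: tuple[int, ...] = PATHWAY_SET_SIZES,
    names: tuple[str, ...] = PATHWAY_NAMES,
    seed: int = 0,
    background_exclude: set[str] | None = None,
) -> GeneSetCollection:
    """Generate a pathway gene-set collection over the protein universe.

    The planted pathway's members are drawn from ``planted_proteins`` — pass
    a coherently regulated set (e.g. the planted downregulated proteins) so
    the pathway's activity score moves as one block, the way a suppressed
    pathway behaves. Other pathways draw uniformly from the universe minus
    ``background_exclude`` (defaults to the planted set), keeping the null
    pathways free of planted signal. Position tags cycle
    upstream/central/downstream within each set.
    """
    rng = np.random.default_rng(seed)
    proteins = [normalize_symbol(p) for p in proteins]
    planted = sorted({normalize_symbol(p) for p in (planted_proteins or set())}
                     & set(proteins))
    exclude = {normalize_symbol(p) for p in
               (background_exclude if background_exclude is not None
                else planted)}
    rest = sorted(set(proteins) - set(planted) - exclude)
    sets: dict[str, list[str]] = {}
    positions: dict[str, str] = {}
    tags = ("upstream", "central", "downstream")
    for name, size in zip(names, set_sizes):
        if name == planted_pathway and planted:
            take = min(size, len(planted))
            members = list(rng.choice(planted, size=take, replace=False))
            if take < size:
                members += list(rng.choice(rest, size=size - take, replace=False))
        else:
            members = list(rng.choice(rest, size=min(size, len(rest)),
                                      replace=False))
        sets[name] = members
        for i, g in enumerate(members):
            positions.setdefault(g, tags[i % 3])
    return GeneSetCollection(sets=sets, positions=positions)
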