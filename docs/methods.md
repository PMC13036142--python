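# Methods

This note documents the statistical models implemented in `kinoproteo`,
the choices made where the methods literature leaves latitude, and what the
synthetic-data generator does and does not emulate.

## Study design and data model

The pipeline targets an 11-plex TMT dose-response experiment: four dose
groups (vehicle, 1, 2.5, 10 µM) at n = 3, 3, 3, 2, one reporter channel per
sample. Input is a PSM-level table (PSM id, protein accession, PSM-level
FDR, 11 reporter intensities). Protein inference and search-engine
validation are upstream of this package; the protein column is taken as
authoritative.

## Preprocessing

* **PSM filter** — keep PSMs with PSM-FDR ≤ 0.01 and strictly positive
  intensity in ≥ 6 of 11 channels. "Non-zero" is read as strictly positive:
  a zero reporter intensity means the ion was not observed.
* **Roll-up** — protein × channel abundance is the sum of reporter
  intensities over the protein's retained PSMs; the per-protein PSM count
  is the number of contributing PSMs. A summed value of exactly 0 becomes a
  missing cell rather than a pseudocounted log — this preserves the
  left-censoring interpretation that the imputation model assumes.
* **QRILC imputation**, per sample column, on the log₂ scale. With observed
  missing rate r, the sorted observed values are regressed (ordinary least
  squares) against standard-normal quantiles of plotting positions confined
  to (r, 1), treating the observed data as the upper 1−r portion of a
  normal distribution; intercept and slope estimate the complete
  distribution's mean and SD. Missing cells are drawn from that normal
  truncated above at its `tail_quantile` quantile (default 0.01, scale
  factor `tune_sigma` = 1.0). Imputation never touches observed cells and
  is deterministic given a seed. Columns with ≥ 50% missing are refused —
  the order-statistic regression is not trustworthy there.
* **QC** — median within-group CV on the linear scale, pre-imputation
  missing rate, and mean pairwise replicate correlation.

## Moderated differential expression

Per protein, group means are ordinary least squares under the group-means
model; the pooled residual variance s² has d = n − k degrees of freedom
(d = 7 for the full design). Because proteins quantified from more spectra
are measured more precisely, the variance prior is a lowess trend (fraction
0.5) of log s² against log PSM count. Two numerical points matter:

* **Chi-square log bias.** E[log s²] = log σ² + ψ(d/2) − log(d/2), which is
  −0.27 at d = 4. The lowess fit is shifted by the negative of this bias
  before exponentiating; without the correction the prior variance is
  understated by ~25% at small d and the moderated p-values become
  anti-conservative (we observed false-discovery proportions drifting to
  the nominal bound before adding it).
* **Prior degrees of freedom.** d₀ is estimated by moment matching on
  z = log(s²/s₀²): under the hierarchical model Var(z) = ψ′(d/2) + ψ′(d₀/2),
  so the excess of the empirical variance over ψ′(d/2) identifies d₀
  (Newton inversion of the trigamma function). Var(z) ≤ ψ′(d/2) means the
  variances scatter no more than sampling alone explains and d₀ = ∞
  (complete shrinkage to the trend).

The moderated statistic is t = log₂FC / (s̃·√(1/n₁+1/n₂)) with
s̃² = (d₀s₀² + ds²)/(d₀+d) on d + d₀ df. Setting `prior_df=0` recovers the
classical equal-variance two-sample t exactly (a tested identity);
`prior_df=inf` gives pure trend shrinkage. Contrasts default to each dose
versus vehicle. P-values are BH-adjusted per contrast. Two significance
tallies are reported — the conjunction rule (FDR < 0.05 and |log₂FC| >
0.585) and FDR-only — because published protein counts use either.

## Effect sizes

Cohen's d uses the (n₁−1, n₂−1)-weighted pooled SD; Hedges'
g = d·[1 − 3/(4(n₁+n₂)−9)] corrects the small-sample bias, making g a
near-unbiased estimator of the population standardized effect. Zero pooled
SD yields an undefined (NaN) effect, flagged and excluded from downstream
rankings rather than set to ±∞. Magnitude classes: |g| < 0.8 small,
[0.8, 1.5) notable, [1.5, 3.0) strong, ≥ 3.0 definitive.

## Pathway activity and enrichment

Member weight W_i = position_i · (−log₁₀FDR_i) · |log₂FC_i| with position
weights upstream 1.5, central 1.0, downstream 0.5 (positions default to
central when unannotated; the position table is a required input, never
inferred). FDR is floored at 10⁻¹⁶ before the log so the weight stays
finite; FDR exactly 1 contributes zero weight. The activity is the
W-weighted mean of member log₂FCs — scale-invariant in W, bounded by the
member log₂FC range, and degenerate (flagged, unweighted mean) when all
weights vanish. The reported dispersion is the SE of the weighted mean,
√(Σ w̃_i²(x_i − x̄_w)²) with normalized weights. Pathway enrichment is a
one-sided Fisher exact test on (in-pathway × significant) with BH across
pathways; the odds ratio is the sample OR.

## Kinome integration

Panels report percent-control (100 = uninhibited); inhibition = 100 − PC.
Duplicate kinase entries collapse to the strongest inhibition. Class
boundaries follow the printed intervals: strong is strictly > 50, moderate
is [30, 50], weak < 30. Concordance quadrants: Concordant-High requires
inhibition > 30 **and strictly negative** g; Concordant-Low requires
inhibition < 30 and g ≥ 0; everything else — including g = 0 at high
inhibition and inhibition exactly 30 — is Discordant. Spearman concordance
is first-class in both signed-g and |g| modes, since both orderings are
scientifically meaningful (direction of effect versus magnitude
concordance). RRHO tests, at each grid point (i, j), the overlap of the
top-i of one ranking with the top-j of the other against the upper-tail
hypergeometric P(X ≥ overlap); the default grid step is max(1, ⌊N/20⌋).
Substrate enrichment is a per-kinase one-sided Fisher test of (substrate ×
downregulated) over the quantified universe; "downregulated" defaults to
FDR < 0.05 and log₂FC < −0.585 at the configured dose (top dose by
default). The Haldane–Anscombe +0.5 correction applies only when a zero
cell occurs. Top-substrate selection orders by |log₂FC| descending with
lexicographic tie-breaks.

## In-vivo arithmetic

Tumor volume is L·W²/2 with L the longer dimension (swapped inputs are
reoriented with a warning). Group summaries use arithmetic means of
final-day volumes. Percent reduction is 100·(control−treated)/control at
one decimal. The Spearman CI uses the Fisher z transform with
SE = 1/√(n−3); for n ≤ 9 the p-value is exact by full permutation
enumeration rather than the t approximation.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline exploits:

* log-normal protein base abundances (log₂ mean 20, SD 1.5);
* within-group biological variation σ(log₂) = 0.25;
* planted differential proteins (default 5%, random sign) shifting
  linearly in log₂ space with dose, reaching ±2 at the top dose;
* per-protein PSM counts uniform on 1–40 (the count distribution is a free
  parameter, not an inference), with per-PSM multiplicative noise (σ = 0.5
  log₂ units) so protein-level precision rises with PSM count;
* left-censored missingness: the lowest-intensity PSM observations per
  sample are zeroed until the target rate (default 2%) is met — the
  simplest mechanism satisfying the MNAR assumption QRILC targets;
* a kinome panel whose pathway labels cycle over 12 families, with
  optional planted strong kinases and controlled proteome overlap;
* a substrate map in which the planted hub's substrates are drawn so the
  expected 2×2 odds ratio equals the target exactly (the expected overlap
  solves a quadratic in the cell count; the small-substrate-set
  approximation biases the realized OR upward and is not used);
* pathway gene sets with the published 13-set size profile, whose planted
  pathway draws from the coherently downregulated planted proteins —
  a suppressed pathway moves as a block, which is what makes its weighted
  activity dominate; other pathways exclude planted proteins entirely.

What it does **not** emulate: chromatography and acquisition effects,
isotopic impurity and TMT ratio compression, peptide-level shared/razor
ambiguity, correlated protein co-regulation, or realistic protein-level
missingness rates (censoring 2% of PSM cells yields ~0.1% protein-level
missingness after roll-up, versus a few percent in real matrices). With
σ(log₂) = 0.25 plus PSM noise, synthetic within-group CVs run ~13–17%,
higher than the single-digit CVs of a well-behaved real TMT experiment.
Passing tests therefore demonstrate correctness and calibration of the
statistics under a clean MNAR/log-normal model, not robustness to every
artefact of real data.

## Problem sizes and tolerances

The operating-characteristic checks run at: null type-I — 20 seeds × 800
proteins (full 11-plex design, nothing planted); power and FDP — 10 seeds
× 2000 proteins in a dedicated 3-vs-3 two-group design with planted
|log₂FC| = 2; planted-pathway dominance — 10 seeds × 2000 proteins;
substrate odds-ratio recovery — maps over a 4000-protein universe with 300
substrates against 300 downregulated proteins (the acceptance script pools
ten such maps, which share margins, for a stable estimate). These sizes
give each check clear resolution at desk scale; results at these sizes are
stated wherever the package reports them.

## Known limitations

* The moderated model assumes normal residuals on the log₂ scale; summed
  lognormal PSM noise is only approximately normal at high PSM counts.
* Imputed cells are treated as observed in downstream variance estimation
  (as in standard impute-then-test workflows), which slightly understates
  uncertainty when missingness is non-trivial.
* The Woolf odds-ratio CI is mildly narrow at moderate counts (~90–92%
  observed coverage for the generator's single-map sampling scheme).
* RRHO p-values are per-cell and not corrected across the grid; the map is
  exploratory by construction.
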