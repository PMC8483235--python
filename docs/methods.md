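# Methods

This note documents the statistical models behind `endomix`, the design of
the synthetic cohort generator, the numerical choices that affect results,
and what the test suite does and does not establish about real data.

## Endotype classification

Sputum samples are partitioned by the established two-threshold rule on
differential cell counts: eosinophils ≥ 3 % and neutrophils ≥ 61 % define
the eosinophilic/neutrophilic axes, with mixed-granulocytic (both high) and
paucigranulocytic (both low) completing the partition. Thresholds are
configurable (`EndotypeThresholds`) but default-locked to 3 %/61 %.
Percentages are compared as decimals without prior rounding — whether the
source cohorts rounded before thresholding is not documented, and unrounded
comparison is the least surprising choice. A missing percentage yields
`unassigned`; no imputation is attempted, so unassigned samples simply drop
out of endotype-conditioned analyses (they still participate in clustering
and ecology).

## Community typing

Profiles are compared with the square root of the Jensen–Shannon divergence
computed with log base 2, which is a proper metric bounded by [0, 1]
(0·log 0 ≡ 0). Ward-linkage agglomeration is applied to this matrix via the
Lance–Williams recurrence. A caveat is inherited from standard
enterotyping practice: Ward's variance semantics are exact only for
squared Euclidean distances, and √JSD is not Euclidean in general; the
procedure is used as the field uses it, as a clustering heuristic whose
output is validated independently.

The number of clusters k maximises the mean silhouette width over
dendrogram cuts for k = 2..10 (ties to the smaller k). Validation uses PAM
(k-medoids) on the same distances, scored by a distance-based
Calinski–Harabasz index derived from the identity
Σᵢ‖xᵢ−μ𝒸‖² = (1/2n𝒸)Σᵢⱼ d²ᵢⱼ. Two practical findings are worth recording:

* **PAM exactness.** The BUILD+SWAP neighbourhood admits local optima even
  at n = 6 (verified against exhaustive enumeration), so `PAMKMedoids`
  solves instances with C(n, k) ≤ 2000 exactly by enumeration and uses
  BUILD+SWAP only beyond that.
* **CH prefers the coarse split.** On cohorts with one large balanced
  cluster and small dominated clusters, the distance-based CH index peaks
  at k = 2 (balanced vs dominated) even when the k = 4 partition matches
  the generative truth almost perfectly. PAM agreement with the Ward
  partition at the silhouette-selected k is therefore the meaningful
  validation statistic; the CH-optimal k is still reported.

Clusters are named by dominance: a cluster whose top mean-abundance genus
exceeds 0.3 is "<Genus>-predominant", otherwise "balanced" (indexed when
several clusters qualify). The 0.3 default cleanly separates reported
dominant abundances (a 0.41 *Haemophilus* biomarker cutoff) from balanced
means (< 0.15). Biomarker thresholds use midrank Mann–Whitney AUC and the
Youden-J-optimal cutoff, ties resolved to the lower cutoff.

Clustering is run on all samples jointly; a per-cohort run is a matter of
subsetting the input table.

## Ecology

Shannon diversity is −Σ p ln p (nats). Bray–Curtis, PCoA (via classical
scaling, with negative eigenvalues reported), one-way PERMANOVA
(pseudo-F on squared distances; R² = SS_between/SS_total;
p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) under seeded label permutation)
and distance-to-centroid dispersion follow the standard definitions.
Dispersion uses group centroids in PCoA space with the imaginary-axis
correction (squared distances on negative-eigenvalue axes subtracted,
clipped at zero) and compares groups by rank-sum tests with BH adjustment —
the original dispersion test statistic is not documented, and rank-sum on
distances is the simplest contract consistent with "deviation from the
centroid". Paired stability–exacerbation shifts pair each exacerbation with
the patient's most recent preceding stable sample (prospective reading of
"paired"); exacerbations with no preceding stable visit are excluded.

## Transitions

The joint endotype × community label collapses to NH (neutrophilic,
*Haemophilus*-predominant), NB (neutrophilic, balanced) and E
(eosinophilic, any community); everything else — including neutrophilic
samples in *Moraxella*/*Streptococcus*-predominant communities — is
EXCLUDED. Pairs are chronologically consecutive visits of one patient; a
pair containing an EXCLUDED sample is dropped rather than bridged
(bridging would inflate measured persistences well away from the
generating transition probabilities). Only stable–stable and
stable–exacerbation contexts are analysed. Odds ratios use ad/bc with the
Haldane–Anscombe +0.5 correction on zero cells (flagged), Woolf log-normal
95 % CIs, and two-sided z p-values. Season is the meteorological quarter of
the visit date; "seasonal change" means the two visits of a pair fall in
different quarters.

## Time series

**Changepoints.** PELT minimises Σ segment SSE + β·(#changepoints) exactly,
with cost evaluated in O(1) from prefix sums. The default penalty is
β = 2σ̂² log n with σ̂² = var(Δx)/2, a first-difference noise estimate
robust to mean shifts. Minimum segment length is 2. One implementation
subtlety: with a minimum segment length, PELT's pruning must be delayed by
min_seg − 1 steps — a candidate failing the pruning test at time t is
dominated by a split at t only once the segment (t, t′) is itself
admissible. Without the delay the algorithm returns suboptimal
segmentations on roughly 1 in 200 random series; with it, output matches
exhaustive search on thousands of random instances.

**Changepoint–event association.** For each genus and each patient with at
least 5 visits, an inter-visit transition "contains" a changepoint when a
new segment starts at the destination visit (the tightest reading of a
break coinciding with a state switch). Transitions pool into one 2×2 table
per genus; significance requires the Woolf CI lower bound to exceed 1.
Events are exacerbation occurrence at the destination visit, or
neutrophilic↔eosinophilic switches between consecutive stable visits.

**Cross-covariance.** Both series are z-scored; r(ℓ) = (1/n)Σ a[t+ℓ]b[t]
(the ccf convention, |r| ≤ 1) for |ℓ| ≤ 1 — visits are sparse and
irregular, so longer lags are not meaningful; positive lag means the genus
leads. The score is the signed maximum over lags; this is a documented
convention (lag-0-only and absolute-value variants are one argument away).
Per-patient scores (patients with ≥ 5 visits and positive variance in both
series) sum to the cumulative score; the null permutes each patient's
abundance series order (cell series fixed), and significance is a pooled
one-sided rank-sum of observed per-patient scores against the pooled
permuted scores, BH-adjusted across genera. The pooled (rather than
per-patient-paired) comparison is the default; the alternative pairing is
not implemented because the pooled test calibrates correctly (type-I error
≈ 0.05 in simulation).

## Differential abundance

The LEfSe-style screen runs a Kruskal–Wallis test per genus with BH FDR as
the primary mode (a flag restores the classic raw-α behaviour). Effect
sizes for screen-passing genera are the mean over 30 class-stratified
bootstrap subsamples (2/3 of samples) of log₁₀(1 + |Δ class means|) on
abundances scaled to the 1–10⁶ range — for two classes this is the
one-dimensional discriminant reading of a single feature, so a 4-decade
abundance difference maps to an effect near 5 and the conventional
LDA > 4 threshold keeps its meaning. The original subclass (within-class
Wilcoxon) stage is omitted: no subclass structure exists in this design.

Two dominance-control normalizations address the compositional shadow of
an overgrown genus: `rescale_dominant` pins the target genus to its
across-sample mean and rescales the remainder proportionally (preserving
non-target ratios), and `quantile_rank` replaces abundances with
within-sample percentile ranks (invariant to any strictly monotone
per-sample transform).

The eosinophilia variance-explained model is a linear mixed model of
sputum eosinophil % on genus abundances and covariates with a per-patient
random intercept; the reported marginal R² is the Nakagawa–Schielzeth
decomposition var(Xβ̂)/(var(Xβ̂) + σ²_patient + σ²_residual). With no
repeated visits the model degrades to OLS with a warning.

## Networks

SparCC: each estimation iteration (default 20) draws fractions from the
per-sample Dirichlet posterior (pseudo-count 1), forms the variation
matrix t_ij = var(log xᵢ/xⱼ), and solves the sparse approximation
t_ij ≈ ωᵢ + ωⱼ for basis variances by least squares, iteratively excluding
the most strongly correlated pair (|r| > 0.1, up to 10 rounds, stopping if
the system would become underdetermined or a genus unrepresented);
r_ij = (ωᵢ + ωⱼ − t_ij)/(2√(ωᵢωⱼ)), median across iterations, clipped to
[−1, 1]. Three genera are accepted (the 3-equation system is exactly
determined and serves as the closed-form oracle).

Edge significance permutes every genus column independently and re-runs
SparCC per permutation. Per-pair permutation p-values at B = 100 cannot
clear BH at q < 0.05 across hundreds of pairs (resolution 1/(B+1)), so
null correlations are studentised per pair (centred/scaled by that pair's
permutation moments — pairs involving rare genera are noisier) and pooled
across pairs, which are exchangeable after column shuffling. The pooled
studentised null gives p-value resolution of 1/(B·#pairs+1) and verified
type-I error ≈ 0.05.

Networks retain edges with q below threshold, capped at the top 100 by |r|
per sign; Louvain modules are computed on the |r|-weighted graph with 10
seeded restarts keeping the best modularity (Louvain is order-dependent).
Microbiome–mediator association residualises each feature on demographic
covariates (configurable set; age, sex, BMI, smoking by default) with a
per-patient random intercept, then computes Spearman correlations for all
genus–mediator pairs with BH FDR (q < 0.1, top 20 per sign). The
hierarchical (HAllA-style) testing layer is deliberately replaced by this
flat all-against-all screen; the residualization step is kept faithful.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, with
ground truth for every sample. It is the package's test bed: its defaults
are the study conditions wherever those are stated, and one-time design
choices elsewhere.

* **Visits.** Visits per patient follow a geometric distribution (p = 0.30)
  truncated at 13 (range 1–13; mean ≈ 3.2, matching ~1,366 samples from
  423 patients). The first visit is stable; later visits are exacerbations
  with probability 0.33 (446/1,366). Gaps are uniform on 28–90 days.
* **States.** A five-state Markov chain over {NH, NB, E, MIXED, PAUCI} with
  separate stable→stable and stable→exacerbation matrices. The NH/NB/E
  diagonals are the reported persistences (0.714/0.384/0.418 stable–stable;
  0.591/0.214/0.333 stable–exacerbation). Off-diagonal mass follows the
  qualitative pattern: NH and E nearly mutually exclusive (direct traffic
  ≤ 6 %), NB interchangeable with both, and the NB row of the exacerbation
  matrix sends ≈ 47.6 % to dominated communities. NH/NB/E rows leak only
  ~2 % into MIXED/PAUCI: the published persistences are measured after
  pair exclusion, so they can only match the raw diagonals if that leak is
  small. MIXED/PAUCI presence comes from the initial distribution
  (0.18/0.28) and their own persistent rows. Consequence: cross-sectional
  state proportions only approximate the published subgroup distribution —
  the persistences, which are the explicitly parameterised quantities,
  take precedence. Transitions out of an exacerbation use the
  stable→stable matrix (recovery).
* **Compositions.** Four community types over 24 named genera, drawn from
  Dirichlet distributions. Balanced: Veillonella+Prevotella combined mean
  0.26 (the reported optimal cutoff for segregating the balanced
  subgroup), top genus mean 0.14, concentration scale 100. Dominated
  (Haemophilus/Moraxella/Streptococcus): dominant mean 0.6, remainder
  proportional to the balanced profile, scale 150. Mixture probabilities
  per state reproduce the reported community proportions
  (~70/15/7/6 % balanced/H/M/S): NH is Haemophilus-predominant and NB
  balanced by definition; E/MIXED/PAUCI carry the dominated minorities.
  These scales were calibrated once so that the documented four-type
  structure is recoverable — which is itself a required property of the
  generator — and then frozen.
* **Colonisation propensity.** Each patient has a standard-normal
  dominance factor z: the dominant genus concentration is scaled by
  exp(0.4·z) and a fixed set of anaerobe/commensal genera is suppressed by
  mean-preserving factors exp(−s·z − s²/2), s ∈ 0.15–0.40. Making z a
  patient-level trait (chronic colonisation) rather than per-sample noise
  keeps persistent *Haemophilus* visit pairs similar — which is what makes
  the neutrophilic-balanced subgroup, not the *Haemophilus* subgroup, show
  the largest paired stability–exacerbation shifts. The *differential*
  suppression matters: uniform suppression of all other genera is exactly
  the compositional closure effect, which SparCC correctly attributes to a
  basis variance rather than co-exclusion. This mechanism is what gives
  the NH subgroup network its high-degree *Haemophilus* hub with negative
  edges.
* **Eosinophilia coupling.** Eosinophil-tracking genera (*Campylobacter*,
  *Granulicatella* at 0.8; *Capnocytophaga*, *Fusobacterium*, *Gemellaceae*
  at 0.6) have concentrations scaled by exp(coupling·z_eos), where z_eos is
  the sample's eosinophil % standardised by population constants
  (mean 3, SD 5) and clipped at ±2 (so extreme eosinophilia cannot turn a
  balanced sample into a *Campylobacter*-dominated outlier). One mechanism
  yields both the cross-sectional eosinophilic enrichment (LEfSe, variance
  explained) and the within-patient temporal co-variation (cross-covariance)
  plus the positive co-occurrence clique in the eosinophilic network.
* **Cells and mediators.** Cell percentages are truncated normals on
  [0, 100] per state with the reported subgroup moments (e.g. NH
  neutrophils 88.8 ± 10.3). The truncation location is solved numerically
  so the *realised* mean equals the target (a normal truncated at 100 with
  location 88.8 would realise ≈ 86). The granulocyte draws are preserved
  and the remaining classes rescaled into the leftover room when the five
  classes exceed 100 %. MIXED/PAUCI moments are design choices consistent
  with their defining thresholds. Ten mediators are drawn as per-state
  normals on the log scale with the reported moments (Th1 pattern high in
  NH, IL-17A/SAA in NB, Th2 markers in E); MIXED/PAUCI get the
  across-state average. Reads are multinomial at depth 29,117 (the
  discovery rarefaction depth; 2,207 is the validation preset).

**What the generator does not emulate.** Sequencing error and read-level
structure; batch effects (batch correction is out of scope — inputs are
assumed post-correction); site differences; induced vs spontaneous sampling;
infection status beyond what states imply; per-state composition variance
calibrated to the real cohorts (not reported anywhere — the chosen
variances are for testability). Passing tests therefore demonstrate that
the pipeline recovers known structure of this model class at realistic
sizes and calibrates correctly under its nulls — not that the original
cohort results are reproduced.

## Problem sizes and determinism

Community-type recovery is exercised at study scale (~1,350 samples, 400
patients): the silhouette margin between k = 4 and coarser cuts only
stabilises near the size of the emulated cohorts, since the two smallest
clusters hold ~3 % of samples each (at ~300 samples the selection misses in
roughly one cohort in ten). Persistence recovery uses stable-visit cohorts
with > 10,000 analysable pairs at low sequencing depth. Calibration checks
use 500 null simulations (PERMANOVA, cross-covariance, CI coverage) and
≥ 550 null pairs (SparCC, mediators). All randomness flows through explicit
seeds (`numpy.random.default_rng`); identical config + seed reproduces
cohorts byte-identically.

## Known limitations

* Ward on √JSD is heuristic for non-Euclidean inputs (above).
* The cross-covariance score's signed-max-over-lags convention slightly
  favours positive associations; the permutation null shares the
  convention, so tests stay calibrated.
* The changepoint–event odds ratio pools transitions across patients,
  ignoring within-patient correlation; its CI coverage is nonetheless
  ≈ 95 % in simulation at the sizes used.
* The NB-greatest-paired-shift direction is a distributional statement; in
  small cohorts (~35 pairs per state) the group medians of the bimodal
  shift distributions can occasionally invert by sampling noise.
* MixedLM fits fall back to OLS on degenerate designs (single-visit
  cohorts) with a warning rather than failing.
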