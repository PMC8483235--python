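# endomix

Longitudinal analysis of the airway microbiome across COPD inflammatory
endotypes: community typing, endotype classification, temporal state
transitions, changepoint–event association, cross-covariance tracking of
genera against sputum cell counts, and compositional co-occurrence /
host–mediator networks — plus a synthetic cohort generator that emulates
the statistical structure of multi-site longitudinal sputum cohorts so the
whole pipeline is testable end to end.

## Who this is for

Researchers analysing 16S-derived genus-level sputum microbiome tables with
longitudinal clinical metadata (patient, visit, stable vs exacerbation,
sputum differential cell counts, optional inflammatory mediator panels) who
want to stratify neutrophilic/eosinophilic COPD by airway ecology and track
how the microbiome moves with patient inflammatory status over time.

## The analysis in brief

* **Endotypes.** Samples are classified from sputum differential cell
  counts: neutrophilic (eosinophils < 3 %, neutrophils ≥ 61 %),
  eosinophilic (eos ≥ 3 %, neu < 61 %), mixed-granulocytic (both high),
  paucigranulocytic (both low); missing counts ⇒ unassigned.
* **Community types.** Ward-linkage hierarchical clustering on the square
  root of the Jensen–Shannon divergence (log base 2, so √JSD ∈ [0, 1] is a
  metric), with k chosen by the mean silhouette width and validated by PAM
  (k-medoids) with a distance-based Calinski–Harabasz index. Clusters are
  named by dominance: "<Genus>-predominant" when the top mean genus exceeds
  0.3, else "balanced".
* **Joint states.** NH = neutrophilic *Haemophilus*-predominant,
  NB = neutrophilic balanced, E = eosinophilic; everything else is excluded
  from transition analysis. Consecutive within-patient visit pairs build
  stable–stable and stable–exacerbation transition tables with per-state
  persistence; covariates (season change, ICS use) get Woolf-CI odds ratios.
* **Time series.** PELT — the pruned exact linear time changepoint
  algorithm under a normal mean-change cost with a BIC-style penalty —
  segments each patient's genus trajectories; inter-visit transitions are
  pooled into 2×2 changepoint × event odds ratios. Per-patient normalised
  cross-covariance (max over lags ≤ 1) between a genus and sputum
  eosinophil/neutrophil % is summed into a cumulative score and tested
  against a within-patient permutation null.
* **Networks.** SparCC compositional correlations (log-ratio variation
  matrix, sparse basis-variance approximation, median over Dirichlet
  posterior resamplings), column-permutation significance with BH FDR,
  Louvain modules; genus–mediator Spearman correlations on mixed-model
  residuals (covariate-adjusted, per-patient random intercept).
* **Ecology.** Shannon diversity, Bray–Curtis dissimilarity, PCoA with
  negative-eigenvalue reporting, one-way PERMANOVA with a seeded
  permutation null, distance-to-centroid dispersion, and paired
  stability–exacerbation Bray–Curtis shifts.

## Worked example

```python
from endomix import (
    default_config, generate_cohort, jsd_distance, fit_community_types,
    name_community_types, classify_dataset, derive_states, transition_table,
)

cfg = default_config(n_patients=120, seed=7)
dataset, truth = generate_cohort(cfg)
print(f"cohort: {dataset.n_samples} sputum samples from {dataset.n_patients} patients")

rel = dataset.table.to_relative()
assignment = fit_community_types(jsd_distance(rel), sample_ids=rel.sample_ids)
assignment = name_community_types(rel, assignment)
print(f"community types: k={assignment.k} "
      f"(mean silhouette {assignment.silhouette_by_k[assignment.k]:.3f})")
print("cluster names:", sorted(assignment.names.values()))

endotypes = classify_dataset(dataset)
states = derive_states(endotypes, assignment.named_labels())
stable = transition_table(dataset, states)["stable-stable"]
print(f"stable-stable pairs: {stable.n_pairs}")
for s in ("NH", "NB", "E"):
    print(f"  persistence({s}) = {stable.persistence(s):.3f}")
```

prints

```
cohort: 387 sputum samples from 120 patients
community types: k=4 (mean silhouette 0.471)
cluster names: ['Haemophilus-predominant', 'Moraxella-predominant', 'Streptococcus-predominant', 'balanced']
stable-stable pairs: 76
  persistence(NH) = 0.818
  persistence(NB) = 0.353
  persistence(E) = 0.300
```

Four community types are recovered — one balanced and three dominated — and
the *Haemophilus* state is far more persistent across stable visits than
the neutrophilic-balanced or eosinophilic states, which interchange. At
this cohort size the persistence estimates are noisy; they converge to the
configured 0.714 / 0.384 / 0.418 as the number of analysable pairs grows
(see `docs/methods.md`).

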