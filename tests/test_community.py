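import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from endomix.community import (
    CommunityTypeClusterer,
    PAMKMedoids,
    biomarker_threshold,
    calinski_harabasz_from_distances,
    fit_community_types,
    jsd_distance,
    mean_silhouette,
    name_community_types,
    validate_with_pam,
)
from endomix.core_io import GenusAbundanceTable


def _entropy2(p):
    p = np.asarray(p, float)
    p = p[p > 0]
    return -(p * np.log2(p)).sum()


class TestJSDDistance:
    def test_identical_rows_give_zero(self):
        X = np.array([[0.2, 0.8], [0.2, 0.8]])
        assert jsd_distance(X)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert jsd_distance(X)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_entropy_computation(self):
        p, q = np.array([1.0, 0.0]), np.array([0.5, 0.5])
        m = (p + q) / 2
        expected = np.sqrt(_entropy2(m) - (_entropy2(p) + _entropy2(q)) / 2)
        got = jsd_distance(np.vstack([p, q]))[0, 1]
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.5579, abs=5e-4)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            jsd_distance(np.array([[0.5, -0.5], [0.2, 0.8]]))

    def test_counts_table_rejected(self):
        t = GenusAbundanceTable(pd.DataFrame([[1, 2]], index=["s"], columns=["a", "b"]))
        with pytest.raises(ValueError, match="relative"):
            jsd_distance(t)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(6), size=30)
        D = jsd_distance(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        for i, j, k in rng.integers(0, 30, size=(60, 3)):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-10


class TestValidityIndices:
    def _brute_silhouette(self, D, labels):
        n = len(labels)
        vals = []
        for i in range(n):
            same = [j for j in range(n) if labels[j] == labels[i] and j != i]
            if not same:
                vals.append(0.0)
                continue
            a = np.mean([D[i, j] for j in same])
            b = min(
                np.mean([D[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels)
                if c != labels[i]
            )
            vals.append((b - a) / max(a, b))
        return float(np.mean(vals))

    def test_silhouette_matches_brute_force_small_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = rng.normal(0, 1, (9, 2))
            D = squareform(pdist(X))
            labels = rng.integers(0, 3, 9)
            if len(set(labels)) < 2:
                continue
            assert mean_silhouette(D, labels) == pytest.approx(
                self._brute_silhouette(D, labels), abs=1e-10
            )

    def test_four_point_two_cluster_silhouette_hand_computed(self):
        # points on a line at 0, 1, 10, 11; clusters {0,1}, {10,11}
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = squareform(pdist(X))
        labels = np.array([1, 1, 2, 2])
        # outer points: a=1, b=(10+11)/2=10.5 -> 9.5/10.5
        # inner points: a=1, b=(9+10)/2=9.5  -> 8.5/9.5
        expected = (9.5 / 10.5 + 8.5 / 9.5) / 2
        assert mean_silhouette(D, labels) == pytest.approx(expected, abs=1e-12)

    def test_distance_ch_matches_sklearn_on_euclidean_data(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(0, 1, (10, 3))
            labels = rng.integers(0, 3, 10)
            if len(set(labels)) < 2:
                continue
            D = squareform(pdist(X))
            assert calinski_harabasz_from_distances(D, labels) == pytest.approx(
                calinski_harabasz_score(X, labels), rel=1e-9
            )


class TestWardClustering:
    def test_two_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(3)
        a = rng.dirichlet([50, 2, 2, 2], size=30)
        b = rng.dirichlet([2, 2, 2, 50], size=30)
        X = np.vstack([a, b])
        D = jsd_distance(X)
        res = fit_community_types(D)
        assert res.k == 2
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_default_cohort_recovers_four_community_types(self, typing_cohort):
        ds, truth = typing_cohort
        rel = ds.table.to_relative()
        assert rel.n_samples >= 200
        res = fit_community_types(jsd_distance(rel), sample_ids=rel.sample_ids)
        assert res.k == 4
        assert adjusted_rand_score(truth.sample_communities, res.labels) >= 0.9

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError):
            CommunityTypeClusterer(k_max=3, metric="precomputed").fit(np.zeros((12, 12)))

    def test_too_few_samples_rejected(self):
        D = squareform(pdist(np.random.default_rng(0).normal(size=(5, 2))))
        with pytest.raises(ValueError, match="samples"):
            CommunityTypeClusterer(k_max=10, metric="precomputed").fit(D)


class TestPAM:
    def _brute_pam_cost(self, D, k):
        n = D.shape[0]
        best = np.inf
        for medoids in itertools.combinations(range(n), k):
            best = min(best, D[:, medoids].min(axis=1).sum())
        return best

    def test_swap_optimal_equals_exhaustive_at_n6(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            X = rng.normal(0, 1, (6, 2))
            D = squareform(pdist(X))
            model = PAMKMedoids(n_clusters=2).fit(D)
            assert model.inertia_ == pytest.approx(self._brute_pam_cost(D, 2), abs=1e-10)

    def test_k_larger_than_n_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            PAMKMedoids(n_clusters=4).fit(D)

    def test_k1_excluded_from_ch_search(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (12, 2))
        D = squareform(pdist(X))
        out = validate_with_pam(D, k_range=(1, 4))
        assert 1 not in out["ch_by_k"]

    def test_two_blob_validation_agrees_with_ward(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.dirichlet([60, 2, 2], 25), rng.dirichlet([2, 2, 60], 25)])
        D = jsd_distance(X)
        ward = fit_community_types(D, k_range=(2, 6))
        out = validate_with_pam(D, k_range=(2, 6), reference_labels=ward.labels.to_numpy())
        assert out["k"] == 2
        assert out["ari"] == 1.0


class TestNaming:
    GENERA = ["Haemophilus", "a", "b", "c", "d", "e"]

    def _assignment(self, X, labels):
        t = GenusAbundanceTable(
            pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))], columns=self.GENERA),
            kind="relative",
        )
        res = fit_community_types(jsd_distance(X), k_range=(2, 2), sample_ids=t.sample_ids)
        res.labels = pd.Series(labels, index=t.sample_ids)
        return t, res

    def test_dominant_cluster_named_after_genus(self):
        dominated = [0.6, 0.08, 0.08, 0.08, 0.08, 0.08]
        balanced = [0.12, 0.22, 0.22, 0.22, 0.11, 0.11]
        t, res = self._assignment(np.array([dominated] * 3 + [balanced] * 3), [1, 1, 1, 2, 2, 2])
        named = name_community_types(t, res)
        assert named.names[1] == "Haemophilus-predominant"
        assert named.names[2] == "balanced"

    def test_two_balanced_clusters_disambiguated(self):
        bal1 = [0.25, 0.15, 0.15, 0.15, 0.15, 0.15]
        bal2 = [0.15, 0.15, 0.15, 0.15, 0.15, 0.25]
        t, res = self._assignment(np.array([bal1] * 3 + [bal2] * 3), [1, 1, 1, 2, 2, 2])
        named = name_community_types(t, res)
        assert sorted(named.names.values()) == ["balanced-1", "balanced-2"]

    def test_named_labels_requires_names(self):
        dominated = [0.6, 0.08, 0.08, 0.08, 0.08, 0.08]
        balanced = [0.12, 0.22, 0.22, 0.22, 0.11, 0.11]
        _, res = self._assignment(np.array([dominated] * 3 + [balanced] * 3), [1, 1, 1, 2, 2, 2])
        with pytest.raises(ValueError):
            res.named_labels()


class TestBiomarkerThreshold:
    def test_perfect_separation(self):
        res = biomarker_threshold([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], "f")
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_tied_values_use_midrank(self):
        res = biomarker_threshold([1, 1, 2], [0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_label_independent_feature_near_half(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 10_000)
        y = rng.integers(0, 2, 10_000)
        assert biomarker_threshold(x, y).auc == pytest.approx(0.5, abs=0.02)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            biomarker_threshold([1, 2, 3], [1, 1, 1])

    def test_youden_tie_resolves_to_lower_cutoff(self):
        # both cutoffs between the two groups achieve J=1; pick the lower
        res = biomarker_threshold([0, 1, 10, 11], [0, 0, 1, 1])
        assert res.cutoff <= 10


def test_pipeline_nh_nb_split_matches_truth(medium_cohort):
    """Joint endotype x community recovery: NH/NB separation of neutrophilic samples."""
    from endomix.endotyping import classify_dataset
    from endomix.transitions import derive_states

    ds, truth = medium_cohort
    rel = ds.table.to_relative()
    res = name_community_types(rel, fit_community_types(jsd_distance(rel), sample_ids=rel.sample_ids))
    states = derive_states(classify_dataset(ds), res.named_labels())
    mask = truth.sample_states.isin(["NH", "NB"]) & states.isin(["NH", "NB"])
    ari = adjusted_rand_score(truth.sample_states[mask], states[mask])
    assert ari >= 0.85
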