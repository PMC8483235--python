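import itertools

import numpy as np
import pandas as pd
import pytest

from endomix.timeseries import (
    PeltSegmenter,
    changepoint_event_or,
    crosscov_perm_test,
    crosscov_score,
    crosscov_test_all,
    pelt_changepoints,
    stable_switch_events,
)


def exhaustive_segmentation(x, penalty, min_seg=2):
    """Oracle: minimise total SSE + penalty over all admissible segmentations."""
    n = len(x)

    def cost(a, b):
        seg = x[a:b]
        return float(((seg - seg.mean()) ** 2).sum())

    best_cost, best_cps = np.inf, []
    positions = range(min_seg, n - min_seg + 1)
    for k in range(0, n // min_seg):
        for cps in itertools.combinations(positions, k):
            bounds = [0, *cps, n]
            if any(b - a < min_seg for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            c = sum(cost(a, b) for a, b in zip(bounds[:-1], bounds[1:])) + penalty * k
            if c < best_cost - 1e-12:
                best_cost, best_cps = c, list(cps)
    return best_cost, best_cps


class TestPelt:
    def test_constant_series_has_no_changepoints(self):
        assert pelt_changepoints(np.full(10, 3.0)).changepoints == []

    def test_noiseless_step_found_at_boundary(self):
        x = np.array([0.0] * 6 + [5.0] * 6)
        res = pelt_changepoints(x)
        assert res.changepoints == [6]
        assert res.segment_means == [0.0, 5.0]

    def test_matches_exhaustive_search_on_short_series(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            x = rng.normal(0, 1, n) + np.repeat(rng.normal(0, 2, 2), [n // 2, n - n // 2])
            pen = float(rng.uniform(0.5, 8))
            res = pelt_changepoints(x, penalty=pen)
            best_cost, _ = exhaustive_segmentation(x, pen)
            bounds = [0, *res.changepoints, n]
            cost = sum(
                float(((x[a:b] - x[a:b].mean()) ** 2).sum())
                for a, b in zip(bounds[:-1], bounds[1:])
            ) + pen * len(res.changepoints)
            assert cost == pytest.approx(best_cost, abs=1e-9)

    def test_changepoint_count_monotone_in_penalty(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40) + np.repeat([0, 4, -3, 2], 10)
        counts = [
            len(pelt_changepoints(x, penalty=p).changepoints) for p in [0.5, 2, 8, 32, 128]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_min_seg_respected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        res = pelt_changepoints(x, penalty=0.1, min_seg=3)
        bounds = [0, *res.changepoints, 20]
        assert all(b - a >= 3 for a, b in zip(bounds[:-1], bounds[1:]))

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            pelt_changepoints(np.array([1.0, np.nan, 2.0, 3.0]))

    def test_estimator_wrapper_exposes_fitted_attributes(self):
        model = PeltSegmenter().fit([0.0] * 6 + [5.0] * 6)
        assert model.changepoints_ == [6]
        assert model.n_segments_ == 2
        assert model.get_params()["min_seg"] == 2


class TestCrossCovScore:
    def test_identical_series_score_one(self):
        x = np.arange(10.0)
        assert crosscov_score(x, x) == pytest.approx(1.0)

    def test_negated_series_at_lag_zero(self):
        x = np.array([1.0, 3, 2, 5, 4, 6])
        assert crosscov_score(x, -x, max_lag=0) == pytest.approx(-1.0)

    def test_shifted_series_found_at_lag_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 40)
        # abundance leads the cell series by one visit
        score_lagged = crosscov_score(base[1:], base[:-1], max_lag=1)
        score_lag0 = crosscov_score(base[1:], base[:-1], max_lag=0)
        assert score_lagged > 0.9
        assert score_lagged > score_lag0

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = crosscov_score(np.ones(6), np.arange(6.0))
        assert np.isnan(out)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crosscov_score(np.ones(5), np.ones(6))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            crosscov_score(np.ones(4), np.ones(4))


class TestCrossCovPermTest:
    def test_coupled_genus_detected(self, longitudinal_cohort):
        ds, _ = longitudinal_cohort
        res = crosscov_perm_test(ds, "Campylobacter", B=200, seed=0)
        assert res.p_value < 0.05
        assert res.cumulative > 0

    def test_cumulative_is_sum_of_patient_scores(self, longitudinal_cohort):
        ds, _ = longitudinal_cohort
        res = crosscov_perm_test(ds, "Granulicatella", B=50, seed=1)
        assert res.cumulative == pytest.approx(res.per_patient.sum())
        assert (res.per_patient.abs() <= 1 + 1e-9).all()

    def test_short_series_patients_excluded(self, longitudinal_cohort):
        ds, _ = longitudinal_cohort
        meta = ds.aligned_metadata()
        visits = meta.groupby("patient_id").size()
        res = crosscov_perm_test(ds, "Veillonella", B=20, seed=2, min_visits=5)
        assert set(res.per_patient.index).issubset(set(visits[visits >= 5].index))

    def test_coupled_genera_have_lower_interpatient_sd(self, longitudinal_cohort):
        # consistent temporal tracking across patients = low interpatient SD
        ds, _ = longitudinal_cohort
        df = crosscov_test_all(
            ds,
            genera=["Campylobacter", "Granulicatella", "Moraxella", "Serratia", "Treponema"],
            B=50,
            seed=3,
        )
        coupled = df.loc[["Campylobacter", "Granulicatella"], "interpatient_sd"].mean()
        uncoupled = df.loc[["Serratia", "Treponema"], "interpatient_sd"].mean()
        assert coupled < uncoupled

    def test_bh_q_present_and_coupled_genus_significant(self, longitudinal_cohort):
        ds, _ = longitudinal_cohort
        df = crosscov_test_all(
            ds,
            genera=["Campylobacter", "Serratia", "Treponema", "Lautropia"],
            B=200,
            seed=4,
        )
        assert df.loc["Campylobacter", "q"] < 0.05


class TestChangepointEventOR:
    def _dataset_with_event_locked_genus(self, n_patients=25, n_visits=8, seed=0):
        """Synthetic cohort whose genus 'locked' shifts exactly at exacerbations."""
        from endomix.core_io import CohortDataset, GenusAbundanceTable, SampleMetadata

        rng = np.random.default_rng(seed)
        rows, meta_rows = [], []
        for p in range(n_patients):
            exac = np.zeros(n_visits, dtype=bool)
            exac[rng.choice(np.arange(1, n_visits), 2, replace=False)] = True
            level = 100.0
            for v in range(n_visits):
                if v > 0 and exac[v]:
                    level = 900.0 if level < 500 else 100.0
                sid = f"p{p}v{v}"
                locked = level + rng.normal(0, 1)
                other = 1000 + rng.normal(0, 5, 2)
                rows.append((sid, [locked, *other]))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": f"p{p}",
                        "visit_index": v + 1,
                        "day_offset": v * 30,
                        "visit_type": "exacerbation" if exac[v] else "stable",
                    }
                )
        table = GenusAbundanceTable(
            pd.DataFrame(
                [np.maximum(r, 0) for _, r in rows],
                index=[s for s, _ in rows],
                columns=["locked", "g1", "g2"],
            ).round(),
            kind="counts",
        )
        meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
        ds = CohortDataset(table=table, metadata=meta)
        events = meta.data["visit_type"] == "exacerbation"
        return ds, events

    def test_event_locked_genus_significant(self):
        ds, events = self._dataset_with_event_locked_genus()
        res = changepoint_event_or(ds, events, min_visits=5)
        assert res.loc["locked", "ci_low"] > 1.0
        assert res.loc["locked", "significant"]

    def test_stationary_cohort_yields_no_significant_genus(self):
        # all trajectories stationary: changepoints (if any) are unrelated
        # to events, and a constant genus has none at all -> corrected OR
        from endomix.core_io import CohortDataset, GenusAbundanceTable, SampleMetadata

        rng = np.random.default_rng(1)
        rows, meta_rows = [], []
        for p in range(20):
            for v in range(8):
                sid = f"p{p}v{v}"
                rows.append((sid, [500, *np.round(1000 + rng.normal(0, 5, 2))]))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": f"p{p}",
                        "visit_index": v + 1,
                        "day_offset": v * 30,
                        "visit_type": "exacerbation" if (v > 0 and rng.uniform() < 0.3) else "stable",
                    }
                )
        table = GenusAbundanceTable(
            pd.DataFrame([r for _, r in rows], index=[s for s, _ in rows], columns=["flat", "g1", "g2"]),
            kind="counts",
        )
        ds = CohortDataset(table=table, metadata=SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id")))
        events = ds.aligned_metadata()["visit_type"] == "exacerbation"
        res = changepoint_event_or(ds, events, min_visits=5)
        assert not res["significant"].any()

    def test_too_few_visits_rejected(self, small_cohort):
        ds, _ = small_cohort
        meta = ds.aligned_metadata()
        with pytest.raises(ValueError, match="no patients"):
            changepoint_event_or(ds, meta["visit_type"] == "exacerbation", min_visits=99)

    def test_stable_switch_events_marks_flips(self, longitudinal_cohort):
        from endomix.endotyping import classify_dataset

        ds, _ = longitudinal_cohort
        endo = classify_dataset(ds)
        marks = stable_switch_events(ds, endo)
        assert marks.dtype == bool
        assert marks.index.equals(ds.aligned_metadata().index)
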