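"""Time-series analysis of per-patient genus trajectories.

Three layers:

* PELT changepoint detection under the normal mean-change cost (within-
  segment sum of squared deviations) with a BIC-style default penalty —
  an exact penalised segmentation with pruning, so the output equals the
  exhaustive optimum;
* pooled 2x2 odds ratios linking changepoints to clinical events
  (exacerbation at the destination visit, or neutrophilic<->eosinophilic
  switches between consecutive stable visits);
* per-patient cross-covariance scores between a genus trajectory and a
  sputum cell-percentage trajectory, aggregated into a cumulative score
  with an interpatient SD and tested against a within-patient permutation
  null by a one-sided rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .core_io import CohortDataset
from .transitions import OddsRatioResult, odds_ratio_from_counts

__all__ = [
    "ChangepointSet",
    "CrossCovResult",
    "PeltSegmenter",
    "pelt_changepoints",
    "changepoint_event_or",
    "crosscov_score",
    "crosscov_perm_test",
    "crosscov_test_all",
]


# ---------------------------------------------------------------------------
# PELT


@dataclass
class ChangepointSet:
    """Segmentation of one trajectory: 0-based first indices of new segments."""

    changepoints: list[int]
    penalty: float
    segment_means: list[float]
    patient_id: str | None = None
    genus: str | None = None

    @property
    def n_segments(self) -> int:
        return len(self.changepoints) + 1


def _segment_cost_factory(x: np.ndarray):
    """O(1) SSE cost for segment [a, b) via prefix sums."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def cost(a: int, b: int) -> float:
        n = b - a
        tot = s1[b] - s1[a]
        return (s2[b] - s2[a]) - tot * tot / n

    return cost


def default_penalty(x: np.ndarray) -> float:
    """BIC-style penalty 2*sigma^2*log(n), sigma^2 from first differences.

    var(diff)/2 is an unbiased noise-variance estimate that is robust to
    mean shifts between segments.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0.0
    sigma2 = float(np.var(np.diff(x), ddof=1) / 2.0) if n > 2 else float(np.var(np.diff(x)) / 2.0)
    return 2.0 * sigma2 * np.log(n)


def pelt_changepoints(
    series: np.ndarray, penalty: float | None = None, min_seg: int = 2
) -> ChangepointSet:
    """Exact minimiser of total segment SSE + penalty * (#segments - 1).

    Returns the ordered 0-based indices at which new segments start. PELT
    pruning preserves exactness for this additive cost. A constant series
    yields an empty changepoint set.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if np.isnan(x).any():
        raise ValueError("series contains missing values; drop them before segmentation")
    if n < 2 * min_seg:
        return ChangepointSet(changepoints=[], penalty=0.0, segment_means=[float(np.mean(x))] if n else [])
    if penalty is None:
        penalty = default_penalty(x)
    if np.allclose(x, x[0]):
        return ChangepointSet(changepoints=[], penalty=float(penalty), segment_means=[float(x[0])])
    cost = _segment_cost_factory(x)

    # F[t] = optimal cost of x[0:t]; candidates pruned per PELT. With a
    # minimum segment length the pruning must be delayed: a start s failing
    # the test at time t is dominated by the split at t only once the
    # segment (t, t') is itself admissible, i.e. from t' >= t + min_seg.
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    fail_at: dict[int, int] = {}
    for t in range(min_seg, n + 1):
        best, best_s = np.inf, 0
        for s in candidates:
            if t - s < min_seg:
                continue
            val = F[s] + cost(s, t) + penalty
            if val < best:
                best, best_s = val, s
        F[t] = best
        last[t] = best_s
        for s in candidates:
            if t - s >= min_seg and s not in fail_at and F[s] + cost(s, t) > F[t]:
                fail_at[s] = t
        candidates = [s for s in candidates if s not in fail_at or t < fail_at[s] + min_seg - 1]
        candidates.append(t)  # t becomes a future segment start
    # backtrack
    breaks = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            breaks.append(s)
        t = s
    breaks.reverse()
    bounds = [0] + breaks + [n]
    means = [float(np.mean(x[a:b])) for a, b in zip(bounds[:-1], bounds[1:])]
    return ChangepointSet(changepoints=breaks, penalty=float(penalty), segment_means=means)


class PeltSegmenter(BaseEstimator):
    """sklearn-style wrapper around :func:`pelt_changepoints`.

    Attributes after ``fit``: ``changepoints_``, ``segment_means_``,
    ``penalty_``, ``n_segments_``.
    """

    def __init__(self, penalty: float | None = None, min_seg: int = 2):
        self.penalty = penalty
        self.min_seg = min_seg

    def fit(self, X, y=None) -> "PeltSegmenter":
        x = np.asarray(X, dtype=float).ravel()
        res = pelt_changepoints(x, penalty=self.penalty, min_seg=self.min_seg)
        self.changepoints_ = res.changepoints
        self.segment_means_ = res.segment_means
        self.penalty_ = res.penalty
        self.n_segments_ = res.n_segments
        return self


# ---------------------------------------------------------------------------
# changepoint–event association


def _patient_trajectories(dataset: CohortDataset, min_visits: int):
    """Yield (patient_id, metadata rows ordered by day) for eligible patients."""
    meta = dataset.aligned_metadata()
    for pid, grp in meta.groupby("patient_id"):
        ordered = grp.sort_values("day_offset")
        if len(ordered) >= min_visits:
            yield pid, ordered


def changepoint_event_or(
    dataset: CohortDataset,
    event_series: pd.Series,
    genera: list[str] | None = None,
    min_visits: int = 5,
    penalty: float | None = None,
    min_seg: int = 2,
) -> pd.DataFrame:
    """Pooled per-genus odds ratios between changepoints and events.

    For each eligible patient (>= ``min_visits`` visits) and genus, a PELT
    segmentation of the relative-abundance trajectory marks the inter-visit
    transitions at which a new segment starts at the destination visit.
    ``event_series`` is a boolean per sample marking the event at that
    (destination) visit. All transitions are pooled into one 2x2 table per
    genus; significance requires the Woolf CI lower bound to exceed 1.
    """
    rel = dataset.table.to_relative()
    genera = genera or rel.genus_names
    eligible = list(_patient_trajectories(dataset, min_visits))
    if not eligible:
        raise ValueError(f"no patients with >= {min_visits} visits")
    rows = []
    for genus in genera:
        a = b = c = d = 0
        for pid, ordered in eligible:
            sids = ordered.index.tolist()
            x = rel.data.loc[sids, genus].to_numpy()
            cps = set(pelt_changepoints(x, penalty=penalty, min_seg=min_seg).changepoints)
            for t in range(1, len(sids)):
                cp = t in cps  # new segment starts at destination visit t
                ev = bool(event_series.get(sids[t], False))
                if cp and ev:
                    a += 1
                elif cp and not ev:
                    b += 1
                elif ev:
                    c += 1
                else:
                    d += 1
        if a + b + c + d == 0:
            raise ValueError("zero eligible transitions")
        res = odds_ratio_from_counts(a, b, c, d)
        rows.append(
            {
                "genus": genus,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p_value,
                "significant": res.ci_low > 1.0,
                "continuity_corrected": res.continuity_corrected,
            }
        )
    return pd.DataFrame(rows).set_index("genus")


def stable_switch_events(dataset: CohortDataset, endotypes: pd.Series) -> pd.Series:
    """Event marks for within-stability neutrophilic<->eosinophilic switches.

    A destination visit is marked when it and the preceding visit are both
    stable and the endotype flips between neutrophilic and eosinophilic.
    """
    meta = dataset.aligned_metadata()
    marks = pd.Series(False, index=meta.index)
    for _, grp in meta.groupby("patient_id"):
        ordered = grp.sort_values("day_offset")
        sids = ordered.index.tolist()
        for prev, cur in zip(sids[:-1], sids[1:]):
            if (
                meta.loc[prev, "visit_type"] == "stable"
                and meta.loc[cur, "visit_type"] == "stable"
                and {endotypes.get(prev), endotypes.get(cur)} == {"neutrophilic", "eosinophilic"}
            ):
                marks[cur] = True
    return marks


# ---------------------------------------------------------------------------
# cross-covariance


def crosscov_score(
    abundance_series: np.ndarray, cell_series: np.ndarray, max_lag: int = 1
) -> float:
    """Normalised cross-correlation, signed maximum over lags |l| <= max_lag.

    Both series are z-scored; r(l) = (1/n) * sum_t a[t+l] * b[t] (the ccf
    convention, so |r| <= 1). Positive lag means the abundance series leads.
    Returns NaN with a warning when either series has zero variance.
    """
    a = np.asarray(abundance_series, dtype=float)
    b = np.asarray(cell_series, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    n = a.size
    if n < 5:
        raise ValueError("need at least 5 time points")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance series; cross-covariance undefined")
        return np.nan
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    best = -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            r = float(np.dot(az[lag:], bz[: n - lag]) / n)
        else:
            r = float(np.dot(az[: n + lag], bz[-lag:]) / n)
        best = max(best, r)
    return best


@dataclass
class CrossCovResult:
    genus: str
    per_patient: pd.Series  # patient_id -> score
    cumulative: float
    interpatient_sd: float
    p_value: float
    n_permutations: int
    seed: int
    q_value: float | None = None
    null_scores: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def crosscov_perm_test(
    dataset: CohortDataset,
    genus: str,
    target: str = "eosinophil_pct",
    B: int = 1000,
    min_visits: int = 5,
    max_lag: int = 1,
    seed: int = 0,
) -> CrossCovResult:
    """Per-patient cross-covariance of a genus with a cell percentage, with a
    within-patient permutation null.

    Patients need >= ``min_visits`` visits and positive variance in both
    series. The null permutes the abundance series order within each patient
    (cell series fixed); significance is a one-sided rank-sum test of the
    observed per-patient scores against the pooled permuted scores.
    """
    rel = dataset.table.to_relative()
    rng = np.random.default_rng(seed)
    scores = {}
    trajectories = []
    for pid, ordered in _patient_trajectories(dataset, min_visits):
        sids = ordered.index.tolist()
        x = rel.data.loc[sids, genus].to_numpy()
        y = ordered[target].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        x, y = x[mask], y[mask]
        if x.size < min_visits or np.std(x) == 0 or np.std(y) == 0:
            continue
        scores[pid] = crosscov_score(x, y, max_lag=max_lag)
        trajectories.append((x, y))
    if not scores:
        raise ValueError(f"no eligible patients with >= {min_visits} visits for {genus}")
    per_patient = pd.Series(scores, name=genus)
    null = np.empty(B * len(trajectories))
    k = 0
    for _ in range(B):
        for x, y in trajectories:
            null[k] = crosscov_score(rng.permutation(x), y, max_lag=max_lag)
            k += 1
    p = float(mannwhitneyu(per_patient.to_numpy(), null, alternative="greater").pvalue)
    return CrossCovResult(
        genus=genus,
        per_patient=per_patient,
        cumulative=float(per_patient.sum()),
        interpatient_sd=float(per_patient.std(ddof=1)) if len(per_patient) > 1 else 0.0,
        p_value=p,
        n_permutations=B,
        seed=seed,
        null_scores=null,
    )


def crosscov_test_all(
    dataset: CohortDataset,
    genera: list[str] | None = None,
    target: str = "eosinophil_pct",
    B: int = 1000,
    min_visits: int = 5,
    max_lag: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-covariance permutation test for many genera with BH adjustment."""
    genera = genera or dataset.table.genus_names
    results = []
    for i, genus in enumerate(genera):
        try:
            res = crosscov_perm_test(
                dataset, genus, target=target, B=B, min_visits=min_visits,
                max_lag=max_lag, seed=seed + i,
            )
        except ValueError:
            continue
        results.append(res)
    if not results:
        raise ValueError("no genus produced an eligible cross-covariance test")
    df = pd.DataFrame(
        {
            "genus": [r.genus for r in results],
            "cumulative": [r.cumulative for r in results],
            "interpatient_sd": [r.interpatient_sd for r in results],
            "n_patients": [len(r.per_patient) for r in results],
            "p": [r.p_value for r in results],
        }
    ).set_index("genus")
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("cumulative", ascending=False)
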