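"""Diversity, ordination, dispersion and paired dissimilarity shifts.

Covers the community-ecology layer: Shannon diversity (nats), Bray–Curtis
dissimilarity, principal coordinates analysis, one-way PERMANOVA with a
seeded permutation null, distance-to-centroid group dispersion with the
imaginary-axis correction for non-Euclidean distance matrices, and the
pairing of exacerbation samples with each patient's most recent preceding
stable sample to measure within-patient microbiome shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core_io import CohortDataset, GenusAbundanceTable

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "shannon",
    "bray_curtis",
    "pcoa",
    "permanova",
    "centroid_dispersion",
    "paired_shift",
]


# ---------------------------------------------------------------------------
# alpha / beta diversity


def shannon(composition: np.ndarray) -> float:
    """Shannon diversity −Σ p ln p in nats, over positive entries."""
    p = np.asarray(composition, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    if p.sum() <= 0:
        raise ValueError("composition sums to zero")
    return float(entropy(p))  # scipy normalises and ignores zeros


def bray_curtis(table: GenusAbundanceTable | np.ndarray) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity matrix, entries in [0, 1]."""
    if isinstance(table, GenusAbundanceTable):
        if table.kind != "relative":
            raise ValueError("bray_curtis expects a relative abundance table")
        X = table.values
    else:
        X = np.asarray(table, dtype=float)
    return squareform(pdist(X, metric="braycurtis"))


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n x n_axes, axes by decreasing eigenvalue
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    has_negative_eigenvalues: bool


def pcoa(dist: np.ndarray) -> OrdinationResult:
    """Classical scaling (PCoA) of a square symmetric distance matrix.

    Delegates the Gower double-centering + eigendecomposition to scikit-bio
    and reports whether negative eigenvalues (non-Euclidean input) occurred.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(D, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    has_neg = bool((eig < -1e-8 * max(abs(eig).max(), 1.0)).any())
    keep = eig > 1e-12
    return OrdinationResult(
        coordinates=coords[:, keep],
        eigenvalues=eig,
        proportion_explained=res.proportion_explained.to_numpy()[keep],
        has_negative_eigenvalues=has_neg,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    return ss_total, ss_within


def permanova(dist: np.ndarray, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k)); R² = SS_between/SS_total;
    p = (1 + #{permuted F ≥ observed}) / (n_perm + 1) under seeded label shuffles.
    """
    D = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    n, k = D.shape[0], uniq.size
    d2 = D**2
    ss_total, ss_within = _permanova_ss(d2, groups)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (k - 1)) / (ss_within / (n - k))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        _, ssw = _permanova_ss(d2, perm)
        f_perm = ((ss_total - ssw) / (k - 1)) / (ssw / (n - k))
        if f_perm >= f_obs:
            exceed += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(ss_between / ss_total),
        p_value=(1 + exceed) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# group dispersion


def centroid_dispersion(dist: np.ndarray, groups) -> dict:
    """Per-sample distance to the group centroid in corrected PCoA space.

    Coordinates on axes with negative eigenvalues contribute negatively to
    the squared distance (Anderson's imaginary-axis correction). Groups are
    compared pairwise by rank-sum tests with Benjamini–Hochberg adjustment.
    """
    D = np.asarray(dist, dtype=float)
    groups = np.asarray(groups)
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(D, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    tol = 1e-10 * max(abs(eig).max(), 1.0)
    pos, neg = eig > tol, eig < -tol
    # skbio zeroes coordinates on negative axes; rebuild them from eigenvectors
    if neg.any():
        G = -0.5 * _gower_center(D**2)
        w, v = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        pos, neg = w > tol, w < -tol
        coords_pos = v[:, pos] * np.sqrt(w[pos])
        coords_neg = v[:, neg] * np.sqrt(-w[neg])
    else:
        coords_pos = coords[:, pos]
        coords_neg = np.zeros((D.shape[0], 0))

    dispersion = np.empty(D.shape[0])
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        if idx.size == 1:
            warnings.warn(f"group {g!r} has a single sample; dispersion set to 0")
            dispersion[idx] = 0.0
            continue
        c_pos = coords_pos[idx].mean(axis=0)
        c_neg = coords_neg[idx].mean(axis=0)
        d2 = ((coords_pos[idx] - c_pos) ** 2).sum(axis=1) - ((coords_neg[idx] - c_neg) ** 2).sum(axis=1)
        dispersion[idx] = np.sqrt(np.maximum(d2, 0.0))

    comparisons = []
    uniq = np.unique(groups)
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            a = dispersion[groups == uniq[i]]
            b = dispersion[groups == uniq[j]]
            if min(a.size, b.size) < 2:
                continue
            p = mannwhitneyu(a, b, alternative="two-sided").pvalue
            comparisons.append({"group_a": uniq[i], "group_b": uniq[j], "p": float(p)})
    if comparisons:
        q = multipletests([c["p"] for c in comparisons], method="fdr_bh")[1]
        for c, qi in zip(comparisons, q):
            c["q"] = float(qi)
    return {"distance_to_centroid": dispersion, "comparisons": comparisons}


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ d2 @ J


# ---------------------------------------------------------------------------
# paired stability–exacerbation shifts


def paired_shift(dataset: CohortDataset, states: pd.Series | None = None) -> pd.DataFrame:
    """Bray–Curtis shift from each patient's preceding stable visit to an
    exacerbation visit.

    Each exacerbation sample is paired with the most recent preceding stable
    sample of the same patient (by day_offset); exacerbations without a
    preceding stable visit are excluded. When ``states`` (per-sample NH/NB/E
    labels) is given, pairs are annotated with the stable sample's state so
    subgroup medians can be compared.
    """
    rel = dataset.table.to_relative()
    meta = dataset.aligned_metadata()
    rows = []
    for pid, grp in meta.groupby("patient_id"):
        ordered = grp.sort_values("day_offset")
        last_stable = None
        for sid, row in ordered.iterrows():
            if row["visit_type"] == "stable":
                last_stable = sid
            elif row["visit_type"] == "exacerbation" and last_stable is not None:
                x = rel.data.loc[last_stable].to_numpy()
                y = rel.data.loc[sid].to_numpy()
                denom = (x + y).sum()
                bc = float(np.abs(x - y).sum() / denom) if denom > 0 else np.nan
                rows.append(
                    {
                        "patient_id": pid,
                        "stable_sample": last_stable,
                        "exacerbation_sample": sid,
                        "bray_curtis": bc,
                        "stable_state": states.get(last_stable) if states is not None else None,
                    }
                )
    if not rows:
        warnings.warn("no pairable stability–exacerbation samples found")
        return pd.DataFrame(
            columns=["patient_id", "stable_sample", "exacerbation_sample", "bray_curtis", "stable_state"]
        )
    return pd.DataFrame(rows)


def paired_shift_comparisons(pairs: pd.DataFrame, states=("NH", "NB", "E")) -> pd.DataFrame:
    """Pairwise rank-sum comparison of paired shifts across stable states."""
    rows = []
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            a = pairs.loc[pairs["stable_state"] == states[i], "bray_curtis"].dropna()
            b = pairs.loc[pairs["stable_state"] == states[j], "bray_curtis"].dropna()
            if min(len(a), len(b)) < 2:
                continue
            p = mannwhitneyu(a, b, alternative="two-sided").pvalue
            rows.append(
                {
                    "state_a": states[i],
                    "state_b": states[j],
                    "median_a": float(a.median()),
                    "median_b": float(b.median()),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
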