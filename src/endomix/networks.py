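"""Co-occurrence and host–mediator networks.

SparCC estimates genus–genus correlations from compositional data via
log-ratio variances: each estimation iteration draws fractions from the
Dirichlet posterior (pseudo-count 1), forms the variation matrix
t_ij = var(log(x_i/x_j)), solves the sparse linear approximation
t_ij ≈ w_i + w_j for the basis variances (iteratively excluding the most
strongly correlated pairs), and converts to correlations
r_ij = (w_i + w_j − t_ij) / (2 sqrt(w_i w_j)); the final estimate is the
median over iterations. Edge significance comes from column-permutation
nulls with BH FDR, modules from seeded Louvain on the |r|-weighted graph,
and microbiome–mediator associations from Spearman correlations of
mixed-model residuals (covariate-adjusted) with BH FDR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .core_io import GenusAbundanceTable

__all__ = [
    "SparCC",
    "sparcc",
    "edge_significance",
    "CooccurrenceNetwork",
    "build_network",
    "residualize_features",
    "feature_mediator_corr",
]


# ---------------------------------------------------------------------------
# SparCC


def _variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i / x_j)) across samples, for all genus pairs."""
    logf = np.log(fractions)
    G = logf.shape[1]
    t = np.zeros((G, G))
    for i in range(G):
        diff = logf[:, i : i + 1] - logf[:, i + 1 :]
        t[i, i + 1 :] = diff.var(axis=0, ddof=1)
    return t + t.T


def basis_variances(t: np.ndarray, excluded: set[tuple[int, int]] | None = None) -> np.ndarray:
    """Solve t_ij ≈ w_i + w_j in least squares over non-excluded pairs."""
    G = t.shape[0]
    excluded = excluded or set()
    rows, rhs = [], []
    for i in range(G):
        for j in range(i + 1, G):
            if (i, j) in excluded:
                continue
            row = np.zeros(G)
            row[i] = row[j] = 1.0
            rows.append(row)
            rhs.append(t[i, j])
    A = np.asarray(rows)
    if A.shape[0] < G:
        raise ValueError("too many excluded pairs; basis system underdetermined")
    w, *_ = np.linalg.lstsq(A, np.asarray(rhs), rcond=None)
    return np.maximum(w, 1e-12)


def _correlations_from_basis(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(w, w))
    r = (w[:, None] + w[None, :] - t) / denom
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _sparcc_single(
    t: np.ndarray, exclusion_threshold: float, max_exclusion_rounds: int
) -> np.ndarray:
    """One SparCC basis solution with iterative strong-pair exclusion."""
    G = t.shape[0]
    excluded: set[tuple[int, int]] = set()
    w = basis_variances(t)
    r = _correlations_from_basis(t, w)
    for _ in range(max_exclusion_rounds):
        r_off = np.abs(r.copy())
        np.fill_diagonal(r_off, 0.0)
        for i, j in excluded:
            r_off[i, j] = r_off[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(r_off), r_off.shape)
        if r_off[i, j] <= exclusion_threshold:
            break
        candidate = excluded | {(min(i, j), max(i, j))}
        # keep the system overdetermined and every genus represented
        n_eq = G * (G - 1) // 2 - len(candidate)
        if n_eq < G:
            break
        counts = np.full(G, G - 1)
        for a, b in candidate:
            counts[a] -= 1
            counts[b] -= 1
        if (counts < 1).any():
            break
        excluded = candidate
        w = basis_variances(t, excluded)
        r = _correlations_from_basis(t, w)
    return r


class SparCC(BaseEstimator):
    """Compositional correlation estimator (samples x genera counts).

    Attributes after ``fit``: ``correlation_`` (G x G, symmetric, unit
    diagonal, entries in [−1, 1]) and ``genus_names_`` when fitted on a
    :class:`GenusAbundanceTable`.
    """

    def __init__(
        self,
        n_est_iter: int = 20,
        exclusion_threshold: float = 0.1,
        max_exclusion_rounds: int = 10,
        seed: int = 0,
    ):
        self.n_est_iter = n_est_iter
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusion_rounds = max_exclusion_rounds
        self.seed = seed

    def fit(self, X, y=None) -> "SparCC":
        if isinstance(X, GenusAbundanceTable):
            self.genus_names_ = X.genus_names
            if X.kind == "relative":
                warnings.warn(
                    "SparCC prefers counts; treating relative abundances as "
                    "counts at a nominal depth of 10,000"
                )
                counts = np.round(X.values * 10_000)
            else:
                counts = X.values
        else:
            counts = np.asarray(X, dtype=float)
        if counts.shape[1] < 3:
            raise ValueError("SparCC needs at least 3 genera")
        zero_genus = np.where(counts.sum(axis=0) == 0)[0]
        if zero_genus.size:
            names = (
                [self.genus_names_[i] for i in zero_genus]
                if hasattr(self, "genus_names_")
                else zero_genus.tolist()
            )
            raise ValueError(f"genera with all-zero counts: {names}")
        rng = np.random.default_rng(self.seed)
        estimates = []
        for _ in range(self.n_est_iter):
            # row-wise Dirichlet(counts + 1) via normalised gamma draws
            g = rng.standard_gamma(counts + 1.0)
            fractions = g / g.sum(axis=1, keepdims=True)
            t = _variation_matrix(fractions)
            estimates.append(
                _sparcc_single(t, self.exclusion_threshold, self.max_exclusion_rounds)
            )
        self.correlation_ = np.clip(np.median(estimates, axis=0), -1.0, 1.0)
        np.fill_diagonal(self.correlation_, 1.0)
        return self


def sparcc(
    table: GenusAbundanceTable | np.ndarray,
    n_est_iter: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Functional wrapper over :class:`SparCC`; returns the correlation matrix."""
    return SparCC(
        n_est_iter=n_est_iter,
        exclusion_threshold=exclusion_threshold,
        max_exclusion_rounds=max_exclusion_rounds,
        seed=seed,
    ).fit(table).correlation_


def edge_significance(
    table: GenusAbundanceTable | np.ndarray,
    observed_r: np.ndarray,
    B: int = 100,
    seed: int = 0,
    **sparcc_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p and BH q per genus pair.

    Null correlations come from ``B`` datasets with every genus column
    permuted independently, SparCC re-run on each. Null correlations are
    studentised per pair (centred and scaled by that pair's permutation
    moments — pairs involving rare genera have noisier estimates) and then
    pooled across pairs, which gives BH-workable p-value resolution at
    moderate B without the heteroskedasticity miscalibration of raw
    pooling: p_ij = (1 + #{pooled |z_null| >= |z_obs_ij|}) / (n_null + 1).
    """
    if B < 20:
        warnings.warn(f"B={B} permutations give a coarse null; consider B >= 100")
    counts = table.values if isinstance(table, GenusAbundanceTable) else np.asarray(table, float)
    rng = np.random.default_rng(seed)
    G = counts.shape[1]
    iu = np.triu_indices(G, k=1)
    null_r = np.empty((B, iu[0].size))
    for b in range(B):
        shuffled = np.column_stack([rng.permutation(counts[:, j]) for j in range(G)])
        null_r[b] = sparcc(shuffled, seed=int(rng.integers(2**31)), **sparcc_kwargs)[iu]
    mu = null_r.mean(axis=0)
    sd = np.maximum(null_r.std(axis=0, ddof=1), 1e-12)
    null_z = np.sort(np.abs((null_r - mu) / sd).ravel())
    obs_z = np.abs((observed_r[iu] - mu) / sd)
    n_null = null_z.size
    exceed_flat = n_null - np.searchsorted(null_z, obs_z, side="left")
    p = np.ones((G, G))
    p[iu] = (1.0 + exceed_flat) / (n_null + 1.0)
    p.T[iu] = p[iu]
    np.fill_diagonal(p, 1.0)
    q_flat = multipletests(p[iu], method="fdr_bh")[1]
    q = np.ones_like(p)
    q[iu] = q_flat
    q.T[iu] = q_flat
    return p, q


# ---------------------------------------------------------------------------
# network assembly


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # genus_a, genus_b, r, q, sign
    modules: dict[str, int]
    modularity: float | None

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


def build_network(
    correlations: np.ndarray,
    q: np.ndarray,
    genus_names: list[str],
    q_threshold: float = 0.05,
    top_k: int = 100,
    louvain_resolution: float = 1.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> CooccurrenceNetwork:
    """Significant-edge network with Louvain modules.

    Edges with q < threshold are capped at ``top_k`` by |r| separately for
    positive (co-occurrence) and negative (co-exclusion) signs; Louvain runs
    on the |r|-weighted graph with ``n_restarts`` seeds keeping the best
    modularity (the algorithm is order-dependent).
    """
    G = len(genus_names)
    records = []
    for i, j in itertools.combinations(range(G), 2):
        if q[i, j] < q_threshold:
            r = correlations[i, j]
            records.append(
                {
                    "genus_a": genus_names[i],
                    "genus_b": genus_names[j],
                    "r": float(r),
                    "q": float(q[i, j]),
                    "sign": "cooccurrence" if r > 0 else "coexclusion",
                }
            )
    edges = pd.DataFrame(records, columns=["genus_a", "genus_b", "r", "q", "sign"])
    if edges.empty:
        warnings.warn("no significant edges; returning an empty network")
        return CooccurrenceNetwork(graph=nx.Graph(), edges=edges, modules={}, modularity=None)
    kept = []
    for sign in ("cooccurrence", "coexclusion"):
        sub = edges[edges["sign"] == sign]
        kept.append(sub.reindex(sub["r"].abs().sort_values(ascending=False).index).head(top_k))
    edges = pd.concat(kept).reset_index(drop=True)

    graph = nx.Graph()
    for _, row in edges.iterrows():
        graph.add_edge(row["genus_a"], row["genus_b"], weight=abs(row["r"]), r=row["r"], q=row["q"])
    best_mod, best_parts = -np.inf, None
    for k in range(n_restarts):
        parts = nx.community.louvain_communities(
            graph, weight="weight", resolution=louvain_resolution, seed=seed + k
        )
        mod = nx.community.modularity(graph, parts, weight="weight", resolution=louvain_resolution)
        if mod > best_mod:
            best_mod, best_parts = mod, parts
    modules = {node: mid for mid, part in enumerate(best_parts) for node in part}
    return CooccurrenceNetwork(graph=graph, edges=edges, modules=modules, modularity=float(best_mod))


# ---------------------------------------------------------------------------
# residualised microbiome–mediator correlation


def residualize_features(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame | None,
    patient_ids: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Residualise each feature on covariates with a patient random intercept.

    Categorical covariates are dummy-coded. With an empty covariate set the
    residuals are the centred values. Falls back to OLS per feature when the
    mixed model cannot be estimated (e.g. all patients single-visit).
    """
    import statsmodels.api as sm

    patient_ids = np.asarray(patient_ids)
    n = matrix.shape[0]
    if covariates is None or covariates.shape[1] == 0:
        return matrix - matrix.mean(axis=0)
    exog = pd.get_dummies(covariates, drop_first=True).astype(float)
    X = sm.add_constant(exog.to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    repeated = pd.Series(patient_ids).value_counts().max() > 1
    out = {}
    for col in matrix.columns:
        yv = matrix[col].to_numpy(dtype=float)
        try:
            if repeated:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.MixedLM(yv, X, groups=patient_ids).fit(reml=True)
                resid = yv - np.asarray(fit.fittedvalues)
            else:
                raise ValueError("no repeated measures")
        except (ValueError, np.linalg.LinAlgError):
            fit = sm.OLS(yv, X).fit()
            resid = np.asarray(fit.resid)
        out[col] = resid
    return pd.DataFrame(out, index=matrix.index)


def feature_mediator_corr(
    residual_genera: pd.DataFrame,
    residual_mediators: pd.DataFrame,
    q_threshold: float = 0.1,
    top_k: int = 20,
) -> pd.DataFrame:
    """Spearman correlation for every genus–mediator pair with BH FDR.

    Returns the full pair table with a ``retained`` flag: significant pairs
    capped at ``top_k`` per sign by |rho|.
    """
    if not residual_genera.index.equals(residual_mediators.index):
        raise ValueError("genus and mediator matrices must be row-aligned by sample")
    rows = []
    for g in residual_genera.columns:
        for m in residual_mediators.columns:
            x = residual_genera[g]
            y = residual_mediators[m]
            mask = x.notna() & y.notna()
            if mask.sum() < 3:
                warnings.warn(f"pair ({g}, {m}) has <3 complete observations; skipped")
                continue
            rho, p = spearmanr(x[mask], y[mask])
            rows.append({"genus": g, "mediator": m, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["retained"] = False
    sig = out[out["q"] < q_threshold]
    for positive in (True, False):
        sub = sig[(sig["rho"] > 0) == positive]
        keep = sub.reindex(sub["rho"].abs().sort_values(ascending=False).index).head(top_k).index
        out.loc[keep, "retained"] = True
    return out
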