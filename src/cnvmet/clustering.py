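"""Molecular subtype discovery: NMF consensus clustering per platform and a
Gaussian latent-variable integrative clustering across platforms.

NMF follows the classic multiplicative Kullback-Leibler update scheme
("brunet"): V ~ WH with W, H >= 0, samples assigned to the argmax
coefficient row.  Stability over random restarts is summarized in a
sample-by-sample consensus (co-clustering frequency) matrix; the number of
clusters k is chosen by the cophenetic correlation of the consensus matrix,
subject to a minimum cluster size, with average silhouette width as
tie-breaker.

The integrative model is the joint Gaussian latent-variable factor model
X_d = W_d Z + eps_d per data type d, eps_d ~ N(0, Psi_d diagonal), with a
shared (k-1)-dimensional latent Z, fitted by EM with lasso soft-thresholding
on the loadings; cluster labels come from k-means on the posterior factor
scores E[Z|X].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .matrix import OmicsMatrix

__all__ = [
    "posneg_split",
    "nonnegative_shift",
    "nmf_brunet",
    "NMFResult",
    "consensus_and_select_k",
    "icluster_fit",
    "IntegrationResult",
    "cluster_agreement",
]

_EPS = np.finfo(float).tiny


def posneg_split(values: pd.DataFrame) -> pd.DataFrame:
    """Non-negative fold-change transform: stack positive and negative parts.

    Each gene row g becomes two rows ``g+`` = max(x, 0) and ``g-`` =
    max(-x, 0).  Unlike a min-shift this leaves no constant background to
    soak up a factor, so a rank-k block structure stays rank-k — the
    preferred transform for consensus NMF on fold-difference data.
    """
    pos = values.clip(lower=0.0)
    neg = (-values).clip(lower=0.0)
    pos.index = pd.Index([f"{g}+" for g in values.index], name=values.index.name)
    neg.index = pd.Index([f"{g}-" for g in values.index], name=values.index.name)
    return pd.concat([pos, neg])


def nonnegative_shift(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Column-wise min-shift onto the non-negative orthant.

    Returns the shifted matrix and the per-column shifts applied (zero for
    columns already non-negative), so the transform is recorded and
    invertible.
    """
    mins = values.min(axis=0)
    shift = (-mins).clip(lower=0.0)
    return values.add(shift, axis=1), shift


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    term = np.where(mask, V * np.log(np.maximum(V, _EPS) / WH), 0.0)
    return float(term.sum() - V.sum() + WH.sum())


def _nmf_single(V: np.ndarray, k: int, rng, max_iter: int, tol: float):
    p, n = V.shape
    scale = np.sqrt(V.mean() / max(k, 1))
    W = rng.uniform(_EPS, 1.0, size=(p, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, n)) * scale
    trace = []
    prev = None
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        obj = _kl_divergence(V, W @ H)
        trace.append(obj)
        if prev is not None and abs(prev - obj) <= tol * max(abs(prev), 1.0):
            break
        prev = obj
    return W, H, np.asarray(trace)


@dataclass
class NMFResult:
    k: int
    W: np.ndarray                    # gene x k basis of the best restart
    H: np.ndarray                    # k x sample coefficients of the best restart
    samples: pd.Index
    labels: pd.Series                # consensus labels (hierarchical cut at k)
    run_assignments: np.ndarray      # restarts x samples argmax assignments
    consensus: np.ndarray            # sample x sample co-clustering frequency
    cophenetic: float
    silhouette: float
    objective_trace: np.ndarray      # KL divergence per iteration, best restart
    objectives: np.ndarray           # final KL per restart
    all_traces: list = None          # per-restart objective traces
    shift: pd.Series | None = None   # recorded non-negativity shift, if applied

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _consensus_stats(consensus: np.ndarray, k: int):
    """Hierarchical labels, cophenetic correlation and silhouette of a
    consensus matrix."""
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Zlink = linkage(condensed, method="average")
    labels = fcluster(Zlink, t=k, criterion="maxclust")
    if condensed.std() == 0:
        coph = 1.0  # all-identical restarts: consensus distances are constant
    else:
        coph = float(cophenet(Zlink, condensed)[0])
    if len(np.unique(labels)) < 2:
        sil = float("nan")
    else:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    return labels, coph, sil


def nmf_brunet(
    V,
    k: int,
    n_restarts: int = 50,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    shift: pd.Series | None = None,
) -> NMFResult:
    """Consensus NMF with multiplicative KL updates.

    ``V`` may be a DataFrame (genes x samples) or an OmicsMatrix; it must be
    non-negative — fold-difference inputs should first go through
    :func:`nonnegative_shift` (pass the recorded shift along for provenance).
    All restarts feed the consensus matrix; the restart with the best (lowest)
    final KL divergence provides W and H.  Deterministic given ``seed``.
    """
    if isinstance(V, OmicsMatrix):
        V = V.values
    samples = V.columns if isinstance(V, pd.DataFrame) else pd.RangeIndex(np.asarray(V).shape[1])
    Varr = np.asarray(V, dtype=float)
    if np.isnan(Varr).any():
        raise ValueError("NMF input contains missing values; impute first")
    if (Varr < 0).any():
        raise ValueError(
            "NMF input has negative entries; apply nonnegative_shift() (column-wise "
            "min-shift) before factorization"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    n = Varr.shape[1]
    rng = np.random.default_rng(seed)
    assignments = np.empty((n_restarts, n), dtype=int)
    objectives = np.empty(n_restarts)
    all_traces = []
    best = None
    for run in range(n_restarts):
        W, H, trace = _nmf_single(Varr, k, rng, max_iter, tol)
        assignments[run] = H.argmax(axis=0)
        objectives[run] = trace[-1]
        all_traces.append(trace)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    co = np.zeros((n, n))
    for run in range(n_restarts):
        a = assignments[run]
        co += (a[:, None] == a[None, :]).astype(float)
    consensus = co / n_restarts
    if k == 1:
        labels = pd.Series(1, index=samples)
        coph, sil = 1.0, float("nan")
    else:
        lab, coph, sil = _consensus_stats(consensus, k)
        labels = pd.Series(lab, index=samples)
    W, H, trace = best
    return NMFResult(
        k=k, W=W, H=H, samples=samples, labels=labels,
        run_assignments=assignments, consensus=consensus,
        cophenetic=coph, silhouette=sil,
        objective_trace=trace, objectives=objectives, all_traces=all_traces,
        shift=shift,
    )


def consensus_and_select_k(
    V,
    k_range=range(2, 6),
    min_members: int = 10,
    n_restarts: int = 50,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
    shift: pd.Series | None = None,
) -> tuple[int | None, dict[int, NMFResult], pd.DataFrame]:
    """Run consensus NMF over a k range and pick k.

    Admissible k have every consensus cluster >= ``min_members``; among those
    the chosen k maximizes the cophenetic correlation, ties broken by higher
    silhouette, then smaller k.  Returns (chosen_k or None, per-k results,
    selection table).
    """
    results: dict[int, NMFResult] = {}
    rows = []
    for i, k in enumerate(k_range):
        res = nmf_brunet(V, k, n_restarts=n_restarts, max_iter=max_iter,
                         tol=tol, seed=seed + 1000 * i, shift=shift)
        admissible = bool((res.cluster_sizes() >= min_members).all())
        results[k] = res
        rows.append({"k": k, "cophenetic": res.cophenetic,
                     "silhouette": res.silhouette, "min_cluster_size":
                     int(res.cluster_sizes().min()), "admissible": admissible})
    table = pd.DataFrame(rows).set_index("k")
    ok = table[table["admissible"]]
    if ok.empty:
        warnings.warn("no k admissible under the minimum-cluster-size rule")
        return None, results, table
    # tie-break: max cophenetic, then max silhouette, then min k
    best_coph = ok["cophenetic"].max()
    cand = ok[ok["cophenetic"] == best_coph]
    best_sil = cand["silhouette"].max()
    cand = cand[(cand["silhouette"] == best_sil) | cand["silhouette"].isna()]
    chosen = int(cand.index.min())
    return chosen, results, table


# ---------------------------------------------------------------------------
# integrative clustering
# ---------------------------------------------------------------------------

@dataclass
class IntegrationResult:
    k: int
    EZ: pd.DataFrame                 # (k-1) x samples posterior factor scores
    W: list[np.ndarray]              # loadings per data type
    psi: list[np.ndarray]            # residual variances per data type
    labels: pd.Series
    loglik_trace: np.ndarray
    converged: bool
    lam: tuple[float, ...]
    degenerate: bool = False         # all loadings shrunk to zero


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def icluster_fit(
    matrices: list,
    k: int,
    lam: float | tuple[float, ...] = 0.2,
    n_starts: int = 50,
    seed: int = 0,
    max_em_iter: int = 200,
    tol: float = 1e-5,
    standardize: bool = True,
) -> IntegrationResult:
    """Joint Gaussian latent-variable clustering across data types.

    Fits X_d = W_d Z + eps_d (Z shared, k-1 factors, Psi_d diagonal) by EM;
    after each M-step the OLS loading update of data type d is elementwise
    soft-thresholded at lambda_d * max|W_d| (lasso shrinkage; lambda_d = 0
    recovers the probabilistic-PCA solution, lambda_d -> 1 zeroes W_d).
    Labels come from k-means (``n_starts`` restarts, seeded) on E[Z|X].
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    mats = [m.values if isinstance(m, OmicsMatrix) else pd.DataFrame(m) for m in matrices]
    samples = mats[0].columns
    for m in mats[1:]:
        if not m.columns.equals(samples):
            extra = set(m.columns).symmetric_difference(samples)
            raise ValueError(f"data types do not share samples; mismatches: {sorted(extra)[:5]}")
    lams = tuple(lam) if np.ndim(lam) else (float(lam),) * len(mats)
    if len(lams) != len(mats):
        raise ValueError("one lambda per data type required")

    blocks = [np.asarray(m, dtype=float) for m in mats]
    if any(np.isnan(b).any() for b in blocks):
        raise ValueError("impute missing values before integrative clustering")
    if standardize:
        blocks = [_standardize_rows(b) for b in blocks]
    sizes = [b.shape[0] for b in blocks]
    X = np.vstack(blocks)
    p, n = X.shape
    q = k - 1

    # deterministic SVD initialization
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    W = U[:, :q] * (S[:q] / np.sqrt(n))
    psi = np.maximum(X.var(axis=1) - (W**2).sum(axis=1), 1e-4)

    bounds = np.cumsum([0] + sizes)
    lam_vec = np.concatenate([np.full(s, l) for s, l in zip(sizes, lams)])

    def _loglik(W, psi):
        # Gaussian marginal loglik via the matrix determinant lemma / Woodbury
        Wp = W / psi[:, None]
        M = np.eye(q) + W.T @ Wp                    # I + W' Psi^-1 W
        sign, logdet_M = np.linalg.slogdet(M)
        logdet = logdet_M + np.log(psi).sum()
        Minv = np.linalg.inv(M)
        XtPx = (X * (X / psi[:, None])).sum()
        WpX = Wp.T @ X                              # q x n
        quad = XtPx - (WpX * (Minv @ WpX)).sum()
        return -0.5 * (n * logdet + quad + n * p * np.log(2 * np.pi))

    trace = []
    converged = False
    for it in range(max_em_iter):
        Wp = W / psi[:, None]
        M = np.eye(q) + W.T @ Wp
        Minv = np.linalg.inv(M)
        EZ = Minv @ (Wp.T @ X)                      # q x n
        EZZ = n * Minv + EZ @ EZ.T
        W_new = (X @ EZ.T) @ np.linalg.inv(EZZ)
        # lasso soft-threshold, scaled per data type
        for d in range(len(sizes)):
            sl = slice(bounds[d], bounds[d + 1])
            block = W_new[sl]
            thr = lams[d] * (np.abs(block).max() if block.size else 0.0)
            W_new[sl] = np.sign(block) * np.maximum(np.abs(block) - thr, 0.0)
        psi_new = np.maximum(
            (X**2).mean(axis=1) - ((W_new * (X @ EZ.T)) / n).sum(axis=1), 1e-6
        )
        W, psi = W_new, psi_new
        ll = _loglik(W, psi)
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) <= tol * max(abs(trace[-2]), 1.0):
            converged = True
            break

    degenerate = bool(np.allclose(W, 0.0))
    Wp = W / psi[:, None]
    M = np.eye(q) + W.T @ Wp
    EZ = np.linalg.solve(M, Wp.T @ X)
    EZ_df = pd.DataFrame(EZ, index=[f"factor{i+1}" for i in range(q)], columns=samples)

    if degenerate:
        warnings.warn("all loadings shrunk to zero (penalty too large); labels degenerate")
        labels = pd.Series(1, index=samples)
    else:
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
        labels = pd.Series(km.fit_predict(EZ.T) + 1, index=samples)

    Ws = [W[bounds[d]:bounds[d + 1]] for d in range(len(sizes))]
    psis = [psi[bounds[d]:bounds[d + 1]] for d in range(len(sizes))]
    return IntegrationResult(
        k=k, EZ=EZ_df, W=Ws, psi=psis, labels=labels,
        loglik_trace=np.asarray(trace), converged=converged,
        lam=lams, degenerate=degenerate,
    )


def cluster_agreement(labels_a, labels_b):
    """Cross-tabulation chi-square (no continuity correction) plus ARI.

    Returns (chi2, df, p, ari).  With a degenerate single-cluster labeling
    the chi-square is undefined (NaN) but the ARI is still reported.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if not a.index.equals(b.index):
        b = b.reindex(a.index)
        if b.isna().any():
            raise ValueError("labelings cover different samples")
    ari = float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
    tab = pd.crosstab(a, b)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return float("nan"), 0, float("nan"), ari
    chi2, p, df, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(chi2), int(df), float(p), ari
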