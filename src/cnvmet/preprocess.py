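"""Matrix-level preprocessing: normalization, filtering, imputation,
probe-to-gene collapse, copy-number segmentation and batch integration.

All operations preserve sample ordering and never invent gene identifiers.
Missingness is carried as NaN throughout; the filter -> impute pipeline
leaves zero missing values and never touches an observed one.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import (
    ISLAND_RELATED,
    PROMOTER_RELATED,
    CpGContext,
    GenicContext,
    OmicsMatrix,
    Platform,
    ProbeAnnotation,
    Scale,
)

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize",
    "tumor_fold_difference",
    "filter_missing",
    "knn_impute",
    "select_met_probes",
    "collapse_probes_to_gene",
    "segment_cnv",
    "combat_adjust",
]


def quantile_normalize(exp: OmicsMatrix) -> OmicsMatrix:
    """Force every sample column onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns; ties within a
    column receive the average of the tied reference values.  Missing
    entries are left untouched: observed values in an incomplete column are
    mapped through interpolated reference quantiles.
    """
    if exp.platform is not Platform.EXP:
        raise ValueError("quantile normalization is defined for expression matrices")
    X = exp.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return exp.with_values(exp.values.copy())

    obs = ~np.isnan(X)
    if obs.all():
        ref = np.sort(X, axis=0).mean(axis=1)
        out = np.empty_like(X)
        for j in range(n_samples):
            ranks = stats.rankdata(X[:, j], method="average")  # 1-based, ties averaged
            out[:, j] = np.interp(ranks, np.arange(1, n_genes + 1), ref)
    else:
        # reference from per-column quantile curves on a common grid
        grid = np.linspace(0.0, 1.0, n_genes)
        curves = np.empty((n_genes, n_samples))
        for j in range(n_samples):
            col = np.sort(X[obs[:, j], j])
            if col.size == 0:
                raise ValueError(f"column {exp.samples[j]!r} has no observed values")
            curves[:, j] = np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
        ref = curves.mean(axis=1)
        out = np.full_like(X, np.nan)
        for j in range(n_samples):
            idx = np.where(obs[:, j])[0]
            ranks = stats.rankdata(X[idx, j], method="average")
            q = (ranks - 1) / max(idx.size - 1, 1)
            out[idx, j] = np.interp(q, grid, ref)
    return exp.with_values(pd.DataFrame(out, index=exp.genes, columns=exp.samples))


def tumor_fold_difference(m: OmicsMatrix, normal_ids) -> OmicsMatrix:
    """Re-express values as fold differences vs the mean non-tumoral profile.

    Each row has its mean over ``normal_ids`` subtracted, so the output is on
    the platform's fold-difference scale (log2 fold for expression, delta
    log-ratio for CNV, delta beta for methylation) and normal columns have
    row mean zero.
    """
    normal_ids = [s for s in normal_ids if s in m.values.columns]
    if not normal_ids:
        raise ValueError(
            "no non-tumoral reference samples found in the matrix; supply at "
            "least one normal sample id to define the fold-difference baseline"
        )
    ref = m.values[normal_ids].mean(axis=1, skipna=True)
    out = m.values.sub(ref, axis=0)
    return OmicsMatrix(platform=m.platform, values=out, scale=Scale.FOLD_DIFFERENCE)


def filter_missing(m: OmicsMatrix, max_missing_frac: float) -> OmicsMatrix:
    """Drop rows whose missing fraction exceeds ``max_missing_frac``."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    frac = m.values.isna().mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_missing: dropped %d/%d rows (> %.0f%% missing)",
                    dropped, len(keep), 100 * max_missing_frac)
    if keep.sum() == 0:
        warnings.warn("filter_missing removed every row")
    return m.with_values(m.values.loc[keep])


def knn_impute(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """k-nearest-neighbour imputation in row (gene) space.

    Distance between two rows is the root-mean-square difference over their
    co-observed columns (rows sharing no column are infinitely far).  A
    missing entry is replaced by the mean of that column's values over the
    ``k`` nearest rows that observe it; if no such donor exists the column
    mean (then the row mean) is used.  Observed entries are never modified.
    """
    X = m.values.to_numpy(dtype=float)
    n_rows = X.shape[0]
    if n_rows < 2:
        raise ValueError("kNN imputation needs at least 2 rows")
    if k >= n_rows:
        warnings.warn(f"k={k} >= number of rows; clipping to {n_rows - 1}")
        k = n_rows - 1
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("every row must have at least one observed value")
    out = X.copy()
    need = np.where(~obs.all(axis=1))[0]
    if need.size == 0:
        return m.with_values(m.values.copy())

    Xz = np.where(obs, X, 0.0)
    col_means = np.nanmean(X, axis=0)
    for i in need:
        # rms distance over co-observed columns to every other row
        shared = obs & obs[i]                      # (n_rows, n_cols)
        n_shared = shared.sum(axis=1)
        diff = (Xz - Xz[i]) * shared
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt((diff**2).sum(axis=1) / n_shared)
        d[n_shared == 0] = np.inf
        d[i] = np.inf
        order = np.argsort(d, kind="stable")
        for j in np.where(~obs[i])[0]:
            donors = order[obs[order, j] & np.isfinite(d[order])][:k]
            if donors.size:
                out[i, j] = X[donors, j].mean()
            elif np.isfinite(col_means[j]):
                out[i, j] = col_means[j]
            else:
                out[i, j] = np.nanmean(X[i])
    return m.with_values(pd.DataFrame(out, index=m.genes, columns=m.samples))


def select_met_probes(ann: ProbeAnnotation, universe: str = "paper") -> set[str]:
    """Select methylation probes for the analysis universe.

    ``universe="paper"`` keeps autosomal probes in CpG-island-related regions
    (island / shore / shelf) or promoter-associated genic regions (TSS-2500 /
    5'UTR / first exon); ``universe="all"`` keeps all autosomal probes.  Sex
    chromosomes are always excluded.
    """
    t = ann.table
    auto = ann.is_autosomal
    if universe == "all":
        keep = auto
    elif universe == "paper":
        island = t["cpg_context"].isin({c.value for c in ISLAND_RELATED})
        promoter = t["genic_context"].isin({c.value for c in PROMOTER_RELATED})
        keep = auto & (island | promoter)
    else:
        raise ValueError(f"unknown probe universe {universe!r}; use 'paper' or 'all'")
    return set(t.loc[keep, "probe_id"])


def collapse_probes_to_gene(
    m: OmicsMatrix,
    per_probe_corr: pd.Series,
    probe_gene: pd.Series,
    mode: str = "min_corr",
) -> OmicsMatrix:
    """Collapse a probe-indexed matrix to one representative probe per gene.

    ``per_probe_corr`` holds one expression-correlation value per probe;
    ``probe_gene`` maps probe id -> gene symbol (empty/NaN = unassigned,
    dropped with a logged count).  ``mode="mean_corr"`` keeps the probe whose
    correlation is closest to the gene's mean correlation (ties: first probe);
    ``mode="min_corr"`` keeps the most negative correlation.
    """
    if mode not in ("mean_corr", "min_corr"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    probes = m.values.index
    gene = probe_gene.reindex(probes)
    unassigned = gene.isna() | (gene == "")
    if unassigned.any():
        logger.info("collapse_probes_to_gene: dropping %d unassigned probes",
                    int(unassigned.sum()))
    keep_rows = []
    for g, group in per_probe_corr.reindex(probes)[~unassigned].groupby(gene[~unassigned]):
        if mode == "min_corr":
            rep = group.idxmin()
        else:
            rep = (group - group.mean()).abs().idxmin()
        keep_rows.append((g, rep))
    order = {p: i for i, p in enumerate(probes)}
    keep_rows.sort(key=lambda t: order[t[1]])  # preserve matrix order
    new = m.values.loc[[p for _, p in keep_rows]].copy()
    new.index = pd.Index([g for g, _ in keep_rows], name="gene")
    return m.with_values(new)


def _max_t_split(x: np.ndarray) -> tuple[int, float]:
    """Best binary split of x maximizing the two-sample |t|; returns (cut, |t|).

    ``cut`` is the size of the left part (1..n-1).  Zero pooled variance with
    unequal means gives |t| = inf.
    """
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    total, total_sq = csum[-1], csq[-1]
    best_cut, best_t = 1, -1.0
    for cut in range(1, n):
        n1, n2 = cut, n - cut
        s1, s2 = csum[cut - 1], total - csum[cut - 1]
        q1, q2 = csq[cut - 1], total_sq - csq[cut - 1]
        m1, m2 = s1 / n1, s2 / n2
        ss = (q1 - n1 * m1**2) + (q2 - n2 * m2**2)
        if n > 2:
            sp2 = max(ss, 0.0) / (n - 2)
        else:
            sp2 = 0.0
        denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        if denom == 0.0:
            t = np.inf if m1 != m2 else 0.0
        else:
            t = abs(m1 - m2) / denom
        if t > best_t:
            best_cut, best_t = cut, t
    return best_cut, best_t


def segment_cnv(
    probe_values,
    positions,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Piecewise-constant fit by recursive binary segmentation.

    A simplified variant of circular binary segmentation (no circularity, no
    pruning): within each interval the split maximizing the two-sample
    t-statistic is accepted iff its permutation p-value is below ``alpha``,
    and the two halves are segmented recursively.  Returns segment means of
    the same length as the input.
    """
    x = np.asarray(probe_values, dtype=float)
    pos = np.asarray(positions)
    if x.size != pos.size:
        raise ValueError("probe_values and positions must have equal length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending within one chromosome")
    rng = np.random.default_rng(seed)
    out = np.empty_like(x)

    def _recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if seg.size < 3:
            out[lo:hi] = seg.mean()
            return
        cut, t_obs = _max_t_split(seg)
        if not np.isfinite(t_obs):
            p = 1.0 / (n_perm + 1)
        else:
            exceed = 0
            for _ in range(n_perm):
                _, t_perm = _max_t_split(rng.permutation(seg))
                if t_perm >= t_obs:
                    exceed += 1
            p = (1 + exceed) / (n_perm + 1)
        if p < alpha:
            _recurse(lo, lo + cut)
            _recurse(lo + cut, hi)
        else:
            out[lo:hi] = seg.mean()

    if x.size == 0:
        return out
    _recurse(0, x.size)
    return out


def combat_adjust(m: OmicsMatrix, batch_labels, parametric_iters: int = 100) -> OmicsMatrix:
    """Parametric empirical-Bayes batch adjustment (location and scale).

    Gene-wise standardization, per-batch location (gamma) and scale (delta^2)
    effects shrunk toward common priors — normal for location, inverse-gamma
    for scale, hyperparameters moment-matched across genes — solved by the
    usual fixed-point iteration, then back-transformed.
    """
    batch = pd.Series(np.asarray(batch_labels), index=m.samples)
    levels = batch.unique()
    if len(levels) < 2:
        raise ValueError("combat_adjust needs at least 2 batches")
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with a single sample cannot be adjusted: {list(small.index)}")

    X = m.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing values before batch adjustment")
    n_genes, n_samples = X.shape
    groups = {b: np.where((batch == b).to_numpy())[0] for b in levels}

    # weighted grand mean and pooled *within-batch* residual variance define
    # the standardization (the batch-mean structure itself is not part of
    # the noise scale)
    batch_means = np.stack([X[:, idx].mean(axis=1) for idx in groups.values()])
    weights = np.array([len(idx) for idx in groups.values()]) / n_samples
    stand_mean = weights @ batch_means
    fitted = np.empty_like(X)
    for bi, idx in enumerate(groups.values()):
        fitted[:, idx] = batch_means[bi][:, None]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    Z = (X - stand_mean[:, None]) / np.sqrt(var_pooled)[:, None]

    Z_adj = Z.copy()
    for b, idx in groups.items():
        nb = len(idx)
        g_hat = Z[:, idx].mean(axis=1)
        # ddof=0 so two statistically identical batches are an exact fixed point
        d_hat = Z[:, idx].var(axis=1, ddof=0)
        d_hat = np.maximum(d_hat, 1e-12)
        # moment-matched hyperpriors
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m_d, s2_d = d_hat.mean(), d_hat.var(ddof=1)
        if s2_d <= 0:
            a_prior, b_prior = 2.0, m_d
        else:
            a_prior = (2 * s2_d + m_d**2) / s2_d
            b_prior = (m_d * s2_d + m_d**3) / s2_d
        g_star, d_star = g_hat.copy(), d_hat.copy()
        for _ in range(parametric_iters):
            g_new = (nb * t2 * g_hat + d_star * g_bar) / (nb * t2 + d_star)
            sse = ((Z[:, idx] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sse + b_prior) / (nb / 2 + a_prior - 1)
            if (np.max(np.abs(g_new - g_star)) < 1e-8
                    and np.max(np.abs(d_new - d_star)) < 1e-8):
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new
        Z_adj[:, idx] = (Z[:, idx] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    X_adj = Z_adj * np.sqrt(var_pooled)[:, None] + stand_mean[:, None]
    return m.with_values(pd.DataFrame(X_adj, index=m.genes, columns=m.samples))
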