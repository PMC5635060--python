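"""Subtype characterization: survival, clinical association, differential
expression, differential mutation and signed KS signature enrichment.

Survival endpoints (overall survival and time to recurrence) are truncated
at five years before Kaplan-Meier estimation and log-rank testing.  The
per-sample signature enrichment score is a signed one-sided two-sample
Kolmogorov-Smirnov statistic: within one sample's expression profile the
signature genes are compared against all remaining genes, D+ capturing a
shift of the signature toward high expression and D- toward low expression;
the score is S = -log10 p(D+) if that exceeds -log10 p(D-), else
-(-log10 p(D-)), and zero on an exact tie.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .matrix import OmicsMatrix, Scale

__all__ = [
    "truncate_survival",
    "km_logrank",
    "chi2_contingency",
    "permuted_t_test",
    "deg_between_subtypes",
    "differential_mutations",
    "EnrichmentScore",
    "ks_enrichment_score",
    "score_signature_panel",
]

SURVIVAL_TRUNCATION_MONTHS = 60.0


def truncate_survival(time, event, horizon: float = SURVIVAL_TRUNCATION_MONTHS):
    """Administratively censor follow-up beyond ``horizon`` months.

    Times strictly beyond the horizon are stored as (horizon, event=0).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if np.any(t <= 0):
        raise ValueError("survival times must be > 0")
    over = t > horizon
    return np.where(over, horizon, t), np.where(over, 0, e)


def km_logrank(time, event, groups, horizon: float = SURVIVAL_TRUNCATION_MONTHS):
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    Returns (curves, chi2, df, p) where ``curves`` maps group label to the
    fitted survival-function DataFrame.  Empty groups are dropped with a
    warning; with no events anywhere the test is undefined and NaN is
    returned.
    """
    t, e = truncate_survival(time, event, horizon)
    g = pd.Series(np.asarray(groups))
    curves = {}
    for label in g.unique():
        idx = (g == label).to_numpy()
        if idx.sum() == 0:
            warnings.warn(f"group {label!r} has no samples; dropped")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[idx], e[idx], label=str(label))
        curves[label] = kmf.survival_function_
    if e.sum() == 0 or g.nunique() < 2:
        return curves, float("nan"), 0, float("nan")
    res = multivariate_logrank_test(t, g.to_numpy(), e)
    return curves, float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


def chi2_contingency(table):
    """Pearson chi-square on a 2-D count table, no continuity correction.

    Returns (chi2, df, p); raises naming the offending row/column if a
    marginal sum is zero.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (tab < 0).any():
        raise ValueError("contingency table must be non-negative")
    row_sums = tab.sum(axis=1)
    col_sums = tab.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"row {i} of the contingency table sums to zero")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"column {j} of the contingency table sums to zero")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def _t_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Student t with pooled variance."""
    nx, ny = x.size, y.size
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    denom = np.sqrt(sp2 * (1 / nx + 1 / ny))
    if denom == 0:
        return np.inf if x.mean() != y.mean() else 0.0
    return (x.mean() - y.mean()) / denom


def permuted_t_test(x, y, B: int = 1000, seed: int = 0) -> float:
    """Two-sided label-permutation p-value for the Student t statistic.

    p = (1 + #{permutations with |t*| >= |t_obs|}) / (B + 1); the +1
    correction keeps p strictly positive (floor 1/(B+1)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need >= 2 observations")
    if B < 100:
        warnings.warn(f"B={B} gives p-value resolution {1/(B+1):.3g}; too coarse "
                      "for stringent cutoffs")
    rng = np.random.default_rng(seed)
    t_obs = abs(_t_statistic(x, y))
    pooled = np.concatenate([x, y])
    nx = x.size
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(pooled)
        if abs(_t_statistic(perm[:nx], perm[nx:])) >= t_obs:
            exceed += 1
    return (1 + exceed) / (B + 1)


def deg_between_subtypes(
    exp: OmicsMatrix,
    labels,
    target_group,
    fold_cut: float = 1.4,
    use_perm_t: bool = False,
    alpha: float = 0.001,
    B: int = 1000,
    seed: int = 0,
    mode: str = "intersection",
) -> tuple[set, set, pd.DataFrame]:
    """Differentially expressed genes of one subtype vs each of the others.

    On log2-scale expression, a gene is UP for the target subtype iff its
    mean difference vs another subtype exceeds log2(fold_cut) — required
    against *every* other subtype with ``mode="intersection"`` (the default,
    strict reading of "compared with the other subtypes"), or against at
    least one with ``mode="union"``.  With ``use_perm_t`` a permutation
    t-test p < alpha is additionally required for each comparison.  DOWN is
    symmetric.  Returns (up, down, per-gene table).
    """
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    labels = pd.Series(np.asarray(labels), index=exp.samples)
    if target_group not in set(labels):
        raise ValueError(f"target group {target_group!r} not present in labels")
    others = [g for g in labels.unique() if g != target_group]
    X = exp.values
    tgt_cols = labels.index[labels == target_group]
    if use_perm_t and len(tgt_cols) < 2:
        raise ValueError("target group must have >= 2 samples for the permutation test")
    cut = np.log2(fold_cut)
    per_comp_up, per_comp_down = [], []
    table = pd.DataFrame(index=X.index)
    for og in others:
        oth_cols = labels.index[labels == og]
        if use_perm_t and len(oth_cols) < 2:
            raise ValueError(f"group {og!r} must have >= 2 samples for the permutation test")
        diff = X[tgt_cols].mean(axis=1) - X[oth_cols].mean(axis=1)
        table[f"log2fd_vs_{og}"] = diff
        up = diff > cut
        down = diff < -cut
        if use_perm_t:
            pvals = pd.Series(
                [
                    permuted_t_test(
                        X.loc[gene, tgt_cols].to_numpy(),
                        X.loc[gene, oth_cols].to_numpy(),
                        B=B,
                        seed=seed + zlib.crc32(str(gene).encode()) % 100000,
                    )
                    if (up.loc[gene] or down.loc[gene])
                    else 1.0
                    for gene in X.index
                ],
                index=X.index,
            )
            table[f"perm_p_vs_{og}"] = pvals
            up &= pvals < alpha
            down &= pvals < alpha
        per_comp_up.append(up)
        per_comp_down.append(down)
    combine = np.logical_and.reduce if mode == "intersection" else np.logical_or.reduce
    up_mask = combine(per_comp_up)
    down_mask = combine(per_comp_down)
    return set(X.index[up_mask]), set(X.index[down_mask]), table


def differential_mutations(
    mut: pd.DataFrame,
    labels,
    min_total: int = 10,
    min_diff: float = 0.05,
) -> pd.DataFrame:
    """Per-gene mutation rates by subtype with the recurrence/difference flags.

    Genes with strictly more than ``min_total`` mutations across the labeled
    samples are retained (recurrently mutated); among those, a gene is
    flagged differential iff its maximum minus minimum per-group rate
    strictly exceeds ``min_diff``.  Samples without a label are excluded
    (count logged in the returned attrs).
    """
    labels = pd.Series(labels)
    keep = [s for s in mut.columns if s in labels.index and pd.notna(labels[s])]
    n_excluded = mut.shape[1] - len(keep)
    m = mut[keep].astype(int)
    lab = labels[keep]
    total = m.sum(axis=1)
    recurrent = m.loc[total > min_total]
    rows = []
    for gene in recurrent.index:
        rates = {g: recurrent.loc[gene, lab.index[lab == g]].mean() for g in lab.unique()}
        rmax, rmin = max(rates.values()), min(rates.values())
        rows.append({
            "gene": gene,
            "total_mutations": int(total[gene]),
            **{f"rate_{g}": r for g, r in rates.items()},
            "rate_diff": rmax - rmin,
            "differential": bool(rmax - rmin > min_diff),
        })
    out = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["total_mutations", "rate_diff", "differential"])
    out.attrs["n_samples_excluded"] = n_excluded
    return out


@dataclass
class EnrichmentScore:
    s_plus: float   # -log10 p(D+): evidence the signature sits high
    s_minus: float  # -log10 p(D-): evidence the signature sits low
    s: float        # signed score per the tie-breaking rule

    @classmethod
    def from_p(cls, p_plus: float, p_minus: float) -> "EnrichmentScore":
        sp = -np.log10(max(p_plus, 1e-300))
        sm = -np.log10(max(p_minus, 1e-300))
        if sp > sm:
            s = sp
        elif sp < sm:
            s = -sm
        else:
            s = 0.0
        return cls(s_plus=float(sp), s_minus=float(sm), s=float(s))


def _one_sided_ks(sig: np.ndarray, rest: np.ndarray) -> tuple[float, float]:
    """D+ and D- for signature vs non-signature values.

    D+ = sup_x (F_rest(x) - F_sig(x)) is large when signature values sit
    above the rest; D- is the mirror.
    """
    allv = np.concatenate([sig, rest])
    grid = np.sort(np.unique(allv))
    F_sig = np.searchsorted(np.sort(sig), grid, side="right") / sig.size
    F_rest = np.searchsorted(np.sort(rest), grid, side="right") / rest.size
    d_plus = float(np.max(F_rest - F_sig))
    d_minus = float(np.max(F_sig - F_rest))
    return max(d_plus, 0.0), max(d_minus, 0.0)


def _ks_p(d: float, n1: int, n2: int) -> float:
    """One-sided asymptotic KS p-value exp(-2 n_eff d^2)."""
    n_eff = n1 * n2 / (n1 + n2)
    return float(min(1.0, np.exp(-2.0 * n_eff * d * d)))


def ks_enrichment_score(profile: pd.Series, signature, min_overlap: int = 3) -> EnrichmentScore | None:
    """Signed KS enrichment of a gene signature within one expression profile.

    ``profile`` maps gene -> expression value for one sample.  Returns None
    (with a warning) when fewer than ``min_overlap`` signature genes are
    present or no non-signature genes remain.
    """
    sig_genes = [g for g in set(signature) if g in profile.index]
    if len(sig_genes) < min_overlap:
        warnings.warn("signature overlaps the profile in fewer than "
                      f"{min_overlap} genes; score undefined")
        return None
    rest_genes = profile.index.difference(sig_genes)
    if len(rest_genes) == 0:
        warnings.warn("signature covers the whole profile; score undefined")
        return None
    if len(profile) < 10 * len(sig_genes):
        warnings.warn("profile is small relative to the signature; the "
                      "asymptotic KS p-value may be inaccurate")
    sig = profile[sig_genes].to_numpy(dtype=float)
    rest = profile[rest_genes].to_numpy(dtype=float)
    d_plus, d_minus = _one_sided_ks(sig, rest)
    return EnrichmentScore.from_p(_ks_p(d_plus, sig.size, rest.size),
                                  _ks_p(d_minus, sig.size, rest.size))


def score_signature_panel(
    exp: OmicsMatrix,
    signatures: dict[str, list],
    labels=None,
    aggressive_group=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed KS enrichment score per sample per signature.

    Returns (scores, summary): ``scores`` is sample x signature; ``summary``
    holds per-subtype mean scores (when ``labels`` are given) and, when an
    ``aggressive_group`` is named, a Mann-Whitney rank test of that subtype
    vs the rest per signature.  Signatures absent from the expression
    universe are skipped with a warning.
    """
    scores = pd.DataFrame(index=exp.samples, dtype=float)
    for name, genes in signatures.items():
        present = [g for g in set(genes) if g in exp.genes]
        if len(present) < 3:
            warnings.warn(f"signature {name!r} has <3 genes in the expression "
                          "universe; skipped")
            continue
        if len(present) >= len(exp.genes):
            warnings.warn(f"signature {name!r} covers the whole expression "
                          "universe; scores undefined")
            scores[name] = np.nan
            continue
        col = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in exp.samples:
                es = ks_enrichment_score(exp.values[s], present)
                col.append(es.s if es is not None else np.nan)
        scores[name] = col
    summary_rows = []
    if labels is not None and len(scores.columns):
        lab = pd.Series(np.asarray(labels), index=exp.samples)
        for name in scores.columns:
            row = {"signature": name}
            for g in sorted(lab.unique()):
                row[f"mean_{g}"] = scores.loc[lab == g, name].mean()
            if aggressive_group is not None:
                a = scores.loc[lab == aggressive_group, name].dropna()
                b = scores.loc[lab != aggressive_group, name].dropna()
                if len(a) and len(b):
                    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                    row["rank_p_aggressive_vs_rest"] = p
            summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    return scores, summary
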