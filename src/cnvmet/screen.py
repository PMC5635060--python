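"""Gene-wise correlation screening for copy-number- and methylation-driven
transcriptional deregulation.

For every gene the Pearson correlation of its expression with its DNA copy
number (r_cnv) and with its methylation level (r_met) is computed over
pairwise-complete samples, variance-stabilized by the Fisher transform
z = arctanh(r), and standardized as z * sqrt(n - 3), which is N(0, 1) under
independence.  Genes in the positive CNV tail (zstd >= 1.96) are called
CNV-correlated (CNVcor); genes in the negative methylation tail
(zstd <= -1.96) are methylation-correlated (METcor) — one-tailed by design,
matching the expected regulation directions (dosage activates, promoter
methylation represses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CpGContext, GeneAnnotation, GenicContext, OmicsMatrix, ProbeAnnotation

__all__ = [
    "genewise_pearson",
    "fisher_z",
    "correlation_table",
    "select_cnvcor_metcor",
    "SkewnessResult",
    "dagostino_skewness_test",
    "summarize_geneset_context",
]

DEFAULT_Z_THRESHOLD = 1.96


def genewise_pearson(a: OmicsMatrix, b: OmicsMatrix, min_pairs: int = 4) -> pd.DataFrame:
    """Row-wise Pearson correlation over pairwise-complete samples.

    Returns a DataFrame indexed by the shared genes with columns ``r`` and
    ``n`` (paired sample count).  Genes with fewer than ``min_pairs``
    complete pairs or zero variance in either vector get ``r = NaN`` and are
    expected to be excluded downstream.
    """
    common_genes = a.genes.intersection(b.genes)
    common_samples = a.samples.intersection(b.samples)
    if len(common_samples) < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} shared samples, found {len(common_samples)}"
        )
    A = a.values.loc[common_genes, common_samples].to_numpy(dtype=float)
    B = b.values.loc[common_genes, common_samples].to_numpy(dtype=float)
    mask = ~np.isnan(A) & ~np.isnan(B)
    n = mask.sum(axis=1).astype(float)
    Az = np.where(mask, A, 0.0)
    Bz = np.where(mask, B, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = Az.sum(1) / n
        mean_b = Bz.sum(1) / n
        cov = (Az * Bz).sum(1) / n - mean_a * mean_b
        var_a = (Az**2).sum(1) / n - mean_a**2
        var_b = (Bz**2).sum(1) / n - mean_b**2
        r = cov / np.sqrt(var_a * var_b)
    bad = (n < min_pairs) | (var_a <= 0) | (var_b <= 0)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return pd.DataFrame({"r": r, "n": n.astype(int)}, index=common_genes)


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = 0.5 * ln((1+r)/(1-r)).

    Correlations of exactly +/-1 are clamped to +/-(1 - 1e-12) with a
    warning; NaN propagates.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).copy()
    at_limit = np.abs(r) >= 1.0
    if np.any(at_limit & ~np.isnan(r)):
        warnings.warn("|r| = 1 clamped before Fisher transform")
        r[at_limit] = np.sign(r[at_limit]) * (1.0 - 1e-12)
    z = np.arctanh(r)
    return float(z[0]) if scalar else z


def correlation_table(
    cnv: OmicsMatrix, met: OmicsMatrix, exp: OmicsMatrix, min_pairs: int = 4
) -> pd.DataFrame:
    """Per-gene correlation screen table for CNV-vs-EXP and MET-vs-EXP.

    Columns: r_cnv, n_cnv, z_cnv, zstd_cnv, r_met, n_met, z_met, zstd_met.
    """
    rc = genewise_pearson(cnv, exp, min_pairs=min_pairs)
    rm = genewise_pearson(met, exp, min_pairs=min_pairs)
    genes = rc.index.intersection(rm.index)
    out = pd.DataFrame(index=genes)
    for tag, tab in (("cnv", rc), ("met", rm)):
        r = tab.loc[genes, "r"].to_numpy()
        n = tab.loc[genes, "n"].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = fisher_z(r)
        out[f"r_{tag}"] = r
        out[f"n_{tag}"] = n.astype(int)
        out[f"z_{tag}"] = z
        out[f"zstd_{tag}"] = z * np.sqrt(np.maximum(n - 3.0, 0.0))
    return out


def select_cnvcor_metcor(
    corr: pd.DataFrame,
    threshold: float = DEFAULT_Z_THRESHOLD,
    standardized: bool = True,
) -> tuple[set, set]:
    """Call CNVcor (positive tail) and METcor (negative tail) gene sets.

    With ``standardized=True`` (default) the threshold applies to
    z * sqrt(n - 3), the N(0,1)-scaled statistic whose 1.96 cutoff carries
    the usual P < 0.05 meaning; ``standardized=False`` thresholds the raw
    Fisher z.  Both tails are strict at the boundary's complement:
    membership requires zstd >= +threshold (CNVcor) or <= -threshold (METcor).
    """
    col_c = "zstd_cnv" if standardized else "z_cnv"
    col_m = "zstd_met" if standardized else "z_met"
    cnvcor = set(corr.index[corr[col_c] >= threshold])
    metcor = set(corr.index[corr[col_m] <= -threshold])
    return cnvcor, metcor


@dataclass
class SkewnessResult:
    g1: float       # sample skewness m3 / m2^{3/2}
    z_stat: float   # D'Agostino (1970) normalizing transform of g1
    p_value: float  # two-sided normal p
    n: int


def dagostino_skewness_test(values) -> SkewnessResult:
    """D'Agostino's test of skewness (two-sided).

    Wraps the standard normalizing transformation of the sample skewness
    g1 = m3 / m2^{3/2}; requires n >= 9 for the approximation to hold.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 9:
        raise ValueError(f"skewness test needs n >= 9, got {x.size}")
    z, p = stats.skewtest(x)
    g1 = stats.skew(x, bias=True)
    return SkewnessResult(g1=float(g1), z_stat=float(z), p_value=float(p), n=int(x.size))


def summarize_geneset_context(
    geneset,
    gene_ann: GeneAnnotation,
    probe_ann: ProbeAnnotation | None = None,
) -> dict:
    """Genomic / epigenomic context composition of a gene set.

    Returns per-arm proportions (set members on the arm / total annotated
    genes on the arm), and — when probe annotation is given — CpG-context and
    genic-context composition vectors for the set vs the whole universe
    (each summing to 1).  Genes without annotation fall into an
    ``unannotated`` bucket.
    """
    geneset = set(geneset)
    tab = gene_ann.table.set_index("gene_symbol")
    annotated = geneset & set(tab.index)
    unannotated = sorted(geneset - annotated)

    arm = gene_ann.arm_label()
    arm_total = arm.value_counts()
    member_mask = gene_ann.table["gene_symbol"].isin(annotated)
    arm_members = arm[member_mask].value_counts()
    arm_prop = (arm_members.reindex(arm_total.index).fillna(0) / arm_total).to_dict()

    out: dict = {
        "n_set": len(geneset),
        "n_unannotated": len(unannotated),
        "unannotated": unannotated,
        "arm_proportion": arm_prop,
    }
    if probe_ann is not None:
        p = probe_ann.table
        in_set = p["gene_symbol"].isin(annotated)
        for ctx, levels in (
            ("cpg_context", [c.value for c in CpGContext]),
            ("genic_context", [c.value for c in GenicContext]),
        ):
            uni = p[ctx].value_counts(normalize=True).reindex(levels).fillna(0.0)
            if in_set.any():
                sel = p.loc[in_set, ctx].value_counts(normalize=True).reindex(levels).fillna(0.0)
            else:
                sel = uni * np.nan
            out[f"{ctx}_universe"] = uni.to_dict()
            out[f"{ctx}_set"] = sel.to_dict()
    return out
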