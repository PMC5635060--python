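"""Per-sample aberration burden in eight categories and their coupling.

Two complementary views of a tumor's aberration load:

* *cor-gene deregulation* — among the CNV-correlated (CNVcor) and
  methylation-correlated (METcor) genes, how many are expressed more than
  twofold above (UP) or below (DOWN) the non-tumoral mean;
* *raw aberrations* — over the whole gene universe, how many genes show a
  copy-number fold difference beyond +/-0.2 (gain / loss) or a beta fold
  difference beyond +/-0.2 (hyper- / hypo-methylation).

Counts are normalized by the size of their gene universe so cohorts with
different panel sizes stay comparable; pairwise Pearson correlations among
the frequency vectors quantify the coupling between copy-number- and
methylation-level deregulation.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import OmicsMatrix, Scale

__all__ = [
    "count_cor_deregulation",
    "count_raw_aberrations",
    "frequency_correlations",
    "burden_correlation",
]

COR_CATEGORIES = ("cnvcor_up", "cnvcor_down", "metcor_up", "metcor_down")
RAW_CATEGORIES = ("cnv_gain", "cnv_loss", "met_hyper", "met_hypo")


def _require_fold(m: OmicsMatrix, what: str) -> None:
    if m.scale is not Scale.FOLD_DIFFERENCE:
        raise ValueError(f"{what} must be on the fold-difference scale, got {m.scale.value}")


def count_cor_deregulation(
    exp_fold: OmicsMatrix,
    cnvcor,
    metcor,
    samples=None,
    fold: float = 2.0,
) -> pd.DataFrame:
    """Count >fold-deregulated CNVcor / METcor genes per sample.

    On the log2 fold-difference expression matrix, a set member counts UP iff
    its value strictly exceeds log2(fold) and DOWN iff it is strictly below
    -log2(fold) ("more than" fold is read strictly).  Genes absent from the
    matrix are warned about and ignored.  Returns one row per sample with the
    four counts plus frequencies (count / gene-set size).
    """
    _require_fold(exp_fold, "expression matrix")
    if fold <= 1.0:
        raise ValueError("fold must be > 1")
    cut = np.log2(fold)
    cols = exp_fold.samples if samples is None else pd.Index(samples)
    out = pd.DataFrame(index=cols)
    for name, genes in (("cnvcor", set(cnvcor)), ("metcor", set(metcor))):
        present = [g for g in exp_fold.genes if g in genes]
        missing = len(genes) - len(present)
        if missing:
            warnings.warn(f"{missing} {name} genes absent from the expression matrix; ignored")
        sub = exp_fold.values.loc[present, cols].to_numpy(dtype=float)
        up = (sub > cut).sum(axis=0)
        down = (sub < -cut).sum(axis=0)
        out[f"{name}_up"] = up
        out[f"{name}_down"] = down
        denom = max(len(present), 1)
        out[f"{name}_up_freq"] = up / denom
        out[f"{name}_down_freq"] = down / denom
    out.index.name = "sample_id"
    return out


def count_raw_aberrations(
    cnv_fold: OmicsMatrix,
    met_fold: OmicsMatrix,
    samples=None,
    cutoff: float = 0.2,
) -> pd.DataFrame:
    """Count whole-universe copy-number and methylation aberrations.

    Gain iff CNV fold difference > cutoff, loss iff < -cutoff; hyper/hypo
    likewise on the methylation (delta-beta) fold matrix.  The one cutoff is
    applied on each platform's native fold-difference scale.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    _require_fold(cnv_fold, "CNV matrix")
    _require_fold(met_fold, "MET matrix")
    cols = cnv_fold.samples.intersection(met_fold.samples) if samples is None else pd.Index(samples)
    out = pd.DataFrame(index=cols)
    for name_pos, name_neg, m in (
        ("cnv_gain", "cnv_loss", cnv_fold),
        ("met_hyper", "met_hypo", met_fold),
    ):
        sub = m.values[cols].to_numpy(dtype=float)
        denom = max(m.shape[0], 1)
        pos = (sub > cutoff).sum(axis=0)
        neg = (sub < -cutoff).sum(axis=0)
        out[name_pos] = pos
        out[name_neg] = neg
        out[f"{name_pos}_freq"] = pos / denom
        out[f"{name_neg}_freq"] = neg / denom
    out.index.name = "sample_id"
    return out


def frequency_correlations(profiles: pd.DataFrame, min_samples: int = 10) -> pd.DataFrame:
    """Pairwise Pearson r and t-test p among all frequency columns.

    ``profiles`` is a per-sample table holding ``*_freq`` columns (counts
    tables from the two counting operations, joined or separate).  Constant
    vectors yield NaN r/p and are flagged.
    """
    freq_cols = [c for c in profiles.columns if c.endswith("_freq")]
    if len(profiles) < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {len(profiles)}")
    rows = []
    for a, b in itertools.combinations(freq_cols, 2):
        x = profiles[a].to_numpy(dtype=float)
        y = profiles[b].to_numpy(dtype=float)
        if np.nanstd(x) == 0 or np.nanstd(y) == 0:
            rows.append((a, b, np.nan, np.nan, True))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((a, b, r, p, False))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "undefined"])


def burden_correlation(raw_profiles: pd.DataFrame) -> tuple[float, float]:
    """Correlation between a sample's total CNV and total MET aberration freq.

    Total CNV burden = gain + loss frequency; total MET burden = hyper + hypo
    frequency.  Returns (r, p).
    """
    cnv = raw_profiles["cnv_gain_freq"] + raw_profiles["cnv_loss_freq"]
    met = raw_profiles["met_hyper_freq"] + raw_profiles["met_hypo_freq"]
    r, p = stats.pearsonr(cnv.to_numpy(), met.to_numpy())
    return float(r), float(p)
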