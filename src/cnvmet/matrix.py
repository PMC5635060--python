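"""Core in-memory containers for gene-by-sample omics matrices and annotation.

The pipeline works on three matched platforms over a shared gene/sample
namespace: DNA copy number (segmented log-ratio, 0 = diploid), DNA
methylation (beta values in [0, 1]) and mRNA expression (log2 scale).
Every platform is carried as an :class:`OmicsMatrix` — a thin, validated
wrapper around a ``pandas.DataFrame`` (genes as rows, samples as columns)
tagged with the platform and the value-scale semantics, so downstream
operations can refuse scale-inappropriate inputs instead of silently
producing nonsense.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "Scale",
    "OmicsMatrix",
    "ProbeAnnotation",
    "AUTOSOMES",
]

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


class Platform(str, enum.Enum):
    CNV = "CNV"
    MET = "MET"
    EXP = "EXP"


class Scale(str, enum.Enum):
    LOG2_EXPRESSION = "log2_expression"
    LOG_RATIO = "log_ratio"
    BETA = "beta"
    FOLD_DIFFERENCE = "fold_difference"


# raw-scale legality: methylation arrives as beta, CNV as log-ratio, expression
# as log2 intensities; every platform may be re-expressed as fold differences.
_LEGAL_SCALES = {
    Platform.CNV: {Scale.LOG_RATIO, Scale.FOLD_DIFFERENCE},
    Platform.MET: {Scale.BETA, Scale.FOLD_DIFFERENCE},
    Platform.EXP: {Scale.LOG2_EXPRESSION, Scale.FOLD_DIFFERENCE},
}


@dataclass
class OmicsMatrix:
    """One platform's gene x sample value matrix.

    Parameters
    ----------
    platform
        Which assay the values come from (CNV / MET / EXP).
    values
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Missing entries are ``NaN``.
    scale
        Value-scale semantics; checked for legality against the platform.
    """

    platform: Platform
    values: pd.DataFrame
    scale: Scale

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        self.scale = Scale(self.scale)
        if self.scale not in _LEGAL_SCALES[self.platform]:
            raise ValueError(
                f"scale {self.scale.value!r} is not legal for platform "
                f"{self.platform.value!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups[:5])!r}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dups[:5])!r}")
        if self.platform is Platform.MET and self.scale is Scale.BETA:
            arr = self.values.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0:
                    raise ValueError("beta values must lie within [0, 1]")

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, scale: Scale | None = None) -> "OmicsMatrix":
        """Return a copy carrying ``values`` (and optionally a new scale)."""
        return replace(self, values=values, scale=self.scale if scale is None else scale)

    def subset_genes(self, genes) -> "OmicsMatrix":
        keep = [g for g in genes if g in self.values.index]
        return self.with_values(self.values.loc[keep])

    def subset_samples(self, samples) -> "OmicsMatrix":
        keep = [s for s in samples if s in self.values.columns]
        return self.with_values(self.values[keep])


class CpGContext(str, enum.Enum):
    ISLAND = "island"
    SHORE = "shore"
    SHELF = "shelf"
    OPEN_SEA = "open_sea"


class GenicContext(str, enum.Enum):
    PROMOTER_TSS2500 = "promoter_tss2500"
    UTR5 = "utr5"
    FIRST_EXON = "first_exon"
    BODY = "body"
    INTERGENIC = "intergenic"


#: CpG-island-related contexts plus promoter-associated genic contexts; the
#: probe universe used when methylation probes are restricted to regions with
#: an expected cis-regulatory role.
ISLAND_RELATED = frozenset({CpGContext.ISLAND, CpGContext.SHORE, CpGContext.SHELF})
PROMOTER_RELATED = frozenset(
    {GenicContext.PROMOTER_TSS2500, GenicContext.UTR5, GenicContext.FIRST_EXON}
)


@dataclass
class ProbeAnnotation:
    """Probe-level annotation table.

    ``table`` columns: probe_id, gene_symbol, chromosome, arm, position,
    cpg_context, genic_context.  Coordinates are 0-based; ``arm`` is "p" or
    "q"; sex-chromosome probes are flagged via ``is_autosomal``.  Each probe
    maps to at most one gene (empty string = intergenic / unassigned).
    """

    table: pd.DataFrame
    _required = (
        "probe_id",
        "gene_symbol",
        "chromosome",
        "arm",
        "position",
        "cpg_context",
        "genic_context",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self._required if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table["probe_id"].duplicated().any():
            raise ValueError("duplicate probe_id in annotation")

    @property
    def is_autosomal(self) -> pd.Series:
        return self.table["chromosome"].isin(AUTOSOMES)

    def arm_label(self) -> pd.Series:
        """Chromosome-arm label, e.g. ``8q``, per probe."""
        chrom = self.table["chromosome"].str.replace("chr", "", regex=False)
        return chrom + self.table["arm"]


@dataclass
class GeneAnnotation:
    """Gene-level annotation: one row per gene with chromosome-arm placement."""

    table: pd.DataFrame  # columns: gene_symbol, chromosome, arm

    def __post_init__(self) -> None:
        for col in ("gene_symbol", "chromosome", "arm"):
            if col not in self.table.columns:
                raise ValueError(f"gene annotation missing column {col!r}")
        if self.table["gene_symbol"].duplicated().any():
            raise ValueError("duplicate gene symbols in annotation")

    def arm_label(self) -> pd.Series:
        chrom = self.table["chromosome"].str.replace("chr", "", regex=False)
        return chrom + self.table["arm"]
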