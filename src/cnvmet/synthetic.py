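"""Synthetic matched multi-omics cohort generator with planted ground truth.

Emulates the data regime of a matched tumor / non-tumor HBV-HCC cohort
profiled on three coupled platforms — segmented DNA copy number (log-ratio),
DNA methylation (beta) and mRNA expression (log2) — together with clinical
covariates, survival endpoints (OS, time-to-recurrence) and a binary somatic
mutation table.

Planted structure, all recoverable downstream:

* a fraction of genes is CNV-driven (expression = baseline + slope * CNV,
  slope > 0) and a disjoint fraction methylation-driven (slope < 0 on beta);
  remaining genes carry aberrations uncoupled from expression;
* copy-number events are segmental (per-arm segments in states near
  {-0.5, 0, +0.5} log-ratio) and methylation events shift a logistic latent,
  guaranteeing beta in (0, 1);
* each segment / methylation-driven gene carries a subtype affinity, so the
  three tumor subtypes differ in *which* genes are aberrant, not just how
  many — giving consensus clustering block structure to find;
* per-sample aberration rates are subtype-graded (high > mid > low) and the
  CNV and methylation rates of a sample are coupled with a configurable
  cohort-wide correlation;
* survival hazards, vascular-invasion rates and two planted mutation genes
  (one enriched in the aggressive subtype, one in the favorable ones) are
  subtype-linked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    AUTOSOMES,
    GeneAnnotation,
    OmicsMatrix,
    Platform,
    ProbeAnnotation,
    Scale,
)
from . import io as _io

__all__ = [
    "CohortConfig",
    "MultiOmicsCohort",
    "generate_cohort",
    "write_cohort",
    "strong_signal_config",
]


def strong_signal_config(seed: int = 0, n_tumor: int = 180, n_genes: int = 1000) -> "CohortConfig":
    """The strong-signal validation scenario.

    Balanced subtypes whose identity is carried by *which* segments are
    aberrant (flat burden profile, high affinity contrast) rather than by
    overall burden, no missingness — the regime in which subtype structure
    should be unambiguously recoverable by every clustering route.
    """
    return CohortConfig(
        seed=seed,
        n_tumor=n_tumor,
        n_normal=30,
        n_genes=n_genes,
        subtype_props=(1 / 3, 1 / 3, 1 / 3),
        burden_by_subtype=(0.25, 0.20, 0.15),
        burden_sd=0.05,
        missing_frac=0.0,
    )


# Clinical category levels mirror a published 64-patient HBV-HCC cohort's
# clinico-pathological table; vascular invasion is the subtype-linked one.
_CLINICAL_LEVELS = {
    "sex": (("Male", "Female"), (0.85, 0.15)),
    "age_group": (("<60", ">=60"), (0.52, 0.48)),
    "stage": (("T1/T2", "T3/T4"), (0.83, 0.17)),
    "tumor_size": (("<5cm", ">=5cm"), (0.44, 0.56)),
    "gross_type": (("Simple nodular", "Multi nodular/infiltrative"), (0.52, 0.48)),
    "afp": (("<400", ">=400"), (0.77, 0.23)),
    "grade": (("I,II", "III,IV"), (0.63, 0.37)),
}
_VASCULAR_INVASION_RATE = (0.78, 0.52, 0.21)  # aggressive -> favorable


def _default_mutation_spec() -> list[tuple[str, tuple[float, ...]]]:
    spec: list[tuple[str, tuple[float, ...]]] = [
        ("BAP1L", (0.15, 0.03, 0.05)),   # aggressive-subtype enriched
        ("CTNNB1L", (0.03, 0.10, 0.11)),  # favorable-subtype enriched
    ]
    # background recurrently mutated genes, subtype-indifferent
    for i, rate in enumerate((0.08, 0.06, 0.05, 0.05, 0.04, 0.04)):
        spec.append((f"MUTBG{i + 1}", (rate,) * 3))
    return spec


@dataclass
class CohortConfig:
    """Generator settings; defaults mirror the matched 64T/30N study design."""

    seed: int = 0
    n_tumor: int = 64
    n_normal: int = 30
    n_genes: int = 2000
    n_subtypes: int = 3
    subtype_props: tuple[float, ...] = (0.20, 0.36, 0.44)
    frac_cnvcor: float = 0.10
    frac_metcor: float = 0.05
    cnv_effect: float = 2.0      # log2 expression per unit CNV log-ratio, > 0
    met_effect: float = -3.0     # log2 expression per unit beta, < 0
    noise_sd: float = 0.30       # residual SD of log2 expression
    burden_by_subtype: tuple[float, ...] = (0.28, 0.18, 0.09)
    burden_sd: float = 0.06      # within-subtype SD of the per-sample rate
    burden_coupling: float = 0.70
    chr8_enrichment: float = 4.0
    genes_per_segment: int = 5
    affinity_boost: float = 3.0  # event-rate multiplier in the matching subtype
    affinity_base: float = 0.1   # multiplier elsewhere
    hazard_os: tuple[float, ...] = (0.020, 0.008, 0.006)   # events / month
    hazard_ttr: tuple[float, ...] = (0.045, 0.015, 0.015)  # planted HR 3
    censor_horizon_months: float = 120.0
    mutation_spec: list = field(default_factory=_default_mutation_spec)
    missing_frac: float = 0.02   # MCAR missingness injected per platform

    def validate(self) -> None:
        if self.n_subtypes < 2:
            raise ValueError("n_subtypes must be >= 2")
        if len(self.subtype_props) != self.n_subtypes:
            raise ValueError("subtype_props length must equal n_subtypes")
        if abs(sum(self.subtype_props) - 1.0) > 1e-9:
            raise ValueError("subtype_props must sum to 1")
        for name in ("frac_cnvcor", "frac_metcor", "missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_cnvcor + self.frac_metcor > 1.0:
            raise ValueError(
                "frac_cnvcor + frac_metcor exceeds 1: the planted CNV-driven and "
                "methylation-driven gene sets are disjoint and cannot cover more "
                "than the gene universe"
            )
        if self.cnv_effect <= 0:
            raise ValueError("cnv_effect must be > 0 (copy-number dosage is positive)")
        if self.met_effect >= 0:
            raise ValueError("met_effect must be < 0 (methylation represses)")
        for rates in (self.hazard_os, self.hazard_ttr):
            if len(rates) != self.n_subtypes or any(r <= 0 for r in rates):
                raise ValueError("hazard rates must be positive, one per subtype")
        if len(self.burden_by_subtype) != self.n_subtypes:
            raise ValueError("burden_by_subtype needs one rate per subtype")
        if not -1.0 <= self.burden_coupling <= 1.0:
            raise ValueError("burden_coupling must lie in [-1, 1]")


@dataclass
class MultiOmicsCohort:
    """Matched CNV / MET / EXP matrices plus clinical, mutation and truth data."""

    cnv: OmicsMatrix
    met: OmicsMatrix
    exp: OmicsMatrix
    gene_annotation: GeneAnnotation
    probe_annotation: ProbeAnnotation
    samples: pd.DataFrame
    mutations: pd.DataFrame  # binary gene x tumor matrix
    truth: dict
    config: CohortConfig

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.samples.loc[self.samples["is_tumor"], "sample_id"])

    @property
    def normal_ids(self) -> list[str]:
        return list(self.samples.loc[~self.samples["is_tumor"], "sample_id"])


def _within_subtype_correlation(cfg: CohortConfig) -> float:
    """Latent correlation so the cohort-wide rate correlation hits the target.

    The subtype means are shared between platforms, so between-subtype
    variance contributes fully-correlated signal; the within-subtype latent
    correlation is solved so that the total equals ``burden_coupling``:

        rho_w = (rho_t * (vb + vw) - vb) / vw
    """
    props = np.asarray(cfg.subtype_props)
    means = np.asarray(cfg.burden_by_subtype)
    mu = float(props @ means)
    vb = float(props @ (means - mu) ** 2)
    vw = cfg.burden_sd**2
    if vw == 0:
        return 0.0
    rho_w = (cfg.burden_coupling * (vb + vw) - vb) / vw
    if not -1.0 <= rho_w <= 1.0:
        warnings.warn(
            "requested burden_coupling is outside the range attainable with the "
            "given subtype burden spread; clamping the within-subtype correlation",
            stacklevel=3,
        )
        rho_w = min(1.0, max(-1.0, rho_w))
    return rho_w


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: CohortConfig) -> MultiOmicsCohort:
    """Draw one cohort.  Bit-identical for identical configs (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_n, n_g, n_s = config.n_tumor, config.n_normal, config.n_genes, config.n_subtypes

    genes = [f"G{i + 1:05d}" for i in range(n_g)]
    tumor_ids = [f"T{i + 1:03d}" for i in range(n_t)]
    normal_ids = [f"N{i + 1:03d}" for i in range(n_n)]
    all_ids = tumor_ids + normal_ids

    # -- subtype labels ---------------------------------------------------
    subtype = rng.choice(n_s, size=n_t, p=np.asarray(config.subtype_props))

    # -- planted gene classes ---------------------------------------------
    n_cnvcor = int(round(config.frac_cnvcor * n_g))
    n_metcor = int(round(config.frac_metcor * n_g))
    perm = rng.permutation(n_g)
    cnvcor_idx = np.sort(perm[:n_cnvcor])
    metcor_idx = np.sort(perm[n_cnvcor : n_cnvcor + n_metcor])
    is_cnvcor = np.zeros(n_g, bool)
    is_cnvcor[cnvcor_idx] = True
    is_metcor = np.zeros(n_g, bool)
    is_metcor[metcor_idx] = True

    # -- genomic layout: arms, chr8 enrichment for CNV-driven genes -------
    arms = [f"{c.removeprefix('chr')}{a}" for c in AUTOSOMES for a in ("p", "q")]
    base_w = np.ones(len(arms))
    w_null = base_w / base_w.sum()
    w_cnv = base_w.copy()
    for i, arm in enumerate(arms):
        if arm in ("8p", "8q"):
            w_cnv[i] *= config.chr8_enrichment
    w_cnv = w_cnv / w_cnv.sum()
    arm_idx = np.empty(n_g, dtype=int)
    arm_idx[~is_cnvcor] = rng.choice(len(arms), size=int((~is_cnvcor).sum()), p=w_null)
    arm_idx[is_cnvcor] = rng.choice(len(arms), size=int(is_cnvcor.sum()), p=w_cnv)
    position = rng.integers(1_000_000, 120_000_000, size=n_g)

    # -- per-sample aberration rates (coupled across platforms) ----------
    rho_w = _within_subtype_correlation(config)
    cov = np.array([[1.0, rho_w], [rho_w, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_t, method="cholesky")
    means = np.asarray(config.burden_by_subtype)[subtype]
    rate_cnv = np.clip(means + config.burden_sd * z[:, 0], 0.02, 0.90)
    rate_met = np.clip(means + config.burden_sd * z[:, 1], 0.02, 0.90)

    # -- copy number: per-arm segments with subtype affinity --------------
    order = np.lexsort((position, arm_idx))  # genome order
    seg_id = np.empty(n_g, dtype=int)
    seg_counter = 0
    for a in range(len(arms)):
        members = order[arm_idx[order] == a]
        for start in range(0, len(members), config.genes_per_segment):
            seg_id[members[start : start + config.genes_per_segment]] = seg_counter
            seg_counter += 1
    n_seg = seg_counter
    seg_dir = rng.choice([-1.0, 1.0], size=n_seg)
    seg_aff = rng.integers(0, n_s, size=n_seg)

    mult = np.where(
        seg_aff[:, None] == subtype[None, :], config.affinity_boost, config.affinity_base
    )  # segment x tumor
    p_event = np.clip(rate_cnv[None, :] * mult, 0.0, 0.95)
    seg_event = rng.random((n_seg, n_t)) < p_event
    cnv_t = (seg_dir[seg_id, None] * 0.5) * seg_event[seg_id, :]
    cnv_t = cnv_t + rng.normal(0.0, 0.05, size=(n_g, n_t))
    cnv_n = rng.normal(0.0, 0.05, size=(n_g, n_n))
    cnv = np.concatenate([cnv_t, cnv_n], axis=1)

    # -- methylation: logistic latent, gene-level events -------------------
    met_base = rng.normal(-0.5, 1.0, size=n_g)  # logit-scale baseline per gene
    gene_dir = rng.choice([-1.0, 1.0], size=n_g)
    gene_aff = rng.integers(0, n_s, size=n_g)
    mult_m = np.where(
        gene_aff[:, None] == subtype[None, :], config.affinity_boost, config.affinity_base
    )
    p_event_m = np.clip(rate_met[None, :] * mult_m, 0.0, 0.95)
    met_event = rng.random((n_g, n_t)) < p_event_m
    latent_t = met_base[:, None] + 2.0 * gene_dir[:, None] * met_event
    latent_t = latent_t + rng.normal(0.0, 0.3, size=(n_g, n_t))
    latent_n = met_base[:, None] + rng.normal(0.0, 0.3, size=(n_g, n_n))
    beta = _sigmoid(np.concatenate([latent_t, latent_n], axis=1))
    beta = np.clip(beta, 1e-6, 1.0 - 1e-6)

    # -- expression: baseline + planted couplings + noise ------------------
    exp_base = rng.normal(7.0, 1.0, size=n_g)
    expr = exp_base[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_t + n_n))
    expr[is_cnvcor, :] += config.cnv_effect * cnv[is_cnvcor, :]
    expr[is_metcor, :] += config.met_effect * (beta[is_metcor, :] - _sigmoid(met_base[is_metcor])[:, None])

    # -- MCAR missingness --------------------------------------------------
    def _inject(m: np.ndarray) -> np.ndarray:
        if config.missing_frac <= 0:
            return m
        mask = rng.random(m.shape) < config.missing_frac
        out = m.astype(float).copy()
        out[mask] = np.nan
        return out

    cnv_m, beta_m, expr_m = _inject(cnv), _inject(beta), _inject(expr)

    # -- survival ----------------------------------------------------------
    def _draw_survival(rates: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
        lam = np.asarray(rates)[subtype]
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.uniform(1.0, config.censor_horizon_months, size=n_t)
        event = (t_event <= t_cens).astype(int)
        t_obs = np.maximum(np.minimum(t_event, t_cens), 0.1)
        return t_obs, event

    os_time, os_event = _draw_survival(config.hazard_os)
    ttr_time, ttr_event = _draw_survival(config.hazard_ttr)

    # -- clinical covariates ----------------------------------------------
    clin: dict[str, np.ndarray] = {}
    for colname, (levels, probs) in _CLINICAL_LEVELS.items():
        clin[colname] = rng.choice(levels, size=n_t, p=np.asarray(probs))
    vi_rate = np.asarray(_VASCULAR_INVASION_RATE[:n_s])
    clin["vascular_invasion"] = np.where(
        rng.random(n_t) < vi_rate[subtype], "Yes", "No"
    )

    samples = pd.DataFrame(
        {
            "sample_id": all_ids,
            "is_tumor": [True] * n_t + [False] * n_n,
            "true_subtype": [int(s) + 1 for s in subtype] + [pd.NA] * n_n,
            "os_time_months": list(np.round(os_time, 2)) + [pd.NA] * n_n,
            "os_event": list(os_event) + [pd.NA] * n_n,
            "ttr_time_months": list(np.round(ttr_time, 2)) + [pd.NA] * n_n,
            "ttr_event": list(ttr_event) + [pd.NA] * n_n,
        }
    )
    for colname in list(_CLINICAL_LEVELS) + ["vascular_invasion"]:
        samples[colname] = list(clin[colname]) + [pd.NA] * n_n

    # -- mutations ---------------------------------------------------------
    mut_genes = [g for g, _ in config.mutation_spec]
    mut = np.zeros((len(mut_genes), n_t), dtype=int)
    for gi, (_, rates) in enumerate(config.mutation_spec):
        r = np.asarray(rates)
        if len(r) != n_s:
            raise ValueError("each mutation_spec entry needs one rate per subtype")
        mut[gi] = (rng.random(n_t) < r[subtype]).astype(int)
    mutations = pd.DataFrame(mut, index=pd.Index(mut_genes, name="gene"), columns=tumor_ids)

    # -- annotation --------------------------------------------------------
    arm_names = np.asarray(arms)[arm_idx]
    gene_ann = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_symbol": genes,
                "chromosome": ["chr" + a[:-1] for a in arm_names],
                "arm": [a[-1] for a in arm_names],
            }
        )
    )
    cpg_levels = np.array(["island", "shore", "shelf", "open_sea"])
    genic_levels = np.array(["promoter_tss2500", "utr5", "first_exon", "body"])
    # methylation-driven genes lean toward open-sea / gene-body probes
    cpg_p_null = np.array([0.45, 0.20, 0.10, 0.25])
    cpg_p_met = np.array([0.20, 0.15, 0.10, 0.55])
    gen_p_null = np.array([0.40, 0.10, 0.15, 0.35])
    gen_p_met = np.array([0.20, 0.05, 0.10, 0.65])
    cpg_ctx = np.where(
        is_metcor,
        rng.choice(cpg_levels, size=n_g, p=cpg_p_met),
        rng.choice(cpg_levels, size=n_g, p=cpg_p_null),
    )
    gen_ctx = np.where(
        is_metcor,
        rng.choice(genic_levels, size=n_g, p=gen_p_met),
        rng.choice(genic_levels, size=n_g, p=gen_p_null),
    )
    probe_ann = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i + 1:06d}" for i in range(n_g)],
                "gene_symbol": genes,
                "chromosome": ["chr" + a[:-1] for a in arm_names],
                "arm": [a[-1] for a in arm_names],
                "position": position,
                "cpg_context": cpg_ctx,
                "genic_context": gen_ctx,
            }
        )
    )

    gidx = pd.Index(genes, name="gene")

    def _om(values, platform, scale):
        return OmicsMatrix(
            platform=platform,
            values=pd.DataFrame(values, index=gidx, columns=all_ids),
            scale=scale,
        )

    truth = {
        "cnvcor": {genes[i] for i in cnvcor_idx},
        "metcor": {genes[i] for i in metcor_idx},
        "subtype": pd.Series([int(s) + 1 for s in subtype], index=tumor_ids, name="true_subtype"),
        "rate_cnv": pd.Series(rate_cnv, index=tumor_ids),
        "rate_met": pd.Series(rate_met, index=tumor_ids),
        "segment_id": pd.Series(seg_id, index=gidx),
        "segment_direction": pd.Series(seg_dir[seg_id], index=gidx),
        "segment_affinity": pd.Series(seg_aff[seg_id] + 1, index=gidx),
        "met_direction": pd.Series(gene_dir, index=gidx),
        "met_affinity": pd.Series(gene_aff + 1, index=gidx),
    }

    return MultiOmicsCohort(
        cnv=_om(cnv_m, Platform.CNV, Scale.LOG_RATIO),
        met=_om(beta_m, Platform.MET, Scale.BETA),
        exp=_om(expr_m, Platform.EXP, Scale.LOG2_EXPRESSION),
        gene_annotation=gene_ann,
        probe_annotation=probe_ann,
        samples=samples,
        mutations=mutations,
        truth=truth,
        config=config,
    )


def write_cohort(cohort: MultiOmicsCohort, directory, overwrite: bool = False) -> list[Path]:
    """Write a cohort as TSV/CSV/GMT files; refuses a non-empty directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace its contents"
        )
    written = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    _io.write_matrix_tsv(cohort.cnv, _w(directory / "cnv.tsv"))
    _io.write_matrix_tsv(cohort.met, _w(directory / "met.tsv"))
    _io.write_matrix_tsv(cohort.exp, _w(directory / "exp.tsv"))
    cohort.samples.to_csv(_w(directory / "clinical.csv"), index=False)
    _io.write_mutations_maf(cohort.mutations, _w(directory / "mutations.maf.tsv"))
    _io.write_probe_annotation(cohort.probe_annotation, _w(directory / "probe_annotation.tsv"))
    cohort.gene_annotation.table.to_csv(_w(directory / "gene_annotation.tsv"), sep="\t", index=False)
    _io.write_gmt(
        {
            "PLANTED_CNVCOR": sorted(cohort.truth["cnvcor"]),
            "PLANTED_METCOR": sorted(cohort.truth["metcor"]),
        },
        _w(directory / "truth.gmt"),
    )
    return written
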