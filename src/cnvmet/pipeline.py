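"""Configuration-driven orchestration of the full analysis.

Stage order: preprocess -> correlation screen -> aberration burden ->
clustering (per-platform NMF consensus, then integrative latent-variable
clustering) -> characterization (survival, clinical chi-square, DEGs,
differential mutations, optional signature scoring).  A second cohort can be
pushed through the identical configuration for validation, with cross-cohort
comparisons of the selected gene sets and subtype structure.

Every run produces a :class:`RunReport` (JSON-serializable) and writes its
artifacts with the configuration hash in each file header, so deterministic
stages reproduce bit-identically from the same config and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aberration as ab
from . import characterize as ch
from . import clustering as cl
from . import io as _io
from . import preprocess as pp
from . import screen as sc
from .matrix import OmicsMatrix, Platform, Scale
from .synthetic import CohortConfig, MultiOmicsCohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_on_cohort"]

CLINICAL_FEATURES = (
    "sex", "age_group", "stage", "tumor_size", "gross_type", "afp", "grade",
    "vascular_invasion",
)


@dataclass
class PipelineConfig:
    """All thresholds and inputs of one pipeline run.

    Exactly one of ``input_dir`` (a directory written by
    :func:`cnvmet.synthetic.write_cohort` or files of the same layout) or
    ``synthetic`` (a :class:`CohortConfig`) must be provided.
    """

    input_dir: str | None = None
    synthetic: CohortConfig | None = None
    output_dir: str | None = None
    signatures_gmt: str | None = None

    max_missing_frac: float = 0.30
    knn_k: int = 10
    z_threshold: float = 1.96
    z_standardized: bool = True
    deregulation_fold: float = 2.0
    raw_cutoff: float = 0.2
    k_min: int = 2
    k_max: int = 5
    min_members: int = 10
    n_restarts: int = 50
    nmf_transform: str = "posneg"  # or "shift"
    icluster_lambda: float = 0.2
    deg_fold: float = 1.4
    deg_use_perm_t: bool = False
    deg_alpha: float = 0.001
    deg_B: int = 1000
    mut_min_total: int = 10
    mut_min_diff: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_dir or a synthetic cohort block must be given"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
            d["synthetic"]["mutation_spec"] = [
                [g, list(r)] for g, r in self.synthetic.mutation_spec
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if syn is not None:
            syn = dict(syn)
            if "mutation_spec" in syn:
                syn["mutation_spec"] = [(g, tuple(r)) for g, r in syn["mutation_spec"]]
            for key in ("subtype_props", "burden_by_subtype", "hazard_os", "hazard_ttr"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            cfg.synthetic = CohortConfig(**syn)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "failed_stage": self.failed_stage, "error": self.error,
             "stages": self.stages},
            indent=2, default=_jsonable,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return str(obj)


def _load_cohort(cfg: PipelineConfig) -> MultiOmicsCohort:
    if cfg.synthetic is not None:
        return generate_cohort(cfg.synthetic)
    d = Path(cfg.input_dir)
    cnv = _io.read_matrix_tsv(d / "cnv.tsv", Platform.CNV, Scale.LOG_RATIO)
    met = _io.read_matrix_tsv(d / "met.tsv", Platform.MET, Scale.BETA)
    exp = _io.read_matrix_tsv(d / "exp.tsv", Platform.EXP, Scale.LOG2_EXPRESSION)
    samples = pd.read_csv(d / "clinical.csv")
    probe_ann = _io.read_probe_annotation(d / "probe_annotation.tsv")
    from .matrix import GeneAnnotation

    gene_ann = GeneAnnotation(pd.read_csv(d / "gene_annotation.tsv", sep="\t"))
    tumors = samples.loc[samples["is_tumor"].astype(bool), "sample_id"]
    mut_path = d / "mutations.maf.tsv"
    mutations = (
        _io.read_mutations_maf(mut_path, samples=tumors)
        if mut_path.exists()
        else pd.DataFrame(index=pd.Index([], name="gene"))
    )
    truth_path = d / "truth.gmt"
    truth = {}
    if truth_path.exists():
        sets = _io.read_gmt(truth_path)
        truth = {"cnvcor": set(sets.get("PLANTED_CNVCOR", [])),
                 "metcor": set(sets.get("PLANTED_METCOR", []))}
    return MultiOmicsCohort(
        cnv=cnv, met=met, exp=exp, gene_annotation=gene_ann,
        probe_annotation=probe_ann, samples=samples, mutations=mutations,
        truth=truth, config=cfg.synthetic,
    )


def _write_with_hash(df: pd.DataFrame, path: Path, cfg_hash: str, **to_csv_kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cnvmet config_hash={cfg_hash}\n")
        df.to_csv(fh, **to_csv_kw)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis for one cohort.

    Any stage failure is recorded in the report (with the partial results of
    earlier stages retained) rather than raised.
    """
    cfg.validate()
    cfg_hash = cfg.config_hash()
    report = RunReport(config_hash=cfg_hash, seed=cfg.seed)
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    stage_fns = [
        ("load", _stage_load),
        ("preprocess", _stage_preprocess),
        ("corr_screen", _stage_screen),
        ("aberration", _stage_aberration),
        ("clustering", _stage_clustering),
        ("characterize", _stage_characterize),
    ]
    for name, fn in stage_fns:
        try:
            summary = fn(cfg, state, outdir, cfg_hash)
            report.stages[name] = summary
            logger.info("stage %s: %s", name, {k: v for k, v in summary.items()
                                               if not isinstance(v, (dict, list))})
        except Exception as exc:  # record and stop; partial outputs retained
            report.failed_stage = name
            report.error = f"{type(exc).__name__}: {exc}"
            logger.exception("stage %s failed", name)
            break
    report._state = state  # in-memory artifacts for library callers
    if outdir is not None:
        report.to_json(outdir / "report.json")
    return report


def _stage_load(cfg, state, outdir, cfg_hash) -> dict:
    cohort = _load_cohort(cfg)
    state["cohort"] = cohort
    tumors = list(cohort.samples.loc[cohort.samples["is_tumor"].astype(bool), "sample_id"])
    normals = list(cohort.samples.loc[~cohort.samples["is_tumor"].astype(bool), "sample_id"])
    state["tumors"], state["normals"] = tumors, normals
    return {"n_tumor": len(tumors), "n_normal": len(normals),
            "n_genes": cohort.exp.shape[0]}


def _stage_preprocess(cfg, state, outdir, cfg_hash) -> dict:
    cohort = state["cohort"]
    summary = {}
    processed = {}
    for tag, m in (("cnv", cohort.cnv), ("met", cohort.met), ("exp", cohort.exp)):
        n0 = m.shape[0]
        m = pp.filter_missing(m, cfg.max_missing_frac)
        if m.values.isna().any().any():
            m = pp.knn_impute(m, k=cfg.knn_k)
        summary[f"{tag}_rows_in"] = n0
        summary[f"{tag}_rows_out"] = m.shape[0]
        processed[tag] = m
    processed["exp"] = pp.quantile_normalize(processed["exp"])
    genes = processed["cnv"].genes.intersection(processed["met"].genes).intersection(
        processed["exp"].genes)
    summary["n_genes_matched"] = len(genes)
    normals = state["normals"]
    for tag in ("cnv", "met", "exp"):
        m = processed[tag].subset_genes(genes)
        state[f"{tag}_fold"] = pp.tumor_fold_difference(m, normals)
    return summary


def _stage_screen(cfg, state, outdir, cfg_hash) -> dict:
    tumors = state["tumors"]
    cnv_t = state["cnv_fold"].subset_samples(tumors)
    met_t = state["met_fold"].subset_samples(tumors)
    exp_t = state["exp_fold"].subset_samples(tumors)
    corr = sc.correlation_table(cnv_t, met_t, exp_t)
    cnvcor, metcor = sc.select_cnvcor_metcor(
        corr, threshold=cfg.z_threshold, standardized=cfg.z_standardized)
    state["corr"], state["cnvcor"], state["metcor"] = corr, cnvcor, metcor
    skew_cnv = sc.dagostino_skewness_test(corr["r_cnv"].dropna())
    skew_met = sc.dagostino_skewness_test(corr["r_met"].dropna())
    cohort = state["cohort"]
    context = sc.summarize_geneset_context(
        cnvcor, cohort.gene_annotation, cohort.probe_annotation)
    context_met = sc.summarize_geneset_context(
        metcor, cohort.gene_annotation, cohort.probe_annotation)
    state["context_cnvcor"], state["context_metcor"] = context, context_met
    if outdir is not None:
        _write_with_hash(corr, outdir / "correlation_screen.tsv", cfg_hash, sep="\t")
        _io.write_gmt({"CNVCOR": sorted(cnvcor), "METCOR": sorted(metcor)},
                      outdir / "selected_genes.gmt")
    return {
        "n_cnvcor": len(cnvcor), "n_metcor": len(metcor),
        "n_overlap": len(cnvcor & metcor),
        "skewness_cnv": skew_cnv.g1, "skewness_cnv_p": skew_cnv.p_value,
        "skewness_met": skew_met.g1, "skewness_met_p": skew_met.p_value,
    }


def _stage_aberration(cfg, state, outdir, cfg_hash) -> dict:
    tumors = state["tumors"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cor_prof = ab.count_cor_deregulation(
            state["exp_fold"], state["cnvcor"], state["metcor"],
            samples=tumors, fold=cfg.deregulation_fold)
    raw_prof = ab.count_raw_aberrations(
        state["cnv_fold"], state["met_fold"], samples=tumors, cutoff=cfg.raw_cutoff)
    profiles = cor_prof.join(raw_prof)
    state["profiles"] = profiles
    freq_corr = ab.frequency_correlations(profiles)
    burden_r, burden_p = ab.burden_correlation(raw_prof)
    state["freq_corr"] = freq_corr
    if outdir is not None:
        _write_with_hash(profiles, outdir / "aberration_profiles.tsv", cfg_hash, sep="\t")
        _write_with_hash(freq_corr, outdir / "frequency_correlations.tsv", cfg_hash,
                         sep="\t", index=False)
    return {"burden_r": burden_r, "burden_p": burden_p,
            "n_freq_pairs": len(freq_corr)}


def _stage_clustering(cfg, state, outdir, cfg_hash) -> dict:
    tumors = state["tumors"]
    summary: dict = {}
    nmf_labels = {}
    chosen_ks = []
    for tag, geneset in (("cnv", state["cnvcor"]), ("met", state["metcor"])):
        m = state[f"{tag}_fold"].subset_genes(sorted(geneset)).subset_samples(tumors)
        if m.shape[0] < 2:
            raise ValueError(f"too few {tag}-correlated genes for clustering")
        if cfg.nmf_transform == "posneg":
            V, shift = cl.posneg_split(m.values), None
        elif cfg.nmf_transform == "shift":
            V, shift = cl.nonnegative_shift(m.values)
        else:
            raise ValueError(f"unknown nmf_transform {cfg.nmf_transform!r}")
        chosen, results, table = cl.consensus_and_select_k(
            V, k_range=range(cfg.k_min, cfg.k_max + 1),
            min_members=cfg.min_members, n_restarts=cfg.n_restarts,
            seed=cfg.seed + (0 if tag == "cnv" else 500_000), shift=shift)
        summary[f"nmf_{tag}_chosen_k"] = chosen
        summary[f"nmf_{tag}_selection"] = table.reset_index().to_dict("records")
        if chosen is not None:
            nmf_labels[tag] = results[chosen].labels
            chosen_ks.append(chosen)
        state[f"nmf_{tag}"] = results
    state["nmf_labels"] = nmf_labels

    if "cnv" in nmf_labels and "met" in nmf_labels:
        chi2, df, p, ari = cl.cluster_agreement(nmf_labels["cnv"], nmf_labels["met"])
        summary["cnv_met_agreement"] = {"chi2": chi2, "df": df, "p": p, "ari": ari}

    ks = sorted(set(chosen_ks)) or [3]
    stacks = [
        state["cnv_fold"].subset_genes(sorted(state["cnvcor"])).subset_samples(tumors),
        state["met_fold"].subset_genes(sorted(state["metcor"])).subset_samples(tumors),
        state["exp_fold"].subset_genes(sorted(state["cnvcor"] | state["metcor"])).subset_samples(tumors),
    ]
    icl = {}
    for k in ks:
        icl[k] = cl.icluster_fit(stacks, k=k, lam=cfg.icluster_lambda,
                                 n_starts=cfg.n_restarts, seed=cfg.seed)
    state["icluster"] = icl
    primary_k = ks[0]
    state["labels"] = icl[primary_k].labels
    summary["icluster_k_run"] = ks
    summary["icluster_primary_k"] = primary_k
    summary["subtype_sizes"] = state["labels"].value_counts().sort_index().to_dict()
    for tag in nmf_labels:
        chi2, df, p, ari = cl.cluster_agreement(state["labels"], nmf_labels[tag])
        summary[f"icluster_vs_nmf_{tag}"] = {"chi2": chi2, "df": df, "p": p, "ari": ari}
    if outdir is not None:
        rows = []
        for method, lab in (("icluster", state["labels"]),
                            *((f"nmf_{t}", l) for t, l in nmf_labels.items())):
            rows.extend({"sample_id": s, "method": method, "label": int(v)}
                        for s, v in lab.items())
        _write_with_hash(pd.DataFrame(rows), outdir / "labels.tsv", cfg_hash,
                         sep="\t", index=False)
    return summary


def _aggressive_subtype(state) -> int:
    """The subtype with the highest mean cor-gene deregulation burden."""
    prof = state["profiles"]
    lab = state["labels"]
    burden = (prof[["cnvcor_up_freq", "cnvcor_down_freq",
                    "metcor_up_freq", "metcor_down_freq"]].sum(axis=1))
    return int(burden.groupby(lab.reindex(burden.index)).mean().idxmax())


def _stage_characterize(cfg, state, outdir, cfg_hash) -> dict:
    cohort = state["cohort"]
    labels = state["labels"]
    tumors = labels.index
    summary: dict = {}
    aggressive = _aggressive_subtype(state)
    summary["aggressive_subtype"] = aggressive

    surv = cohort.samples.set_index("sample_id").loc[tumors]
    for endpoint, (tcol, ecol) in (("OS", ("os_time_months", "os_event")),
                                   ("TTR", ("ttr_time_months", "ttr_event"))):
        if tcol not in surv or surv[tcol].isna().all():
            continue
        mask = surv[tcol].notna()
        _, chi2, df, p = ch.km_logrank(
            surv.loc[mask, tcol].astype(float),
            surv.loc[mask, ecol].astype(int),
            labels[mask.index[mask]])
        summary[f"logrank_{endpoint}"] = {"chi2": chi2, "df": df, "p": p}

    clin = {}
    for feat in CLINICAL_FEATURES:
        if feat not in surv.columns or surv[feat].isna().all():
            continue
        tab = pd.crosstab(surv[feat], labels)
        try:
            chi2, df, p = ch.chi2_contingency(tab.to_numpy())
            clin[feat] = {"chi2": chi2, "df": df, "p": p}
        except ValueError as exc:
            clin[feat] = {"error": str(exc)}
    summary["clinical_chi2"] = clin

    exp_t = state["exp_fold"].subset_samples(list(tumors))
    up, down, _ = ch.deg_between_subtypes(
        exp_t, labels, aggressive, fold_cut=cfg.deg_fold,
        use_perm_t=cfg.deg_use_perm_t, alpha=cfg.deg_alpha, B=cfg.deg_B,
        seed=cfg.seed)
    state["deg_up"], state["deg_down"] = up, down
    summary["n_deg_up"], summary["n_deg_down"] = len(up), len(down)

    if cohort.mutations is not None and cohort.mutations.shape[0] > 0:
        mut_tab = ch.differential_mutations(
            cohort.mutations, labels, min_total=cfg.mut_min_total,
            min_diff=cfg.mut_min_diff)
        state["mutations_table"] = mut_tab
        summary["n_recurrently_mutated"] = int(len(mut_tab))
        summary["differential_mutations"] = (
            sorted(mut_tab.index[mut_tab["differential"]]) if len(mut_tab) else [])

    if cfg.signatures_gmt:
        sigs = _io.read_gmt(cfg.signatures_gmt)
        scores, sig_summary = ch.score_signature_panel(
            exp_t, sigs, labels=labels, aggressive_group=aggressive)
        state["signature_scores"] = scores
        summary["signatures_scored"] = list(scores.columns)
        if outdir is not None:
            _write_with_hash(scores, outdir / "signature_scores.tsv", cfg_hash, sep="\t")

    if outdir is not None:
        _io.write_gmt({"DEG_UP": sorted(up), "DEG_DOWN": sorted(down)},
                      outdir / "deg.gmt")
        if "mutations_table" in state and len(state["mutations_table"]):
            _write_with_hash(state["mutations_table"],
                             outdir / "differential_mutations.tsv", cfg_hash, sep="\t")
    return summary


def integrated_aberration(
    fold_a: OmicsMatrix,
    fold_b: OmicsMatrix,
    partner: tuple[OmicsMatrix, OmicsMatrix] | None = None,
    cutoff: float = 0.2,
):
    """Aberration counting on two batch-integrated cohorts.

    Concatenates the shared-gene fold matrices of two cohorts for one
    platform pair (CNV in ``fold_a``/``fold_b``, MET in ``partner``),
    empirical-Bayes-adjusts the batch effect between cohorts, and counts
    raw aberrations on the integrated matrices.  Returns the per-sample
    profile table over both cohorts.
    """
    genes = fold_a.genes.intersection(fold_b.genes)
    a, b = fold_a.values.loc[genes], fold_b.values.loc[genes]
    merged = OmicsMatrix(platform=fold_a.platform,
                         values=pd.concat([a, b], axis=1),
                         scale=Scale.FOLD_DIFFERENCE)
    batches = ["cohort1"] * a.shape[1] + ["cohort2"] * b.shape[1]
    cnv_adj = pp.combat_adjust(merged, batches)
    if partner is None:
        raise ValueError("integrated_aberration needs the MET fold matrices of both cohorts")
    ma, mb = partner
    mgenes = ma.genes.intersection(mb.genes)
    merged_m = OmicsMatrix(platform=ma.platform,
                           values=pd.concat([ma.values.loc[mgenes],
                                             mb.values.loc[mgenes]], axis=1),
                           scale=Scale.FOLD_DIFFERENCE)
    met_adj = pp.combat_adjust(merged_m, batches)
    return ab.count_raw_aberrations(cnv_adj, met_adj, cutoff=cutoff)


def validate_on_cohort(cfg_train: PipelineConfig, report_train: RunReport,
                       cfg_second: PipelineConfig) -> tuple[RunReport, dict]:
    """Re-run the identical pipeline on a second cohort and compare.

    Thresholds are copied from the training configuration (inputs and seed
    come from ``cfg_second``); the comparison covers gene-set overlap
    (Jaccard), chromosome-arm context concordance and subtype-count
    agreement.
    """
    carried = dataclasses.asdict(cfg_train)
    for key in ("input_dir", "synthetic", "output_dir", "seed", "signatures_gmt"):
        carried.pop(key, None)
    cfg2 = dataclasses.replace(cfg_second, **carried)
    report2 = run_pipeline(cfg2)
    s1, s2 = report_train._state, report2._state
    comparison: dict = {}
    if report2.failed_stage is None and "cnvcor" in s1 and "cnvcor" in s2:
        shared = s1["corr"].index.intersection(s2["corr"].index)
        frac_shared = len(shared) / max(len(s1["corr"].index), 1)
        comparison["gene_overlap_fraction"] = frac_shared
        if frac_shared < 0.5:
            warnings.warn("gene namespaces overlap by less than 50%; proceeding")
        for name in ("cnvcor", "metcor"):
            a = {g for g in s1[name] if g in shared}
            b = {g for g in s2[name] if g in shared}
            union = a | b
            comparison[f"{name}_jaccard"] = len(a & b) / len(union) if union else float("nan")
        arms1 = pd.Series(s1["context_cnvcor"]["arm_proportion"])
        arms2 = pd.Series(s2["context_cnvcor"]["arm_proportion"])
        common = arms1.index.intersection(arms2.index)
        if len(common) > 2 and arms1[common].std() > 0 and arms2[common].std() > 0:
            comparison["arm_context_concordance"] = float(
                np.corrcoef(arms1[common], arms2[common])[0, 1])
        k1 = report_train.stages.get("clustering", {}).get("icluster_primary_k")
        k2 = report2.stages.get("clustering", {}).get("icluster_primary_k")
        comparison["subtype_count_agreement"] = bool(k1 == k2)
        comparison["k_train"], comparison["k_validation"] = k1, k2
    return report2, comparison
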