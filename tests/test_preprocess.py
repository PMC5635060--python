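"""Preprocessing operations against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from cnvmet.matrix import OmicsMatrix, Platform, ProbeAnnotation, Scale
from cnvmet.preprocess import (
    combat_adjust,
    collapse_probes_to_gene,
    filter_missing,
    knn_impute,
    quantile_normalize,
    segment_cnv,
    select_met_probes,
    tumor_fold_difference,
)


def _exp(values, columns=None):
    df = pd.DataFrame(values, columns=columns)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    if columns is None:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    return OmicsMatrix(Platform.EXP, df, Scale.LOG2_EXPRESSION)


class TestQuantileNormalize:
    def test_permuted_columns_are_fixed_point(self, rng):
        col = rng.normal(size=30)
        m = _exp(np.column_stack([col, rng.permutation(col)]))
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_closed_form_reference(self):
        m = _exp(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_matches_sort_average_oracle(self, rng):
        X = rng.normal(size=(50, 10))
        out = quantile_normalize(_exp(X)).values.to_numpy()
        ref = np.sort(X, axis=0).mean(axis=1)        # oracle reference
        oracle = np.empty_like(X)
        for j in range(X.shape[1]):
            oracle[:, j] = ref[np.argsort(np.argsort(X[:, j]))]
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        assert np.ptp(out.mean(axis=0)) < 1e-12

    def test_missing_entries_left_missing(self, rng):
        X = rng.normal(size=(40, 5))
        X[3, 2] = np.nan
        out = quantile_normalize(_exp(X)).values.to_numpy()
        assert np.isnan(out[3, 2])
        assert np.isnan(out).sum() == 1

    def test_single_sample_warns_unchanged(self, rng):
        m = _exp(rng.normal(size=(10, 1)))
        with pytest.warns(UserWarning, match="single-sample"):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)


class TestFoldDifference:
    def test_constants_become_zero(self):
        m = _exp(np.full((4, 5), 7.0))
        out = tumor_fold_difference(m, ["s3", "s4"])
        assert (out.values.to_numpy() == 0).all()
        assert out.scale is Scale.FOLD_DIFFERENCE

    def test_simple_arithmetic(self):
        m = _exp(np.array([[3.0, 1.0, 1.0]]), columns=["t", "n1", "n2"])
        out = tumor_fold_difference(m, ["n1", "n2"])
        np.testing.assert_allclose(out.values.to_numpy(), [[2.0, 0.0, 0.0]])

    def test_normal_columns_centered(self, default_cohort):
        c = default_cohort
        out = tumor_fold_difference(c.exp, c.normal_ids)
        centers = out.values[c.normal_ids].mean(axis=1).abs()
        assert (centers.dropna() < 1e-10).all()

    def test_idempotent_on_centered_matrix(self, rng):
        m = _exp(rng.normal(size=(20, 8)))
        normals = ["s5", "s6", "s7"]
        once = tumor_fold_difference(m, normals)
        twice = tumor_fold_difference(once, normals)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_no_normals_is_an_error(self, rng):
        with pytest.raises(ValueError, match="non-tumoral reference"):
            tumor_fold_difference(_exp(rng.normal(size=(5, 4))), ["absent"])


class TestFilterMissing:
    def test_thirty_percent_rule(self):
        row = np.ones((1, 10))
        row[0, :4] = np.nan  # 40% missing
        out = filter_missing(_exp(row), 0.3)
        assert out.shape[0] == 0

    def test_threshold_one_is_identity(self, rng):
        X = rng.normal(size=(15, 6))
        X[rng.random(X.shape) < 0.5] = np.nan
        X[:, 0] = 1.0  # keep every row observed at least once
        m = _exp(X)
        out = filter_missing(m, 1.0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_matches_row_scan_oracle(self, rng):
        X = rng.normal(size=(200, 10))
        X[rng.random(X.shape) < 0.2] = np.nan
        out = filter_missing(_exp(X), 0.5)
        keep = [i for i in range(200) if np.isnan(X[i]).mean() <= 0.5]  # oracle
        assert out.shape[0] == len(keep)
        assert list(out.genes) == [f"g{i}" for i in keep]


def _knn_oracle(X, k):
    """Quadratic brute-force kNN imputation with identical semantics."""
    X = X.copy()
    obs = ~np.isnan(X)
    out = X.copy()
    n = X.shape[0]
    for i in range(n):
        if obs[i].all():
            continue
        d = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            shared = obs[i] & obs[j]
            if shared.sum() == 0:
                continue
            d[j] = np.sqrt(((X[i, shared] - X[j, shared]) ** 2).mean())
        order = np.argsort(d, kind="stable")
        for c in np.where(~obs[i])[0]:
            donors = [j for j in order if np.isfinite(d[j]) and obs[j, c]][:k]
            if donors:
                out[i, c] = X[donors, c].mean()
            else:
                out[i, c] = np.nanmean(X[:, c])
    return out


class TestKnnImpute:
    def test_duplicate_row_supplies_value(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [9.0, 9.0, 9.0]])
        out = knn_impute(_exp(X), k=1).values.to_numpy()
        assert out[1, 2] == 3.0

    def test_complete_matrix_is_identity(self, rng):
        m = _exp(rng.normal(size=(12, 5)))
        out = knn_impute(m, k=3)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_matches_quadratic_oracle_exactly(self, rng):
        X = rng.normal(size=(100, 20))
        X[rng.random(X.shape) < 0.05] = np.nan
        X[np.isnan(X).all(axis=1), 0] = 0.0
        out = knn_impute(_exp(X), k=10).values.to_numpy()
        np.testing.assert_array_equal(out, _knn_oracle(X, 10))
        assert not np.isnan(out).any()

    def test_observed_entries_untouched(self, rng):
        X = rng.normal(size=(30, 8))
        mask = rng.random(X.shape) < 0.1
        Xm = X.copy()
        Xm[mask] = np.nan
        out = knn_impute(_exp(Xm), k=5).values.to_numpy()
        np.testing.assert_array_equal(out[~mask], X[~mask])

    def test_large_k_clipped_with_warning(self, rng):
        X = rng.normal(size=(5, 4))
        X[0, 0] = np.nan
        with pytest.warns(UserWarning, match="clipping"):
            knn_impute(_exp(X), k=50)


def _probe_fixture(rng, n=1000):
    chroms = np.array([f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"])
    tab = pd.DataFrame({
        "probe_id": [f"cg{i:05d}" for i in range(n)],
        "gene_symbol": [f"G{i % 400}" for i in range(n)],
        "chromosome": rng.choice(chroms, size=n),
        "arm": rng.choice(["p", "q"], size=n),
        "position": rng.integers(0, 1_000_000, size=n),
        "cpg_context": rng.choice(["island", "shore", "shelf", "open_sea"], size=n),
        "genic_context": rng.choice(
            ["promoter_tss2500", "utr5", "first_exon", "body", "intergenic"], size=n),
    })
    return ProbeAnnotation(tab)


class TestSelectMetProbes:
    def test_sex_chromosome_probes_always_excluded(self):
        ann = ProbeAnnotation(pd.DataFrame({
            "probe_id": ["a", "b"], "gene_symbol": ["G1", "G2"],
            "chromosome": ["chrX", "chr1"], "arm": ["p", "q"],
            "position": [1, 2], "cpg_context": ["island", "island"],
            "genic_context": ["promoter_tss2500", "promoter_tss2500"]}))
        assert select_met_probes(ann, "paper") == {"b"}
        assert select_met_probes(ann, "all") == {"b"}

    def test_open_sea_body_depends_on_universe(self):
        ann = ProbeAnnotation(pd.DataFrame({
            "probe_id": ["a"], "gene_symbol": ["G1"], "chromosome": ["chr2"],
            "arm": ["p"], "position": [1], "cpg_context": ["open_sea"],
            "genic_context": ["body"]}))
        assert select_met_probes(ann, "paper") == set()
        assert select_met_probes(ann, "all") == {"a"}

    def test_matches_set_comprehension_oracle(self, rng):
        ann = _probe_fixture(rng)
        got = select_met_probes(ann, "paper")
        t = ann.table
        oracle = {
            r.probe_id for r in t.itertuples()
            if r.chromosome not in ("chrX", "chrY")
            and (r.cpg_context in ("island", "shore", "shelf")
                 or r.genic_context in ("promoter_tss2500", "utr5", "first_exon"))
        }
        assert got == oracle

    def test_unknown_universe_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown probe universe"):
            select_met_probes(_probe_fixture(rng, 10), "everything")


class TestCollapseProbes:
    def _matrix(self, probes, rng):
        df = pd.DataFrame(rng.normal(size=(len(probes), 4)), index=probes,
                          columns=list("abcd"))
        return OmicsMatrix(Platform.MET, df, Scale.FOLD_DIFFERENCE)

    def test_single_probe_genes_are_identity(self, rng):
        m = self._matrix(["p1", "p2"], rng)
        corr = pd.Series({"p1": 0.3, "p2": -0.2})
        gene = pd.Series({"p1": "G1", "p2": "G2"})
        out = collapse_probes_to_gene(m, corr, gene, mode="min_corr")
        assert list(out.genes) == ["G1", "G2"]
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_min_corr_keeps_most_negative(self, rng):
        m = self._matrix(["p1", "p2"], rng)
        corr = pd.Series({"p1": -0.6, "p2": 0.1})
        gene = pd.Series({"p1": "G1", "p2": "G1"})
        out = collapse_probes_to_gene(m, corr, gene, mode="min_corr")
        np.testing.assert_array_equal(out.values.loc["G1"], m.values.loc["p1"])

    def test_mean_corr_matches_argmin_oracle(self, rng):
        probes = [f"p{i}" for i in range(9)]
        m = self._matrix(probes, rng)
        corr = pd.Series(rng.uniform(-1, 1, size=9), index=probes)
        gene = pd.Series([f"G{i // 3}" for i in range(9)], index=probes)
        out = collapse_probes_to_gene(m, corr, gene, mode="mean_corr")
        for g in ("G0", "G1", "G2"):
            members = gene.index[gene == g]
            rep = (corr[members] - corr[members].mean()).abs().idxmin()  # oracle
            np.testing.assert_array_equal(out.values.loc[g], m.values.loc[rep])


class TestSegmentCnv:
    def test_constant_signal_single_segment(self):
        x = np.full(30, 1.5)
        out = segment_cnv(x, np.arange(30), seed=0)
        np.testing.assert_allclose(out, x)

    def test_noiseless_step_two_exact_segments(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        out = segment_cnv(x, np.arange(40), seed=0)
        np.testing.assert_allclose(out, x)
        assert len(np.unique(out)) == 2

    def test_too_few_probes_single_segment(self):
        out = segment_cnv([1.0, 5.0], [0, 1], seed=0)
        np.testing.assert_allclose(out, [3.0, 3.0])

    def test_noisy_steps_near_exhaustive_oracle(self, rng):
        true = np.r_[np.zeros(25), np.full(25, 1.2), np.full(25, -0.8)]
        x = true + rng.normal(0, 0.15, size=75)
        out = segment_cnv(x, np.arange(75), n_perm=200, seed=1)
        bounds = np.where(np.diff(out) != 0)[0] + 1

        def best_split(lo, hi):  # exhaustive max-|t| oracle
            seg = x[lo:hi]
            best, bt = None, -1
            for cut in range(1, len(seg)):
                a, b = seg[:cut], seg[cut:]
                sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                             / (len(a) + len(b) - 2) * (1 / len(a) + 1 / len(b)))
                t = abs(a.mean() - b.mean()) / sp
                if t > bt:
                    best, bt = lo + cut, t
            return best

        first = best_split(0, 75)
        assert min(abs(b - first) for b in bounds) <= 2
        # every true changepoint is recovered to within 2 probes
        for true_b in (25, 50):
            assert min(abs(b - true_b) for b in bounds) <= 2


class TestCombat:
    def _m(self, X):
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(X.shape[0])],
                          columns=[f"s{i}" for i in range(X.shape[1])])
        return OmicsMatrix(Platform.EXP, df, Scale.FOLD_DIFFERENCE)

    def test_identical_batches_are_fixed_point(self, rng):
        half = rng.normal(size=(50, 20))
        X = np.hstack([half, half])
        out = combat_adjust(self._m(X), ["a"] * 20 + ["b"] * 20)
        assert np.max(np.abs(out.values.to_numpy() - X)) < 1e-6

    def test_location_shift_removed(self, rng):
        """A pure +2 batch shift (unit noise) is removed: the systematic
        component vanishes and per-gene residuals stay at the batch-mean
        sampling-noise scale (EB shrinkage leaves that noise untouched by
        design — matching the reference implementation's behavior)."""
        X = rng.normal(size=(200, 60))
        X[:, 30:] += 2.0
        out = combat_adjust(self._m(X), ["a"] * 30 + ["b"] * 30).values.to_numpy()
        signed = out[:, :30].mean(axis=1) - out[:, 30:].mean(axis=1)
        assert abs(signed.mean()) < 0.05           # systematic +2 shift gone
        # residuals bounded by batch-mean sampling noise (sd sqrt(2/30))
        assert np.abs(signed).max() < 4 * np.sqrt(2 / 30)

    def test_scale_effect_equalized(self, rng):
        X = rng.normal(size=(200, 60))
        X[:, 30:] *= 3.0
        out = combat_adjust(self._m(X), ["a"] * 30 + ["b"] * 30).values.to_numpy()
        v1 = out[:, :30].var(axis=1)
        v2 = out[:, 30:].var(axis=1)
        ratio = np.median(v2 / v1)
        assert 0.8 < ratio < 1.25

    def test_singleton_batch_rejected(self, rng):
        with pytest.raises(ValueError, match="single sample"):
            combat_adjust(self._m(rng.normal(size=(10, 4))), ["a", "a", "a", "b"])

    def test_agrees_with_scanpy_combat(self, rng):
        import anndata
        import scanpy as scanpy_mod

        X = rng.normal(size=(80, 40))
        X[:, 20:] += 1.5
        X[:, 20:] *= 1.8
        mine = combat_adjust(self._m(X), ["a"] * 20 + ["b"] * 20).values.to_numpy()
        ad = anndata.AnnData(X.T.astype(np.float64))
        ad.obs["batch"] = ["a"] * 20 + ["b"] * 20
        theirs = scanpy_mod.pp.combat(ad, key="batch", inplace=False).T
        # same model family; minor estimator (ddof/EB iteration) differences
        assert np.corrcoef(mine.ravel(), theirs.ravel())[0, 1] > 0.999
        assert np.max(np.abs(mine - theirs)) < 0.15 * X.std()
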