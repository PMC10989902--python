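"""Mantel machinery, LMG decomposition, driver models, db-RDA, forests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilassembly import (
    PairMatrix,
    dbrda_forward,
    dominant_taxa_select,
    lmg_importance,
    mantel,
    partial_mantel,
    rf_importance,
    taxon_driver_models,
)
from soilassembly.exceptions import (
    CollinearityError,
    DegenerateInputError,
    InvalidArgumentError,
)

from conftest import table_from_array


def sym(values, labels, kind="euclidean_driver"):
    values = np.asarray(values, dtype=float)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return PairMatrix(labels, values, kind)


def random_pair(n, rng, kind="euclidean_driver"):
    return sym(rng.uniform(0, 1, size=(n, n)), [f"s{i}" for i in range(n)], kind)


def gradient_pair(u, noise, rng, labels):
    d = np.abs(u[:, None] - u[None, :]) + noise * rng.uniform(0, 1, (len(u), len(u)))
    return sym(d, labels)


class TestMantel:
    def test_identity_gives_r_one_minimal_p(self, rng):
        A = random_pair(10, rng)
        res = mantel(A, A, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_zero_variance_rejected(self):
        labels = list("abcd")
        A = sym(np.ones((4, 4)), labels)
        B = random_pair(4, np.random.default_rng(0))
        B = PairMatrix(labels, B.values, B.kind)
        with pytest.raises(DegenerateInputError):
            mantel(A, B, n_perm=99)

    def test_type_one_error_calibrated(self):
        # independent random matrices: rejection rate at alpha=0.05 must sit
        # in [0.02, 0.09] over 200 replicates
        rejections = 0
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(5000 + i)
            A = random_pair(15, rng)
            B = random_pair(15, rng)
            if mantel(A, B, n_perm=199, seed=i).p <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    def test_power_at_planted_effect(self):
        hits = 0
        reps = 20
        for i in range(reps):
            rng = np.random.default_rng(800 + i)
            u = rng.uniform(0, 1, 15)
            labels = [f"s{j}" for j in range(15)]
            A = gradient_pair(u, 0.4, rng, labels)
            B = gradient_pair(u, 0.4, rng, labels)
            if mantel(A, B, n_perm=199, seed=i).p <= 0.05:
                hits += 1
        assert hits / reps >= 0.8

    def test_spearman_variant_monotone_invariant(self, rng):
        A = random_pair(8, rng)
        B = PairMatrix(A.labels, A.values**3, A.kind)
        res = mantel(A, B, n_perm=99, seed=0, method="spearman")
        assert res.r == pytest.approx(1.0)


class TestPartialMantel:
    def test_controlling_for_unrelated_matrix_keeps_r(self, rng):
        labels = [f"s{i}" for i in range(20)]
        u = rng.uniform(0, 1, 20)
        A = gradient_pair(u, 0.3, rng, labels)
        B = gradient_pair(u, 0.3, rng, labels)
        C = random_pair(20, rng)
        C = PairMatrix(labels, C.values, C.kind)
        plain = mantel(A, B, n_perm=99, seed=0).r
        partial = partial_mantel(A, B, C, n_perm=99, seed=0).r
        assert abs(plain - partial) < 0.1

    def test_controlling_for_itself_removes_correlation(self, rng):
        labels = [f"s{i}" for i in range(12)]
        u = rng.uniform(0, 1, 12)
        A = gradient_pair(u, 0.3, rng, labels)
        B = gradient_pair(u, 0.3, rng, labels)
        res = partial_mantel(A, B, B, n_perm=99, seed=0)
        assert abs(res.r) < 0.15

    def test_identical_matrices_with_random_control(self, rng):
        A = random_pair(10, rng)
        C = PairMatrix(A.labels, random_pair(10, rng).values, "euclidean_driver")
        res = partial_mantel(A, A, C, n_perm=199, seed=0)
        assert res.r > 0.99
        assert res.p == pytest.approx(1 / 200)


class TestLMG:
    def test_orthogonal_design_shares_equal_marginal_r2(self, rng):
        n, p = 60, 3
        raw = rng.standard_normal((n, p))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = pd.DataFrame(q, columns=["x1", "x2", "x3"])
        y = 3.0 * q[:, 0] + 2.0 * q[:, 1] + 0.5 * rng.standard_normal(n)
        res = lmg_importance(X, y)
        for j, col in enumerate(X.columns):
            marginal = np.corrcoef(q[:, j], y)[0, 1] ** 2
            assert res.shares[col] == pytest.approx(marginal, abs=1e-9)
        assert res.shares.sum() == pytest.approx(res.total_r2, abs=1e-9)

    def test_single_predictor_share_is_r2(self, rng):
        x = rng.standard_normal(50)
        y = 2 * x + rng.standard_normal(50)
        res = lmg_importance(pd.DataFrame({"x": x}), y)
        assert res.shares["x"] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_duplicated_columns_raise_collinearity(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
        with pytest.raises(CollinearityError):
            lmg_importance(X, rng.standard_normal(30))

    def test_shares_sum_to_r2_and_order_invariant(self, rng):
        n, p = 50, 5
        X = pd.DataFrame(
            rng.standard_normal((n, p)) @ np.linalg.cholesky(
                0.5 * np.eye(p) + 0.5 * np.ones((p, p))
            ).T,
            columns=list("abcde"),
        )
        y = X["a"] * 1.5 + X["c"] - X["e"] + rng.standard_normal(n)
        res = lmg_importance(X, y)
        assert (res.shares >= -1e-12).all()
        assert res.shares.sum() == pytest.approx(res.total_r2, abs=1e-9)
        shuffled = lmg_importance(X[list("edcba")], y)
        for col in "abcde":
            assert shuffled.shares[col] == pytest.approx(res.shares[col], abs=1e-12)

    def test_sampling_estimator_close_to_exact(self, rng):
        n, p = 60, 4
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=list("abcd"))
        y = X["a"] + 0.5 * X["b"] + rng.standard_normal(n)
        exact = lmg_importance(X, y, method="exact")
        sampled = lmg_importance(X, y, method="sampling", n_orderings=3000, seed=0)
        assert np.allclose(sampled.shares, exact.shares, atol=0.02)

    def test_too_many_predictors_for_exact(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 13)))
        with pytest.raises(InvalidArgumentError):
            lmg_importance(X, rng.standard_normal(40))


class TestDominantTaxa:
    def test_prevalence_strictly_above_half(self):
        counts = np.zeros((100, 3), dtype=int)
        counts[:49, 0] = 1000  # abundant but in 49% of samples
        counts[:60, 1] = 1000
        counts[:, 2] = 1
        t = table_from_array(counts)
        dom = dominant_taxa_select(t, prevalence_min=0.5, abundance_top=0.67)
        assert "T1" not in dom
        assert "T2" in dom

    def test_loose_thresholds_keep_all_taxa(self, rng):
        t = table_from_array(rng.integers(1, 10, size=(20, 6)))
        assert dominant_taxa_select(t, prevalence_min=0.0, abundance_top=1.0) == t.taxon_ids

    def test_invariant_to_sample_order(self, rng):
        counts = rng.integers(0, 30, size=(30, 10))
        counts[:, 0] += 1
        t = table_from_array(counts)
        shuffled = table_from_array(
            counts[::-1], samples=[f"S{i}" for i in range(30)][::-1]
        )
        assert set(dominant_taxa_select(t)) == set(dominant_taxa_select(shuffled))


class TestTaxonDriverModels:
    def _setup(self, rng, n=60):
        drivers = pd.DataFrame(
            {
                "pH": rng.standard_normal(n),
                "AI": rng.standard_normal(n),
                "AD": rng.standard_normal(n),
                "Neg": rng.standard_normal(n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        return drivers

    def test_planted_single_driver_identified(self, rng):
        n = 60
        drivers = self._setup(rng, n)
        signal = 1.0 + 0.2 * drivers["AD"] + 0.005 * rng.standard_normal(n)
        counts = np.column_stack([
            np.round(2000 * np.exp(signal)).astype(int),
            rng.integers(500, 1500, size=(n, 3)),
        ])
        t = table_from_array(counts, samples=list(drivers.index))
        res = taxon_driver_models(
            t, drivers, ["T1"], abiotic=["pH", "AI"], biotic=["AD", "Neg"]
        )
        assert res["per_taxon"].loc["T1", "best_predictor"] == "AD"

    def test_r2_bio_never_below_r2_nonbio(self, rng):
        n = 50
        drivers = self._setup(rng, n)
        counts = rng.integers(1, 100, size=(n, 6))
        t = table_from_array(counts, samples=list(drivers.index))
        res = taxon_driver_models(
            t, drivers, t.taxon_ids, abiotic=["pH", "AI"], biotic=["AD", "Neg"]
        )
        assert (
            res["per_taxon"]["r2_bio"] >= res["per_taxon"]["r2_nonbio"] - 1e-12
        ).all()

    def test_null_response_rarely_significant(self):
        insignificant = 0
        for i in range(5):
            rng = np.random.default_rng(900 + i)
            n = 50
            drivers = self._setup(rng, n)
            counts = rng.integers(1, 100, size=(n, 8))
            t = table_from_array(counts, samples=list(drivers.index))
            res = taxon_driver_models(
                t, drivers, t.taxon_ids, abiotic=["pH", "AI"], biotic=["AD", "Neg"]
            )
            if not (res["wilcoxon_p"] <= 0.05):
                insignificant += 1
        assert insignificant >= 3


class TestDbRDAForward:
    def test_driver_aligned_with_first_axis_selected_first(self, rng):
        # build a Bray-Curtis matrix from a strong one-dimensional gradient
        n = 30
        u = np.sort(rng.uniform(0, 1, n))
        counts = np.zeros((n, 12), dtype=int)
        centers = np.linspace(0, 1, 12)
        for i in range(n):
            kernel = np.exp(-((u[i] - centers) ** 2) / 0.02)
            counts[i] = np.round(500 * kernel / kernel.sum()).astype(int) + 1
        t = table_from_array(counts)
        from soilassembly import bray_curtis

        bc = bray_curtis(t)
        drivers = pd.DataFrame(
            {
                "grad": u + 0.01 * rng.standard_normal(n),
                "noise1": rng.standard_normal(n),
                "noise2": rng.standard_normal(n),
            },
            index=bc.labels,
        )
        sel = dbrda_forward(bc, drivers, alpha=0.05, n_perm=99, seed=0)
        assert len(sel) >= 1
        assert sel.iloc[0]["variable"] == "grad"
        assert (sel["cumulative_r2"].diff().dropna() >= -1e-12).all()
        assert sel["cumulative_r2"].iloc[-1] <= 1 + 1e-9

    def test_pure_noise_drivers_rarely_admitted(self, rng):
        clean = 0
        reps = 20
        for i in range(reps):
            r = np.random.default_rng(300 + i)
            n = 25
            counts = r.integers(1, 60, size=(n, 15))
            t = table_from_array(counts)
            from soilassembly import bray_curtis

            bc = bray_curtis(t)
            drivers = pd.DataFrame(
                r.standard_normal((n, 5)),
                columns=list("abcde"),
                index=bc.labels,
            )
            sel = dbrda_forward(bc, drivers, alpha=0.05, n_perm=99, seed=i)
            if len(sel) <= 1:
                clean += 1
        assert clean / reps >= 0.9


class TestRFImportance:
    def _data(self, rng, n=40):
        X = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["x1", "x2", "x3"]
        )
        y = 2.0 * X["x1"].to_numpy() + 0.3 * rng.standard_normal(n)
        return X, y

    def test_planted_driver_top_ranked_and_significant(self, rng):
        X, y = self._data(rng)
        res = rf_importance(X, y, n_trees=100, n_perm=29, seed=1)
        assert res.index[0] == "x1"
        assert res.loc["x1", "p"] <= 0.05

    def test_deterministic_given_seed(self, rng):
        X, y = self._data(rng)
        a = rf_importance(X, y, n_trees=50, n_perm=9, seed=3)
        b = rf_importance(X, y, n_trees=50, n_perm=9, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_constant_response_rejected(self, rng):
        X, _ = self._data(rng)
        with pytest.raises(DegenerateInputError):
            rf_importance(X, np.ones(len(X)), n_trees=10, n_perm=9, seed=0)


class TestMantelCrossCheck:
    def test_statistic_matches_scikit_bio(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        n = 12
        labels = [f"s{i}" for i in range(n)]
        A = random_pair(n, rng)
        B = random_pair(n, rng)
        ours = mantel(A, B, n_perm=99, seed=0).r
        theirs, _, _ = skbio_mantel(
            DistanceMatrix(A.values, ids=labels),
            DistanceMatrix(B.values, ids=labels),
            method="pearson", permutations=0,
        )
        assert ours == pytest.approx(float(theirs), abs=1e-12)


class TestFDRSwitch:
    def test_bh_adjustment_added_and_no_smaller_than_raw(self, rng):
        n = 50
        drivers = pd.DataFrame(
            {"pH": rng.standard_normal(n), "AD": rng.standard_normal(n)},
            index=[f"s{i}" for i in range(n)],
        )
        counts = rng.integers(1, 100, size=(n, 6))
        t = table_from_array(counts, samples=list(drivers.index))
        res = taxon_driver_models(
            t, drivers, t.taxon_ids, abiotic=["pH"], biotic=["AD"], fdr_bh=True
        )
        pt = res["per_taxon"]
        assert "model_p_adj" in pt.columns
        assert (pt["model_p_adj"] >= pt["model_p"] - 1e-12).all()
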