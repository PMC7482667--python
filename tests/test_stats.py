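"""Statistics chain: oracles, invariants and degenerate-input behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from lfqnet import stats as S
from lfqnet.io import AbundanceMatrix


def brute_force_bh(p):
    """Step-up BH executed literally: q_(i) = min over j>=i of p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def linear_matrix(values, samples=None, counts=None):
    names = [f"P{i:04d}" for i in range(len(values))]
    samples = samples or [f"S{i:02d}" for i in range(len(values[0]))]
    return AbundanceMatrix(
        pd.DataFrame(values, index=names, columns=samples, dtype=float),
        scale="linear",
        unique_peptide_counts=None
        if counts is None
        else pd.Series(counts, index=names),
    )


class TestPeptideFilter:
    def test_threshold(self):
        mat = linear_matrix([[1, 2], [3, 4], [5, 6]], counts=[1, 2, 5])
        kept = S.filter_by_unique_peptides(mat, 2)
        assert kept.protein_ids == ["P0001", "P0002"]

    def test_min_zero_is_identity(self):
        mat = linear_matrix([[1, 2], [3, 4]], counts=[1, 2])
        assert S.filter_by_unique_peptides(mat, 0).protein_ids == mat.protein_ids

    def test_counts_absent_raises(self):
        mat = linear_matrix([[1, 2]])
        with pytest.raises(ValueError, match="skip"):
            S.filter_by_unique_peptides(mat)

    def test_matches_brute_force_on_random_counts(self, rng):
        counts = rng.integers(0, 6, size=100)
        mat = linear_matrix(rng.uniform(1, 10, size=(100, 3)), counts=counts)
        kept = S.filter_by_unique_peptides(mat, 2)
        expected = [f"P{i:04d}" for i in range(100) if counts[i] >= 2]
        assert kept.protein_ids == expected


class TestNormalization:
    def test_equal_totals_unchanged(self):
        mat = linear_matrix([[1.0, 2.0], [3.0, 2.0]])
        out = S.normalize_total_intensity(mat)
        assert np.allclose(out.values, mat.values)

    def test_doubled_sample_rescaled(self, rng):
        base = rng.uniform(1, 10, size=(20, 4))
        doubled = base.copy()
        doubled[:, 0] *= 2
        out = S.normalize_total_intensity(linear_matrix(doubled))
        sums = out.values.sum(axis=0)
        assert np.allclose(sums, sums.iloc[0])

    def test_conserves_grand_total(self, rng):
        values = rng.uniform(1, 10, size=(15, 6))
        values[values < 2] = np.nan
        mat = linear_matrix(np.where(np.isnan(values), np.nan, values + 1))
        out = S.normalize_total_intensity(mat)
        assert np.nansum(out.values.to_numpy()) == pytest.approx(
            np.nansum(mat.values.to_numpy())
        )

    def test_single_sample_unchanged(self):
        mat = linear_matrix([[5.0], [7.0]])
        assert np.allclose(S.normalize_total_intensity(mat).values, mat.values)

    def test_zero_total_sample_named(self):
        values = pd.DataFrame(
            [[np.nan, 1.0]], index=["A"], columns=["bad", "good"], dtype=float
        )
        mat = AbundanceMatrix(values, scale="linear")
        with pytest.raises(ValueError, match="bad"):
            S.normalize_total_intensity(mat)


class TestImputation:
    def _matrix_with_missing(self, rng, n_missing=40):
        values = rng.normal(28, 1, size=(60, 8))
        mask = rng.uniform(size=values.shape) < n_missing / values.size
        values[mask] = np.nan
        names = [f"P{i:04d}" for i in range(60)]
        return AbundanceMatrix(
            pd.DataFrame(values, index=names, columns=[f"S{i}" for i in range(8)]),
            scale="log2",
        )

    def test_no_missing_is_identity(self, rng):
        mat = AbundanceMatrix(
            pd.DataFrame(rng.normal(28, 1, size=(5, 4))).rename(index=str, columns=str),
            scale="log2",
        )
        out = S.impute_missing(mat, seed=1)
        assert np.array_equal(out.values.to_numpy(), mat.values.to_numpy())

    def test_deterministic_under_seed(self, rng):
        mat = self._matrix_with_missing(rng)
        a = S.impute_missing(mat, seed=7).values.to_numpy()
        b = S.impute_missing(mat, seed=7).values.to_numpy()
        assert np.array_equal(a, b)
        c = S.impute_missing(mat, seed=8).values.to_numpy()
        assert not np.array_equal(a, c)

    def test_downshifted_distribution(self):
        """Monte-Carlo: imputed draws center on sample mean - 1.8 SD."""
        rng = np.random.default_rng(0)
        n = 20000
        values = rng.normal(28, 1, size=(n, 2))
        missing = np.zeros(n, dtype=bool)
        missing[::2] = True
        values[missing, 0] = np.nan
        mat = AbundanceMatrix(
            pd.DataFrame(values, index=[f"P{i}" for i in range(n)], columns=["S1", "S2"]),
            scale="log2",
        )
        observed = mat.values["S1"].dropna()
        mu, sd = observed.mean(), observed.std(ddof=1)
        imputed = S.impute_missing(mat, seed=3).values.loc[missing, "S1"]
        se = 0.3 * sd / np.sqrt(len(imputed))
        assert abs(imputed.mean() - (mu - 1.8 * sd)) < 3 * se
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.05)

    def test_sample_with_single_observation_raises(self):
        values = pd.DataFrame(
            {"S1": [1.0, np.nan, np.nan], "S2": [1.0, 2.0, 3.0]},
            index=["A", "B", "C"],
        )
        with pytest.raises(ValueError, match="S1"):
            S.impute_missing(AbundanceMatrix(values, scale="log2"), seed=0)


class TestBH:
    def test_single_p(self):
        assert S.bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_executed_step_up(self):
        assert S.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            S.bh_adjust([0.5, 1.5])

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 60))
        assert np.allclose(S.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(S.bh_adjust(p)[perm], S.bh_adjust(p[perm]))

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=50)
        q = S.bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


def _two_group(rng, n_prot=40, effect=0.0):
    samples = [f"MGI_{i:02d}" for i in range(6)] + [f"MGII_{i:02d}" for i in range(6)]
    values = rng.normal(28, 0.5, size=(n_prot, 12))
    values[:, 6:] += effect
    mat = AbundanceMatrix(
        pd.DataFrame(values, index=[f"P{i:04d}" for i in range(n_prot)], columns=samples),
        scale="log2",
    )
    meta = pd.Series(["MGI"] * 6 + ["MGII"] * 6, index=samples)
    return mat, meta


class TestAnova:
    def test_two_groups_f_equals_pooled_t_squared(self, rng):
        mat, meta = _two_group(rng)
        res = S.anova_screen(mat, meta)
        a = mat.values.iloc[:, :6].to_numpy()
        b = mat.values.iloc[:, 6:].to_numpy()
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(res["statistic"], t**2, atol=1e-10)
        assert np.allclose(res["p_value"], p, atol=1e-12)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(202)
        samples = [f"G{g}_{i}" for g in "ABC" for i in range(10)]
        values = rng.normal(28, 0.5, size=(2000, 30))
        mat = AbundanceMatrix(
            pd.DataFrame(values, index=[f"P{i:04d}" for i in range(2000)], columns=samples),
            scale="log2",
        )
        meta = pd.Series([s[1] for s in samples], index=samples)
        res = S.anova_screen(mat, meta, alpha=0.05)
        assert abs(res["significant"].mean() - 0.05) <= 0.01

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(7)
        mat, meta = _two_group(rng, n_prot=10, effect=0.0)
        values = mat.values.copy()
        values.iloc[0, 6:] += 2.0
        mat2 = AbundanceMatrix(values, scale="log2")
        # n=6/group; with n=10/group the detection is even stronger
        res = S.anova_screen(mat2, meta)
        assert res["p_value"].iloc[0] < 0.001

    def test_degenerate_zero_variance_flagged(self):
        values = pd.DataFrame(
            np.ones((3, 4)), index=list("ABC"), columns=["G1_a", "G1_b", "G2_a", "G2_b"]
        )
        meta = pd.Series(["G1", "G1", "G2", "G2"], index=values.columns)
        res = S.anova_screen(AbundanceMatrix(values, scale="log2"), meta)
        assert (res["p_value"] == 1.0).all()
        assert res["degenerate"].all()


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0]], index=["A"], columns=["a1", "a2", "b1", "b2"]
        )
        meta = pd.Series(["A", "A", "B", "B"], index=values.columns)
        res = S.ttest_pair(AbundanceMatrix(values, scale="log2"), meta, "A", "B")
        assert res["statistic"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_matches_welch_formula(self, rng):
        mat, meta = _two_group(rng)
        res = S.ttest_pair(mat, meta, "MGI", "MGII")
        a = mat.values.iloc[:, :6].to_numpy()
        b = mat.values.iloc[:, 6:].to_numpy()
        va, vb = a.var(axis=1, ddof=1) / 6, b.var(axis=1, ddof=1) / 6
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 5 + vb**2 / 5)
        p = 2 * sps.t.sf(np.abs(t), df)
        assert np.allclose(res["statistic"], t, atol=1e-12)
        assert np.allclose(res["p_value"], p, atol=1e-12)

    def test_label_swap_negates_fc(self, rng):
        mat, meta = _two_group(rng, effect=0.7)
        ab = S.ttest_pair(mat, meta, "MGI", "MGII")
        ba = S.ttest_pair(mat, meta, "MGII", "MGI")
        assert np.allclose(ab["log2_fc"], -ba["log2_fc"])
        assert np.allclose(ab["p_value"], ba["p_value"])

    def test_unknown_group_raises(self, rng):
        mat, meta = _two_group(rng)
        with pytest.raises(ValueError, match="MGIII"):
            S.ttest_pair(mat, meta, "MGI", "MGIII")


class TestVolcano:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.2, 0.01, "UP"),
            (-1.2, 0.01, "DOWN"),
            (3.0, 0.5, "NS"),
            (1.19, 0.01, "NS"),
            (0.0, 1e-9, "NS"),
        ],
    )
    def test_classification_rule(self, fc, p, expected):
        de = pd.DataFrame({"protein": ["x"], "log2_fc": [fc], "p_value": [p]})
        assert S.classify_volcano(de)["volcano_class"].iloc[0] == expected


class TestClusteringPCA:
    def test_planted_cluster_recovery(self, rng):
        values = rng.normal(28, 0.1, size=(20, 10))
        values[:, 5:] += 10.0
        mat = AbundanceMatrix(
            pd.DataFrame(values, index=[f"P{i}" for i in range(20)],
                         columns=[f"S{i}" for i in range(10)]),
            scale="log2",
        )
        labels = S.ward_cluster(mat, 2)
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_singleton_clusters(self, small_log2_matrix):
        mat, _ = small_log2_matrix
        assert S.ward_cluster(mat, len(mat.sample_ids)).nunique() == len(mat.sample_ids)

    def test_k_too_large_raises(self, small_log2_matrix):
        mat, _ = small_log2_matrix
        with pytest.raises(ValueError, match="k"):
            S.ward_cluster(mat, 99)

    def test_rank_one_data_pc1(self, rng):
        direction = rng.normal(size=6)
        coeffs = rng.normal(size=12)
        values = 28 + np.outer(direction, coeffs)
        mat = AbundanceMatrix(
            pd.DataFrame(values, index=[f"P{i}" for i in range(6)],
                         columns=[f"S{i}" for i in range(12)]),
            scale="log2",
        )
        _, evr = S.pca_scores(mat, 2)
        assert evr[0] > 0.999


class TestDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20, 20, 20, 20), 1.0),
            ((21, 20, 20, 20), 0.5),  # ddCt = +1
            ((18, 20, 20, 20), 4.0),  # ddCt = -2
        ],
    )
    def test_closed_form(self, cts, expected):
        assert S.ddct_fold_change(*cts) == pytest.approx(expected)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            S.ddct_fold_change(np.nan, 20, 20, 20)


class TestPipeline:
    def test_both_processing_orders_run(self, rng):
        from lfqnet.synthetic import make_truth, simulate_abundance_matrix

        truth = make_truth(n_proteins=12, n_edges=6, seed=5)
        mat, meta = simulate_abundance_matrix(truth)
        for order in (True, False):
            out = S.run_stats_pipeline(
                mat, meta, contrast=("MGI", "MGII"), seed=1,
                normalize_before_impute=order,
            )
            assert out["matrix"].is_complete()
            assert {"anova", "ttest", "volcano", "clusters", "pca"} <= set(out)
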