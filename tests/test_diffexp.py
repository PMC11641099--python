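"""Filtering, normalization, PCA, the NB Wald test and BH correction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circrpl.diffexp import (
    DesignError,
    bh_adjust,
    cross_tissue_overlap,
    filter_expressed,
    nb_wald_de,
    normalize,
    run_pca,
    shared_de,
)
from circrpl.io_formats import CountMatrix


def make_cm(counts, conditions=None, libs=None, project="P1"):
    counts = np.asarray(counts)
    n = counts.shape[1]
    samples = [f"s{i + 1}" for i in range(n)]
    if conditions is None:
        conditions = ["control"] * (n // 2) + ["RPL"] * (n - n // 2)
    if libs is None:
        libs = [10_000_000] * n
    sheet = pd.DataFrame(
        {"project_id": [project] * n, "condition": conditions, "library_size": libs},
        index=pd.Index(samples, name="sample_id"),
    )
    df = pd.DataFrame(
        counts,
        index=[f"chr1:{100 + i * 10}|{1000 + i * 10}:+" for i in range(counts.shape[0])],
        columns=samples,
    )
    return CountMatrix(df, sheet)


class TestFilter:
    def test_half_the_samples_rule(self):
        cm = make_cm([[5, 5, 5, 0, 0, 0], [4, 4, 4, 4, 4, 4]])
        kept = filter_expressed(cm)
        assert list(kept.counts.index) == [cm.counts.index[0]]

    def test_exhaustive_pass_count_grid(self):
        # for every n and every number of passing samples, the rule is
        # pass iff npass >= ceil(n/2)
        for n in range(1, 13):
            for npass in range(n + 1):
                row = [5] * npass + [0] * (n - npass)
                cm = make_cm([row], conditions=["control"] * n)
                kept = filter_expressed(cm)
                expected = npass >= math.ceil(n / 2)
                assert (len(kept.counts) == 1) == expected, (n, npass)

    def test_monotone_in_min_count(self):
        rng = np.random.default_rng(0)
        cm = make_cm(rng.integers(0, 12, size=(40, 8)))
        prev = set(filter_expressed(cm, min_count=1).counts.index)
        for mc in range(2, 10):
            cur = set(filter_expressed(cm, min_count=mc).counts.index)
            assert cur <= prev
            prev = cur

    def test_empty_matrix_ok(self):
        cm = make_cm(np.zeros((0, 4), dtype=int))
        assert filter_expressed(cm).counts.empty


class TestNormalize:
    def test_library_size_scaling(self):
        cm = make_cm([[10, 10]], conditions=["control", "RPL"], libs=[10**7, 10**7])
        norm, s = normalize(cm)
        assert norm.iloc[0, 0] == pytest.approx(1e-6)
        assert list(s) == [10**7, 10**7]

    def test_base_mean_hand_arithmetic(self):
        cm = make_cm([[5, 0, 7]], conditions=["control"] * 3, libs=[10**7] * 3)
        norm, _ = normalize(cm)
        assert norm.iloc[0].mean() == pytest.approx(4.0e-7)

    def test_equal_libraries_rank_preserving(self):
        rng = np.random.default_rng(1)
        cm = make_cm(rng.integers(0, 100, size=(30, 4)))
        norm, _ = normalize(cm)
        for j in range(4):
            assert (
                norm.iloc[:, j].rank().values == cm.counts.iloc[:, j].rank().values
            ).all()


class TestPCA:
    def test_identical_samples_identical_scores(self):
        col = np.arange(1, 21)
        cm = make_cm(np.column_stack([col, col, col * 3, col * 3]))
        scores, _ = run_pca(cm, n_components=2)
        assert np.allclose(scores.iloc[0], scores.iloc[1])
        assert np.allclose(scores.iloc[2], scores.iloc[3])

    def test_variance_explained_ordering(self):
        rng = np.random.default_rng(2)
        cm = make_cm(rng.integers(0, 50, size=(20, 6)))
        _, ve = run_pca(cm, n_components=3)
        assert all(ve[i] >= ve[i + 1] for i in range(len(ve) - 1))
        assert ve.sum() <= 1.0 + 1e-12

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 60, size=(20, 6))
        cm = make_cm(counts)
        scores, ve = run_pca(cm, n_components=2)
        x = np.log2(counts.T / 1e7 + 1e-8)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (x.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for k in range(2):
            proj = xc @ v[:, k]
            got = scores.iloc[:, k].to_numpy()
            assert np.allclose(np.abs(proj), np.abs(got), atol=1e-8)
        assert np.allclose(ve[:2], w[:2] / w.sum(), atol=1e-12)

    def test_too_few_samples_raises(self):
        cm = make_cm([[1, 2]], conditions=["control", "RPL"])
        with pytest.raises(DesignError):
            run_pca(cm, n_components=3)


class TestBH:
    def test_single_pvalue(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (bh_adjust([1.0] * 5) == 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_padj_at_least_pvalue(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-15).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=120))
    def test_matches_independent_step_up(self, pvals):
        """Independent oracle: explicit min-over-larger-ranks definition."""
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            expected[order[i]] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
            )
        assert np.allclose(bh_adjust(p), expected)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 300))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs)


class TestNBWald:
    def test_identical_groups_null(self):
        row = [20, 22, 18, 21, 20, 22, 18, 21]
        cm = make_cm([row])
        res = nb_wald_de(cm)
        assert abs(res["log2FoldChange"].iloc[0]) < 0.05
        assert res["pvalue"].iloc[0] > 0.5

    def test_all_zero_rows_kept_with_p_one(self):
        cm = make_cm([[0] * 8, [10, 12, 9, 11, 30, 33, 29, 31]])
        res = nb_wald_de(cm)
        assert res["pvalue"].iloc[0] == 1.0
        assert len(res) == 2

    def test_zero_group_flagged_finite_lfc(self):
        cm = make_cm([[0, 0, 0, 0, 40, 45, 38, 42]])
        res = nb_wald_de(cm)
        assert res["zero_group"].iloc[0]
        assert np.isfinite(res["log2FoldChange"].iloc[0])
        assert res["log2FoldChange"].iloc[0] > 2

    def test_design_errors(self):
        cm = make_cm([[1, 2, 3]], conditions=["control", "control", "RPL"])
        with pytest.raises(DesignError):
            nb_wald_de(cm)
        cm2 = make_cm(np.full((1, 4), 1.5))
        with pytest.raises(ValueError):
            nb_wald_de(cm2)

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(30, size=(25, 8))
        cond = ["control"] * 4 + ["RPL"] * 4
        res1 = nb_wald_de(make_cm(counts, conditions=cond))
        res2 = nb_wald_de(make_cm(counts, conditions=cond[4:] + cond[:4]))
        assert np.allclose(
            res1["log2FoldChange"].values, -res2["log2FoldChange"].values, atol=1e-6
        )
        assert np.allclose(res1["pvalue"].values, res2["pvalue"].values, atol=1e-6)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(25, size=(20, 8))
        cm = make_cm(counts)
        res1 = nb_wald_de(cm)
        perm = rng.permutation(8)
        cm2 = CountMatrix(cm.counts.iloc[:, perm], cm.samples.iloc[perm])
        res2 = nb_wald_de(cm2)
        assert np.allclose(
            res1["log2FoldChange"].values, res2["log2FoldChange"].values, atol=1e-9
        )
        assert np.allclose(res1["padj"].values, res2["padj"].values, atol=1e-9)

    def test_significance_thresholds_are_strict(self):
        rng = np.random.default_rng(8)
        counts = np.vstack(
            [
                rng.poisson([20] * 4 + [90] * 4),  # strong effect
                rng.poisson(25, size=8),  # null
            ]
        )
        res = nb_wald_de(make_cm(counts))
        sig = res["significant"]
        for _, r in res.iterrows():
            assert r["significant"] == (
                r["padj"] < 0.05 and abs(r["log2FoldChange"]) > 0.58
            )
        assert sig.iloc[0]


class TestOverlap:
    def test_disjoint_two_sets(self):
        df = cross_tissue_overlap({"A": {1, 2, 3}, "B": {4, 5}})
        by_pattern = {(r["A"], r["B"]): r["count"] for _, r in df.iterrows()}
        assert by_pattern == {(1, 0): 3, (0, 1): 2}

    def test_four_identical_sets_center_only(self):
        s = set(range(7))
        df = cross_tissue_overlap({c: s for c in "ABCD"})
        assert len(df) == 1
        assert df["count"].iloc[0] == 7
        assert (df[["A", "B", "C", "D"]].iloc[0] == 1).all()

    def test_matches_brute_force_pattern_tally(self):
        rng = np.random.default_rng(9)
        universe = list(range(200))
        sets = {
            name: set(rng.choice(universe, size=rng.integers(10, 80), replace=False))
            for name in "ABCD"
        }
        df = cross_tissue_overlap(sets)
        # brute force over all 2^4 membership patterns
        names = sorted(sets)
        tally = {}
        for el in set().union(*sets.values()):
            pat = tuple(int(el in sets[n]) for n in names)
            tally[pat] = tally.get(pat, 0) + 1
        got = {
            tuple(int(r[n]) for n in names): int(r["count"]) for _, r in df.iterrows()
        }
        assert got == tally
        assert df["count"].sum() == len(set().union(*sets.values()))

    def test_shared_de(self):
        sets = {"A": {1, 2}, "B": {2, 3}, "C": {4}}
        assert shared_de(sets) == {2}
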