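"""Read counting, depth normalization, the regularized t-statistic and DHS selection."""

import numpy as np
import pandas as pd
import pytest

from tfcooc import (
    CountMatrix,
    SampleSheet,
    SequenceSource,
    characterize_dhs,
    count_reads,
    normalize_log,
    select_cts,
    select_dhs,
    select_ubiq,
    t_statistic,
)
from tfcooc.chromatin import load_count_matrix
from .conftest import make_windows


def sheet(samples_cts):
    return SampleSheet(
        pd.DataFrame(
            {"sample_id": [s for s, _ in samples_cts], "cell_type": [c for _, c in samples_cts]}
        )
    )


class TestCountReads:
    def test_five_prime_end_half_open_boundary(self):
        ws = make_windows(2)
        sh = sheet([("s1", "A")])
        mat = count_reads(ws, {"s1": [("chr1", 199, 230, "+")]}, sh)
        assert mat.values[:, 0].tolist() == [1, 0]

    def test_minus_strand_uses_right_end(self):
        ws = make_windows(2)
        sh = sheet([("s1", "A")])
        mat = count_reads(ws, {"s1": [("chr1", 195, 230, "-")]}, sh)
        assert mat.values[:, 0].tolist() == [0, 1]

    def test_empty_stream_gives_zero_matrix(self):
        ws = make_windows(3)
        sh = sheet([("s1", "A"), ("s2", "B")])
        mat = count_reads(ws, {"s1": [], "s2": []}, sh)
        assert not mat.values.any()

    def test_unknown_chromosome_warns_and_skips(self):
        ws = make_windows(1)
        sh = sheet([("s1", "A")])
        with pytest.warns(UserWarning, match="unknown chromosomes"):
            mat = count_reads(ws, {"s1": [("chrX", 0, 30, "+")]}, sh)
        assert not mat.values.any()


class TestNormalizeLog:
    def test_depth_factors_hand_example(self):
        # sample A counts [2,2], sample B [4,4]: factors 1.5 and 0.75, all -> ln 4
        sh = sheet([("A", "x"), ("B", "y")])
        raw = CountMatrix(make_windows(2), sh, np.array([[2, 4], [2, 4]]), "raw")
        out = normalize_log(raw)
        np.testing.assert_allclose(out.values, np.log(4.0))

    def test_zero_count_maps_to_zero(self):
        sh = sheet([("A", "x"), ("B", "y")])
        raw = CountMatrix(make_windows(2), sh, np.array([[0, 8], [4, 0]]), "raw")
        assert normalize_log(raw).values[0, 0] == 0.0
        assert normalize_log(raw).values[1, 1] == 0.0

    def test_equal_means_reduce_to_log1p(self):
        sh = sheet([("A", "x"), ("B", "y")])
        vals = np.array([[1, 3], [5, 3]])
        raw = CountMatrix(make_windows(2), sh, vals, "raw")
        np.testing.assert_allclose(normalize_log(raw).values, np.log(vals + 1.0))

    def test_common_integer_scaling_preserves_factors(self):
        sh = sheet([("A", "x"), ("B", "y")])
        vals = np.array([[1.0, 3.0], [5.0, 2.0]])
        f1 = np.exp(normalize_log(CountMatrix(make_windows(2), sh, vals, "raw")).values) - 1
        f3 = np.exp(normalize_log(CountMatrix(make_windows(2), sh, 3 * vals, "raw")).values) - 1
        np.testing.assert_allclose(f3 / np.where(f1 == 0, 1, f1), np.where(f1 == 0, 1, 3.0))

    def test_all_zero_sample_rejected(self):
        sh = sheet([("A", "x"), ("B", "y")])
        raw = CountMatrix(make_windows(2), sh, np.array([[0, 8], [0, 4]]), "raw")
        with pytest.raises(ValueError, match="'A'"):
            normalize_log(raw)


def straight_line_t(values, groups):
    """Independent plain-loop evaluation of the regularized t formulas."""
    n_w = values.shape[0]
    m = len(groups)
    cell_means = np.zeros((n_w, m))
    for j, g in enumerate(groups):
        for w in range(n_w):
            cell_means[w, j] = sum(values[w, i] for i in g) / len(g)
    global_mean = cell_means.sum(axis=1) / m
    s = np.zeros(n_w)
    dof = sum(len(g) - 1 for g in groups)
    for w in range(n_w):
        ss = 0.0
        for j, g in enumerate(groups):
            for i in g:
                ss += (values[w, i] - cell_means[w, j]) ** 2
        s[w] = (ss / dof) ** 0.5
    s0 = s.mean()
    t = np.zeros((n_w, m))
    for j, g in enumerate(groups):
        scale = (1 / m + 1 / len(g)) ** 0.5
        for w in range(n_w):
            t[w, j] = (cell_means[w, j] - global_mean[w]) / (scale * (s[w] + s0))
    return t


class TestTStatistic:
    def logmat(self, values, samples_cts):
        return CountMatrix(make_windows(values.shape[0]), sheet(samples_cts), values, "log")

    def test_all_equal_input_gives_zero(self):
        lm = self.logmat(np.full((3, 4), 2.5), [("a", "A"), ("b", "A"), ("c", "B"), ("d", "B")])
        assert np.allclose(t_statistic(lm).t, 0.0)

    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(42)
        values = rng.gamma(2.0, 1.0, size=(3, 8))
        labels = [("s%d" % i, "A" if i < 4 else "B") for i in range(8)]
        res = t_statistic(self.logmat(values, labels))
        expected = straight_line_t(values, [[0, 1, 2, 3], [4, 5, 6, 7]])
        np.testing.assert_allclose(res.t, expected, atol=1e-12)

    def test_within_cell_type_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.random((4, 6))
        labels = [("s%d" % i, "A" if i < 3 else "B") for i in range(6)]
        swapped = values[:, [1, 0, 2, 3, 5, 4]]
        t1 = t_statistic(self.logmat(values, labels)).t
        t2 = t_statistic(self.logmat(swapped, labels)).t
        np.testing.assert_allclose(t1, t2)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.random((5, 6))
        labels = [("s%d" % i, "AB"[i % 2]) for i in range(6)]
        t1 = t_statistic(self.logmat(values, labels)).t
        t2 = t_statistic(self.logmat(values + 7.5, labels)).t
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_cell_mean_deviations_sum_to_zero(self):
        rng = np.random.default_rng(5)
        values = rng.random((10, 9))
        labels = [("s%d" % i, "ABC"[i % 3]) for i in range(9)]
        res = t_statistic(self.logmat(values, labels))
        dev = res.cell_means - res.global_mean[:, None]
        assert np.abs(dev.sum(axis=1)).max() < 1e-9

    def test_singleton_cell_type_gets_t_but_not_pooled_sd(self):
        rng = np.random.default_rng(6)
        values = rng.random((4, 3))
        labels = [("a", "A"), ("b", "A"), ("c", "B")]
        res = t_statistic(self.logmat(values, labels))
        assert np.isfinite(res.t).all()
        # pooled SD equals the SD of cell type A alone (B is singleton)
        expected_s = np.sqrt(((values[:, :2] - values[:, :2].mean(1, keepdims=True)) ** 2).sum(1))
        np.testing.assert_allclose(res.s, expected_s)

    def test_error_cases(self):
        with pytest.raises(ValueError, match="2 cell types"):
            t_statistic(self.logmat(np.ones((2, 2)), [("a", "A"), ("b", "A")]))
        with pytest.raises(ValueError, match="single sample"):
            t_statistic(self.logmat(np.ones((2, 2)), [("a", "A"), ("b", "B")]))


class TestSelection:
    def spec(self, t, global_mean=None, windows=None):
        from tfcooc import SpecificityResult

        n, m = t.shape
        ws = windows or make_windows(n)
        gm = global_mean if global_mean is not None else np.ones(n)
        return SpecificityResult(ws, [f"ct{j}" for j in range(m)], t, np.ones(n), 1.0, np.zeros((n, m)), gm)

    def test_top_l_descending_with_coordinate_ties(self):
        t = np.array([[1.0], [3.0], [3.0], [2.0]])
        sel = select_cts(self.spec(t), l=3)
        assert [w.start for w in sel["ct0"]] == [200, 400, 600]

    def test_l_equal_window_count_returns_all(self):
        t = np.array([[0.5], [0.1], [0.9]])
        sel = select_cts(self.spec(t), l=3)
        assert [w.start for w in sel["ct0"]] == [400, 0, 200]

    def test_l_exceeding_windows_rejected(self):
        with pytest.raises(ValueError):
            select_cts(self.spec(np.zeros((2, 1))), l=3)

    def test_closed_window_never_ubiquitous(self):
        t = np.array([[0.0, 0.0], [5.0, -5.0], [0.1, -0.1], [0.2, -0.2]])
        gm = np.array([0.0, 9.0, 8.0, 7.0])  # window 0 closed despite t == 0
        sel = select_ubiq(self.spec(t, gm), l=1, open_quantile=0.5)
        assert sel[0].start != 0

    def test_separable_planted_fixture(self):
        # 50 flat-open windows (t ~ 0, high mean) vs 50 specific (large |t|);
        # one specific window has the unique minimum mean, so at quantile 0.0
        # the strict eligibility rule excludes exactly that one window.
        rng = np.random.default_rng(0)
        t = np.vstack([rng.normal(0, 0.01, (50, 2)), rng.normal(0, 0.01, (50, 2)) + [6, -6]])
        gm = np.concatenate([np.full(50, 10.0), np.full(50, 10.0)])
        gm[-1] = 5.0
        sel = select_ubiq(self.spec(t, gm), l=50, open_quantile=0.0)
        assert {w.start for w in sel} == {w.start for w in make_windows(50)}

    def test_too_few_eligible_reports_count(self):
        t = np.zeros((4, 1))
        gm = np.array([1.0, 1.0, 1.0, 9.0])
        with pytest.raises(ValueError, match="1 eligible"):
            select_ubiq(self.spec(t, gm), l=2, open_quantile=0.7)

    def test_select_dhs_strata_disjoint(self, default_bundle):
        from tfcooc import analyze_bundle

        res = analyze_bundle(default_bundle)
        ubiq = {w.id for w in res.selection.ubiq}
        for ws in res.selection.cts.values():
            assert not ubiq & {w.id for w in ws}


class TestCharacterize:
    def test_gc_of_pure_gc_sequence(self):
        ws = make_windows(1, width=10)
        genome = SequenceSource({"chr1": "GGCCGGCCGC"})
        assert characterize_dhs(ws, genome)["mean_gc"] == 1.0

    def test_annotation_equal_to_windows(self):
        ws = make_windows(3, width=10)
        genome = SequenceSource({"chr1": "ACGT" * 10})
        res = characterize_dhs(ws, genome, {"self": [(w.chrom, w.start, w.end) for w in ws]})
        assert res["overlap_fraction"]["self"] == 1.0

    def test_partial_overlap_fraction(self):
        ws = make_windows(10, width=10)
        genome = SequenceSource({"chr1": "ACGT" * 30})
        promoters = [("chr1", 0, 5), ("chr1", 12, 13), ("chr1", 25, 26), ("chr1", 33, 34)]
        res = characterize_dhs(ws, genome, {"promoter": promoters})
        assert res["overlap_fraction"]["promoter"] == pytest.approx(0.4)

    def test_window_beyond_chromosome_end(self):
        ws = make_windows(2, width=10)
        genome = SequenceSource({"chr1": "ACGTACGTAC"})
        with pytest.raises(KeyError):
            characterize_dhs(ws, genome)


def test_count_matrix_tsv_round_trip(tmp_path, default_bundle):
    path = tmp_path / "counts.tsv"
    default_bundle.counts.to_frame().to_csv(path, sep="\t")
    back = load_count_matrix(path, default_bundle.counts.samples)
    np.testing.assert_allclose(back.values, default_bundle.counts.values)
    assert [w.id for w in back.windows] == [w.id for w in default_bundle.counts.windows]
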