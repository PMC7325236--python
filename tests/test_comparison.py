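"""Wilcoxon/BH machinery against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from methylbench import (
    PerformanceVector,
    best_method_set,
    bh_adjust,
    intra_method_winner,
    paired_wilcoxon,
    summarize_table,
)
from methylbench.evaluation import ScoreRecord


def brute_force_wilcoxon_p(d):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    ts = np.array(
        [
            ranks[list(signs)].sum()
            for signs in itertools.product([False, True], repeat=len(d))
        ]
    )
    return min(1.0, 2 * min(np.mean(ts <= t_obs), np.mean(ts >= t_obs)))


def vec(method, scale, values, metric="mae"):
    return PerformanceVector(method, scale, metric, np.asarray(values, float))


class TestPairedWilcoxon:
    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for n in (5, 6, 8, 10, 12):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            p, degenerate = paired_wilcoxon(a, b)
            assert not degenerate
            assert p == pytest.approx(brute_force_wilcoxon_p(a - b), abs=1e-12)

    def test_identical_vectors_degenerate(self):
        a = np.linspace(0.1, 0.5, 20)
        p, degenerate = paired_wilcoxon(a, a)
        assert p == 1.0 and degenerate

    def test_full_dominance_minimal_p(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.5, 1.0, size=100)
        a = b - rng.uniform(0.01, 0.1, size=100)
        p, _ = paired_wilcoxon(a, b)
        assert p < 1e-15

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(size=40)
        assert paired_wilcoxon(a, b)[0] == pytest.approx(paired_wilcoxon(b, a)[0])


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_literal_step_up_recomputation(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=25)
        # literal BH: sort, scale by m/rank, enforce monotonicity from the top
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=40)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestIntraMethodWinner:
    def test_identical_vectors_none(self):
        a = vec("mean", "beta", np.linspace(0.02, 0.04, 30))
        b = vec("mean", "M", np.linspace(0.02, 0.04, 30))
        assert intra_method_winner(a, b) == "none"

    def test_beta_dominant_wins(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0.03, 0.05, size=100)
        beta = m - 0.005
        assert intra_method_winner(vec("x", "beta", beta), vec("x", "M", m)) == "beta"

    def test_m_dominant_wins(self):
        rng = np.random.default_rng(2)
        beta = rng.uniform(0.03, 0.05, size=100)
        m = beta - 0.005
        assert intra_method_winner(vec("x", "beta", beta), vec("x", "M", m)) == "M"


class TestBestMethodSet:
    def test_identical_cells_all_in_set(self):
        base = np.linspace(0.02, 0.05, 20)
        cells = [vec(m, "beta", base) for m in ("a", "b", "c")]
        assert best_method_set(cells) == {("a", "beta"), ("b", "beta"), ("c", "beta")}

    def test_strict_dominance_unique_member(self):
        rng = np.random.default_rng(4)
        worst = rng.uniform(0.05, 0.08, size=100)
        cells = [
            vec("best", "beta", worst - 0.02),
            vec("mid", "beta", worst - 0.01),
            vec("worst", "beta", worst),
        ]
        assert best_method_set(cells) == {("best", "beta")}

    def test_two_equivalent_good_cells(self):
        rng = np.random.default_rng(6)
        good = rng.uniform(0.02, 0.03, size=100)
        jitter = rng.normal(scale=1e-4, size=100)
        cells = [
            vec("g1", "beta", good),
            vec("g2", "beta", good + jitter),
            vec("bad", "beta", good + 0.02),
        ]
        assert best_method_set(cells) == {("g1", "beta"), ("g2", "beta")}

    def test_adding_dominated_cell_preserves_members(self):
        rng = np.random.default_rng(8)
        good = rng.uniform(0.02, 0.03, size=60)
        cells = [vec("g1", "beta", good), vec("g2", "M", good + rng.normal(scale=1e-4, size=60))]
        before = best_method_set(cells)
        cells.append(vec("bad", "beta", good + 0.05))
        after = best_method_set(cells)
        assert before <= after


def _records(scores_by_cell, mechanism="MCAR", status="healthy"):
    records = []
    for (method, scale), values in scores_by_cell.items():
        for rep, v in enumerate(values):
            records.append(
                ScoreRecord(
                    dataset="d1",
                    method=method,
                    scale=scale,
                    mechanism=mechanism,
                    repetition=rep,
                    n_scored=10,
                    n_ignored=0,
                    mae=v,
                    rmse=v * 1.3,
                )
            )
    return records


class TestSummarizeTable:
    def test_mean_and_sd_arithmetic(self):
        recs = _records({("mean", "beta"): [0.02, 0.04], ("mean", "M"): [0.03, 0.05]})
        reports = summarize_table(recs, alpha=0.05)
        mae_report = [r for r in reports if r.metric == "mae"][0]
        mu, sd = mae_report.summary[("mean", "beta")]
        assert mu == pytest.approx(0.03)
        assert sd == pytest.approx(0.014142, abs=1e-6)
        # too few repetitions to test: no winners, every cell in the best set
        assert mae_report.best_set == {("mean", "beta"), ("mean", "M")}

    def test_regenerated_report_identical(self):
        rng = np.random.default_rng(10)
        cells = {
            ("mean", "beta"): rng.uniform(0.02, 0.05, 20),
            ("mean", "M"): rng.uniform(0.02, 0.05, 20),
            ("knn", "beta"): rng.uniform(0.03, 0.06, 20),
            ("knn", "M"): rng.uniform(0.03, 0.06, 20),
        }
        recs = _records(cells)
        r1 = summarize_table(recs)
        r2 = summarize_table(recs)
        assert [r.to_json() for r in r1] == [r.to_json() for r in r2]

    def test_grand_mean_consistency(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0.01, 0.09, size=50)
        recs = _records({("mean", "beta"): values, ("mean", "M"): values + 0.01})
        report = [r for r in summarize_table(recs) if r.metric == "mae"][0]
        assert report.summary[("mean", "beta")][0] == pytest.approx(values.mean(), abs=1e-12)
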