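"""Wilcoxon rank-sum, BH adjustment, stage summaries, and threshold calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from telncrna.errors import ValidationError
from telncrna.stats import (DifferentialRecord, ExpressionMatrix,
                            benjamini_hochberg, call_degs, call_zga_genes,
                            stage_class_summary, wilcoxon_rank_sum)
from telncrna.te import TEClass, classify_transcript

from conftest import make_repeat, make_transcript


def enumeration_pvalue(x, y, alternative="two_sided"):
    """Complete enumeration over all labelings of the pooled sample."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_of(xs, ys))
    us = np.array(us)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_small_sample_exact_example(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.u == 0
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(2 / 6)

    def test_identical_samples_p_one_on_normal_path(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "normal_approx"  # ties force the normal path
        assert res.pvalue == 1.0

    def test_all_values_equal_degenerate(self):
        assert wilcoxon_rank_sum([5.0] * 4, [5.0] * 4).pvalue == 1.0

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_exact_equals_enumeration_all_small_sizes(self, alternative):
        rng = np.random.default_rng(21)
        for n in range(1, 9):
            for m in range(1, 10 - n + 1):
                x = rng.normal(size=n)
                y = rng.normal(size=m)
                res = wilcoxon_rank_sum(x, y, alternative)
                assert res.method == "exact"
                assert res.pvalue == pytest.approx(
                    enumeration_pvalue(list(x), list(y), alternative), abs=1e-12)

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            x = rng.normal(size=int(rng.integers(2, 8)))
            y = rng.normal(size=int(rng.integers(2, 8)))
            res = wilcoxon_rank_sum(x, y, "two_sided")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.u == pytest.approx(ref.statistic)
            assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_path_close_to_exact_at_n8(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = wilcoxon_rank_sum(x, y, method="exact").pvalue
            approx = wilcoxon_rank_sum(x, y, method="normal").pvalue
            assert abs(exact - approx) < 0.02

    def test_tie_corrected_variance_matches_scipy(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            x = rng.integers(0, 6, size=15).astype(float)
            y = rng.integers(0, 6, size=18).astype(float)
            res = wilcoxon_rank_sum(x, y, "two_sided")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic")
            assert res.method == "normal_approx"
            assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=10)
            y = rng.normal(size=12)
            if wilcoxon_rank_sum(x, y).pvalue <= 0.05:
                hits += 1
        assert 0.035 <= hits / reps <= 0.065

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestBenjaminiHochberg:
    def test_step_up_monotonization(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert benjamini_hochberg([0.37]) == [0.37]
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]
        assert benjamini_hochberg([]) == []

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            ours = benjamini_hochberg(p)
            ref = statsmodels.multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref)

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = np.array(benjamini_hochberg(p))
        assert ((adj >= 0) & (adj <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_idempotent_on_fully_monotonized_output(self):
        # when step-up monotonization collapses the adjusted values to a
        # single level, re-adjusting is a fixed point
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert benjamini_hochberg(adj) == pytest.approx(adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])


def rec(gid, lfc, p, padj, f1=2.0, f2=2.0):
    return DifferentialRecord(gid, lfc, p, padj, f1, f2)


class TestThresholdCalls:
    def test_zga_examples(self):
        records = [rec("keep", 1.2, 0.001, 0.005),
                   rec("boundary_padj", 1.0, 0.001, 0.01),
                   rec("down", -1.5, 0.001, 0.001)]
        assert call_zga_genes(records) == {"keep", "down"}
        assert call_zga_genes(records, direction="up_only") == {"keep"}

    def test_zga_fc_boundary_inclusive_padj_strict(self):
        records = [rec("fc_edge", 1.0, 0.001, 0.0099),
                   rec("padj_edge", 2.0, 0.001, 0.01)]
        assert call_zga_genes(records) == {"fc_edge"}

    def test_deg_boundaries_all_inclusive(self):
        records = [rec("edge", -1.0, 0.05, 0.9, 1.0, 0.2),
                   rec("p_out", 1.5, 0.051, 0.9, 2.0, 0.2),
                   rec("fpkm_out", 1.5, 0.01, 0.9, 0.5, 0.5),
                   rec("fc_out", 0.99, 0.01, 0.9, 2.0, 0.2)]
        assert call_degs(records) == {"edge"}

    def test_calls_equal_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        records = []
        for i in range(2000):
            p = float(rng.choice([0.049, 0.05, 0.051, rng.uniform()]))
            q = float(rng.choice([0.0099, 0.01, 0.011, rng.uniform()]))
            lfc = float(rng.choice([-1.0, -0.99, 0.99, 1.0, rng.normal(0, 2)]))
            f1 = float(rng.choice([0.99, 1.0, rng.lognormal()]))
            f2 = float(rng.choice([0.99, 1.0, rng.lognormal()]))
            records.append(rec(f"g{i}", lfc, p, q, f1, f2))
        zga = {r.gene_id for r in records if abs(r.log2fc) >= 1 and r.padj < 0.01}
        degs = {r.gene_id for r in records
                if r.pvalue <= 0.05 and max(r.fpkm_group1, r.fpkm_group2) >= 1
                and abs(r.log2fc) >= 1}
        assert call_zga_genes(records) == zga
        assert call_degs(records) == degs

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        records = [rec(f"g{i}", float(rng.normal(0, 2)), float(rng.uniform()),
                       float(rng.uniform()), float(rng.lognormal()),
                       float(rng.lognormal())) for i in range(500)]
        base = call_degs(records)
        assert call_degs(records, p_max=0.01) <= base
        assert call_degs(records, fpkm_min=5.0) <= base
        assert call_degs(records, lfc_min=2.0) <= base
        assert call_zga_genes(records, padj_max=0.001) <= call_zga_genes(records)


class TestStageSummary:
    def _matrix(self, data, stage_of):
        df = pd.DataFrame(data).T
        df.index.name = "feature_id"
        return ExpressionMatrix(values=df, stage_of=stage_of)

    def _sine_assoc(self, tid):
        t = make_transcript(tid, exons=((100, 200),))
        return classify_transcript(t, [make_repeat(start=100, end=200)])

    def test_single_feature_median(self):
        matrix = self._matrix({"t1": {"s1": 1.0, "s2": 3.0}},
                              {"s1": "2C", "s2": "2C"})
        (s,) = stage_class_summary(matrix, [self._sine_assoc("t1")], TEClass.SINE)
        assert s.median == pytest.approx(1.5)  # median of log2{2, 4} = {1, 2}
        assert s.n == 2 and s.stage == "2C"

    def test_class_without_members_is_empty(self):
        matrix = self._matrix({"t1": {"s1": 1.0}}, {"s1": "2C"})
        assert stage_class_summary(matrix, [self._sine_assoc("t1")],
                                   TEClass.LINE) == []

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(31)
        stages = {f"s{i}": ("2C" if i < 4 else "8C") for i in range(8)}
        data = {f"t{j}": {s: float(rng.lognormal(1, 1)) for s in stages}
                for j in range(12)}
        matrix = self._matrix(data, stages)
        assocs = [self._sine_assoc(f"t{j}") for j in range(12)]
        summaries = stage_class_summary(matrix, assocs, TEClass.SINE)
        for s in summaries:
            pooled = np.array([np.log2(data[f"t{j}"][smp] + 1)
                               for j in range(12)
                               for smp in stages if stages[smp] == s.stage])
            assert s.n == pooled.size
            assert s.mean == pytest.approx(pooled.mean())
            assert s.median == pytest.approx(np.median(pooled))
            assert s.q1 == pytest.approx(np.percentile(pooled, 25))
            assert s.q3 == pytest.approx(np.percentile(pooled, 75))
            assert s.q1 <= s.median <= s.q3

    def test_unknown_association_id_rejected(self):
        matrix = self._matrix({"t1": {"s1": 1.0}}, {"s1": "2C"})
        with pytest.raises(ValidationError):
            stage_class_summary(matrix, [self._sine_assoc("missing")],
                                TEClass.SINE)


def test_negative_fpkm_rejected():
    df = pd.DataFrame({"s1": [-1.0]}, index=["t1"])
    with pytest.raises(ValidationError):
        ExpressionMatrix(values=df, stage_of={"s1": "2C"})
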