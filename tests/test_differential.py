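"""Consensus building, normalization and the NB differential test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atacnet.differential import (
    CountMatrix,
    Sample,
    build_consensus,
    call_unique_peaks,
    estimate_common_dispersion,
    normalize,
    test_differential as nb_lrt_test,
)
from atacnet.intervals import GenomicInterval, IntervalSet
from .conftest import random_interval_set


def make_matrix(counts: np.ndarray, conditions=("A", "A", "B", "B")) -> CountMatrix:
    n = counts.shape[0]
    peaks = IntervalSet(
        [GenomicInterval("chr1", i * 1000, i * 1000 + 500, name=f"p{i:05d}") for i in range(n)]
    )
    samples = [Sample(f"s{j}", c, j) for j, c in enumerate(conditions)]
    df = pd.DataFrame(counts, index=[f"p{i:05d}" for i in range(n)],
                      columns=[s.sample_id for s in samples])
    return CountMatrix(peaks, samples, df)


class TestConsensus:
    def test_replicated_peak_kept_single_dropped(self):
        shared = GenomicInterval("chr1", 100, 300, name="x")
        only1 = GenomicInterval("chr1", 5_000, 5_200, name="y")
        s1 = IntervalSet([shared, only1], "r1")
        s2 = IntervalSet([GenomicInterval("chr1", 150, 350)], "r2")
        cons = build_consensus([s1, s2], min_samples=2)
        assert [(iv.start, iv.end) for iv in cons] == [(100, 350)]

    def test_min_samples_validation(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            build_consensus([s, s], min_samples=3)
        with pytest.raises(ValueError):
            build_consensus([s], min_samples=1)

    @pytest.mark.parametrize("min_samples", [1, 2, 3])
    def test_matches_membership_oracle(self, min_samples):
        rng = np.random.default_rng(11)
        sets = [random_interval_set(rng, 120, span=30_000, label=f"s{i}") for i in range(3)]
        cons = build_consensus(sets, min_samples=min_samples)
        from atacnet.intervals import merge

        union = merge(IntervalSet([iv for s in sets for iv in s]))
        for u in union:
            support = sum(any(u.overlap(iv) > 0 for iv in s) for s in sets)
            present = any(c.start == u.start and c.end == u.end and c.chrom == u.chrom
                          for c in cons)
            assert present == (support >= min_samples)


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        counts = np.tile(np.arange(1, 21)[:, None], (1, 4))
        m = normalize(make_matrix(counts))
        assert np.allclose(m.size_factors, 1.0)

    def test_doubled_sample_scales_proportionally(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 200, size=50)
        counts = np.stack([base, 2 * base], axis=1)
        m = normalize(make_matrix(counts, conditions=("A", "B")))
        ratio = m.size_factors.iloc[1] / m.size_factors.iloc[0]
        assert ratio == pytest.approx(2.0)

    def test_global_scaling_leaves_log2fc_unchanged(self):
        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(10, 0.1, size=(100, 4))
        r1 = nb_lrt_test(make_matrix(counts))
        r2 = nb_lrt_test(make_matrix(counts * 10))
        assert np.allclose(r1["log2fc"], r2["log2fc"], atol=0.05)

    def test_total_count_fallback(self, caplog):
        counts = np.array([[5, 0], [0, 5], [10, 0]])
        import logging

        with caplog.at_level(logging.INFO, logger="atacnet.differential"):
            m = normalize(make_matrix(counts, conditions=("A", "B")))
        assert np.allclose(np.exp(np.mean(np.log(m.size_factors))), 1.0)


class TestDifferentialTest:
    def test_identical_counts_null(self):
        counts = np.tile([[100, 100, 100, 100]], (10, 1))
        res = nb_lrt_test(make_matrix(counts))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_two_conditions_required(self):
        counts = np.random.default_rng(0).poisson(50, size=(10, 2))
        with pytest.raises(ValueError, match="two conditions"):
            nb_lrt_test(make_matrix(counts, conditions=("A", "A")))

    def test_condition_relabeling_flips_sign(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(10, 0.1, size=(200, 4))
        r_ab = nb_lrt_test(make_matrix(counts, ("A", "A", "B", "B")))
        r_ba = nb_lrt_test(make_matrix(counts[:, [2, 3, 0, 1]], ("B", "B", "A", "A")))
        assert np.allclose(r_ab["log2fc"], -r_ba["log2fc"], atol=1e-9)
        assert np.allclose(r_ab["pvalue"], r_ba["pvalue"], atol=1e-9)

    def test_qvalues_monotone_in_pvalue_rank(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.05, size=(300, 4))
        res = nb_lrt_test(make_matrix(counts)).sort_values("pvalue")
        assert (np.diff(res["qvalue"].to_numpy()) >= -1e-12).all()

    def test_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        disp, mu = 0.1, 100.0
        counts = rng.negative_binomial(1 / disp, 1 / (1 + disp * mu), size=(3000, 4))
        m = normalize(make_matrix(counts))
        est = estimate_common_dispersion(m)
        assert est == pytest.approx(disp, rel=0.15)

    def test_poisson_limit(self):
        # with dispersion forced to 0 the NB LRT must equal the Poisson LRT
        rng = np.random.default_rng(5)
        counts = rng.poisson(80, size=(400, 4))
        matrix = make_matrix(counts)
        res = nb_lrt_test(matrix, dispersion=0.0)
        sf = matrix.size_factors.to_numpy()

        def poisson_lrt_p(y):
            def ll(yy, ss):
                q = yy.sum() / ss.sum()
                return stats.poisson.logpmf(yy, np.maximum(ss * q, 1e-12)).sum()

            lrt = max(0.0, 2 * (ll(y[:2], sf[:2]) + ll(y[2:], sf[2:]) - ll(y, sf)))
            return stats.chi2.sf(lrt, df=1)

        oracle = np.array([poisson_lrt_p(row) for row in counts.astype(float)])
        assert np.allclose(res["pvalue"], oracle, atol=1e-6)


class TestUniquePeaks:
    def test_occupancy_trivial_cases(self):
        pa = GenomicInterval("chr1", 100, 300, name="a")
        shared = GenomicInterval("chr1", 10_000, 10_400, name="s")
        a_sets = [IntervalSet([pa, shared], "a1"), IntervalSet([pa, shared], "a2")]
        b_sets = [IntervalSet([shared], "b1"), IntervalSet([shared], "b2")]
        ua, ub, sh = call_unique_peaks({"A": a_sets, "B": b_sets})
        assert [(iv.start, iv.end) for iv in ua] == [(100, 300)]
        assert len(ub) == 0
        assert [(iv.start, iv.end) for iv in sh] == [(10_000, 10_400)]

    def test_partition_covers_union(self, dataset):
        cfg = dataset.config
        by_cond = {
            c: [dataset.sample_peaks[s.sample_id] for s in dataset.samples if s.condition == c]
            for c in (cfg.condition_a, cfg.condition_b)
        }
        ua, ub, sh = call_unique_peaks(by_cond)
        n_true = len(dataset.truth_peaks)
        assert len(ua) + len(ub) + len(sh) == n_true

    def test_affinity_mode_recovers_truth(self, dataset):
        matrix = dataset.counts
        res = nb_lrt_test(matrix)
        cfg = dataset.config
        by_cond = {
            c: [dataset.sample_peaks[s.sample_id] for s in dataset.samples if s.condition == c]
            for c in (cfg.condition_a, cfg.condition_b)
        }
        ua, ub, _ = call_unique_peaks(
            by_cond, mode="affinity", results=res, consensus=matrix.peaks
        )
        truth_a = set(dataset.truth_peaks.query("condition == @cfg.condition_a")["peak_id"])
        truth_b = set(dataset.truth_peaks.query("condition == @cfg.condition_b")["peak_id"])
        got_a = {iv.name for iv in ua}
        got_b = {iv.name for iv in ub}
        assert len(got_a & truth_a) / len(truth_a) >= 0.9
        assert len(got_b & truth_b) / len(truth_b) >= 0.9

    def test_unknown_mode_rejected(self):
        s = [IntervalSet([GenomicInterval("chr1", 0, 10)])]
        with pytest.raises(ValueError, match="unknown mode"):
            call_unique_peaks({"A": s, "B": s}, mode="bogus")
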