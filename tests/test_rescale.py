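"""Mappability/CNV correction and the dip statistic.

The dip statistic is checked against an independent brute-force oracle:
minimax fitting of a piecewise-linear unimodal CDF by linear programming,
enumerating the segment containing the mode.
"""

import numpy as np
import pytest
from scipy.optimize import linprog

import binpbs as bp


# ---------------------------------------------------------------------------
# LP minimax oracle for the dip statistic
# ---------------------------------------------------------------------------

def dip_lp(xs):
    """min over piecewise-linear unimodal CDFs G of sup |F_n - G|.

    For the segment containing the mode, G may rise then fall in slope around
    an interior knot, which is feasible iff the segment's chord slope is at
    least one neighbor's slope — hence two LPs per candidate mode segment.
    """
    x = np.sort(np.asarray(xs, float))
    n = len(x)
    dx = np.maximum(np.diff(x), 1e-12)
    c = np.zeros(n + 1)
    c[-1] = 1.0

    def slope_row(i):
        row = np.zeros(n + 1)
        row[i + 1] += 1 / dx[i]
        row[i] -= 1 / dx[i]
        return row

    def solve(conv_pairs, conc_pairs, extra_ge):
        A_ub, b_ub = [], []
        for i in range(n):
            for target in (i / n, (i + 1) / n):
                row = np.zeros(n + 1); row[i] = 1; row[-1] = -1
                A_ub.append(row); b_ub.append(target)
                row = np.zeros(n + 1); row[i] = -1; row[-1] = -1
                A_ub.append(row); b_ub.append(-target)
        for i in range(n - 1):
            row = np.zeros(n + 1); row[i] = 1; row[i + 1] = -1
            A_ub.append(row); b_ub.append(0.0)
        for i, j in conv_pairs:  # slope_i <= slope_j
            A_ub.append(slope_row(i) - slope_row(j)); b_ub.append(0.0)
        for i, j in conc_pairs + extra_ge:  # slope_i >= slope_j
            A_ub.append(slope_row(j) - slope_row(i)); b_ub.append(0.0)
        res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=[(0, 1)] * n + [(0, 1)], method="highs")
        return res.fun if res.success else np.inf

    nseg = n - 1
    chain = lambda lo, hi: [(i, i + 1) for i in range(lo, hi)]
    best = min(
        solve(chain(0, nseg - 1), [], []),   # mode beyond the right end
        solve([], chain(0, nseg - 1), []),   # mode before the left end
    )
    for k in range(nseg):
        conv = chain(0, k - 1)
        conc = chain(k + 1, nseg - 1)
        if k > 0:
            best = min(best, solve(conv, conc, [(k, k - 1)]))
        if k < nseg - 1:
            best = min(best, solve(conv, conc, [(k, k + 1)]))
        if k == 0 or k == nseg - 1:
            best = min(best, solve(conv, conc, []))
    return best


class TestDipStatistic:
    def test_matches_lp_oracle_on_random_samples(self):
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(4, 14))
            if trial % 3 == 0:
                xs = rng.random(n)
            elif trial % 3 == 1:
                xs = np.concatenate(
                    [rng.normal(0, 1, n // 2), rng.normal(8, 1, n - n // 2)]
                )
            else:
                xs = rng.exponential(1, n)
            assert bp.dip_statistic(xs) == pytest.approx(dip_lp(xs), abs=1e-8)

    def test_known_small_sample_floor(self):
        # unimodal-compatible samples sit at the 1/(2n) lower bound
        assert bp.dip_statistic([0.0, 1.0]) == pytest.approx(0.25)
        assert bp.dip_statistic(np.linspace(0, 1, 10)) == pytest.approx(0.05)

    def test_separated_modes_have_large_dip(self):
        rng = np.random.default_rng(0)
        uni = bp.dip_statistic(rng.normal(0, 1, 1000))
        bim = bp.dip_statistic(
            np.concatenate([rng.normal(0, 1, 500), rng.normal(6, 1, 500)])
        )
        assert bim > 5 * uni


class TestDipTest:
    def test_unimodal_not_rejected(self):
        rng = np.random.default_rng(3)
        _, p = bp.dip_test(rng.normal(0, 1, 2000), n_boot=500, seed=1)
        assert p > 0.05

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 1000), rng.normal(6, 1, 1000)])
        _, p = bp.dip_test(x, n_boot=2000, seed=1)
        assert p < 0.001

    def test_preconditions(self):
        with pytest.raises(ValueError):
            bp.dip_test(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            bp.dip_test(np.arange(10.0), n_boot=50)
        with pytest.warns(UserWarning, match="degenerate"):
            d, p = bp.dip_test(np.ones(100))
        assert (d, p) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# mappability
# ---------------------------------------------------------------------------

class TestMappability:
    def test_constant_track(self, toy_bins):
        bins = bp.average_mappability(toy_bins, [("chr1", 0, 50_000, 1.0)])
        assert np.allclose(bins.table["mappability"], 1.0)

    def test_half_and_half(self, toy_bins):
        track = [("chr1", 0, 2500, 1.0), ("chr1", 2500, 5000, 0.0)]
        bins = bp.average_mappability(toy_bins, track)
        assert bins.table["mappability"][0] == pytest.approx(0.5)

    def test_per_base_average_matches_brute_force(self, toy_bins):
        rng = np.random.default_rng(7)
        scores = rng.random(5000)
        # 50 bp runs of constant score emulate a per-base track compactly
        track = [
            ("chr1", i, i + 50, float(scores[i // 50])) for i in range(0, 5000, 50)
        ]
        bins = bp.average_mappability(toy_bins, track)
        brute = np.mean(np.repeat(scores[:100], 50))
        assert bins.table["mappability"][0] == pytest.approx(brute)

    def test_read_length_validation(self, toy_bins):
        with pytest.raises(ValueError, match="mappability track"):
            bp.average_mappability(toy_bins, [("chr1", 0, 50_000, 1.0)], read_length=42)
        # paired-end forces the 100 bp track regardless of read_length
        bins = bp.average_mappability(
            toy_bins, [("chr1", 0, 50_000, 0.8)], read_length=42, paired_end=True
        )
        assert np.allclose(bins.table["mappability"], 0.8)

    def test_score_range_validated(self, toy_bins):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bp.average_mappability(toy_bins, [("chr1", 0, 5000, 1.5)])

    @pytest.mark.parametrize(
        "score,expected", [(1.0, 10.0), (0.8, 12.5), (0.4, np.nan)]
    )
    def test_rescale_rule(self, toy_bins, score, expected):
        bins = bp.average_mappability(toy_bins, [("chr1", 0, 50_000, score)])
        counts = bp.BinTrack(np.full(10, 10.0), bins, "raw_counts")
        out = bp.mappability_rescale(counts, bins)
        if np.isnan(expected):
            assert np.isnan(out.values).all()
            assert (out.bins.table["excluded_reason"] == "low_mappability").all()
        else:
            assert np.allclose(out.values, expected)

    def test_rescale_never_decreases(self, toy_bins):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0.5, 1.0, 10)
        track = [
            ("chr1", j * 5000, (j + 1) * 5000, float(scores[j])) for j in range(10)
        ]
        bins = bp.average_mappability(toy_bins, track)
        counts = bp.BinTrack(rng.gamma(3, 10, 10), bins, "raw_counts")
        out = bp.mappability_rescale(counts, bins)
        assert np.all(out.values >= counts.values - 1e-12)

    def test_min_mappability_validated(self, toy_bins):
        bins = bp.average_mappability(toy_bins, [("chr1", 0, 50_000, 1.0)])
        counts = bp.BinTrack(np.ones(10), bins, "raw_counts")
        with pytest.raises(ValueError):
            bp.mappability_rescale(counts, bins, min_mappability=0.0)


# ---------------------------------------------------------------------------
# CNV detection / ploidy estimation
# ---------------------------------------------------------------------------

def _control(n_bins, seed, cnv_segments=()):
    spec = bp.SimulationSpec(
        n_bins=n_bins, alpha=100.0, beta=1.0, lam=1.0, seed=seed,
        cnv_segments=cnv_segments,
    )
    return bp.simulate_counts(spec).counts


class TestDetectCnv:
    def test_diploid_not_detected(self):
        res = bp.detect_cnv(_control(20_000, seed=1), n_boot=1000, seed=1)
        assert not res.detected
        assert np.all(res.ploidy_ratio.values == 1.0)

    def test_cnv_segment_detected(self):
        # 1.5x over 10% of the genome, straddling subset boundaries
        counts = _control(20_000, seed=2, cnv_segments=[(6_500, 8_500, 1.5)])
        res = bp.detect_cnv(counts, n_boot=1000, seed=1)
        assert res.detected

    def test_constant_counts_degenerate(self, toy_bins):
        bins = bp.make_genome_bins({"chr1": 5000 * 100}, 5000)
        counts = bp.BinTrack(np.full(100, 5.0), bins, "raw_counts")
        with pytest.warns(UserWarning, match="constant"):
            res = bp.detect_cnv(counts, n_subsets=20)
        assert not res.detected

    def test_too_few_bins(self):
        bins = bp.make_genome_bins({"chr1": 5000 * 30}, 5000)
        counts = bp.BinTrack(np.arange(30.0), bins, "raw_counts")
        with pytest.raises(ValueError, match="usable bins"):
            bp.detect_cnv(counts, n_subsets=20)


class TestEstimatePloidy:
    def test_two_state_recovery(self):
        counts = _control(20_000, seed=3, cnv_segments=[(3_000, 9_000, 1.5)])
        res = bp.estimate_ploidy(counts, seed=0)
        r = res.ploidy_ratio.values
        # 70% of bins diploid, 30% at 1.5x
        assert np.median(r[:3_000]) == pytest.approx(1.0, abs=0.05)
        assert np.median(r[3_000:9_000]) == pytest.approx(1.5, abs=0.075)
        assert np.median(r[9_000:]) == pytest.approx(1.0, abs=0.05)

    def test_single_mode_all_ratio_one(self):
        res = bp.estimate_ploidy(_control(10_000, seed=4), seed=0)
        assert np.allclose(res.ploidy_ratio.values, 1.0, atol=0.05)

    def test_diploid_is_majority_mode_even_when_lower(self):
        # 60% of bins at half counts: the 0.5c mode is diploid, rest ~2x
        counts = _control(20_000, seed=5, cnv_segments=[(0, 12_000, 0.5)])
        res = bp.estimate_ploidy(counts, seed=0)
        r = res.ploidy_ratio.values
        assert np.median(r[:12_000]) == pytest.approx(1.0, abs=0.05)
        assert np.median(r[12_000:]) == pytest.approx(2.0, abs=0.1)


class TestCnvRescale:
    def test_arithmetic(self, toy_bins):
        counts = bp.BinTrack(np.full(10, 30.0), toy_bins, "raw_counts")
        ratio = bp.BinTrack(np.full(10, 1.5), toy_bins, "rescaled_counts")
        cnv = bp.CnvResult(np.array([]), True, ratio)
        out = bp.cnv_rescale(counts, cnv)
        assert np.allclose(out.values, 20.0)

    def test_identity_at_ratio_one(self, toy_bins):
        counts = bp.BinTrack(np.arange(10.0), toy_bins, "raw_counts")
        cnv = bp.CnvResult(np.array([]), False, bp.BinTrack(np.ones(10), toy_bins, "rescaled_counts"))
        assert np.allclose(bp.cnv_rescale(counts, cnv).values, counts.values)

    def test_rescale_restores_unimodality(self):
        counts = _control(20_000, seed=6, cnv_segments=[(6_500, 8_500, 1.6)])
        det = bp.detect_cnv(counts, n_boot=1000, seed=1)
        assert det.detected
        ploidy = bp.estimate_ploidy(counts, seed=0)
        fixed = bp.cnv_rescale(counts, ploidy)
        _, p = bp.dip_test(fixed.usable_values(), n_boot=500, seed=2)
        assert p > 0.05

    def test_nonpositive_ratio_rejected(self, toy_bins):
        counts = bp.BinTrack(np.ones(10), toy_bins, "raw_counts")
        bad = bp.CnvResult(np.array([]), True, None)
        with pytest.raises(ValueError):
            bp.cnv_rescale(counts, bad)
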