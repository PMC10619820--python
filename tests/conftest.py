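import numpy as np
import pytest

import binpbs as bp


@pytest.fixture(scope="session")
def toy_bins():
    """Ten 5 kB bins on one chromosome."""
    return bp.make_genome_bins({"chr1": 50_000}, 5000)


@pytest.fixture(scope="session")
def mixture_sim():
    """Medium mixture simulation shared across read-only tests."""
    spec = bp.SimulationSpec(n_bins=100_000, lam=0.8, signal_factor=6.0, seed=11)
    return bp.simulate_counts(spec)


@pytest.fixture(scope="session")
def mixture_fit(mixture_sim):
    emp = bp.empirical_distribution(mixture_sim.counts)
    fit = bp.fit_background(mixture_sim.counts, emp=emp)
    bp.fit_quality(emp, fit)
    return emp, fit


def brute_force_overlap_bins(bins, intervals, min_overlap_bp=1):
    """O(bins x intervals) interval-intersection oracle."""
    tab = bins.table
    out = np.zeros(len(bins), dtype=bool)
    for j in range(len(bins)):
        for chrom, s, e in intervals:
            if chrom != tab.at[j, "chrom"]:
                continue
            ov = min(e, tab.at[j, "end"]) - max(s, tab.at[j, "start"])
            if ov >= min_overlap_bp:
                out[j] = True
    return out
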