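import numpy as np
import pandas as pd
import pytest

from methdrift import core
from methdrift.core import DECREASE, INCREASE, NONE


def _loci(rows):
    cols = ["chrom", "pos", "n_cpg",
            "depth_D1", "meth_D1", "depth_D2", "meth_D2",
            "depth_PR1", "meth_PR1", "depth_PR2", "meth_PR2"]
    return pd.DataFrame(rows, columns=cols)


def test_locus_pass_filter():
    loci = _loci([
        ["chr1", 0, 3, 30, 1, 25, 1, 40, 1, 22, 1],    # passes
        ["chr1", 50, 1, 30, 1, 25, 1, 40, 1, 22, 1],   # too few CpGs
        ["chr1", 100, 3, 19, 1, 25, 1, 40, 1, 22, 1],  # one shallow replicate
        ["chr1", 150, 3, np.nan, np.nan, 25, 1, 40, 1, 22, 1],  # NaN cell ok
        ["chr1", 200, 3] + [np.nan] * 8,               # no data at all
    ])
    assert list(core.locus_pass_filter(loci)) == [True, False, False, True, False]


def test_classify_locus_change_directions():
    # increase in PR = negative delta (fmc_D - fmc_PR)
    loci = _loci([
        # consistent increase: PR higher in both replicates
        ["chr1", 0, 3, 100, 20, 100, 22, 100, 60, 100, 58],
        # consistent decrease: PR lower in both
        ["chr1", 1, 3, 100, 80, 100, 82, 100, 30, 100, 28],
        # inconsistent: deltas of opposite sign
        ["chr1", 2, 3, 100, 50, 100, 50, 100, 60, 100, 40],
    ])
    calls = core.classify_locus_change(loci)
    assert list(calls["direction"]) == [INCREASE, DECREASE, NONE]
    assert list(calls["consistent"]) == [True, True, False]
    assert calls["delta"].iloc[0] == pytest.approx((0.20 - 0.60 + 0.22 - 0.58) / 2)


def test_classify_locus_change_min_abs_delta():
    loci = _loci([
        ["chr1", 0, 3, 100, 50, 100, 50, 100, 52, 100, 53],  # |delta| = 0.025
    ])
    assert core.classify_locus_change(loci)["direction"].iloc[0] == INCREASE
    gated = core.classify_locus_change(loci, min_abs_delta=0.075)
    assert gated["direction"].iloc[0] == NONE


def test_classify_locus_change_alpha_gate_matches_scipy():
    from scipy import stats as sps

    loci = _loci([
        ["chr1", 0, 3, 100, 20, 100, 22, 100, 60, 100, 58],
        ["chr1", 1, 3, 100, 48, 100, 52, 100, 50, 100, 55],
    ])
    calls = core.classify_locus_change(loci, alpha=0.05)
    d = np.array([[0.20, 0.22], [0.48, 0.52]])
    pr = np.array([[0.60, 0.58], [0.50, 0.55]])
    for i in range(2):
        expected = sps.ttest_ind(d[i], pr[i]).pvalue
        assert calls["p"].iloc[i] == pytest.approx(expected)
    assert calls["direction"].iloc[0] == INCREASE
    assert calls["direction"].iloc[1] == NONE  # not significant


def test_single_replicate_degrades_without_crash():
    loci = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [0], "n_cpg": [3],
         "depth_D1": [100], "meth_D1": [20],
         "depth_PR1": [100], "meth_PR1": [60]}
    )
    calls = core.classify_locus_change(loci, alpha=0.05)
    assert np.isnan(calls["p"].iloc[0])
    assert calls["direction"].iloc[0] == NONE  # cannot be significant
    no_alpha = core.classify_locus_change(loci)
    assert no_alpha["direction"].iloc[0] == INCREASE


def test_classify_peak_change():
    peaks = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5,
            "start": [0, 300, 600, 900, 1200],
            "end": [250, 550, 850, 1150, 1450],
            # eligible+inc, eligible+dec, not eligible, fold below gate, unbounded
            "enr_D_1": [10.0, 30.0, 4.0, 16.0, 0.0],
            "enr_D_2": [10.0, 30.0, 4.0, 16.0, 0.0],
            "enr_PR_1": [20.0, 10.0, 8.0, 20.0, 18.0],
            "enr_PR_2": [20.0, 10.0, 8.0, 20.0, 18.0],
        }
    )
    calls = core.classify_peak_change(peaks, min_enrichment=15, min_fold=1.5)
    assert list(calls["direction"]) == [INCREASE, DECREASE, NONE, NONE, INCREASE]
    assert calls["fold"].iloc[0] == pytest.approx(2.0)
    assert bool(calls["unbounded_fold"].iloc[4])


def test_change_histogram_zero_bin():
    h = core.change_histogram([-0.06, -0.01, 0.0, 0.02, 0.11], bin_width=0.05)
    assert int(h["count"].sum()) == 5
    zero_bin = h.loc[np.isclose(h["bin_lo"], 0.0)]
    assert int(zero_bin["count"].iloc[0]) == 2  # 0.0 and 0.02


def test_rrbs_within_peaks_test_manual_counts():
    from scipy import stats as sps

    loci = _loci([
        ["chr1", 100, 3, 100, 20, 100, 20, 100, 60, 100, 60],  # inc, in peak
        ["chr1", 500, 3, 100, 80, 100, 80, 100, 30, 100, 30],  # dec, in peak
        ["chr1", 104, 3, 100, 20, 100, 20, 100, 60, 100, 60],  # inc, window enters peak
        ["chr1", 5000, 3, 100, 20, 100, 20, 100, 60, 100, 60],  # inc, outside
        ["chr1", 6000, 3, 100, 80, 100, 80, 100, 30, 100, 30],  # dec, outside
    ])
    calls = core.classify_locus_change(loci)
    peaks = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [90, 450], "end": [140, 600]}
    )
    res = core.rrbs_within_peaks_test(loci, calls, peaks, [True, True])
    assert (res.n1, res.n2) == (2, 1)
    assert (res.ref1, res.ref2) == (3, 2)
    assert res.p == pytest.approx(sps.fisher_exact([[2, 1], [3, 2]])[1])
    with pytest.raises(ValueError, match="no overlapping loci"):
        core.rrbs_within_peaks_test(loci, calls, peaks, [False, False])


def test_stratified_ratio_normalization_identity():
    # subset composition already matches the reference: ratio unchanged
    rng = np.random.default_rng(0)
    fmc = rng.random(400)
    direction = np.where(rng.random(400) < 0.6, INCREASE, DECREASE)
    df = pd.DataFrame({"fmc_D": fmc, "direction": direction})
    raw = (direction == INCREASE).sum() / (direction == DECREASE).sum()
    ratio, weights = core.stratified_ratio_normalization(df, df)
    assert ratio == pytest.approx(raw, rel=1e-6)
    assert weights == pytest.approx(np.ones(400) * weights.mean(), rel=1e-6)


def test_stratified_ratio_normalization_reweights():
    # subset all-low fmc, reference uniform; after matching the reference
    # composition the high-fmc strata (absent in subset) are merged away
    # and the ratio reflects subset direction mix unchanged within strata.
    sub = pd.DataFrame(
        {"fmc_D": [0.05] * 6 + [0.15] * 4,
         "direction": [INCREASE] * 6 + [DECREASE] * 4}
    )
    ref = pd.DataFrame(
        {"fmc_D": [0.05] * 5 + [0.15] * 5, "direction": [INCREASE] * 10}
    )
    ratio, _ = core.stratified_ratio_normalization(sub, ref)
    # equal stratum weights -> I weight 6*(5/6), D weight 4*(5/4) -> ratio 1
    assert ratio == pytest.approx(1.0, abs=1e-6)


def test_cpg_adjusted_correlation_perfect():
    loci = _loci([
        ["chr1", 0, 2, 100, 20, 100, 20, 100, 20, 100, 20],
        ["chr1", 100, 4, 100, 50, 100, 50, 100, 50, 100, 50],
        ["chr1", 200, 5, 100, 80, 100, 80, 100, 80, 100, 80],
    ])
    windows = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "pos": [0, 100, 200],
         # coverage proportional to fmc * n_cpg -> adjusted coverage == fmc
         "coverage": [0.2 * 2, 0.5 * 4, 0.8 * 5]}
    )
    r, merged = core.cpg_adjusted_correlation(windows, loci)
    assert r == pytest.approx(1.0)
    assert len(merged) == 3
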