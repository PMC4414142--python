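"""Locus/peak filtering, methylation-change classification and
MeCap–RRBS concordance.

Direction conventions
---------------------
The canonical change direction everywhere in the package is *increase in
the poor-responder (older) group*.  For RRBS loci the per-replicate delta
is ``fmc_D − fmc_PR`` (donor minus poor responder), so an *increase* has
negative delta.  For MeCap peaks the fold change is
``mean(enr_PR) / mean(enr_D)``, so an *increase* has fold > 1.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as mio
from .genome import GenomicInterval, build_overlap_index
from .stats import ContingencyResult, contingency_vs_reference, ttest_rows

log = logging.getLogger(__name__)

INCREASE = "increase"
DECREASE = "decrease"
NONE = "none"

READ_LEN = 36


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def locus_pass_filter(loci: pd.DataFrame, min_cpg: int = 2, min_depth: int = 20) -> pd.Series:
    """Per-locus inclusion mask: >= ``min_cpg`` CpGs in the 36-bp window and
    every *present* (group, replicate) depth >= ``min_depth``.

    Missing (NaN) depth cells do not fail the filter; a locus entirely
    without depth data fails it.
    """
    depth_cols = [c for c in loci.columns if c.startswith("depth_")]
    depths = loci[depth_cols].to_numpy(dtype=float)
    any_present = np.isfinite(depths).any(axis=1)
    deep_enough = np.nanmin(np.where(np.isfinite(depths), depths, np.inf), axis=1) >= min_depth
    ok = (loci["n_cpg"].to_numpy() >= min_cpg) & any_present & deep_enough
    return pd.Series(ok, index=loci.index, name="pass_filter")


# ---------------------------------------------------------------------------
# change classification
# ---------------------------------------------------------------------------

def classify_locus_change(
    loci: pd.DataFrame,
    min_abs_delta: float = 0.0,
    require_consistency: bool = True,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Classify per-locus methylation change between groups D and PR.

    Returns a DataFrame aligned with ``loci`` carrying:

    ``delta``
        Mean over replicates of per-replicate ``fmc_D − fmc_PR``.
    ``consistent``
        All per-replicate deltas strictly share a sign.
    ``p``
        Two-sided independent t-test of per-replicate fmc_D vs fmc_PR
        (NaN when undefined, e.g. single replicates).
    ``significant``
        ``p < alpha`` (False where p is NaN or no alpha gate requested).
    ``direction``
        ``increase`` (delta < 0), ``decrease`` (delta > 0) or ``none``;
        gated by ``min_abs_delta``, consistency and significance as
        requested.
    """
    fmc_d = mio.rrbs_fmc(loci, "D").to_numpy(dtype=float)
    fmc_pr = mio.rrbs_fmc(loci, "PR").to_numpy(dtype=float)
    if fmc_d.shape[1] == 0 or fmc_pr.shape[1] == 0:
        raise ValueError("loci table lacks replicate columns for one of the groups")
    n_rep = min(fmc_d.shape[1], fmc_pr.shape[1])
    deltas = fmc_d[:, :n_rep] - fmc_pr[:, :n_rep]  # paired by replicate index
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_delta = np.nanmean(deltas, axis=1)
    finite = np.isfinite(deltas)
    n_finite = finite.sum(axis=1)
    all_pos = np.where(finite, deltas > 0, True).all(axis=1) & (n_finite > 0)
    all_neg = np.where(finite, deltas < 0, True).all(axis=1) & (n_finite > 0)
    consistent = all_pos | all_neg

    single = int((n_finite <= 1).sum())
    if single and (require_consistency or alpha is not None):
        log.warning(
            "%d loci have a single replicate pair; degrading to single-experiment "
            "mode for them (t-test undefined, treated as not significant)", single
        )
    p = ttest_rows(fmc_d, fmc_pr)
    significant = (p < alpha) if alpha is not None else np.zeros(len(loci), dtype=bool)
    significant = np.where(np.isfinite(p), significant, False)

    direction = np.where(mean_delta < 0, INCREASE, DECREASE)
    gate = np.abs(mean_delta) >= min_abs_delta
    gate &= np.isfinite(mean_delta) & (mean_delta != 0)
    if require_consistency:
        gate &= consistent
    if alpha is not None:
        gate &= significant.astype(bool)
    direction = np.where(gate, direction, NONE)

    return pd.DataFrame(
        {
            "delta": mean_delta,
            "consistent": consistent,
            "p": p,
            "significant": significant.astype(bool),
            "direction": direction,
        },
        index=loci.index,
    )


def classify_peak_change(
    peaks: pd.DataFrame,
    min_enrichment: float = 15.0,
    min_fold: float = 1.0,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Classify per-peak MeCap enrichment change between groups.

    A peak is *eligible* iff max(mean enr_D, mean enr_PR) >= ``min_enrichment``.
    The fold change mean(enr_PR)/mean(enr_D) is gated by ``min_fold`` (and
    its reciprocal for decreases) and, when >= 2 experiments and ``alpha``
    given, a two-sided t-test on log enrichments.  With duplicate
    experiments (as typical for MeCap) the t-test has very low power; this
    is honoured but logged.
    """
    d_cols = sorted(c for c in peaks.columns if c.startswith("enr_D_"))
    pr_cols = sorted(c for c in peaks.columns if c.startswith("enr_PR_"))
    if not d_cols or not pr_cols:
        raise ValueError("peak table lacks enr_D_*/enr_PR_* columns")
    enr_d = peaks[d_cols].to_numpy(dtype=float)
    enr_pr = peaks[pr_cols].to_numpy(dtype=float)
    mean_d = np.nanmean(enr_d, axis=1)
    mean_pr = np.nanmean(enr_pr, axis=1)
    eligible = np.fmax(mean_d, mean_pr) >= min_enrichment

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_pr / mean_d
    unbounded = (mean_d == 0) & (mean_pr > 0)

    if alpha is not None:
        if enr_d.shape[1] == 2:
            log.warning("t-test on duplicate experiments has low power")
        with np.errstate(divide="ignore"):
            p = ttest_rows(np.log(np.maximum(enr_d, 1e-12)), np.log(np.maximum(enr_pr, 1e-12)))
        significant = np.where(np.isfinite(p), p < alpha, False)
    else:
        p = np.full(len(peaks), np.nan)
        significant = np.ones(len(peaks), dtype=bool)

    direction = np.full(len(peaks), NONE, dtype=object)
    inc = eligible & significant & ((fold >= min_fold) & (fold > 1) | unbounded)
    dec = eligible & significant & (fold <= 1 / min_fold) & (fold < 1) & ~unbounded
    direction[inc] = INCREASE
    direction[dec] = DECREASE

    return pd.DataFrame(
        {
            "mean_enr_D": mean_d,
            "mean_enr_PR": mean_pr,
            "fold": fold,
            "unbounded_fold": unbounded,
            "eligible": eligible,
            "p": p,
            "significant": np.asarray(significant, dtype=bool),
            "direction": direction,
        },
        index=peaks.index,
    )


def change_histogram(values: Sequence[float], bin_width: float = 0.05,
                     vmin: float | None = None, vmax: float | None = None) -> pd.DataFrame:
    """Histogram of change values (delta fmc or log2 fold) in fixed-width
    bins; bins are [lo, hi), the value 0 falls in the bin starting at 0.

    Returns columns ``bin_lo, bin_hi, count``; counts sum to the number of
    finite input values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return pd.DataFrame({"bin_lo": [], "bin_hi": [], "count": []})
    lo = vmin if vmin is not None else np.floor(v.min() / bin_width) * bin_width
    hi = vmax if vmax is not None else np.floor(v.max() / bin_width) * bin_width + bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    idx = np.clip(np.floor((v - lo) / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})


# ---------------------------------------------------------------------------
# MeCap <-> RRBS concordance
# ---------------------------------------------------------------------------

def rrbs_within_peaks_test(
    loci: pd.DataFrame,
    calls: pd.DataFrame,
    peaks: pd.DataFrame,
    peak_mask: Sequence[bool],
    read_len: int = READ_LEN,
) -> ContingencyResult:
    """I/D ratio of RRBS loci falling inside selected MeCap peaks, with a
    Fisher probability against the full consistent-change reference set.

    ``calls`` must come from :func:`classify_locus_change` on ``loci``;
    the reference set is all loci with direction != none, the subset those
    whose 36-bp window overlaps any peak where ``peak_mask`` is True.
    """
    directed = calls["direction"] != NONE
    ref_i = int(((calls["direction"] == INCREASE) & directed).sum())
    ref_d = int(((calls["direction"] == DECREASE) & directed).sum())

    sel = peaks.loc[np.asarray(peak_mask, dtype=bool)]
    feats = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), i)
        for i, r in enumerate(sel.itertuples(index=False))
    ]
    index = build_overlap_index(feats)
    in_peak = np.fromiter(
        (
            len(index.query(c, int(p), int(p) + read_len)) > 0
            for c, p in zip(loci["chrom"], loci["pos"])
        ),
        dtype=bool,
        count=len(loci),
    )
    sub = directed.to_numpy() & in_peak
    sub_i = int((calls["direction"].to_numpy() == INCREASE)[sub].sum())
    sub_d = int((calls["direction"].to_numpy() == DECREASE)[sub].sum())
    if sub_i + sub_d == 0:
        raise ValueError("no overlapping loci: subset is empty")
    return contingency_vs_reference(sub_i, sub_d, ref_i, ref_d)


def stratified_ratio_normalization(
    subset: pd.DataFrame,
    reference: pd.DataFrame,
    n_bins: int = 10,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> tuple[float, np.ndarray]:
    """I/D ratio of a locus subset after reweighting to the reference's
    donor-methylation composition.

    Both frames need columns ``fmc_D`` (donor group mean methylation) and
    ``direction``.  Subset loci are binned by donor fmc into ``n_bins``
    equal-width strata and iteratively reweighted (proportional fitting)
    until the subset's weighted stratum proportions match the reference's
    and the I/D ratio moves by less than ``tol``.  Empty reference strata
    are merged into their lower neighbour with a warning.

    Returns (normalized ratio, per-locus weights).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)

    def bin_of(fmc: np.ndarray) -> np.ndarray:
        b = np.clip(np.digitize(fmc, edges[1:-1]), 0, n_bins - 1)
        return b

    ref_bins = bin_of(reference["fmc_D"].to_numpy(dtype=float))
    sub_bins = bin_of(subset["fmc_D"].to_numpy(dtype=float))
    ref_prop = np.bincount(ref_bins, minlength=n_bins).astype(float)
    sub_count = np.bincount(sub_bins, minlength=n_bins).astype(float)

    # merge strata the reference cannot inform into the nearest lower
    # occupied stratum (lowest stratum merges upward)
    merge_to = np.arange(n_bins)
    for b in range(n_bins):
        if ref_prop[b] == 0 and sub_count[b] > 0:
            log.warning("empty reference stratum %d merged with neighbour", b)
            neighbours = [j for j in range(n_bins) if ref_prop[j] > 0]
            if not neighbours:
                raise ValueError("reference has no occupied strata")
            merge_to[b] = min(neighbours, key=lambda j: abs(j - b))
    ref_bins = merge_to[ref_bins]
    sub_bins = merge_to[sub_bins]
    ref_prop = np.bincount(ref_bins, minlength=n_bins).astype(float)
    ref_prop /= ref_prop.sum()

    inc = (subset["direction"] == INCREASE).to_numpy()
    dec = (subset["direction"] == DECREASE).to_numpy()
    weights = np.ones(len(subset), dtype=float)
    prev_ratio = np.inf
    ratio = np.nan
    for _ in range(max_iter):
        wsum = np.bincount(sub_bins, weights=weights, minlength=n_bins)
        total = weights.sum()
        factor = np.ones(n_bins)
        occupied = wsum > 0
        factor[occupied] = (ref_prop[occupied] * total) / wsum[occupied]
        weights = weights * factor[sub_bins]
        wi = float(weights[inc].sum())
        wd = float(weights[dec].sum())
        if wd == 0:
            raise ValueError("no decrease loci in subset after reweighting")
        ratio = wi / wd
        if abs(ratio - prev_ratio) < tol:
            break
        prev_ratio = ratio
    return ratio, weights


def cpg_adjusted_correlation(windows: pd.DataFrame, loci: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between CpG-density-adjusted MeCap coverage and
    RRBS fractional methylation over directly overlapping 36-bp windows.

    ``windows`` needs columns ``chrom, pos, coverage``; ``loci`` needs
    ``chrom, pos, n_cpg`` plus donor replicate columns.  Adjusted coverage
    is raw coverage / window CpG count.  Returns (r, paired table).
    """
    fmc = mio.rrbs_fmc(loci, "D").mean(axis=1)
    left = loci[["chrom", "pos", "n_cpg"]].assign(fmc_D=fmc)
    merged = left.merge(windows[["chrom", "pos", "coverage"]], on=["chrom", "pos"])
    if len(merged) < 2:
        raise ValueError("fewer than 2 overlapping windows")
    merged["adjusted_coverage"] = merged["coverage"] / merged["n_cpg"]
    r = float(sps.pearsonr(merged["adjusted_coverage"], merged["fmc_D"])[0])
    return r, merged
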