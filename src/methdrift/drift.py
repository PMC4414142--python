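"""Age-related methylation drift: bimodal level distribution and per-bin
increase/decrease ratios as a function of baseline (donor) methylation.

Loci are binned by the donor-group mean fractional methylation with
half-open bins [lo, hi); the final bin is closed at 1.0.  The reference
for per-bin Fisher tests is the full consistent-change locus set and, by
default, includes the bin under test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import io as mio
from .core import DECREASE, INCREASE, NONE
from .stats import fisher_exact_2x2

__all__ = [
    "methylation_histogram",
    "restricted_histogram",
    "drift_table",
    "drift_heatmap_matrix",
]


def donor_fmc(loci: pd.DataFrame) -> pd.Series:
    """Donor-group mean fractional methylation per locus."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return mio.rrbs_fmc(loci, "D").mean(axis=1)


def _bin_index(fmc: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    n_bins = int(round(1.0 / bin_width))
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 1 evenly")
    idx = np.floor(fmc / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # fmc == 1.0 joins the last bin
    return idx, n_bins


def methylation_histogram(loci: pd.DataFrame, bin_width: float = 0.05) -> pd.DataFrame:
    """Percentage of loci per donor-methylation bin.

    Returns columns ``bin_lo, bin_hi, count, percent``; percentages sum
    to 100 (up to 1e-9).
    """
    fmc = donor_fmc(loci).to_numpy(dtype=float)
    fmc = fmc[np.isfinite(fmc)]
    if len(fmc) == 0:
        raise ValueError("no loci with donor methylation values")
    idx, n_bins = _bin_index(fmc, bin_width)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "percent": 100.0 * counts / counts.sum(),
        }
    )


def restricted_histogram(
    loci: pd.DataFrame, calls: pd.DataFrame, min_abs_delta: float = 0.075,
    bin_width: float = 0.05
) -> pd.DataFrame:
    """Donor-methylation histogram restricted to loci with consistent
    change of at least ``min_abs_delta`` in magnitude."""
    keep = calls["consistent"].to_numpy() & (
        np.abs(calls["delta"].to_numpy()) >= min_abs_delta
    )
    return methylation_histogram(loci.loc[keep], bin_width=bin_width)


def drift_table(
    loci: pd.DataFrame,
    calls: pd.DataFrame,
    bin_width: float = 0.05,
    min_bin_count: int = 20,
    reference: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-donor-methylation-bin increase/decrease counts, I/D ratio and
    Fisher probability against the reference set.

    ``calls`` is the output of ``classify_locus_change``; only loci with a
    direction (increase or decrease) enter the table.  ``reference``
    defaults to the (I, D) totals over all such loci.  Bins with fewer
    than ``min_bin_count`` directed loci are suppressed.
    """
    direction = calls["direction"].to_numpy()
    directed = direction != NONE
    fmc = donor_fmc(loci).to_numpy(dtype=float)
    ok = directed & np.isfinite(fmc)
    if reference is None:
        ref_i = int((direction[ok] == INCREASE).sum())
        ref_d = int((direction[ok] == DECREASE).sum())
    else:
        ref_i, ref_d = int(reference[0]), int(reference[1])
    if ref_d == 0:
        raise ValueError("reference set has zero decrease loci")

    idx, n_bins = _bin_index(fmc[ok], bin_width)
    inc = direction[ok] == INCREASE
    i_counts = np.bincount(idx[inc], minlength=n_bins)
    d_counts = np.bincount(idx[~inc], minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width

    rows = []
    for b in range(n_bins):
        i, d = int(i_counts[b]), int(d_counts[b])
        if i + d < min_bin_count:
            continue
        ratio = i / d if d else np.inf
        p = fisher_exact_2x2(i, d, ref_i, ref_d)
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n_increase": i,
                "n_decrease": d,
                "id_ratio": ratio,
                "fisher_p": p,
                "i_fraction": i / (i + d),
            }
        )
    out = pd.DataFrame(rows, columns=[
        "bin_lo", "bin_hi", "n_increase", "n_decrease", "id_ratio", "fisher_p", "i_fraction",
    ])
    out.attrs["reference"] = (ref_i, ref_d)
    out.attrs["reference_ratio"] = ref_i / ref_d
    return out


def drift_heatmap_matrix(
    datasets: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    bin_width: float = 0.05,
    min_bin_count: int = 200,
    statistic: str = "mean_delta",
) -> pd.DataFrame:
    """Signed per-bin change-intensity matrix: one row per dataset, one
    column per donor-methylation bin.

    ``datasets`` maps name -> (loci, calls).  ``statistic`` is
    ``mean_delta`` (mean signed −delta, positive = increase in poor
    responders) or ``id_fraction`` (I − D as a fraction of directed loci).
    Cells from bins under ``min_bin_count`` loci are NaN.
    """
    n_bins = int(round(1.0 / bin_width))
    cols = [f"{b * bin_width:.2f}" for b in range(n_bins)]
    rows = {}
    for name, (loci, calls) in datasets.items():
        fmc = donor_fmc(loci).to_numpy(dtype=float)
        direction = calls["direction"].to_numpy()
        delta = calls["delta"].to_numpy(dtype=float)
        ok = np.isfinite(fmc)
        idx, _ = _bin_index(fmc[ok], bin_width)
        vals = np.full(n_bins, np.nan)
        for b in range(n_bins):
            m = idx == b
            if m.sum() < min_bin_count:
                continue
            if statistic == "mean_delta":
                # sign flipped so positive = higher methylation in PR
                vals[b] = -np.nanmean(delta[ok][m])
            elif statistic == "id_fraction":
                i = (direction[ok][m] == INCREASE).sum()
                d = (direction[ok][m] == DECREASE).sum()
                vals[b] = (i - d) / (i + d) if (i + d) else np.nan
            else:
                raise ValueError(f"unknown statistic {statistic!r}")
        rows[name] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
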