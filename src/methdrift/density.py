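"""Per-gene methylome-feature densities, GC-rich coverage and the
quintile down/up-ratio analysis.

bsDens — the bisulfite read-position density of a gene — is
``100 * (number of 36-bp loci within the gene * 36) / gene length``; the
MeCap peak density is the analogous quantity with each peak's actual
width.  Both act as proxies for intragenic GC/CpG density.  A locus is
"within the gene" when its 36-bp window midpoint lies in [start, end).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import READ_LEN
from .drift import donor_fmc
from .genome import GeneModel, GenomicInterval, build_overlap_index
from .stats import fisher_exact_2x2

__all__ = [
    "compute_bsdens",
    "compute_gene_density",
    "compute_gc_rich_coverage",
    "quintile_di_table",
    "gene_subset",
]


def compute_bsdens(gene_length: int, n_loci: int, read_len: int = READ_LEN) -> float:
    """bsDens = 100 * n_loci * read_len / gene_length (not clamped at 100)."""
    if gene_length <= 0:
        raise ValueError("zero-length gene")
    return 100.0 * n_loci * read_len / gene_length


def compute_gene_density(
    genes: list[GeneModel],
    loci: pd.DataFrame | None = None,
    peaks: pd.DataFrame | None = None,
    read_len: int = READ_LEN,
) -> pd.DataFrame:
    """Per-gene density metrics from RRBS loci and/or MeCap peaks.

    Returns a DataFrame indexed by gene_id with columns ``length``,
    ``n_loci``, ``bsdens``, ``mean_meth`` (mean donor fmc of intragenic
    loci), ``pos_min``/``pos_max`` (oriented fractional positions of the
    most 5′/3′-proximal locus midpoints), ``n_peaks`` and
    ``peak_density``.  Loci are assigned by window midpoint; a feature
    overlapping several (nested) genes counts once in each.
    """
    gene_index = build_overlap_index(
        [GenomicInterval(g.chrom, g.start, g.end, k) for k, g in enumerate(genes)]
    )
    n = len(genes)
    out = pd.DataFrame(
        {
            "length": [g.length for g in genes],
            "n_loci": 0,
            "bsdens": 0.0,
            "mean_meth": np.nan,
            "pos_min": np.nan,
            "pos_max": np.nan,
            "n_peaks": 0,
            "peak_density": 0.0,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    if loci is not None and len(loci):
        fmc = donor_fmc(loci).to_numpy(dtype=float)
        n_loci = np.zeros(n, dtype=int)
        meth_sum = np.zeros(n)
        meth_n = np.zeros(n, dtype=int)
        pos_min = np.full(n, np.inf)
        pos_max = np.full(n, -np.inf)
        mids = loci["pos"].to_numpy(dtype=int) + read_len // 2
        chroms = loci["chrom"].to_numpy()
        for j in range(len(loci)):
            for k in gene_index.query_point(chroms[j], int(mids[j])):
                n_loci[k] += 1
                frac = genes[k].oriented_fraction(int(mids[j]))
                pos_min[k] = min(pos_min[k], frac)
                pos_max[k] = max(pos_max[k], frac)
                if np.isfinite(fmc[j]):
                    meth_sum[k] += fmc[j]
                    meth_n[k] += 1
        out["n_loci"] = n_loci
        out["bsdens"] = [
            compute_bsdens(genes[k].length, int(n_loci[k]), read_len) for k in range(n)
        ]
        with np.errstate(invalid="ignore"):
            out["mean_meth"] = np.where(meth_n > 0, meth_sum / np.maximum(meth_n, 1), np.nan)
        out["pos_min"] = np.where(np.isfinite(pos_min), pos_min, np.nan)
        out["pos_max"] = np.where(np.isfinite(pos_max), pos_max, np.nan)
    if peaks is not None and len(peaks):
        n_peaks = np.zeros(n, dtype=int)
        width_sum = np.zeros(n)
        for row in peaks.itertuples(index=False):
            center = (int(row.start) + int(row.end)) // 2
            for k in gene_index.query_point(row.chrom, center):
                n_peaks[k] += 1
                width_sum[k] += int(row.end) - int(row.start)
        out["n_peaks"] = n_peaks
        out["peak_density"] = 100.0 * width_sum / out["length"].to_numpy()
    return out


def compute_gc_rich_coverage(
    sequence: str, window: int = 100, gc_threshold: float = 0.5
) -> float:
    """Percentage of a sequence covered by GC-rich sliding windows.

    A window of ``window`` bp (step 1) is GC-rich when its G+C fraction
    exceeds ``gc_threshold`` (N counts as non-GC); a base is covered when
    any window containing it is GC-rich.  Sequences shorter than the
    window are evaluated as a single whole-sequence window.
    """
    seq = sequence.upper()
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((gc == ord("G")) | (gc == ord("C"))).astype(np.int64)
    if L < window:
        frac = is_gc.sum() / L
        return 100.0 if frac > gc_threshold else 0.0
    csum = np.concatenate([[0], np.cumsum(is_gc)])
    win_gc = (csum[window:] - csum[:-window]) / window  # window i covers [i, i+window)
    passing = win_gc > gc_threshold
    pass_csum = np.concatenate([[0], np.cumsum(passing)])
    n_windows = L - window + 1
    j = np.arange(L)
    lo = np.maximum(0, j - window + 1)
    hi = np.minimum(j, n_windows - 1)
    covered = (pass_csum[hi + 1] - pass_csum[lo]) > 0
    covered &= lo <= hi
    return 100.0 * covered.sum() / L


def quintile_di_table(
    density: pd.DataFrame,
    classes: pd.Series,
    metric: str = "bsdens",
    n_bins: int = 5,
) -> pd.DataFrame:
    """Down/up-gene-count ratio per density quintile, with Fisher tests
    against the whole reference set.

    The reference set is every gene with a valid expression class and at
    least one methylome feature of the chosen metric.  Genes are sorted
    by the metric (ties broken by gene_id for determinism) and split into
    ``n_bins`` equal-count bins, remainder genes going to the lowest
    bins.  Each bin reports the median metric, (n_down, n_up), the D/I
    ratio, and the two-sided Fisher probability of its pair against the
    reference totals.
    """
    feature_col = "n_loci" if metric == "bsdens" else "n_peaks"
    classes = classes.reindex(density.index)
    ref = density.loc[classes.notna().to_numpy() & (density[feature_col] > 0)]
    if len(ref) < n_bins:
        raise ValueError(f"need at least {n_bins} genes, got {len(ref)}")
    cls = classes.reindex(ref.index)
    order = ref.assign(_gid=ref.index.astype(str)).sort_values(
        [metric, "_gid"], kind="stable"
    )
    # equal-count split; remainder distributed to the lowest quintiles
    base, rem = divmod(len(order), n_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
    ref_down = int((cls == "down").sum())
    ref_up = int((cls == "up").sum())
    rows = []
    pos = 0
    for b, size in enumerate(sizes):
        idx = order.index[pos:pos + size]
        pos += size
        sub_cls = cls.reindex(idx)
        n_down = int((sub_cls == "down").sum())
        n_up = int((sub_cls == "up").sum())
        rows.append(
            {
                "quintile": b + 1,
                "n_genes": size,
                "median_metric": float(order[metric].iloc[pos - size:pos].median()),
                "n_down": n_down,
                "n_up": n_up,
                "di_ratio": n_down / n_up if n_up else np.inf,
                "fisher_p": fisher_exact_2x2(n_down, n_up, ref_down, ref_up),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["reference"] = (ref_down, ref_up)
    out.attrs["n_reference_genes"] = len(ref)
    return out


def gene_subset(density: pd.DataFrame, criterion: str) -> pd.Index:
    """Gene ids matching a positional/methylation criterion.

    Criteria (genes without loci never match):

    - ``meth_lo`` / ``meth_hi``: mean intragenic donor methylation < / > 0.5
    - ``five_prime_quartile``: all loci within the first quarter of
      oriented gene length (pos_max < 0.25)
    - ``three_prime_quartile``: all loci within the last quarter
      (pos_min > 0.75)
    - ``quartile_1`` .. ``quartile_4``: all loci within that quartile
    - ``dens_hi``: bsDens > 0.5

    Compose subsets by intersecting the returned indexes.
    """
    has = density["n_loci"] > 0
    if criterion == "meth_lo":
        mask = has & (density["mean_meth"] < 0.5)
    elif criterion == "meth_hi":
        mask = has & (density["mean_meth"] > 0.5)
    elif criterion == "five_prime_quartile":
        mask = has & (density["pos_max"] < 0.25)
    elif criterion == "three_prime_quartile":
        mask = has & (density["pos_min"] > 0.75)
    elif criterion.startswith("quartile_"):
        k = int(criterion.split("_")[1])
        if not 1 <= k <= 4:
            raise ValueError(f"quartile index out of range: {criterion}")
        lo, hi = (k - 1) / 4.0, k / 4.0
        upper = density["pos_max"] <= hi if k == 4 else density["pos_max"] < hi
        mask = has & (density["pos_min"] >= lo) & upper
    elif criterion == "dens_hi":
        mask = has & (density["bsdens"] > 0.5)
    else:
        raise ValueError(f"unknown subset criterion: {criterion!r}")
    return density.index[mask.fillna(False)]
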