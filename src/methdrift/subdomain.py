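"""Gene-subdomain localisation of methylation enrichment and its
association with the direction of expression change.

Expression classes follow the thresholds used throughout: *down*/*up*
need FDR < 0.05 and |logFC| > 0.5 (sign decides); *minimal* needs
FDR > 0.05 and |logFC| < 0.3; anything else is *excluded*.

Subdomains are assigned from the strand-oriented distance of the
methylation-enrichment centre to the TSS/TES anchors, with precedence
three_prime_subregion > three_prime > five_prime > mid so that short
genes (centre close to both anchors) resolve deterministically toward
the 3′ end, the focus of the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval, build_overlap_index, oriented_distances
from .stats import ContingencyResult, contingency_vs_reference

log = logging.getLogger(__name__)

DOWN, UP, MINIMAL, EXCLUDED = "down", "up", "minimal", "excluded"
FIVE_PRIME, MID, THREE_PRIME, SUBREGION, CONTROL, OTHER = (
    "five_prime", "mid", "three_prime", "three_prime_subregion", "control", "other",
)
SUBDOMAINS = (FIVE_PRIME, MID, THREE_PRIME, SUBREGION)


@dataclass(frozen=True)
class SubdomainParams:
    """Distance windows (bp, transcription-oriented) defining subdomains."""

    tss_window: int = 2000
    tes_window: int = 2000
    mid_margin: int = 3000
    subregion: tuple[int, int] = (-1300, -500)  # upstream of TES, inside gene


def classify_expression(
    logfc: float, fdr: float, fdr_max: float = 0.05, lfc_min: float = 0.5,
    minimal_lfc: float = 0.3,
) -> str:
    """Expression class of one gene from its logFC and FDR."""
    if fdr < fdr_max and abs(logfc) > lfc_min:
        return DOWN if logfc < 0 else UP
    if fdr > fdr_max and abs(logfc) < minimal_lfc:
        return MINIMAL
    return EXCLUDED


def classify_expression_table(expr: pd.DataFrame, **thresholds) -> pd.Series:
    """Vectorised expression classes for a (gene_id, logFC, FDR) table."""
    fdr_max = thresholds.get("fdr_max", 0.05)
    lfc_min = thresholds.get("lfc_min", 0.5)
    minimal_lfc = thresholds.get("minimal_lfc", 0.3)
    logfc = expr["logFC"].to_numpy(dtype=float)
    fdr = expr["FDR"].to_numpy(dtype=float)
    cls = np.full(len(expr), EXCLUDED, dtype=object)
    sig = (fdr < fdr_max) & (np.abs(logfc) > lfc_min)
    cls[sig & (logfc < 0)] = DOWN
    cls[sig & (logfc >= 0)] = UP
    cls[(fdr > fdr_max) & (np.abs(logfc) < minimal_lfc)] = MINIMAL
    return pd.Series(cls, index=expr.index, name="expr_class")


def classify_enrichment_location(
    gene: GeneModel, center: int, params: SubdomainParams = SubdomainParams(),
    chrom: str | None = None,
) -> str:
    """Subdomain of a methylation-enrichment centre relative to a gene.

    Distances are strand-oriented; the 3′ subregion is one-sided (inside
    the gene body, upstream of the TES), while the 5′/3′-end windows span
    both sides of their anchor.
    """
    if chrom is not None and chrom != gene.chrom:
        raise ValueError(
            f"chromosome mismatch: peak on {chrom}, gene {gene.gene_id} on {gene.chrom}"
        )
    dist_tss, dist_tes = oriented_distances(gene, center)
    lo, hi = params.subregion
    if lo <= dist_tes <= hi:
        return SUBREGION
    if abs(dist_tes) <= params.tes_window:
        return THREE_PRIME
    inside = gene.contains(center)
    if inside and 0 <= dist_tss <= params.tss_window:
        return FIVE_PRIME
    if inside and dist_tss > params.mid_margin and abs(dist_tes) > params.mid_margin:
        return MID
    return OTHER


def assign_gene_subdomains(
    genes: list[GeneModel],
    peaks: pd.DataFrame,
    min_enrichment: float = 5.0,
    params: SubdomainParams = SubdomainParams(),
    exclusive: bool = False,
) -> pd.DataFrame:
    """Per-gene subdomain membership from enriched-region centres.

    Peaks pass the enrichment gate when the larger of the two group mean
    enrichments is >= ``min_enrichment``; the peak centre is the interval
    midpoint.  A gene may belong to several subdomains (one per
    overlapping enriched region) unless ``exclusive``, in which case only
    the highest-precedence subdomain is kept.  Returns a boolean
    DataFrame indexed by gene_id with one column per subdomain plus
    ``any_peak`` (overlap with any enriched region, used for the control
    definition).
    """
    d_cols = [c for c in peaks.columns if c.startswith("enr_D_")]
    pr_cols = [c for c in peaks.columns if c.startswith("enr_PR_")]
    if d_cols and pr_cols:
        mean_d = peaks[d_cols].mean(axis=1)
        mean_pr = peaks[pr_cols].mean(axis=1)
        passing = peaks.loc[np.fmax(mean_d, mean_pr) >= min_enrichment]
    else:
        passing = peaks
    margin = max(params.tes_window, params.tss_window)
    index = build_overlap_index(
        [
            GenomicInterval(g.chrom, g.start - margin, g.end + margin, k)
            for k, g in enumerate(genes)
        ]
    )
    member = pd.DataFrame(
        False,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=list(SUBDOMAINS) + ["any_peak"],
    )
    any_col = member.columns.get_loc("any_peak")
    precedence = {SUBREGION: 0, THREE_PRIME: 1, FIVE_PRIME: 2, MID: 3}
    best: dict[int, int] = {}
    hits: dict[int, set[str]] = {}
    for row in passing.itertuples(index=False):
        center = (int(row.start) + int(row.end)) // 2
        for k in index.query_point(row.chrom, center):
            g = genes[k]
            # genuine intersection with the gene span marks the gene as
            # peak-overlapped (excluding it from the control set)
            if int(row.end) > g.start and int(row.start) < g.end:
                member.iloc[k, any_col] = True
            sd = classify_enrichment_location(g, center, params)
            if sd == OTHER:
                continue
            member.iloc[k, any_col] = True
            if exclusive:
                rank = precedence[sd]
                if k not in best or rank < best[k]:
                    best[k] = rank
                    hits[k] = {sd}
            else:
                hits.setdefault(k, set()).add(sd)
    for k, sds in hits.items():
        for sd in sds:
            member.iloc[k, member.columns.get_loc(sd)] = True
    return member


def subdomain_contingency(
    membership: pd.DataFrame,
    classes: pd.Series,
) -> dict[str, ContingencyResult]:
    """Per-subdomain (n_down, n_up) vs control Fisher contingency.

    ``membership`` is the output of :func:`assign_gene_subdomains`;
    ``classes`` maps gene_id -> expression class.  Only down/up genes
    enter.  Control genes have significant expression change and no
    overlap with any enriched region.
    """
    classes = classes.reindex(membership.index)
    is_down = (classes == DOWN).to_numpy()
    is_up = (classes == UP).to_numpy()
    de = is_down | is_up
    control = de & ~membership["any_peak"].to_numpy()
    ctrl_down = int((control & is_down).sum())
    ctrl_up = int((control & is_up).sum())
    if ctrl_down + ctrl_up == 0:
        raise ValueError("empty control set")
    out: dict[str, ContingencyResult] = {}
    out[CONTROL] = ContingencyResult(ctrl_down, ctrl_up, ctrl_down, ctrl_up, 1.0)
    for sd in SUBDOMAINS:
        in_sd = membership[sd].to_numpy() & de
        n_down = int((in_sd & is_down).sum())
        n_up = int((in_sd & is_up).sum())
        out[sd] = contingency_vs_reference(n_down, n_up, ctrl_down, ctrl_up)
    return out


def metagene_profile(
    track: pd.DataFrame,
    genes: list[GeneModel],
    classes: pd.Series,
    anchor: str = "TES",
    window_bp: int = 2000,
    step_bp: int = 50,
) -> pd.DataFrame:
    """Mean track value per oriented-distance bin, per expression class.

    ``track`` is a bedGraph DataFrame (positions without coverage count
    as 0).  Distances run −window..+window in steps of ``step_bp``
    (2·window/step + 1 bins); negative TES distance is inside the gene
    body, negative TSS distance is upstream of the gene.  Returns a
    DataFrame indexed by oriented distance with one column per class.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    dists = np.arange(-window_bp, window_bp + 1, step_bp)
    by_chrom = {
        c: sub.sort_values("start") for c, sub in track.groupby("chrom", sort=False)
    }

    def track_values(chrom: str, positions: np.ndarray) -> np.ndarray:
        sub = by_chrom.get(chrom)
        if sub is None:
            return np.zeros(len(positions))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["value"].to_numpy(dtype=float)
        i = np.searchsorted(starts, positions, side="right") - 1
        ok = (i >= 0) & (positions < ends[np.clip(i, 0, len(ends) - 1)])
        out = np.zeros(len(positions))
        out[ok] = vals[i[ok]]
        return out

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for g in genes:
        cls = classes.get(g.gene_id)
        if cls is None:
            continue
        base = g.tss if anchor == "TSS" else g.tes
        sign = 1 if g.strand == "+" else -1
        positions = base + sign * dists
        vals = track_values(g.chrom, positions)
        if cls not in sums:
            sums[cls] = np.zeros(len(dists))
            counts[cls] = 0
        sums[cls] += vals
        counts[cls] += 1
    cols = {}
    for cls, s in sums.items():
        if counts[cls] == 0:
            log.warning("class %s has zero genes; omitted", cls)
            continue
        cols[cls] = s / counts[cls]
    return pd.DataFrame(cols, index=pd.Index(dists, name="distance"))


def max_difference_window(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    distances: np.ndarray,
    min_width_bins: int = 2,
) -> tuple[float, float, float]:
    """Contiguous distance interval (>= ``min_width_bins`` bins) maximising
    mean(profile_a − profile_b).

    Ties break toward the window whose centre is closest to the anchor
    (distance 0), then the shorter window.  Returns
    (distance_lo, distance_hi, mean_difference).
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    d = a - b
    n = len(d)
    if n < min_width_bins:
        raise ValueError("profile shorter than minimum window width")
    csum = np.concatenate([[0.0], np.cumsum(d)])
    best = None
    for i in range(n):
        for j in range(i + min_width_bins, n + 1):
            mean = (csum[j] - csum[i]) / (j - i)
            center = abs((distances[i] + distances[j - 1]) / 2.0)
            key = (-mean, center, j - i)
            if best is None or key < best[0]:
                best = (key, i, j, mean)
    _, i, j, mean = best
    return float(distances[i]), float(distances[j - 1]), float(mean)
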