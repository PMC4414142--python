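"""Strand-aware gene models and a fast overlapping-feature index.

Coordinates are 0-based, half-open throughout the package (BED native;
1-based formats are converted on read).  The transcription end site (TES)
is anchored on the last transcribed base (``end - 1`` on the + strand,
``start`` on the − strand) so that base-pair distance windows such as
"−1300 to −500 bp from the TES" have a well-defined reference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "GenomicInterval",
    "OverlapIndex",
    "build_overlap_index",
    "oriented_distances",
]


@dataclass(frozen=True)
class GeneModel:
    """A transcription unit with strand-aware TSS/TES anchors.

    Parameters
    ----------
    gene_id : str
        Unique identifier.
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open genomic span; ``start < end``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def oriented_fraction(self, pos: int) -> float:
        """Fractional position along transcription: 0 at TSS, 1 at the TES end."""
        if self.length == 1:
            return 0.0
        if self.strand == "+":
            return (pos - self.start) / (self.length - 1)
        return (self.end - 1 - pos) / (self.length - 1)


@dataclass(frozen=True)
class GenomicInterval:
    """A plain half-open interval carrying an opaque payload identifier."""

    chrom: str
    start: int
    end: int
    payload_id: object = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"malformed interval {self.payload_id!r} "
                f"{self.chrom}:[{self.start}, {self.end}): start must be < end"
            )


class OverlapIndex:
    """Immutable per-chromosome interval index for overlap queries.

    Intervals are stored per chromosome in start-sorted numpy arrays; a
    query binary-searches for candidates with ``start < query_end`` and
    filters them by ``end > query_start``.  Results are identical to an
    exhaustive all-pairs overlap test.
    """

    def __init__(self, features: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        self._features = list(features)
        for f in self._features:
            if not isinstance(f, GenomicInterval):
                f = GenomicInterval(*f)  # type: ignore[misc]
            by_chrom.setdefault(f.chrom, []).append(f)
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, feats in by_chrom.items():
            order = np.argsort([f.start for f in feats], kind="stable")
            starts = np.array([feats[i].start for i in order], dtype=np.int64)
            ends = np.array([feats[i].end for i in order], dtype=np.int64)
            ids = np.array([feats[i].payload_id for i in order], dtype=object)
            self._index[chrom] = (starts, ends, ids)

    def __len__(self) -> int:
        return len(self._features)

    def query(self, chrom: str, start: int, end: int | None = None) -> list:
        """Payload ids of features overlapping ``chrom:[start, end)``.

        A point query (``end`` omitted) is the 1-bp interval ``[start, start+1)``.
        """
        if end is None:
            end = start + 1
        if end <= start:
            raise ValueError(f"query interval [{start}, {end}) is empty")
        entry = self._index.get(chrom)
        if entry is None:
            return []
        starts, ends, ids = entry
        hi = int(np.searchsorted(starts, end, side="left"))
        mask = ends[:hi] > start
        return list(ids[:hi][mask])

    def query_point(self, chrom: str, pos: int) -> list:
        return self.query(chrom, pos, pos + 1)


def build_overlap_index(features: Sequence[GenomicInterval]) -> OverlapIndex:
    """Build an :class:`OverlapIndex`; malformed intervals are rejected
    with the offending record identified (via ``GenomicInterval`` validation).
    """
    return OverlapIndex(features)


def oriented_distances(gene: GeneModel, pos: int) -> tuple[int, int]:
    """Signed distances (bp) from ``pos`` to the gene's TSS and TES,
    measured in transcription orientation.

    Positive values lie downstream of the anchor in the direction of
    transcription; a negative TES distance is upstream of the TES,
    i.e. inside the gene body.

    Raises
    ------
    ValueError
        If the position's chromosome context does not match (checked by
        callers holding chromosome information; this function is purely
        coordinate arithmetic).
    """
    if gene.strand == "+":
        return pos - gene.tss, pos - gene.tes
    return gene.tss - pos, gene.tes - pos


def oriented_distances_checked(gene: GeneModel, chrom: str, pos: int) -> tuple[int, int]:
    """As :func:`oriented_distances` but verifying the chromosome."""
    if chrom != gene.chrom:
        raise ValueError(
            f"chromosome mismatch: position on {chrom}, gene {gene.gene_id} on {gene.chrom}"
        )
    return oriented_distances(gene, pos)
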