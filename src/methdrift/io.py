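"""Readers and writers for gene models, methylation tables and tracks.

Supported inputs
----------------
* Gene models: BED6 or GTF (GTF transcripts of a gene are collapsed to the
  min-start/max-end span).
* RRBS locus tables: Bismark ``.cov`` files (one per group/replicate, merged
  on position) or the package's single-file ``pipeline_tsv`` dialect, which
  carries the per-window CpG count that Bismark coverage files lack.
* MethylCap (MeCap) data: peak tables as BED plus per-experiment enrichment
  columns, and enrichment tracks as bedGraph.
* Differential-expression tables: TSV with gene, logFC, FDR.

All genomic coordinates are converted to 0-based half-open on read.

In-memory containers are pandas DataFrames:

* RRBS loci: columns ``chrom, pos, n_cpg`` plus ``depth_<G><r>`` /
  ``meth_<G><r>`` for each group G in {D, PR} and replicate r (1-based);
  missing cells are NaN, never zero.
* MeCap peaks: ``chrom, start, end`` plus ``enr_D_<e>`` / ``enr_PR_<e>``
  per experiment e.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel

GROUPS = ("D", "PR")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, format: str = "BED6") -> list[GeneModel]:
    """Read gene models from BED6 or GTF.

    GTF gene/transcript records sharing a ``gene_id`` are collapsed to a
    single model spanning min(start)..max(end).
    """
    path = Path(path)
    if format.upper() == "BED6":
        return _read_bed6(path)
    if format.upper() == "GTF":
        return _read_gtf(path)
    raise ValueError(f"unknown gene model format: {format!r}")


def _read_bed6(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs >= 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: zero/negative length record {name}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            genes.append(GeneModel(name, chrom, start, end, strand))
    return genes


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def _read_gtf(path: Path) -> list[GeneModel]:
    spans: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: GTF needs 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "transcript", "exon", "mRNA"):
                continue
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise ValueError(f"{path}:{lineno}: record lacks gene_id attribute")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing strand")
            gid = m.group(1)
            start0, end0 = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if end0 <= start0:
                raise ValueError(f"{path}:{lineno}: zero-length record for {gid}")
            rec = spans.get(gid)
            if rec is None:
                spans[gid] = [chrom, start0, end0, strand]
            else:
                if rec[0] != chrom or rec[3] != strand:
                    raise ValueError(f"gene {gid}: inconsistent chrom/strand across records")
                rec[1] = min(rec[1], start0)
                rec[2] = max(rec[2], end0)
    return [GeneModel(gid, c, s, e, st) for gid, (c, s, e, st) in spans.items()]


def write_gene_models_bed(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        }
    )


# ---------------------------------------------------------------------------
# RRBS locus tables
# ---------------------------------------------------------------------------

def read_rrbs(path_or_mapping, dialect: str = "pipeline_tsv") -> pd.DataFrame:
    """Read an RRBS locus table.

    Parameters
    ----------
    path_or_mapping
        For ``pipeline_tsv``: a single path.  For ``bismark_cov``: a nested
        mapping ``{group: {replicate: path}}`` (replicates 1-based); files
        are merged on (chrom, pos) with absent cells left as NaN.
    dialect : {"pipeline_tsv", "bismark_cov"}
    """
    if dialect == "pipeline_tsv":
        return _read_pipeline_tsv(Path(path_or_mapping))
    if dialect == "bismark_cov":
        return _read_bismark_set(path_or_mapping)
    raise ValueError(f"unknown RRBS dialect: {dialect!r}")


def _read_pipeline_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "n_cpg"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pipeline_tsv needs columns {sorted(required)}")
    _validate_rrbs(df, str(path))
    return df


def _read_bismark_cov(path: Path) -> pd.DataFrame:
    cols = ["chrom", "start1", "end1", "pct", "count_meth", "count_unmeth"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["start1"].astype(int) - 1,  # 1-based -> 0-based
            "meth": df["count_meth"].astype(int),
            "depth": (df["count_meth"] + df["count_unmeth"]).astype(int),
        }
    )
    if (out["meth"] > out["depth"]).any():
        bad = out.index[out["meth"] > out["depth"]][0]
        raise ValueError(f"{path}: methylated count exceeds depth at row {bad}")
    return out


def _read_bismark_set(mapping: Mapping[str, Mapping[int, object]]) -> pd.DataFrame:
    """Merge per-group/replicate Bismark cov files into a wide locus table.

    Bismark coverage files carry no per-window CpG count; ``n_cpg`` is set
    to 1 per position (the caller may supply counts separately).
    """
    merged: pd.DataFrame | None = None
    for group, reps in mapping.items():
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        for rep, path in reps.items():
            sub = _read_bismark_cov(Path(path))
            sub = sub.rename(
                columns={"depth": f"depth_{group}{rep}", "meth": f"meth_{group}{rep}"}
            )
            merged = sub if merged is None else merged.merge(sub, on=["chrom", "pos"], how="outer")
    if merged is None:
        raise ValueError("empty group/replicate mapping")
    merged.insert(2, "n_cpg", 1)
    merged = merged.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    _validate_rrbs(merged, "bismark set")
    return merged


def _validate_rrbs(df: pd.DataFrame, origin: str) -> None:
    for col in df.columns:
        if col.startswith("meth_"):
            depth_col = "depth_" + col[5:]
            if depth_col not in df.columns:
                raise ValueError(f"{origin}: column {col} has no matching {depth_col}")
            bad = df[col] > df[depth_col]
            if bad.any():
                raise ValueError(
                    f"{origin}: methylated count exceeds depth at row {int(bad.idxmax())}"
                )
    if "n_cpg" in df.columns and (df["n_cpg"].dropna() < 1).any():
        raise ValueError(f"{origin}: n_cpg must be >= 1")


def rrbs_replicates(df: pd.DataFrame, group: str) -> list[int]:
    """Replicate indices present for ``group`` in a wide locus table."""
    pat = re.compile(rf"^depth_{group}(\d+)$")
    reps = sorted(int(m.group(1)) for c in df.columns if (m := pat.match(c)))
    return reps


def rrbs_fmc(df: pd.DataFrame, group: str) -> pd.DataFrame:
    """Per-replicate fractional methylation (meth/depth) for a group."""
    reps = rrbs_replicates(df, group)
    out = {}
    for r in reps:
        out[r] = df[f"meth_{group}{r}"] / df[f"depth_{group}{r}"]
    return pd.DataFrame(out, index=df.index)


def write_rrbs(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    _write_tsv(df, path, header_lines)


# ---------------------------------------------------------------------------
# MeCap peaks and tracks
# ---------------------------------------------------------------------------

def read_mecap(peaks_path, track_path=None, n_experiments: int | None = None):
    """Read MeCap peak table (and optionally the enrichment bedGraph track).

    The peak table is TSV with columns ``chrom, start, end`` then
    ``enr_D_<e>`` / ``enr_PR_<e>`` per experiment.  Returns
    ``(peaks, track)`` where ``track`` is None unless ``track_path`` given.
    """
    peaks = pd.read_csv(peaks_path, sep="\t", comment="#")
    required = {"chrom", "start", "end"}
    if not required.issubset(peaks.columns):
        raise ValueError(f"{peaks_path}: peak table needs columns {sorted(required)}")
    if (peaks["end"] <= peaks["start"]).any():
        raise ValueError(f"{peaks_path}: peak with end <= start")
    enr_cols = [c for c in peaks.columns if c.startswith("enr_")]
    if not enr_cols:
        raise ValueError(f"{peaks_path}: no enrichment columns (enr_D_1, ...)")
    if (peaks[enr_cols] < 0).any().any():
        raise ValueError(f"{peaks_path}: negative enrichment value")
    if n_experiments is not None:
        for g in GROUPS:
            have = [c for c in enr_cols if c.startswith(f"enr_{g}_")]
            if len(have) != n_experiments:
                raise ValueError(
                    f"{peaks_path}: expected {n_experiments} experiments for group {g}"
                )
    track = read_bedgraph(track_path) if track_path is not None else None
    return peaks, track


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph track; intervals must be non-overlapping per chromosome."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: bedGraph interval with end <= start")
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    same = df["chrom"].values[1:] == df["chrom"].values[:-1]
    overlap = df["start"].values[1:] < df["end"].values[:-1]
    if np.any(same & overlap):
        i = int(np.nonzero(same & overlap)[0][0]) + 1
        raise ValueError(f"{path}: overlapping bedGraph intervals near row {i}")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def write_mecap_peaks(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    _write_tsv(df, path, header_lines)


# ---------------------------------------------------------------------------
# expression tables & generic results
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a differential-expression table (gene_id, logFC, FDR)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "logFC", "FDR"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expression table needs columns {sorted(required)}")
    if ((df["FDR"] < 0) | (df["FDR"] > 1)).any():
        raise ValueError(f"{path}: FDR outside [0, 1]")
    if not np.isfinite(df["logFC"]).all():
        raise ValueError(f"{path}: non-finite logFC")
    return df


def write_results(tables: Mapping[str, pd.DataFrame], outdir,
                  summary: Mapping | None = None,
                  header_lines: Sequence[str] = ()) -> dict[str, Path]:
    """Write named result tables as TSV plus a JSON summary.

    Returns a mapping of table name -> written path.  Empty tables yield
    header-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        _write_tsv(df, p, header_lines)
        written[name] = p
    if summary is not None:
        sp = outdir / "summary.json"
        with open(sp, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        written["summary"] = sp
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_tsv(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
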