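"""Readers and writers for the plain-text genomics formats the pipeline
consumes and emits.

Internal coordinates are 0-based half-open everywhere; 1-based dialects
(UCSC rmsk dumps with 1-based starts, Bismark coverage files) are converted
on read and re-converted on write, so write(read(x)) round-trips records
exactly.  Malformed lines raise ``FormatError`` carrying file and line
number.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .coverage import DepthTrack, ReadRecord
from .intervals import GenomicInterval, RepeatAnnotation, TargetRegion
from .methylation import CpGRecord

PathLike = Union[str, Path]


class FormatError(ValueError):
    def __init__(self, path: PathLike, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """BED3+ (0-based half-open); extra columns ignored."""
    out = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(path, lineno, "expected >= 3 tab-separated fields")
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
    return out


def write_bed(
    path: PathLike,
    intervals: Iterable[GenomicInterval],
    extra: Optional[Sequence[Sequence]] = None,
) -> None:
    """BED3, optionally with extra columns (one row per interval)."""
    ivs = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if extra is not None:
                cols.extend(str(v) for v in extra[i])
            fh.write("\t".join(cols) + "\n")


def read_reads_bed(path: PathLike) -> list[ReadRecord]:
    """BED6-with-mapq read dialect: chrom start end name mapq strand [dup].

    Column 5 (BED score) carries MAPQ; optional column 7 is 0/1 duplicate.
    """
    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 5:
            raise FormatError(path, lineno, "expected >= 5 fields (need mapq)")
        try:
            out.append(
                ReadRecord(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    mapq=int(f[4]),
                    is_duplicate=bool(int(f[6])) if len(f) > 6 else False,
                    mate_id=f[3] or None,
                )
            )
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
    return out


# ---------------------------------------------------------------------------
# bedGraph / wiggle depth tracks
# ---------------------------------------------------------------------------


def read_bedgraph(path: PathLike, chrom: Optional[str] = None) -> DepthTrack:
    """bedGraph (0-based half-open) to a contiguous DepthTrack.

    Uncovered gaps inside the span are depth 0.  With multiple chroms in the
    file, ``chrom`` selects one.
    """
    rows = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 4:
            raise FormatError(path, lineno, "expected 4 fields")
        try:
            c, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
        if chrom is None or c == chrom:
            rows.append((c, s, e, v))
    if not rows:
        raise ValueError(f"{path}: no depth records" + (f" for {chrom}" if chrom else ""))
    chroms = {r[0] for r in rows}
    if len(chroms) > 1:
        raise ValueError(
            f"{path}: multiple chroms {sorted(chroms)}; pass chrom= to select one"
        )
    start = min(r[1] for r in rows)
    end = max(r[2] for r in rows)
    depth = np.zeros(end - start)
    for _, s, e, v in rows:
        depth[s - start : e - start] = v
    return DepthTrack(rows[0][0], start, depth)


def write_bedgraph(path: PathLike, track: DepthTrack) -> None:
    """Run-length-compressed bedGraph; zero-depth runs are omitted."""
    d = track.depth
    with open(path, "w") as fh:
        if len(d) == 0:
            return
        edges = np.flatnonzero(np.diff(d)) + 1
        bounds = np.concatenate(([0], edges, [len(d)]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            v = d[s]
            if v == 0:
                continue
            val = int(v) if float(v).is_integer() else float(v)
            fh.write(
                f"{track.chrom}\t{track.start + s}\t{track.start + e}\t{val}\n"
            )


def read_wiggle(path: PathLike) -> DepthTrack:
    """fixedStep/variableStep wiggle to a DepthTrack.

    Wiggle is 1-based: a fixedStep block with start=p covers 0-based
    [p-1, p-1+span).  Only single-chrom files are supported.
    """
    values: dict[int, float] = {}
    chrom = None
    mode = None
    pos = step = span = None
    for lineno, line in _data_lines(path):
        f = line.split()
        if f[0] in ("fixedStep", "variableStep"):
            mode = f[0]
            kv = dict(p.split("=", 1) for p in f[1:])
            if "chrom" not in kv:
                raise FormatError(path, lineno, "declaration missing chrom=")
            if chrom is not None and kv["chrom"] != chrom:
                raise FormatError(path, lineno, "multiple chroms not supported")
            chrom = kv["chrom"]
            span = int(kv.get("span", 1))
            if mode == "fixedStep":
                if "start" not in kv:
                    raise FormatError(path, lineno, "fixedStep missing start=")
                pos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
            continue
        if mode is None:
            raise FormatError(path, lineno, "data before any step declaration")
        try:
            if mode == "fixedStep":
                v = float(f[0])
                p = pos
                pos += step
            else:
                p = int(f[0]) - 1
                v = float(f[1])
        except (ValueError, IndexError) as exc:
            raise FormatError(path, lineno, str(exc)) from exc
        for i in range(span):
            values[p + i] = v
    if not values:
        raise ValueError(f"{path}: empty wiggle")
    start = min(values)
    end = max(values) + 1
    depth = np.zeros(end - start)
    for p, v in values.items():
        depth[p - start] = v
    return DepthTrack(chrom, start, depth)


# ---------------------------------------------------------------------------
# RepeatMasker rmsk table
# ---------------------------------------------------------------------------

_RMSK_COLS = ("genoName", "genoStart", "genoEnd", "swScore")


def read_rmsk(path: PathLike, one_based_starts: bool = False) -> list[RepeatAnnotation]:
    """UCSC rmsk-style TSV with genoName/genoStart/genoEnd/swScore columns.

    Without a header, the first four columns are taken in that order.  UCSC
    database dumps are 0-based; set ``one_based_starts`` for 1-based dialects
    (starts are decremented on read).  An optional ``elementLength`` column
    overrides the genomic span as the element length.
    """
    out = []
    idx = {c: i for i, c in enumerate(_RMSK_COLS)}
    elem_idx = None
    header_seen = False
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if not header_seen and any(c in f for c in _RMSK_COLS):
            idx = {c: f.index(c) for c in _RMSK_COLS if c in f}
            missing = set(_RMSK_COLS) - set(idx)
            if missing:
                raise FormatError(path, lineno, f"header missing {sorted(missing)}")
            if "elementLength" in f:
                elem_idx = f.index("elementLength")
            header_seen = True
            continue
        header_seen = True
        try:
            start = int(f[idx["genoStart"]]) - (1 if one_based_starts else 0)
            out.append(
                RepeatAnnotation(
                    GenomicInterval(f[idx["genoName"]], start, int(f[idx["genoEnd"]])),
                    sw_score=int(f[idx["swScore"]]),
                    element_length=(
                        int(f[elem_idx]) if elem_idx is not None else None
                    ),
                )
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(path, lineno, str(exc)) from exc
    return out


def write_rmsk(path: PathLike, repeats: Iterable[RepeatAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("genoName\tgenoStart\tgenoEnd\tswScore\telementLength\n")
        for r in repeats:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.sw_score}\t{r.element_length}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> dict[str, str]:
    """All sequences of a FASTA file as {name: sequence}."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: PathLike, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Bismark-coverage CpG tables
# ---------------------------------------------------------------------------


def read_cpg_tsv(path: PathLike) -> list[CpGRecord]:
    """Bismark coverage format: chrom, start(1-based), end(inclusive),
    percent, meth_count, unmeth_count."""
    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise FormatError(path, lineno, "expected 6 fields")
        try:
            start1, end1 = int(f[1]), int(f[2])
            out.append(
                CpGRecord(
                    GenomicInterval(f[0], start1 - 1, end1),
                    meth_count=int(f[4]),
                    unmeth_count=int(f[5]),
                )
            )
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from exc
    return out


def write_cpg_tsv(path: PathLike, records: Iterable[CpGRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            pct = 0.0 if r.depth == 0 else 100 * r.meth_count / r.depth
            fh.write(
                f"{r.position.chrom}\t{r.position.start + 1}\t{r.position.end}"
                f"\t{pct:.6g}\t{r.meth_count}\t{r.unmeth_count}\n"
            )


# ---------------------------------------------------------------------------
# Minimal SAM
# ---------------------------------------------------------------------------


def read_minimal_sam(path: PathLike) -> list[ReadRecord]:
    """Mapped reads from a (headered) SAM file via pysam.

    Consumes QNAME, FLAG (duplicate bit 0x400), RNAME, POS, MAPQ and CIGAR
    (reference span via the alignment's reference end).
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            end = aln.reference_end
            if end is None or end <= aln.reference_start:
                continue
            out.append(
                ReadRecord(
                    GenomicInterval(aln.reference_name, aln.reference_start, end),
                    mapq=aln.mapping_quality,
                    is_duplicate=aln.is_duplicate,
                    mate_id=aln.query_name,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def write_manifest(path: PathLike, params: dict) -> None:
    """JSON manifest echoing every run parameter (plus interpreter version)."""
    payload = dict(params)
    payload.setdefault("python", sys.version.split()[0])
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def target_from_bed(path: PathLike, name: Optional[str] = None) -> TargetRegion:
    return TargetRegion(name or Path(path).stem, read_bed(path))
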