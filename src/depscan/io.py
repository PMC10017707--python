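"""Readers and writers for the plain-text formats the pipeline touches.

BED records are 0-based half-open.  BED3, BED6 and BED6+1 (seventh column =
sample id) are supported; ``track``/``browser``/``#`` lines are skipped.
Count matrices are TSV with a ``locus`` index column (``chrom:start-end``)
and one column per sample.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "BedFormatError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_count_matrix",
    "write_count_matrix",
    "parse_locus_id",
]


class BedFormatError(ValueError):
    """Malformed line in a BED-like file; message names file and line number."""


_LOCUS_RE = re.compile(r"^(.+):(\d+)-(\d+)$")


def parse_locus_id(locus_id: str) -> GenomicInterval:
    m = _LOCUS_RE.match(locus_id)
    if not m:
        raise ValueError(f"cannot parse locus id {locus_id!r}")
    return GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3)))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6(+1) into interval records.

    Raises :class:`BedFormatError` naming the offending line on malformed
    input (non-integer coordinates, start >= end, bad strand).
    """
    out: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = f[3] if len(f) > 3 else ""
            try:
                score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: bad score field") from exc
            strand = f[5] if len(f) > 5 else "."
            sample = f[6] if len(f) > 6 else ""
            try:
                out.append(
                    GenomicInterval(f[0], start, end, name, score, strand, sample)
                )
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(records: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6, plus a seventh sample column if any record carries one."""
    records = list(records)
    with_sample = any(r.sample for r in records)
    with open(path, "w") as fh:
        for r in records:
            fields = [
                r.chrom,
                str(r.start),
                str(r.end),
                r.name or r.locus_id,
                format(r.score, ".6g"),
                r.strand,
            ]
            if with_sample:
                fields.append(r.sample)
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph track into a DataFrame (chrom, start, end, value)."""
    rows = []
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise BedFormatError(f"{path}:{lineno}: need 4 columns")
            try:
                rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: bad field") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "locus"
    return df


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix = matrix.copy()
    matrix.index.name = "locus"
    matrix.to_csv(path, sep="\t", float_format="%.6g")
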