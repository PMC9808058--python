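"""Readers and writers for the annotation formats the pipeline touches.

Everything is normalized into two small domain types:

* :class:`GeneAnnotation` — a gene with contig, strand, transcription start
  site (TSS) and genomic span;
* :class:`RepeatFeature` — one repetitive-element instance with its
  RepeatMasker-style ``class/family`` label (e.g. ``SINE/Alu``, ``LINE/L1``).

Internal coordinates are 0-based half-open everywhere.  GFF3 input
(1-based closed) and RepeatMasker ``.out`` input (1-based inclusive) are
shifted on read and shifted back on write.  All readers transparently accept
gzip-compressed files by the ``.gz`` extension.

Records that parse but violate a type invariant (e.g. an unknown strand
symbol, ``end <= start``) are skipped with a logged warning; lines that do
not parse at all raise :class:`ParseError` naming the offending line number.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "RepeatFeature",
    "ParseError",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_repeat_annotation",
    "write_repeat_annotation",
    "read_matrix",
    "write_matrix",
]


class ParseError(ValueError):
    """A line of an annotation file could not be parsed."""


#: accepted strand symbols, normalized to ASCII "+" / "-"
_STRANDS = {"+": "+", "-": "-", "−": "-"}


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its transcription start site.

    ``tss`` is the 0-based position of the first transcribed base: the span
    start on the + strand and ``end - 1`` on the − strand.
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start <= self.tss < self.end):
            raise ValueError(
                f"{self.gene_id}: require 0 <= start <= tss < end, "
                f"got start={self.start}, tss={self.tss}, end={self.end}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RepeatFeature:
    """One repeat instance; ``repeat_class`` is the class/family label."""

    contig: str
    start: int
    end: int
    repeat_name: str
    repeat_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(
                f"{self.repeat_name}: invalid span [{self.start}, {self.end})"
            )
        if not self.repeat_class:
            raise ValueError(f"{self.repeat_name}: empty repeat class")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

def _tss_for(strand: str, start: int, end: int) -> int:
    return start if strand == "+" else end - 1


def _iter_bed6(path: str | Path) -> Iterator[GeneAnnotation]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 BED fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            strand = _STRANDS.get(fields[5])
            if strand is None:
                logger.warning("%s: line %d: unknown strand %r, record skipped", path, lineno, fields[5])
                continue
            try:
                yield GeneAnnotation(
                    gene_id=fields[3], contig=fields[0], strand=strand,
                    tss=_tss_for(strand, start, end), start=start, end=end,
                )
            except ValueError as exc:
                logger.warning("%s: line %d: %s, record skipped", path, lineno, exc)


def _gff3_attr(attrs: str, keys: Sequence[str] = ("ID", "gene_id", "Name")) -> str | None:
    for item in attrs.strip().strip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


def _iter_gff3_genes(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> Iterator[GeneAnnotation]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 tab-separated GFF3 fields")
            if fields[2] not in feature_types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            strand = _STRANDS.get(fields[6])
            if strand is None:
                logger.warning("%s: line %d: unknown strand %r, record skipped", path, lineno, fields[6])
                continue
            gene_id = _gff3_attr(fields[8]) or f"{fields[0]}:{start1}-{end1}"
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            try:
                yield GeneAnnotation(
                    gene_id=gene_id, contig=fields[0], strand=strand,
                    tss=_tss_for(strand, start, end), start=start, end=end,
                )
            except ValueError as exc:
                logger.warning("%s: line %d: %s, record skipped", path, lineno, exc)


def read_gene_annotation(path: str | Path, format: str = "bed6") -> list[GeneAnnotation]:
    """Read gene annotations from BED6 or GFF3 (gene features only)."""
    if format == "bed6":
        return list(_iter_bed6(path))
    if format == "gff3":
        return list(_iter_gff3_genes(path))
    raise ValueError(f"unknown gene annotation format: {format!r}")


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path, format: str = "bed6") -> None:
    """Write genes as BED6 or as minimal GFF3 ``gene`` lines (involution of read)."""
    genes = list(genes)
    with _open_text(path, "wt") as fh:
        if format == "bed6":
            for g in genes:
                fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        elif format == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.contig}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
        else:
            raise ValueError(f"unknown gene annotation format: {format!r}")


# ---------------------------------------------------------------------------
# repeat annotations
# ---------------------------------------------------------------------------

def _iter_rmsk_out(path: str | Path) -> Iterator[RepeatFeature]:
    # RepeatMasker .out: 2 header lines + 1 blank, then whitespace-delimited
    # records; begin/end are 1-based inclusive query coordinates.
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if not fields[0].lstrip("-").isdigit():
                if lineno <= 3:
                    continue  # header
                raise ParseError(f"{path}: line {lineno}: expected numeric SW score")
            if len(fields) < 11:
                raise ParseError(f"{path}: line {lineno}: truncated RepeatMasker record")
            try:
                begin, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            try:
                yield RepeatFeature(
                    contig=fields[4], start=begin - 1, end=end,
                    repeat_name=fields[9], repeat_class=fields[10],
                )
            except ValueError as exc:
                logger.warning("%s: line %d: %s, record skipped", path, lineno, exc)


def _iter_bed_class(path: str | Path) -> Iterator[RepeatFeature]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >=4 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if len(fields) >= 7:
                name, rclass = fields[3], fields[6]
            elif "#" in fields[3]:
                name, rclass = fields[3].split("#", 1)
            else:
                raise ParseError(
                    f"{path}: line {lineno}: no repeat class (need 'name#class/family' or a 7th column)"
                )
            try:
                yield RepeatFeature(contig=fields[0], start=start, end=end,
                                    repeat_name=name, repeat_class=rclass)
            except ValueError as exc:
                logger.warning("%s: line %d: %s, record skipped", path, lineno, exc)


def read_repeat_annotation(path: str | Path, dialect: str = "rmsk_out") -> list[RepeatFeature]:
    """Read repeat annotations from RepeatMasker ``.out`` or a class-annotated BED."""
    if dialect == "rmsk_out":
        return list(_iter_rmsk_out(path))
    if dialect == "bed_class":
        return list(_iter_bed_class(path))
    raise ValueError(f"unknown repeat annotation dialect: {dialect!r}")


def write_repeat_annotation(repeats: Iterable[RepeatFeature], path: str | Path,
                            dialect: str = "rmsk_out") -> None:
    repeats = list(repeats)
    with _open_text(path, "wt") as fh:
        if dialect == "rmsk_out":
            fh.write(
                "   SW   perc perc perc  query     position in query    matching  repeat         position in repeat\n"
                "score   div. del. ins.  sequence  begin end   (left)   repeat    class/family  begin end (left) ID\n"
                "\n"
            )
            for i, r in enumerate(repeats, start=1):
                fh.write(
                    f"  100    0.0  0.0  0.0  {r.contig}  {r.start + 1} {r.end}  (0)  + "
                    f" {r.repeat_name}  {r.repeat_class}  1 {r.length} (0) {i}\n"
                )
        elif dialect == "bed_class":
            for r in repeats:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.repeat_name}#{r.repeat_class}\n")
        else:
            raise ValueError(f"unknown repeat annotation dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# repeat-content matrix TSV
# ---------------------------------------------------------------------------

_FLOOR_TAG = "#floor_value="


def write_matrix(matrix, path: str | Path) -> None:
    """Write a :class:`~repsig.promoter_repeatome.RepeatContentMatrix` as TSV.

    The floor sentinel is carried in a leading ``#floor_value=`` comment line
    so that ``read_matrix(write_matrix(m)) == m`` bit-identically (pandas
    writes floats with shortest round-trip repr).
    """
    if matrix.values.empty:
        raise ValueError("refusing to write an empty repeat-content matrix")
    if matrix.values.index.duplicated().any():
        raise ValueError("matrix has duplicate gene IDs")
    with _open_text(path, "wt") as fh:
        fh.write(f"{_FLOOR_TAG}{matrix.floor_value!r}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id")


def read_matrix(path: str | Path):
    """Read a repeat-content matrix TSV written by :func:`write_matrix`."""
    from .promoter_repeatome import RepeatContentMatrix

    floor_value = -math.inf
    with _open_text(path) as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith(_FLOOR_TAG):
            floor_value = float(first[len(_FLOOR_TAG):].strip())
        else:
            fh.seek(pos)
        values = pd.read_csv(fh, sep="\t", index_col="gene_id", float_precision="round_trip")
    if values.index.duplicated().any():
        dupes = sorted(set(values.index[values.index.duplicated()]))
        raise ValueError(f"matrix has duplicate gene IDs: {dupes}")
    return RepeatContentMatrix(values=values, floor_value=floor_value)
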