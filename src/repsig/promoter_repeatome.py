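"""Promoter extraction, repeat overlap, and the repeat-content (RC) score.

The RC score treats each repeat class as a unigram over a window of
exploration of length ``Le`` (the promoter, 2 kb by default).  For a class
*r* with ``Nr`` instances overlapping the promoter and ``Lr`` total
promoter-clipped base pairs,

    RC(r) = log10(Nr * Lr / Le)

so frequency and coverage contribute separately.  A class with no instance
in a promoter is *absent*; in the assembled gene x class matrix absent cells
are filled with a floor sentinel ``log10(1 / (2 * Le))``, strictly below the
smallest attainable score ``log10(1 / Le)`` (one 1-bp hit), which keeps the
matrix fully numeric while ranking "no repeat" below "smallest repeat".

Conventions (documented so the brute-force oracle can match them exactly):

* promoters lie strictly 5' of the TSS: ``[tss - w, tss)`` on +,
  ``[tss + 1, tss + 1 + w)`` on −, clipped at contig edges; ``Le`` stays the
  configured window even for clipped promoters;
* repeats are clipped at promoter boundaries, never excluded, and same-class
  overlaps are not merged — each instance counts;
* ``tss_distance`` is measured from the hit edge nearest the TSS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneAnnotation, RepeatFeature

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterRegion",
    "PromoterRepeatHit",
    "RepeatContentMatrix",
    "extract_promoter",
    "overlap_repeats",
    "repeat_content",
    "repeat_content_floor",
    "build_matrix",
]

DEFAULT_WINDOW_BP = 2000


@dataclass(frozen=True)
class PromoterRegion:
    """The window of exploration 5' of a gene's TSS (0-based half-open)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    window_bp: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: promoter end < start")
        if self.end - self.start > self.window_bp:
            raise ValueError(f"{self.gene_id}: promoter longer than its window")

    @property
    def is_empty(self) -> bool:
        return self.end == self.start

    @property
    def tss(self) -> int:
        # the promoter abuts the TSS on its strand-proximal side
        return self.end if self.strand == "+" else self.start - 1


@dataclass(frozen=True)
class PromoterRepeatHit:
    gene_id: str
    repeat_class: str
    clipped_length: int
    tss_distance: int
    order_rank: int

    def __post_init__(self) -> None:
        if self.clipped_length < 1:
            raise ValueError("clipped_length must be >= 1")
        if self.tss_distance < 0 or self.order_rank < 1:
            raise ValueError("tss_distance must be >= 0 and order_rank >= 1")


@dataclass
class RepeatContentMatrix:
    """Genes x repeat classes of RC scores (the weighted matrix).

    ``values`` is a fully numeric DataFrame (floor applied); ``dropped``
    records genes excluded for having no hit in any analyzed class (or an
    empty promoter), keyed by gene id with a reason string.
    """

    values: pd.DataFrame
    floor_value: float
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        finite = self.values.to_numpy()[np.isfinite(self.values.to_numpy())]
        if finite.size and finite.min() < self.floor_value - 1e-12:
            raise ValueError("matrix entry below the floor sentinel")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def repeat_classes(self) -> list[str]:
        return list(self.values.columns)

    def equals(self, other: "RepeatContentMatrix") -> bool:
        return self.floor_value == other.floor_value and self.values.equals(other.values)


def repeat_content_floor(window_bp: int) -> float:
    """Sentinel for an absent class: below any attainable RC score."""
    return math.log10(1.0 / (2.0 * window_bp))


def extract_promoter(gene: GeneAnnotation, window_bp: int = DEFAULT_WINDOW_BP,
                     contig_lengths: Mapping[str, int] | None = None) -> PromoterRegion:
    """Strand-aware promoter window immediately 5' of the TSS.

    Clipped at position 0 and, when ``contig_lengths`` is given, at the
    contig end; ``window_bp`` is recorded unchanged so RC scores stay
    comparable across genes.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if gene.strand == "+":
        start, end = gene.tss - window_bp, gene.tss
    else:
        start, end = gene.tss + 1, gene.tss + 1 + window_bp
    start = max(start, 0)
    if contig_lengths is not None:
        clen = contig_lengths[gene.contig]
        end = min(end, clen)
        start = min(start, clen)
    end = max(end, start)
    return PromoterRegion(gene_id=gene.gene_id, contig=gene.contig,
                          start=start, end=end, strand=gene.strand, window_bp=window_bp)


def overlap_repeats(promoter: PromoterRegion,
                    repeats: Sequence[RepeatFeature]) -> list[PromoterRepeatHit]:
    """Repeats with >=1 bp intersection, clipped, ranked by distance to TSS."""
    raw: list[tuple[int, int, int, str, str]] = []
    for r in repeats:
        if r.contig != promoter.contig:
            continue
        lo = max(r.start, promoter.start)
        hi = min(r.end, promoter.end)
        if hi <= lo:
            continue
        if promoter.strand == "+":
            dist = promoter.end - hi
        else:
            dist = lo - promoter.start
        raw.append((dist, lo, hi - lo, r.repeat_class, r.repeat_name))
    raw.sort(key=lambda t: (t[0], t[1], t[3], t[4]))
    return [
        PromoterRepeatHit(gene_id=promoter.gene_id, repeat_class=rclass,
                          clipped_length=length, tss_distance=dist, order_rank=rank)
        for rank, (dist, _lo, length, rclass, _name) in enumerate(raw, start=1)
    ]


def repeat_content(hits: Sequence[PromoterRepeatHit], repeat_class: str,
                   window_bp: int = DEFAULT_WINDOW_BP) -> float | None:
    """RC = log10(Nr * Lr / Le); ``None`` marks an absent class (Nr = 0)."""
    if window_bp < 1:
        raise ValueError("window_bp (Le) must be >= 1")
    lengths = [h.clipped_length for h in hits if h.repeat_class == repeat_class]
    nr = len(lengths)
    if nr == 0:
        return None
    return math.log10(nr * sum(lengths) / window_bp)


class _ContigIndex:
    """Repeats of one contig sorted by start, for windowed candidate lookup."""

    def __init__(self, repeats: list[RepeatFeature]):
        self.repeats = sorted(repeats, key=lambda r: (r.start, r.end, r.repeat_class, r.repeat_name))
        self.starts = np.array([r.start for r in self.repeats], dtype=np.int64)
        self.ends = np.array([r.end for r in self.repeats], dtype=np.int64)

    def candidates(self, start: int, end: int) -> list[RepeatFeature]:
        hi = int(np.searchsorted(self.starts, end, side="left"))
        mask = self.ends[:hi] > start
        return [self.repeats[i] for i in np.flatnonzero(mask)]


def build_matrix(genes: Sequence[GeneAnnotation], repeats: Sequence[RepeatFeature],
                 window_bp: int = DEFAULT_WINDOW_BP,
                 classes: Sequence[str] | None = None,
                 contig_lengths: Mapping[str, int] | None = None) -> RepeatContentMatrix:
    """Assemble the gene x repeat-class weighted matrix of RC scores.

    Rows are the genes with at least one promoter hit among the analyzed
    classes (others are dropped and reported); columns are the analyzed
    classes in lexicographic order; absent cells carry the floor sentinel.
    """
    if not genes:
        raise ValueError("need at least one gene")
    if not repeats:
        raise ValueError("need at least one repeat")
    whitelist = set(classes) if classes is not None else None
    if whitelist is not None:
        repeats = [r for r in repeats if r.repeat_class in whitelist]

    by_contig: dict[str, list[RepeatFeature]] = {}
    for r in repeats:
        by_contig.setdefault(r.contig, []).append(r)
    index = {contig: _ContigIndex(rs) for contig, rs in by_contig.items()}

    floor = repeat_content_floor(window_bp)
    rows: dict[str, dict[str, float]] = {}
    dropped: dict[str, str] = {}
    seen_classes: set[str] = set()
    for gene in genes:
        promoter = extract_promoter(gene, window_bp, contig_lengths)
        if promoter.is_empty:
            dropped[gene.gene_id] = "empty_promoter"
            continue
        cidx = index.get(gene.contig)
        cand = cidx.candidates(promoter.start, promoter.end) if cidx else []
        hits = overlap_repeats(promoter, cand)
        if not hits:
            dropped[gene.gene_id] = "no_promoter_repeats"
            continue
        row: dict[str, float] = {}
        for rclass in {h.repeat_class for h in hits}:
            row[rclass] = repeat_content(hits, rclass, window_bp)
            seen_classes.add(rclass)
        rows[gene.gene_id] = row

    if not rows:
        raise ValueError(
            f"no gene retained: {len(genes)} genes in, "
            f"{sum(v == 'empty_promoter' for v in dropped.values())} empty promoters, "
            f"{sum(v == 'no_promoter_repeats' for v in dropped.values())} without promoter repeats"
        )
    columns = sorted(whitelist) if whitelist is not None else sorted(seen_classes)
    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    values = values.reindex(columns=columns).fillna(floor)
    values.index.name = "gene_id"
    if dropped:
        logger.info("build_matrix: dropped %d/%d genes with no analyzed promoter repeat",
                    len(dropped), len(genes))
    return RepeatContentMatrix(values=values, floor_value=floor, dropped=dropped)
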