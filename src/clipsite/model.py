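"""Core in-memory containers shared across the pipeline.

All coordinates are 0-based half-open on the genomic (plus) strand; conversion
to 1-based (GFF3) or stranded transcript coordinates happens only at I/O and
coordinate-map boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

Strand = str  # "+" or "-"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class CandidateSite:
    """Single-nucleotide candidate binding position with a peak-calling score."""

    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise ValueError("candidate sites must have width 1")

    @property
    def pos(self) -> int:
        return self.interval.start


class CrosslinkTrack:
    """Sparse per-nucleotide crosslink-event counts for one (pseudo-)replicate.

    Counts are keyed by ``(chrom, strand)`` and stored as ``position -> count``
    maps; only strictly positive counts are stored.
    """

    def __init__(self, label: str = "") -> None:
        self.label = label
        self._data: Dict[Tuple[str, Strand], Dict[int, int]] = {}

    def add(self, chrom: str, strand: Strand, pos: int, count: int) -> None:
        if count < 0:
            raise ValueError(f"negative count {count} at {chrom}:{pos}")
        if count == 0:
            return
        key = (chrom, strand)
        bucket = self._data.setdefault(key, {})
        bucket[pos] = bucket.get(pos, 0) + int(count)

    def counts(self, chrom: str, strand: Strand) -> Dict[int, int]:
        return self._data.get((chrom, strand), {})

    def get(self, chrom: str, strand: Strand, pos: int) -> int:
        return self._data.get((chrom, strand), {}).get(pos, 0)

    def keys(self) -> Iterator[Tuple[str, Strand]]:
        return iter(sorted(self._data))

    def window_sum(self, chrom: str, strand: Strand, start: int, end: int) -> int:
        bucket = self._data.get((chrom, strand), {})
        if len(bucket) > 4 * (end - start):
            return sum(bucket.get(p, 0) for p in range(start, end))
        return sum(c for p, c in bucket.items() if start <= p < end)

    def window_counts(
        self, chrom: str, strand: Strand, start: int, end: int
    ) -> np.ndarray:
        """Dense count vector on [start, end), genomic (plus-strand) order."""
        bucket = self._data.get((chrom, strand), {})
        out = np.zeros(end - start, dtype=np.int64)
        for p, c in bucket.items():
            if start <= p < end:
                out[p - start] = c
        return out

    def total(self) -> int:
        return sum(sum(b.values()) for b in self._data.values())

    def merge(self, other: "CrosslinkTrack", label: str = "") -> "CrosslinkTrack":
        out = CrosslinkTrack(label or f"{self.label}+{other.label}")
        for track in (self, other):
            for (chrom, strand), bucket in track._data.items():
                for pos, c in bucket.items():
                    out.add(chrom, strand, pos, c)
        return out

    def __add__(self, other: "CrosslinkTrack") -> "CrosslinkTrack":
        return self.merge(other)

    def items(self) -> Iterator[Tuple[str, Strand, int, int]]:
        for (chrom, strand) in sorted(self._data):
            for pos in sorted(self._data[(chrom, strand)]):
                yield chrom, strand, pos, self._data[(chrom, strand)][pos]


@dataclass
class BindingSite:
    """Finalized fixed-width binding site centered on a crosslink maximum."""

    id: str
    interval: GenomicInterval
    center: int
    total_count: int
    per_replicate_counts: Tuple[int, ...]
    center_score: float
    strength: Optional[float] = None
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    region: Optional[str] = None
    tx_center: Optional[int] = None

    def __post_init__(self) -> None:
        mid = (self.interval.start + self.interval.end - 1) // 2
        if self.center != mid:
            raise ValueError(
                f"center {self.center} is not the midpoint of "
                f"[{self.interval.start}, {self.interval.end})"
            )


@dataclass
class Transcript:
    """Transcript with exon/CDS/UTR structure and spliced coordinate maps."""

    id: str
    gene_id: str
    chrom: str
    strand: Strand
    level: str  # "1" | "2" | "3" | "NA"
    exons: List[Tuple[int, int]] = field(default_factory=list)
    cds: List[Tuple[int, int]] = field(default_factory=list)
    utr5: List[Tuple[int, int]] = field(default_factory=list)
    utr3: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def introns(self) -> List[Tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i][1] < exons[i + 1][0]
        ]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def regions(self, kind: str) -> List[Tuple[int, int]]:
        return {
            "5UTR": self.utr5,
            "CDS": self.cds,
            "3UTR": self.utr3,
            "intron": self.introns,
            "exon": sorted(self.exons),
        }[kind]

    def genomic_to_tx(self, pos: int) -> Optional[int]:
        """Map a genomic position to spliced 5'->3' transcript coordinates.

        Returns None for intronic or out-of-span positions.
        """
        exons = sorted(self.exons)
        offset = 0
        if self.strand == "+":
            for s, e in exons:
                if s <= pos < e:
                    return offset + (pos - s)
                offset += e - s
        else:
            for s, e in reversed(exons):
                if s <= pos < e:
                    return offset + (e - 1 - pos)
                offset += e - s
        return None

    def tx_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.spliced_length:
            raise ValueError(f"transcript position {tpos} out of bounds")
        exons = sorted(self.exons)
        offset = tpos
        if self.strand == "+":
            for s, e in exons:
                if offset < e - s:
                    return s + offset
                offset -= e - s
        else:
            for s, e in reversed(exons):
                if offset < e - s:
                    return e - 1 - offset
                offset -= e - s
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: Dict[str, str]) -> str:
        from .seqmotif import reverse_complement  # local to avoid cycle

        seq = "".join(genome[self.chrom][s:e] for s, e in sorted(self.exons))
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: Strand
    level: str  # "1" | "2" | "3" | "NA"
    biotype: str  # "protein_coding" | "lncRNA" | ...
    transcripts: Dict[str, Transcript] = field(default_factory=dict)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass
class TranscriptAnnotation:
    """Gene/transcript models with annotation levels and region structure."""

    genes: Dict[str, Gene] = field(default_factory=dict)
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def genes_overlapping(
        self, interval: GenomicInterval, stranded: bool = True
    ) -> List[Gene]:
        return [
            g
            for g in self.genes.values()
            if g.span.overlaps(interval, stranded=stranded)
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptAnnotation):
            return NotImplemented
        return _ann_key(self) == _ann_key(other)


def _ann_key(ann: TranscriptAnnotation):
    return sorted(
        (
            g.id,
            g.chrom,
            g.start,
            g.end,
            g.strand,
            g.level,
            g.biotype,
            sorted(
                (
                    t.id,
                    t.level,
                    tuple(sorted(t.exons)),
                    tuple(sorted(t.cds)),
                    tuple(sorted(t.utr5)),
                    tuple(sorted(t.utr3)),
                )
                for t in g.transcripts.values()
            ),
        )
        for g in ann.genes.values()
    )
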