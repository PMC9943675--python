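"""Readers and writers for the standard formats the pipeline touches.

Conventions
-----------
* internal coordinates: 0-based half-open, everywhere
* GFF3: 1-based closed (converted at the boundary)
* BED6 / bedGraph: 0-based half-open
* all text readers are gzip-transparent
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Dict, Iterable, List, Optional, TextIO, Tuple, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    BindingSite,
    CandidateSite,
    CrosslinkTrack,
    Gene,
    GenomicInterval,
    Transcript,
    TranscriptAnnotation,
)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file; message carries file context and line number."""


def xopen(path: PathLike, mode: str = "rt") -> TextIO:
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> Dict[str, str]:
    with xopen(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Dict[str, str], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR"}
_TX_TYPES = {"mRNA", "transcript", "lnc_RNA"}


def read_gff3(source: Union[PathLike, TextIO]) -> TranscriptAnnotation:
    """Parse a GFF3 annotation into :class:`TranscriptAnnotation`.

    Gene and transcript rows must carry a ``level`` attribute (``1``–``3`` or
    ``NA``). Raises :class:`FormatError` naming the offending line for broken
    parent links or unknown strands.
    """
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        with xopen(source) as fh:
            text = fh.read()

    lineno_of: Dict[str, int] = {}
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"GFF3 line {i}: expected 9 columns")
        if fields[6] not in ("+", "-"):
            raise FormatError(f"GFF3 line {i}: unknown strand {fields[6]!r}")
        for attr in fields[8].split(";"):
            if attr.startswith("ID="):
                lineno_of.setdefault(attr[3:], i)

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    ann = TranscriptAnnotation()
    for f in db.features_of_type("gene"):
        ann.genes[f.id] = Gene(
            id=f.id,
            chrom=f.seqid,
            start=f.start - 1,
            end=f.end,
            strand=f.strand,
            level=f.attributes.get("level", ["NA"])[0],
            biotype=f.attributes.get("gene_type", ["protein_coding"])[0],
        )

    tx_of: Dict[str, Transcript] = {}
    for ttype in _TX_TYPES:
        for f in db.features_of_type(ttype):
            parents = f.attributes.get("Parent", [])
            if not parents or parents[0] not in ann.genes:
                raise FormatError(
                    f"GFF3 line {lineno_of.get(f.id, '?')}: transcript {f.id} "
                    f"has no known parent gene"
                )
            gene = ann.genes[parents[0]]
            tx = Transcript(
                id=f.id,
                gene_id=gene.id,
                chrom=f.seqid,
                strand=f.strand,
                level=f.attributes.get("level", ["NA"])[0],
            )
            gene.transcripts[tx.id] = tx
            tx_of[tx.id] = tx

    kind_of = {"exon": "exons", "CDS": "cds"}
    for t in _UTR5_TYPES:
        kind_of[t] = "utr5"
    for t in _UTR3_TYPES:
        kind_of[t] = "utr3"
    for ftype, attr in kind_of.items():
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            if not parents or parents[0] not in tx_of:
                raise FormatError(
                    f"GFF3 line {lineno_of.get(f.id, '?')}: {ftype} feature "
                    f"has no known parent transcript"
                )
            getattr(tx_of[parents[0]], attr).append((f.start - 1, f.end))

    for tx in tx_of.values():
        if not tx.exons:
            raise FormatError(f"transcript {tx.id} has no exons")
        tx.exons.sort()
        tx.cds.sort()
        tx.utr5.sort()
        tx.utr3.sort()
    return ann


def write_gff3(ann: TranscriptAnnotation, path: PathLike) -> None:
    lines = ["##gff-version 3"]

    def row(chrom, ftype, start, end, strand, attrs) -> str:
        attr_s = ";".join(f"{k}={v}" for k, v in attrs)
        return f"{chrom}\tclipsite\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_s}"

    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        lines.append(
            row(
                g.chrom,
                "gene",
                g.start,
                g.end,
                g.strand,
                [("ID", g.id), ("level", g.level), ("gene_type", g.biotype)],
            )
        )
        for tid in sorted(g.transcripts):
            t = g.transcripts[tid]
            ttype = "mRNA" if g.is_coding else "transcript"
            lines.append(
                row(
                    t.chrom,
                    ttype,
                    t.start,
                    t.end,
                    t.strand,
                    [("ID", t.id), ("Parent", g.id), ("level", t.level)],
                )
            )
            parts = (
                [("exon", iv) for iv in t.exons]
                + [("CDS", iv) for iv in t.cds]
                + [("five_prime_UTR", iv) for iv in t.utr5]
                + [("three_prime_UTR", iv) for iv in t.utr3]
            )
            for i, (ftype, (s, e)) in enumerate(parts):
                lines.append(
                    row(
                        t.chrom,
                        ftype,
                        s,
                        e,
                        t.strand,
                        [("ID", f"{t.id}:{ftype}:{i}"), ("Parent", t.id)],
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def _read_bedgraph_stream(
    fh: Iterable[str], strand: str, track: CrosslinkTrack, name: str
) -> None:
    for i, line in enumerate(fh, start=1):
        line = line.strip()
        if not line or line.startswith(("track", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{name} line {i}: expected 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), fields[3]
        count = float(value)
        if count < 0 or count != int(count):
            raise FormatError(
                f"{name} line {i}: crosslink counts must be non-negative integers, "
                f"got {value}"
            )
        for pos in range(start, end):
            track.add(chrom, strand, pos, int(count))


def read_bedgraph_pair(
    plus: Union[PathLike, TextIO],
    minus: Union[PathLike, TextIO],
    label: str = "",
) -> CrosslinkTrack:
    """Read a stranded bedGraph pair into one :class:`CrosslinkTrack`.

    Multi-nucleotide spans are expanded to per-nucleotide counts; zero-valued
    spans are dropped.
    """
    track = CrosslinkTrack(label)
    for source, strand in ((plus, "+"), (minus, "-")):
        if hasattr(source, "read"):
            _read_bedgraph_stream(source, strand, track, f"bedGraph[{strand}]")
        else:
            with xopen(source) as fh:
                _read_bedgraph_stream(fh, strand, track, str(source))
    return track


def write_bedgraph_pair(
    track: CrosslinkTrack, plus_path: PathLike, minus_path: PathLike
) -> None:
    handles = {"+": open(plus_path, "w"), "-": open(minus_path, "w")}
    try:
        for chrom, strand, pos, count in track.items():
            handles[strand].write(f"{chrom}\t{pos}\t{pos + 1}\t{count}\n")
    finally:
        for fh in handles.values():
            fh.close()


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_binding_sites_bed(sites: Iterable[BindingSite], out: Union[PathLike, TextIO]) -> None:
    """Write finalized binding sites as BED6.

    The score column is the total crosslink count clamped to [0, 1000]; the
    true count and the strength travel in the name field as ``id|count|strength``.
    """
    own = not hasattr(out, "write")
    fh: TextIO = open(out, "w") if own else out  # type: ignore[assignment]
    try:
        for s in sites:
            strength = "" if s.strength is None else f"{s.strength:.6g}"
            name = f"{s.id}|{s.total_count}|{strength}"
            score = min(max(s.total_count, 0), 1000)
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                f"{name}\t{score}\t{s.interval.strand}\n"
            )
    finally:
        if own:
            fh.close()


def read_binding_sites_bed(source: Union[PathLike, TextIO]) -> List[BindingSite]:
    own = not hasattr(source, "read")
    fh: TextIO = xopen(source) if own else source  # type: ignore[assignment]
    sites = []
    try:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"BED6 line {i}: expected 6 columns")
            chrom, start, end, name, _score, strand = fields
            parts = name.split("|")
            sid, count = parts[0], int(parts[1])
            strength = float(parts[2]) if len(parts) > 2 and parts[2] else None
            start, end = int(start), int(end)
            sites.append(
                BindingSite(
                    id=sid,
                    interval=GenomicInterval(chrom, start, end, strand),
                    center=(start + end - 1) // 2,
                    total_count=count,
                    per_replicate_counts=(),
                    center_score=float(_score),
                    strength=strength,
                )
            )
    finally:
        if own:
            fh.close()
    return sites


def read_candidates_bed(source: Union[PathLike, TextIO]) -> List[CandidateSite]:
    """Read width-1 scored candidate sites (PureCLIP-like BED6)."""
    own = not hasattr(source, "read")
    fh: TextIO = xopen(source) if own else source  # type: ignore[assignment]
    out = []
    try:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"candidate BED line {i}: expected 6 columns")
            chrom, start, end, _name, score, strand = fields[:6]
            start, end = int(start), int(end)
            if end - start != 1:
                raise FormatError(f"candidate BED line {i}: width must be 1")
            out.append(
                CandidateSite(GenomicInterval(chrom, start, end, strand), float(score))
            )
    finally:
        if own:
            fh.close()
    return sorted(out, key=lambda c: (c.interval.chrom, c.interval.strand, c.pos))


def write_candidates_bed(candidates: Iterable[CandidateSite], path: PathLike) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.interval.chrom}\t{c.pos}\t{c.pos + 1}\tcand\t"
                f"{c.score:.6g}\t{c.interval.strand}\n"
            )


# ---------------------------------------------------------------------------
# TSV / GMT
# ---------------------------------------------------------------------------

def read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: PathLike, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)


def read_gmt(path: PathLike) -> Dict[str, List[str]]:
    """Read a GMT gene-set file: term, description, genes...  per line."""
    sets: Dict[str, List[str]] = {}
    with xopen(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {i}: expected >=3 columns")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Dict[str, List[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sets[term])
            fh.write(f"{term}\tclipsite\t{genes}\n")


# ---------------------------------------------------------------------------
# validation (CLI `validate` backend)
# ---------------------------------------------------------------------------

def validate_inputs(
    gff3: Optional[PathLike] = None,
    bedgraph_pairs: Optional[List[Tuple[PathLike, PathLike]]] = None,
    fasta: Optional[PathLike] = None,
) -> List[str]:
    """Check format invariants; return a list of human-readable problems."""
    problems: List[str] = []
    ann = None
    if gff3 is not None:
        try:
            ann = read_gff3(gff3)
        except FormatError as exc:
            problems.append(str(exc))
    if fasta is not None and ann is not None:
        genome = read_fasta(fasta)
        for g in ann.genes.values():
            if g.chrom not in genome:
                problems.append(f"gene {g.id}: chromosome {g.chrom} not in FASTA")
            elif g.end > len(genome[g.chrom]):
                problems.append(f"gene {g.id}: extends past end of {g.chrom}")
    for plus, minus in bedgraph_pairs or []:
        try:
            read_bedgraph_pair(plus, minus)
        except FormatError as exc:
            problems.append(str(exc))
    return problems
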