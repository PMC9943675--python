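"""Assignment of binding sites to genes, transcripts and transcript regions.

Region conflicts between isoforms are resolved by the hierarchy
3'UTR > 5'UTR > CDS > intron; noncoding genes map to ``noncoding``. Sites
overlapping two eligible genes are assigned uniformly at random with a seeded
generator so reruns reproduce the choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import (
    BindingSite,
    CrosslinkTrack,
    Gene,
    GenomicInterval,
    Transcript,
    TranscriptAnnotation,
)

logger = logging.getLogger(__name__)

REGION_HIERARCHY = ("3UTR", "5UTR", "CDS", "intron")
REGION_LABELS = REGION_HIERARCHY + ("noncoding",)


@dataclass
class AssignmentResult:
    """Per-site assignments plus per-transcript strongest-site groups."""

    table: pd.DataFrame  # site_id, gene_id, transcript_id, region, strength, tx_pos
    groups: Dict[str, str]  # transcript id -> strongest-site region label
    seed: int = 0
    n_unassigned: int = 0
    n_junction_dropped: int = 0


def filter_genes_by_level(ann: TranscriptAnnotation) -> TranscriptAnnotation:
    """Apply the annotation-level filters.

    Level-3 genes are removed when overlapped by a level-1/2 gene; transcripts
    of level NA are removed when their gene has any level-1..3 transcript.
    """
    genes = list(ann.genes.values())
    kept: Dict[str, Gene] = {}
    for g in genes:
        if g.level == "3":
            shadowed = any(
                h.id != g.id
                and h.level in ("1", "2")
                and h.chrom == g.chrom
                and h.start < g.end
                and g.start < h.end
                for h in genes
            )
            if shadowed:
                continue
        new_tx = dict(g.transcripts)
        if any(t.level in ("1", "2", "3") for t in new_tx.values()):
            new_tx = {tid: t for tid, t in new_tx.items() if t.level != "NA"}
        kept[g.id] = Gene(
            id=g.id,
            chrom=g.chrom,
            start=g.start,
            end=g.end,
            strand=g.strand,
            level=g.level,
            biotype=g.biotype,
            transcripts=new_tx,
        )
    return TranscriptAnnotation(genes=kept, chrom_lengths=dict(ann.chrom_lengths))


def assign_gene(
    site: BindingSite,
    eligible: Sequence[Gene],
    rng: np.random.Generator,
) -> Optional[str]:
    """Pick the gene a site belongs to; random uniform choice on multi-overlap."""
    hits = [g for g in eligible if g.span.overlaps(site.interval)]
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0].id
    hits = sorted(hits, key=lambda g: g.id)
    return hits[int(rng.integers(len(hits)))].id


def assign_region(site: BindingSite, gene: Gene) -> str:
    """Hierarchical region label across all kept transcripts of the gene."""
    if not gene.is_coding:
        return "noncoding"
    iv = site.interval
    found: Set[str] = set()
    for tx in gene.transcripts.values():
        for kind in ("3UTR", "5UTR", "CDS", "intron"):
            for s, e in tx.regions(kind):
                if s < iv.end and iv.start < e:
                    found.add(kind)
    for kind in REGION_HIERARCHY:
        if kind in found:
            return kind
    # boundary case: inside the gene span but no annotated feature
    logger.info("site %s has no region overlap in gene %s; labeling intron", site.id, gene.id)
    return "intron"


def gene_crosslink_totals(
    ann: TranscriptAnnotation, tracks: Sequence[CrosslinkTrack]
) -> Dict[str, int]:
    """Total crosslink events (all replicates summed) within each gene span."""
    totals: Dict[str, int] = {}
    for gid, gene in ann.genes.items():
        totals[gid] = sum(
            t.window_sum(gene.chrom, gene.strand, gene.start, gene.end) for t in tracks
        )
    return totals


def canonical_transcript(gene: Gene) -> Optional[Transcript]:
    """Longest kept transcript (spliced length; id breaks ties)."""
    if not gene.transcripts:
        return None
    return max(gene.transcripts.values(), key=lambda t: (t.spliced_length, t.id))


def assign_sites(
    sites: Sequence[BindingSite],
    ann: TranscriptAnnotation,
    tracks: Sequence[CrosslinkTrack],
    seed: int = 0,
    strength_by_relative_count: bool = True,
) -> AssignmentResult:
    """Full assignment: gene, region, strength, transcript coordinates.

    Strength is the site's crosslink count relative to its gene's total
    crosslink events (set ``strength_by_relative_count=False`` to rank by raw
    counts instead). Transcript coordinates refer to the gene's canonical
    (longest kept) transcript; sites spanning an exon junction of that
    transcript are left without a transcript position and counted.
    """
    kept = filter_genes_by_level(ann)
    rng = np.random.default_rng(seed)
    totals = gene_crosslink_totals(kept, tracks)
    genes = sorted(kept.genes.values(), key=lambda g: g.id)

    rows: List[dict] = []
    n_unassigned = 0
    n_junction = 0
    for site in sites:
        gid = assign_gene(site, genes, rng)
        if gid is None:
            n_unassigned += 1
            continue
        gene = kept.genes[gid]
        region = assign_region(site, gene)
        total = totals.get(gid, 0)
        strength = site.total_count / total if total > 0 else float("nan")
        tx = canonical_transcript(gene)
        tx_pos: Optional[int] = None
        tid = None
        if tx is not None:
            tid = tx.id
            positions = [
                tx.genomic_to_tx(p)
                for p in range(site.interval.start, site.interval.end)
            ]
            if all(p is not None for p in positions):
                span = sorted(positions)  # type: ignore[arg-type]
                if span[-1] - span[0] == len(positions) - 1:
                    tx_pos = tx.genomic_to_tx(site.center)
                else:
                    n_junction += 1
            else:
                n_junction += 1
        site.gene_id = gid
        site.region = region
        site.strength = strength
        site.transcript_id = tid
        site.tx_center = tx_pos
        rows.append(
            dict(
                site_id=site.id,
                chrom=site.interval.chrom,
                start=site.interval.start,
                end=site.interval.end,
                strand=site.interval.strand,
                center=site.center,
                gene_id=gid,
                transcript_id=tid,
                region=region,
                total_count=site.total_count,
                strength=strength,
                tx_pos=tx_pos if tx_pos is not None else -1,
            )
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "site_id", "chrom", "start", "end", "strand", "center", "gene_id",
            "transcript_id", "region", "total_count", "strength", "tx_pos",
        ],
    )
    groups = strongest_site_grouping(table, strength_by_relative_count)
    return AssignmentResult(
        table=table,
        groups=groups,
        seed=seed,
        n_unassigned=n_unassigned,
        n_junction_dropped=n_junction,
    )


def strongest_site_grouping(
    table: pd.DataFrame, by_relative: bool = True
) -> Dict[str, str]:
    """Per-transcript region group = region of the strongest binding site.

    Ties break toward the higher raw count, then the 5'-most site in
    transcript orientation.
    """
    groups: Dict[str, str] = {}
    if table.empty:
        return groups
    for tid, sub in table.dropna(subset=["transcript_id"]).groupby("transcript_id"):
        key_col = "strength" if by_relative else "total_count"
        sub = sub.copy()
        # 5'-most: smaller genomic center on +, larger on -
        sub["five_prime_rank"] = np.where(
            sub["strand"] == "+", sub["center"], -sub["center"]
        )
        sub = sub.sort_values(
            by=[key_col, "total_count", "five_prime_rank"],
            ascending=[False, False, True],
            kind="mergesort",
        )
        groups[str(tid)] = str(sub.iloc[0]["region"])
    return groups


def sites_per_region_normalized(
    table: pd.DataFrame,
    ann: TranscriptAnnotation,
    tracks: Sequence[CrosslinkTrack],
) -> pd.DataFrame:
    """Length-normalized binding-site density per transcript region.

    Only genes with at least one crosslink event contribute; per gene the
    region length is the mean over its kept transcripts, and the density is
    the number of sites in the region class divided by the summed mean
    lengths.
    """
    kept = filter_genes_by_level(ann)
    totals = gene_crosslink_totals(kept, tracks)
    selected = [g for g in kept.genes.values() if totals.get(g.id, 0) > 0]

    length_sum = {r: 0.0 for r in REGION_HIERARCHY}
    for gene in selected:
        if not gene.transcripts or not gene.is_coding:
            continue
        for region in REGION_HIERARCHY:
            lens = [
                sum(e - s for s, e in tx.regions(region))
                for tx in gene.transcripts.values()
            ]
            length_sum[region] += float(np.mean(lens)) if lens else 0.0

    counts = table["region"].value_counts().to_dict() if not table.empty else {}
    rows = []
    for region in REGION_HIERARCHY:
        n = int(counts.get(region, 0))
        total_len = length_sum[region]
        density = n / total_len if total_len > 0 else float("nan")
        rows.append(dict(region=region, n_sites=n, mean_length_sum=total_len, density=density))
    return pd.DataFrame(rows)


def to_transcript_coords(
    sites: Sequence[BindingSite], ann: TranscriptAnnotation
) -> Tuple[List[BindingSite], int]:
    """Sites that map unambiguously into their canonical transcript's spliced
    coordinates; returns (mapped sites, number dropped)."""
    mapped = [s for s in sites if s.tx_center is not None]
    return mapped, len(sites) - len(mapped)
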