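"""Binding-site definition from crosslink-event tracks.

The procedure mirrors the established iCLIP post-processing recipe:

1. merge the four replicate tracks into two pseudo-replicates;
2. call single-nucleotide candidate sites on the pseudo-replicates (here a
   documented fold-enrichment stand-in for an external HMM caller, or
   externally supplied scored BED6 candidates);
3. chain candidates closer than 5 nt into regions, discard isolated
   candidates, pick centers iteratively at the crosslink maximum, widen by
   2 nt to 5-nt sites, and keep a site only if its center carries the maximum
   candidate score within the site;
4. filter for reproducibility: a site must be supported by sufficient
   crosslink coverage (per-replicate 0.05-quantile threshold of positive
   per-site counts) in at least two of four replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import BindingSite, CandidateSite, CrosslinkTrack, GenomicInterval


@dataclass
class SiteCallParams:
    merge_distance: int = 5  # candidates closer than this are merged
    isolation_distance: int = 4  # lone candidates without a neighbor within this die
    half_width: int = 2  # sites span center +- half_width
    min_supporting_replicates: int = 2
    support_quantile: float = 0.05
    candidate_min_fold: float = 4.0  # stand-in caller enrichment threshold
    candidate_pseudocount: float = 1.0
    background_window: int = 501
    support_strict: bool = False  # True: count > threshold instead of >=

    def validate(self, n_replicates: int = 4) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if not 0 < self.support_quantile < 1:
            raise ValueError("support_quantile must lie in (0, 1)")
        if self.min_supporting_replicates > n_replicates:
            raise ValueError("min_supporting_replicates exceeds replicate count")

    @property
    def width(self) -> int:
        return 2 * self.half_width + 1


@dataclass
class SiteCallLog:
    """Run ledger: per-stage record counts and reproducibility thresholds."""

    n_candidates: int = 0
    n_regions: int = 0
    n_isolated_discarded: int = 0
    n_sites_defined: int = 0
    n_score_rule_discarded: int = 0
    n_boundary_discarded: int = 0
    n_sites_after_reproducibility: int = 0
    replicate_thresholds: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def merge_pseudoreplicates(
    tracks: Sequence[CrosslinkTrack],
    grouping: Tuple[Tuple[int, int], Tuple[int, int]] = ((0, 1), (2, 3)),
) -> List[CrosslinkTrack]:
    """Sum the four replicate tracks pairwise into two pseudo-replicates."""
    if len(tracks) != 4:
        raise ValueError(f"expected exactly 4 replicate tracks, got {len(tracks)}")
    flat = [i for pair in grouping for i in pair]
    if sorted(flat) != [0, 1, 2, 3]:
        raise ValueError(f"grouping {grouping} is not a partition of the 4 replicates")
    out = []
    for k, (i, j) in enumerate(grouping, start=1):
        out.append(tracks[i].merge(tracks[j], label=f"pseudo{k}"))
    return out


def call_candidate_sites(
    pseudo: Sequence[CrosslinkTrack], params: SiteCallParams
) -> List[CandidateSite]:
    """Fold-enrichment stand-in caller on the two pseudo-replicate tracks.

    A position is a candidate when it carries crosslink events in *both*
    pseudo-replicates and its summed count is enriched over the local
    background: ``score = log2((c + eps) / (b + eps))`` where ``b`` is the
    mean count in a centered window (default 501 nt) excluding the center
    +-2 nt, and ``score >= log2(candidate_min_fold)``.
    """
    if len(pseudo) != 2:
        raise ValueError("candidate calling expects exactly 2 pseudo-replicates")
    eps = params.candidate_pseudocount
    min_score = float(np.log2(params.candidate_min_fold))
    half_bg = params.background_window // 2
    out: List[CandidateSite] = []
    keys = sorted(set(pseudo[0].keys()) | set(pseudo[1].keys()))
    for chrom, strand in keys:
        c1 = pseudo[0].counts(chrom, strand)
        c2 = pseudo[1].counts(chrom, strand)
        common = sorted(set(c1) & set(c2))
        if not common:
            continue
        lo, hi = min(min(c1), min(c2)), max(max(c1), max(c2))
        dense = np.zeros(hi - lo + 1, dtype=np.float64)
        for bucket in (c1, c2):
            for p, c in bucket.items():
                dense[p - lo] += c
        csum = np.concatenate([[0.0], np.cumsum(dense)])

        def window_sum(a: int, b: int) -> float:
            a = max(a, lo)
            b = min(b, hi + 1)
            if b <= a:
                return 0.0
            return float(csum[b - lo] - csum[a - lo])

        for pos in common:
            c = c1[pos] + c2[pos]
            a, b = pos - half_bg, pos + half_bg + 1
            excl_lo, excl_hi = pos - 2, pos + 3
            total = window_sum(a, b) - window_sum(excl_lo, excl_hi)
            n_bg = (min(b, hi + 1) - max(a, lo)) - (
                min(excl_hi, hi + 1) - max(excl_lo, lo)
            )
            bg = total / n_bg if n_bg > 0 else 0.0
            score = float(np.log2((c + eps) / (bg + eps)))
            if score >= min_score:
                out.append(
                    CandidateSite(GenomicInterval(chrom, pos, pos + 1, strand), score)
                )
    return sorted(out, key=lambda c: (c.interval.chrom, c.interval.strand, c.pos))


def _chain_regions(
    positions: Sequence[int], merge_distance: int
) -> List[List[int]]:
    regions: List[List[int]] = []
    for pos in positions:
        if regions and pos - regions[-1][-1] < merge_distance:
            regions[-1].append(pos)
        else:
            regions.append([pos])
    return regions


def define_binding_sites(
    candidates: Sequence[CandidateSite],
    merged_track: CrosslinkTrack,
    params: SiteCallParams,
    log: Optional[SiteCallLog] = None,
) -> List[BindingSite]:
    """Merge candidates into regions and emit centered, widened binding sites.

    Within a region, centers are picked iteratively at the position with the
    highest merged-track crosslink count (ties break 5'-most in transcript
    orientation). A chosen center consumes every candidate within
    ``2 * half_width`` of itself: the candidates inside the widened site
    define it, and the flanking band can no longer seed a site that would
    overlap it, which guarantees per-strand non-overlap. A site survives only
    if its center's candidate score is the maximum among candidate positions
    inside the site (ties at the center pass).
    """
    log = log if log is not None else SiteCallLog()
    log.n_candidates += len(candidates)
    by_key: Dict[Tuple[str, str], List[CandidateSite]] = {}
    for c in candidates:
        by_key.setdefault((c.interval.chrom, c.interval.strand), []).append(c)

    sites: List[BindingSite] = []
    counter = 0
    for (chrom, strand) in sorted(by_key):
        cands = sorted(by_key[(chrom, strand)], key=lambda c: c.pos)
        score_of = {c.pos: c.score for c in cands}
        regions = _chain_regions([c.pos for c in cands], params.merge_distance)
        for region in regions:
            if len(region) == 1:
                log.n_isolated_discarded += 1
                continue
            log.n_regions += 1
            remaining = set(region)
            while remaining:
                counts = {p: merged_track.get(chrom, strand, p) for p in remaining}
                best = max(counts.values())
                tied = [p for p, c in counts.items() if c == best]
                # 5'-most in transcript orientation
                center = min(tied) if strand == "+" else max(tied)
                start = center - params.half_width
                end = center + params.half_width + 1
                remaining -= {
                    p for p in remaining if abs(p - center) <= 2 * params.half_width
                }
                if start < 0:  # site would run off the chromosome edge
                    log.n_boundary_discarded += 1
                    continue
                in_site_scores = [
                    score_of[p] for p in region if start <= p < end
                ]
                if score_of[center] < max(in_site_scores):
                    log.n_score_rule_discarded += 1
                    continue
                counter += 1
                total = merged_track.window_sum(chrom, strand, start, end)
                sites.append(
                    BindingSite(
                        id=f"bs{counter:06d}",
                        interval=GenomicInterval(chrom, start, end, strand),
                        center=center,
                        total_count=int(total),
                        per_replicate_counts=(),
                        center_score=score_of[center],
                    )
                )
    _assert_non_overlapping(sites)
    log.n_sites_defined += len(sites)
    return sites


def _assert_non_overlapping(sites: Sequence[BindingSite]) -> None:
    by_key: Dict[Tuple[str, str], List[BindingSite]] = {}
    for s in sites:
        by_key.setdefault((s.interval.chrom, s.interval.strand), []).append(s)
    for group in by_key.values():
        group.sort(key=lambda s: s.interval.start)
        for a, b in zip(group, group[1:]):
            if b.interval.start < a.interval.end:
                raise AssertionError(
                    f"internal invariant violated: overlapping sites "
                    f"{a.id} and {b.id}"
                )


def attach_replicate_counts(
    sites: Sequence[BindingSite], tracks: Sequence[CrosslinkTrack]
) -> None:
    """Fill per-replicate counts (and total) for each site, in place."""
    for s in sites:
        iv = s.interval
        counts = tuple(
            int(t.window_sum(iv.chrom, iv.strand, iv.start, iv.end)) for t in tracks
        )
        s.per_replicate_counts = counts
        s.total_count = int(sum(counts))


def reproducibility_thresholds(
    sites: Sequence[BindingSite],
    tracks: Sequence[CrosslinkTrack],
    params: SiteCallParams,
) -> List[float]:
    """Per-replicate support threshold: the ``support_quantile`` of positive
    per-site counts of that replicate, floored at 1."""
    thresholds = []
    for r, track in enumerate(tracks):
        per_site = np.array([s.per_replicate_counts[r] for s in sites])
        positive = per_site[per_site > 0]
        if positive.size == 0:
            warnings.warn(
                f"replicate {track.label or r}: no site has crosslink events; "
                f"support threshold defaults to 1"
            )
            thresholds.append(1.0)
            continue
        t_r = float(np.quantile(positive, params.support_quantile))
        thresholds.append(max(t_r, 1.0))
    return thresholds


def reproducibility_filter(
    sites: Sequence[BindingSite],
    tracks: Sequence[CrosslinkTrack],
    params: SiteCallParams,
    log: Optional[SiteCallLog] = None,
) -> List[BindingSite]:
    """Keep sites supported in at least ``min_supporting_replicates`` replicates.

    A replicate supports a site when its in-site count reaches that
    replicate's coverage threshold (closed comparison by default).
    """
    params.validate(n_replicates=len(tracks))
    if sites and (not sites[0].per_replicate_counts or len(sites[0].per_replicate_counts) != len(tracks)):
        attach_replicate_counts(sites, tracks)
    if not sites:
        return []
    thresholds = reproducibility_thresholds(sites, tracks, params)
    kept = []
    for s in sites:
        if params.support_strict:
            support = sum(c > t for c, t in zip(s.per_replicate_counts, thresholds))
        else:
            support = sum(c >= t for c, t in zip(s.per_replicate_counts, thresholds))
        if support >= params.min_supporting_replicates:
            kept.append(s)
    if log is not None:
        log.replicate_thresholds = {
            (tracks[r].label or f"rep{r+1}"): thresholds[r] for r in range(len(tracks))
        }
        log.n_sites_after_reproducibility = len(kept)
    return kept


def call_binding_sites(
    tracks: Sequence[CrosslinkTrack],
    params: Optional[SiteCallParams] = None,
    candidates: Optional[Sequence[CandidateSite]] = None,
    grouping: Tuple[Tuple[int, int], Tuple[int, int]] = ((0, 1), (2, 3)),
) -> Tuple[List[BindingSite], SiteCallLog]:
    """End-to-end site definition from four replicate tracks.

    External candidates (a PureCLIP-like scored BED) may be supplied; if not,
    the fold-enrichment stand-in caller runs on the pseudo-replicates.
    """
    params = params or SiteCallParams()
    params.validate(n_replicates=len(tracks))
    log = SiteCallLog()
    if candidates is None:
        pseudo = merge_pseudoreplicates(tracks, grouping)
        candidates = call_candidate_sites(pseudo, params)
    merged = tracks[0]
    for t in tracks[1:]:
        merged = merged.merge(t, label="merged")
    sites = define_binding_sites(candidates, merged, params, log)
    attach_replicate_counts(sites, tracks)
    sites = reproducibility_filter(sites, tracks, params, log)
    return sites, log
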