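"""Naive reference implementations used only as independent test oracles."""

from typing import Dict, List, Sequence, Tuple


def brute_force_binding_sites(
    positions: Sequence[int],
    scores: Dict[int, float],
    counts: Dict[int, int],
    strand: str,
    merge_distance: int = 5,
    half_width: int = 2,
) -> List[Tuple[int, int, int]]:
    """Enumerate regions and centers by repeated naive scanning.

    Returns (start, end, center) triples. Semantics: chain candidates with
    successive distance < merge_distance; drop singleton regions; repeatedly
    scan the remaining candidates of a region for the one with the highest
    count (ties to the 5'-most in transcript orientation), widen by
    half_width, consume every candidate within 2*half_width of the center,
    and keep the site only when the center score is the maximum score over
    candidate positions inside the site.
    """
    positions = sorted(positions)
    # region chaining by exhaustive pairwise scan (deliberately naive)
    regions: List[List[int]] = []
    for p in positions:
        placed = False
        for region in regions:
            if any(abs(p - q) < merge_distance for q in region) and p > max(region):
                region.append(p)
                placed = True
                break
        if not placed:
            regions.append([p])

    out: List[Tuple[int, int, int]] = []
    for region in regions:
        if len(region) == 1:
            continue
        live = list(region)
        while live:
            best_count = max(counts.get(p, 0) for p in live)
            tied = [p for p in live if counts.get(p, 0) == best_count]
            center = min(tied) if strand == "+" else max(tied)
            start, end = center - half_width, center + half_width + 1
            live = [p for p in live if abs(p - center) > 2 * half_width]
            if start < 0:
                continue
            site_scores = [scores[p] for p in region if start <= p < end]
            if scores[center] >= max(site_scores):
                out.append((start, end, center))
    return sorted(out)


def bh_step_up(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(prev, pvalues[i] * m / rank_from_top)
        adj[i] = value
        prev = value
    return adj


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration of the support."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    pmf = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))
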