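import numpy as np
import pytest

from clipsite.model import CandidateSite, CrosslinkTrack, GenomicInterval
from clipsite.synthio import SimConfig, generate_all


@pytest.fixture(scope="session")
def small_run():
    """One 30-gene synthetic run shared by read-only tests."""
    cfg = SimConfig(n_genes=30, seed=7)
    genome, ann, truth, tracks, omics = generate_all(cfg)
    return dict(cfg=cfg, genome=genome, ann=ann, truth=truth, tracks=tracks, omics=omics)


def make_track(counts, chrom="chr1", strand="+", label="t"):
    """Build a track from a {pos: count} map."""
    t = CrosslinkTrack(label)
    for pos, c in counts.items():
        t.add(chrom, strand, pos, c)
    return t


def make_candidates(scored_positions, chrom="chr1", strand="+"):
    """Candidates from a {pos: score} map."""
    return [
        CandidateSite(GenomicInterval(chrom, p, p + 1, strand), s)
        for p, s in sorted(scored_positions.items())
    ]


def random_instance(rng, span=200, max_candidates=20, chrom="chr1", strand=None):
    """A random small site-calling instance (track + candidates)."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n = rng.integers(1, max_candidates + 1)
    positions = sorted(rng.choice(span, size=n, replace=False).tolist())
    scores = {p: float(np.round(rng.uniform(0.5, 8.0), 3)) for p in positions}
    counts = {}
    for p in positions:
        for off in range(-2, 3):
            q = p + off
            if q >= 0 and rng.random() < 0.7:
                counts[q] = counts.get(q, 0) + int(rng.integers(1, 30))
    track = make_track(counts, chrom=chrom, strand=strand)
    cands = make_candidates(scores, chrom=chrom, strand=strand)
    return track, cands
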