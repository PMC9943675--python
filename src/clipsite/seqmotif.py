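"""Sequence characterization of binding sites on spliced transcripts.

All analyses run in transcript orientation on the RNA alphabet (T is
normalized to U internally and re-expressed as T only at I/O). The three
5-mer scan windows relative to the binding-site center are
[-7, +7] (site plus 5 nt flanks), [-27, -8] upstream and [+8, +27]
downstream; sequence logos use a 51-nt window with a 21-nt display slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PURINES = frozenset("AG")
RNA_ALPHABET = "ACGU"

WINDOWS: Dict[str, Tuple[int, int]] = {
    "center": (-7, 7),
    "upstream": (-27, -8),
    "downstream": (8, 27),
    "logo": (-25, 25),
    "site": (-2, 2),
}


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTU", "TGCAA"))[::-1]


@dataclass
class KmerTable:
    """Relative k-mer frequencies per window class plus background."""

    k: int
    table: pd.DataFrame  # kmer, purine_count, freq_<class>..., freq_background
    n_skipped: Dict[str, int]

    def enrichment(self, window: str) -> pd.Series:
        freq = self.table[f"freq_{window}"]
        bg = self.table["freq_background"].replace(0.0, np.nan)
        out = freq / bg
        out.index = self.table["kmer"]
        return out


def extract_windows(
    tx_positions: Iterable[Tuple[str, int]],
    tx_sequences: Dict[str, str],
    bounds: Tuple[int, int],
) -> Tuple[List[str], int]:
    """Extract 5'->3' windows ``[center+lo, center+hi]`` around site centers.

    ``tx_positions`` are (transcript id, spliced center position) pairs.
    Windows falling outside the transcript are dropped and counted.
    """
    lo, hi = bounds
    out: List[str] = []
    dropped = 0
    for tid, center in tx_positions:
        seq = tx_sequences.get(tid)
        if seq is None:
            dropped += 1
            continue
        a, b = center + lo, center + hi + 1
        if a < 0 or b > len(seq):
            dropped += 1
            continue
        out.append(to_rna(seq[a:b]))
    return out, dropped


def sample_background(
    tx_sequences: Dict[str, str],
    eligible_transcripts: Iterable[str],
    n: int,
    width: int,
    rng: np.random.Generator,
) -> Tuple[List[str], List[Tuple[str, int]]]:
    """Draw ``n`` windows uniformly over all valid positions of the eligible
    (crosslinked) transcripts; returns (sequences, (transcript, start) pairs)."""
    if n < 1:
        raise ValueError("background sample size must be >= 1")
    tids = sorted(set(eligible_transcripts) & set(tx_sequences))
    slots = [(tid, len(tx_sequences[tid]) - width + 1) for tid in tids]
    slots = [(tid, m) for tid, m in slots if m > 0]
    total = sum(m for _, m in slots)
    if total == 0:
        raise ValueError(
            f"no eligible background positions of width {width} "
            f"across {len(tids)} transcripts"
        )
    cum = np.cumsum([m for _, m in slots])
    draws = rng.integers(0, total, size=n)
    seqs: List[str] = []
    positions: List[Tuple[str, int]] = []
    for d in draws:
        i = int(np.searchsorted(cum, d, side="right"))
        start = int(d - (cum[i - 1] if i else 0))
        tid = slots[i][0]
        seqs.append(to_rna(tx_sequences[tid][start : start + width]))
        positions.append((tid, start))
    return seqs, positions


def purine_count(kmer: str) -> int:
    return sum(b in PURINES for b in kmer)


def _count_kmers(seqs: Sequence[str], k: int) -> Tuple[Dict[str, int], int]:
    counts: Dict[str, int] = {}
    skipped = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if any(b not in RNA_ALPHABET for b in kmer):
                skipped += 1
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts, skipped


def kmer_enrichment(
    foreground: Dict[str, Sequence[str]],
    background: Sequence[str],
    k: int = 5,
) -> KmerTable:
    """Relative overlapping k-mer frequencies per window class vs background.

    Every possible k-mer appears in the table (zeros allowed); per class the
    frequencies sum to 1. K-mers spanning non-ACGU symbols are skipped and
    counted.
    """
    all_kmers = ["".join(p) for p in product(RNA_ALPHABET, repeat=k)]
    data: Dict[str, list] = {
        "kmer": all_kmers,
        "purine_count": [purine_count(m) for m in all_kmers],
    }
    n_skipped: Dict[str, int] = {}
    classes = dict(foreground)
    classes["background"] = list(background)
    for name, seqs in classes.items():
        counts, skipped = _count_kmers(seqs, k)
        n_skipped[name] = skipped
        total = sum(counts.values())
        data[f"freq_{name}"] = [
            counts.get(m, 0) / total if total else 0.0 for m in all_kmers
        ]
    return KmerTable(k=k, table=pd.DataFrame(data), n_skipped=n_skipped)


def logo_matrix(windows: Sequence[str]) -> pd.DataFrame:
    """Per-position base frequencies and information content (bits).

    Information content is ``2 - H(position)`` with the plug-in entropy
    estimate. Positions are indexed relative to the window center.
    """
    if not windows:
        raise ValueError("logo_matrix requires at least one window")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("logo windows must be equal length")
    center = width // 2
    rows = []
    for i in range(width):
        column = [w[i] for w in windows]
        n = sum(1 for b in column if b in RNA_ALPHABET)
        freqs = {b: (sum(1 for c in column if c == b) / n if n else 0.0) for b in RNA_ALPHABET}
        probs = np.array([freqs[b] for b in RNA_ALPHABET])
        nz = probs[probs > 0]
        entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else 2.0
        rows.append(
            dict(rel_pos=i - center, **{f"freq_{b}": freqs[b] for b in RNA_ALPHABET},
                 information_bits=2.0 - entropy)
        )
    return pd.DataFrame(rows)


def logo_display_slice(logo: pd.DataFrame, width: int = 21) -> pd.DataFrame:
    """Central slice of a logo matrix (the figure-style 21-nt view)."""
    half = width // 2
    return logo[(logo["rel_pos"] >= -half) & (logo["rel_pos"] <= half)].reset_index(drop=True)


def purine_stats(site_sequences: Sequence[str]) -> pd.DataFrame:
    """G-centered and >=3-purine fractions of 5-nt binding-site sequences."""
    seqs = [to_rna(s) for s in site_sequences]
    if any(len(s) != 5 for s in seqs):
        raise ValueError("site sequences must be exactly 5 nt")
    n = len(seqs)
    n_g = sum(1 for s in seqs if s[2] == "G")
    n_pur = sum(1 for s in seqs if purine_count(s) >= 3)
    return pd.DataFrame(
        [
            dict(statistic="center_is_G", numerator=n_g, denominator=n,
                 fraction=n_g / n if n else float("nan")),
            dict(statistic="three_or_more_purines", numerator=n_pur, denominator=n,
                 fraction=n_pur / n if n else float("nan")),
        ]
    )


def fraction_pct(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage rounded to the printed precision used in reports."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, digits)
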