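"""Single-strandedness analysis around binding sites.

Per-nucleotide unpaired probabilities in 501-nt windows are transformed to
log-odds (the raw probabilities are bimodal; the log-odds are bell-shaped)
and summarized as per-position z-scores of the foreground mean against the
distribution of background-draw means (resampled background: draws of
``n_regions_per_draw`` windows repeated ``n_draws`` times). P-values are
``2 * Phi(-|z|)`` with Benjamini-Hochberg correction over the displayed
central 201 positions, where edge-of-window folding bias is absent.

Three probability backends: ``external`` shells out to the RNAplfold binary
(equilibrium partition-function folding, sliding window w=100, max span
l=30), ``toy`` is a deterministic complementarity heuristic for desk-scale
tests, ``precomputed`` reads a per-position TSV.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .integrate import benjamini_hochberg

PROB_CLAMP = 1e-10


@dataclass
class AccessParams:
    window: int = 501
    fold_window: int = 100  # RNAplfold -W
    max_span: int = 30  # RNAplfold -L
    n_regions_per_draw: int = 1000
    n_draws: int = 1000
    display_center: int = 201
    seed: int = 0

    def validate(self) -> None:
        if self.window % 2 != 1:
            raise ValueError("window must be odd")
        if self.display_center > self.window:
            raise ValueError("display_center cannot exceed window")
        for name in ("fold_window", "max_span", "n_regions_per_draw", "n_draws"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# unpaired-probability backends
# ---------------------------------------------------------------------------

_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}


def _toy_unpaired(seq: str, max_span: int) -> np.ndarray:
    """Deterministic heuristic: 1 minus local complementarity density,
    logistic-squashed. A position surrounded by many Watson-Crick partners
    within the pairing span gets a low unpaired probability."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    density = np.zeros(n)
    # indicator of each base, cumulative sums for windowed partner counts
    cums = {}
    for base in "ACGU":
        ind = (arr == ord(base)).astype(np.float64)
        cums[base] = np.concatenate([[0.0], np.cumsum(ind)])
    for i in range(n):
        partner = _PAIR.get(seq[i])
        if partner is None:
            density[i] = 0.0
            continue
        a = max(0, i - max_span)
        b = min(n, i + max_span + 1)
        cnt = cums[partner][b] - cums[partner][a]
        span = b - a - 1
        density[i] = cnt / span if span > 0 else 0.0
    return 1.0 / (1.0 + np.exp(-(2.0 - 8.0 * density)))


def _external_unpaired(seq: str, fold_window: int, max_span: int) -> np.ndarray:
    """Unpaired probabilities from the RNAplfold binary (u = 1)."""
    exe = shutil.which("RNAplfold")
    if exe is None:
        raise RuntimeError(
            "RNAplfold binary not found; use backend='toy' or "
            "backend='precomputed' instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        proc = subprocess.run(
            [exe, "-W", str(min(fold_window, len(seq))), "-L", str(max_span), "-u", "1"],
            input=f">q\n{seq}\n",
            text=True,
            cwd=tmp,
            capture_output=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"RNAplfold failed: {proc.stderr.strip()}")
        lunp = Path(tmp) / "q_lunp"
        probs = np.full(len(seq), np.nan)
        for line in lunp.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            pos = int(fields[0]) - 1
            probs[pos] = float(fields[1]) if fields[1] != "NA" else np.nan
    return probs


def unpaired_probabilities(
    sequence: str,
    params: AccessParams,
    backend: str = "toy",
    precomputed: Optional[Union[str, Path, pd.DataFrame]] = None,
) -> np.ndarray:
    """Per-nucleotide probability of being unpaired, one of three backends."""
    params.validate()
    if backend == "toy":
        return _toy_unpaired(sequence, params.max_span)
    if backend == "external":
        return _external_unpaired(sequence, params.fold_window, params.max_span)
    if backend == "precomputed":
        if precomputed is None:
            raise ValueError("precomputed backend requires a table")
        df = (
            pd.read_csv(precomputed, sep="\t", float_precision="round_trip")
            if not isinstance(precomputed, pd.DataFrame)
            else precomputed
        )
        return df["prob"].to_numpy(dtype=float)
    raise ValueError(f"unknown backend {backend!r}")


def write_precomputed(probs: np.ndarray, path: Union[str, Path]) -> None:
    pd.DataFrame({"pos": np.arange(len(probs)), "prob": probs}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# log-odds and z-scores
# ---------------------------------------------------------------------------

def logodds(p: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Natural-log odds of an unpaired probability, clamped away from 0/1."""
    p = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return np.log(p / (1.0 - p))


def window_logodds(
    sequences: Sequence[str],
    params: AccessParams,
    backend: str = "toy",
) -> np.ndarray:
    """Log-odds matrix (n sequences x window) for equal-length windows."""
    rows = []
    for seq in sequences:
        if len(seq) != params.window:
            raise ValueError(
                f"window sequence length {len(seq)} != params.window {params.window}"
            )
        rows.append(logodds(unpaired_probabilities(seq, params, backend)))
    return np.asarray(rows)


@dataclass
class AccessibilityProfile:
    table: pd.DataFrame  # rel_pos, z, p, padj, bg_mean, bg_sd
    n_foreground: int
    n_background_pool: int


def accessibility_zscore(
    foreground: np.ndarray,
    background_pool: np.ndarray,
    params: AccessParams,
    rng: Optional[np.random.Generator] = None,
) -> AccessibilityProfile:
    """Resampled-background z-score profile of foreground accessibility.

    ``foreground`` and ``background_pool`` are log-odds matrices with
    ``params.window`` columns. Each of ``n_draws`` draws samples
    ``n_regions_per_draw`` background windows without replacement (with
    replacement across draws); per position the z-score compares the
    foreground mean with the mean/SD of the draw means. BH correction runs
    across the central ``display_center`` positions only.
    """
    params.validate()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    foreground = np.asarray(foreground, dtype=float)
    background_pool = np.asarray(background_pool, dtype=float)
    if foreground.ndim != 2 or foreground.shape[1] != params.window:
        raise ValueError("foreground must be (n, window)")
    nb = background_pool.shape[0]
    if nb < params.n_regions_per_draw:
        raise ValueError(
            f"background pool has {nb} windows; need at least "
            f"{params.n_regions_per_draw} per draw"
        )
    m = foreground.mean(axis=0)
    draw_means = np.empty((params.n_draws, params.window))
    for d in range(params.n_draws):
        idx = rng.choice(nb, size=params.n_regions_per_draw, replace=False)
        draw_means[d] = background_pool[idx].mean(axis=0)
    bg_mean = draw_means.mean(axis=0)
    bg_sd = draw_means.std(axis=0, ddof=1)
    zero = np.nonzero(bg_sd == 0)[0]
    if zero.size:
        half = params.window // 2
        raise ValueError(
            f"background SD is zero at relative position {int(zero[0]) - half}; "
            f"z-score undefined"
        )
    z = (m - bg_mean) / bg_sd
    p = 2.0 * norm.sf(np.abs(z))

    half = params.window // 2
    rel = np.arange(params.window) - half
    chalf = params.display_center // 2
    central = np.abs(rel) <= chalf
    padj = np.full(params.window, np.nan)
    padj[central] = benjamini_hochberg(p[central])

    table = pd.DataFrame(
        dict(rel_pos=rel, z=z, p=p, padj=padj, bg_mean=bg_mean, bg_sd=bg_sd)
    )
    return AccessibilityProfile(
        table=table, n_foreground=foreground.shape[0], n_background_pool=nb
    )
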