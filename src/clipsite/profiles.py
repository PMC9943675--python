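"""Crosslink-pattern summaries: normalized heatmaps and metaprofiles.

Per-window crosslink vectors are min-max normalized (accounting for
expression differences between transcripts), smoothed with a cubic smoothing
spline and inflated to a fixed output dimension; site metaprofiles average
the normalized signal in a 65-nt window around binding-site centers; scaled
metaprofiles kernel-density-estimate crosslink positions rescaled to [0, 1]
within their region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.stats import gaussian_kde

from .model import BindingSite, CrosslinkTrack, GenomicInterval


@dataclass
class ProfileParams:
    heatmap_first_n: int = 300
    coverage_min: float = 1e2
    coverage_max: float = 1e6
    smooth_param: float = 0.5  # 0..1 roughness-penalty weight
    out_dim: int = 500
    site_window: int = 65

    def validate(self) -> None:
        if not self.coverage_min < self.coverage_max:
            raise ValueError("coverage_min must be < coverage_max")
        if self.out_dim < 2:
            raise ValueError("out_dim must be >= 2")
        if self.site_window % 2 != 1:
            raise ValueError("site_window must be odd")
        if not 0 <= self.smooth_param < 1:
            raise ValueError("smooth_param must lie in [0, 1)")


def minmax_normalize(vector: Sequence[float]) -> np.ndarray:
    """Affine rescale to [0, 1]; constant vectors map to zeros."""
    x = np.asarray(vector, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _lam_from_smooth_param(spar: float, n: int) -> float:
    # exponential map of the 0..1 smoothing weight onto the penalty scale;
    # the n^-3 factor keeps the effective roughness penalty stable across
    # input lengths, and spar=0.5 visibly smooths unit-variance noise while
    # preserving isolated peaks
    return 256.0 ** (3.0 * spar - 1.0) / n**3


def smooth_profile(vector: Sequence[float], params: ProfileParams) -> np.ndarray:
    """Cubic smoothing spline evaluated on ``out_dim`` equally spaced points.

    Vectors shorter than 4 fall back to linear interpolation with a warning.
    """
    params.validate()
    y = np.asarray(vector, dtype=float)
    grid = np.linspace(0.0, 1.0, params.out_dim)
    if y.size < 4:
        warnings.warn("profile shorter than 4 points; linear interpolation used")
        x = np.linspace(0.0, 1.0, y.size) if y.size > 1 else np.array([0.5])
        return np.interp(grid, x, y)
    x = np.linspace(0.0, 1.0, y.size)
    if params.smooth_param == 0.0:
        spline = make_smoothing_spline(x, y, lam=0.0)
    else:
        spline = make_smoothing_spline(x, y, lam=_lam_from_smooth_param(params.smooth_param, y.size))
    return np.asarray(spline(grid))


def region_window_heatmap(
    track: CrosslinkTrack,
    regions: Sequence[GenomicInterval],
    params: ProfileParams,
    region_ids: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Normalized, smoothed heatmap over the first N nt of each region.

    Each region contributes the crosslink counts of its first
    ``heatmap_first_n`` nt in 5'->3' orientation; regions whose window total
    falls outside ``[coverage_min, coverage_max]`` are excluded. Rows are
    min-max normalized, spline-smoothed to ``out_dim`` columns and sorted by
    the position of their maximum.
    """
    params.validate()
    region_ids = list(region_ids) if region_ids is not None else [
        f"r{i}" for i in range(len(regions))
    ]
    rows = []
    kept: List[str] = []
    argmaxes = []
    for rid, iv in zip(region_ids, regions):
        n = min(params.heatmap_first_n, len(iv))
        if iv.strand == "+":
            counts = track.window_counts(iv.chrom, iv.strand, iv.start, iv.start + n)
        else:
            counts = track.window_counts(iv.chrom, iv.strand, iv.end - n, iv.end)[::-1]
        total = counts.sum()
        if not params.coverage_min <= total <= params.coverage_max:
            continue
        smoothed = smooth_profile(minmax_normalize(counts), params)
        rows.append(smoothed)
        kept.append(rid)
        argmaxes.append(int(np.argmax(smoothed)))
    if not rows:
        return np.empty((0, params.out_dim)), []
    order = np.argsort(argmaxes, kind="mergesort")
    matrix = np.asarray(rows)[order]
    kept = [kept[i] for i in order]
    return matrix, kept


def site_metaprofile(
    track: CrosslinkTrack,
    sites: Sequence[BindingSite],
    params: ProfileParams,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Mean min-max-normalized crosslink signal around site centers.

    Returns (metaprofile vector of length ``site_window``, per-site matrix,
    number of skipped sites). Windows run 5'->3' in transcript orientation.
    """
    params.validate()
    half = params.site_window // 2
    rows = []
    skipped = 0
    for s in sites:
        iv = s.interval
        a, b = s.center - half, s.center + half + 1
        if a < 0:
            skipped += 1
            continue
        counts = track.window_counts(iv.chrom, iv.strand, a, b).astype(float)
        if iv.strand == "-":
            counts = counts[::-1]
        rows.append(minmax_normalize(counts))
    if not rows:
        return np.zeros(params.site_window), np.empty((0, params.site_window)), skipped
    matrix = np.asarray(rows)
    return matrix.mean(axis=0), matrix, skipped


def scaled_region_metaprofile(
    track: CrosslinkTrack,
    regions_by_group: Dict[str, Sequence[GenomicInterval]],
    grid_points: int = 200,
) -> Dict[str, pd.DataFrame]:
    """Density of crosslink events over positions scaled to [0, 1] per group.

    Every event at position x of a region of length L contributes its scaled
    position (5'->3'); the density is a Gaussian KDE (Silverman bandwidth)
    with boundary reflection at 0 and 1. Empty groups are omitted with a
    warning.
    """
    out: Dict[str, pd.DataFrame] = {}
    grid = np.linspace(0.0, 1.0, grid_points)
    for group, regions in regions_by_group.items():
        scaled: List[float] = []
        for iv in regions:
            if len(iv) < 1:
                continue
            counts = track.window_counts(iv.chrom, iv.strand, iv.start, iv.end)
            if iv.strand == "-":
                counts = counts[::-1]
            pos = np.nonzero(counts)[0]
            for p in pos:
                scaled.extend([p / len(iv)] * int(counts[p]))
        if len(scaled) < 2:
            warnings.warn(f"group {group!r} has fewer than 2 events; omitted")
            continue
        data = np.asarray(scaled)
        augmented = np.concatenate([data, -data, 2.0 - data])
        kde = gaussian_kde(augmented, bw_method="silverman")
        density = 3.0 * kde(grid)
        out[group] = pd.DataFrame({"scaled_pos": grid, "density": density})
    return out
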