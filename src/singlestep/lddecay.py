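"""Linkage-disequilibrium decay from genotype correlations.

r² between marker pairs is the squared Pearson correlation of gene-content
vectors (the genotype-based analogue of haplotype r², equal to it under
random mating).  Pairwise r² within a maximum distance is binned by physical
distance; the decay distance is where the binned mean first drops below a
threshold (default r² = 0.2), linearly interpolated between bin midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from singlestep.genotypes import MarkerData


@dataclass(frozen=True)
class LdCurve:
    """Binned LD decay: (bin bounds, mean r², pair count) per distance bin."""

    bins: pd.DataFrame
    max_dist_bp: int
    r2_threshold: float
    decay_distance_bp: float

    def mean_r2(self) -> np.ndarray:
        return self.bins["mean_r2"].to_numpy()


def pair_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared genotype correlation between two markers.

    Computed on jointly non-missing samples; returns NaN (undefined) when a
    marker is monomorphic on that joint set.  Invariant to allele-label
    flips and symmetric in its arguments.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("call vectors must have equal length")
    joint = ~np.isnan(g1) & ~np.isnan(g2)
    if joint.sum() < 2:
        raise ValueError("need at least two jointly non-missing samples")
    a, b = g1[joint], g2[joint]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def decay_curve(
    md: MarkerData,
    max_dist_bp: int = 1_000_000,
    bin_width_bp: int = 10_000,
    r2_threshold: float = 0.2,
) -> LdCurve:
    """Mean r² by distance bin over all intra-chromosomal pairs within
    ``max_dist_bp``.

    Markers are sorted by map position internally, so shuffled input gives
    identical results.  Missing calls are mean-imputed before the vectorized
    correlation; monomorphic markers are excluded.  Bins without pairs have
    ``mean_r2`` = NaN (undefined, not zero).
    """
    md = md.sorted_by_map()
    edges = np.arange(0, max_dist_bp + bin_width_bp, bin_width_bp)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    for c in pd.unique(md.chrom):
        sel = np.where(md.chrom == c)[0]
        if sel.size < 2:
            continue
        calls = md.calls[:, sel].copy()
        mu = np.nanmean(calls, axis=0)
        miss = np.isnan(calls)
        if miss.any():
            calls[miss] = np.broadcast_to(mu, calls.shape)[miss]
        sd = calls.std(axis=0)
        poly = sd > 0
        sel, calls, sd = sel[poly], calls[:, poly], sd[poly]
        if sel.size < 2:
            continue
        std = (calls - calls.mean(axis=0)) / sd
        corr = (std.T @ std) / calls.shape[0]
        cp = md.pos[sel].astype(np.int64)
        for i in range(len(sel) - 1):
            hi = np.searchsorted(cp, cp[i] + max_dist_bp, side="right")
            if hi <= i + 1:
                continue
            d = cp[i + 1: hi] - cp[i]
            r2 = corr[i, i + 1: hi] ** 2
            which = np.minimum((d - 1) // bin_width_bp, n_bins - 1)
            np.add.at(sums, which, r2)
            np.add.at(counts, which, 1)

    if counts.sum() == 0:
        raise ValueError("no qualifying marker pairs within max_dist_bp")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = pd.DataFrame({
        "bin_lo_bp": edges[:-1],
        "bin_hi_bp": edges[1:],
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })
    decay = _decay_distance(bins, r2_threshold)
    return LdCurve(bins=bins, max_dist_bp=max_dist_bp,
                   r2_threshold=r2_threshold, decay_distance_bp=decay)


def _decay_distance(bins: pd.DataFrame, threshold: float) -> float:
    """First crossing of the binned mean below the threshold, linearly
    interpolated between adjacent occupied bin midpoints; NaN if never."""
    occ = bins[bins["n_pairs"] > 0]
    mids = ((occ["bin_lo_bp"] + occ["bin_hi_bp"]) / 2.0).to_numpy()
    r2 = occ["mean_r2"].to_numpy()
    if len(r2) == 0:
        return float("nan")
    if r2[0] < threshold:
        return float(mids[0])
    below = np.where(r2 < threshold)[0]
    if below.size == 0:
        return float("nan")
    k = below[0]
    x0, x1, y0, y1 = mids[k - 1], mids[k], r2[k - 1], r2[k]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - threshold) * (x1 - x0) / (y0 - y1))
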