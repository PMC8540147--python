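"""Linkage-disequilibrium decay: pairwise r-squared against genetic distance.

r-squared here is the squared Pearson correlation of genotype dosages over
the samples called at both markers (the composite, phase-free measure
appropriate to unphased array calls).  Pairs are restricted to the same
chromosome and a maximum cM separation.  The decay curve is the binned mean
of r-squared by distance, and the headline quantity is the distance at which
that curve first falls below a threshold (linear interpolation between bin
centers), e.g. the distance at r^2 = 0.1 used to set a gene-linkage window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, validate_marker_map

__all__ = [
    "pairwise_r2",
    "DecayCurve",
    "decay_curve",
    "distance_at_threshold",
    "plot_decay",
]


def pairwise_r2(
    gm: GenotypeMatrix,
    marker_map: pd.DataFrame,
    max_dist_cM: float = 50.0,
    min_shared_calls: int = 10,
) -> pd.DataFrame:
    """LDTable: same-chromosome marker pairs with distance and r-squared.

    Pairs with fewer than ``min_shared_calls`` jointly called samples or
    with zero dosage variance at either marker are skipped (counted in the
    ``n_skipped`` attribute of the returned frame).
    """
    marker_map = validate_marker_map(marker_map)
    pos = marker_map.set_index("marker_id")
    missing = [m for m in gm.marker_ids if m not in pos.index]
    if missing:
        raise ValueError(f"markers without map positions: {missing[:5]}")
    g = gm.dosages.astype(float)
    g[gm.missing_mask] = np.nan
    rows = []
    n_skipped = 0
    chrom = pos.loc[list(gm.marker_ids), "chromosome"].to_numpy()
    cm = pos.loc[list(gm.marker_ids), "position_cM"].to_numpy(dtype=float)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = idx[np.argsort(cm[idx], kind="stable")]
        for a_i, i in enumerate(order):
            for j in order[a_i + 1 :]:
                dist = abs(cm[j] - cm[i])
                if dist > max_dist_cM:
                    break
                x, y = g[:, i], g[:, j]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < min_shared_calls:
                    n_skipped += 1
                    continue
                xs, ys = x[ok], y[ok]
                vx, vy = xs.var(), ys.var()
                if vx == 0 or vy == 0:
                    n_skipped += 1
                    continue
                cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
                rows.append(
                    {
                        "marker_a": gm.marker_ids[i],
                        "marker_b": gm.marker_ids[j],
                        "chromosome": c,
                        "dist_cM": dist,
                        "r2": cov * cov / (vx * vy),
                    }
                )
    if not rows:
        raise ValueError("no eligible marker pairs")
    table = pd.DataFrame(rows)
    table.attrs["n_skipped"] = n_skipped
    return table


@dataclass
class DecayCurve:
    """Binned LD-decay profile."""

    bin_left: np.ndarray
    bin_center: np.ndarray
    mean_r2: np.ndarray  # NaN for empty bins
    n_pairs: np.ndarray
    bin_width: float


def decay_curve(ld_table: pd.DataFrame, bin_width: float = 0.25) -> DecayCurve:
    """Mean r-squared in contiguous distance bins starting at 0."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = ld_table["dist_cM"].to_numpy(dtype=float)
    r2 = ld_table["r2"].to_numpy(dtype=float)
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    which = np.minimum((d / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    left = np.arange(n_bins) * bin_width
    if (counts > 0).sum() < 2:
        raise ValueError("need at least 2 nonempty bins")
    return DecayCurve(left, left + bin_width / 2.0, means, counts, bin_width)


def distance_at_threshold(curve: DecayCurve, r2_threshold: float = 0.1) -> float:
    """cM distance at which binned mean r-squared crosses the threshold.

    Scans nonempty bins outward from 0 and linearly interpolates between
    the last bin center at/above the threshold and the first below it.
    Returns +inf if the curve never falls below the threshold.
    """
    ok = ~np.isnan(curve.mean_r2)
    centers = curve.bin_center[ok]
    means = curve.mean_r2[ok]
    below = means < r2_threshold
    if not below.any():
        return np.inf
    first_below = int(np.argmax(below))
    if first_below == 0:
        return float(centers[0])
    x0, x1 = centers[first_below - 1], centers[first_below]
    y0, y1 = means[first_below - 1], means[first_below]
    return float(x0 + (y0 - r2_threshold) / (y0 - y1) * (x1 - x0))


def plot_decay(curve: DecayCurve, r2_threshold: float | None = 0.1, ax=None):
    """Diagnostic scatter of binned mean r-squared vs distance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = ~np.isnan(curve.mean_r2)
    ax.plot(curve.bin_center[ok], curve.mean_r2[ok], "o-", ms=3)
    if r2_threshold is not None:
        ax.axhline(r2_threshold, ls="--", color="grey")
    ax.set_xlabel("distance (cM)")
    ax.set_ylabel("mean $r^2$")
    return ax
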