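"""Linkage disequilibrium: pairwise r², decay curves, and r²₀.₃.

r² is the squared Pearson correlation between the dosage vectors of two
variants over the samples called at both ("composite" LD — phase-free, the
appropriate choice for unphased chip genotypes). Decay curves average r²
in contiguous physical-distance bins per population; because LD levels are
sensitive to sample size, populations are compared after downsampling to
equal n. The summary statistic r²₀.₃ is the physical distance at which the
binned mean r² drops — and stays — below 0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

log = logging.getLogger("selsig")

#: Sentinel returned when a decay curve never settles below the threshold.
NOT_REACHED = "not_reached"


def pairwise_r2(
    g: GenotypeMatrix,
    max_dist: int = 500_000,
    sample_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """All same-chromosome variant pairs within ``max_dist`` bp.

    Returns a DataFrame with columns ``vid_i, vid_j, dist, r2``. For each
    pair the correlation uses pairwise-complete samples; pairs where either
    variant is monomorphic in that subset (or with <2 complete samples) are
    skipped and counted in the log. Variants must be sorted by (chrom, pos).
    """
    v = g.variants
    chrom_arr = v["chrom"].to_numpy()
    pos_arr = v["pos"].to_numpy()
    for c in np.unique(chrom_arr):
        if not np.all(np.diff(pos_arr[chrom_arr == c]) > 0):
            raise ValueError(f"variants not position-sorted on chromosome {c}")
    order_ok = v.groupby("chrom", sort=False).ngroup().is_monotonic_increasing
    if not order_ok:
        raise ValueError("variants not grouped by chromosome")

    calls = g.calls if sample_index is None else g.calls[sample_index, :]
    X = calls.astype(float)
    valid = calls != MISSING

    out_i, out_j, out_d, out_r2 = [], [], [], []
    n_skipped = 0
    for c in dict.fromkeys(chrom_arr):
        idx = np.flatnonzero(chrom_arr == c)
        pos = pos_arr[idx]
        for a, i in enumerate(idx):
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            J = idx[a + 1 : hi]
            if J.size == 0:
                continue
            xi = X[:, i][:, None]
            vi = valid[:, i][:, None]
            XJ = X[:, J]
            both = vi & valid[:, J]
            n = both.sum(axis=0).astype(float)
            xw = np.where(both, xi, 0.0)
            yw = np.where(both, XJ, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sx = xw.sum(axis=0)
                sy = yw.sum(axis=0)
                sxx = (xw * xw).sum(axis=0) - sx * sx / n
                syy = (yw * yw).sum(axis=0) - sy * sy / n
                sxy = (xw * yw).sum(axis=0) - sx * sy / n
                r2 = (sxy * sxy) / (sxx * syy)
            ok = (n >= 2) & (sxx > 0) & (syy > 0)
            n_skipped += int((~ok).sum())
            out_i.extend([v["vid"].iloc[i]] * int(ok.sum()))
            out_j.extend(v["vid"].iloc[J[ok]])
            out_d.append(pos_arr[J[ok]] - pos[a])
            out_r2.append(np.clip(r2[ok], 0.0, 1.0))
    if n_skipped:
        log.info("pairwise_r2: skipped %d monomorphic/undersized pairs", n_skipped)
    return pd.DataFrame(
        {
            "vid_i": out_i,
            "vid_j": out_j,
            "dist": np.concatenate(out_d) if out_d else np.array([], dtype=int),
            "r2": np.concatenate(out_r2) if out_r2 else np.array([], dtype=float),
        }
    )


@dataclass(frozen=True)
class LDDecayCurve:
    """Mean r² per physical-distance bin; empty bins hold nan, not 0."""

    bin_edges: np.ndarray  # len = n_bins + 1, contiguous ascending
    mean_r2: np.ndarray  # nan where n_pairs == 0
    n_pairs: np.ndarray
    population: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        occupied = self.n_pairs > 0
        vals = self.mean_r2[occupied]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("mean r2 out of [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
                "population": self.population,
            }
        )


def decay_curve(
    pairs: pd.DataFrame,
    bin_width: int = 1_000,
    max_dist: int | None = None,
    population: str = "",
) -> LDDecayCurve:
    """Bin pair r² by distance into [k·w, (k+1)·w) bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dist = np.asarray(pairs["dist"], dtype=float)
    r2 = np.asarray(pairs["r2"], dtype=float)
    if max_dist is None:
        max_dist = int(dist.max()) + 1 if dist.size else bin_width
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    k = np.minimum((dist // bin_width).astype(int), n_bins - 1)
    n = np.bincount(k, minlength=n_bins) if dist.size else np.zeros(n_bins, int)
    s = np.bincount(k, weights=r2, minlength=n_bins) if dist.size else np.zeros(n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return LDDecayCurve(bin_edges=edges, mean_r2=mean, n_pairs=n, population=population)


def r2_threshold_distance(
    curve: LDDecayCurve, threshold: float = 0.3
) -> int | str:
    """Distance (bp) past which the binned mean r² stays below ``threshold``.

    Returns the left edge of the first occupied bin from which every later
    occupied bin is also below threshold; 0 if the first occupied bin already
    qualifies and is the origin bin; the ``NOT_REACHED`` sentinel if the
    curve never settles below the threshold. Empty bins are ignored (never
    interpolated).
    """
    occ = np.flatnonzero(curve.n_pairs > 0)
    if occ.size == 0:
        raise ValueError("decay curve has no occupied bins")
    below = curve.mean_r2[occ] < threshold
    # last occupied bin at/above threshold; answer is the next occupied bin
    above = np.flatnonzero(~below)
    if above.size == 0:
        first = occ[0]
        return 0 if first == 0 else int(curve.bin_edges[first])
    if above[-1] == occ.size - 1:
        return NOT_REACHED
    return int(curve.bin_edges[occ[above[-1] + 1]])


def downsample(
    g: GenotypeMatrix, population: str, n: int, seed: int = 0
) -> GenotypeMatrix:
    """Uniformly subsample one population to ``n`` samples (others untouched)."""
    idx = g.sample_indices(population)
    if n > idx.size:
        raise ValueError(
            f"cannot downsample population {population!r} of size {idx.size} to {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(idx, size=n, replace=False))
    keep = np.sort(
        np.concatenate(
            [chosen, np.setdiff1d(np.arange(g.n_samples), idx, assume_unique=False)]
        )
    )
    return g.subset_samples(keep)


def population_decay_curves(
    g: GenotypeMatrix,
    max_dist: int = 500_000,
    bin_width: int = 1_000,
    equalize_n: bool = True,
    seed: int = 0,
) -> dict[str, LDDecayCurve]:
    """Per-population decay curves, optionally at equal sample sizes."""
    pops = g.populations
    if equalize_n and len(pops) > 1:
        n_min = min(g.sample_indices(p).size for p in pops)
        for p in pops:
            g = downsample(g, p, n_min, seed=seed)
    out = {}
    for p in pops:
        pairs = pairwise_r2(g, max_dist=max_dist, sample_index=g.sample_indices(p))
        out[p] = decay_curve(pairs, bin_width=bin_width, max_dist=max_dist, population=p)
    return out
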