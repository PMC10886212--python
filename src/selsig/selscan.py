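"""Sliding-window sweep scan: FST, nucleotide diversity ratio, thresholds.

The scan slides a fixed window (default 5 Mb, step 100 kb) along each
chromosome and computes, from per-SNP allele frequencies in the two
populations:

* Nei-style FST per window, as a ratio of sums over the window's SNPs:
  ``FST = (Σ Ht - Σ Hs) / Σ Ht`` with per-SNP
  ``Hs = [2p̂₁(1-p̂₁) + 2p̂₂(1-p̂₂)] / 2`` and ``Ht = 2p̄(1-p̄)``,
  p̄ the unweighted mean of the two population frequencies. A
  Weir–Cockerham estimator is available as a flag for comparison with
  common tooling.
* Nucleotide diversity θπ per population, per bp: the sum over the window's
  SNPs of the unbiased per-site heterozygosity ``(n_c/(n_c-1))·2p̂(1-p̂)``
  (n_c = called alleles), divided by the window length.
* The diversity ratio θπ(pop1)/θπ(pop2) — pop1 is the numerator population.

Windows beyond empirical quantile thresholds are called as sweeps: a window
is selected for the numerator population when FST is in the top fraction
(default 1%) AND the ratio is in the bottom fraction (its diversity is
depleted), and for the denominator population when FST is in the top
fraction AND the ratio is in the top fraction. Thresholds are nearest-rank
quantiles applied inclusively on the unscaled statistics; min–max scaling is
provided for display and is rank-preserving, so scaled thresholds would
select identical windows. Selected windows are merged per direction into
regions, and the SNPs inside the regions are the candidate SNPs.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

log = logging.getLogger("selsig")

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps", "fst", "pi_p1", "pi_p2", "pi_ratio",
]


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------

def window_starts(chrom_len: int, window: int, step: int) -> np.ndarray:
    """1-based start positions; floor((L - window)/step) + 1 windows for L >= window."""
    if window < step:
        raise ValueError("window must be >= step")
    if chrom_len < window:
        return np.array([], dtype=np.int64)
    n = (chrom_len - window) // step + 1
    return 1 + step * np.arange(n, dtype=np.int64)


def chromosome_lengths(g: GenotypeMatrix) -> dict[str, int]:
    """Fallback chromosome lengths: the last SNP position per chromosome."""
    return {
        str(c): int(p)
        for c, p in g.variants.groupby("chrom", sort=False)["pos"].max().items()
    }


def _per_snp_stats(g: GenotypeMatrix, pop1: str, pop2: str) -> pd.DataFrame:
    """Per-SNP frequencies, heterozygosities and unbiased per-site diversity."""
    i1 = g.sample_indices(pop1)
    i2 = g.sample_indices(pop2)

    def pop_stats(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        calls = g.calls[idx, :]
        called = calls != MISSING
        n_c = 2 * called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_c > 0, alt / np.maximum(n_c, 1), np.nan)
            pi = np.where(
                n_c >= 2, (n_c / np.maximum(n_c - 1, 1)) * 2.0 * p * (1.0 - p), np.nan
            )
        return p, pi, n_c

    p1, pi1, n1 = pop_stats(i1)
    p2, pi2, n2 = pop_stats(i2)
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    return pd.DataFrame(
        {
            "chrom": g.variants["chrom"].to_numpy(),
            "pos": g.variants["pos"].to_numpy(),
            "p1": p1, "p2": p2, "pi1": pi1, "pi2": pi2,
            "n1": n1, "n2": n2, "hs": hs, "ht": ht,
        }
    )


def _wc_per_snp(g: GenotypeMatrix, pop1: str, pop2: str) -> tuple[np.ndarray, np.ndarray]:
    """Weir–Cockerham per-SNP variance components (a, a+b+c) for 2 demes."""
    comps = []
    for pop in (pop1, pop2):
        calls = g.calls[g.sample_indices(pop), :]
        called = calls != MISSING
        n = called.sum(axis=0).astype(float)  # diploid individuals called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(calls != MISSING, calls, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h = np.where(called, calls == 1, False).sum(axis=0) / np.maximum(n, 1)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, a + b + c


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def _window_sums(
    pos: np.ndarray, values: np.ndarray, starts: np.ndarray, window: int
) -> np.ndarray:
    """Sum ``values`` (nan = skip) over SNPs inside each [start, start+window-1]."""
    vals = np.nan_to_num(values, nan=0.0)
    cum = np.concatenate([[0.0], np.cumsum(vals)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window - 1, side="right")
    return cum[hi] - cum[lo]


def scan_windows(
    g: GenotypeMatrix,
    pop1: str,
    pop2: str,
    window: int = 5_000_000,
    step: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
    fst_estimator: str = "nei",
) -> pd.DataFrame:
    """Sliding-window FST and per-population θπ over both populations.

    Returns one row per window: chrom, start, end (1-based inclusive),
    n_snps, fst, pi_p1, pi_p2 (per bp), pi_ratio (pop1/pop2). Windows where
    Σ Ht = 0 (FST undefined) get nan fst; windows where θπ(pop2) = 0 get nan
    pi_ratio. SNPs lacking >= 2 called alleles in either population are
    excluded from all sums.
    """
    if pop1 == pop2:
        raise ValueError("population labels must differ")
    if fst_estimator not in ("nei", "wc"):
        raise ValueError(f"unknown fst estimator {fst_estimator!r}")
    snp = _per_snp_stats(g, pop1, pop2)
    usable = (snp["n1"] >= 2) & (snp["n2"] >= 2)
    if fst_estimator == "wc":
        wc_num, wc_den = _wc_per_snp(g, pop1, pop2)
    lengths = chrom_lengths or chromosome_lengths(g)

    rows = []
    for chrom in dict.fromkeys(snp["chrom"]):
        sel = (snp["chrom"] == chrom).to_numpy() & usable.to_numpy()
        sub = snp[sel]
        pos = sub["pos"].to_numpy()
        L = int(lengths.get(str(chrom), pos.max() if len(pos) else 0))
        starts = window_starts(L, window, step)
        if starts.size == 0:
            continue
        n_snps = _window_sums(pos, np.ones(len(sub)), starts, window).astype(int)
        if fst_estimator == "nei":
            num = _window_sums(pos, sub["ht"].to_numpy() - sub["hs"].to_numpy(), starts, window)
            den = _window_sums(pos, sub["ht"].to_numpy(), starts, window)
        else:
            num = _window_sums(pos, wc_num[sel], starts, window)
            den = _window_sums(pos, wc_den[sel], starts, window)
        pi1 = _window_sums(pos, sub["pi1"].to_numpy(), starts, window) / window
        pi2 = _window_sums(pos, sub["pi2"].to_numpy(), starts, window) / window
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
            ratio = np.where(pi2 > 0, pi1 / np.where(pi2 > 0, pi2, 1.0), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": str(chrom),
                    "start": starts,
                    "end": starts + window - 1,
                    "n_snps": n_snps,
                    "fst": fst,
                    "pi_p1": pi1,
                    "pi_p2": pi2,
                    "pi_ratio": ratio,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def window_pi(
    g: GenotypeMatrix,
    population: str,
    window: int = 5_000_000,
    step: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window θπ (per bp) for one population: chrom, start, end, n_snps, pi."""
    others = [p for p in g.populations if p != population]
    if not others:
        g.sample_indices(population)  # raises for unknown labels
        raise ValueError("window_pi needs a second population present in the matrix")
    w = scan_windows(g, population, others[0], window, step, chrom_lengths)
    return w[["chrom", "start", "end", "n_snps"]].assign(pi=w["pi_p1"])


def window_fst(
    g: GenotypeMatrix,
    pop1: str,
    pop2: str,
    window: int = 5_000_000,
    step: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
    fst_estimator: str = "nei",
) -> pd.DataFrame:
    """Per-window FST between two populations."""
    w = scan_windows(g, pop1, pop2, window, step, chrom_lengths, fst_estimator)
    return w[["chrom", "start", "end", "n_snps", "fst"]]


# ---------------------------------------------------------------------------
# scaling and thresholds
# ---------------------------------------------------------------------------

def minmax_scale(values: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); nan entries pass through; error if degenerate."""
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to scale")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError("min-max scaling undefined: all values equal")
    return (x - lo) / (hi - lo)


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the value at rank ceil(q*m) of the sorted sample."""
    x = np.sort(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    rank = max(1, math.ceil(q * x.size))
    return float(x[rank - 1])


@dataclass(frozen=True)
class SweepCallSet:
    """Thresholds, selected windows per direction, merged regions, candidates."""

    fst_q99: float
    ratio_q99: float
    ratio_q01: float
    windows_pop1_selected: pd.DataFrame
    windows_pop2_selected: pd.DataFrame
    regions_pop1: pd.DataFrame  # chrom, start, end (1-based inclusive)
    regions_pop2: pd.DataFrame
    candidate_snps: pd.DataFrame  # variant columns + direction
    pop1: str = "pop1"
    pop2: str = "pop2"

    def thresholds_dict(self) -> dict[str, float]:
        return {
            "fst_q99": self.fst_q99,
            "ratio_q99": self.ratio_q99,
            "ratio_q01": self.ratio_q01,
        }

    def write_thresholds(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.thresholds_dict(), indent=2) + "\n")


def merge_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended 1-based inclusive windows per chromosome."""
    if windows.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif int(s) <= cur_e + 1:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _snps_in_regions(
    g: GenotypeMatrix, regions: pd.DataFrame, direction: str
) -> pd.DataFrame:
    hits = []
    v = g.variants
    for r in regions.itertuples(index=False):
        m = (v["chrom"].astype(str) == str(r.chrom)) & v["pos"].between(r.start, r.end)
        hits.append(v[m])
    if not hits:
        return v.iloc[0:0].assign(direction=pd.Series(dtype=str))
    out = pd.concat(hits).drop_duplicates(subset=["chrom", "pos"])
    return out.assign(direction=direction)


def call_sweeps(
    windows: pd.DataFrame,
    g: GenotypeMatrix | None = None,
    top_frac: float = 0.01,
    min_snps: int = 2,
    combine: str = "intersect",
    pop1: str = "pop1",
    pop2: str = "pop2",
) -> SweepCallSet:
    """Call sweep windows from the scan table by empirical quantile thresholds.

    Quantiles (nearest-rank, applied inclusively) are computed over windows
    with at least ``min_snps`` SNPs and defined fst and pi_ratio. Selected
    for ``pop1`` (the θπ-ratio numerator population — its diversity is
    depleted): fst >= top quantile AND ratio <= bottom quantile. Selected for
    ``pop2``: fst >= top quantile AND ratio >= top quantile. ``combine``
    may be ``union`` to OR the two criteria instead. Candidate SNPs are
    extracted from the merged regions when ``g`` is given.
    """
    if combine not in ("intersect", "union"):
        raise ValueError(f"unknown combine mode {combine!r}")
    valid = windows[
        (windows["n_snps"] >= min_snps)
        & np.isfinite(windows["fst"])
        & np.isfinite(windows["pi_ratio"])
    ]
    n_excluded = len(windows) - len(valid)
    if n_excluded:
        log.info("call_sweeps: excluded %d windows (min_snps/undefined stats)", n_excluded)
    if len(valid) < 100:
        warnings.warn(
            f"only {len(valid)} usable windows; {top_frac:.0%} quantile "
            "thresholds have coarse resolution",
            stacklevel=2,
        )
    empty = valid.iloc[0:0]
    fst_vals = valid["fst"].to_numpy()
    ratio_vals = valid["pi_ratio"].to_numpy()
    degenerate = (
        valid.empty
        or (np.nanmax(fst_vals) == np.nanmin(fst_vals))
        or (np.nanmax(ratio_vals) == np.nanmin(ratio_vals))
    )
    if degenerate:
        warnings.warn("degenerate statistic distribution; no sweeps called", stacklevel=2)
        sel1, sel2 = empty, empty
        fst_q99 = ratio_q99 = ratio_q01 = float("nan")
    else:
        fst_q99 = nearest_rank_quantile(fst_vals, 1.0 - top_frac)
        ratio_q99 = nearest_rank_quantile(ratio_vals, 1.0 - top_frac)
        ratio_q01 = nearest_rank_quantile(ratio_vals, top_frac)
        hi_fst = valid["fst"] >= fst_q99
        lo_ratio = valid["pi_ratio"] <= ratio_q01
        hi_ratio = valid["pi_ratio"] >= ratio_q99
        if combine == "intersect":
            sel1 = valid[hi_fst & lo_ratio]
            sel2 = valid[hi_fst & hi_ratio]
        else:
            sel1 = valid[hi_fst | lo_ratio]
            sel2 = valid[hi_fst | hi_ratio]
    regions1 = merge_windows(sel1)
    regions2 = merge_windows(sel2)
    if g is not None:
        cand = pd.concat(
            [_snps_in_regions(g, regions1, pop1), _snps_in_regions(g, regions2, pop2)],
            ignore_index=True,
        )
    else:
        cand = pd.DataFrame(columns=["chrom", "pos", "vid", "ref", "alt", "direction"])
    return SweepCallSet(
        fst_q99=fst_q99,
        ratio_q99=ratio_q99,
        ratio_q01=ratio_q01,
        windows_pop1_selected=sel1.reset_index(drop=True),
        windows_pop2_selected=sel2.reset_index(drop=True),
        regions_pop1=regions1,
        regions_pop2=regions2,
        candidate_snps=cand,
        pop1=pop1,
        pop2=pop2,
    )


def write_regions_bed(regions: pd.DataFrame, path: str | Path, name: str = ".") -> None:
    """Write merged regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


# ---------------------------------------------------------------------------
# recovery scoring against planted truth
# ---------------------------------------------------------------------------

def region_precision_recall(
    callset: SweepCallSet, truth: "list", pop1: str, pop2: str
) -> tuple[float, float]:
    """Region-level precision/recall of called regions against truth sweeps.

    A called region is a true positive if it overlaps a truth interval
    planted in the matching population; a truth interval is recovered if
    some matching-direction region overlaps it. Precision is TP regions /
    called regions, recall is recovered truths / all truths.
    """
    def overlaps(a_start, a_end, b_start, b_end) -> bool:
        return a_start <= b_end and b_start <= a_end

    called = [
        (r.chrom, r.start, r.end, pop)
        for regions, pop in ((callset.regions_pop1, pop1), (callset.regions_pop2, pop2))
        for r in regions.itertuples(index=False)
    ]
    truths = [(s.chrom, s.start, s.end, s.swept_pop) for s in truth]
    tp = sum(
        any(c[3] == t[3] and c[0] == t[0] and overlaps(c[1], c[2], t[1], t[2]) for t in truths)
        for c in called
    )
    recovered = sum(
        any(c[3] == t[3] and c[0] == t[0] and overlaps(c[1], c[2], t[1], t[2]) for c in called)
        for t in truths
    )
    precision = tp / len(called) if called else 0.0
    recall = recovered / len(truths) if truths else 1.0
    return precision, recall
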