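"""Windowed selection scans: Weir-Cockerham FST, nucleotide diversity and its
ratio, and cross-population extended haplotype homozygosity (XP-EHH).

All three statistics are computed on the same sliding-window grid (150 kb
windows, 75 kb step by default) and candidate selection regions are the
windows falling in the top quantile of all three simultaneously.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .intervals import GenomicInterval, IntervalSet, merge_intervals
from .io import GenotypeMatrix

__all__ = [
    "make_windows",
    "fst_windowed",
    "weir_cockerham_components",
    "pi_windowed",
    "pi_ratio",
    "xpehh",
    "standardize_xpehh",
    "window_xpehh",
    "intersect_top_quantile",
]


def make_windows(chrom_sizes: dict[str, int], window: int = 150_000,
                 step: int = 75_000) -> pd.DataFrame:
    """Full sliding windows: starts 0, step, 2*step, ... with start+window <= L."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    rows = []
    for chrom in sorted(chrom_sizes):
        L = chrom_sizes[chrom]
        start = 0
        while start + window <= L:
            rows.append((chrom, start, start + window))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _pop_masks(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> tuple[np.ndarray, np.ndarray]:
    if gm.populations is None:
        raise ValueError("genotype matrix carries no population labels")
    labels = np.asarray(gm.populations)
    a, b = labels == pop_a, labels == pop_b
    if not a.any() or not b.any():
        raise ValueError(f"empty population among ({pop_a!r}, {pop_b!r})")
    return a, b


def weir_cockerham_components(dos_a: np.ndarray, dos_b: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components for two populations.

    Inputs are (samples x sites) dosage blocks (nan = missing). Returns
    (a, a+b+c): the among-population component and the total, site-wise.
    Sites with fewer than two genotyped individuals in either population get
    nan in both.
    """
    r = 2
    comp_a_num = []
    comp_total = []
    n_i = np.stack([np.sum(~np.isnan(d), axis=0) for d in (dos_a, dos_b)])  # (2, S)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_i = np.stack([np.nanmean(d, axis=0) / 2.0 for d in (dos_a, dos_b)])
        # heterozygote frequency among *called* individuals
        h_i = np.stack([(d == 1).sum(axis=0) / np.maximum(n, 1)
                        for d, n in zip((dos_a, dos_b), n_i)])
    valid = (n_i >= 2).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n_i ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    total = a + b + c
    a = np.where(valid, a, np.nan)
    total = np.where(valid, total, np.nan)
    # monomorphic across both samples: zero information, excluded from sums
    mono = (pbar == 0) | (pbar == 1)
    a = np.where(mono, np.nan, a)
    total = np.where(mono, np.nan, total)
    return a, total


def _window_index(windows: pd.DataFrame, chroms: np.ndarray,
                  positions: np.ndarray) -> list[np.ndarray]:
    """Variant index (columns) falling in each window; positions are 1-based."""
    pts = positions - 1
    out = []
    for w in windows.itertuples(index=False):
        out.append(np.flatnonzero((chroms == w.chrom) & (pts >= w.start) & (pts < w.end)))
    return out


def fst_windowed(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                 windows: pd.DataFrame, ratio_of_sums: bool = True) -> pd.DataFrame:
    """Windowed Weir-Cockerham FST between two labelled populations.

    The default is the ratio-of-sums ("weighted") estimator
    sum(a) / sum(a+b+c) over the usable sites of a window; negative values
    are reported as-is. Windows with no usable site get nan.
    """
    ma, mb = _pop_masks(gm, pop_a, pop_b)
    a, total = weir_cockerham_components(gm.dosages[ma], gm.dosages[mb])
    out = windows.copy()
    vals, counts = [], []
    for idx in _window_index(windows, gm.chroms, gm.positions):
        aa, tt = a[idx], total[idx]
        use = ~np.isnan(aa) & ~np.isnan(tt)
        counts.append(int(use.sum()))
        if not use.any() or tt[use].sum() == 0:
            vals.append(np.nan)
        elif ratio_of_sums:
            vals.append(aa[use].sum() / tt[use].sum())
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                per_site = aa[use] / tt[use]
            vals.append(float(np.nanmean(per_site)))
    out["n_variants"] = counts
    out["fst"] = vals
    return out


def pi_windowed(gm: GenotypeMatrix, pop: str, windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed nucleotide diversity within one population.

    Per site, h = 2 j (n - j) / (n (n - 1)) with n the non-missing allele
    count and j the alt count; window pi = sum(h) / window length, so
    monomorphic and uncalled positions dilute rather than truncate.
    """
    if gm.populations is None:
        raise ValueError("genotype matrix carries no population labels")
    mask = np.asarray(gm.populations) == pop
    if not mask.any():
        raise ValueError(f"empty population {pop!r}")
    d = gm.dosages[mask]
    n = 2.0 * np.sum(~np.isnan(d), axis=0)
    j = np.nansum(d, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * j * (n - j) / (n * (n - 1.0))
    h = np.where(n >= 2, h, 0.0)
    out = windows.copy()
    vals, counts = [], []
    for w, idx in zip(windows.itertuples(index=False),
                      _window_index(windows, gm.chroms, gm.positions)):
        counts.append(len(idx))
        vals.append(float(h[idx].sum()) / (w.end - w.start))
    out["n_variants"] = counts
    out["pi"] = vals
    return out


def pi_ratio(pi_a: pd.DataFrame, pi_b: pd.DataFrame) -> pd.DataFrame:
    """Per-window pi_A / pi_B on identical window grids; nan when pi_B = 0."""
    if not (pi_a[["chrom", "start", "end"]].values == pi_b[["chrom", "start", "end"]].values).all():
        raise ValueError("window grids differ")
    out = pi_a[["chrom", "start", "end"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pi_a["pi"].to_numpy() / pi_b["pi"].to_numpy()
    out["pi_ratio"] = np.where(pi_b["pi"].to_numpy() > 0, ratio, np.nan)
    return out


# ---------------------------------------------------------------------------
# XP-EHH

def _ehh_curve(haps: np.ndarray, core: int, direction: int,
               cutoff: float = 0.0) -> tuple[list[float], list[int]]:
    """Whole-sample EHH values walking out from `core` (inclusive) one SNP at a time.

    Returns (ehh values, site indices), starting at the core itself where
    haplotypes are grouped by the core column alone. The walk stops one site
    past the first crossing below `cutoff` (EHH decays monotonically, so no
    later site can contribute to the truncated integral).
    """
    n = haps.shape[0]
    denom = n * (n - 1) / 2
    gid = np.zeros(n, dtype=np.int64)
    ehhs: list[float] = []
    sites: list[int] = []
    idx = core
    while 0 <= idx < haps.shape[1]:
        gid = gid * 2 + haps[:, idx]
        _, gid, counts = np.unique(gid, return_inverse=True, return_counts=True)
        ehh = float(np.sum(counts * (counts - 1) / 2) / denom)
        ehhs.append(ehh)
        sites.append(idx)
        if ehh < cutoff or ehh == 0.0:
            break
        idx += direction
    return ehhs, sites


def _ihh_one_side(haps: np.ndarray, core: int, gpos: np.ndarray, direction: int,
                  cutoff: float) -> float:
    """Trapezoidal integral of EHH over |genetic distance|, truncated at cutoff."""
    ehhs, sites = _ehh_curve(haps, core, direction, cutoff)
    dist = [abs(gpos[s] - gpos[core]) for s in sites]
    ihh = 0.0
    for k in range(1, len(ehhs)):
        lo, hi = ehhs[k], ehhs[k - 1]
        if lo < cutoff:
            break
        ihh += 0.5 * (lo + hi) * (dist[k] - dist[k - 1])
    return ihh


@njit(cache=True)
def _ihh_all(haps, gpos, cutoff):
    """iHH (left + right, cutoff-truncated trapezoid) at every core SNP."""
    n, m = haps.shape
    denom = n * (n - 1) / 2.0
    out = np.zeros(m)
    gid = np.empty(n, np.int64)
    new_gid = np.empty(n, np.int64)
    relabel = np.empty(2 * n, np.int64)
    counts = np.empty(n, np.int64)
    for core in range(m):
        total = 0.0
        for direction in (1, -1):
            for i in range(n):
                gid[i] = 0
            n_groups = 1
            prev_ehh = 1.0
            prev_d = 0.0
            idx = core
            first = True
            while 0 <= idx < m:
                for k in range(2 * n_groups):
                    relabel[k] = -1
                nxt = 0
                for i in range(n):
                    key = gid[i] * 2 + haps[i, idx]
                    if relabel[key] < 0:
                        relabel[key] = nxt
                        nxt += 1
                    new_gid[i] = relabel[key]
                for i in range(n):
                    gid[i] = new_gid[i]
                n_groups = nxt
                for k in range(n_groups):
                    counts[k] = 0
                for i in range(n):
                    counts[gid[i]] += 1
                s = 0.0
                for k in range(n_groups):
                    s += counts[k] * (counts[k] - 1) / 2.0
                ehh = s / denom
                d = abs(gpos[idx] - gpos[core])
                if first:
                    first = False
                else:
                    if ehh < cutoff:
                        break
                    total += 0.5 * (ehh + prev_ehh) * (d - prev_d)
                if ehh == 0.0:
                    break
                prev_ehh = ehh
                prev_d = d
                idx += direction
        out[core] = total
    return out


def xpehh(haps_a: np.ndarray, haps_b: np.ndarray, genetic_pos: np.ndarray,
          ehh_cutoff: float = 0.05) -> np.ndarray:
    """Raw per-SNP XP-EHH: ln(iHH_A / iHH_B) from whole-sample EHH decay.

    `haps_*` are (haplotypes x sites) 0/1 arrays on a shared site grid;
    `genetic_pos` gives strictly increasing genetic positions (cM). Scores
    are nan where either integral is zero.
    """
    genetic_pos = np.asarray(genetic_pos, dtype=float)
    if np.any(np.diff(genetic_pos) <= 0):
        raise ValueError("genetic positions must be strictly increasing")
    if haps_a.shape[1] != haps_b.shape[1] or haps_a.shape[1] != len(genetic_pos):
        raise ValueError("haplotype site grids differ")
    ihh_a = _ihh_all(np.ascontiguousarray(haps_a, dtype=np.int8), genetic_pos,
                     ehh_cutoff)
    ihh_b = _ihh_all(np.ascontiguousarray(haps_b, dtype=np.int8), genetic_pos,
                     ehh_cutoff)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.log(ihh_a / ihh_b)
    scores[(ihh_a <= 0) | (ihh_b <= 0)] = np.nan
    return scores


def standardize_xpehh(raw: np.ndarray) -> np.ndarray:
    """Genome-wide z-standardization of raw XP-EHH scores (nan-aware)."""
    mu = np.nanmean(raw)
    sd = np.nanstd(raw)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize: zero or undefined spread")
    return (raw - mu) / sd


def window_xpehh(z: np.ndarray, chroms: np.ndarray, positions: np.ndarray,
                 windows: pd.DataFrame) -> pd.DataFrame:
    """Mean standardized XP-EHH per window (nan when no scored SNP falls in it)."""
    out = windows.copy()
    vals, counts = [], []
    for idx in _window_index(windows, np.asarray(chroms, dtype=object),
                             np.asarray(positions)):
        zz = z[idx]
        zz = zz[~np.isnan(zz)]
        counts.append(len(zz))
        vals.append(float(zz.mean()) if len(zz) else np.nan)
    out["n_variants"] = counts
    out["xpehh_mean"] = vals
    return out


def intersect_top_quantile(stats: dict[str, pd.DataFrame], q: float = 0.005
                           ) -> tuple[pd.DataFrame, IntervalSet]:
    """Candidate selection regions: windows in the top-q tail of every statistic.

    Each frame must share the (chrom, start, end) grid and carry its value in
    the last column. Per statistic, windows with value >= the (1-q) quantile
    of non-missing values are selected (ties included); candidates are
    windows selected by all statistics, merged when overlapping or adjacent.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    names = list(stats)
    grid = stats[names[0]][["chrom", "start", "end"]]
    selected = np.ones(len(grid), dtype=bool)
    for name in names:
        df = stats[name]
        if not (df[["chrom", "start", "end"]].values == grid.values).all():
            raise ValueError("window grids differ between statistics")
        vals = df.iloc[:, -1].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if len(finite) == 0:
            raise ValueError(f"statistic {name!r} has no finite values")
        thresh = np.quantile(finite, 1 - q)
        selected &= ~np.isnan(vals) & (vals >= thresh)
    hits = grid[selected]
    regions = IntervalSet(merge_intervals(
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in hits.itertuples(index=False)
    ))
    return hits.reset_index(drop=True), regions
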