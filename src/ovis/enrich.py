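"""Interval-overlap enrichment and signal summaries.

Fold enrichment of a chromatin-state set within a feature set follows the
ChromHMM OverlapEnrichment convention, computed on base pairs:

    fold = (overlap_bp / state_bp) / (feature_bp / genome_bp)

so 1 is the random expectation. Significance comes from a circular-shift
permutation null that preserves the size and spacing of the feature
intervals within each chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlap_bp
from .io import SignalTrack

__all__ = [
    "fold_enrichment",
    "permutation_pvalue",
    "signal_over_intervals",
    "binned_correlation",
]


def fold_enrichment(states: IntervalSet, features: IntervalSet,
                    genome_bp: int) -> float:
    """Base-pair fold enrichment of `states` within `features`; nan if either set is empty."""
    state_bp = states.total_bp()
    feature_bp = features.total_bp()
    if state_bp == 0 or feature_bp == 0:
        return float("nan")
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    ov = overlap_bp(states, features)
    return (ov / state_bp) / (feature_bp / genome_bp)


def _shift_intervals(features: IntervalSet, chrom_sizes: dict[str, int],
                     rng: np.random.Generator) -> IntervalSet:
    """Circularly shift each chromosome's features by one uniform offset."""
    shifted: list[GenomicInterval] = []
    for chrom in features.chroms:
        L = chrom_sizes[chrom]
        offset = int(rng.integers(0, L))
        starts, ends = features.arrays(chrom)
        for s, e in zip(starts, ends):
            s2, e2 = (int(s) + offset) % L, (int(e) + offset - 1) % L + 1
            if s2 < e2:
                shifted.append(GenomicInterval(chrom, s2, e2))
            else:  # wrapped around the origin: split in two
                shifted.append(GenomicInterval(chrom, s2, L))
                shifted.append(GenomicInterval(chrom, 0, e2))
    return IntervalSet(shifted)


def permutation_pvalue(states: IntervalSet, features: IntervalSet,
                       chrom_sizes: dict[str, int], n_perm: int = 1000,
                       seed: int | None = None) -> tuple[float, float]:
    """Empirical p-value for fold >= observed under circular-shift permutations.

    Returns (observed fold, p) with the add-one rule
    p = (1 + #{perm >= obs}) / (n_perm + 1), so p is always in (0, 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genome_bp = sum(chrom_sizes.values())
    obs = fold_enrichment(states, features, genome_bp)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = fold_enrichment(states, _shift_intervals(features, chrom_sizes, rng),
                               genome_bp)
        if perm >= obs:
            hits += 1
    return obs, (1 + hits) / (n_perm + 1)


def signal_over_intervals(values: dict[str, np.ndarray],
                          interval_sets: dict[str, IntervalSet]) -> pd.Series:
    """Mean of a per-position signal over each named interval set.

    `values` maps chromosome to a per-base vector (e.g. CpG methylation
    levels, nan where unobserved). Empty or fully-unobserved sets give nan.
    """
    out = {}
    for label, ivset in interval_sets.items():
        chunks = []
        for iv in ivset.merged():
            if iv.chrom in values:
                chunks.append(values[iv.chrom][iv.start:iv.end])
        if chunks:
            cat = np.concatenate(chunks)
            out[label] = float(np.nanmean(cat)) if np.isfinite(cat).any() else float("nan")
        else:
            out[label] = float("nan")
    return pd.Series(out, name="mean_signal")


def binned_correlation(tracks: dict[str, SignalTrack]) -> pd.DataFrame:
    """Pearson correlation matrix of binned tracks sharing one grid."""
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need >= 2 tracks")
    sizes = {tracks[n].bin_size for n in names}
    if len(sizes) != 1:
        raise ValueError("tracks must share a bin size")
    mat = np.vstack([tracks[n].concatenated() for n in names])
    corr = np.corrcoef(mat)
    return pd.DataFrame(corr, index=names, columns=names)
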