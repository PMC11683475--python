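"""Expression normalization and tissue-specificity scoring.

The tissue-specificity index tau for a gene expressed at level x_i in tissue
i (of n) is

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1),

0 for uniform expression, 1 for expression confined to a single tissue.
Genes with tau strictly above 0.8 are called tissue-specific and assigned to
their maximally expressing tissue.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, count_overlaps
from .io import GeneModel

__all__ = [
    "compute_tpm",
    "tau",
    "call_specific_genes",
    "group_by_enhancer_count",
]


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series | dict) -> pd.DataFrame:
    """Transcripts-per-million normalization of a genes x samples count matrix.

    TPM_g = 1e6 * (count_g / length_g) / sum_h (count_h / length_h), per column.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"zero total expression in sample {bad!r}")
    return rate.div(totals, axis=1) * 1e6


def tau(x: Sequence[float]) -> float:
    """Tissue-specificity index of one expression vector; nan if all-zero."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau needs a vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        warnings.warn("all-zero expression vector: tau undefined")
        return float("nan")
    xhat = x / m
    return float(np.sum(1.0 - xhat) / (len(x) - 1))


def call_specific_genes(expr: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Score every gene's tau and call tissue-specific genes.

    `expr` is genes x tissues (TPM). Returns a frame with columns
    tau, tissue (argmax tissue), specific (tau strictly > threshold).
    Ties on the maximum go to the lowest tissue index, with a warning.
    """
    values = expr.to_numpy(dtype=float)
    taus = np.full(len(expr), np.nan)
    arg = np.zeros(len(expr), dtype=int)
    for i, row in enumerate(values):
        m = row.max()
        if m > 0:
            taus[i] = np.sum(1.0 - row / m) / (row.size - 1)
            arg[i] = int(np.argmax(row))
            if np.sum(row == m) > 1:
                warnings.warn(f"tie for maximum expression at gene {expr.index[i]!r}; "
                              "assigning lowest tissue index")
    out = pd.DataFrame(
        {
            "tau": taus,
            "tissue": expr.columns.to_numpy()[arg],
            "specific": (taus > threshold) & ~np.isnan(taus),
        },
        index=expr.index,
    )
    out.loc[np.isnan(taus), "tissue"] = None
    return out


def group_by_enhancer_count(
    genes: Sequence[GeneModel],
    enhancers: IntervalSet,
    boundaries: tuple[int, int] = (1, 5),
) -> pd.DataFrame:
    """Group genes by the number of enhancer intervals overlapping the gene body.

    Genes overlapping no enhancer are excluded. With boundaries (a, b) the
    groups are count == a .. (low), a < count <= b (mid), count > b (high);
    the defaults give the 1 / 2-5 / >=6 split.
    """
    lo, hi = boundaries
    if not (0 < lo <= hi):
        raise ValueError("boundaries must satisfy 0 < low <= high")
    bodies = [g.body for g in genes]
    counts = count_overlaps(bodies, enhancers)
    keep = counts > 0
    labels = np.where(counts <= lo, f"<={lo}",
                      np.where(counts <= hi, f"{lo + 1}-{hi}", f">={hi + 1}"))
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "n_enhancers": counts,
            "group": labels,
        }
    )[keep].reset_index(drop=True)
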