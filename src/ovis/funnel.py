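"""Causal-variant prioritization funnel.

Significant GWAS SNPs are successively intersected with (1) selection-sweep
regions, (2) open chromatin (ATAC peaks, union over replicates) AND H3K27ac
peaks (union over replicates) — both required — and (3) annotated with the
topologically associating domain (TAD) containing them plus every gene whose
TSS lies in that TAD. Candidate-local genotype-stratified expression tests
on the linked genes then rank the surviving variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, points_in_intervals
from .io import GeneModel, GenotypeMatrix

__all__ = [
    "FunnelReport",
    "run_funnel",
    "genotype_expression_test",
    "allele_freq_by_population",
    "rank_candidates",
]


@dataclass
class FunnelReport:
    """Per-stage counts and the final candidate table."""

    stage_counts: dict[str, int]
    candidates: pd.DataFrame

    def summary(self) -> str:
        lines = ["Causal-variant prioritization funnel", "=" * 47]
        for stage, n in self.stage_counts.items():
            lines.append(f"{stage:<38s} {n:>6d}")
        if len(self.candidates):
            lines.append("")
            lines.append("top candidates:")
            cols = [c for c in ("variant_id", "neglog10p", "tad_id",
                                "linked_genes", "min_expr_p")
                    if c in self.candidates.columns]
            lines.append(self.candidates[cols].head(5).to_string(index=False))
        return "\n".join(lines)


def _tad_lookup(positions_0based: np.ndarray, chroms: np.ndarray,
                tads: IntervalSet) -> list[str | None]:
    """TAD id containing each point, or None. TADs are assumed disjoint."""
    out: list[str | None] = [None] * len(positions_0based)
    tad_list = list(tads)
    for i, (c, p) in enumerate(zip(chroms, positions_0based)):
        for j, iv in enumerate(tad_list):
            if iv.chrom == c and iv.start <= p < iv.end:
                out[i] = iv.name or f"tad_{j}"
                break
    return out


def run_funnel(assoc: pd.DataFrame, threshold: float, sweep_regions: IntervalSet,
               ocr_peaks: Sequence[IntervalSet], k27ac_peaks: Sequence[IntervalSet],
               tads: IntervalSet, genes: Sequence[GeneModel]) -> FunnelReport:
    """Run the intersection funnel over a GWAS association table.

    `assoc` needs columns variant_id, chrom, pos (1-based), neglog10p.
    `ocr_peaks` / `k27ac_peaks` are per-replicate peak sets; membership in
    the union of replicates counts ("peaks of at least one replicate").
    Returns the report with monotone non-increasing stage counts; SNPs in no
    TAD are retained with a missing TAD and no linked genes.
    """
    counts: dict[str, int] = {"input": len(assoc)}
    sig = assoc[assoc["neglog10p"] > threshold].copy()
    counts["significant"] = len(sig)

    pts = sig["pos"].to_numpy(dtype=np.int64) - 1
    chroms = sig["chrom"].to_numpy(dtype=object)
    in_sweep = points_in_intervals(chroms, pts, sweep_regions)
    sig["in_sweep"] = in_sweep
    stage2 = sig[in_sweep].copy()
    counts["in_sweep"] = len(stage2)

    ocr_union = IntervalSet([iv for s in ocr_peaks for iv in s]).merged()
    k27_union = IntervalSet([iv for s in k27ac_peaks for iv in s]).merged()
    pts2 = stage2["pos"].to_numpy(dtype=np.int64) - 1
    chroms2 = stage2["chrom"].to_numpy(dtype=object)
    stage2["in_ocr"] = points_in_intervals(chroms2, pts2, ocr_union)
    stage2["in_k27ac"] = points_in_intervals(chroms2, pts2, k27_union)
    stage3 = stage2[stage2["in_ocr"] & stage2["in_k27ac"]].copy()
    counts["in_ocr_and_k27ac"] = len(stage3)

    pts3 = stage3["pos"].to_numpy(dtype=np.int64) - 1
    chroms3 = stage3["chrom"].to_numpy(dtype=object)
    tad_ids = _tad_lookup(pts3, chroms3, tads)
    stage3["tad_id"] = tad_ids
    gene_by_tad: dict[str, list[str]] = {}
    tss_chroms = np.array([g.chrom for g in genes], dtype=object)
    tss_pts = np.array([g.tss - 1 for g in genes], dtype=np.int64)
    gene_tads = _tad_lookup(tss_pts, tss_chroms, tads)
    for g, t in zip(genes, gene_tads):
        if t is not None:
            gene_by_tad.setdefault(t, []).append(g.gene_id)
    stage3["linked_genes"] = [
        tuple(gene_by_tad.get(t, ())) if t is not None else ()
        for t in tad_ids
    ]
    counts["with_tad"] = int(stage3["tad_id"].notna().sum())
    return FunnelReport(counts, stage3.reset_index(drop=True))


def genotype_expression_test(expression: np.ndarray, dosages: np.ndarray,
                             method: str = "anova",
                             min_per_class: int = 3) -> float:
    """p-value for expression differing across genotype classes at one SNP.

    One-way ANOVA across the dosage classes (0/1/2) by default;
    Kruskal-Wallis with method="kruskal". Classes with fewer than
    `min_per_class` individuals are dropped; with fewer than two usable
    classes the test is undefined (nan, with a warning).
    """
    expression = np.asarray(expression, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(expression) & ~np.isnan(dosages)
    groups = [expression[ok & (dosages == g)] for g in (0, 1, 2)]
    groups = [g for g in groups if len(g) >= min_per_class]
    if len(groups) < 2:
        warnings.warn("fewer than two usable genotype classes: test undefined")
        return float("nan")
    if method == "anova":
        return float(stats.f_oneway(*groups).pvalue)
    if method == "kruskal":
        return float(stats.kruskal(*groups).pvalue)
    raise ValueError(f"unknown method {method!r}")


def allele_freq_by_population(dosages: np.ndarray,
                              populations: Sequence[str]) -> pd.Series:
    """Alt-allele frequency per population: sum(dosage) / (2 * n_called)."""
    dosages = np.asarray(dosages, dtype=float)
    labels = np.asarray(populations)
    if len(labels) != len(dosages):
        raise ValueError("labels do not cover all individuals")
    out = {}
    for pop in pd.unique(labels):
        d = dosages[labels == pop]
        called = ~np.isnan(d)
        out[pop] = float(np.nansum(d) / (2 * called.sum())) if called.any() else float("nan")
    return pd.Series(out, name="alt_freq")


def rank_candidates(report: FunnelReport, gm: GenotypeMatrix,
                    expression: pd.DataFrame) -> pd.DataFrame:
    """Attach genotype-stratified expression tests and rank the candidates.

    `expression` is genes x individuals (same sample order as `gm`). Ranking:
    minimum linked-gene expression p ascending (candidates without any tested
    gene last), then GWAS -log10 p descending, then coordinate.
    """
    cands = report.candidates.copy()
    vid_index = {v.vid: j for j, v in enumerate(gm.variants)}
    expr_ps: list[dict[str, float]] = []
    min_ps: list[float] = []
    for row in cands.itertuples(index=False):
        j = vid_index.get(row.variant_id)
        ps: dict[str, float] = {}
        if j is not None:
            dos = gm.dosages[:, j]
            for gid in row.linked_genes:
                if gid in expression.index:
                    ps[gid] = genotype_expression_test(
                        expression.loc[gid].to_numpy(dtype=float), dos)
        expr_ps.append(ps)
        finite = [p for p in ps.values() if np.isfinite(p)]
        min_ps.append(min(finite) if finite else float("nan"))
    cands["expr_p_by_gene"] = expr_ps
    cands["min_expr_p"] = min_ps
    cands = cands.sort_values(
        by=["min_expr_p", "neglog10p", "chrom", "pos"],
        ascending=[True, False, True, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    cands.insert(0, "rank", np.arange(1, len(cands) + 1))
    return cands
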