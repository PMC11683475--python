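"""End-to-end scenario analysis: from a truth bundle to ranked candidates.

This wires the library stages together in the canonical order — variant QC,
mixed-model GWAS, three-statistic selection scan, top-quantile intersection,
and the prioritization funnel — and is what the acceptance workflow and the
worked example in the README run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sweep as sweep_mod
from .funnel import FunnelReport, rank_candidates, run_funnel
from .gwas import GWASResults, MixedModelGWAS, bonferroni_threshold, filter_variants
from .intervals import IntervalSet
from .simulate import TruthBundle

__all__ = ["ScenarioResult", "run_scenario"]


@dataclass
class ScenarioResult:
    """Everything the end-to-end scenario analysis produces."""

    gwas: GWASResults
    threshold: float
    window_stats: dict[str, pd.DataFrame]
    sweep_regions: IntervalSet
    funnel: FunnelReport
    candidates: pd.DataFrame

    def summary(self) -> str:
        parts = [self.gwas.summary(), "", self.funnel.summary()]
        return "\n".join(parts)


def run_scenario(bundle: TruthBundle, q: float = 0.005,
                 peak_tissue: str = "tail_fat",
                 trait: str = "tail_fat_weight") -> ScenarioResult:
    """Run GWAS + selection scan + funnel on one truth bundle.

    The pi ratio is oriented as non-selected / selected population so that
    reduced diversity in the selected population raises the statistic, and
    XP-EHH is selected vs non-selected; peak membership is restricted to
    `peak_tissue` (the trait-relevant tissue).
    """
    gm, _ = filter_variants(bundle.genotypes)
    model = MixedModelGWAS.from_dataframe(
        bundle.phenotypes, trait, gm,
        covariates=["birthplace", "batch", "season"], n_pcs=3)
    res = model.fit()
    m_tests = int(res.table["p"].notna().sum())
    threshold = bonferroni_threshold(m_tests)

    cfg = bundle.config
    sel = cfg.selected_pop
    other = next(p for p in cfg.pop_sizes if p != sel)
    windows = sweep_mod.make_windows(cfg.chrom_sizes)
    fst = sweep_mod.fst_windowed(gm, sel, other, windows)
    pi_sel = sweep_mod.pi_windowed(gm, sel, windows)
    pi_oth = sweep_mod.pi_windowed(gm, other, windows)
    ratio = sweep_mod.pi_ratio(pi_oth, pi_sel)
    hap_labels = np.repeat(np.asarray(gm.populations), 2)
    cm = gm.positions / 1e6 * cfg.cm_per_mb
    raw = sweep_mod.xpehh(gm.haplotypes[hap_labels == sel],
                          gm.haplotypes[hap_labels == other], cm)
    z = sweep_mod.standardize_xpehh(raw)
    xp = sweep_mod.window_xpehh(z, gm.chroms, gm.positions, windows)
    stats = {
        "fst": fst[["chrom", "start", "end", "fst"]],
        "pi_ratio": ratio[["chrom", "start", "end", "pi_ratio"]],
        "xpehh": xp[["chrom", "start", "end", "xpehh_mean"]],
    }
    _, regions = sweep_mod.intersect_top_quantile(stats, q=q)

    report = run_funnel(res.table, threshold, regions,
                        bundle.peaks[peak_tissue]["ATAC"],
                        bundle.peaks[peak_tissue]["H3K27ac"],
                        bundle.tads, bundle.genes)
    ranked = rank_candidates(report, gm, bundle.expression_individual)
    return ScenarioResult(gwas=res, threshold=threshold, window_stats=stats,
                          sweep_regions=regions, funnel=report, candidates=ranked)
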