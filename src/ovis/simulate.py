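"""Seeded generators for every input the pipeline consumes, with planted truth.

The scenario emulates a two-population livestock study: a baseline level of
neutral differentiation between populations (Balding-Nichols allele
frequencies at F), one sweep region at elevated differentiation (F_sweep)
carrying an extended shared haplotype in the selected population, a planted
causal regulatory variant inside a tissue-restricted enhancer inside a TAD
containing its target gene, a quantitative trait with fixed covariate
effects + polygenic term + residual noise, per-tissue chromatin-mark tracks
realized from a known six-state architecture, and tissue-specific expression
with controllable specificity.

Everything is deterministic under (config, seed): every random draw goes
through one `numpy.random.default_rng(seed)` stream per generator.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas import grm_vanraden
from .intervals import GenomicInterval, IntervalSet, points_in_intervals
from .io import (GeneModel, GenotypeMatrix, SignalTrack, VariantRecord,
                 write_bed, write_bedgraph, write_gene_models, write_vcf)

__all__ = ["ScenarioConfig", "TruthBundle", "simulate_populations",
           "simulate_phenotypes", "simulate_epigenome", "simulate_expression",
           "make_truth_bundle"]

TISSUES = ("cartilage", "cecum", "pituitary", "hypothalamus", "liver",
           "loin", "rumen", "spleen", "tail_fat")

# per-state Poisson rate class for each mark (ATAC, H3K4me3, H3K27ac):
# 2 = strong foreground, 1 = weak foreground, 0 = background
STATE_MARKS = {
    "TssA": (2, 2, 2),
    "TssW": (1, 2, 0),
    "EnhA": (2, 0, 2),
    "EnhAW": (1, 0, 1),
    "ATAC_Is": (2, 0, 0),
    "Quies": (0, 0, 0),
}


@dataclass
class ScenarioConfig:
    """Study design of the synthetic scenario (defaults ARE the study conditions)."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 3_000_000})
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"FAT": 250, "THIN": 250})
    n_variants: int = 5000
    baseline_f: float = 0.02
    sweep_f: float = 0.5
    sweep_region: tuple[str, int, int] = ("chr1", 1_275_000, 1_425_000)
    sweep_hap_fraction: float = 0.6  # selected pop haplotypes carrying the core haplotype
    causal_pos: int = 1_351_000  # 1-based, inside the tail-fat enhancer
    causal_pop_freqs: dict[str, float] = field(
        default_factory=lambda: {"FAT": 0.8, "THIN": 0.2})
    beta: float = 1.0  # phenotypic SDs per alt allele
    h2: float = 0.4  # polygenic heritability (excluding the causal SNP)
    n_decoys: int = 22  # sweep-region LD proxies outside peaks
    decoy_flip_rate: float = 0.02
    bystander_flip_rate: float = 0.10  # the second, non-causal peak-resident SNP
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "birthplace": {"north": 0.0, "south": 0.3, "west": -0.2},
        "batch": {f"b{i}": 0.05 * (i - 3) for i in range(1, 8)},
        "season": {"spring": 0.0, "summer": -0.1, "autumn": 0.1, "winter": 0.2},
    })
    tissues: tuple[str, ...] = TISSUES
    bin_size: int = 200
    lambda_bg: float = 1.0
    lambda_weak: float = 4.0
    lambda_fg: float = 10.0
    n_genes: int = 30
    tad_size: int = 400_000
    target_gene: str = "gene_TRG"
    target_tss: int = 1_400_000
    n_specific_genes: int = 9  # one planted specific gene per tissue
    expr_hi: float = 200.0
    expr_lo: float = 10.0
    expr_sigma: float = 0.25  # log-normal noise on tissue expression
    expr_delta: float = 1.0  # target-gene expression shift per alt allele, in noise SDs
    expr_noise_sd: float = 1.0
    cm_per_mb: float = 1.0

    def __post_init__(self):
        if not 0 < self.baseline_f < self.sweep_f < 1:
            raise ValueError("need 0 < F < F_sweep < 1")
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must lie in [0, 1)")
        if self.lambda_fg <= self.lambda_bg:
            raise ValueError("lambda_fg <= lambda_bg: states unidentifiable")
        chrom, s, e = self.sweep_region
        if chrom not in self.chrom_sizes or e > self.chrom_sizes[chrom] or s < 0:
            raise ValueError("sweep region outside the genome")
        if not (s < self.causal_pos - 1 < e):
            raise ValueError("causal variant must lie inside the sweep region")
        if set(self.causal_pop_freqs) != set(self.pop_sizes):
            raise ValueError("causal_pop_freqs must name every population")

    @property
    def selected_pop(self) -> str:
        """Population carrying the swept haplotype (highest causal alt freq)."""
        return max(self.causal_pop_freqs, key=self.causal_pop_freqs.get)

    @property
    def causal_enhancer(self) -> GenomicInterval:
        chrom = self.sweep_region[0]
        start = (self.causal_pos - 1) // self.bin_size * self.bin_size - self.bin_size
        return GenomicInterval(chrom, start, start + 6 * self.bin_size)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Architecture (genes, TADs, chromatin elements)

def _gene_models(cfg: ScenarioConfig) -> list[GeneModel]:
    """Evenly spaced genes, alternating strand; one designated target gene."""
    chrom = next(iter(cfg.chrom_sizes))
    L = cfg.chrom_sizes[chrom]
    genes = []
    spacing = L // (cfg.n_genes + 1)
    for i in range(cfg.n_genes):
        tss = (i + 1) * spacing
        strand = "+" if i % 2 == 0 else "-"
        span = 8_000
        start, end = (tss, tss + span) if strand == "+" else (tss - span, tss)
        genes.append(GeneModel(f"gene_{i:03d}", chrom, strand,
                               tss if strand == "+" else end,
                               end if strand == "+" else start,
                               length=1_500 + 100 * (i % 10)))
    genes.append(GeneModel(cfg.target_gene, chrom, "+", cfg.target_tss,
                           cfg.target_tss + 8_000, length=2_000))
    return genes


def _tads(cfg: ScenarioConfig) -> IntervalSet:
    ivs = []
    for chrom, L in cfg.chrom_sizes.items():
        for i, start in enumerate(range(0, L - cfg.tad_size + 1, cfg.tad_size)):
            ivs.append(GenomicInterval(chrom, start, start + cfg.tad_size,
                                       name=f"{chrom}_tad{i:02d}"))
    return IntervalSet(ivs)


def _state_architecture(cfg: ScenarioConfig) -> dict[str, dict[str, IntervalSet]]:
    """Planted per-tissue interval sets per state (non-quiescent only).

    Promoters sit at every gene TSS in every tissue; a block of shared
    enhancers and ATAC islands recurs across tissues; each tissue gets one
    private (tissue-specific) enhancer; the causal enhancer exists only in
    tail fat.
    """
    chrom = next(iter(cfg.chrom_sizes))
    genes = _gene_models(cfg)
    arch: dict[str, dict[str, list[GenomicInterval]]] = {
        t: {s: [] for s in STATE_MARKS if s != "Quies"} for t in cfg.tissues}
    bs = cfg.bin_size
    for gi, g in enumerate(genes):
        start = ((g.tss - 1) // bs - 2) * bs
        iv = GenomicInterval(chrom, max(start, 0), max(start, 0) + 5 * bs)
        label = "TssA" if gi % 3 != 2 else "TssW"
        for t in cfg.tissues:
            arch[t][label].append(iv)
    sweep_chrom, sw_s, sw_e = cfg.sweep_region
    blocked = IntervalSet([GenomicInterval(sweep_chrom, sw_s - 10_000, sw_e + 10_000)])
    # shared elements on a deterministic lattice, skipping promoters and the sweep
    slot = 37_000
    L = cfg.chrom_sizes[chrom]
    k = 0
    for pos in range(25_000, L - 10 * bs, slot):
        iv = GenomicInterval(chrom, pos, pos + 6 * bs)
        if points_in_intervals([chrom], [pos], blocked)[0]:
            continue
        label = ("EnhA", "EnhAW", "ATAC_Is")[k % 3]
        for t in cfg.tissues:
            arch[t][label].append(iv)
        k += 1
    # one private enhancer per tissue
    for ti, t in enumerate(cfg.tissues):
        pos = 40_000 + ti * 53_000 + 18_000
        if not points_in_intervals([chrom], [pos], blocked)[0]:
            arch[t]["EnhA"].append(GenomicInterval(chrom, pos, pos + 4 * bs))
    # the causal enhancer: tail fat only, inside the sweep
    arch["tail_fat"]["EnhA"].append(cfg.causal_enhancer)
    return {t: {s: IntervalSet(ivs) for s, ivs in d.items()} for t, d in arch.items()}


# ---------------------------------------------------------------------------
# Genotypes

def simulate_populations(cfg: ScenarioConfig, seed: int) -> GenotypeMatrix:
    """Balding-Nichols genotypes with a planted sweep, causal SNP and decoys.

    Per variant, an ancestral frequency p ~ U(0.05, 0.95); per population,
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with F = F_sweep inside the
    sweep region and the baseline F elsewhere; phased haplotypes ~
    Bernoulli(p_pop). Inside the sweep, a fraction of the selected
    population's haplotypes is replaced by one shared core haplotype (the
    haplotype-homozygosity signal). Decoy variants are near-copies of the
    causal column placed outside peaks; one "bystander" near-copy sits
    inside the causal enhancer.
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(cfg.chrom_sizes))
    L = cfg.chrom_sizes[chrom]
    sw_chrom, sw_s, sw_e = cfg.sweep_region

    special = _special_positions(cfg)
    n_bg = cfg.n_variants - len(special)
    pos = rng.choice(np.arange(1, L + 1), size=cfg.n_variants * 2, replace=False)
    pos = np.setdiff1d(pos, np.array(special))[:n_bg]
    positions = np.sort(np.concatenate([pos, np.array(special)]))
    assert len(positions) == cfg.n_variants

    in_sweep = (positions - 1 >= sw_s) & (positions - 1 < sw_e)
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_variants)
    pops = list(cfg.pop_sizes)
    labels = np.concatenate([[p] * cfg.pop_sizes[p] for p in pops])
    hap_blocks = []
    causal_j = int(np.searchsorted(positions, cfg.causal_pos))
    for p in pops:
        F = np.where(in_sweep, cfg.sweep_f, cfg.baseline_f)
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_pop = rng.beta(a, b)
        p_pop[causal_j] = cfg.causal_pop_freqs[p]
        n_hap = 2 * cfg.pop_sizes[p]
        hap_blocks.append((rng.uniform(size=(n_hap, cfg.n_variants)) < p_pop).astype(np.int8))
    haps = np.vstack(hap_blocks)

    # extended core haplotype in the selected population
    sel_start = 2 * sum(cfg.pop_sizes[p] for p in pops[:pops.index(cfg.selected_pop)])
    n_sel_hap = 2 * cfg.pop_sizes[cfg.selected_pop]
    sweep_cols = np.flatnonzero(in_sweep)
    core = haps[sel_start, sweep_cols].copy()
    core[sweep_cols == causal_j] = 1  # the core haplotype carries the alt allele
    carriers = sel_start + np.flatnonzero(
        rng.uniform(size=n_sel_hap) < cfg.sweep_hap_fraction)
    for h in carriers:
        haps[h, sweep_cols] = core

    # decoys and bystander: near-copies of the causal column
    causal_col = haps[:, causal_j]
    decoy_pos, bystander_pos = special[1:-1], special[-1]
    for ppos, flip in ([(q, cfg.decoy_flip_rate) for q in decoy_pos]
                       + [(bystander_pos, cfg.bystander_flip_rate)]):
        j = int(np.searchsorted(positions, ppos))
        col = causal_col.copy()
        flips = rng.uniform(size=len(col)) < flip
        col[flips] = 1 - col[flips]
        haps[:, j] = col

    dosages = (haps[0::2] + haps[1::2]).astype(float)
    variants = [VariantRecord(chrom, int(p), "A", "C", vid=f"{chrom}:{p}")
                for p in positions]
    return GenotypeMatrix(dosages, [f"ind_{i:04d}" for i in range(len(labels))],
                          variants, populations=labels, haplotypes=haps)


def _special_positions(cfg: ScenarioConfig) -> list[int]:
    """[causal, decoys..., bystander] 1-based positions, unique and planted.

    Decoys are spread through the sweep region at positions at least 2 kb
    away from every planted chromatin element of every tissue, so they can
    never fall inside a peak.
    """
    sw_chrom, sw_s, sw_e = cfg.sweep_region
    enh = cfg.causal_enhancer
    arch = _state_architecture(cfg)
    blocked = IntervalSet([
        GenomicInterval(iv.chrom, max(iv.start - 2_000, 0), iv.end + 2_000)
        for d in arch.values() for s in d.values() for iv in s
    ]).merged()
    decoys: list[int] = []
    step = (sw_e - sw_s - 40_000) // (cfg.n_decoys + 8)  # headroom for skips
    q = sw_s + 20_000
    while len(decoys) < cfg.n_decoys:
        q += step
        if q - 1 >= sw_e:
            raise ValueError("cannot place all decoys inside the sweep region")
        if not points_in_intervals([sw_chrom], [q - 1], blocked)[0]:
            decoys.append(q)
    bystander = cfg.causal_pos + 2 * cfg.bin_size  # still inside the enhancer
    assert enh.start <= bystander - 1 < enh.end
    return [cfg.causal_pos] + decoys + [bystander]


# ---------------------------------------------------------------------------
# Phenotypes

def simulate_phenotypes(gm: GenotypeMatrix, cfg: ScenarioConfig,
                        seed: int) -> pd.DataFrame:
    """Trait = mean + covariate effects + beta * causal dosage + polygenic + noise.

    The polygenic term u ~ N(0, sigma_g^2 K) uses the VanRaden kinship of the
    simulated genotypes; sigma_g^2 + sigma_e^2 = 1 so `beta` is in phenotypic
    SDs. Also emits a simulated carcass weight and the ratio trait.
    """
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    causal_j = int(np.searchsorted(gm.positions, cfg.causal_pos))
    g = np.nan_to_num(gm.dosages[:, causal_j])

    covs = {}
    effects = np.zeros(n)
    for name, levels in cfg.covariate_effects.items():
        keys = list(levels)
        assign = rng.integers(0, len(keys), size=n)
        covs[name] = [keys[a] for a in assign]
        effects += np.array([levels[keys[a]] for a in assign])

    K = grm_vanraden(gm)
    sigma_g2, sigma_e2 = cfg.h2, 1 - cfg.h2
    jitter = 1e-6 * np.eye(n)
    chol = np.linalg.cholesky(K + jitter)
    u = np.sqrt(sigma_g2) * (chol @ rng.standard_normal(n))
    e = np.sqrt(sigma_e2) * rng.standard_normal(n)
    tail_fat = 5.0 + effects + cfg.beta * g + u + e

    u2 = np.sqrt(sigma_g2) * (chol @ rng.standard_normal(n))
    carcass = 30.0 + 0.5 * effects + 2.0 * (u2 + np.sqrt(sigma_e2) * rng.standard_normal(n))
    df = pd.DataFrame({"individual": gm.samples, **covs,
                       "tail_fat_weight": tail_fat,
                       "carcass_weight": carcass,
                       "tail_fat_ratio": tail_fat / carcass})
    return df


# ---------------------------------------------------------------------------
# Epigenome

def simulate_epigenome(cfg: ScenarioConfig, seed: int):
    """Per-tissue mark tracks, true per-bin state labels and peak intervals.

    Bin counts are Poisson(lambda_bg) in background bins, Poisson(lambda_fg)
    where a state's defining mark is strongly on, Poisson(lambda_weak) for
    weak states. Peak sets are the planted enriched intervals per mark per
    tissue (two identical replicates, emulating duplicate assays).
    """
    rng = np.random.default_rng(seed)
    arch = _state_architecture(cfg)
    state_names = list(STATE_MARKS)
    quies = state_names.index("Quies")
    lam_by_class = {0: cfg.lambda_bg, 1: cfg.lambda_weak, 2: cfg.lambda_fg}
    tracks: dict[str, dict[str, SignalTrack]] = {}
    true_states: dict[str, dict[str, np.ndarray]] = {}
    peaks: dict[str, dict[str, list[IntervalSet]]] = {}
    marks = ("ATAC", "H3K4me3", "H3K27ac")
    for tissue in cfg.tissues:
        state_vec = {}
        lam = {m: {} for m in marks}
        peak_ivs: dict[str, list[GenomicInterval]] = {m: [] for m in marks}
        for chrom, L in cfg.chrom_sizes.items():
            nb = ceil(L / cfg.bin_size)
            sv = np.full(nb, quies, dtype=np.int32)
            lm = {m: np.full(nb, cfg.lambda_bg) for m in marks}
            for s, ivset in arch[tissue].items():
                si = state_names.index(s)
                for iv in ivset:
                    if iv.chrom != chrom:
                        continue
                    b0, b1 = iv.start // cfg.bin_size, ceil(iv.end / cfg.bin_size)
                    sv[b0:b1] = si
                    for mi, m in enumerate(marks):
                        cls = STATE_MARKS[s][mi]
                        if cls > 0:
                            lm[m][b0:b1] = lam_by_class[cls]
                            peak_ivs[m].append(GenomicInterval(chrom, b0 * cfg.bin_size,
                                                               b1 * cfg.bin_size))
            state_vec[chrom] = sv
            for m in marks:
                lam[m][chrom] = lm[m]
        tracks[tissue] = {
            m: SignalTrack({c: rng.poisson(lam[m][c]).astype(float)
                            for c in cfg.chrom_sizes}, cfg.bin_size)
            for m in marks
        }
        true_states[tissue] = state_vec
        peaks[tissue] = {m: [IntervalSet(peak_ivs[m]).merged(),
                             IntervalSet(peak_ivs[m]).merged()] for m in marks}
    return tracks, true_states, peaks


# ---------------------------------------------------------------------------
# Expression

def simulate_expression(cfg: ScenarioConfig, gm: GenotypeMatrix, seed: int
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x tissue TPM-like matrix plus per-individual expression.

    The first `n_specific_genes` genes are planted tissue-specific (mean
    expr_hi in one tissue, expr_lo elsewhere, log-normal noise), giving
    planted tau > 0.8 at the default 20-fold contrast. Per-individual
    expression of the target gene is a + delta * causal dosage + noise;
    all other genes are genotype-independent.
    """
    if cfg.expr_hi <= cfg.expr_lo:
        raise ValueError("expr_hi must exceed expr_lo")
    rng = np.random.default_rng(seed)
    genes = _gene_models(cfg)
    ids = [g.gene_id for g in genes]
    n_t = len(cfg.tissues)
    base = np.full((len(ids), n_t), cfg.expr_lo * 4.0)
    for i in range(min(cfg.n_specific_genes, len(ids) - 1)):
        base[i, :] = cfg.expr_lo
        base[i, i % n_t] = cfg.expr_hi
    noise = rng.lognormal(mean=0.0, sigma=cfg.expr_sigma, size=base.shape)
    tissue_expr = pd.DataFrame(base * noise, index=ids, columns=list(cfg.tissues))

    causal_j = int(np.searchsorted(gm.positions, cfg.causal_pos))
    g = np.nan_to_num(gm.dosages[:, causal_j])
    n = gm.n_samples
    indiv = np.empty((len(ids), n))
    for i, gid in enumerate(ids):
        mu = 10.0 + 0.1 * i
        indiv[i] = mu + cfg.expr_noise_sd * rng.standard_normal(n)
        if gid == cfg.target_gene:
            indiv[i] += cfg.expr_delta * cfg.expr_noise_sd * g
    indiv_expr = pd.DataFrame(indiv, index=ids, columns=gm.samples)
    return tissue_expr, indiv_expr


# ---------------------------------------------------------------------------
# Bundle

@dataclass
class TruthBundle:
    """Everything the pipeline needs, plus the planted ground truth."""

    config: ScenarioConfig
    seed: int
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    tracks: dict  # tissue -> mark -> SignalTrack
    true_states: dict  # tissue -> chrom -> per-bin state index (STATE_MARKS order)
    peaks: dict  # tissue -> mark -> [replicate IntervalSets]
    tads: IntervalSet
    genes: list[GeneModel]
    expression_tissue: pd.DataFrame
    expression_individual: pd.DataFrame
    causal_id: str
    decoy_ids: list[str]
    bystander_id: str

    @property
    def sweep_region(self) -> GenomicInterval:
        c, s, e = self.config.sweep_region
        return GenomicInterval(c, s, e)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config.config_hash(),
            "n_samples": self.genotypes.n_samples,
            "n_variants": self.genotypes.n_variants,
            "causal_id": self.causal_id,
            "n_decoys": len(self.decoy_ids),
            "tissues": list(self.config.tissues),
        }

    def write(self, outdir: str | Path) -> None:
        """Materialize the bundle as VCF / BED / bedGraph / TSV files."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(out / "genotypes.vcf", self.genotypes)
        pd.DataFrame({"individual": self.genotypes.samples,
                      "population": self.genotypes.populations}).to_csv(
            out / "populations.tsv", sep="\t", index=False)
        self.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        write_gene_models(out / "genes.tsv", self.genes)
        write_bed(out / "tads.bed", self.tads)
        self.expression_tissue.to_csv(out / "expression_tissue.tsv", sep="\t")
        self.expression_individual.to_csv(out / "expression_individual.tsv", sep="\t")
        for tissue, marks in self.tracks.items():
            for mark, track in marks.items():
                write_bedgraph(out / f"{tissue}_{mark}.bedgraph", track)
        for tissue, marks in self.peaks.items():
            for mark, reps in marks.items():
                for r, ivset in enumerate(reps, 1):
                    write_bed(out / f"{tissue}_{mark}_rep{r}_peaks.bed", ivset)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)


def make_truth_bundle(cfg: ScenarioConfig | None = None, seed: int = 0,
                      with_epigenome: bool = True) -> TruthBundle:
    """Wire all generators together under one seed."""
    cfg = cfg or ScenarioConfig()
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    gm = simulate_populations(cfg, sub[0])
    pheno = simulate_phenotypes(gm, cfg, sub[1])
    if with_epigenome:
        tracks, true_states, peaks = simulate_epigenome(cfg, sub[2])
    else:
        tracks, true_states, peaks = {}, {}, {}
    tissue_expr, indiv_expr = simulate_expression(cfg, gm, sub[3])
    chrom = next(iter(cfg.chrom_sizes))
    specials = _special_positions(cfg)
    return TruthBundle(
        config=cfg, seed=seed, genotypes=gm, phenotypes=pheno, tracks=tracks,
        true_states=true_states, peaks=peaks, tads=_tads(cfg),
        genes=_gene_models(cfg), expression_tissue=tissue_expr,
        expression_individual=indiv_expr,
        causal_id=f"{chrom}:{cfg.causal_pos}",
        decoy_ids=[f"{chrom}:{p}" for p in specials[1:-1]],
        bystander_id=f"{chrom}:{specials[-1]}",
    )
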