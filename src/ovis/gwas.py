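"""Mixed-linear-model genome-wide association.

The model for a quantitative trait y over n individuals is

    y = X beta + g_j b_j + u + e,      u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

with X the fixed covariates (intercept, one-hot factors such as birthplace /
batch / season, top genotype PCs), K the VanRaden genomic relationship
matrix, and g_j the tested SNP dosage. Variance components are estimated
once by REML on the null model (no SNP) after a single eigendecomposition of
K; every SNP is then tested by generalized least squares with the components
held fixed (the P3D / EMMAX approximation). Significance uses the Bonferroni
threshold -log10(alpha / M).

`MixedModelGWAS` / `GWASResults` follow the statsmodels fit/results idiom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypeMatrix

__all__ = [
    "filter_variants",
    "grm_vanraden",
    "ld_prune",
    "pca_covariates",
    "build_design",
    "MixedModelGWAS",
    "GWASResults",
    "bonferroni_threshold",
]


# ---------------------------------------------------------------------------
# Variant QC

def filter_variants(gm: GenotypeMatrix, maf: float = 0.05,
                    max_missing: float = 0.8) -> tuple[GenotypeMatrix, pd.Series]:
    """Site filters applied after DP masking: biallelic SNP, call rate, MAF.

    `max_missing` follows the vcftools convention: keep sites with call rate
    >= max_missing. Returns the filtered matrix and a per-rule removal report
    with rules applied in order (SNP-ness, call rate, MAF).
    """
    keep = np.ones(gm.n_variants, dtype=bool)
    report: dict[str, int] = {}
    is_snp = np.array([v.is_snp for v in gm.variants])
    report["not_biallelic_snp"] = int((~is_snp).sum())
    keep &= is_snp

    call_rate = np.mean(~np.isnan(gm.dosages), axis=0)
    fail_cr = keep & (call_rate < max_missing)
    report["low_call_rate"] = int(fail_cr.sum())
    keep &= ~fail_cr

    freq = gm.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf_arr = np.minimum(freq, 1 - freq)
    fail_maf = keep & (np.isnan(maf_arr) | (maf_arr < maf))
    report["low_maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    report["kept"] = int(keep.sum())
    return gm.take_variants(keep), pd.Series(report, name="n_variants")


def _impute_center(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages; return (imputed matrix, allele freqs)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(dosages, axis=0)
    filled = np.where(np.isnan(dosages), mean, dosages)
    return filled, mean / 2.0


def grm_vanraden(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix K = Z Z' / (2 sum p(1-p))."""
    filled, p = _impute_center(gm.dosages)
    Z = filled - 2 * p
    denom = 2 * np.sum(p * (1 - p))
    if denom == 0:
        raise ValueError("all variants monomorphic: GRM undefined")
    return (Z @ Z.T) / denom


def ld_prune(gm: GenotypeMatrix, window: int = 50, step: int = 5,
             r2: float = 0.2) -> np.ndarray:
    """PLINK-style --indep-pairwise pruning; returns a boolean keep mask.

    Slides a `window`-SNP window by `step`; within each window greedily
    removes the later SNP of any pair with squared correlation > r2.
    """
    filled, _ = _impute_center(gm.dosages)
    m = gm.n_variants
    keep = np.ones(m, dtype=bool)
    sd = filled.std(axis=0)
    keep &= sd > 0  # monomorphic columns carry no information
    mu = filled.mean(axis=0)
    Xs = np.where(sd > 0, (filled - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    n = Xs.shape[0]
    start = 0
    while start < m:
        idx = np.array([j for j in range(start, min(start + window, m)) if keep[j]])
        if len(idx) > 1:
            C = (Xs[:, idx].T @ Xs[:, idx]) / n
            r2mat = C * C
            for ai in range(len(idx)):
                if not keep[idx[ai]]:
                    continue
                for bi in range(ai + 1, len(idx)):
                    if keep[idx[bi]] and r2mat[ai, bi] > r2:
                        keep[idx[bi]] = False
        start += step
    return keep


def pca_covariates(gm: GenotypeMatrix, n_pcs: int = 3,
                   prune: tuple[int, int, float] | None = (50, 5, 0.2)) -> np.ndarray:
    """Top principal components of the centered, scaled genotype matrix.

    LD-prunes first (PLINK 50/5/0.2 defaults), then takes the left singular
    vectors; columns are orthonormal.
    """
    sub = gm.take_variants(ld_prune(gm, *prune)) if prune is not None else gm
    filled, p = _impute_center(sub.dosages)
    sd = filled.std(axis=0)
    ok = sd > 0
    Xs = (filled[:, ok] - filled[:, ok].mean(axis=0)) / sd[ok]
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    if n_pcs > U.shape[1]:
        raise ValueError(f"requested {n_pcs} PCs from rank-{U.shape[1]} data")
    return U[:, :n_pcs]


def build_design(covariates: pd.DataFrame | None, pcs: np.ndarray | None,
                 n: int) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept + one-hot factors + numeric + PCs.

    Factor columns are dummy-coded against their first level. Raises if the
    assembled matrix is rank-deficient, naming the offending columns.
    """
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True)
                for dn in dummies.columns:
                    cols.append(dummies[dn].to_numpy(dtype=float))
                    names.append(str(dn))
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
    if pcs is not None:
        for k in range(pcs.shape[1]):
            cols.append(pcs[:, k])
            names.append(f"PC{k + 1}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    return X, names


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance on the -log10 scale: -log10(alpha / M)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return -math.log10(alpha / n_tests)


# ---------------------------------------------------------------------------
# Model / Results

class MixedModelGWAS:
    """Single-trait mixed-linear-model association scan.

    Parameters
    ----------
    y : phenotype vector (n,)
    genotypes : GenotypeMatrix (QC-filtered)
    covariates : DataFrame of fixed covariates (factors auto-dummy-coded)
    n_pcs : genotype PCs appended to the fixed effects (0 to disable)
    K : kinship matrix; computed by `grm_vanraden` when omitted
    """

    def __init__(self, y: np.ndarray, genotypes: GenotypeMatrix,
                 covariates: pd.DataFrame | None = None, n_pcs: int = 3,
                 K: np.ndarray | None = None):
        self.y = np.asarray(y, dtype=float)
        if np.isnan(self.y).any():
            raise ValueError("phenotype contains missing values")
        self.genotypes = genotypes
        if len(self.y) != genotypes.n_samples:
            raise ValueError("phenotype / genotype sample mismatch")
        self.K = grm_vanraden(genotypes) if K is None else np.asarray(K, dtype=float)
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")
        pcs = pca_covariates(genotypes, n_pcs) if n_pcs > 0 else None
        self.X, self.covariate_names = build_design(covariates, pcs, len(self.y))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str,
                       genotypes: GenotypeMatrix,
                       covariates: list[str] | None = None, **kwargs):
        covs = data[covariates] if covariates else None
        return cls(data[trait].to_numpy(dtype=float), genotypes, covs, **kwargs)

    # -- null model -------------------------------------------------------
    def _reml_neg_ll(self, log_delta: float, eigvals: np.ndarray,
                     Uy: np.ndarray, UX: np.ndarray) -> float:
        """Negative restricted log-likelihood profiled over sigma_g^2.

        delta = sigma_e^2 / sigma_g^2; rotated covariance is
        sigma_g^2 diag(d_i + delta).
        """
        delta = math.exp(log_delta)
        n, p = UX.shape
        w = eigvals + delta
        XtWX = UX.T @ (UX / w[:, None])
        XtWy = UX.T @ (Uy / w)
        beta = np.linalg.solve(XtWX, XtWy)
        resid = Uy - UX @ beta
        rss = float(resid @ (resid / w))
        sigma_g2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * math.log(2 * math.pi * sigma_g2)
            + np.sum(np.log(w))
            + (n - p)
            - math.log(max(np.linalg.det(UX.T @ UX), 1e-300))
            + math.log(max(np.linalg.det(XtWX), 1e-300))
        )
        return -ll

    def fit(self, delta_bounds: tuple[float, float] = (1e-5, 1e5),
            n_grid: int = 61) -> "GWASResults":
        """Estimate variance components by REML and scan all SNPs (P3D)."""
        d, U = np.linalg.eigh(self.K)
        d = np.clip(d, 0.0, None)
        Uy = U.T @ self.y
        UX = U.T @ self.X
        spread = d.max() - d.min()
        boundary = False
        if spread < 1e-10 * max(d.max(), 1.0):
            warnings.warn("kinship is (a multiple of) the identity: "
                          "variance split unidentifiable; returning boundary fit")
            delta = delta_bounds[1]
            boundary = True
        else:
            grid = np.linspace(math.log(delta_bounds[0]), math.log(delta_bounds[1]), n_grid)
            vals = [self._reml_neg_ll(g, d, Uy, UX) for g in grid]
            k = int(np.argmin(vals))
            lo = grid[max(k - 1, 0)]
            hi = grid[min(k + 1, n_grid - 1)]
            res = optimize.minimize_scalar(self._reml_neg_ll, bounds=(lo, hi),
                                           args=(d, Uy, UX), method="bounded")
            delta = math.exp(res.x)
        n, p = UX.shape
        w = d + delta
        XtWX = UX.T @ (UX / w[:, None])
        beta = np.linalg.solve(XtWX, UX.T @ (Uy / w))
        resid = Uy - UX @ beta
        sigma_g2 = float(resid @ (resid / w)) / (n - p)
        sigma_e2 = sigma_g2 * delta
        reml_ll = -self._reml_neg_ll(math.log(delta), d, Uy, UX)
        scan = self._scan(U, w)
        return GWASResults(self, sigma_g2=sigma_g2, sigma_e2=sigma_e2,
                           reml_ll=reml_ll, boundary=boundary, table=scan)

    def _scan(self, U: np.ndarray, w: np.ndarray) -> pd.DataFrame:
        """GLS Wald test per SNP on whitened data, covariates projected out."""
        inv_sqrt_w = 1.0 / np.sqrt(w)
        yt = (U.T @ self.y) * inv_sqrt_w
        Xt = (U.T @ self.X) * inv_sqrt_w[:, None]
        filled, _ = _impute_center(self.genotypes.dosages)
        Gt = (U.T @ filled) * inv_sqrt_w[:, None]
        Q, _ = np.linalg.qr(Xt)
        yr = yt - Q @ (Q.T @ yt)
        Gr = Gt - Q @ (Q.T @ Gt)
        gss = np.einsum("ij,ij->j", Gr, Gr)
        mono = gss <= 1e-12
        if mono.any():
            warnings.warn(f"{int(mono.sum())} monomorphic SNP(s): no test result")
        n, p = Xt.shape
        dof = n - p - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = (Gr.T @ yr) / gss
            rss = float(yr @ yr) - beta ** 2 * gss
            sigma2 = rss / dof
            se = np.sqrt(sigma2 / gss)
            tstat = beta / se
        pvals = 2 * stats.t.sf(np.abs(tstat), dof)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        beta[mono] = np.nan
        se[mono] = np.nan
        pvals[mono] = np.nan
        v = self.genotypes.variants
        return pd.DataFrame({
            "variant_id": [x.vid for x in v],
            "chrom": [x.chrom for x in v],
            "pos": [x.pos for x in v],
            "beta": beta,
            "se": se,
            "p": pvals,
            "neglog10p": -np.log10(pvals),
        })


@dataclass
class GWASResults:
    """Fitted variance components plus the per-SNP association table."""

    model: MixedModelGWAS
    sigma_g2: float
    sigma_e2: float
    reml_ll: float
    boundary: bool
    table: pd.DataFrame

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    def lambda_gc(self) -> float:
        """Genomic-control inflation: median chi2 over its null median 0.4549."""
        p = self.table["p"].dropna().to_numpy()
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        thr = bonferroni_threshold(int(self.table["p"].notna().sum()), alpha)
        return self.table[self.table["neglog10p"] > thr]

    def summary(self) -> str:
        m = int(self.table["p"].notna().sum())
        thr = bonferroni_threshold(m) if m else float("nan")
        lines = [
            "Mixed-linear-model GWAS",
            "=" * 47,
            f"samples:            {self.model.genotypes.n_samples}",
            f"variants tested:    {m}",
            f"fixed effects:      {len(self.model.covariate_names)} "
            f"({', '.join(self.model.covariate_names[:6])}"
            f"{', ...' if len(self.model.covariate_names) > 6 else ''})",
            f"sigma_g^2:          {self.sigma_g2:.4f}",
            f"sigma_e^2:          {self.sigma_e2:.4f}",
            f"h2 (pseudo):        {self.h2:.3f}" + ("  [boundary]" if self.boundary else ""),
            f"REML logL:          {self.reml_ll:.2f}",
            f"lambda_GC:          {self.lambda_gc():.3f}",
            f"-log10 threshold:   {thr:.2f} (Bonferroni, alpha=0.05)",
            f"significant SNPs:   {len(self.significant())}",
        ]
        return "\n".join(lines)

    def plot_manhattan(self, ax=None, alpha: float = 0.05):
        """Manhattan plot with the Bonferroni line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        tab = self.table.dropna(subset=["p"])
        offset = 0
        for i, (chrom, sub) in enumerate(tab.groupby("chrom", sort=True)):
            ax.scatter(sub["pos"] + offset, sub["neglog10p"], s=4,
                       color="C0" if i % 2 == 0 else "C1", label=None)
            offset += sub["pos"].max()
        thr = bonferroni_threshold(len(tab), alpha)
        ax.axhline(thr, color="red", linestyle="--", linewidth=1)
        ax.set_xlabel("position")
        ax.set_ylabel(r"$-\log_{10} p$")
        return ax
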