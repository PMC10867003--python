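"""Mixed-linear-model GWAS: SNP QC, LD utilities, kinship, REML, and the scan.

The association engine follows the EMMAX approximation: the variance
components of the null mixed model

    y = X b + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

are estimated once by REML (profiling the ratio delta = sigma_e^2 /
sigma_g^2 on the eigenspectrum of the covariate-projected kinship), and
every SNP is then tested by generalized least squares after whitening
with Sigma^{-1/2}, Sigma = sigma_g^2 K + sigma_e^2 I.  P-values use the
t distribution with n - q - 1 degrees of freedom.

LD is the squared Pearson correlation of allele dosages over
pairwise-complete accessions; pruning mirrors the windowed
``--indep-pairwise`` procedure (window/step in SNP counts, greedy removal
of the lower-MAF member of each offending pair).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import (
    AssociationResult,
    GenotypeMatrix,
    KinshipMatrix,
    VarianceComponents,
)

__all__ = [
    "snp_qc",
    "ld_r2",
    "ld_prune",
    "kinship",
    "reml_fit",
    "emmax_scan",
    "mlm_gwas",
    "bonferroni_threshold",
    "ld_decay",
]

logger = logging.getLogger(__name__)

#: null median of the 1-df chi-square, used for the genomic-inflation factor
CHI2_1_MEDIAN = 0.4549364231195724


def snp_qc(G: GenotypeMatrix, maf_min: float = 0.05,
           missing_max: float = 0.25) -> GenotypeMatrix:
    """Drop SNPs failing MAF >= ``maf_min`` (inclusive) or missing rate
    <= ``missing_max`` (inclusive)."""
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= missing_max <= 1.0:
        raise ValueError("missing_max must be in [0, 1]")
    maf_ok = G.maf() >= maf_min
    miss_ok = G.missing_rate() <= missing_max
    logger.info("snp_qc: %d SNPs fail MAF, %d fail missing rate, %d kept of %d",
                int((~maf_ok).sum()), int((~miss_ok).sum()),
                int((maf_ok & miss_ok).sum()), G.n_snps)
    return G.take_snps(maf_ok & miss_ok)


def ld_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (missing-aware).

    Returns NaN when fewer than 3 pairwise-complete accessions remain or
    either vector has zero variance on the complete pairs.
    """
    gi = np.asarray(g_i, dtype=float)
    gj = np.asarray(g_j, dtype=float)
    ok = ~np.isnan(gi) & ~np.isnan(gj)
    if ok.sum() < 3:
        return float("nan")
    x, y = gi[ok], gj[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def _window_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise r^2 matrix of a dosage block (columns = SNPs), missing-aware
    via mean imputation within the block (adequate at QC'd missingness)."""
    d = dosage.copy()
    mean = np.nanmean(d, axis=0)
    idx = np.nonzero(np.isnan(d))
    d[idx] = mean[idx[1]]
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = np.nan
    c = (d.T @ d) / len(d)
    r = c / np.outer(sd, sd)
    return r * r


def ld_prune(G: GenotypeMatrix, window_snps: int = 50, step_snps: int = 10,
             r2_max: float = 0.1) -> GenotypeMatrix:
    """Windowed LD pruning (``--indep-pairwise``-style).

    Windows of ``window_snps`` consecutive SNPs advance by ``step_snps``
    over the original SNP order.  Within a window, while any surviving pair
    exceeds ``r2_max``, the pair scanned first in position order is
    resolved by removing its lower-MAF member (ties: the larger position).
    """
    if step_snps > window_snps:
        raise ValueError("step_snps must not exceed window_snps")
    if step_snps <= 0:
        raise ValueError("step_snps must be positive")
    n = G.n_snps
    maf = G.maf()
    pos = G.snps.pos.to_numpy()
    removed = np.zeros(n, dtype=bool)
    for w_start in range(0, max(n - 1, 1), step_snps):
        w = np.arange(w_start, min(w_start + window_snps, n))
        w = w[~removed[w]]
        if len(w) < 2:
            if w_start + window_snps >= n:
                break
            continue
        r2 = _window_r2(G.dosage[:, w])
        alive = np.ones(len(w), dtype=bool)
        while True:
            offender = None
            for ii in range(len(w)):
                if not alive[ii]:
                    continue
                for jj in range(ii + 1, len(w)):
                    if alive[jj] and r2[ii, jj] > r2_max:
                        offender = (ii, jj)
                        break
                if offender:
                    break
            if offender is None:
                break
            ii, jj = offender
            i, j = w[ii], w[jj]
            if maf[i] < maf[j] or (maf[i] == maf[j] and pos[i] > pos[j]):
                alive[ii] = False
                removed[i] = True
            else:
                alive[jj] = False
                removed[j] = True
        if w_start + window_snps >= n:
            break
    return G.take_snps(~removed)


def kinship(G: GenotypeMatrix, method: str = "centered_grm") -> KinshipMatrix:
    """Accession relatedness from (LD-pruned) genotypes.

    ``centered_grm``: K = Z Z^T / m with Z the column-centered dosages
    scaled by sqrt(2 p (1 - p)); ``ibs``: proportion of shared alleles.
    Missing dosages are mean-imputed; K is symmetrized and PSD-repaired by
    clipping negative eigenvalues at zero.
    """
    if G.n_snps == 0:
        raise ValueError("cannot compute kinship from zero SNPs")
    X = G.imputed_dosage()
    m = X.shape[1]
    if method == "centered_grm":
        p = X.mean(axis=0) / 2.0
        denom = np.sqrt(2.0 * p * (1.0 - p))
        denom[denom == 0] = 1.0
        Z = (X - 2.0 * p) / denom
        K = Z @ Z.T / m
    elif method == "ibs":
        I0 = (X < 0.5).astype(float)
        I1 = ((X >= 0.5) & (X < 1.5)).astype(float)
        I2 = (X >= 1.5).astype(float)
        d1 = I0 @ I1.T + I1 @ I0.T + I1 @ I2.T + I2 @ I1.T
        d2 = I0 @ I2.T + I2 @ I0.T
        K = 1.0 - (d1 + 2.0 * d2) / (2.0 * m)
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    K = (K + K.T) / 2.0
    evals, evecs = np.linalg.eigh(K)
    if evals[0] < 0:
        K = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        K = (K + K.T) / 2.0
    return KinshipMatrix(K=K, accessions=list(G.accessions), method=method)


def reml_fit(y: np.ndarray, K: KinshipMatrix | np.ndarray,
             X_cov: np.ndarray | None = None,
             grid: tuple[float, float, int] = (-10.0, 10.0, 100),
             tol: float = 1e-6) -> VarianceComponents:
    """REML variance components by profiling log(delta) on a dense grid
    followed by bounded scalar refinement.

    ``y`` must be complete (drop missing accessions first); ``X_cov``
    defaults to an intercept.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y contains missing values; drop them before reml_fit")
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = len(y)
    X = np.ones((n, 1)) if X_cov is None else np.atleast_2d(np.asarray(X_cov, dtype=float))
    if X.shape[0] != n:
        X = X.T
    q = X.shape[1]
    if n <= q + 1:
        raise ValueError("not enough observations for REML (n <= q + 1)")

    # eigenspectrum of the covariate-projected kinship S K S
    Q, _ = np.linalg.qr(X, mode="complete")
    B = Q[:, q:]  # orthonormal basis of the complement of span(X)
    M = B.T @ Kmat @ B
    xi, U = np.linalg.eigh((M + M.T) / 2.0)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (B.T @ y)
    nq = n - q
    eta2 = eta ** 2

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = xi + delta
        rss = float(np.sum(eta2 / denom))
        return -0.5 * (nq * np.log(nq / (2 * np.pi)) - nq
                       - nq * np.log(rss) - float(np.sum(np.log(denom))))

    lo, hi, npts = grid
    grid_pts = np.linspace(lo, hi, npts)
    vals = np.array([neg_restricted_ll(g) for g in grid_pts])
    best = int(np.argmin(vals))
    a = grid_pts[max(best - 1, 0)]
    b = grid_pts[min(best + 1, npts - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(a, b),
                                   method="bounded", options={"xatol": tol})
    log_delta = float(res.x) if res.fun <= vals[best] else float(grid_pts[best])
    delta = float(np.exp(log_delta))
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / nq)
    sigma_e2 = delta * sigma_g2
    return VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta,
                              reml_loglik=-neg_restricted_ll(log_delta))


def emmax_scan(y: np.ndarray, G: GenotypeMatrix, K: KinshipMatrix | np.ndarray,
               vc: VarianceComponents, X_cov: np.ndarray | None = None,
               trait: str = "trait") -> AssociationResult:
    """Per-SNP GLS association with the EMMAX whitening transform.

    Variance components are taken from ``vc`` (fitted on the null model)
    and reused for every SNP; missing dosages are mean-imputed per SNP.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    X = np.ones((n, 1)) if X_cov is None else np.atleast_2d(np.asarray(X_cov, dtype=float))
    if X.shape[0] != n:
        X = X.T
    q = X.shape[1]
    df = n - q - 1
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")

    d, U = np.linalg.eigh(Kmat)
    w = vc.sigma_g2 * np.clip(d, 0.0, None) + vc.sigma_e2
    if np.any(w <= 0):
        raise ValueError("singular marginal covariance; check variance components")
    scale = 1.0 / np.sqrt(w)
    # whitened data: W^T = diag(scale) U^T
    yw = scale * (U.T @ y)
    Xw = scale[:, None] * (U.T @ X)
    Gw = scale[:, None] * (U.T @ G.imputed_dosage())

    # residualize against whitened covariates (Frisch-Waugh)
    Qx, _ = np.linalg.qr(Xw)
    yr = yw - Qx @ (Qx.T @ yw)
    Gr = Gw - Qx @ (Qx.T @ Gw)

    gg = np.einsum("ij,ij->j", Gr, Gr)
    degenerate = gg <= 1e-12 * max(float(np.max(gg)), 1.0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} SNP(s) have zero variance after "
                      "whitening; their p-values are set to missing")
    gg_safe = np.where(degenerate, np.nan, gg)
    beta = (Gr.T @ yr) / gg_safe
    rss = float(yr @ yr) - beta ** 2 * gg_safe
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)

    valid = ~np.isnan(p)
    if valid.any():
        chi2 = stats.chi2.isf(np.clip(p[valid], 1e-300, 1.0), 1)
        lambda_gc = float(np.median(chi2) / CHI2_1_MEDIAN)
    else:
        lambda_gc = float("nan")
    table = pd.DataFrame({
        "chrom": G.snps.chrom.to_numpy(),
        "pos": G.snps.pos.to_numpy(),
        "beta": beta,
        "se": se,
        "t": t,
        "p": p,
    }, index=G.snps.index)
    return AssociationResult(trait=trait, table=table, lambda_gc=lambda_gc,
                             n_used=n, df=df, vc=vc)


def mlm_gwas(trait_values: pd.Series, G: GenotypeMatrix,
             K: KinshipMatrix | None = None,
             trait: str | None = None) -> AssociationResult:
    """Convenience wrapper: drop missing accessions, fit REML, run the scan.

    ``trait_values`` is indexed by accession id; ``K`` defaults to the
    centered GRM of ``G`` (computed on all SNPs of ``G``; pass a kinship
    from LD-pruned genotypes for production use).
    """
    trait = trait or str(trait_values.name)
    v = trait_values.reindex(G.accessions)
    ok = ~v.isna().to_numpy()
    idx = np.flatnonzero(ok)
    Gs = G.take_accessions(idx) if not ok.all() else G
    if K is None:
        K = kinship(ld_prune(snp_qc(Gs)))
    Kmat = K.K[np.ix_(idx, idx)] if not ok.all() else K.K
    y = v.to_numpy(dtype=float)[idx]
    vc = reml_fit(y, Kmat)
    return emmax_scan(y, Gs, Kmat, vc, trait=trait)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def ld_decay(G: GenotypeMatrix, max_dist_bp: int = 100_000,
             bin_width_bp: int = 1000) -> tuple[pd.DataFrame, float | None]:
    """Mean pairwise r^2 per distance bin, and the decay distance.

    All same-chromosome SNP pairs within ``max_dist_bp`` are used (missing
    dosages mean-imputed).  The decay distance is the midpoint of the first
    bin whose mean r^2 falls below 0.1; None (flagged) when no bin does.
    """
    if bin_width_bp <= 0:
        raise ValueError("bin_width_bp must be > 0")
    pos = G.snps.pos.to_numpy()
    chroms = G.snps.chrom.to_numpy()
    # normalized (mean-imputed, centered, unit-variance) dosage columns:
    # r^2 between columns is then a dot product
    Z = G.imputed_dosage()
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = np.nan
    Z = Z / (sd * np.sqrt(len(Z)))
    dist_parts, r2_parts = [], []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        j_hi = np.searchsorted(p, p + max_dist_bp, side="right")
        for a in range(len(idx)):
            if j_hi[a] <= a + 1:
                continue
            cols = idx[a + 1:j_hi[a]]
            r2 = (Z[:, idx[a]] @ Z[:, cols]) ** 2
            dist_parts.append(p[a + 1:j_hi[a]] - p[a])
            r2_parts.append(r2)
    dists = np.concatenate(dist_parts) if dist_parts else np.empty(0)
    r2s = np.concatenate(r2_parts) if r2_parts else np.empty(0)
    ok = ~np.isnan(r2s)
    dists, r2s = dists[ok].astype(float), r2s[ok]
    edges = np.arange(0, max_dist_bp + bin_width_bp, bin_width_bp)
    which = np.digitize(dists, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append(((edges[b] + edges[b + 1]) / 2.0,
                     float(r2s[sel].mean()) if sel.any() else float("nan"),
                     int(sel.sum())))
    table = pd.DataFrame(rows, columns=["distance_bp", "mean_r2", "n_pairs"])
    below = table.dropna(subset=["mean_r2"]).query("mean_r2 < 0.1")
    decay = float(below.distance_bp.iloc[0]) if len(below) else None
    return table, decay
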