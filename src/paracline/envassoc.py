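"""Latent-factor environmental-association genome scan.

Each SNP's genotype is regressed on the environmental variable while
conditioning on K latent factors that capture population structure — the
deterministic least-squares analogue of a latent factor mixed model: the
factors are the top-K left singular vectors of the centered, mean-imputed
genotype matrix, and significance comes from the env coefficient's
t-statistic.  Raw p-values are recalibrated with the genomic inflation
factor (median chi-square method) and converted to q-values by
Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants_io import GenotypeMatrix

logger = logging.getLogger("paracline")

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = 0.4549


@dataclass
class EnvAssocResult:
    """Per-SNP environmental-association statistics for one scan."""

    z: np.ndarray
    p_raw: np.ndarray
    p_cal: np.ndarray
    q: np.ndarray
    K: int
    lambda_gc: float
    sites: pd.DataFrame | None = None
    df: int | None = None  # residual df of the per-SNP regression

    def to_frame(self) -> pd.DataFrame:
        df = (
            self.sites[["chrom", "pos"]].copy()
            if self.sites is not None
            else pd.DataFrame(index=range(len(self.z)))
        )
        df["z"] = self.z
        df["p_raw"] = self.p_raw
        df["p_cal"] = self.p_cal
        df["q"] = self.q
        return df


@dataclass
class OutlierGeneSet:
    q_threshold: float
    min_snps: int
    genes: dict[str, int]  # gene id -> count of qualifying SNPs

    def gene_ids(self) -> set[str]:
        return set(self.genes)


def fit_latent_factors(gm: GenotypeMatrix, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-K latent factors of the centered, mean-imputed genotype matrix.

    Scores (samples x K) are orthonormal left singular vectors; loadings are
    ``diag(s) @ Vt`` rows.  The sign of each factor is fixed by making its
    largest-magnitude score entry positive, so output is reproducible.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if K >= gm.n_samples:
        raise ValueError("K must be smaller than the number of samples")
    x = gm.imputed()
    x -= x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :K].copy()
    loadings = (s[:K, None] * vt[:K]).copy()
    for k in range(K):
        j = np.argmax(np.abs(scores[:, k]))
        if scores[j, k] < 0:
            scores[:, k] *= -1
            loadings[k] *= -1
    return scores, loadings


def env_association(
    gm: GenotypeMatrix,
    env: np.ndarray,
    K: int = 2,
    lambda_override: float | None = None,
) -> EnvAssocResult:
    """Scan every SNP for association with the environmental variable.

    Per SNP, OLS of the (mean-imputed) genotype on
    ``[intercept, env, K latent factors]``; ``z`` is the env coefficient
    over its standard error and ``p_raw`` comes from the t reference with
    ``n - K - 2`` degrees of freedom.  ``p_cal`` applies genomic-control
    recalibration (``lambda_override`` replaces the estimated factor) and
    ``q`` is Benjamini–Hochberg over all SNPs.

    Following the ridge formulation of the latent factor model, the
    conditioning factors are the top-K left singular vectors of the
    genotype matrix **after projecting out the environmental variable**:
    estimating them from the raw matrix would let a strong genome-wide
    cline masquerade as structure and be absorbed into the factors.
    """
    env = np.asarray(env, dtype=float)
    n = gm.n_samples
    if len(env) != n:
        raise ValueError("env must have one value per sample")
    if n < K + 2:
        raise ValueError("need at least K + 2 samples")
    g = gm.imputed()
    if K > 0:
        scores = _latent_factors_given_env(g, env, K)
        design = np.column_stack([np.ones(n), env, scores])
        # flag (not error) if env carries no information beyond the
        # intercept and factors (e.g. a constant environment)
        fcols = design[:, [0] + list(range(2, K + 2))]
        resid_env = env - fcols @ np.linalg.lstsq(fcols, env, rcond=None)[0]
        scale = max(float(env.std()), 1e-12)
        if resid_env.std() < 1e-6 * scale:
            warnings.warn(
                "environmental variable is collinear with the intercept or "
                "latent factors; z-scores reported as computed",
                stacklevel=2,
            )
    else:
        design = np.column_stack([np.ones(n), env])
    df = n - design.shape[1]
    beta, se = _batched_ols(design, g)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p_raw = 2.0 * stats.t.sf(np.abs(z), df)
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    lam = lambda_override if lambda_override is not None else genomic_inflation(z)
    p_cal = calibrate_pvalues(z, lam) if lam > 0 else p_raw.copy()
    q = bh_qvalues(p_cal)
    return EnvAssocResult(
        z=z, p_raw=p_raw, p_cal=p_cal, q=q, K=K, lambda_gc=lam, sites=gm.sites, df=df
    )


def _latent_factors_given_env(g: np.ndarray, env: np.ndarray, K: int) -> np.ndarray:
    """Top-K left singular vectors of the genotype matrix with the
    environmental direction (and the mean) projected out; sign fixed by the
    largest-magnitude entry."""
    n = g.shape[0]
    x = np.column_stack([np.ones(n), env])
    qx, _ = np.linalg.qr(x)
    resid = g - qx @ (qx.T @ g)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    scores = u[:, :K].copy()
    for k in range(K):
        j = np.argmax(np.abs(scores[:, k]))
        if scores[j, k] < 0:
            scores[:, k] *= -1
    return scores


def _batched_ols(x: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each column of ``ys`` on design ``x``; returns the coefficient
    and standard error of column 1 (the env term)."""
    n, k = x.shape
    # pseudoinverse so a degenerate design (flagged upstream) still yields
    # finite output instead of a hard failure
    xtx_inv = np.linalg.pinv(x.T @ x)
    betas = xtx_inv @ (x.T @ ys)  # k x m
    resid = ys - x @ betas
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / (n - k)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    return betas[1], se


def genomic_inflation(z: np.ndarray) -> float:
    """Genomic inflation factor ``median(z^2) / 0.4549``."""
    z = np.asarray(z, dtype=float)
    if len(z) < 10:
        raise ValueError("need at least 10 z-scores")
    lam = float(np.median(z**2) / CHI2_1_MEDIAN)
    if lam == 0:
        warnings.warn("all z-scores are zero; lambda_gc = 0", stacklevel=2)
    return lam


def calibrate_pvalues(z: np.ndarray, lambda_gc: float) -> np.ndarray:
    """Genomic-control p-values: upper chi-square(1) tail of ``z^2 / lambda``."""
    if lambda_gc <= 0:
        raise ValueError("lambda_gc must be positive")
    p = stats.chi2.sf(np.asarray(z, dtype=float) ** 2 / lambda_gc, df=1)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def outlier_genes(
    result: EnvAssocResult,
    snp_to_genes: dict[int, list[str]],
    q_threshold: float,
    min_snps: int = 1,
) -> OutlierGeneSet:
    """Genes containing at least ``min_snps`` SNPs with ``q < q_threshold``."""
    counts: dict[str, int] = {}
    for j in np.flatnonzero(result.q < q_threshold):
        for gene in snp_to_genes.get(int(j), ()):
            counts[gene] = counts.get(gene, 0) + 1
    genes = {g: c for g, c in counts.items() if c >= min_snps}
    return OutlierGeneSet(q_threshold=q_threshold, min_snps=min_snps, genes=genes)


def combine_runs(results: list[EnvAssocResult]) -> EnvAssocResult:
    """Combine repeated scans by per-SNP median z, then recalibrate.

    With the deterministic factor estimator all runs are identical and the
    combination is a no-op; the entry point exists for stochastic factor
    methods.
    """
    if not results:
        raise ValueError("no results to combine")
    m = len(results[0].z)
    for r in results[1:]:
        if len(r.z) != m:
            raise ValueError("mismatched SNP sets across runs")
    z = np.median(np.vstack([r.z for r in results]), axis=0)
    first = results[0]
    lam = genomic_inflation(z)
    if first.df is not None:
        p_raw = 2.0 * stats.t.sf(np.abs(z), first.df)
    else:
        p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    p_cal = calibrate_pvalues(z, lam) if lam > 0 else p_raw.copy()
    return EnvAssocResult(
        z=z,
        p_raw=p_raw,
        p_cal=p_cal,
        q=bh_qvalues(p_cal),
        K=first.K,
        lambda_gc=lam,
        sites=first.sites,
        df=first.df,
    )
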