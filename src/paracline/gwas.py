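"""Linear mixed-model association for body weight with kinship correction.

Model per SNP::

    y = W a + x b + u + e,   u ~ MVN(0, delta * tau^-1 K),  e ~ MVN(0, tau^-1 I)

where ``W`` holds the covariates (intercept and sex), ``x`` the focal SNP's
genotypes, ``K`` the centered kinship matrix, and ``delta`` the ratio of
the two variance components.  The implementation eigendecomposes ``K``
once; per SNP the likelihood (REML by default, ML for the likelihood-ratio
test) is maximized over ``delta`` on a log10 grid spanning [-5, 5] with
bounded refinement, followed by GLS estimation of the fixed effects.

The per-SNP fraction of phenotypic variance explained is the standard
effect-size/allele-frequency formula::

    PVE = 2 b^2 f(1-f) / (2 b^2 f(1-f) + se(b)^2 2 N f(1-f))

with ``f`` the minor allele frequency and ``N`` the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .envassoc import bh_qvalues
from .variants_io import MISSING, GenotypeMatrix

_LOG10_DELTA_GRID = np.linspace(-5.0, 5.0, 61)


def centered_kinship(gm: GenotypeMatrix) -> np.ndarray:
    """Centered kinship ``K = Xc Xc' / p`` from mean-imputed genotypes."""
    if gm.n_sites == 0:
        raise ValueError("kinship needs at least one SNP")
    if gm.n_samples < 2:
        raise ValueError("kinship needs at least two samples")
    x = gm.imputed()
    x -= x.mean(axis=0)
    return (x @ x.T) / gm.n_sites


def pve(beta: float, se_beta: float, maf: float, n: int) -> float:
    """Fraction of phenotypic variance explained by one SNP."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if n < 1:
        raise ValueError("N must be at least 1")
    if se_beta <= 0:
        raise ValueError("se_beta must be positive")
    het = 2.0 * maf * (1.0 - maf)
    num = beta**2 * het
    return num / (num + se_beta**2 * 2.0 * n * maf * (1.0 - maf))


def _neg_ll(log10_delta, s, yt, xt, reml):
    """Negative profile (restricted) log-likelihood at one delta."""
    delta = 10.0**log10_delta
    w = 1.0 / (delta * s + 1.0)
    n, q = xt.shape
    a = xt.T @ (w[:, None] * xt)
    b = xt.T @ (w * yt)
    try:
        beta = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yt - xt @ beta
    rss = float(np.sum(w * resid**2))
    if rss <= 0:
        return np.inf
    logdet_h = float(np.sum(np.log(delta * s + 1.0)))
    if reml:
        nf = n - q
        sign, logdet_a = np.linalg.slogdet(a)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            nf * np.log(2.0 * np.pi) + nf + nf * np.log(rss / nf)
            + logdet_h + logdet_a
        )
    else:
        ll = -0.5 * (n * np.log(2.0 * np.pi) + n + n * np.log(rss / n) + logdet_h)
    return -ll


def _optimize_delta(s, yt, xt, reml):
    vals = [_neg_ll(g, s, yt, xt, reml) for g in _LOG10_DELTA_GRID]
    i = int(np.argmin(vals))
    lo = _LOG10_DELTA_GRID[max(i - 1, 0)]
    hi = _LOG10_DELTA_GRID[min(i + 1, len(_LOG10_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        _neg_ll, bounds=(lo, hi), args=(s, yt, xt, reml), method="bounded"
    )
    if res.fun <= vals[i]:
        return float(res.x), -float(res.fun)
    return float(_LOG10_DELTA_GRID[i]), -float(vals[i])


def _gls_fit(delta, s, yt, xt):
    w = 1.0 / (delta * s + 1.0)
    a = xt.T @ (w[:, None] * xt)
    a_inv = np.linalg.inv(a)
    beta = a_inv @ (xt.T @ (w * yt))
    resid = yt - xt @ beta
    rss = float(np.sum(w * resid**2))
    n, q = xt.shape
    sigma2 = rss / (n - q)
    se = np.sqrt(sigma2 * np.diag(a_inv))
    return beta, se


def lmm_association(
    gm: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray,
    kinship: np.ndarray,
    reml: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Mixed-model association of every SNP with the phenotype.

    Parameters
    ----------
    covariates : ndarray
        n x c design including the intercept column.
    reml : bool
        Use REML (default) or ML to estimate the per-SNP variance ratio.
        The likelihood-ratio test always compares ML log-likelihoods, both
        evaluated at that SNP's estimated variance ratio.

    Returns a DataFrame with per-SNP ``maf``, ``beta``, ``se_beta``,
    ``delta``, ``p_wald``, ``p_lrt``, ``q`` (BH over all SNPs) and ``pve``.
    Constant SNPs (``maf == 0``) are an error: filter first.
    """
    y = np.asarray(y, dtype=float)
    w_cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    n = gm.n_samples
    if w_cov.shape[0] != n or len(y) != n:
        raise ValueError("phenotype/covariate dimensions do not match samples")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(w_cov)):
        raise ValueError("phenotypes and covariates must be complete")
    if np.linalg.matrix_rank(w_cov) < w_cov.shape[1]:
        raise ValueError("singular covariate matrix")
    k = np.asarray(kinship, dtype=float)
    if not np.allclose(k, k.T, atol=1e-9):
        raise ValueError("kinship matrix must be symmetric")
    s, u = np.linalg.eigh(k)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise ValueError("kinship matrix is not positive semidefinite")
    s = np.clip(s, 0.0, None)

    x_imp = gm.imputed()
    freqs = gm.allele_frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    if np.any(maf <= 0):
        bad = int(np.flatnonzero(maf <= 0)[0])
        raise ValueError(
            f"constant SNP at site index {bad} (maf = 0); filter sites first"
        )

    yt = u.T @ y
    wt = u.T @ w_cov
    xt_all = u.T @ x_imp
    c = w_cov.shape[1]

    m = gm.n_sites
    beta = np.empty(m)
    se = np.empty(m)
    delta_out = np.empty(m)
    p_wald = np.empty(m)
    p_lrt = np.empty(m)
    for j in range(m):
        xt = np.column_stack([wt, xt_all[:, j]])
        log10_d, _ = _optimize_delta(s, yt, xt, reml=reml)
        delta = 10.0**log10_d
        b, ses = _gls_fit(delta, s, yt, xt)
        beta[j] = b[-1]
        se[j] = ses[-1]
        delta_out[j] = delta
        t = b[-1] / ses[-1]
        p_wald[j] = 2.0 * stats.t.sf(abs(t), n - c - 1)
        # Profile likelihood ratio at the estimated variance ratio: both the
        # full and the covariates-only ML log-likelihoods are evaluated at
        # this SNP's delta-hat, mirroring how the Wald test conditions on it.
        # Re-optimizing delta under pure ML is ill-posed here: the centered
        # kinship annihilates the all-ones vector, which lies in the
        # covariate span, so the ML profile decreases without bound as
        # delta grows; the REML profile cancels that drift.
        ll_full = -_neg_ll(log10_d, s, yt, xt, reml=False)
        ll_null = -_neg_ll(log10_d, s, yt, wt, reml=False)
        lrt = max(2.0 * (ll_full - ll_null), 0.0)
        p_lrt[j] = stats.chi2.sf(lrt, df=1)

    p_wald = np.clip(p_wald, np.finfo(float).tiny, 1.0)
    p_lrt = np.clip(p_lrt, np.finfo(float).tiny, 1.0)
    out = gm.sites[["chrom", "pos"]].copy()
    out["maf"] = maf
    out["beta"] = beta
    out["se_beta"] = se
    out["delta"] = delta_out
    out["p_wald"] = p_wald
    out["p_lrt"] = p_lrt
    out["q"] = bh_qvalues(p_wald)
    out["pve"] = [
        pve(beta[j], se[j], maf[j], n) if se[j] > 0 else np.nan for j in range(m)
    ]
    out.attrs["fdr"] = fdr
    out.attrs["n_samples"] = n
    return out


def gene_pve(results: pd.DataFrame, snp_to_genes: dict[int, list[str]]) -> pd.DataFrame:
    """Per-gene PVE of the most strongly associated SNP.

    The representative SNP per gene minimizes ``p_wald``; ties are broken
    by smallest genomic position.
    """
    rows = []
    gene_sites: dict[str, list[int]] = {}
    for j, genes in snp_to_genes.items():
        for g in genes:
            gene_sites.setdefault(g, []).append(j)
    for gene, sites in gene_sites.items():
        sub = results.iloc[sorted(sites)]
        best = sub.sort_values(["p_wald", "pos"], kind="stable").iloc[0]
        rows.append(
            {
                "gene_id": gene,
                "top_pos": int(best["pos"]),
                "p_wald": best["p_wald"],
                "pve": best["pve"],
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
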