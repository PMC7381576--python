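"""Latent-factor genotype-environment association scan.

Population structure is absorbed by K latent factors estimated from the
genotype matrix itself (truncated SVD of the centered, scaled matrix —
the deterministic least-squares counterpart of an LFMM fit). Each locus
is then tested by ordinary least squares of genotype on the scanned
variable plus the factors; the variable's t-statistic is mapped to a
z-score, the z-distribution is recalibrated by the genomic inflation
factor lambda = median(z^2) / median(chi^2_1), and candidates are called
by Benjamini-Hochberg FDR on the calibrated p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeaConfig
from .datatypes import MISSING, GenotypeMatrix

#: median of the chi-squared distribution with 1 degree of freedom
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def estimate_latent_factors(geno: GenotypeMatrix, k: int) -> np.ndarray:
    """First ``k`` left singular vectors (scaled by singular values) of
    the standardized genotype matrix; deterministic up to the fixed sign
    convention (largest-magnitude coordinate positive)."""
    if k == 0:
        return np.empty((geno.n_individuals, 0))
    if (geno.genotypes == MISSING).any():
        raise ValueError("matrix contains missing genotypes; impute first")
    x = geno.genotypes.astype(np.float64)
    sd = x.std(axis=0)
    x = x[:, sd > 0]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    rank = min(x.shape)
    if k >= rank:
        raise ValueError(f"k={k} must be below the matrix rank ({rank})")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for c in range(k):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            u[:, c] *= -1.0
    return u * s


def lfmm_scan(geno: GenotypeMatrix, variable, factors: np.ndarray):
    """Per-locus association test adjusting for the latent factors.

    Fits genotype ~ intercept + variable + factors at every locus in one
    shot (common design matrix), returns ``(z, p_raw, flags)`` where
    ``flags`` marks loci with zero residual variance (recorded with
    p = 1). The variable is standardized internally, so results are
    invariant to affine rescaling.
    """
    v = np.asarray(variable, dtype=np.float64)
    if (geno.genotypes == MISSING).any():
        raise ValueError("matrix contains missing genotypes; impute first")
    if len(v) != geno.n_individuals:
        raise ValueError("variable length must match individuals")
    if not np.isfinite(v).all():
        raise ValueError("variable contains non-finite values")
    if np.ptp(v) == 0:
        raise ValueError("variable is constant")
    v = (v - v.mean()) / v.std()
    n = len(v)
    d = np.column_stack([np.ones(n), v, factors])
    p_par = d.shape[1]
    df = n - p_par
    if df <= 0:
        raise ValueError("more parameters than individuals")
    g = geno.genotypes.astype(np.float64)
    dtd_inv = np.linalg.pinv(d.T @ d)
    beta = dtd_inv @ (d.T @ g)  # p_par x L
    resid = g - d @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    zero = sigma2 <= np.finfo(float).eps * n
    se = np.sqrt(np.maximum(sigma2, 1e-300) * dtd_inv[1, 1])
    t = np.where(zero, 0.0, beta[1] / se)
    # map the t statistic onto the standard-normal scale
    p_t = 2.0 * stats.t.sf(np.abs(t), df)
    z = np.sign(t) * stats.norm.isf(np.clip(p_t / 2.0, 1e-300, 1.0))
    p_raw = np.where(zero, 1.0, np.clip(p_t, 1e-300, 1.0))
    z = np.where(zero, 0.0, z)
    return z, p_raw, zero


def calibrate_and_call(z: np.ndarray, fdr_q: float = 0.05):
    """Genomic-inflation calibration and BH candidate calling.

    Returns ``(lambda, p_adjusted, candidate_mask)``; lambda is
    ``median(z^2)`` over the chi-squared-1 median, calibrated p-values
    come from ``z^2 / lambda``.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size < 10:
        raise ValueError("need at least 10 loci to calibrate")
    lam = float(np.median(z**2) / _CHI2_1_MEDIAN)
    if lam <= 0:
        raise ValueError("degenerate z-scores (all zero)")
    p_adj = stats.chi2.sf(z**2 / lam, 1)
    p_adj = np.clip(p_adj, 1e-300, 1.0)
    from statsmodels.stats.multitest import multipletests

    reject, _, _, _ = multipletests(p_adj, alpha=fdr_q, method="fdr_bh")
    return lam, p_adj, reject


@dataclass
class GeaResult:
    """Scan results across variables for one sample (typically one year)."""

    locus_ids: np.ndarray
    variables: list
    z: pd.DataFrame  # L x variables
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame
    lam: dict  # variable -> genomic inflation factor
    candidates: dict  # variable -> set of locus ids
    k_latent: int

    def candidate_counts(self) -> pd.Series:
        return pd.Series({v: len(self.candidates[v]) for v in self.variables})

    def all_candidates(self) -> set:
        out: set = set()
        for v in self.variables:
            out |= self.candidates[v]
        return out


def run_gea(
    geno: GenotypeMatrix, env: pd.DataFrame, config: GeaConfig | None = None
) -> GeaResult:
    """Full scan: latent factors once, then one test per variable.

    ``env`` holds one column per scanned variable (rows aligned with the
    genotype matrix). Variables are scanned separately; a warning is
    emitted when two scanned variables are collinear (|r| > 0.8), as
    latitude and sampling date are by survey design.
    """
    config = config or GeaConfig()
    missing_cols = [v for v in config.variables if v not in env.columns]
    if missing_cols:
        raise ValueError(f"environment table lacks columns {missing_cols}")
    sub = env[list(config.variables)].astype(float)
    corr = sub.corr()
    for i, a in enumerate(config.variables):
        for b in config.variables[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > 0.8:
                warnings.warn(
                    f"variables '{a}' and '{b}' are collinear (r={r:.2f}); "
                    "their candidate sets are not independent"
                )
    factors = estimate_latent_factors(geno, config.k_latent)
    z_cols, praw_cols, padj_cols, lam, cands = {}, {}, {}, {}, {}
    for var in config.variables:
        z, p_raw, _ = lfmm_scan(geno, sub[var].to_numpy(), factors)
        lam_v, p_adj, reject = calibrate_and_call(z, config.fdr_q)
        z_cols[var] = z
        praw_cols[var] = p_raw
        padj_cols[var] = p_adj
        lam[var] = lam_v
        cands[var] = set(geno.locus_ids[reject])
    idx = pd.Index(geno.locus_ids, name="locus_id")
    return GeaResult(
        locus_ids=geno.locus_ids,
        variables=list(config.variables),
        z=pd.DataFrame(z_cols, index=idx),
        p_raw=pd.DataFrame(praw_cols, index=idx),
        p_adjusted=pd.DataFrame(padj_cols, index=idx),
        lam=lam,
        candidates=cands,
        k_latent=config.k_latent,
    )


def cross_year_overlap(candidates_a: dict, candidates_b: dict):
    """Candidate overlap between two years.

    Takes the per-variable candidate dicts of each year; returns
    ``(shared, per_variable)`` where ``shared`` is the intersection of the
    per-year unions and ``per_variable`` maps each common variable to its
    own intersection.
    """
    union_a = set().union(*candidates_a.values()) if candidates_a else set()
    union_b = set().union(*candidates_b.values()) if candidates_b else set()
    shared = union_a & union_b
    per_variable = {
        v: candidates_a[v] & candidates_b[v]
        for v in set(candidates_a) & set(candidates_b)
    }
    return shared, per_variable
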