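"""Pairwise FST (Nei-family estimator), label-permutation significance,
genotype PCA, and the balanced-subsampling FST/PCA contrast.

The estimator follows the Nei (1987) / Nei & Chesser corrections: with
``n_i`` genotyped individuals, alt-allele frequency ``p_i`` and observed
heterozygosity ``Ho_i`` per group at a locus, and harmonic-mean sample
size ``n~``,

    Hs = n~/(n~-1) * (mean_i 2 p_i (1-p_i) - Ho / (2 n~))
    Ht = 2 pbar (1-pbar) + Hs/(n~ k) - Ho/(2 n~ k)
    Dst = Ht - Hs

and pairwise FST is the ratio of averages ``sum(Dst)/sum(Ht)`` over loci
polymorphic in the pooled pair. Negative estimates are reported as
computed; the table writer floors them at zero for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

_CHI_EPS = 1e-300


# ----------------------------------------------------------------------
# estimator core
# ----------------------------------------------------------------------

def _count_arrays(geno: GenotypeMatrix):
    """Per-individual per-locus called/alt/het indicator arrays (float32)."""
    g = geno.genotypes
    called = (g != MISSING).astype(np.float32)
    alt = np.where(g == MISSING, 0, g).astype(np.float32)
    het = (g == 1).astype(np.float32)
    return called, alt, het


def fst_from_counts(n, alt, het):
    """Nei-family FST from per-group counts.

    ``n``, ``alt``, ``het`` have shape ``(..., k, L)``: genotyped
    individuals, alt-allele copies and heterozygote counts per group and
    locus. Returns ``(fst, per_locus)`` where ``fst`` has the leading
    batch shape and ``per_locus`` is a dict of the locus-level components
    (Hs, Ht, Dst, valid mask) with the same batch shape.
    """
    n = np.asarray(n, dtype=np.float64)
    alt = np.asarray(alt, dtype=np.float64)
    het = np.asarray(het, dtype=np.float64)
    k = n.shape[-2]
    valid = (n >= 2).all(axis=-2)
    n_safe = np.where(n > 0, n, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_safe)
        ho = het / n_safe
        n_harm = k / (1.0 / n_safe).sum(axis=-2)
        ho_bar = np.nanmean(ho, axis=-2)
        hs_raw = np.nanmean(2.0 * p * (1.0 - p), axis=-2)
        hs = n_harm / (n_harm - 1.0) * (hs_raw - ho_bar / (2.0 * n_harm))
        p_bar = np.nanmean(p, axis=-2)
        ht_raw = 2.0 * p_bar * (1.0 - p_bar)
        ht = ht_raw + hs / (n_harm * k) - ho_bar / (2.0 * n_harm * k)
        dst = ht - hs
        poly = (p_bar > 0.0) & (p_bar < 1.0)
    use = valid & poly & np.isfinite(dst) & np.isfinite(ht)
    dst_sum = np.where(use, dst, 0.0).sum(axis=-1)
    ht_sum = np.where(use, ht, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht_sum > 0, dst_sum / np.where(ht_sum > 0, ht_sum, 1.0), np.nan)
    per_locus = {"Hs": hs, "Ht": ht, "Dst": dst, "used": use}
    return fst, per_locus


def _group_counts(geno: GenotypeMatrix, group_rows):
    called, alt, het = _count_arrays(geno)
    n = np.stack([called[r].sum(axis=0) for r in group_rows])
    a = np.stack([alt[r].sum(axis=0) for r in group_rows])
    h = np.stack([het[r].sum(axis=0) for r in group_rows])
    return n, a, h


@dataclass
class FstResult:
    """Pairwise FST matrix with optional permutation p-values and
    per-locus audit components (keyed by group pair)."""

    groups: list
    fst: pd.DataFrame
    p_values: pd.DataFrame | None = None
    B: int | None = None
    per_locus_components: dict = field(default_factory=dict)

    def table(self, floor_negative: bool = True) -> pd.DataFrame:
        """Publication-style table: FST below the diagonal, permutation
        p above (negative estimates floored at 0 for display)."""
        g = self.groups
        out = pd.DataFrame("", index=g, columns=g, dtype=object)
        for i, gi in enumerate(g):
            for j, gj in enumerate(g):
                if i == j:
                    out.loc[gi, gj] = "*"
                elif i > j:
                    v = self.fst.loc[gi, gj]
                    if floor_negative and np.isfinite(v):
                        v = max(v, 0.0)
                    out.loc[gi, gj] = f"{v:.3f}"
                elif self.p_values is not None:
                    out.loc[gi, gj] = f"{self.p_values.loc[gi, gj]:.3f}"
        return out


def nei_pairwise_fst(
    geno: GenotypeMatrix, labels, keep_components: bool = False
) -> FstResult:
    """All pairwise FST values among the label groups."""
    labels = np.asarray(list(labels), dtype=object)
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows_of = {g: np.where(labels == g)[0] for g in groups}
    for g, rows in rows_of.items():
        if ((geno.genotypes[rows] != MISSING).sum(axis=0) >= 2).sum() == 0:
            raise ValueError(f"group '{g}' has <2 genotyped individuals at all loci")
    fst = pd.DataFrame(np.nan, index=groups, columns=groups)
    comps = {}
    for ga, gb in combinations(groups, 2):
        n, a, h = _group_counts(geno, [rows_of[ga], rows_of[gb]])
        val, pl = fst_from_counts(n, a, h)
        fst.loc[ga, gb] = fst.loc[gb, ga] = float(val)
        if keep_components:
            comps[(ga, gb)] = pd.DataFrame(
                {
                    "locus_id": geno.locus_ids,
                    "Hs": pl["Hs"],
                    "Ht": pl["Ht"],
                    "Dst": pl["Dst"],
                    "used": pl["used"],
                }
            )
    return FstResult(groups=groups, fst=fst, per_locus_components=comps)


def fst_permutation_test(
    geno: GenotypeMatrix, labels, B: int = 1000, seed: int = 0
) -> FstResult:
    """Pairwise FST with label-permutation p-values.

    For each pair the two groups are pooled, group-1 membership is
    re-drawn ``B`` times, and ``p = (1 + #{FST_perm >= FST_obs})/(B+1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    result = nei_pairwise_fst(geno, labels)
    labels = np.asarray(list(labels), dtype=object)
    groups = result.groups
    rng = np.random.default_rng(seed)
    pvals = pd.DataFrame(np.nan, index=groups, columns=groups)
    called, alt, het = _count_arrays(geno)
    for ga, gb in combinations(groups, 2):
        rows = np.where((labels == ga) | (labels == gb))[0]
        n1 = int((labels[rows] == ga).sum())
        pooled_called = called[rows]
        pooled_alt = alt[rows]
        pooled_het = het[rows]
        tot_n = pooled_called.sum(axis=0)
        tot_a = pooled_alt.sum(axis=0)
        tot_h = pooled_het.sum(axis=0)
        keys = rng.random((B, len(rows)))
        order = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        sel = np.zeros((B, len(rows)), dtype=np.float32)
        np.put_along_axis(sel, order, 1.0, axis=1)
        g1_n = sel @ pooled_called
        g1_a = sel @ pooled_alt
        g1_h = sel @ pooled_het
        n = np.stack([g1_n, tot_n[None, :] - g1_n], axis=1)  # B x 2 x L
        a = np.stack([g1_a, tot_a[None, :] - g1_a], axis=1)
        h = np.stack([g1_h, tot_h[None, :] - g1_h], axis=1)
        perm_fst, _ = fst_from_counts(n, a, h)
        obs = result.fst.loc[ga, gb]
        p = (1 + int(np.nansum(perm_fst >= obs))) / (B + 1)
        pvals.loc[ga, gb] = pvals.loc[gb, ga] = p
    result.p_values = pvals
    result.B = B
    return result


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray  # N x k
    loadings: np.ndarray  # L_kept x k
    eigenvalues: np.ndarray  # k
    dropped_loci: np.ndarray  # zero-variance locus ids
    kept_loci: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def pca_genotypes(geno: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of the centered, unit-variance-scaled genotype matrix.

    Requires a complete matrix (impute first); zero-variance loci are
    dropped and reported. Component signs are fixed by making the
    largest-magnitude loading coordinate positive.
    """
    if (geno.genotypes == MISSING).any():
        raise ValueError("matrix contains missing genotypes; impute first")
    x = geno.genotypes.astype(np.float64)
    sd = x.std(axis=0)
    keep = sd > 0
    dropped = geno.locus_ids[~keep]
    x = x[:, keep]
    if x.shape[1] < 2:
        raise ValueError("fewer than 2 variable loci")
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: dominant loading coordinate positive
    for c in range(k):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    eig = s**2 / max(x.shape[0] - 1, 1)
    return PcaResult(
        scores=u * s,
        loadings=vt.T,
        eigenvalues=eig,
        dropped_loci=dropped,
        kept_loci=geno.locus_ids[keep],
    )


# ----------------------------------------------------------------------
# balanced subsampling contrast
# ----------------------------------------------------------------------

@dataclass
class BalancedSubsampleSummary:
    """FST and PCA geometry across R balanced subsamples: per-draw pairwise
    FST values, PC1/PC2 eigenvalue shares, and group-centroid distances in
    the PC1-PC2 plane."""

    n_eq: int
    R: int
    fst_draws: pd.DataFrame  # R rows, one column per group pair
    pc_shares: pd.DataFrame  # R rows, columns PC1/PC2
    centroid_distances: pd.DataFrame  # R rows, one column per group pair

    def fst_cv(self) -> pd.Series:
        """Coefficient of variation of each pairwise FST across draws."""
        return self.fst_draws.std(axis=0) / self.fst_draws.mean(axis=0).abs()


def balanced_subsample_contrast(
    geno: GenotypeMatrix, labels, n_eq: int, R: int = 50, seed: int = 0
) -> BalancedSubsampleSummary:
    """Draw R balanced subsamples (``n_eq`` per group, without
    replacement) and record pairwise FST alongside PCA eigenstructure.

    On unbalanced mixture surveys the PCA representation swings with the
    subsample while relative FST values stay put; this summary makes that
    contrast measurable.
    """
    labels = np.asarray(list(labels), dtype=object)
    groups = sorted(pd.unique(labels))
    rows_of = {g: np.where(labels == g)[0] for g in groups}
    smallest = min(len(r) for r in rows_of.values())
    if n_eq > smallest:
        raise ValueError(f"n_eq={n_eq} exceeds smallest group size {smallest}")
    rng = np.random.default_rng(seed)
    pair_cols = [f"{a}:{b}" for a, b in combinations(groups, 2)]
    fst_rows, share_rows, cent_rows = [], [], []
    for _ in range(R):
        take = np.concatenate(
            [rng.choice(rows_of[g], size=n_eq, replace=False) for g in groups]
        )
        sub_labels = np.repeat(groups, n_eq)
        sub = geno.take_individuals(take)
        res = nei_pairwise_fst(sub, sub_labels)
        fst_rows.append(
            [res.fst.loc[a, b] for a, b in combinations(groups, 2)]
        )
        pca = pca_genotypes(sub)
        share_rows.append(pca.explained_variance_ratio[:2])
        cents = {
            g: pca.scores[sub_labels == g, :2].mean(axis=0) for g in groups
        }
        cent_rows.append(
            [float(np.linalg.norm(cents[a] - cents[b])) for a, b in combinations(groups, 2)]
        )
    return BalancedSubsampleSummary(
        n_eq=n_eq,
        R=R,
        fst_draws=pd.DataFrame(fst_rows, columns=pair_cols),
        pc_shares=pd.DataFrame(share_rows, columns=["PC1", "PC2"]),
        centroid_distances=pd.DataFrame(cent_rows, columns=pair_cols),
    )
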