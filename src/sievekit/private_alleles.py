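"""Year-private alleles per population and the subsampling null for
allele loss.

An allele is *private* to year A within a population if at least one
non-missing genotype in the (population, A) sample carries it while no
non-missing genotype in the (population, B) sample does. Because the
smaller year's sample loses rare alleles by chance alone, significance is
judged against a null built by repeatedly drawing the smaller sample size
without replacement from the pooled two-year sample and counting how many
alleles the draw fails to capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix


@dataclass
class PrivateAlleleResult:
    """Private-allele counts, sharing and permutation significance.

    ``per_population`` maps population label to a dict with sample sizes,
    the two private-allele sets (frozensets of ``(locus_id, allele)``)
    and, after testing, the p-value pair. Years are ordered so year A is
    the smaller calendar year.
    """

    years: tuple
    per_population: dict = field(default_factory=dict)
    shared_matrix: pd.DataFrame | None = None
    null_distributions: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    B: int | None = None
    seed: int | None = None
    notes: str = (
        "per-population p-values are reported without multiple-testing "
        "correction"
    )


def _allele_presence(geno: GenotypeMatrix, rows):
    """(ref_present, alt_present, any_called) boolean arrays per locus."""
    g = geno.genotypes[rows]
    called = g != MISSING
    ref = ((g == 0) | (g == 1)) & called
    alt = ((g == 1) | (g == 2)) & called
    return ref.any(axis=0), alt.any(axis=0), called.any(axis=0)


def count_private_alleles(
    geno: GenotypeMatrix, labels, years
) -> PrivateAlleleResult:
    """Count year-private alleles within each population.

    ``labels`` and ``years`` give each individual's population and survey
    year; exactly two distinct years are required. Loci with no called
    genotype in either year group of a population are excluded from that
    population's comparison.
    """
    labels = np.asarray(list(labels), dtype=object)
    years = np.asarray(list(years))
    year_pair = tuple(sorted(pd.unique(years)))
    if len(year_pair) != 2:
        raise ValueError(f"exactly two years required, got {year_pair}")
    ya, yb = year_pair
    result = PrivateAlleleResult(years=year_pair)
    for pop in sorted(pd.unique(labels)):
        rows_a = np.where((labels == pop) & (years == ya))[0]
        rows_b = np.where((labels == pop) & (years == yb))[0]
        if len(rows_a) == 0 or len(rows_b) == 0:
            import warnings

            warnings.warn(f"population '{pop}' absent in one year; skipped")
            continue
        ref_a, alt_a, any_a = _allele_presence(geno, rows_a)
        ref_b, alt_b, any_b = _allele_presence(geno, rows_b)
        valid = any_a & any_b
        priv_a, priv_b = set(), set()
        for j in np.where(valid)[0]:
            lid = geno.locus_ids[j]
            if ref_a[j] and not ref_b[j]:
                priv_a.add((lid, 0))
            if alt_a[j] and not alt_b[j]:
                priv_a.add((lid, 1))
            if ref_b[j] and not ref_a[j]:
                priv_b.add((lid, 0))
            if alt_b[j] and not alt_a[j]:
                priv_b.add((lid, 1))
        result.per_population[pop] = {
            "n_yearA": len(rows_a),
            "n_yearB": len(rows_b),
            "private_in_A": frozenset(priv_a),
            "private_in_B": frozenset(priv_b),
        }
    return result


def shared_private_alleles(result: PrivateAlleleResult) -> pd.DataFrame:
    """Pairwise counts of year-A private alleles shared between
    populations (alleles lost from both populations' year-B samples)."""
    pops = sorted(result.per_population)
    mat = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for x in pops:
        for y in pops:
            shared = (
                result.per_population[x]["private_in_A"]
                & result.per_population[y]["private_in_A"]
            )
            mat.loc[x, y] = len(shared)
    result.shared_matrix = mat
    return mat


def lost_allele_null(
    geno_combined: GenotypeMatrix, n_sub: int, B: int, seed: int
) -> np.ndarray:
    """Null distribution of lost-allele counts at sample size ``n_sub``.

    Each of ``B`` iterations draws ``n_sub`` individuals without
    replacement from the combined two-year sample and counts the alleles
    present in the combined sample but absent among the draw's non-missing
    genotypes.
    """
    n = geno_combined.n_individuals
    if n_sub <= 0:
        raise ValueError("n_sub must be positive")
    if n_sub > n:
        raise ValueError(f"n_sub={n_sub} exceeds combined sample size {n}")
    if B < 1:
        raise ValueError("B must be >= 1")
    g = geno_combined.genotypes
    called = g != MISSING
    ref = (((g == 0) | (g == 1)) & called).astype(np.float32)
    alt = (((g == 1) | (g == 2)) & called).astype(np.float32)
    carriers = np.hstack([ref, alt])  # N x 2L carrier indicators
    present = carriers.any(axis=0)
    carriers = carriers[:, present]
    total_present = carriers.shape[1]
    if n_sub == n:
        return np.zeros(B, dtype=np.int64)

    rng = np.random.default_rng(seed)
    # B subsample indicator rows via partial argsort of uniform keys
    keys = rng.random((B, n))
    order = np.argpartition(keys, n_sub - 1, axis=1)[:, :n_sub]
    sub = np.zeros((B, n), dtype=np.float32)
    np.put_along_axis(sub, order, 1.0, axis=1)
    captured = (sub @ carriers) > 0.5
    return (total_present - captured.sum(axis=1)).astype(np.int64)


def private_allele_test(observed: int, null: np.ndarray):
    """Add-one permutation p-values for an observed lost-allele count.

    Returns ``(p_upper, p_lower)``: the probability of the null losing at
    least / at most as many alleles as observed.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    b = null.size
    p_upper = (1 + int((null >= observed).sum())) / (b + 1)
    p_lower = (1 + int((null <= observed).sum())) / (b + 1)
    return p_upper, p_lower


def run_private_allele_analysis(
    geno: GenotypeMatrix, labels, years, B: int = 1000, seed: int = 0
) -> PrivateAlleleResult:
    """Counts, sharing matrix and both directional tests per population.

    For each population the year-A private count (alleles undetected in
    year B) is referred to the null at the year-B sample size
    (``p_more_in_A``, upper tail), and the year-B private count to the
    null at the year-A sample size (``p_fewer_in_B``, lower tail).
    """
    labels = np.asarray(list(labels), dtype=object)
    years_arr = np.asarray(list(years))
    result = count_private_alleles(geno, labels, years_arr)
    shared_private_alleles(result)
    result.B = B
    result.seed = seed
    ya, yb = result.years
    for k, pop in enumerate(sorted(result.per_population)):
        rows = np.where(labels == pop)[0]
        combined = geno.take_individuals(rows)
        rec = result.per_population[pop]
        null_b = lost_allele_null(combined, rec["n_yearB"], B, seed=seed * 7919 + 2 * k)
        null_a = lost_allele_null(combined, rec["n_yearA"], B, seed=seed * 7919 + 2 * k + 1)
        result.null_distributions[(pop, rec["n_yearB"])] = null_b
        result.null_distributions[(pop, rec["n_yearA"])] = null_a
        p_more_in_a, _ = private_allele_test(len(rec["private_in_A"]), null_b)
        _, p_fewer_in_b = private_allele_test(len(rec["private_in_B"]), null_a)
        result.p_values[pop] = (p_more_in_a, p_fewer_in_b)
    return result


def private_allele_table(result: PrivateAlleleResult) -> pd.DataFrame:
    """Per-population summary (sample sizes, private counts, p-values)."""
    ya, yb = result.years
    rows = []
    for pop in sorted(result.per_population):
        rec = result.per_population[pop]
        p = result.p_values.get(pop, (np.nan, np.nan))
        rows.append(
            {
                "population": pop,
                f"n_{ya}": rec["n_yearA"],
                f"n_{yb}": rec["n_yearB"],
                f"private_{ya}": len(rec["private_in_A"]),
                f"private_{yb}": len(rec["private_in_B"]),
                f"p_more_private_{ya}": p[0],
                f"p_fewer_private_{yb}": p[1],
            }
        )
    return pd.DataFrame(rows)
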