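"""Genotype quality control: staged locus/individual filters, replicate
concordance, and mode imputation of residual missing calls.

The filter cascade mirrors RADseq practice for this kind of panel and is
applied in a fixed, logged order so every removal is auditable:

1. drop loci genotyped in fewer than ``pop_genotyped_min`` of individuals
   in *every* population (a locus survives if any population covers it);
2. drop loci missing in at least ``locus_missing_max`` of individuals;
3. drop individuals missing more than ``indiv_missing_max`` of the loci
   retained so far;
4. recompute the global minor allele frequency on the survivors and drop
   loci below ``maf_min``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCConfig
from .datatypes import (
    MISSING,
    DegenerateDataError,
    GenotypeMatrix,
)


@dataclass
class FilterResult:
    """Outcome of :func:`apply_filters` with full bookkeeping."""

    filtered: GenotypeMatrix
    removed_loci: pd.DataFrame  # columns: locus_id, reason
    removed_individuals: pd.DataFrame  # columns: individual_id, reason
    log: pd.DataFrame  # one row per rule: rule, n_loci/indiv before+after


def apply_filters(
    geno: GenotypeMatrix, labels, qc: QCConfig | None = None
) -> FilterResult:
    """Apply the four-stage filter cascade.

    ``labels`` assigns every individual a population (a single
    pseudo-population is fine); loci are judged within populations only
    at stage 1.
    """
    qc = qc or QCConfig()
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != geno.n_individuals:
        raise ValueError("labels must cover every individual")

    gm = geno
    removed_loci: list[tuple[str, str]] = []
    removed_indiv: list[tuple[str, str]] = []
    log_rows = []

    def _log(rule, before, after):
        log_rows.append(
            {
                "rule": rule,
                "n_loci_before": before[1],
                "n_loci_after": after[1],
                "n_individuals_before": before[0],
                "n_individuals_after": after[0],
            }
        )

    # 1: population-level genotyping rate
    before = gm.genotypes.shape
    groups = pd.unique(labels)
    ok_any = np.zeros(gm.n_loci, dtype=bool)
    for grp in groups:
        rows = np.where(labels == grp)[0]
        rate = gm.called[rows].mean(axis=0)
        ok_any |= rate >= qc.pop_genotyped_min
    drop = np.where(~ok_any)[0]
    removed_loci += [(gm.locus_ids[j], "pop_genotyped_min") for j in drop]
    gm = gm.take_loci(np.where(ok_any)[0])
    _log("pop_genotyped_min", before, gm.genotypes.shape)

    # 2: overall locus missingness
    before = gm.genotypes.shape
    miss = gm.missing_rate_per_locus()
    keep = miss < qc.locus_missing_max
    removed_loci += [
        (gm.locus_ids[j], "locus_missing_max") for j in np.where(~keep)[0]
    ]
    gm = gm.take_loci(np.where(keep)[0])
    _log("locus_missing_max", before, gm.genotypes.shape)
    if gm.n_loci == 0:
        raise DegenerateDataError("all loci removed by missingness filters")

    # 3: individual missingness over retained loci
    before = gm.genotypes.shape
    miss_i = gm.missing_rate_per_individual()
    keep_i = miss_i <= qc.indiv_missing_max
    removed_indiv += [
        (gm.individual_ids[i], "indiv_missing_max") for i in np.where(~keep_i)[0]
    ]
    labels = labels[keep_i]
    gm = gm.take_individuals(np.where(keep_i)[0])
    _log("indiv_missing_max", before, gm.genotypes.shape)
    if gm.n_individuals == 0:
        raise DegenerateDataError("all individuals removed by missingness filter")

    # 4: global MAF on the survivors (non-missing genotypes only)
    before = gm.genotypes.shape
    maf = gm.minor_allele_frequency()
    keep = np.nan_to_num(maf, nan=-1.0) >= qc.maf_min
    removed_loci += [(gm.locus_ids[j], "maf_min") for j in np.where(~keep)[0]]
    gm = gm.take_loci(np.where(keep)[0])
    _log("maf_min", before, gm.genotypes.shape)
    if gm.n_loci == 0:
        raise DegenerateDataError("all loci removed by the MAF filter")

    return FilterResult(
        filtered=gm,
        removed_loci=pd.DataFrame(removed_loci, columns=["locus_id", "reason"]),
        removed_individuals=pd.DataFrame(
            removed_indiv, columns=["individual_id", "reason"]
        ),
        log=pd.DataFrame(log_rows),
    )


def replicate_concordance(geno: GenotypeMatrix, meta: pd.DataFrame):
    """Concordance per replicate pair and which member to keep.

    Concordance is the fraction of loci genotyped in both members that
    agree. The member with fewer missing calls is retained; ties break
    to the lexicographically smaller id. Returns ``(table, retained_ids)``
    where ``retained_ids`` lists the individual to keep from each pair.
    """
    row_of = {iid: i for i, iid in enumerate(geno.individual_ids)}
    groups = meta.dropna(subset=["replicate_group"]).groupby("replicate_group")
    rows, retained = [], []
    for grp, sub in groups:
        members = sorted(sub["individual_id"])
        if len(members) < 2:
            warnings.warn(f"replicate group '{grp}' has a single member; skipped")
            continue
        a, b = members[0], members[1]
        ga, gb = geno.genotypes[row_of[a]], geno.genotypes[row_of[b]]
        both = (ga != MISSING) & (gb != MISSING)
        conc = float((ga[both] == gb[both]).mean()) if both.any() else np.nan
        miss_a, miss_b = int((ga == MISSING).sum()), int((gb == MISSING).sum())
        keep = a if miss_a < miss_b else b if miss_b < miss_a else min(a, b)
        rows.append(
            {
                "replicate_group": grp,
                "member_a": a,
                "member_b": b,
                "n_both_genotyped": int(both.sum()),
                "concordance": conc,
                "retained": keep,
            }
        )
        retained.append(keep)
    return pd.DataFrame(rows), retained


def drop_replicate_duplicates(geno: GenotypeMatrix, meta: pd.DataFrame):
    """Keep one member per replicate pair (the better-genotyped one)."""
    table, retained = replicate_concordance(geno, meta)
    drop = set()
    for _, row in table.iterrows():
        loser = row["member_b"] if row["retained"] == row["member_a"] else row["member_a"]
        drop.add(loser)
    keep_mask = ~np.isin(geno.individual_ids.astype(str), sorted(drop))
    gm = geno.take_individuals(np.where(keep_mask)[0])
    meta = meta[~meta["individual_id"].isin(drop)].reset_index(drop=True)
    return gm, meta, table


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with the locus's modal genotype.

    Residual missingness after filtering is a few percent, where the
    downstream matrix methods (PCA, latent factors, per-locus regression)
    are insensitive to the imputation rule; the per-locus mode is
    deterministic, with ties broken toward the lower genotype value.
    """
    g = geno.genotypes
    counts = np.stack([(g == v).sum(axis=0) for v in (0, 1, 2)])  # 3 x L
    if (counts.sum(axis=0) == 0).any():
        bad = geno.locus_ids[counts.sum(axis=0) == 0]
        raise DegenerateDataError(
            f"loci entirely missing ({list(bad)[:5]}...); run apply_filters first"
        )
    mode = counts.argmax(axis=0).astype(np.int8)  # argmax takes the lowest on ties
    out = np.where(g == MISSING, mode[None, :], g).astype(np.int8)
    return GenotypeMatrix(out, geno.locus_ids, geno.individual_ids)
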