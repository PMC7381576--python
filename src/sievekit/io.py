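"""Readers and writers for the formats the pipeline exchanges.

Genepop (2-digit written; 2- or 3-digit accepted on read) is parsed here
directly — the format is line-oriented and tiny. VCF v4.2 is read through
pysam; the writer emits a minimal GT-only dialect that pysam round-trips.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    METADATA_COLUMNS,
    GenotypeMatrix,
    ParseError,
    empty_metadata,
)

_GENEPOP_CODE = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}


def _polarize_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip loci so the alternate allele is the globally less frequent one."""
    p = gm.alt_frequency()
    flip = p > 0.5
    g = gm.genotypes.copy()
    cols = np.where(flip)[0]
    sub = g[:, cols]
    g[:, cols] = np.where(sub == MISSING, MISSING, 2 - sub)
    return GenotypeMatrix(g, gm.locus_ids, gm.individual_ids)


# ----------------------------------------------------------------------
# genepop
# ----------------------------------------------------------------------

def write_genepop(gm: GenotypeMatrix, path, pop_of=None, title="sievekit export"):
    """Write a 2-digit genepop file.

    ``pop_of`` maps individual id -> POP block label (e.g. station); all
    individuals land in one block when omitted. Blocks are emitted in
    sorted label order, individuals in input order within a block.
    """
    ids = list(gm.individual_ids)
    if pop_of is None:
        blocks = {"all": ids}
    else:
        blocks = {}
        for iid in ids:
            blocks.setdefault(str(pop_of[iid]), []).append(iid)
    row_of = {iid: i for i, iid in enumerate(ids)}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in gm.locus_ids:
            fh.write(str(locus) + "\n")
        for label in sorted(blocks):
            fh.write("POP\n")
            for iid in blocks[label]:
                row = gm.genotypes[row_of[iid]]
                codes = " ".join(_GENEPOP_CODE[int(g)] for g in row)
                fh.write(f"{iid} ,  {codes}\n")


def read_genepop(path, polarize="preserve"):
    """Read a genepop file into a :class:`GenotypeMatrix`.

    Allele codes of 2 or 3 digits are accepted; each locus must carry at
    most two distinct non-zero codes. With ``polarize="preserve"`` the
    higher allele code is the alternate allele; ``"minor"`` re-polarizes
    to the globally less frequent allele.

    Returns ``(GenotypeMatrix, metadata)`` where metadata is a partial
    frame carrying individual ids and the POP block label as
    ``station_id``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_ids.extend(chunk)
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no POP keyword found")

    ids, rows, blocks = [], [], []
    block = -1
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            block += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}:{lineno + 1}: expected 'id , genotypes'")
        name, _, geno_part = line.partition(",")
        tokens = geno_part.split()
        if len(tokens) != len(locus_ids):
            raise ParseError(
                f"{path}:{lineno + 1}: {len(tokens)} genotypes for "
                f"{len(locus_ids)} loci"
            )
        row = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(f"{path}:{lineno + 1}: bad genotype code '{tok}'")
            half = len(tok) // 2
            row.append((int(tok[:half]), int(tok[half:])))
        ids.append(name.strip())
        rows.append(row)
        blocks.append(block)
    if not ids:
        raise ParseError(f"{path}: no individuals")

    n, l = len(ids), len(locus_ids)
    geno = np.full((n, l), MISSING, dtype=np.int8)
    for j in range(l):
        codes = sorted(
            {a for r in rows for a in r[j] if a != 0}
        )
        if len(codes) > 2:
            raise ParseError(f"{path}: locus {locus_ids[j]} has >2 alleles")
        if len(codes) == 2:
            alt = codes[-1]
        elif codes:
            # one observed code: code 1 is the reference by convention
            alt = None if codes[0] == 1 else codes[0]
        else:
            alt = None
        for i2, r in enumerate(rows):
            a, b = r[j]
            if a == 0 or b == 0:
                continue
            g = (1 if alt is not None and a == alt else 0) + (
                1 if alt is not None and b == alt else 0
            )
            geno[i2, j] = g
    gm = GenotypeMatrix(geno, np.array(locus_ids, dtype=object), np.array(ids, dtype=object))
    if polarize == "minor":
        gm = _polarize_minor(gm)
    meta = empty_metadata(ids)
    meta["station_id"] = [f"block{b}" for b in blocks]
    return gm, meta


# ----------------------------------------------------------------------
# VCF (minimal GT-only v4.2 dialect)
# ----------------------------------------------------------------------

_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path):
    """Write a minimal uncompressed VCF v4.2 with GT only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in gm.individual_ids)
            + "\n"
        )
        for j, locus in enumerate(gm.locus_ids):
            gts = "\t".join(_VCF_GT[int(g)] for g in gm.genotypes[:, j])
            fh.write(f"chr1\t{j + 1}\t{locus}\tA\tC\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path, polarize="preserve"):
    """Read a VCF into a :class:`GenotypeMatrix` (GT field only).

    Non-biallelic records are skipped; a single warning reports how many.
    Alt-allele copies are counted against the record's ALT allele
    (``polarize="minor"`` re-polarizes globally afterwards).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        locus_ids, rows = [], []
        n_skipped = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            row = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    continue
                row[i] = sum(1 for a in alleles if a == 1)
            locus_ids.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}")
            rows.append(row)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic VCF record(s)")
    if not rows:
        raise ParseError(f"{path}: no biallelic records")
    geno = np.stack(rows, axis=1)
    gm = GenotypeMatrix(geno, np.array(locus_ids, dtype=object), np.array(samples, dtype=object))
    if polarize == "minor":
        gm = _polarize_minor(gm)
    return gm, empty_metadata(samples)


def load_genotypes(path, format=None, polarize="preserve"):
    """Load genotypes from genepop or VCF (dispatch on ``format`` or
    file suffix). Returns ``(GenotypeMatrix, partial metadata)``."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "vcf" if suffix == ".vcf" else "genepop"
    if format == "genepop":
        return read_genepop(path, polarize=polarize)
    if format == "vcf":
        return read_vcf(path, polarize=polarize)
    raise ValueError(f"unknown format '{format}'")


# ----------------------------------------------------------------------
# metadata + truth
# ----------------------------------------------------------------------

def write_metadata(meta: pd.DataFrame, path):
    meta[METADATA_COLUMNS].to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(
        path,
        dtype={
            "individual_id": str,
            "station_id": str,
            "population_label": str,
            "replicate_group": str,
        },
    )
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    return meta[METADATA_COLUMNS]


def write_truth(truth: dict, path):
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
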