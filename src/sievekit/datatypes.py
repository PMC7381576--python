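"""Core containers: genotype matrices and per-individual sample metadata.

Genotypes are stored as alternate-allele copy counts (0/1/2) in a dense
``int8`` array with ``MISSING = -1`` as the missing sentinel, the natural
desk-scale representation for biallelic SNP panels of a few thousand loci.
Sample metadata travels as a :class:`pandas.DataFrame` with a fixed column
set (year, station, environment, phenotypes, optional population label and
replicate group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call; distinct from all valid copy counts.
MISSING: int = -1

#: Fixed metadata column order (one record per genotyped individual).
METADATA_COLUMNS = [
    "individual_id",
    "year",
    "station_id",
    "latitude",
    "sample_date",
    "temperature",
    "chlorophyll",
    "length",
    "weight",
    "lipid_pct",
    "population_label",
    "replicate_group",
]


class SievekitError(Exception):
    """Base class for all package errors."""


class ConfigError(SievekitError):
    """Invalid configuration (bad field values, unknown keys, ...)."""


class DegenerateDataError(SievekitError):
    """An operation produced or received data it cannot meaningfully use
    (e.g. no survivors after selection, all loci filtered out)."""


class ParseError(SievekitError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of alternate-allele copy counts.

    Parameters
    ----------
    genotypes
        ``(N, L)`` integer array with entries in ``{0, 1, 2, MISSING}``.
    locus_ids
        ``L`` locus labels.
    individual_ids
        ``N`` individual labels.
    """

    genotypes: np.ndarray
    locus_ids: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n, l = self.genotypes.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(self.locus_ids) != l:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {l} columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be in {0, 1, 2, MISSING}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.genotypes != MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.genotypes.copy(), self.locus_ids.copy(), self.individual_ids.copy()
        )

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.genotypes[index], self.locus_ids, self.individual_ids[index]
        )

    def take_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.genotypes[:, index], self.locus_ids[index], self.individual_ids
        )

    # -- summaries -------------------------------------------------------
    def allele_counts(self, rows=None):
        """Alt-allele copy counts and called-genotype counts per locus.

        Returns ``(alt_copies, n_called)`` arrays of length ``L`` computed
        over ``rows`` (default: all individuals), ignoring missing calls.
        """
        g = self.genotypes if rows is None else self.genotypes[np.asarray(rows)]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), called.sum(axis=0).astype(np.int64)

    def alt_frequency(self, rows=None) -> np.ndarray:
        """Alt-allele frequency per locus (NaN where no calls)."""
        alt, n = self.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def minor_allele_frequency(self, rows=None) -> np.ndarray:
        p = self.alt_frequency(rows)
        return np.minimum(p, 1.0 - p)

    def missing_rate_per_locus(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=0)

    def missing_rate_per_individual(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.locus_ids, other.locus_ids)
            and np.array_equal(self.individual_ids, other.individual_ids)
        )


@dataclass
class AlleleFrequencySet:
    """Per-population alternate-allele frequencies (K x L) plus the
    ancestral frequencies and the drift parameter that generated them."""

    freqs: np.ndarray
    ancestral: np.ndarray | None = None
    inbreeding_coefficient: float | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2:
            raise ValueError("freqs must be K x L")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_populations(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]


def empty_metadata(individual_ids) -> pd.DataFrame:
    """A metadata frame with one row per individual and NaN covariates."""
    meta = pd.DataFrame({"individual_id": list(individual_ids)})
    for col in METADATA_COLUMNS[1:]:
        meta[col] = np.nan
    return meta[METADATA_COLUMNS]
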