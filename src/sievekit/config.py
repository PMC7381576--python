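"""Configuration objects for the simulator, QC, GEA scan and pipeline.

All stochastic stages derive independent child streams from a single master
seed via :func:`child_rng`, so one integer fully determines a run.
"""

from __future__ import annotations

import difflib
import zlib
from dataclasses import dataclass, field, fields

import numpy as np

from .datatypes import ConfigError


def child_rng(seed: int, *tags: str) -> np.random.Generator:
    """Independent child generator for stage ``tags`` under ``seed``.

    Tags are hashed with CRC32 into the seed-sequence entropy, giving
    stable, order-sensitive, well-separated streams per named stage.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(t).encode("utf8")) for t in tags
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SieveLocus:
    """One viability-selected locus: which allele is disfavored (0 = ref,
    1 = alt) and the per-copy selection coefficient s in [0, 1]."""

    disfavored_allele: int
    s: float


@dataclass
class AllometryParams:
    """Year-specific log(weight) ~ log(length) line: intercept ``a``
    (log-gram at 1 mm), slope ``b``, and residual standard deviation."""

    a: float
    b: float
    sd: float


def _default_sieve_loci(n_loci: int) -> dict[int, dict[int, SieveLocus]]:
    """Default selection regime: an average year (2014, no sieve) and an
    anomalous year (2015) with s = 0.5 against the alt allele at 2% of loci."""
    n_sieve = max(1, round(0.02 * n_loci))
    return {
        2014: {},
        2015: {i: SieveLocus(disfavored_allele=1, s=0.5) for i in range(n_sieve)},
    }


def _default_gradient_loci(n_loci: int) -> dict[int, float]:
    """Five latitude-cline loci at the top of the index range, log-odds
    tilt 0.6 per alt copy per SD latitude (~0.3 genotype shift per SD)."""
    n_grad = min(5, n_loci)
    return {n_loci - 1 - i: 0.6 for i in range(n_grad)}


@dataclass
class SieveConfig:
    """Full parameterization of the selective-sieve forward simulator.

    Defaults emulate the study system: K = 4 spawning populations at mean
    pairwise FST ~ 0.02, two survey years with very unequal sample sizes
    (321 vs 77), viability selection (s = 0.5 on 2% of loci) in the
    anomalous second year only, latitude-cline loci acting on sampling
    inclusion, a warmer / low-chlorophyll second year, and year-dependent
    length-weight allometry (lower intercept, steeper slope in year 2).
    """

    n_populations: int = 4
    n_loci: int = 5000
    target_fst: float = 0.02
    age_range_reproductive: tuple[int, int] = (8, 100)
    cohort_years: tuple[int, ...] = (2014, 2015)
    n_larvae_per_pop_year: int = 500
    sieve_loci: dict[int, dict[int, SieveLocus]] | None = None
    gradient_loci: dict[int, float] | None = None
    n_stations: int = 10
    station_mixture_concentration: float = 1.0
    survey_sample_sizes: dict[int, int] | None = None
    allometry: dict[int, AllometryParams] | None = None
    missing_rate: float = 0.05
    n_replicate_pairs: int = 4
    selection_mode: str = "relative"  # "relative" (soft) or "absolute"
    sieve_survivor_fraction: float = 0.5
    # within-year heterogeneity of the sieve: carriers of disfavored alleles
    # are additionally under-sampled at warm stations (tilt scales with s)
    sieve_temperature_tilt: float = 1.0
    # sieve loci whose disfavored allele also depresses lipid content
    n_condition_coupled_loci: int = 3
    lipid_coupling: float = 4.0  # % lipid lost per disfavored allele copy
    explicit_age_structure: bool = False
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.sieve_loci is None:
            self.sieve_loci = _default_sieve_loci(self.n_loci)
        if self.gradient_loci is None:
            self.gradient_loci = _default_gradient_loci(self.n_loci)
        if self.survey_sample_sizes is None:
            self.survey_sample_sizes = {2014: 321, 2015: 77}
        if self.allometry is None:
            # crossing point 60 mm: larger fish unaffected, smaller fish
            # lighter in the anomalous year
            self.allometry = {
                2014: AllometryParams(a=-11.36, b=3.0, sd=0.10),
                2015: AllometryParams(a=-12.38, b=3.25, sd=0.10),
            }
        self.validate()

    def validate(self) -> None:
        errs = []
        if self.n_populations < 2:
            errs.append("n_populations must be >= 2")
        if self.n_loci < 1:
            errs.append("n_loci must be >= 1")
        if not (0.0 < self.target_fst < 1.0):
            errs.append("target_fst must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            errs.append("missing_rate must lie in [0, 1)")
        if self.selection_mode not in ("relative", "absolute"):
            errs.append("selection_mode must be 'relative' or 'absolute'")
        if not (0.0 < self.sieve_survivor_fraction <= 1.0):
            errs.append("sieve_survivor_fraction must lie in (0, 1]")
        if self.sieve_temperature_tilt < 0:
            errs.append("sieve_temperature_tilt must be >= 0")
        if self.n_condition_coupled_loci < 0:
            errs.append("n_condition_coupled_loci must be >= 0")
        if self.lipid_coupling < 0:
            errs.append("lipid_coupling must be >= 0")
        if self.n_replicate_pairs < 0:
            errs.append("n_replicate_pairs must be >= 0")
        if self.n_stations < 1:
            errs.append("n_stations must be >= 1")
        if self.station_mixture_concentration <= 0:
            errs.append("station_mixture_concentration must be > 0")
        lo, hi = self.age_range_reproductive
        if not (0 < lo <= hi):
            errs.append("age_range_reproductive must be 0 < min <= max")
        sieve_idx: set[int] = set()
        for year, loci in self.sieve_loci.items():
            for idx, sl in loci.items():
                sieve_idx.add(idx)
                if not (0 <= idx < self.n_loci):
                    errs.append(f"sieve locus {idx} out of range for year {year}")
                if not (0.0 <= sl.s <= 1.0):
                    errs.append(f"selection coefficient {sl.s} not in [0, 1]")
                if sl.disfavored_allele not in (0, 1):
                    errs.append("disfavored_allele must be 0 or 1")
        grad_idx = set(self.gradient_loci)
        for idx in grad_idx:
            if not (0 <= idx < self.n_loci):
                errs.append(f"gradient locus {idx} out of range")
        if sieve_idx & grad_idx:
            errs.append("sieve and gradient locus sets must be disjoint")
        for year, n in self.survey_sample_sizes.items():
            if n < 1:
                errs.append(f"survey sample size for {year} must be >= 1")
        if errs:
            raise ConfigError("; ".join(errs))


@dataclass
class QCConfig:
    """Two-stage SNP/individual filtering thresholds.

    Defaults follow the study protocol: loci genotyped in < 10% of
    individuals in every population are dropped, then loci missing in
    >= 15% of individuals, then individuals missing > 20% of retained
    loci, then loci with global minor allele frequency < 0.10.
    """

    locus_missing_max: float = 0.15
    indiv_missing_max: float = 0.20
    maf_min: float = 0.10
    pop_genotyped_min: float = 0.10

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{f.name}={v} must lie in [0, 1]")


GEA_VARIABLES = (
    "latitude",
    "sample_date",
    "temperature",
    "chlorophyll",
    "lipid_pct",
    "condition_index",
)


@dataclass
class GeaConfig:
    """Genotype-environment association scan settings: number of latent
    factors (default 4, matching the study's LFMM runs) and the FDR level
    for candidate calling."""

    k_latent: int = 4
    variables: tuple[str, ...] = GEA_VARIABLES
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        errs = []
        if self.k_latent < 0:
            errs.append("k_latent must be >= 0")
        if not self.variables:
            errs.append("variables must be non-empty")
        unknown = set(self.variables) - set(GEA_VARIABLES)
        if unknown:
            errs.append(f"unknown variables: {sorted(unknown)}")
        if not (0.0 < self.fdr_q < 1.0):
            errs.append("fdr_q must lie in (0, 1)")
        if errs:
            raise ConfigError("; ".join(errs))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see :mod:`sievekit.pipeline`)."""

    out_dir: str = "sievekit_run"
    input_dir: str | None = None  # read an existing dataset instead of simulating
    seed: int = 1234
    B_private: int = 1000
    B_fst: int = 1000
    label_source: str = "truth"  # "truth" (simulated) or "metadata"
    simulate: SieveConfig = field(default_factory=SieveConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    gea: GeaConfig = field(default_factory=GeaConfig)

    def __post_init__(self) -> None:
        errs = []
        if self.B_private < 1:
            errs.append("B_private must be >= 1")
        if self.B_fst < 1:
            errs.append("B_fst must be >= 1")
        if self.label_source not in ("truth", "metadata"):
            errs.append("label_source must be 'truth' or 'metadata'")
        if not isinstance(self.seed, (int, np.integer)):
            errs.append("seed must be an integer")
        if errs:
            raise ConfigError("; ".join(errs))


# -- structured-text (YAML) config loading ------------------------------

_SECTION_TYPES = {"simulate": SieveConfig, "qc": QCConfig, "gea": GeaConfig}


def _coerce_section(cls, data: dict, errors: list, prefix: str):
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            msg = f"unknown key '{prefix}{key}'"
            if hint:
                msg += f" (did you mean '{hint[0]}'?)"
            errors.append(msg)
            continue
        kwargs[key] = val
    if cls is SieveConfig:
        if "sieve_loci" in kwargs and kwargs["sieve_loci"] is not None:
            kwargs["sieve_loci"] = {
                int(y): {int(i): SieveLocus(int(v[0]), float(v[1])) for i, v in d.items()}
                for y, d in kwargs["sieve_loci"].items()
            }
        if "gradient_loci" in kwargs and kwargs["gradient_loci"] is not None:
            kwargs["gradient_loci"] = {
                int(i): float(v) for i, v in kwargs["gradient_loci"].items()
            }
        if "survey_sample_sizes" in kwargs and kwargs["survey_sample_sizes"] is not None:
            kwargs["survey_sample_sizes"] = {
                int(y): int(n) for y, n in kwargs["survey_sample_sizes"].items()
            }
        if "allometry" in kwargs and kwargs["allometry"] is not None:
            kwargs["allometry"] = {
                int(y): AllometryParams(*map(float, v)) for y, v in kwargs["allometry"].items()
            }
        for tup in ("age_range_reproductive", "cohort_years"):
            if tup in kwargs and kwargs[tup] is not None:
                kwargs[tup] = tuple(kwargs[tup])
    if cls is GeaConfig and "variables" in kwargs:
        kwargs["variables"] = tuple(kwargs["variables"])
    try:
        return cls(**kwargs)
    except (ConfigError, TypeError, ValueError) as exc:
        errors.append(f"{prefix.rstrip('.') or 'top level'}: {exc}")
        return None


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected with a closest-match suggestion; all errors
    are aggregated into one :class:`ConfigError`. Missing fields fall back
    to documented defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")

    errors: list[str] = []
    top_known = {f.name for f in fields(RunConfig)}
    kwargs = {}
    for key, val in data.items():
        if key not in top_known:
            hint = difflib.get_close_matches(key, top_known, n=1)
            msg = f"unknown key '{key}'"
            if hint:
                msg += f" (did you mean '{hint[0]}'?)"
            errors.append(msg)
            continue
        if key in _SECTION_TYPES:
            if not isinstance(val, dict):
                errors.append(f"section '{key}' must be a mapping")
                continue
            section = _coerce_section(_SECTION_TYPES[key], val, errors, f"{key}.")
            if section is not None:
                kwargs[key] = section
        else:
            kwargs[key] = val
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    try:
        return RunConfig(**kwargs)
    except (ConfigError, TypeError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
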