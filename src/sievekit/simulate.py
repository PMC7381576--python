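"""Forward simulator for cohort-specific ("selective sieve") selection.

The generative model: K spawning populations diverge from a common
ancestor under a Balding-Nichols drift model calibrated to a target
pairwise FST. Each survey year, every population releases a larval cohort
by Hardy-Weinberg sampling from its allele-frequency vector (the
age-structured parental pool of long-lived adults is represented by that
stable vector; an explicit per-age mode is available for portfolio-effect
experiments). Larvae then pass through the year's viability sieve —
independent survival with probability prod_l (1-s_l)^(copies of the
disfavored allele) — and the survivors are sampled at pelagic stations
whose population mixtures are Dirichlet draws. Gradient loci tilt
inclusion probability along the latitude/date axis of the survey, planting
a genotype-environment cline. Phenotypes follow year-specific length-
weight allometry, and missingness plus technical replicate pairs are
injected last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import SieveConfig, child_rng
from .datatypes import (
    MISSING,
    AlleleFrequencySet,
    DegenerateDataError,
    GenotypeMatrix,
)

_POP_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def population_letter(pop: int) -> str:
    return _POP_LETTERS[pop] if pop < 26 else f"P{pop}"


# ----------------------------------------------------------------------
# divergence
# ----------------------------------------------------------------------

def solve_drift_f(target_fst: float) -> float:
    """Balding-Nichols F giving expected pairwise FST ``target_fst``.

    For two populations drifted independently from a shared ancestor the
    expected Nei pairwise FST is F/(2-F); invert numerically.
    """
    return float(brentq(lambda f: f / (2.0 - f) - target_fst, 0.0, 1.0 - 1e-9))


def simulate_ancestral_populations(cfg: SieveConfig) -> AlleleFrequencySet:
    """Draw per-population allele frequencies around a common ancestor.

    Ancestral frequencies are uniform on [0.1, 0.9] (the post-MAF-filter
    regime of the real data); each population's frequency at each locus is
    a Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) draw with F solved to
    hit ``target_fst``.
    """
    rng = child_rng(cfg.seed, "ancestral")
    anc = rng.uniform(0.1, 0.9, size=cfg.n_loci)
    f = solve_drift_f(cfg.target_fst)
    if f < 1e-10:
        freqs = np.tile(anc, (cfg.n_populations, 1))
    else:
        a = anc * (1.0 - f) / f
        b = (1.0 - anc) * (1.0 - f) / f
        freqs = rng.beta(a, b, size=(cfg.n_populations, cfg.n_loci))
    return AlleleFrequencySet(freqs=freqs, ancestral=anc, inbreeding_coefficient=f)


def _select_frequencies(p: np.ndarray, sieve: dict) -> np.ndarray:
    """Deterministic allele-frequency update after one round of
    multiplicative viability selection (per-copy fitness 1-s)."""
    p = p.copy()
    for idx, sl in sieve.items():
        if sl.disfavored_allele == 1:
            p[idx] = p[idx] * (1.0 - sl.s) / (1.0 - p[idx] * sl.s)
        else:
            q = 1.0 - p[idx]
            q = q * (1.0 - sl.s) / (1.0 - q * sl.s)
            p[idx] = 1.0 - q
    return p


def _parental_pool(freqs: AlleleFrequencySet, pop: int, year: int, cfg: SieveConfig):
    """Larval source frequencies for one population and birth year.

    Implicit mode (default) returns the population vector unchanged. The
    explicit age-structure mode averages per-age parental pools, each
    shaped by the sieve of its own birth year (configured regimes where
    given, otherwise a reproducible random historical regime per year).
    """
    p = freqs.freqs[pop]
    if not cfg.explicit_age_structure:
        return p
    lo, hi = cfg.age_range_reproductive
    pools = []
    for age in range(lo, hi + 1):
        birth_year = year - age
        if birth_year in cfg.sieve_loci:
            sieve = cfg.sieve_loci[birth_year]
        else:
            hrng = child_rng(cfg.seed, "historical-sieve", birth_year)
            n_sel = max(1, round(0.02 * cfg.n_loci))
            idx = hrng.choice(cfg.n_loci, size=n_sel, replace=False)
            from .config import SieveLocus

            sieve = {
                int(i): SieveLocus(int(hrng.integers(0, 2)), 0.5) for i in idx
            }
        pools.append(_select_frequencies(p, sieve))
    return np.mean(pools, axis=0)


# ----------------------------------------------------------------------
# cohorts and the sieve
# ----------------------------------------------------------------------

def simulate_cohort(
    freqs: AlleleFrequencySet, pop: int, year: int, cfg: SieveConfig
) -> GenotypeMatrix:
    """Hardy-Weinberg larval cohort of ``n_larvae_per_pop_year`` diploids."""
    if pop >= freqs.n_populations:
        raise ValueError(f"population index {pop} out of range")
    rng = child_rng(cfg.seed, "cohort", pop, year)
    p = _parental_pool(freqs, pop, year, cfg)
    n = cfg.n_larvae_per_pop_year
    geno = rng.binomial(2, p, size=(n, freqs.n_loci)).astype(np.int8)
    ids = np.array(
        [f"{population_letter(pop)}-{year}-{i:05d}" for i in range(n)], dtype=object
    )
    loci = np.array([f"locus{j:05d}" for j in range(freqs.n_loci)], dtype=object)
    return GenotypeMatrix(geno, loci, ids)


def apply_selective_sieve(larvae: GenotypeMatrix, year: int, cfg: SieveConfig):
    """First-year viability selection.

    Each larva's viability is
    ``w = prod_l (1 - s_l)^(copies of the disfavored allele at l)`` over
    the year's sieve loci; the returned log records ``w`` for every
    larva. In the default ``"relative"`` mode selection is soft
    (density-regulated): a fixed number ``round(tau * N)`` of survivors
    (``tau = sieve_survivor_fraction``) is drawn by viability-weighted
    sampling without replacement, so selection acts on relative viability
    and a desk-scale cohort is not annihilated by the joint load of many
    selected loci; zero-viability larvae (an ``s = 1`` allele) never
    survive. ``selection_mode="absolute"`` draws independent Bernoulli
    survival at ``w`` itself (appropriate for few or weak sieve loci).
    Returns ``(survivors, survival_log)``.
    """
    sieve = cfg.sieve_loci.get(year, {})
    n = larvae.n_individuals
    prob = np.ones(n)
    for idx, sl in sieve.items():
        g = larvae.genotypes[:, idx].astype(float)
        copies = g if sl.disfavored_allele == 1 else 2.0 - g
        prob *= (1.0 - sl.s) ** copies
    tag = str(larvae.individual_ids[0]) if n else ""
    rng = child_rng(cfg.seed, "sieve", year, tag)
    if cfg.selection_mode == "relative":
        viable = prob > 0
        if not viable.any():
            raise DegenerateDataError(
                f"year-{year} sieve leaves zero viability for every larva"
            )
        n_surv = min(int(viable.sum()), max(1, round(cfg.sieve_survivor_fraction * n)))
        with np.errstate(divide="ignore"):
            keys = np.where(viable, np.log(prob) + rng.gumbel(size=n), -np.inf)
        survived = np.zeros(n, dtype=bool)
        survived[np.argsort(keys)[::-1][:n_surv]] = True
    else:
        survived = rng.random(n) < prob
    if not survived.any():
        raise DegenerateDataError(
            f"no survivors of the year-{year} sieve; weaken selection or "
            "increase n_larvae_per_pop_year"
        )
    log = pd.DataFrame(
        {
            "individual_id": larvae.individual_ids,
            "survival_prob": prob,
            "survived": survived,
        }
    )
    return larvae.take_individuals(np.where(survived)[0]), log


# ----------------------------------------------------------------------
# survey assembly
# ----------------------------------------------------------------------

_YEAR_SURVEY = {
    # (first ordinal day, last ordinal day, temperature base degC, chl base mg/m3)
    2014: (189, 226, 9.0, 2.0),
    2015: (194, 203, 11.0, 1.0),
}
_DEFAULT_SURVEY = (189, 225, 9.0, 2.0)


def station_plan(cfg: SieveConfig, year: int) -> pd.DataFrame:
    """Survey plan: per-station latitude, date, environment, population
    mixture and sample quota. Latitude and date increase together
    (collinear by design — the survey moves northward through the season).
    """
    rng = child_rng(cfg.seed, "stations", year)
    s = cfg.n_stations
    k = cfg.n_populations
    lat = np.linspace(55.0, 60.0, s) if s > 1 else np.array([57.5])
    d0, d1, temp0, chl0 = _YEAR_SURVEY.get(year, _DEFAULT_SURVEY)
    date = np.round(np.linspace(d0, d1, s)).astype(int) if s > 1 else np.array([d0])
    temp = temp0 - 0.1 * (lat - lat.mean()) + rng.normal(0.0, 0.5, size=s)
    chl = np.clip(chl0 + 0.1 * (lat - lat.mean()) + rng.normal(0.0, 0.3, size=s), 0.05, None)
    conc = cfg.station_mixture_concentration
    if np.isinf(conc):
        mix = np.full((s, k), 1.0 / k)
    else:
        mix = rng.dirichlet(np.full(k, conc), size=s)
    n = cfg.survey_sample_sizes[year]
    quota = np.full(s, n // s, dtype=int)
    quota[: n % s] += 1
    plan = pd.DataFrame(
        {
            "station_id": [f"{year}-S{i:02d}" for i in range(s)],
            "latitude": lat,
            "sample_date": date,
            "temperature": temp,
            "chlorophyll": chl,
            "quota": quota,
        }
    )
    plan["mixture"] = list(mix)
    return plan


def assemble_survey(
    survivors_by_pop: list[GenotypeMatrix], year: int, cfg: SieveConfig
):
    """Sample the year's survey from the pooled post-sieve populations.

    Stations draw individuals without replacement with weights
    ``mixture[pop] * exp(sum_g beta_g (g - 1) z_lat)`` over gradient loci
    — the exponential tilt plants the latitude/date cline that the GEA
    scan is meant to recover.
    """
    rng = child_rng(cfg.seed, "survey", year)
    plan = station_plan(cfg, year)
    n_request = int(plan["quota"].sum())
    pops = np.concatenate(
        [np.full(g.n_individuals, i) for i, g in enumerate(survivors_by_pop)]
    )
    geno = np.vstack([g.genotypes for g in survivors_by_pop])
    ids = np.concatenate([g.individual_ids for g in survivors_by_pop])
    loci = survivors_by_pop[0].locus_ids
    if n_request > len(ids):
        raise DegenerateDataError(
            f"survey of {n_request} requested but only {len(ids)} survivors"
        )
    lat = plan["latitude"].to_numpy()
    z_lat = (lat - lat.mean()) / lat.std() if len(lat) > 1 and lat.std() > 0 else np.zeros_like(lat)

    grad_idx = np.array(sorted(cfg.gradient_loci), dtype=int)
    grad_beta = np.array([cfg.gradient_loci[i] for i in grad_idx])
    grad_score = (
        (geno[:, grad_idx].astype(float) - 1.0) @ grad_beta
        if len(grad_idx)
        else np.zeros(len(ids))
    )
    # sieve heterogeneity during dispersal: disfavored-allele carriers are
    # additionally depleted at warm stations in their sieve year
    sieve = cfg.sieve_loci.get(year, {})
    temp = plan["temperature"].to_numpy()
    z_temp = (
        (temp - temp.mean()) / temp.std()
        if len(temp) > 1 and temp.std() > 0
        else np.zeros_like(temp)
    )
    sieve_score = np.zeros(len(ids))
    if sieve and cfg.sieve_temperature_tilt > 0:
        for idx, sl in sieve.items():
            g = geno[:, idx].astype(float)
            copies = g if sl.disfavored_allele == 1 else 2.0 - g
            sieve_score -= cfg.sieve_temperature_tilt * sl.s * (copies - 1.0)

    remaining = np.ones(len(ids), dtype=bool)
    chosen_rows, meta_rows = [], []
    for si in range(len(plan)):
        row = plan.iloc[si]
        mix = row["mixture"]
        logw = (
            np.log(np.asarray(mix)[pops] + 1e-300)
            + grad_score * z_lat[si]
            + sieve_score * z_temp[si]
        )
        # Gumbel-max trick: weighted sampling without replacement
        keys = logw + rng.gumbel(size=len(ids))
        keys[~remaining] = -np.inf
        take = np.argsort(keys)[::-1][: int(row["quota"])]
        remaining[take] = False
        for t in take:
            chosen_rows.append(t)
            meta_rows.append(
                {
                    "individual_id": ids[t],
                    "year": year,
                    "station_id": row["station_id"],
                    "latitude": row["latitude"],
                    "sample_date": int(row["sample_date"]),
                    "temperature": row["temperature"],
                    "chlorophyll": row["chlorophyll"],
                    "length": np.nan,
                    "weight": np.nan,
                    "lipid_pct": np.nan,
                    "population_label": population_letter(int(pops[t])),
                    "replicate_group": np.nan,
                }
            )
    chosen_rows = np.array(chosen_rows)
    gm = GenotypeMatrix(geno[chosen_rows], loci, ids[chosen_rows])
    return gm, pd.DataFrame(meta_rows)


# ----------------------------------------------------------------------
# phenotypes, missingness, replicates
# ----------------------------------------------------------------------

def _lipid_genetic_load(meta, geno, cfg):
    """Per-individual lipid decrement from the condition-coupled sieve
    loci of each individual's own survey year, centered within year."""
    load = np.zeros(len(meta))
    if geno is None or cfg.lipid_coupling == 0:
        return load
    row_of = {iid: i for i, iid in enumerate(geno.individual_ids)}
    years = meta["year"].to_numpy()
    for year in np.unique(years):
        sieve = cfg.sieve_loci.get(int(year), {})
        coupled = sorted(sieve)[: cfg.n_condition_coupled_loci]
        if not coupled:
            continue
        rows = np.array([row_of[i] for i in meta.loc[years == year, "individual_id"]])
        copies = np.zeros(len(rows))
        for idx in coupled:
            sl = sieve[idx]
            g = geno.genotypes[rows, idx].astype(float)
            g = np.where(g < 0, 1.0, g)  # missing treated as average
            copies += g if sl.disfavored_allele == 1 else 2.0 - g
        load[years == year] = cfg.lipid_coupling * (copies - copies.mean())
    return load


def generate_phenotypes(
    meta: pd.DataFrame, cfg: SieveConfig, geno: GenotypeMatrix | None = None
) -> pd.DataFrame:
    """Draw length, weight and lipid content for every surveyed fish.

    Length is lognormal around a mean that grows through the season
    (young-of-the-year growth) with substantial within-date spread; log
    weight follows the year's allometric line plus residual noise; lipid
    content is an affine function of the allometric residual and
    temperature, minus the genetic load at the year's condition-coupled
    sieve loci when genotypes are supplied, clamped to [0, 60]%.
    """
    rng = child_rng(cfg.seed, "phenotype")
    meta = meta.copy()
    lengths = np.empty(len(meta))
    weights = np.empty(len(meta))
    lipids = np.empty(len(meta))
    year_min_date = meta.groupby("year")["sample_date"].transform("min")
    rel_date = (meta["sample_date"] - year_min_date).to_numpy(dtype=float)
    years = meta["year"].to_numpy()
    lipid_load = _lipid_genetic_load(meta, geno, cfg)
    for i in range(len(meta)):
        par = cfg.allometry.get(int(years[i]))
        if par is None:
            raise ValueError(f"no allometry parameters for year {years[i]}")
        mean_len = 25.0 + 0.6 * rel_date[i]
        length = float(np.exp(np.log(mean_len) + rng.normal(0.0, 0.15)))
        eps = float(rng.normal(0.0, par.sd)) if par.sd > 0 else 0.0
        log_w = par.a + par.b * np.log(length) + eps
        lipid = 12.0 + 25.0 * eps + 0.8 * (meta["temperature"].iat[i] - 9.0)
        lipid += float(rng.normal(0.0, 2.0)) - lipid_load[i]
        lengths[i] = length
        weights[i] = np.exp(log_w)
        lipids[i] = np.clip(lipid, 0.0, 60.0)
    meta["length"] = lengths
    meta["weight"] = weights
    meta["lipid_pct"] = lipids
    return meta


def inject_missingness_and_replicates(
    geno: GenotypeMatrix, cfg: SieveConfig, meta: pd.DataFrame | None = None
):
    """Append technical replicate pairs, then mask entries MCAR.

    Replicated individuals share genotypes but receive independent
    missingness; both members carry the original id as
    ``replicate_group``. Returns ``(GenotypeMatrix, metadata | None)``.
    """
    rng = child_rng(cfg.seed, "missingness")
    n = geno.n_individuals
    n_pairs = min(cfg.n_replicate_pairs, n)
    rep_idx = np.sort(rng.choice(n, size=n_pairs, replace=False)) if n_pairs else np.array([], dtype=int)

    g = np.vstack([geno.genotypes, geno.genotypes[rep_idx]])
    ids = np.concatenate(
        [geno.individual_ids, [f"{geno.individual_ids[i]}-rep" for i in rep_idx]]
    )
    if cfg.missing_rate > 0:
        mask = rng.random(g.shape) < cfg.missing_rate
        g = np.where(mask, MISSING, g).astype(np.int8)
    out = GenotypeMatrix(g, geno.locus_ids, ids)

    if meta is None:
        return out, None
    meta = meta.copy()
    rep_ids = [geno.individual_ids[i] for i in rep_idx]
    meta["replicate_group"] = np.where(
        meta["individual_id"].isin(rep_ids), meta["individual_id"], np.nan
    )
    extra = meta[meta["individual_id"].isin(rep_ids)].copy()
    extra["replicate_group"] = extra["individual_id"]
    extra["individual_id"] = extra["individual_id"] + "-rep"
    meta = pd.concat([meta, extra], ignore_index=True)
    return out, meta


# ----------------------------------------------------------------------
# full dataset
# ----------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """One simulated two-year survey: genotypes, metadata and the truth
    record (labels, sieve/gradient loci, drift parameter, seeds)."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    truth: dict
    frequencies: AlleleFrequencySet


def simulate_dataset(cfg: SieveConfig) -> SimulatedDataset:
    """Run the full generative chain for every cohort year."""
    freqs = simulate_ancestral_populations(cfg)
    gms, metas = [], []
    for year in cfg.cohort_years:
        survivors = []
        for pop in range(cfg.n_populations):
            larvae = simulate_cohort(freqs, pop, year, cfg)
            surv, _ = apply_selective_sieve(larvae, year, cfg)
            survivors.append(surv)
        gm, meta = assemble_survey(survivors, year, cfg)
        gms.append(gm)
        metas.append(meta)
    geno = GenotypeMatrix(
        np.vstack([g.genotypes for g in gms]),
        gms[0].locus_ids,
        np.concatenate([g.individual_ids for g in gms]),
    )
    meta = pd.concat(metas, ignore_index=True)
    meta = generate_phenotypes(meta, cfg, geno)
    geno, meta = inject_missingness_and_replicates(geno, cfg, meta)

    locus_ids = list(geno.locus_ids)
    truth = {
        "population_labels": dict(
            zip(meta["individual_id"], meta["population_label"])
        ),
        "sieve_loci": {
            str(year): [
                {
                    "locus_id": locus_ids[idx],
                    "disfavored_allele": sl.disfavored_allele,
                    "s": sl.s,
                }
                for idx, sl in sorted(loci.items())
            ]
            for year, loci in cfg.sieve_loci.items()
        },
        "gradient_loci": {
            locus_ids[idx]: beta for idx, beta in sorted(cfg.gradient_loci.items())
        },
        "drift_f": freqs.inbreeding_coefficient,
        "target_fst": cfg.target_fst,
        "seed": cfg.seed,
    }
    return SimulatedDataset(geno, meta, truth, freqs)


def write_dataset(geno: GenotypeMatrix, meta: pd.DataFrame, truth: dict, out_dir):
    """Write genepop, VCF, metadata CSV and truth JSON; returns paths."""
    from pathlib import Path

    from . import io as skio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genepop": out / "genotypes.genepop",
        "vcf": out / "genotypes.vcf",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.json",
    }
    station_of = dict(zip(meta["individual_id"], meta["station_id"]))
    skio.write_genepop(geno, paths["genepop"], pop_of=station_of)
    skio.write_vcf(geno, paths["vcf"])
    skio.write_metadata(meta, paths["metadata"])
    skio.write_truth(truth, paths["truth"])
    return paths
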