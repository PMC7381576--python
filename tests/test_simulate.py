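"""Forward simulator: divergence model, cohorts, sieve, survey assembly,
phenotypes, missingness and dataset writing."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from sievekit import (
    DegenerateDataError,
    SieveConfig,
    SieveLocus,
    apply_selective_sieve,
    assemble_survey,
    generate_phenotypes,
    inject_missingness_and_replicates,
    nei_pairwise_fst,
    simulate_ancestral_populations,
    simulate_cohort,
    simulate_dataset,
    write_dataset,
)
from sievekit.datatypes import MISSING, GenotypeMatrix
from sievekit.io import read_genepop, read_truth
from sievekit.simulate import solve_drift_f, station_plan


def _no_sieve(**kw):
    base = dict(
        sieve_loci={2014: {}, 2015: {}},
        gradient_loci={},
        missing_rate=0.0,
        n_replicate_pairs=0,
    )
    base.update(kw)
    return SieveConfig(**base)


# ----------------------------------------------------------------------
# ancestral divergence
# ----------------------------------------------------------------------

def test_realized_pairwise_fst_tracks_target():
    """Mean pairwise FST on large simulated samples lands within 20% of
    the configured target (K=4, L=5000)."""
    cfg = _no_sieve(n_loci=5000, target_fst=0.03, n_larvae_per_pop_year=500, seed=11)
    freqs = simulate_ancestral_populations(cfg)
    cohorts = [simulate_cohort(freqs, p, 2014, cfg) for p in range(4)]
    gm = GenotypeMatrix(
        np.vstack([c.genotypes for c in cohorts]),
        cohorts[0].locus_ids,
        np.concatenate([c.individual_ids for c in cohorts]),
    )
    labels = np.repeat(list("ABCD"), 500)
    fst = nei_pairwise_fst(gm, labels).fst
    vals = fst.to_numpy()[np.triu_indices(4, 1)]
    assert abs(vals.mean() - 0.03) < 0.2 * 0.03
    # and each pair inside the simulator's own 0.5x-2x guarantee
    assert ((vals > 0.015) & (vals < 0.06)).all()


def test_zero_divergence_limit_gives_identical_populations():
    cfg = _no_sieve(n_loci=50, target_fst=1e-13, seed=1)
    freqs = simulate_ancestral_populations(cfg)
    assert np.allclose(freqs.freqs, freqs.freqs[0][None, :])


def test_ancestral_frequencies_deterministic_under_seed():
    cfg = _no_sieve(n_loci=100, seed=9)
    a = simulate_ancestral_populations(cfg)
    b = simulate_ancestral_populations(cfg)
    assert np.array_equal(a.freqs, b.freqs)


def test_drift_f_solves_pairwise_expectation():
    # expected pairwise FST under independent drift is F/(2-F)
    for t in (0.008, 0.02, 0.031):
        f = solve_drift_f(t)
        assert f / (2 - f) == pytest.approx(t, abs=1e-10)


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

def test_cohort_respects_fixed_and_intermediate_frequencies():
    cfg = _no_sieve(n_loci=3, n_larvae_per_pop_year=10_000, seed=3)
    freqs = simulate_ancestral_populations(cfg)
    freqs.freqs[0] = [0.0, 0.5, 1.0]
    cohort = simulate_cohort(freqs, 0, 2014, cfg)
    g = cohort.genotypes
    assert (g[:, 0] == 0).all()
    assert (g[:, 2] == 2).all()
    se = np.sqrt(2 * 0.5 * 0.5 / 10_000)
    assert abs(g[:, 1].mean() - 1.0) < 3 * se


def test_cohort_deterministic_under_seed():
    cfg = _no_sieve(n_loci=40, seed=21)
    freqs = simulate_ancestral_populations(cfg)
    a = simulate_cohort(freqs, 1, 2015, cfg)
    b = simulate_cohort(freqs, 1, 2015, cfg)
    assert a == b


# ----------------------------------------------------------------------
# selective sieve
# ----------------------------------------------------------------------

def test_absolute_sieve_heterozygote_survival_probability():
    """One s=0.5 locus: the logged viability is (1-s)^copies exactly."""
    cfg = _no_sieve(
        n_loci=1,
        sieve_loci={2015: {0: SieveLocus(disfavored_allele=1, s=0.5)}},
        selection_mode="absolute",
        seed=5,
    )
    larvae = GenotypeMatrix(
        np.array([[0], [1], [2]], dtype=np.int8),
        np.array(["l0"], dtype=object),
        np.array(["a", "b", "c"], dtype=object),
    )
    _, log = apply_selective_sieve(larvae, 2015, cfg)
    assert log["survival_prob"].tolist() == [1.0, 0.5, 0.25]


def test_lethal_allele_is_absorbing():
    cfg = _no_sieve(
        n_loci=2,
        n_larvae_per_pop_year=400,
        sieve_loci={2015: {0: SieveLocus(1, 1.0)}},
        seed=6,
    )
    freqs = simulate_ancestral_populations(cfg)
    freqs.freqs[0] = [0.3, 0.5]
    larvae = simulate_cohort(freqs, 0, 2015, cfg)
    survivors, _ = apply_selective_sieve(larvae, 2015, cfg)
    assert (survivors.genotypes[:, 0] == 0).all()


def test_neutral_sieve_preserves_allele_frequencies():
    """With all s=0, survivor frequencies are unbiased: pooled over 200
    replicate cohorts the survivor allele count stays inside a 4-sigma
    binomial band around the larval frequency."""
    devs = []
    for rep in range(200):
        cfg = _no_sieve(
            n_loci=4, n_larvae_per_pop_year=60,
            sieve_loci={2014: {i: SieveLocus(1, 0.0) for i in range(4)}},
            sieve_survivor_fraction=0.5, seed=3000 + rep,
        )
        freqs = simulate_ancestral_populations(cfg)
        larvae = simulate_cohort(freqs, 0, 2014, cfg)
        surv, _ = apply_selective_sieve(larvae, 2014, cfg)
        devs.append(
            surv.genotypes.mean(axis=0) / 2 - larvae.genotypes.mean(axis=0) / 2
        )
    devs = np.array(devs)
    # mean deviation across replicates ~ N(0, sd/sqrt(200))
    z = devs.mean(axis=0) / (devs.std(axis=0) / np.sqrt(len(devs)))
    assert (np.abs(z) < 4).all()


def test_sieve_with_zero_survivors_raises():
    cfg = _no_sieve(
        n_loci=1,
        sieve_loci={2015: {0: SieveLocus(1, 1.0)}},
        seed=8,
    )
    larvae = GenotypeMatrix(
        np.array([[1], [2], [2]], dtype=np.int8),
        np.array(["l0"], dtype=object),
        np.array(["a", "b", "c"], dtype=object),
    )
    with pytest.raises(DegenerateDataError):
        apply_selective_sieve(larvae, 2015, cfg)


def test_relative_sieve_keeps_survivor_fraction():
    cfg = _no_sieve(
        n_loci=100, n_larvae_per_pop_year=400,
        sieve_loci={2015: {i: SieveLocus(1, 0.5) for i in range(10)}},
        sieve_survivor_fraction=0.25, seed=12,
    )
    freqs = simulate_ancestral_populations(cfg)
    larvae = simulate_cohort(freqs, 0, 2015, cfg)
    survivors, _ = apply_selective_sieve(larvae, 2015, cfg)
    assert survivors.n_individuals == 100


# ----------------------------------------------------------------------
# survey assembly
# ----------------------------------------------------------------------

def test_station_mixtures_sum_to_one(small_cfg):
    plan = station_plan(small_cfg, 2014)
    for mix in plan["mixture"]:
        assert np.asarray(mix).sum() == pytest.approx(1.0)
    assert plan["quota"].sum() == small_cfg.survey_sample_sizes[2014]


def test_infinite_concentration_gives_equal_mixtures():
    cfg = _no_sieve(n_loci=10, station_mixture_concentration=np.inf)
    plan = station_plan(cfg, 2014)
    for mix in plan["mixture"]:
        assert np.allclose(mix, 0.25)


def test_latitude_and_date_collinear_by_design(small_cfg):
    plan = station_plan(small_cfg, 2014)
    assert (np.diff(plan["latitude"]) > 0).all()
    assert (np.diff(plan["sample_date"]) >= 0).all()


def test_gradient_locus_frequency_monotone_in_latitude():
    """A planted cline locus shows a significant genotype-latitude rank
    correlation among ~300 sampled fish."""
    cfg = _no_sieve(
        n_populations=2, n_loci=50, target_fst=0.005,
        gradient_loci={49: 0.6},
        n_larvae_per_pop_year=400,
        survey_sample_sizes={2014: 300, 2015: 40},
        seed=17,
    )
    freqs = simulate_ancestral_populations(cfg)
    survivors = []
    for p in range(2):
        larvae = simulate_cohort(freqs, p, 2014, cfg)
        surv, _ = apply_selective_sieve(larvae, 2014, cfg)
        survivors.append(surv)
    gm, meta = assemble_survey(survivors, 2014, cfg)
    rho, p = stats.spearmanr(meta["latitude"], gm.genotypes[:, 49])
    assert rho > 0 and p < 0.01


def test_survey_larger_than_survivor_pool_raises(small_cfg):
    cfg = dataclasses.replace(
        small_cfg, survey_sample_sizes={2014: 10_000, 2015: 40}
    )
    freqs = simulate_ancestral_populations(cfg)
    survivors = []
    for p in range(cfg.n_populations):
        larvae = simulate_cohort(freqs, p, 2014, cfg)
        surv, _ = apply_selective_sieve(larvae, 2014, cfg)
        survivors.append(surv)
    with pytest.raises(DegenerateDataError):
        assemble_survey(survivors, 2014, cfg)


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def test_zero_residual_sd_puts_fish_exactly_on_the_line(small_dataset, small_cfg):
    from sievekit.config import AllometryParams

    cfg = dataclasses.replace(
        small_cfg,
        allometry={
            2014: AllometryParams(a=-11.0, b=3.0, sd=0.0),
            2015: AllometryParams(a=-11.0, b=3.0, sd=0.0),
        },
        lipid_coupling=0.0,
    )
    meta = generate_phenotypes(small_dataset.metadata, cfg)
    resid = np.log(meta["weight"]) - (-11.0 + 3.0 * np.log(meta["length"]))
    assert np.abs(resid).max() < 1e-9


def test_lipid_is_clamped_to_percent_range(small_dataset):
    assert small_dataset.metadata["lipid_pct"].between(0, 60).all()


def test_condition_coupled_sieve_loci_depress_lipid():
    """Carriers of disfavored alleles at the condition-coupled loci are
    leaner in the sieve year."""
    cfg = SieveConfig(
        n_loci=300, n_larvae_per_pop_year=400,
        survey_sample_sizes={2014: 100, 2015: 150},
        sieve_loci={2014: {}, 2015: {i: SieveLocus(1, 0.5) for i in range(6)}},
        gradient_loci={}, missing_rate=0.0, n_replicate_pairs=0,
        n_condition_coupled_loci=3, lipid_coupling=4.0, seed=77,
    )
    ds = simulate_dataset(cfg)
    m15 = ds.metadata["year"] == 2015
    rows = [
        np.where(ds.genotypes.individual_ids == i)[0][0]
        for i in ds.metadata.loc[m15, "individual_id"]
    ]
    load = ds.genotypes.genotypes[rows][:, :3].sum(axis=1)
    r = np.corrcoef(load, ds.metadata.loc[m15, "lipid_pct"])[0, 1]
    assert r < -0.3


# ----------------------------------------------------------------------
# missingness + replicates
# ----------------------------------------------------------------------

def test_zero_missing_rate_only_appends_replicates(small_dataset):
    cfg = _no_sieve(n_loci=30, n_replicate_pairs=2, missing_rate=0.0, seed=31)
    gm = simulate_cohort(simulate_ancestral_populations(cfg), 0, 2014, cfg)
    out, _ = inject_missingness_and_replicates(gm, cfg)
    assert out.n_individuals == gm.n_individuals + 2
    assert np.array_equal(out.genotypes[: gm.n_individuals], gm.genotypes)
    for rep_row in range(gm.n_individuals, out.n_individuals):
        rid = str(out.individual_ids[rep_row]).removesuffix("-rep")
        orig = np.where(gm.individual_ids == rid)[0][0]
        assert np.array_equal(out.genotypes[rep_row], gm.genotypes[orig])


def test_missingness_rate_realized_within_binomial_error():
    cfg = _no_sieve(
        n_loci=5000, n_larvae_per_pop_year=200, missing_rate=0.05,
        n_replicate_pairs=0, seed=33,
    )
    gm = simulate_cohort(simulate_ancestral_populations(cfg), 0, 2014, cfg)
    out, _ = inject_missingness_and_replicates(gm, cfg)
    n_cells = out.genotypes.size
    rate = (out.genotypes == MISSING).mean()
    se = np.sqrt(0.05 * 0.95 / n_cells)
    assert abs(rate - 0.05) < 3 * se


# ----------------------------------------------------------------------
# full dataset + writing
# ----------------------------------------------------------------------

def test_dataset_deterministic_under_config(small_cfg, small_dataset):
    again = simulate_dataset(small_cfg)
    assert again.genotypes == small_dataset.genotypes
    assert again.metadata.equals(small_dataset.metadata)
    assert again.truth == small_dataset.truth


def test_written_dataset_roundtrips_and_truth_lists_sieve_loci(
    tmp_path, small_dataset, small_cfg
):
    paths = write_dataset(
        small_dataset.genotypes, small_dataset.metadata, small_dataset.truth, tmp_path
    )
    back, _ = read_genepop(paths["genepop"])
    # genepop groups rows by station; align by id before comparing
    order = {iid: k for k, iid in enumerate(back.individual_ids)}
    idx = [order[i] for i in small_dataset.genotypes.individual_ids]
    assert np.array_equal(
        back.genotypes[idx], small_dataset.genotypes.genotypes
    )
    truth = read_truth(paths["truth"])
    expected = {
        small_dataset.genotypes.locus_ids[i]
        for i in small_cfg.sieve_loci[2015]
    }
    assert {e["locus_id"] for e in truth["sieve_loci"]["2015"]} == expected


def test_explicit_age_structure_mode_runs_and_differs(small_cfg):
    cfg = dataclasses.replace(small_cfg, explicit_age_structure=True)
    freqs = simulate_ancestral_populations(cfg)
    implicit = simulate_cohort(freqs, 0, 2014, small_cfg)
    explicit = simulate_cohort(freqs, 0, 2014, cfg)
    assert explicit.genotypes.shape == implicit.genotypes.shape
    assert not np.array_equal(explicit.genotypes, implicit.genotypes)
    again = simulate_cohort(freqs, 0, 2014, cfg)
    assert explicit == again
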