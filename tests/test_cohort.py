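"""Synthetic cohort generator: determinism, spectrum, effects, read model."""

import numpy as np
import pytest

from poolscreen.cohort import (
    AlleleFrequencyModel,
    CohortConfig,
    CoverageModel,
    generate_cohort,
    sample_site_frequency_spectrum,
    simulate_pool_read_counts,
)
from poolscreen.pools import Pool

from conftest import make_manual_cohort


def test_cohort_size_and_phenotype_invariants():
    cfg = CohortConfig(n_cases=4016, n_controls=2872, n_sites=50, seed=1)
    cohort = generate_cohort(cfg)
    ind = cohort.individuals
    assert len(ind) == 6888
    assert (ind["status"] == "case").sum() == 4016
    controls = ind[ind["status"] == "control"]
    assert controls["age_at_diagnosis"].isna().all()
    assert (controls["onset_group"] == "control").all()
    cases = ind[ind["status"] == "case"]
    early = cases["age_at_diagnosis"] < 40
    assert (cases.loc[early, "onset_group"] == "early").all()
    assert (cases.loc[~early, "onset_group"] == "late").all()
    assert (cases["onset_group"] == "early").sum() == 1346


def test_seed_determinism_bit_identical():
    cfg = CohortConfig(n_cases=100, n_controls=80, n_sites=60, n_pathogenic=3, seed=9)
    a, b = generate_cohort(cfg), generate_cohort(cfg)
    assert np.array_equal(a.genotypes, b.genotypes)
    assert a.individuals.equals(b.individuals)
    assert a.variants.equals(b.variants)
    pool = Pool("P1", 1, "all", tuple(a.individuals["id"][:20]))
    ra = simulate_pool_read_counts([pool], a, rng=5)
    rb = simulate_pool_read_counts([pool], b, rng=5)
    assert ra.equals(rb)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_cases=0)
    with pytest.raises(ValueError):
        CohortConfig(error_rate=0.5)
    with pytest.raises(ValueError):
        CohortConfig(n_pathogenic=2, pathogenic_or=0.5)
    with pytest.raises(ValueError):
        AlleleFrequencyModel(af_min=0.0)


def test_genotype_marginals_match_binomial():
    """Per-site allele counts track Binomial(2n, AF) within 3 SE."""
    af = 0.005
    cfg = CohortConfig(
        n_cases=1000,
        n_controls=1000,
        n_sites=400,
        af_model=AlleleFrequencyModel(af_min=af, af_max=af, common_weight=0.0),
        seed=4,
    )
    cohort = generate_cohort(cfg)
    ac = cohort.genotypes.sum(axis=0)
    expected = 2 * 2000 * af
    se = np.sqrt(2 * 2000 * af * (1 - af) / 400)
    assert abs(ac.mean() - expected) < 3 * se


def test_sfs_point_mass_centres_allele_count_at_one():
    """Point mass at AF 1/(2n): cohort allele counts are ~Poisson(1), so
    the modal discovered count is a singleton and the mean count is 1."""
    model = AlleleFrequencyModel(
        af_min=1 / (2 * 3720), af_max=1 / (2 * 3720), common_weight=0.0
    )
    afs = sample_site_frequency_spectrum(2000, model, rng=0)
    assert np.allclose(afs, 1 / 7440)
    rng = np.random.default_rng(1)
    ac = rng.binomial(2, afs[None, :], size=(3720, 2000)).sum(axis=0)
    assert ac.mean() == pytest.approx(1.0, abs=3 / np.sqrt(2000))
    disc = ac[ac > 0]
    counts = np.bincount(disc)
    assert counts.argmax() == 1
    assert (disc == 1).mean() > 0.5


def test_sfs_defaults_reproduce_rare_variant_spectrum():
    """Default spectrum: ~54% singletons, ~81% of discovered variants at
    cohort AF <= 0.001 in a 3720-individual cohort (medians, 20 reps)."""
    rng = np.random.default_rng(7)
    singles, lows = [], []
    for _ in range(20):
        afs = sample_site_frequency_spectrum(655, rng=rng)
        ac = rng.binomial(7440, afs)  # sum of 3720 Binomial(2, af) draws
        disc = ac[ac > 0]
        singles.append((disc == 1).mean())
        lows.append((disc / 7440 <= 0.001).mean())
    assert np.median(singles) >= 0.45
    assert np.median(lows) >= 0.70
    assert abs(np.median(singles) - 0.54) <= 0.07
    assert abs(np.median(lows) - 0.81) <= 0.06


def test_null_effect_gives_equal_carrier_rates():
    """OR=1 pathogenic site: case and control carrier rates agree within
    binomial error over 200 replicates."""
    a = c = 0
    n_cases, n_controls = 1000, 800
    for rep in range(200):
        cfg = CohortConfig(
            n_cases=n_cases, n_controls=n_controls, n_sites=5,
            class_weights={"missense": 1.0},
            n_pathogenic=1, pathogenic_or=1.0, pathogenic_af=0.005, seed=rep,
        )
        cohort = generate_cohort(cfg)
        j = int(np.flatnonzero(cohort.variants["pathogenic"])[0])
        carrier = cohort.genotypes[:, j] > 0
        is_case = (cohort.individuals["status"] == "case").to_numpy()
        a += carrier[is_case].sum()
        c += carrier[~is_case].sum()
    p1, p0 = a / (200 * n_cases), c / (200 * n_controls)
    pooled = (a + c) / (200 * (n_cases + n_controls))
    se = np.sqrt(pooled * (1 - pooled) * (1 / (200 * n_cases) + 1 / (200 * n_controls)))
    assert abs(p1 - p0) < 4 * se


def test_pathogenic_effect_reproduces_configured_odds_ratio():
    """OR=6 at AF 5e-4, cohort-sized groups: Monte-Carlo log-OR over 500
    replicates (pooled counts) within 10% of log 6."""
    a = b = c = d = 0
    for rep in range(500):
        cfg = CohortConfig(
            n_cases=4016, n_controls=2872, n_sites=4,
            class_weights={"missense": 1.0},
            n_pathogenic=1, pathogenic_or=6.0, pathogenic_af=0.0005, seed=10_000 + rep,
        )
        cohort = generate_cohort(cfg)
        j = int(np.flatnonzero(cohort.variants["pathogenic"])[0])
        carrier = cohort.genotypes[:, j] > 0
        is_case = (cohort.individuals["status"] == "case").to_numpy()
        a += carrier[is_case].sum()
        b += (~carrier[is_case]).sum()
        c += carrier[~is_case].sum()
        d += (~carrier[~is_case]).sum()
    log_or = np.log((a * d) / (b * c))
    assert abs(log_or - np.log(6.0)) < 0.1 * np.log(6.0)


def test_read_count_model_mean():
    """c=1 of 2N=40 at depth 600, e=0.005: mean alt count ~ 15.9."""
    n_sites = 10_000
    geno = np.zeros((20, n_sites), dtype=np.int8)
    geno[0, :] = 1  # one carrier at every site
    cohort = make_manual_cohort(geno)
    pool = Pool("P1", 1, "all", tuple(cohort.individuals["id"]))
    cov = CoverageModel(median_range=(600.0, 600.0), dispersion=1e9)
    counts = simulate_pool_read_counts([pool], cohort, coverage=cov, error_rate=0.005, rng=3)
    expected = 600 * ((1 / 40) * 0.995 + (39 / 40) * (0.005 / 3))
    assert expected == pytest.approx(15.92, abs=0.05)
    assert counts["alt_count"].mean() == pytest.approx(expected, abs=0.2)


def test_read_count_model_edge_cases():
    n_sites = 50
    # c = 0, e = 0 -> alt 0 everywhere
    cohort0 = make_manual_cohort(np.zeros((10, n_sites), dtype=np.int8))
    pool = Pool("P1", 1, "all", tuple(cohort0.individuals["id"]))
    counts0 = simulate_pool_read_counts([pool], cohort0, error_rate=0.0, rng=1)
    assert (counts0["alt_count"] == 0).all()
    # all 2N alleles alt, e = 0 -> alt == depth
    cohort2 = make_manual_cohort(np.full((10, n_sites), 2, dtype=np.int8))
    pool2 = Pool("P1", 1, "all", tuple(cohort2.individuals["id"]))
    counts2 = simulate_pool_read_counts([pool2], cohort2, error_rate=0.0, rng=1)
    assert (counts2["alt_count"] == counts2["depth"]).all()


def test_missing_pool_member_raises():
    cohort = make_manual_cohort(np.zeros((5, 3), dtype=np.int8))
    pool = Pool("P1", 1, "all", ("I000", "ghost"))
    with pytest.raises(KeyError):
        simulate_pool_read_counts([pool], cohort, rng=0)


def test_empirical_alt_fraction_converges_with_depth():
    """Alt fraction converges to p_c as depth grows."""
    geno = np.zeros((20, 2000), dtype=np.int8)
    geno[0, :] = 1
    cohort = make_manual_cohort(geno)
    pool = Pool("P1", 1, "all", tuple(cohort.individuals["id"]))
    cov = CoverageModel(median_range=(20000.0, 20000.0), dispersion=1e9)
    counts = simulate_pool_read_counts([pool], cohort, coverage=cov, error_rate=0.005, rng=8)
    p = (1 / 40) * 0.995 + (39 / 40) * (0.005 / 3)
    frac = (counts["alt_count"] / counts["depth"]).mean()
    assert frac == pytest.approx(p, rel=0.01)
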