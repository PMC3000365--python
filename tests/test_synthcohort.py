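import numpy as np
import pytest

from repeatdyn import (
    CohortConfig,
    DriftParams,
    PeriodicParams,
    TissueDynamics,
    TraceRenderConfig,
    TractPopulation,
    default_tissue_dynamics,
    fit_single_gaussian,
    generate_cohort,
    mix_populations,
    population_with_insertions,
    render_trace,
    small_pool_subsample,
    zero_truncated_poisson,
)


def test_render_config_validation():
    with pytest.raises(ValueError):
        TraceRenderConfig(attenuation=0.0)
    with pytest.raises(ValueError):
        TraceRenderConfig(grid_step=0.0)
    with pytest.raises(ValueError):
        TraceRenderConfig(noise_sd=-1.0)
    cfg = TraceRenderConfig()
    assert cfg.sigma_repeats(119) == pytest.approx(1.98)


def test_render_area_normalisation(quiet_render):
    pop = TractPopulation.founder(5000)
    cfg = TraceRenderConfig(attenuation=1.0, noise_sd=0.0)
    tr = render_trace(pop, cfg)
    assert tr.area == pytest.approx(cfg.area_scale, rel=1e-3)
    # ...independently of the tract count (PCR plateaus every sample)
    tr2 = render_trace(TractPopulation.founder(500), cfg)
    assert tr2.area == pytest.approx(tr.area, rel=1e-3)


def test_render_broadening_calibration(quiet_render):
    # a monodisperse founder sample must measure sigma = 1.98 repeats
    pop = TractPopulation.founder(1000)
    fit = fit_single_gaussian(render_trace(pop, quiet_render, seed=5))
    assert fit.mean_repeats == pytest.approx(119.0, abs=0.05)
    assert fit.sigma_repeats == pytest.approx(1.98, abs=0.05)


def test_render_attenuation_biases_long_tracts():
    pop = TractPopulation(np.array([119] * 500 + [169] * 500))
    flat = TraceRenderConfig(attenuation=1.0, noise_sd=0.0)
    att = TraceRenderConfig(attenuation=0.99, noise_sd=0.0)
    half = 86.0 + 3.0 * 144.0
    for cfg, expect_equal in ((flat, True), (att, False)):
        tr = render_trace(pop, cfg)
        lowside = tr.intensity[tr.size_bp < half].sum()
        highside = tr.intensity[tr.size_bp >= half].sum()
        if expect_equal:
            assert lowside == pytest.approx(highside, rel=0.02)
        else:
            assert lowside > 1.2 * highside


def test_render_rejects_empty_population(quiet_render):
    with pytest.raises(ValueError):
        render_trace(TractPopulation(np.empty(0, dtype=int)), quiet_render)


def test_zero_truncated_poisson():
    rng = np.random.default_rng(0)
    draws = zero_truncated_poisson(rng, 2.2, 200_000)
    assert draws.min() >= 1
    assert draws.mean() == pytest.approx(2.2, abs=0.02)
    with pytest.raises(ValueError):
        zero_truncated_poisson(rng, 0.9, 10)


def test_population_with_insertions():
    pop = population_with_insertions(
        10_000, founder=119, expanding_fraction=0.46, mean_events=2.2, seed=1
    )
    gains = pop.repeats - 119
    assert (gains >= 0).all()
    assert set(np.unique(gains % 7)) == {0}
    np.testing.assert_array_equal(gains, 7 * pop.event_counts)
    assert (pop.event_counts > 0).sum() == 4600
    assert pop.event_counts[pop.event_counts > 0].mean() == pytest.approx(2.2, abs=0.1)


def test_mix_populations():
    a = TractPopulation(np.full(100, 119))
    b = TractPopulation(np.full(100, 126))
    mixed = mix_populations(a, b, 0.25)
    assert mixed.n_tracts == 100
    assert (mixed.repeats == 119).sum() == 25
    with pytest.raises(ValueError):
        mix_populations(a, b, 1.5)
    with pytest.raises(ValueError):
        mix_populations(a, TractPopulation(np.full(10, 126)), 0.0)


def test_small_pool_subsample():
    pop = TractPopulation(np.arange(100, 200))
    sub = small_pool_subsample(pop, 10, seed=0)
    assert sub.n_tracts == 10
    assert np.isin(sub.repeats, pop.repeats).all()
    with pytest.raises(ValueError):
        small_pool_subsample(pop, 0, seed=0)


def test_tissue_dynamics_validation():
    with pytest.raises(ValueError):
        TissueDynamics()
    with pytest.raises(ValueError):
        TissueDynamics(periodic=PeriodicParams(0.01), expanding_fraction=1.5)
    defaults = default_tissue_dynamics()
    assert set(defaults) == {
        "tail", "heart", "lung", "spleen", "liver", "cortex", "striatum",
    }
    assert defaults["striatum"].expanding_fraction == pytest.approx(0.45)
    assert defaults["cortex"].expanding_fraction == pytest.approx(0.20)
    assert defaults["liver"].drift is not None
    assert defaults["liver"].periodic is not None


def test_generate_cohort_structure():
    cfg = CohortConfig(n_mice=2, n_tracts_per_sample=300, seed=7)
    cohort = generate_cohort(cfg)
    n_tissues = len(cfg.tissues)
    assert len(cohort.samples) == 2 * (1 + (len(cfg.ages) - 1) * n_tissues)
    tails3 = cohort.select(tissue="tail", age_weeks=3.0)
    assert len(tails3) == 2
    for s in tails3:  # the 3-week reference is the monodisperse founder
        assert (s.population.repeats == cfg.founder_repeats).all()
    stri = cohort.select(tissue="striatum", age_weeks=21.0)
    assert len(stri) == 2
    for s in stri:
        gains = s.population.repeats - cfg.founder_repeats
        assert set(np.unique(gains % 7)) == {0}
        assert 0 < (gains > 0).sum() < s.population.n_tracts
        assert s.trace.meta.tissue == "striatum"
        assert s.trace.meta.age_weeks == 21.0


def test_generate_cohort_reproducible():
    cfg = CohortConfig(n_mice=1, n_tracts_per_sample=200, seed=3)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    for sa, sb in zip(a.samples, b.samples):
        np.testing.assert_array_equal(sa.population.repeats, sb.population.repeats)
        np.testing.assert_array_equal(sa.trace.intensity, sb.trace.intensity)


def test_cohort_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_mice=0)
    with pytest.raises(ValueError):
        CohortConfig(ages=(3.0, 3.0))
    with pytest.raises(ValueError):
        CohortConfig(tissues={"brainstem": TissueDynamics(drift=DriftParams(0.01, 0.0))})
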