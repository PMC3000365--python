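import numpy as np
import pytest

from repeatdyn import (
    DriftParams,
    PCRResourceError,
    PeriodicParams,
    TractPopulation,
    simulate_combined,
    simulate_pcr,
    simulate_periodic,
    simulate_unitary,
    triangular_step_pmf,
)

TAIL = DriftParams(0.026414, 0.009859)


def test_population_validation():
    with pytest.raises(ValueError):
        TractPopulation(np.array([[1, 2]]))
    with pytest.raises(ValueError):
        TractPopulation(np.array([1, -2]))
    with pytest.raises(ValueError):
        TractPopulation(np.array([1, 2]), event_counts=np.array([0]))
    pop = TractPopulation.founder(10, 119)
    assert pop.n_tracts == 10
    assert (pop.repeats == 119).all()
    assert (pop.event_counts == 0).all()


def test_triangular_pmf():
    pmf = triangular_step_pmf()
    assert set(pmf) == {5, 6, 7, 8, 9}
    assert sum(pmf.values()) == pytest.approx(1.0)
    assert pmf[7] == max(pmf.values())
    assert pmf[5] == pmf[9]


def test_periodic_params_validation():
    with pytest.raises(ValueError):
        PeriodicParams(1.5)
    with pytest.raises(ValueError):
        PeriodicParams(0.01, {0: 1.0})
    with pytest.raises(ValueError):
        PeriodicParams(0.01, {7: 0.6, 8: 0.6})
    assert PeriodicParams(0.01, {5: 0.5, 9: 0.5}).mean_step == pytest.approx(7.0)


def test_unitary_moments():
    n, days = 100_000, 119
    pop = simulate_unitary(TractPopulation.founder(n), TAIL, days, seed=11)
    delta = pop.repeats.astype(float) - 119.0
    mean_t = TAIL.drift_per_day * days
    var_t = (TAIL.total_rate - TAIL.drift_per_day**2) * days
    se_mean = np.sqrt(var_t / n)
    se_var = var_t * np.sqrt(2.0 / (n - 1))
    assert abs(delta.mean() - mean_t) < 3 * se_mean
    assert abs(delta.var(ddof=1) - var_t) < 3 * se_var


def test_unitary_aggregate_matches_in_distribution():
    n, days = 50_000, 60
    a = simulate_unitary(TractPopulation.founder(n), TAIL, days, seed=5, mode="per_tract")
    b = simulate_unitary(TractPopulation.founder(n), TAIL, days, seed=6, mode="aggregate")
    da = a.repeats.astype(float) - 119.0
    db = b.repeats.astype(float) - 119.0
    se = np.sqrt(2.0 * da.var() / n)
    assert abs(da.mean() - db.mean()) < 3 * se
    assert abs(da.var(ddof=1) - db.var(ddof=1)) < 4 * da.var() * np.sqrt(2.0 / n)


def test_unitary_modes_and_edges():
    pop = TractPopulation.founder(100)
    same = simulate_unitary(pop, TAIL, 0, seed=1)
    assert (same.repeats == 119).all()
    with pytest.raises(ValueError):
        simulate_unitary(pop, TAIL, -1, seed=1)
    with pytest.raises(ValueError):
        simulate_unitary(pop, TAIL, 10, seed=1, mode="bogus")
    # lengths are floored at zero
    tiny = simulate_unitary(TractPopulation.founder(500, 1), DriftParams(0.0, 0.5), 30, seed=2)
    assert (tiny.repeats >= 0).all()


def test_periodic_purity_and_event_counts():
    pop = simulate_periodic(TractPopulation.founder(5000), PeriodicParams(0.02), 126, seed=3)
    gains = pop.repeats - 119
    assert set(np.unique(gains % 7)) == {0}
    np.testing.assert_array_equal(gains, 7 * pop.event_counts)


def test_reproducibility_bit_exact():
    a = simulate_unitary(TractPopulation.founder(1000), TAIL, 50, seed=9)
    b = simulate_unitary(TractPopulation.founder(1000), TAIL, 50, seed=9)
    np.testing.assert_array_equal(a.repeats, b.repeats)
    c = simulate_periodic(TractPopulation.founder(1000), PeriodicParams(0.02), 50, seed=9)
    d = simulate_periodic(TractPopulation.founder(1000), PeriodicParams(0.02), 50, seed=9)
    np.testing.assert_array_equal(c.repeats, d.repeats)


def test_combined_degenerate_compositions():
    pop = TractPopulation.founder(2000)
    per = PeriodicParams(0.02)
    only_periodic = simulate_combined(pop, DriftParams(0.0, 0.0), per, 60, seed=4)
    pure_periodic = simulate_periodic(pop, per, 60, seed=4)
    np.testing.assert_array_equal(only_periodic.repeats, pure_periodic.repeats)
    np.testing.assert_array_equal(only_periodic.event_counts, pure_periodic.event_counts)

    only_unitary = simulate_combined(pop, TAIL, PeriodicParams(0.0), 60, seed=4)
    pure_unitary = simulate_unitary(pop, TAIL, 60, seed=4)
    np.testing.assert_array_equal(only_unitary.repeats, pure_unitary.repeats)


def test_pcr_identity_without_slippage():
    templates = TractPopulation(np.array([110, 119, 119, 125]))
    res = simulate_pcr(templates, cycles=8, slip_prob=0.0, dup_prob=0.7, seed=1)
    lengths, counts = np.unique(res.lengths, return_counts=True)
    # no new lengths can appear, and every template length survives
    assert set(lengths) == {110, 119, 125}
    assert counts[lengths == 119] > counts[lengths == 110]
    assert not res.subsampled
    assert res.scale_factor == 1.0


def test_pcr_variance_grows_with_slippage():
    templates = TractPopulation(np.full(50, 119))
    lo = simulate_pcr(templates, cycles=10, slip_prob=0.01, dup_prob=1.0, seed=2)
    hi = simulate_pcr(templates, cycles=10, slip_prob=0.10, dup_prob=1.0, seed=2)
    assert lo.lengths.var() < hi.lengths.var()
    assert abs(float(hi.lengths.mean()) - 119.0) < 0.5  # unbiased by default


def test_pcr_cap_and_resource_error():
    templates = TractPopulation(np.full(10, 119))
    res = simulate_pcr(templates, cycles=12, slip_prob=0.0, dup_prob=1.0,
                       seed=0, max_molecules=1000)
    assert res.n_molecules == 1000
    assert res.subsampled
    assert res.scale_factor > 1.0
    with pytest.raises(PCRResourceError):
        simulate_pcr(templates, cycles=12, slip_prob=0.0, dup_prob=1.0,
                     seed=0, max_molecules=1000, subsample=False)


def test_pcr_validation():
    templates = TractPopulation(np.full(4, 119))
    with pytest.raises(ValueError):
        simulate_pcr(templates, cycles=0)
    with pytest.raises(ValueError):
        simulate_pcr(templates, slip_prob=1.5)
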