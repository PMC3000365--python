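"""Synthetic electropherogram cohorts: the forward measurement model.

The analysis in this package inverts a measurement process (PCR + capillary
electrophoresis) that maps a population of integer tract lengths to a smooth
intensity curve.  This module implements that forward process so that cohorts
with known ground truth can be generated and the whole pipeline validated:

* each tract of length ``L`` contributes a Gaussian kernel at ``86 + 3 L`` bp
  whose width is the PCR broadening ``sigma(L) = c0 + c1 * L`` repeats
  (length-dependent, mildly increasing -- polymerase slippage grows with
  tract length),
* longer tracts amplify less efficiently: kernel weights decay by a constant
  factor per extra repeat,
* additive Gaussian noise, clipped at zero, models baseline fluctuation.

Default broadening is calibrated so that a founder-length (119-repeat) sample
measures sigma = 1.98 repeats, the 3-week tail value; the founder population
itself is monodisperse, so the measured 3-week width is attributed entirely
to the measurement process.  Cohort defaults mirror the study design:
founder ~119 repeats, ages 3/10/21 weeks, ~10,000 tracts per sample,
tail-like drift in tail/heart/lung/spleen, periodic 7-repeat insertion in
striatum (expanding fraction ~45%) and cortex (~20%), and combined dynamics
with a broad step distribution in liver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .driftmodel import DriftParams
from .simulator import (
    PeriodicParams,
    TractPopulation,
    simulate_combined,
    simulate_periodic,
    simulate_unitary,
)
from .traces import Trace, TraceMeta, size_from_repeats

__all__ = [
    "TraceRenderConfig",
    "TissueDynamics",
    "CohortConfig",
    "CohortSample",
    "Cohort",
    "render_trace",
    "generate_cohort",
    "mix_populations",
    "small_pool_subsample",
    "population_with_insertions",
    "zero_truncated_poisson",
    "default_tissue_dynamics",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: PCR broadening slope per repeat; c0 solved so sigma(119) = 1.98 repeats.
_DEFAULT_C1 = 0.005
_DEFAULT_C0 = 1.98 - _DEFAULT_C1 * 119


@dataclass(frozen=True)
class TraceRenderConfig:
    """Forward measurement model parameters.

    ``sigma(L) = sigma_c0 + sigma_c1 * L`` (repeats), ``attenuation`` is the
    relative amplification weight per extra repeat (1 = none), ``noise_sd``
    the additive intensity noise, ``grid_step`` the bp sampling density.
    """

    sigma_c0: float = _DEFAULT_C0
    sigma_c1: float = _DEFAULT_C1
    attenuation: float = 0.995
    noise_sd: float = 1.0
    grid_step: float = 0.5
    reference_repeats: int | None = None  # attenuation anchor; default min length
    area_scale: float = 10000.0  # total rendered area, intensity*bp

    def __post_init__(self):
        if not (0.0 < self.attenuation <= 1.0):
            raise ValueError("attenuation must lie in (0, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.area_scale <= 0:
            raise ValueError("area_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def sigma_repeats(self, repeats) -> np.ndarray | float:
        return self.sigma_c0 + self.sigma_c1 * np.asarray(repeats, dtype=float)


def render_trace(
    pop: TractPopulation,
    cfg: TraceRenderConfig = TraceRenderConfig(),
    seed: int = 0,
    meta: TraceMeta | None = None,
) -> Trace:
    """Render a tract population into an electropherogram trace.

    Kernel weights are normalised so the noiseless total area equals
    ``cfg.area_scale`` regardless of tract count: PCR amplifies every sample
    to a comparable plateau, so trace intensity does not scale with the
    number of template molecules.
    """
    if pop.n_tracts == 0:
        raise ValueError("population is empty")
    lengths, counts = np.unique(pop.repeats, return_counts=True)
    sig_rep = np.asarray(cfg.sigma_repeats(lengths), dtype=float)
    if np.any(sig_rep <= 0):
        raise ValueError("sigma(L) must be positive over the population support")
    ref = cfg.reference_repeats if cfg.reference_repeats is not None else lengths.min()
    weights = counts.astype(float) * cfg.attenuation ** (lengths - ref)
    weights *= cfg.area_scale / weights.sum()
    centers = size_from_repeats(lengths)
    sig_bp = 3.0 * sig_rep
    pad = 6.0 * float(sig_bp.max()) + cfg.grid_step
    grid = np.arange(centers.min() - pad, centers.max() + pad, cfg.grid_step)
    z = (grid[None, :] - centers[:, None]) / sig_bp[:, None]
    amps = weights / (sig_bp * _SQRT_2PI)
    intensity = np.sum(amps[:, None] * np.exp(-0.5 * z * z), axis=0)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=grid.size)
        np.clip(intensity, 0.0, None, out=intensity)
    return Trace(grid, intensity, meta=meta)


@dataclass(frozen=True)
class TissueDynamics:
    """Per-tissue instability model: drift and/or periodic insertion acting on
    the ``expanding_fraction`` of tracts (periodic only; drift acts on all)."""

    drift: DriftParams | None = None
    periodic: PeriodicParams | None = None
    expanding_fraction: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.expanding_fraction <= 1.0):
            raise ValueError("expanding_fraction must lie in [0, 1]")
        if self.drift is None and self.periodic is None:
            raise ValueError("tissue dynamics need a drift and/or periodic model")


def default_tissue_dynamics() -> dict[str, TissueDynamics]:
    """Study-condition defaults, one entry per sampled tissue.

    Tail-like tissues drift at the rates estimated from the tail cohort
    (p_e=0.0264, p_c=0.0099 per tract per day); striatum and cortex insert
    7-repeat segments at 0.018 events per expanding tract per day with
    expanding fractions of 45% and 20%; liver combines drift with a broad
    (uniform 3..12) insertion-length distribution.
    """
    tail_drift = DriftParams(0.026414, 0.009859)
    seven = PeriodicParams(0.018, {7: 1.0})
    broad = PeriodicParams(
        0.018, {s: 0.1 for s in range(3, 13)}
    )
    out = {t: TissueDynamics(drift=tail_drift) for t in ("tail", "heart", "lung", "spleen")}
    out["striatum"] = TissueDynamics(periodic=seven, expanding_fraction=0.45)
    out["cortex"] = TissueDynamics(periodic=seven, expanding_fraction=0.20)
    out["liver"] = TissueDynamics(drift=tail_drift, periodic=broad)
    return out


@dataclass(frozen=True)
class CohortConfig:
    n_mice: int = 42
    founder_repeats: int = 119
    ages: tuple[float, ...] = (3.0, 10.0, 21.0)
    n_tracts_per_sample: int = 10000
    tissues: Mapping[str, TissueDynamics] = field(default_factory=default_tissue_dynamics)
    render: TraceRenderConfig = field(default_factory=TraceRenderConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_mice < 1 or self.n_tracts_per_sample < 1:
            raise ValueError("n_mice and n_tracts_per_sample must be positive")
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("ages must be strictly increasing")
        from .traces import TISSUES

        bad = set(self.tissues) - TISSUES
        if bad:
            raise ValueError(f"unknown tissues in config: {sorted(bad)}")


@dataclass
class CohortSample:
    mouse: str
    tissue: str
    age_weeks: float
    trace: Trace
    population: TractPopulation  # ground truth


@dataclass
class Cohort:
    samples: list[CohortSample]
    config: CohortConfig

    def select(self, tissue: str | None = None, age_weeks: float | None = None):
        out = self.samples
        if tissue is not None:
            out = [s for s in out if s.tissue == tissue]
        if age_weeks is not None:
            out = [s for s in out if s.age_weeks == age_weeks]
        return out


def _evolve(
    pop: TractPopulation, dyn: TissueDynamics, days: int, rng: np.random.Generator
) -> TractPopulation:
    def child() -> int:
        return int(rng.integers(2**31))

    if dyn.periodic is not None:
        out = pop.copy()
        n = out.n_tracts
        n_exp = int(round(dyn.expanding_fraction * n))
        idx = rng.choice(n, size=n_exp, replace=False)
        sub = TractPopulation(out.repeats[idx], out.event_counts[idx])
        if dyn.drift is not None:
            sub = simulate_combined(sub, dyn.drift, dyn.periodic, days, child())
            rest_mask = np.ones(n, dtype=bool)
            rest_mask[idx] = False
            rest = TractPopulation(out.repeats[rest_mask], out.event_counts[rest_mask])
            rest = simulate_unitary(rest, dyn.drift, days, child())
            out.repeats[rest_mask] = rest.repeats
            out.event_counts[rest_mask] = rest.event_counts
        else:
            sub = simulate_periodic(sub, dyn.periodic, days, child())
        out.repeats[idx] = sub.repeats
        out.event_counts[idx] = sub.event_counts
        return out
    return simulate_unitary(pop, dyn.drift, days, child())


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a full multi-tissue, multi-age cohort with ground truth.

    Per mouse: a monodisperse founder population at ``founder_repeats``; the
    first age is sampled as the tail reference rendered from the founder
    population; each later age renders, per tissue, a copy of the founder
    population evolved by that tissue's dynamics for the elapsed days.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    def child() -> int:
        return int(rng.integers(2**31))

    samples: list[CohortSample] = []
    ref_age = cfg.ages[0]
    for m in range(cfg.n_mice):
        mouse = f"m{m:03d}"
        founder = TractPopulation.founder(cfg.n_tracts_per_sample, cfg.founder_repeats)
        meta = TraceMeta(mouse=mouse, tissue="tail", age_weeks=ref_age)
        samples.append(
            CohortSample(
                mouse,
                "tail",
                ref_age,
                render_trace(founder, cfg.render, seed=child(), meta=meta),
                founder,
            )
        )
        for age in cfg.ages[1:]:
            days = int(round((age - ref_age) * 7))
            for tissue, dyn in cfg.tissues.items():
                pop = _evolve(founder, dyn, days, rng)
                meta = TraceMeta(mouse=mouse, tissue=tissue, age_weeks=age)
                samples.append(
                    CohortSample(
                        mouse,
                        tissue,
                        age,
                        render_trace(pop, cfg.render, seed=child(), meta=meta),
                        pop,
                    )
                )
    return Cohort(samples, cfg)


def mix_populations(
    a: TractPopulation, b: TractPopulation, ratio: float
) -> TractPopulation:
    """Deterministic weighted concatenation: the first ``round(ratio * n)``
    tracts come from ``a``, the rest from ``b``; the total count equals
    ``a.n_tracts``."""
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must lie in [0, 1]")
    n = a.n_tracts
    k = int(round(ratio * n))
    if k > a.n_tracts or n - k > b.n_tracts:
        raise ValueError("populations too small for the requested mix")
    return TractPopulation(
        np.concatenate([a.repeats[:k], b.repeats[: n - k]]),
        np.concatenate([a.event_counts[:k], b.event_counts[: n - k]]),
    )


def small_pool_subsample(pop: TractPopulation, k: int, seed: int) -> TractPopulation:
    """Uniform sample of ``k`` tracts without replacement (a dilution step)."""
    if not (1 <= k <= pop.n_tracts):
        raise ValueError("k must lie in [1, n_tracts]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pop.n_tracts, size=k, replace=False)
    return TractPopulation(pop.repeats[idx], pop.event_counts[idx])


def zero_truncated_poisson(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    """Zero-truncated Poisson counts whose truncated mean equals ``mean``.

    Solves ``lam / (1 - exp(-lam)) = mean`` for the underlying rate, then
    redraws zeros.  Requires ``mean > 1``.
    """
    if mean <= 1.0:
        raise ValueError("the mean of a zero-truncated Poisson exceeds 1")
    lam = brentq(lambda x: x / (1.0 - math.exp(-x)) - mean, 1e-9, 10.0 * mean)
    out = rng.poisson(lam, size=size)
    while True:
        zero = out == 0
        nz = int(zero.sum())
        if nz == 0:
            return out
        out[zero] = rng.poisson(lam, size=nz)


def population_with_insertions(
    n_tracts: int,
    founder: int,
    expanding_fraction: float,
    mean_events: float,
    seed: int,
    step_pmf: Mapping[int, float] | None = None,
) -> TractPopulation:
    """Directly construct a periodically expanded population: a founder-length
    core plus an expanding subset whose per-tract event counts are
    zero-truncated Poisson with the given mean, each event inserting a length
    drawn from ``step_pmf`` (default: point mass at 7)."""
    if not (0.0 <= expanding_fraction <= 1.0):
        raise ValueError("expanding_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    params = PeriodicParams(0.0, step_pmf or {7: 1.0})
    n_exp = int(round(expanding_fraction * n_tracts))
    repeats = np.full(n_tracts, founder, dtype=np.int64)
    events = np.zeros(n_tracts, dtype=np.int64)
    if n_exp:
        counts = zero_truncated_poisson(rng, mean_events, n_exp)
        total = int(counts.sum())
        steps = rng.choice(params._steps, size=total, p=params._probs)
        gains = np.zeros(n_exp, dtype=np.int64)
        np.add.at(gains, np.repeat(np.arange(n_exp), counts), steps)
        repeats[:n_exp] += gains
        events[:n_exp] = counts
    return TractPopulation(repeats, events)
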