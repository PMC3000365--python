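"""Forward Monte Carlo engines for repeat-tract populations.

Four stochastic processes are simulated over a population of integer CAG
tract lengths, all with a one-day time step and independent tracts:

* the unitary +/-1 random walk (tail-type drift),
* the periodic insertion process (striatum/cortex-type: with a small daily
  probability a tract gains one ~7-repeat segment; insertions only, since the
  data show no periodically spaced peaks below the founder length),
* their combination (liver-type / model-contrast runs), and
* an error-prone PCR branching process (template doubling with per-daughter
  +/-1 slippage), used to separate amplification artefacts from biology.

Seeding discipline: every engine derives two independent child streams (one
for the unitary branch, one for the periodic branch) from the given integer
seed, so a combined run with one process zeroed is bit-identical to the
corresponding single-process run under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .driftmodel import DriftParams

__all__ = [
    "TractPopulation",
    "PeriodicParams",
    "PCRResult",
    "PCRResourceError",
    "simulate_unitary",
    "simulate_periodic",
    "simulate_combined",
    "simulate_pcr",
    "triangular_step_pmf",
]


@dataclass
class TractPopulation:
    """Integer CAG counts for a sample of DNA tracts, plus per-tract tallies
    of periodic insertion events."""

    repeats: np.ndarray
    event_counts: np.ndarray | None = None

    def __post_init__(self):
        self.repeats = np.asarray(self.repeats, dtype=np.int64)
        if self.repeats.ndim != 1:
            raise ValueError("repeats must be 1-D")
        if np.any(self.repeats < 0):
            raise ValueError("repeat counts must be non-negative")
        if self.event_counts is None:
            self.event_counts = np.zeros_like(self.repeats)
        else:
            self.event_counts = np.asarray(self.event_counts, dtype=np.int64)
            if self.event_counts.shape != self.repeats.shape:
                raise ValueError("event_counts must match repeats in length")
            if np.any(self.event_counts < 0):
                raise ValueError("event_counts must be non-negative")

    @classmethod
    def founder(cls, n_tracts: int, repeats: int = 119) -> "TractPopulation":
        """A homogeneous population at the founder length."""
        return cls(np.full(n_tracts, repeats, dtype=np.int64))

    @property
    def n_tracts(self) -> int:
        return int(self.repeats.size)

    def copy(self) -> "TractPopulation":
        return TractPopulation(self.repeats.copy(), self.event_counts.copy())


def triangular_step_pmf(lo: int = 5, hi: int = 9, mode: int = 7) -> dict[int, float]:
    """Discrete triangular pmf over insertion lengths (default support 5..9)."""
    steps = np.arange(lo, hi + 1)
    w = np.minimum(steps - lo + 1, hi - steps + 1).astype(float)
    w /= w.sum()
    return {int(s): float(p) for s, p in zip(steps, w)}


@dataclass(frozen=True)
class PeriodicParams:
    """Daily insertion probability and the pmf over insertion lengths."""

    event_prob: float
    step_pmf: Mapping[int, float] = field(default_factory=lambda: {7: 1.0})

    def __post_init__(self):
        if not (0.0 <= self.event_prob <= 1.0):
            raise ValueError("event_prob must lie in [0, 1]")
        steps = np.array(sorted(self.step_pmf), dtype=np.int64)
        probs = np.array([self.step_pmf[int(s)] for s in steps], dtype=float)
        if steps.size == 0 or np.any(steps <= 0):
            raise ValueError("step_pmf must be over positive integers")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValueError("step_pmf probabilities must be non-negative, sum to 1")
        object.__setattr__(self, "_steps", steps)
        object.__setattr__(self, "_probs", probs / probs.sum())

    @property
    def mean_step(self) -> float:
        return float(np.dot(self._steps, self._probs))


def _rng_pair(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    a, b = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(a), np.random.default_rng(b)


def _check_days(days) -> int:
    if days < 0 or int(days) != days:
        raise ValueError("days must be a non-negative integer")
    return int(days)


def simulate_unitary(
    pop: TractPopulation,
    params: DriftParams,
    days: int,
    seed: int,
    mode: Literal["per_tract", "aggregate"] = "per_tract",
) -> TractPopulation:
    """Daily +/-1 Bernoulli walk: each tract each day independently gains one
    repeat with probability ``p_e``, loses one with probability ``p_c``, else
    stays put (mutually exclusive outcomes); lengths are floored at zero.

    ``aggregate`` draws each tract's day-outcome counts as one multinomial
    (identical final-state distribution, no per-day trajectories).
    """
    days = _check_days(days)
    rng_u, _ = _rng_pair(seed)
    out = pop.copy()
    n = out.n_tracts
    p_e, p_c = params.p_e, params.p_c
    if days == 0 or params.total_rate == 0:
        return out
    if mode == "per_tract":
        r = out.repeats
        for _ in range(days):
            u = rng_u.random(n)
            r += (u < p_e).astype(np.int64)
            r -= ((u >= p_e) & (u < p_e + p_c)).astype(np.int64)
            np.maximum(r, 0, out=r)
    elif mode == "aggregate":
        draws = rng_u.multinomial(days, [p_e, p_c, 1.0 - p_e - p_c], size=n)
        out.repeats = np.maximum(out.repeats + draws[:, 0] - draws[:, 1], 0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def simulate_periodic(
    pop: TractPopulation, params: PeriodicParams, days: int, seed: int
) -> TractPopulation:
    """Daily insertion process: with probability ``event_prob`` a tract gains
    one segment of length drawn from ``step_pmf``; ``event_counts`` tally the
    events.  There is no contraction branch."""
    days = _check_days(days)
    _, rng_p = _rng_pair(seed)
    out = pop.copy()
    _periodic_days(out, params, days, rng_p)
    return out


def _periodic_days(
    pop: TractPopulation, params: PeriodicParams, days: int, rng: np.random.Generator
) -> None:
    if days == 0 or params.event_prob == 0:
        return
    n = pop.n_tracts
    steps, probs = params._steps, params._probs
    for _ in range(days):
        hit = rng.random(n) < params.event_prob
        k = int(hit.sum())
        if k == 0:
            continue
        ins = rng.choice(steps, size=k, p=probs)
        pop.repeats[hit] += ins
        pop.event_counts[hit] += 1


def simulate_combined(
    pop: TractPopulation,
    unitary: DriftParams,
    periodic: PeriodicParams,
    days: int,
    seed: int,
) -> TractPopulation:
    """Apply the unitary walk and the periodic insertion process each day,
    independently, to every tract.  With either process zeroed this is
    bit-identical to the corresponding single-process engine."""
    days = _check_days(days)
    rng_u, rng_p = _rng_pair(seed)
    out = pop.copy()
    n = out.n_tracts
    p_e, p_c = unitary.p_e, unitary.p_c
    steps, probs = periodic._steps, periodic._probs
    r = out.repeats
    for _ in range(days):
        if unitary.total_rate > 0:
            u = rng_u.random(n)
            r += (u < p_e).astype(np.int64)
            r -= ((u >= p_e) & (u < p_e + p_c)).astype(np.int64)
            np.maximum(r, 0, out=r)
        if periodic.event_prob > 0:
            hit = rng_p.random(n) < periodic.event_prob
            k = int(hit.sum())
            if k:
                ins = rng_p.choice(steps, size=k, p=probs)
                r[hit] += ins
                out.event_counts[hit] += 1
    return out


class PCRResourceError(RuntimeError):
    """Branching population exceeded the cap with subsampling disabled."""


@dataclass
class PCRResult:
    """Final molecule-length multiset of a branching PCR simulation."""

    lengths: np.ndarray
    subsampled: bool
    scale_factor: float  # estimated true molecule count = len(lengths) * factor

    @property
    def n_molecules(self) -> int:
        return int(self.lengths.size)


def simulate_pcr(
    templates: TractPopulation,
    cycles: int = 35,
    slip_prob: float = 0.0,
    dup_prob: float = 0.9,
    seed: int = 0,
    up_bias: float = 0.5,
    max_molecules: int = 1_000_000,
    subsample: bool = True,
) -> PCRResult:
    """Error-prone PCR as a branching process.

    Each cycle every molecule duplicates with probability ``dup_prob``; each
    daughter independently suffers a +/-1 repeat slip with probability
    ``slip_prob`` (sign up with probability ``up_bias``).  When the population
    exceeds ``max_molecules`` it is uniformly subsampled (recorded in the
    result) unless ``subsample`` is disabled, in which case
    :class:`PCRResourceError` is raised.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    for name, p in (("slip_prob", slip_prob), ("dup_prob", dup_prob), ("up_bias", up_bias)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = templates.repeats.astype(np.int64).copy()
    scale = 1.0
    subsampled = False
    for _ in range(cycles):
        dup = rng.random(lengths.size) < dup_prob
        daughters = lengths[dup].copy()
        if slip_prob > 0 and daughters.size:
            slip = rng.random(daughters.size) < slip_prob
            ns = int(slip.sum())
            if ns:
                delta = np.where(rng.random(ns) < up_bias, 1, -1)
                daughters[slip] = np.maximum(daughters[slip] + delta, 0)
        lengths = np.concatenate([lengths, daughters])
        if lengths.size > max_molecules:
            if not subsample:
                raise PCRResourceError(
                    f"population of {lengths.size} exceeds cap {max_molecules}"
                )
            idx = rng.choice(lengths.size, size=max_molecules, replace=False)
            scale *= lengths.size / max_molecules
            lengths = lengths[idx]
            subsampled = True
    return PCRResult(lengths, subsampled, scale)
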