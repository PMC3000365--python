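# Methods

## Measurement model

A sample holds ~10,000 DNA tracts; PCR amplification and capillary
electrophoresis map them to an intensity curve over called fragment size.
The forward model (`synthcohort.render_trace`) places, for each tract of `L`
repeats, a Gaussian kernel at `86 + 3 L` bp whose width is the PCR broadening

```
sigma(L) = c0 + c1 * L      (repeats; defaults c1 = 0.005, c0 = 1.385)
```

calibrated so a monodisperse founder sample (119 repeats) measures
sigma = 1.98 repeats — the 3-week tail width, which is attributed entirely to
measurement because the tract population at that age is taken as
monodisperse.  Kernel weights decay by a constant `attenuation` factor per
extra repeat (longer templates amplify less efficiently; default 0.995, and
1.0 in the closed-loop validation runs so that area shares equal tract
shares exactly).  The curve is normalised to a fixed total area
(`area_scale`, default 10,000 intensity·bp) regardless of tract count,
because PCR drives every sample to a comparable plateau; additive Gaussian
noise (sd 1.0) is clipped at zero.  Grid step: 0.5 bp.

Limits of generator realism: no stutter side-products, no baseline slope or
size-calling nonlinearity, Gaussian (not skewed) kernels, noise independent
of signal level.  These omissions make synthetic traces somewhat cleaner
than instrument output; tolerances in the closed-loop tests absorb the
difference between fitted and generator parameters, not instrument error.

## Unitary drift model

Each tract independently gains one repeat with daily probability `p_e` and
loses one with `p_c` (mutually exclusive).  First two moments after `t` days:

```
mu(t)      = mu(0) + (p_e - p_c) t
sigma^2(t) = sigma^2(0) + (p_e + p_c) t
```

The variance expression drops the exact per-step term `-(p_e - p_c)^2`
(~1% of the retained term at these rates); the simulator realises the exact
walk, the estimator inverts the approximate moments — the closed-loop tests
confirm the discrepancy is well inside tolerance.  Inversion of the tail
statistics (Δmu = 1.97, sigma 1.98 → 2.87, T = 119 d) gives
`p_e = 0.026414`, `p_c = 0.009859`; these unrounded values parameterise all
tail-type simulations.  Genome-wide scaling multiplies a per-tract rate by
2.5×10⁹ / 360 (the ~360 nt tract as a representative genomic segment),
giving ~252,000 unitary events per cell per day for the summed rate.

A single Gaussian fitted by least squares to a rendered walk distribution
carries a small negative bias in the mean (~0.06 repeats here) because the
walk density is positively skewed while the model is symmetric.  The
estimator used on the real data shares this bias, so the closed loop
reproduces the printed statistics within tolerance without correcting it.

## Periodic expansion model

With daily probability `event_prob` a tract gains one segment of
`step_pmf`-distributed length (default: point mass at 7 repeats); there is no
periodic contraction branch.  Day-granularity Bernoulli steps are used for
both processes; in combined runs the unitary and periodic steps are applied
independently every day.  Seeding derives two independent child streams from
one integer seed so that a combined run with either process zeroed is
bit-identical to the corresponding single-process run.

## Peak decomposition

Traces are decomposed into consecutive normal components by a masked,
derivative-free scheme:

1. locate the tallest residual lobe (on a 5-point moving average; ties break
   toward lower bp);
2. estimate its window by walking outward until the curve clearly rises again
   (valley) or decays below 1% of the apex; estimate sigma from the width at
   the level actually crossed — at least half maximum, or midway between apex
   and the valley floor when overlap keeps the valley above half maximum —
   converted by the Gaussian decay relation `sigma = width / sqrt(2 ln(apex/L))`;
3. fit one Gaussian by Nelder–Mead on the windowed residual (simplex steps
   scaled to the problem: sub-bp in the mean, ~10% in log sigma and log
   amplitude; fits wider than twice the lobe span are rejected as
   degenerate);
4. subtract and repeat until the model both accounts for ≥ 98% of the
   trapezoidal trace area **and** leaves ≤ 2% as unexplained positive
   residual — the area ratio alone is blind to an over-soaked window
   compensating a missed lobe;
5. polish all parameters with one joint Nelder–Mead pass, trust-bounded
   around the greedy structure (mean within ±2 sigma, sigma within ~×1.5,
   amplitude within ×2, via a tanh reparametrisation).  Structure discovery
   belongs to the greedy phase: an unbounded joint step can reach lower
   squared error by broadening one component into a catch-all for sub-1%
   tail mass, which is not a peak in the instrument's sense;
6. drop components below 1% of the fitted area and re-polish.

The schedule is deterministic for a given trace and seed.  Peak
resolvability — used for the model-contrast experiment — is the fraction of
adjacent fitted peak pairs separated by more than twice the pooled
(area-weighted RMS) sigma of the decomposition.

## Periodicity estimators

Peak-to-peak intervals are fitted-mean differences in repeats, pooled over
samples; intervals ≥ 12 repeats are excluded as two unresolved consecutive
steps (a halve-as-two-steps mode exists behind a flag).  Fitted areas are
rescaled to the ~10,000 tracts per sample; the insertion index `k` is ordinal
from the founder peak (with a consistency warning when spacings deviate > 50%
from the modal spacing; a spacing-based assignment mode is provided).  The
non-expanding fraction is the first-peak area share; total insertions are
`sum_k k * counts_k`; the per-tract per-day event rate divides by the
expanding-tract count by convention, with the all-tract variant reported for
transparency.  Interval sd uses the sample convention (ddof = 1).

## Key default parameters

| quantity | value |
| --- | --- |
| founder length | 119 repeats (443 bp amplicon) |
| flank / repeat size | 86 bp / 3 bp |
| tail drift | p_e 0.026414, p_c 0.009859 per tract per day |
| periodic step | 7 repeats (point mass) |
| brain event rate | 0.018 per expanding tract per day |
| expanding fraction | 0.45 striatum, 0.20 cortex |
| elapsed time | 119 d (tail, 3→20 wk biopsy) / 126 d (brain, 3→21 wk) |
| measurement sigma | 1.98 repeats at founder length |
| doublet cutoff | 12 repeats |
| decomposition stop | ≥ 98% area explained, ≤ 2% positive residual |

## Numerical notes

* Nelder–Mead is used throughout (the objective is smooth but cheap and
  low-dimensional; derivative-free keeps the masked/greedy scheme simple).
  Initial simplexes are always constructed explicitly: the library default of
  perturbing coordinates by 5% would move a ~500 bp mean across neighbouring
  peaks.
* Sigma and amplitude are optimised in log space to keep them positive.
* The zero-truncated Poisson used by the direct cohort constructor solves
  `lam / (1 - exp(-lam)) = mean` by Brent's method, then redraws zeros.
* All engines take integer seeds; identical seeds give bit-identical output.
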