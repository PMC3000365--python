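#!/usr/bin/env python
"""Why the brain peaks must come from large quantised steps.

Contrast experiment: evolve 20,000 cells for 126 days under (a) the pure
7-repeat insertion process and (b) the same process plus tail-level unitary
noise, render both, decompose, and score the peak-resolvability metric
(fraction of adjacent fitted peaks separated by more than twice the pooled
width).  If the unitary walk ran at tail rates in brain, the regularly spaced
peaks could not survive; they stay crisp only when the continuous component is
far weaker.
"""

from pathlib import Path

import numpy as np

from repeatdyn import (
    DriftParams,
    PeriodicParams,
    TraceRenderConfig,
    TractPopulation,
    decompose,
    peak_resolvability,
    render_trace,
    simulate_combined,
    simulate_periodic,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "04_model_contrast.txt"
RENDER = TraceRenderConfig(attenuation=1.0)
N, DAYS, PROB = 20_000, 126, 0.018
TAIL = DriftParams(0.026414, 0.009859)
QUARTER = DriftParams(TAIL.p_e / 4, TAIL.p_c / 4)
SEEDS = (50, 51, 52, 53, 54)


def score(drift: DriftParams | None) -> list[float]:
    out = []
    for s in SEEDS:
        founder = TractPopulation.founder(N)
        if drift is None:
            pop = simulate_periodic(founder, PeriodicParams(PROB), DAYS, s)
        else:
            pop = simulate_combined(founder, drift, PeriodicParams(PROB), DAYS, s)
        dec = decompose(render_trace(pop, RENDER, seed=s + 1000))
        out.append(peak_resolvability(dec))
    return out


def main() -> None:
    lines = []
    for label, drift in (
        ("pure_periodic", None),
        ("quarter_tail_unitary", QUARTER),
        ("full_tail_unitary", TAIL),
    ):
        r = score(drift)
        lines.append(
            f"{label}: mean_resolvability={np.mean(r):.2f} "
            f"per_seed={[round(v, 2) for v in r]}"
        )
    OUT.parent.mkdir(exist_ok=True)
    OUT.write_text("\n".join(lines) + "\n")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
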