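#!/usr/bin/env python
"""Quantify interface-mediated coarsening across condensation cycles.

Ten simulated cells with merge-on-dissolution enabled, and ten with it
disabled, are analysed at the first frame of each condensation cycle: mean
area of small (< 5 um^2) aggregates per cycle, averaged across cells.
With merging the mean grows monotonically (coarsening); without it the
slope is statistically indistinguishable from zero.
"""

from pathlib import Path

import numpy as np
from scipy import stats

from condenstat import SimParams, cycle_coarsening, cycle_report, simulate_cell
from condenstat import io as cio

RESULTS = Path("results")
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    for label, merge in (("merge_on", True), ("merge_off", False)):
        per_cell = []
        n_monotone = 0
        for seed in range(10):
            stack, roi, _ = simulate_cell(SimParams(seed=seed, merge_on_dissolution=merge))
            rep = cycle_coarsening(stack, roi)
            per_cell.append(rep)
            n_monotone += bool(np.all(np.diff(rep.mean_small_area_um2) >= 0))
        out = cycle_report(per_cell)
        cio.write_results(out, RESULTS / f"cycles_{label}.csv")
        y = np.concatenate([r.mean_small_area_um2.to_numpy() for r in per_cell])
        x = np.tile(np.arange(1, 5), 10)
        res = stats.linregress(x, y)
        print(f"{label}: cycle means "
              f"{np.round(out.mean_small_area_um2.to_numpy(), 3).tolist()} um^2, "
              f"monotone {n_monotone}/10, slope {res.slope:.4f} "
              f"+- {res.stderr:.4f} um^2/cycle")


if __name__ == "__main__":
    main()
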