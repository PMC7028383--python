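#!/usr/bin/env python
"""Photon budget for reliable calcium-transient detection.

Computes the baseline photon rate a GCaMP6s-expressing neuron must deliver
for a given discriminability d', the detection operating points, the penalty
imposed by out-of-focus background, and the photon-counting pile-up error
budget.  Writes results/photon_budget.csv and prints the headline numbers.
"""

import pathlib

import numpy as np
import pandas as pd

from mpcalcium import fidelity as fi
from mpcalcium.fidelity import GCAMP6S

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    for d in (1.0, 2.0, 3.0, 4.0):
        for sbr in (np.inf, 2.0, 1.0):
            f0 = fi.min_baseline_rate(GCAMP6S, d, sbr)
            tpr, fpr = fi.detection_rates(d)
            rows.append(
                {
                    "d_prime": d,
                    "sbr": sbr,
                    "f0_required_photons_per_s": f0,
                    "true_positive_rate": tpr,
                    "false_positive_rate": fpr,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "photon_budget.csv", index=False)

    f0_3 = fi.min_baseline_rate(GCAMP6S, 3.0)
    tpr, fpr = fi.detection_rates(3.0)
    print(f"GCaMP6s (dF/F 0.30, tau 2 s), background-free:")
    print(f"  d'=3 requires F0 = {f0_3:.0f} photons/s "
          f"-> {tpr:.1%} true / {fpr:.1%} false positives")
    print(f"  at SBR=1 the same budget yields d' = "
          f"{fi.dprime(GCAMP6S, f0_3, 1.0):.2f} (reduction x{2**0.5:.2f})")
    lam = 0.05
    print(f"  photon counting at 5% of the rep rate undercounts by "
          f"{100 * fi.stacking_error(lam):.2f}% (<= 2.5%)")
    print(f"wrote {OUT / 'photon_budget.csv'}")


if __name__ == "__main__":
    main()
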