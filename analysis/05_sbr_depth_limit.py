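#!/usr/bin/env python
"""Signal-to-background ratio versus depth for 2PE and 3PE.

Evaluates the theoretical SBR profiles at χ = 50 (≈2% labeled volume), finds
the two-photon depth limit where SBR = 1, and closes the loop on synthetic
vasculature stacks: Otsu staining segmentation recovers the volume fraction
and the brightest-percentile SBR measurement tracks the imposed profile.
Writes results/sbr_vs_depth.csv.
"""

import pathlib

import numpy as np
import pandas as pd

from mpcalcium import sbr_model as sm
from mpcalcium import synthetic_data as sd

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    staining = sm.StainingModel(chi=50)
    depths = np.linspace(0.5, 7.0, 27)
    p2 = sm.sbr_vs_depth(2, staining, depths, wavelength_nm=920.0)
    p3 = sm.sbr_vs_depth(3, staining, depths, wavelength_nm=1320.0)
    pd.DataFrame(
        {"depth_eals": depths, "sbr_2p_920": p2.sbr, "sbr_3p_1320": p3.sbr}
    ).to_csv(OUT / "sbr_vs_depth.csv", index=False)

    limit = sm.sbr_depth_limit(2, staining, wavelength_nm=920.0)
    print(f"2PE SBR = 1 at {limit:.2f} EALs for chi = 50 "
          f"({limit * 154:.0f} um at EAL 154 um)")
    print(f"shallow (0.5 EAL) SBR: 2PE {p2.sbr[0]:.0f}, 3PE {p3.sbr[0]:.0f}")
    print(f"apparent dF/F at SBR=1: {sm.apparent_dff(0.30, 1.0):.2f} "
          f"(half of the true 0.30)")

    stack, mask = sd.gen_stack(sd.StackSpec(seed=42))
    est = sm.estimate_staining(stack)
    meas = sm.measure_sbr(stack, background_mask=~mask.any(axis=0))
    print(f"synthetic stack: labeled fraction {est.volume_fraction:.3f} "
          f"(target 0.02), chi {est.chi:.0f}; "
          f"measured SBR falls {meas.sbr[0]:.0f} -> {meas.sbr[-1]:.0f} over the stack")
    print(f"wrote {OUT / 'sbr_vs_depth.csv'}")


if __name__ == "__main__":
    main()
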