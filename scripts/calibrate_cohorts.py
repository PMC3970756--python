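#!/usr/bin/env python
"""Recompute the calibration behind the synthetic-cohort defaults.

Prints the tipping boundary gbar_Na(gbar_K) of the reference cell, the
add-Na distances implied by the default cohort medians, and the injury
magnitude that lands the median injured muscle cell on its boundary.
Run this after changing model parameters to re-derive the constants in
``afferentsim.population``.
"""

import numpy as np

from afferentsim import reference_model
from afferentsim.experiments import local_boundary_gNa
from afferentsim.population import (
    CUTANEOUS_GK_MEDIAN,
    MUSCLE_GK_MEDIAN,
    NAIVE_GNA_MEDIAN,
    InjurySpec,
)


def main() -> None:
    template = reference_model("normal")
    print("tipping boundary gNa(gK), mS/cm^2:")
    boundary = {}
    for gK in (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0):
        b = local_boundary_gNa(template, gK)
        boundary[gK] = b
        print(f"  gK = {gK:4.2f}  ->  gNa* = {b:.3f}")

    C = template.core.C
    for name, gK in (("cutaneous", CUTANEOUS_GK_MEDIAN), ("muscle", MUSCLE_GK_MEDIAN)):
        b = local_boundary_gNa(template, gK)
        dist = b - NAIVE_GNA_MEDIAN
        print(
            f"{name}: median (gNa, gK) = ({NAIVE_GNA_MEDIAN}, {gK}), "
            f"add-Na distance = {dist:.3f} mS/cm^2 = {dist / C:.3f} nS/pF"
        )

    injury = InjurySpec()
    gK_after = MUSCLE_GK_MEDIAN * (1.0 - injury.k_loss.median)
    b_after = local_boundary_gNa(template, gK_after)
    gNa_after = NAIVE_GNA_MEDIAN + injury.na_gain_nS_pF.median * C
    print(
        f"median injured muscle cell: (gNa, gK) = ({gNa_after:.3f}, {gK_after:.3f}); "
        f"boundary gNa* = {b_after:.3f} "
        f"(margin {gNa_after - b_after:+.3f} mS/cm^2; ~0 means half the cohort converts)"
    )


if __name__ == "__main__":
    main()
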