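#!/usr/bin/env python
"""Gating-charge extraction from slab-model energy-voltage curves.

Builds a synthetic residue set whose closed-form charge displacement sums
to -0.7 e (the reference total for the inward-to-outward transition),
predicts the linear energy-voltage curves, fits the total and per-residue
gating charges back (with and without noise) and ranks the contributors
against the 0.1 e reporting threshold.
"""
import numpy as np

from vsglt.gating_charge import (
    ChargeSite, field_fraction, fit_gating_charge, per_residue_contributions,
    predict_energy_curves,
)
from vsglt.io import write_results
from vsglt.synthetic import SyntheticSpec, gen_energy_curves

# synthetic stand-in site set: dominant contributors plus minor ones,
# engineered to displace -0.7 e in total across the slab field
SITES = [
    ChargeSite("R273", +1.0, -9.0, -15.0),
    ChargeSite("K471", +1.0, 10.5, 6.0),
    ChargeSite("E68", -1.0, -3.0, 0.6),
    ChargeSite("E88", -1.0, 1.0, 4.0),
    ChargeSite("D189", -1.0, -2.0, 0.4),
    ChargeSite("minor1", -0.5, 0.0, 3.0),
    ChargeSite("minor2", +0.5, 2.0, 2.6),
    ChargeSite("minor3", -0.5, 5.0, 5.6),
]


def main() -> None:
    truth = sum(s.charge_e * (field_fraction(s.z_of) - field_fraction(s.z_if))
                for s in SITES)
    clean = fit_gating_charge(predict_energy_curves(SITES))
    print(f"noiseless fit: q_total = {clean.q_total_e:.6f} e "
          f"(closed form {truth:.6f} e, R^2 = {clean.fit_r2:.6f})")

    recovered = [
        fit_gating_charge(gen_energy_curves(SyntheticSpec(seed=s), SITES)[0]).q_total_e
        for s in range(200)
    ]
    print(f"noisy recovery (1% of span, 200 seeds): "
          f"{np.mean(recovered):.4f} +- {np.std(recovered):.4f} e")

    table = per_residue_contributions(clean, threshold_e=0.1)
    flagged = table.loc[table["flagged"], "residue_id"].tolist()
    print(f"residues contributing >= 0.1 e: {flagged}")
    write_results(table, "results/gating_charge_contributions.csv", fmt="csv",
                  config={"stage": "gating_charge", "threshold_e": 0.1})
    print("wrote results/gating_charge_contributions.csv")


if __name__ == "__main__":
    main()
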