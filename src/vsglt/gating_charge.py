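"""Gating-charge extraction from energy-versus-voltage curves.

The voltage-dependent part of the electrostatic free energy of a membrane
protein conformation is the sum over its charges of charge times local
potential.  Here the potential profile across the membrane is a linear slab
ramp: with the membrane-normal coordinate z increasing toward the
extracellular face, the field fraction f(z) rises linearly from 0 at the
intracellular boundary (z_low) to 1 at the extracellular boundary (z_high),
and the local potential is phi(z) = V * (1 - f(z)) for an applied potential
V (inside minus outside, extracellular bath grounded).

For the transition from the inward-facing (IF) to the outward-facing (OF)
conformation, the energy difference is then exactly linear in voltage,

    dW(V) = W_OF - W_IF = -V * sum_i q_i * (f(z_of,i) - f(z_if,i)),

and the total gating charge is recovered from the slope of an ordinary
least-squares line: q_total = sum_i q_i * df_i = -slope.  With this
convention a negative q_total means that a negative membrane potential
lowers the energy of the outward-facing state — the behaviour reported for
vSGLT, whose calculated gating charge is about -0.7 e.

The slab ramp is a desk-scale surrogate for a continuum-electrostatics
potential profile; externally computed dW(V) tables can be fed directly to
:func:`fit_gating_charge` for real-structure work.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChargeSite",
    "EnergyVoltageCurve",
    "GatingChargeResult",
    "field_fraction",
    "predict_energy_curves",
    "fit_gating_charge",
    "per_residue_contributions",
    "DEFAULT_VOLTAGES",
]

#: default voltage series: 11 points spanning +-150 mV
DEFAULT_VOLTAGES: np.ndarray = np.linspace(-0.150, 0.150, 11)


@dataclass(frozen=True)
class ChargeSite:
    """A charged residue with membrane-normal positions in the two conformations.

    ``z_if`` / ``z_of`` are the coordinates (angstrom) in the inward- and
    outward-facing states; z increases toward the extracellular side.
    """

    residue_id: str
    charge_e: float
    z_if: float
    z_of: float

    def __post_init__(self) -> None:
        for name in ("charge_e", "z_if", "z_of"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} of site {self.residue_id!r} must be finite")


@dataclass(frozen=True)
class EnergyVoltageCurve:
    """OF-minus-IF energy difference (e*V units) over a voltage series."""

    voltages: np.ndarray
    delta_energy: np.ndarray
    per_residue: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        w = np.asarray(self.delta_energy, dtype=float)
        if v.shape != w.shape or v.ndim != 1:
            raise ValueError("voltages and delta_energy must be equal-length 1-D arrays")
        if v.size < 3:
            raise ValueError("need at least 3 voltage points for fitting")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "delta_energy", w)
        if self.per_residue is not None:
            pr = {k: np.asarray(a, dtype=float) for k, a in self.per_residue.items()}
            for k, a in pr.items():
                if a.shape != v.shape:
                    raise ValueError(f"per-residue curve {k!r} length mismatch")
            object.__setattr__(self, "per_residue", pr)


@dataclass(frozen=True)
class GatingChargeResult:
    """Fitted gating charge, per-residue decomposition and fit quality."""

    q_total_e: float
    intercept: float
    fit_r2: float
    per_residue: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_residue:
            total = sum(self.per_residue.values())
            if abs(total - self.q_total_e) > 1e-6:
                raise ValueError(
                    f"per-residue contributions sum to {total}, expected {self.q_total_e}"
                )


def field_fraction(z, z_low: float = -15.0, z_high: float = 15.0):
    """Fraction of the transmembrane field crossed at coordinate z (angstrom).

    0 below ``z_low`` (intracellular boundary), 1 above ``z_high``
    (extracellular boundary), linear ramp inside; continuous everywhere.
    Accepts scalars or arrays.
    """
    if not z_low < z_high:
        raise ValueError("z_low must be below z_high")
    frac = np.clip((np.asarray(z, dtype=float) - z_low) / (z_high - z_low), 0.0, 1.0)
    return float(frac) if np.isscalar(z) else frac


def predict_energy_curves(
    sites: Sequence[ChargeSite],
    voltages: Sequence[float] | None = None,
    z_low: float = -15.0,
    z_high: float = 15.0,
) -> EnergyVoltageCurve:
    """Slab-model OF-minus-IF energy difference, exactly linear in voltage.

    dW(V) = -V * sum_i q_i * (f(z_of,i) - f(z_if,i)), with one per-residue
    curve per site (duplicated residue ids are summed).
    """
    if len(sites) == 0:
        raise ValueError("need at least one charge site")
    volts = DEFAULT_VOLTAGES if voltages is None else np.asarray(voltages, dtype=float)
    per_residue: dict[str, np.ndarray] = {}
    total = np.zeros_like(volts)
    for site in sites:
        df = field_fraction(site.z_of, z_low, z_high) - field_fraction(site.z_if, z_low, z_high)
        curve = -volts * site.charge_e * df
        per_residue[site.residue_id] = per_residue.get(site.residue_id, 0.0) + curve
        total = total + curve
    return EnergyVoltageCurve(voltages=volts, delta_energy=total, per_residue=per_residue)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2 (R^2 = 1 for an exact fit)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_gating_charge(curve: EnergyVoltageCurve) -> GatingChargeResult:
    """Extract the gating charge from the slope of the energy-voltage line.

    Returns q_total = -slope of dW(V): the charge displaced during the
    IF->OF transition, negative when a negative potential lowers the
    outward-facing state's energy.  Per-residue contributions are fitted the
    same way when per-residue curves are present and sum to the total.
    """
    v = curve.voltages
    if np.ptp(v) == 0.0:
        raise ValueError("all voltages identical; slope is undefined")
    slope, intercept, r2 = _ols_line(v, curve.delta_energy)
    per_residue: dict[str, float] = {}
    if curve.per_residue is not None:
        for rid, w in curve.per_residue.items():
            s, _, _ = _ols_line(v, w)
            per_residue[rid] = -s
        # absorb rounding so the decomposition sums exactly to the total
        gap = -slope - sum(per_residue.values())
        if abs(gap) > 1e-6:
            raise ValueError(
                f"per-residue slopes sum to {sum(per_residue.values())}, "
                f"inconsistent with total {-slope} (gap {gap:.3g})"
            )
    return GatingChargeResult(q_total_e=-slope, intercept=intercept, fit_r2=r2,
                              per_residue=per_residue)


def per_residue_contributions(
    result: GatingChargeResult, threshold_e: float = 0.1
) -> pd.DataFrame:
    """Rank residues by |contribution|, flagging those at or above ``threshold_e``.

    Mirrors the published residue/contribution layout: columns residue_id,
    contribution_e, abs_contribution_e, flagged; sorted by absolute
    contribution, descending.
    """
    if not result.per_residue:
        raise ValueError("result carries no per-residue curves")
    table = pd.DataFrame(
        {
            "residue_id": list(result.per_residue),
            "contribution_e": list(result.per_residue.values()),
        }
    )
    table["abs_contribution_e"] = table["contribution_e"].abs()
    table["flagged"] = table["abs_contribution_e"] >= threshold_e
    table = table.sort_values("abs_contribution_e", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)
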