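"""Membrane-potential and fluorescence-quenching calibrations.

Proteoliposome membrane potentials are set by K+ diffusion potentials in the
presence of valinomycin and quantified with the Nernst equation,
E = (RT/zF) ln([K+]out/[K+]in).  Transporter orientation is assayed by
pyrene-maleimide quenching with iodide, quantified by the Stern-Volmer
relation F0/F = 1 + K_D [Q].  Oxonol VI fluorescence ratios tabulated
against the nominal Nernst voltage verify that the intended potential was
actually established.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .transport_cycle import FARADAY, GAS_CONSTANT

__all__ = [
    "QuenchSeries",
    "PotentialSetup",
    "SternVolmerFit",
    "nernst_potential",
    "stern_volmer_fit",
    "oxonol_voltage_curve",
]


@dataclass(frozen=True)
class QuenchSeries:
    """Quencher concentrations (molar) and matching F0/F ratios."""

    quencher_M: np.ndarray
    f_ratio: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_M, dtype=float)
        f = np.asarray(self.f_ratio, dtype=float)
        if q.ndim != 1 or q.shape != f.shape:
            raise ValueError("concentrations and ratios must be equal-length 1-D arrays")
        if np.any(q < 0):
            raise ValueError("quencher concentrations must be >= 0")
        if not np.any(q == 0):
            raise ValueError("series must include the [Q]=0 reference point")
        object.__setattr__(self, "quencher_M", q)
        object.__setattr__(self, "f_ratio", f)


@dataclass(frozen=True)
class PotentialSetup:
    """K+ gradient defining a valinomycin diffusion potential."""

    k_out_mM: float
    k_in_mM: float
    temperature_K: float = 298.15
    ion_charge_z: int = 1

    def __post_init__(self) -> None:
        if self.k_out_mM <= 0 or self.k_in_mM <= 0:
            raise ValueError("K+ concentrations must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.ion_charge_z == 0:
            raise ValueError("ion charge must be nonzero")


@dataclass(frozen=True)
class SternVolmerFit:
    """Fitted Stern-Volmer constant with its standard error."""

    k_d_per_M: float
    stderr_per_M: float
    intercept: float
    negative_flagged: bool


def nernst_potential(setup: PotentialSetup) -> float:
    """Equilibrium potential in volts: E = (RT/zF) ln([K+]out/[K+]in).

    Depends only on the concentration ratio and is antisymmetric under
    swapping the two compartments.
    """
    rt_zf = GAS_CONSTANT * setup.temperature_K / (setup.ion_charge_z * FARADAY)
    return rt_zf * math.log(setup.k_out_mM / setup.k_in_mM)


def stern_volmer_fit(series: QuenchSeries, fix_intercept: bool = True) -> SternVolmerFit:
    """Least-squares Stern-Volmer constant K_D from F0/F = 1 + K_D [Q].

    By default the intercept is constrained to 1 (the relation's zero-quencher
    limit); ``fix_intercept=False`` frees it.  A negative fitted K_D is
    flagged, not clipped.
    """
    q = series.quencher_M
    y = series.f_ratio
    if q.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(q) == 0:
        raise ValueError("all quencher concentrations identical")
    n = q.size
    if fix_intercept:
        # regression through the fixed point (0, 1)
        k_d = float(np.dot(q, y - 1.0) / np.dot(q, q))
        intercept = 1.0
        dof = n - 1
        resid = y - (1.0 + k_d * q)
        s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
        stderr = math.sqrt(s2 / float(q @ q))
    else:
        k_d, intercept = np.polyfit(q, y, 1)
        dof = n - 2
        resid = y - (intercept + k_d * q)
        s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
        sxx = float(np.sum((q - q.mean()) ** 2))
        stderr = math.sqrt(s2 / sxx)
    return SternVolmerFit(
        k_d_per_M=float(k_d), stderr_per_M=float(stderr),
        intercept=float(intercept), negative_flagged=bool(k_d < 0),
    )


def oxonol_voltage_curve(
    f2_over_f1: Sequence[Sequence[float]],
    setups: Sequence[PotentialSetup],
) -> pd.DataFrame:
    """Tabulate oxonol fluorescence ratios against the predicted Nernst voltage.

    ``f2_over_f1`` holds replicate F2/F1 ratios per buffer (F2: with
    valinomycin; F1: without).  Returns a table sorted by voltage with mean
    and SD per buffer plus a ``monotonic`` attribute-column diagnostic
    (whether the mean ratio is monotone in voltage — reported, not enforced).
    """
    if len(f2_over_f1) != len(setups):
        raise ValueError("need one replicate group per buffer setup")
    rows = []
    for ratios, setup in zip(f2_over_f1, setups):
        arr = np.asarray(ratios, dtype=float)
        if arr.size == 0:
            raise ValueError("each buffer needs at least one replicate ratio")
        rows.append({
            "voltage_mV": 1e3 * nernst_potential(setup),
            "ratio_mean": float(arr.mean()),
            "ratio_sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n_replicates": int(arr.size),
        })
    table = pd.DataFrame(rows).sort_values("voltage_mV", kind="mergesort").reset_index(drop=True)
    diffs = np.diff(table["ratio_mean"].to_numpy())
    table.attrs["monotonic"] = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return table
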