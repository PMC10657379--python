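"""Five-state alternating-access kinetics of vSGLT with voltage-dependent rates.

The transport cycle is the classic stochastic-release scheme:

    1 (outward apo) --Na+--> 2 (outward, Na bound) --Gal--> 3 (occluded)
      --> 4 (inward, loaded) --> 5 (inward apo) --> 1

Ligand-binding steps carry concentration factors ([Na]o on 1->2, [Gal]o on
2->3 and [Gal]i[Na]i on 5->4 for the physiological orientation; swapped for
the flipped orientation found in proteoliposomes).  Each directed rate is
scaled by a Boltzmann factor in the membrane potential V (inside minus
outside),

    k_ij = k0_ij * exp(-(eta_ij + eps_ij) F V / (R T)),

where eta is the protein gating-charge movement and eps the coupled-ion
charge movement attributed to that directed rate.  Flipped transporters
experience the opposite field, so their rates use exp(+...).

Around the forward cycle the net protein charge movement must vanish (the
protein returns to its starting conformation) and the net ion movement must
be +1 e (one Na+ crosses per cycle).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import constants, integrate, linalg

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "AVOGADRO",
    "TRANSITIONS",
    "FORWARD_TRANSITIONS",
    "Orientation",
    "Conditions",
    "TransportParameters",
    "StateDistribution",
    "MixedSteadyState",
    "SweepResult",
    "UptakeTimeCourse",
    "CycleChargeReport",
    "DegenerateGeneratorError",
    "SolverDisagreementError",
    "NonStationaryError",
    "scale_rate",
    "build_generator",
    "steady_state",
    "edge_fluxes",
    "cycle_flux",
    "inward_fraction",
    "mixed_steady_state",
    "voltage_sweep",
    "uptake_time_course",
    "validate_cycle_charges",
]

FARADAY: float = constants.physical_constants["Faraday constant"][0]  # C/mol
GAS_CONSTANT: float = constants.R  # J/(mol K)
AVOGADRO: float = constants.Avogadro

#: all ten directed transition labels of the cycle
TRANSITIONS: tuple[str, ...] = ("12", "21", "23", "32", "34", "43", "45", "54", "51", "15")
#: forward (uptake) direction around the cycle
FORWARD_TRANSITIONS: tuple[str, ...] = ("12", "23", "34", "45", "51")
_REVERSE_OF: dict[str, str] = {"12": "21", "23": "32", "34": "43", "45": "54", "51": "15"}

#: expected unit string per transition in parameter tables
RATE_UNITS: dict[str, str] = {t: "1/s" for t in TRANSITIONS}
RATE_UNITS["12"] = "1/(M*s)"
RATE_UNITS["23"] = "1/(M*s)"
RATE_UNITS["54"] = "1/(M^2*s)"

Orientation = Literal["normal", "flipped"]

_MAX_EXPONENT = 700.0  # beyond this exp() overflows a double


class DegenerateGeneratorError(ValueError):
    """Rate matrix has more than one stationary distribution."""


class SolverDisagreementError(RuntimeError):
    """ODE-integration and null-space steady states disagree beyond tolerance."""


class NonStationaryError(ValueError):
    """Edge fluxes of a supposed steady state disagree beyond tolerance."""


@dataclass(frozen=True)
class Conditions:
    """Experimental conditions: membrane potential and substrate concentrations.

    voltage_V is inside-minus-outside, so physiological potentials are negative.
    Concentrations are molar.
    """

    voltage_V: float = 0.0
    na_out: float = 0.073
    na_in: float = 0.0
    gal_out: float = 28e-6
    gal_in: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.voltage_V):
            raise ValueError("voltage must be finite")
        for name in ("na_out", "na_in", "gal_out", "gal_in"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"concentration {name}={value!r} must be finite and >= 0")

    def swapped(self) -> "Conditions":
        """Conditions with intra- and extracellular compartments exchanged."""
        return Conditions(
            voltage_V=self.voltage_V,
            na_out=self.na_in,
            na_in=self.na_out,
            gal_out=self.gal_in,
            gal_in=self.gal_out,
        )


def _check_transition_map(name: str, mapping: Mapping[str, float]) -> dict[str, float]:
    unknown = set(mapping) - set(TRANSITIONS)
    if unknown:
        raise ValueError(f"{name}: unknown transition labels {sorted(unknown)}")
    missing = set(TRANSITIONS) - set(mapping)
    if missing:
        raise ValueError(f"{name}: missing transition labels {sorted(missing)}")
    out = {t: float(mapping[t]) for t in TRANSITIONS}
    for t, v in out.items():
        if not math.isfinite(v):
            raise ValueError(f"{name}[{t}]={v!r} is not finite")
    return out


@dataclass(frozen=True)
class TransportParameters:
    """Base rates and per-directed-rate charge movements of the five-state cycle.

    ``base_rates`` maps each directed transition label to its zero-voltage rate
    constant (1/s; 1/(M*s) for 12 and 23; 1/(M^2*s) for 54).  ``eta`` and
    ``epsilon`` carry the protein and ion charge movements entering the
    voltage factor of each directed rate; the *net* movement from state i to j
    is eta[ij] - eta[ji] (likewise for epsilon), following the convention that
    charge transfer influences forward and reverse rates equally when the two
    directions carry opposite halves of the net charge.
    """

    base_rates: Mapping[str, float]
    eta: Mapping[str, float]
    epsilon: Mapping[str, float]
    q_gc_total: float = -0.7
    temperature_K: float = 298.15
    faraday: float = FARADAY
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_rates", _check_transition_map("base_rates", self.base_rates))
        object.__setattr__(self, "eta", _check_transition_map("eta", self.eta))
        object.__setattr__(self, "epsilon", _check_transition_map("epsilon", self.epsilon))
        for t, k in self.base_rates.items():
            if k < 0:
                raise ValueError(f"base rate k0[{t}]={k} must be >= 0")
        if not (math.isfinite(self.temperature_K) and self.temperature_K > 0):
            raise ValueError("temperature_K must be positive and finite")

    # -- net charge bookkeeping -------------------------------------------------
    def net_eta(self, forward_label: str) -> float:
        return self.eta[forward_label] - self.eta[_REVERSE_OF[forward_label]]

    def net_epsilon(self, forward_label: str) -> float:
        return self.epsilon[forward_label] - self.epsilon[_REVERSE_OF[forward_label]]

    def eta_cycle_sum(self) -> float:
        return sum(self.net_eta(t) for t in FORWARD_TRANSITIONS)

    def epsilon_cycle_sum(self) -> float:
        return sum(self.net_epsilon(t) for t in FORWARD_TRANSITIONS)

    def validate(self, tol: float = 1e-9) -> None:
        """Raise if the cycle charge sums violate their physical constraints."""
        s_eta = self.eta_cycle_sum()
        if abs(s_eta) > tol:
            raise ValueError(f"protein charge does not close around the cycle: sum eta = {s_eta}")
        s_eps = self.epsilon_cycle_sum()
        if abs(s_eps - 1.0) > tol:
            raise ValueError(f"ion charge per cycle must be +1 e: sum epsilon = {s_eps}")

    @classmethod
    def from_net_charges(
        cls,
        base_rates: Mapping[str, float],
        eta_net: Mapping[str, float],
        epsilon_net: Mapping[str, float],
        q_gc_total: float = -0.7,
        temperature_K: float = 298.15,
    ) -> "TransportParameters":
        """Build parameters from net per-transition charges (symmetric split).

        ``eta_net`` / ``epsilon_net`` map forward labels (12, 23, 34, 45, 51)
        to the net charge moved from i to j; each direction receives half,
        with opposite sign, so the equilibrium constant of the step carries
        the full net charge while forward and reverse rates are influenced
        equally.
        """
        eta: dict[str, float] = {}
        eps: dict[str, float] = {}
        for fwd in FORWARD_TRANSITIONS:
            rev = _REVERSE_OF[fwd]
            eta[fwd] = 0.5 * float(eta_net.get(fwd, 0.0))
            eta[rev] = -0.5 * float(eta_net.get(fwd, 0.0))
            eps[fwd] = 0.5 * float(epsilon_net.get(fwd, 0.0))
            eps[rev] = -0.5 * float(epsilon_net.get(fwd, 0.0))
        return cls(base_rates=base_rates, eta=eta, epsilon=eps,
                   q_gc_total=q_gc_total, temperature_K=temperature_K)

    def with_gating_charge(
        self, q_gc: float, redistribution: str = "proportional"
    ) -> "TransportParameters":
        """Return a parameter set whose protein gating charge totals ``q_gc``.

        ``redistribution='proportional'`` rescales the reference eta map by
        q_gc / q_gc_total; ``'inner-gate'`` places the whole charge on the
        3->4 transition with the compensating return on 5->1.
        """
        if redistribution == "proportional":
            if self.q_gc_total == 0 and q_gc != 0:
                raise ValueError("cannot rescale a zero reference gating charge")
            scale = 0.0 if q_gc == 0 else q_gc / self.q_gc_total
            eta = {t: scale * v for t, v in self.eta.items()}
        elif redistribution == "inner-gate":
            eta = {t: 0.0 for t in TRANSITIONS}
            eta["34"], eta["43"] = 0.5 * q_gc, -0.5 * q_gc
            eta["51"], eta["15"] = -0.5 * q_gc, 0.5 * q_gc
        else:
            raise ValueError(f"unknown redistribution rule {redistribution!r}")
        return replace(self, eta=eta, q_gc_total=q_gc)


@dataclass(frozen=True)
class StateDistribution:
    """Occupancies of the five cycle states for one transporter orientation."""

    occupancies: np.ndarray
    orientation: Orientation = "normal"

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancies, dtype=float)
        if occ.shape != (5,):
            raise ValueError("need exactly five occupancies")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ValueError(f"occupancies outside [0,1]: {occ}")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancies must sum to 1, got {occ.sum()!r}")
        object.__setattr__(self, "occupancies", occ)

    def __getitem__(self, state: int) -> float:
        """Occupancy of state 1..5."""
        if not 1 <= state <= 5:
            raise IndexError("states are numbered 1..5")
        return float(self.occupancies[state - 1])


@dataclass(frozen=True)
class MixedSteadyState:
    """Steady state of an equimolar (or weighted) mixed-orientation population."""

    normal: StateDistribution
    flipped: StateDistribution
    flux_normal: float
    flux_flipped: float
    flipped_fraction: float
    turnover: float          # net uptake, cycles/s per transporter
    inward_fraction: float   # weighted mean of per-orientation inward fractions


@dataclass
class SweepResult:
    """Per-voltage turnover and inward-facing fractions for one gating-charge variant."""

    q_gc: float
    voltages: np.ndarray
    turnover_normal: np.ndarray
    turnover_flipped: np.ndarray
    turnover_mixed: np.ndarray
    inward_fraction_normal: np.ndarray
    inward_fraction_flipped: np.ndarray
    inward_fraction_mixed: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            self.voltages, self.turnover_normal, self.turnover_flipped,
            self.turnover_mixed, self.inward_fraction_normal,
            self.inward_fraction_flipped, self.inward_fraction_mixed,
        ]
        n = len(self.voltages)
        if any(len(a) != n for a in arrays):
            raise ValueError("sweep arrays must share one length")
        for name in ("inward_fraction_normal", "inward_fraction_flipped", "inward_fraction_mixed"):
            a = getattr(self, name)
            if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
                raise ValueError(f"{name} outside [0,1]")


@dataclass(frozen=True)
class UptakeTimeCourse:
    """Finite-lumen uptake trace: accumulated galactose per transporter."""

    times_s: np.ndarray
    galactose_molecules: np.ndarray
    na_in_M: np.ndarray
    gal_in_M: np.ndarray


@dataclass(frozen=True)
class CycleChargeReport:
    """Diagnostic report of the cycle charge-conservation checks."""

    eta_cycle_sum: float
    epsilon_cycle_sum: float
    net_eta: dict[str, float]
    net_epsilon: dict[str, float]
    eta_shares: dict[str, float]  # share of q_gc_total per forward transition
    warnings: list[str]
    ok: bool


# ---------------------------------------------------------------------------
# rate scaling and generator assembly
# ---------------------------------------------------------------------------

def scale_rate(
    k0: float,
    q_eff: float,
    voltage_V: float,
    temperature_K: float,
    orientation: Orientation = "normal",
    transition: str | None = None,
) -> float:
    """Voltage-scale a base rate: k0*exp(-+ q_eff F V / (R T)).

    Normal orientation uses the minus sign; flipped transporters see the
    opposite field and use the plus sign.
    """
    for name, v in (("k0", k0), ("q_eff", q_eff), ("voltage_V", voltage_V),
                    ("temperature_K", temperature_K)):
        if not math.isfinite(v):
            raise ValueError(f"{name}={v!r} is not finite")
    if k0 < 0:
        raise ValueError("base rate must be >= 0")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    if orientation not in ("normal", "flipped"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sign = -1.0 if orientation == "normal" else 1.0
    exponent = sign * q_eff * FARADAY * voltage_V / (GAS_CONSTANT * temperature_K)
    if abs(exponent) > _MAX_EXPONENT:
        label = f" on transition {transition}" if transition else ""
        raise OverflowError(
            f"voltage factor exponent {exponent:.3g}{label} would overflow "
            f"(q_eff={q_eff}, V={voltage_V})"
        )
    return k0 * math.exp(exponent)


def _concentration_factors(cond: Conditions, orientation: Orientation) -> dict[str, float]:
    if orientation == "normal":
        return {"12": cond.na_out, "23": cond.gal_out, "54": cond.gal_in * cond.na_in}
    return {"12": cond.na_in, "23": cond.gal_in, "54": cond.gal_out * cond.na_out}


def directed_rates(
    params: TransportParameters, cond: Conditions, orientation: Orientation
) -> dict[str, float]:
    """Effective (voltage- and concentration-scaled) rate of every directed transition."""
    conc = _concentration_factors(cond, orientation)
    rates = {}
    for t in TRANSITIONS:
        q_eff = params.eta[t] + params.epsilon[t]
        k = scale_rate(params.base_rates[t], q_eff, cond.voltage_V,
                       params.temperature_K, orientation, transition=t)
        rates[t] = k * conc.get(t, 1.0)
    return rates


def build_generator(
    params: TransportParameters, cond: Conditions, orientation: Orientation = "normal"
) -> np.ndarray:
    """Assemble the 5x5 master-equation generator Q with dC/dt = Q @ C.

    Off-diagonal entry Q[j-1, i-1] is the effective rate i->j; each diagonal
    entry is minus its column sum, so every column sums to zero.
    """
    rates = directed_rates(params, cond, orientation)
    Q = np.zeros((5, 5))
    for label, k in rates.items():
        i, j = int(label[0]) - 1, int(label[1]) - 1
        Q[j, i] += k
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=0))
    return Q


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def _steady_state_nullspace(Q: np.ndarray) -> np.ndarray:
    ns = linalg.null_space(Q)
    if ns.shape[1] != 1:
        raise DegenerateGeneratorError(
            f"generator has a {ns.shape[1]}-dimensional null space; "
            "the chain is reducible or degenerate"
        )
    v = ns[:, 0]
    v = v * np.sign(v.sum())
    if np.any(v < -1e-10 * max(1.0, np.abs(v).max())):
        raise DegenerateGeneratorError("null vector is not sign-definite")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def _steady_state_ode(
    Q: np.ndarray,
    rel_tol: float = 1e-10,
    window_s: float = 1.0,
    max_time_s: float = 1e6,
) -> np.ndarray:
    """Integrate dC/dt = QC from the uniform start until the state stops moving.

    Convergence: maximum relative state change below ``rel_tol`` over a
    ``window_s`` stretch of model time, with a hard cap at ``max_time_s``.
    """
    y = np.full(5, 0.2)

    def rhs(_t: float, state: np.ndarray) -> np.ndarray:
        return Q @ state

    elapsed = 0.0
    chunk = window_s
    while elapsed < max_time_s:
        sol = integrate.solve_ivp(rhs, (0.0, chunk), y, method="LSODA",
                                  rtol=1e-12, atol=1e-14)
        if not sol.success:  # pragma: no cover - LSODA on a linear system
            raise RuntimeError(f"steady-state integration failed: {sol.message}")
        y_new = sol.y[:, -1]
        elapsed += chunk
        # probe a fixed 1-window stretch for residual motion
        probe = integrate.solve_ivp(rhs, (0.0, window_s), y_new, method="LSODA",
                                    rtol=1e-12, atol=1e-14)
        y_probe = probe.y[:, -1]
        elapsed += window_s
        change = np.max(np.abs(y_probe - y_new) / np.maximum(np.abs(y_new), 1e-12))
        y = y_probe
        if change < rel_tol:
            break
        chunk *= 2.0
    y = np.clip(y, 0.0, None)
    return y / y.sum()


def steady_state(
    generator: np.ndarray,
    orientation: Orientation = "normal",
    method: str = "nullspace",
    cross_check_tol: float = 1e-8,
) -> StateDistribution:
    """Stationary distribution of the cycle: Q C = 0, sum C = 1, C >= 0.

    ``method`` is ``'nullspace'`` (SVD null space of Q), ``'ode'`` (long-time
    integration of the master equation) or ``'both'``, which computes the two
    independently and raises :class:`SolverDisagreementError` if they differ
    by more than ``cross_check_tol`` elementwise.
    """
    Q = np.asarray(generator, dtype=float)
    if Q.shape != (5, 5):
        raise ValueError("generator must be 5x5")
    col_residual = np.abs(Q.sum(axis=0)).max()
    if col_residual > 1e-9 * max(1.0, np.abs(Q).max()):
        raise ValueError(f"generator columns must sum to zero (residual {col_residual:.3g})")
    if method == "nullspace":
        occ = _steady_state_nullspace(Q)
    elif method == "ode":
        occ = _steady_state_ode(Q)
    elif method == "both":
        occ_ns = _steady_state_nullspace(Q)
        occ_ode = _steady_state_ode(Q)
        gap = np.abs(occ_ns - occ_ode).max()
        if gap > cross_check_tol:
            raise SolverDisagreementError(
                f"null-space and ODE steady states differ by {gap:.3g} "
                f"(tolerance {cross_check_tol:.3g})"
            )
        occ = occ_ns
    else:
        raise ValueError(f"unknown method {method!r}")
    return StateDistribution(occ, orientation)


# ---------------------------------------------------------------------------
# fluxes and population observables
# ---------------------------------------------------------------------------

def edge_fluxes(
    params: TransportParameters, cond: Conditions, ss: StateDistribution
) -> np.ndarray:
    """Net forward flux on each cycle edge (1-2, 2-3, 3-4, 4-5, 5-1)."""
    rates = directed_rates(params, cond, ss.orientation)
    C = ss.occupancies
    out = np.empty(5)
    for idx, fwd in enumerate(FORWARD_TRANSITIONS):
        rev = _REVERSE_OF[fwd]
        i, j = int(fwd[0]) - 1, int(fwd[1]) - 1
        out[idx] = rates[fwd] * C[i] - rates[rev] * C[j]
    return out


def cycle_flux(
    params: TransportParameters,
    cond: Conditions,
    ss: StateDistribution,
    tol: float = 1e-9,
) -> float:
    """Steady-state cycle flux in cycles/s per transporter (positive = forward).

    Evaluated on the 2->3 edge; at a true steady state the net flux is the
    same on every edge, which is asserted to within ``tol``.
    """
    fluxes = edge_fluxes(params, cond, ss)
    spread = fluxes.max() - fluxes.min()
    scale = max(1.0, np.abs(fluxes).max())
    if spread > tol * scale:
        raise NonStationaryError(
            f"edge fluxes disagree by {spread:.3g} (tolerance {tol:.3g} x {scale:.3g}); "
            "the distribution is not stationary"
        )
    return float(fluxes[1])


def inward_fraction(ss: StateDistribution) -> float:
    """Probability of the inward-facing conformation: occupancy of states 4 + 5."""
    return float(ss.occupancies[3] + ss.occupancies[4])


def mixed_steady_state(
    params: TransportParameters,
    cond: Conditions,
    flipped_fraction: float = 0.5,
    method: str = "nullspace",
) -> MixedSteadyState:
    """Steady state of a liposome population with both transporter orientations.

    A forward cycle of a flipped transporter exports cargo from the lumen, so
    its contribution to net uptake is the negative of its forward cycle flux.
    """
    if not 0.0 <= flipped_fraction <= 1.0:
        raise ValueError("flipped_fraction must lie in [0, 1]")
    ss_n = steady_state(build_generator(params, cond, "normal"), "normal", method=method)
    ss_f = steady_state(build_generator(params, cond, "flipped"), "flipped", method=method)
    j_n = cycle_flux(params, cond, ss_n)
    j_f = cycle_flux(params, cond, ss_f)
    w = flipped_fraction
    turnover = (1.0 - w) * j_n + w * (-j_f)
    inward = (1.0 - w) * inward_fraction(ss_n) + w * inward_fraction(ss_f)
    return MixedSteadyState(
        normal=ss_n, flipped=ss_f, flux_normal=j_n, flux_flipped=j_f,
        flipped_fraction=w, turnover=turnover, inward_fraction=inward,
    )


def voltage_sweep(
    params: TransportParameters,
    cond: Conditions,
    voltages: Sequence[float],
    q_gc_variants: Iterable[float] | None = None,
    redistribution: str = "proportional",
    flipped_fraction: float = 0.5,
    normalize: bool = False,
) -> dict[float, SweepResult]:
    """Turnover and inward fractions across a voltage grid, per gating-charge variant.

    ``normalize=True`` rescales the turnover columns to their value at the grid
    point closest to 0 mV (skipped for a variant whose 0 mV turnover is zero).
    """
    volts = np.asarray(list(voltages), dtype=float)
    if volts.size == 0:
        raise ValueError("voltage grid is empty")
    if q_gc_variants is None:
        q_gc_variants = [params.q_gc_total]
    results: dict[float, SweepResult] = {}
    for q_gc in q_gc_variants:
        p = params.with_gating_charge(q_gc, redistribution=redistribution)
        cols = {k: np.empty(volts.size) for k in
                ("tn", "tf", "tm", "fn", "ff", "fm")}
        for idx, v in enumerate(volts):
            ms = mixed_steady_state(p, replace(cond, voltage_V=float(v)),
                                    flipped_fraction=flipped_fraction)
            cols["tn"][idx] = ms.flux_normal
            cols["tf"][idx] = -ms.flux_flipped
            cols["tm"][idx] = ms.turnover
            cols["fn"][idx] = inward_fraction(ms.normal)
            cols["ff"][idx] = inward_fraction(ms.flipped)
            cols["fm"][idx] = ms.inward_fraction
        if normalize:
            anchor = int(np.argmin(np.abs(volts)))
            for key in ("tn", "tf", "tm"):
                ref = cols[key][anchor]
                if ref != 0:
                    cols[key] = cols[key] / ref
        results[float(q_gc)] = SweepResult(
            q_gc=float(q_gc), voltages=volts,
            turnover_normal=cols["tn"], turnover_flipped=cols["tf"],
            turnover_mixed=cols["tm"], inward_fraction_normal=cols["fn"],
            inward_fraction_flipped=cols["ff"], inward_fraction_mixed=cols["fm"],
        )
    return results


def uptake_time_course(
    params: TransportParameters,
    cond: Conditions,
    lumen_volume_L: float = 5e-19,
    duration_s: float = 900.0,
    leak_per_s: float = 0.0,
    flipped_fraction: float = 0.5,
    n_points: int = 241,
    voltage_decay_per_s: float = 0.0,
) -> UptakeTimeCourse:
    """Simulate accumulated galactose in a finite lumen served by one transporter.

    The transporter population is assumed to relax to its cycle steady state
    much faster than the lumen composition changes, so the instantaneous
    mixed-population flux is evaluated at the current internal concentrations
    while a first-order leak (``leak_per_s``) relaxes luminal Na+ toward the
    external concentration, dissipating the driving gradient.  With
    ``voltage_decay_per_s`` > 0 the clamped potential also decays
    exponentially toward 0, emulating the rundown of the K+ diffusion
    potential; with the potential held fixed, a negative voltage sustains
    accumulation indefinitely and only the chemical gradient dissipates.
    """
    if lumen_volume_L <= 0:
        raise ValueError("lumen volume must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if leak_per_s < 0 or voltage_decay_per_s < 0:
        raise ValueError("dissipation rates must be >= 0")
    if max(params.base_rates.values()) == 0.0:
        # no transport at all: the trace is identically zero
        times = np.linspace(0.0, duration_s, n_points)
        zeros = np.zeros_like(times)
        return UptakeTimeCourse(times_s=times, galactose_molecules=zeros,
                                na_in_M=np.full_like(times, cond.na_in),
                                gal_in_M=np.full_like(times, cond.gal_in))
    conv = 1.0 / (AVOGADRO * lumen_volume_L)  # molecules/s -> M/s

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        na_i, gal_i = max(y[0], 0.0), max(y[1], 0.0)
        volt = cond.voltage_V * math.exp(-voltage_decay_per_s * t)
        c = replace(cond, na_in=na_i, gal_in=gal_i, voltage_V=volt)
        ms = mixed_steady_state(params, c, flipped_fraction=flipped_fraction)
        d_na = ms.turnover * conv + leak_per_s * (cond.na_out - na_i)
        d_gal = ms.turnover * conv
        return np.array([d_na, d_gal])

    times = np.linspace(0.0, duration_s, n_points)
    y0 = np.array([cond.na_in, cond.gal_in])
    sol = integrate.solve_ivp(rhs, (0.0, duration_s), y0, t_eval=times,
                              method="LSODA", rtol=1e-8, atol=1e-12)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"uptake integration failed: {sol.message}")
    na = np.clip(sol.y[0], 0.0, None)
    gal = np.clip(sol.y[1], 0.0, None)
    molecules = (gal - cond.gal_in) * AVOGADRO * lumen_volume_L
    return UptakeTimeCourse(times_s=times, galactose_molecules=molecules,
                            na_in_M=na, gal_in_M=gal)


def validate_cycle_charges(params: TransportParameters, tol: float = 1e-9) -> CycleChargeReport:
    """Check cycle closure of the charge maps; report, never silently fix.

    The protein charge must sum to zero around the forward cycle and the ion
    charge to +1 e.  Per-transition shares of the total gating charge are
    reported relative to ``q_gc_total`` (conformational legs of the
    outward-to-inward direction carry the forward share; the return leg 5->1
    carries its negative).
    """
    s_eta = params.eta_cycle_sum()
    s_eps = params.epsilon_cycle_sum()
    warnings: list[str] = []
    if abs(s_eta) > tol:
        warnings.append(
            f"protein charge does not close around the cycle: |sum eta| = {abs(s_eta):.6g}"
        )
    if abs(s_eps - 1.0) > tol:
        warnings.append(
            f"ion charge per cycle differs from +1 e by {abs(s_eps - 1.0):.6g}"
        )
    net_eta = {t: params.net_eta(t) for t in FORWARD_TRANSITIONS}
    net_eps = {t: params.net_epsilon(t) for t in FORWARD_TRANSITIONS}
    if params.q_gc_total != 0:
        shares = {t: v / params.q_gc_total for t, v in net_eta.items()}
    else:
        shares = {t: 0.0 for t in FORWARD_TRANSITIONS}
    return CycleChargeReport(
        eta_cycle_sum=s_eta, epsilon_cycle_sum=s_eps,
        net_eta=net_eta, net_epsilon=net_eps, eta_shares=shares,
        warnings=warnings, ok=not warnings,
    )
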