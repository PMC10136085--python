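"""Equilibrium, robustness, leakage and consumption analyses.

The internal (hat) dynamics of both circuits are positive systems whose
linear part has a positive dominant (Frobenius) eigenvalue for any positive
parameters, so the unforced origin is unstable and the hat coordinates settle
at a strictly positive equilibrium.  That equilibrium fixes the operating
concentrations and causes persistent fuel consumption in the DSD realisation.
Rate asymmetry between the '+' and '-' rails couples the represented I/O
dynamics to the internal positive dynamics and shifts the represented output
away from zero; symmetric leakage cancels in the represented output while an
asymmetric one does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .circuits import (
    IntegralCircuitParams,
    StateFeedbackParams,
    build_integral_circuit,
)
from .crn import Trajectory, mak_vector_field, simulate
from .dsd import DSDNetwork
from .dualrail import AsymmetricParam, rotate, signal

__all__ = [
    "EquilibriumReport",
    "AsymmetryReport",
    "LeakComparison",
    "ConsumptionReport",
    "unforced_equilibria_integral",
    "internal_unforced_eigenvalues",
    "high_gain_pole_check",
    "asymmetric_analysis",
    "leak_response_compare",
    "consumption_report",
]


@dataclass
class EquilibriumReport:
    """Unforced equilibria of the internal (hat) dynamics."""

    equilibria: list[tuple[float, float]]  # (y_hat*, v_hat* or x_hat*)
    trivial_included: bool
    frobenius_eigenvalue: float
    stable_origin: bool
    only_trivial: bool = False


@dataclass
class AsymmetryReport:
    """Equilibrium offsets of the represented signals under rail asymmetry."""

    bar_hat_params: dict[str, tuple[float, float]]
    predicted_offsets: tuple[float, float]  # (y_bar*, v_bar*) closed form
    equilibrium: dict[str, float]  # solved (v_bar, y_bar, v_hat, y_hat)
    simulated_offsets: tuple[float, float] | None
    coupling_terms: list[str]
    residual: float


@dataclass
class LeakComparison:
    """Deviation of the output between a leak-free and a leaky run."""

    sup_bar_deviation: float
    terminal_bar_deviation: float
    sup_hat_deviation: float
    terminal_hat_deviation: float
    step_amplitude: float


@dataclass
class ConsumptionReport:
    """Fuel depletion and waste accumulation over a simulated horizon."""

    consumed: dict[str, float]  # nM over horizon, per supplied species
    terminal_rates: dict[str, float]  # nM/s depletion rate at t_end
    waste: dict[str, float]  # terminal accumulation per waste species
    output_settled: bool
    persistent_consumption: bool
    max_terminal_rate: float


# -- unforced equilibria -----------------------------------------------------


def unforced_equilibria_integral(p: IntegralCircuitParams) -> EquilibriumReport:
    """Positive equilibria of the unforced integral-circuit hat dynamics.

    The fixed points solve 0 = ki*y - (eta/2)*v^2 and
    0 = b*v - a*y - (eta/2)*y^2; eliminating v and factoring the trivial
    root leaves the cubic
    (eta^3/8b^2) y^3 + (a eta^2/2b^2) y^2 + (eta a^2/2b^2) y - ki = 0,
    which has exactly one positive root for any positive parameters
    (one sign change), with v_hat* = sqrt(2 ki y_hat*/eta).
    """
    a, b, ki, eta = p.a, p.b, p.ki, p.eta
    coeffs = [
        eta**3 / (8 * b * b),
        a * eta * eta / (2 * b * b),
        eta * a * a / (2 * b * b),
        -ki,
    ]
    equilibria: list[tuple[float, float]] = [(0.0, 0.0)]
    only_trivial = True
    for y in np.roots(coeffs):
        if abs(y.imag) < 1e-12 * max(1.0, abs(y.real)) and y.real > 0:
            only_trivial = False
            yr = float(y.real)
            equilibria.append((yr, math.sqrt(2 * ki * yr / eta)))
    lam = internal_unforced_eigenvalues("integral", p)[0]
    return EquilibriumReport(
        equilibria=equilibria,
        trivial_included=True,
        frobenius_eigenvalue=lam,
        stable_origin=lam < 0,
        only_trivial=only_trivial,
    )


def internal_unforced_eigenvalues(circuit_type: str, params) -> tuple[float, float]:
    """Eigenvalues of the linear part of the unforced hat dynamics.

    Integral circuit: lambda = (-a +/- sqrt(a^2 + 4 ki b)) / 2; state
    feedback: lambda = (q/2)(k1 +/- sqrt(k1^2 + 4 k2)).  The larger root is
    positive for any positive parameters — the Frobenius eigenvalue pushing
    the unforced internal dynamics away from the origin.
    """
    if circuit_type == "integral":
        a, b, ki = params.a, params.b, params.ki
        s = math.sqrt(a * a + 4 * ki * b)
        return (0.5 * (-a + s), 0.5 * (-a - s))
    if circuit_type == "state_feedback":
        q, k1, k2 = params.q, params.k1, params.k2
        s = math.sqrt(k1 * k1 + 4 * k2)
        return ((q / 2) * (k1 + s), (q / 2) * (k1 - s))
    raise ValueError(f"unknown circuit type {circuit_type!r}")


def high_gain_pole_check(p: IntegralCircuitParams) -> tuple[float, float]:
    """Real parts of the represented closed-loop poles.

    For a high integral gain ki > a^2/(4b) the poles are complex with real
    part exactly -a/2 — set solely by the degradation reactions; otherwise the
    two real poles are returned.
    """
    a, b, ki = p.a, p.b, p.ki
    disc = a * a - 4 * ki * b
    if disc < 0:
        return (-a / 2, -a / 2)
    s = math.sqrt(disc)
    return (0.5 * (-a + s), 0.5 * (-a - s))


# -- asymmetric parametrisation ---------------------------------------------


def _rotated_field(bars: dict[str, float], hats: dict[str, float], eta: float):
    """Unforced rotated-coordinate field of the integral circuit with
    independent rail rates; state ordering (v_bar, y_bar, v_hat, y_hat)."""

    kib, kih = bars["ki"], hats["ki"]
    ab, ah = bars["a"], hats["a"]
    bb, bh = bars["b"], hats["b"]

    def f(s: np.ndarray) -> np.ndarray:
        vb, yb, vh, yh = s
        return np.array(
            [
                -kih / 2 * yb - kib / 2 * yh,
                bh / 2 * vb - ah / 2 * yb + bb / 2 * vh - ab / 2 * yh,
                kih / 2 * yh - eta / 2 * (vh * vh - vb * vb) + kib / 2 * yb,
                bh / 2 * vh - ah / 2 * yh - eta / 2 * (yh * yh - yb * yb) + bb / 2 * vb - ab / 2 * yb,
            ]
        )

    return f


def asymmetric_analysis(
    p: IntegralCircuitParams,
    asym: list[AsymmetricParam],
    simulate_check: bool = True,
    t_end: float = 2e4,
) -> AsymmetryReport:
    """Unforced equilibrium of the integral circuit with independent rail rates.

    Solves the rotated equilibrium system numerically (damped Newton from the
    symmetric closed form), reports the closed-form offset relations
    y_bar* = -(ki_bar/ki_hat) y_hat* and the v_bar* expression that follows
    from the linear equilibrium conditions, and optionally cross-validates
    against the long-time limit of the asymmetric mass-action ODEs.
    """
    table = {a.name: a for a in asym}
    bars = {n: (table[n].bar if n in table else 0.0) for n in ("a", "b", "ki")}
    defaults = {"a": p.a, "b": p.b, "ki": p.ki}
    hats = {n: (table[n].hat if n in table else 2 * defaults[n]) for n in ("a", "b", "ki")}

    # symmetric closed-form start: effective symmetric rates are hat/2
    sym = IntegralCircuitParams(
        a=hats["a"] / 2, b=hats["b"] / 2, ki=hats["ki"] / 2, eta=p.eta
    )
    rep = unforced_equilibria_integral(sym)
    pos = [e for e in rep.equilibria if e[0] > 0]
    y0, v0 = pos[0] if pos else (1.0, 1.0)
    f = _rotated_field(bars, hats, p.eta)
    sol = root(f, np.array([0.0, 0.0, v0, y0]), method="hybr", tol=1e-12)
    vb, yb, vh, yh = sol.x
    resid = float(np.max(np.abs(f(sol.x))))

    # closed-form offsets from the linear equilibrium conditions
    yb_pred = -(bars["ki"] / hats["ki"]) * yh
    vb_pred = -(bars["b"] / hats["b"]) * vh + yh * (
        -(hats["a"] / hats["b"]) * (bars["ki"] / hats["ki"]) + bars["a"] / hats["b"]
    )

    coupling = [
        f"{name}_bar={bars[name]:.3g}" for name in ("a", "b", "ki") if bars[name] != 0.0
    ]

    simulated: tuple[float, float] | None = None
    if simulate_check:
        asym_map = {a.name: (a.plus_rate, a.minus_rate) for a in asym}
        circuit = build_integral_circuit(p, reference=0.0, asymmetry=asym_map)
        # small positive kick off the unstable origin, symmetric so bars start 0
        for sname in ("V+", "V-", "Y+", "Y-"):
            circuit.crn.get_species(sname).initial_concentration = 1.0
        traj = simulate(circuit.crn, t_end=t_end, n_points=200)
        ybar, _ = rotate(traj, circuit.pair("Y"))
        vbar, _ = rotate(traj, circuit.pair("V"))
        simulated = (float(ybar[-1]), float(vbar[-1]))

    return AsymmetryReport(
        bar_hat_params={n: (bars[n], hats[n]) for n in ("a", "b", "ki")},
        predicted_offsets=(yb_pred, vb_pred),
        equilibrium={"v_bar": vb, "y_bar": yb, "v_hat": vh, "y_hat": yh},
        simulated_offsets=simulated,
        coupling_terms=coupling,
        residual=resid,
    )


# -- leakage -----------------------------------------------------------------


def leak_response_compare(
    p: IntegralCircuitParams,
    rho_plus: float,
    rho_minus: float,
    z_plus0: float = 1.0,
    z_minus0: float = 1.0,
    reference: float = 10.0,
    horizon: float = 8e3,
    n_points: int = 400,
) -> LeakComparison:
    """Compare output trajectories of the integral circuit with and without
    leak sources on the output pair.

    For a symmetric leak (equal rates and equal source concentrations) the
    leak contribution cancels in the represented output y_bar while the
    internal y_hat still shifts; an asymmetric leak biases y_bar itself.
    """
    from .dsd import inject_leak

    base = build_integral_circuit(p, reference=reference)
    leaky = inject_leak(base, "Y", rho_plus, rho_minus, z_plus0, z_minus0)
    traj0 = simulate(base.crn, t_end=horizon, n_points=n_points)
    traj1 = simulate(leaky.crn, t_end=horizon, n_points=n_points)
    pair = base.pair("Y")
    b0, h0 = rotate(traj0, pair)
    b1, h1 = rotate(traj1, pair)
    return LeakComparison(
        sup_bar_deviation=float(np.max(np.abs(b1 - b0))),
        terminal_bar_deviation=float(abs(b1[-1] - b0[-1])),
        sup_hat_deviation=float(np.max(np.abs(h1 - h0))),
        terminal_hat_deviation=float(abs(h1[-1] - h0[-1])),
        step_amplitude=reference,
    )


# -- fuel consumption --------------------------------------------------------


def consumption_report(
    net: DSDNetwork,
    traj: Trajectory,
    output_pair: tuple[str, str] | None = None,
    target: float | None = None,
    settled_tol: float = 0.01,
    rate_threshold: float = 1e-6,
) -> ConsumptionReport:
    """Deplete/waste accounting for a dynamically simulated DSD network.

    ``output_pair`` names the (plus, minus) output strands in the expanded
    network; with ``target`` (the commanded step, nM) the report flags
    persistent consumption: a fuel depletion rate above ``rate_threshold``
    (nM/s) while the represented output sits within ``settled_tol`` of the
    target — the experimental signature of the positive internal equilibrium.
    The depletion rate is evaluated at the first grid point where the output
    reaches the target (fuel pools are finite, so on long horizons depletion
    itself eventually degrades tracking), or at the end of the horizon if the
    output never gets there.
    """
    if traj.meta.get("clamped"):
        raise ValueError("consumption is undefined for a clamped-auxiliary trajectory")
    field_fn = mak_vector_field(net.crn)
    settled = False
    at = len(traj.times) - 1
    if output_pair is not None and target is not None and target != 0:
        ybar = traj[output_pair[0]] - traj[output_pair[1]]
        hits = np.nonzero(np.abs(ybar - target) < settled_tol * abs(target))[0]
        if hits.size:
            settled = True
            at = int(hits[0])
    state = np.array([traj[s.name][at] for s in net.crn.species])
    rates = field_fn(state)
    idx = net.crn.species_index()
    consumed = {}
    terminal = {}
    for name in sorted(net.supplied):
        series = traj[name]
        consumed[name] = float(max(series[0] - series[-1], 0.0))
        terminal[name] = float(max(-rates[idx[name]], 0.0))
    waste = {
        s.name: float(traj[s.name][-1]) for s in net.crn.species if s.role == "waste"
    }
    max_rate = max(terminal.values()) if terminal else 0.0
    return ConsumptionReport(
        consumed=consumed,
        terminal_rates=terminal,
        waste=waste,
        output_settled=settled,
        persistent_consumption=settled and max_rate > rate_threshold,
        max_terminal_rate=float(max_rate),
    )
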