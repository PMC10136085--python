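"""Constructors for the two reduced dual-rail feedback circuits.

Two closed loops are provided, each buildable as an abstract CRN of catalysis,
degradation and annihilation reactions:

* integral control of a stable first-order plant Y(s) = b/(s+a) V(s) with
  control V(s) = ki/s (R(s) - Y(s)); closed loop b*ki / (s^2 + a s + b*ki);
* static state feedback v = r - k1 x - k2 y around the double integrator with
  per-stage gain q; closed loop q^2 / (s^2 + q k1 s + q^2 k2).

The difference (bar) coordinates of the built CRNs reproduce these linear
closed loops exactly when the '+' and '-' rail rates match; the summed (hat)
coordinates carry the internal positive nonlinear dynamics.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy.linalg import expm

from .crn import CRN, Reaction, Species
from .dualrail import DualRailCRN, DualRailPair

__all__ = [
    "IntegralCircuitParams",
    "StateFeedbackParams",
    "SecondOrderSummary",
    "build_integral_circuit",
    "build_state_feedback_circuit",
    "closed_loop_summary",
    "critical_damping_gain",
    "linear_reference_response",
]

#: default annihilation rate, (nM s)^-1 — fast relative to all unimolecular
#: rates at nanomolar concentrations (eta * conc >> q*k1 etc.)
DEFAULT_ETA = 1e-3
#: default constant reference step on the plus rail, nM
DEFAULT_REFERENCE = 10.0


@dataclass
class IntegralCircuitParams:
    """First-order plant pole a, plant gain b, integral gain ki (all s^-1),
    annihilation rate eta ((nM s)^-1)."""

    a: float = 2.5e-3
    b: float = 1e-3
    ki: float = 5e-2
    eta: float = DEFAULT_ETA
    include_output_annihilation: bool = True

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.ki, self.eta) <= 0:
            raise ValueError("all rates must be > 0")


@dataclass
class StateFeedbackParams:
    """Integrator gain q (s^-1), dimensionless feedback gains k1 (damping) and
    k2 (tracking; unity for zero steady-state error), annihilation rate eta."""

    q: float = 8e-3
    k1: float = 1.0
    k2: float = 1.0
    eta: float = DEFAULT_ETA
    variant: Literal["catalytic_degradation", "degradation"] = "degradation"
    include_x_annihilation: bool = True

    def __post_init__(self) -> None:
        if min(self.q, self.k1, self.k2, self.eta) <= 0:
            raise ValueError("all rates and gains must be > 0")
        if self.variant not in ("catalytic_degradation", "degradation"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class SecondOrderSummary:
    """Closed-loop poles, natural frequency, damping and DC gain."""

    poles: tuple[complex, complex]
    natural_frequency: float
    damping: float
    dc_gain: float


def _rail_rate(
    name: str, default: float, asymmetry: Mapping[str, tuple[float, float]] | None, rail: str
) -> float:
    """Pick the '+'/'-' rail rate for parameter ``name``.

    The rail is that of the *reactant* species: the rate multiplying x_plus in
    the kinetics is the plus rate, regardless of which rail the product feeds.
    """
    if asymmetry and name in asymmetry:
        plus, minus = asymmetry[name]
        return plus if rail == "+" else minus
    return default


def build_integral_circuit(
    p: IntegralCircuitParams,
    reference: float = DEFAULT_REFERENCE,
    asymmetry: Mapping[str, tuple[float, float]] | None = None,
) -> DualRailCRN:
    """Assemble the integral-control CRN: six catalysis, two degradation and
    two annihilation reactions (one annihilation when the output annihilation
    is omitted for the reduced DSD implementation).

    The error subtraction is folded into the integrator by cross-wiring the
    output catalysis Y+/- -> Y+/- + V-/+, which realises the negative error
    gain while every rate stays positive.  ``asymmetry`` optionally overrides
    parameters "a", "b", "ki" with independent (plus, minus) rail rates.
    ``reference`` sets the constant plus-rail input concentration r+ (nM);
    reference species take part only as catalysts, so they stay constant.
    """
    species = [
        Species("R+", "reference_plus", reference),
        Species("R-", "reference_minus", 0.0),
        Species("V+", "signal_plus", 0.0),
        Species("V-", "signal_minus", 0.0),
        Species("Y+", "signal_plus", 0.0),
        Species("Y-", "signal_minus", 0.0),
    ]
    rr = lambda name, default, rail: _rail_rate(name, default, asymmetry, rail)
    reactions = [
        # plant gain: V -> V + Y at rate b
        Reaction({"V+": 1}, {"V+": 1, "Y+": 1}, rr("b", p.b, "+"), "catalysis", "b"),
        Reaction({"V-": 1}, {"V-": 1, "Y-": 1}, rr("b", p.b, "-"), "catalysis", "b"),
        # plant pole: Y -> 0 at rate a
        Reaction({"Y+": 1}, {}, rr("a", p.a, "+"), "degradation", "a"),
        Reaction({"Y-": 1}, {}, rr("a", p.a, "-"), "degradation", "a"),
        # integral action on the reference: R -> R + V at rate ki
        Reaction({"R+": 1}, {"R+": 1, "V+": 1}, rr("ki", p.ki, "+"), "catalysis", "ki"),
        Reaction({"R-": 1}, {"R-": 1, "V-": 1}, rr("ki", p.ki, "-"), "catalysis", "ki"),
        # negative error gain: Y feeds the opposite integrator rail
        Reaction({"Y+": 1}, {"Y+": 1, "V-": 1}, rr("ki", p.ki, "+"), "catalysis", "ki"),
        Reaction({"Y-": 1}, {"Y-": 1, "V+": 1}, rr("ki", p.ki, "-"), "catalysis", "ki"),
        Reaction({"V+": 1, "V-": 1}, {}, p.eta, "annihilation", "eta"),
    ]
    if p.include_output_annihilation:
        reactions.append(Reaction({"Y+": 1, "Y-": 1}, {}, p.eta, "annihilation", "eta"))
    crn = CRN(species=species, reactions=reactions)
    pairs = [
        DualRailPair("R", "R+", "R-"),
        DualRailPair("V", "V+", "V-"),
        DualRailPair("Y", "Y+", "Y-"),
    ]
    return DualRailCRN(crn=crn, pairs=pairs, input_pairs=["R"], output_pairs=["Y"])


def build_state_feedback_circuit(
    p: StateFeedbackParams,
    reference: float = DEFAULT_REFERENCE,
    asymmetry: Mapping[str, tuple[float, float]] | None = None,
) -> DualRailCRN:
    """Assemble the double-integrator state-feedback CRN.

    ``variant="catalytic_degradation"`` realises the self-damping gain q*k1 as
    cross-rail autocatalysis X+/- -> X+/- + X-/+ backed by fast annihilation
    (eight catalysis + two annihilations); ``variant="degradation"`` realises
    it directly as degradation X+/- -> 0 (six catalysis + two degradations +
    annihilations).  Both share the Y+/- -> X-/+ cross-wiring carrying q*k2.
    """
    species = [
        Species("R+", "reference_plus", reference),
        Species("R-", "reference_minus", 0.0),
        Species("X+", "signal_plus", 0.0),
        Species("X-", "signal_minus", 0.0),
        Species("Y+", "signal_plus", 0.0),
        Species("Y-", "signal_minus", 0.0),
    ]
    rr = lambda name, default, rail: _rail_rate(name, default, asymmetry, rail)
    reactions = [
        # first integrator input: R -> R + X at rate q
        Reaction({"R+": 1}, {"R+": 1, "X+": 1}, rr("q", p.q, "+"), "catalysis", "q"),
        Reaction({"R-": 1}, {"R-": 1, "X-": 1}, rr("q", p.q, "-"), "catalysis", "q"),
        # second integrator: X -> X + Y at rate q
        Reaction({"X+": 1}, {"X+": 1, "Y+": 1}, rr("q", p.q, "+"), "catalysis", "q"),
        Reaction({"X-": 1}, {"X-": 1, "Y-": 1}, rr("q", p.q, "-"), "catalysis", "q"),
        # output feedback: Y feeds the opposite X rail at rate q*k2
        Reaction({"Y+": 1}, {"Y+": 1, "X-": 1}, rr("qk2", p.q * p.k2, "+"), "catalysis", "qk2"),
        Reaction({"Y-": 1}, {"Y-": 1, "X+": 1}, rr("qk2", p.q * p.k2, "-"), "catalysis", "qk2"),
    ]
    if p.variant == "catalytic_degradation":
        reactions += [
            # self-repression via the opposite rail plus fast annihilation
            Reaction({"X+": 1}, {"X+": 1, "X-": 1}, rr("qk1", p.q * p.k1, "+"), "catalysis", "qk1"),
            Reaction({"X-": 1}, {"X-": 1, "X+": 1}, rr("qk1", p.q * p.k1, "-"), "catalysis", "qk1"),
        ]
    else:
        reactions += [
            Reaction({"X+": 1}, {}, rr("qk1", p.q * p.k1, "+"), "degradation", "qk1"),
            Reaction({"X-": 1}, {}, rr("qk1", p.q * p.k1, "-"), "degradation", "qk1"),
        ]
    reactions.append(Reaction({"Y+": 1, "Y-": 1}, {}, p.eta, "annihilation", "eta"))
    if p.include_x_annihilation:
        reactions.append(Reaction({"X+": 1, "X-": 1}, {}, p.eta, "annihilation", "eta"))
    crn = CRN(species=species, reactions=reactions)
    pairs = [
        DualRailPair("R", "R+", "R-"),
        DualRailPair("X", "X+", "X-"),
        DualRailPair("Y", "Y+", "Y-"),
    ]
    return DualRailCRN(crn=crn, pairs=pairs, input_pairs=["R"], output_pairs=["Y"])


# -- linear reference models -------------------------------------------------


def closed_loop_summary(
    circuit_type: Literal["integral", "state_feedback"],
    params: IntegralCircuitParams | StateFeedbackParams,
) -> SecondOrderSummary:
    """Poles, natural frequency, damping and DC gain of the represented
    second-order closed loop."""
    if circuit_type == "integral":
        a, b, ki = params.a, params.b, params.ki
        disc = cmath.sqrt(a * a - 4 * b * ki)
        poles = (0.5 * (-a + disc), 0.5 * (-a - disc))
        wn = float(np.sqrt(b * ki))
        xi = a / (2 * np.sqrt(b * ki))
        dc = 1.0
    elif circuit_type == "state_feedback":
        q, k1, k2 = params.q, params.k1, params.k2
        disc = cmath.sqrt(k1 * k1 - 4 * k2)
        poles = ((q / 2) * (-k1 + disc), (q / 2) * (-k1 - disc))
        wn = float(q * np.sqrt(k2))
        xi = k1 / (2 * np.sqrt(k2))
        dc = 1.0 / k2
    else:
        raise ValueError(f"unknown circuit type {circuit_type!r}")
    return SecondOrderSummary(poles=poles, natural_frequency=wn, damping=float(xi), dc_gain=dc)


def critical_damping_gain(k2: float = 1.0) -> float:
    """Feedback gain k1 at which the state-feedback loop is critically damped.

    Solves damping(k1) = 1 numerically on the closed-loop characteristics;
    analytically k1 = 2*sqrt(k2).
    """
    from scipy.optimize import brentq

    def resid(k1: float) -> float:
        p = StateFeedbackParams(q=1.0, k1=k1, k2=k2)
        return closed_loop_summary("state_feedback", p).damping - 1.0

    return float(brentq(resid, 1e-3, 1e3, xtol=1e-12, rtol=1e-14))


def _state_matrices(
    circuit_type: str, params
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if circuit_type == "integral":
        # states (v, y): v' = ki (r - y), y' = b v - a y
        A = np.array([[0.0, -params.ki], [params.b, -params.a]])
        B = np.array([params.ki, 0.0])
    elif circuit_type == "state_feedback":
        # states (x, y): x' = q r - q k2 y - q k1 x, y' = q x
        q = params.q
        A = np.array([[-q * params.k1, -q * params.k2], [q, 0.0]])
        B = np.array([q, 0.0])
    else:
        raise ValueError(f"unknown circuit type {circuit_type!r}")
    C = np.array([0.0, 1.0])
    return A, B, C


def linear_reference_response(
    circuit_type: Literal["integral", "state_feedback"],
    params,
    r: float,
    t_grid: np.ndarray,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Exact step response of the represented linear closed loop on ``t_grid``.

    Computed with the augmented matrix exponential (no numerical integration);
    serves as ground truth for the CRN simulations.
    """
    A, B, C = _state_matrices(circuit_type, params)
    x = np.zeros(2) if x0 is None else np.asarray(x0, dtype=float)
    aug = np.zeros((3, 3))
    aug[:2, :2] = A
    aug[:2, 2] = B * r
    out = np.empty(len(t_grid))
    for i, t in enumerate(np.asarray(t_grid, dtype=float)):
        M = expm(aug * t)
        out[i] = C @ (M[:2, :2] @ x + M[:2, 2])
    return out
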