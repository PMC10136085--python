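"""Dual-rail signal layer.

A possibly-negative signal p is represented by a pair of non-negative species
concentrations, p = x_plus - x_minus.  The rotated coordinates
(bar, hat) = (x_plus - x_minus, x_plus + x_minus) separate the represented
input/output dynamics (bar) from the internal positive dynamics (hat).  When
each '+'-rail reaction has the same rate as its '-'-rail twin, the bimolecular
annihilation terms cancel exactly in the bar dynamics and the represented
system is linear; :func:`io_cancellation_check` verifies this symbolically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy as sp

from .crn import CRN, Species, Trajectory

__all__ = [
    "DualRailPair",
    "DualRailCRN",
    "AsymmetricParam",
    "CancellationReport",
    "signal",
    "rotate",
    "decompose",
    "io_cancellation_check",
]


@dataclass(frozen=True)
class DualRailPair:
    """Named (plus, minus) species pair representing one signal."""

    base_name: str
    plus: str
    minus: str

    def __post_init__(self) -> None:
        if self.plus == self.minus:
            raise ValueError(f"pair {self.base_name!r}: plus and minus species coincide")


@dataclass
class DualRailCRN:
    """A CRN annotated with dual-rail pairs and designated I/O pairs."""

    crn: CRN
    pairs: list[DualRailPair]
    input_pairs: list[str] = field(default_factory=list)
    output_pairs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        declared = set(self.crn.species_names)
        seen: dict[str, str] = {}
        for p in self.pairs:
            for name in (p.plus, p.minus):
                if name not in declared:
                    raise ValueError(f"pair {p.base_name!r} references undeclared {name!r}")
                if name in seen:
                    raise ValueError(
                        f"species {name!r} belongs to both pairs {seen[name]!r} and {p.base_name!r}"
                    )
                seen[name] = p.base_name
        # every rail-role species must belong to exactly one pair
        for s in self.crn.species:
            if s.role in ("signal_plus", "signal_minus") and s.name not in seen:
                raise ValueError(f"rail species {s.name!r} belongs to no pair")
        known = {p.base_name for p in self.pairs}
        for group in (self.input_pairs, self.output_pairs):
            for base in group:
                if base not in known:
                    raise ValueError(f"unknown pair {base!r} in I/O designation")

    def pair(self, base_name: str) -> DualRailPair:
        for p in self.pairs:
            if p.base_name == base_name:
                return p
        raise KeyError(base_name)


@dataclass
class AsymmetricParam:
    """Independent '+'/'-' rail rates for one design parameter.

    ``bar`` = plus_rate - minus_rate and ``hat`` = plus_rate + minus_rate are
    the mismatch and the total; a symmetric parametrisation has bar = 0.
    """

    name: str
    plus_rate: float
    minus_rate: float

    def __post_init__(self) -> None:
        if self.plus_rate <= 0 or self.minus_rate <= 0:
            raise ValueError(f"parameter {self.name!r}: rates must be > 0")

    @property
    def bar(self) -> float:
        return self.plus_rate - self.minus_rate

    @property
    def hat(self) -> float:
        return self.plus_rate + self.minus_rate


def signal(traj: Trajectory, pair: DualRailPair) -> np.ndarray:
    """Represented signal p(t) = x_plus(t) - x_minus(t); may be negative."""
    return traj[pair.plus] - traj[pair.minus]


def rotate(traj: Trajectory, pair: DualRailPair) -> tuple[np.ndarray, np.ndarray]:
    """Rotated coordinates (bar, hat) = (x_plus - x_minus, x_plus + x_minus).

    Exactly invertible: x_plus_minus = (hat +/- bar) / 2.
    """
    plus, minus = traj[pair.plus], traj[pair.minus]
    return plus - minus, plus + minus


def decompose(param: AsymmetricParam) -> tuple[float, float]:
    """Return (bar, hat) = (plus - minus, plus + minus) for a rate parameter."""
    return param.bar, param.hat


# -- symbolic cancellation check --------------------------------------------


@dataclass
class CancellationReport:
    """Per-pair difference dynamics and surviving nonlinear monomials.

    ``residuals`` maps each pair's base name to the list of bimolecular
    monomials (as strings) that fail to cancel in d(x+ - x-)/dt; all lists are
    empty iff the construction is rate-symmetric.  ``difference_dynamics``
    holds the full symbolic expression of each pair's difference dynamics.
    """

    residuals: dict[str, list[str]]
    difference_dynamics: dict[str, sp.Expr]

    @property
    def is_clean(self) -> bool:
        return all(not terms for terms in self.residuals.values())

    def to_json(self) -> str:
        payload = {
            "clean": self.is_clean,
            "residuals": self.residuals,
            "difference_dynamics": {k: str(v) for k, v in self.difference_dynamics.items()},
        }
        return json.dumps(payload, indent=2)


class UnsupportedStructureError(ValueError):
    """A reaction outside the catalysis/degradation/annihilation repertoire."""


def _exact(value: float) -> sp.Rational:
    # exact rational image of the float: equal rates cancel exactly
    return sp.Rational(Fraction(value))


def symbolic_field(crn: CRN) -> tuple[dict[str, sp.Expr], dict[sp.Symbol, sp.Symbol]]:
    """Symbolic mass-action field, species names as symbols, exact rates."""
    syms = {s.name: sp.Symbol(f"x_{i}", nonnegative=True) for i, s in enumerate(crn.species)}
    dx: dict[str, sp.Expr] = {s.name: sp.Integer(0) for s in crn.species}
    for rxn in crn.reactions:
        flux = _exact(rxn.rate_constant)
        for name, c in rxn.reactants.items():
            flux *= syms[name] ** c
        for name, c in rxn.reactants.items():
            dx[name] -= c * flux
        for name, c in rxn.products.items():
            dx[name] += c * flux
    # substitute pretty symbols for reporting
    pretty = {
        syms[s.name]: sp.Symbol(s.name.replace("+", "p").replace("-", "m").replace("'", "p"))
        for s in crn.species
    }
    return {name: sp.expand(expr.subs(pretty)) for name, expr in dx.items()}, pretty


def io_cancellation_check(drcrn: DualRailCRN) -> CancellationReport:
    """Form d(x+ - x-)/dt symbolically per pair and report terms that break
    the represented linear dynamics.

    The difference dynamics are rewritten in rotated coordinates
    (bar = x+ - x-, hat = x+ + x-).  A residual is any surviving bimolecular
    monomial or any dependence on a hat coordinate: for a rate-symmetric
    construction the annihilation terms cancel and the difference dynamics
    close on the bar coordinates alone, so the report is empty; a mismatched
    unimolecular pair couples the hat (internal positive) dynamics into the
    represented system and shows up as a hat-bearing residual.

    All reactions must be catalysis, degradation, annihilation or abstract
    leak catalysis; arbitrary DSD-step reactions are rejected.
    """
    for rxn in drcrn.crn.reactions:
        if rxn.tag not in ("catalysis", "degradation", "annihilation", "leak"):
            raise UnsupportedStructureError(
                f"reaction tagged {rxn.tag!r} is outside the supported repertoire"
            )
    fields, pretty = symbolic_field(drcrn.crn)
    # rotated substitution per pair; unpaired species stay in natural coordinates
    subs: dict[sp.Symbol, sp.Expr] = {}
    hat_syms: set[sp.Symbol] = set()
    bar_syms: set[sp.Symbol] = set()
    def psym(name: str) -> sp.Symbol:
        return sp.Symbol(name.replace("+", "p").replace("-", "m").replace("'", "p"))
    for pair in drcrn.pairs:
        bar = sp.Symbol(f"{pair.base_name}_bar")
        hat = sp.Symbol(f"{pair.base_name}_hat")
        bar_syms.add(bar)
        hat_syms.add(hat)
        subs[psym(pair.plus)] = (hat + bar) / 2
        subs[psym(pair.minus)] = (hat - bar) / 2
    residuals: dict[str, list[str]] = {}
    dyn: dict[str, sp.Expr] = {}
    for pair in drcrn.pairs:
        diff = sp.expand(fields[pair.plus] - fields[pair.minus])
        dyn[pair.base_name] = diff
        rotated = sp.expand(diff.subs(subs))
        bad: list[str] = []
        for term in sp.Add.make_args(rotated):
            degree = sum(
                sp.degree(term, gen=s) for s in bar_syms | hat_syms if term.has(s)
            )
            if degree >= 2 or any(term.has(h) for h in hat_syms):
                bad.append(str(term))
        residuals[pair.base_name] = sorted(bad)
    return CancellationReport(residuals=residuals, difference_dynamics=dyn)
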