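"""Chemical reaction networks under deterministic mass-action kinetics.

A CRN is a list of species and a list of irreversible reactions with integer
stoichiometry and a positive rate constant.  Units are fixed throughout the
package: concentrations in nM, time in seconds, unimolecular rates in s^-1 and
bimolecular rates in (nM s)^-1.  The same container holds both the abstract
dual-rail circuits and the expanded strand-displacement networks, which are
themselves ordinary mass-action CRNs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "CRN",
    "Trajectory",
    "CRNStructureError",
    "IntegrationError",
    "mak_vector_field",
    "jacobian_at",
    "simulate",
    "parse_crn",
    "format_crn",
    "to_sbml",
]

#: roles a species may play; used by the dual-rail layer and the DSD compiler
SPECIES_ROLES = frozenset(
    {
        "signal_plus",
        "signal_minus",
        "reference_plus",
        "reference_minus",
        "auxiliary_single",
        "template_double",
        "intermediate",
        "waste",
        "leak_source",
    }
)

REACTION_TAGS = frozenset({"catalysis", "degradation", "annihilation", "dsd_step", "leak"})


class CRNStructureError(ValueError):
    """Raised when a network references undeclared species or is malformed."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Species:
    """A chemical species with a role annotation and initial concentration (nM)."""

    name: str
    role: str = "auxiliary_single"
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise ValueError(f"unknown species role {self.role!r} for {self.name!r}")
        if self.initial_concentration < 0:
            raise ValueError(f"negative initial concentration for {self.name!r}")


@dataclass
class Reaction:
    """One irreversible mass-action reaction.

    ``reactants`` and ``products`` map species names to non-negative integer
    stoichiometric coefficients.  ``label`` ties the reaction to the design
    parameter it realises (e.g. ``"ki"``), which the DSD compiler and the
    asymmetry machinery use to locate it.
    """

    reactants: dict[str, int]
    products: dict[str, int]
    rate_constant: float
    tag: str = "dsd_step"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ValueError("rate_constant must be > 0")
        if self.tag not in REACTION_TAGS:
            raise ValueError(f"unknown reaction tag {self.tag!r}")
        for side in (self.reactants, self.products):
            for name, coeff in side.items():
                if coeff < 0 or int(coeff) != coeff:
                    raise ValueError(f"stoichiometry must be a non-negative integer ({name})")
        order = sum(self.reactants.values())
        if order not in (1, 2, 3):
            raise ValueError(f"total reactant stoichiometry must be 1, 2 or 3, got {order}")

    @property
    def order(self) -> int:
        return sum(self.reactants.values())


@dataclass
class CRN:
    """Species plus reactions; every referenced species must be declared."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- bookkeeping ---------------------------------------------------------

    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CRNStructureError(f"duplicate species names: {dupes}")
        declared = set(names)
        for i, rxn in enumerate(self.reactions):
            for name in (*rxn.reactants, *rxn.products):
                if name not in declared:
                    raise CRNStructureError(
                        f"reaction {i} references undeclared species {name!r}"
                    )

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def get_species(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], dtype=float)

    def copy(self) -> "CRN":
        return CRN(
            species=[Species(s.name, s.role, s.initial_concentration) for s in self.species],
            reactions=[
                Reaction(dict(r.reactants), dict(r.products), r.rate_constant, r.tag, r.label)
                for r in self.reactions
            ],
        )


@dataclass
class Trajectory:
    """Simulated concentration histories on a strictly increasing time grid."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_species)
    species_names: list[str]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            j = self.species_names.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in trajectory") from None
        return self.concentrations[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=self.species_names)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# -- mass-action kinetics ----------------------------------------------------


def _stoich_arrays(crn: CRN) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reactant matrix A (M x N), net stoichiometry S = (B - A)^T (N x M), rates."""
    idx = crn.species_index()
    n, m = len(crn.species), len(crn.reactions)
    A = np.zeros((m, n))
    S = np.zeros((n, m))
    rates = np.empty(m)
    for k, rxn in enumerate(crn.reactions):
        rates[k] = rxn.rate_constant
        for name, c in rxn.reactants.items():
            A[k, idx[name]] += c
            S[idx[name], k] -= c
        for name, c in rxn.products.items():
            S[idx[name], k] += c
    return A, S, rates


def mak_vector_field(
    crn: CRN, clamp: Iterable[str] = ()
) -> Callable[[np.ndarray], np.ndarray]:
    """Return the polynomial vector field x_dot_j = sum_m gamma_m (b_jm - a_jm) prod_j x_j^a_jm.

    Species named in ``clamp`` are held constant (their derivative is zeroed);
    the DSD layer uses this for the large-excess auxiliary approximation.
    """
    crn.validate()
    A, S, rates = _stoich_arrays(crn)
    idx = crn.species_index()
    clamped = np.zeros(len(crn.species), dtype=bool)
    for name in clamp:
        clamped[idx[name]] = True

    def field(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        # flux_m = gamma_m * prod_j x_j^{a_jm}; A is sparse in practice but tiny
        with np.errstate(invalid="ignore"):
            flux = rates * np.prod(np.power(x[None, :], A), axis=1)
        dx = S @ flux
        dx[clamped] = 0.0
        return dx

    return field


def jacobian_at(
    crn: CRN, state: np.ndarray, clamp: Iterable[str] = ()
) -> np.ndarray:
    """Analytic Jacobian of the mass-action field at ``state``."""
    crn.validate()
    A, S, rates = _stoich_arrays(crn)
    idx = crn.species_index()
    x = np.asarray(state, dtype=float)
    m, n = A.shape
    # d flux_k / d x_j = gamma_k * a_kj * x_j^(a_kj - 1) * prod_{l != j} x_l^a_kl
    dflux = np.zeros((m, n))
    for k in range(m):
        base = rates[k]
        cols = np.nonzero(A[k])[0]
        for j in cols:
            term = base * A[k, j]
            for l in cols:
                a = A[k, l]
                if l == j:
                    if a > 1:
                        term *= x[l] ** (a - 1)
                else:
                    term *= x[l] ** a
            dflux[k, j] = term
    J = S @ dflux
    for name in clamp:
        J[idx[name], :] = 0.0
    return J


def simulate(
    crn: CRN,
    t_end: float,
    n_points: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "BDF",
    clamp: Iterable[str] = (),
    initial_state: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the mass-action ODEs deterministically on [0, t_end].

    Uses a stiff implicit scheme by default: expanded DSD networks mix rates
    spanning four or more orders of magnitude.  Small negative excursions from
    the solver are clipped to zero on output; excursions below -100*atol are
    recorded in ``meta["negative_excursion"]``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    field = mak_vector_field(crn, clamp=clamp)
    clamp = tuple(clamp)

    def rhs(_t, x):
        return field(x)

    def jac(_t, x):
        return jacobian_at(crn, x, clamp=clamp)

    x0 = crn.initial_state() if initial_state is None else np.asarray(initial_state, float)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs, (0.0, t_end), x0, method=method, t_eval=t_eval, rtol=rtol, atol=atol, jac=jac
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_time=last)
    conc = sol.y.T.copy()
    tol_neg = 100.0 * atol
    worst = float(conc.min(initial=0.0))
    meta = {
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "n_points": n_points,
        "negative_excursion": worst < -tol_neg,
        "min_concentration": worst,
        "clamped": list(clamp),
    }
    np.clip(conc, 0.0, None, out=conc)
    return Trajectory(times=t_eval, concentrations=conc, species_names=crn.species_names, meta=meta)


# -- text format -------------------------------------------------------------
#
# One reaction per line:   A + 2 B -> C @ 1e-3
# The empty side is written "0" or "Ø".  A trailing prime on a species name
# marks the minus rail for the optional dual-rail importer.

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_'+\-]*)\s*$")


def _parse_side(text: str) -> dict[str, int]:
    text = text.strip()
    if text in ("0", "Ø", ""):
        return {}
    side: dict[str, int] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"cannot parse reaction term {term!r}")
        coeff = int(m.group(1) or 1)
        name = m.group(2)
        side[name] = side.get(name, 0) + coeff
    return side


def _guess_tag(reactants: dict[str, int], products: dict[str, int]) -> str:
    n_react = sum(reactants.values())
    if n_react == 1 and not products:
        return "degradation"
    if n_react == 2 and len(reactants) == 2 and not products:
        return "annihilation"
    if n_react == 1 and sum(products.values()) == 2 and next(iter(reactants)) in products:
        return "catalysis"
    return "dsd_step"


def parse_crn(text: str) -> CRN:
    """Parse the line-oriented reaction format; species are auto-declared.

    Splitting on '+' makes '+'/'-' suffixes unusable here, so the importer
    follows the prime convention: a trailing apostrophe marks the minus rail.
    """
    species: dict[str, Species] = {}
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line or "@" not in line:
            raise ValueError(f"line {lineno}: expected 'reactants -> products @ rate'")
        lhs, rest = line.split("->", 1)
        rhs, rate_s = rest.rsplit("@", 1)
        reactants = _parse_side(lhs)
        products = _parse_side(rhs)
        rate = float(rate_s)
        for name in (*reactants, *products):
            if name not in species:
                role = "signal_minus" if name.endswith("'") else "auxiliary_single"
                species[name] = Species(name, role=role)
        reactions.append(
            Reaction(reactants, products, rate, tag=_guess_tag(reactants, products))
        )
    return CRN(species=list(species.values()), reactions=reactions)


def format_crn(crn: CRN) -> str:
    """Serialize to the text format; round-trips through :func:`parse_crn`.

    Rail species are renamed for the file convention ('X+' -> 'X',
    'X-' -> "X'") since '+' delimits reaction terms; names are collision-checked.
    """
    rename: dict[str, str] = {}
    taken = set()
    for s in crn.species:
        if s.name.endswith("+"):
            cand = s.name[:-1]
        elif s.name.endswith("-"):
            cand = s.name[:-1] + "'"
        else:
            cand = s.name
        while cand in taken:
            cand += "_"
        rename[s.name] = cand
        taken.add(cand)

    def side(terms: Mapping[str, int]) -> str:
        if not terms:
            return "0"
        parts = []
        for name, coeff in terms.items():
            nm = rename[name]
            parts.append(nm if coeff == 1 else f"{coeff} {nm}")
        return " + ".join(parts)

    lines = [
        f"{side(r.reactants)} -> {side(r.products)} @ {r.rate_constant:.12g}"
        for r in crn.reactions
    ]
    return "\n".join(lines) + "\n"


# -- SBML export -------------------------------------------------------------


def to_sbml(crn: CRN, model_id: str = "crn") -> str:
    """Serialise the network as an SBML Level 3 Version 2 document string.

    Species and mass-action kinetic laws only; written directly as XML.
    """
    from lxml import etree

    SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
    MATHML_NS = "http://www.w3.org/1998/Math/MathML"
    sbml = etree.Element("{%s}sbml" % SBML_NS, nsmap={None: SBML_NS})
    sbml.set("level", "3")
    sbml.set("version", "2")
    model = etree.SubElement(sbml, "{%s}model" % SBML_NS, id=model_id)
    comp_list = etree.SubElement(model, "{%s}listOfCompartments" % SBML_NS)
    etree.SubElement(
        comp_list, "{%s}compartment" % SBML_NS, id="main", constant="true", size="1"
    )

    def sid(name: str) -> str:
        return (
            name.replace("+", "_plus").replace("-", "_minus").replace("'", "_p")
        )

    sp_list = etree.SubElement(model, "{%s}listOfSpecies" % SBML_NS)
    for s in crn.species:
        etree.SubElement(
            sp_list,
            "{%s}species" % SBML_NS,
            id=sid(s.name),
            name=s.name,
            compartment="main",
            initialConcentration=repr(s.initial_concentration),
            hasOnlySubstanceUnits="false",
            boundaryCondition="false",
            constant="false",
        )
    rx_list = etree.SubElement(model, "{%s}listOfReactions" % SBML_NS)
    for i, rxn in enumerate(crn.reactions):
        rx = etree.SubElement(
            rx_list, "{%s}reaction" % SBML_NS, id=f"r{i}", reversible="false"
        )
        if rxn.reactants:
            lo = etree.SubElement(rx, "{%s}listOfReactants" % SBML_NS)
            for name, c in rxn.reactants.items():
                etree.SubElement(
                    lo,
                    "{%s}speciesReference" % SBML_NS,
                    species=sid(name),
                    stoichiometry=str(c),
                    constant="true",
                )
        if rxn.products:
            lo = etree.SubElement(rx, "{%s}listOfProducts" % SBML_NS)
            for name, c in rxn.products.items():
                etree.SubElement(
                    lo,
                    "{%s}speciesReference" % SBML_NS,
                    species=sid(name),
                    stoichiometry=str(c),
                    constant="true",
                )
        kl = etree.SubElement(rx, "{%s}kineticLaw" % SBML_NS)
        math = etree.SubElement(kl, "{%s}math" % MATHML_NS, nsmap={None: MATHML_NS})
        apply_el = etree.SubElement(math, "{%s}apply" % MATHML_NS)
        etree.SubElement(apply_el, "{%s}times" % MATHML_NS)
        cn = etree.SubElement(apply_el, "{%s}cn" % MATHML_NS)
        cn.text = repr(rxn.rate_constant)
        for name, c in rxn.reactants.items():
            for _ in range(c):
                ci = etree.SubElement(apply_el, "{%s}ci" % MATHML_NS)
                ci.text = sid(name)
    return etree.tostring(sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()
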