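"""Compiler from dual-rail CRNs to DNA strand-displacement reaction networks.

Each abstract reaction is expanded into a toehold-mediated scheme:

* catalysis Xi -> Xi + Xj: a Join template captures the input strand, two
  auxiliary exchanges hand an intermediate signal strand to a Fork template,
  which releases the regenerated input and the product, with an irreversible
  final cleanup;
* degradation Y -> 0: a single Join template captures the signal strand
  irreversibly into inert waste;
* annihilation X+ + X- -> 0: cooperative hybridisation — one template binds
  either input reversibly and completes irreversibly into waste only when both
  are present.

Rates follow the toehold model: a reaction mediated by a signal toehold runs
at c*kt where 0 < c <= 1 is the engineered complementarity degree and kt the
maximum signal-toehold binding rate; auxiliary exchanges run at kbnd both
ways.  Templates and fuel strands are supplied at the high concentration Cmax,
so each capture approximates a unimolecular reaction of rate Cmax*c*kt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .crn import CRN, Reaction, Species
from .dualrail import DualRailCRN

__all__ = [
    "RateScheme",
    "DSDNetwork",
    "Census",
    "UnsupportedReactionError",
    "expand_catalysis",
    "expand_degradation",
    "expand_annihilation",
    "expand_crn",
    "census",
    "effective_rates",
    "inject_leak",
    "inject_dsd_leak",
]


class UnsupportedReactionError(ValueError):
    """Raised for reactions outside the catalysis/degradation/annihilation shapes."""


@dataclass
class RateScheme:
    """Physical parameters of the strand-displacement implementation.

    ``complementarity`` maps abstract reaction labels (the design parameter a
    reaction realises, e.g. ``"ki"``) to toehold complementarity degrees
    c in (0, 1].  ``kleak`` > 0 turns the irreversible degradation captures
    into reversible ones (leaky unbinding).  ``clamp_auxiliaries`` freezes all
    supplied species at Cmax during simulation (the large-excess idealisation).
    """

    Cmax: float = 1e4  # nM
    kt: float = 1e-4  # (nM s)^-1, signal-toehold maximum binding rate
    kbnd: float = 1e-3  # (nM s)^-1, auxiliary-toehold binding rate
    kubnd: float = 0.1  # s^-1, unbinding rate
    complementarity: dict[str, float] = field(default_factory=dict)
    kleak: float = 0.0  # s^-1; 0 disables leak
    clamp_auxiliaries: bool = False

    def __post_init__(self) -> None:
        if self.Cmax <= 0:
            raise ValueError("Cmax must be > 0")
        for key, c in self.complementarity.items():
            if not 0 < c <= 1:
                raise ValueError(f"complementarity degree for {key!r} must be in (0, 1]")
        if self.kleak < 0:
            raise ValueError("kleak must be >= 0")

    def degree_for(self, rxn: Reaction) -> float:
        key = rxn.label
        if key is None or key not in self.complementarity:
            raise KeyError(
                f"no complementarity degree for reaction labelled {key!r}; "
                f"known labels: {sorted(self.complementarity)}"
            )
        return self.complementarity[key]

    @classmethod
    def from_json(cls, path) -> "RateScheme":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


@dataclass
class Census:
    double_stranded_supplied: int
    single_stranded_supplied: int
    waste_species: int
    intermediate_species: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class DSDNetwork:
    """An expanded strand-displacement network; itself a mass-action CRN.

    ``supplied`` are the template complexes and fuel strands initialised at
    Cmax.  ``recycled`` are strands that shuttle within a cascade (released by
    the Join stage, consumed by the Fork stage); they start at zero and are
    excluded from the supplied census.  ``input_strands`` are the reference
    signal strands.  ``provenance`` maps each DSD reaction index to the index
    of the abstract reaction it implements (-1 for injected leak reactions).
    """

    crn: CRN
    strandedness: dict[str, str]
    supplied: set[str]
    recycled: set[str]
    input_strands: set[str]
    provenance: dict[int, int]
    scheme: RateScheme
    source_labels: dict[int, str | None] = field(default_factory=dict)

    def clamped_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.supplied)) if self.scheme.clamp_auxiliaries else ()

    def sidecar_json(self) -> str:
        return json.dumps(
            {
                "strandedness": self.strandedness,
                "supplied": sorted(self.supplied),
                "recycled": sorted(self.recycled),
                "input_strands": sorted(self.input_strands),
                "provenance": {str(k): v for k, v in self.provenance.items()},
            },
            indent=2,
        )


def _san(name: str) -> str:
    """ASCII strand name: drop '+', render the minus rail / prime as 'p'."""
    return name.replace("+", "").replace("-", "p").replace("'", "p")


class _Expander:
    """Accumulates species and reactions while expanding one dual-rail CRN."""

    def __init__(self, scheme: RateScheme):
        self.scheme = scheme
        self.species: dict[str, Species] = {}
        self.reactions: list[Reaction] = []
        self.strandedness: dict[str, str] = {}
        self.supplied: set[str] = set()
        self.recycled: set[str] = set()
        self.input_strands: set[str] = set()
        self.provenance: dict[int, int] = {}
        self.source_labels: dict[int, str | None] = {}

    def add_species(
        self, name: str, role: str, strands: str, conc: float = 0.0, supplied: bool = False
    ) -> str:
        if name not in self.species:
            self.species[name] = Species(name, role=role, initial_concentration=conc)
            self.strandedness[name] = strands
            if supplied:
                self.supplied.add(name)
        return name

    def add_signal(self, abstract: Species) -> str:
        name = _san(abstract.name)
        if name not in self.species:
            self.species[name] = Species(
                name, role=abstract.role, initial_concentration=abstract.initial_concentration
            )
            self.strandedness[name] = "single"
            if abstract.role in ("reference_plus", "reference_minus"):
                self.input_strands.add(name)
        return name

    def emit(self, rxn: Reaction, source_index: int, source_label: str | None) -> None:
        self.provenance[len(self.reactions)] = source_index
        self.source_labels[len(self.reactions)] = source_label
        self.reactions.append(rxn)

    # -- per-shape templates -------------------------------------------------

    def catalysis(self, rxn: Reaction, idx: int, sig_species: Mapping[str, Species]) -> None:
        react_name = next(iter(rxn.reactants))
        prods = dict(rxn.products)
        prods[react_name] -= 1
        prod_name = next(n for n, c in prods.items() if c > 0)
        R = self.add_signal(sig_species[react_name])
        P = self.add_signal(sig_species[prod_name])
        cid = f"{P}{R}"
        c = self.scheme.degree_for(rxn)
        kt, kbnd, Cmax = self.scheme.kt, self.scheme.kbnd, self.scheme.Cmax
        J = self.add_species(f"Join{cid}", "template_double", "double", Cmax, supplied=True)
        J1 = self.add_species(f"Join{cid}_1", "intermediate", "double")
        J2 = self.add_species(f"Join{cid}_2", "intermediate", "double")
        F = self.add_species(f"Fork{cid}", "template_double", "double", Cmax, supplied=True)
        F1 = self.add_species(f"Fork{cid}_1", "intermediate", "double")
        F2 = self.add_species(f"Fork{cid}_2", "intermediate", "double")
        F3 = self.add_species(f"Fork{cid}_3", "intermediate", "double")
        F4 = self.add_species(f"Fork{cid}_4", "waste", "double")
        # released by the Join stage and taken back by the Fork stage; supplied
        # at Cmax like the other fuels but counted as recycled in the census
        ret = self.add_species(f"aux_{cid}_r", "auxiliary_single", "single", Cmax, supplied=True)
        self.recycled.add(ret)
        f1 = self.add_species(f"aux_{cid}_1", "auxiliary_single", "single", Cmax, supplied=True)
        sig = self.add_species(f"sig_{cid}", "intermediate", "single")
        f2 = self.add_species(f"aux_{cid}_2", "auxiliary_single", "single", Cmax, supplied=True)
        f3 = self.add_species(f"aux_{cid}_3", "auxiliary_single", "single", Cmax, supplied=True)
        lab = rxn.label
        steps = [
            # Join capture of the input strand, slowed by the complementarity degree
            ({R: 1, J: 1}, {J1: 1, ret: 1}, c * kt),
            ({J1: 1, ret: 1}, {R: 1, J: 1}, kt),
            # auxiliary exchange releasing the intermediate signal strand
            ({J1: 1, f1: 1}, {J2: 1, sig: 1}, kbnd),
            ({J2: 1, sig: 1}, {J1: 1, f1: 1}, kbnd),
            # intermediate strand hands over to the Fork template
            ({sig: 1, F: 1}, {F1: 1, f1: 1}, kbnd),
            ({F1: 1, f1: 1}, {sig: 1, F: 1}, kbnd),
            # Fork releases the regenerated input strand
            ({F1: 1, ret: 1}, {F2: 1, R: 1}, kbnd),
            ({F2: 1, R: 1}, {F1: 1, ret: 1}, kt),
            # Fork releases the product strand
            ({F2: 1, f2: 1}, {F3: 1, P: 1}, kt),
            ({F3: 1, P: 1}, {F2: 1, f2: 1}, kt),
            # irreversible cleanup into inert waste
            ({F3: 1, f3: 1}, {F4: 1}, kt),
        ]
        for reactants, products, rate in steps:
            self.emit(Reaction(reactants, products, rate, "dsd_step", lab), idx, lab)

    def degradation(self, rxn: Reaction, idx: int, sig_species: Mapping[str, Species]) -> None:
        react_name = next(iter(rxn.reactants))
        R = self.add_signal(sig_species[react_name])
        c = self.scheme.degree_for(rxn)
        Cmax = self.scheme.Cmax
        J = self.add_species(f"Join{R}", "template_double", "double", Cmax, supplied=True)
        J1 = self.add_species(f"Join{R}_1", "waste", "double")
        d = self.add_species(f"d{R}", "waste", "single")
        lab = rxn.label
        self.emit(
            Reaction({J: 1, R: 1}, {J1: 1, d: 1}, c * self.scheme.kt, "dsd_step", lab), idx, lab
        )
        if self.scheme.kleak > 0:
            self.emit(
                Reaction({J1: 1, d: 1}, {J: 1, R: 1}, self.scheme.kleak, "leak", lab), idx, lab
            )

    def annihilation(self, rxn: Reaction, idx: int, sig_species: Mapping[str, Species]) -> None:
        names = list(rxn.reactants)
        if len(names) != 2:
            raise UnsupportedReactionError("annihilation needs two distinct reactants")
        A = self.add_signal(sig_species[names[0]])
        B = self.add_signal(sig_species[names[1]])
        c = self.scheme.degree_for(rxn)
        kt, kubnd, Cmax = self.scheme.kt, self.scheme.kubnd, self.scheme.Cmax
        Ann = self.add_species(f"Ann{A}{B}", "template_double", "double", Cmax, supplied=True)
        IA = self.add_species(f"I{A}", "intermediate", "double")
        IB = self.add_species(f"I{B}", "intermediate", "double")
        WA = self.add_species(f"W{A}", "waste", "double")
        WB = self.add_species(f"W{B}", "waste", "double")
        lab = rxn.label
        steps = [
            ({Ann: 1, A: 1}, {IA: 1}, c * kt),
            ({IA: 1}, {Ann: 1, A: 1}, kubnd),
            ({IA: 1, B: 1}, {WA: 1, WB: 1}, c * kt),
            ({Ann: 1, B: 1}, {IB: 1}, c * kt),
            ({IB: 1}, {Ann: 1, B: 1}, kubnd),
            ({IB: 1, A: 1}, {WA: 1, WB: 1}, c * kt),
        ]
        for reactants, products, rate in steps:
            self.emit(Reaction(reactants, products, rate, "dsd_step", lab), idx, lab)

    def expand_reaction(self, rxn: Reaction, idx: int, sig_species: Mapping[str, Species]) -> None:
        if rxn.tag == "catalysis":
            react = next(iter(rxn.reactants))
            ok = (
                len(rxn.reactants) == 1
                and rxn.order == 1
                and sum(rxn.products.values()) == 2
                and rxn.products.get(react, 0) >= 1
            )
            if not ok:
                raise UnsupportedReactionError(f"malformed catalysis reaction {rxn}")
            self.catalysis(rxn, idx, sig_species)
        elif rxn.tag == "degradation":
            if rxn.order != 1 or rxn.products:
                raise UnsupportedReactionError(f"malformed degradation reaction {rxn}")
            self.degradation(rxn, idx, sig_species)
        elif rxn.tag == "annihilation":
            if rxn.order != 2 or len(rxn.reactants) != 2 or rxn.products:
                raise UnsupportedReactionError(f"malformed annihilation reaction {rxn}")
            self.annihilation(rxn, idx, sig_species)
        else:
            raise UnsupportedReactionError(
                f"reaction tagged {rxn.tag!r} cannot be compiled to DSD"
            )

    def network(self) -> DSDNetwork:
        crn = CRN(species=list(self.species.values()), reactions=self.reactions)
        return DSDNetwork(
            crn=crn,
            strandedness=self.strandedness,
            supplied=self.supplied,
            recycled=self.recycled,
            input_strands=self.input_strands,
            provenance=self.provenance,
            scheme=self.scheme,
            source_labels=self.source_labels,
        )


def _single_reaction_network(rxn: Reaction, scheme: RateScheme) -> DSDNetwork:
    names = set(rxn.reactants) | set(rxn.products)
    sig_species = {n: Species(n, role="signal_plus") for n in names}
    exp = _Expander(scheme)
    exp.expand_reaction(rxn, 0, sig_species)
    return exp.network()


def expand_catalysis(rxn: Reaction, scheme: RateScheme) -> DSDNetwork:
    """Expand one catalysis reaction Xi -> Xi + Xj through Join/Fork templates."""
    if rxn.tag != "catalysis":
        raise UnsupportedReactionError("expected a catalysis reaction")
    return _single_reaction_network(rxn, scheme)


def expand_degradation(rxn: Reaction, scheme: RateScheme) -> DSDNetwork:
    """Expand one degradation reaction Y -> 0 as an irreversible Join capture."""
    if rxn.tag != "degradation":
        raise UnsupportedReactionError("expected a degradation reaction")
    return _single_reaction_network(rxn, scheme)


def expand_annihilation(rxn: Reaction, scheme: RateScheme) -> DSDNetwork:
    """Expand one annihilation reaction via cooperative hybridisation."""
    if rxn.tag != "annihilation":
        raise UnsupportedReactionError("expected an annihilation reaction")
    return _single_reaction_network(rxn, scheme)


def expand_crn(drcrn: DualRailCRN, scheme: RateScheme) -> DSDNetwork:
    """Expand a whole dual-rail CRN; signal strands are shared across cascades."""
    sig_species = {s.name: s for s in drcrn.crn.species}
    exp = _Expander(scheme)
    unsupported = [
        f"#{i} ({r.tag})"
        for i, r in enumerate(drcrn.crn.reactions)
        if r.tag not in ("catalysis", "degradation", "annihilation")
    ]
    if unsupported:
        raise UnsupportedReactionError(f"cannot compile reactions: {', '.join(unsupported)}")
    for i, rxn in enumerate(drcrn.crn.reactions):
        exp.expand_reaction(rxn, i, sig_species)
    return exp.network()


def census(net: DSDNetwork) -> Census:
    """Species counts by strandedness and supplied/waste/intermediate class.

    Single-stranded supplied count follows the convention of three fuel
    strands per catalysis cascade (the recycled Join-released strand is not
    counted) plus the reference input strands.
    """
    ds_supplied = sum(1 for n in net.supplied if net.strandedness[n] == "double")
    ss_supplied = sum(
        1 for n in net.supplied if net.strandedness[n] == "single" and n not in net.recycled
    ) + len(net.input_strands)
    waste = sum(1 for s in net.crn.species if s.role == "waste")
    inter = sum(1 for s in net.crn.species if s.role == "intermediate")
    return Census(ds_supplied, ss_supplied, waste, inter)


def effective_rates(net: DSDNetwork, drcrn: DualRailCRN) -> dict[str, float]:
    """Approximate rate each abstract reaction label realises under the
    large-excess idealisation: Cmax*c*kt for catalysis/degradation captures,
    c*kt (binding-limited, bimolecular) for annihilation."""
    scheme = net.scheme
    out: dict[str, float] = {}
    for rxn in drcrn.crn.reactions:
        if rxn.label is None:
            continue
        c = scheme.degree_for(rxn)
        if rxn.tag in ("catalysis", "degradation"):
            out[rxn.label] = scheme.Cmax * c * scheme.kt
        elif rxn.tag == "annihilation":
            out[rxn.label] = c * scheme.kt
    return out


def inject_leak(
    drcrn: DualRailCRN,
    output_pair: str,
    rho_plus: float,
    rho_minus: float,
    z_plus0: float = 1.0,
    z_minus0: float = 1.0,
) -> DualRailCRN:
    """Abstract-level leak: add sources Z+/- catalysing the output strands.

    Models spurious release of the output species at rates rho_plus/minus
    (approximately Cmax*kleak when the sources interact with high-concentration
    auxiliaries); the leak structure is duplicated on both rails.  Passing
    rho = 0 on both rails returns an unmodified copy.
    """
    pair = drcrn.pair(output_pair)
    crn = drcrn.crn.copy()
    if rho_plus == 0 and rho_minus == 0:
        return DualRailCRN(crn, list(drcrn.pairs), list(drcrn.input_pairs), list(drcrn.output_pairs))
    crn.species.append(Species("Z+", "leak_source", z_plus0))
    crn.species.append(Species("Z-", "leak_source", z_minus0))
    if rho_plus > 0:
        crn.reactions.append(
            Reaction({"Z+": 1}, {"Z+": 1, pair.plus: 1}, rho_plus, "leak", "rho")
        )
    if rho_minus > 0:
        crn.reactions.append(
            Reaction({"Z-": 1}, {"Z-": 1, pair.minus: 1}, rho_minus, "leak", "rho")
        )
    crn.validate()
    return DualRailCRN(crn, list(drcrn.pairs), list(drcrn.input_pairs), list(drcrn.output_pairs))


def inject_dsd_leak(net: DSDNetwork, kleak: float) -> DSDNetwork:
    """DSD-level leak: make every irreversible degradation capture reversible
    at rate ``kleak``.  ``kleak = 0`` returns the network unchanged."""
    if kleak == 0:
        return net
    crn = net.crn.copy()
    provenance = dict(net.provenance)
    labels = dict(net.source_labels)
    new_rxns: list[Reaction] = []
    for i, rxn in enumerate(crn.reactions):
        is_capture = (
            rxn.tag == "dsd_step"
            and any(n.startswith("Join") for n in rxn.reactants)
            and any(n.startswith("d") and net.strandedness.get(n) == "single" for n in rxn.products)
        )
        if is_capture:
            new_rxns.append(
                Reaction(dict(rxn.products), dict(rxn.reactants), kleak, "leak", rxn.label)
            )
            provenance[len(crn.reactions) + len(new_rxns) - 1] = net.provenance[i]
            labels[len(crn.reactions) + len(new_rxns) - 1] = rxn.label
    crn.reactions.extend(new_rxns)
    crn.validate()
    return DSDNetwork(
        crn=crn,
        strandedness=dict(net.strandedness),
        supplied=set(net.supplied),
        recycled=set(net.recycled),
        input_strands=set(net.input_strands),
        provenance=provenance,
        scheme=net.scheme,
        source_labels=labels,
    )
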