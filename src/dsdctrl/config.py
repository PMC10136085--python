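"""Run configuration and the end-to-end pipeline: build -> (expand) -> simulate
-> analyze -> report.

Configs are JSON (``//`` comment lines are stripped).  Outputs are plain text:
the reaction network in the line format, trajectories as CSV, reports as JSON;
every emitted file records the config hash so runs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, ValidationError, field_validator

from .analysis import unforced_equilibria_integral
from .circuits import (
    IntegralCircuitParams,
    StateFeedbackParams,
    build_integral_circuit,
    build_state_feedback_circuit,
    closed_loop_summary,
)
from .crn import format_crn, simulate, to_sbml
from .dsd import RateScheme, census, effective_rates, expand_crn, inject_leak
from .dualrail import rotate

__all__ = ["RunConfig", "load_config", "validate_config", "run", "load_scheme"]

BUILTIN_SCHEMES = {"integral_default", "state_feedback_default"}


class CircuitBlock(BaseModel):
    type: Literal["integral", "state_feedback"]
    variant: Literal["catalytic_degradation", "degradation"] = "degradation"
    a: float = 2.5e-3
    b: float = 1e-3
    ki: float = 5e-2
    q: float = 8e-3
    k1: float = 1.0
    k2: float = 1.0
    eta: float = 1e-3
    include_output_annihilation: bool = True
    include_x_annihilation: bool = True

    @field_validator("a", "b", "ki", "q", "k1", "k2", "eta")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("rates and gains must be > 0")
        return v


class SimulationBlock(BaseModel):
    t_end: float = Field(default=8e3, gt=0)
    n_points: int = Field(default=400, ge=2)
    rtol: float = Field(default=1e-8, gt=0)
    atol: float = Field(default=1e-12, gt=0)
    method: str = "BDF"


class LeakBlock(BaseModel):
    rho_plus: float = Field(default=0.0, ge=0)
    rho_minus: float = Field(default=0.0, ge=0)
    z_plus0: float = Field(default=1.0, ge=0)
    z_minus0: float = Field(default=1.0, ge=0)


class SchemeBlock(BaseModel):
    Cmax: float = Field(default=1e4, gt=0)
    kt: float = Field(default=1e-4, gt=0)
    kbnd: float = Field(default=1e-3, gt=0)
    kubnd: float = Field(default=0.1, gt=0)
    complementarity: dict[str, float] = Field(default_factory=dict)
    kleak: float = Field(default=0.0, ge=0)
    clamp_auxiliaries: bool = False

    @field_validator("complementarity")
    @classmethod
    def _degrees(cls, v: dict[str, float]) -> dict[str, float]:
        for key, c in v.items():
            if not 0 < c <= 1:
                raise ValueError(f"complementarity degree for {key!r} must be in (0, 1]")
        return v

    def to_scheme(self) -> RateScheme:
        return RateScheme(**self.model_dump())


class RunConfig(BaseModel):
    circuit: CircuitBlock
    level: Literal["abstract_crn", "dsd"] = "abstract_crn"
    scheme: Optional[str | SchemeBlock] = None
    simulation: SimulationBlock = SimulationBlock()
    reference: float = Field(default=10.0, ge=0)
    leak: Optional[LeakBlock] = None
    asymmetry: dict[str, tuple[float, float]] = Field(default_factory=dict)
    output_dir: str = "out"
    export_sbml: bool = False

    def model_post_init(self, _ctx) -> None:
        if self.level == "dsd" and self.scheme is None:
            raise ValueError("level='dsd' requires a scheme")

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_scheme(ref: str | SchemeBlock | None) -> RateScheme:
    if ref is None:
        raise ValueError("no rate scheme given")
    if isinstance(ref, SchemeBlock):
        return ref.to_scheme()
    if ref in BUILTIN_SCHEMES:
        text = resources.files("dsdctrl.schemes").joinpath(f"{ref}.json").read_text()
        return RateScheme(**json.loads(text))
    return RateScheme.from_json(ref)


def _strip_comments(text: str) -> str:
    return "\n".join(l for l in text.splitlines() if not l.lstrip().startswith("//"))


def load_config(path) -> RunConfig:
    data = json.loads(_strip_comments(Path(path).read_text()))
    return RunConfig.model_validate(data)


def validate_config(path) -> list[str]:
    """Return a machine-readable list of validation errors (empty if valid)."""
    try:
        load_config(path)
    except ValidationError as err:
        return [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
    except (ValueError, OSError, json.JSONDecodeError) as err:
        return [str(err)]
    return []


def _build(config: RunConfig):
    c = config.circuit
    asym = {k: tuple(v) for k, v in config.asymmetry.items()} or None
    if c.type == "integral":
        params = IntegralCircuitParams(
            a=c.a, b=c.b, ki=c.ki, eta=c.eta,
            include_output_annihilation=c.include_output_annihilation,
        )
        return params, build_integral_circuit(params, reference=config.reference, asymmetry=asym)
    params = StateFeedbackParams(
        q=c.q, k1=c.k1, k2=c.k2, eta=c.eta, variant=c.variant,
        include_x_annihilation=c.include_x_annihilation,
    )
    return params, build_state_feedback_circuit(params, reference=config.reference, asymmetry=asym)


def run(config: RunConfig) -> dict[str, str]:
    """Execute the pipeline described by ``config``; returns artifact paths.

    Deterministic: identical configs produce byte-identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    written: dict[str, str] = {}

    def emit(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        written[name] = str(path)

    params, circuit = _build(config)
    if config.leak is not None and (config.leak.rho_plus or config.leak.rho_minus):
        circuit = inject_leak(
            circuit, circuit.output_pairs[0],
            config.leak.rho_plus, config.leak.rho_minus,
            config.leak.z_plus0, config.leak.z_minus0,
        )
    emit("circuit.crn.txt", f"# config {h}\n" + format_crn(circuit.crn))
    if config.export_sbml:
        emit("circuit.sbml.xml", to_sbml(circuit.crn))

    sim = config.simulation
    traj = simulate(
        circuit.crn, t_end=sim.t_end, n_points=sim.n_points,
        rtol=sim.rtol, atol=sim.atol, method=sim.method,
    )
    emit("trajectory_crn.csv", traj.to_frame().to_csv(index=False))

    ypair = circuit.pair(circuit.output_pairs[0])
    ybar, yhat = rotate(traj, ypair)
    summary = closed_loop_summary(config.circuit.type, params)
    report: dict = {
        "config_hash": h,
        "closed_loop": {
            "poles": [[p.real, p.imag] for p in summary.poles],
            "natural_frequency": summary.natural_frequency,
            "damping": summary.damping,
            "dc_gain": summary.dc_gain,
        },
        "terminal_output_signal": float(ybar[-1]),
        "terminal_output_hat": float(yhat[-1]),
    }
    if config.circuit.type == "integral":
        eq = unforced_equilibria_integral(params)
        report["unforced_equilibria"] = {
            "pairs_yhat_vhat": eq.equilibria,
            "frobenius_eigenvalue": eq.frobenius_eigenvalue,
            "stable_origin": eq.stable_origin,
        }

    if config.level == "dsd":
        scheme = load_scheme(config.scheme)
        net = expand_crn(_build(config)[1], scheme)  # leak-free abstract base
        emit("dsd.crn.txt", f"# config {h}\n" + format_crn(net.crn))
        emit("dsd_sidecar.json", net.sidecar_json())
        dsd_traj = simulate(
            net.crn, t_end=sim.t_end, n_points=sim.n_points,
            rtol=sim.rtol, atol=sim.atol, method=sim.method,
            clamp=net.clamped_names(),
        )
        emit("trajectory_dsd.csv", dsd_traj.to_frame().to_csv(index=False))
        ybar_dsd = dsd_traj["Y"] - dsd_traj["Yp"]
        gap = float(np.max(np.abs(ybar_dsd - ybar)))
        report["dsd"] = {
            "census": census(net).as_dict(),
            "effective_rates": effective_rates(net, circuit),
            "output_gap_sup": gap,
        }

    emit("report.json", json.dumps(report, indent=2))
    emit("config_echo.json", json.dumps({"hash": h, **config.model_dump()}, indent=2, default=str))
    return written
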