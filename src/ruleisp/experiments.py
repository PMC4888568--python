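"""Stimulation protocols and perturbation experiments.

A :class:`Protocol` is an insulin step at t=0 (dose in nM, converted to
molecules/cell via NA*V) with a constant amino-acid input, simulated over
[t0, t] minutes.  A :class:`Perturbation` either removes a named feedback
loop's rules or scales a named parameter; both return a new model and
leave the original untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .isp import FEEDBACK_RULES, UnitContext, nM_to_molecules
from .network import RuleModel, generate_network
from .ode import SimulationResult, simulate_deterministic


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class Protocol:
    """Insulin stimulation protocol: a dose step at t=0, amino acids constant."""

    insulin_nM: float = 100.0
    t_start: float = 0.0
    t_end: float = 60.0
    grid_dt: float = 0.1
    amino_acid_level: Optional[float] = None  # molecules/cell; None = model default
    context: UnitContext = field(default_factory=UnitContext)

    def __post_init__(self):
        if self.insulin_nM < 0:
            raise ProtocolError("insulin dose must be non-negative")
        if self.t_end <= self.t_start:
            raise ProtocolError("protocol duration must be positive")


@dataclass(frozen=True)
class Perturbation:
    """remove_rule_set on a named feedback, or scale_parameter by a factor."""

    kind: str  # "remove_rule_set" | "scale_parameter"
    target: str
    factor: float = 1.0

    def __post_init__(self):
        if self.kind not in ("remove_rule_set", "scale_parameter"):
            raise ProtocolError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "scale_parameter" and self.factor <= 0:
            raise ProtocolError("scale factor must be positive")


def apply_perturbation(model: RuleModel, perturbation: Perturbation) -> RuleModel:
    """Return a perturbed copy of the model; the original is untouched."""
    out = model.copy()
    if perturbation.kind == "remove_rule_set":
        try:
            removed = set(FEEDBACK_RULES[perturbation.target])
        except KeyError:
            raise ProtocolError(
                f"unknown feedback {perturbation.target!r}; "
                f"valid: {sorted(FEEDBACK_RULES)}"
            ) from None
        out.rules = [r for r in out.rules if r.name not in removed]
        out.name = f"{model.name}_wo_{perturbation.target}"
    else:
        if perturbation.target not in out.parameters:
            raise ProtocolError(
                f"unknown parameter {perturbation.target!r}; "
                f"valid: {sorted(out.parameters)[:10]}..."
            )
        out.parameters[perturbation.target] = (
            out.parameters[perturbation.target] * perturbation.factor
        )
        out.name = f"{model.name}_{perturbation.target}x{perturbation.factor:g}"
    return out


def zero_feedback_rates(model: RuleModel, feedback: str) -> RuleModel:
    """Alternative ablation route: keep the feedback's rules but zero every
    rate constant they reference (must match rule removal exactly)."""
    out = model.copy()
    try:
        names = set(FEEDBACK_RULES[feedback])
    except KeyError:
        raise ProtocolError(f"unknown feedback {feedback!r}") from None
    # zero only constants not shared with any other rule (e.g. Vmax is shared
    # between the PKC and p70S6K serine-phosphorylation rules; k15 is not)
    other_syms: set[str] = set()
    for rule in out.rules:
        if rule.name not in names:
            other_syms |= rule.symbols()
    zeroed = 0
    for rule in out.rules:
        if rule.name in names:
            for law in (rule.rate_law, rule.reverse_rate_law):
                if law is None:
                    continue
                for sym in law.constants:
                    if sym not in other_syms:
                        out.parameters[sym] = 0.0
                        zeroed += 1
    if zeroed == 0:
        raise ProtocolError(f"feedback {feedback!r} has no rule-specific rate constant")
    return out


def run_insulin_protocol(
    model: RuleModel,
    protocol: Protocol = Protocol(),
    rtol: float = 1e-8,
    atol: float = 1e-4,
    pre_equilibrate: bool = False,
) -> SimulationResult:
    """Simulate the model under an insulin step applied at t=0.

    ``pre_equilibrate`` first relaxes the system to steady state with zero
    insulin (amino acids present) and uses that state as t=0; by default
    the simulation starts directly from the listed initial conditions,
    which are themselves the insulin-free resting state.
    """
    m = model.copy()
    net = generate_network(m)
    idx = net.species_index()
    initial = list(net.initial_counts)
    ins_label = "INS()"
    if ins_label not in idx:
        raise ProtocolError("model has no insulin input species")
    if protocol.amino_acid_level is not None:
        aa_label = "AA()"
        if aa_label in idx:
            initial[idx[aa_label]] = protocol.amino_acid_level
    if pre_equilibrate:
        initial[idx[ins_label]] = 0.0
        rest = simulate_deterministic(
            net, (0.0, 500.0), grid_dt=10.0, initial=initial, rtol=rtol, atol=atol
        )
        initial = list(rest.trajectories[:, -1])
    initial[idx[ins_label]] = nM_to_molecules(protocol.insulin_nM, protocol.context)
    return simulate_deterministic(
        net,
        (protocol.t_start, protocol.t_end),
        grid_dt=protocol.grid_dt,
        initial=initial,
        rtol=rtol,
        atol=atol,
    )


# default dose sweep: log-spaced 0.1-100 nM plus zero
DEFAULT_DOSES: tuple[float, ...] = (0.0, 0.1, 0.316, 1.0, 3.16, 10.0, 31.6, 100.0)


def glut4_dose_response(
    model: RuleModel,
    doses: Sequence[float] = DEFAULT_DOSES,
    t_eval: float = 60.0,
    observable: str = "GLUT4_mem",
) -> dict[float, float]:
    """GLUT4-membrane observable at ``t_eval`` minutes, one run per dose."""
    if len(doses) == 0:
        raise ProtocolError("empty dose list")
    if any(d < 0 for d in doses):
        raise ProtocolError("doses must be non-negative")
    out = {}
    for d in doses:
        res = run_insulin_protocol(model, Protocol(insulin_nM=d, t_end=t_eval))
        out[float(d)] = float(res.observable_by_name(observable)[-1])
    return out


def normalize_for_comparison(trace: np.ndarray) -> np.ndarray:
    """Rescale a trace to [0, 1]; a constant trace maps to all zeros."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    lo, hi = trace.min(), trace.max()
    if hi == lo:
        return np.zeros_like(trace)
    return (trace - lo) / (hi - lo)
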