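"""Toy fixture models with hand-derived reference answers.

Each fixture carries the dialect text, the hand-enumerated species and
reaction lists (the oracle the generated network must reproduce), and,
where one exists, a closed-form solution.  These are first-class package
objects used both in the test suite and as minimal usage examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from . import dialect
from .network import RuleModel


@dataclass
class FixtureModel:
    name: str
    model: RuleModel
    reference_species: list[str]          # canonical labels, hand-derived
    reference_reaction_count: int
    closed_form: Optional[Callable] = None
    notes: str = ""


_BINDING = """
begin molecule types
  L(r)
  R(l)
end molecule types
begin parameters
  kon 1.0e-3
  koff 0.1
end parameters
begin seed species
  L(r) 100.0
  R(l) 80.0
end seed species
begin observables
  LR L(r!1).R(l!1)
end observables
begin reaction rules
  bind: L(r) + R(l) <-> L(r!1).R(l!1) ma(kon), ma(koff)
end reaction rules
"""


def _binding_equilibrium(l0=100.0, r0=80.0, kon=1.0e-3, koff=0.1):
    """Equilibrium complex count: root of kon(L0-c)(R0-c) = koff*c."""
    kd = koff / kon
    b = l0 + r0 + kd
    return (b - math.sqrt(b * b - 4 * l0 * r0)) / 2


_TWO_SITE = """
begin molecule types
  S(a~0~P,b~0~P)
end molecule types
begin parameters
  ka 0.5
  kpa 0.2
  kb 0.3
  kpb 0.1
end parameters
begin seed species
  S(a~0,b~0) 1000.0
end seed species
begin observables
  ppS S(a~P,b~P)
end observables
begin reaction rules
  phos_a: S(a~0) <-> S(a~P) ma(ka), ma(kpa)
  phos_b: S(b~0) <-> S(b~P) ma(kb), ma(kpb)
end reaction rules
"""


_LINEAR = """
begin molecule types
  Y()
end molecule types
begin parameters
  k 10.0
  d 0.5
end parameters
begin seed species
  Y() 0.0
end seed species
begin observables
  Y_total Y()
end observables
begin reaction rules
  turnover: 0 <-> Y() ma(k), ma(d)
end reaction rules
"""


def _linear_solution(t, k=10.0, d=0.5, y0=0.0):
    """y(t) = k/d + (y0 - k/d) e^{-dt}; steady state k/d."""
    yss = k / d
    return yss + (y0 - yss) * math.exp(-d * t)


def _linear_sensitivity_k(t0, t1, k=10.0, d=0.5, y0=0.0):
    """Closed-form window-averaged relative sensitivity of y wrt k (percent).

    With y(t) = yss(1-e^{-dt}) + y0 e^{-dt} and yss = k/d,
    dy/dk = (1-e^{-dt})/d, so s(t) = (1-e^{-dt}) yss / y(t).
    """
    import scipy.integrate as si

    def s(t):
        y = _linear_solution(t, k, d, y0)
        if y <= 0:
            return 0.0
        return (1 - math.exp(-d * t)) * (k / d) / y

    val, _ = si.quad(s, t0, t1, limit=200)
    return 100.0 * val / (t1 - t0)


_HILL_FEEDBACK = """
begin molecule types
  A(s~off~on)
end molecule types
begin parameters
  vmax 2.0
  Kd 500.0
  nh 2.0
  krev 0.4
end parameters
begin seed species
  A(s~off) 1000.0
end seed species
begin observables
  A_on A(s~on)
end observables
begin reaction rules
  switch: A(s~off) <-> A(s~on) hill(vmax; A_on; Kd; nh), ma(krev)
end reaction rules
"""


def _catalogue() -> dict[str, Callable[[], FixtureModel]]:
    return {
        "binding": lambda: FixtureModel(
            name="binding",
            model=dialect.loads(_BINDING, name="binding"),
            reference_species=["L(r)", "R(l)", "L(r!1).R(l!1)"],
            reference_reaction_count=2,
            closed_form=_binding_equilibrium,
            notes="reversible bimolecular binding; closed-form equilibrium",
        ),
        "two_site": lambda: FixtureModel(
            name="two_site",
            model=dialect.loads(_TWO_SITE, name="two_site"),
            reference_species=[
                "S(a~0,b~0)", "S(a~P,b~0)", "S(a~0,b~P)", "S(a~P,b~P)",
            ],
            reference_reaction_count=8,
            notes="two independent binary phospho-sites; 2^2 = 4 states",
        ),
        "linear": lambda: FixtureModel(
            name="linear",
            model=dialect.loads(_LINEAR, name="linear"),
            reference_species=["Y()"],
            reference_reaction_count=2,
            closed_form=_linear_solution,
            notes="production-degradation y'=k-d*y with analytic sensitivity",
        ),
        "hill_feedback": lambda: FixtureModel(
            name="hill_feedback",
            model=dialect.loads(_HILL_FEEDBACK, name="hill_feedback"),
            reference_species=["A(s~off)", "A(s~on)"],
            reference_reaction_count=2,
            notes="positive Hill feedback motif (modifier observable)",
        ),
    }


def fixture_names() -> list[str]:
    return sorted(_catalogue())


def generate_fixture(name: str) -> FixtureModel:
    """Deterministic fixture with hand-derived reference answers."""
    cat = _catalogue()
    try:
        return cat[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; catalogue: {sorted(cat)}"
        ) from None


linear_solution = _linear_solution
linear_sensitivity_k = _linear_sensitivity_k
binding_equilibrium = _binding_equilibrium
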