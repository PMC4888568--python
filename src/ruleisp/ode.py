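"""ODE compilation and deterministic simulation of a generated network.

Copy-number units throughout: species amounts in molecules/cell, time in
minutes, first-order constants in 1/min, second-order constants in
1/(molecules*min).  The compiled right-hand side is
``d(count)/dt = S @ rates`` with mass-action rates
``c * prod(reactant counts)`` and Hill-modulated rates
``c * H(X) * prod(reactant counts)`` where X is the copy number of the
modifier observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import RuleError
from .network import Observable, ReactionNetwork


class SimulationError(Exception):
    """Integration failure; carries the last successful time."""

    def __init__(self, message: str, last_time: Optional[float] = None):
        super().__init__(message)
        self.last_time = last_time


def observable_weights(network: ReactionNetwork, obs: Observable) -> np.ndarray:
    """Embedding-multiplicity weight of an observable over network species."""
    w = np.zeros(len(network.species))
    for pat in obs.patterns:
        if pat.universe is not network.model.universe:
            # patterns may come from an equivalent universe; validate types
            for pm in pat.molecules:
                if pm.type_name not in network.model.universe:
                    raise RuleError(f"observable {obs.name}: unknown molecule {pm.type_name}")
        for i, sp in enumerate(network.species):
            w[i] += len(pat.embeddings(sp))
    return w


@dataclass
class CompiledODE:
    """Index-array form of the network ODEs (structure only; parameter values
    are bound at evaluation time so perturbations do not recompile)."""

    network: ReactionNetwork
    stoich: np.ndarray          # (n_species, n_reactions)
    r1: np.ndarray              # first reactant index per reaction, -1 if none
    r2: np.ndarray              # second reactant index per reaction, -1 if none
    const_syms: list[tuple[str, ...]]
    stat_factors: np.ndarray
    hill_id: np.ndarray         # index into hill tables, -1 = pure mass action
    hill_w: np.ndarray          # (n_hill, n_species) modifier weights
    hill_kd_sym: list[str]
    hill_n_sym: list[object]    # str symbol or float literal
    hill_inhib: np.ndarray
    free_mask: np.ndarray       # 0 for constant species, 1 otherwise

    def bind(self, params: Mapping[str, float]):
        """Return f(t, y) with numeric constants bound from ``params``."""
        c = np.array(
            [
                sf * float(np.prod([params[s] for s in syms])) if syms else sf
                for syms, sf in zip(self.const_syms, self.stat_factors)
            ]
        )
        n_hill = len(self.hill_kd_sym)
        if n_hill:
            kd = np.array([params[s] for s in self.hill_kd_sym])
            nn = np.array(
                [params[s] if isinstance(s, str) else float(s) for s in self.hill_n_sym]
            )
            inhib = self.hill_inhib.astype(bool)
        stoich = self.stoich
        r1, r2, hid = self.r1, self.r2, self.hill_id
        free = self.free_mask
        has_r1 = r1 >= 0
        has_r2 = r2 >= 0
        has_hill = hid >= 0
        hill_w = self.hill_w

        def f(t, y):
            yc = np.maximum(y, 0.0)
            rates = c.copy()
            rates[has_r1] *= yc[r1[has_r1]]
            rates[has_r2] *= yc[r2[has_r2]]
            if n_hill:
                x = hill_w @ yc
                xn = x ** nn
                kdn = kd ** nn
                h = np.where(inhib, kdn / (kdn + xn), xn / (kdn + xn))
                rates[has_hill] *= h[hid[has_hill]]
            return (stoich @ rates) * free

        return f


def compile_rate_equations(network: ReactionNetwork) -> CompiledODE:
    """Compile a reaction network into an ODE right-hand-side specification.

    Raises a compilation error listing every unresolved parameter symbol.
    """
    model = network.model
    n_sp = len(network.species)
    n_rx = len(network.reactions)
    missing = set()
    for rxn in network.reactions:
        for s in rxn.rate_law.symbols():
            if s not in model.parameters:
                missing.add(s)
    if missing:
        raise RuleError(f"unresolved parameter symbols: {sorted(missing)}")

    stoich = np.zeros((n_sp, n_rx))
    r1 = np.full(n_rx, -1, dtype=int)
    r2 = np.full(n_rx, -1, dtype=int)
    const_syms = []
    stat_factors = np.zeros(n_rx)
    hill_id = np.full(n_rx, -1, dtype=int)
    hill_rows = []
    hill_kd_sym: list[str] = []
    hill_n_sym: list[object] = []
    hill_inhib: list[bool] = []
    hill_key: dict[tuple, int] = {}

    for j, rxn in enumerate(network.reactions):
        if len(rxn.reactants) > 2:
            raise RuleError("reactions with more than two reactants are not supported")
        for i in rxn.reactants:
            stoich[i, j] -= 1
        for i in rxn.products:
            stoich[i, j] += 1
        if len(rxn.reactants) >= 1:
            r1[j] = rxn.reactants[0]
        if len(rxn.reactants) == 2:
            r2[j] = rxn.reactants[1]
        const_syms.append(rxn.rate_law.constants)
        stat_factors[j] = rxn.stat_factor
        law = rxn.rate_law
        if law.kind == "hill":
            obs = model.observables[law.modifier]
            key = (law.modifier, law.kd, law.n, law.inhibitory)
            if key not in hill_key:
                hill_key[key] = len(hill_rows)
                hill_rows.append(observable_weights(network, obs))
                hill_kd_sym.append(law.kd)
                hill_n_sym.append(law.n)
                hill_inhib.append(law.inhibitory)
            hill_id[j] = hill_key[key]

    labels = network.labels
    free_mask = np.array(
        [0.0 if lab in model.constant_species else 1.0 for lab in labels]
    )
    return CompiledODE(
        network=network,
        stoich=stoich,
        r1=r1,
        r2=r2,
        const_syms=const_syms,
        stat_factors=stat_factors,
        hill_id=hill_id,
        hill_w=np.array(hill_rows) if hill_rows else np.zeros((0, n_sp)),
        hill_kd_sym=hill_kd_sym,
        hill_n_sym=hill_n_sym,
        hill_inhib=np.array(hill_inhib, dtype=bool),
        free_mask=free_mask,
    )


@dataclass
class SimulationResult:
    """Time grid (min) and per-species copy-number trajectories."""

    network: ReactionNetwork
    times: np.ndarray            # (n_t,)
    trajectories: np.ndarray     # (n_species, n_t)

    def observable(self, obs: Observable) -> np.ndarray:
        w = observable_weights(self.network, obs)
        return w @ self.trajectories

    def observable_by_name(self, name: str) -> np.ndarray:
        return self.observable(self.network.model.observables[name])

    def species_trace(self, label: str) -> np.ndarray:
        return self.trajectories[self.network.species_index()[label]]

    def to_frame(self):
        """Tidy (time, name, value) DataFrame of all species trajectories."""
        import pandas as pd

        labels = self.network.labels
        rows = {
            "time": np.repeat(self.times, len(labels)),
            "name": np.tile(labels, len(self.times)),
            "value": self.trajectories.T.reshape(-1),
        }
        return pd.DataFrame(rows)


def simulate_deterministic(
    network: ReactionNetwork,
    t_span: tuple[float, float] = (0.0, 60.0),
    grid_dt: float = 0.1,
    params: Optional[Mapping[str, float]] = None,
    initial: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-4,
    compiled: Optional[CompiledODE] = None,
) -> SimulationResult:
    """Stiff-capable deterministic integration sampled on a uniform grid.

    Defaults follow the copy-number scale of the insulin-pathway model:
    relative tolerance 1e-8 and absolute tolerance 1e-4 molecules, output
    every 0.1 min over [0, 60] min.
    """
    if t_span[1] <= t_span[0]:
        raise ValueError("t_span must be increasing")
    ode = compiled if compiled is not None else compile_rate_equations(network)
    p = dict(network.model.parameters)
    if params:
        p.update(params)
    y0 = np.array(initial if initial is not None else network.initial_counts, dtype=float)
    if (y0 < 0).any():
        raise ValueError("initial state must be non-negative")
    f = ode.bind(p)
    times = np.arange(t_span[0], t_span[1] + grid_dt / 2, grid_dt)
    sol = solve_ivp(
        f,
        t_span,
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = sol.t[-1] if len(sol.t) else t_span[0]
        raise SimulationError(f"integration failed: {sol.message}", last_time=last)
    return SimulationResult(network=network, times=sol.t, trajectories=sol.y)


def evaluate_observables(
    result: SimulationResult, observables: Sequence[Observable]
) -> dict[str, np.ndarray]:
    """Trace per observable: sum over species of embedding count x copies."""
    return {o.name: result.observable(o) for o in observables}
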