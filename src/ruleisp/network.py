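"""Reaction-network generation: fixed-point closure of rules over seed species.

A :class:`RuleModel` bundles molecule types, parameters, seed species with
initial copy numbers, pattern-defined observables and reaction rules.
:func:`generate_network` iteratively applies every rule to the growing
species set until no new species arise, yielding a :class:`ReactionNetwork`
with indexed reactions and symbolic rate expressions ready for ODE
compilation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    MoleculeTypeUniverse,
    Pattern,
    RateLaw,
    Rule,
    RuleError,
    SpeciesGraph,
    StructureError,
)


class ClosureError(Exception):
    """Network generation failed to reach a fixed point within the caps."""


class ParameterSet(dict):
    """name -> value map; values must be finite."""

    def __setitem__(self, key, value):
        value = float(value)
        if not math.isfinite(value):
            raise ValueError(f"parameter {key!r} must be finite, got {value}")
        super().__setitem__(key, value)

    def copy(self) -> "ParameterSet":
        return ParameterSet(self)


@dataclass
class Observable:
    """Pattern-defined output: sum of matched copy numbers weighted by
    embedding multiplicity across all species."""

    name: str
    patterns: list[Pattern]


@dataclass
class RuleModel:
    """A complete rule-based model definition."""

    universe: MoleculeTypeUniverse
    parameters: ParameterSet
    seeds: list[tuple[SpeciesGraph, float]]
    rules: list[Rule]
    observables: dict[str, Observable] = field(default_factory=dict)
    constant_species: set = field(default_factory=set)  # canonical labels held fixed
    name: str = "model"

    def validate(self) -> None:
        """Every rate-law symbol must resolve; every hill modifier must name
        a declared observable.  Raises with the full list of offenders."""
        missing_params = []
        missing_obs = []
        for rule in self.rules:
            for sym in rule.symbols():
                if sym not in self.parameters:
                    missing_params.append((rule.name, sym))
            for law in (rule.rate_law, rule.reverse_rate_law):
                if law is not None and law.kind == "hill" and law.modifier not in self.observables:
                    missing_obs.append((rule.name, law.modifier))
        problems = []
        if missing_params:
            problems.append(f"unresolved parameters: {sorted(set(missing_params))}")
        if missing_obs:
            problems.append(f"unknown hill modifier observables: {sorted(set(missing_obs))}")
        if problems:
            raise RuleError("; ".join(problems))

    def copy(self) -> "RuleModel":
        return RuleModel(
            universe=self.universe,
            parameters=self.parameters.copy(),
            seeds=list(self.seeds),
            rules=list(self.rules),
            observables=dict(self.observables),
            constant_species=set(self.constant_species),
            name=self.name,
        )


@dataclass
class Reaction:
    """One directed network reaction with a symbolic rate expression.

    rate = (product of rate-law constants) * stat_factor
           * [hill factor if any] * product of reactant copy numbers
    """

    reactants: tuple[int, ...]  # species indices (with repetition = stoichiometry)
    products: tuple[int, ...]
    rate_law: RateLaw
    stat_factor: float
    rule_name: str

    def rate_string(self) -> str:
        parts = list(self.rate_law.constants)
        if self.stat_factor != 1.0:
            parts.append(repr(self.stat_factor))
        body = "*".join(parts) if parts else "1"
        if self.rate_law.kind == "hill":
            law = self.rate_law
            form = "inhibitory_hill" if law.inhibitory else "hill"
            body += f"*{form}({law.modifier};Kd={law.kd},n={law.n})"
        for idx in self.reactants:
            body += f"*x[{idx}]"
        return body


@dataclass
class ReactionNetwork:
    """Enumerated species (seeds first, then discovery order) and reactions."""

    model: RuleModel
    species: list[SpeciesGraph]
    initial_counts: list[float]
    reactions: list[Reaction]

    @property
    def labels(self) -> list[str]:
        return [s.canonical_label() for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def content_hash(self) -> str:
        """Stable hash of the generated network (species + reactions + params)."""
        import hashlib

        h = hashlib.sha256()
        for lab in self.labels:
            h.update(lab.encode())
        for r in self.reactions:
            h.update(f"{r.reactants}->{r.products}@{r.rate_string()}".encode())
        for k in sorted(self.model.parameters):
            h.update(f"{k}={self.model.parameters[k]!r}".encode())
        return h.hexdigest()[:16]


def _directed_rules(rules: Sequence[Rule]) -> list[Rule]:
    out = []
    for r in rules:
        out.append(r)
        if r.reversible:
            out.append(r.reversed())
    return out


def generate_network(
    model: RuleModel,
    max_species: int = 10_000,
    max_iterations: int = 50,
) -> ReactionNetwork:
    """Fixed-point closure: apply rules to the growing species set until no
    new species arise.

    Species order is stable (seeds first, then discovery order); the result
    is independent of rule-list order up to that discovery order's canonical
    species *set*.  An iteration/species cap guards non-terminating rule sets.
    """
    model.validate()
    species: list[SpeciesGraph] = []
    index: dict[str, int] = {}
    initials: list[float] = []

    for g, n0 in model.seeds:
        lab = g.canonical_label()
        if lab in index:
            raise StructureError(f"duplicate seed species {lab}")
        if n0 < 0:
            raise StructureError(f"negative initial count for {lab}")
        index[lab] = len(species)
        species.append(g)
        initials.append(float(n0))

    directed = _directed_rules(model.rules)
    reactions: list[Reaction] = []
    seen_reactions: set = set()

    def add_species(g: SpeciesGraph) -> int:
        lab = g.canonical_label()
        if lab not in index:
            if len(species) >= max_species:
                raise ClosureError(
                    f"species cap {max_species} exceeded (last rule fired: {current_rule.name})"
                )
            index[lab] = len(species)
            species.append(g)
            initials.append(0.0)
        return index[lab]

    reaction_index: dict[tuple, Reaction] = {}

    def slot_denominator(rule: Rule) -> int:
        # BioNetGen convention: ordered slot enumeration counts each unordered
        # assignment once per ordering of identical pattern slots, and a
        # symmetric pattern matches itself once per automorphism
        sig_groups: dict[str, int] = {}
        denom = 1
        for pat in rule.reactants:
            sig = pat.signature()
            sig_groups[sig] = sig_groups.get(sig, 0) + 1
            denom *= pat.automorphism_count()
        for m in sig_groups.values():
            denom *= math.factorial(m)
        return denom

    for _ in range(max_iterations):
        n_species_before = len(species)
        n_reactions_before = len(reactions)
        snapshot = list(species)  # species available this sweep
        for current_rule in directed:
            n_slots = len(current_rule.reactants)
            combos = (
                [()] if n_slots == 0
                else itertools.product(range(len(snapshot)), repeat=n_slots)
            )
            denom = slot_denominator(current_rule)
            for combo in combos:
                key = (current_rule.name, combo)
                if key in seen_reactions:
                    continue
                seen_reactions.add(key)
                graphs = [snapshot[i] for i in combo]
                for prods, count in current_rule.apply(graphs):
                    prod_idx = tuple(sorted(add_species(p) for p in prods))
                    react_idx = tuple(sorted(combo))
                    rkey = (current_rule.name, react_idx, prod_idx)
                    factor = count / denom
                    if rkey in reaction_index:
                        reaction_index[rkey].stat_factor += factor
                    else:
                        rxn = Reaction(
                            reactants=react_idx,
                            products=prod_idx,
                            rate_law=current_rule.rate_law,
                            stat_factor=factor,
                            rule_name=current_rule.name,
                        )
                        reaction_index[rkey] = rxn
                        reactions.append(rxn)
        if len(species) == n_species_before and len(reactions) == n_reactions_before:
            break
    else:
        raise ClosureError(f"no fixed point within {max_iterations} iterations")

    return ReactionNetwork(model=model, species=species, initial_counts=initials, reactions=reactions)
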