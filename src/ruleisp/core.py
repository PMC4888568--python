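"""Site-graph data model for rule-based modelling.

Molecules are typed objects carrying named sites; a site holds exactly one
internal state (phospho-state, localization, ...) and at most one bond.
Connected site-graphs are chemical species; partially specified site-graphs
are patterns used as rule recognition motifs ("don't care, don't write":
a site not mentioned by a pattern is unconstrained, a site written without
a bond mark must be unbound).

Species identity is canonical-label based: two species graphs are the same
chemical species iff their canonical labels are equal, which is invariant
under any reordering of molecules, sites or bond indices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union


class RuleError(Exception):
    """Model-definition error (unknown molecule type, site or state)."""


class StructureError(Exception):
    """Species-graph invariant violation (e.g. disconnected species)."""


# ---------------------------------------------------------------------------
# molecule types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MoleculeType:
    """A molecule class: a name plus named sites with allowed internal states.

    A site with an empty state tuple is a pure binding site (no internal
    state); localization is an ordinary site state (e.g. ``loc~mem``/``loc~cyt``).
    """

    name: str
    sites: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for s, states in self.sites.items():
            if s in seen:
                raise RuleError(f"duplicate site {s!r} in molecule type {self.name}")
            seen.add(s)
        object.__setattr__(self, "sites", dict(self.sites))

    def default_states(self) -> dict[str, Optional[str]]:
        return {s: (states[0] if states else None) for s, states in self.sites.items()}


class MoleculeTypeUniverse:
    """Registry of molecule types; validates species and patterns against it."""

    def __init__(self, types: Iterable[MoleculeType] = ()):
        self._types: dict[str, MoleculeType] = {}
        for t in types:
            self.add(t)

    def add(self, t: MoleculeType) -> None:
        if t.name in self._types:
            raise RuleError(f"molecule type {t.name!r} declared twice")
        self._types[t.name] = t

    def __getitem__(self, name: str) -> MoleculeType:
        try:
            return self._types[name]
        except KeyError:
            raise RuleError(f"unknown molecule type {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._types

    def __iter__(self):
        return iter(self._types.values())


# ---------------------------------------------------------------------------
# species graphs
# ---------------------------------------------------------------------------

Endpoint = tuple[int, str]  # (molecule index, site name)


class SpeciesGraph:
    """A concrete molecular complex: molecules, site states and bonds.

    ``molecules`` is a sequence of (type name, {site: state}) with every site
    of the type present and set to one allowed state (``None`` for stateless
    binding sites).  ``bonds`` maps each bound endpoint to its partner.
    """

    def __init__(
        self,
        universe: MoleculeTypeUniverse,
        molecules: Sequence[tuple[str, Mapping[str, Optional[str]]]],
        bonds: Iterable[tuple[Endpoint, Endpoint]] = (),
    ):
        self.universe = universe
        mols = []
        for tname, states in molecules:
            mtype = universe[tname]
            full = {}
            for site, allowed in mtype.sites.items():
                if site in states:
                    st = states[site]
                elif allowed:
                    raise StructureError(
                        f"species molecule {tname} missing state for site {site!r}"
                    )
                else:
                    st = None
                if allowed and st not in allowed:
                    raise StructureError(
                        f"state {st!r} not allowed for {tname}.{site} (allowed {allowed})"
                    )
                if not allowed and st is not None:
                    raise StructureError(f"site {tname}.{site} carries no internal state")
                full[site] = st
            for site in states:
                if site not in mtype.sites:
                    raise StructureError(f"unknown site {site!r} on molecule {tname}")
            mols.append((tname, full))
        self.molecules: list[tuple[str, dict[str, Optional[str]]]] = mols
        self.bonds: dict[Endpoint, Endpoint] = {}
        for a, b in bonds:
            self._add_bond(a, b)
        self._label: Optional[str] = None

    # -- construction helpers ------------------------------------------------

    def _add_bond(self, a: Endpoint, b: Endpoint) -> None:
        for ep in (a, b):
            i, site = ep
            if not (0 <= i < len(self.molecules)):
                raise StructureError(f"bond endpoint {ep} out of range")
            tname = self.molecules[i][0]
            if site not in self.universe[tname].sites:
                raise StructureError(f"bond endpoint {ep}: no site {site!r} on {tname}")
            if ep in self.bonds:
                raise StructureError(f"site {ep} carries more than one bond")
        if a == b:
            raise StructureError("a site cannot bind itself")
        self.bonds[a] = b
        self.bonds[b] = a
        self._label = None

    def copy(self) -> "SpeciesGraph":
        g = SpeciesGraph.__new__(SpeciesGraph)
        g.universe = self.universe
        g.molecules = [(t, dict(s)) for t, s in self.molecules]
        g.bonds = dict(self.bonds)
        g._label = self._label
        return g

    # -- topology ------------------------------------------------------------

    def neighbours(self, i: int) -> set[int]:
        out = set()
        for (mi, _), (mj, _) in self.bonds.items():
            if mi == i:
                out.add(mj)
        return out

    def connected_components(self) -> list[list[int]]:
        unseen = set(range(len(self.molecules)))
        comps = []
        while unseen:
            stack = [unseen.pop()]
            comp = set(stack)
            while stack:
                cur = stack.pop()
                for nb in self.neighbours(cur):
                    if nb in unseen:
                        unseen.discard(nb)
                        comp.add(nb)
                        stack.append(nb)
            comps.append(sorted(comp))
        return comps

    def is_connected(self) -> bool:
        return len(self.molecules) <= 1 or len(self.connected_components()) == 1

    def subgraph(self, indices: Sequence[int]) -> "SpeciesGraph":
        index = {old: new for new, old in enumerate(indices)}
        mols = [(self.molecules[i][0], dict(self.molecules[i][1])) for i in indices]
        bonds = []
        for (i, si), (j, sj) in self.bonds.items():
            if i in index and j in index and i < j:
                bonds.append(((index[i], si), (index[j], sj)))
        return SpeciesGraph(self.universe, mols, bonds)

    # -- canonical labelling ---------------------------------------------

    def _refine_colours(self) -> list[int]:
        """Iterative refinement: colour by (type, states), then repeatedly by
        the multiset of bond neighbourhood colours, until stable."""
        base = []
        for tname, states in self.molecules:
            base.append((tname, tuple(sorted((s, st or "") for s, st in states.items()))))
        palette = {v: k for k, v in enumerate(sorted(set(base)))}
        colours = [palette[b] for b in base]
        while True:
            sigs = []
            for i in range(len(self.molecules)):
                nb = []
                for (mi, si), (mj, sj) in self.bonds.items():
                    if mi == i:
                        nb.append((si, sj, colours[mj]))
                sigs.append((colours[i], tuple(sorted(nb))))
            palette = {v: k for k, v in enumerate(sorted(set(sigs)))}
            new = [palette[s] for s in sigs]
            if new == colours:
                return colours
            colours = new

    _PERM_CAP = 40320  # refuse pathological automorphism searches (8!)

    def canonical_label(self) -> str:
        if self._label is not None:
            return self._label
        if not self.is_connected():
            raise StructureError("species graph must be connected")
        colours = self._refine_colours()
        # group automorphic candidates: orderings respect colour classes,
        # lexicographically smallest serialization wins (deterministic tie-break)
        order_groups: dict[int, list[int]] = {}
        for i, c in enumerate(colours):
            order_groups.setdefault(c, []).append(i)
        group_perms = []
        total = 1
        for c in sorted(order_groups):
            members = order_groups[c]
            total *= _factorial(len(members))
            group_perms.append(list(itertools.permutations(members)))
        if total > self._PERM_CAP:
            raise StructureError("automorphism search too large for canonicalization")
        best = None
        for combo in itertools.product(*group_perms):
            ordering = [i for perm in combo for i in perm]
            s = self._serialize(ordering)
            if best is None or s < best:
                best = s
        self._label = best
        return best

    def _serialize(self, ordering: Sequence[int]) -> str:
        pos = {old: new for new, old in enumerate(ordering)}
        # assign bond ids by first appearance in the chosen order
        bond_ids: dict[frozenset, int] = {}
        next_id = 1
        for old in ordering:
            tname, _ = self.molecules[old]
            for site in sorted(self.universe[tname].sites):
                ep = (old, site)
                if ep in self.bonds:
                    key = frozenset((ep, self.bonds[ep]))
                    if key not in bond_ids:
                        bond_ids[key] = next_id
                        next_id += 1
        parts = []
        for old in ordering:
            tname, states = self.molecules[old]
            sparts = []
            for site in sorted(self.universe[tname].sites):
                tok = site
                st = states[site]
                if st is not None:
                    tok += f"~{st}"
                ep = (old, site)
                if ep in self.bonds:
                    tok += f"!{bond_ids[frozenset((ep, self.bonds[ep]))]}"
                sparts.append(tok)
            parts.append(f"{tname}({','.join(sparts)})")
        return ".".join(parts)

    # -- identity ----------------------------------------------------------

    def __eq__(self, other):
        return isinstance(other, SpeciesGraph) and self.canonical_label() == other.canonical_label()

    def __hash__(self):
        return hash(self.canonical_label())

    def __repr__(self):
        try:
            return f"SpeciesGraph({self.canonical_label()})"
        except StructureError:
            return f"SpeciesGraph(<disconnected {len(self.molecules)} molecules>)"


def _factorial(n: int) -> int:
    out = 1
    for k in range(2, n + 1):
        out *= k
    return out


def canonicalize_species(graph: SpeciesGraph) -> str:
    """Deterministic isomorphism-invariant label for a connected species graph."""
    return graph.canonical_label()


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------


class BondMark(Enum):
    DONT_CARE = "?"   # site not mentioned: any state, any bond
    UNBOUND = "."     # site written without a bond: must be free
    BOUND_ANY = "+"   # must be bound, partner unspecified


@dataclass(frozen=True)
class PatternSite:
    state: Optional[str] = None           # None = don't care
    bond: Union[BondMark, int] = BondMark.DONT_CARE  # int = bond label within pattern


@dataclass
class PatternMolecule:
    type_name: str
    sites: dict[str, PatternSite] = field(default_factory=dict)


class Pattern:
    """A partially specified, connected site-graph used as one reactant slot.

    Sites omitted from a pattern molecule match any state and any bond;
    a site written with ``BondMark.UNBOUND`` matches only bond-free sites.
    Integer bond labels shared by two sites require a bond between them.
    """

    def __init__(self, universe: MoleculeTypeUniverse, molecules: Sequence[PatternMolecule]):
        self.universe = universe
        self.molecules = list(molecules)
        endpoints: dict[int, list[Endpoint]] = {}
        for i, pm in enumerate(self.molecules):
            mtype = universe[pm.type_name]
            for site, ps in pm.sites.items():
                if site not in mtype.sites:
                    raise RuleError(f"pattern references unknown site {pm.type_name}.{site}")
                if ps.state is not None and ps.state not in mtype.sites[site]:
                    raise RuleError(
                        f"pattern state {ps.state!r} not allowed for {pm.type_name}.{site}"
                    )
                if isinstance(ps.bond, int):
                    endpoints.setdefault(ps.bond, []).append((i, site))
        self.bonds: dict[Endpoint, Endpoint] = {}
        for label, eps in endpoints.items():
            if len(eps) != 2:
                raise RuleError(f"pattern bond label {label} used {len(eps)} times (need 2)")
            a, b = eps
            self.bonds[a] = b
            self.bonds[b] = a
        if self.molecules and not self._connected():
            raise RuleError("a reactant pattern must be connected (one slot per component)")

    def _connected(self) -> bool:
        n = len(self.molecules)
        if n <= 1:
            return True
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for (i, _), (j, _) in self.bonds.items():
            adj[i].add(j)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n

    # -- matching ------------------------------------------------------------

    def embeddings(self, species: SpeciesGraph) -> list[dict[int, int]]:
        """All injective embeddings of this pattern into ``species``.

        Returns maps {pattern molecule index -> species molecule index}.
        Results are cached per species object (species graphs are treated
        as immutable once built).
        """
        cache = self.__dict__.setdefault("_emb_cache", {})
        hit = cache.get(id(species))
        if hit is not None and hit[0] is species:
            return hit[1]
        # quick reject: every pattern molecule type must occur in the species
        sp_types = {t for t, _ in species.molecules}
        if any(pm.type_name not in sp_types for pm in self.molecules):
            cache[id(species)] = (species, [])
            return []
        n = len(self.molecules)
        results: list[dict[int, int]] = []

        def site_ok(pm: PatternMolecule, pi: int, mi: int, assignment: dict[int, int]) -> bool:
            tname, states = species.molecules[mi]
            if tname != pm.type_name:
                return False
            for site, ps in pm.sites.items():
                if ps.state is not None and states.get(site) != ps.state:
                    return False
                ep = (mi, site)
                bound = ep in species.bonds
                if ps.bond is BondMark.UNBOUND and bound:
                    return False
                if ps.bond is BondMark.BOUND_ANY and not bound:
                    return False
                if isinstance(ps.bond, int):
                    if not bound:
                        return False
                    other = self.bonds[(pi, site)]
                    oi, osite = other
                    if oi in assignment:
                        if species.bonds[ep] != (assignment[oi], osite):
                            return False
                    else:
                        tj, _ = species.molecules[species.bonds[ep][0]]
                        if species.bonds[ep][1] != osite or tj != self.molecules[oi].type_name:
                            return False
            return True

        def backtrack(pi: int, assignment: dict[int, int]):
            if pi == n:
                results.append(dict(assignment))
                return
            pm = self.molecules[pi]
            for mi in range(len(species.molecules)):
                if mi in assignment.values():
                    continue
                assignment[pi] = mi
                if site_ok(pm, pi, mi, assignment):
                    # re-check previously placed molecules' bond constraints to pi
                    ok = all(
                        site_ok(self.molecules[pj], pj, mj, assignment)
                        for pj, mj in assignment.items()
                    )
                    if ok:
                        backtrack(pi + 1, assignment)
                del assignment[pi]

        backtrack(0, {})
        cache[id(species)] = (species, results)
        return results

    def automorphism_count(self) -> int:
        """Number of self-bijections preserving types, site constraints and
        bond structure (used in the rate statistical factor for symmetric
        patterns, e.g. a homodimer dissociation pattern has 2)."""
        cached = self.__dict__.get("_aut_count")
        if cached is not None:
            return cached
        n = len(self.molecules)
        count = 0
        for perm in itertools.permutations(range(n)):
            ok = True
            for i, pm in enumerate(self.molecules):
                om = self.molecules[perm[i]]
                if pm.type_name != om.type_name or pm.sites != om.sites:
                    ok = False
                    break
            if ok:
                for (i, si), (j, sj) in self.bonds.items():
                    if self.bonds.get((perm[i], si)) != (perm[j], sj):
                        ok = False
                        break
            if ok:
                count += 1
        self.__dict__["_aut_count"] = count
        return count

    def signature(self) -> str:
        """Deterministic text form (used for pattern identity in rate factors)."""
        parts = []
        for pm in self.molecules:
            toks = []
            for site in sorted(pm.sites):
                ps = pm.sites[site]
                t = site
                if ps.state is not None:
                    t += f"~{ps.state}"
                if isinstance(ps.bond, int):
                    t += f"!{ps.bond}"
                elif ps.bond is BondMark.BOUND_ANY:
                    t += "!+"
                elif ps.bond is BondMark.DONT_CARE:
                    t += "!?"
                # UNBOUND: mentioned with no bond mark
                toks.append(t)
            parts.append(f"{pm.type_name}({','.join(toks)})")
        return ".".join(parts)

    def __repr__(self):
        return f"Pattern({self.signature()})"


def match_pattern(pattern: Pattern, species: SpeciesGraph) -> list[dict[int, int]]:
    """Every distinct embedding of ``pattern`` into ``species``."""
    return pattern.embeddings(species)


# ---------------------------------------------------------------------------
# rate laws and rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateLaw:
    """Kinetic law of a rule.

    ``mass_action``: rate = (product of the named constants) x product of
    reactant copy numbers x statistical factor.

    ``hill``: a saturating modulation of mass action,
    rate = c * H(X) * product of reactant copy numbers, with
    H(X) = X^n / (Kd^n + X^n) (activating) or Kd^n / (Kd^n + X^n)
    (``inhibitory=True``), X being the copy number of a named modifier
    observable.  ``n`` may be a parameter symbol or a numeric literal.
    """

    kind: str  # "mass_action" | "hill"
    constants: tuple[str, ...]
    modifier: Optional[str] = None
    kd: Optional[str] = None
    n: Union[str, float, None] = None
    inhibitory: bool = False

    def __post_init__(self):
        if self.kind not in ("mass_action", "hill"):
            raise RuleError(f"unknown rate-law kind {self.kind!r}")
        if self.kind == "hill" and (self.modifier is None or self.kd is None or self.n is None):
            raise RuleError("hill law needs modifier, Kd and n")

    def symbols(self) -> set[str]:
        out = set(self.constants)
        if self.kind == "hill":
            out.add(self.kd)
            if isinstance(self.n, str):
                out.add(self.n)
        return out


def mass_action(*constants: str) -> RateLaw:
    return RateLaw("mass_action", tuple(constants))


def hill(constants, modifier: str, kd: str, n, inhibitory: bool = False) -> RateLaw:
    if isinstance(constants, str):
        constants = (constants,)
    return RateLaw("hill", tuple(constants), modifier=modifier, kd=kd, n=n,
                   inhibitory=inhibitory)


@dataclass
class Rule:
    """A reaction rule: reactant patterns -> product patterns plus a rate law.

    Pattern molecules are aligned positionally between the concatenated
    reactant side and the concatenated product side; a product molecule
    beyond the reactant count is synthesized, a missing one is deleted.
    ``reversible`` rules carry a second rate law for the reversed rule.
    """

    name: str
    reactants: list[Pattern]
    products: list[Pattern]
    rate_law: RateLaw
    reversible: bool = False
    reverse_rate_law: Optional[RateLaw] = None

    def __post_init__(self):
        if self.reversible and self.reverse_rate_law is None:
            raise RuleError(f"rule {self.name}: reversible but no reverse rate law")

    def reversed(self) -> "Rule":
        if not self.reversible:
            raise RuleError(f"rule {self.name} is not reversible")
        return Rule(
            name=self.name + "_rev",
            reactants=self.products,
            products=self.reactants,
            rate_law=self.reverse_rate_law,
        )

    def symbols(self) -> set[str]:
        out = self.rate_law.symbols()
        if self.reverse_rate_law is not None:
            out |= self.reverse_rate_law.symbols()
        return out

    # -- application ---------------------------------------------------------

    def _aligned(self):
        """Flattened (side, pattern index, molecule-in-pattern) alignment."""
        r_flat = [(p, i) for p in self.reactants for i in range(len(p.molecules))]
        p_flat = [(p, i) for p in self.products for i in range(len(p.molecules))]
        return r_flat, p_flat

    def apply(self, reactant_graphs: Sequence[SpeciesGraph]) -> list[tuple[list[SpeciesGraph], int]]:
        """Apply this rule to an ordered tuple of reactant species.

        Returns a list of (product species list, count) pairs, one per
        distinct product outcome, where count is the number of embedding
        combinations producing that outcome.  Inapplicable edits yield no
        reaction rather than an error.
        """
        if len(reactant_graphs) != len(self.reactants):
            raise RuleError(
                f"rule {self.name} takes {len(self.reactants)} reactants, got {len(reactant_graphs)}"
            )
        emb_lists = []
        for pat, g in zip(self.reactants, reactant_graphs):
            embs = pat.embeddings(g)
            if not embs:
                return []
            emb_lists.append(embs)

        # disjoint union of reactant graphs
        universe = (
            self.reactants[0].universe if self.reactants else self.products[0].universe
        )
        offsets = []
        off = 0
        for g in reactant_graphs:
            offsets.append(off)
            off += len(g.molecules)

        r_flat, p_flat = self._aligned()
        outcomes: dict[tuple[str, ...], int] = {}
        outcome_graphs: dict[tuple[str, ...], list[SpeciesGraph]] = {}

        for combo in itertools.product(*emb_lists):
            # global map: flattened reactant-pattern molecule -> union index
            gmap: list[int] = []
            for slot, emb in enumerate(combo):
                pat = self.reactants[slot]
                for pi in range(len(pat.molecules)):
                    gmap.append(offsets[slot] + emb[pi])
            prods = self._apply_edits(universe, reactant_graphs, offsets, r_flat, p_flat, gmap)
            if prods is None:
                continue
            key = tuple(sorted(p.canonical_label() for p in prods))
            outcomes[key] = outcomes.get(key, 0) + 1
            outcome_graphs[key] = prods
        return [(outcome_graphs[k], c) for k, c in sorted(outcomes.items())]

    def _apply_edits(self, universe, reactant_graphs, offsets, r_flat, p_flat, gmap):
        # build union graph
        union = SpeciesGraph.__new__(SpeciesGraph)
        union.universe = universe
        union.molecules = []
        union.bonds = {}
        union._label = None
        for off, g in zip(offsets, reactant_graphs):
            union.molecules.extend((t, dict(s)) for t, s in g.molecules)
            for (i, si), (j, sj) in g.bonds.items():
                union.bonds[(off + i, si)] = (off + j, sj)

        n_align = min(len(r_flat), len(p_flat))
        # positions where the aligned molecules keep their type are edits;
        # a type change at a position means delete + synthesize (A() -> B())
        aligned = [
            k
            for k in range(n_align)
            if r_flat[k][0].molecules[r_flat[k][1]].type_name
            == p_flat[k][0].molecules[p_flat[k][1]].type_name
        ]
        aligned_set = set(aligned)

        def drop_bond(ep):
            if ep in union.bonds:
                other = union.bonds.pop(ep)
                union.bonds.pop(other, None)

        # deletions: unaligned reactant molecules
        deleted = set()
        for k in range(len(r_flat)):
            if k in aligned_set:
                continue
            mi = gmap[k]
            deleted.add(mi)
            tname, _ = union.molecules[mi]
            for site in universe[tname].sites:
                drop_bond((mi, site))

        # synthesized molecules: unaligned product molecules
        synth_index: dict[int, int] = {}
        for k in range(len(p_flat)):
            if k in aligned_set:
                continue
            pp, pi = p_flat[k]
            pm = pp.molecules[pi]
            mtype = universe[pm.type_name]
            states = mtype.default_states()
            for site, ps in pm.sites.items():
                if ps.state is not None:
                    states[site] = ps.state
            union.molecules.append((pm.type_name, states))
            synth_index[k] = len(union.molecules) - 1

        def target_index(k: int) -> int:
            return gmap[k] if k in aligned_set else synth_index[k]

        # state changes and bond-mark edits on aligned + synthesized molecules
        for k in range(len(p_flat)):
            pp, pi = p_flat[k]
            pm = pp.molecules[pi]
            mi = target_index(k)
            tname, states = union.molecules[mi]
            for site, ps in pm.sites.items():
                if ps.state is not None:
                    states[site] = ps.state
                if ps.bond is BondMark.UNBOUND:
                    drop_bond((mi, site))

        # bonds required by product patterns
        for p in self.products:
            for (ai, asite), (bi, bsite) in p.bonds.items():
                # locate flattened indices of these pattern molecules
                ka = kb = None
                for k, (pp, pi) in enumerate(p_flat):
                    if pp is p and pi == ai:
                        ka = k
                    if pp is p and pi == bi:
                        kb = k
                ma, mb = target_index(ka), target_index(kb)
                epa, epb = (ma, asite), (mb, bsite)
                if union.bonds.get(epa) == epb:
                    continue
                if epa in union.bonds or epb in union.bonds:
                    return None  # edit not applicable: site already bound
                union.bonds[epa] = epb
                union.bonds[epb] = epa

        # remove deleted molecules, reindex
        keep = [i for i in range(len(union.molecules)) if i not in deleted]
        if not keep:
            return []
        final = union.subgraph(keep) if deleted else union
        comps = final.connected_components()
        return [final.subgraph(c) if len(comps) > 1 else final for c in comps]


def apply_rule(rule: Rule, reactants: Sequence[SpeciesGraph]):
    """One (products, multiplicity) entry per distinct product outcome."""
    return rule.apply(reactants)
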