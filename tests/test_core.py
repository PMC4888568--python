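"""Site-graph engine: canonical labels, pattern matching, rule application."""

import itertools
import random

import pytest

from ruleisp.core import (
    BondMark,
    MoleculeType,
    MoleculeTypeUniverse,
    PatternMolecule,
    PatternSite,
    Rule,
    RuleError,
    SpeciesGraph,
    StructureError,
    apply_rule,
    canonicalize_species,
    mass_action,
    match_pattern,
)
from ruleisp.dialect import parse_pattern, parse_rule, parse_species


@pytest.fixture
def universe():
    return MoleculeTypeUniverse(
        [
            MoleculeType("A", {"x": ("0", "P"), "b": ()}),
            MoleculeType("B", {"a": ()}),
            MoleculeType("AKT", {"T": ("0", "P"), "S": ("0", "P")}),
            MoleculeType("IRS1", {"Y": ("0", "P"), "S": ("0", "P"), "pi3k": ()}),
            MoleculeType("PI3K", {"irs": ()}),
            MoleculeType("D", {"x": ("0", "P"), "b": ()}),
        ]
    )


class TestCanonicalLabels:
    def test_site_order_irrelevant(self, universe):
        g1 = SpeciesGraph(universe, [("A", {"x": "0", "b": None})])
        g2 = SpeciesGraph(universe, [("A", {"b": None, "x": "0"})])
        assert canonicalize_species(g1) == canonicalize_species(g2)

    def test_molecule_order_irrelevant_in_dimer(self, universe):
        d1 = parse_species(universe, "A(x~0,b!1).B(a!1)")
        d2 = parse_species(universe, "B(a!1).A(x~0,b!1)")
        assert canonicalize_species(d1) == canonicalize_species(d2)

    def test_distinct_phosphoforms_get_distinct_labels(self, universe):
        g1 = parse_species(universe, "AKT(T~P,S~0)")
        g2 = parse_species(universe, "AKT(T~0,S~P)")
        assert canonicalize_species(g1) != canonicalize_species(g2)

    def test_disconnected_graph_rejected(self, universe):
        g = SpeciesGraph(universe, [("A", {"x": "0"}), ("B", {})])
        with pytest.raises(StructureError):
            canonicalize_species(g)

    def test_bond_relabelling_irrelevant(self, universe):
        # same triangle-free chain written with different bond ids
        g1 = parse_species(universe, "A(x~0,b!1).B(a!1)")
        g2 = parse_species(universe, "A(x~0,b!7).B(a!7)")
        assert canonicalize_species(g1) == canonicalize_species(g2)

    def test_labels_partition_like_brute_force_isomorphism(self):
        """Canonical equality must coincide with permutation-isomorphism on
        random small multi-bond site-graphs (chains up to 4 molecules)."""
        uni = MoleculeTypeUniverse(
            [MoleculeType("M", {"x": ("0", "P"), "l": (), "r": ()})]
        )
        rng = random.Random(7)
        graphs = []
        for _ in range(30):
            n = rng.randint(1, 4)
            mols = [("M", {"x": rng.choice("0P"), "l": None, "r": None}) for _ in range(n)]
            # chain topology r_i - l_{i+1} keeps it connected
            bonds = [((i, "r"), (i + 1, "l")) for i in range(n - 1)]
            graphs.append(SpeciesGraph(uni, mols, bonds))

        def brute_isomorphic(g1, g2):
            if len(g1.molecules) != len(g2.molecules):
                return False
            b1 = {frozenset(p) for p in g1.bonds.items()}
            for perm in itertools.permutations(range(len(g2.molecules))):
                if any(
                    g1.molecules[i] != g2.molecules[perm[i]]
                    for i in range(len(g1.molecules))
                ):
                    continue
                mapped = {
                    frozenset((((perm[i], si)), ((perm[j], sj))))
                    for (i, si), (j, sj) in g1.bonds.items()
                }
                if mapped == {frozenset(p) for p in g2.bonds.items()}:
                    return True
            return False

        for g1 in graphs:
            for g2 in graphs:
                assert (
                    canonicalize_species(g1) == canonicalize_species(g2)
                ) == brute_isomorphic(g1, g2)


class TestPatternMatching:
    def test_partial_specification_matches_complex(self, universe):
        species = parse_species(universe, "IRS1(Y~P,S~0,pi3k!1).PI3K(irs!1)")
        pattern = parse_pattern(universe, "IRS1(Y~P)")
        assert len(match_pattern(pattern, species)) == 1

    def test_written_site_means_unbound(self, universe):
        bound = parse_species(universe, "A(x~0,b!1).B(a!1)")
        pattern = parse_pattern(universe, "A(b)")
        assert match_pattern(pattern, bound) == []
        free = parse_species(universe, "A(x~0)")
        assert len(match_pattern(pattern, free)) == 1

    def test_bound_any_wildcard(self, universe):
        bound = parse_species(universe, "A(x~0,b!1).B(a!1)")
        pattern = parse_pattern(universe, "A(b!+)")
        assert len(match_pattern(pattern, bound)) == 1

    def test_symmetric_homodimer_two_embeddings(self, universe):
        dimer = parse_species(universe, "D(x~0,b!1).D(x~0,b!1)")
        pattern = parse_pattern(universe, "D(x~0)")
        assert len(match_pattern(pattern, dimer)) == 2

    def test_unknown_molecule_type_is_definition_error(self, universe):
        with pytest.raises(RuleError):
            parse_pattern(universe, "NOSUCH(x~0)")

    def test_unknown_site_is_definition_error(self, universe):
        with pytest.raises(RuleError):
            parse_pattern(universe, "A(nosite~0)")


class TestRuleApplication:
    def test_binding_rule_produces_canonical_complex(self, universe):
        rule = parse_rule(universe, "bind: A(b) + B(a) -> A(b!1).B(a!1) ma(k)")
        a = parse_species(universe, "A(x~0)")
        b = parse_species(universe, "B(a)")
        outcomes = apply_rule(rule, (a, b))
        assert len(outcomes) == 1
        products, count = outcomes[0]
        assert count == 1
        assert [p.canonical_label() for p in products] == [
            parse_species(universe, "A(x~0,b!1).B(a!1)").canonical_label()
        ]

    def test_state_requirement_blocks_application(self, universe):
        rule = parse_rule(universe, "phos: AKT(T~0) -> AKT(T~P) ma(k)")
        phosphorylated = parse_species(universe, "AKT(T~P,S~0)")
        assert apply_rule(rule, (phosphorylated,)) == []

    def test_symmetric_reactant_embeddings_merge_with_multiplicity(self, universe):
        """A rule matching twice on a symmetric dimer yields one reaction of
        multiplicity 2 (duplicate outcomes merged after canonicalization)."""
        rule = parse_rule(universe, "phos: D(x~0) -> D(x~P) ma(k)")
        dimer = parse_species(universe, "D(x~0,b!1).D(x~0,b!1)")
        outcomes = apply_rule(rule, (dimer,))
        assert len(outcomes) == 1
        products, count = outcomes[0]
        assert count == 2
        assert products[0].canonical_label() == parse_species(
            universe, "D(x~P,b!1).D(x~0,b!1)"
        ).canonical_label()

    def test_unbinding_splits_into_components(self, universe):
        rule = parse_rule(universe, "unbind: A(b!1).B(a!1) -> A(b) + B(a) ma(k)")
        complex_ = parse_species(universe, "A(x~P,b!1).B(a!1)")
        outcomes = apply_rule(rule, (complex_,))
        assert len(outcomes) == 1
        products, _ = outcomes[0]
        labels = sorted(p.canonical_label() for p in products)
        assert labels == sorted(
            [
                parse_species(universe, "A(x~P)").canonical_label(),
                parse_species(universe, "B(a)").canonical_label(),
            ]
        )

    def test_synthesis_and_degradation(self, universe):
        synth = parse_rule(universe, "s: 0 -> B(a) ma(k)")
        outcomes = synth.apply(())
        assert len(outcomes) == 1
        products, count = outcomes[0]
        assert count == 1 and products[0].canonical_label() == "B(a)"
        deg = parse_rule(universe, "d: B(a) -> 0 ma(k)")
        outcomes = deg.apply((parse_species(universe, "B(a)"),))
        assert outcomes == [([], 1)]

    def test_reversed_rule_swaps_sides(self, universe):
        rule = parse_rule(
            universe, "bind: A(b) + B(a) <-> A(b!1).B(a!1) ma(kon), ma(koff)"
        )
        rev = rule.reversed()
        assert len(rev.reactants) == 1 and len(rev.products) == 2
        assert rev.rate_law.constants == ("koff",)
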