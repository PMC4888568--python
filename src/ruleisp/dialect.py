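"""Text dialect for rule-based models (BNGL-like).

Blocks::

    begin molecule types
      IR(loc~mem~cyt,ins~0~1~2,Y~0~P)     # ~ separates allowed states
      PI3K(irs)                            # site with no ~ is a pure binding site
    end molecule types
    begin parameters
      k1 3.32e-5
    end parameters
    begin seed species
      $INS() 180664          # $ marks a constant (clamped) species
      IR(loc~mem,ins~0,Y~0) 90000
    end seed species
    begin observables
      ppERK ERK(T~P,Y~P)     # name followed by one or more patterns
    end observables
    begin reaction rules
      r01: IR(loc~mem,ins~0,Y~0) + INS() <-> IR(loc~mem,ins~1,Y~P) ma(k1), ma(k_1)
      r08: IRS1(S~0) -> IRS1(S~P) hill(Vmax; PKC_act; Kd_pkc; n)
    end reaction rules

Pattern semantics: an unmentioned site matches anything; a mentioned site
without a bond mark must be unbound; ``!+`` requires a bond to an unnamed
partner; ``!?`` leaves the bond unconstrained; paired integer labels
require an explicit bond.  Rate laws: ``ma(sym[*sym...])`` mass action,
``hill(c; X; Kd; n)`` activating Hill on modifier observable X,
``ihill(c; X; Kd; n)`` the inhibitory form Kd^n/(Kd^n+X^n).  In rules that
consume or create molecules, the consumed/created molecules are written
last on their side (molecule alignment is positional).
"""

from __future__ import annotations

import re
from typing import Optional, Union

from .core import (
    BondMark,
    MoleculeType,
    MoleculeTypeUniverse,
    Pattern,
    PatternMolecule,
    PatternSite,
    RateLaw,
    Rule,
    RuleError,
    SpeciesGraph,
)
from .network import Observable, ParameterSet, RuleModel

_MOL_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)\(([^()]*)\)")


class DialectError(RuleError):
    pass


# ---------------------------------------------------------------------------
# string -> objects
# ---------------------------------------------------------------------------


def _split_molecules(text: str) -> list[tuple[str, str]]:
    """Split 'A(x~0,b!1).B(a!1)' into [('A', 'x~0,b!1'), ('B', 'a!1')]."""
    out = []
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _MOL_RE.match(text, pos)
        if not m:
            raise DialectError(f"cannot parse molecule at {text[pos:]!r}")
        out.append((m.group(1), m.group(2)))
        pos = m.end()
        if pos < len(text):
            if text[pos] != ".":
                raise DialectError(f"expected '.' between molecules in {text!r}")
            pos += 1
    return out


def _parse_site_token(tok: str):
    """-> (site, state or None, bond spec) with bond spec in
    {None (unwritten), BondMark, int}."""
    bond: Union[BondMark, int, None] = None
    if "!" in tok:
        tok, bond_s = tok.split("!", 1)
        if bond_s == "+":
            bond = BondMark.BOUND_ANY
        elif bond_s == "?":
            bond = BondMark.DONT_CARE
        else:
            bond = int(bond_s)
    state = None
    if "~" in tok:
        tok, state = tok.split("~", 1)
    return tok, state, bond


def parse_pattern(universe: MoleculeTypeUniverse, text: str) -> Pattern:
    mols = []
    for tname, body in _split_molecules(text):
        sites = {}
        if body.strip():
            for tok in body.split(","):
                site, state, bond = _parse_site_token(tok.strip())
                if bond is None:
                    bond = BondMark.UNBOUND  # mentioned without a bond mark
                sites[site] = PatternSite(state=state, bond=bond)
        mols.append(PatternMolecule(tname, sites))
    return Pattern(universe, mols)


def parse_species(universe: MoleculeTypeUniverse, text: str) -> SpeciesGraph:
    mols = []
    bond_eps: dict[int, list] = {}
    for mi, (tname, body) in enumerate(_split_molecules(text)):
        states = {}
        if body.strip():
            for tok in body.split(","):
                site, state, bond = _parse_site_token(tok.strip())
                if isinstance(bond, BondMark):
                    raise DialectError(f"species cannot use bond wildcard on {tname}.{site}")
                if state is not None:
                    states[site] = state
                if isinstance(bond, int):
                    bond_eps.setdefault(bond, []).append((mi, site))
        mols.append((tname, states))
    bonds = []
    for label, eps in bond_eps.items():
        if len(eps) != 2:
            raise DialectError(f"bond label {label} used {len(eps)} times")
        bonds.append(tuple(eps))
    return SpeciesGraph(universe, mols, bonds)


def _parse_rate_law(text: str) -> RateLaw:
    text = text.strip()
    m = re.match(r"(ma|hill|ihill)\((.*)\)$", text)
    if not m:
        raise DialectError(f"cannot parse rate law {text!r}")
    kind, body = m.group(1), m.group(2)
    if kind == "ma":
        syms = tuple(s.strip() for s in body.split("*"))
        return RateLaw("mass_action", syms)
    parts = [p.strip() for p in body.split(";")]
    if len(parts) != 4:
        raise DialectError(f"hill law needs 'c; X; Kd; n', got {text!r}")
    consts = tuple(s.strip() for s in parts[0].split("*"))
    n: Union[str, float] = parts[3]
    try:
        n = float(parts[3])
    except ValueError:
        pass
    return RateLaw(
        "hill", consts, modifier=parts[1], kd=parts[2], n=n, inhibitory=(kind == "ihill")
    )


def _parse_side(universe, text: str) -> list[Pattern]:
    text = text.strip()
    if text == "0":
        return []
    return [parse_pattern(universe, part.strip()) for part in text.split("+")]


def parse_rule(universe: MoleculeTypeUniverse, line: str) -> Rule:
    m = re.match(r"([A-Za-z_][\w.-]*)\s*:\s*(.*)$", line.strip())
    if not m:
        raise DialectError(f"rule line needs 'name: ...': {line!r}")
    name, rest = m.group(1), m.group(2)
    reversible = "<->" in rest
    arrow = "<->" if reversible else "->"
    lhs, rhs = rest.split(arrow, 1)
    # the rate law(s) trail the product side: split at the first law keyword
    mlaw = re.search(r"\b(ma|hill|ihill)\(", rhs)
    if not mlaw:
        raise DialectError(f"rule {name}: missing rate law")
    prod_text, law_text = rhs[: mlaw.start()], rhs[mlaw.start():]
    laws = _split_laws(law_text)
    if reversible and len(laws) != 2:
        raise DialectError(f"rule {name}: reversible rule needs two rate laws")
    if not reversible and len(laws) != 1:
        raise DialectError(f"rule {name}: expected one rate law")
    return Rule(
        name=name,
        reactants=_parse_side(universe, lhs),
        products=_parse_side(universe, prod_text),
        rate_law=_parse_rate_law(laws[0]),
        reversible=reversible,
        reverse_rate_law=_parse_rate_law(laws[1]) if reversible else None,
    )


def _split_laws(text: str) -> list[str]:
    """Split 'ma(k1), ma(k_1)' at top-level commas."""
    out, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if cur:
        out.append("".join(cur))
    return [s.strip() for s in out if s.strip()]


# ---------------------------------------------------------------------------
# whole-model reader / writer
# ---------------------------------------------------------------------------


def _parse_molecule_type(line: str) -> MoleculeType:
    m = _MOL_RE.match(line.strip())
    if not m or m.end() != len(line.strip()):
        raise DialectError(f"cannot parse molecule type {line!r}")
    name, body = m.group(1), m.group(2)
    sites = {}
    if body.strip():
        for tok in body.split(","):
            parts = tok.strip().split("~")
            sites[parts[0]] = tuple(parts[1:])
    return MoleculeType(name, sites)


def loads(text: str, name: str = "model") -> RuleModel:
    """Parse a full model from dialect text."""
    blocks: dict[str, list[str]] = {}
    current: Optional[str] = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("begin "):
            current = line[6:].strip()
            blocks[current] = []
        elif line.startswith("end "):
            if current != line[4:].strip():
                raise DialectError(f"mismatched block end: {line!r}")
            current = None
        else:
            if current is None:
                raise DialectError(f"statement outside block: {line!r}")
            blocks[current].append(line)

    universe = MoleculeTypeUniverse()
    for line in blocks.get("molecule types", []):
        universe.add(_parse_molecule_type(line))

    params = ParameterSet()
    for line in blocks.get("parameters", []):
        parts = line.split()
        if len(parts) != 2:
            raise DialectError(f"parameter line needs 'name value': {line!r}")
        params[parts[0]] = float(parts[1])

    seeds = []
    constant_species = set()
    for line in blocks.get("seed species", []):
        parts = line.rsplit(None, 1)
        if len(parts) != 2:
            raise DialectError(f"seed line needs 'species count': {line!r}")
        spec_text, count = parts
        constant = spec_text.startswith("$")
        if constant:
            spec_text = spec_text[1:]
        g = parse_species(universe, spec_text)
        if constant:
            constant_species.add(g.canonical_label())
        seeds.append((g, float(count)))

    observables = {}
    for line in blocks.get("observables", []):
        parts = line.split()
        oname, pats = parts[0], parts[1:]
        if not pats:
            raise DialectError(f"observable {oname}: no patterns")
        observables[oname] = Observable(oname, [parse_pattern(universe, p) for p in pats])

    rules = [parse_rule(universe, line) for line in blocks.get("reaction rules", [])]

    model = RuleModel(
        universe=universe,
        parameters=params,
        seeds=seeds,
        rules=rules,
        observables=observables,
        constant_species=constant_species,
        name=name,
    )
    model.validate()
    return model


def load(path, name: Optional[str] = None) -> RuleModel:
    with open(path) as fh:
        text = fh.read()
    return loads(text, name=name or str(path))


# -- writer -----------------------------------------------------------------


def _format_molecule_type(t: MoleculeType) -> str:
    toks = []
    for site, states in t.sites.items():
        toks.append(site + "".join(f"~{s}" for s in states))
    return f"{t.name}({','.join(toks)})"


def _format_species(g: SpeciesGraph) -> str:
    return g.canonical_label()


def _format_pattern(p: Pattern) -> str:
    return p.signature()


def _format_law(law: RateLaw) -> str:
    c = "*".join(law.constants)
    if law.kind == "mass_action":
        return f"ma({c})"
    kw = "ihill" if law.inhibitory else "hill"
    n = law.n if isinstance(law.n, str) else repr(law.n)
    return f"{kw}({c}; {law.modifier}; {law.kd}; {n})"


def _format_side(patterns) -> str:
    if not patterns:
        return "0"
    return " + ".join(_format_pattern(p) for p in patterns)


def dumps(model: RuleModel) -> str:
    out = []
    out.append("begin molecule types")
    for t in model.universe:
        out.append("  " + _format_molecule_type(t))
    out.append("end molecule types")
    out.append("begin parameters")
    for k in model.parameters:
        out.append(f"  {k} {model.parameters[k]!r}")
    out.append("end parameters")
    out.append("begin seed species")
    for g, n0 in model.seeds:
        prefix = "$" if g.canonical_label() in model.constant_species else ""
        out.append(f"  {prefix}{_format_species(g)} {n0!r}")
    out.append("end seed species")
    out.append("begin observables")
    for obs in model.observables.values():
        pats = " ".join(_format_pattern(p) for p in obs.patterns)
        out.append(f"  {obs.name} {pats}")
    out.append("end observables")
    out.append("begin reaction rules")
    for r in model.rules:
        arrow = "<->" if r.reversible else "->"
        laws = _format_law(r.rate_law)
        if r.reversible:
            laws += ", " + _format_law(r.reverse_rate_law)
        out.append(
            f"  {r.name}: {_format_side(r.reactants)} {arrow} {_format_side(r.products)} {laws}"
        )
    out.append("end reaction rules")
    return "\n".join(out) + "\n"


def dump(model: RuleModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps(model))
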