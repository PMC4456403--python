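"""The concrete Kappa backend.

Implements the semantic parameter of the language — site-expression typing,
default, update, seal — together with the translation from normal-form
rules and initial populations to a flat Kappa program, the well-typedness
checks, the KaSim v3-dialect writer, and canonicalisation helpers used for
golden comparisons.

Compartments are encoded as an extra ``comp`` site, appended after the
(lexicographically) sorted ordinary sites, whose internal state is the
dot-joined compartment path (``"top"`` for the empty path).  Agents in
different compartments are thereby distinguished in flat Kappa.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .ir import AgentDecl, AgentInst, ElaboratedModel, NormalRule, Value
from .syntax import (
    IVal, IWild, IIdent, I_WILD, LAny, LBound, LFree, LIdent, LLabel,
    L_ANY, L_BOUND, L_FREE, SiteExpr, SiteType,
)

COMP_SITE = "comp"
TOP_TOKEN = "top"


class KappaError(Exception):
    """Raised when a translated rule or initial condition is ill-typed."""


# ---------------------------------------------------------------------------
# The semantic parameter: operations on site expressions


def default_site(stype: SiteType) -> SiteExpr:
    """Default expression for an unspecified site: wildcard internal state
    and wildcard (free-or-bound) link."""
    return SiteExpr(I_WILD, L_ANY)


def update_site(old: SiteExpr, new: SiteExpr) -> SiteExpr:
    """Overwrite componentwise, except where the identity is used."""
    internal = old.internal if isinstance(new.internal, IIdent) else new.internal
    link = old.link if isinstance(new.link, LIdent) else new.link
    return SiteExpr(internal, link)


def typecheck_site(se: SiteExpr, stype: SiteType) -> bool:
    """A site expression types against ``binding(V)`` iff its internal
    values (a singleton or empty set) lie in V."""
    if isinstance(se.internal, IVal):
        return se.internal.value in stype.values
    return True


def seal_site(se: SiteExpr, ns: str) -> SiteExpr:
    """Confine a link label to namespace ``ns`` by prepending ``ns`` to the
    label's existing namespace; other links are unchanged."""
    if isinstance(se.link, LLabel):
        return SiteExpr(se.internal, LLabel(se.link.k, ns + se.link.ns))
    return se


# ---------------------------------------------------------------------------
# Flat Kappa objects


@dataclass(frozen=True)
class KappaSite:
    name: str
    internal: Union[IVal, IWild]
    link: Union[LAny, LBound, LFree, int]  # int = encoded link label


@dataclass(frozen=True)
class KappaAgent:
    name: str
    sites: tuple[KappaSite, ...]


@dataclass(frozen=True)
class KappaRule:
    lhs: tuple[KappaAgent, ...]
    rhs: tuple[KappaAgent, ...]
    rate: float
    label: str


@dataclass
class KappaProgram:
    """A flat Kappa program: a set of rules plus initial conditions.

    ``rules`` keeps production order but has set semantics: composition
    deduplicates on the canonical (lhs, rhs, rate) form.  ``signatures``
    maps each printable agent name to its site signature (internal values
    in declaration order), used by the writer and the simulator.
    """

    rules: list[KappaRule] = field(default_factory=list)
    inits: list[tuple[tuple[KappaAgent, ...], int]] = field(default_factory=list)
    signatures: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = field(
        default_factory=dict)

    def rule_keys(self) -> set[str]:
        return {canon_rule(r) for r in self.rules}


# ---------------------------------------------------------------------------
# Link-label encoding and agent translation


class LinkEncoder:
    """Injective map from restricted labels ``(k, namespace)`` to
    consecutive positive integers, in first-occurrence order (labels in
    Kappa are rule-scoped, so a per-rule encoding suffices)."""

    def __init__(self) -> None:
        self.table: dict[tuple[int, str], int] = {}

    def enc(self, label: LLabel) -> int:
        key = (label.k, label.ns)
        if key not in self.table:
            self.table[key] = len(self.table) + 1
        return self.table[key]


def kap_sites(sites: Iterable[tuple[str, SiteType, SiteExpr]],
              encoder: LinkEncoder,
              suppress_trivial: bool = True) -> tuple[KappaSite, ...]:
    """Linearise a typed site assignment: sites in lexicographic name
    order, types discarded, labels encoded.  Sites carrying no constraint
    (wildcard internal, free-or-bound link) are dropped from patterns when
    ``suppress_trivial``.  Identity variants must not survive to here."""
    out = []
    for name, _stype, se in sorted(sites, key=lambda t: t[0]):
        if isinstance(se.internal, IIdent) or isinstance(se.link, LIdent):
            raise KappaError(
                f"identity site expression leaked to the backend at site {name!r}")
        if suppress_trivial and isinstance(se.internal, IWild) \
                and isinstance(se.link, LAny):
            continue
        link = encoder.enc(se.link) if isinstance(se.link, LLabel) else se.link
        out.append(KappaSite(name, se.internal, link))
    return tuple(out)


def _path_token(path: tuple[str, ...]) -> str:
    return ".".join(path) if path else TOP_TOKEN


def kap(value: Value, name_map: dict[int, str], encoder: LinkEncoder,
        suppress_trivial: bool = True) -> tuple[KappaAgent, ...]:
    """Translate a normal-form agent value to a list of Kappa agents,
    appending the compartment-encoding ``comp`` site to each."""
    agents = []
    for inst in value:
        sites = kap_sites(inst.sites, encoder, suppress_trivial)
        sites += (KappaSite(COMP_SITE, IVal(_path_token(inst.path)), L_FREE),)
        agents.append(KappaAgent(name_map.get(inst.uid, inst.name), sites))
    return tuple(agents)


# ---------------------------------------------------------------------------
# Well-typedness


def _check_label_pairing(agents: tuple[KappaAgent, ...], where: str) -> None:
    counts: dict[int, int] = {}
    for a in agents:
        seen = set()
        for s in a.sites:
            if s.name in seen:
                raise KappaError(f"duplicate site {s.name!r} on agent {a.name!r}")
            seen.add(s.name)
            if isinstance(s.link, int):
                counts[s.link] = counts.get(s.link, 0) + 1
    for k, c in counts.items():
        if c != 2:
            raise KappaError(
                f"link label {k} occurs {c} time(s) on {where}; must occur exactly twice")


def _align_by_name(lhs: tuple[KappaAgent, ...], rhs: tuple[KappaAgent, ...]):
    """Greedy positional alignment of rule sides by agent name; returns
    (pairs, deleted lhs indices, created rhs indices)."""
    pairs, deleted, created = [], [], []
    i = j = 0
    while i < len(lhs) and j < len(rhs):
        if lhs[i].name == rhs[j].name:
            pairs.append((i, j))
            i += 1
            j += 1
        elif lhs[i].name not in {a.name for a in rhs[j:]}:
            deleted.append(i)
            i += 1
        else:
            created.append(j)
            j += 1
    deleted.extend(range(i, len(lhs)))
    created.extend(range(j, len(rhs)))
    return pairs, deleted, created


def _check_rhs_wildcards(rule: KappaRule) -> None:
    """Free-or-bound ``?`` is a pattern-only construct: on the RHS it is
    accepted only when the corresponding LHS agent carries the identical
    site (no side effect); bound-to-something ``!_`` likewise."""
    pairs, _, created = _align_by_name(rule.lhs, rule.rhs)
    lhs_of = {j: i for i, j in pairs}
    for j, agent in enumerate(rule.rhs):
        for s in agent.sites:
            if isinstance(s.link, (LAny, LBound)):
                ok = False
                if j in lhs_of:
                    ok = s in rule.lhs[lhs_of[j]].sites
                if not ok:
                    raise KappaError(
                        f"wildcard link on product site {agent.name}.{s.name} "
                        f"in rule {rule.label!r} would be a side effect")


def check_rule(rule: KappaRule) -> None:
    _check_label_pairing(rule.lhs, f"LHS of rule {rule.label!r}")
    _check_label_pairing(rule.rhs, f"RHS of rule {rule.label!r}")
    _check_rhs_wildcards(rule)


# ---------------------------------------------------------------------------
# Printable agent names and signatures


def resolve_names(decls: dict[int, AgentDecl]) -> dict[int, str]:
    """Printable Kappa name per ``new`` definition: the declared name when
    globally unique; on collision the defining identifier; with a numeric
    suffix as a last resort."""
    by_name: dict[str, list[int]] = {}
    for uid, d in sorted(decls.items()):
        by_name.setdefault(d.name, []).append(uid)
    out: dict[int, str] = {}
    taken: set[str] = set(by_name)
    for name, uids in by_name.items():
        if len(uids) == 1:
            out[uids[0]] = name
            continue
        taken.discard(name)
        for idx, uid in enumerate(uids):
            d = decls[uid]
            cand = d.idents[0] if d.idents else f"{name}{idx + 1}"
            while cand in taken or cand in out.values():
                cand += "_"
            out[uid] = cand
            taken.add(cand)
    return out


def build_signatures(model: ElaboratedModel,
                     name_map: dict[int, str]) -> dict:
    tokens = sorted({_path_token(inst.path)
                     for rules_or_inits in (model.rules,)
                     for r in rules_or_inits
                     for side in (r.lhs, r.rhs)
                     for v in side for inst in v}
                    | {_path_token(inst.path)
                       for v, _ in model.inits for inst in v}
                    | {TOP_TOKEN})
    sigs = {}
    used = {inst.uid
            for r in model.rules for side in (r.lhs, r.rhs)
            for v in side for inst in v}
    used |= {inst.uid for v, _ in model.inits for inst in v}
    for uid in sorted(used):
        d = model.decls.get(uid)
        if d is None:
            continue
        sites = sorted(d.sig, key=lambda t: t[0])
        entry = tuple((s, t.values) for s, t in sites)
        entry += ((COMP_SITE, tuple(tokens)),)
        sigs[name_map.get(uid, d.name)] = entry
    return sigs


# ---------------------------------------------------------------------------
# Translation entry points


_LABEL_SANITISE = re.compile(r"[^A-Za-z0-9_.]")


def rule_to_kappa(rule: NormalRule, name_map: dict[int, str]) -> KappaRule:
    """Translate one normal-form rule; fails unless the result is
    well-typed (each link label exactly twice per side, unique sites)."""
    encoder = LinkEncoder()
    lhs = tuple(a for v in rule.lhs for a in kap(v, name_map, encoder))
    rhs = tuple(a for v in rule.rhs for a in kap(v, name_map, encoder))
    label = _LABEL_SANITISE.sub("_", rule.name)
    kr = KappaRule(lhs, rhs, rule.rate, label)
    check_rule(kr)
    return kr


def ground_value(value: Value, decls: dict[int, AgentDecl]) -> Value:
    """Ground a value for use as an initial condition: a wildcard internal
    state defaults to the first declared value of the site's type, a
    free-or-bound link defaults to free.  Bound-to-something cannot be
    grounded and is an error."""
    out = []
    for inst in value:
        sites = []
        for s, t, se in inst.sites:
            internal, link = se.internal, se.link
            if isinstance(internal, IWild):
                internal = IVal(t.values[0])
            if isinstance(link, LAny):
                link = L_FREE
            if isinstance(link, LBound):
                raise KappaError(
                    f"initial condition site {inst.name}.{s} is bound to an "
                    "unspecified partner; initial agents must be ground")
            sites.append((s, t, SiteExpr(internal, link)))
        out.append(AgentInst(inst.path, inst.uid, inst.name, inst.alias,
                             tuple(sites)))
    return tuple(out)


def init_to_kappa(value: Value, count: int, name_map: dict[int, str],
                  decls: dict[int, AgentDecl]) -> tuple[tuple[KappaAgent, ...], int]:
    if count <= 0:
        raise KappaError("initial population count must be positive")
    encoder = LinkEncoder()
    agents = kap(ground_value(value, decls), name_map, encoder,
                 suppress_trivial=False)
    _check_label_pairing(agents, "initial condition")
    return agents, count


def compose(k1: KappaProgram, k2: KappaProgram) -> KappaProgram:
    """Parallel composition: rule-set union (canonical-form identity),
    init-list concatenation; the empty program is the identity."""
    out = KappaProgram(list(k1.rules), list(k1.inits) + list(k2.inits),
                       {**k1.signatures, **k2.signatures})
    keys = k1.rule_keys()
    for r in k2.rules:
        if canon_rule(r) not in keys:
            out.rules.append(r)
            keys.add(canon_rule(r))
    return out


def to_kappa(model: ElaboratedModel) -> KappaProgram:
    """Translate an elaborated model into a well-typed flat Kappa program."""
    name_map = resolve_names(model.decls)
    prog = KappaProgram(signatures=build_signatures(model, name_map))
    keys: set[str] = set()
    for rule in model.rules:
        kr = rule_to_kappa(rule, name_map)
        key = canon_rule(kr)
        if key not in keys:
            keys.add(key)
            prog.rules.append(kr)
    for value, count in model.inits:
        prog.inits.append(init_to_kappa(value, count, name_map, model.decls))
    return prog


# ---------------------------------------------------------------------------
# Printing and canonicalisation


def site_to_str(s: KappaSite) -> str:
    out = s.name
    if isinstance(s.internal, IVal):
        out += f"~{s.internal.value}"
    if isinstance(s.link, int):
        out += f"!{s.link}"
    elif isinstance(s.link, LBound):
        out += "!_"
    elif isinstance(s.link, LAny):
        out += "?"
    return out


def agent_to_str(a: KappaAgent) -> str:
    return f"{a.name}({','.join(site_to_str(s) for s in a.sites)})"


def side_to_str(agents: tuple[KappaAgent, ...]) -> str:
    return ",".join(agent_to_str(a) for a in agents)


def _fmt_rate(r: float) -> str:
    return f"{r:g}"


def canon_sides(side_a, side_b) -> tuple[str, str]:
    """Render two agent lists with link labels renumbered in order of first
    occurrence scanning ``side_a`` then ``side_b``."""
    renum: dict[int, int] = {}

    def rn(agents):
        out = []
        for a in agents:
            sites = []
            for s in a.sites:
                if isinstance(s.link, int):
                    if s.link not in renum:
                        renum[s.link] = len(renum) + 1
                    s = KappaSite(s.name, s.internal, renum[s.link])
                sites.append(s)
            out.append(KappaAgent(a.name, tuple(sites)))
        return side_to_str(tuple(out))

    return rn(side_a), rn(side_b)


def canon_rule(rule: KappaRule) -> str:
    """Canonical form of a rule: label dropped, links renumbered."""
    lhs, rhs = canon_sides(rule.lhs, rule.rhs)
    return f"{lhs} -> {rhs} @ {_fmt_rate(rule.rate)}"


def canonicalise(prog: KappaProgram) -> list[str]:
    """Sorted canonical rule forms plus canonical init lines — the shape
    compared in golden tests (rule order and label numbering abstracted)."""
    rules = sorted(canon_rule(r) for r in prog.rules)
    inits = sorted(f"%init: {n} {canon_sides(agents, ())[0]}"
                   for agents, n in prog.inits)
    return rules + inits


def reversible_pairs(prog: KappaProgram) -> int:
    """Number of unordered pairs of directed rules with mirrored sides
    (rates ignored): the reversible-rule count of the flat model."""
    sides = [canon_sides(r.lhs, r.rhs) for r in prog.rules]
    used = [False] * len(sides)
    pairs = 0
    for i, (l1, r1) in enumerate(sides):
        if used[i]:
            continue
        for j in range(i + 1, len(sides)):
            if used[j]:
                continue
            l2m, r2m = canon_sides(prog.rules[j].rhs, prog.rules[j].lhs)
            if (l1, r1) == (l2m, r2m):
                used[i] = used[j] = True
                pairs += 1
                break
    return pairs


def write_kasim(prog: KappaProgram) -> str:
    """Serialise to the KaSim v3 dialect: %agent signatures, one quoted
    rule line per rule, %init lines.  Output ordering is deterministic."""
    lines = ["# flat Kappa model generated by lbskappa (KaSim v3 dialect)"]
    for name in sorted(prog.signatures):
        sites = []
        for site, values in prog.signatures[name]:
            sites.append(site + "".join(f"~{v}" for v in values))
        lines.append(f"%agent: {name}({','.join(sites)})")
    for r in prog.rules:
        lines.append(f"'{r.label}' {side_to_str(r.lhs)} -> "
                     f"{side_to_str(r.rhs)} @ {_fmt_rate(r.rate)}")
    for agents, n in prog.inits:
        lines.append(f"%init: {n} {side_to_str(agents)}")
    return "\n".join(lines) + "\n"


_RULE_LINE = re.compile(r"^'([^']*)'\s*(.*?)\s*->\s*(.*?)\s*@\s*(\S+)\s*$")
_AGENT_LINE = re.compile(r"^%agent:\s*([\w.']+)\s*\(([^)]*)\)\s*$")
_INIT_LINE = re.compile(r"^%init:\s*(\d+)\s+(.*)$")


def read_kasim(text: str) -> KappaProgram:
    """Read back the KaSim v3-dialect subset this package writes:
    ``%agent`` signatures, quoted rule lines, ``%init`` lines."""
    prog = KappaProgram()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _AGENT_LINE.match(line)
        if m:
            sites = []
            if m.group(2).strip():
                for part in m.group(2).split(","):
                    toks = part.strip().split("~")
                    sites.append((toks[0], tuple(toks[1:]) or ("u", "p")))
            prog.signatures[m.group(1)] = tuple(sites)
            continue
        m = _INIT_LINE.match(line)
        if m:
            prog.inits.append((parse_kappa_pattern(m.group(2)), int(m.group(1))))
            continue
        m = _RULE_LINE.match(line)
        if m:
            label, lhs_txt, rhs_txt, rate_txt = m.groups()
            lhs = parse_kappa_pattern(lhs_txt) if lhs_txt else ()
            rhs = parse_kappa_pattern(rhs_txt) if rhs_txt else ()
            prog.rules.append(KappaRule(lhs, rhs, float(rate_txt), label))
            continue
        if line.startswith("%"):
            continue  # directives outside the written subset are ignored
        raise KappaError(f"cannot read line {lineno}: {raw!r}")
    return prog


# ---------------------------------------------------------------------------
# A small KaSim-pattern parser (observables, simulator tests)


_PAT_AGENT = re.compile(r"\s*([A-Za-z][\w.']*)\s*\(([^)]*)\)\s*")
_PAT_SITE = re.compile(
    r"\s*([A-Za-z][\w.']*)\s*(?:~([\w.]+))?\s*(!\d+|!_|\?)?\s*$")


def parse_kappa_pattern(text: str) -> tuple[KappaAgent, ...]:
    """Parse a flat Kappa pattern like ``A(x~u!1),B(y!1)``.

    A mentioned site with no link decoration means *free* (KaSim
    convention); an unmentioned site is unconstrained.
    """
    agents = []
    pos = 0
    while pos < len(text):
        m = _PAT_AGENT.match(text, pos)
        if not m:
            raise KappaError(f"cannot parse pattern at: {text[pos:]!r}")
        name, body = m.group(1), m.group(2)
        sites = []
        if body.strip():
            for part in body.split(","):
                sm = _PAT_SITE.match(part)
                if not sm:
                    raise KappaError(f"cannot parse site {part!r}")
                internal = IVal(sm.group(2)) if sm.group(2) else I_WILD
                link_txt = sm.group(3)
                if link_txt is None:
                    link: Union[LAny, LBound, LFree, int] = L_FREE
                elif link_txt == "!_":
                    link = L_BOUND
                elif link_txt == "?":
                    link = L_ANY
                else:
                    link = int(link_txt[1:])
                sites.append(KappaSite(sm.group(1), internal, link))
        agents.append(KappaAgent(name, tuple(sites)))
        pos = m.end()
        if pos < len(text):
            if text[pos] != ",":
                raise KappaError(f"expected ',' between agents at {text[pos:]!r}")
            pos += 1
    if not agents:
        raise KappaError("empty pattern")
    return tuple(agents)
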