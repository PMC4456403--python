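"""Elaboration: from desugared abstract syntax to normal-form rules.

This is the general semantics of the language instantiated for Kappa.  It
threads an environment through the program, evaluating definitions,
compartment locations, module invocations (with agent subtyping), agent
updates and non-deterministic choice down to located, fully typed agent
lists with evaluated rates, plus initial populations.

Key mechanisms
--------------
* ``new`` creates an agent that is universally unique within the model
  (a fresh uid); repeating an identical definition yields distinct agents.
  An alias list (``agent P1, P2, P3 = new P{...}``) defines one agent but
  tags each identifier's value so updates can address one occurrence
  inside a homo-multimeric complex.
* Choice values expand rules to the Cartesian product of alternatives;
  several references to the same choice identifier within one rule select
  the same alternative (non-determinism is resolved per rule, not per
  occurrence).
* Module invocation binds formals to actuals, checks subtyping (the actual
  may carry more sites/agents than the formal requires; an explicitly
  declared formal site type must equal the actual's), and substitutes the
  formal agent/site names throughout the body.  Link labels written inside
  a body are sealed into a child namespace — the parent namespace extended
  with the bits of a global invocation counter — so labels in the body can
  never capture labels from actual-parameter expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .ir import AgentDecl, AgentInst, ElaboratedModel, NormalRule, Value
from .kappa import default_site, seal_site, typecheck_site, update_site
from .syntax import (
    ActualAgent, ActualExpr, AgentDef, AnnotEntry, AsBind, Choice, CompDef,
    Compose, Ident, Init, Invoke, Loc, LocP, ModuleDef, NewAgent, Nil, Par,
    Program, RBin, RConst, RIdent, RateDef, RateExpr, Rule, Scoped, Script,
    ScriptDef, SiteType, Update,
)

Assign = frozenset  # of (choice_id, branch)
Alt = tuple  # (Value, Assign)


class ElabError(Exception):
    pass


@dataclass(frozen=True)
class ModuleClosure:
    defn: ModuleDef
    env: "Env"


@dataclass(frozen=True)
class Env:
    agents: dict = field(default_factory=dict)
    comps: dict = field(default_factory=dict)        # name -> parent | None
    comp_subst: dict = field(default_factory=dict)   # formal -> actual
    rates: dict = field(default_factory=dict)
    modules: dict = field(default_factory=dict)
    name_subst: dict = field(default_factory=dict)   # formal agent name -> actual
    site_subst: dict = field(default_factory=dict)   # (formal name, site) -> actual
    namespace: str = ""

    def extend(self, **kw) -> "Env":
        return replace(self, **kw)


def _merge(a: Assign, b: Assign) -> Optional[Assign]:
    branch: dict[int, int] = {}
    for cid, br in a | b:
        if branch.setdefault(cid, br) != br:
            return None
    return a | b


def _combine(alt_lists: list[list[Alt]]) -> list[tuple[tuple[Value, ...], Assign]]:
    out: list[tuple[tuple[Value, ...], Assign]] = [((), frozenset())]
    for alts in alt_lists:
        nxt = []
        for values, a in out:
            for v, b in alts:
                m = _merge(a, b)
                if m is not None:
                    nxt.append((values + (v,), m))
        out = nxt
    return out


def _root_ident(expr) -> Optional[str]:
    while True:
        if isinstance(expr, Ident):
            return expr.name
        if isinstance(expr, (Update,)):
            expr = expr.base
        elif isinstance(expr, Loc):
            expr = expr.body
        else:
            return None


class Elaborator:
    def __init__(self, allow_scripts: bool = False):
        self.decls: dict[int, AgentDecl] = {}
        self.comps: dict[str, Optional[str]] = {}  # global declaration record
        self._uid = 0
        self._invocations = 0
        self._choices = 0
        self._rules = 0
        self.allow_scripts = allow_scripts
        from .scripting import ScriptEnvironment
        self.script_env = ScriptEnvironment()

    # counters -----------------------------------------------------------

    def _fresh_uid(self) -> int:
        self._uid += 1
        return self._uid

    def _fresh_choice(self) -> int:
        self._choices += 1
        return self._choices

    def _child_namespace(self, env: Env) -> str:
        self._invocations += 1
        return env.namespace + format(self._invocations, "b")

    # rates ----------------------------------------------------------------

    def eval_rate(self, e: Union[RateExpr, str], env: Env) -> float:
        if isinstance(e, str):
            e = RIdent(e)
        if isinstance(e, RConst):
            return e.value
        if isinstance(e, RIdent):
            if e.name not in env.rates:
                raise ElabError(f"unbound rate identifier {e.name!r}")
            return env.rates[e.name]
        if isinstance(e, RBin):
            left = self.eval_rate(e.left, env)
            right = self.eval_rate(e.right, env)
            if e.op == "*":
                return left * right
            if e.op == "/":
                if right == 0:
                    raise ElabError("division by zero in rate expression")
                return left / right
            if e.op == "+":
                return left + right
            return left - right
        raise ElabError(f"bad rate expression {e!r}")

    # agent expressions ----------------------------------------------------

    def _new_agent(self, name: str, sig, idents: tuple[str, ...]) -> AgentDecl:
        decl = AgentDecl(self._fresh_uid(), name, tuple(sig), idents)
        self.decls[decl.uid] = decl
        return decl

    def _decl_value(self, decl: AgentDecl, alias: Optional[str]) -> Value:
        sites = tuple((s, t, default_site(t)) for s, t in decl.sig)
        return (AgentInst((), decl.uid, decl.name, alias, sites),)

    def eval_expr(self, e, env: Env) -> list[Alt]:
        if isinstance(e, Ident):
            if e.name not in env.agents:
                raise ElabError(f"undefined agent identifier {e.name!r}")
            return env.agents[e.name]
        if isinstance(e, NewAgent):
            if e.name is None:
                raise ElabError("'new' without an agent name outside a definition")
            decl = self._new_agent(e.name, e.sig, ())
            return [(self._decl_value(decl, None), frozenset())]
        if isinstance(e, Compose):
            out = []
            for values, a in _combine([self.eval_expr(e.left, env),
                                       self.eval_expr(e.right, env)]):
                out.append((values[0] + values[1], a))
            return out
        if isinstance(e, Choice):
            cid = self._fresh_choice()
            alts: list[Alt] = []
            seen: set[Value] = set()
            for branch, sub in enumerate((e.left, e.right)):
                for v, a in self.eval_expr(sub, env):
                    m = _merge(a, frozenset({(cid, branch)}))
                    if m is not None and v not in seen:
                        seen.add(v)
                        alts.append((v, m))
            return alts
        if isinstance(e, Loc):
            comp = env.comp_subst.get(e.comp, e.comp)
            if comp not in env.comps:
                raise ElabError(f"undeclared compartment {e.comp!r}")
            out = []
            for v, a in self.eval_expr(e.body, env):
                out.append((tuple(replace(i, path=(comp,) + i.path) for i in v), a))
            return out
        if isinstance(e, Update):
            return [(self._apply_update(v, e, env), a)
                    for v, a in self.eval_expr(e.base, env)]
        if isinstance(e, AsBind):
            raise ElabError("'as' binding survived desugaring")
        raise ElabError(f"cannot evaluate agent expression {e!r}")

    def _apply_update(self, value: Value, node: Update, env: Env) -> Value:
        if node.target is None:
            if len(value) != 1:
                raise ElabError("atomic update abbreviation applied to a complex")
            idx = 0
            key_name = _root_ident(node.base)
        else:
            target = env.name_subst.get(node.target, node.target)
            path = tuple(env.comp_subst.get(c, c) for c in node.path)
            cands = [i for i, inst in enumerate(value) if inst.alias == target]
            if not cands:
                cands = [i for i, inst in enumerate(value) if inst.name == target]
            if node.path:
                cands = [i for i in cands if value[i].path == path]
            if not cands:
                raise ElabError(f"update target {node.target!r} not found in value")
            if len(cands) > 1:
                raise ElabError(
                    f"update target {node.target!r} is ambiguous; "
                    "use an agent alias to disambiguate")
            idx = cands[0]
            key_name = node.target
        inst = value[idx]
        sites = {s: (t, se) for s, t, se in inst.sites}
        order = [s for s, _, _ in inst.sites]
        for s, se in node.assigns:
            s2 = env.site_subst.get((key_name, s), s) if key_name else s
            if s2 not in sites:
                raise ElabError(
                    f"agent {inst.name!r} has no site {s2!r} (update on {s!r})")
            stype, old = sites[s2]
            new = update_site(old, seal_site(se, env.namespace))
            if not typecheck_site(new, stype):
                raise ElabError(
                    f"internal state {new.internal!r} not declared for site "
                    f"{inst.name}.{s2} (type {stype.values})")
            sites[s2] = (stype, new)
        new_sites = tuple((s, sites[s][0], sites[s][1]) for s in order)
        return value[:idx] + (replace(inst, sites=new_sites),) + value[idx + 1:]

    # programs -------------------------------------------------------------

    def elab(self, p: Program, env: Env):
        if isinstance(p, Nil):
            return [], []
        if isinstance(p, Par):
            r1, i1 = self.elab(p.left, env)
            r2, i2 = self.elab(p.right, env)
            return r1 + r2, i1 + i2
        if isinstance(p, Scoped):
            return self.elab(p.body, self.define(p.defn, env))
        if isinstance(p, LocP):
            comp = env.comp_subst.get(p.comp, p.comp)
            if comp not in env.comps:
                raise ElabError(f"undeclared compartment {p.comp!r}")
            rules, inits = self.elab(p.body, env)
            rules = [replace(r, lhs=_prefix_side(r.lhs, comp),
                             rhs=_prefix_side(r.rhs, comp)) for r in rules]
            inits = [(_prefix_value(v, comp), n) for v, n in inits]
            return rules, inits
        if isinstance(p, Rule):
            return self._elab_rule(p, env), []
        if isinstance(p, Invoke):
            return self._invoke(p, env)
        if isinstance(p, Init):
            alts = self.eval_expr(p.expr, env)
            if len(alts) != 1:
                raise ElabError(
                    "initial population of a non-deterministic agent expression")
            return [], [(alts[0][0], p.count)]
        if isinstance(p, ScriptDef):
            self.script_env = self.script_env.collect(p.code)
            return self.elab(p.cont, env)
        if isinstance(p, Script):
            return self._run_script(p, env)
        raise ElabError(f"cannot elaborate program node {p!r}")

    def _elab_rule(self, p: Rule, env: Env) -> list[NormalRule]:
        rate = self.eval_rate(p.fwd, env)
        if rate < 0:
            raise ElabError(f"negative rate {rate} in rule")
        lhs_alts = _combine([self.eval_expr(e, env) for e in p.lhs])
        rhs_alts = _combine([self.eval_expr(e, env) for e in p.rhs])
        rules = []
        for lhs, a in lhs_alts:
            for rhs, b in rhs_alts:
                if _merge(a, b) is None:
                    continue
                self._rules += 1
                name = f"{env.namespace or 'e'}.{self._rules}"
                rules.append(NormalRule(lhs, rhs, rate, name))
        return rules

    # definitions ----------------------------------------------------------

    def define(self, d, env: Env) -> Env:
        if isinstance(d, AgentDef):
            agents = dict(env.agents)
            if isinstance(d.expr, NewAgent):
                decl = self._new_agent(d.expr.name, d.expr.sig, d.idents)
                for ident in d.idents:
                    agents[ident] = [(self._decl_value(decl, ident), frozenset())]
            else:
                if len(d.idents) != 1:
                    raise ElabError(
                        f"alias list {d.idents} on a non-'new' definition")
                agents[d.idents[0]] = self.eval_expr(d.expr, env)
            return env.extend(agents=agents)
        if isinstance(d, CompDef):
            if d.parent is not None and d.parent not in env.comps:
                raise ElabError(f"parent compartment {d.parent!r} undeclared")
            if d.name in env.comps:
                raise ElabError(f"compartment {d.name!r} already declared")
            if self.comps.setdefault(d.name, d.parent) != d.parent:
                raise ElabError(
                    f"compartment {d.name!r} redeclared with a different parent")
            return env.extend(comps={**env.comps, d.name: d.parent})
        if isinstance(d, RateDef):
            value = self.eval_rate(d.expr, env)
            if value < 0:
                raise ElabError(f"negative rate definition {d.name!r}")
            return env.extend(rates={**env.rates, d.name: value})
        if isinstance(d, ModuleDef):
            return env.extend(modules={**env.modules,
                                       d.name: ModuleClosure(d, env)})
        raise ElabError(f"cannot process definition {d!r}")

    # module invocation ------------------------------------------------------

    def _resolve_annot(self, annot, expr, env: Env):
        """Resolve an actual annotation's written names through the current
        substitution; returns a list of (agent name, [site names])."""
        resolved = []
        for entry in annot:
            wname = entry.name or _root_ident(expr)
            sites = [env.site_subst.get((wname, s), s) if wname else s
                     for s, _t in entry.sites]
            resolved.append((env.name_subst.get(wname, wname) if wname else None,
                             sites, [t for _s, t in entry.sites]))
        return resolved

    @staticmethod
    def _find_agent(value: Value, name: str) -> AgentInst:
        cands = [i for i in value if i.alias == name]
        if not cands:
            cands = [i for i in value if i.name == name]
        if not cands:
            raise ElabError(f"annotation names agent {name!r} absent from the "
                            "actual parameter value")
        if len(cands) > 1:
            raise ElabError(f"annotation agent {name!r} is ambiguous in the "
                            "actual parameter value")
        return cands[0]

    def _invoke(self, p: Invoke, env: Env):
        if p.module not in env.modules:
            raise ElabError(f"undefined module {p.module!r}")
        closure = env.modules[p.module]
        d = closure.defn
        nc, na, nr = len(d.comp_formals), len(d.agent_formals), len(d.rate_formals)
        if len(p.actuals) != nc + na + nr:
            raise ElabError(
                f"module {d.name!r} expects {nc + na + nr} actual parameters, "
                f"got {len(p.actuals)}")
        comp_actuals = p.actuals[:nc]
        agent_actuals = p.actuals[nc:nc + na]
        rate_actuals = p.actuals[nc + na:]

        comp_subst = dict(closure.env.comp_subst)
        for formal, actual in zip(d.comp_formals, comp_actuals):
            if not (isinstance(actual, ActualExpr) and isinstance(actual.expr, str)):
                raise ElabError(f"compartment actual for {formal!r} must be an "
                                "identifier")
            comp = env.comp_subst.get(actual.expr, actual.expr)
            if comp not in env.comps:
                raise ElabError(f"undeclared compartment {actual.expr!r}")
            comp_subst[formal] = comp

        agents = dict(closure.env.agents)
        name_subst = dict(closure.env.name_subst)
        site_subst = dict(closure.env.site_subst)
        bound: set[str] = set()
        for (formal_id, formal_annot), actual in zip(d.agent_formals, agent_actuals):
            if formal_id in bound:
                raise ElabError(f"formal parameter {formal_id!r} bound twice")
            bound.add(formal_id)
            if not isinstance(actual, ActualAgent):
                raise ElabError(
                    f"agent actual for {formal_id!r} must carry an annotation "
                    "(expr:annotation)")
            alts = self.eval_expr(actual.expr, env)
            resolved = self._resolve_annot(actual.annot, actual.expr, env)
            if len(resolved) != len(formal_annot):
                raise ElabError(
                    f"annotation for {formal_id!r} lists {len(resolved)} agents, "
                    f"formal requires {len(formal_annot)}")
            # fill in omitted actual agent names from the value: an
            # abbreviated annotation like Raf:{x} (or a bare-identifier
            # root) names the value's unique agent name
            for k, ((aname, asites, atypes), entry) in enumerate(
                    zip(resolved, actual.annot)):
                present = aname is not None and any(
                    i.alias == aname or i.name == aname for i in alts[0][0])
                if entry.name is None and not present:
                    names = {i.name for i in alts[0][0]}
                    if len(names) != 1:
                        raise ElabError(
                            f"annotation for {formal_id!r} must name its agent")
                    resolved[k] = (names.pop(), asites, atypes)
            for value, _a in alts:
                self._check_subtype(formal_id, formal_annot, resolved, value)
            agents[formal_id] = alts
            for fe, (aname, asites, _t) in zip(formal_annot, resolved):
                f_name = fe.name or formal_id
                name_subst[f_name] = aname
                if len(fe.sites) != len(asites):
                    raise ElabError(
                        f"annotation for {formal_id!r}: formal lists "
                        f"{len(fe.sites)} sites, actual lists {len(asites)}")
                for (f_site, _ft), a_site in zip(fe.sites, asites):
                    site_subst[(f_name, f_site)] = a_site

        rates = dict(closure.env.rates)
        for formal, actual in zip(d.rate_formals, rate_actuals):
            if not isinstance(actual, ActualExpr):
                raise ElabError(f"rate actual for {formal!r} must be a rate "
                                "expression")
            rates[formal] = self.eval_rate(actual.expr, env)

        child = closure.env.extend(
            agents=agents, comps=env.comps, comp_subst=comp_subst,
            rates=rates, name_subst=name_subst, site_subst=site_subst,
            modules={**closure.env.modules, d.name: closure},
            namespace=self._child_namespace(env))
        return self.elab(d.body, child)

    def _check_subtype(self, formal_id: str, formal_annot, resolved,
                       value: Value) -> None:
        """Actual values may carry extra agents and sites (subtyping); every
        agent/site the annotation names must exist, and a site type the
        formal declares explicitly must equal the actual's declared type."""
        for fe, (aname, asites, atypes) in zip(formal_annot, resolved):
            inst = self._find_agent(value, aname)
            declared = {s: t for s, t, _ in inst.sites}
            for (f_site, f_type), a_site, a_type in zip(fe.sites, asites, atypes):
                if a_site not in declared:
                    raise ElabError(
                        f"annotation site {aname}.{a_site} absent from the "
                        f"actual for {formal_id!r}")
                for want in (f_type, a_type):
                    if want is not None and declared[a_site] != want:
                        raise ElabError(
                            f"site type mismatch for {aname}.{a_site}: declared "
                            f"{declared[a_site].values}, required {want.values}")

    # scripts ----------------------------------------------------------------

    def _run_script(self, p: Script, env: Env):
        if not self.allow_scripts:
            raise ElabError(
                "embedded scripts are disabled; enable with allow_scripts=True "
                "(CLI: --allow-scripts)")
        from .scripting import run_script, splice
        from .parser import parse_program
        from .desugar import desugar
        text = run_script(p.code, self.script_env)
        try:
            generated = desugar(parse_program(text))
        except Exception as exc:
            raise ElabError(f"script output failed to parse: {exc}") from exc
        return self.elab(splice(generated, p.cont), env)


def _prefix_value(value: Value, comp: str) -> Value:
    return tuple(replace(i, path=(comp,) + i.path) for i in value)


def _prefix_side(side, comp: str):
    return tuple(_prefix_value(v, comp) for v in side)


def _check_paths(model: ElaboratedModel) -> None:
    paths = {inst.path
             for r in model.rules for side in (r.lhs, r.rhs)
             for v in side for inst in v}
    paths |= {inst.path for v, _ in model.inits for inst in v}
    for path in paths:
        for i, comp in enumerate(path):
            if comp not in model.comps:
                raise ElabError(f"undeclared compartment {comp!r} in path {path}")
            want_parent = path[i - 1] if i else None
            if model.comps[comp] != want_parent:
                raise ElabError(
                    f"compartment path {path} is not a chain in the declared "
                    f"compartment tree ({comp!r} has parent "
                    f"{model.comps[comp]!r})")


def elaborate(program: Program, allow_scripts: bool = False) -> ElaboratedModel:
    """Elaborate a desugared program to normal-form rules and initial
    populations.  The nil program yields the empty model."""
    el = Elaborator(allow_scripts=allow_scripts)
    rules, inits = el.elab(program, Env())
    model = ElaboratedModel(rules, inits, el.decls, dict(el.comps))
    _check_paths(model)
    return model
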