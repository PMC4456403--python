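"""Desugaring: reduce surface abbreviations to the core abstract syntax.

After desugaring a program contains no reversible rules (split into the two
directed rules), no inline ``as`` bindings (hoisted to agent definitions
scoping over the rule and the remainder of the program), no ``new`` without
an agent name (the defining identifier is substituted), and no omitted
site-expression components: in an update assignment an omitted internal
state becomes the identity (leave unchanged) and an omitted link becomes
free.  The pass is idempotent.
"""

from __future__ import annotations

from dataclasses import replace

from .syntax import (
    AgentDef, AsBind, Choice, CompDef, Compose, Ident, Init, Invoke, Loc,
    LocP, ModuleDef, NewAgent, Nil, Par, Program, RateDef, Rule, Scoped,
    Script, ScriptDef, SiteExpr, Update, ActualAgent, I_IDENT, L_FREE,
)


class DesugarError(Exception):
    pass


def _desugar_site(se: SiteExpr) -> SiteExpr:
    internal = se.internal if se.internal is not None else I_IDENT
    link = se.link if se.link is not None else L_FREE
    if internal is se.internal and link is se.link:
        return se
    return SiteExpr(internal, link)


def _desugar_expr(e, binds: list | None = None):
    """Desugar an agent expression; if ``binds`` is given, strip AsBind
    nodes into it (in source order) — otherwise AsBind is an error here."""
    if isinstance(e, AsBind):
        if binds is None:
            raise DesugarError("'as' binding is only allowed in rules")
        body = _desugar_expr(e.body)
        binds.append((e.ident, body))
        return Ident(e.ident)
    if isinstance(e, Compose):
        return Compose(_desugar_expr(e.left), _desugar_expr(e.right))
    if isinstance(e, Choice):
        return Choice(_desugar_expr(e.left), _desugar_expr(e.right))
    if isinstance(e, Loc):
        return Loc(e.comp, _desugar_expr(e.body))
    if isinstance(e, Update):
        assigns = tuple((s, _desugar_site(se)) for s, se in e.assigns)
        return Update(_desugar_expr(e.base), e.path, e.target, assigns)
    return e  # NewAgent, Ident


def _desugar_rule(r: Rule):
    """Return (hoisted agent definitions, directed rules)."""
    binds: list = []
    lhs = tuple(_desugar_expr(e, binds) for e in r.lhs)
    rhs = tuple(_desugar_expr(e, binds) for e in r.rhs)
    defs = [AgentDef((ident,), expr) for ident, expr in binds]
    rules = [Rule(lhs, rhs, r.fwd, None)]
    if r.rev is not None:
        rules.append(Rule(rhs, lhs, r.rev, None))
    return defs, rules


def _desugar_defn(d):
    if isinstance(d, AgentDef):
        expr = _desugar_expr(d.expr)
        if isinstance(expr, NewAgent) and expr.name is None:
            expr = replace(expr, name=d.idents[0])
        if len(d.idents) > 1 and not isinstance(expr, NewAgent):
            raise DesugarError(
                f"alias list {d.idents} requires a 'new' agent expression")
        return AgentDef(d.idents, expr)
    if isinstance(d, ModuleDef):
        return replace(d, body=desugar(d.body))
    return d  # CompDef, RateDef


def _wrap(defs, node: Program) -> Program:
    for d in reversed(defs):
        node = Scoped(d, node)
    return node


def _par(left: Program, right: Program) -> Program:
    if isinstance(right, Nil):
        return left
    if isinstance(left, Nil):
        return right
    return Par(left, right)


def desugar(p: Program) -> Program:
    """Desugar a parsed program (idempotent)."""
    if isinstance(p, Rule):
        defs, rules = _desugar_rule(p)
        node: Program = rules[0]
        for r in rules[1:]:
            node = Par(node, r)
        return _wrap(defs, node)
    if isinstance(p, Par):
        if isinstance(p.left, Rule):
            # hoisted 'as' definitions scope over the rest of the program
            defs, rules = _desugar_rule(p.left)
            node: Program = desugar(p.right)
            for r in reversed(rules):
                node = _par(r, node)
            return _wrap(defs, node)
        return _par(desugar(p.left), desugar(p.right))
    if isinstance(p, Scoped):
        return Scoped(_desugar_defn(p.defn), desugar(p.body))
    if isinstance(p, LocP):
        return LocP(p.comp, desugar(p.body))
    if isinstance(p, Invoke):
        actuals = tuple(
            ActualAgent(_desugar_expr(a.expr), a.annot)
            if isinstance(a, ActualAgent) else a
            for a in p.actuals)
        return Invoke(p.module, actuals)
    if isinstance(p, Init):
        return Init(_desugar_expr(p.expr), p.count)
    if isinstance(p, Script):
        return Script(p.code, desugar(p.cont))
    if isinstance(p, ScriptDef):
        return ScriptDef(p.code, desugar(p.cont))
    return p  # Nil
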