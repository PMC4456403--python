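"""Top-level compilation pipeline: source text -> flat Kappa program."""

from __future__ import annotations

import json
from dataclasses import dataclass

from .desugar import desugar
from .elaborate import elaborate
from .ir import ElaboratedModel, NormalRule, Value
from .kappa import KappaProgram, to_kappa, write_kasim
from .parser import parse_program
from .syntax import (
    IVal, IWild, IIdent, LAny, LBound, LFree, LIdent, LLabel, SiteExpr,
)


@dataclass
class CompiledModel:
    model: ElaboratedModel
    kappa: KappaProgram

    @property
    def kasim_text(self) -> str:
        return write_kasim(self.kappa)


def compile_text(source: str, allow_scripts: bool = False) -> CompiledModel:
    """Parse, desugar, elaborate and translate a model to flat Kappa."""
    ast = desugar(parse_program(source))
    model = elaborate(ast, allow_scripts=allow_scripts)
    return CompiledModel(model, to_kappa(model))


def compile_file(path, allow_scripts: bool = False) -> CompiledModel:
    with open(path, encoding="utf-8") as fh:
        return compile_text(fh.read(), allow_scripts=allow_scripts)


# ---------------------------------------------------------------------------
# JSON dump of the intermediate representation (--dump-ir)


def _site_expr_json(se: SiteExpr):
    if isinstance(se.internal, IVal):
        internal = se.internal.value
    elif isinstance(se.internal, IWild):
        internal = "?"
    elif isinstance(se.internal, IIdent):
        internal = "e"
    else:
        internal = None
    link = se.link
    if isinstance(link, LLabel):
        link_j = {"label": link.k, "namespace": link.ns}
    elif isinstance(link, LAny):
        link_j = "?"
    elif isinstance(link, LBound):
        link_j = "_"
    elif isinstance(link, LFree):
        link_j = "free"
    elif isinstance(link, LIdent):
        link_j = "e"
    else:
        link_j = None
    return {"internal": internal, "link": link_j}


def _value_json(value: Value):
    return [{
        "path": list(inst.path),
        "name": inst.name,
        "uid": inst.uid,
        "alias": inst.alias,
        "sites": {s: {"type": list(t.values), **_site_expr_json(se)}
                  for s, t, se in inst.sites},
    } for inst in value]


def _rule_json(rule: NormalRule):
    return {
        "name": rule.name,
        "rate": rule.rate,
        "lhs": [_value_json(v) for v in rule.lhs],
        "rhs": [_value_json(v) for v in rule.rhs],
    }


def ir_to_json(model: ElaboratedModel) -> str:
    """Serialise the elaborated intermediate representation for debugging."""
    doc = {
        "rules": [_rule_json(r) for r in model.rules],
        "inits": [{"count": n, "value": _value_json(v)}
                  for v, n in model.inits],
        "agents": [{"uid": d.uid, "name": d.name,
                    "identifiers": list(d.idents),
                    "signature": {s: list(t.values) for s, t in d.sig}}
                   for d in model.decls.values()],
        "compartments": model.comps,
    }
    return json.dumps(doc, indent=2)
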