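"""Abstract syntax for LBS-kappa.

The language describes site-graph rewrite rules over *agents* (proteins or
other molecular species) whose named sites carry an internal state (e.g.
``u``/``p`` for phosphorylation) and at most one bond.  On top of flat rules
it layers agent expressions (complex abbreviation, update, choice), a static
compartment hierarchy, and parameterised modules with agent subtyping.

Site expressions are pairs ``(internal, link)``.  The internal state is a
value, a wildcard ``?`` (any value) or the identity (used in updates: leave
unchanged).  The link is free-or-bound ``?``, bound-to-something ``!_``,
free, a restricted label ``(k, b)`` where ``b`` is a bit-string namespace
confining labels introduced inside module bodies, or the identity ``!e``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union


# ---------------------------------------------------------------------------
# Site types and site expressions


@dataclass(frozen=True)
class SiteType:
    """Finite set of internal-state tokens a site may take.

    ``values`` preserves declaration order (the first value is the default
    used when grounding initial conditions).  The conventional default type
    is ``(u p)``.
    """

    values: tuple[str, ...] = ("u", "p")

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("site type must declare at least one value")


DEFAULT_SITE_TYPE = SiteType()


# Internal-state variants -------------------------------------------------

@dataclass(frozen=True)
class IVal:
    value: str


@dataclass(frozen=True)
class IWild:
    """Wildcard internal state ``?``: matches any value."""


@dataclass(frozen=True)
class IIdent:
    """Identity internal state: in an update, leave the state unchanged."""


Internal = Union[IVal, IWild, IIdent]

I_WILD = IWild()
I_IDENT = IIdent()


# Link variants -----------------------------------------------------------

@dataclass(frozen=True)
class LAny:
    """Free-or-bound wildcard ``?``."""


@dataclass(frozen=True)
class LBound:
    """Bound to something unspecified, ``!_``."""


@dataclass(frozen=True)
class LFree:
    """Unbound."""


@dataclass(frozen=True)
class LLabel:
    """Restricted link label: source label ``k`` in namespace ``ns``.

    ``ns`` is a bit-string (``'0'``/``'1'`` characters); labels written in
    source carry the empty namespace and are sealed into the namespace of
    the enclosing module invocation during elaboration.
    """

    k: int
    ns: str = ""


@dataclass(frozen=True)
class LIdent:
    """Identity link ``!e``: in an update, leave the bond unchanged."""


Link = Union[LAny, LBound, LFree, LLabel, LIdent]

L_ANY = LAny()
L_BOUND = LBound()
L_FREE = LFree()
L_IDENT = LIdent()


@dataclass(frozen=True)
class SiteExpr:
    """A site expression ``(internal, link)``.

    ``internal``/``link`` may be ``None`` straight out of the parser,
    meaning the component was omitted in the source; desugaring resolves
    omissions (omitted internal => identity, omitted link => free).
    """

    internal: Optional[Internal] = None
    link: Optional[Link] = None


# ---------------------------------------------------------------------------
# Agent expressions


@dataclass(frozen=True)
class NewAgent:
    """``new n{sigma}``: a fresh agent, universally unique within the model.

    ``name`` may be ``None`` (omitted in source); desugaring substitutes the
    defining identifier.  ``sig`` maps site names to site types, in
    declaration order.
    """

    name: Optional[str]
    sig: tuple[tuple[str, SiteType], ...]


@dataclass(frozen=True)
class Ident:
    name: str


@dataclass(frozen=True)
class Loc:
    """``c[e]``: agents of ``e`` located in compartment ``c`` (relative to
    the enclosing location)."""

    comp: str
    body: "AgentExpr"


@dataclass(frozen=True)
class Compose:
    """Complex composition ``e - e'``."""

    left: "AgentExpr"
    right: "AgentExpr"


@dataclass(frozen=True)
class Update:
    """``e<path[name{assigns}]>``: the same value as ``e`` except for the
    sites mentioned in ``assigns`` on the targeted agent.

    ``target`` is an agent name or alias; ``None`` marks the atomic-update
    abbreviation ``X{...}`` which applies to the sole agent of an atomic
    base.  ``assigns`` preserves source order.
    """

    base: "AgentExpr"
    path: tuple[str, ...]
    target: Optional[str]
    assigns: tuple[tuple[str, SiteExpr], ...]


@dataclass(frozen=True)
class Choice:
    """Non-deterministic grouping ``e or e'``: rules mentioning the value
    expand to one concrete rule per alternative."""

    left: "AgentExpr"
    right: "AgentExpr"


@dataclass(frozen=True)
class AsBind:
    """Inline definition ``e as id`` inside a rule; hoisted to an agent
    definition by desugaring, scoping over the remainder of the program."""

    body: "AgentExpr"
    ident: str


AgentExpr = Union[NewAgent, Ident, Loc, Compose, Update, Choice, AsBind]


# ---------------------------------------------------------------------------
# Annotations (module agent parameters)


@dataclass(frozen=True)
class AnnotEntry:
    """One located-agent entry of an annotation: ``name{site[:type]...}``.

    ``name`` may be ``None`` (abbreviated ``id:{m}`` form); ``sites`` pairs
    each site name with an optional declared type (``None`` = unconstrained
    for formals, = look up the value's type for actuals).
    """

    name: Optional[str]
    sites: tuple[tuple[str, Optional[SiteType]], ...]


Annotation = tuple[AnnotEntry, ...]


# ---------------------------------------------------------------------------
# Rate expressions


@dataclass(frozen=True)
class RConst:
    value: float


@dataclass(frozen=True)
class RIdent:
    name: str


@dataclass(frozen=True)
class RBin:
    op: str  # one of * / + -
    left: "RateExpr"
    right: "RateExpr"


RateExpr = Union[RConst, RIdent, RBin]

RATE_ONE = RConst(1.0)


# ---------------------------------------------------------------------------
# Definitions


@dataclass(frozen=True)
class AgentDef:
    """``agent id[, id...] = e;`` — several identifiers (aliases) are only
    legal when ``e`` is a ``new`` expression."""

    idents: tuple[str, ...]
    expr: AgentExpr


@dataclass(frozen=True)
class CompDef:
    name: str
    parent: Optional[str] = None


@dataclass(frozen=True)
class RateDef:
    name: str
    expr: RateExpr


@dataclass(frozen=True)
class ModuleDef:
    name: str
    comp_formals: tuple[str, ...]
    agent_formals: tuple[tuple[str, Annotation], ...]
    rate_formals: tuple[str, ...]
    body: "Program"


Definition = Union[AgentDef, CompDef, RateDef, ModuleDef]


# ---------------------------------------------------------------------------
# Programs


@dataclass(frozen=True)
class Rule:
    lhs: tuple[AgentExpr, ...]
    rhs: tuple[AgentExpr, ...]
    fwd: RateExpr = RATE_ONE
    rev: Optional[RateExpr] = None  # present iff written reversible


@dataclass(frozen=True)
class Par:
    left: "Program"
    right: "Program"


@dataclass(frozen=True)
class LocP:
    comp: str
    body: "Program"


@dataclass(frozen=True)
class Scoped:
    defn: Definition
    body: "Program"


@dataclass(frozen=True)
class ActualAgent:
    expr: AgentExpr
    annot: Annotation


@dataclass(frozen=True)
class ActualExpr:
    """A non-annotated actual: a rate expression or a bare identifier whose
    kind (compartment / rate) is resolved against the formals."""

    expr: Union[RateExpr, str]


Actual = Union[ActualAgent, ActualExpr]


@dataclass(frozen=True)
class Invoke:
    module: str
    actuals: tuple[Actual, ...]


@dataclass(frozen=True)
class Init:
    expr: AgentExpr
    count: int


@dataclass(frozen=True)
class Nil:
    pass


NIL = Nil()


@dataclass(frozen=True)
class Script:
    """``script { code };`` — host-language code evaluating to LBS-kappa
    program text with a trailing hole; ``cont`` fills the hole."""

    code: str
    cont: "Program"


@dataclass(frozen=True)
class ScriptDef:
    """``scriptdef { code };`` — host-language definitions accumulated into
    the script environment for subsequent script blocks."""

    code: str
    cont: "Program"


Program = Union[Rule, Par, LocP, Scoped, Invoke, Init, Nil, Script, ScriptDef]


def iter_program(node: Program):
    """Yield every program node in a pre-order walk (into bodies and
    continuations, not into agent expressions)."""
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        if isinstance(n, Par):
            stack += [n.right, n.left]
        elif isinstance(n, (LocP,)):
            stack.append(n.body)
        elif isinstance(n, Scoped):
            if isinstance(n.defn, ModuleDef):
                stack.append(n.defn.body)
            stack.append(n.body)
        elif isinstance(n, (Script, ScriptDef)):
            stack.append(n.cont)
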