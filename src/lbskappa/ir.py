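"""Intermediate representation: the normal forms produced by elaboration.

A *normal-form agent value* is a list of located, fully typed agents; a
*normal-form rule* pairs such values with an evaluated rate constant and a
namespace-derived name.  These are the objects the Kappa backend consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .syntax import SiteExpr, SiteType


@dataclass(frozen=True)
class AgentDecl:
    """One ``new`` agent definition: the source of agent identity."""

    uid: int
    name: str
    sig: tuple[tuple[str, SiteType], ...]
    idents: tuple[str, ...]  # defining identifiers (aliases)


@dataclass(frozen=True)
class AgentInst:
    """One agent occurrence inside a normal-form value."""

    path: tuple[str, ...]
    uid: int
    name: str
    alias: Optional[str]
    sites: tuple[tuple[str, SiteType, SiteExpr], ...]  # declaration order

    def site_expr(self, site: str) -> SiteExpr:
        for s, _, se in self.sites:
            if s == site:
                return se
        raise KeyError(site)


# a normal-form agent value: one connected-complex-shaped agent list
Value = tuple[AgentInst, ...]


@dataclass(frozen=True)
class NormalRule:
    lhs: tuple[Value, ...]
    rhs: tuple[Value, ...]
    rate: float
    name: str  # namespace at production point + per-rule counter


@dataclass
class ElaboratedModel:
    rules: list[NormalRule]
    inits: list[tuple[Value, int]]
    decls: dict[int, AgentDecl]
    comps: dict[str, Optional[str]]  # compartment -> parent
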