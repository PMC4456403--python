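"""Model fixtures and synthetic model generation.

The language's classic worked models are shipped as ``.lbsk`` sources
under ``models/`` and exposed through :func:`fixture`, each with its
expected flat-rule count and, where a flat expansion is known, a
hand-inlined flat golden source for token-level comparison.
:func:`random_model` generates well-formed random models with a
by-construction ground-truth expansion count, for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    source: str
    expected_rule_count: Optional[int] = None
    golden: Optional[str] = None       # flat source whose compilation must match
    allow_scripts: bool = False


def _load(model: str) -> str:
    return (resources.files("lbskappa") / "models" / f"{model}.lbsk").read_text()


_REGISTRY: dict[str, dict] = {
    "intro_phospho": dict(expected_rule_count=3, golden="intro_phospho_flat"),
    "nondet_mek_erk": dict(expected_rule_count=4, golden="nondet_mek_erk_flat"),
    "complex_update": dict(expected_rule_count=2, golden="complex_update_flat"),
    "gene_expression_compartments": dict(expected_rule_count=4),
    "chemotaxis": dict(expected_rule_count=16),
    "mapk": dict(expected_rule_count=30),
    "mapk_single_cycle": dict(expected_rule_count=6),
    "insulin_excerpt": dict(expected_rule_count=6),
    "script_variants": dict(expected_rule_count=100, allow_scripts=True),
    "script_ring": dict(expected_rule_count=0, allow_scripts=True),
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def fixture(name: str) -> FixtureSpec:
    """Load a named fixture (source text plus expectations)."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}")
    info = dict(_REGISTRY[name])
    golden = info.pop("golden", None)
    return FixtureSpec(name=name, source=_load(name),
                       golden=_load(golden) if golden else None, **info)


# ---------------------------------------------------------------------------
# Ring initial condition


def ring_init(n: int, modulus: Optional[int] = None) -> str:
    """A single ``init`` statement for a closed ring of ``n`` protomers,
    each bound x-to-y to its neighbour with link indices taken modulo the
    ring size (so bond count equals agent count)."""
    if n < 3:
        raise ValueError("a ring needs at least 3 protomers")
    m = modulus or n
    protomers = "-".join(
        f"P{{f~0, s, x!{i % m}, y!{(i + 1) % m}}}" for i in range(1, n + 1))
    return f"init {protomers} 1;"


def ring_model(n: int) -> str:
    """A complete compilable model: protomer declaration plus ring init."""
    return ("agent P = new P{f:(0 1), x:(0 1), y:(0 1), s};\n"
            + ring_init(n) + "\n")


# ---------------------------------------------------------------------------
# Random model generation with ground-truth expansion counts


@dataclass(frozen=True)
class RandomModel:
    source: str
    expected_rules: int
    seed: int


def random_model(seed: int, n_agents: int = 6, n_modules: int = 2,
                 max_depth: int = 2) -> RandomModel:
    """Generate a well-formed random model exercising new/update/choice/
    modules/compartments, with the number of flat rules it must expand to
    recorded by construction.

    Every generated rule carries a distinct rate constant so that no two
    concrete rules can collapse under the rule-set union.
    """
    if min(n_agents, n_modules, max_depth) <= 0:
        raise ValueError("generator parameters must be positive")
    rng = np.random.default_rng(seed)
    n_agents = max(n_agents, 4)
    lines: list[str] = ["// randomly generated model", "comp cell;"]
    expected = 0
    rate_counter = [0]

    def fresh_rate() -> str:
        rate_counter[0] += 1
        return f"{rate_counter[0]}.{rng.integers(1, 10)}"

    agents = [f"A{i}" for i in range(n_agents)]
    for a in agents:
        lines.append(f"agent {a} = new {{a, b}};")

    # non-deterministic families: two variants sharing a common agent name
    # (updates through a module formal address the common name)
    n_choices = int(rng.integers(1, max(2, n_agents // 2) + 1))
    choices: list[str] = []
    for j in range(n_choices):
        lines.append(f"agent V{j}a = new V{j}{{a, b}};")
        lines.append(f"agent V{j}b = new V{j}{{a, b}};")
        lines.append(f"agent C{j} = V{j}a or V{j}b;")
        choices.append(f"C{j}")

    # a bind/unbind module, optionally wrapped to max_depth by forwarders
    lines.append(
        "module bind0(agent k:{m}, s:{n}; rate r1; rate r2){\n"
        "  k{m} + s{n} -> {r1} k{m!1}-s{n!1} |\n"
        "  k{m!1}-s{n!1} -> {r2} k{m} + s{n}\n"
        "};")
    depth = int(rng.integers(1, max_depth + 1))
    for d in range(1, depth):
        lines.append(
            f"module bind{d}(agent k:{{m}}, s:{{n}}; rate r1; rate r2){{\n"
            f"  bind{d - 1}(k:{{m}}, s:{{n}}, r1, r2)\n"
            "};")
    top = f"bind{depth - 1}"

    def multiplier(name: str) -> int:
        return 2 if name.startswith("C") else 1

    pool = agents + choices
    n_invocations = max(1, n_modules)
    for _ in range(n_invocations):
        k, s = (pool[i] for i in rng.choice(len(pool), size=2, replace=False))
        call = f"{top}({k}:{{a}}, {s}:{{b}}, {fresh_rate()}, {fresh_rate()})"
        if rng.random() < 0.3:
            call = f"cell[ {call} ]"
        lines.append(call + "|")
        expected += 2 * multiplier(k) * multiplier(s)

    # a top-level choice rule: internal-state flip, alternatives co-vary
    c = choices[int(rng.integers(len(choices)))]
    lines.append(f"{c}{{a~u}} -> {{{fresh_rate()}}} {c}{{a~p}}|")
    expected += 2

    a0 = agents[int(rng.integers(n_agents))]
    lines.append(f"init {a0}{{a~u, b~u}} {int(rng.integers(1, 50))};")
    return RandomModel("\n".join(lines) + "\n", expected, seed)
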