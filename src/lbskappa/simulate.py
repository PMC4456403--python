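"""Desk-scale stochastic simulation of compiled flat Kappa programs.

The simulator embeds the full mixture explicitly — every agent instance
with its internal states and bonds — and draws events with Gillespie's
direct method.  Rule activity is ``rate constant x number of embeddings``,
where an embedding is an injective site-graph morphism from the rule's
left-hand side into the mixture; no automorphism division is applied
(matching KaSim's convention).  This direct enumeration is quadratic-ish
per event and intended for small systems (the mixture is capped at 1e5
agents), not for performance parity with production Kappa simulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kappa import (
    COMP_SITE, KappaAgent, KappaError, KappaProgram, KappaRule,
    _align_by_name, parse_kappa_pattern,
)
from .syntax import IVal, IWild, LAny, LBound, LFree

DEFAULT_MIXTURE_CAP = 100_000


class SimulationError(Exception):
    pass


@dataclass
class MixAgent:
    name: str
    # site -> [internal value, partner (agent id, site) or None]
    sites: dict[str, list]


class Mixture:
    """A multiset of ground agent instances with mutual bond pointers."""

    def __init__(self, signatures: dict, cap: int = DEFAULT_MIXTURE_CAP):
        self.signatures = signatures
        self.cap = cap
        self.agents: dict[int, MixAgent] = {}
        self._next = 0

    def spawn(self, name: str, sites: dict[str, list]) -> int:
        if len(self.agents) >= self.cap:
            raise SimulationError(
                f"mixture exceeds the {self.cap}-agent cap")
        aid = self._next
        self._next += 1
        self.agents[aid] = MixAgent(name, sites)
        return aid

    def spawn_default(self, name: str) -> int:
        if name not in self.signatures:
            raise SimulationError(f"no signature for agent {name!r}")
        sites = {s: [values[0], None] for s, values in self.signatures[name]}
        return self.spawn(name, sites)

    def unbind(self, aid: int, site: str) -> None:
        partner = self.agents[aid].sites[site][1]
        if partner is not None:
            pid, psite = partner
            self.agents[pid].sites[psite][1] = None
            self.agents[aid].sites[site][1] = None

    def bind(self, a: tuple[int, str], b: tuple[int, str]) -> None:
        self.unbind(*a)
        self.unbind(*b)
        self.agents[a[0]].sites[a[1]][1] = b
        self.agents[b[0]].sites[b[1]][1] = a

    def delete(self, aid: int) -> None:
        for site in list(self.agents[aid].sites):
            self.unbind(aid, site)
        del self.agents[aid]

    def check_invariants(self) -> None:
        """Debug check: mutual bond pointers; internal values declared."""
        for aid, agent in self.agents.items():
            sig = dict(self.signatures.get(agent.name, ()))
            for site, (value, partner) in agent.sites.items():
                if site in sig and value not in sig[site]:
                    raise SimulationError(
                        f"agent {agent.name}#{aid} site {site} carries "
                        f"undeclared value {value!r}")
                if partner is not None:
                    pid, psite = partner
                    if pid not in self.agents or \
                            self.agents[pid].sites[psite][1] != (aid, site):
                        raise SimulationError(
                            f"dangling bond at {agent.name}#{aid}.{site}")


def build_mixture(prog: KappaProgram, cap: int = DEFAULT_MIXTURE_CAP) -> Mixture:
    mix = Mixture(prog.signatures, cap)
    for agents, count in prog.inits:
        for _ in range(count):
            ids = []
            bonds: dict[int, list[tuple[int, str]]] = {}
            for a in agents:
                sites = {}
                declared = dict(prog.signatures.get(a.name, ()))
                for s, values in declared.items():
                    sites[s] = [values[0], None]
                for s in a.sites:
                    internal = s.internal.value if isinstance(s.internal, IVal) \
                        else declared.get(s.name, ("?",))[0]
                    sites[s.name] = [internal, None]
                aid = mix.spawn(a.name, sites)
                ids.append(aid)
                for s in a.sites:
                    if isinstance(s.link, int):
                        bonds.setdefault(s.link, []).append((aid, s.name))
            for label, ends in bonds.items():
                if len(ends) != 2:
                    raise SimulationError(
                        f"init bond label {label} has {len(ends)} endpoints")
                mix.bind(ends[0], ends[1])
    return mix


# ---------------------------------------------------------------------------
# Pattern embeddings


def find_embeddings(pattern: Sequence[KappaAgent],
                    mix: Mixture) -> list[tuple[int, ...]]:
    """All injective, constraint-respecting matches of a pattern (a list of
    agents with shared link labels) into the mixture, as tuples of agent
    ids in pattern order."""
    label_ends: dict[int, list[tuple[int, str]]] = {}
    for pidx, agent in enumerate(pattern):
        for s in agent.sites:
            if isinstance(s.link, int):
                label_ends.setdefault(s.link, []).append((pidx, s.name))
    for label, ends in label_ends.items():
        if len(ends) != 2:
            raise SimulationError(
                f"pattern link {label} has {len(ends)} endpoints")

    results: list[tuple[int, ...]] = []
    assign: list[Optional[int]] = [None] * len(pattern)
    used: set[int] = set()

    def site_ok(pidx: int, aid: int) -> bool:
        agent = mix.agents[aid]
        pat = pattern[pidx]
        if agent.name != pat.name:
            return False
        for s in pat.sites:
            if s.name not in agent.sites:
                return False
            value, partner = agent.sites[s.name]
            if isinstance(s.internal, IVal) and value != s.internal.value:
                return False
            link = s.link
            if isinstance(link, LFree):
                if partner is not None:
                    return False
            elif isinstance(link, LBound):
                if partner is None:
                    return False
            elif isinstance(link, int):
                if partner is None:
                    return False
                (p1, s1), (p2, s2) = label_ends[link]
                other_p, other_s = (p2, s2) if (p1, s1) == (pidx, s.name) else (p1, s1)
                if partner[1] != other_s:
                    return False
                if assign[other_p] is not None and partner[0] != assign[other_p]:
                    return False
                if mix.agents[partner[0]].name != pattern[other_p].name:
                    return False
        return True

    def backtrack(pidx: int) -> None:
        if pidx == len(pattern):
            results.append(tuple(assign))  # type: ignore[arg-type]
            return
        for aid in mix.agents:
            if aid in used or not site_ok(pidx, aid):
                continue
            assign[pidx] = aid
            used.add(aid)
            backtrack(pidx + 1)
            used.discard(aid)
            assign[pidx] = None

    backtrack(0)
    return results


def count_embeddings(pattern: Sequence[KappaAgent], mix: Mixture) -> int:
    return len(find_embeddings(pattern, mix))


# ---------------------------------------------------------------------------
# Rule application


def apply_rule(mix: Mixture, rule: KappaRule,
               embedding: tuple[int, ...]) -> None:
    pairs, deleted, created = _align_by_name(rule.lhs, rule.rhs)
    rhs_to_mix: dict[int, int] = {}
    for i, j in pairs:
        rhs_to_mix[j] = embedding[i]
    for i in deleted:
        mix.delete(embedding[i])
    for j in created:
        agent = rule.rhs[j]
        aid = mix.spawn_default(agent.name)
        rhs_to_mix[j] = aid
    # internal states and explicit unbinding
    bonds: dict[int, list[tuple[int, str]]] = {}
    for j, agent in enumerate(rule.rhs):
        aid = rhs_to_mix[j]
        for s in agent.sites:
            if s.name not in mix.agents[aid].sites:
                raise SimulationError(
                    f"agent {agent.name} has no site {s.name!r}")
            if isinstance(s.internal, IVal):
                mix.agents[aid].sites[s.name][0] = s.internal.value
            if isinstance(s.link, LFree):
                mix.unbind(aid, s.name)
            elif isinstance(s.link, int):
                bonds.setdefault(s.link, []).append((aid, s.name))
            # LAny / LBound on the RHS: bond untouched (checked at compile)
    for label, ends in bonds.items():
        if len(ends) != 2:
            raise SimulationError(
                f"rule {rule.label!r} would create a dangling bond {label}")
        mix.bind(ends[0], ends[1])


# ---------------------------------------------------------------------------
# Gillespie's direct method


@dataclass
class Trajectory:
    times: list[float]
    counts: dict[str, list[int]]
    seed: int
    terminated_early: bool = False
    final_time: float = 0.0

    def final_counts(self) -> dict[str, int]:
        return {k: v[-1] for k, v in self.counts.items()}


def ssa(prog: KappaProgram, tmax: float, seed: int,
        observables: Optional[dict[str, Sequence[KappaAgent] | str]] = None,
        max_events: Optional[int] = None,
        cap: int = DEFAULT_MIXTURE_CAP,
        debug_invariants: bool = False) -> Trajectory:
    """Simulate a compiled program to time ``tmax``.

    ``observables`` maps a column name to a pattern (either already parsed
    or a KaSim pattern string); the trajectory records the embedding count
    of each observable after every event.  A fixed seed gives a
    bit-reproducible trajectory.
    """
    obs: dict[str, tuple[KappaAgent, ...]] = {}
    for name, pat in (observables or {}).items():
        obs[name] = parse_kappa_pattern(pat) if isinstance(pat, str) else tuple(pat)
    mix = build_mixture(prog, cap)
    rng = np.random.default_rng(seed)
    t = 0.0
    traj = Trajectory([0.0], {k: [count_embeddings(p, mix)]
                              for k, p in obs.items()}, seed)
    events = 0
    while True:
        if max_events is not None and events >= max_events:
            break
        embeddings = [find_embeddings(r.lhs, mix) for r in prog.rules]
        activities = np.array([r.rate * len(e)
                               for r, e in zip(prog.rules, embeddings)])
        total = float(activities.sum())
        if total <= 0.0:
            traj.terminated_early = True
            break
        t += rng.exponential(1.0 / total)
        if t >= tmax:
            t = tmax
            break
        ridx = int(np.searchsorted(np.cumsum(activities),
                                   rng.random() * total, side="right"))
        emb = embeddings[ridx][int(rng.integers(len(embeddings[ridx])))]
        apply_rule(mix, prog.rules[ridx], emb)
        if debug_invariants:
            mix.check_invariants()
        events += 1
        traj.times.append(t)
        for name, pat in obs.items():
            traj.counts[name].append(count_embeddings(pat, mix))
    traj.final_time = t
    return traj


def trajectory_to_csv(traj: Trajectory, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time"] + list(traj.counts))
        for i, t in enumerate(traj.times):
            writer.writerow([f"{t:.6g}"] +
                            [traj.counts[k][i] for k in traj.counts])
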