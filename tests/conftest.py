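import itertools

import pytest

from lbskappa import compile_text, fixture
from lbskappa.kappa import KappaAgent
from lbskappa.syntax import IVal, LAny, LBound, LFree


@pytest.fixture(scope="session")
def compiled():
    """Compile each bundled fixture once per session."""
    cache = {}

    def get(name: str):
        if name not in cache:
            spec = fixture(name)
            cache[name] = compile_text(spec.source,
                                       allow_scripts=spec.allow_scripts)
        return cache[name]

    return get


def brute_force_embeddings(pattern, mix):
    """Independent oracle: enumerate all injections of pattern agents into
    mixture agents and keep the constraint-respecting ones."""
    label_ends = {}
    for pidx, agent in enumerate(pattern):
        for s in agent.sites:
            if isinstance(s.link, int):
                label_ends.setdefault(s.link, []).append((pidx, s.name))

    def ok(perm):
        for pidx, agent in enumerate(pattern):
            m = mix.agents[perm[pidx]]
            if m.name != agent.name:
                return False
            for s in agent.sites:
                if s.name not in m.sites:
                    return False
                value, partner = m.sites[s.name]
                if isinstance(s.internal, IVal) and value != s.internal.value:
                    return False
                if isinstance(s.link, LFree) and partner is not None:
                    return False
                if isinstance(s.link, LBound) and partner is None:
                    return False
                if isinstance(s.link, int):
                    (p1, s1), (p2, s2) = label_ends[s.link]
                    other = (p2, s2) if (p1, s1) == (pidx, s.name) else (p1, s1)
                    if partner != (perm[other[0]], other[1]):
                        return False
        return True

    ids = list(mix.agents)
    return [perm for perm in itertools.permutations(ids, len(pattern))
            if ok(perm)]
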