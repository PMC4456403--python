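"""Mixture construction, embedding counting, and the SSA loop."""

import math

import numpy as np
import pytest

from conftest import brute_force_embeddings
from lbskappa import (
    build_mixture, compile_text, count_embeddings, find_embeddings, fixture,
    parse_kappa_pattern, ring_init, ssa,
)
from lbskappa.simulate import SimulationError


def mixture_of(src, **kw):
    return build_mixture(compile_text(src, **kw).kappa)


class TestEmbeddings:
    def test_free_monomers(self):
        mix = mixture_of("agent Raf = new {x};\ninit Raf{x~u} 10")
        assert count_embeddings(parse_kappa_pattern("Raf(x)"), mix) == 10

    def test_dimer_pattern_counts_bound_pairs_only(self):
        src = ("agent A = new {s};\nagent B = new {t};\n"
               "init A{s~u!1}-B{t~u!1} 3 | init A{s~u} 2")
        mix = mixture_of(src)
        pat = parse_kappa_pattern("A(s!1),B(t!1)")
        assert count_embeddings(pat, mix) == 3
        assert count_embeddings(parse_kappa_pattern("A(s)"), mix) == 2
        assert count_embeddings(parse_kappa_pattern("A(s!_)"), mix) == 3
        assert count_embeddings(parse_kappa_pattern("A(s?)"), mix) == 5

    def test_state_mismatch_gives_zero(self):
        mix = mixture_of("agent MEK = new {S222};\ninit MEK{S222~p} 6")
        assert count_embeddings(parse_kappa_pattern("MEK(S222~u)"), mix) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_counts_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_mono = int(rng.integers(0, 6))
        n_dimer = int(rng.integers(0, 6))
        n_flip = int(rng.integers(0, 4))
        src = ("agent A = new {s, f};\nagent B = new {t};\n"
               + (f"init A{{s~u, f~u}} {n_mono} | " if n_mono else "")
               + (f"init A{{s~u, f~p!1}}-B{{t~u!1}} {n_dimer} | "
                  if n_dimer else "")
               + (f"init B{{t~p}} {n_flip} | " if n_flip else "")
               + "A -> ")
        mix = mixture_of(src)
        assert len(mix.agents) <= 20
        for pat_txt in ("A(s)", "A(f~p)", "A(s!1),B(t!1)", "B(t?)",
                        "A(f~p!1),B(t!1)", "A(s~u,f~u)", "B(t!_)"):
            pat = parse_kappa_pattern(pat_txt)
            got = sorted(find_embeddings(pat, mix))
            want = sorted(brute_force_embeddings(pat, mix))
            assert got == want, pat_txt


class TestSSA:
    def test_empty_rule_set_yields_flat_trajectory(self):
        prog = compile_text("agent A = new {x};\ninit A{x~u} 7").kappa
        traj = ssa(prog, tmax=1.0, seed=1, observables={"A": "A()"})
        assert traj.terminated_early
        assert traj.counts["A"] == [7]

    def test_seeded_runs_are_identical(self):
        src = "agent A = new {};\nA -> {1.0} | init A 30"
        prog = compile_text(src).kappa
        t1 = ssa(prog, tmax=3.0, seed=11, observables={"A": "A()"})
        t2 = ssa(prog, tmax=3.0, seed=11, observables={"A": "A()"})
        assert t1.times == t2.times and t1.counts == t2.counts

    def test_death_process_matches_closed_form(self):
        # A -> 0 at rate k: E[N(t)] = n0 * exp(-k t)
        n0, k, t_obs, reps = 40, 1.0, 0.5, 120
        prog = compile_text(
            f"agent A = new {{}};\nA -> {{{k}}} | init A {n0}").kappa
        finals = []
        for rep in range(reps):
            traj = ssa(prog, tmax=t_obs, seed=1000 + rep,
                       observables={"A": "A()"})
            finals.append(traj.counts["A"][-1])
        mean = float(np.mean(finals))
        expected = n0 * math.exp(-k * t_obs)
        se = max(float(np.std(finals)) / math.sqrt(reps), 1e-9)
        assert abs(mean - expected) <= 3 * se

    def test_phosphorylation_is_monotone_without_phosphatase(self):
        src = (fixture("intro_phospho").source
               + "| init Raf{x, y~u} 30 | init MEK{t~u, S218~u, S222~u} 30")
        prog = compile_text(src).kappa
        traj = ssa(prog, tmax=4.0, seed=5,
                   observables={"pMEK": "MEK(S222~p)"})
        counts = traj.counts["pMEK"]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > 0

    def test_mass_conservation_in_conformational_spread(self):
        # chemotaxis rules neither create nor delete protomers
        ring = ("| init "
                + "-".join(f"P1{{f~0, s, x!{i % 6}, y!{(i + 1) % 6}}}"
                           for i in range(1, 7)) + " 1")
        src = fixture("chemotaxis").source + ring
        prog = compile_text(src).kappa
        mix = build_mixture(prog)
        n0 = len(mix.agents)
        traj = ssa(prog, tmax=0.05, seed=3, observables={"P": "P()"},
                   max_events=40, debug_invariants=True)
        assert len(traj.times) > 1  # events actually happened
        assert all(c == n0 for c in traj.counts["P"])

    def test_creation_and_transport_in_compartment_model(self):
        src = (fixture("gene_expression_compartments").source
               + "| cell[ nucleus[ init gene{} 1 | init rnap{} 1 ] ]")
        prog = compile_text(src).kappa
        traj = ssa(prog, tmax=20.0, seed=3, max_events=60,
                   observables={"mRNA_nuc": "mRNA(comp~cell.nucleus)",
                                "MEK_cell": "MEK(comp~cell)"},
                   debug_invariants=True)
        assert max(traj.counts["mRNA_nuc"]) >= 1

    def test_mixture_cap_enforced(self):
        prog = compile_text("agent A = new {};\ninit A 50").kappa
        with pytest.raises(SimulationError, match="cap"):
            ssa(prog, tmax=1.0, seed=0, cap=10)
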