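# lbskappa

A compiler from **LBS-κ** — a high-level, modular rule-based modelling
language for molecular biology — down to flat **Kappa** (KaSim v3 dialect),
together with a desk-scale stochastic simulator for the compiled models.

## The problem

Rule-based languages such as Kappa describe biochemistry as rewrite rules
over *site graphs*: an agent (typically a protein) has named sites, each
carrying an internal state (e.g. `u`/`p` for a phosphorylation state) and at
most one bond. A rule such as

```
Raf(x~p), MEK(S222~u) -> Raf(x~p!1), MEK(S222~u!1)
```

binds phosphorylated Raf to unphosphorylated MEK *in any molecular context*,
which is what lets rule-based models sidestep the combinatorial explosion of
species in signalling pathways. Flat Kappa, however, offers no structure for
organising the rules of a large model. LBS-κ layers on top of it:

- **complex abbreviation and update** — name a complex once
  (`agent c1 = EGFR{CR!_, Y1148~p!1}-Shc{PTB!1, Y318~u};`) and write the
  product of a rule as a *delta* (`c1 -> c1<Shc{Y318~p}>`);
- **parameterised modules with subtyping** — a phosphorylation module takes
  any kinase/substrate pair that has *at least* the required sites with
  matching types, so one module body serves a whole cascade;
- **agent aliases** — address one protomer inside a homo-multimer
  (`agent P1, P2, P3 = new P{...};` then update only `P2`);
- **non-determinism** — `agent M = MEK1 or MEK2;` makes rules expand to the
  Cartesian product over family variants;
- **a compartment tree** with cross-compartment transport rules
  (`nucleus[mRNA] -> mRNA` inside `cell[...]`), encoded in flat Kappa as an
  extra `comp` site;
- **embedded scripts** — host-language (Python) blocks that generate program
  text, e.g. a 34-protomer ring initial condition.

The compiler elaborates all of this to a set of flat, well-typed Kappa rules
plus initial conditions, and writes a `.ka` file. Link labels written inside
module bodies are *sealed* into per-invocation namespaces (bit-strings), so
a label `1` in a module body can never capture a label `1` from an actual
parameter; at emission every rule's labels are re-encoded injectively as
consecutive integers.

The bundled simulator embeds the mixture explicitly and runs Gillespie's
direct method with rule activity = rate constant × number of embeddings
(injective site-graph matches; KaSim's convention, no automorphism division).

## Worked example

The classic three-rule phosphorylation motif, written once as a module and
instantiated for Raf/MEK:

```
module phosphorylate(agent k:{m}, s:{n}){
  k{m} + s{n~u} -> k{m!1}-s{n~u!1} |
  k{m!1}-s{n~u!1} -> k{m!1}-s{n~p!1} |
  k{m!1}-s{n!1} -> k{m} + s{n}
};
agent Raf = new {x, y};
agent MEK = new {t, S218, S222};
phosphorylate(Raf:{x}, MEK:{S222})
```

Compiling it (`lbsk compile --fixture intro_phospho`) prints:

```
# flat Kappa model generated by lbskappa (KaSim v3 dialect)
%agent: MEK(S218~u~p,S222~u~p,t~u~p,comp~top)
%agent: Raf(x~u~p,y~u~p,comp~top)
'1.1' Raf(x,comp~top),MEK(S222~u,comp~top) -> Raf(x!1,comp~top),MEK(S222~u!1,comp~top) @ 1
'1.2' Raf(x!1,comp~top),MEK(S222~u!1,comp~top) -> Raf(x!1,comp~top),MEK(S222~p!1,comp~top) @ 1
'1.3' Raf(x!1,comp~top),MEK(S222!1,comp~top) -> Raf(x,comp~top),MEK(S222,comp~top) @ 1
compiled 3 rule(s), 0 initial condition(s)
```

The formal site `m` became `x`, `n` became `S222` (the unbinding rule
mentions S222 without a state, so it applies whether phosphorylated or
not), the module's
bond label was sealed into the invocation's namespace, and every agent
carries the compartment-encoding site `comp` (`top` = no compartment).

From Python:

```python
from lbskappa import compile_text, fixture, ssa

src = fixture("intro_phospho").source + \
    "| init Raf{x, y~u} 30 | init MEK{t~u, S218~u, S222~u} 30"
prog = compile_text(src).kappa
traj = ssa(prog, tmax=4.0, seed=5, observables={"pMEK": "MEK(S222~p)"})
print(traj.final_counts())    # {'pMEK': 28} — monotone without a phosphatase
```

Larger worked models ship as fixtures (`lbsk compile --fixture NAME`):
a MAPK cascade whose 6-rule `cycle` module instantiated five times expands
to 30 flat rules, a chemotactic switch ring whose nested `flips`/`flip`
modules expand to 8 reversible (16 directed) rules, an insulin-signalling
excerpt, and two script-generated models (`--allow-scripts`).

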