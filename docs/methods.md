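# Methods

This note documents the semantics the compiler implements, the numerical
and design choices made where the design was genuinely open, what the
bundled models and the random-model generator do and do not exercise, and
the known limitations.

## The language and its elaboration

An LBS-κ program elaborates, by a structural traversal threading an
environment, into *normal-form rules* — located, fully typed agent lists
with evaluated rate constants — plus initial populations. The environment
binds agent identifiers to values, compartments to their parents, rates to
reals, and modules to closures over their definition environment (lexical
scoping).

**Site expressions** are pairs (internal state, link). The internal state
is a value, a wildcard `?`, or the identity; the link is free-or-bound `?`,
bound-to-something `!_`, free, a restricted label `(k, b)` with a bit-string
namespace `b`, or the identity `!e`. A site type is the finite set of
internal values the site admits; the default is `{u, p}`. An unmentioned
site of a `new` agent carries the default expression `(?, ?)` — no
constraint at all.

**Update omission rule.** All site literals that survive desugaring sit
inside updates (the atomic abbreviation `Raf{x~p}` is an update of the
defining value). In an update assignment, an *omitted internal state means
identity* (leave the state unchanged) and an *omitted link means free*;
link identity must be written explicitly as `!e`. This asymmetry is forced
jointly by two usages that any consistent rule must reproduce: passing a
state-constrained kinase (`Raf{n~p}`) into a module must preserve the `~p`
through the body's `k{m}` updates (so internal omission cannot overwrite
with a wildcard), while the module's binding rule `k{m} + s{n~u} -> ...`
must require the sites free on the left (so link omission cannot mean
identity — the defaults are free-or-bound and would make the product
ill-formed). The explicit `!e` is exactly what catalytic rules use to
change a state while keeping the enzyme–substrate bond.

**Modules and subtyping.** A formal agent parameter carries an annotation —
a complex-shaped pattern of agent names and site names, optionally with
site types. At invocation the actual's annotation is resolved through the
enclosing substitution, each named agent must exist in the actual value
(alias first, then agent name, unambiguously), each named site must exist
on it, and a site type the formal declares *explicitly* must equal the
actual's declared type. An unstated formal site type is unconstrained: the
typing relation still rejects any body literal that uses an internal value
the actual's type does not declare, which is where real violations surface.
The formal→actual mapping is a simultaneous renaming of (agent name, site
name) pairs applied to update targets, update assignments and nested
annotations throughout the body.

**Namespaces and sealing.** Link labels written in source carry the empty
namespace. When a literal is evaluated, its labels are sealed into the
current namespace; the i-th module invocation (a global counter) elaborates
its body under the parent namespace extended with the binary digits of i.
Labels from actual-parameter expressions are evaluated in the caller's
namespace, so body labels can never capture them, and sibling invocations
can never alias. At translation each rule's distinct (label, namespace)
pairs map to consecutive positive integers in first-occurrence order —
injective per rule, which suffices because Kappa labels are rule-scoped.

**Choice.** Every `or` creates a choice point; an identifier bound to a
choice carries the set of alternatives tagged with (choice-point, branch).
A rule expands to the Cartesian product of its expressions' alternatives,
keeping only branch-consistent combinations, so two references to the same
identifier in one rule select the same variant (a rule over `M = MEK1 or
MEK2` and `E = ERK1 or ERK2` yields 4 rules, not 16). Values are
deduplicated per choice, making `a or a` a single alternative.

**Compartments** form a tree declared with `comp c;` / `comp c inside p;`
(use of an undeclared compartment is an error). A located program prefixes
the compartment onto the path of every agent beneath it; a located agent
literal resolves relative to the enclosing location. In flat Kappa each
agent gets a final `comp` site whose internal state is the dot-joined path
(`top` for the empty path), so agents in different compartments cannot be
confused by the simulator. Transport rules need not balance agent counts
per compartment.

**`as` bindings** may appear on either side of a rule (products included —
the cascade models bind a product complex and reuse it in the next rule);
they hoist to agent definitions scoping over the rule and the rest of the
program.

## Translation to flat Kappa

Sites linearise in lexicographic name order, types are dropped, the `comp`
site is appended last. Pattern sites carrying no constraint (wildcard
internal, free-or-bound link) are suppressed — mentioning them is
semantically identical to omitting them in Kappa, and suppression makes the
emitted rules match hand-written flat models token for token. A rule is
rejected unless each link label occurs exactly twice per side and site
names are unique per agent. A free-or-bound link on a product site is
accepted only when the corresponding reactant agent carries the identical
site (a pure spectator constraint, which the cascade's fifth layer uses);
otherwise it would be a silent side effect and is a compile error.

**Printable names.** A `new` agent's emitted name is its declared name when
globally unique; when several `new` definitions share a name (the
MEK1/MEK2 family pattern), each uses its defining identifier, with a
numeric suffix as a last resort. Alias lists (`P1, P2, P3 = new P{...}`)
are one definition, so the protomers all print as `P`.

**Initial conditions** must be ground. Following the KaSim convention, a
wildcard internal state is grounded to the *first declared value* of the
site's type and a free-or-bound link to free before the groundness check;
bound-to-something cannot be grounded and is an error. Without this
defaulting, idiomatic inits that mention a site only to bind it (the ring
generator's `x!i`) would be rejected.

**Rule-set semantics.** The compiled program is a set of rules: composition
unions on the canonical (lhs, rhs, rate) form with per-rule link
renumbering, rule labels excluded. Reversible-pair counting matches
directed rules whose canonicalised sides mirror, ignoring rates (forward
and reverse rates differ).

## Embedded scripts

Script blocks hold Python code evaluated in a restricted namespace (a
curated set of pure builtins; imports are rejected; no filesystem or
network). The block's value — the value of its final expression — must be a
string: an LBS-κ fragment with an implicit hole at the end. The fragment is
parsed and desugared, the block's continuation is spliced into the hole,
and elaboration recurses. `scriptdef` bodies are definition-only; they
concatenate in program order into a script environment prepended to every
subsequent evaluation (later definitions shadow earlier ones). Script
execution is off by default (`--allow-scripts`).

## The simulator

The mixture is an explicit multiset of ground agent instances with mutual
bond pointers, built from the compiled inits and capped at 1e5 agents.
Rule activity is rate constant × embedding count, where embeddings are
injective site-graph morphisms of the whole left-hand side (a pattern of n
agents with shared labels), found by backtracking; no automorphism division
is applied, matching KaSim (so a homodimerisation rule's activity counts
ordered pairs). Events follow Gillespie's direct method with numpy's PCG64
generator; a fixed seed reproduces trajectories bit for bit.

Rule application aligns reactant and product agents greedily by name in
order; unmatched reactants are deleted (bonds broken as a side effect),
unmatched products created with signature-default states. This alignment is
exact for rules produced by this compiler's update semantics (products are
deltas of reactants) and for pure creation/degradation; rules that both
delete and create *same-named* agents could misalign, a known limitation
irrelevant to the bundled models. Product sites left unmentioned (or
suppressed) are untouched; a product link label rebinds its two endpoints,
breaking any previous bonds; free unbinds. An optional debug mode rechecks
pointer mutuality and declared internal values after every event.

Observables are flat Kappa patterns; their embedding counts are recorded
after every event.

## Synthetic models and what the tests show

The bundled fixtures are the language's classic worked models: the
phosphorylation module, the MEK/ERK family rule, the protomer-triple
update, the compartmentalised gene-expression example, the chemotaxis
switch ring, the MAPK cascade (full and single-cycle), an
insulin-signalling excerpt (whose `bpu3`/`pho`/`unbind` module bodies are
minimal synthetic reconstructions inferred from how they are used), and
the two script-generated models.
Golden tests compare the compiled modular models against compilations of
the hand-inlined flat texts, canonicalised (rule order and label numbering
abstracted); this checks module elaboration against an independent route
through the pipeline that uses no module machinery.

`random_model(seed, ...)` generates models exercising new/choice/modules/
compartments with a by-construction expected flat-rule count: bind/unbind
module invocations over distinct agent pairs (2 rules each, ×2 per choice-
valued parameter), choice families as two `new` variants sharing an agent
name, and a covarying state-flip rule. Every generated rule carries a
distinct rate so the rule-set union cannot collapse counts. These models
are structurally realistic but small (defaults: ≥4 agents, ≤2-deep module
nesting) and do not exercise scripts or `as` bindings.

Statistical checks use deliberately small problem sizes chosen for a
desk-scale suite: the death-process calibration runs 40 agents at unit
rate to t = 0.5 over 200 replicates (120 in the unit test), asserting the
replicate mean of the closed form n₀e^(−kt) within three standard errors;
embedding counts are verified against a brute-force all-injections oracle
on mixtures of at most 20 agents; the parse↔print round-trip runs over 100
generated models. Passing these shows the machinery is exact on models of
this scale; it says nothing about performance on genome-scale rule sets.

## Known limitations

- No static detection of link-label misuse before rule production; dangling
  labels surface as backend errors with the offending rule named.
- The simulator recomputes all embeddings per event (no incremental update
  or just-in-time reaction generation); it is a correctness oracle, not a
  production simulator.
- No BNGL output, no SBML import/export, no KaSim process invocation, no
  perturbation (`%mod:`) directives.
- Script blocks assume balanced braces outside string literals; a brace
  imbalance inside an f-string expression would confuse block capture.
- `init` of a non-deterministic (choice-valued) expression is rejected
  rather than expanded; the intended population of each variant is
  ambiguous.
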