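"""Backend semantic operations, translation and writer."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from lbskappa import compile_text, compose, fixture, read_kasim, write_kasim
from lbskappa.kappa import (
    KappaError, KappaProgram, LinkEncoder, canon_rule, default_site,
    kap, kap_sites, seal_site, typecheck_site, update_site,
)
from lbskappa.ir import AgentInst
from lbskappa.syntax import (
    IVal, I_IDENT, I_WILD, L_ANY, L_BOUND, L_FREE, L_IDENT, LLabel,
    SiteExpr, SiteType,
)

INTERNALS = [IVal("u"), IVal("p"), I_WILD, I_IDENT]
LINKS = [L_ANY, L_BOUND, L_FREE, L_IDENT, LLabel(1), LLabel(2, "0")]
SITE_EXPRS = [SiteExpr(i, l) for i in INTERNALS for l in LINKS]

site_exprs = st.sampled_from(SITE_EXPRS)


class TestSiteOps:
    @pytest.mark.parametrize("stype", [SiteType(), SiteType(("0", "1"))])
    def test_default_is_double_wildcard_independent_of_values(self, stype):
        se = default_site(stype)
        assert se == SiteExpr(I_WILD, L_ANY)
        assert typecheck_site(se, stype)

    @pytest.mark.parametrize("old, new, expected", [
        (SiteExpr(IVal("u"), L_FREE), SiteExpr(IVal("p"), L_IDENT),
         SiteExpr(IVal("p"), L_FREE)),
        (SiteExpr(IVal("p"), LLabel(1, "0")), SiteExpr(IVal("u"), L_IDENT),
         SiteExpr(IVal("u"), LLabel(1, "0"))),
        (SiteExpr(IVal("x"), LLabel(2)), SiteExpr(I_IDENT, L_IDENT),
         SiteExpr(IVal("x"), LLabel(2))),
    ])
    def test_update_componentwise(self, old, new, expected):
        assert update_site(old, new) == expected

    @given(x=site_exprs, y=site_exprs)
    @settings(max_examples=200, derandomize=True)
    def test_update_right_absorbing_and_identity_neutral(self, x, y):
        assert update_site(update_site(x, y), y) == update_site(x, y)
        assert update_site(x, SiteExpr(I_IDENT, L_IDENT)) == x

    @pytest.mark.parametrize("se, values, ok", [
        (SiteExpr(IVal("gdp"), L_FREE), ("gtp", "gdp"), True),
        (SiteExpr(I_WILD, L_FREE), ("0", "1"), True),
        (SiteExpr(IVal("p"), L_FREE), ("0", "1"), False),
    ])
    def test_typing_relation(self, se, values, ok):
        assert typecheck_site(se, SiteType(values)) is ok

    def test_seal_prepends_namespace_to_labels_only(self):
        assert seal_site(SiteExpr(IVal("u"), LLabel(1, "")), "0") == \
            SiteExpr(IVal("u"), LLabel(1, "0"))
        assert seal_site(SiteExpr(IVal("u"), L_FREE), "101") == \
            SiteExpr(IVal("u"), L_FREE)
        twice = seal_site(seal_site(SiteExpr(I_WILD, LLabel(1)), "1"), "0")
        assert twice.link == LLabel(1, "01")

    @given(se=site_exprs, ns=st.text(alphabet="01", max_size=4))
    @settings(max_examples=200, derandomize=True)
    def test_seal_preserves_internal_and_non_label_links(self, se, ns):
        sealed = seal_site(se, ns)
        assert sealed.internal == se.internal
        if not isinstance(se.link, LLabel):
            assert sealed.link == se.link


class TestLinkEncoding:
    def test_encoding_injective_over_small_universe(self):
        labels = [LLabel(k, b) for k in (1, 2, 3)
                  for b in ("", "0", "1", "00", "01", "10", "11")]
        enc = LinkEncoder()
        codes = [enc.enc(l) for l in labels]
        assert len(set(codes)) == len(labels)
        assert codes == list(range(1, len(labels) + 1))  # first-occurrence order

    def test_same_source_label_in_distinct_namespaces_separates(self):
        enc = LinkEncoder()
        assert enc.enc(LLabel(1, "")) != enc.enc(LLabel(1, "0"))
        assert enc.enc(LLabel(1, "")) == 1  # stable on re-query


class TestLinearisation:
    def _inst(self, names):
        sites = tuple((n, SiteType(), SiteExpr(I_WILD, L_FREE)) for n in names)
        return AgentInst((), 1, "A", None, sites)

    def test_site_order_matches_sorting_oracle(self):
        import random
        rng = random.Random(0)
        for _ in range(25):
            names = rng.sample(
                ["S222", "S218", "t", "a", "B", "zz", "x1", "x10"],
                k=rng.randint(1, 8))
            out = kap_sites(self._inst(names).sites, LinkEncoder(),
                            suppress_trivial=False)
            assert [s.name for s in out] == sorted(names)

    def test_empty_assignment(self):
        assert kap_sites((), LinkEncoder()) == ()

    def test_identity_leak_is_an_error(self):
        sites = (("x", SiteType(), SiteExpr(I_IDENT, L_FREE)),)
        with pytest.raises(KappaError, match="identity"):
            kap_sites(sites, LinkEncoder())

    def test_comp_site_appended_last_with_path_token(self):
        inst = AgentInst(("cell", "nucleus"), 1, "mRNA", None, ())
        (agent,) = kap((inst,), {}, LinkEncoder())
        assert agent.sites[-1].name == "comp"
        assert agent.sites[-1].internal == IVal("cell.nucleus")

    def test_empty_path_encodes_top(self):
        inst = AgentInst((), 1, "A", None, ())
        (agent,) = kap((inst,), {}, LinkEncoder())
        assert agent.sites[-1].internal == IVal("top")


class TestTranslation:
    def test_dangling_link_label_rejected(self):
        src = "agent A = new {x};\nA{x!1} -> A{x}"
        with pytest.raises(KappaError, match="link label"):
            compile_text(src)

    def test_degradation_rule_has_empty_product(self):
        prog = compile_text("agent S = new {};\nS -> ").kappa
        (rule,) = prog.rules
        assert rule.rhs == () and len(rule.lhs) == 1

    def test_init_wildcard_grounded_to_first_declared_value(self):
        prog = compile_text(
            "agent P = new {f:(0 1), s};\ninit P{f~1} 5").kappa
        ((agents, n),) = [prog.inits[0]]
        sites = {s.name: s for s in agents[0].sites}
        assert sites["f"].internal == IVal("1")
        assert sites["s"].internal == IVal("u")  # grounded default
        assert n == 5

    def test_init_bound_to_something_rejected(self):
        with pytest.raises(KappaError, match="ground"):
            compile_text("agent P = new {s};\ninit P{s!_} 1")

    def test_zero_init_count_rejected(self):
        from lbskappa import ParseError
        with pytest.raises(ParseError):
            compile_text("agent P = new {s};\ninit P{s~u} 0")

    def test_mek_erk_printable_names_use_defining_identifiers(self):
        prog = compile_text(fixture("nondet_mek_erk").source).kappa
        names = {a.name for r in prog.rules for a in r.lhs + r.rhs}
        assert names == {"MEK1", "MEK2", "ERK1", "ERK2"}

    def test_chemotaxis_protomers_share_printable_name(self):
        prog = compile_text(fixture("complex_update").source).kappa
        names = {a.name for r in prog.rules for a in r.lhs + r.rhs}
        assert names == {"P"}

    def test_rhs_free_or_bound_without_lhs_counterpart_rejected(self):
        src = "agent A = new {x};\nA{x~u} -> A{x~p!?}"
        with pytest.raises(KappaError, match="side effect"):
            compile_text(src)

    def test_rhs_free_or_bound_unchanged_from_lhs_accepted(self):
        # a state-constrained spectator site stays free-or-bound on both
        # sides (MAPK fifth-layer style)
        src = "agent A = new {x, y};\nA{x~u, y~p!?} -> A{x~p, y~p!?}"
        (rule,) = compile_text(src).kappa.rules
        assert rule is not None


class TestCompose:
    def test_nil_is_identity(self):
        k = compile_text("agent A = new {x};\nA -> A{x~p}").kappa
        zero = KappaProgram()
        assert [canon_rule(r) for r in compose(k, zero).rules] == \
            [canon_rule(r) for r in k.rules]

    def test_self_composition_keeps_rules_doubles_inits(self):
        k = compile_text(
            "agent A = new {x};\nA -> A{x~p} | init A{x~u} 3").kappa
        both = compose(k, k)
        assert len(both.rules) == len(k.rules)
        assert len(both.inits) == 2 * len(k.inits)


class TestWriter:
    def test_phospho_writer_line_counts(self):
        text = write_kasim(compile_text(fixture("intro_phospho").source).kappa)
        lines = text.splitlines()
        assert sum(1 for l in lines if l.startswith("'")) == 3
        assert sum(1 for l in lines if l.startswith("%agent:")) == 2

    def test_empty_program_is_header_only(self):
        text = write_kasim(compile_text("").kappa)
        assert all(l.startswith("#") for l in text.splitlines() if l)

    def test_mek_erk_writer_names(self):
        text = write_kasim(compile_text(fixture("nondet_mek_erk").source).kappa)
        rules = [l for l in text.splitlines() if l.startswith("'")]
        assert len(rules) == 4
        assert any("MEK1(" in l and "ERK2(" in l for l in rules)

    def test_write_read_round_trip(self):
        src = fixture("mapk").source
        prog = compile_text(src).kappa
        back = read_kasim(write_kasim(prog))
        assert sorted(canon_rule(r) for r in back.rules) == \
            sorted(canon_rule(r) for r in prog.rules)

    def test_deterministic_output(self):
        a = write_kasim(compile_text(fixture("chemotaxis").source).kappa)
        b = write_kasim(compile_text(fixture("chemotaxis").source).kappa)
        assert a == b


def independent_well_typed(prog: KappaProgram) -> None:
    """Straight re-statement of the well-typedness conditions, independent
    of the backend's checker."""
    for rule in prog.rules:
        for side in (rule.lhs, rule.rhs):
            labels = [s.link for a in side for s in a.sites
                      if isinstance(s.link, int)]
            assert all(labels.count(k) == 2 for k in set(labels))
            for a in side:
                names = [s.name for s in a.sites]
                assert len(names) == len(set(names))
    for agents, count in prog.inits:
        assert count > 0
        for a in agents:
            for s in a.sites:
                assert isinstance(s.internal, IVal)  # ground: no wildcards
                assert isinstance(s.link, int) or s.link == L_FREE


def test_every_fixture_passes_independent_well_typedness():
    from lbskappa import fixture_names
    for name in fixture_names():
        spec = fixture(name)
        prog = compile_text(spec.source,
                            allow_scripts=spec.allow_scripts).kappa
        independent_well_typed(prog)
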