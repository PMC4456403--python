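"""Elaboration: modules, subtyping, updates, choice, compartments, rates."""

import pytest

from lbskappa import ElabError, canonicalise, compile_text, fixture
from lbskappa.desugar import desugar
from lbskappa.elaborate import elaborate
from lbskappa.parser import parse_program
from lbskappa.syntax import IVal, LLabel


def compiled(src, **kw):
    return compile_text(src, **kw)


def elaborated(src, **kw):
    return elaborate(desugar(parse_program(src)), **kw)


class TestBasics:
    def test_nil_program_is_empty(self):
        model = elaborated("")
        assert model.rules == [] and model.inits == []

    def test_parallel_composition_is_associative_with_nil_identity(self):
        a = "agent A = new {x};"
        left = compiled(f"{a} A -> | nil | A{{x~p}} -> ").kappa
        right = compiled(f"{a} nil | A -> | A{{x~p}} -> ").kappa
        # set-of-rules semantics: grouping and nil do not matter
        assert canonicalise(left) == canonicalise(right)

    def test_repeated_new_definitions_are_distinct_agents(self):
        src = ("agent c = new Shc{PTB, Y318};\n"
               "agent d = new Shc{PTB, Y318};\n"
               "c + d -> c<Shc{Y318~p}>-d")
        model = elaborated(src)
        (rule,) = model.rules
        uids = {inst.uid for v in rule.lhs for inst in v}
        assert len(uids) == 2

    def test_undefined_identifier_fails(self):
        with pytest.raises(ElabError, match="undefined agent identifier"):
            elaborated("A -> B")

    def test_internal_value_outside_declared_type_fails(self):
        with pytest.raises(ElabError, match="not declared"):
            elaborated("agent R = new {n:(gtp gdp)};\nR{n~p} -> R{n~gtp}")


class TestUpdates:
    def test_update_selects_aliased_protomer_only(self):
        model = elaborated(fixture("complex_update").source)
        fwd = model.rules[0]
        (lhs_value,), (rhs_value,) = fwd.lhs, fwd.rhs
        f_before = [dict((s, se) for s, _t, se in inst.sites)["f"].internal
                    for inst in lhs_value]
        f_after = [dict((s, se) for s, _t, se in inst.sites)["f"].internal
                   for inst in rhs_value]
        assert f_before == [IVal("0"), IVal("0"), IVal("0")]
        assert f_after == [IVal("0"), IVal("1"), IVal("0")]

    def test_empty_update_is_identity(self):
        src = "agent A = new {x};\nagent b = A{x~p};\nb -> b<A{}>"
        model = elaborated(src)
        (rule,) = model.rules
        assert rule.lhs == rule.rhs

    def test_complex_extension_with_new_bond(self):
        # c2<SoS{b!4}> composed with Ras{S1S2~gdp!4}: the bond reaches
        # across the composition
        src = ("agent EGFR = new {Y1148};\nagent Shc = new {PTB, Y318};\n"
               "agent Grb2 = new {SH2, SH3};\nagent SoS = new {a, b};\n"
               "agent Ras = new {S1S2:(gdp gtp)};\n"
               "agent c2 = EGFR{Y1148~p!1}-Shc{PTB!1, Y318~p!2}-"
               "Grb2{SH2!2, SH3!3}-SoS{a!3, b};\n"
               "c2 + Ras{S1S2~gdp} -> c2<SoS{b!4}>-Ras{S1S2~gdp!4}")
        model = elaborated(src)
        (rule,) = model.rules
        (rhs_value,) = rule.rhs
        sos = next(i for i in rhs_value if i.name == "SoS")
        ras = next(i for i in rhs_value if i.name == "Ras")
        assert isinstance(sos.site_expr("b").link, LLabel)
        assert sos.site_expr("b").link.k == 4
        assert ras.site_expr("S1S2").link.k == 4
        assert ras.site_expr("S1S2").internal == IVal("gdp")

    def test_ambiguous_update_without_alias_fails(self):
        src = ("agent P = new P{f:(0 1)};\n"
               "agent c = P{f~0}-P{f~0};\nc -> c<P{f~1}>")
        with pytest.raises(ElabError, match="ambiguous"):
            elaborated(src)


class TestChoice:
    def test_family_binding_expands_to_four_rules(self):
        model = elaborated(fixture("nondet_mek_erk").source)
        assert len(model.rules) == 4

    def test_choice_of_identical_branches_is_one_value(self):
        src = "agent A = new {x};\nagent C = A or A;\nC{x~u} -> C{x~p}"
        model = elaborated(src)
        assert len(model.rules) == 1

    def test_three_binary_choices_give_eight_rules(self):
        src = ("agent A1 = new A{x};\nagent A2 = new A{x};\n"
               "agent B1 = new B{x};\nagent B2 = new B{x};\n"
               "agent D1 = new D{x};\nagent D2 = new D{x};\n"
               "agent CA = A1 or A2;\nagent CB = B1 or B2;\n"
               "agent CD = D1 or D2;\n"
               "CA{x} + CB{x} + CD{x} -> CA{x~p} + CB{x~p} + CD{x~p}")
        model = elaborated(src)
        assert len(model.rules) == 8

    def test_same_choice_covaries_across_rule_sides(self):
        # M on both sides selects the same variant: 2 rules, not 4
        src = ("agent A1 = new A{x};\nagent A2 = new A{x};\n"
               "agent M = A1 or A2;\nM{x~u} -> M{x~p}")
        assert len(elaborated(src).rules) == 2


class TestModules:
    def test_phospho_invocation_equals_hand_inlined_body(self):
        mod = compiled(fixture("intro_phospho").source).kappa
        flat = compiled(fixture("intro_phospho").golden).kappa
        assert canonicalise(mod) == canonicalise(flat)

    def test_module_with_nil_body(self):
        src = ("module noop(agent k:{m}){ nil };\n"
               "agent A = new {x};\nnoop(A:{x})")
        model = elaborated(src)
        assert model.rules == [] and model.inits == []

    def test_arity_mismatch_fails(self):
        src = ("module m(agent k:{m}, s:{n}){ nil };\n"
               "agent A = new {x};\nm(A:{x})")
        with pytest.raises(ElabError, match="expects 2"):
            elaborated(src)

    def test_annotation_missing_site_fails(self):
        src = ("module m(agent k:{m}){ nil };\n"
               "agent A = new {x};\nm(A:{y})")
        with pytest.raises(ElabError, match="absent"):
            elaborated(src)

    def test_explicit_formal_site_type_must_match(self):
        src = ("module m(agent k:k{m:(0 1)}){ nil };\n"
               "agent A = new {x};\nm(A:{x})")
        with pytest.raises(ElabError, match="type mismatch"):
            elaborated(src)

    def test_subtype_check_passes_for_ras(self):
        # extra sites on the actual and an unstated formal site type are
        # fine: subtyping requires only the named sites to exist
        src = ("module m(agent k:{m}){ nil };\n"
               "agent Ras = new {n:(gtp gdp), extra};\nm(Ras:{n})")
        elaborated(src)  # must not raise

    def test_complex_valued_actual_with_constrained_kinase(self):
        # the kinase slot is a state-constrained agent (MAPK layers 2-3)
        src = ("module m(agent k:{m}, s:{n}){ "
               "k{m} + s{n~u} -> k{m!1}-s{n~u!1} };\n"
               "agent MEK = new {S218, S222, n};\nagent ERK = new {T185};\n"
               "m(MEK{S218~p, S222~p, n}:{n}, ERK:{T185})")
        model = elaborated(src)
        (rule,) = model.rules
        kin = rule.lhs[0][0]
        assert kin.site_expr("S218").internal == IVal("p")
        assert kin.site_expr("S222").internal == IVal("p")

    def test_sibling_invocations_seal_labels_apart(self):
        # two invocations of a body using label 1 must yield rules whose
        # label namespaces differ (four distinct restricted labels overall)
        src = ("module m(agent k:{m}, s:{n}){ "
               "k{m} + s{n} -> k{m!1}-s{n!1} };\n"
               "agent A = new {x};\nagent B = new {y};\n"
               "agent C = new {x};\nagent D = new {y};\n"
               "m(A:{x}, B:{y}) | m(C:{x}, D:{y})")
        model = elaborated(src)
        namespaces = set()
        for rule in model.rules:
            for v in rule.rhs:
                for inst in v:
                    for _s, _t, se in inst.sites:
                        if isinstance(se.link, LLabel):
                            namespaces.add(se.link.ns)
        assert len(namespaces) == 2  # one namespace per sibling invocation


class TestCompartments:
    def test_transport_rule_paths(self):
        model = elaborated(fixture("gene_expression_compartments").source)
        transport = next(
            r for r in model.rules
            if [i.path for v in r.lhs for i in v] == [("cell", "nucleus")]
            and [i.path for v in r.rhs for i in v] == [("cell",)])
        assert transport is not None

    def test_doubly_nested_location(self):
        src = ("comp cell;\ncomp nucleus inside cell;\n"
               "agent P = new {x};\ncell[nucleus[ P -> P{x~p} ]]")
        model = elaborated(src)
        (rule,) = model.rules
        assert rule.lhs[0][0].path == ("cell", "nucleus")

    def test_top_level_agents_have_empty_path(self):
        model = elaborated("agent A = new {x};\nA -> A{x~p}")
        assert model.rules[0].lhs[0][0].path == ()

    def test_undeclared_compartment_fails(self):
        with pytest.raises(ElabError, match="undeclared compartment"):
            elaborated("agent A = new {x};\ncell[ A -> A{x~p} ]")

    def test_inside_parent_must_exist(self):
        with pytest.raises(ElabError, match="undeclared"):
            elaborated("comp nucleus inside cell;")


class TestRates:
    @pytest.mark.parametrize("defs, expr, expected", [
        ("rate r1 = 100; rate k = 1;", "r1*k", 100.0),
        ("", "0.1", 0.1),
        ("rate r1 = 1; rate k = 10;", "r1*k", 10.0),
    ])
    def test_rate_evaluation(self, defs, expr, expected):
        src = f"{defs}\nagent A = new {{x}};\nA -> {{{expr}}} A{{x~p}}"
        model = elaborated(src)
        assert model.rules[0].rate == pytest.approx(expected)

    def test_unbound_rate_identifier_fails(self):
        with pytest.raises(ElabError, match="unbound rate"):
            elaborated("agent A = new {x};\nA -> {kk} A{x~p}")

    def test_chemotaxis_rate_multipliers(self):
        model = elaborated(fixture("chemotaxis").source)
        rates = sorted(r.rate for r in model.rules)
        # k=1 block: fwd 1,1,1,100 rev 200,2,2,2; k=10 block: fwd scaled
        assert rates.count(200.0) == 2
        assert rates.count(1000.0) == 1
        assert rates.count(100.0) == 1
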