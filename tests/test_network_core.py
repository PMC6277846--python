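"""Stoichiometric data model: equation grammar, core-network assembly,
element balancing, and table/SBML round trips."""

import io
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laswitch.network_core import (
    ConfigurationError,
    EnzymeConfig,
    Metabolite,
    ModelValidationError,
    Reaction,
    ReactionParseError,
    StoichiometricModel,
    build_core_model,
    check_balance,
    format_reaction_equation,
    parse_reaction_equation,
    read_model_table,
    read_sbml_subset,
    write_model_table,
    write_sbml_subset,
)


class TestParseEquation:
    def test_six_entry_irreversible(self):
        stoich, reversible = parse_reaction_equation(
            "ch4 + o2 + qh2 -> ch3oh + h2o + q")
        assert not reversible
        assert stoich == {"ch4": -1, "o2": -1, "qh2": -1,
                          "ch3oh": 1, "h2o": 1, "q": 1}

    def test_explicit_coefficients(self):
        stoich, _ = parse_reaction_equation(
            "3 hcho + adp + pi + nad -> pyr + atp + nadh + h2o")
        assert stoich["hcho"] == -3
        assert stoich["pyr"] == 1

    def test_reversible_arrow_sets_flag(self):
        _, reversible = parse_reaction_equation("a <-> b")
        assert reversible

    @pytest.mark.parametrize("text", [
        "a <-> ",                  # empty product side, reversible
        " <-> b",
        "a -> a",                  # same metabolite both sides
        "a + a -> b",              # duplicate on one side
        "2x a -> b",               # malformed coefficient
        "a b c -> d",              # malformed term
        "a = b",                   # no arrow
    ])
    def test_malformed_equations_raise(self, text):
        with pytest.raises(ReactionParseError):
            parse_reaction_equation(text)

    @given(st.dictionaries(
        st.from_regex(r"[a-z][a-z0-9_]{0,6}", fullmatch=True),
        st.one_of(st.integers(1, 9).map(float), st.just(0.5)),
        min_size=2, max_size=6))
    @settings(max_examples=50, derandomize=True)
    def test_format_parse_round_trip(self, coefs):
        mets = list(coefs)
        stoich = {m: (-c if i % 2 == 0 else c)
                  for i, (m, c) in enumerate(coefs.items())}
        if not any(v < 0 for v in stoich.values()) or \
           not any(v > 0 for v in stoich.values()):
            stoich[mets[0]] = -abs(stoich[mets[0]])
            stoich[mets[-1]] = abs(stoich[mets[-1]])
        if len({m: v for m, v in stoich.items()}) < 2:
            return
        rxn = Reaction("r", dict(stoich))
        parsed, _ = parse_reaction_equation(format_reaction_equation(rxn))
        assert parsed == rxn.stoichiometry


class TestBuildCoreModel:
    def test_calcium_wiring(self, ca_model):
        assert "MXA" in ca_model.reactions
        assert "MXALa" not in ca_model.reactions
        assert "XOXF" not in ca_model.reactions
        assert "H4F_RECLAIM" not in ca_model.reactions

    def test_lanthanum_wiring(self, la_model):
        assert "MXALa" in la_model.reactions
        assert "XOXF" in la_model.reactions
        assert "H4F_RECLAIM" in la_model.reactions
        assert "MXA" not in la_model.reactions

    def test_no_route_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_core_model(EnzymeConfig(mxaFI_active=False, xoxF_active=False))

    def test_objective_is_biomass(self, ca_model):
        assert ca_model.objective_reactions == ["BIOMASS"]

    def test_maintenance_sets_ngam_floor(self):
        m = build_core_model(EnzymeConfig.calcium(maintenance_atp=2.5))
        assert m.reactions["NGAM"].lower_bound == 2.5

    def test_negative_energetics_rejected(self):
        with pytest.raises(ConfigurationError):
            EnzymeConfig(po_nadh=-0.1)


class TestBalance:
    @pytest.mark.parametrize("config", [EnzymeConfig.calcium(),
                                        EnzymeConfig.lanthanum()])
    def test_default_models_balance(self, config):
        report = check_balance(build_core_model(config), elements=("C", "O", "H"))
        assert report.passed, report.imbalances

    def test_carbon_closes_on_every_internal_reaction(self, la_model):
        report = check_balance(la_model, elements=("C",))
        assert report.passed

    def test_pmmo_oxygen_hydrogen_closure(self, ca_model):
        rxn = ca_model.reactions["PMMO"]
        for elem in ("O", "H"):
            net = sum(coef * ca_model.metabolites[mid].formula.get(elem, 0)
                      for mid, coef in rxn.stoichiometry.items())
            assert net == 0

    def test_constructed_defect_is_reported(self, la_model):
        broken = la_model.copy()
        del broken.reactions["MXALa"].stoichiometry["h2o"]
        report = check_balance(broken, elements=("C", "O", "H"))
        assert not report.passed
        assert "MXALa" in report.imbalances
        assert abs(report.imbalances["MXALa"]["O"]) == 1

    def test_formula_free_non_pseudo_metabolite_rejected(self):
        m = StoichiometricModel()
        m.add_metabolite(Metabolite("mystery"))
        m.add_metabolite(Metabolite("x", formula={"C": 1}))
        m.add_reaction(Reaction("r", {"mystery": -1, "x": 1}))
        with pytest.raises(ModelValidationError):
            check_balance(m)


class TestTableRoundTrip:
    def test_round_trip_identity(self, la_model):
        buf = io.StringIO()
        write_model_table(la_model, buf)
        again = read_model_table(io.StringIO(buf.getvalue()))
        assert set(again.reactions) == set(la_model.reactions)
        for rid, rxn in la_model.reactions.items():
            other = again.reactions[rid]
            assert other.stoichiometry == pytest.approx(rxn.stoichiometry)
            assert (other.lower_bound, other.upper_bound) == \
                   (rxn.lower_bound, rxn.upper_bound)
            assert other.objective_coefficient == rxn.objective_coefficient
            assert other.is_lumped == rxn.is_lumped
        assert set(again.metabolites) == set(la_model.metabolites)
        for mid, met in la_model.metabolites.items():
            assert again.metabolites[mid].formula == met.formula
            assert again.metabolites[mid].is_pseudo == met.is_pseudo

    def test_bad_bounds_rejected(self):
        text = ("id\tname\tequation\tlb\tub\tobjective\n"
                "r1\t\ta -> b\t5\t1\t0\n"
                "# metabolites\n"
                "id\tformula\tpseudo\texchange\tcompartment\tname\n"
                "a\t-\t1\t0\tc\t\nb\t-\t1\t0\tc\t\n")
        with pytest.raises(ModelValidationError):
            read_model_table(io.StringIO(text))

    def test_unknown_metabolite_names_row(self):
        text = ("id\tname\tequation\tlb\tub\tobjective\n"
                "rx\t\ta -> ghost\t0\t10\t0\n"
                "# metabolites\n"
                "id\tformula\tpseudo\texchange\tcompartment\tname\n"
                "a\t-\t1\t0\tc\t\n")
        with pytest.raises(ModelValidationError, match="rx"):
            read_model_table(io.StringIO(text))

    def test_hand_written_toy_file(self):
        text = ("id\tname\tequation\tlb\tub\tobjective\n"
                "UP\tuptake\ts_e -> s\t0\t10\t0\n"
                "CONV\t\ts -> p\t0\t100\t0\n"
                "OUT\t\tp -> p_e\t0\t100\t1\n"
                "# metabolites\n"
                "id\tformula\tpseudo\texchange\tcompartment\tname\n"
                "s_e\t-\t1\t1\te\t\ns\t-\t1\t0\tc\t\n"
                "p\t-\t1\t0\tc\t\np_e\t-\t1\t1\te\t\n")
        model = read_model_table(io.StringIO(text))
        assert len(model.reactions) == 3
        assert model.objective_reactions == ["OUT"]


class TestSbml:
    def test_sbml_round_trip(self, la_model, tmp_path):
        path = tmp_path / "core.xml"
        write_sbml_subset(la_model, path)
        again = read_sbml_subset(path)
        assert set(again.reactions) == set(la_model.reactions)
        for rid, rxn in la_model.reactions.items():
            other = again.reactions[rid]
            assert other.stoichiometry == pytest.approx(rxn.stoichiometry)
            assert other.lower_bound == pytest.approx(rxn.lower_bound)
            assert other.upper_bound == pytest.approx(rxn.upper_bound)
            assert other.is_lumped == rxn.is_lumped
        assert again.objective_reactions == ["BIOMASS"]
        exch = {m for m, met in again.metabolites.items()
                if met.is_exchange_species}
        assert exch == {m for m, met in la_model.metabolites.items()
                        if met.is_exchange_species}

    def test_minimal_hand_written_sbml(self, tmp_path):
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="toy">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="a" compartment="c" constant="false" boundaryCondition="true"
               hasOnlySubstanceUnits="false"/>
      <species id="b" compartment="c" constant="false" boundaryCondition="false"
               hasOnlySubstanceUnits="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r1" reversible="false" fast="false">
        <listOfReactants><speciesReference species="a" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="b" stoichiometry="2" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
        path = tmp_path / "toy.xml"
        path.write_text(sbml)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = read_sbml_subset(path)
        assert len(model.reactions) == 1
        assert model.reactions["r1"].stoichiometry == {"a": -1.0, "b": 2.0}

    def test_missing_bounds_and_objective_warn(self, tmp_path, la_model):
        # strip fbc entirely by writing the minimal file above
        self_path = tmp_path / "noobj.xml"
        self_path.write_text("""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="noobj">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="x" compartment="c" constant="false" boundaryCondition="false"
               hasOnlySubstanceUnits="false"/>
      <species id="y" compartment="c" constant="false" boundaryCondition="false"
               hasOnlySubstanceUnits="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="conv" reversible="true" fast="false">
        <listOfReactants><speciesReference species="x" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="y" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
""")
        with pytest.warns(UserWarning):
            model = read_sbml_subset(self_path)
        assert model.objective_reactions == []
        rxn = model.reactions["conv"]
        assert rxn.lower_bound == -1000.0 and rxn.upper_bound == 1000.0

    def test_unreadable_xml_raises_io_error(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model></sbml>")
        with pytest.raises(IOError):
            read_sbml_subset(bad)
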