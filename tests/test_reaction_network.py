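"""Unit tests for the network data model, RHS compilation, and moieties.

The four pathway RHS functions are cross-checked against hand-coded
oracle derivative functions written directly from the reaction lists,
independently of the generic rate-law compiler.
"""

import numpy as np
import pytest

from hepatosim.reaction_network import (
    HillFactor,
    InvalidModelError,
    Parameter,
    PathwayModel,
    Reaction,
    Species,
    build_rhs,
    conserved_moieties,
    mass_action,
    michaelis_menten,
    stoichiometry_matrix,
    validate_model,
)
from hepatosim.pathway_models import (
    build_apoptosis_model,
    build_bglucuronidase_model,
    build_deconjugation_model,
    build_ros_model,
)
from hepatosim.synthetic_data import (
    isomerization_fixture,
    production_degradation_fixture,
)


def two_species_chain():
    return PathwayModel(
        "chain",
        (Species("A", initial_concentration=1.0), Species("B")),
        (Reaction("conv", (("A", 1),), (("B", 1),), rate_law=mass_action("k")),
         Reaction("sink", (("B", 1),), (), rate_law=mass_action("kd"))),
        {"k": Parameter("k", 1e-3, "1/s"), "kd": Parameter("kd", 1e-3, "1/s")},
        "B")


class TestValidation:
    def test_well_formed_chain_is_clean(self):
        rep = validate_model(two_species_chain())
        assert rep.errors == [] and rep.warnings == []

    def test_unknown_species_reference_is_an_error(self):
        m = two_species_chain()
        bad = Reaction("bad", (("X9", 1),), (), rate_law=mass_action("k"))
        m = PathwayModel(m.name, m.species, m.reactions + (bad,),
                         m.parameters, m.biomarker_id)
        rep = validate_model(m)
        assert len(rep.errors) == 1 and "X9" in rep.errors[0]

    def test_isolated_species_is_a_warning_not_error(self):
        m = two_species_chain()
        m = PathwayModel(m.name, m.species + (Species("Nrf2_unused"),),
                         m.reactions, m.parameters, m.biomarker_id)
        rep = validate_model(m)
        assert rep.errors == []
        assert len(rep.warnings) == 1 and "Nrf2_unused" in rep.warnings[0]

    def test_negative_initial_concentration_is_an_error(self):
        m = two_species_chain()
        m = PathwayModel(
            m.name, (Species("A", initial_concentration=-1.0),) + m.species[1:],
            m.reactions, m.parameters, m.biomarker_id)
        assert any("negative" in e for e in validate_model(m).errors)

    def test_orphan_modifier_is_an_error(self):
        m = two_species_chain()
        rxn = Reaction("mod", (("A", 1),), (("B", 1),),
                       modifiers=(("B", "inhibitor"),),
                       rate_law=mass_action("k"))   # no hill factor for B
        m = PathwayModel(m.name, m.species, (rxn,), m.parameters, m.biomarker_id)
        assert any("no hill factor" in e for e in validate_model(m).errors)

    def test_nan_parameter_rejected_at_build_time(self):
        m = two_species_chain().with_parameters({"k": float("nan")})
        with pytest.raises(InvalidModelError):
            build_rhs(m)


class TestStoichiometryMatrix:
    def test_single_conversion_column(self):
        m = two_species_chain()
        N, rows = stoichiometry_matrix(m)
        assert rows == ["A", "B"]
        assert N[:, 0].tolist() == [-1, 1]

    def test_dimerization_stoichiometry(self):
        m = PathwayModel(
            "dimer", (Species("A", initial_concentration=2.0), Species("C")),
            (Reaction("dim", (("A", 2),), (("C", 1),),
                      rate_law=mass_action("k")),),
            {"k": Parameter("k", 1.0, "1/nM/s")}, "C")
        N, rows = stoichiometry_matrix(m)
        assert rows == ["A", "C"] and N[:, 0].tolist() == [-2, 1]

    def test_boundary_species_row_is_excluded(self):
        m = PathwayModel(
            "bnd",
            (Species("A", initial_concentration=1.0),
             Species("B", initial_concentration=1.0, is_boundary=True),
             Species("C")),
            (Reaction("r", (("A", 1), ("B", 1)), (("C", 1),),
                      rate_law=mass_action("k")),),
            {"k": Parameter("k", 1.0, "1/nM/s")}, "C")
        N, rows = stoichiometry_matrix(m)
        assert rows == ["A", "C"] and N[:, 0].tolist() == [-1, 1]


class TestBuildRhs:
    def test_production_degradation_closed_form(self):
        m = production_degradation_fixture(k_p=1.0, k_d=0.1)
        rhs = build_rhs(m)
        assert rhs(0.0, np.array([0.0]))[0] == pytest.approx(1.0)
        # steady state at k_p/k_d = 10 nM
        assert rhs(0.0, np.array([10.0]))[0] == pytest.approx(0.0, abs=1e-15)

    def test_boundary_derivative_is_exactly_zero(self):
        m = build_ros_model()
        rhs = build_rhs(m)
        y = np.linspace(1.0, 50.0, len(m.species))
        dy = rhs(0.0, y)
        for i, sp in enumerate(m.species):
            if sp.is_boundary:
                assert dy[i] == 0.0

    def test_negative_concentrations_floored_in_fluxes(self):
        m = production_degradation_fixture(k_p=1.0, k_d=0.1)
        rhs = build_rhs(m)
        # at X = -5 the degradation flux uses X = 0, so dX/dt = k_p
        assert rhs(0.0, np.array([-5.0]))[0] == pytest.approx(1.0)

    def test_hill_inhibition_halves_mm_flux_at_ic50(self):
        m = PathwayModel(
            "mmhill",
            (Species("S", initial_concentration=100.0),
             Species("P"),
             Species("I", initial_concentration=5.0, is_boundary=True)),
            (Reaction("enz", (("S", 1),), (("P", 1),),
                      modifiers=(("I", "inhibitor"),),
                      rate_law=michaelis_menten(
                          km="km", vmax="vmax",
                          factors=(HillFactor("I", "inhibition", "ic50", "n"),))),),
            {"vmax": Parameter("vmax", 2.0, "nM/s"),
             "km": Parameter("km", 100.0, "nM"),
             "ic50": Parameter("ic50", 5.0, "nM"),
             "n": Parameter("n", 1.0, "dimensionless")},
            "P")
        rhs = build_rhs(m)
        y = np.array([100.0, 0.0, 5.0])
        uninhibited = 2.0 * 100.0 / (100.0 + 100.0)
        assert rhs(0.0, y)[1] == pytest.approx(uninhibited / 2.0, rel=1e-14)


# ---------------------------------------------------------------------------
# hand-coded oracle RHS for the four pathway models
# ---------------------------------------------------------------------------

def _hill_inh(x, half, n):
    return half**n / (half**n + x**n)


def _hill_act(x, half, n):
    return x**n / (half**n + x**n)


def oracle_ros(model, y):
    p = model.parameter_values()
    c = dict(zip(model.species_ids, np.maximum(y, 0.0)))
    h = _hill_inh(c["GA"], p["ga_ros_ic50"], p["ga_ros_n"])
    d = {sid: 0.0 for sid in model.species_ids}
    d["CYP2E1"] = p["k_cyp2e1_syn"] * c["ethanol"] - p["k_cyp2e1_deg"] * c["CYP2E1"]
    d["TLR4"] = p["k_tlr4_act"] * c["LPS"] - p["k_tlr4_deg"] * c["TLR4"]
    d["NADPH_oxidase"] = (p["k_nox_act"] * c["TLR4"]
                          - p["k_nox_deg"] * c["NADPH_oxidase"])
    d["ROS"] = (p["k_ros_cyp"] * p["injury_fold"] * c["CYP2E1"] * h
                + p["k_ros_nox"] * p["injury_fold"] * c["NADPH_oxidase"] * h
                + p["k_ros_basal"] * p["injury_fold"]
                - p["k_ros_clear"] * c["ROS"])
    d["NFkB"] = p["k_nfkb_act"] * c["ROS"] - p["k_nfkb_deg"] * c["NFkB"]
    d["STAT3"] = p["k_stat3_act"] * c["ROS"] - p["k_stat3_deg"] * c["STAT3"]
    d["AMPK"] = (p["k_ampk_syn"]
                 * _hill_inh(c["ROS"], p["ros_ampk_ic50"], p["ros_ampk_n"])
                 - p["k_ampk_deg"] * c["AMPK"])
    d["Nrf2"] = (p["k_nrf2_syn"]
                 * _hill_inh(c["ROS"], p["ros_nrf2_ic50"], p["ros_nrf2_n"])
                 - p["k_nrf2_deg"] * c["Nrf2"])
    return np.array([d[s] for s in model.species_ids])


def oracle_deconjugation(model, y):
    p = model.parameter_values()
    c = dict(zip(model.species_ids, np.maximum(y, 0.0)))
    h = _hill_inh(c["GA"], p["ga_deconj_ki"], p["ga_deconj_n"])
    v_conj = (p["kcat_conj"] * c["UDPGT"] * c["toxin"]
              / (p["km_conj"] + c["toxin"]))
    v_enz = (p["kcat_deconj"] * c["beta_glucuronidase"]
             * c["glucuronide_conjugate"]
             / (p["km_deconj"] + c["glucuronide_conjugate"]) * h)
    v_spont = p["k_deconj_spont"] * c["glucuronide_conjugate"]
    v_ex = p["k_excrete"] * c["glucuronide_conjugate"]
    d = {sid: 0.0 for sid in model.species_ids}
    d["UDPGT"] = p["k_udpgt_syn"] - p["k_udpgt_deg"] * c["UDPGT"]
    d["beta_glucuronidase"] = (p["k_bgluc_syn"] * c["endotoxin"]
                               - p["k_bgluc_deg"] * c["beta_glucuronidase"])
    d["glucuronide_conjugate"] = v_conj - v_ex - v_enz - v_spont
    d["glucuronide_deconjugate"] = (v_enz + v_spont
                                    - p["k_reabsorb"] * c["glucuronide_deconjugate"])
    d["excreted_conjugate"] = v_ex - p["k_bile_clear"] * c["excreted_conjugate"]
    return np.array([d[s] for s in model.species_ids])


def oracle_apoptosis(model, y):
    p = model.parameter_values()
    c = dict(zip(model.species_ids, np.maximum(y, 0.0)))
    h1 = _hill_inh(c["GA"], p["ga_c8_ic50"], p["ga_c8_n"])
    h2 = _hill_inh(c["GA"], p["ga_rel_ic50"], p["ga_rel_n"])
    hB = _hill_inh(c["Bcl2"], p["bcl2_rel_ic50"], p["bcl2_rel_n"])
    hX = _hill_act(c["Bax"], p["bax_rel_ec50"], p["bax_rel_n"])
    v_act = p["k_c8_act_fadd"] * c["procaspase8"] * c["FADD"] * h1
    v_bas = p["k_c8_act_basal"] * c["procaspase8"]
    v_tr = p["k_bid_trunc"] * c["Bid"] * c["caspase8"]
    v_rel = (p["k_cytc_rel"] * c["cytochrome_c_mito"] * c["tBid"]
             * hB * hX * h2)
    v_leak = p["k_cytc_leak"] * c["cytochrome_c_mito"]
    v_apo = p["k_apop_form"] * c["cytochrome_c_cyt"] * c["Apaf1"]
    v_cl = p["k_parp_cleave"] * c["PARP"] * c["caspase3"]
    v_rep = p["k_parp_repair"] * c["cPARP"]
    d = {sid: 0.0 for sid in model.species_ids}
    d["Fas"] = p["k_fas_act"] * c["TNFa"] - p["k_fas_deg"] * c["Fas"]
    d["FADD"] = p["k_fadd_rec"] * c["Fas"] - p["k_fadd_deg"] * c["FADD"]
    d["procaspase8"] = (p["k_c8_syn"] - p["k_c8pro_deg"] * c["procaspase8"]
                        - v_act - v_bas)
    d["caspase8"] = v_act + v_bas - p["k_c8_deg"] * c["caspase8"]
    d["Bid"] = p["k_bid_syn"] - p["k_bid_deg"] * c["Bid"] - v_tr
    d["tBid"] = v_tr - p["k_tbid_deg"] * c["tBid"]
    d["Bcl2"] = p["k_bcl2_syn"] - p["k_bcl2_deg"] * c["Bcl2"]
    d["Bax"] = p["k_bax_syn"] - p["k_bax_deg"] * c["Bax"]
    d["cytochrome_c_cyt"] = (v_rel + v_leak - p["k_cytc_deg"]
                             * c["cytochrome_c_cyt"] - v_apo)
    d["Apaf1"] = p["k_apaf1_syn"] - p["k_apaf1_deg"] * c["Apaf1"] - v_apo
    d["apoptosome"] = v_apo - p["k_apop_deg"] * c["apoptosome"]
    d["caspase9"] = (p["k_c9_act"] * c["apoptosome"]
                     - p["k_c9_deg"] * c["caspase9"])
    d["caspase3"] = (p["k_c3_act"] * c["caspase9"]
                     - p["k_c3_deg"] * c["caspase3"])
    d["PARP"] = v_rep - v_cl
    d["cPARP"] = v_cl - v_rep
    return np.array([d[s] for s in model.species_ids])


def oracle_bgluc(model, y):
    p = model.parameter_values()
    c = dict(zip(model.species_ids, np.maximum(y, 0.0)))
    h = _hill_inh(c["GA"], p["ga_nfkb_ic50"], p["ga_nfkb_n"])
    v_dim = p["k_tlr4_dim"] * c["TLR4"] ** 2
    v_t6 = p["k_traf6_act"] * c["TRAF6_inactive"] * c["IRAK_complex"]
    d = {sid: 0.0 for sid in model.species_ids}
    d["TLR4"] = p["k_tlr4_act"] * c["LPS"] - p["k_tlr4_deg"] * c["TLR4"] - 2 * v_dim
    d["TLR4_dimer"] = v_dim - p["k_dimer_deg"] * c["TLR4_dimer"]
    d["adaptor_complex"] = (p["k_adaptor_rec"] * c["TLR4_dimer"]
                            - p["k_adaptor_deg"] * c["adaptor_complex"])
    d["IRAK_complex"] = (p["k_irak_act"] * c["adaptor_complex"]
                         - p["k_irak_deg"] * c["IRAK_complex"])
    d["TRAF6_inactive"] = (p["k_traf6_syn"]
                           - p["k_traf6i_deg"] * c["TRAF6_inactive"] - v_t6)
    d["TRAF6_active"] = v_t6 - p["k_traf6a_deg"] * c["TRAF6_active"]
    d["NFkB"] = (p["k_nfkb_act"] * c["TRAF6_active"] * h + p["k_nfkb_basal"]
                 - p["k_nfkb_deg"] * c["NFkB"])
    d["cMyc"] = p["k_cmyc_syn"] * c["NFkB"] - p["k_cmyc_deg"] * c["cMyc"]
    d["beta_glucuronidase"] = (p["k_bgluc_expr"] * c["cMyc"]
                               - p["k_bgluc_deg"] * c["beta_glucuronidase"])
    return np.array([d[s] for s in model.species_ids])


@pytest.mark.parametrize("builder,oracle", [
    (build_ros_model, oracle_ros),
    (build_deconjugation_model, oracle_deconjugation),
    (build_apoptosis_model, oracle_apoptosis),
    (build_bglucuronidase_model, oracle_bgluc),
], ids=["ros", "deconjugation", "apoptosis", "bgluc_synthesis"])
def test_compiled_rhs_matches_hand_coded_oracle(builder, oracle):
    """The generic rate-law compiler and an independently hand-written
    derivative function agree to 1e-12 relative at random states."""
    model = builder()
    rhs = build_rhs(model)
    rng = np.random.default_rng(42)
    scale = np.maximum(model.initial_state(), 1.0)
    for _ in range(20):
        y = rng.uniform(0.0, 2.0, len(model.species)) * scale
        got = rhs(0.0, y)
        want = oracle(model, y)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-300)


class TestConservedMoieties:
    def test_closed_isomerization_conserves_total(self):
        laws = conserved_moieties(isomerization_fixture())
        assert laws == [{"A": 1, "B": 1}]

    def test_open_chain_has_no_conservation(self):
        assert conserved_moieties(production_degradation_fixture()) == []

    def test_apoptosis_parp_pool_is_conserved(self):
        laws = conserved_moieties(build_apoptosis_model())
        assert {"PARP": 1, "cPARP": 1} in laws
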