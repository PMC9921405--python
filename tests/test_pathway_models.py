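"""Structure of the four pathway models and model integration."""

import numpy as np
import pytest

from hepatosim.pathway_models import (
    CONTROL_CONDITIONS,
    GA_MECHANISMS,
    PATHWAYS,
    IntegrationError,
    build_bglucuronidase_model,
    build_deconjugation_model,
    build_integrated_model,
    build_pathway_model,
    build_ros_model,
    export_reaction_table,
    integrate_models,
)
from hepatosim.reaction_network import build_rhs, validate_model
from hepatosim.simulation import steady_state
from hepatosim.synthetic_data import (
    isomerization_fixture,
    production_degradation_fixture,
)

EXPECTED_BIOMARKERS = {
    "ros": "ROS",
    "deconjugation": "glucuronide_deconjugate",
    "apoptosis": "cPARP",
    "bgluc_synthesis": "beta_glucuronidase",
}

MINIMUM_SPECIES = {
    "ros": {"ethanol", "LPS", "TLR4", "CYP2E1", "NADPH_oxidase", "ROS",
            "NFkB", "STAT3", "AMPK", "Nrf2", "GA"},
    "deconjugation": {"toxin", "glucuronic_acid", "UDPGT",
                      "glucuronide_conjugate", "beta_glucuronidase",
                      "glucuronide_deconjugate", "excreted_conjugate",
                      "endotoxin", "GA"},
    "apoptosis": {"TNFa", "Fas", "FADD", "procaspase8", "caspase8", "Bid",
                  "tBid", "Bcl2", "Bax", "cytochrome_c_mito",
                  "cytochrome_c_cyt", "Apaf1", "apoptosome", "caspase9",
                  "caspase3", "PARP", "cPARP", "GA"},
    "bgluc_synthesis": {"LPS", "TLR4", "TLR4_dimer", "adaptor_complex",
                        "IRAK_complex", "TRAF6_inactive", "TRAF6_active",
                        "NFkB", "cMyc", "beta_glucuronidase", "GA"},
}


@pytest.mark.parametrize("pathway", PATHWAYS)
class TestBuilders:
    def test_model_validates_cleanly(self, pathway):
        rep = validate_model(build_pathway_model(pathway))
        assert rep.errors == []

    def test_required_species_present(self, pathway):
        model = build_pathway_model(pathway)
        assert MINIMUM_SPECIES[pathway] <= set(model.species_ids)

    def test_biomarker_designation(self, pathway):
        model = build_pathway_model(pathway)
        assert model.biomarker_id == EXPECTED_BIOMARKERS[pathway]
        assert not model.get_species(model.biomarker_id).is_boundary

    def test_ga_is_clamped_boundary_species(self, pathway):
        sp = build_pathway_model(pathway).get_species("GA")
        assert sp.is_boundary and sp.initial_concentration == 0.0

    def test_zero_ga_makes_inhibition_factors_unity(self, pathway):
        """With GA = 0 every GA Hill factor is exactly 1, so the RHS is
        independent of the GA dose-response parameters."""
        model = build_pathway_model(pathway)
        spec = GA_MECHANISMS[pathway]
        ic50_names = [p for p in spec.parameters if "ic50" in p or "ki" in p]
        altered = model.with_parameters(
            {p: model.parameters[p].value * 10 for p in ic50_names})
        rhs_a, rhs_b = build_rhs(model), build_rhs(altered)
        rng = np.random.default_rng(3)
        ga_idx = model.species_ids.index("GA")
        for _ in range(5):
            y = rng.uniform(0.0, 10.0, len(model.species))
            y[ga_idx] = 0.0
            np.testing.assert_array_equal(rhs_a(0.0, y), rhs_b(0.0, y))

    def test_reaction_table_export(self, pathway):
        model = build_pathway_model(pathway)
        df = export_reaction_table(model)
        assert len(df) == len(model.reactions)
        assert {"reaction_id", "equation", "rate_law", "parameters"} <= set(df)


class TestControlConditions:
    def test_stressor_presets_match_study_conditions(self):
        dec = build_deconjugation_model()
        assert dec.get_species("endotoxin").initial_concentration == 0.1
        apo = build_pathway_model("apoptosis")
        assert apo.get_species("TNFa").initial_concentration == 0.0012
        bgs = build_bglucuronidase_model()
        assert bgs.get_species("LPS").initial_concentration == 0.1
        ros = build_ros_model()
        assert ros.parameters["injury_fold"].value == 10.0
        assert CONTROL_CONDITIONS["ros"].stressor_level == 10.0

    def test_injury_fold_scales_ros_production_tenfold(self):
        basal = build_ros_model(injury_fold=1.0)
        injured = build_ros_model(injury_fold=10.0)
        y = basal.initial_state()
        i_ros = basal.species_ids.index("ROS")
        d_basal = build_rhs(basal)(0.0, y)[i_ros]
        d_injured = build_rhs(injured)(0.0, y)[i_ros]
        # at t=0 ROS=0, so the derivative is pure production
        assert d_injured == pytest.approx(10.0 * d_basal, rel=1e-12)


class TestIntegration:
    def test_single_model_integration_is_rhs_equivalent(self):
        m = build_ros_model()
        mi = integrate_models([m])
        rhs, rhs_i = build_rhs(m), build_rhs(mi)
        rng = np.random.default_rng(5)
        for _ in range(5):
            y = rng.uniform(0.0, 20.0, len(m.species))
            np.testing.assert_allclose(rhs_i(0.0, y), rhs(0.0, y), rtol=1e-15)

    def test_disjoint_models_give_block_concatenated_rhs(self):
        a = production_degradation_fixture()
        b = isomerization_fixture()
        mi = integrate_models([a, b], shared_ids=())
        assert mi.species_ids == ("production_degradation__X",
                                  "isomerization__A", "isomerization__B")
        y = np.array([2.0, 3.0, 4.0])
        got = build_rhs(mi)(0.0, y)
        want = np.concatenate([build_rhs(a)(0.0, y[:1]),
                               build_rhs(b)(0.0, y[1:])])
        np.testing.assert_allclose(got, want, rtol=1e-15)

    def test_synthesized_bgluc_drives_deconjugation_flux(self):
        """In the coupled merge the deconjugation flux uses the enzyme level
        produced by the synthesis cascade (4.75 nM at control), so the
        deconjugate steady state matches the intrinsic model's control."""
        dec = build_deconjugation_model(bgluc_source="external")
        syn = build_bglucuronidase_model()
        mi = integrate_models([dec, syn],
                              shared_ids=("GA", "beta_glucuronidase"))
        res = steady_state(mi, 0.0)
        assert res.values["beta_glucuronidase"] == pytest.approx(4.75, rel=5e-3)
        assert res.values["deconjugation__glucuronide_deconjugate"] == \
            pytest.approx(4.9e-3, rel=0.02)

    def test_restricted_rhs_equals_standalone_rhs(self):
        """Restricted to one member model's species (shared species clamped
        at their merged initial values) the integrated RHS reproduces the
        standalone RHS."""
        ros = build_ros_model()
        syn = build_bglucuronidase_model()
        mi = integrate_models([ros, syn], shared_ids=("GA",))
        rhs_i = build_rhs(mi)
        rhs_ros = build_rhs(ros)
        rng = np.random.default_rng(11)
        idx = {sid: i for i, sid in enumerate(mi.species_ids)}
        for _ in range(5):
            y_full = rng.uniform(0.0, 10.0, len(mi.species))
            y_full[idx["GA"]] = 0.0  # shared species at merged initial
            y_ros = np.array([
                y_full[idx[sid if sid == "GA" else f"ros__{sid}"]]
                for sid in ros.species_ids])
            d_full = rhs_i(0.0, y_full)
            d_ros = rhs_ros(0.0, y_ros)
            for k, sid in enumerate(ros.species_ids):
                j = idx[sid if sid == "GA" else f"ros__{sid}"]
                assert d_full[j] == pytest.approx(d_ros[k], rel=1e-14,
                                                  abs=1e-300)

    def test_conflicting_initial_concentration_raises(self):
        a = build_ros_model()
        b = build_bglucuronidase_model().with_species(
            "GA", initial_concentration=5.0)
        with pytest.raises(IntegrationError, match="GA"):
            integrate_models([a, b], shared_ids=("GA",))

    def test_conflicting_boundary_flag_raises(self):
        a = build_ros_model()
        b = build_bglucuronidase_model().with_species("GA", is_boundary=False)
        with pytest.raises(IntegrationError, match="boundary"):
            integrate_models([a, b], shared_ids=("GA",))

    def test_full_integrated_model_valid_both_coupling_modes(self):
        for coupled in (True, False):
            mi = build_integrated_model(coupled=coupled)
            assert validate_model(mi).ok
        assert "beta_glucuronidase" in build_integrated_model(True).species_ids
        assert ("deconjugation__beta_glucuronidase"
                in build_integrated_model(False).species_ids)
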