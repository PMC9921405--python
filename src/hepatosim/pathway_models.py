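"""The four hepatic-detoxification pathway models and their integration.

Each builder returns a :class:`~hepatosim.reaction_network.PathwayModel`
for one liver-toxicity pathway, with D-glucaric acid (GA) attached as a
clamped boundary species acting through the mechanism reported for that
pathway:

* **ROS production** — toxin-driven ROS generation via CYP2E1 and NADPH
  oxidase under a 10-fold oxidative-injury scaling; GA suppresses the
  iron-catalysed (Fenton) component of ROS production, leaving a
  Fenton-independent basal route untouched (hence the residual ROS floor).
* **Deconjugation/deglucuronidation** — UDPGT-catalysed glucuronidation,
  biliary excretion, and beta-glucuronidase-catalysed deconjugation that
  re-liberates toxins; GA inhibits beta-glucuronidase (cooperative
  competitive form, expressed as a multiplicative Hill factor), while a
  small spontaneous-hydrolysis route is GA-insensitive.
* **Hepatic apoptosis** — the TNF-alpha/Fas death-receptor cascade through
  caspase-8, Bid truncation, Bcl-2/Bax-gated cytochrome-c release,
  apoptosome assembly and effector caspases to PARP cleavage; GA acts
  through the Bcl-2/Bax axis, damping both caspase-8 activation and the
  gated cytochrome-c release.  PARP + cPARP form a conserved pool.
* **beta-glucuronidase synthesis** — the LPS -> TLR4 -> adaptor -> IRAK ->
  TRAF6 -> NF-kB -> c-Myc expression cascade; GA (via its metabolites)
  inhibits the TRAF6-dependent NF-kB activation step, a small
  TRAF6-independent basal NF-kB activity being insensitive.

The default parameter values are the package's *reference calibrated
parameterization*: rate constants chosen from the steady-state design
equations of each network and refined by :func:`hepatosim.calibration.
calibrate` so that the printed control and GA-dosed biomarker steady
states are reproduced simultaneously.  They are a parameterization
consistent with those outputs, not uniquely identified constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .calibration import QualConstraint, QuantTarget
from .pharmacokinetics import DOSE_GRID_MG
from .reaction_network import (
    HillFactor,
    Parameter,
    PathwayModel,
    Reaction,
    Species,
    build_rhs,
    mass_action,
    michaelis_menten,
    validate_model,
)

__all__ = [
    "PATHWAYS",
    "GAInteractionSpec",
    "ControlCondition",
    "GA_MECHANISMS",
    "CONTROL_CONDITIONS",
    "build_ros_model",
    "build_deconjugation_model",
    "build_apoptosis_model",
    "build_bglucuronidase_model",
    "build_pathway_model",
    "build_integrated_model",
    "integrate_models",
    "IntegrationError",
    "reference_calibration",
    "export_reaction_table",
]

PATHWAYS = ("ros", "deconjugation", "apoptosis", "bgluc_synthesis")


@dataclass(frozen=True)
class GAInteractionSpec:
    """How GA attaches to one pathway (mechanism + dose-response parameters).

    ``parameters`` names the half-saturation (IC50/EC50, nM) and Hill
    exponent parameters of the attachment, resolved against the pathway
    model's parameter table.
    """

    target_pathway: str
    mechanism: str
    parameters: tuple[str, ...]


@dataclass(frozen=True)
class ControlCondition:
    """Stressor preset defining the control (zero-GA) state of a pathway."""

    pathway: str
    stressor_species: str
    stressor_level: float   # nM, or fold-change for the injury scaling
    stressor_units: str
    ga_level: float = 0.0


GA_MECHANISMS: dict[str, GAInteractionSpec] = {
    "ros": GAInteractionSpec("ros", "fenton_suppression",
                             ("ga_ros_ic50", "ga_ros_n")),
    "deconjugation": GAInteractionSpec("deconjugation",
                                       "competitive_bgluc_inhibition",
                                       ("ga_deconj_ki", "ga_deconj_n")),
    "apoptosis": GAInteractionSpec("apoptosis",
                                   "bcl2bax_caspase8_downregulation",
                                   ("ga_c8_ic50", "ga_c8_n",
                                    "ga_rel_ic50", "ga_rel_n")),
    "bgluc_synthesis": GAInteractionSpec("bgluc_synthesis",
                                         "nfkb_expression_inhibition",
                                         ("ga_nfkb_ic50", "ga_nfkb_n")),
}

CONTROL_CONDITIONS: dict[str, ControlCondition] = {
    "ros": ControlCondition("ros", "ROS", 10.0, "fold"),
    "deconjugation": ControlCondition("deconjugation", "endotoxin", 0.1, "nM"),
    "apoptosis": ControlCondition("apoptosis", "TNFa", 0.0012, "nM"),
    "bgluc_synthesis": ControlCondition("bgluc_synthesis", "LPS", 0.1, "nM"),
}


def _params(table: dict[str, tuple[float, str]]) -> dict[str, Parameter]:
    return {name: Parameter(name, value, units)
            for name, (value, units) in table.items()}


def _ga_factor(ic50: str, n: str) -> HillFactor:
    return HillFactor("GA", "inhibition", ic50, n)


# ---------------------------------------------------------------------------
# ROS production pathway
# ---------------------------------------------------------------------------

def build_ros_model(injury_fold: float = 10.0) -> PathwayModel:
    """ROS production model under oxidative hepatic injury.

    ``injury_fold`` scales every ROS-production flux relative to the basal
    (healthy) parameterization; the control condition of the study is the
    default 10-fold injury.  Biomarker: ROS.
    """
    species = (
        Species("ethanol", "Ethanol", "extracellular", 1000.0, True),
        Species("LPS", "LPS / endotoxin", "extracellular", 0.1, True),
        Species("GA", "D-glucaric acid", "extracellular", 0.0, True),
        Species("CYP2E1", "Cytochrome P450 2E1"),
        Species("TLR4", "Active TLR4 receptor"),
        Species("NADPH_oxidase", "Active NADPH oxidase"),
        Species("ROS", "Reactive oxygen species"),
        Species("NFkB", "Active NF-kB"),
        Species("STAT3", "Active STAT3"),
        Species("AMPK", "Active AMPK"),
        Species("Nrf2", "Active Nrf2"),
    )
    parameters = _params({
        "injury_fold": (injury_fold, "dimensionless"),
        "k_cyp2e1_syn": (1e-5, "1/s"),
        "k_cyp2e1_deg": (1e-3, "1/s"),
        "k_tlr4_act": (0.01, "1/s"),
        "k_tlr4_deg": (1e-3, "1/s"),
        "k_nox_act": (0.01, "1/s"),
        "k_nox_deg": (1e-3, "1/s"),
        "k_ros_cyp": (2.70369e-4, "1/s"),
        "k_ros_nox": (2.70369e-4, "1/s"),
        "k_ros_basal": (1.59262e-3, "nM/s"),
        "k_ros_clear": (1e-3, "1/s"),
        "ga_ros_ic50": (99.7902, "nM"),
        "ga_ros_n": (2.0, "dimensionless"),
        "k_nfkb_act": (1e-5, "1/s"),
        "k_nfkb_deg": (1e-3, "1/s"),
        "k_stat3_act": (1e-5, "1/s"),
        "k_stat3_deg": (1e-3, "1/s"),
        "k_ampk_syn": (1e-3, "nM/s"),
        "k_ampk_deg": (1e-3, "1/s"),
        "ros_ampk_ic50": (50.0, "nM"),
        "ros_ampk_n": (1.0, "dimensionless"),
        "k_nrf2_syn": (1e-3, "nM/s"),
        "k_nrf2_deg": (1e-3, "1/s"),
        "ros_nrf2_ic50": (50.0, "nM"),
        "ros_nrf2_n": (1.0, "dimensionless"),
    })
    ga = _ga_factor("ga_ros_ic50", "ga_ros_n")
    reactions = (
        # ethanol-induced CYP2E1 expression and turnover
        Reaction("cyp2e1_induction", (("ethanol", 1),), (("ethanol", 1), ("CYP2E1", 1)),
                 rate_law=mass_action("k_cyp2e1_syn")),
        Reaction("cyp2e1_degradation", (("CYP2E1", 1),), (),
                 rate_law=mass_action("k_cyp2e1_deg")),
        # endotoxin -> TLR4 -> NADPH oxidase activation
        Reaction("tlr4_activation", (("LPS", 1),), (("LPS", 1), ("TLR4", 1)),
                 rate_law=mass_action("k_tlr4_act")),
        Reaction("tlr4_deactivation", (("TLR4", 1),), (),
                 rate_law=mass_action("k_tlr4_deg")),
        Reaction("nox_activation", (("TLR4", 1),), (("TLR4", 1), ("NADPH_oxidase", 1)),
                 rate_law=mass_action("k_nox_act")),
        Reaction("nox_deactivation", (("NADPH_oxidase", 1),), (),
                 rate_law=mass_action("k_nox_deg")),
        # ROS production: Fenton-dependent enzymatic routes (GA-suppressed)
        Reaction("ros_production_cyp2e1", (("CYP2E1", 1),), (("CYP2E1", 1), ("ROS", 1)),
                 modifiers=(("GA", "inhibitor"),),
                 rate_law=mass_action("k_ros_cyp", "injury_fold", factors=(ga,))),
        Reaction("ros_production_nox",
                 (("NADPH_oxidase", 1),), (("NADPH_oxidase", 1), ("ROS", 1)),
                 modifiers=(("GA", "inhibitor"),),
                 rate_law=mass_action("k_ros_nox", "injury_fold", factors=(ga,))),
        # Fenton-independent basal ROS generation (GA-insensitive floor)
        Reaction("ros_production_basal", (), (("ROS", 1),),
                 rate_law=mass_action("k_ros_basal", "injury_fold")),
        Reaction("ros_clearance", (("ROS", 1),), (),
                 rate_law=mass_action("k_ros_clear")),
        # downstream amplification of inflammatory signalling
        Reaction("nfkb_activation", (("ROS", 1),), (("ROS", 1), ("NFkB", 1)),
                 rate_law=mass_action("k_nfkb_act")),
        Reaction("nfkb_deactivation", (("NFkB", 1),), (),
                 rate_law=mass_action("k_nfkb_deg")),
        Reaction("stat3_activation", (("ROS", 1),), (("ROS", 1), ("STAT3", 1)),
                 rate_law=mass_action("k_stat3_act")),
        Reaction("stat3_deactivation", (("STAT3", 1),), (),
                 rate_law=mass_action("k_stat3_deg")),
        # ROS suppresses the hepatoprotective AMPK and Nrf2 axes
        Reaction("ampk_synthesis", (), (("AMPK", 1),),
                 modifiers=(("ROS", "inhibitor"),),
                 rate_law=mass_action(
                     "k_ampk_syn",
                     factors=(HillFactor("ROS", "inhibition",
                                         "ros_ampk_ic50", "ros_ampk_n"),))),
        Reaction("ampk_deactivation", (("AMPK", 1),), (),
                 rate_law=mass_action("k_ampk_deg")),
        Reaction("nrf2_synthesis", (), (("Nrf2", 1),),
                 modifiers=(("ROS", "inhibitor"),),
                 rate_law=mass_action(
                     "k_nrf2_syn",
                     factors=(HillFactor("ROS", "inhibition",
                                         "ros_nrf2_ic50", "ros_nrf2_n"),))),
        Reaction("nrf2_deactivation", (("Nrf2", 1),), (),
                 rate_law=mass_action("k_nrf2_deg")),
    )
    return PathwayModel("ros", species, reactions, parameters, "ROS")


# ---------------------------------------------------------------------------
# deconjugation / deglucuronidation pathway
# ---------------------------------------------------------------------------

def build_deconjugation_model(bgluc_source: str = "intrinsic") -> PathwayModel:
    """Deconjugation model; biomarker: glucuronide deconjugate.

    ``bgluc_source`` is ``"intrinsic"`` (beta-glucuronidase maintained by
    an endotoxin-driven synthesis/turnover pair inside this model) or
    ``"external"`` (no intrinsic turnover; the enzyme level is supplied by
    a merged synthesis model, see :func:`integrate_models`).
    """
    if bgluc_source not in ("intrinsic", "external"):
        raise ValueError(f"unknown bgluc_source {bgluc_source!r}")
    species = (
        Species("endotoxin", "Endotoxin", "extracellular", 0.1, True),
        Species("GA", "D-glucaric acid", "extracellular", 0.0, True),
        Species("toxin", "Unconjugated toxin", "cytosol", 100.0, True),
        Species("glucuronic_acid", "Glucuronic acid", "cytosol", 1000.0, True),
        Species("UDPGT", "UDP-glucuronosyltransferase"),
        Species("glucuronide_conjugate", "Glucuronide conjugate"),
        Species("beta_glucuronidase", "beta-glucuronidase"),
        Species("glucuronide_deconjugate", "Glucuronide deconjugate", "bile"),
        Species("excreted_conjugate", "Excreted conjugate", "bile"),
    )
    parameters = _params({
        "k_udpgt_syn": (0.01, "nM/s"),
        "k_udpgt_deg": (1e-3, "1/s"),
        "k_bgluc_syn": (0.0475, "1/s"),
        "k_bgluc_deg": (1e-3, "1/s"),
        "kcat_conj": (0.011, "1/s"),
        "km_conj": (1000.0, "nM"),
        "k_excrete": (1e-3, "1/s"),
        "k_bile_clear": (1e-3, "1/s"),
        "kcat_deconj": (1.04056e-4, "1/s"),
        "km_deconj": (1000.0, "nM"),
        "ga_deconj_ki": (1.09084e4, "nM"),
        "ga_deconj_n": (5.00016, "dimensionless"),
        "k_deconj_spont": (8.6383e-10, "1/s"),
        "k_reabsorb": (1e-3, "1/s"),
    })
    reactions = [
        Reaction("udpgt_synthesis", (), (("UDPGT", 1),),
                 rate_law=mass_action("k_udpgt_syn")),
        Reaction("udpgt_degradation", (("UDPGT", 1),), (),
                 rate_law=mass_action("k_udpgt_deg")),
        # phase-II conjugation of the toxin to glucuronic acid
        Reaction("conjugation",
                 (("toxin", 1), ("glucuronic_acid", 1), ("UDPGT", 1)),
                 (("UDPGT", 1), ("glucuronide_conjugate", 1)),
                 rate_law=michaelis_menten(km="km_conj", kcat="kcat_conj",
                                           enzyme="UDPGT", substrate="toxin")),
        Reaction("biliary_excretion",
                 (("glucuronide_conjugate", 1),), (("excreted_conjugate", 1),),
                 rate_law=mass_action("k_excrete")),
        Reaction("bile_clearance", (("excreted_conjugate", 1),), (),
                 rate_law=mass_action("k_bile_clear")),
        # enzymatic deconjugation, competitively inhibited by GA
        Reaction("deconjugation_enzymatic",
                 (("glucuronide_conjugate", 1), ("beta_glucuronidase", 1)),
                 (("beta_glucuronidase", 1), ("glucuronide_deconjugate", 1),
                  ("glucuronic_acid", 1)),
                 modifiers=(("GA", "inhibitor"),),
                 rate_law=michaelis_menten(
                     km="km_deconj", kcat="kcat_deconj",
                     enzyme="beta_glucuronidase",
                     substrate="glucuronide_conjugate",
                     factors=(_ga_factor("ga_deconj_ki", "ga_deconj_n"),))),
        # slow spontaneous hydrolysis, not enzyme mediated (GA-insensitive)
        Reaction("deconjugation_spontaneous",
                 (("glucuronide_conjugate", 1),),
                 (("glucuronide_deconjugate", 1), ("glucuronic_acid", 1)),
                 rate_law=mass_action("k_deconj_spont")),
        Reaction("reabsorption", (("glucuronide_deconjugate", 1),), (),
                 rate_law=mass_action("k_reabsorb")),
    ]
    if bgluc_source == "intrinsic":
        reactions[2:2] = [
            Reaction("bgluc_synthesis", (("endotoxin", 1),),
                     (("endotoxin", 1), ("beta_glucuronidase", 1)),
                     rate_law=mass_action("k_bgluc_syn")),
            Reaction("bgluc_degradation", (("beta_glucuronidase", 1),), (),
                     rate_law=mass_action("k_bgluc_deg")),
        ]
    return PathwayModel("deconjugation", species, tuple(reactions), parameters,
                        "glucuronide_deconjugate")


# ---------------------------------------------------------------------------
# hepatic apoptosis pathway
# ---------------------------------------------------------------------------

def build_apoptosis_model() -> PathwayModel:
    """Death-receptor apoptosis cascade; biomarker: cleaved PARP.

    Strictly parallel branches are collapsed (caspase-8/10 into one
    initiator pool, caspase-3/7 into one effector pool) to keep the
    calibration identifiable.  PARP + cPARP is a conserved pool of
    2000 nM; a slow repair/resynthesis reaction returns cPARP to PARP so
    that the steady-state cleaved fraction tracks effector-caspase
    activity.
    """
    species = (
        Species("TNFa", "TNF-alpha", "extracellular", 0.0012, True),
        Species("GA", "D-glucaric acid", "extracellular", 0.0, True),
        Species("Fas", "Ligated Fas/TNFR death receptor"),
        Species("FADD", "Recruited FADD adaptor"),
        Species("procaspase8", "Pro-caspase-8/10 pool"),
        Species("caspase8", "Active initiator caspase-8/10"),
        Species("Bid", "Bid"),
        Species("tBid", "Truncated Bid"),
        Species("Bcl2", "Bcl-2"),
        Species("Bax", "Bax"),
        Species("cytochrome_c_mito", "Mitochondrial cytochrome c",
                "mitochondria", 1000.0, True),
        Species("cytochrome_c_cyt", "Cytosolic cytochrome c"),
        Species("Apaf1", "Apaf-1"),
        Species("apoptosome", "Apoptosome complex"),
        Species("caspase9", "Active caspase-9"),
        Species("caspase3", "Active effector caspase-3/7 pool"),
        Species("PARP", "PARP", "nucleus", 2000.0),
        Species("cPARP", "Cleaved PARP", "nucleus", 0.0),
    )
    parameters = _params({
        "k_fas_act": (0.83333, "1/s"),
        "k_fas_deg": (1e-3, "1/s"),
        "k_fadd_rec": (1e-3, "1/s"),
        "k_fadd_deg": (1e-3, "1/s"),
        "k_c8_syn": (0.01, "nM/s"),
        "k_c8pro_deg": (1e-3, "1/s"),
        "k_c8_act_fadd": (8.27775e-6, "1/nM/s"),
        "ga_c8_ic50": (3899.48, "nM"),
        "ga_c8_n": (1.0, "dimensionless"),
        "k_c8_act_basal": (9.8787e-5, "1/s"),
        "k_c8_deg": (1e-3, "1/s"),
        "k_bid_syn": (0.01, "nM/s"),
        "k_bid_deg": (1e-3, "1/s"),
        "k_bid_trunc": (1e-4, "1/nM/s"),
        "k_tbid_deg": (1e-3, "1/s"),
        "k_bcl2_syn": (0.002, "nM/s"),
        "k_bcl2_deg": (1e-3, "1/s"),
        "k_bax_syn": (0.004, "nM/s"),
        "k_bax_deg": (1e-3, "1/s"),
        "k_cytc_rel": (4.4006e-7, "1/nM/s"),
        "bcl2_rel_ic50": (2.0, "nM"),
        "bcl2_rel_n": (1.0, "dimensionless"),
        "bax_rel_ec50": (4.0, "nM"),
        "bax_rel_n": (1.0, "dimensionless"),
        "ga_rel_ic50": (4.60027e5, "nM"),
        "ga_rel_n": (1.0, "dimensionless"),
        "k_cytc_leak": (9.1246e-7, "1/s"),
        "k_cytc_deg": (1e-3, "1/s"),
        "k_apop_form": (2e-5, "1/nM/s"),
        "k_apaf1_syn": (5e-3, "nM/s"),
        "k_apaf1_deg": (1e-3, "1/s"),
        "k_apop_deg": (1e-3, "1/s"),
        "k_c9_act": (0.01, "1/s"),
        "k_c9_deg": (1e-3, "1/s"),
        "k_c3_act": (1e-3, "1/s"),
        "k_c3_deg": (1e-3, "1/s"),
        "k_parp_cleave": (1.72197e-4, "1/nM/s"),
        "k_parp_repair": (1e-4, "1/s"),
    })
    reactions = (
        # receptor ligation and adaptor recruitment
        Reaction("receptor_ligation", (("TNFa", 1),), (("TNFa", 1), ("Fas", 1)),
                 rate_law=mass_action("k_fas_act")),
        Reaction("receptor_decay", (("Fas", 1),), (),
                 rate_law=mass_action("k_fas_deg")),
        Reaction("fadd_recruitment", (("Fas", 1),), (("Fas", 1), ("FADD", 1)),
                 rate_law=mass_action("k_fadd_rec")),
        Reaction("fadd_decay", (("FADD", 1),), (),
                 rate_law=mass_action("k_fadd_deg")),
        # initiator caspase pool and its activation; GA damps the
        # FADD-dependent route through the Bcl-2/Bax axis
        Reaction("procaspase8_synthesis", (), (("procaspase8", 1),),
                 rate_law=mass_action("k_c8_syn")),
        Reaction("procaspase8_decay", (("procaspase8", 1),), (),
                 rate_law=mass_action("k_c8pro_deg")),
        Reaction("caspase8_activation_fadd",
                 (("procaspase8", 1), ("FADD", 1)), (("caspase8", 1), ("FADD", 1)),
                 modifiers=(("GA", "inhibitor"),),
                 rate_law=mass_action("k_c8_act_fadd",
                                      factors=(_ga_factor("ga_c8_ic50",
                                                          "ga_c8_n"),))),
        Reaction("caspase8_activation_basal",
                 (("procaspase8", 1),), (("caspase8", 1),),
                 rate_law=mass_action("k_c8_act_basal")),
        Reaction("caspase8_decay", (("caspase8", 1),), (),
                 rate_law=mass_action("k_c8_deg")),
        # Bid truncation
        Reaction("bid_synthesis", (), (("Bid", 1),),
                 rate_law=mass_action("k_bid_syn")),
        Reaction("bid_decay", (("Bid", 1),), (),
                 rate_law=mass_action("k_bid_deg")),
        Reaction("bid_truncation",
                 (("Bid", 1), ("caspase8", 1)), (("tBid", 1), ("caspase8", 1)),
                 rate_law=mass_action("k_bid_trunc")),
        Reaction("tbid_decay", (("tBid", 1),), (),
                 rate_law=mass_action("k_tbid_deg")),
        # Bcl-2 / Bax balance
        Reaction("bcl2_synthesis", (), (("Bcl2", 1),),
                 rate_law=mass_action("k_bcl2_syn")),
        Reaction("bcl2_decay", (("Bcl2", 1),), (),
                 rate_law=mass_action("k_bcl2_deg")),
        Reaction("bax_synthesis", (), (("Bax", 1),),
                 rate_law=mass_action("k_bax_syn")),
        Reaction("bax_decay", (("Bax", 1),), (),
                 rate_law=mass_action("k_bax_deg")),
        # tBid-induced, Bcl-2/Bax-gated cytochrome-c release; the GA factor
        # models the raised Bcl-2:Bax ratio under supplementation
        Reaction("cytc_release_gated",
                 (("cytochrome_c_mito", 1), ("tBid", 1)),
                 (("cytochrome_c_cyt", 1), ("tBid", 1)),
                 modifiers=(("Bcl2", "inhibitor"), ("Bax", "activator"),
                            ("GA", "inhibitor")),
                 rate_law=mass_action(
                     "k_cytc_rel",
                     factors=(HillFactor("Bcl2", "inhibition",
                                         "bcl2_rel_ic50", "bcl2_rel_n"),
                              HillFactor("Bax", "activation",
                                         "bax_rel_ec50", "bax_rel_n"),
                              _ga_factor("ga_rel_ic50", "ga_rel_n")))),
        Reaction("cytc_basal_leak",
                 (("cytochrome_c_mito", 1),), (("cytochrome_c_cyt", 1),),
                 rate_law=mass_action("k_cytc_leak")),
        Reaction("cytc_resequestration", (("cytochrome_c_cyt", 1),), (),
                 rate_law=mass_action("k_cytc_deg")),
        # apoptosome assembly and effector caspases
        Reaction("apaf1_synthesis", (), (("Apaf1", 1),),
                 rate_law=mass_action("k_apaf1_syn")),
        Reaction("apaf1_decay", (("Apaf1", 1),), (),
                 rate_law=mass_action("k_apaf1_deg")),
        Reaction("apoptosome_formation",
                 (("cytochrome_c_cyt", 1), ("Apaf1", 1)), (("apoptosome", 1),),
                 rate_law=mass_action("k_apop_form")),
        Reaction("apoptosome_decay", (("apoptosome", 1),), (),
                 rate_law=mass_action("k_apop_deg")),
        Reaction("caspase9_activation",
                 (("apoptosome", 1),), (("apoptosome", 1), ("caspase9", 1)),
                 rate_law=mass_action("k_c9_act")),
        Reaction("caspase9_decay", (("caspase9", 1),), (),
                 rate_law=mass_action("k_c9_deg")),
        Reaction("caspase3_activation",
                 (("caspase9", 1),), (("caspase9", 1), ("caspase3", 1)),
                 rate_law=mass_action("k_c3_act")),
        Reaction("caspase3_decay", (("caspase3", 1),), (),
                 rate_law=mass_action("k_c3_deg")),
        # PARP cleavage within the conserved PARP + cPARP pool
        Reaction("parp_cleavage",
                 (("PARP", 1), ("caspase3", 1)), (("cPARP", 1), ("caspase3", 1)),
                 rate_law=mass_action("k_parp_cleave")),
        Reaction("parp_repair", (("cPARP", 1),), (("PARP", 1),),
                 rate_law=mass_action("k_parp_repair")),
    )
    return PathwayModel("apoptosis", species, reactions, parameters, "cPARP")


# ---------------------------------------------------------------------------
# beta-glucuronidase synthesis pathway
# ---------------------------------------------------------------------------

def build_bglucuronidase_model() -> PathwayModel:
    """LPS -> TLR4 -> NF-kB -> c-Myc beta-glucuronidase expression cascade.

    Biomarker: beta-glucuronidase.  The MyD88/TIRAP/TRIF/TRAM adaptors are
    folded into one adaptor-complex species and IRAK1/2/4 into one kinase
    complex.
    """
    species = (
        Species("LPS", "LPS / endotoxin", "extracellular", 0.1, True),
        Species("GA", "D-glucaric acid", "extracellular", 0.0, True),
        Species("TLR4", "TLR4 monomer"),
        Species("TLR4_dimer", "TLR4 homodimer"),
        Species("adaptor_complex", "MyD88/TIRAP/TRIF/TRAM adaptor complex"),
        Species("IRAK_complex", "IRAK1/2/4 kinase complex"),
        Species("TRAF6_inactive", "TRAF6 (inactive)"),
        Species("TRAF6_active", "TRAF6 (active)"),
        Species("NFkB", "Active NF-kB", "nucleus"),
        Species("cMyc", "c-Myc", "nucleus"),
        Species("beta_glucuronidase", "beta-glucuronidase"),
    )
    parameters = _params({
        "k_tlr4_act": (0.02, "1/s"),
        "k_tlr4_deg": (1e-3, "1/s"),
        "k_tlr4_dim": (5e-4, "1/nM/s"),
        "k_dimer_deg": (1e-3, "1/s"),
        "k_adaptor_rec": (2e-3, "1/s"),
        "k_adaptor_deg": (1e-3, "1/s"),
        "k_irak_act": (1e-3, "1/s"),
        "k_irak_deg": (1e-3, "1/s"),
        "k_traf6_syn": (5e-3, "nM/s"),
        "k_traf6i_deg": (1e-3, "1/s"),
        "k_traf6_act": (2e-4, "1/nM/s"),
        "k_traf6a_deg": (1e-3, "1/s"),
        "k_nfkb_act": (9.017e-4, "1/s"),
        "ga_nfkb_ic50": (1999.66, "nM"),
        "ga_nfkb_n": (2.0, "dimensionless"),
        "k_nfkb_basal": (2.48547e-4, "nM/s"),
        "k_nfkb_deg": (1e-3, "1/s"),
        "k_cmyc_syn": (1e-3, "1/s"),
        "k_cmyc_deg": (1e-3, "1/s"),
        "k_bgluc_expr": (4.75017e-3, "1/s"),
        "k_bgluc_deg": (1e-3, "1/s"),
    })
    reactions = (
        Reaction("tlr4_activation", (("LPS", 1),), (("LPS", 1), ("TLR4", 1)),
                 rate_law=mass_action("k_tlr4_act")),
        Reaction("tlr4_decay", (("TLR4", 1),), (),
                 rate_law=mass_action("k_tlr4_deg")),
        Reaction("tlr4_dimerization", (("TLR4", 2),), (("TLR4_dimer", 1),),
                 rate_law=mass_action("k_tlr4_dim")),
        Reaction("dimer_decay", (("TLR4_dimer", 1),), (),
                 rate_law=mass_action("k_dimer_deg")),
        Reaction("adaptor_recruitment",
                 (("TLR4_dimer", 1),), (("TLR4_dimer", 1), ("adaptor_complex", 1)),
                 rate_law=mass_action("k_adaptor_rec")),
        Reaction("adaptor_decay", (("adaptor_complex", 1),), (),
                 rate_law=mass_action("k_adaptor_deg")),
        Reaction("irak_activation",
                 (("adaptor_complex", 1),),
                 (("adaptor_complex", 1), ("IRAK_complex", 1)),
                 rate_law=mass_action("k_irak_act")),
        Reaction("irak_decay", (("IRAK_complex", 1),), (),
                 rate_law=mass_action("k_irak_deg")),
        Reaction("traf6_synthesis", (), (("TRAF6_inactive", 1),),
                 rate_law=mass_action("k_traf6_syn")),
        Reaction("traf6_inactive_decay", (("TRAF6_inactive", 1),), (),
                 rate_law=mass_action("k_traf6i_deg")),
        Reaction("traf6_activation",
                 (("TRAF6_inactive", 1), ("IRAK_complex", 1)),
                 (("TRAF6_active", 1), ("IRAK_complex", 1)),
                 rate_law=mass_action("k_traf6_act")),
        Reaction("traf6_active_decay", (("TRAF6_active", 1),), (),
                 rate_law=mass_action("k_traf6a_deg")),
        # NF-kB activation: TRAF6-dependent route inhibited by GA metabolites
        Reaction("nfkb_activation_traf6",
                 (("TRAF6_active", 1),), (("TRAF6_active", 1), ("NFkB", 1)),
                 modifiers=(("GA", "inhibitor"),),
                 rate_law=mass_action("k_nfkb_act",
                                      factors=(_ga_factor("ga_nfkb_ic50",
                                                          "ga_nfkb_n"),))),
        Reaction("nfkb_activation_basal", (), (("NFkB", 1),),
                 rate_law=mass_action("k_nfkb_basal")),
        Reaction("nfkb_decay", (("NFkB", 1),), (),
                 rate_law=mass_action("k_nfkb_deg")),
        Reaction("cmyc_expression", (("NFkB", 1),), (("NFkB", 1), ("cMyc", 1)),
                 rate_law=mass_action("k_cmyc_syn")),
        Reaction("cmyc_decay", (("cMyc", 1),), (),
                 rate_law=mass_action("k_cmyc_deg")),
        Reaction("bgluc_expression",
                 (("cMyc", 1),), (("cMyc", 1), ("beta_glucuronidase", 1)),
                 rate_law=mass_action("k_bgluc_expr")),
        Reaction("bgluc_degradation", (("beta_glucuronidase", 1),), (),
                 rate_law=mass_action("k_bgluc_deg")),
    )
    return PathwayModel("bgluc_synthesis", species, reactions, parameters,
                        "beta_glucuronidase")


_BUILDERS = {
    "ros": build_ros_model,
    "deconjugation": build_deconjugation_model,
    "apoptosis": build_apoptosis_model,
    "bgluc_synthesis": build_bglucuronidase_model,
}


def build_pathway_model(pathway: str, **kwargs) -> PathwayModel:
    """Build one of the four pathway models by tag."""
    try:
        builder = _BUILDERS[pathway]
    except KeyError:
        raise ValueError(f"unknown pathway {pathway!r}; choose from {PATHWAYS}")
    return builder(**kwargs)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class IntegrationError(ValueError):
    pass


DEFAULT_SHARED_IDS = ("GA", "beta_glucuronidase")


def integrate_models(models: list[PathwayModel],
                     shared_ids: tuple[str, ...] = DEFAULT_SHARED_IDS,
                     name: str = "integrated") -> PathwayModel:
    """Merge pathway models into one network.

    Species whose id is in ``shared_ids`` keep their canonical id and are
    merged into a single state (fluxes from all contributing reactions
    sum); all other species, all reactions and all parameters are
    namespaced ``<model name>__<id>``.  Merged species must agree on
    initial concentration and boundary status, else
    :class:`IntegrationError`.  The integrated biomarker is the first
    model's biomarker.
    """
    if not models:
        raise IntegrationError("no models to integrate")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise IntegrationError(f"duplicate model names: {names}")

    merged_species: dict[str, tuple[Species, str]] = {}
    species_out: list[Species] = []
    reactions_out: list[Reaction] = []
    params_out: dict[str, Parameter] = {}

    for model in models:
        smap: dict[str, str] = {}
        for s in model.species:
            if s.id in shared_ids:
                smap[s.id] = s.id
                if s.id in merged_species:
                    ref, owner = merged_species[s.id]
                    if ref.initial_concentration != s.initial_concentration:
                        raise IntegrationError(
                            f"conflicting initial concentrations for shared "
                            f"species {s.id!r}: {ref.initial_concentration} "
                            f"({owner}) vs {s.initial_concentration} "
                            f"({model.name})")
                    if ref.is_boundary != s.is_boundary:
                        raise IntegrationError(
                            f"conflicting boundary flags for shared species "
                            f"{s.id!r}: {ref.is_boundary} ({owner}) vs "
                            f"{s.is_boundary} ({model.name})")
                else:
                    merged_species[s.id] = (s, model.name)
                    species_out.append(s)
            else:
                new_id = f"{model.name}__{s.id}"
                smap[s.id] = new_id
                species_out.append(replace(s, id=new_id))

        pmap = {p: f"{model.name}__{p}" for p in model.parameters}
        for pname, par in model.parameters.items():
            params_out[pmap[pname]] = replace(par, name=pmap[pname])

        for rxn in model.reactions:
            law = rxn.rate_law
            new_law = replace(
                law,
                rate_constants=tuple(pmap[p] for p in law.rate_constants),
                kcat=pmap.get(law.kcat) if law.kcat else None,
                vmax=pmap.get(law.vmax) if law.vmax else None,
                km=pmap.get(law.km) if law.km else None,
                enzyme=smap.get(law.enzyme) if law.enzyme else None,
                substrate=smap.get(law.substrate) if law.substrate else None,
                factors=tuple(replace(f, species_id=smap[f.species_id],
                                      half_conc=pmap[f.half_conc],
                                      hill_n=pmap[f.hill_n])
                              for f in law.factors))
            reactions_out.append(replace(
                rxn,
                id=f"{model.name}__{rxn.id}",
                reactants=tuple((smap[s], n) for s, n in rxn.reactants),
                products=tuple((smap[s], n) for s, n in rxn.products),
                modifiers=tuple((smap[s], role) for s, role in rxn.modifiers),
                rate_law=new_law))

    first = models[0]
    biomarker = (first.biomarker_id if first.biomarker_id in shared_ids
                 else f"{first.name}__{first.biomarker_id}")
    integrated = PathwayModel(name, tuple(species_out), tuple(reactions_out),
                              params_out, biomarker)
    rep = validate_model(integrated)
    if not rep.ok:
        raise IntegrationError("integration produced an invalid model: "
                               + "; ".join(rep.errors))
    return integrated


def build_integrated_model(coupled: bool = True) -> PathwayModel:
    """All four pathways in one network.

    With ``coupled=True`` the synthesis pathway's beta-glucuronidase is
    the enzyme that drives the deconjugation flux (one shared species);
    with ``coupled=False`` each model keeps its own local enzyme pool and
    only GA is shared.
    """
    ros = build_ros_model()
    apop = build_apoptosis_model()
    bgluc = build_bglucuronidase_model()
    if coupled:
        dec = build_deconjugation_model(bgluc_source="external")
        shared = ("GA", "beta_glucuronidase")
    else:
        dec = build_deconjugation_model(bgluc_source="intrinsic")
        shared = ("GA",)
    return integrate_models([ros, dec, apop, bgluc], shared_ids=shared)


# ---------------------------------------------------------------------------
# reference calibration problems
# ---------------------------------------------------------------------------

def reference_calibration(pathway: str) -> tuple[list[QuantTarget],
                                                 list[QualConstraint],
                                                 dict[str, tuple[float, float]]]:
    """Targets, qualitative constraints, and free-parameter bounds for one
    pathway's calibration to the printed steady-state biomarker values."""
    if pathway == "ros":
        targets = [QuantTarget("ros", 0.0, 70.0, tol_rel=0.01),
                   QuantTarget("ros", 1.8, 16.0, tol_rel=0.01)]
        constraints = [QualConstraint("ros", "saturation_above_dose", dose=1.8),
                       QualConstraint("ros", "monotone_nonincreasing")]
        bounds = {"k_ros_cyp": (1e-6, 1e-1), "k_ros_nox": (1e-6, 1e-1),
                  "k_ros_basal": (1e-5, 1e-1), "ga_ros_ic50": (10.0, 2000.0)}
    elif pathway == "deconjugation":
        targets = [QuantTarget("deconjugation", 0.0, 4.9e-3, tol_rel=0.02),
                   QuantTarget("deconjugation", 26.0, 1.7e-5, tol_rel=0.02),
                   QuantTarget("deconjugation", 52.0, 8.9e-6, tol_rel=0.02)]
        constraints = [QualConstraint("deconjugation", "no_effect_at_dose",
                                      dose=1.8),
                       QualConstraint("deconjugation", "monotone_nonincreasing")]
        bounds = {"kcat_deconj": (1e-6, 1e-2), "k_deconj_spont": (1e-12, 1e-7),
                  "ga_deconj_ki": (1e3, 1e5), "ga_deconj_n": (1.0, 6.0)}
    elif pathway == "apoptosis":
        targets = [QuantTarget("apoptosis", 0.0, 1217.0, tol_abs=1.0),
                   QuantTarget("apoptosis", 26.0, 1211.0, tol_abs=1.0),
                   QuantTarget("apoptosis", 52.0, 1208.0, tol_abs=1.0),
                   QuantTarget("apoptosis", 120.0, 1202.0, tol_abs=1.0)]
        constraints = [QualConstraint("apoptosis", "no_effect_at_dose",
                                      dose=1.8),
                       QualConstraint("apoptosis", "monotone_nonincreasing")]
        bounds = {"k_parp_cleave": (1e-5, 1e-2), "k_c8_act_fadd": (1e-8, 1e-4),
                  "ga_c8_ic50": (3e3, 3e5), "k_cytc_rel": (1e-8, 1e-5),
                  "ga_rel_ic50": (6e4, 6e6)}
    elif pathway == "bgluc_synthesis":
        targets = [QuantTarget("bgluc_synthesis", 0.0, 4.75, tol_rel=0.01),
                   QuantTarget("bgluc_synthesis", 26.0, 1.19, tol_rel=0.01)]
        constraints = [QualConstraint("bgluc_synthesis", "saturation_above_dose",
                                      dose=26.0),
                       QualConstraint("bgluc_synthesis",
                                      "monotone_nonincreasing")]
        bounds = {"k_bgluc_expr": (1e-4, 1e-1), "k_nfkb_basal": (1e-6, 1e-2),
                  "ga_nfkb_ic50": (100.0, 2e4)}
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    return targets, constraints, bounds


# ---------------------------------------------------------------------------
# reaction table export
# ---------------------------------------------------------------------------

def export_reaction_table(model: PathwayModel) -> pd.DataFrame:
    """Human-readable reaction table (one row per reaction)."""
    rows = []
    for rxn in model.reactions:
        def side(pairs):
            return " + ".join(f"{n} {sid}" if n > 1 else sid
                              for sid, n in pairs) or "(nothing)"
        pnames = list(rxn.rate_law.rate_constants)
        for attr in ("kcat", "vmax", "km"):
            val = getattr(rxn.rate_law, attr)
            if val:
                pnames.append(val)
        for fac in rxn.rate_law.factors:
            pnames.extend([fac.half_conc, fac.hill_n])
        pstr = "; ".join(f"{p}={model.parameters[p].value:g} "
                         f"[{model.parameters[p].units}]" for p in pnames)
        rows.append({
            "reaction_id": rxn.id,
            "equation": f"{side(rxn.reactants)} -> {side(rxn.products)}",
            "rate_law": rxn.rate_law.kind,
            "modifiers": "; ".join(f"{sid} ({role})"
                                   for sid, role in rxn.modifiers),
            "parameters": pstr,
        })
    return pd.DataFrame(rows)
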