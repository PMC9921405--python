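"""Fixture networks and synthetic observations with known ground truth.

Small models with closed-form steady states make every pipeline stage
testable without external data, and seeded synthetic observations from
known parameter sets support calibration / parameter-recovery testing.
Observation noise is multiplicative log-normal: biomarker values span many
orders of magnitude, so additive noise would destroy the small targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reaction_network import (
    HillFactor,
    Parameter,
    PathwayModel,
    Reaction,
    Species,
    mass_action,
)
from .simulation import SolverSettings, TWO_DAYS_S, steady_state

__all__ = [
    "SyntheticObservationSet",
    "make_fixture_models",
    "production_degradation_fixture",
    "isomerization_fixture",
    "hill_cascade_fixture",
    "generate_observations",
    "perturb_parameters",
]


def production_degradation_fixture(k_p: float = 1.0, k_d: float = 0.1,
                                   x0: float = 0.0) -> PathwayModel:
    """0 -> X at k_p, X -> 0 at k_d; steady state X_ss = k_p / k_d.

    With the defaults, X_ss = 10 nM.
    """
    return PathwayModel(
        "production_degradation",
        (Species("X", initial_concentration=x0),),
        (Reaction("production", (), (("X", 1),), rate_law=mass_action("k_p")),
         Reaction("degradation", (("X", 1),), (), rate_law=mass_action("k_d"))),
        {"k_p": Parameter("k_p", k_p, "nM/s"),
         "k_d": Parameter("k_d", k_d, "1/s")},
        "X")


def isomerization_fixture(k_f: float = 1e-3, k_r: float = 2e-3,
                          a0: float = 6.0, b0: float = 4.0) -> PathwayModel:
    """Closed isomerization A <-> B; A + B is conserved.

    Steady state: A_ss = (a0 + b0) * k_r / (k_f + k_r).
    """
    return PathwayModel(
        "isomerization",
        (Species("A", initial_concentration=a0),
         Species("B", initial_concentration=b0)),
        (Reaction("forward", (("A", 1),), (("B", 1),), rate_law=mass_action("k_f")),
         Reaction("reverse", (("B", 1),), (("A", 1),), rate_law=mass_action("k_r"))),
        {"k_f": Parameter("k_f", k_f, "1/s"),
         "k_r": Parameter("k_r", k_r, "1/s")},
        "B")


def hill_cascade_fixture(k1: float = 1.0, k2: float = 1e-3, k3: float = 1e-3,
                         ic50: float = 1000.0, hill_n: float = 1.0) -> PathwayModel:
    """Three-step cascade with one Hill-inhibited step.

    0 -> A at k1 * IC50^n/(IC50^n + GA^n); A -> B at k2; B -> 0 at k3.
    Closed-form fixed point: B_ss = (k1 / k3) * h(GA); at GA = IC50 with
    n = 1 the downstream steady state is exactly half its uninhibited
    value (the inhibited step is the only GA-sensitive one and the chain
    is linear).
    """
    return PathwayModel(
        "hill_cascade",
        (Species("GA", compartment="extracellular", is_boundary=True),
         Species("A",), Species("B",)),
        (Reaction("input", (), (("A", 1),),
                  modifiers=(("GA", "inhibitor"),),
                  rate_law=mass_action(
                      "k1", factors=(HillFactor("GA", "inhibition",
                                                "ic50", "hill_n"),))),
         Reaction("convert", (("A", 1),), (("B", 1),),
                  rate_law=mass_action("k2")),
         Reaction("output", (("B", 1),), (), rate_law=mass_action("k3"))),
        {"k1": Parameter("k1", k1, "nM/s"),
         "k2": Parameter("k2", k2, "1/s"),
         "k3": Parameter("k3", k3, "1/s"),
         "ic50": Parameter("ic50", ic50, "nM"),
         "hill_n": Parameter("hill_n", hill_n, "dimensionless")},
        "B")


def make_fixture_models() -> dict[str, PathwayModel]:
    """Catalog of small models with analytically known steady states."""
    return {
        "production_degradation": production_degradation_fixture(),
        "isomerization": isomerization_fixture(),
        "hill_cascade": hill_cascade_fixture(),
    }


# ---------------------------------------------------------------------------
# synthetic observations
# ---------------------------------------------------------------------------

@dataclass
class SyntheticObservationSet:
    """Noisy biomarker observations from a known parameterization."""

    model_name: str
    biomarker_id: str
    parameters: dict[str, float]
    doses_mg: tuple[float, ...]
    truth_nM: tuple[float, ...]              # noise-free steady states
    observations: np.ndarray                 # (replicate, dose)
    noise_sigma: float
    seed: int


def generate_observations(model: PathwayModel, doses_mg,
                          parameters: dict[str, float] | None = None,
                          noise_sigma: float = 0.0, seed: int = 0,
                          n_replicates: int = 1,
                          duration_s: float = TWO_DAYS_S,
                          settings: SolverSettings = SolverSettings(),
                          ) -> SyntheticObservationSet:
    """Simulate steady states per dose and apply log-normal noise.

    Ground truth must be steady; a non-steady simulation is an error.
    Seed-deterministic; with ``noise_sigma = 0`` observations equal the
    generating steady states exactly.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if parameters:
        model = model.with_parameters(parameters)
    doses = tuple(float(d) for d in doses_mg)
    truth = []
    for d in doses:
        res = steady_state(model, d, duration_s, settings)
        if not res.is_steady:
            raise RuntimeError(
                f"model {model.name!r} not steady at dose {d} mg "
                f"(max relative rate {res.max_relative_rate:.3g}); synthetic "
                f"ground truth must be a steady state")
        truth.append(res.values[model.biomarker_id])
    rng = np.random.default_rng(seed)
    truth_arr = np.array(truth)
    if noise_sigma == 0.0:
        obs = np.tile(truth_arr, (n_replicates, 1))
    else:
        factors = np.exp(noise_sigma * rng.standard_normal(
            (n_replicates, len(doses))))
        obs = truth_arr[None, :] * factors
    return SyntheticObservationSet(
        model_name=model.name, biomarker_id=model.biomarker_id,
        parameters=model.parameter_values(), doses_mg=doses,
        truth_nM=tuple(truth), observations=obs,
        noise_sigma=noise_sigma, seed=seed)


def perturb_parameters(parameters: dict[str, float], sigma: float,
                       seed: int = 0,
                       bounds: dict[str, tuple[float, float]] | None = None,
                       ) -> dict[str, float]:
    """Multiply each parameter by a seeded log-normal factor.

    With ``bounds`` given, perturbed values are clipped into the bounds.
    ``sigma = 0`` is the identity.  Used to create calibration starting
    points and recovery tasks.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for name in sorted(parameters):
        value = parameters[name] * float(np.exp(sigma * rng.standard_normal()))
        if bounds and name in bounds:
            lo, hi = bounds[name]
            value = min(max(value, lo), hi)
        out[name] = value
    return out
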