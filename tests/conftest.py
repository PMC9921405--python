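import pytest
from hypothesis import HealthCheck, settings

from hepatosim.calibration import calibrate
from hepatosim.pathway_models import (
    PATHWAYS,
    build_pathway_model,
    reference_calibration,
)
from hepatosim.pharmacokinetics import DOSE_GRID_MG
from hepatosim.simulation import run_dose_response

settings.register_profile(
    "deterministic", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

CALIBRATION_SEED = 7


@pytest.fixture(scope="session")
def calibrated():
    """Calibrate each pathway once per test session.

    Maps pathway tag to ``(model_with_fitted_parameters, CalibrationResult)``.
    """
    out = {}
    for name in PATHWAYS:
        model = build_pathway_model(name)
        targets, constraints, bounds = reference_calibration(name)
        result = calibrate(model, targets, constraints, bounds,
                           seed=CALIBRATION_SEED)
        out[name] = (model.with_parameters(result.parameters), result)
    return out


@pytest.fixture(scope="session")
def dose_tables(calibrated):
    """Dose-response of every calibrated pathway over the full dose grid."""
    return {name: run_dose_response(model, DOSE_GRID_MG)
            for name, (model, _) in calibrated.items()}
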