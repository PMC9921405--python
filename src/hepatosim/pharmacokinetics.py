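"""Dose-to-serum conversion for D-glucaric acid (GA) supplementation.

Doses are labelled in mg per 100 mL of juice; the peak serum (Cmax)
concentration scales linearly with dose at 1.5 uM per mg/100 mL, a constant
that reproduces the printed dose table (1.8 -> 2.7, 26 -> 39, 52 -> 78,
120 -> 180 uM) with zero residual.  Serum GA is taken equal to mean liver
GA, so the model input is simply the serum value converted to nM and
clamped for the whole simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CMAX_UM_PER_MG",
    "DOSE_GRID_MG",
    "DoseSpec",
    "dose_to_serum",
    "dose_to_model_input",
]

#: Cmax slope, uM serum per (mg / 100 mL) dose.
CMAX_UM_PER_MG = 1.5

#: Default supplementation grid, mg / 100 mL.
DOSE_GRID_MG = (0.0, 1.8, 26.0, 52.0, 120.0)


@dataclass(frozen=True)
class DoseSpec:
    """One supplementation level and its derived concentrations."""

    dose_mg: float           # mg per 100 mL
    serum_uM: float          # peak serum concentration
    model_input_nM: float    # clamped GA concentration fed to the models

    @classmethod
    def from_dose(cls, dose_mg: float) -> "DoseSpec":
        serum = dose_to_serum(dose_mg)
        return cls(dose_mg=dose_mg, serum_uM=serum, model_input_nM=serum * 1000.0)


def dose_to_serum(dose_mg: float) -> float:
    """Serum GA concentration (uM) for a dose in mg per 100 mL."""
    if dose_mg < 0:
        raise ValueError(f"dose must be >= 0, got {dose_mg!r}")
    return CMAX_UM_PER_MG * dose_mg


def dose_to_model_input(dose_mg: float) -> float:
    """Clamped GA model input (nM) for a dose in mg per 100 mL."""
    return dose_to_serum(dose_mg) * 1000.0
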