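"""Time-course integration, steady-state detection, dose-response tables.

Simulations run over a two-day horizon (172,800 s) with a stiff-capable
solver (LSODA, rtol 1e-8, atol 1e-12 nM by default); the cascades span
roughly nine orders of magnitude in concentration, hence the tight
absolute tolerance.  Steadiness is judged from the RHS at the final state
-- the dimensionless rate ``|dX/dt| * t_final / max(|X|, floor)`` -- not
from trajectory flatness, because slow transients can masquerade as flat
on coarse output grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .pharmacokinetics import dose_to_model_input, dose_to_serum
from .reaction_network import PathwayModel, build_rhs

__all__ = [
    "TWO_DAYS_S",
    "SolverSettings",
    "Trajectory",
    "SteadyStateResult",
    "DoseResponseTable",
    "SimulationError",
    "simulate_timecourse",
    "detect_steady_state",
    "steady_state",
    "run_dose_response",
]

#: The study's simulation horizon: two days, in seconds.
TWO_DAYS_S = 172_800.0

GA_SPECIES_ID = "GA"


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration.  Defaults are deliberately strict."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12          # nM
    n_points: int = 201
    steady_rel_threshold: float = 1e-4
    steady_floor: float = 1e-6   # nM; guards the relative rate for ~0 species


class SimulationError(RuntimeError):
    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    """Sampled solution of one model at one GA dose."""

    times: np.ndarray                  # s, ascending
    states: np.ndarray                 # (time, species), nM
    species_ids: tuple[str, ...]
    model: PathwayModel
    dose_mg: float

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.states[:, self.species_ids.index(species_id)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species_ids))
        df.insert(0, "time_s", self.times)
        return df


@dataclass
class SteadyStateResult:
    is_steady: bool
    values: dict[str, float]           # final concentrations, nM
    max_relative_rate: float
    threshold: float


@dataclass
class DoseResponseTable:
    """Biomarker steady state per GA dose (doses sorted ascending)."""

    biomarker_id: str
    doses_mg: tuple[float, ...]
    values_nM: tuple[float, ...]
    is_steady: tuple[bool, ...]
    warnings: list[str] = field(default_factory=list)

    def value_at(self, dose_mg: float) -> float:
        return self.values_nM[self.doses_mg.index(dose_mg)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_mg_per_100mL": self.doses_mg,
            "serum_uM": [dose_to_serum(d) for d in self.doses_mg],
            "biomarker": self.biomarker_id,
            "steady_state_nM": self.values_nM,
            "is_steady": self.is_steady,
        })


def _dosed_initial_state(model: PathwayModel, dose_mg: float) -> np.ndarray:
    y0 = model.initial_state()
    if dose_mg < 0:
        raise ValueError(f"dose must be >= 0, got {dose_mg!r}")
    if dose_mg > 0:
        if GA_SPECIES_ID not in model.species_ids:
            raise ValueError(
                f"model {model.name!r} has no {GA_SPECIES_ID!r} species; "
                f"only dose 0 is meaningful")
        if not model.get_species(GA_SPECIES_ID).is_boundary:
            raise ValueError(f"{GA_SPECIES_ID!r} must be a boundary species")
        y0[model.species_ids.index(GA_SPECIES_ID)] = dose_to_model_input(dose_mg)
    return y0


def simulate_timecourse(model: PathwayModel, dose_mg: float = 0.0,
                        duration_s: float = TWO_DAYS_S,
                        settings: SolverSettings = SolverSettings()) -> Trajectory:
    """Integrate a model with GA clamped at the dose's serum level.

    GA is set at t = 0 and, being a boundary species, held constant for the
    whole run.  Output is sampled on a uniform grid of
    ``settings.n_points`` times.  Deterministic given model and settings.
    """
    rhs = build_rhs(model)
    y0 = _dosed_initial_state(model, dose_mg)
    t_eval = np.linspace(0.0, duration_s, settings.n_points)
    sol = solve_ivp(rhs, (0.0, duration_s), y0, method=settings.method,
                    rtol=settings.rtol, atol=settings.atol, t_eval=t_eval)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(
            f"solver failed for model {model.name!r} at dose {dose_mg} mg: "
            f"{sol.message} (last good time {last:g} s)", last_time=last)
    return Trajectory(times=sol.t, states=sol.y.T,
                      species_ids=model.species_ids, model=model,
                      dose_mg=dose_mg)


def detect_steady_state(traj: Trajectory,
                        rel_threshold: float = SolverSettings.steady_rel_threshold,
                        floor: float = SolverSettings.steady_floor) -> SteadyStateResult:
    """Judge steadiness from the RHS at the trajectory's final state."""
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    rhs = build_rhs(traj.model)
    y = traj.final_state
    dy = rhs(traj.times[-1], y)
    t = traj.times[-1] if traj.times[-1] > 0 else 1.0
    rel = np.abs(dy) * t / np.maximum(np.abs(y), floor)
    max_rel = float(rel.max()) if rel.size else 0.0
    return SteadyStateResult(
        is_steady=bool(max_rel < rel_threshold),
        values=dict(zip(traj.species_ids, map(float, y))),
        max_relative_rate=max_rel,
        threshold=rel_threshold,
    )


def steady_state(model: PathwayModel, dose_mg: float = 0.0,
                 duration_s: float = TWO_DAYS_S,
                 settings: SolverSettings = SolverSettings()) -> SteadyStateResult:
    """Two-point simulation straight to the final state (calibration path)."""
    rhs = build_rhs(model)
    y0 = _dosed_initial_state(model, dose_mg)
    sol = solve_ivp(rhs, (0.0, duration_s), y0, method=settings.method,
                    rtol=settings.rtol, atol=settings.atol,
                    t_eval=(duration_s,))
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(
            f"solver failed for model {model.name!r} at dose {dose_mg} mg: "
            f"{sol.message} (last good time {last:g} s)", last_time=last)
    y = sol.y[:, -1]
    dy = rhs(duration_s, y)
    rel = np.abs(dy) * duration_s / np.maximum(np.abs(y), settings.steady_floor)
    max_rel = float(rel.max()) if rel.size else 0.0
    return SteadyStateResult(
        is_steady=bool(max_rel < settings.steady_rel_threshold),
        values=dict(zip(model.species_ids, map(float, y))),
        max_relative_rate=max_rel,
        threshold=settings.steady_rel_threshold,
    )


def run_dose_response(model: PathwayModel, doses_mg,
                      duration_s: float = TWO_DAYS_S,
                      settings: SolverSettings = SolverSettings()) -> DoseResponseTable:
    """One steady-state simulation per dose, biomarker values tabulated."""
    doses = sorted(float(d) for d in doses_mg)
    if len(set(doses)) != len(doses):
        raise ValueError(f"doses must be distinct, got {doses_mg!r}")
    values, steady, warnings = [], [], []
    for d in doses:
        try:
            res = steady_state(model, d, duration_s, settings)
        except SimulationError as exc:
            raise SimulationError(f"dose {d} mg: {exc}",
                                  last_time=exc.last_time) from exc
        values.append(res.values[model.biomarker_id])
        steady.append(res.is_steady)
        if not res.is_steady:
            warnings.append(
                f"dose {d} mg: not steady at t={duration_s:g} s "
                f"(max relative rate {res.max_relative_rate:.3g})")
    return DoseResponseTable(
        biomarker_id=model.biomarker_id,
        doses_mg=tuple(doses),
        values_nM=tuple(values),
        is_steady=tuple(steady),
        warnings=warnings,
    )
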