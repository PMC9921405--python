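"""Kinetic parameter calibration against steady-state biomarker targets.

The unknown rate constants of each pathway model are estimated so that
the printed control and GA-dosed biomarker steady states hold
simultaneously, subject to qualitative dose-response constraints
(no-effect doses, saturation, monotonicity).  The objective is a weighted
log-space least-squares: residuals ``(ln y_sim - ln y_target) /
ln(1 + tol)`` so that a residual of 1 sits exactly on a target's
tolerance, plus hinge penalties for violated qualitative constraints.
Parameters are optimised in log10 space (targets span 1e-6 ... 1e3 nM).

Multi-start: the model's current parameter values plus seeded
Latin-hypercube draws over the bounds; starts are polished in order of
initial loss with ``scipy.optimize.least_squares`` until one is accepted
(all targets within tolerance and all constraints passing) or the polish
budget is exhausted.  Deterministic given the seed.

Unidentified parameters are acceptable and expected: the deliverable is a
parameterization consistent with all printed outputs, not unique
constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .reaction_network import PathwayModel
from .simulation import SimulationError, SolverSettings, TWO_DAYS_S, steady_state

__all__ = [
    "QuantTarget",
    "QualConstraint",
    "ConstraintCheck",
    "CalibrationResult",
    "CalibrationError",
    "calibrate",
    "check_qualitative_constraints",
    "save_parameters",
    "load_parameters",
]


@dataclass(frozen=True)
class QuantTarget:
    """A printed steady-state biomarker value to reproduce.

    Exactly one of ``tol_rel`` (relative) or ``tol_abs`` (nM) applies; the
    absolute form exists for cPARP, whose printed dose effects are
    sub-percent.
    """

    pathway: str
    dose_mg: float
    value_nM: float
    tol_rel: float | None = 0.01
    tol_abs: float | None = None

    @property
    def rel_tolerance(self) -> float:
        if self.tol_abs is not None:
            return self.tol_abs / self.value_nM
        return self.tol_rel

    def within_tolerance(self, simulated: float) -> bool:
        if self.tol_abs is not None:
            return abs(simulated - self.value_nM) <= self.tol_abs
        return abs(simulated - self.value_nM) <= self.tol_rel * self.value_nM


@dataclass(frozen=True)
class QualConstraint:
    """A qualitative dose-response shape requirement.

    kinds: ``no_effect_at_dose`` (biomarker at ``dose`` within ``tolerance``
    of control), ``saturation_above_dose`` (all values at doses >= ``dose``
    agree within ``tolerance``), ``monotone_nonincreasing`` (values never
    rise with dose beyond ``tolerance``).
    """

    pathway: str
    kind: str
    dose: float | None = None
    tolerance: float = 0.01

    def required_doses(self, dose_grid) -> list[float]:
        if self.kind == "no_effect_at_dose":
            return [0.0, self.dose]
        if self.kind == "saturation_above_dose":
            return [d for d in dose_grid if d >= self.dose]
        if self.kind == "monotone_nonincreasing":
            return list(dose_grid)
        raise ValueError(f"unknown constraint kind {self.kind!r}")


@dataclass
class ConstraintCheck:
    constraint: QualConstraint
    passed: bool
    detail: str


@dataclass
class CalibrationResult:
    parameters: dict[str, float]
    units: dict[str, str]
    loss: float
    residuals: dict[str, float]          # per-target, in tolerance units
    target_values: dict[str, float]      # simulated biomarker per target
    constraint_report: list[ConstraintCheck]
    accepted: bool
    seed: int
    n_starts: int
    start_losses: list[float]
    n_polished: int

    def to_dict(self) -> dict:
        return {
            "parameters": {k: {"value": v, "units": self.units.get(k, "")}
                           for k, v in self.parameters.items()},
            "loss": self.loss,
            "residuals": self.residuals,
            "target_values": self.target_values,
            "constraints": [{"kind": c.constraint.kind,
                             "dose": c.constraint.dose,
                             "passed": c.passed, "detail": c.detail}
                            for c in self.constraint_report],
            "accepted": self.accepted,
            "seed": self.seed,
            "n_starts": self.n_starts,
        }


class CalibrationError(RuntimeError):
    def __init__(self, message: str, diagnostics: list[str] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


# ---------------------------------------------------------------------------
# qualitative constraint checking
# ---------------------------------------------------------------------------

def check_qualitative_constraints(values_by_dose: dict[float, float],
                                  constraints: list[QualConstraint],
                                  ) -> list[ConstraintCheck]:
    """Evaluate constraints against a biomarker-per-dose mapping.

    ``values_by_dose`` may come from a
    :class:`~hepatosim.simulation.DoseResponseTable` (``dict(zip(t.doses_mg,
    t.values_nM))``).  A missing dose raises ``KeyError`` naming the dose.
    """
    report: list[ConstraintCheck] = []
    doses = sorted(values_by_dose)

    def value(d: float) -> float:
        try:
            return values_by_dose[d]
        except KeyError:
            raise KeyError(f"constraint requires dose {d} mg, absent from "
                           f"the dose-response table") from None

    for con in constraints:
        if con.kind == "no_effect_at_dose":
            v0, vd = value(0.0), value(con.dose)
            dev = abs(vd - v0) / abs(v0) if v0 else abs(vd)
            ok = dev < con.tolerance
            detail = (f"|value({con.dose}) - value(0)| / value(0) = {dev:.3g} "
                      f"(tolerance {con.tolerance:g})")
        elif con.kind == "saturation_above_dose":
            sat = [value(d) for d in doses if d >= con.dose]
            if not sat:
                raise KeyError(f"constraint requires doses >= {con.dose} mg, "
                               f"absent from the dose-response table")
            lo, hi = min(sat), max(sat)
            dev = (hi - lo) / hi if hi else 0.0
            ok = dev < con.tolerance
            detail = (f"spread over doses >= {con.dose} mg = {dev:.3g} "
                      f"(tolerance {con.tolerance:g})")
        elif con.kind == "monotone_nonincreasing":
            worst = 0.0
            for lo_d, hi_d in zip(doses, doses[1:]):
                vl, vh = value(lo_d), value(hi_d)
                if vl > 0:
                    worst = max(worst, (vh - vl) / vl)
            ok = worst <= con.tolerance
            detail = (f"max relative increase along doses = {worst:.3g} "
                      f"(tolerance {con.tolerance:g})")
        else:
            raise ValueError(f"unknown constraint kind {con.kind!r}")
        report.append(ConstraintCheck(con, ok, detail))
    return report


def _constraint_violations(values_by_dose: dict[float, float],
                           constraints: list[QualConstraint]) -> list[float]:
    """Smooth-ish hinge magnitudes (0 when satisfied), for the objective."""
    out: list[float] = []
    doses = sorted(values_by_dose)
    for con in constraints:
        if con.kind == "no_effect_at_dose":
            v0, vd = values_by_dose[0.0], values_by_dose[con.dose]
            dev = abs(vd - v0) / abs(v0) if v0 else abs(vd)
            out.append(max(0.0, dev / con.tolerance - 1.0))
        elif con.kind == "saturation_above_dose":
            sat = [values_by_dose[d] for d in doses if d >= con.dose]
            lo, hi = min(sat), max(sat)
            dev = (hi - lo) / hi if hi else 0.0
            out.append(max(0.0, dev / con.tolerance - 1.0))
        elif con.kind == "monotone_nonincreasing":
            worst = 0.0
            for lo_d, hi_d in zip(doses, doses[1:]):
                vl, vh = values_by_dose[lo_d], values_by_dose[hi_d]
                if vl > 0:
                    worst = max(worst, (vh - vl) / vl)
            out.append(max(0.0, worst / con.tolerance - 1.0))
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_TINY = 1e-300


def calibrate(model: PathwayModel,
              targets: list[QuantTarget],
              constraints: list[QualConstraint] | None = None,
              bounds: dict[str, tuple[float, float]] | None = None,
              seed: int = 0,
              n_starts: int = 20,
              max_polish: int = 5,
              dose_grid: tuple[float, ...] = (0.0, 1.8, 26.0, 52.0, 120.0),
              duration_s: float = TWO_DAYS_S,
              settings: SolverSettings = SolverSettings(),
              constraint_weight: float = 10.0) -> CalibrationResult:
    """Fit the parameters named in ``bounds`` to the steady-state targets.

    Returns the best :class:`CalibrationResult` found, accepted or not.
    Raises :class:`CalibrationError` only if every start fails to simulate.
    """
    if not targets:
        raise ValueError("at least one target is required")
    constraints = list(constraints or [])
    if not bounds:
        raise ValueError("bounds must name at least one free parameter")
    for pname, (lo, hi) in bounds.items():
        if pname not in model.parameters:
            raise KeyError(f"unknown parameter {pname!r}")
        if not (0 < lo < hi):
            raise ValueError(f"bounds for {pname!r} must be positive and "
                             f"ordered, got ({lo}, {hi})")

    free = sorted(bounds)
    lo10 = np.log10([bounds[p][0] for p in free])
    hi10 = np.log10([bounds[p][1] for p in free])

    doses_needed = sorted({t.dose_mg for t in targets}
                          | {d for c in constraints
                             for d in c.required_doses(dose_grid)})
    tol_scale = np.array([math.log1p(t.rel_tolerance) for t in targets])
    log_targets = np.array([math.log(t.value_nM) for t in targets])

    def simulate(x10: np.ndarray) -> dict[float, float]:
        m = model.with_parameters({p: 10.0 ** v for p, v in zip(free, x10)})
        out: dict[float, float] = {}
        for d in doses_needed:
            res = steady_state(m, d, duration_s, settings)
            out[d] = res.values[model.biomarker_id]
        return out

    def residuals(x10: np.ndarray) -> np.ndarray:
        vals = simulate(x10)
        r_t = (np.log([max(vals[t.dose_mg], _TINY) for t in targets])
               - log_targets) / tol_scale
        r_c = [constraint_weight * v
               for v in _constraint_violations(vals, constraints)]
        return np.concatenate([r_t, r_c]) if r_c else r_t

    # ---- multi-start -------------------------------------------------
    rng = np.random.default_rng(seed)
    current = np.log10([model.parameters[p].value for p in free])
    current = np.clip(current, lo10, hi10)
    starts = [current]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free),
                                     seed=int(rng.integers(2**31)))
        sample = sampler.random(n=n_starts - 1)
        starts.extend(lo10 + sample * (hi10 - lo10))

    start_losses: list[float] = []
    for x in starts:
        try:
            r = residuals(x)
            start_losses.append(float(r @ r))
        except SimulationError as exc:
            start_losses.append(float("inf"))

    if not np.isfinite(start_losses).any():
        raise CalibrationError(
            "all starts failed to simulate",
            diagnostics=[f"start {i}: loss {l}"
                         for i, l in enumerate(start_losses)])

    def evaluate(x10: np.ndarray, loss: float, n_polished: int) -> CalibrationResult:
        vals = simulate(x10)
        sim = {f"{t.pathway}@{t.dose_mg}mg": vals[t.dose_mg] for t in targets}
        res = {key: (math.log(max(vals[t.dose_mg], _TINY)) - lt) / ts
               for key, t, lt, ts in zip(sim, targets, log_targets, tol_scale)}
        report = check_qualitative_constraints(vals, constraints)
        accepted = (all(t.within_tolerance(vals[t.dose_mg]) for t in targets)
                    and all(c.passed for c in report))
        params = {p: 10.0 ** v for p, v in zip(free, x10)}
        units = {p: model.parameters[p].units for p in free}
        return CalibrationResult(
            parameters=params, units=units, loss=loss, residuals=res,
            target_values=sim, constraint_report=report, accepted=accepted,
            seed=seed, n_starts=len(starts), start_losses=start_losses,
            n_polished=n_polished)

    order = np.argsort(start_losses)
    best_x, best_loss = None, float("inf")
    n_polished = 0
    for idx in order[:max_polish]:
        if not np.isfinite(start_losses[idx]):
            break
        n_polished += 1
        try:
            fit = least_squares(residuals, starts[idx], bounds=(lo10, hi10),
                                method="trf", xtol=1e-14, ftol=1e-14,
                                gtol=1e-14, max_nfev=200 * len(free))
        except SimulationError:
            continue
        loss = float(2 * fit.cost)
        if loss < best_loss:
            best_x, best_loss = fit.x, loss
        result = evaluate(fit.x, loss, n_polished)
        if result.accepted:
            return result
    if best_x is None:
        best_idx = int(order[0])
        best_x, best_loss = starts[best_idx], start_losses[best_idx]
    return evaluate(best_x, best_loss, n_polished)


# ---------------------------------------------------------------------------
# parameter file I/O
# ---------------------------------------------------------------------------

PARAMETER_FILE_VERSION = 1


def save_parameters(path, parameters: dict[str, float],
                    units: dict[str, str] | None = None,
                    metadata: dict | None = None) -> None:
    """Write a versioned flat parameter file (JSON)."""
    payload = {
        "format": "hepatosim-parameters",
        "version": PARAMETER_FILE_VERSION,
        "parameters": {k: {"value": v, "units": (units or {}).get(k, "")}
                       for k, v in parameters.items()},
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_parameters(path) -> dict[str, float]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "hepatosim-parameters":
        raise ValueError(f"{path}: not a hepatosim parameter file")
    return {k: float(v["value"]) for k, v in payload["parameters"].items()}
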