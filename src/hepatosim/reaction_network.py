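"""Core data model for biochemical reaction networks.

A :class:`PathwayModel` is a list of species, a list of reactions with
explicit kinetic rate laws, and a flat table of named parameters.  Models
compile to an ODE right-hand side ``dy/dt = N·v(y)`` where ``N`` is the
stoichiometry matrix and ``v`` the vector of reaction fluxes.

Conventions
-----------
* Concentrations are in nM, time in seconds.  First-order rate constants
  carry s^-1, second-order constants nM^-1 s^-1, Vmax nM s^-1, Km and
  IC50/EC50 nM; Hill exponents are dimensionless.
* A *boundary* species is clamped: its time derivative is exactly zero in
  any compiled RHS, whatever reactions touch it.
* Rate laws are either mass action (k · prod reactant^stoich) or
  Michaelis-Menten (kcat·[E]·S/(Km+S), or Vmax·S/(Km+S) when no enzyme is
  designated).  Either base law may be multiplied by Hill factors,
  IC50^n/(IC50^n + I^n) for an inhibitor and A^n/(EC50^n + A^n) for an
  activator; the effector of every Hill factor must be declared as a
  reaction modifier and vice versa.
* Concentrations are floored at zero inside flux evaluation so that stiff
  solvers may transiently undershoot without producing negative fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy

__all__ = [
    "COMPARTMENTS",
    "Species",
    "Parameter",
    "HillFactor",
    "RateLaw",
    "Reaction",
    "PathwayModel",
    "ValidationReport",
    "InvalidModelError",
    "validate_model",
    "stoichiometry_matrix",
    "build_rhs",
    "conserved_moieties",
    "mass_action",
    "michaelis_menten",
]

COMPARTMENTS = ("extracellular", "cytosol", "mitochondria", "nucleus", "bile")


@dataclass(frozen=True)
class Species:
    """A named chemical entity.

    ``initial_concentration`` is in nM.  ``is_boundary`` marks a clamped
    species whose concentration is held at its initial value for the whole
    simulation.
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    initial_concentration: float = 0.0
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass(frozen=True)
class Parameter:
    """A named kinetic constant with units."""

    name: str
    value: float
    units: str = "dimensionless"


@dataclass(frozen=True)
class HillFactor:
    """Multiplicative Hill modulation of a base flux.

    ``kind`` is ``"inhibition"`` (factor IC50^n/(IC50^n + [X]^n)) or
    ``"activation"`` (factor [X]^n/(EC50^n + [X]^n)).  ``half_conc`` and
    ``hill_n`` are parameter *names* resolved against the owning model.
    """

    species_id: str
    kind: str
    half_conc: str
    hill_n: str


@dataclass(frozen=True)
class RateLaw:
    """Kinetic law of a single reaction.

    ``kind`` is ``"mass_action"`` or ``"michaelis_menten"``.  For mass
    action the effective rate constant is the product of the parameters
    named in ``rate_constants`` (this lets e.g. a basal constant and a
    condition-scaling factor stay separately named).  For Michaelis-Menten,
    ``kcat``/``vmax`` and ``km`` name parameters, ``enzyme`` optionally
    names a catalytic species (which must appear unchanged on both sides of
    the reaction) and ``substrate`` names the saturating substrate
    (defaults to the first non-enzyme reactant).
    """

    kind: str
    rate_constants: tuple[str, ...] = ()
    kcat: str | None = None
    vmax: str | None = None
    km: str | None = None
    enzyme: str | None = None
    substrate: str | None = None
    factors: tuple[HillFactor, ...] = ()


def mass_action(*rate_constants: str, factors: Iterable[HillFactor] = ()) -> RateLaw:
    return RateLaw(kind="mass_action", rate_constants=tuple(rate_constants),
                   factors=tuple(factors))


def michaelis_menten(km: str, kcat: str | None = None, vmax: str | None = None,
                     enzyme: str | None = None, substrate: str | None = None,
                     factors: Iterable[HillFactor] = ()) -> RateLaw:
    return RateLaw(kind="michaelis_menten", kcat=kcat, vmax=vmax, km=km,
                   enzyme=enzyme, substrate=substrate, factors=tuple(factors))


@dataclass(frozen=True)
class Reaction:
    """Reactants/products with integer stoichiometry plus a rate law.

    A catalyst is expressed by listing the same species as reactant and
    product with equal stoichiometry (net zero).  ``modifiers`` declares
    Hill-factor effectors as ``(species_id, role)`` with role ``inhibitor``
    or ``activator``.
    """

    id: str
    reactants: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    modifiers: tuple[tuple[str, str], ...] = ()
    rate_law: RateLaw = field(default_factory=lambda: RateLaw("mass_action"))
    name: str = ""


@dataclass(frozen=True)
class PathwayModel:
    """Species + reactions + parameters + one designated biomarker."""

    name: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    parameters: Mapping[str, Parameter]
    biomarker_id: str

    # -- convenience ----------------------------------------------------
    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)

    def parameter_values(self) -> dict[str, float]:
        return {k: p.value for k, p in self.parameters.items()}

    def with_parameters(self, values: Mapping[str, float]) -> "PathwayModel":
        """Return a copy with the given parameter values substituted."""
        params = dict(self.parameters)
        for k, v in values.items():
            if k not in params:
                raise KeyError(f"unknown parameter {k!r}")
            params[k] = replace(params[k], value=float(v))
        return replace(self, parameters=params)

    def with_species(self, sid: str, **changes) -> "PathwayModel":
        """Return a copy with one species' fields changed (e.g. clamp level)."""
        new = tuple(replace(s, **changes) if s.id == sid else s for s in self.species)
        if all(s is o for s, o in zip(new, self.species)):
            raise KeyError(sid)
        return replace(self, species=new)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


class InvalidModelError(ValueError):
    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__("invalid model: " + "; ".join(report.errors))


def validate_model(model: PathwayModel) -> ValidationReport:
    """Check the structural invariants of a model; report, never raise."""
    rep = ValidationReport()
    ids = [s.id for s in model.species]
    seen = set()
    for sid in ids:
        if sid in seen:
            rep.errors.append(f"duplicate species id {sid!r}")
        seen.add(sid)
    for s in model.species:
        if s.initial_concentration < 0:
            rep.errors.append(
                f"species {s.id!r} has negative initial concentration "
                f"{s.initial_concentration!r}")
        if s.compartment not in COMPARTMENTS:
            rep.errors.append(f"species {s.id!r} has unknown compartment "
                              f"{s.compartment!r}")

    known = set(ids)
    touched: set[str] = set()
    rxn_ids: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in rxn_ids:
            rep.errors.append(f"duplicate reaction id {rxn.id!r}")
        rxn_ids.add(rxn.id)
        for sid, stoich in rxn.reactants + rxn.products:
            if sid not in known:
                rep.errors.append(
                    f"reaction {rxn.id!r} references unknown species {sid!r}")
            else:
                touched.add(sid)
            if stoich <= 0 or int(stoich) != stoich:
                rep.errors.append(
                    f"reaction {rxn.id!r}: stoichiometry of {sid!r} must be a "
                    f"positive integer, got {stoich!r}")
        modifier_ids = set()
        for sid, role in rxn.modifiers:
            if sid not in known:
                rep.errors.append(
                    f"reaction {rxn.id!r} references unknown modifier {sid!r}")
            else:
                touched.add(sid)
            if role not in ("inhibitor", "activator"):
                rep.errors.append(
                    f"reaction {rxn.id!r}: modifier {sid!r} has unknown role "
                    f"{role!r}")
            modifier_ids.add(sid)
        factor_ids = set()
        for fac in rxn.rate_law.factors:
            factor_ids.add(fac.species_id)
            if fac.species_id not in known:
                rep.errors.append(
                    f"reaction {rxn.id!r}: hill factor references unknown "
                    f"species {fac.species_id!r}")
            if fac.kind not in ("inhibition", "activation"):
                rep.errors.append(
                    f"reaction {rxn.id!r}: hill factor on {fac.species_id!r} "
                    f"has unknown kind {fac.kind!r}")
        # every modifier must act through a hill factor, and vice versa
        for sid in modifier_ids - factor_ids:
            rep.errors.append(
                f"reaction {rxn.id!r}: modifier {sid!r} has no hill factor")
        for sid in factor_ids - modifier_ids:
            rep.errors.append(
                f"reaction {rxn.id!r}: hill factor effector {sid!r} is not a "
                f"declared modifier")
        rep.errors.extend(_check_rate_law(model, rxn))

    for s in model.species:
        if s.id not in touched:
            rep.warnings.append(f"species {s.id!r} has no incident reactions")

    if model.biomarker_id not in known:
        rep.errors.append(f"biomarker {model.biomarker_id!r} is not a species")
    else:
        if model.get_species(model.biomarker_id).is_boundary:
            rep.errors.append(
                f"biomarker {model.biomarker_id!r} is a boundary species")

    for pname, par in model.parameters.items():
        if pname != par.name:
            rep.errors.append(f"parameter key {pname!r} != name {par.name!r}")
        if not np.isfinite(par.value):
            rep.errors.append(f"parameter {pname!r} is not finite")
        elif par.value < 0:
            rep.errors.append(f"parameter {pname!r} is negative")
    return rep


def _check_rate_law(model: PathwayModel, rxn: Reaction) -> list[str]:
    errs: list[str] = []
    law = rxn.rate_law
    params = model.parameters

    def need(pname: str | None, what: str) -> None:
        if pname is not None and pname not in params:
            errs.append(f"reaction {rxn.id!r}: {what} parameter {pname!r} "
                        f"is not defined")

    if law.kind == "mass_action":
        if not law.rate_constants:
            errs.append(f"reaction {rxn.id!r}: mass action law without rate "
                        f"constants")
        for pname in law.rate_constants:
            need(pname, "rate")
    elif law.kind == "michaelis_menten":
        need(law.km, "Km")
        if law.km is None:
            errs.append(f"reaction {rxn.id!r}: Michaelis-Menten law needs Km")
        if (law.kcat is None) == (law.vmax is None):
            errs.append(f"reaction {rxn.id!r}: Michaelis-Menten law needs "
                        f"exactly one of kcat or vmax")
        need(law.kcat, "kcat")
        need(law.vmax, "Vmax")
        if (law.kcat is not None) and law.enzyme is None:
            errs.append(f"reaction {rxn.id!r}: kcat form requires an enzyme")
        reac = {sid: n for sid, n in rxn.reactants}
        prod = {sid: n for sid, n in rxn.products}
        if law.enzyme is not None and reac.get(law.enzyme) != prod.get(law.enzyme):
            errs.append(f"reaction {rxn.id!r}: enzyme {law.enzyme!r} must "
                        f"appear unchanged on both sides")
        sub = law.substrate or _default_substrate(rxn)
        if sub is None or sub not in reac:
            errs.append(f"reaction {rxn.id!r}: Michaelis-Menten substrate "
                        f"{sub!r} is not a reactant")
    else:
        errs.append(f"reaction {rxn.id!r}: unknown rate law kind {law.kind!r}")

    for fac in law.factors:
        need(fac.half_conc, "half-saturation")
        need(fac.hill_n, "hill exponent")
        if fac.hill_n in params and params[fac.hill_n].value < 1:
            errs.append(f"reaction {rxn.id!r}: hill exponent "
                        f"{fac.hill_n!r} must be >= 1")
    return errs


def _default_substrate(rxn: Reaction) -> str | None:
    enzyme = rxn.rate_law.enzyme
    for sid, _ in rxn.reactants:
        if sid != enzyme:
            return sid
    return None


def _require_valid(model: PathwayModel) -> None:
    rep = validate_model(model)
    if not rep.ok:
        raise InvalidModelError(rep)


# ---------------------------------------------------------------------------
# stoichiometry and RHS compilation
# ---------------------------------------------------------------------------

def stoichiometry_matrix(model: PathwayModel) -> tuple[np.ndarray, list[str]]:
    """Integer net-stoichiometry matrix over *non-boundary* species.

    Returns ``(N, row_ids)`` with ``N[i, j]`` the net stoichiometry of
    species ``row_ids[i]`` in reaction ``j``.  Boundary species are excluded
    structurally, which makes the zero-derivative clamp unbreakable.
    """
    _require_valid(model)
    rows = [s.id for s in model.species if not s.is_boundary]
    index = {sid: i for i, sid in enumerate(rows)}
    N = np.zeros((len(rows), len(model.reactions)), dtype=int)
    for j, rxn in enumerate(model.reactions):
        for sid, n in rxn.reactants:
            if sid in index:
                N[index[sid], j] -= n
        for sid, n in rxn.products:
            if sid in index:
                N[index[sid], j] += n
    return N, rows


def _compile_flux(model: PathwayModel, rxn: Reaction,
                  index: dict[str, int]) -> Callable[[np.ndarray], float]:
    """Build a scalar flux evaluator for one reaction (concentrations in nM)."""
    law = rxn.rate_law
    p = model.parameter_values()

    factors: list[tuple[int, bool, float, float]] = []
    for fac in law.factors:
        factors.append((index[fac.species_id], fac.kind == "inhibition",
                        p[fac.half_conc], p[fac.hill_n]))

    def hill(y: np.ndarray) -> float:
        f = 1.0
        for i, inhib, half, n in factors:
            xn = y[i] ** n
            hn = half ** n
            f *= hn / (hn + xn) if inhib else xn / (hn + xn)
        return f

    if law.kind == "mass_action":
        k = float(np.prod([p[name] for name in law.rate_constants]))
        terms = [(index[sid], n) for sid, n in rxn.reactants]

        def flux(y: np.ndarray) -> float:
            v = k
            for i, n in terms:
                v *= y[i] ** n
            return v * hill(y)

        return flux

    # michaelis_menten
    km = p[law.km]
    sub = index[law.substrate or _default_substrate(rxn)]
    if law.kcat is not None:
        kcat = p[law.kcat]
        enz = index[law.enzyme]

        def flux(y: np.ndarray) -> float:
            s = y[sub]
            return kcat * y[enz] * s / (km + s) * hill(y)
    else:
        vmax = p[law.vmax]

        def flux(y: np.ndarray) -> float:
            s = y[sub]
            return vmax * s / (km + s) * hill(y)

    return flux


def build_rhs(model: PathwayModel) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the model to a derivative evaluator ``f(t, y) -> dy/dt``.

    ``y`` is ordered like ``model.species``; derivatives of boundary species
    are exactly zero.  Negative input concentrations are floored at zero
    inside flux evaluation.  Raises :class:`InvalidModelError` on an invalid
    model (including non-finite parameters).
    """
    _require_valid(model)
    index = model.species_index()
    n_species = len(model.species)
    boundary = np.array([s.is_boundary for s in model.species])

    # full-size stoichiometry with boundary rows zeroed
    N = np.zeros((n_species, len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for sid, n in rxn.reactants:
            N[index[sid], j] -= n
        for sid, n in rxn.products:
            N[index[sid], j] += n
    N[boundary, :] = 0.0

    fluxes = [_compile_flux(model, rxn, index) for rxn in model.reactions]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(np.asarray(y, float), 0.0)
        v = np.array([f(yc) for f in fluxes])
        return N @ v

    return rhs


# ---------------------------------------------------------------------------
# conserved moieties
# ---------------------------------------------------------------------------

def conserved_moieties(model: PathwayModel) -> list[dict[str, int]]:
    """Nonnegative integer conservation laws of the network.

    Each returned mapping ``{species_id: weight}`` satisfies
    ``w^T · N = 0`` over the non-boundary stoichiometry matrix, i.e. the
    weighted concentration sum is invariant along any trajectory.  The
    left null space is computed exactly (rational arithmetic); basis
    vectors are rescaled to primitive integers and combined pairwise where
    needed to obtain nonnegative representatives.  For networks whose left
    null space has a nonnegative basis (all models shipped here) the result
    spans the full space.
    """
    N, rows = stoichiometry_matrix(model)
    if not rows:
        return []
    basis = sympy.Matrix(N.T).nullspace()
    vectors: list[tuple[int, ...]] = []
    for vec in basis:
        fracs = [Fraction(sympy.nsimplify(x)) for x in vec]
        denom = np.lcm.reduce([f.denominator for f in fracs]) if fracs else 1
        ints = [int(f * denom) for f in fracs]
        g = int(np.gcd.reduce([abs(i) for i in ints if i] or [1]))
        ints = [i // g for i in ints]
        vectors.append(tuple(ints))

    nonneg: list[tuple[int, ...]] = []

    def admit(v: Sequence[int]) -> None:
        if all(x >= 0 for x in v) and any(x > 0 for x in v):
            if tuple(v) not in nonneg:
                nonneg.append(tuple(v))
        elif all(x <= 0 for x in v) and any(x < 0 for x in v):
            admit(tuple(-x for x in v))

    for v in vectors:
        admit(v)
    # pairwise combinations may fix mixed-sign basis vectors
    for i, vi in enumerate(vectors):
        for vj in vectors[i + 1:]:
            admit(tuple(a + b for a, b in zip(vi, vj)))
            admit(tuple(a - b for a, b in zip(vi, vj)))
    return [{sid: w for sid, w in zip(rows, v) if w} for v in nonneg]
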