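"""Biochemical reaction networks with typed rate laws, compiled to ODEs.

All three pathway models (canonical Wnt with plakoglobin competition, the
RhoA-ROCK/actin/MKL1 cascade, and the integrated crosstalk network) are
expressed in this single representation: species with initial concentrations,
reactions with one of a closed catalogue of five rate-law kinds, and timed
events that reset species levels (typically boundary inputs such as Wnt).

Units are nM for concentrations and minutes for time throughout.

The rate-law catalogue is deliberately closed so that every kinetic term in
the shipped models is auditable:

``mass_action``
    v = k * prod_i [S_i]^n_i over the substrates (default: the reactants).
``saturating_signal``
    v = k * [Signal] * [Substrate] / (K + [Substrate]); the Michaelis form
    used for enzyme-mediated (de)phosphorylation steps.
``modifier_mass_action``
    v = k * [modifier] * [substrate]; bilinear catalysis, e.g. ROCK-driven
    actin polymerisation.
``competitive_promoter``
    v = (basal + act*[A]/K_act) / (1 + [A]/K_act + sum_j [R_j]/K_rep_<R_j>);
    quasi-equilibrium occupancy of a shared promoter site with an optional
    activating complex A and any number of repressing complexes R_j.
``constant_synthesis``
    v = k (nM/min), a zeroth-order source.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

__all__ = [
    "RATE_LAW_KINDS",
    "SpeciesDef",
    "RateLaw",
    "ReactionDef",
    "Event",
    "NetworkModel",
    "CompiledODE",
    "eval_rate",
    "compile_odes",
    "validate_model",
]

RATE_LAW_KINDS = (
    "mass_action",
    "saturating_signal",
    "modifier_mass_action",
    "competitive_promoter",
    "constant_synthesis",
)


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species.

    Boundary species (pathway inputs such as Wnt, Wnt5b, RhoGEF, RhoGAP) are
    held constant by the integrator: reactions may reference or even formally
    consume them, but their time derivative is clamped to zero and their
    level changes only through events.
    """

    name: str
    initial_concentration: float = 0.0
    is_boundary: bool = False


@dataclass
class RateLaw:
    """A kinetic law of one of the catalogue kinds.

    ``species_refs`` binds the law's named roles to species:

    - mass_action: ``{"substrates": [name, ...]}`` (repeats give order > 1);
      filled from the reaction's reactants if omitted.
    - saturating_signal: ``{"signal": name, "substrate": name}``.
    - modifier_mass_action: ``{"modifier": name, "substrate": name}``.
    - competitive_promoter: ``{"activator": name or None,
      "repressors": [name, ...]}``; the repression constant for species R is
      the parameter ``K_rep_<R>``.
    - constant_synthesis: no refs.
    """

    kind: str
    parameters: dict[str, float]
    species_refs: dict = field(default_factory=dict)

    def referenced_species(self) -> list[str]:
        out: list[str] = []
        for value in self.species_refs.values():
            if value is None:
                continue
            if isinstance(value, str):
                out.append(value)
            else:
                out.extend(v for v in value if v is not None)
        return out


@dataclass
class ReactionDef:
    """A reaction: stoichiometry, modifiers, and a rate law.

    ``label`` is a short unique identifier; the Wnt model uses the original
    reaction numbering (r1-r17 for the published core, r20-r23 for the
    extension) so every parameter can be traced to its reaction.
    """

    label: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    rate_law: RateLaw
    modifiers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate_law.kind == "mass_action" and "substrates" not in self.rate_law.species_refs:
            subs: list[str] = []
            for name, stoich in self.reactants:
                subs.extend([name] * stoich)
            self.rate_law.species_refs["substrates"] = subs


@dataclass(frozen=True)
class Event:
    """Set ``species`` to ``new_value`` (nM) at ``time`` (min).

    Events are applied as hard integrator restarts in time order; ties are
    broken by declaration order.
    """

    time: float
    species: str
    new_value: float


def _rate_expr(law: RateLaw, conc, params):
    """Evaluate a rate law over numeric or symbolic concentration/parameter maps."""
    kind = law.kind
    if kind == "mass_action":
        rate = params["k"]
        for name in law.species_refs["substrates"]:
            rate = rate * conc[name]
        return rate
    if kind == "saturating_signal":
        signal = conc[law.species_refs["signal"]]
        substrate = conc[law.species_refs["substrate"]]
        return params["k"] * signal * substrate / (params["K"] + substrate)
    if kind == "modifier_mass_action":
        return params["k"] * conc[law.species_refs["modifier"]] * conc[law.species_refs["substrate"]]
    if kind == "competitive_promoter":
        activator = law.species_refs.get("activator")
        repressors = law.species_refs.get("repressors", [])
        numer = params["basal"]
        denom = 1
        if activator is not None:
            occ = conc[activator] / params["K_act"]
            numer = numer + params["act"] * occ
            denom = denom + occ
        for name in repressors:
            denom = denom + conc[name] / params[f"K_rep_{name}"]
        return numer / denom
    if kind == "constant_synthesis":
        return params["k"]
    raise ValueError(f"unknown rate-law kind: {kind!r}")


def eval_rate(rate_law: RateLaw, concentrations: dict[str, float]) -> float:
    """Instantaneous rate (nM/min) of ``rate_law`` at the given concentrations.

    Raises ``ValueError`` for an unknown kind or a negative concentration and
    ``KeyError`` if a referenced species is missing from the map.
    """
    if rate_law.kind not in RATE_LAW_KINDS:
        raise ValueError(f"unknown rate-law kind: {rate_law.kind!r}")
    for name in rate_law.referenced_species():
        if name not in concentrations:
            raise KeyError(f"species {name!r} missing from concentration map")
        if concentrations[name] < 0:
            raise ValueError(f"negative concentration for species {name!r}")
    return float(_rate_expr(rate_law, concentrations, rate_law.parameters))


@dataclass
class NetworkModel:
    """A reaction network: species, reactions, shared constants and events."""

    name: str
    species: list[SpeciesDef] = field(default_factory=list)
    reactions: list[ReactionDef] = field(default_factory=list)
    global_parameters: dict[str, float] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)

    # -- introspection -----------------------------------------------------
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def boundary_mask(self) -> np.ndarray:
        return np.array([s.is_boundary for s in self.species], dtype=bool)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], dtype=float)

    def get_reaction(self, label: str) -> ReactionDef:
        for r in self.reactions:
            if r.label == label:
                return r
        raise KeyError(f"no reaction labelled {label!r}")

    # -- parameters --------------------------------------------------------
    def parameters(self) -> dict[str, float]:
        """Flat map ``"<reaction label>.<param>" -> value`` over all rate laws."""
        out: dict[str, float] = {}
        for r in self.reactions:
            for pname, value in r.rate_law.parameters.items():
                out[f"{r.label}.{pname}"] = value
        return out

    def with_parameters(self, updates: dict[str, float]) -> "NetworkModel":
        """Copy of the model with the given flat-named parameters replaced."""
        model = self.copy()
        known = model.parameters()
        for key, value in updates.items():
            if key not in known:
                raise KeyError(f"unknown parameter {key!r}")
            label, pname = key.split(".", 1)
            model.get_reaction(label).rate_law.parameters[pname] = value
        return model

    def scale_parameters(self, keys: list[str], factor: float) -> "NetworkModel":
        current = self.parameters()
        return self.with_parameters({k: current[k] * factor for k in keys})

    # -- edits -------------------------------------------------------------
    def copy(self) -> "NetworkModel":
        return _copy.deepcopy(self)

    def rename_species(self, old: str, new: str) -> None:
        """Rename a species everywhere it is referenced (in place)."""
        if new in self.species_names():
            raise ValueError(f"species {new!r} already exists")
        idx = self.species_index()[old]
        s = self.species[idx]
        self.species[idx] = SpeciesDef(new, s.initial_concentration, s.is_boundary)

        def _sub(name):
            return new if name == old else name

        for r in self.reactions:
            r.reactants = [(_sub(n), c) for n, c in r.reactants]
            r.products = [(_sub(n), c) for n, c in r.products]
            r.modifiers = [_sub(n) for n in r.modifiers]
            refs = r.rate_law.species_refs
            for key, value in list(refs.items()):
                if isinstance(value, str):
                    refs[key] = _sub(value)
                elif isinstance(value, list):
                    refs[key] = [_sub(v) for v in value]
            params = r.rate_law.parameters
            if f"K_rep_{old}" in params:
                params[f"K_rep_{new}"] = params.pop(f"K_rep_{old}")
        self.events = [
            Event(e.time, _sub(e.species), e.new_value) for e in self.events
        ]

    def remove_reaction(self, label: str) -> None:
        before = len(self.reactions)
        self.reactions = [r for r in self.reactions if r.label != label]
        if len(self.reactions) == before:
            raise KeyError(f"no reaction labelled {label!r}")

    def remove_species(self, name: str) -> None:
        for r in self.reactions:
            touched = {n for n, _ in r.reactants} | {n for n, _ in r.products}
            touched |= set(r.modifiers) | set(r.rate_law.referenced_species())
            if name in touched:
                raise ValueError(f"species {name!r} still referenced by reaction {r.label}")
        self.species = [s for s in self.species if s.name != name]

    def set_initial(self, name: str, value: float) -> None:
        idx = self.species_index()[name]
        old = self.species[idx]
        self.species[idx] = SpeciesDef(old.name, float(value), old.is_boundary)

    def set_boundary_levels(self, levels: dict[str, float]) -> "NetworkModel":
        """Copy with boundary species pinned at the given levels."""
        model = self.copy()
        index = model.species_index()
        for name, value in levels.items():
            if name not in index:
                raise KeyError(f"unknown species {name!r}")
            if not model.species[index[name]].is_boundary:
                raise ValueError(f"species {name!r} is not a boundary input")
            model.set_initial(name, value)
        return model


def validate_model(model: NetworkModel) -> list[str]:
    """Check model invariants; returns human-readable violations (empty = valid)."""
    violations: list[str] = []
    seen: set[str] = set()
    for s in model.species:
        if s.name in seen:
            violations.append(f"duplicate species name: {s.name}")
        seen.add(s.name)
        if s.initial_concentration < 0:
            violations.append(
                f"negative initial concentration for species {s.name}: "
                f"{s.initial_concentration}"
            )
    labels: set[str] = set()
    for r in model.reactions:
        if r.label in labels:
            violations.append(f"duplicate reaction label: {r.label}")
        labels.add(r.label)
        for name, stoich in list(r.reactants) + list(r.products):
            if name not in seen:
                violations.append(f"reaction {r.label}: unknown species {name}")
            if not (isinstance(stoich, int) and stoich > 0):
                violations.append(
                    f"reaction {r.label}: stoichiometric coefficient for {name} "
                    f"must be a positive integer, got {stoich!r}"
                )
        for name in list(r.modifiers) + r.rate_law.referenced_species():
            if name not in seen:
                violations.append(f"reaction {r.label}: unknown species {name}")
        if r.rate_law.kind not in RATE_LAW_KINDS:
            violations.append(f"reaction {r.label}: unknown rate-law kind {r.rate_law.kind!r}")
        for pname, value in r.rate_law.parameters.items():
            if not math.isfinite(value) or value < 0:
                violations.append(
                    f"reaction {r.label}: rate constant {pname} must be >= 0, got {value}"
                )
    for e in model.events:
        if e.time < 0:
            violations.append(f"event on {e.species}: negative time {e.time}")
        if e.new_value < 0:
            violations.append(f"event on {e.species}: negative value {e.new_value}")
        if e.species not in seen:
            violations.append(f"event on unknown species {e.species}")
    return violations


@dataclass
class CompiledODE:
    """A model compiled to a vectorised right-hand side.

    ``rhs(t, y, p)`` and ``jac(t, y, p)`` take the state vector in
    ``species_names`` order and the parameter vector in ``param_names``
    order; boundary species rows are identically zero.
    """

    model: NetworkModel
    species_names: list[str]
    param_names: list[str]
    p0: np.ndarray
    rhs: callable
    jac: callable

    def param_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        p = self.p0.copy()
        if overrides:
            index = {name: i for i, name in enumerate(self.param_names)}
            for key, value in overrides.items():
                p[index[key]] = value
        return p


def compile_odes(model: NetworkModel) -> CompiledODE:
    """Compile the network to a derivative function dy/dt = f(t, y, p).

    Each non-boundary species derivative is the stoichiometry-weighted sum of
    its reaction rates; boundary species have zero derivative. The symbolic
    rates are lambdified together with an analytic Jacobian, which keeps the
    stiff integrators fast on the ~25-species pathway models.
    """
    problems = validate_model(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))

    names = model.species_names()
    conc_syms = {name: sp.Symbol(f"y{i}", nonnegative=True) for i, name in enumerate(names)}
    param_names: list[str] = []
    p0: list[float] = []
    dydt = {name: sp.Integer(0) for name in names}
    boundary = {s.name for s in model.species if s.is_boundary}

    for r in model.reactions:
        psyms: dict[str, sp.Symbol] = {}
        for pname, value in r.rate_law.parameters.items():
            flat = f"{r.label}.{pname}"
            psyms[pname] = sp.Symbol(f"p{len(param_names)}")
            param_names.append(flat)
            p0.append(float(value))
        rate = _rate_expr(r.rate_law, conc_syms, psyms)
        for name, stoich in r.reactants:
            dydt[name] = dydt[name] - stoich * rate
        for name, stoich in r.products:
            dydt[name] = dydt[name] + stoich * rate

    exprs = sp.Matrix(
        [sp.Integer(0) if name in boundary else dydt[name] for name in names]
    )
    y_vec = sp.Matrix([conc_syms[name] for name in names])
    p_vec = sp.Matrix([sp.Symbol(f"p{i}") for i in range(len(param_names))])
    jac_exprs = exprs.jacobian(y_vec)

    f = sp.lambdify((y_vec, p_vec), exprs, modules="numpy", cse=True)
    J = sp.lambdify((y_vec, p_vec), jac_exprs, modules="numpy", cse=True)

    n = len(names)

    def rhs(t, y, p):
        return np.asarray(f(y, p), dtype=float).reshape(n)

    def jac(t, y, p):
        return np.asarray(J(y, p), dtype=float).reshape(n, n)

    return CompiledODE(
        model=model,
        species_names=names,
        param_names=param_names,
        p0=np.array(p0, dtype=float),
        rhs=rhs,
        jac=jac,
    )
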