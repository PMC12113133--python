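"""Stage 3: mass-action ODE generation, parameter assignment and simulation.

Every reaction contributes the elementary rate

    v = k · Π reactant_concᵉˣᵖ · Π modifier_conc

to the derivative of each participant weighted by its net stoichiometry.
Gene species are boundary species with identically zero derivative: the model
assumes genes are present at a sufficient, constant concentration, so a
gene's initial concentration acts as a knob (this is what the perturbation
scenarios move).  Units are µM and hours throughout.

The default time grid mirrors the study design: 150 output intervals of
0.28 h each (42 h total), with the first 85 intervals (~24 h) mapped onto one
mammalian cell cycle.  Integration uses a stiff-capable implicit solver
(LSODA) with rtol 1e−6 / atol 1e−9; steady state is declared at the first
output interval where every non-phenotype species satisfies
|dC/dt| / max(C, floor) < criterion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .model_schema import (
    NetworkModel,
    Reaction,
    ReactionType,
    SpeciesKind,
    Plk1NetError,
)

__all__ = [
    "ParameterSource",
    "ParameterTable",
    "InitialConditionPolicy",
    "SimulationSettings",
    "Trajectory",
    "SteadyStateReport",
    "SolverError",
    "ParameterError",
    "assign_parameters",
    "build_rate_law",
    "assemble_odes",
    "initial_state",
    "simulate",
    "detect_steady_state",
]


class SolverError(Plk1NetError):
    """Numerical integration failed; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class ParameterError(Plk1NetError):
    pass


class ParameterSource(enum.Enum):
    CURATED = "CURATED"
    DEFAULT_BY_TYPE = "DEFAULT_BY_TYPE"


@dataclass
class ParameterTable:
    """Rate constant per reaction with its provenance flag."""

    entries: dict[str, tuple[float, ParameterSource]] = field(default_factory=dict)

    def k(self, reaction_id: str) -> float:
        return self.entries[reaction_id][0]

    def __len__(self) -> int:
        return len(self.entries)

    def n_curated(self) -> int:
        return sum(1 for _, src in self.entries.values()
                   if src is ParameterSource.CURATED)


@dataclass
class InitialConditionPolicy:
    """Initial concentrations (µM): genes at a homogeneous basal 1.0, proteins
    declared free-form at 5.0, everything else starts empty; ``overrides``
    take precedence over all rules."""

    gene_ic: float = 1.0
    free_protein_ic: float = 5.0
    default_ic: float = 0.0
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.gene_ic, self.free_protein_ic, self.default_ic,
                  *self.overrides.values()):
            if v < 0:
                raise Plk1NetError(f"negative initial concentration {v}")

    def ic_for(self, kind: SpeciesKind, free_form: bool, species_id: str) -> float:
        if species_id in self.overrides:
            return self.overrides[species_id]
        if kind is SpeciesKind.GENE:
            return self.gene_ic
        if free_form and kind in (SpeciesKind.PROTEIN, SpeciesKind.COMPLEX):
            return self.free_protein_ic
        return self.default_ic


@dataclass
class SimulationSettings:
    n_intervals: int = 150
    interval_hours: float = 0.28
    integration_steps_per_interval: int = 100
    cell_cycle_intervals: int = 85
    absolute_tolerance: float = 1e-9
    relative_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_intervals < self.cell_cycle_intervals:
            raise Plk1NetError(
                "n_intervals must cover the cell-cycle interval count"
            )
        if self.interval_hours <= 0:
            raise Plk1NetError("interval_hours must be positive")

    @property
    def horizon_hours(self) -> float:
        return self.n_intervals * self.interval_hours

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon_hours, self.n_intervals + 1)


@dataclass
class Trajectory:
    """Concentrations on the output grid: ``concentrations[i, j]`` is species
    ``species_ids[j]`` at ``times[i]`` (µM)."""

    times: np.ndarray
    concentrations: np.ndarray
    species_ids: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)

    def index(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    def series(self, species_id: str) -> np.ndarray:
        return self.concentrations[:, self.index(species_id)]

    def at_interval(self, interval: int) -> np.ndarray:
        """State vector at the given output interval (0 = initial state)."""
        return self.concentrations[interval]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.concentrations, index=self.times,
                            columns=self.species_ids).rename_axis("time_h")


@dataclass
class SteadyStateReport:
    reached: bool
    first_interval: int | None
    first_time_h: float | None
    residual: float


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def assign_parameters(
    model: NetworkModel,
    curated: Mapping[str, float] | None = None,
    defaults: Mapping[ReactionType, float] | None = None,
) -> ParameterTable:
    """Give every reaction a rate constant: curated values win, everything
    else falls back to its reaction-type default."""
    from .network_construction import DEFAULT_RATE_CONSTANTS

    curated = dict(curated or {})
    defaults = dict(defaults or DEFAULT_RATE_CONSTANTS)
    missing_types = [t for t in ReactionType if t not in defaults]
    if missing_types:
        raise ParameterError(
            f"defaults missing for reaction types: "
            f"{[t.value for t in missing_types]}"
        )
    for rid, k in curated.items():
        if not k > 0:
            raise ParameterError(f"curated k for reaction {rid} must be "
                                 f"positive, got {k}")
    table = ParameterTable()
    for rx in model.reactions.values():
        if rx.id in curated:
            table.entries[rx.id] = (float(curated[rx.id]),
                                    ParameterSource.CURATED)
        else:
            table.entries[rx.id] = (float(defaults[rx.rtype]),
                                    ParameterSource.DEFAULT_BY_TYPE)
    return table


def parameters_from_model(model: NetworkModel) -> ParameterTable:
    """Treat the rate constants stored on the model's reactions as curated."""
    return ParameterTable(entries={
        rx.id: (rx.k, ParameterSource.CURATED)
        for rx in model.reactions.values()
    })


# ---------------------------------------------------------------------------
# rate laws and the ODE right-hand side
# ---------------------------------------------------------------------------

def build_rate_law(
    reaction: Reaction,
    k: float,
    species_index: Mapping[str, int] | None = None,
) -> Callable[[Mapping[str, float] | np.ndarray], float]:
    """Return the mass-action velocity function of one reaction.

    With ``species_index`` given, the returned callable takes a state vector;
    otherwise it takes a mapping from species id to concentration.  Synthesis
    reactions (transcription, translation, direct synthesis) have no
    reactants, so their velocity is zero-order apart from the modifier
    concentrations.
    """
    if not k > 0:
        raise ParameterError(f"rate constant must be positive, got {k}")
    if species_index is None:
        def law(conc: Mapping[str, float]) -> float:
            v = k
            for sid, stoich in reaction.reactants:
                v *= conc[sid] ** stoich
            for sid in reaction.modifiers:
                v *= conc[sid]
            return v
        return law

    r_idx = np.array([species_index[s] for s, _ in reaction.reactants], dtype=int)
    r_exp = np.array([n for _, n in reaction.reactants], dtype=float)
    m_idx = np.array([species_index[s] for s in reaction.modifiers], dtype=int)

    def law_vec(state: np.ndarray) -> float:
        v = k
        if r_idx.size:
            v *= float(np.prod(state[r_idx] ** r_exp))
        if m_idx.size:
            v *= float(np.prod(state[m_idx]))
        return v

    return law_vec


def assemble_odes(
    model: NetworkModel,
    params: ParameterTable,
) -> tuple[Callable[[float, np.ndarray], np.ndarray], list[str]]:
    """Compile the model into an ODE right-hand side.

    Returns ``(rhs, species_ids)`` where ``species_ids`` fixes the state
    ordering (model insertion order) and ``rhs(t, y)`` evaluates dC/dt.  Gene
    rows are forced to zero: genes are constant boundary species.
    """
    species_ids = list(model.species.keys())
    index = {sid: i for i, sid in enumerate(species_ids)}
    n_sp = len(species_ids)
    gene_mask = np.array(
        [model.species[sid].kind is SpeciesKind.GENE for sid in species_ids]
    )

    # per-reaction sparse structure
    ks = []
    r_idx, r_exp, m_idx, net_idx, net_coef = [], [], [], [], []
    for rx in model.reactions.values():
        ks.append(params.k(rx.id))
        r_idx.append(np.array([index[s] for s, _ in rx.reactants], dtype=int))
        r_exp.append(np.array([n for _, n in rx.reactants], dtype=float))
        m_idx.append(np.array([index[s] for s in rx.modifiers], dtype=int))
        net: dict[int, float] = {}
        for s, n in rx.reactants:
            net[index[s]] = net.get(index[s], 0.0) - n
        for s, n in rx.products:
            net[index[s]] = net.get(index[s], 0.0) + n
        items = sorted(net.items())
        net_idx.append(np.array([i for i, _ in items], dtype=int))
        net_coef.append(np.array([c for _, c in items], dtype=float))
    ks_arr = np.array(ks, dtype=float)
    n_rx = len(ks)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n_sp)
        for j in range(n_rx):
            v = ks_arr[j]
            ri = r_idx[j]
            if ri.size:
                v *= np.prod(y[ri] ** r_exp[j])
            mi = m_idx[j]
            if mi.size:
                v *= np.prod(y[mi])
            dy[net_idx[j]] += net_coef[j] * v
        dy[gene_mask] = 0.0
        return dy

    return rhs, species_ids


def initial_state(
    model: NetworkModel,
    ic_policy: InitialConditionPolicy,
    species_ids: list[str] | None = None,
) -> np.ndarray:
    species_ids = species_ids or list(model.species.keys())
    return np.array([
        ic_policy.ic_for(model.species[sid].kind,
                         model.species[sid].free_form, sid)
        for sid in species_ids
    ])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    model: NetworkModel,
    params: ParameterTable | None = None,
    ic_policy: InitialConditionPolicy | None = None,
    settings: SimulationSettings | None = None,
) -> Trajectory:
    """Integrate the model deterministically and sample interval boundaries.

    Uses LSODA (switches to a stiff BDF scheme automatically).  Output
    concentrations within absolute tolerance of zero are clipped to zero, so
    integrator wobble never reports negative amounts.
    """
    params = params or parameters_from_model(model)
    ic_policy = ic_policy or InitialConditionPolicy()
    settings = settings or SimulationSettings()
    rhs, species_ids = assemble_odes(model, params)
    y0 = initial_state(model, ic_policy, species_ids)
    sol = solve_ivp(
        rhs,
        (0.0, settings.horizon_hours),
        y0,
        method="LSODA",
        t_eval=settings.times,
        rtol=settings.relative_tolerance,
        atol=settings.absolute_tolerance,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SolverError(f"integration failed: {sol.message}", last)
    conc = sol.y.T.copy()
    conc[np.abs(conc) <= settings.absolute_tolerance * 10] = 0.0
    np.clip(conc, 0.0, None, out=conc)
    return Trajectory(times=sol.t, concentrations=conc, species_ids=species_ids)


def detect_steady_state(
    traj: Trajectory,
    rhs: Callable[[float, np.ndarray], np.ndarray],
    criterion: float = 1e-3,
    floor: float = 1e-6,
    phenotype_mask: np.ndarray | None = None,
) -> SteadyStateReport:
    """Find the first output interval at which the system is stationary.

    The per-species residual at interval *i* is |dC/dt| / max(C, floor) in
    h⁻¹; steady state holds when its maximum over non-phenotype species drops
    below ``criterion``.  Phenotype species accumulate by design and are
    excluded via ``phenotype_mask`` (True = exclude).
    """
    n_t = len(traj.times)
    if n_t < 3:
        raise Plk1NetError("trajectory must cover at least 2 intervals")
    include = np.ones(len(traj.species_ids), dtype=bool)
    if phenotype_mask is not None:
        include &= ~np.asarray(phenotype_mask, dtype=bool)
    first = None
    residual = np.inf
    for i in range(1, n_t):
        y = traj.concentrations[i]
        dy = rhs(traj.times[i], y)
        norm = np.abs(dy[include]) / np.maximum(y[include], floor)
        residual = float(norm.max()) if norm.size else 0.0
        if residual < criterion and first is None:
            first = i
    return SteadyStateReport(
        reached=first is not None,
        first_interval=first,
        first_time_h=float(traj.times[first]) if first is not None else None,
        residual=residual,
    )


def phenotype_mask_for(model: NetworkModel, species_ids: list[str]) -> np.ndarray:
    return np.array([
        model.species[sid].kind is SpeciesKind.PHENOTYPE for sid in species_ids
    ])
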