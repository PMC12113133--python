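"""Stage 4: perturbation scenarios, affected-species detection and synergy.

A scenario rescales the initial concentration of one or more gene (or
lumped complex-gene) species and re-runs the simulation with identical
solver settings.  The default grid follows the study design: the three hub
targets *cdk1*, *plk1* and *cohesin* plus their joint triple, each at
0.01×, 0.1×, 10× and 100× of the 1.0 µM basal gene concentration —
16 scenarios, named Sce1…Sce16 in that fixed order.

A species counts as *affected* by a scenario when, at the evaluation
interval (default: interval 85, the cell-cycle endpoint), its |log2 ratio|
versus baseline reaches the fold threshold, or its time-averaged absolute
relative deviation over the whole horizon reaches the deviation threshold.
Perturbed species themselves (and the gene knobs) are excluded.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mass_action_engine import (
    InitialConditionPolicy,
    ParameterTable,
    SimulationSettings,
    Trajectory,
    parameters_from_model,
    simulate,
)
from .model_schema import NetworkModel, Plk1NetError, SpeciesKind

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "AffectedConfig",
    "AffectedSpecies",
    "AffectedSpeciesReport",
    "ProcessImpact",
    "SynergyVerdict",
    "SynergyReport",
    "ConfigurationError",
    "DEFAULT_SCENARIO_FACTORS",
    "build_scenario_grid",
    "default_scenario_grid",
    "run_scenarios",
    "affected_species",
    "aggregate_by_process",
    "directional_synergy",
]


class ConfigurationError(Plk1NetError):
    pass


DEFAULT_SCENARIO_FACTORS = (0.01, 0.1, 10.0, 100.0)


@dataclass(frozen=True)
class Scenario:
    """Named set of initial-concentration overrides (µM)."""

    name: str
    ic_overrides: Mapping[str, float] = field(default_factory=dict)


@dataclass
class AffectedConfig:
    """Thresholds of the affected-species rule.

    ``log2_threshold`` applies to the endpoint log2 ratio (default log2 1.5);
    ``deviation_threshold`` to the time-averaged absolute relative deviation;
    ``evaluation_interval`` is the output interval compared (cell-cycle end).
    ``epsilon`` regularises ratios of near-zero concentrations.
    """

    log2_threshold: float = float(np.log2(1.5))
    deviation_threshold: float = 0.2
    evaluation_interval: int = 85
    epsilon: float = 1e-9


@dataclass(frozen=True)
class AffectedSpecies:
    species_id: str
    log2_ratio: float
    avg_relative_deviation: float
    affected: bool


@dataclass
class AffectedSpeciesReport:
    scenario: str
    evaluation_time_h: float
    effects: list[AffectedSpecies]

    @property
    def affected_ids(self) -> list[str]:
        return [e.species_id for e in self.effects if e.affected]

    def effect_of(self, species_id: str) -> AffectedSpecies:
        for e in self.effects:
            if e.species_id == species_id:
                return e
        raise KeyError(species_id)


@dataclass
class ProcessImpact:
    """Per-process tally of affected members, ranked by fraction affected
    (ties by count, then name)."""

    rows: list[tuple[str, int, float]]  # (process, n affected, fraction)


class SynergyVerdict(enum.Enum):
    NONE = "NONE"
    ONE_WAY_A_TO_B = "ONE_WAY_A_TO_B"
    ONE_WAY_B_TO_A = "ONE_WAY_B_TO_A"
    TWO_WAY = "TWO_WAY"


@dataclass
class SynergyReport:
    pair: tuple[str, str]
    forward_effect: float  # perturb A, |log2 effect| on B's readout
    reverse_effect: float
    forward_affected: bool
    reverse_affected: bool
    verdict: SynergyVerdict


# ---------------------------------------------------------------------------
# scenario grid
# ---------------------------------------------------------------------------

def build_scenario_grid(
    model: NetworkModel,
    targets: Sequence[Sequence[str]],
    factors: Sequence[float] = DEFAULT_SCENARIO_FACTORS,
    base_ic: float = 1.0,
) -> list[Scenario]:
    """One scenario per (target group × factor), named Sce1…SceN in grid
    order (groups outer, factors inner).  A joint group overrides every one
    of its members simultaneously at ``base_ic × factor``."""
    if any(f <= 0 for f in factors):
        raise ConfigurationError("scenario factors must be positive")
    for group in targets:
        for sid in group:
            if sid not in model.species:
                raise ConfigurationError(
                    f"scenario target species {sid!r} not in model"
                )
    scenarios = []
    n = 0
    for group in targets:
        for f in factors:
            n += 1
            scenarios.append(Scenario(
                name=f"Sce{n}",
                ic_overrides={sid: base_ic * f for sid in group},
            ))
    return scenarios


def default_scenario_grid(
    model: NetworkModel,
    cdk1: str,
    plk1: str,
    cohesin: str,
    factors: Sequence[float] = DEFAULT_SCENARIO_FACTORS,
    base_ic: float = 1.0,
) -> list[Scenario]:
    """The 16-scenario study grid over the three hub knobs and their joint
    triple."""
    return build_scenario_grid(
        model,
        targets=[[cdk1], [plk1], [cohesin], [cdk1, plk1, cohesin]],
        factors=factors,
        base_ic=base_ic,
    )


def run_scenarios(
    model: NetworkModel,
    params: ParameterTable | None = None,
    ic_policy: InitialConditionPolicy | None = None,
    settings: SimulationSettings | None = None,
    scenarios: Sequence[Scenario] = (),
) -> dict[str, Trajectory]:
    """Simulate the baseline plus every scenario with identical settings.

    The returned mapping always contains ``"baseline"``.  A scenario whose
    integration fails is recorded (logged) and skipped; the rest continue.
    """
    params = params or parameters_from_model(model)
    ic_policy = ic_policy or InitialConditionPolicy()
    settings = settings or SimulationSettings()
    out: dict[str, Trajectory] = {
        "baseline": simulate(model, params, ic_policy, settings)
    }
    for sce in scenarios:
        policy = InitialConditionPolicy(
            gene_ic=ic_policy.gene_ic,
            free_protein_ic=ic_policy.free_protein_ic,
            default_ic=ic_policy.default_ic,
            overrides={**ic_policy.overrides, **sce.ic_overrides},
        )
        try:
            out[sce.name] = simulate(model, params, policy, settings)
        except Plk1NetError as exc:
            logger.error("scenario %s failed: %s", sce.name, exc)
    return out


# ---------------------------------------------------------------------------
# baseline differencing
# ---------------------------------------------------------------------------

def affected_species(
    baseline: Trajectory,
    scenario: Trajectory,
    config: AffectedConfig | None = None,
    scenario_name: str = "scenario",
    exclude: Sequence[str] = (),
) -> AffectedSpeciesReport:
    """Compare a scenario trajectory against baseline and flag affected
    species.  ``exclude`` lists the perturbed species (and their knobs),
    which never appear in the report.  Effects are ordered by descending
    |log2 ratio|, ties by species id."""
    config = config or AffectedConfig()
    if baseline.species_ids != scenario.species_ids or not np.array_equal(
        baseline.times, scenario.times
    ):
        raise Plk1NetError("baseline and scenario grids do not match")
    i_eval = config.evaluation_interval
    if i_eval >= len(baseline.times):
        raise Plk1NetError(
            f"evaluation interval {i_eval} outside trajectory "
            f"({len(baseline.times) - 1} intervals)"
        )
    eps = config.epsilon
    base_end = baseline.concentrations[i_eval]
    sce_end = scenario.concentrations[i_eval]
    log2_ratio = np.log2((sce_end + eps) / (base_end + eps))
    denom = np.maximum(baseline.concentrations, eps)
    avg_dev = np.mean(
        np.abs(scenario.concentrations - baseline.concentrations) / denom,
        axis=0,
    )
    excluded = set(exclude)
    effects = []
    for j, sid in enumerate(baseline.species_ids):
        if sid in excluded:
            continue
        flag = (
            abs(log2_ratio[j]) >= config.log2_threshold
            or avg_dev[j] >= config.deviation_threshold
        )
        effects.append(AffectedSpecies(
            species_id=sid,
            log2_ratio=float(log2_ratio[j]),
            avg_relative_deviation=float(avg_dev[j]),
            affected=bool(flag),
        ))
    effects.sort(key=lambda e: (-abs(e.log2_ratio), e.species_id))
    return AffectedSpeciesReport(
        scenario=scenario_name,
        evaluation_time_h=float(baseline.times[i_eval]),
        effects=effects,
    )


def aggregate_by_process(
    report: AffectedSpeciesReport,
    model: NetworkModel,
) -> ProcessImpact:
    """Roll affected species up to the biological-process level.

    A species belonging to several processes counts toward each of them.
    Rows are ranked by fraction affected, then count, then name.
    """
    affected = set(report.affected_ids)
    rows = []
    for proc in model.processes.values():
        members = proc.members or {
            s.id for s in model.species.values() if proc.name in s.processes
        }
        if not members:
            continue
        n_aff = sum(1 for sid in members if sid in affected)
        rows.append((proc.name, n_aff, n_aff / len(members)))
    rows.sort(key=lambda r: (-r[2], -r[1], r[0]))
    return ProcessImpact(rows=rows)


# ---------------------------------------------------------------------------
# directional synergy
# ---------------------------------------------------------------------------

def directional_synergy(
    model: NetworkModel,
    params: ParameterTable | None,
    ic_policy: InitialConditionPolicy | None,
    settings: SimulationSettings | None,
    gene_a: str,
    gene_b: str,
    readout_a: str,
    readout_b: str,
    factor: float = 100.0,
    config: AffectedConfig | None = None,
) -> SynergyReport:
    """Test whether perturbing A moves B's protein readout and vice versa.

    Forward: multiply ``gene_a``'s initial concentration by ``factor`` and
    measure the |log2 effect| on ``readout_b`` at the evaluation interval;
    reverse swaps the roles.  The verdict thresholds both directions with
    the affected-species rule, yielding NONE / one-way / TWO_WAY.
    """
    params = params or parameters_from_model(model)
    ic_policy = ic_policy or InitialConditionPolicy()
    settings = settings or SimulationSettings()
    config = config or AffectedConfig()
    for sid in (gene_a, gene_b, readout_a, readout_b):
        if sid not in model.species:
            raise ConfigurationError(f"species {sid!r} not in model")

    base_a = ic_policy.ic_for(model.species[gene_a].kind,
                              model.species[gene_a].free_form, gene_a)
    base_b = ic_policy.ic_for(model.species[gene_b].kind,
                              model.species[gene_b].free_form, gene_b)
    scenarios = [
        Scenario(name="__fwd", ic_overrides={gene_a: base_a * factor}),
        Scenario(name="__rev", ic_overrides={gene_b: base_b * factor}),
    ]
    trajs = run_scenarios(model, params, ic_policy, settings, scenarios)
    fwd = affected_species(trajs["baseline"], trajs["__fwd"], config,
                           "__fwd", exclude=(gene_a,))
    rev = affected_species(trajs["baseline"], trajs["__rev"], config,
                           "__rev", exclude=(gene_b,))
    f_eff = fwd.effect_of(readout_b)
    r_eff = rev.effect_of(readout_a)
    if f_eff.affected and r_eff.affected:
        verdict = SynergyVerdict.TWO_WAY
    elif f_eff.affected:
        verdict = SynergyVerdict.ONE_WAY_A_TO_B
    elif r_eff.affected:
        verdict = SynergyVerdict.ONE_WAY_B_TO_A
    else:
        verdict = SynergyVerdict.NONE
    return SynergyReport(
        pair=(gene_a, gene_b),
        forward_effect=abs(f_eff.log2_ratio),
        reverse_effect=abs(r_eff.log2_ratio),
        forward_affected=f_eff.affected,
        reverse_affected=r_eff.affected,
        verdict=verdict,
    )
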