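"""Synthetic inputs for every pipeline stage, plus hand-coded circuit fixtures.

The generators emulate the structural features of the curated data the
pipeline assumes — multi-process interaction networks with hub species and
cross-process member overlap, log-uniform kinetic constants, Bernoulli
expression calls at high expression probability (with planted low-expression
genes standing in for histone genes invisible to poly-A RNA-seq), and
two-cluster log2 fold-change structure with additive Gaussian noise.  Every
generator is a pure function of its seed and spec, and each one draws from an
independent substream keyed by (seed, generator name), so adding a generator
never perturbs the output of another.

The circuit fixtures are small, literature-shaped reaction models of the
three PLK1 genomic-instability circuits — the chromosomal passenger complex
(CPC), the mitotic checkpoint complex (MCC) and the anaphase-promoting
complex / separase axis (APCC) — plus a minimal two-gene cascade and a
merged demo network.  Their rate constants stay within [0.1, 5] of the
natural unit for each reaction type so each fixture settles well inside the
85-interval cell-cycle window.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_delimitation import ExpressionCallMatrix
from .circuit_expression import CircuitDefinition, Log2FCMatrix
from .mass_action_engine import ParameterTable, assign_parameters, parameters_from_model
from .model_schema import (
    InteractionClass,
    InteractionRecord,
    Mechanism,
    NetworkModel,
    ProcessCategory,
    ProcessDefinition,
    ReactionType,
    Sign,
    Plk1NetError,
    canonical_species_id,
    SpeciesKind,
)
from .network_construction import ConstructionPolicy, build_network

__all__ = [
    "GenerationError",
    "NetworkGenSpec",
    "ParamGenSpec",
    "generate_network",
    "generate_parameters",
    "generate_expression_calls",
    "generate_log2fc",
    "circuit_fixture",
    "FIXTURE_NAMES",
]


class GenerationError(Plk1NetError):
    pass


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent substream per (seed, generator name)."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]
    )


# ---------------------------------------------------------------------------
# interaction-network generator
# ---------------------------------------------------------------------------

@dataclass
class NetworkGenSpec:
    """Shape of a synthetic curated network.

    ``overlap_fraction`` is the fraction of each process's membership shared
    with its neighbouring process; hubs receive extra edges until their
    degree reaches ``hub_degree_multiplier`` times the median non-hub degree;
    ``modification_fraction`` of protein–protein edges carry an enzymatic
    mechanism (phosphorylation/ubiquitination/acetylation) instead of a bare
    signed influence.
    """

    n_proteins: int = 40
    n_complexes: int = 3
    n_processes: int = 4
    overlap_fraction: float = 0.25
    n_hubs: int = 2
    hub_degree_multiplier: float = 4.0
    modification_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_complexes", "n_processes", "n_hubs"):
            if getattr(self, name) < 1:
                raise GenerationError(f"{name} must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise GenerationError("overlap_fraction must be in [0, 1]")
        if self.n_proteins < self.n_processes:
            raise GenerationError("need at least one protein per process")


def generate_network(
    spec: NetworkGenSpec,
) -> tuple[list[InteractionRecord], list[ProcessDefinition], dict]:
    """Draw a synthetic curated interaction set with known ground truth.

    Returns ``(records, process definitions, truth)`` where ``truth`` holds
    the designated hub names and the per-process protein memberships used to
    lay out the edges.
    """
    rng = _rng(spec.seed, "network")
    proteins = [f"P{i:03d}" for i in range(1, spec.n_proteins + 1)]
    hubs = proteins[: spec.n_hubs]
    processes = [f"Process {chr(65 + i)}" for i in range(spec.n_processes)]

    # contiguous membership blocks with the requested neighbour overlap
    block = max(2, spec.n_proteins // spec.n_processes)
    shift = max(1, int(round(block * (1.0 - spec.overlap_fraction))))
    memberships: dict[str, list[str]] = {}
    for pi, proc in enumerate(processes):
        start = (pi * shift) % spec.n_proteins
        members = [proteins[(start + j) % spec.n_proteins] for j in range(block)]
        for hub in hubs:  # hubs belong to every process
            if hub not in members:
                members.append(hub)
        memberships[proc] = members
    achieved_overlap = (
        len(set(memberships[processes[0]]) & set(memberships[processes[-1]]))
        if spec.n_processes > 1 else block
    )
    if spec.n_processes > 1 and spec.overlap_fraction > 0 and achieved_overlap == 0:
        raise GenerationError("requested overlap not achievable with these sizes")

    records: list[InteractionRecord] = []
    degree: dict[str, int] = {p: 0 for p in proteins}
    mechanisms = [Mechanism.PHOSPHORYLATION, Mechanism.UBIQUITINATION,
                  Mechanism.ACETYLATION]

    def add_edge(a: str, b: str, proc: str) -> None:
        if rng.random() < spec.modification_fraction:
            mech = mechanisms[int(rng.integers(len(mechanisms)))]
            sign = Sign.POSITIVE
        else:
            mech = None
            sign = Sign.POSITIVE if rng.random() < 0.7 else Sign.NEGATIVE
        records.append(InteractionRecord(
            source=a, target=b, iclass=InteractionClass.PROTEIN_PROTEIN,
            sign=sign, mechanism=mech, process=proc,
            provenance="synthetic",
        ))
        degree[a] += 1
        degree[b] += 1

    for proc in processes:
        members = memberships[proc]
        n_edges = 2 * len(members)
        for _ in range(n_edges):
            a, b = rng.choice(len(members), size=2, replace=False)
            add_edge(members[a], members[b], proc)
        # one phenotype edge per process
        src = members[int(rng.integers(len(members)))]
        records.append(InteractionRecord(
            source=src, target=f"{proc} outcome",
            iclass=InteractionClass.PROTEIN_PROCESS,
            sign=Sign.POSITIVE, mechanism=None, process=proc,
            provenance="synthetic",
        ))
        degree[src] += 1

    # complexes: 3 random subunits each, bound within a random process
    for ci in range(spec.n_complexes):
        proc = processes[ci % spec.n_processes]
        members = memberships[proc]
        subs = rng.choice(len(members), size=min(3, len(members)), replace=False)
        for si in subs:
            records.append(InteractionRecord(
                source=members[si], target=f"CX{ci + 1}",
                iclass=InteractionClass.PROTEIN_COMPLEX,
                sign=Sign.UNSIGNED, mechanism=Mechanism.BINDING,
                process=proc, provenance="synthetic",
            ))
            degree[members[si]] += 1

    # top hubs up: add edges until each hub clears the degree target
    non_hub = [degree[p] for p in proteins[spec.n_hubs:]]
    target = spec.hub_degree_multiplier * float(np.median(non_hub))
    for hub in hubs:
        while degree[hub] < target:
            proc = processes[int(rng.integers(len(processes)))]
            members = [m for m in memberships[proc] if m != hub]
            add_edge(hub, members[int(rng.integers(len(members)))], proc)

    defs = []
    for proc in processes:
        n_rec = sum(1 for r in records if r.process == proc)
        member_ids = {
            canonical_species_id(m, SpeciesKind.PROTEIN)
            for m in memberships[proc]
        }
        defs.append(ProcessDefinition(
            name=proc, category=ProcessCategory.CELL_PROCESS,
            species_count=len(member_ids), interaction_count=n_rec,
            members=member_ids,
        ))
    truth = {"hubs": list(hubs), "memberships": memberships}
    return records, defs, truth


# ---------------------------------------------------------------------------
# kinetic-parameter generator
# ---------------------------------------------------------------------------

@dataclass
class ParamGenSpec:
    """Log-uniform sampling range per reaction type (min, max, both > 0)."""

    ranges: dict[ReactionType, tuple[float, float]] = field(
        default_factory=lambda: {t: (0.1, 10.0) for t in ReactionType}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for t, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise GenerationError(
                    f"invalid range for {t.value}: ({lo}, {hi})"
                )


def generate_parameters(model: NetworkModel, spec: ParamGenSpec) -> ParameterTable:
    """Draw every reaction's rate constant log-uniformly from its type range."""
    rng = _rng(spec.seed, "parameters")
    from .mass_action_engine import ParameterSource

    table = ParameterTable()
    for rx in model.reactions.values():
        lo, hi = spec.ranges[rx.rtype]
        k = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        table.entries[rx.id] = (k, ParameterSource.DEFAULT_BY_TYPE)
    return table


# ---------------------------------------------------------------------------
# expression-call generator
# ---------------------------------------------------------------------------

def generate_expression_calls(
    n_genes: int,
    n_cancers: int,
    p_expressed: float = 0.9,
    planted_low_genes: Sequence[str] | int = 0,
    seed: int = 0,
) -> ExpressionCallMatrix:
    """Bernoulli(p) expression calls with planted low-expression genes.

    Planted genes (named explicitly or the first *n* generated genes) are
    called expressed at p/10, emulating gene families that real expression
    assays systematically miss.
    """
    if not 0.0 <= p_expressed <= 1.0:
        raise GenerationError("p_expressed must lie in [0, 1]")
    rng = _rng(seed, "expression")
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    if isinstance(planted_low_genes, int):
        planted = set(genes[:planted_low_genes])
    else:
        planted = set(planted_low_genes)
    calls = np.empty((n_genes, n_cancers), dtype=bool)
    for i, g in enumerate(genes):
        p = p_expressed / 10.0 if g in planted else p_expressed
        calls[i] = rng.random(n_cancers) < p
    cancers = [f"C{j:02d}" for j in range(1, n_cancers + 1)]
    return ExpressionCallMatrix(genes=genes, cancers=cancers, calls=calls)


# ---------------------------------------------------------------------------
# log2 fold-change generator
# ---------------------------------------------------------------------------

def generate_log2fc(
    n_cancers: int,
    circuits: Sequence[CircuitDefinition],
    cluster2_effect: float = 2.0,
    noise_sd: float = 0.3,
    mixed_genes: Sequence[str] = (),
    seed: int = 0,
) -> tuple[Log2FCMatrix, dict[str, int]]:
    """Two-cluster log2FC structure with additive Gaussian noise.

    A random half of the cancer types forms cluster 2 and receives
    ``+cluster2_effect`` on every circuit gene; ``mixed_genes`` get the
    effect sign-flipped there instead, emulating heterogeneously deregulated
    genes.  Returns the matrix and the true per-cancer labels (1 or 2).
    """
    if noise_sd < 0:
        raise GenerationError("noise_sd must be non-negative")
    rng = _rng(seed, "log2fc")
    genes: list[str] = []
    for c in circuits:
        for g in c.genes:
            if g not in genes:
                genes.append(g)
    cancers = [f"C{j:02d}" for j in range(1, n_cancers + 1)]
    labels_vec = np.ones(n_cancers, dtype=int)
    cluster2 = rng.choice(n_cancers, size=n_cancers // 2, replace=False)
    labels_vec[cluster2] = 2
    values = rng.normal(0.0, noise_sd, size=(n_cancers, len(genes)))
    mixed = set(mixed_genes)
    for gi, g in enumerate(genes):
        effect = -cluster2_effect if g in mixed else cluster2_effect
        values[labels_vec == 2, gi] += effect
    matrix = Log2FCMatrix(cancers=cancers, genes=genes, values=values)
    return matrix, {c: int(l) for c, l in zip(cancers, labels_vec)}


# ---------------------------------------------------------------------------
# circuit fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("CPC", "MCC", "APCC", "CASCADE2", "FULL_DEMO")

_PP = InteractionClass.PROTEIN_PROTEIN
_PC = InteractionClass.PROTEIN_COMPLEX
_PPROC = InteractionClass.PROTEIN_PROCESS


def _rec(source, target, iclass, sign=Sign.POSITIVE, mech=None, process=""):
    return InteractionRecord(source=source, target=target, iclass=iclass,
                             sign=sign, mechanism=mech, process=process,
                             provenance="fixture")


def _cpc_records() -> list[InteractionRecord]:
    proc = "Spindle Assembly"
    return [
        _rec("AURKB", "CPC", _PC, Sign.UNSIGNED, Mechanism.BINDING, proc),
        _rec("INCENP", "CPC", _PC, Sign.UNSIGNED, Mechanism.BINDING, proc),
        _rec("BIRC5", "CPC", _PC, Sign.UNSIGNED, Mechanism.BINDING, proc),
        _rec("CDCA8", "CPC", _PC, Sign.UNSIGNED, Mechanism.BINDING, proc),
        _rec("PLK1", "BIRC5", _PP, Sign.POSITIVE,
             Mechanism.PHOSPHORYLATION, proc),
        _rec("PP1", "BIRC5", _PP, Sign.NEGATIVE,
             Mechanism.DEPHOSPHORYLATION, proc),
        _rec("PLK1", "FOXM1", _PP, Sign.POSITIVE,
             Mechanism.EXPRESSION_REGULATION, proc),
        _rec("FOXM1", "AURKB", _PP, Sign.POSITIVE,
             Mechanism.EXPRESSION_REGULATION, proc),
        _rec("AURKB", "Spindle Assembly Checkpoint Surveillance", _PPROC,
             Sign.POSITIVE, None, proc),
    ]


def _mcc_records() -> list[InteractionRecord]:
    proc = "Kinetochore Assembly"
    recs = [
        _rec(sub, "MCC", _PC, Sign.UNSIGNED, Mechanism.BINDING, proc)
        for sub in ("BUB1B", "BUB3", "CDC20", "MAD2")
    ]
    recs += [
        _rec("FBXO5", "APC/C", _PC, Sign.NEGATIVE, None, proc),
        _rec("MCC", "APC/C", _PC, Sign.NEGATIVE, None, proc),
        _rec("PLK1", "BUB1B", _PP, Sign.POSITIVE,
             Mechanism.PHOSPHORYLATION, proc),
        _rec("PLK1", "KIF2C", _PP, Sign.POSITIVE,
             Mechanism.PHOSPHORYLATION, proc),
        _rec("PLK1", "CDC20", _PP, Sign.POSITIVE,
             Mechanism.PHOSPHORYLATION, proc),
        _rec("CENPE", "Chromosome-Microtubule Attachment", _PPROC,
             Sign.POSITIVE, None, proc),
        _rec("KIF2C", "Chromosome-Microtubule Attachment", _PPROC,
             Sign.POSITIVE, None, proc),
        _rec("KNL1", "Kinetochore Platform Assembly", _PPROC,
             Sign.POSITIVE, None, proc),
        _rec("ZWINT", "Kinetochore Platform Assembly", _PPROC,
             Sign.POSITIVE, None, proc),
    ]
    return recs


def _apcc_records() -> list[InteractionRecord]:
    proc = "Sister Chromatid Cohesion"
    return [
        _rec("FBXO5", "APC/C", _PC, Sign.NEGATIVE, None, proc),
        _rec("PLK1", "FBXO5", _PP, Sign.POSITIVE,
             Mechanism.PHOSPHORYLATION, proc),
        _rec("PLK1", "FBXO5", _PP, Sign.NEGATIVE, None, proc),
        _rec("APC/C", "PTTG1", _PP, Sign.NEGATIVE, None, proc),
        _rec("PTTG1", "ESPL1", _PP, Sign.NEGATIVE, None, proc),
        # first-stage arm cohesin removal is driven directly by PLK1;
        # second-stage centromeric removal requires separase
        _rec("PLK1", "COHESIN", _PC, Sign.NEGATIVE, None, proc),
        _rec("ESPL1", "COHESIN", _PC, Sign.NEGATIVE, None, proc),
        _rec("ESPL1", "Sister Chromatid Segregation", _PPROC,
             Sign.POSITIVE, None, proc),
    ]


def _cascade2_records() -> list[InteractionRecord]:
    proc = "Cascade"
    return [
        _rec("A", "B", _PP, Sign.POSITIVE,
             Mechanism.EXPRESSION_REGULATION, proc),
        _rec("B", "Cascade Output", _PPROC, Sign.POSITIVE, None, proc),
    ]


_COHESIN_SUBUNITS = ("PDS5A", "RAD21", "SMC1A", "SMC3")


def circuit_fixture(
    name: str,
) -> tuple[NetworkModel, ParameterTable, dict]:
    """Build one of the named fixtures; returns (model, parameters, expected).

    ``expected`` records ground-truth structure for assertions: key species
    ids, the perturbation knob, and circuit membership of downstream readouts
    (for FULL_DEMO).  Every fixture passes model validation.
    """
    name = name.upper()
    if name not in FIXTURE_NAMES:
        raise GenerationError(
            f"unknown fixture {name!r}; valid: {FIXTURE_NAMES}"
        )
    policy = ConstructionPolicy(free_form_proteins=frozenset({"PP1"}))
    if name == "CPC":
        records = _cpc_records()
    elif name == "MCC":
        records = _mcc_records()
    elif name == "APCC":
        records = _apcc_records()
    elif name == "CASCADE2":
        records = _cascade2_records()
    else:  # FULL_DEMO: union with shared PLK1 / CDC20 / APC-C nodes
        records = _cpc_records() + _mcc_records() + _apcc_records()

    model = build_network(records, policy)
    cohesin_id = canonical_species_id("COHESIN", SpeciesKind.COMPLEX)
    if cohesin_id in model.species:
        model.species[cohesin_id].subunit_genes = _COHESIN_SUBUNITS
    # fixture kinetics: first-order turnover at 1.0 h⁻¹ so even species that
    # drain to zero (free-form enzymes, sequestered subunits) settle well
    # inside the 85-interval cell-cycle window
    from .network_construction import DEFAULT_RATE_CONSTANTS

    fixture_defaults = dict(DEFAULT_RATE_CONSTANTS)
    fixture_defaults[ReactionType.DEGRADATION] = 1.0
    for rx in model.reactions.values():
        rx.k = fixture_defaults[rx.rtype]
    params = parameters_from_model(model)
    expected: dict = {
        "plk1_gene": canonical_species_id("PLK1", SpeciesKind.GENE),
        "circuit_members": {
            "CPC": [canonical_species_id("BIRC5", SpeciesKind.PROTEIN) + "_P",
                    canonical_species_id("AURKB", SpeciesKind.PROTEIN)],
            "MCC": [canonical_species_id("BUB1B", SpeciesKind.PROTEIN) + "_P",
                    canonical_species_id("KIF2C", SpeciesKind.PROTEIN) + "_P"],
            "APCC": [canonical_species_id("FBXO5", SpeciesKind.PROTEIN) + "_P"],
        },
    }
    if name == "CASCADE2":
        expected.update({
            "gene_a": canonical_species_id("A", SpeciesKind.GENE),
            "gene_b": canonical_species_id("B", SpeciesKind.GENE),
            "protein_a": canonical_species_id("A", SpeciesKind.PROTEIN),
            "protein_b": canonical_species_id("B", SpeciesKind.PROTEIN),
        })
    return model, params, expected
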