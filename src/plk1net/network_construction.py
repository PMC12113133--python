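"""Stage 2: mechanical expansion of curated interactions into a reaction network.

Construction rules, applied in pipeline order by :func:`build_network`:

1. :func:`map_interactions_to_reactions` — curated records become species and
   curated reactions: protein–complex binding groups become a single
   association assembling the complex; protein→process records become
   catalysed production of a cumulative phenotype species; expression
   regulation and generic signed influences are queued for wiring after the
   central-dogma expansion; unsigned records with no mechanism are excluded
   (and logged), mirroring the curation rule that entities without a clear
   positive or negative influence are dropped.
2. :func:`add_modification_reactions` — phosphorylation, dephosphorylation,
   ubiquitination and acetylation records create the modified target form
   (once, however many enzymes target it) and a state transition catalysed by
   the enzyme.
3. :func:`expand_central_dogma` — every unmodified, non-free-form protein
   gains its gene, mRNA, transcription and translation; complexes on the
   direct-synthesis list gain a lumped gene + mRNA + a single direct-synthesis
   step instead of subunit assembly, so the gene and mRNA populations always
   pair up one-to-one.
4. Pending regulations are attached: a positive regulator becomes a modifier
   on the target's transcription; a negative regulator catalyses degradation
   of the target's mRNA (keeping every rate law pure mass action).
5. :func:`add_degradation_closure` — every protein and complex form (and, for
   boundedness, every mRNA) gets exactly one first-order degradation.

Gene species are constant-concentration boundary species throughout: never
consumed, never produced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model_schema import (
    InteractionClass,
    InteractionRecord,
    Mechanism,
    Modification,
    NetworkModel,
    ProcessCategory,
    ProcessDefinition,
    Reaction,
    ReactionType,
    Sign,
    Species,
    SpeciesKind,
    Plk1NetError,
    canonical_species_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConstructionPolicy",
    "ConstructionError",
    "DEFAULT_DIRECT_SYNTHESIS_COMPLEXES",
    "DEFAULT_RATE_CONSTANTS",
    "map_interactions_to_reactions",
    "add_modification_reactions",
    "expand_central_dogma",
    "add_degradation_closure",
    "merge_processes",
    "build_network",
]


class ConstructionError(Plk1NetError):
    """A construction rule cannot be applied to the given inputs."""


#: Complexes assumed to be synthesised directly, without subunit assembly.
DEFAULT_DIRECT_SYNTHESIS_COMPLEXES = frozenset({
    "LAMININ",
    "CONDENSIN I",
    "COHESIN",
    "Origin Recognition",
    "Nuclear pore",
    "Dynactin",
    "Dynein",
    "Proteasome Endopeptidase",
    "APC/C",
    "MCM",
    "RNA Polymerase II",
})

#: Default mass-action rate constants by reaction type (h⁻¹ · µM^(1−order)).
DEFAULT_RATE_CONSTANTS: dict[ReactionType, float] = {
    ReactionType.TRANSCRIPTION: 1.0,
    ReactionType.TRANSLATION: 1.0,
    ReactionType.DEGRADATION: 0.5,
    ReactionType.STATE_TRANSITION: 1.0,
    ReactionType.ASSOCIATION: 0.5,
    ReactionType.DIRECT_SYNTHESIS: 1.0,
}

_MECH_FLAG = {
    Mechanism.PHOSPHORYLATION: Modification.PHOSPHO,
    Mechanism.UBIQUITINATION: Modification.UBIQ,
    Mechanism.ACETYLATION: Modification.ACETYL,
}


@dataclass
class ConstructionPolicy:
    """Tunable choices of the construction rules.

    ``direct_synthesis_complexes`` and ``free_form_proteins`` are disjoint
    name sets; ``default_k`` supplies the rate constant for every reaction
    the rules create; ``mrna_degradation`` keeps mRNA pools bounded under
    constant gene concentration.
    """

    direct_synthesis_complexes: frozenset[str] = DEFAULT_DIRECT_SYNTHESIS_COMPLEXES
    free_form_proteins: frozenset[str] = frozenset()
    default_k: dict[ReactionType, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_CONSTANTS)
    )
    mrna_degradation: bool = True

    def __post_init__(self) -> None:
        self.direct_synthesis_complexes = frozenset(
            n.upper() for n in self.direct_synthesis_complexes
        )
        self.free_form_proteins = frozenset(
            n.upper() for n in self.free_form_proteins
        )
        clash = self.direct_synthesis_complexes & self.free_form_proteins
        if clash:
            raise Plk1NetError(
                f"names cannot be both direct-synthesis and free-form: "
                f"{sorted(clash)}"
            )

    def k(self, rtype: ReactionType) -> float:
        return self.default_k[rtype]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _ensure_species(
    model: NetworkModel,
    name: str,
    kind: SpeciesKind,
    process: str | None = None,
    **kw,
) -> Species:
    sid = canonical_species_id(name, kind)
    sp = model.species.get(sid)
    if sp is None:
        sp = model.add_species(
            Species(id=sid, name=name, kind=kind,
                    gene_symbol=name.upper() if kind is SpeciesKind.PROTEIN else None,
                    **kw)
        )
    if process:
        sp.processes.add(process)
        if process in model.processes:
            model.processes[process].members.add(sid)
    return sp


def _ensure_process(model: NetworkModel, name: str) -> ProcessDefinition:
    if name and name not in model.processes:
        model.processes[name] = ProcessDefinition(
            name=name, category=ProcessCategory.CELL_PROCESS
        )
    return model.processes.get(name)


def _unique_rid(model: NetworkModel, base: str) -> str:
    rid, n = base, 1
    while rid in model.reactions:
        n += 1
        rid = f"{base}_{n}"
    return rid


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def map_interactions_to_reactions(
    records: Sequence[InteractionRecord],
    policy: ConstructionPolicy | None = None,
) -> NetworkModel:
    """Translate curated interaction records into the base reaction network.

    Binding records targeting the same complex are pooled into one
    association reaction whose reactants are the distinct subunit proteins.
    Protein→process records each produce the corresponding phenotype species
    catalytically.  Regulation records (expression regulation, or any signed
    influence without a structural mechanism) are queued on the model and
    wired to transcription/degradation by :func:`build_network` once the
    central dogma has been expanded.  Unsigned records with no mechanism are
    excluded with a log line.
    """
    policy = policy or ConstructionPolicy()
    model = NetworkModel()
    model.pending_regulations = []  # (source name, target name, sign)
    complex_subunits: dict[str, list[str]] = {}

    for rec in records:
        _ensure_process(model, rec.process)
        # pre-create complex targets so later records can reference them
        if rec.iclass is InteractionClass.PROTEIN_COMPLEX:
            _ensure_species(model, rec.target, SpeciesKind.COMPLEX, rec.process)

    def resolve_source(rec: InteractionRecord) -> Species:
        # a curated source may itself be a complex already in the model
        cxid = canonical_species_id(rec.source, SpeciesKind.COMPLEX)
        if cxid in model.species:
            sp = model.species[cxid]
            if rec.process:
                sp.processes.add(rec.process)
                if rec.process in model.processes:
                    model.processes[rec.process].members.add(sp.id)
            return sp
        return _ensure_species(model, rec.source, SpeciesKind.PROTEIN,
                               rec.process)

    for rec in records:
        src = resolve_source(rec)
        if rec.iclass is InteractionClass.PROTEIN_PROCESS:
            ph = _ensure_species(model, rec.target, SpeciesKind.PHENOTYPE,
                                 rec.process)
            rid = _unique_rid(model, f"st_{src.id}__{ph.id}")
            model.add_reaction(Reaction(
                id=rid, rtype=ReactionType.STATE_TRANSITION,
                products=((ph.id, 1),), modifiers=(src.id,),
                k=policy.k(ReactionType.STATE_TRANSITION),
            ))
            continue
        if rec.iclass is InteractionClass.PROTEIN_COMPLEX:
            cx = _ensure_species(model, rec.target, SpeciesKind.COMPLEX,
                                 rec.process)
            if rec.mechanism is Mechanism.BINDING:
                complex_subunits.setdefault(cx.id, [])
                if src.id not in complex_subunits[cx.id]:
                    complex_subunits[cx.id].append(src.id)
            elif rec.mechanism in _MECH_FLAG or (
                rec.mechanism is Mechanism.DEPHOSPHORYLATION
            ):
                pass  # species exist; add_modification_reactions wires them
            elif rec.sign is not Sign.UNSIGNED:
                model.pending_regulations.append(
                    (rec.source, rec.target, rec.sign)
                )
            else:
                logger.info("excluded record %s -> %s (unsigned, no mechanism)",
                            rec.source, rec.target)
            continue
        if rec.iclass is InteractionClass.PROTEIN_SMALL_MOLECULE:
            sm = _ensure_species(model, rec.target, SpeciesKind.SMALL_MOLECULE,
                                 rec.process)
            if rec.sign is Sign.POSITIVE:
                rid = _unique_rid(model, f"st_{src.id}__{sm.id}")
                model.add_reaction(Reaction(
                    id=rid, rtype=ReactionType.STATE_TRANSITION,
                    products=((sm.id, 1),), modifiers=(src.id,),
                    k=policy.k(ReactionType.STATE_TRANSITION),
                ))
            elif rec.sign is Sign.NEGATIVE:
                rid = _unique_rid(model, f"st_{sm.id}__by_{src.id}")
                model.add_reaction(Reaction(
                    id=rid, rtype=ReactionType.STATE_TRANSITION,
                    reactants=((sm.id, 1),), modifiers=(src.id,),
                    k=policy.k(ReactionType.STATE_TRANSITION),
                ))
            else:
                logger.info("excluded record %s -> %s (unsigned, no mechanism)",
                            rec.source, rec.target)
            continue
        # PROTEIN_PROTEIN
        if rec.mechanism in _MECH_FLAG or rec.mechanism is Mechanism.DEPHOSPHORYLATION:
            # species only; the reaction is added by add_modification_reactions
            _ensure_species(model, rec.target, SpeciesKind.PROTEIN, rec.process)
        elif rec.mechanism is Mechanism.EXPRESSION_REGULATION or (
            rec.mechanism in (None, Mechanism.BINDING)
            and rec.sign is not Sign.UNSIGNED
        ):
            _ensure_species(model, rec.target, SpeciesKind.PROTEIN, rec.process)
            model.pending_regulations.append((rec.source, rec.target, rec.sign))
        else:
            logger.info("excluded record %s -> %s (unsigned, no mechanism)",
                        rec.source, rec.target)

    for cxid, subunits in complex_subunits.items():
        cx = model.species[cxid]
        cx.subunit_genes = tuple(
            model.species[sid].gene_symbol or model.species[sid].name
            for sid in subunits
        )
        rid = _unique_rid(model, f"assoc_{cxid}")
        model.add_reaction(Reaction(
            id=rid, rtype=ReactionType.ASSOCIATION,
            reactants=tuple((sid, 1) for sid in subunits),
            products=((cxid, 1),),
            k=policy.k(ReactionType.ASSOCIATION),
        ))

    for proc in model.processes.values():
        proc.species_count = len(proc.members)
        proc.interaction_count = sum(1 for r in records if r.process == proc.name)
    return model


def add_modification_reactions(
    model: NetworkModel,
    records: Sequence[InteractionRecord],
    policy: ConstructionPolicy | None = None,
) -> NetworkModel:
    """Create modified species and their state-transition reactions.

    Adding modification records is idempotent at the species level: however
    many enzymes target the same (substrate, state) pair, the modified form
    is created once, while each enzyme contributes its own catalysed
    transition.  A dephosphorylation record whose target has no
    phosphorylated form is a construction error.
    """
    policy = policy or ConstructionPolicy()
    model = model.copy()
    mod_records = [r for r in records if r.mechanism in _MECH_FLAG]
    dephos_records = [r for r in records
                      if r.mechanism is Mechanism.DEPHOSPHORYLATION]

    def target_species(name: str) -> Species:
        for kind in (SpeciesKind.PROTEIN, SpeciesKind.COMPLEX):
            sid = canonical_species_id(name, kind)
            if sid in model.species:
                return model.species[sid]
        return _ensure_species(model, name, SpeciesKind.PROTEIN)

    for rec in mod_records:
        flag = _MECH_FLAG[rec.mechanism]
        src = _ensure_species(model, rec.source, SpeciesKind.PROTEIN, rec.process)
        base = target_species(rec.target)
        mod_id = canonical_species_id(base.name, base.kind,
                                      base.modifications | flag)
        if mod_id not in model.species:
            model.add_species(Species(
                id=mod_id,
                name=f"{base.name}{'~' + flag.name}",
                kind=base.kind,
                modifications=base.modifications | flag,
                subunit_genes=tuple(base.subunit_genes),
                processes=set(base.processes) | ({rec.process} if rec.process else set()),
                gene_symbol=base.gene_symbol,
                parent_id=base.id,
            ))
        rid = f"mod_{base.id}__{mod_id}__by_{src.id}"
        if rid not in model.reactions:
            model.add_reaction(Reaction(
                id=rid, rtype=ReactionType.STATE_TRANSITION,
                reactants=((base.id, 1),), products=((mod_id, 1),),
                modifiers=(src.id,),
                k=policy.k(ReactionType.STATE_TRANSITION),
            ))

    for rec in dephos_records:
        src = _ensure_species(model, rec.source, SpeciesKind.PROTEIN, rec.process)
        base = target_species(rec.target)
        phos = base if Modification.PHOSPHO in base.modifications else None
        if phos is None:
            pid = canonical_species_id(base.name, base.kind,
                                       base.modifications | Modification.PHOSPHO)
            phos = model.species.get(pid)
        if phos is None:
            raise ConstructionError(
                f"dephosphorylation of {rec.target}: no phosphorylated form "
                f"exists in the model"
            )
        unphos_id = phos.parent_id or canonical_species_id(
            base.name, base.kind, phos.modifications & ~Modification.PHOSPHO
        )
        if unphos_id not in model.species:
            raise ConstructionError(
                f"dephosphorylation of {rec.target}: unmodified parent "
                f"{unphos_id} missing"
            )
        rid = f"demod_{phos.id}__{unphos_id}__by_{src.id}"
        if rid not in model.reactions:
            model.add_reaction(Reaction(
                id=rid, rtype=ReactionType.STATE_TRANSITION,
                reactants=((phos.id, 1),), products=((unphos_id, 1),),
                modifiers=(src.id,),
                k=policy.k(ReactionType.STATE_TRANSITION),
            ))
    return model


def expand_central_dogma(
    model: NetworkModel,
    policy: ConstructionPolicy | None = None,
) -> NetworkModel:
    """Add genes, mRNAs and synthesis reactions for every synthesised species.

    Unmodified proteins outside the free-form set gain gene + mRNA +
    transcription + translation.  Complexes on the direct-synthesis list
    gain a lumped gene + mRNA and one direct-synthesis reaction (mRNA
    modifier → complex), standing in for subunit synthesis and assembly.
    Modified forms never gain synthesis of their own — they arise only
    through state transitions from the parent form.
    """
    policy = policy or ConstructionPolicy()
    model = model.copy()
    for sp in list(model.species.values()):
        if sp.modifications is not Modification.NONE:
            continue
        direct = (
            sp.kind is SpeciesKind.COMPLEX
            and sp.name.upper() in policy.direct_synthesis_complexes
        )
        plain = (
            sp.kind is SpeciesKind.PROTEIN
            and not sp.free_form
            and sp.name.upper() not in policy.free_form_proteins
        )
        if not (direct or plain):
            if sp.kind is SpeciesKind.PROTEIN and (
                sp.free_form or sp.name.upper() in policy.free_form_proteins
            ):
                sp.free_form = True
            continue
        symbol = sp.gene_symbol or sp.name
        if plain and not symbol:
            raise ConstructionError(
                f"protein {sp.id} has no gene symbol and is not free-form"
            )
        gid = canonical_species_id(symbol, SpeciesKind.GENE)
        mid = canonical_species_id(symbol, SpeciesKind.MRNA)
        if gid not in model.species:
            model.add_species(Species(
                id=gid, name=symbol.lower(), kind=SpeciesKind.GENE,
                processes=set(sp.processes), gene_symbol=symbol.upper(),
            ))
        if mid not in model.species:
            model.add_species(Species(
                id=mid, name=f"{symbol.lower()} mRNA", kind=SpeciesKind.MRNA,
                processes=set(sp.processes), gene_symbol=symbol.upper(),
            ))
        tx_id = f"tx_{gid}"
        if tx_id not in model.reactions:
            model.add_reaction(Reaction(
                id=tx_id, rtype=ReactionType.TRANSCRIPTION,
                products=((mid, 1),), modifiers=(gid,),
                k=policy.k(ReactionType.TRANSCRIPTION),
            ))
        syn_type = (ReactionType.DIRECT_SYNTHESIS if direct
                    else ReactionType.TRANSLATION)
        syn_id = f"{'ds' if direct else 'tl'}_{sp.id}"
        if syn_id not in model.reactions:
            model.add_reaction(Reaction(
                id=syn_id, rtype=syn_type,
                products=((sp.id, 1),), modifiers=(mid,),
                k=policy.k(syn_type),
            ))
    return model


def _apply_pending_regulations(
    model: NetworkModel, policy: ConstructionPolicy
) -> NetworkModel:
    """Wire queued regulation edges onto the expanded model (in place).

    Positive regulators join the target's transcription as extra modifiers;
    negative regulators catalyse first-order degradation of the target mRNA
    (or of the target protein itself when it has no mRNA), so all rate laws
    stay pure mass action.
    """
    pending = getattr(model, "pending_regulations", [])
    for source, target, sign in pending:
        src_id = next(
            (sid for sid in (
                canonical_species_id(source, SpeciesKind.COMPLEX),
                canonical_species_id(source, SpeciesKind.PROTEIN),
            ) if sid in model.species),
            None,
        )
        if src_id is None:
            logger.info("regulation source %s absent; edge dropped", source)
            continue
        if sign is Sign.POSITIVE:
            tx_id = f"tx_{canonical_species_id(target, SpeciesKind.GENE)}"
            rx = model.reactions.get(tx_id)
            if rx is None:
                logger.info("no transcription for %s; positive regulation "
                            "by %s dropped", target, source)
                continue
            if src_id not in rx.modifiers:
                rx.modifiers = tuple(sorted((*rx.modifiers, src_id)))
            model.metadata[f"regulation:{tx_id}:{src_id}"] = "POSITIVE"
        else:
            victim = next(
                (sid for sid in (
                    canonical_species_id(target, SpeciesKind.MRNA),
                    canonical_species_id(target, SpeciesKind.PROTEIN),
                    canonical_species_id(target, SpeciesKind.COMPLEX),
                ) if sid in model.species),
                None,
            )
            if victim is None:
                logger.info("regulation target %s absent; edge dropped", target)
                continue
            rid = _unique_rid(model, f"rep_{victim}__by_{src_id}")
            model.add_reaction(Reaction(
                id=rid, rtype=ReactionType.STATE_TRANSITION,
                reactants=((victim, 1),), modifiers=(src_id,),
                k=policy.k(ReactionType.STATE_TRANSITION),
            ))
            model.metadata[f"regulation:{rid}:{src_id}"] = "NEGATIVE"
    model.pending_regulations = []
    return model


def add_degradation_closure(
    model: NetworkModel,
    policy: ConstructionPolicy | None = None,
) -> NetworkModel:
    """Give every protein, complex (all modification states) and mRNA exactly
    one first-order degradation reaction.  Genes and phenotype species never
    degrade.  Applying the closure twice adds nothing.
    """
    policy = policy or ConstructionPolicy()
    model = model.copy()
    degraded = model.degraded_species()
    kinds = {SpeciesKind.PROTEIN, SpeciesKind.COMPLEX}
    if policy.mrna_degradation:
        kinds.add(SpeciesKind.MRNA)
    for sp in list(model.species.values()):
        if sp.kind in kinds and sp.id not in degraded:
            model.add_reaction(Reaction(
                id=_unique_rid(model, f"deg_{sp.id}"),
                rtype=ReactionType.DEGRADATION,
                reactants=((sp.id, 1),),
                k=policy.k(ReactionType.DEGRADATION),
            ))
    return model


def merge_processes(models: Iterable[NetworkModel]) -> NetworkModel:
    """Unify per-process models into one global network.

    Species with identical canonical ids are merged (process memberships
    unioned); reactions with identical (type, reactants, products, modifiers)
    structure are kept once, retaining the first-seen rate constant — a
    structural duplicate with a conflicting k triggers a warning naming both
    values.
    """
    merged = NetworkModel()
    seen: dict[tuple, str] = {}
    for model in models:
        for sp in model.species.values():
            merged.add_species(sp.copy(), merge=True)
        for rx in model.reactions.values():
            key = rx.structure_key()
            if key in seen:
                kept = merged.reactions[seen[key]]
                if kept.k != rx.k:
                    warnings.warn(
                        f"conflicting rate constants for structurally "
                        f"identical reactions {kept.id} (k={kept.k}) and "
                        f"{rx.id} (k={rx.k}); keeping the first",
                        stacklevel=2,
                    )
                continue
            new = rx.copy()
            new.id = _unique_rid(merged, rx.id)
            merged.add_reaction(new)
            seen[key] = new.id
        for proc in model.processes.values():
            if proc.name in merged.processes:
                tgt = merged.processes[proc.name]
                tgt.members |= proc.members
                tgt.species_count = len(tgt.members)
                tgt.interaction_count += proc.interaction_count
            else:
                merged.processes[proc.name] = proc.copy()
        merged.metadata.update(model.metadata)
    return merged


def build_network(
    records: Sequence[InteractionRecord],
    policy: ConstructionPolicy | None = None,
) -> NetworkModel:
    """Run the full construction pipeline on a curated record set."""
    policy = policy or ConstructionPolicy()
    model = map_interactions_to_reactions(records, policy)
    pending = list(getattr(model, "pending_regulations", []))
    model = add_modification_reactions(model, records, policy)
    model = expand_central_dogma(model, policy)
    model.pending_regulations = pending
    model = _apply_pending_regulations(model, policy)
    model = add_degradation_closure(model, policy)
    return model
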