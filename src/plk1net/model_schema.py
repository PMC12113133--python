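"""Domain types for the PLK1 genomic-instability reaction network.

The network couples six kinds of biological species (genes, mRNAs, proteins,
protein complexes, small molecules, and cumulative "phenotype" species that
stand for external biological processes) through six reaction types
(transcription, translation, state transition, association, degradation and
direct synthesis of pre-assembled complexes).  Every reaction carries a single
mass-action rate constant; units are µM for concentrations and hours for time,
so a rate constant has units h⁻¹·µM^(1−order) where the order is the total
reactant stoichiometry plus the number of catalytic modifiers.

This module defines the in-memory containers, canonical species identifiers,
readers/writers for tab-separated interaction tables and for the
species/reaction/parameter table triple used for model deposition, SBML
Level 3 import/export (via libsbml), and structural model validation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import libsbml
import pandas as pd

__all__ = [
    "SpeciesKind",
    "Modification",
    "ReactionType",
    "InteractionClass",
    "Sign",
    "Mechanism",
    "ProcessCategory",
    "Species",
    "Reaction",
    "ProcessDefinition",
    "InteractionRecord",
    "NetworkModel",
    "Plk1NetError",
    "SchemaError",
    "TableParseError",
    "ModelValidationError",
    "UnsupportedKineticLawError",
    "canonical_species_id",
    "read_interaction_table",
    "write_interaction_table",
    "write_sbml",
    "read_sbml",
    "validate_model",
    "write_model_tables",
    "read_model_tables",
    "load_process_table",
    "load_deposited_model",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class Plk1NetError(Exception):
    """Base class for all package errors."""


class SchemaError(Plk1NetError):
    """A table is missing a required column."""


class TableParseError(Plk1NetError):
    """A table row holds an unknown enumeration token or malformed value."""


class ModelValidationError(Plk1NetError):
    """A model violates structural invariants; carries the violation list."""

    def __init__(self, violations: Sequence[str]):
        super().__init__(
            "model validation failed:\n" + "\n".join(f"  - {v}" for v in violations)
        )
        self.violations = list(violations)


class UnsupportedKineticLawError(Plk1NetError):
    """An SBML kinetic law is not pure mass action."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class SpeciesKind(enum.Enum):
    GENE = "GENE"
    MRNA = "MRNA"
    PROTEIN = "PROTEIN"
    COMPLEX = "COMPLEX"
    SMALL_MOLECULE = "SMALL_MOLECULE"
    PHENOTYPE = "PHENOTYPE"


class Modification(enum.Flag):
    """Post-translational modification state.

    The empty flag means the unmodified form.  Dephosphorylation is a reaction
    that removes ``PHOSPHO``, not a state of its own.
    """

    NONE = 0
    PHOSPHO = enum.auto()
    UBIQ = enum.auto()
    ACETYL = enum.auto()


#: id suffix for each single modification flag
_MOD_SUFFIX = {
    Modification.PHOSPHO: "_P",
    Modification.UBIQ: "_Ub",
    Modification.ACETYL: "_Ac",
}


class ReactionType(enum.Enum):
    TRANSCRIPTION = "TRANSCRIPTION"
    TRANSLATION = "TRANSLATION"
    STATE_TRANSITION = "STATE_TRANSITION"
    ASSOCIATION = "ASSOCIATION"
    DEGRADATION = "DEGRADATION"
    DIRECT_SYNTHESIS = "DIRECT_SYNTHESIS"


class InteractionClass(enum.Enum):
    PROTEIN_PROTEIN = "PROTEIN_PROTEIN"
    PROTEIN_COMPLEX = "PROTEIN_COMPLEX"
    PROTEIN_SMALL_MOLECULE = "PROTEIN_SMALL_MOLECULE"
    PROTEIN_PROCESS = "PROTEIN_PROCESS"


class Sign(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNSIGNED = "UNSIGNED"


class Mechanism(enum.Enum):
    PHOSPHORYLATION = "PHOSPHORYLATION"
    DEPHOSPHORYLATION = "DEPHOSPHORYLATION"
    UBIQUITINATION = "UBIQUITINATION"
    ACETYLATION = "ACETYLATION"
    BINDING = "BINDING"
    EXPRESSION_REGULATION = "EXPRESSION_REGULATION"


class ProcessCategory(enum.Enum):
    CELL_PROCESS = "CELL_PROCESS"
    DISEASE = "DISEASE"
    PATHOLOGICAL = "PATHOLOGICAL"


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

_KIND_PREFIX = {
    SpeciesKind.GENE: "g_",
    SpeciesKind.MRNA: "m_",
    SpeciesKind.PROTEIN: "p_",
    SpeciesKind.COMPLEX: "cx_",
    SpeciesKind.SMALL_MOLECULE: "sm_",
    SpeciesKind.PHENOTYPE: "ph_",
}
_PREFIX_KIND = {v: k for k, v in _KIND_PREFIX.items()}


def _sanitize(symbol: str) -> str:
    out = []
    for ch in symbol.strip():
        out.append(ch if (ch.isalnum() or ch == "_") else "_")
    token = "".join(out)
    return token or "X"


def canonical_species_id(
    name: str,
    kind: SpeciesKind,
    modifications: Modification = Modification.NONE,
) -> str:
    """Build the canonical id for a species: kind prefix + sanitized symbol +
    modification suffixes (``_P``, ``_Ub``, ``_Ac`` in that fixed order).

    The convention makes cross-process deduplication deterministic: any two
    curation rows naming the same molecule in the same state map to the same
    id regardless of the process they came from.
    """
    sid = _KIND_PREFIX[kind] + _sanitize(name).upper()
    for flag in (Modification.PHOSPHO, Modification.UBIQ, Modification.ACETYL):
        if flag in modifications:
            sid += _MOD_SUFFIX[flag]
    return sid


def _mods_to_str(mods: Modification) -> str:
    return "+".join(
        f.name for f in (Modification.PHOSPHO, Modification.UBIQ, Modification.ACETYL)
        if f in mods
    )


def _mods_from_str(s: str) -> Modification:
    mods = Modification.NONE
    for tok in filter(None, (t.strip() for t in s.split("+"))):
        try:
            mods |= Modification[tok]
        except KeyError:
            raise TableParseError(f"unknown modification flag {tok!r}") from None
    return mods


@dataclass
class Species:
    """A typed node of the reaction network.

    Parameters
    ----------
    id : str
        Unique canonical identifier (see :func:`canonical_species_id`).
    name : str
        Display symbol (HGNC-style for genes/proteins).
    kind : SpeciesKind
    modifications : Modification
        Post-translational state; the empty flag for unmodified species.
    subunit_genes : tuple of str
        Coding genes of complex subunits; non-empty only for ``COMPLEX``.
    processes : set of str
        Names of the biological processes this species belongs to.
    free_form : bool
        Protein assumed present without an explicit synthesis process.
    gene_symbol : str or None
        Coding gene of a ``PROTEIN`` species.
    parent_id : str or None
        For modified species, the id of the unmodified parent form; kept as
        explicit metadata rather than recovered by id parsing.
    """

    id: str
    name: str
    kind: SpeciesKind
    modifications: Modification = Modification.NONE
    subunit_genes: tuple[str, ...] = ()
    processes: set[str] = field(default_factory=set)
    free_form: bool = False
    gene_symbol: str | None = None
    parent_id: str | None = None

    def copy(self) -> "Species":
        return replace(self, subunit_genes=tuple(self.subunit_genes),
                       processes=set(self.processes))


@dataclass
class Reaction:
    """A typed mass-action transformation.

    ``reactants`` and ``products`` are multisets encoded as tuples of
    ``(species id, stoichiometry)``; ``modifiers`` are catalysts that enter
    the rate law linearly but are not consumed.  ``k`` is the single rate
    constant in h⁻¹·µM^(1−order) with order = Σ reactant stoichiometry +
    number of modifiers.
    """

    id: str
    rtype: ReactionType
    reactants: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    modifiers: tuple[str, ...] = ()
    k: float = 1.0

    def __post_init__(self) -> None:
        self.reactants = tuple(sorted((s, int(n)) for s, n in self.reactants))
        self.products = tuple(sorted((s, int(n)) for s, n in self.products))
        self.modifiers = tuple(sorted(set(self.modifiers)))

    @property
    def order(self) -> int:
        return sum(n for _, n in self.reactants) + len(self.modifiers)

    def structure_key(self) -> tuple:
        """Identity used for redundant-reaction elimination during merging."""
        return (self.rtype, self.reactants, self.products, self.modifiers)

    def copy(self) -> "Reaction":
        return replace(self)


@dataclass
class ProcessDefinition:
    """One curated biological process with its bookkeeping counts."""

    name: str
    category: ProcessCategory
    species_count: int = 0
    interaction_count: int = 0
    members: set[str] = field(default_factory=set)

    def copy(self) -> "ProcessDefinition":
        return replace(self, members=set(self.members))


@dataclass(frozen=True)
class InteractionRecord:
    """A curated interaction, one row of the ingestion table."""

    source: str
    target: str
    iclass: InteractionClass
    sign: Sign
    mechanism: Mechanism | None
    process: str
    provenance: str = ""


class NetworkModel:
    """The full reaction system: species, reactions and process index.

    Species and reactions are kept in insertion-ordered mappings keyed by id;
    iteration order is therefore deterministic for identical construction
    histories, which makes SBML export byte-reproducible.
    """

    def __init__(
        self,
        species: Iterable[Species] = (),
        reactions: Iterable[Reaction] = (),
        processes: Iterable[ProcessDefinition] = (),
        metadata: Mapping[str, str] | None = None,
    ):
        self.species: dict[str, Species] = {}
        self.reactions: dict[str, Reaction] = {}
        self.processes: dict[str, ProcessDefinition] = {}
        self.metadata: dict[str, str] = dict(metadata or {})
        for s in species:
            self.add_species(s)
        for r in reactions:
            self.add_reaction(r)
        for p in processes:
            self.processes[p.name] = p

    # -- mutation -----------------------------------------------------------
    def add_species(self, sp: Species, merge: bool = False) -> Species:
        """Add a species; with ``merge=True`` an existing species with the
        same id has its process memberships unioned instead of raising."""
        existing = self.species.get(sp.id)
        if existing is not None:
            if not merge:
                raise ModelValidationError([f"duplicate species id {sp.id}"])
            existing.processes |= sp.processes
            existing.free_form = existing.free_form or sp.free_form
            if not existing.subunit_genes and sp.subunit_genes:
                existing.subunit_genes = tuple(sp.subunit_genes)
            if existing.gene_symbol is None:
                existing.gene_symbol = sp.gene_symbol
            return existing
        self.species[sp.id] = sp
        return sp

    def add_reaction(self, rx: Reaction) -> Reaction:
        if rx.id in self.reactions:
            raise ModelValidationError([f"duplicate reaction id {rx.id}"])
        self.reactions[rx.id] = rx
        return rx

    # -- queries ------------------------------------------------------------
    def species_of_kind(self, kind: SpeciesKind) -> list[Species]:
        return [s for s in self.species.values() if s.kind is kind]

    def reactions_of_type(self, rtype: ReactionType) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.rtype is rtype]

    def degraded_species(self) -> set[str]:
        return {
            r.reactants[0][0]
            for r in self.reactions.values()
            if r.rtype is ReactionType.DEGRADATION and r.reactants
        }

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            (s.copy() for s in self.species.values()),
            (r.copy() for r in self.reactions.values()),
            (p.copy() for p in self.processes.values()),
            dict(self.metadata),
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<NetworkModel species={len(self.species)} "
            f"reactions={len(self.reactions)} processes={len(self.processes)}>"
        )


# ---------------------------------------------------------------------------
# Interaction-table I/O (tab-separated, fixed header)
# ---------------------------------------------------------------------------

INTERACTION_COLUMNS = (
    "source", "target", "iclass", "sign", "mechanism", "process", "provenance",
)


def _parse_enum(enum_cls, token: str, row: int, column: str):
    token = str(token).strip()
    try:
        return enum_cls(token.upper())
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise TableParseError(
            f"row {row}: unknown {column} token {token!r} (valid: {valid})"
        ) from None


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a curated interaction table (tab-separated UTF-8).

    The header must name the seven fields ``source target iclass sign
    mechanism process provenance``; ``mechanism`` and ``provenance`` may be
    empty.  Row numbers (1-based over data rows) are preserved in error
    messages.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records: list[InteractionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        iclass = _parse_enum(InteractionClass, row.iclass, i, "iclass")
        sign = _parse_enum(Sign, row.sign, i, "sign")
        mech_tok = str(row.mechanism).strip()
        mechanism = (
            _parse_enum(Mechanism, mech_tok, i, "mechanism") if mech_tok else None
        )
        records.append(
            InteractionRecord(
                source=str(row.source).strip(),
                target=str(row.target).strip(),
                iclass=iclass,
                sign=sign,
                mechanism=mechanism,
                process=str(row.process).strip(),
                provenance=str(row.provenance).strip(),
            )
        )
    return records


def write_interaction_table(records: Iterable[InteractionRecord],
                            path: str | Path) -> None:
    """Write interaction records in the dialect read_interaction_table expects."""
    rows = [
        {
            "source": r.source,
            "target": r.target,
            "iclass": r.iclass.value,
            "sign": r.sign.value,
            "mechanism": r.mechanism.value if r.mechanism else "",
            "process": r.process,
            "provenance": r.provenance,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(INTERACTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(model: NetworkModel) -> list[str]:
    """Check structural invariants; return the list of violations (empty iff
    the model is valid).  Never raises and never mutates the model.

    Checked invariants: all reaction participants resolve to declared
    species; phenotype species are never consumed; gene species are never
    produced; reaction-type arity contracts (degradation 1→0, transcription
    gene⇒mRNA, translation mRNA⇒protein); positive rate constants; every
    non-free-form protein or complex carries at least one degradation
    reaction (mass-balance closure).
    """
    v: list[str] = []
    sp = model.species
    for r in model.reactions.values():
        for sid, _ in (*r.reactants, *r.products):
            if sid not in sp:
                v.append(f"reaction {r.id}: unknown participant {sid}")
        for sid in r.modifiers:
            if sid not in sp:
                v.append(f"reaction {r.id}: unknown modifier {sid}")
        if not (r.k > 0) or not math.isfinite(r.k):
            v.append(f"reaction {r.id}: non-positive rate constant k={r.k}")
        for sid, _ in r.reactants:
            if sid in sp and sp[sid].kind is SpeciesKind.PHENOTYPE:
                v.append(f"reaction {r.id}: phenotype {sid} used as reactant")
        for sid, _ in r.products:
            if sid in sp and sp[sid].kind is SpeciesKind.GENE:
                v.append(f"reaction {r.id}: gene {sid} appears as product")
        if r.rtype is ReactionType.DEGRADATION:
            if len(r.reactants) != 1 or r.products or r.modifiers:
                v.append(f"degradation {r.id}: must be single reactant, no "
                         f"products, no modifiers")
        elif r.rtype is ReactionType.TRANSCRIPTION:
            ok = (
                not r.reactants
                and len(r.products) == 1
                and r.products[0][0] in sp
                and sp[r.products[0][0]].kind is SpeciesKind.MRNA
                and sum(1 for m in r.modifiers
                        if m in sp and sp[m].kind is SpeciesKind.GENE) == 1
            )
            if not ok:
                v.append(f"transcription {r.id}: must produce one mRNA with "
                         f"exactly one gene modifier")
        elif r.rtype is ReactionType.TRANSLATION:
            ok = (
                not r.reactants
                and len(r.products) == 1
                and r.products[0][0] in sp
                and sp[r.products[0][0]].kind in
                (SpeciesKind.PROTEIN, SpeciesKind.COMPLEX)
                and len(r.modifiers) == 1
                and r.modifiers[0] in sp
                and sp[r.modifiers[0]].kind is SpeciesKind.MRNA
            )
            if not ok:
                v.append(f"translation {r.id}: must produce one protein with "
                         f"exactly one mRNA modifier")
    degraded = model.degraded_species()
    for s in model.species.values():
        if s.kind in (SpeciesKind.PROTEIN, SpeciesKind.COMPLEX):
            if not s.free_form and s.id not in degraded:
                v.append(f"species {s.id}: protein/complex lacks a degradation "
                         f"reaction")
        if s.modifications is not Modification.NONE and s.parent_id is None:
            v.append(f"species {s.id}: modified form lacks parent reference")
    return v


def assert_valid(model: NetworkModel) -> None:
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)


# ---------------------------------------------------------------------------
# SBML export / import
# ---------------------------------------------------------------------------

_NS = "http://plk1net.local/schema"


def _check(value, message: str):
    if value is None:
        raise Plk1NetError(f"libsbml failure: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise Plk1NetError(f"libsbml error {value}: {message}")
    return value


def _species_annotation(s: Species) -> str:
    attrs = {
        "kind": s.kind.value,
        "mods": _mods_to_str(s.modifications),
        "free_form": "1" if s.free_form else "0",
        "gene": s.gene_symbol or "",
        "subunits": ",".join(s.subunit_genes),
        "processes": ";".join(sorted(s.processes)),
        "parent": s.parent_id or "",
    }
    # plain attribute formatting; values never contain quotes by construction
    attr_s = " ".join(f'{k}="{v}"' for k, v in attrs.items())
    return f'<plk1net:species xmlns:plk1net="{_NS}" {attr_s}/>'


def write_sbml(model: NetworkModel, path: str | Path) -> None:
    """Serialize a validated model to SBML Level 3 Version 2.

    Every reaction is emitted irreversible with a mass-action kinetic law
    ``k · Π reactantᵉ · Π modifier`` whose rate constant is a local parameter
    named ``k``.  Species kind, modification state and process memberships go
    into a package-namespace annotation (SBML has no native gene/protein
    typing); gene species are flagged as boundary species so their
    concentration is held constant by any compliant simulator.
    """
    assert_valid(model)
    doc = libsbml.SBMLDocument(3, 2)
    m = _check(doc.createModel(), "createModel")
    m.setId(model.metadata.get("model_id", "plk1net_model"))
    comp = m.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    for s in model.species.values():
        sb = m.createSpecies()
        sb.setId(s.id)
        sb.setName(s.name)
        sb.setCompartment("cell")
        sb.setInitialConcentration(0.0)
        sb.setHasOnlySubstanceUnits(False)
        sb.setBoundaryCondition(s.kind is SpeciesKind.GENE)
        sb.setConstant(False)
        _check(sb.setAnnotation(_species_annotation(s)), f"annotation {s.id}")

    for r in model.reactions.values():
        rb = m.createReaction()
        rb.setId(r.id)
        rb.setReversible(False)
        _check(
            rb.setAnnotation(
                f'<plk1net:reaction xmlns:plk1net="{_NS}" '
                f'rtype="{r.rtype.value}"/>'
            ),
            f"annotation {r.id}",
        )
        for sid, stoich in r.reactants:
            ref = rb.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(stoich))
            ref.setConstant(True)
        for sid, stoich in r.products:
            ref = rb.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(stoich))
            ref.setConstant(True)
        for sid in r.modifiers:
            ref = rb.createModifier()
            ref.setSpecies(sid)
        law = rb.createKineticLaw()
        terms = ["k"]
        for sid, stoich in r.reactants:
            terms.append(sid if stoich == 1 else f"{sid}^{stoich}")
        terms.extend(r.modifiers)
        _check(law.setFormula(" * ".join(terms)), f"kinetic law {r.id}")
        p = law.createLocalParameter()
        p.setId("k")
        p.setValue(float(r.k))

    if model.processes:
        elems = []
        for proc in model.processes.values():
            members = ",".join(sorted(proc.members))
            elems.append(
                f'<plk1net:process name="{proc.name}" '
                f'category="{proc.category.value}" '
                f'species_count="{proc.species_count}" '
                f'interaction_count="{proc.interaction_count}" '
                f'members="{members}"/>'
            )
        ann = (
            f'<plk1net:processes xmlns:plk1net="{_NS}">'
            + "".join(elems) + "</plk1net:processes>"
        )
        _check(m.setAnnotation(ann), "model process annotation")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise Plk1NetError(f"could not write SBML to {path}")


def _annotation_attrs(node: libsbml.XMLNode, element: str) -> dict[str, str] | None:
    """Find the first <plk1net:element> child and return its attributes."""
    found = _annotation_attrs_all(node, element)
    return found[0] if found else None


def _annotation_attrs_all(node: libsbml.XMLNode, element: str) -> list[dict[str, str]]:
    out: list[dict[str, str]] = []

    def walk(n: libsbml.XMLNode) -> None:
        if n.getName() == element and n.getURI() == _NS:
            attrs = n.getAttributes()
            out.append({attrs.getName(i): attrs.getValue(i)
                        for i in range(attrs.getLength())})
        for i in range(n.getNumChildren()):
            walk(n.getChild(i))

    walk(node)
    return out


_ALLOWED_AST = {
    libsbml.AST_TIMES,
    libsbml.AST_POWER,
    libsbml.AST_FUNCTION_POWER,
    libsbml.AST_NAME,
    libsbml.AST_INTEGER,
    libsbml.AST_REAL,
}


def _assert_mass_action(ast: libsbml.ASTNode, rid: str) -> None:
    if ast is None:
        raise UnsupportedKineticLawError(f"reaction {rid}: missing kinetic law")
    t = ast.getType()
    if t not in _ALLOWED_AST:
        raise UnsupportedKineticLawError(
            f"reaction {rid}: kinetic law is not pure mass action "
            f"(operator {libsbml.formulaToString(ast)!r})"
        )
    if t in (libsbml.AST_POWER, libsbml.AST_FUNCTION_POWER):
        base, expo = ast.getChild(0), ast.getChild(1)
        if base.getType() != libsbml.AST_NAME or expo.getType() not in (
            libsbml.AST_INTEGER, libsbml.AST_REAL
        ):
            raise UnsupportedKineticLawError(
                f"reaction {rid}: non-mass-action exponent"
            )
        return
    for i in range(ast.getNumChildren()):
        _assert_mass_action(ast.getChild(i), rid)


def read_sbml(path: str | Path) -> NetworkModel:
    """Load an SBML file written by :func:`write_sbml` (or any SBML L3 model
    with pure mass-action kinetic laws and a single rate parameter per
    reaction).

    Species kinds are recovered from the package annotation when present and
    from the id prefix convention otherwise; a reaction whose kinetic law is
    not a plain product of one constant and species concentrations (e.g. a
    Michaelis–Menten law) raises :class:`UnsupportedKineticLawError`.
    """
    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getError(0)
        raise Plk1NetError(f"SBML parse error: {err.getMessage()}")
    m = doc.getModel()
    if m is None:
        raise Plk1NetError(f"{path}: no model element")

    model = NetworkModel()
    for i in range(m.getNumSpecies()):
        sb = m.getSpecies(i)
        attrs = None
        if sb.isSetAnnotation():
            attrs = _annotation_attrs(sb.getAnnotation(), "species")
        if attrs:
            kind = SpeciesKind(attrs["kind"])
            mods = _mods_from_str(attrs.get("mods", ""))
            sp = Species(
                id=sb.getId(),
                name=sb.getName() or sb.getId(),
                kind=kind,
                modifications=mods,
                subunit_genes=tuple(filter(None, attrs.get("subunits", "").split(","))),
                processes=set(filter(None, attrs.get("processes", "").split(";"))),
                free_form=attrs.get("free_form", "0") == "1",
                gene_symbol=attrs.get("gene") or None,
                parent_id=attrs.get("parent") or None,
            )
        else:
            prefix = sb.getId().split("_", 1)[0] + "_"
            kind = _PREFIX_KIND.get(prefix, SpeciesKind.PROTEIN)
            sp = Species(id=sb.getId(), name=sb.getName() or sb.getId(), kind=kind)
        model.add_species(sp)

    for i in range(m.getNumReactions()):
        rb = m.getReaction(i)
        rid = rb.getId()
        rtype = ReactionType.STATE_TRANSITION
        if rb.isSetAnnotation():
            attrs = _annotation_attrs(rb.getAnnotation(), "reaction")
            if attrs and "rtype" in attrs:
                rtype = ReactionType(attrs["rtype"])
        law = rb.getKineticLaw()
        if law is None:
            raise UnsupportedKineticLawError(f"reaction {rid}: no kinetic law")
        _assert_mass_action(law.getMath(), rid)
        k = None
        for j in range(law.getNumLocalParameters()):
            p = law.getLocalParameter(j)
            if p.getId() == "k":
                k = p.getValue()
        if k is None and law.getNumLocalParameters() == 1:
            k = law.getLocalParameter(0).getValue()
        if k is None:
            raise UnsupportedKineticLawError(
                f"reaction {rid}: no local rate parameter found"
            )
        model.add_reaction(
            Reaction(
                id=rid,
                rtype=rtype,
                reactants=tuple(
                    (rb.getReactant(j).getSpecies(),
                     int(round(rb.getReactant(j).getStoichiometry())))
                    for j in range(rb.getNumReactants())
                ),
                products=tuple(
                    (rb.getProduct(j).getSpecies(),
                     int(round(rb.getProduct(j).getStoichiometry())))
                    for j in range(rb.getNumProducts())
                ),
                modifiers=tuple(
                    rb.getModifier(j).getSpecies()
                    for j in range(rb.getNumModifiers())
                ),
                k=float(k),
            )
        )

    if m.isSetAnnotation():
        for attrs in _annotation_attrs_all(m.getAnnotation(), "process"):
            model.processes[attrs["name"]] = ProcessDefinition(
                name=attrs["name"],
                category=ProcessCategory(attrs["category"]),
                species_count=int(attrs.get("species_count", 0)),
                interaction_count=int(attrs.get("interaction_count", 0)),
                members=set(filter(None, attrs.get("members", "").split(","))),
            )
    return model


# ---------------------------------------------------------------------------
# Deposited-style species/reaction/parameter tables
# ---------------------------------------------------------------------------

def _fmt_participants(parts: tuple[tuple[str, int], ...]) -> str:
    return ";".join(f"{n}*{sid}" if n != 1 else sid for sid, n in parts)


def _parse_participants(text: str) -> tuple[tuple[str, int], ...]:
    out = []
    for tok in filter(None, (t.strip() for t in str(text).split(";"))):
        if "*" in tok:
            n, sid = tok.split("*", 1)
            out.append((sid.strip(), int(n)))
        else:
            out.append((tok, 1))
    return tuple(out)


def write_model_tables(model: NetworkModel, directory: str | Path) -> None:
    """Write the species/reactions/parameters TSV triple used for deposition.

    ``reactions.tsv`` columns: reaction id, type, reactants, products,
    modifiers, k; participants are ``;``-joined with ``n*id`` stoichiometry
    prefixes.  ``parameters.tsv`` repeats every reaction's rate constant so
    the parameter list can be audited in isolation.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": s.id,
                "name": s.name,
                "kind": s.kind.value,
                "modifications": _mods_to_str(s.modifications),
                "free_form": int(s.free_form),
                "gene_symbol": s.gene_symbol or "",
                "subunit_genes": ",".join(s.subunit_genes),
                "processes": ";".join(sorted(s.processes)),
                "parent_id": s.parent_id or "",
            }
            for s in model.species.values()
        ]
    ).to_csv(directory / "species.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "type": r.rtype.value,
                "reactants": _fmt_participants(r.reactants),
                "products": _fmt_participants(r.products),
                "modifiers": ";".join(r.modifiers),
                "k": repr(r.k),
            }
            for r in model.reactions.values()
        ]
    ).to_csv(directory / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"reaction_id": r.id, "k": repr(r.k)} for r in model.reactions.values()]
    ).to_csv(directory / "parameters.tsv", sep="\t", index=False)


def read_model_tables(directory: str | Path) -> NetworkModel:
    """Read the species/reactions/parameters TSV triple back into a model."""
    directory = Path(directory)
    sdf = pd.read_csv(directory / "species.tsv", sep="\t", dtype=str,
                      keep_default_na=False)
    rdf = pd.read_csv(directory / "reactions.tsv", sep="\t", dtype=str,
                      keep_default_na=False)
    model = NetworkModel()
    for i, row in enumerate(sdf.itertuples(index=False), start=1):
        model.add_species(
            Species(
                id=row.id,
                name=row.name,
                kind=_parse_enum(SpeciesKind, row.kind, i, "kind"),
                modifications=_mods_from_str(row.modifications),
                subunit_genes=tuple(filter(None, row.subunit_genes.split(","))),
                processes=set(filter(None, row.processes.split(";"))),
                free_form=row.free_form in ("1", "True", "true"),
                gene_symbol=row.gene_symbol or None,
                parent_id=row.parent_id or None,
            )
        )
    for i, row in enumerate(rdf.itertuples(index=False), start=1):
        model.add_reaction(
            Reaction(
                id=row.id,
                rtype=_parse_enum(ReactionType, row.type, i, "type"),
                reactants=_parse_participants(row.reactants),
                products=_parse_participants(row.products),
                modifiers=tuple(filter(None, row.modifiers.split(";"))),
                k=float(row.k),
            )
        )
    params_path = directory / "parameters.tsv"
    if params_path.exists():
        pdf = pd.read_csv(params_path, sep="\t", dtype=str,
                          keep_default_na=False)
        for row in pdf.itertuples(index=False):
            if row.reaction_id in model.reactions:
                model.reactions[row.reaction_id].k = float(row.k)
    return model


def load_process_table(path: str | Path | None = None) -> list[ProcessDefinition]:
    """Load the curated nine-process definition table.

    Without ``path`` the packaged table ships with the library: the nine
    genomic-instability processes PLK1 participates in, each with its curated
    species and interaction counts (members are not enumerated at this
    level).  Columns: ``category process species interactions``.
    """
    if path is None:
        from importlib import resources

        path = resources.files("plk1net").joinpath("data/process_table.tsv")
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("category", "process", "species", "interactions")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"process table missing column(s): {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        out.append(ProcessDefinition(
            name=row.process,
            category=_parse_enum(ProcessCategory, row.category, i, "category"),
            species_count=int(row.species),
            interaction_count=int(row.interactions),
        ))
    return out


def load_deposited_model(directory: str | Path) -> NetworkModel:
    """Load a deposited model from its species/reaction/parameter tables.

    ``directory`` must hold ``species.tsv``, ``reactions.tsv`` and
    ``parameters.tsv`` in the dialect of :func:`write_model_tables`
    (mirroring the deposited reaction and parameter lists).  Raises
    :class:`FileNotFoundError` when the tables are absent.
    """
    directory = Path(directory)
    for fname in ("species.tsv", "reactions.tsv", "parameters.tsv"):
        if not (directory / fname).exists():
            raise FileNotFoundError(
                f"deposited model table {directory / fname} not found; the "
                f"deposited dataset must be placed there manually"
            )
    return read_model_tables(directory)
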