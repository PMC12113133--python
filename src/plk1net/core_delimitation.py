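"""Stage 1: delimit the core gene set and characterize network hubs.

The curated gene universe is filtered against a pan-cancer expression-call
matrix (gene × cancer type, boolean "expressed in that tumor dataset").  A
gene survives when it is called expressed in enough cancer types — either a
fraction of the panel (default 75%, rounded up) or an explicit count
override; the pipeline default carries an override of 16 of 20 cancer types.
Hubs are read off the curated edge list by interaction degree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_schema import (
    InteractionClass,
    InteractionRecord,
    ProcessDefinition,
    Species,
    SpeciesKind,
    Plk1NetError,
)

__all__ = [
    "ExpressionCallMatrix",
    "CoreFilterConfig",
    "filter_core_genes",
    "extract_unique_genes",
    "interaction_degree",
]


@dataclass
class ExpressionCallMatrix:
    """Boolean gene × cancer expression calls.

    ``calls[i, j]`` is True when gene ``genes[i]`` is expressed in the tumor
    dataset of cancer type ``cancers[j]``.
    """

    genes: list[str]
    cancers: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if len(set(self.genes)) != len(self.genes):
            raise Plk1NetError("duplicate gene symbols in expression matrix")
        if len(set(self.cancers)) != len(self.cancers):
            raise Plk1NetError("duplicate cancer codes in expression matrix")
        if self.calls.shape != (len(self.genes), len(self.cancers)):
            raise Plk1NetError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.genes)} genes × {len(self.cancers)} cancers"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionCallMatrix":
        """Read a 0/1 matrix with genes in rows and cancer codes in columns."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            cancers=[str(c) for c in df.columns],
            calls=df.to_numpy() != 0,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.calls.astype(int), index=self.genes, columns=self.cancers
        ).to_csv(path, sep="\t")

    def intersect(self, other: "ExpressionCallMatrix") -> "ExpressionCallMatrix":
        """Elementwise AND with a confirmatory matrix (e.g. proteomic calls)
        over the shared gene/cancer labels; genes or cancers absent from the
        confirmatory matrix keep their transcriptomic call unchanged."""
        out = self.calls.copy()
        gi = {g: i for i, g in enumerate(other.genes)}
        ci = {c: j for j, c in enumerate(other.cancers)}
        for i, g in enumerate(self.genes):
            if g not in gi:
                continue
            for j, c in enumerate(self.cancers):
                if c in ci:
                    out[i, j] &= other.calls[gi[g], ci[c]]
        return ExpressionCallMatrix(list(self.genes), list(self.cancers), out)


@dataclass
class CoreFilterConfig:
    """Inclusion rule for the core filter.

    ``fraction_threshold`` is the fraction of the cancer panel a gene must be
    expressed in (applied as a ceiling on the count); ``min_count_override``,
    when set, replaces the fraction rule with an absolute count.  The default
    pipeline configuration uses ``min_count_override=16`` on the 20-cancer
    panel.
    """

    fraction_threshold: float = 0.75
    min_count_override: int | None = None

    def required_count(self, n_cancers: int) -> int:
        if self.min_count_override is not None:
            if not (1 <= self.min_count_override <= n_cancers):
                raise Plk1NetError(
                    f"min_count_override {self.min_count_override} out of "
                    f"range [1, {n_cancers}]"
                )
            return self.min_count_override
        if not (0.0 < self.fraction_threshold <= 1.0):
            raise Plk1NetError(
                f"fraction_threshold {self.fraction_threshold} not in (0, 1]"
            )
        return math.ceil(self.fraction_threshold * n_cancers)


def filter_core_genes(
    matrix: ExpressionCallMatrix,
    config: CoreFilterConfig | None = None,
) -> tuple[list[str], dict[str, int]]:
    """Retain genes expressed in at least the required number of cancer types.

    Returns ``(retained, counts)`` where ``retained`` is ordered by
    descending expression count, ties broken by symbol, and ``counts`` maps
    every input gene to its expression count.
    """
    if not matrix.genes or not matrix.cancers:
        raise Plk1NetError("expression matrix is empty")
    config = config or CoreFilterConfig()
    need = config.required_count(len(matrix.cancers))
    counts = {
        g: int(matrix.calls[i].sum()) for i, g in enumerate(matrix.genes)
    }
    retained = sorted(
        (g for g, c in counts.items() if c >= need),
        key=lambda g: (-counts[g], g),
    )
    return retained, counts


def extract_unique_genes(
    processes: Iterable[ProcessDefinition],
    species: Iterable[Species] | dict[str, Species],
) -> list[str]:
    """Union of coding genes over all process members, deduplicated and sorted.

    Proteins contribute their coding gene symbol; complexes contribute every
    subunit gene.  A protein with neither a gene symbol nor the free-form
    flag produces a warning record (it cannot be tied to a gene).
    """
    if isinstance(species, dict):
        index = species
    else:
        index = {s.id: s for s in species}
    genes: set[str] = set()
    for proc in processes:
        for sid in proc.members:
            sp = index.get(sid)
            if sp is None:
                continue
            if sp.kind is SpeciesKind.PROTEIN:
                if sp.gene_symbol:
                    genes.add(sp.gene_symbol.upper())
                elif not sp.free_form:
                    warnings.warn(
                        f"protein {sp.id} has no coding gene symbol",
                        stacklevel=2,
                    )
            elif sp.kind is SpeciesKind.COMPLEX:
                genes.update(g.upper() for g in sp.subunit_genes)
    return sorted(genes)


def interaction_degree(
    records: Sequence[InteractionRecord],
) -> tuple[dict[str, int], list[tuple[str, int]]]:
    """Count, per species name, the curated interaction records it appears in.

    The degree of a species is the number of distinct records in which it
    occurs as source or target (parallel edges from different processes each
    count).  For protein→process records only the protein side is counted:
    the process target is an end phenotype, not an interactor.  Returns the
    degree map and a ranking sorted by descending degree, ties alphabetical.
    """
    degree: dict[str, int] = {}
    for rec in records:
        degree[rec.source] = degree.get(rec.source, 0) + 1
        if rec.iclass is not InteractionClass.PROTEIN_PROCESS:
            degree[rec.target] = degree.get(rec.target, 0) + 1
    ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return degree, ranked
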