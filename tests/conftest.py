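"""Shared fixtures: hand-built motifs and generated models."""

import numpy as np
import pytest

from plk1net import (
    Modification,
    NetworkModel,
    Reaction,
    ReactionType,
    Species,
    SpeciesKind,
)


def central_dogma_motif(k_tr=2.0, d_m=1.0, k_tl=3.0, d_p=2.0) -> NetworkModel:
    """gene → mRNA → protein with first-order turnover.

    Analytic steady state: m* = k_tr·G/d_m, p* = k_tl·m*/d_p.
    """
    return NetworkModel(
        species=[
            Species("g_X", "x", SpeciesKind.GENE),
            Species("m_X", "x mRNA", SpeciesKind.MRNA),
            Species("p_X", "X", SpeciesKind.PROTEIN, gene_symbol="X"),
        ],
        reactions=[
            Reaction("tx_g_X", ReactionType.TRANSCRIPTION,
                     products=(("m_X", 1),), modifiers=("g_X",), k=k_tr),
            Reaction("deg_m_X", ReactionType.DEGRADATION,
                     reactants=(("m_X", 1),), k=d_m),
            Reaction("tl_p_X", ReactionType.TRANSLATION,
                     products=(("p_X", 1),), modifiers=("m_X",), k=k_tl),
            Reaction("deg_p_X", ReactionType.DEGRADATION,
                     reactants=(("p_X", 1),), k=d_p),
        ],
    )


def closed_association_motif(k=0.3) -> NetworkModel:
    """A + B → C with no synthesis or degradation (moiety-conserving)."""
    return NetworkModel(
        species=[
            Species("p_A", "A", SpeciesKind.PROTEIN, free_form=True),
            Species("p_B", "B", SpeciesKind.PROTEIN, free_form=True),
            Species("cx_C", "C", SpeciesKind.COMPLEX, free_form=True,
                    subunit_genes=("A", "B")),
        ],
        reactions=[
            Reaction("assoc_C", ReactionType.ASSOCIATION,
                     reactants=(("p_A", 1), ("p_B", 1)),
                     products=(("cx_C", 1),), k=k),
        ],
    )


def decay_motif(k=1.0, with_phenotype=False) -> NetworkModel:
    species = [Species("p_S", "S", SpeciesKind.PROTEIN, free_form=True)]
    reactions = [Reaction("deg_p_S", ReactionType.DEGRADATION,
                          reactants=(("p_S", 1),), k=k)]
    if with_phenotype:
        species.append(Species("ph_OUT", "out", SpeciesKind.PHENOTYPE))
        reactions.append(Reaction("st_out", ReactionType.STATE_TRANSITION,
                                  products=(("ph_OUT", 1),),
                                  modifiers=("p_S",), k=1.0))
    return NetworkModel(species=species, reactions=reactions)


@pytest.fixture
def motif():
    return central_dogma_motif()


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
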