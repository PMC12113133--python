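"""Construction rules: central dogma, modifications, closure, merging."""

import warnings

import pytest

from plk1net import (
    ConstructionError,
    ConstructionPolicy,
    InteractionClass,
    InteractionRecord,
    Mechanism,
    NetworkModel,
    Reaction,
    ReactionType,
    Sign,
    Species,
    SpeciesKind,
    add_degradation_closure,
    add_modification_reactions,
    build_network,
    canonical_species_id,
    expand_central_dogma,
    map_interactions_to_reactions,
    merge_processes,
    validate_model,
    write_sbml,
)
from plk1net.synthetic_data import NetworkGenSpec, generate_network


def rec(source, target, iclass=InteractionClass.PROTEIN_PROTEIN,
        sign=Sign.POSITIVE, mech=None, process="p"):
    return InteractionRecord(source=source, target=target, iclass=iclass,
                             sign=sign, mechanism=mech, process=process,
                             provenance="")


def protein_model(*names, free_form=()):
    return NetworkModel(species=[
        Species(canonical_species_id(n, SpeciesKind.PROTEIN), n,
                SpeciesKind.PROTEIN, gene_symbol=n,
                free_form=n in free_form)
        for n in names
    ])


class TestExpandCentralDogma:
    def test_one_protein_gains_gene_mrna_and_two_reactions(self):
        model = expand_central_dogma(protein_model("PLK1"))
        assert len(model.species) == 3
        assert len(model.reactions) == 2
        assert len(model.species_of_kind(SpeciesKind.GENE)) == 1
        assert len(model.species_of_kind(SpeciesKind.MRNA)) == 1

    def test_free_form_protein_untouched(self):
        model = expand_central_dogma(protein_model("PP1", free_form=("PP1",)))
        assert len(model.species) == 1
        assert len(model.reactions) == 0

    def test_exempt_accounting(self):
        # 60 proteins, 12 free-form, 8 modified duplicates: genes and mRNAs
        # are created only for the 40 synthesised parents, and pair up 1:1
        names = [f"PR{i:03d}" for i in range(60)]
        free = set(names[:12])
        model = protein_model(*names, free_form=free)
        from plk1net import Modification

        for n in names[12:20]:
            pid = canonical_species_id(n, SpeciesKind.PROTEIN)
            model.species[pid].modifications = Modification.PHOSPHO
            model.species[pid].parent_id = pid
        model = expand_central_dogma(model)
        assert len(model.species_of_kind(SpeciesKind.GENE)) == 40
        assert len(model.species_of_kind(SpeciesKind.MRNA)) == 40

    def test_direct_synthesis_complex(self):
        model = NetworkModel(species=[
            Species("cx_COHESIN", "COHESIN", SpeciesKind.COMPLEX,
                    subunit_genes=("PDS5A", "RAD21", "SMC1A", "SMC3"))
        ])
        model = expand_central_dogma(model)
        ds = model.reactions_of_type(ReactionType.DIRECT_SYNTHESIS)
        assert len(ds) == 1
        assert ds[0].products == (("cx_COHESIN", 1),)
        # lumped gene/mRNA pair keeps gene and mRNA populations equal
        assert len(model.species_of_kind(SpeciesKind.GENE)) == 1
        assert len(model.species_of_kind(SpeciesKind.MRNA)) == 1


class TestModificationReactions:
    def test_phosphorylation_creates_modified_form(self):
        model = protein_model("PLK1", "BIRC5")
        model = add_modification_reactions(
            model, [rec("PLK1", "BIRC5", mech=Mechanism.PHOSPHORYLATION)])
        assert "p_BIRC5_P" in model.species
        rx = [r for r in model.reactions.values()
              if r.rtype is ReactionType.STATE_TRANSITION][0]
        assert rx.reactants == (("p_BIRC5", 1),)
        assert rx.products == (("p_BIRC5_P", 1),)
        assert rx.modifiers == ("p_PLK1",)

    def test_two_kinases_one_species_two_reactions(self):
        model = protein_model("PLK1", "AURKB", "BIRC5")
        model = add_modification_reactions(model, [
            rec("PLK1", "BIRC5", mech=Mechanism.PHOSPHORYLATION),
            rec("AURKB", "BIRC5", mech=Mechanism.PHOSPHORYLATION),
        ])
        phospho = [s for s in model.species if s.endswith("_P")]
        assert phospho == ["p_BIRC5_P"]
        assert len(model.reactions_of_type(ReactionType.STATE_TRANSITION)) == 2

    def test_dephosphorylation_without_phospho_form_errors(self):
        model = protein_model("PP1", "BIRC5")
        with pytest.raises(ConstructionError, match="phosphorylated"):
            add_modification_reactions(
                model,
                [rec("PP1", "BIRC5", mech=Mechanism.DEPHOSPHORYLATION)])

    def test_modified_pair_set_matches_oracle(self, rng):
        names = [f"P{i}" for i in range(10)]
        mechs = [Mechanism.PHOSPHORYLATION, Mechanism.UBIQUITINATION,
                 Mechanism.ACETYLATION]
        records = [
            rec(names[rng.integers(10)], names[rng.integers(10)],
                mech=mechs[rng.integers(3)])
            for _ in range(40)
        ]
        model = add_modification_reactions(protein_model(*names), records)
        from plk1net import Modification

        suffix = {Mechanism.PHOSPHORYLATION: Modification.PHOSPHO,
                  Mechanism.UBIQUITINATION: Modification.UBIQ,
                  Mechanism.ACETYLATION: Modification.ACETYL}
        expected = {
            canonical_species_id(r.target, SpeciesKind.PROTEIN,
                                 suffix[r.mechanism])
            for r in records
        }
        got = {s.id for s in model.species.values()
               if s.modifications.value != 0}
        assert got == expected


class TestDegradationClosure:
    def test_adds_only_missing(self):
        model = protein_model("A", "B", "C")
        model.add_reaction(Reaction("deg_p_A", ReactionType.DEGRADATION,
                                    reactants=(("p_A", 1),), k=0.5))
        closed = add_degradation_closure(model)
        added = len(closed.reactions) - len(model.reactions)
        assert added == 2

    def test_phenotype_never_degraded(self):
        model = NetworkModel(species=[
            Species("ph_OUT", "out", SpeciesKind.PHENOTYPE)])
        closed = add_degradation_closure(model)
        assert len(closed.reactions) == 0

    def test_idempotent(self):
        model = add_degradation_closure(protein_model("A", "B"))
        again = add_degradation_closure(model)
        assert len(again.reactions) == len(model.reactions)


class TestMapInteractions:
    def test_cpc_binding_records_pool_into_one_association(self):
        records = [
            rec(sub, "CPC", InteractionClass.PROTEIN_COMPLEX,
                Sign.UNSIGNED, Mechanism.BINDING)
            for sub in ("AURKB", "INCENP", "BIRC5", "CDCA8")
        ]
        model = map_interactions_to_reactions(records)
        assoc = model.reactions_of_type(ReactionType.ASSOCIATION)
        assert len(assoc) == 1
        assert len(assoc[0].reactants) == 4
        assert assoc[0].products == (("cx_CPC", 1),)

    def test_process_record_produces_phenotype(self):
        model = map_interactions_to_reactions(
            [rec("PLK1", "Spindle Assembly",
                 InteractionClass.PROTEIN_PROCESS)])
        ph = model.species_of_kind(SpeciesKind.PHENOTYPE)
        assert len(ph) == 1
        rx = model.reactions_of_type(ReactionType.STATE_TRANSITION)[0]
        assert rx.products[0][0] == ph[0].id
        assert rx.modifiers == ("p_PLK1",)
        assert rx.reactants == ()

    def test_unsigned_no_mechanism_excluded_with_log(self, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="plk1net.network_construction"):
            model = map_interactions_to_reactions(
                [rec("A", "B", sign=Sign.UNSIGNED, mech=None)])
        assert len(model.reactions) == 0
        assert any("excluded" in m for m in caplog.messages)


class TestMergeProcesses:
    def test_shared_species_and_reaction_unified(self):
        def one(process):
            m = protein_model("PLK1")
            m.species["p_PLK1"].processes = {process}
            m.add_reaction(Reaction("deg_p_PLK1", ReactionType.DEGRADATION,
                                    reactants=(("p_PLK1", 1),), k=0.5))
            return m

        merged = merge_processes([one("a"), one("b")])
        assert len(merged.species) == 1
        assert len(merged.reactions) == 1
        assert merged.species["p_PLK1"].processes == {"a", "b"}

    def test_conflicting_k_warns_and_keeps_first(self):
        m1 = protein_model("X")
        m1.add_reaction(Reaction("deg_p_X", ReactionType.DEGRADATION,
                                 reactants=(("p_X", 1),), k=0.5))
        m2 = protein_model("X")
        m2.add_reaction(Reaction("deg_p_X", ReactionType.DEGRADATION,
                                 reactants=(("p_X", 1),), k=0.9))
        with pytest.warns(UserWarning, match="conflicting"):
            merged = merge_processes([m1, m2])
        assert merged.reactions["deg_p_X"].k == 0.5

    def test_union_matches_brute_force(self, rng):
        models, union = [], set()
        for s in range(4):
            recs, _d, _t = generate_network(
                NetworkGenSpec(n_proteins=12, n_processes=2, seed=s))
            m = build_network(recs)
            models.append(m)
            union |= set(m.species)
        merged = merge_processes(models)
        assert set(merged.species) == union

    def test_species_bound_by_per_process_sum(self):
        recs, defs, _t = generate_network(
            NetworkGenSpec(n_proteins=30, n_processes=4,
                           overlap_fraction=0.4, seed=1))
        model = map_interactions_to_reactions(recs)
        total = sum(d.species_count for d in defs)
        merged_proteins = len(model.species_of_kind(SpeciesKind.PROTEIN))
        assert merged_proteins <= total


class TestFullConstruction:
    def test_gene_equals_mrna_and_reachability(self):
        recs, _d, _t = generate_network(NetworkGenSpec(seed=2))
        model = build_network(recs)
        assert validate_model(model) == []
        genes = model.species_of_kind(SpeciesKind.GENE)
        mrnas = model.species_of_kind(SpeciesKind.MRNA)
        assert len(genes) == len(mrnas)
        # every synthesised protein: gene -> (1 transcription) -> mRNA ->
        # (1 translation/direct synthesis) -> product
        for sp in model.species.values():
            if sp.kind is SpeciesKind.PROTEIN and not sp.free_form \
                    and sp.modifications.value == 0:
                gid = canonical_species_id(sp.gene_symbol, SpeciesKind.GENE)
                mid = canonical_species_id(sp.gene_symbol, SpeciesKind.MRNA)
                tx = [r for r in model.reactions.values()
                      if r.rtype is ReactionType.TRANSCRIPTION
                      and gid in r.modifiers]
                syn = [r for r in model.reactions.values()
                       if r.rtype in (ReactionType.TRANSLATION,
                                      ReactionType.DIRECT_SYNTHESIS)
                       and mid in r.modifiers]
                assert len(tx) == 1 and len(syn) == 1

    def test_reaction_category_tally(self):
        recs, _d, _t = generate_network(NetworkGenSpec(seed=4))
        model = build_network(recs)
        by_type = {t: len(model.reactions_of_type(t)) for t in ReactionType}
        assert sum(by_type.values()) == len(model.reactions)

    def test_construction_is_deterministic_byte_identical_sbml(self, tmp_path):
        recs, _d, _t = generate_network(NetworkGenSpec(seed=6))
        p1, p2 = tmp_path / "a.xml", tmp_path / "b.xml"
        write_sbml(build_network(recs), p1)
        write_sbml(build_network(list(recs)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_gene_species_never_consumed_or_produced(self):
        recs, _d, _t = generate_network(NetworkGenSpec(seed=8))
        model = build_network(recs)
        gene_ids = {s.id for s in model.species_of_kind(SpeciesKind.GENE)}
        for rx in model.reactions.values():
            for sid, _n in (*rx.reactants, *rx.products):
                assert sid not in gene_ids
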