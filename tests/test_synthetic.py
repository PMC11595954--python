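"""Simulator ground truth: determinism, mutation-log replay, process properties."""

import math

import numpy as np
import pytest

from mitomarker.errors import SimulationError
from mitomarker.mito_io import extract_gene
from mitomarker.phylo import newick_read, rf_distance
from mitomarker.seqcore import gc_content, translate_cds
from mitomarker.synthetic_data import (
    DEFAULT_GENE_LENGTHS,
    SimConfig,
    example_genus_collection,
    plant_diagnostics,
    replay_leaf_genes,
    simulate_collection,
)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = SimConfig(n_taxa=4, genome_length=35_000, seed=21)
        r1, t1 = simulate_collection(cfg)
        r2, t2 = simulate_collection(cfg)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert [x.features for x in r1] == [x.features for x in r2]
        assert t1.mutation_log == t2.mutation_log

    def test_different_seed_differs(self):
        r1, _ = simulate_collection(SimConfig(n_taxa=3, genome_length=35_000, seed=1))
        r2, _ = simulate_collection(SimConfig(n_taxa=3, genome_length=35_000, seed=2))
        assert r1[0].sequence != r2[0].sequence


class TestStructure:
    def test_all_genes_annotated_with_table_lengths(self, small_collection):
        records, _ = small_collection
        for rec in records:
            for gene, length in DEFAULT_GENE_LENGTHS.items():
                assert extract_gene(rec, gene).length == length

    def test_minus_strand_genes_are_strand_resolved(self, small_collection):
        records, truth = small_collection
        rec = records[0]
        feat = extract_gene(rec, "nad6")
        assert feat.strand == "-"
        # a CDS extracted strand-resolved must still translate
        assert translate_cds(feat.sequence)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(SimulationError, match="too small"):
            simulate_collection(SimConfig(n_taxa=3, genome_length=10_000, seed=0))

    def test_gc_within_one_point_of_target(self):
        records, _ = simulate_collection(
            SimConfig(n_taxa=3, genome_length=55_000, genome_gc=0.27, seed=8)
        )
        for rec in records:
            assert abs(gc_content(rec.sequence) - 0.27) < 0.01


class TestMutationLog:
    def test_replay_reproduces_every_leaf(self, small_collection):
        records, truth = small_collection
        leaves = replay_leaf_genes(truth)
        for rec in records:
            for feat in rec.features:
                assert leaves[rec.accession][feat.gene_name] == feat.sequence

    def test_replay_covers_indels_and_introns(self, example_collection):
        records, truth = example_collection
        kinds = {e.kind for e in truth.mutation_log}
        assert {"ins", "del", "intron"} & kinds
        leaves = replay_leaf_genes(truth)
        for rec in records:
            for feat in rec.features:
                assert leaves[rec.accession][feat.gene_name] == feat.sequence

    def test_zero_rate_means_identical_taxa(self):
        records, truth = simulate_collection(
            SimConfig(n_taxa=4, subst_rate=0.0, genome_length=35_000,
                      rrna_intron_count_range=(0, 0), seed=5)
        )
        assert not truth.mutation_log
        ref = records[0]
        for rec in records[1:]:
            assert rec.sequence == ref.sequence


class TestSynonymousMode:
    def test_proteins_fixed_while_nucleotides_diverge(self):
        records, truth = simulate_collection(
            SimConfig(
                n_taxa=4,
                subst_rate=0.0,
                gene_rate_overrides={"atp9": 0.5},
                synonymous_only=frozenset({"atp9"}),
                genome_length=35_000,
                rrna_intron_count_range=(0, 0),
                seed=13,
            )
        )
        seqs = [extract_gene(r, "atp9").sequence for r in records]
        proteins = {translate_cds(s) for s in seqs}
        assert len(proteins) == 1
        assert len(set(seqs)) > 1
        assert all(e.gene == "atp9" and e.kind == "sub" for e in truth.mutation_log)


class TestSubstitutionProcess:
    def test_pairwise_distance_matches_jukes_cantor_expectation(self):
        """Observed p-distance agrees with (3/4)(1 - exp(-4 mu t / 3))."""
        mu, t_pair = 0.05, 1.0  # two 0.5 branches to a common ancestor
        L = 30_000
        expected = 0.75 * (1 - math.exp(-4 * mu * t_pair / 3))
        obs = []
        for seed in range(5):
            records, _ = simulate_collection(
                SimConfig(
                    n_taxa=3,
                    tree_newick="(x:0.5,y:0.5,z:0.5);",
                    gene_lengths={},
                    rrna_lengths={"rrnl": L},
                    rrna_intron_count_range=(0, 0),
                    subst_rate=mu,
                    genome_length=45_000,
                    seed=30 + seed,
                )
            )
            by_acc = {r.accession: extract_gene(r, "rrnl").sequence for r in records}
            x, y = by_acc["x"], by_acc["y"]
            obs.append(sum(1 for a, b in zip(x, y) if a != b) / L)
        mean = sum(obs) / len(obs)
        se = math.sqrt(expected * (1 - expected) / L) / math.sqrt(len(obs))
        assert abs(mean - expected) < 3 * se

    def test_cds_substitutions_never_create_premature_stops(self, small_collection):
        records, _ = small_collection
        for rec in records:
            for gene in DEFAULT_GENE_LENGTHS:
                translate_cds(extract_gene(rec, gene).sequence)


class TestRrnaIntrons:
    def test_lengths_vary_across_taxa(self, example_collection):
        records, _ = example_collection
        for gene in ("rrnl", "rrns"):
            lengths = {extract_gene(r, gene).length for r in records}
            assert len(lengths) > 1

    def test_intron_count_in_configured_range(self, example_collection):
        records, truth = example_collection
        for rec in records:
            n = sum(
                1
                for e in truth.mutation_log
                if e.branch == rec.accession and e.kind == "intron" and e.gene == "rrnl"
            )
            assert 1 <= n <= 4


class TestPlantDiagnostics:
    def test_empty_plan_is_identity(self, small_collection):
        records, truth = small_collection
        out, _ = plant_diagnostics(records, truth, [])
        assert out is records

    def test_planted_site_becomes_diagnostic(self, example_collection):
        from mitomarker.align_variants import diagnostic_site_count, msa

        records, truth = example_collection
        seqs = sorted((r.accession, extract_gene(r, "atp9").sequence) for r in records)
        groups = {acc: f"clade{truth.clades[acc]}" for acc, _ in seqs}
        assert diagnostic_site_count(msa(seqs), groups) == 2

    def test_collision_with_existing_mutation_rejected(self, small_collection):
        records, truth = small_collection
        sub = next(e for e in truth.mutation_log if e.kind == "sub")
        new_base = "ACGT".replace(sub.alt, "")[0]
        with pytest.raises(SimulationError, match="collision"):
            plant_diagnostics(
                records, truth, [([records[0].accession], sub.gene, sub.position, new_base)]
            )

    def test_planting_same_base_rejected(self, small_collection):
        records, truth = small_collection
        feat = extract_gene(records[0], "atp8")
        current = feat.sequence[9]
        with pytest.raises(SimulationError, match="already"):
            plant_diagnostics(
                records, truth, [([records[0].accession], "atp8", 10, current)]
            )

    def test_updates_genome_and_feature_consistently(self, small_collection):
        records, truth = small_collection
        feat = extract_gene(records[0], "nad6")  # minus strand
        base = "ACGT".replace(feat.sequence[4], "")[0]
        out, _ = plant_diagnostics(
            records, truth, [([records[0].accession], "nad6", 5, base)]
        )
        new_feat = extract_gene(out[0], "nad6")
        assert new_feat.sequence[4] == base
        # re-extracting from the genome must agree with the stored feature
        from mitomarker.seqcore import reverse_complement

        genome_slice = out[0].sequence[new_feat.start - 1 : new_feat.end]
        assert reverse_complement(genome_slice) == new_feat.sequence


class TestFixedTree:
    def test_supplied_newick_is_respected(self):
        nwk = "((p:0.3,q:0.3):0.3,(r:0.3,s:0.3):0.3,u:0.6);"
        records, truth = simulate_collection(
            SimConfig(tree_newick=nwk, n_taxa=5, genome_length=35_000,
                      rrna_intron_count_range=(0, 0), seed=4)
        )
        assert sorted(r.accession for r in records) == ["p", "q", "r", "s", "u"]
        assert rf_distance(truth.true_tree, newick_read(nwk))[0] == 0


def test_example_collection_truth_clades(example_collection):
    _, truth = example_collection
    assert truth.clades == {
        "A1": 1, "A2": 1, "A3": 1, "B1": 2, "B2": 2, "B3": 2,
        "C1": 3, "C2": 3, "C3": 3,
    }
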