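"""The synthetic genome generator: determinism, event conservation,
coordinate/sequence consistency of the truth ledger, and the planting
operations' contracts."""

import numpy as np
import pytest

from sbpkit.kaks import CodonAlignment, SaturationError, ng86, translate
from sbpkit.mir156 import revcomp_dna
from sbpkit.simulate import (
    GenomeSimulator,
    SimulationConfig,
    SyntheticTruth,
    evolve_cds,
    generate_expression_matrix,
    generate_genome,
    random_cds,
)


def small_config(**overrides):
    base = dict(
        seed=7, n_chromosomes=2, genes_per_chromosome=80,
        n_tandem_events=2, n_segmental_events=1, segmental_block_len=61,
        segmental_retention=0.3, n_mirna_loci=2,
        mirna_mutation_counts=(0, 1), mirna_strands=("+", "-"),
        mirna_inside_coding=(False, False), mirna_hairpin=(True, True),
        n_face_to_face_pairs=1, face_to_face_gaps=(5000,),
        family_fraction=0.08,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_config_identical_output(self):
        g1 = generate_genome(small_config())
        g2 = generate_genome(small_config())
        assert g1.genome == g2.genome
        assert g1.cds == g2.cds
        assert [
            (t.source, t.copy) for t in g1.truth.tandem_pairs
        ] == [(t.source, t.copy) for t in g2.truth.tandem_pairs]

    def test_written_files_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_genome(small_config()).write_outputs(d1)
        generate_genome(small_config()).write_outputs(d2)
        for name in ["genome.fa", "annotation.gff3", "proteins.fa",
                     "cds.fa", "truth.json"]:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_truth_ledger_round_trips(self, tmp_path):
        g = generate_genome(small_config())
        p = tmp_path / "truth.json"
        g.truth.to_json(p)
        back = SyntheticTruth.from_json(p)
        assert [t.copy for t in back.tandem_pairs] == [
            t.copy for t in g.truth.tandem_pairs
        ]
        assert back.segmental_blocks[0].retained_pairs == (
            g.truth.segmental_blocks[0].retained_pairs
        )


class TestEventConservation:
    def test_planted_event_counts_match_config(self, genome):
        truth = genome.truth
        cfg = genome.config
        assert len(truth.tandem_pairs) == cfg.n_tandem_events
        assert len(truth.segmental_blocks) == cfg.n_segmental_events
        assert len(truth.mirna_loci) == cfg.n_mirna_loci
        assert len(truth.face_to_face_pairs) == cfg.n_face_to_face_pairs

    def test_infeasible_request_rejected(self):
        cfg = SimulationConfig(
            seed=0, n_chromosomes=1, genes_per_chromosome=0,
            n_tandem_events=1, n_segmental_events=0, n_mirna_loci=0,
            n_face_to_face_pairs=0,
        )
        with pytest.raises(ValueError, match="chromosome"):
            generate_genome(cfg)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_tandem_events=-1).validate()


class TestLedgerConsistency:
    """Every planted event must be recoverable from the emitted files."""

    def test_gene_ids_resolve(self, genome):
        ann = genome.annotation
        for t in genome.truth.tandem_pairs:
            assert t.source in ann and t.copy in ann
        for s in genome.truth.segmental_blocks:
            for a, b in s.retained_pairs:
                assert a in ann and b in ann

    def test_mirna_sequences_match_coordinates(self, genome):
        matures = {m.id: m.sequence.replace("U", "T") for m in genome.matures}
        for m in genome.truth.mirna_loci:
            found = genome.genome[m.chromosome][m.start - 1 : m.end]
            if m.strand == "-":
                found = revcomp_dna(found)
            mm = sum(a != b for a, b in zip(found, matures[m.mature_id]))
            assert mm == m.mismatches

    def test_face_to_face_gaps_exact(self, genome):
        ann = genome.annotation
        for f in genome.truth.face_to_face_pairs:
            a, b = ann[f.gene_a], ann[f.gene_b]
            assert b.start - a.end - 1 == f.gap
            if f.convergent:
                assert (a.strand, b.strand) == ("+", "-")

    def test_cds_matches_genome_slice(self, genome):
        for g in list(genome.annotation)[:25]:
            raw = genome.genome[g.chromosome][g.start - 1 : g.end]
            expected = raw if g.strand == "+" else revcomp_dna(raw)
            assert genome.cds[g.id] == expected

    def test_genes_do_not_overlap(self, genome):
        for chrom in genome.annotation.chromosomes:
            genes = genome.annotation.genes_on(chrom)
            for a, b in zip(genes, genes[1:]):
                assert a.end < b.start


class TestPlantingOperations:
    def make_builder(self):
        cfg = small_config(
            n_tandem_events=0, n_segmental_events=0, n_mirna_loci=0,
            n_face_to_face_pairs=0,
        )
        sim = GenomeSimulator(cfg)
        sim.build_backbone()
        return sim

    def family_gene_id(self, sim):
        for chrom in sorted(sim.chroms):
            for g in sim.chroms[chrom]:
                if g.family:
                    return g.id
        raise AssertionError("no family gene in backbone")

    def test_tandem_no_spacer_is_adjacent(self):
        sim = self.make_builder()
        src = self.family_gene_id(sim)
        copy = sim.plant_tandem_duplication(src, intervening=0, target_ks=0.3)
        for genes in sim.chroms.values():
            ids = [g.id for g in genes]
            if src in ids:
                assert ids[ids.index(src) + 1] == copy

    def test_tandem_one_spacer_between(self):
        sim = self.make_builder()
        src = self.family_gene_id(sim)
        copy = sim.plant_tandem_duplication(src, intervening=1, target_ks=0.3)
        for genes in sim.chroms.values():
            ids = [g.id for g in genes]
            if src in ids:
                i = ids.index(src)
                assert ids[i + 2] == copy
                spacer = genes[i + 1]
                assert not spacer.family and spacer.id not in (src, copy)

    def test_tandem_zero_divergence_identical_cds(self):
        sim = self.make_builder()
        src = self.family_gene_id(sim)
        copy = sim.plant_tandem_duplication(src, intervening=0, target_ks=0.0)
        by_id = {g.id: g for genes in sim.chroms.values() for g in genes}
        assert by_id[copy].cds == by_id[src].cds

    def test_segmental_full_retention(self):
        sim = self.make_builder()
        truth = sim.plant_segmental_block(61, retention=1.0, target_ks=0.3)
        assert len(truth.retained_pairs) == 61

    def test_segmental_ceiling_rule(self):
        sim = self.make_builder()
        truth = sim.plant_segmental_block(61, retention=0.2, target_ks=0.3)
        assert len(truth.retained_pairs) == 13  # ceil(12.2)

    def test_segmental_zero_retention_rejected(self):
        sim = self.make_builder()
        with pytest.raises(ValueError, match="retention"):
            sim.plant_segmental_block(61, retention=0.0, target_ks=0.3)

    def test_segmental_same_chromosome_allowed(self):
        sim = self.make_builder()
        truth = sim.plant_segmental_block(
            61, retention=0.3, target_ks=0.3,
            src_chrom="chr1", dst_chrom="chr1",
        )
        ids = {g.id for g in sim.chroms["chr1"]}
        assert set(truth.block_b) <= ids

    def test_face_to_face_orientation_negative_control(self):
        sim = self.make_builder()
        a, b = sim.plant_face_to_face_pair("g1", "g6", gap=5000, convergent=False)
        by_id = {g.id: g for genes in sim.chroms.values() for g in genes}
        assert by_id[a].strand == by_id[b].strand == "+"

    def test_mirna_before_coordinates_rejected(self):
        sim = self.make_builder()
        from sbpkit.simulate import DEFAULT_MATURES

        with pytest.raises(AssertionError):
            sim.plant_mirna_locus(DEFAULT_MATURES[0], 0, "+", False, True)

    def test_mirna_inside_coding_without_genes_rejected(self):
        cfg = small_config(
            genes_per_chromosome=0, n_tandem_events=0, n_segmental_events=0,
            n_mirna_loci=0, n_face_to_face_pairs=0,
        )
        sim = GenomeSimulator(cfg)
        sim.build_backbone()
        sim.assign_coordinates()
        from sbpkit.simulate import DEFAULT_MATURES

        with pytest.raises(ValueError, match="coding gene"):
            sim.plant_mirna_locus(DEFAULT_MATURES[0], 0, "+", True, False)


class TestEvolveCds:
    def test_zero_targets_identity(self):
        cds = random_cds(np.random.default_rng(0), 50)
        assert evolve_cds(cds, 0.0, 0.0, 1) == cds

    def test_same_seed_same_output(self):
        cds = random_cds(np.random.default_rng(0), 100)
        assert evolve_cds(cds, 0.4, 0.1, 99) == evolve_cds(cds, 0.4, 0.1, 99)

    def test_frame_and_translatability_preserved(self):
        cds = random_cds(np.random.default_rng(2), 120)
        out = evolve_cds(cds, 0.6, 0.2, 3)
        assert len(out) == len(cds)
        prot = translate(out)
        assert "*" not in prot[:-1]

    def test_saturating_target_rejected(self):
        cds = random_cds(np.random.default_rng(1), 100)
        with pytest.raises(SaturationError):
            evolve_cds(cds, 5.0, 0.0, 2)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            evolve_cds("ATGTAAAAATAA", 0.1, 0.0, 0)

    @pytest.mark.parametrize("target", [0.3, 1.0])
    def test_ks_recovered_near_target(self, target):
        a = random_cds(np.random.default_rng(10), 300)
        vals = []
        for seed in range(4):
            b = evolve_cds(a, target, 0.0, 50 + seed)
            vals.append(ng86(CodonAlignment.from_ungapped(a, b)).ks)
        assert abs(np.mean(vals) - target) < 0.12


class TestExpressionMatrix:
    def test_planted_folds_realized_exactly(self):
        df, _ = generate_expression_matrix(
            ["g1", "g2"], ["cold"], {"g1": [("cold", 2.0)], "g2": [("cold", 0.5)]}
        )
        assert df.loc["g1", "cold_treat"] / df.loc["g1", "cold_control"] == 2.0
        assert df.loc["g2", "cold_treat"] / df.loc["g2", "cold_control"] == 0.5

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            generate_expression_matrix(["g1"], ["cold"], {"gX": [("cold", 2.0)]})

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            generate_expression_matrix(["g1"], ["cold"], {"g1": [("cold", 0.0)]})

    def test_noise_leaves_planted_cells_exact(self):
        df, _ = generate_expression_matrix(
            ["g1", "g2"], ["cold"], {"g1": [("cold", 1.5)]},
            noise_sd=5.0, seed=3,
        )
        assert df.loc["g1", "cold_treat"] / df.loc["g1", "cold_control"] == 1.5
        assert df.loc["g2", "cold_treat"] != 100.0 or df.loc["g2", "cold_control"] != 100.0
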