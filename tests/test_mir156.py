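"""miR156 locus prediction, target scoring, co-location and
face-to-face detection."""

import numpy as np
import pytest
from Bio.Seq import Seq

from sbpkit.dupsynteny import make_micro_fragment
from sbpkit.fold import fold
from sbpkit.mir156 import (
    GenomicHit,
    HairpinCriteria,
    MatureMiRNA,
    PrecursorCandidate,
    co_location,
    coding_filter,
    dedupe_matures,
    extract_precursor,
    face_to_face_scan,
    hairpin_eval,
    mature_scan,
    mir_sbp_synteny,
    revcomp_dna,
    target_scan,
)
from sbpkit.model import AnnotationSet, GeneLocus, HomologyHit, HomologyTable

from conftest import make_annotation

MAT = MatureMiRNA("mirX", "UGACAGAAGAGAGUGAGCAC")  # 20 nt


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def plant(seq, pos, insert):
    return seq[:pos] + insert + seq[pos + len(insert):]


def oracle_scan(genome, matures, min_len=19, max_mismatch=2):
    """Independent sliding-window Hamming scan (plain python, Biopython
    reverse complement), with the same merge-to-best rule."""
    hits = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for mat in matures:
            dna = mat.sequence.replace("U", "T")
            windows = [dna] + [
                w for L in range(min_len, len(dna)) for w in (dna[:L], dna[-L:])
            ]
            for strand in "+-":
                raw = []
                for w in dict.fromkeys(windows):
                    pat = w if strand == "+" else str(Seq(w).reverse_complement())
                    L = len(w)
                    for s in range(len(seq) - L + 1):
                        mm = 0
                        for x, y in zip(seq[s : s + L], pat):
                            if x != y:
                                mm += 1
                                if mm > max_mismatch:
                                    break
                        if mm <= max_mismatch:
                            raw.append((s + 1, s + L, mm, L))
                raw.sort()
                clusters = []
                for h in raw:
                    if clusters and h[0] <= max(x[1] for x in clusters[-1]):
                        clusters[-1].append(h)
                    else:
                        clusters.append([h])
                for cl in clusters:
                    best = min(cl, key=lambda h: (h[2], -h[3], h[0]))
                    hits.append((mat.id, chrom, best[0], best[1], strand, best[2]))
    return sorted(hits)


class TestMatureScan:
    def test_exact_planted_copy_single_hit(self):
        rng = np.random.default_rng(0)
        genome = {"c": plant(random_dna(rng, 3000), 1000, MAT.sequence.replace("U", "T"))}
        hits = mature_scan(genome, [MAT])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.mismatches) == (1001, 1020, "+", 0)

    def test_three_mismatches_excluded(self):
        rng = np.random.default_rng(1)
        dna = list(MAT.sequence.replace("U", "T"))
        for i in (5, 9, 14):  # interior positions
            dna[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[dna[i]]
        genome = {"c": plant(random_dna(rng, 3000), 1000, "".join(dna))}
        assert mature_scan(genome, [MAT]) == []

    def test_reverse_complement_reported_on_minus(self):
        rng = np.random.default_rng(2)
        rc = revcomp_dna(MAT.sequence)
        genome = {"c": plant(random_dna(rng, 3000), 500, rc)}
        hits = mature_scan(genome, [MAT])
        assert len(hits) == 1 and hits[0].strand == "-"
        assert hits[0].start == 501

    def test_equivalent_to_brute_force(self):
        """Exact oracle equivalence on a sequence with planted copies at
        0, 1, 2 and 3 mismatches on both strands."""
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 5000)
        dna = MAT.sequence.replace("U", "T")
        seq = plant(seq, 200, dna)
        mut = list(dna); mut[7] = "A" if mut[7] != "A" else "C"
        seq = plant(seq, 1200, "".join(mut))
        seq = plant(seq, 2400, revcomp_dna(dna))
        genome = {"c1": seq}
        got = sorted(
            (h.mature_id, h.chromosome, h.start, h.end, h.strand, h.mismatches)
            for h in mature_scan(genome, [MAT])
        )
        assert got == oracle_scan(genome, [MAT])

    def test_dedupe_matures(self):
        a = MatureMiRNA("a", "UGACAGAAGAGAGUGAGCAC")
        b = MatureMiRNA("b", "UGACAGAAGAGAGUGAGCAC")
        assert [m.id for m in dedupe_matures([a, b])] == ["a"]


class TestPrecursorExtraction:
    def make_genome(self, n=10_000, seed=4):
        return {"c": random_dna(np.random.default_rng(seed), n)}

    def test_interior_hit_gets_full_flanks(self):
        genome = self.make_genome()
        hit = GenomicHit("m", "c", 1000, 1020, "+", 0, 21)
        cand = extract_precursor(hit, genome, flank=200)
        assert (cand.start, cand.end) == (800, 1220)
        assert cand.mature_offset == 200
        assert cand.sequence == genome["c"][799:1220]

    def test_truncated_at_sequence_start(self):
        genome = self.make_genome()
        hit = GenomicHit("m", "c", 50, 70, "+", 0, 21)
        cand = extract_precursor(hit, genome, flank=200)
        assert (cand.start, cand.end) == (1, 270)
        assert cand.mature_offset == 49

    def test_minus_strand_reverse_complemented(self):
        genome = self.make_genome()
        hit = GenomicHit("m", "c", 1000, 1020, "-", 0, 21)
        cand = extract_precursor(hit, genome, flank=200)
        assert cand.sequence == revcomp_dna(genome["c"][799:1220])
        # mature is flank-distance from the 5' end on the hit strand
        assert cand.mature_offset == 200


class TestCodingFilter:
    def setup_method(self):
        self.ann = make_annotation(3, gene_length=900, gap=1000)
        # genes at 1001-1900, 2900-3799, 4799-5698

    def cand(self, start, end):
        hit = GenomicHit("m", "chr1", start, end, "+", 0, end - start + 1)
        return PrecursorCandidate(hit=hit, sequence="A" * 60, start=1,
                                  end=60, mature_offset=0)

    def test_hit_inside_gene_removed(self):
        kept, removed = coding_filter([self.cand(1200, 1219)], self.ann)
        assert kept == [] and len(removed) == 1

    def test_intergenic_hit_retained(self):
        kept, removed = coding_filter([self.cand(2000, 2019)], self.ann)
        assert len(kept) == 1 and removed == []

    def test_single_nucleotide_overlap_removed(self):
        # gene 2 spans 2900-3799; a hit ending exactly at its first base
        # overlaps by 1 nt and is removed, one base earlier it is kept
        kept, removed = coding_filter([self.cand(2881, 2900)], self.ann)
        assert kept == [] and len(removed) == 1
        kept, removed = coding_filter([self.cand(2880, 2899)], self.ann)
        assert len(kept) == 1


def stem_loop_precursor(mature_dna, loop="AACAAA", arm_pad=10, rng_seed=5):
    """Mature on the 5' arm of a clean inverted repeat inside flanks."""
    rng = np.random.default_rng(rng_seed)
    left = mature_dna + random_dna(rng, arm_pad)
    unit = left + loop + revcomp_dna(left)
    flank = random_dna(rng, 30)
    seq = flank + unit + flank
    return seq, len(flank)  # mature offset


class TestHairpinEval:
    def make_candidate(self, sequence, offset, mature_len=20):
        hit = GenomicHit("m", "c", 1, mature_len, "+", 0, mature_len)
        return PrecursorCandidate(hit=hit, sequence=sequence, start=1,
                                  end=len(sequence), mature_offset=offset)

    def test_perfect_inverted_repeat_passes(self):
        dna = MAT.sequence.replace("U", "T")
        seq, offset = stem_loop_precursor(dna)
        cand = self.make_candidate(seq, offset)
        ev = hairpin_eval(cand)
        assert ev.passes
        assert ev.mature_paired >= 14 and ev.single_arm

    def test_homopolymer_fails_with_zero_pairs(self):
        cand = self.make_candidate("A" * 200, 50)
        ev = hairpin_eval(cand)
        assert not ev.passes and ev.mature_paired == 0

    def test_mature_spanning_terminal_loop_fails(self):
        arm = random_dna(np.random.default_rng(6), 15)
        hairpin = arm + "AACAAA" + revcomp_dna(arm)
        # mature centered on the loop: self-pairing within its own span
        cand = self.make_candidate(hairpin, 5)
        ev = hairpin_eval(cand)
        assert not ev.single_arm and not ev.passes

    def test_criteria_are_configurable(self):
        dna = MAT.sequence.replace("U", "T")
        seq, offset = stem_loop_precursor(dna)
        cand = self.make_candidate(seq, offset)
        strict = HairpinCriteria(min_mature_paired=21)
        ev = hairpin_eval(cand, strict)
        assert not ev.passes  # 20-mer cannot pair 21 bases


# mature with G at positions 5 and 20 so wobble and tail-mismatch
# examples are constructible
TMAT = MatureMiRNA("t", "ACGUGACGUGACGUGACGUGA")  # 21 nt


def perfect_site(mature_rna):
    """Transcript window perfectly complementary (antiparallel)."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in mature_rna)[::-1]


class TestTargetScan:
    def build_transcript(self, site, flank=30):
        return "C" * flank + site + "C" * flank

    def test_perfect_complement_scores_zero(self):
        tx = self.build_transcript(perfect_site(TMAT.sequence))
        sites = target_scan(TMAT, tx)
        assert min(s.expectation for s in sites) == 0.0

    def test_mismatch_at_position_20_scores_one(self):
        site = list(perfect_site(TMAT.sequence))
        # transcript index pairing mature position p is (len - p) in site
        idx = len(TMAT.sequence) - 20
        assert TMAT.sequence[19] == "G"  # pos 20
        site[idx] = "A"  # not C (pair) and not U (wobble)
        tx = self.build_transcript("".join(site))
        sites = target_scan(TMAT, tx)
        assert min(s.expectation for s in sites) == pytest.approx(1.0)

    def test_wobble_in_seed_scores_one(self):
        site = list(perfect_site(TMAT.sequence))
        idx = len(TMAT.sequence) - 5
        assert TMAT.sequence[4] == "G"  # pos 5
        site[idx] = "U"  # G:U wobble, doubled in the seed region
        tx = self.build_transcript("".join(site))
        sites = target_scan(TMAT, tx)
        assert min(s.expectation for s in sites) == pytest.approx(1.0)

    def test_expectation_invariant_under_padding(self):
        site = perfect_site(TMAT.sequence)
        e1 = min(s.expectation for s in target_scan(TMAT, self.build_transcript(site, 20)))
        e2 = min(s.expectation for s in target_scan(TMAT, self.build_transcript(site, 80)))
        assert e1 == e2 == 0.0

    def test_breakdown_sums_to_expectation(self):
        site = list(perfect_site(TMAT.sequence))
        site[3] = "A"
        tx = self.build_transcript("".join(site))
        best = min(target_scan(TMAT, tx), key=lambda s: s.expectation)
        assert sum(p for _, p in best.breakdown) == pytest.approx(best.expectation)


class TestCoLocation:
    def test_hit_inside_fragment_span(self):
        ann = make_annotation(61)
        frag = make_micro_fragment("chr1_g31", ann, k=30)
        span_start = ann["chr1_g1"].start
        hit = GenomicHit("m", "chr1", span_start + 10, span_start + 29, "+", 0, 20)
        assert co_location(hit, [frag], ann) == ["chr1_g31"]

    def test_other_chromosome_not_colocated(self):
        ann = make_annotation(61)
        frag = make_micro_fragment("chr1_g31", ann, k=30)
        hit = GenomicHit("m", "chr9", 500, 519, "+", 0, 20)
        assert co_location(hit, [frag], ann) == []

    def test_one_nt_outside_span_not_colocated(self):
        ann = make_annotation(61)
        frag = make_micro_fragment("chr1_g31", ann, k=30)
        span_start = ann["chr1_g1"].start
        hit = GenomicHit("m", "chr1", span_start - 20, span_start - 1, "+", 0, 20)
        assert co_location(hit, [frag], ann) == []


class TestMirSbpSynteny:
    def build(self, with_homology=True):
        a = make_annotation(61, chromosome="chr1")
        b_genes = []
        for g in make_annotation(61, chromosome="chr2"):
            fam = g.id == "chr2_g31"
            b_genes.append(
                GeneLocus(id=g.id, chromosome="chr2", start=g.start, end=g.end,
                          strand="+", family_member=fam,
                          group="g1" if fam else None)
            )
        ann = AnnotationSet(list(a) + b_genes)
        pairs = [(f"chr1_g{i + 1}", f"chr2_g{i + 1}") for i in range(61)]
        table = hits_for_pairs(pairs) if with_homology else HomologyTable([])
        return ann, table

    def test_planted_block_pair_found(self):
        ann, table = self.build()
        # miR between two genes of the chr1 block
        g10, g11 = ann["chr1_g10"], ann["chr1_g11"]
        hit = GenomicHit("m", "chr1", g10.end + 10, g10.end + 29, "+", 0, 20)
        result = mir_sbp_synteny([hit], ann, table)
        assert len(result) == 1
        assert result[0].sbp_gene == "chr2_g31"
        assert len(result[0].support) >= 10

    def test_colocation_excluded(self):
        ann, table = self.build()
        g10 = ann["chr2_g10"]
        hit = GenomicHit("m", "chr2", g10.end + 10, g10.end + 29, "+", 0, 20)
        assert mir_sbp_synteny([hit], ann, table) == []

    def test_no_homology_empty(self):
        ann, table = self.build(with_homology=False)
        g10 = ann["chr1_g10"]
        hit = GenomicHit("m", "chr1", g10.end + 10, g10.end + 29, "+", 0, 20)
        assert mir_sbp_synteny([hit], ann, table) == []


def hits_for_pairs(pairs, score=500.0):
    return HomologyTable(
        [
            HomologyHit(a, b, 95.0, 100, 5, 0, 1, 100, 1, 100, 1e-30, score)
            for a, b in pairs
        ]
    ).symmetric_closure()


def f2f_annotation(spec):
    """spec: list of (id, group, strand, start, end)."""
    return AnnotationSet(
        [
            GeneLocus(id=i, chromosome="chr1", start=s, end=e, strand=st,
                      family_member=True, group=g)
            for i, g, st, s, e in spec
        ]
    )


class TestFaceToFace:
    def test_convergent_pair_below_threshold_reported(self):
        ann = f2f_annotation(
            [("a", "g1", "+", 1000, 3000), ("b", "g6", "-", 9001, 11000)]
        )
        pairs = face_to_face_scan(ann)
        assert len(pairs) == 1
        assert pairs[0].gap == 6000
        assert pairs[0].hairpin_region == ("chr1", 3001, 9000)

    def test_gap_exactly_8000_excluded(self):
        ann = f2f_annotation(
            [("a", "g1", "+", 1000, 3000), ("b", "g6", "-", 11001, 13000)]
        )
        assert face_to_face_scan(ann) == []

    def test_gap_7999_included(self):
        ann = f2f_annotation(
            [("a", "g1", "+", 1000, 3000), ("b", "g6", "-", 11000, 13000)]
        )
        assert [p.gap for p in face_to_face_scan(ann)] == [7999]

    def test_same_strand_pair_excluded(self):
        ann = f2f_annotation(
            [("a", "g1", "+", 1000, 3000), ("b", "g6", "+", 9001, 11000)]
        )
        assert face_to_face_scan(ann) == []

    def test_group_order_on_chromosome_is_free(self):
        # g6 gene left, g1 gene right: still a valid convergent pair
        ann = f2f_annotation(
            [("a", "g6", "+", 1000, 3000), ("b", "g1", "-", 9001, 11000)]
        )
        assert len(face_to_face_scan(ann)) == 1

    def test_agrees_with_brute_force_on_synthetic_genome(self, genome):
        ann = genome.annotation
        found = {
            (p.gene_a, p.gene_b) for p in face_to_face_scan(ann)
        }
        expected = set()
        fam = ann.family_members()
        for ga in fam:
            for gb in fam:
                if ga.id >= gb.id:
                    continue
                if {ga.group, gb.group} != {"g1", "g6"}:
                    continue
                if ga.chromosome != gb.chromosome:
                    continue
                left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
                if (
                    left.strand == "+" and right.strand == "-"
                    and left.end < right.start
                    and right.start - left.end - 1 < 8000
                ):
                    expected.add((left.id, right.id))
        assert found == expected

    def test_planted_pairs_recovered_and_boundary_excluded(self, genome):
        found = {(p.gene_a, p.gene_b) for p in face_to_face_scan(genome.annotation)}
        for truth in genome.truth.face_to_face_pairs:
            pair = (truth.gene_a, truth.gene_b)
            if truth.boundary_negative:
                assert pair not in found
            else:
                assert pair in found
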