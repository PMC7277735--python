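"""miR156 locus prediction, target scoring, SBP co-location/synteny and
face-to-face origin detection.

Locus prediction follows the homology route: an exhaustive ungapped
Hamming scan of the genome against reference mature sequences (both
strands, sub-windows down to a minimum matched length), +/-200 nt
precursor extraction truncated at sequence ends, removal of candidates
whose mature hit overlaps a protein-coding gene, and a stem-loop
evaluation of the precursor by base-pair maximization.

Target sites are scored with a psRNATarget-style expectation: mismatch
1.0, G:U wobble 0.5, gap 2.0, all penalties doubled over mature
positions 2-13 (the seed-proximal region); lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dupsynteny import MicroFragment, _support_pairs, make_micro_fragment
from .fold import Structure, fold
from .model import AnnotationSet, HomologyTable

_RC = str.maketrans("ACGTU", "TGCAA")


def revcomp_dna(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_RC)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A reference mature miRNA sequence (RNA alphabet, 19-24 nt)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGU"):
            raise ValueError(f"{self.id}: mature sequence must be RNA (ACGU)")
        if not 19 <= len(seq) <= 24:
            raise ValueError(f"{self.id}: mature length {len(seq)} outside 19-24 nt")
        object.__setattr__(self, "sequence", seq)


def dedupe_matures(matures: Iterable[MatureMiRNA]) -> list[MatureMiRNA]:
    """Drop redundant mature sequences, keeping the first id seen."""
    seen: set[str] = set()
    out = []
    for m in matures:
        if m.sequence not in seen:
            seen.add(m.sequence)
            out.append(m)
    return out


@dataclass
class GenomicHit:
    """An ungapped genomic match to a mature sequence."""

    mature_id: str
    chromosome: str
    start: int  # 1-based closed, + strand coordinates
    end: int
    strand: str
    mismatches: int
    matched_length: int


def _hamming_hits(
    chrom_arr: np.ndarray, pattern: str, max_mismatch: int
) -> tuple[np.ndarray, np.ndarray]:
    """All window starts (0-based) with Hamming distance <= max_mismatch."""
    L = len(pattern)
    if chrom_arr.size < L:
        return np.array([], dtype=int), np.array([], dtype=int)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(chrom_arr, L)
    mm = (windows != pat).sum(axis=1)
    idx = np.nonzero(mm <= max_mismatch)[0]
    return idx, mm[idx]


def mature_scan(
    genome: Mapping[str, str],
    matures: Sequence[MatureMiRNA],
    min_len: int = 19,
    max_mismatch: int = 2,
) -> list[GenomicHit]:
    """Exhaustive ungapped scan of both strands for near-matches.

    Every window matching a mature (or a >= min_len prefix/suffix of it)
    with at most ``max_mismatch`` mismatches is a hit; overlapping hits
    for the same mature on the same strand are merged to the best
    (fewest mismatches, then longest, then leftmost).
    """
    hits: list[GenomicHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper().replace("U", "T")
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for mat in matures:
            dna = mat.sequence.replace("U", "T")
            raw: list[GenomicHit] = []
            windows: list[str] = [dna]
            for L in range(min_len, len(dna)):
                windows.append(dna[:L])   # prefix
                windows.append(dna[-L:])  # suffix
            for strand in "+-":
                for w in dict.fromkeys(windows):
                    pattern = w if strand == "+" else revcomp_dna(w)
                    starts, mms = _hamming_hits(arr, pattern, max_mismatch)
                    for s0, mm in zip(starts, mms):
                        raw.append(
                            GenomicHit(
                                mature_id=mat.id, chromosome=chrom,
                                start=int(s0) + 1, end=int(s0) + len(w),
                                strand=strand, mismatches=int(mm),
                                matched_length=len(w),
                            )
                        )
                # merge overlapping raw hits on this strand
                stranded = sorted(
                    (h for h in raw if h.strand == strand),
                    key=lambda h: (h.start, h.end),
                )
                merged: list[list[GenomicHit]] = []
                for h in stranded:
                    if merged and h.start <= max(x.end for x in merged[-1]):
                        merged[-1].append(h)
                    else:
                        merged.append([h])
                for cluster in merged:
                    best = min(
                        cluster,
                        key=lambda h: (h.mismatches, -h.matched_length, h.start),
                    )
                    hits.append(best)
                raw = [h for h in raw if h.strand != strand]
    hits.sort(key=lambda h: (h.chromosome, h.start, h.strand, h.mature_id))
    return hits


@dataclass
class HairpinEval:
    """Stem-loop evaluation of a precursor around its mature span."""

    structure: Structure
    mature_paired: int
    mature_unpaired: int
    loops_in_mature: int
    single_arm: bool
    passes: bool


@dataclass
class HairpinCriteria:
    """Config-exposed pass criteria (conventional plant-miRNA defaults,
    adjustable because published criteria sets vary)."""

    min_mature_paired: int = 14
    max_star_mismatch: int = 6
    max_loops_in_mature: int = 1
    min_loop: int = 3


@dataclass
class PrecursorCandidate:
    """A mature hit with its extracted precursor and hairpin evaluation."""

    hit: GenomicHit
    sequence: str  # 5'->3' on the hit strand
    start: int  # genomic, + strand coordinates
    end: int
    mature_offset: int  # 0-based offset of the mature within `sequence`
    hairpin: HairpinEval | None = None
    passes_criteria: bool = False

    @property
    def mature_length(self) -> int:
        return self.hit.matched_length


def extract_precursor(
    hit: GenomicHit, genome: Mapping[str, str], flank: int = 200
) -> PrecursorCandidate:
    """Mature hit plus up to ``flank`` nt on each side, truncated at the
    sequence ends; reported 5'->3' on the hit strand."""
    chrom_seq = genome[hit.chromosome]
    start = max(1, hit.start - flank)
    end = min(len(chrom_seq), hit.end + flank)
    seq = chrom_seq[start - 1 : end].upper()
    if hit.strand == "+":
        offset = hit.start - start
    else:
        seq = revcomp_dna(seq)
        offset = end - hit.end
    return PrecursorCandidate(
        hit=hit, sequence=seq, start=start, end=end, mature_offset=offset
    )


def coding_filter(
    candidates: Sequence[PrecursorCandidate], annotation: AnnotationSet
) -> tuple[list[PrecursorCandidate], list[PrecursorCandidate]]:
    """Split candidates into (kept, removed): a candidate is removed when
    its mature-hit interval overlaps any gene feature by >= 1 nt."""
    kept, removed = [], []
    for cand in candidates:
        overlap = annotation.genes_overlapping(
            cand.hit.chromosome, cand.hit.start, cand.hit.end
        )
        (removed if overlap else kept).append(cand)
    return kept, removed


def hairpin_eval(
    candidate: PrecursorCandidate, criteria: HairpinCriteria | None = None
) -> HairpinEval:
    """Fold the precursor and test the stem-loop criteria for the mature.

    The mature must lie on one arm (every paired mature base has its
    partner outside the mature span, all on the same side), be mostly
    paired, differ from its star by few unpaired positions, and contain
    at most ``max_loops_in_mature`` unpaired runs.
    """
    crit = criteria or HairpinCriteria()
    structure = fold(candidate.sequence, min_loop=crit.min_loop)
    lo = candidate.mature_offset
    hi = lo + candidate.mature_length  # exclusive
    partners = [structure.pairs[i] for i in range(lo, hi) if i in structure.pairs]
    n_self = sum(1 for p in partners if lo <= p < hi)
    n_right = sum(1 for p in partners if p >= hi)
    n_left = sum(1 for p in partners if p < lo)
    # the star arm is the side pairing the majority of the mature; stray
    # pairs to the opposite side are flank artifacts of base-pair
    # maximization and count as unpaired
    arm_paired = max(n_right, n_left)
    paired = arm_paired
    unpaired = (hi - lo) - arm_paired
    # self-pairing means the mature spans the terminal loop of its stem
    single_arm = n_self == 0 and arm_paired > 0
    loops = 0
    in_run = False
    for i in range(lo, hi):
        if i not in structure.pairs:
            if not in_run:
                loops += 1
                in_run = True
        else:
            in_run = False
    passes = (
        single_arm
        and paired >= crit.min_mature_paired
        and unpaired <= crit.max_star_mismatch
        and loops <= crit.max_loops_in_mature
    )
    ev = HairpinEval(
        structure=structure, mature_paired=paired, mature_unpaired=unpaired,
        loops_in_mature=loops, single_arm=single_arm, passes=passes,
    )
    candidate.hairpin = ev
    candidate.passes_criteria = passes
    return ev


def predict_loci(
    genome: Mapping[str, str],
    annotation: AnnotationSet,
    matures: Sequence[MatureMiRNA],
    min_len: int = 19,
    max_mismatch: int = 2,
    flank: int = 200,
    criteria: HairpinCriteria | None = None,
) -> dict[str, list[PrecursorCandidate]]:
    """Full locus-prediction pipeline.

    Returns {"passed": ..., "failed_hairpin": ..., "in_coding": ...};
    the scan's mismatch filter has already excluded >= 3-mismatch copies.
    """
    hits = mature_scan(genome, dedupe_matures(matures), min_len, max_mismatch)
    candidates = [extract_precursor(h, genome, flank) for h in hits]
    kept, in_coding = coding_filter(candidates, annotation)
    passed, failed = [], []
    for cand in kept:
        hairpin_eval(cand, criteria)
        (passed if cand.passes_criteria else failed).append(cand)
    return {"passed": passed, "failed_hairpin": failed, "in_coding": in_coding}


# --- target prediction ----------------------------------------------------


@dataclass
class TargetSite:
    """A scored miRNA binding site on a transcript (1-based, closed)."""

    transcript_id: str
    start: int
    end: int
    expectation: float
    breakdown: list[tuple[int, float]]  # (mature position 1-based, penalty)


def perfect_site_for(mature_rna: str) -> str:
    """The transcript window perfectly complementary to a mature
    sequence (antiparallel, RNA alphabet)."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    rna = mature_rna.upper().replace("T", "U")
    return "".join(comp[b] for b in rna)[::-1]


def _pair_penalty(mature_base: str, transcript_base: str) -> float:
    """0 for Watson-Crick, 0.5 for G:U wobble, 1.0 for mismatch."""
    m, t = mature_base, transcript_base
    if (m, t) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
        return 0.0
    if (m, t) in (("G", "U"), ("U", "G")):
        return 0.5
    return 1.0


def target_scan(
    mature: MatureMiRNA | str,
    transcript: str,
    transcript_id: str = "transcript",
    max_expectation: float = 5.0,
    seed_start: int = 2,
    seed_end: int = 13,
    gap_penalty: float = 2.0,
) -> list[TargetSite]:
    """Score candidate binding sites by the declared expectation scheme.

    The mature is aligned antiparallel to the transcript (semi-global:
    mature fully aligned, transcript ends free) minimizing the penalty
    sum; penalties at mature positions ``seed_start..seed_end`` are
    doubled.  Sites with expectation <= ``max_expectation`` are reported,
    overlapping sites collapsed to the best.
    """
    mat = mature.sequence if isinstance(mature, MatureMiRNA) else mature.upper().replace("T", "U")
    tx = transcript.upper().replace("T", "U")
    m, n = len(mat), len(tx)
    if n < m:
        raise ValueError("transcript shorter than the mature sequence")
    rev = mat[::-1]  # rev[k] is mature position m-k (1-based)

    def weight(pos: int) -> float:
        return 2.0 if seed_start <= pos <= seed_end else 1.0

    INF = float("inf")
    dp = np.full((m + 1, n + 1), INF)
    dp[0, :] = 0.0  # free transcript prefix
    for k in range(1, m + 1):
        pos = m - k + 1  # mature position of rev[k-1]
        w = weight(pos)
        dp[k, 0] = dp[k - 1, 0] + gap_penalty * w
        sub = np.array([_pair_penalty(rev[k - 1], tb) * w for tb in tx])
        for j in range(1, n + 1):
            dp[k, j] = min(
                dp[k - 1, j - 1] + sub[j - 1],
                dp[k - 1, j] + gap_penalty * w,
                dp[k, j - 1] + gap_penalty * w,
            )
    ends = [j for j in range(1, n + 1) if dp[m, j] <= max_expectation]
    sites: list[TargetSite] = []
    for j_end in ends:
        k, j = m, j_end
        breakdown: list[tuple[int, float]] = []
        while k > 0:
            pos = m - k + 1
            w = weight(pos)
            if j > 0 and dp[k, j] == dp[k - 1, j - 1] + _pair_penalty(rev[k - 1], tx[j - 1]) * w:
                breakdown.append((pos, _pair_penalty(rev[k - 1], tx[j - 1]) * w))
                k, j = k - 1, j - 1
            elif dp[k, j] == dp[k - 1, j] + gap_penalty * w:
                breakdown.append((pos, gap_penalty * w))
                k -= 1
            else:
                breakdown.append((pos, gap_penalty * w))
                j -= 1
        breakdown.reverse()
        sites.append(
            TargetSite(
                transcript_id=transcript_id, start=j + 1, end=j_end,
                expectation=float(dp[m, j_end]), breakdown=breakdown,
            )
        )
    # collapse overlapping sites to the best expectation
    sites.sort(key=lambda s: (s.start, s.end))
    out: list[TargetSite] = []
    for s in sites:
        if out and s.start <= out[-1].end:
            if (s.expectation, s.start) < (out[-1].expectation, out[-1].start):
                out[-1] = s
        else:
            out.append(s)
    return out


# --- co-location, synteny, face-to-face -----------------------------------


def fragment_span(
    fragment: MicroFragment, annotation: AnnotationSet
) -> tuple[str, int, int]:
    genes = [annotation[g] for g in fragment.genes]
    return fragment.chromosome, min(g.start for g in genes), max(g.end for g in genes)


def co_location(
    hit: GenomicHit,
    fragments: Sequence[MicroFragment],
    annotation: AnnotationSet,
) -> list[str]:
    """Anchors of the fragments whose genomic span contains the hit."""
    out = []
    for frag in fragments:
        chrom, lo, hi = fragment_span(frag, annotation)
        if chrom == hit.chromosome and lo <= hit.start and hit.end <= hi:
            out.append(frag.anchor)
    return out


def mirna_fragment_genes(
    hit: GenomicHit, annotation: AnnotationSet, k: int = 30
) -> list[str]:
    """The nearest <= k genes on each side of a miRNA hit (the miRNA
    itself is not a coding gene, so the window has no anchor gene)."""
    chrom_genes = annotation.genes_on(hit.chromosome)
    n_before = sum(1 for g in chrom_genes if g.start <= hit.start)
    lo = max(0, n_before - k)
    hi = min(len(chrom_genes), n_before + k)
    return [g.id for g in chrom_genes[lo:hi]]


@dataclass
class MirSbpSynteny:
    """A synteny relationship between a miR156 locus and an SBP gene."""

    hit: GenomicHit
    sbp_gene: str
    support: list[tuple[str, str]]


def mir_sbp_synteny(
    hits: Sequence[GenomicHit],
    annotation: AnnotationSet,
    homology: HomologyTable,
    min_pairs: int = 10,
    window: int = 30,
) -> list[MirSbpSynteny]:
    """miR156-anchored fragments vs SBP-anchored fragments, with
    co-locations excluded from the result."""
    family = [g.id for g in annotation.family_members()]
    sbp_fragments = {g: make_micro_fragment(g, annotation, k=window) for g in family}
    out: list[MirSbpSynteny] = []
    for hit in hits:
        mir_genes = mirna_fragment_genes(hit, annotation, k=window)
        colocated = set(
            co_location(hit, list(sbp_fragments.values()), annotation)
        )
        for sbp, frag in sbp_fragments.items():
            if sbp in colocated:
                continue
            support = _support_pairs(mir_genes, frag.genes, homology)
            if len(support) >= min_pairs:
                out.append(MirSbpSynteny(hit=hit, sbp_gene=sbp, support=support))
    return out


@dataclass
class FaceToFacePair:
    """Two convergently transcribed genes with 3' ends facing across a
    short intergenic gap — the candidate substrate for hairpin origin."""

    gene_a: str  # + strand, left
    gene_b: str  # - strand, right
    gap: int
    group_a: str | None
    group_b: str | None
    hairpin_region: tuple[str, int, int]  # chromosome, start, end (may be empty)


def face_to_face_scan(
    annotation: AnnotationSet,
    group_a: str = "g1",
    group_b: str = "g6",
    max_gap: int = 8000,
) -> list[FaceToFacePair]:
    """Convergent pairs with one gene from each group and an intergenic
    gap strictly below ``max_gap``.

    The left gene must be on + and the right on - (3' ends facing); the
    groups may occur in either chromosomal order.  The intergenic
    interval is attached as the candidate hairpin region.
    """
    members_a = [g for g in annotation.family_members() if g.group == group_a]
    members_b = [g for g in annotation.family_members() if g.group == group_b]
    out: list[FaceToFacePair] = []
    for ga in members_a:
        for gb in members_b:
            if ga.chromosome != gb.chromosome:
                continue
            left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
            if left.strand != "+" or right.strand != "-":
                continue
            if left.end >= right.start:
                continue
            gap = right.start - left.end - 1
            if gap >= max_gap:
                continue
            out.append(
                FaceToFacePair(
                    gene_a=left.id, gene_b=right.id, gap=gap,
                    group_a=left.group, group_b=right.group,
                    hairpin_region=(ga.chromosome, left.end + 1, right.start - 1),
                )
            )
    out.sort(key=lambda p: (p.hairpin_region[0], p.gene_a, p.gene_b))
    return out
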