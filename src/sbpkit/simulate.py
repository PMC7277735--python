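"""Synthetic multi-chromosome genomes with planted, ledgered events.

The simulator emulates the genomic structures the analysis stages look
for: a focal gene family (group-labelled, sharing a scorable domain),
tandem duplications (adjacent or with one unrelated spacer gene),
segmental duplications (paired blocks of >= 61 genes with a controlled
fraction of retained homolog pairs diverged to a target Ks), miR156 loci
(exact and mutated copies of reference mature sequences, inside and
outside coding genes, on both strands, with or without a hairpin-forming
inverted-repeat context), convergent face-to-face gene pairs at exact
intergenic distances, and expression matrices with exact planted fold
changes.  Every planted event is recorded in a machine-readable truth
ledger so recovery can be scored without external data.

Simplifications relative to real genomes (single-exon genes, no indel
evolution, uniform substitution process) are deliberate; see the package
documentation for what passing tests do and do not show.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .kaks import (
    GENETIC_CODE,
    STOP_CODONS,
    CodonAlignment,
    SaturationError,
    ng86,
    translate,
)
from .mir156 import MatureMiRNA, revcomp_dna
from .model import AnnotationSet, GeneLocus

_BASES = "ACGT"
_SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)

# Reference mature sequences of the miR156/157 family (miRBase-style);
# the two are treated as one family throughout.
DEFAULT_MATURES = (
    MatureMiRNA("miR156", "UGACAGAAGAGAGUGAGCAC"),
    MatureMiRNA("miR157", "UUGACAGAAGAUAGAGAGCAC"),
)

DEFAULT_GROUPS = ("g1", "g2", "g3", "g4", "g5", "g6", "g7", "g8", "g9", "ds", "ms")

# Root of the synthetic family-defining domain (50 aa, zinc-finger-like
# cysteine/histidine spacing; a synthetic stand-in, not a real profile).
_DOMAIN_ROOT = "MCQVEGCGTDLSKAKQYHRRHKVCEVHAKASSVFLAGLKQRFCQQCSRFH"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome generator.

    The defaults define the reference study conditions used throughout
    the test suite: 2 chromosomes x 300 genes, 5 tandem events, 3
    segmental blocks of 61 genes, 6 miR156 loci of which two are designed
    negatives (one with 3 mismatches, one inside a coding gene), and 3
    face-to-face pairs including one at the excluded boundary gap of
    8000 nt.
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 300
    mean_gene_length: int = 900
    mean_intergenic_gap: int = 2000
    family_fraction: float = 0.05
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    n_tandem_events: int = 5
    n_segmental_events: int = 3
    segmental_block_len: int = 61
    segmental_retention: float = 0.25
    target_ks_values: tuple[float, ...] = (0.3, 0.5, 1.0)
    n_mirna_loci: int = 6
    mirna_mutation_counts: tuple[int, ...] = (0, 1, 2, 0, 3, 0)
    mirna_strands: tuple[str, ...] = ("+", "-", "+", "+", "+", "+")
    mirna_inside_coding: tuple[bool, ...] = (False, False, False, False, False, True)
    mirna_hairpin: tuple[bool, ...] = (True, True, True, True, True, False)
    n_face_to_face_pairs: int = 3
    face_to_face_gaps: tuple[int, ...] = (6000, 3000, 8000)
    face_to_face_groups: tuple[str, str] = ("g1", "g6")
    matures: tuple[MatureMiRNA, ...] = DEFAULT_MATURES

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "genes_per_chromosome": self.genes_per_chromosome,
            "n_tandem_events": self.n_tandem_events,
            "n_segmental_events": self.n_segmental_events,
            "n_mirna_loci": self.n_mirna_loci,
            "n_face_to_face_pairs": self.n_face_to_face_pairs,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, v in (
            ("family_fraction", self.family_fraction),
            ("segmental_retention", self.segmental_retention),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_mirna_loci > 0:
            for name, seq in (
                ("mirna_mutation_counts", self.mirna_mutation_counts),
                ("mirna_strands", self.mirna_strands),
                ("mirna_inside_coding", self.mirna_inside_coding),
                ("mirna_hairpin", self.mirna_hairpin),
            ):
                if len(seq) < self.n_mirna_loci:
                    raise ValueError(f"{name} shorter than n_mirna_loci")
        if self.n_face_to_face_pairs > len(self.face_to_face_gaps):
            raise ValueError("face_to_face_gaps shorter than n_face_to_face_pairs")


# --- truth ledger ---------------------------------------------------------


@dataclass
class TandemTruth:
    source: str
    copy: str
    intervening: int
    target_ks: float


@dataclass
class SegmentalTruth:
    block_a: list[str]
    block_b: list[str]
    retained_pairs: list[tuple[str, str]]
    target_ks: float
    anchor_a: str
    anchor_b: str


@dataclass
class MirnaTruth:
    locus_id: str
    mature_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    mismatches: int
    inside_coding: bool
    hairpin: bool
    designed_negative: bool


@dataclass
class FaceToFaceTruth:
    gene_a: str  # left gene
    gene_b: str  # right gene
    gap: int
    convergent: bool
    boundary_negative: bool  # gap >= detection threshold by design


@dataclass
class SyntheticTruth:
    """Machine-readable ledger of every planted event."""

    tandem_pairs: list[TandemTruth] = field(default_factory=list)
    segmental_blocks: list[SegmentalTruth] = field(default_factory=list)
    mirna_loci: list[MirnaTruth] = field(default_factory=list)
    face_to_face_pairs: list[FaceToFaceTruth] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": "sbpkit-truth-1",
            "tandem_pairs": [asdict(t) for t in self.tandem_pairs],
            "segmental_blocks": [asdict(s) for s in self.segmental_blocks],
            "mirna_loci": [asdict(m) for m in self.mirna_loci],
            "face_to_face_pairs": [asdict(f) for f in self.face_to_face_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != "sbpkit-truth-1":
            raise ValueError("unrecognized truth-ledger schema")
        truth = cls()
        truth.tandem_pairs = [TandemTruth(**t) for t in payload["tandem_pairs"]]
        truth.segmental_blocks = [
            SegmentalTruth(
                block_a=s["block_a"], block_b=s["block_b"],
                retained_pairs=[tuple(p) for p in s["retained_pairs"]],
                target_ks=s["target_ks"], anchor_a=s["anchor_a"],
                anchor_b=s["anchor_b"],
            )
            for s in payload["segmental_blocks"]
        ]
        truth.mirna_loci = [MirnaTruth(**m) for m in payload["mirna_loci"]]
        truth.face_to_face_pairs = [
            FaceToFaceTruth(**f) for f in payload["face_to_face_pairs"]
        ]
        return truth


# --- CDS evolution --------------------------------------------------------


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop."""
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)
    )
    return "ATG" + body + "TAA"


def _pair_ks_ka(original: str, current: str) -> tuple[float, float]:
    aln = CodonAlignment.from_ungapped(original, current)
    res = ng86(aln)
    return res.ks, res.ka


def evolve_cds(
    cds: str,
    target_ks: float,
    target_ka: float,
    seed: int | np.random.Generator,
) -> str:
    """Apply random point substitutions until the NG86 + Jukes-Cantor
    estimate of the (input, output) pair reaches the targets.

    Synonymous substitutions are accepted while Ks is below target,
    nonsynonymous ones while Ka is; substitutions creating a stop codon
    are resampled, so the frame and translatability are preserved.  A
    trailing stop codon is never touched.  Targets near the Jukes-Cantor
    saturation limit are rejected.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    if target_ks < 0 or target_ka < 0:
        raise ValueError("divergence targets must be >= 0")
    for target in (target_ks, target_ka):
        p_needed = 0.75 * (1.0 - math.exp(-4.0 * target / 3.0))
        if p_needed >= 0.74:
            raise SaturationError(
                f"target divergence {target} is beyond the Jukes-Cantor limit"
            )
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n = len(codons)
    mutable = n - 1 if codons[-1] in STOP_CODONS else n
    for i, c in enumerate(codons[:mutable]):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i + 1}")
    if mutable == 0:
        raise ValueError("no mutable codons")
    if target_ks == 0 and target_ka == 0:
        return cds
    original = codons[:]
    ks_hat = ka_hat = 0.0
    max_proposals = 500 * n + 10_000
    proposals = 0
    while ks_hat < target_ks or ka_hat < target_ka:
        proposals += 1
        if proposals > max_proposals:
            raise SaturationError(
                f"divergence targets (Ks={target_ks}, Ka={target_ka}) not "
                f"reached after {max_proposals} proposals: saturated"
            )
        ci = int(rng.integers(0, mutable))
        pos = int(rng.integers(0, 3))
        base = _BASES[int(rng.integers(0, 4))]
        cur = codons[ci]
        if base == cur[pos]:
            continue
        mutant = cur[:pos] + base + cur[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[cur]
        if synonymous and ks_hat >= target_ks:
            continue
        if not synonymous and ka_hat >= target_ka:
            continue
        codons[ci] = mutant
        try:
            ks_hat, ka_hat = _pair_ks_ka("".join(original), "".join(codons))
        except SaturationError:
            codons[ci] = cur  # back out the saturating substitution
    return "".join(codons)


# --- the generator --------------------------------------------------------


@dataclass
class _PlannedGene:
    id: str
    cds: str
    strand: str
    family: bool = False
    group: str | None = None
    forced_gap_before: int | None = None


@dataclass
class SyntheticGenome:
    """In-memory result of a simulation run."""

    config: SimulationConfig
    genome: dict[str, str]
    annotation: AnnotationSet
    proteins: dict[str, str]
    cds: dict[str, str]
    matures: list[MatureMiRNA]
    truth: SyntheticTruth
    domain_instances: list[str]

    def domain_model(self, max_negatives: int = 200):
        """PSSM over the group domain variants, threshold calibrated
        midway between the weakest family protein and the strongest
        background window (the labels are known here by construction)."""
        from .seqtools import DomainModel

        model = DomainModel.from_sequences(self.domain_instances)
        positives = [g.protein for g in self.annotation.family_members()]
        negatives = [
            g.protein for g in self.annotation
            if not g.family_member and len(g.protein) >= model.length
        ][:max_negatives]
        model.calibrate(positives, negatives)
        return model

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_fasta(self.genome, outdir / "genome.fa")
        sio.write_gff3(self.annotation, outdir / "annotation.gff3")
        sio.write_fasta(self.proteins, outdir / "proteins.fa")
        sio.write_fasta(self.cds, outdir / "cds.fa")
        sio.write_fasta(
            {m.id: m.sequence for m in self.matures}, outdir / "matures.fa"
        )
        with open(outdir / "domains.fa", "w") as fh:
            for i, d in enumerate(self.domain_instances):
                fh.write(f">domain_{i + 1}\n{d}\n")
        if self.domain_instances:
            self.domain_model().to_tsv(outdir / "domain_model.tsv")
        self.truth.to_json(outdir / "truth.json")


class GenomeSimulator:
    """Two-stage builder: gene-plan operations first, coordinates next,
    then sequence-level operations (miRNA planting), then emission."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.truth = SyntheticTruth()
        self._counter = 0
        self._mir_counter = 0
        self.chroms: dict[str, list[_PlannedGene]] = {}
        self.group_ancestors: dict[str, str] = {}
        self.group_domains: dict[str, str] = {}
        self._coords: dict[str, tuple[str, int, int]] | None = None
        self._seqs: dict[str, np.ndarray] | None = None
        self._used_mirna: dict[str, list[tuple[int, int]]] = {}

    # -- id helpers --

    def _new_id(self) -> str:
        self._counter += 1
        return f"G{self._counter:05d}"

    # -- sequence factories --

    def _n_codons(self) -> int:
        mean = max(60, self.config.mean_gene_length // 3)
        n = int(self.rng.normal(mean, mean / 6))
        return max(60, n)

    def _background_gene(self) -> _PlannedGene:
        return _PlannedGene(
            id=self._new_id(),
            cds=random_cds(self.rng, self._n_codons()),
            strand="+" if self.rng.random() < 0.5 else "-",
        )

    def _domain_for_group(self, group: str) -> str:
        if group not in self.group_domains:
            aas = "ACDEFGHIKLMNPQRSTVWY"
            domain = list(_DOMAIN_ROOT)
            n_mut = int(round(0.3 * len(domain)))
            sites = self.rng.choice(len(domain), size=n_mut, replace=False)
            for s in sites:
                choices = [a for a in aas if a != domain[s]]
                domain[s] = choices[int(self.rng.integers(0, len(choices)))]
            self.group_domains[group] = "".join(domain)
        return self.group_domains[group]

    def _ancestor_for_group(self, group: str) -> str:
        if group not in self.group_ancestors:
            domain_aa = self._domain_for_group(group)
            # encode the domain with one fixed codon per amino acid
            codon_for = {}
            for codon in _SENSE_CODONS:
                codon_for.setdefault(GENETIC_CODE[codon], codon)
            domain_cds = "".join(codon_for[a] for a in domain_aa)
            n = max(60, self._n_codons())
            flank = random_cds(self.rng, n)
            insert_at = 3 * (10 + int(self.rng.integers(0, 20)))
            cds = flank[:insert_at] + domain_cds + flank[insert_at:]
            self.group_ancestors[group] = cds
        return self.group_ancestors[group]

    def _family_gene(self, group: str, ks: float = 0.15, ka: float = 0.03) -> _PlannedGene:
        ancestor = self._ancestor_for_group(group)
        cds = evolve_cds(ancestor, ks, ka, self.rng)
        return _PlannedGene(
            id=self._new_id(), cds=cds,
            strand="+" if self.rng.random() < 0.5 else "-",
            family=True, group=group,
        )

    # -- stage A: gene plan --

    def build_backbone(self) -> None:
        cfg = self.config
        for c in range(1, cfg.n_chromosomes + 1):
            genes: list[_PlannedGene] = []
            for _ in range(cfg.genes_per_chromosome):
                if cfg.group_labels and self.rng.random() < cfg.family_fraction:
                    group = cfg.group_labels[
                        int(self.rng.integers(0, len(cfg.group_labels)))
                    ]
                    genes.append(self._family_gene(group))
                else:
                    genes.append(self._background_gene())
            self.chroms[f"chr{c}"] = genes

    def plant_tandem_duplication(
        self, gene_id: str, intervening: int, target_ks: float
    ) -> str:
        """Insert a diverged copy adjacent to the source gene, optionally
        separated by one fresh non-homologous spacer gene."""
        if intervening not in (0, 1):
            raise ValueError("intervening must be 0 or 1")
        for chrom, genes in self.chroms.items():
            for idx, g in enumerate(genes):
                if g.id == gene_id:
                    copy = _PlannedGene(
                        id=self._new_id(),
                        cds=evolve_cds(g.cds, target_ks, target_ks / 8.0, self.rng),
                        strand=g.strand, family=g.family, group=g.group,
                    )
                    insert = [copy]
                    if intervening == 1:
                        insert = [self._background_gene(), copy]
                    genes[idx + 1 : idx + 1] = insert
                    self.truth.tandem_pairs.append(
                        TandemTruth(
                            source=gene_id, copy=copy.id,
                            intervening=intervening, target_ks=target_ks,
                        )
                    )
                    return copy.id
        raise ValueError(f"gene {gene_id} not found; no room to duplicate")

    def _block_spans(self, chrom: str) -> list[tuple[int, int]]:
        """Index spans of previously planted blocks on a chromosome."""
        idx = {g.id: i for i, g in enumerate(self.chroms[chrom])}
        spans = []
        for t in self.truth.segmental_blocks:
            for block in (t.block_a, t.block_b):
                pos = [idx[i] for i in block if i in idx]
                if len(pos) >= 2:
                    spans.append((min(pos), max(pos)))
        return spans

    def plant_segmental_block(
        self,
        block_len: int,
        retention: float,
        target_ks: float,
        src_chrom: str | None = None,
        dst_chrom: str | None = None,
    ) -> SegmentalTruth:
        """Copy a run of ``block_len`` genes into a new block elsewhere,
        retaining ceil(retention * block_len) diverged homolog pairs
        (order preserved); the central gene pair is a family anchor.

        Source runs and insertion points avoid previously planted blocks,
        so no block is ever split or double-copied.
        """
        n_retained = math.ceil(retention * block_len)
        if n_retained < 1:
            raise ValueError("retention yields < 1 homolog pair: undetectable block")

        def free_starts(chrom: str) -> list[int]:
            genes = self.chroms[chrom]
            spans = self._block_spans(chrom)
            return [
                s for s in range(len(genes) - block_len + 1)
                if all(s + block_len <= lo or s > hi for lo, hi in spans)
            ]

        if src_chrom is None:
            candidates = [c for c in sorted(self.chroms) if free_starts(c)]
            if not candidates:
                raise ValueError(
                    f"no chromosome with {block_len} free genes available for a block"
                )
            src_chrom = candidates[int(self.rng.integers(0, len(candidates)))]
        src_genes = self.chroms[src_chrom]
        starts = free_starts(src_chrom)
        if not starts:
            raise ValueError(
                f"chromosome {src_chrom} has no free run of {block_len} genes"
            )
        start = starts[int(self.rng.integers(0, len(starts)))]
        block_a = src_genes[start : start + block_len]
        center = block_len // 2
        anchor_src = block_a[center]
        if not anchor_src.family:
            # promote the central gene so both blocks carry a family anchor
            group = self.config.group_labels[
                int(self.rng.integers(0, len(self.config.group_labels)))
            ]
            promoted = self._family_gene(group)
            anchor_src.cds = promoted.cds
            anchor_src.family = True
            anchor_src.group = promoted.group
        retained_idx = {center}
        others = [i for i in range(block_len) if i != center]
        pick = self.rng.choice(len(others), size=n_retained - 1, replace=False)
        retained_idx.update(others[i] for i in pick)
        if dst_chrom is None:
            other = [c for c in self.chroms if c != src_chrom]
            dst_chrom = (
                other[int(self.rng.integers(0, len(other)))] if other else src_chrom
            )
        block_b: list[_PlannedGene] = []
        retained_pairs: list[tuple[str, str]] = []
        anchor_b_id = ""
        for i, src in enumerate(block_a):
            if i in retained_idx:
                copy = _PlannedGene(
                    id=self._new_id(),
                    cds=evolve_cds(src.cds, target_ks, target_ks / 8.0, self.rng),
                    strand=src.strand, family=src.family, group=src.group,
                )
                retained_pairs.append((src.id, copy.id))
                if i == center:
                    anchor_b_id = copy.id
                block_b.append(copy)
            else:
                block_b.append(self._background_gene())
        dst_genes = self.chroms[dst_chrom]
        # insertion must not split the source run or any planted block
        forbidden = [(start, start + block_len - 1)] if dst_chrom == src_chrom else []
        forbidden += self._block_spans(dst_chrom)
        positions = [
            p for p in range(len(dst_genes) + 1)
            if all(p <= lo or p > hi for lo, hi in forbidden)
        ]
        if not positions:
            raise ValueError(f"no room for a block on {dst_chrom}")
        at = positions[int(self.rng.integers(0, len(positions)))]
        dst_genes[at:at] = block_b
        truth = SegmentalTruth(
            block_a=[g.id for g in block_a],
            block_b=[g.id for g in block_b],
            retained_pairs=retained_pairs,
            target_ks=target_ks,
            anchor_a=anchor_src.id,
            anchor_b=anchor_b_id,
        )
        self.truth.segmental_blocks.append(truth)
        return truth

    def plant_face_to_face_pair(
        self,
        group_a: str,
        group_b: str,
        gap: int,
        convergent: bool = True,
        boundary_negative: bool = False,
    ) -> tuple[str, str]:
        """Insert two new family genes with an exact intergenic gap; with
        ``convergent`` the left gene is + and the right -, 3' ends facing."""
        if gap < 0:
            raise ValueError("gap must be >= 0")
        left = self._family_gene(group_a)
        right = self._family_gene(group_b)
        if convergent:
            left.strand, right.strand = "+", "-"
        else:
            left.strand = right.strand = "+"
        right.forced_gap_before = gap
        chrom = f"chr{1 + int(self.rng.integers(0, self.config.n_chromosomes))}"
        genes = self.chroms[chrom]
        spans = self._block_spans(chrom)
        positions = [
            p for p in range(len(genes) + 1)
            if all(p <= lo or p > hi for lo, hi in spans)
        ]
        at = positions[int(self.rng.integers(0, len(positions)))]
        genes[at:at] = [left, right]
        self.truth.face_to_face_pairs.append(
            FaceToFaceTruth(
                gene_a=left.id, gene_b=right.id, gap=gap,
                convergent=convergent, boundary_negative=boundary_negative,
            )
        )
        return left.id, right.id

    # -- stage B: coordinates and raw sequence --

    def assign_coordinates(self) -> None:
        coords: dict[str, tuple[str, int, int]] = {}
        seqs: dict[str, np.ndarray] = {}
        cfg = self.config
        for chrom in sorted(self.chroms):
            pos = 0
            placed = []
            for g in self.chroms[chrom]:
                if g.forced_gap_before is not None:
                    gap = g.forced_gap_before
                else:
                    gap = max(
                        100, int(self.rng.normal(cfg.mean_intergenic_gap,
                                                 cfg.mean_intergenic_gap / 4))
                    )
                start = pos + gap + 1
                end = start + len(g.cds) - 1
                coords[g.id] = (chrom, start, end)
                placed.append((g, start, end))
                pos = end
            total = pos + max(100, cfg.mean_intergenic_gap)
            arr = np.frombuffer(
                bytes("".join(_BASES[i] for i in self.rng.integers(0, 4, total)),
                      "ascii"),
                dtype=np.uint8,
            ).copy()
            for g, start, end in placed:
                seq = g.cds if g.strand == "+" else revcomp_dna(g.cds)
                arr[start - 1 : end] = np.frombuffer(seq.encode(), dtype=np.uint8)
            seqs[chrom] = arr
        self._coords = coords
        self._seqs = seqs

    # -- stage C: miRNA planting on the assembled sequence --

    def _mutate_mature(self, mature_dna: str, mismatches: int) -> str:
        """Mutate exactly `mismatches` interior positions (never the two
        bases at either end, so no sub-window evades the mismatch count)."""
        L = len(mature_dna)
        if mismatches == 0:
            return mature_dna
        interior = np.arange(2, L - 2)
        sites = self.rng.choice(len(interior), size=mismatches, replace=False)
        out = list(mature_dna)
        for s in sites:
            i = int(interior[s])
            choices = [b for b in _BASES if b != out[i]]
            out[i] = choices[int(self.rng.integers(0, len(choices)))]
        return "".join(out)

    def _free_intergenic_slot(self, length: int, margin: int = 250) -> tuple[str, int]:
        """A +strand offset inside an intergenic interval with `margin` nt
        clearance from the nearest gene and other planted loci."""
        assert self._coords is not None and self._seqs is not None
        for _ in range(500):
            chrom = f"chr{1 + int(self.rng.integers(0, self.config.n_chromosomes))}"
            genes = [
                (s, e) for (c, s, e) in self._coords.values() if c == chrom
            ]
            genes.sort()
            arr = self._seqs[chrom]
            bounds = [(0, genes[0][0] - 1)] if genes else [(0, len(arr))]
            for (s1, e1), (s2, e2) in zip(genes, genes[1:]):
                bounds.append((e1, s2 - 1))
            gaps = [
                (lo, hi) for lo, hi in bounds
                if hi - lo >= length + 2 * margin
            ]
            if not gaps:
                continue
            lo, hi = gaps[int(self.rng.integers(0, len(gaps)))]
            start = int(self.rng.integers(lo + margin, hi - margin - length + 1)) + 1
            interval = (start, start + length - 1)
            clash = any(
                not (interval[1] < s - margin or interval[0] > e + margin)
                for s, e in self._used_mirna.get(chrom, [])
            )
            if clash:
                continue
            self._used_mirna.setdefault(chrom, []).append(interval)
            return chrom, start
        raise ValueError("no intergenic room for a miRNA locus")

    def plant_mirna_locus(
        self,
        mature: MatureMiRNA,
        mismatches: int,
        strand: str,
        inside_coding: bool,
        hairpin: bool,
        max_mismatch_rule: int = 2,
    ) -> MirnaTruth:
        """Write a (possibly mutated) copy of the mature sequence into the
        assembled genome, with an inverted-repeat star arm when a hairpin
        context is requested."""
        assert self._coords is not None and self._seqs is not None, (
            "assign_coordinates() must run before miRNA planting"
        )
        if strand not in "+-":
            raise ValueError("strand must be + or -")
        mature_dna = mature.sequence.replace("U", "T")
        planted = self._mutate_mature(mature_dna, mismatches)
        L = len(planted)
        self._mir_counter += 1
        locus_id = f"MIR{self._mir_counter:03d}"
        if inside_coding:
            hosts = [
                (gid, c, s, e)
                for gid, (c, s, e) in sorted(self._coords.items())
                if e - s + 1 >= L + 40 and not self._gene_is_family(gid)
            ]
            if not hosts:
                raise ValueError("no coding gene available to host the locus")
            gid, chrom, gs, ge = hosts[int(self.rng.integers(0, len(hosts)))]
            offset = int(self.rng.integers(gs + 10, ge - 10 - L + 1))
            start = offset
            block = planted if strand == "+" else revcomp_dna(planted)
            self._seqs[chrom][start - 1 : start - 1 + L] = np.frombuffer(
                block.encode(), dtype=np.uint8
            )
            end = start + L - 1
        else:
            loop = "".join(
                _BASES[i] for i in self.rng.integers(0, 4, 8)
            )
            unit_len = L + 8 + L if hairpin else L
            chrom, ustart = self._free_intergenic_slot(unit_len)
            arr = self._seqs[chrom]
            if strand == "+":
                start = ustart
            else:
                # on -, the mature reads 5'->3' from the right edge
                start = ustart + unit_len - L
            end = start + L - 1
            for attempt in range(50):
                unit = planted + loop + revcomp_dna(planted) if hairpin else planted
                if strand == "-":
                    unit = revcomp_dna(unit)
                arr[ustart - 1 : ustart - 1 + unit_len] = np.frombuffer(
                    unit.encode(), dtype=np.uint8
                )
                if mismatches <= max_mismatch_rule:
                    break
                # a designed mismatch-negative must evade EVERY reference
                # mature (similar family members can otherwise still match
                # within the rule); resample the mutation until it does
                if not self._neighbourhood_hit(chrom, start, end, max_mismatch_rule):
                    break
                planted = self._mutate_mature(mature_dna, mismatches)
            else:
                raise ValueError(
                    f"could not plant a {mismatches}-mismatch negative that "
                    f"evades all reference matures"
                )
        truth = MirnaTruth(
            locus_id=locus_id, mature_id=mature.id, chromosome=chrom,
            start=start, end=end, strand=strand, mismatches=mismatches,
            inside_coding=inside_coding, hairpin=hairpin,
            designed_negative=(mismatches > max_mismatch_rule) or inside_coding,
        )
        self.truth.mirna_loci.append(truth)
        return truth

    def _neighbourhood_hit(
        self, chrom: str, start: int, end: int, max_mismatch: int
    ) -> bool:
        """True when a scan of the planted locus's neighbourhood against
        all reference matures yields a hit covering [start, end]."""
        from .mir156 import mature_scan

        arr = self._seqs[chrom]
        lo = max(1, start - 40)
        hi = min(len(arr), end + 40)
        local = arr[lo - 1 : hi].tobytes().decode()
        hits = mature_scan(
            {chrom: local}, list(self.config.matures), max_mismatch=max_mismatch
        )
        return any(
            h.start + lo - 1 <= start and end <= h.end + lo - 1 for h in hits
        )

    def _gene_is_family(self, gene_id: str) -> bool:
        for genes in self.chroms.values():
            for g in genes:
                if g.id == gene_id:
                    return g.family
        return False

    # -- emission --

    def emit(self) -> SyntheticGenome:
        assert self._coords is not None and self._seqs is not None
        genome = {c: self._seqs[c].tobytes().decode() for c in sorted(self._seqs)}
        loci = []
        proteins: dict[str, str] = {}
        cds_map: dict[str, str] = {}
        for chrom in sorted(self.chroms):
            for g in self.chroms[chrom]:
                c, s, e = self._coords[g.id]
                raw = genome[c][s - 1 : e]
                cds = raw if g.strand == "+" else revcomp_dna(raw)
                prot = translate(cds).rstrip("*")
                loci.append(
                    GeneLocus(
                        id=g.id, chromosome=c, start=s, end=e, strand=g.strand,
                        family_member=g.family, group=g.group,
                        protein=prot, cds=cds,
                    )
                )
                proteins[g.id] = prot
                cds_map[g.id] = cds
        annotation = AnnotationSet(loci)
        domains = sorted(self.group_domains.values())
        return SyntheticGenome(
            config=self.config, genome=genome, annotation=annotation,
            proteins=proteins, cds=cds_map,
            matures=list(self.config.matures), truth=self.truth,
            domain_instances=domains,
        )


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Run the full simulation: backbone, planted events, coordinates,
    miRNA loci, emission.  Identical config => identical output."""
    config.validate()
    sim = GenomeSimulator(config)
    sim.build_backbone()
    cfg = config
    ks_cycle = list(cfg.target_ks_values) or [0.5]

    # segmental blocks first (they add the most genes)
    for i in range(cfg.n_segmental_events):
        sim.plant_segmental_block(
            block_len=cfg.segmental_block_len,
            retention=cfg.segmental_retention,
            target_ks=ks_cycle[i % len(ks_cycle)],
        )

    # tandem events on family genes not already used
    family_pool = [
        g.id
        for chrom in sorted(sim.chroms)
        for g in sim.chroms[chrom]
        if g.family
    ]
    used: set[str] = set()
    for i in range(cfg.n_tandem_events):
        pool = [g for g in family_pool if g not in used]
        if not pool:
            raise ValueError(
                "no family gene available for a tandem event on any chromosome"
            )
        src = pool[int(sim.rng.integers(0, len(pool)))]
        used.add(src)
        sim.plant_tandem_duplication(
            src, intervening=i % 2, target_ks=ks_cycle[i % len(ks_cycle)]
        )

    for i in range(cfg.n_face_to_face_pairs):
        gap = cfg.face_to_face_gaps[i]
        sim.plant_face_to_face_pair(
            cfg.face_to_face_groups[0], cfg.face_to_face_groups[1],
            gap=gap, convergent=True, boundary_negative=gap >= 8000,
        )

    sim.assign_coordinates()

    for i in range(cfg.n_mirna_loci):
        sim.plant_mirna_locus(
            mature=cfg.matures[i % len(cfg.matures)],
            mismatches=cfg.mirna_mutation_counts[i],
            strand=cfg.mirna_strands[i],
            inside_coding=cfg.mirna_inside_coding[i],
            hairpin=cfg.mirna_hairpin[i],
        )
    return sim.emit()


# --- expression matrices --------------------------------------------------


def generate_expression_matrix(
    genes: Sequence[str],
    conditions: Sequence[str],
    planted_responses: dict[str, list[tuple[str, float]]],
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[tuple[str, float]]]]:
    """Control/treatment expression columns with exact planted folds.

    Every condition gets a ``<cond>_control`` and ``<cond>_treat`` column;
    planted (condition, fold) responses are realized exactly before any
    noise (bounded, applied to non-planted cells only so the planted
    ratios stay exact).  Folds must be > 0; unknown gene ids are errors.
    """
    rng = np.random.default_rng(seed)
    gene_set = set(genes)
    for g, resp in planted_responses.items():
        if g not in gene_set:
            raise ValueError(f"unknown gene id in planted responses: {g}")
        for cond, fold in resp:
            if cond not in conditions:
                raise ValueError(f"unknown condition {cond!r} for gene {g}")
            if fold <= 0:
                raise ValueError("planted folds must be > 0")
    columns: dict[str, list[float]] = {}
    planted = {
        (g, c): fold
        for g, resp in planted_responses.items()
        for c, fold in resp
    }
    for cond in conditions:
        ctrl, treat = [], []
        for g in genes:
            c = baseline
            fold = planted.get((g, cond))
            if fold is None:
                t = baseline
                if noise_sd > 0:
                    t = max(0.0, t + float(rng.normal(0, noise_sd)))
                    c = max(0.0, c + float(rng.normal(0, noise_sd)))
            else:
                t = baseline * fold
            ctrl.append(c)
            treat.append(t)
        columns[f"{cond}_control"] = ctrl
        columns[f"{cond}_treat"] = treat
    df = pd.DataFrame(columns, index=list(genes))
    df.index.name = "gene"
    return df, planted_responses
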