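"""Protein sequence utilities: pairwise alignment, the internal fallback
homology search, PSSM domain scanning, group assignment and
physicochemical properties.

The domain scanner is a position-specific score matrix (PSSM) surrogate
for a profile-HMM search: family membership is decided by the best
ungapped window score against a calibrated threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import GeneLocus, HomologyHit, HomologyTable  # noqa: F401  (re-export)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Karlin-Altschul constants for gapped BLOSUM62 11/1 searches; used only
# as a monotone E-value surrogate, calibration is not claimed.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class Alignment:
    """A pairwise global alignment with affine gap costs."""

    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity(self) -> float:
        pairs = [
            (x, y) for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        ]
        if not pairs:
            return 0.0
        return sum(x == y for x, y in pairs) / len(pairs)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length k costs open + k * extend (BLAST convention)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Optimal global alignment with affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend``.  Empty input
    is rejected.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    result = aligner.align(a, b)
    best = result[0]
    return Alignment(aligned_a=best[0], aligned_b=best[1], score=result.score)


def align_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Score-only variant of :func:`global_align` (faster, no traceback)."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    return _make_aligner(matrix, gap_open, gap_extend).score(a, b)


def evalue_surrogate(score: float, m: int, n: int) -> float:
    """Monotone E-value surrogate: Karlin-Altschul form K*m*n*exp(-lambda*S).

    Downstream code only thresholds this quantity; absolute calibration
    against any particular search engine is not claimed.
    """
    log_e = math.log(_KA_K) + math.log(m) + math.log(n) - _KA_LAMBDA * score
    if log_e < -700:
        return 0.0
    return math.exp(log_e)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def internal_homology_search(
    proteins: Mapping[str, str],
    score_threshold: float = 50.0,
    prefilter_k: int | None = 5,
    min_shared_kmers: int = 8,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> HomologyTable:
    """All-vs-all protein homology via global alignment.

    With ``prefilter_k`` set, only pairs sharing at least
    ``min_shared_kmers`` exact k-mers are aligned (a seeding heuristic in
    the spirit of word-based search engines); ``prefilter_k=None`` aligns
    every pair.  Pairs scoring >= ``score_threshold`` are reported with an
    E-value surrogate.
    """
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValueError("need at least 2 proteins")
    if prefilter_k is None:
        candidates = list(combinations(ids, 2))
    else:
        kmers = {i: _kmer_set(proteins[i], prefilter_k) for i in ids}
        index: dict[str, list[str]] = {}
        for i in ids:
            for km in kmers[i]:
                index.setdefault(km, []).append(i)
        shared: dict[tuple[str, str], int] = {}
        for members in index.values():
            if len(members) < 2:
                continue
            for a, b in combinations(members, 2):
                shared[(a, b)] = shared.get((a, b), 0) + 1
        candidates = [p for p, c in sorted(shared.items()) if c >= min_shared_kmers]
    hits: list[HomologyHit] = []
    for a, b in candidates:
        aln = global_align(proteins[a], proteins[b], matrix, gap_open, gap_extend)
        if aln.score < score_threshold:
            continue
        cols = [
            (x, y) for x, y in zip(aln.aligned_a, aln.aligned_b)
            if x != "-" and y != "-"
        ]
        n_ident = sum(x == y for x, y in cols)
        gapopen = sum(
            1
            for i in range(len(aln.aligned_a))
            if (aln.aligned_a[i] == "-" and (i == 0 or aln.aligned_a[i - 1] != "-"))
            or (aln.aligned_b[i] == "-" and (i == 0 or aln.aligned_b[i - 1] != "-"))
        )
        length = len(aln.aligned_a)
        ev = evalue_surrogate(aln.score, len(proteins[a]), len(proteins[b]))
        hit = HomologyHit(
            query=a, subject=b,
            pident=100.0 * n_ident / len(cols) if cols else 0.0,
            length=length, mismatch=len(cols) - n_ident, gapopen=gapopen,
            qstart=1, qend=len(proteins[a]),
            sstart=1, send=len(proteins[b]),
            evalue=ev, bitscore=aln.score,
        )
        hits.append(hit)
    return HomologyTable(hits).symmetric_closure()


@dataclass
class DomainModel:
    """Position-specific score matrix over the 20 standard amino acids.

    ``matrix`` has shape (length, 20); log2-odds scores against a uniform
    background.  ``threshold`` is the window-score cut-off deciding family
    membership.
    """

    matrix: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(AMINO_ACIDS):
            raise ValueError("PSSM must have shape (length, 20)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PSSM scores must be finite")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in self.matrix.argmax(axis=1))

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        pseudocount: float = 0.5,
        threshold_fraction: float = 0.6,
    ) -> "DomainModel":
        """Build a PSSM from equal-length (gap-free) domain instances.

        The default threshold is ``threshold_fraction`` of the maximum
        achievable window score; calibrate() refines it from labelled
        examples.
        """
        if not sequences:
            raise ValueError("need at least one sequence")
        L = len(sequences[0])
        if any(len(s) != L for s in sequences):
            raise ValueError("domain instances must have equal length")
        counts = np.full((L, len(AMINO_ACIDS)), pseudocount)
        for s in sequences:
            for i, aa in enumerate(s.upper()):
                if aa not in _AA_INDEX:
                    raise ValueError(f"non-standard residue {aa!r} in domain instance")
                counts[i, _AA_INDEX[aa]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        matrix = np.log2(freqs * len(AMINO_ACIDS))
        model = cls(matrix=matrix, threshold=0.0)
        model.threshold = threshold_fraction * model.max_score
        return model

    def calibrate(self, positives: Iterable[str], negatives: Iterable[str]) -> float:
        """Set the threshold midway between the weakest positive and the
        strongest negative window score."""
        pos = [scan_domain(p, self, use_threshold=False).score for p in positives]
        neg = [scan_domain(n, self, use_threshold=False).score for n in negatives]
        if not pos:
            raise ValueError("need at least one positive example")
        lo = max(neg) if neg else min(pos) - 1.0
        hi = min(pos)
        if lo >= hi:
            raise ValueError("positives and negatives are not separable")
        self.threshold = 0.5 * (lo + hi)
        return self.threshold

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#threshold\t%.6f\n" % self.threshold)
            fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, row in enumerate(self.matrix):
                fh.write(str(i + 1) + "\t" + "\t".join("%.6f" % x for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainModel":
        threshold = None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#threshold"):
                    threshold = float(line.split("\t")[1])
                    continue
                if not line or line.startswith("pos\t"):
                    continue
                rows.append([float(x) for x in line.split("\t")[1:]])
        if threshold is None:
            raise ValueError("PSSM file lacks a #threshold line")
        return cls(matrix=np.array(rows), threshold=threshold)


@dataclass
class DomainHit:
    score: float
    offset: int  # 0-based window start in the protein
    is_hit: bool


def scan_domain(
    protein: str, model: DomainModel, use_threshold: bool = True
) -> DomainHit | None:
    """Best ungapped PSSM window on the protein; None if it is shorter
    than the model.  Non-standard residues score the column minimum."""
    protein = protein.upper()
    n, L = len(protein), model.length
    if n < L:
        return None
    col_min = model.matrix.min(axis=1)
    enc = np.array([_AA_INDEX.get(aa, -1) for aa in protein])
    n_windows = n - L + 1
    scores = np.zeros(n_windows)
    for j in range(L):
        idx = enc[j : j + n_windows]
        col = np.where(idx >= 0, model.matrix[j][idx], col_min[j])
        scores += col
    best = int(scores.argmax())
    score = float(scores[best])
    is_hit = (score >= model.threshold) if use_threshold else True
    return DomainHit(score=score, offset=best, is_hit=is_hit)


@dataclass
class GroupCall:
    """Result of nearest-reference group assignment."""

    label: str | None
    score: float
    ambiguous: bool


def assign_group(
    query: str, references: Mapping[str, Sequence[str]]
) -> GroupCall:
    """Assign the label of the best-scoring reference group.

    ``references`` maps label -> reference protein sequences.  The call is
    ambiguous when two different labels achieve exactly the top score;
    ties are surfaced, never silently broken.
    """
    if not references or any(len(v) == 0 for v in references.values()):
        raise ValueError("every candidate label needs at least one reference")
    best_per_label = {
        label: max(align_score(query, ref) for ref in refs)
        for label, refs in references.items()
    }
    top = max(best_per_label.values())
    winners = sorted(l for l, s in best_per_label.items() if s == top)
    if len(winners) > 1:
        return GroupCall(label=None, score=top, ambiguous=True)
    return GroupCall(label=winners[0], score=top, ambiguous=False)


# --- physicochemical properties -------------------------------------------

with resources.files("sbpkit.data").joinpath("pka_bjellqvist.json").open() as _fh:
    _PKA = json.load(_fh)

# average (isotope-abundance-weighted) residue masses, Da
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524


@dataclass
class ProteinProperties:
    length: int
    molecular_weight: float
    isoelectric_point: float


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (Bjellqvist pKa set)."""
    pos = 0.0
    neg = 0.0
    nterm = _PKA["n_terminus"].get(protein[0], _PKA["n_terminus"]["default"])
    cterm = _PKA["c_terminus"].get(protein[-1], _PKA["c_terminus"]["default"])
    pos += 1.0 / (1.0 + 10 ** (ph - nterm))
    neg += 1.0 / (1.0 + 10 ** (cterm - ph))
    for aa, pka in _PKA["side_chain_basic"].items():
        n = protein.count(aa)
        if n:
            pos += n / (1.0 + 10 ** (ph - pka))
    for aa, pka in _PKA["side_chain_acidic"].items():
        n = protein.count(aa)
        if n:
            neg += n / (1.0 + 10 ** (pka - ph))
    return pos - neg


def protein_properties(protein: str, tol: float = 1e-4) -> ProteinProperties:
    """Length, average molecular weight and isoelectric point.

    MW is the sum of average residue masses plus one water; pI is found by
    bisection of the net-charge curve to ``tol`` pH units.  Non-standard
    residues are rejected.
    """
    protein = protein.upper()
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - set(_RESIDUE_MASS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    mw = sum(_RESIDUE_MASS[aa] for aa in protein) + WATER_MASS
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    pi = 0.5 * (lo + hi)
    return ProteinProperties(
        length=len(protein), molecular_weight=mw, isoelectric_point=pi
    )
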