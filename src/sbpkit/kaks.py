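"""Codon alignment and NG86 Ka/Ks estimation.

The estimator is the classic Nei–Gojobori (1986) method: synonymous and
nonsynonymous site counts per codon from the fraction of one-step
mutations that preserve the encoded amino acid, difference counts from
averaging over all minimal mutational pathways between each codon pair
(pathways crossing a stop codon are dropped and the weights
renormalized), and a Jukes–Cantor multiple-hit correction applied to the
per-site proportions.  Mutations that create a stop codon are counted as
nonsynonymous in site counting, so S + N = 3 x (counted codons).

Only the standard genetic code is supported; it is pinned in
``data/genetic_code.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import permutations

_BASES = "ACGT"

with resources.files("sbpkit.data").joinpath("genetic_code.json").open() as _fh:
    GENETIC_CODE: dict[str, str] = json.load(_fh)

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


class SaturationError(ValueError):
    """Raised when a proportion of differences exceeds the JC limit (3/4)."""


def translate(cds: str) -> str:
    """Translate a CDS (DNA, length divisible by 3) with the standard code."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        try:
            out.append(GENETIC_CODE[codon])
        except KeyError:
            raise ValueError(f"invalid codon {codon!r} at position {i + 1}") from None
    return "".join(out)


@lru_cache(maxsize=None)
def synonymous_site_count(codon: str) -> float:
    """Synonymous sites in a codon: per position, the fraction of the three
    possible point mutations that are synonymous.  Changes to stop codons
    count as nonsynonymous."""
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site counts")
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged with equal weight over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded and the remaining
    paths reweighted; in the (rare) case that every path crosses a stop,
    all paths are used unweighted so the pair still contributes.
    """
    if GENETIC_CODE[codon_a] == "*" or GENETIC_CODE[codon_b] == "*":
        raise ValueError("pathway counting requires sense codons")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    valid: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        res = walk(order)
        if res is not None:
            valid.append(res)
        # for the all-stops fallback, score ignoring the stop exclusion
        sd = nd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            a1 = GENETIC_CODE[cur]
            a2 = GENETIC_CODE[nxt]
            if a1 == a2 and a1 != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        all_paths.append((sd, nd))
    pool = valid if valid else all_paths
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


@dataclass
class CodonAlignment:
    """Paired codon columns from two CDSs, gaps threaded from a protein
    alignment.  ``pairs`` holds only the counted columns: no gap in either
    sequence and no stop codon."""

    pairs: list[tuple[str, str]]
    n_columns: int
    n_dropped: int

    @classmethod
    def from_ungapped(cls, cds_a: str, cds_b: str) -> "CodonAlignment":
        """Build directly from two equal-length, in-frame CDSs."""
        cds_a = cds_a.upper().replace("U", "T")
        cds_b = cds_b.upper().replace("U", "T")
        if len(cds_a) != len(cds_b):
            raise ValueError("CDS lengths differ")
        if len(cds_a) % 3:
            raise ValueError("CDS length not divisible by 3")
        pairs = []
        dropped = 0
        n_cols = len(cds_a) // 3
        for i in range(0, len(cds_a), 3):
            ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
            if ca in STOP_CODONS or cb in STOP_CODONS:
                dropped += 1
                continue
            pairs.append((ca, cb))
        return cls(pairs=pairs, n_columns=n_cols, n_dropped=dropped)


def codon_align(cds_a: str, cds_b: str, aligned_a: str, aligned_b: str) -> CodonAlignment:
    """Thread a protein alignment back onto the two CDSs.

    ``aligned_a``/``aligned_b`` are the gapped protein rows; each protein
    column expands to one codon column.  The translation of each CDS must
    equal its aligned row with gaps removed.
    """
    cds_a = cds_a.upper().replace("U", "T")
    cds_b = cds_b.upper().replace("U", "T")
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows have different lengths")
    for name, cds, row in (("A", cds_a, aligned_a), ("B", cds_b, aligned_b)):
        prot = translate(cds)
        # trailing stop in the CDS is tolerated and trimmed
        if prot.endswith("*"):
            prot = prot[:-1]
        ungapped = row.replace("-", "")
        if prot != ungapped:
            # find first mismatch for the error message
            pos = next(
                (i for i, (x, y) in enumerate(zip(prot, ungapped)) if x != y),
                min(len(prot), len(ungapped)),
            )
            raise ValueError(
                f"sequence {name}: translation does not match aligned protein "
                f"at residue {pos + 1}"
            )
    pairs: list[tuple[str, str]] = []
    dropped = 0
    ia = ib = 0
    for col_a, col_b in zip(aligned_a, aligned_b):
        codon_a = codon_b = None
        if col_a != "-":
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            ia += 1
        if col_b != "-":
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            ib += 1
        if codon_a is None or codon_b is None:
            dropped += 1
            continue
        if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
            dropped += 1
            continue
        pairs.append((codon_a, codon_b))
    return CodonAlignment(pairs=pairs, n_columns=len(aligned_a), n_dropped=dropped)


@dataclass
class KaKsResult:
    """NG86 estimates for one aligned CDS pair.

    ``ratio`` is None when Ks = 0 (undefined by zero divide).
    """

    ka: float
    ks: float
    ratio: float | None
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int


def jukes_cantor(p: float) -> float:
    """JC69 distance for a proportion of differing sites."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: distance saturated")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_counts(alignment: CodonAlignment) -> tuple[float, float, float, float]:
    """Raw NG86 site and difference counts (S, N, Sd, Nd), before any
    multiple-hit correction."""
    if not alignment.pairs:
        raise ValueError("no counted codon pairs in alignment")
    S = 0.0
    Sd = Nd = 0.0
    for ca, cb in alignment.pairs:
        S += 0.5 * (synonymous_site_count(ca) + synonymous_site_count(cb))
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * len(alignment.pairs) - S
    return S, N, Sd, Nd


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Estimate Ka and Ks from a codon alignment by the NG86 method."""
    S, N, Sd, Nd = ng86_counts(alignment)
    n = len(alignment.pairs)
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = (ka / ks) if ks > 0 else None
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, S=S, N=N, Sd=Sd, Nd=Nd, n_codons=n)


def kaks_for_pair(cds_a: str, cds_b: str) -> KaKsResult:
    """Convenience: protein-align two CDSs, thread codons, run NG86."""
    from .seqtools import global_align

    prot_a = translate(cds_a).rstrip("*")
    prot_b = translate(cds_b).rstrip("*")
    aln = global_align(prot_a, prot_b)
    return ng86(codon_align(cds_a, cds_b, aln.aligned_a, aln.aligned_b))
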