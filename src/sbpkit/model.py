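"""Core domain objects shared across the pipeline.

A :class:`GeneLocus` is a positioned, stranded gene on a chromosome with
optional family/group labels and sequences attached.  An
:class:`AnnotationSet` is the validated, ordered collection of loci that
every downstream stage consumes.  A :class:`HomologyTable` holds pairwise
protein hits in the conventional 12-column tabular layout, whatever search
engine produced them.

Coordinates are 1-based, fully closed (GFF3 convention) throughout.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Iterable, Iterator


@dataclass
class GeneLocus:
    """A gene on a chromosome.

    ``family_member`` marks membership in the focal gene family (SBP-box
    in the motivating application); ``group`` is the phylogenetic group
    label (e.g. ``g1``..``g9``, ``ds``, ``ms``) and may only be set for
    family members.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    family_member: bool = False
    group: str | None = None
    protein: str | None = None
    cds: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.id}: end ({self.end}) < start ({self.start})"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.id}: start must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.group is not None and not self.family_member:
            raise ValueError(f"gene {self.id}: group set on non-family gene")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def three_prime(self) -> int:
        """Coordinate of the 3' end (strand-aware)."""
        return self.end if self.strand == "+" else self.start


class AnnotationSet:
    """Validated gene annotation, indexed by id and by chromosomal rank.

    Genes are kept sorted by (chromosome, start); rank is the 0-based
    position of a gene within its chromosome's order.
    """

    def __init__(self, genes: Iterable[GeneLocus]):
        genes = sorted(genes, key=lambda g: (g.chromosome, g.start, g.id))
        self._by_id: dict[str, GeneLocus] = {}
        self._by_chrom: dict[str, list[GeneLocus]] = {}
        for g in genes:
            if g.id in self._by_id:
                raise ValueError(f"duplicate gene id: {g.id}")
            self._by_id[g.id] = g
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        self._rank: dict[str, int] = {}
        for chrom_genes in self._by_chrom.values():
            for i, g in enumerate(chrom_genes):
                self._rank[g.id] = i

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[GeneLocus]:
        for chrom in sorted(self._by_chrom):
            yield from self._by_chrom[chrom]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneLocus:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene_id}") from None

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chromosome: str) -> list[GeneLocus]:
        return list(self._by_chrom.get(chromosome, []))

    def rank(self, gene_id: str) -> int:
        """0-based rank of the gene within its chromosome's gene order."""
        self[gene_id]
        return self._rank[gene_id]

    def by_rank(self, chromosome: str, rank: int) -> GeneLocus:
        return self._by_chrom[chromosome][rank]

    def family_members(self) -> list[GeneLocus]:
        return [g for g in self if g.family_member]

    def intervening(self, a: str, b: str) -> list[GeneLocus] | None:
        """Genes strictly between a and b in chromosomal order.

        Returns None when the two genes sit on different chromosomes.
        """
        ga, gb = self[a], self[b]
        if ga.chromosome != gb.chromosome:
            return None
        lo, hi = sorted((self._rank[a], self._rank[b]))
        return self._by_chrom[ga.chromosome][lo + 1 : hi]

    def genes_overlapping(self, chromosome: str, start: int, end: int) -> list[GeneLocus]:
        """Genes whose [start, end] interval overlaps the query by >= 1 nt."""
        chrom_genes = self._by_chrom.get(chromosome, [])
        starts = [g.start for g in chrom_genes]
        # genes are sorted by start; anything starting after `end` is out
        hi = bisect.bisect_right(starts, end)
        return [g for g in chrom_genes[:hi] if g.end >= start]

    def with_sequences(
        self,
        proteins: dict[str, str] | None = None,
        cds: dict[str, str] | None = None,
    ) -> "AnnotationSet":
        """Return a copy with protein/CDS sequences attached by gene id."""
        out = []
        for g in self:
            out.append(
                replace(
                    g,
                    protein=(proteins or {}).get(g.id, g.protein),
                    cds=(cds or {}).get(g.id, g.cds),
                )
            )
        return AnnotationSet(out)


@dataclass(frozen=True)
class HomologyHit:
    """One row of 12-column tabular pairwise-search output."""

    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    @property
    def is_self(self) -> bool:
        return self.query == self.subject


class HomologyTable:
    """Pairwise homology hits with unordered-pair lookup.

    ``evalue`` is an E-value or a documented monotone surrogate for one;
    the only contract downstream is thresholding.
    """

    def __init__(self, hits: Iterable[HomologyHit]):
        self.hits: list[HomologyHit] = list(hits)
        for h in self.hits:
            if h.evalue < 0:
                raise ValueError(
                    f"negative E-value for pair {h.query}/{h.subject}"
                )
        self._best: dict[tuple[str, str], HomologyHit] = {}
        for h in self.hits:
            if h.is_self:
                continue
            key = (h.query, h.subject) if h.query < h.subject else (h.subject, h.query)
            prev = self._best.get(key)
            if prev is None or h.bitscore > prev.bitscore:
                self._best[key] = h

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[HomologyHit]:
        return iter(self.hits)

    def is_homologous(self, a: str, b: str) -> bool:
        if a == b:
            return False
        key = (a, b) if a < b else (b, a)
        return key in self._best

    def best_hit(self, a: str, b: str) -> HomologyHit | None:
        key = (a, b) if a < b else (b, a)
        return self._best.get(key)

    def pairs(self) -> list[tuple[str, str]]:
        """Distinct unordered non-self pairs present in the table."""
        return sorted(self._best)

    def partners(self, gene_id: str) -> list[str]:
        out = {b if a == gene_id else a for a, b in self._best if gene_id in (a, b)}
        return sorted(out)

    def filtered(self, max_evalue: float) -> "HomologyTable":
        return HomologyTable(h for h in self.hits if h.evalue <= max_evalue)

    def symmetric_closure(self) -> "HomologyTable":
        """Add the mirrored row for every hit whose reverse is absent."""
        seen = {(h.query, h.subject) for h in self.hits}
        extra = []
        for h in self.hits:
            if (h.subject, h.query) not in seen:
                extra.append(
                    HomologyHit(
                        h.subject, h.query, h.pident, h.length, h.mismatch,
                        h.gapopen, h.sstart, h.send, h.qstart, h.qend,
                        h.evalue, h.bitscore,
                    )
                )
        return HomologyTable(self.hits + extra)
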