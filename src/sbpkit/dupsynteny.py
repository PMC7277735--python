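"""Micro-fragment synteny and duplication analysis.

The unit of comparison is the micro-fragment: the anchor gene plus up to
30 coding genes on each side (truncated at chromosome ends).  Two
fragments are syntenic when they share at least ``min_pairs`` (default
10) distinct homologous gene pairs under a one-to-one greedy matching;
within one genome such a pair evidences a segmental duplication, between
genomes shared ancestry — one code path serves both.

Tandem duplications are paralogs that are adjacent on one chromosome or
separated by exactly one gene that is homologous to neither.  Tandem
takes precedence over segmental when a pair satisfies both definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import AnnotationSet, HomologyTable


@dataclass
class MicroFragment:
    """Ordered window of <= 2k+1 genes around an anchor."""

    anchor: str
    genes: list[str]
    chromosome: str

    def __post_init__(self) -> None:
        if self.anchor not in self.genes:
            raise ValueError(f"anchor {self.anchor} not in fragment genes")


@dataclass
class SyntenyPair:
    """Two micro-fragments sharing >= min_pairs homologous gene pairs."""

    anchor_a: str
    anchor_b: str
    support: list[tuple[str, str]]
    same_species: bool = True
    group_a: str | None = None
    group_b: str | None = None
    ks: float | None = None

    @property
    def n_support(self) -> int:
        return len(self.support)

    @property
    def intra_group(self) -> bool:
        return (
            self.group_a is not None
            and self.group_b is not None
            and self.group_a == self.group_b
        )


@dataclass
class DuplicationEvent:
    """A classified duplicated gene pair with Ka/Ks attached."""

    gene_a: str
    gene_b: str
    kind: str  # "tandem" | "segmental"
    group_a: str | None = None
    group_b: str | None = None
    ka: float | None = None
    ks: float | None = None
    ratio: float | None = None

    @property
    def intra_group(self) -> bool:
        return (
            self.group_a is not None
            and self.group_b is not None
            and self.group_a == self.group_b
        )


def make_micro_fragment(
    anchor: str, annotation: AnnotationSet, k: int = 30
) -> MicroFragment:
    """Fragment of up to k genes upstream + anchor + k downstream,
    truncated at chromosome ends."""
    gene = annotation[anchor]
    chrom_genes = annotation.genes_on(gene.chromosome)
    rank = annotation.rank(anchor)
    lo = max(0, rank - k)
    hi = min(len(chrom_genes), rank + k + 1)
    return MicroFragment(
        anchor=anchor,
        genes=[g.id for g in chrom_genes[lo:hi]],
        chromosome=gene.chromosome,
    )


def _support_pairs(
    genes_a: Sequence[str], genes_b: Sequence[str], homology: HomologyTable
) -> list[tuple[str, str]]:
    """One-to-one greedy matching of homologous pairs between two gene
    sets, by descending homology score; a gene is never paired with
    itself and supports at most one pair even when the sets overlap."""
    set_b = set(genes_b)
    candidates = []
    for a in genes_a:
        for b in homology.partners(a):
            if b == a or b not in set_b:
                continue
            hit = homology.best_hit(a, b)
            candidates.append((hit.bitscore, a, b))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    support: list[tuple[str, str]] = []
    for _score, a, b in candidates:
        if a in used_a or b in used_b:
            continue
        if b in used_a or a in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        support.append((a, b))
    return support


def detect_synteny(
    frag_a: MicroFragment,
    frag_b: MicroFragment,
    homology: HomologyTable,
    min_pairs: int = 10,
    family_only: bool = False,
    annotation: AnnotationSet | None = None,
) -> SyntenyPair | None:
    """Synteny between two fragments by the >= min_pairs homolog rule.

    Support is counted as a one-to-one greedy maximum matching by
    descending homology score (each gene used at most once); a gene is
    never paired with itself.  Self-comparison (same anchor) returns None.
    With ``family_only`` the support is restricted to focal-family genes
    (requires ``annotation``).
    """
    if frag_a.anchor == frag_b.anchor:
        return None
    genes_a: Sequence[str] = frag_a.genes
    genes_b: Sequence[str] = frag_b.genes
    if family_only:
        if annotation is None:
            raise ValueError("family_only support needs the annotation")
        genes_a = [g for g in genes_a if annotation[g].family_member]
        genes_b = [g for g in genes_b if annotation[g].family_member]
    support = _support_pairs(genes_a, genes_b, homology)
    if len(support) < min_pairs:
        return None
    return SyntenyPair(anchor_a=frag_a.anchor, anchor_b=frag_b.anchor, support=support)


def classify_tandem(
    gene_a: str, gene_b: str, annotation: AnnotationSet, homology: HomologyTable
) -> bool:
    """True iff the pair is a tandem duplication: same chromosome, and
    adjacent or separated by exactly one gene homologous to neither."""
    between = annotation.intervening(gene_a, gene_b)
    if between is None:  # different chromosomes
        return False
    if len(between) == 0:
        return True
    if len(between) == 1:
        spacer = between[0].id
        return not (
            homology.is_homologous(spacer, gene_a)
            or homology.is_homologous(spacer, gene_b)
        )
    return False


def call_duplications(
    annotation: AnnotationSet,
    homology: HomologyTable,
    min_pairs: int = 10,
    window: int = 30,
    family_only_support: bool = False,
) -> tuple[list[DuplicationEvent], list[SyntenyPair], list[tuple[str, str]]]:
    """Classify every homologous family gene pair.

    Returns (events, synteny_pairs, unclassified): tandem events, then
    segmental events each backed by a fragment-pair synteny, and the
    homologous pairs supported by neither (reported, excluded from event
    counts).  Tandem takes precedence for pairs satisfying both.
    """
    family = [g.id for g in annotation.family_members()]
    family_set = set(family)
    fragments = {g: make_micro_fragment(g, annotation, k=window) for g in family}
    events: list[DuplicationEvent] = []
    synteny_pairs: list[SyntenyPair] = []
    unclassified: list[tuple[str, str]] = []
    for a, b in homology.pairs():
        if a not in family_set or b not in family_set:
            continue
        ga, gb = annotation[a], annotation[b]
        if classify_tandem(a, b, annotation, homology):
            events.append(
                DuplicationEvent(
                    gene_a=a, gene_b=b, kind="tandem",
                    group_a=ga.group, group_b=gb.group,
                )
            )
            continue
        pair = detect_synteny(
            fragments[a], fragments[b], homology, min_pairs=min_pairs,
            family_only=family_only_support, annotation=annotation,
        )
        if pair is not None:
            pair.group_a, pair.group_b = ga.group, gb.group
            synteny_pairs.append(pair)
            events.append(
                DuplicationEvent(
                    gene_a=a, gene_b=b, kind="segmental",
                    group_a=ga.group, group_b=gb.group,
                )
            )
        else:
            unclassified.append((a, b))
    return events, synteny_pairs, unclassified


def attach_kaks(
    events: Iterable[DuplicationEvent], annotation: AnnotationSet
) -> list[DuplicationEvent]:
    """Compute NG86 Ka/Ks for each event's gene pair (CDS required)."""
    from .kaks import SaturationError, kaks_for_pair

    out = []
    for ev in events:
        cds_a = annotation[ev.gene_a].cds
        cds_b = annotation[ev.gene_b].cds
        if cds_a and cds_b:
            try:
                res = kaks_for_pair(cds_a, cds_b)
                ev.ka, ev.ks, ev.ratio = res.ka, res.ks, res.ratio
            except SaturationError:
                ev.ka = ev.ks = ev.ratio = None
        out.append(ev)
    return out


@dataclass
class SyntenyCensus:
    """Group-level accounting of synteny relationships."""

    group_matrix: pd.DataFrame  # symmetric group x group pair counts
    intra_total: int
    inter_total: int
    inter_group_shares: pd.DataFrame  # per group, % shares over partner groups
    incidence: pd.DataFrame  # gene x partner-group counts (one per synteny)


def synteny_census(pairs: Sequence[SyntenyPair]) -> SyntenyCensus:
    """Count intra- vs inter-group synteny relationships.

    Each synteny is counted once for each of the two genes making it up
    in the gene-level incidence matrix; the group matrix counts each
    relationship once.
    """
    labelled = [p for p in pairs if p.group_a is not None and p.group_b is not None]
    groups = sorted({p.group_a for p in labelled} | {p.group_b for p in labelled})
    matrix = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    genes = sorted({p.anchor_a for p in labelled} | {p.anchor_b for p in labelled})
    incidence = pd.DataFrame(0, index=genes, columns=groups, dtype=int)
    intra = inter = 0
    for p in labelled:
        matrix.loc[p.group_a, p.group_b] += 1
        if p.group_a != p.group_b:
            matrix.loc[p.group_b, p.group_a] += 1
            inter += 1
        else:
            intra += 1
        incidence.loc[p.anchor_a, p.group_b] += 1
        incidence.loc[p.anchor_b, p.group_a] += 1
    shares = pd.DataFrame(0.0, index=groups, columns=groups)
    for g in groups:
        row = matrix.loc[g].copy()
        row[g] = 0  # inter-group shares only
        total = row.sum()
        if total > 0:
            shares.loc[g] = 100.0 * row / total
    return SyntenyCensus(
        group_matrix=matrix,
        intra_total=intra,
        inter_total=inter,
        inter_group_shares=shares,
        incidence=incidence,
    )


def aggregate_ks(partners: Sequence[tuple[str, float]]) -> list[float]:
    """Collapse a gene's one-to-many Ks values.

    Values sharing a partner species are averaged into one; values from
    different species are kept separate (not averaged).  Output follows
    the order of first appearance of each species.
    """
    order: list[str] = []
    per_species: dict[str, list[float]] = {}
    for species, ks in partners:
        if not (ks == ks and abs(ks) != float("inf")):
            raise ValueError(f"non-finite Ks for species {species}")
        if species not in per_species:
            order.append(species)
            per_species[species] = []
        per_species[species].append(ks)
    return [sum(per_species[s]) / len(per_species[s]) for s in order]


def bin_fractions(
    values: Sequence[float], edges: Sequence[float] = (1.2, 2.0)
) -> dict[str, float] | None:
    """Fractions of values per Ks bin; None for an empty input
    (undefined, not zero)."""
    if not values:
        return None
    edges = list(edges)
    labels = [f"<{edges[0]:g}"]
    labels += [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)]
    labels += [f">={edges[-1]:g}"]
    counts = [0] * (len(edges) + 1)
    for v in values:
        i = sum(v >= e for e in edges)
        counts[i] += 1
    n = len(values)
    return {label: c / n for label, c in zip(labels, counts)}


def ks_binning(
    events: Sequence[DuplicationEvent], edges: Sequence[float] = (1.2, 2.0)
) -> dict[str, dict[str, float] | None]:
    """Ks-bin fractions for intra- vs inter-group duplication events."""
    intra = [e.ks for e in events if e.intra_group and e.ks is not None]
    inter = [
        e.ks
        for e in events
        if e.ks is not None
        and e.group_a is not None
        and e.group_b is not None
        and not e.intra_group
    ]
    return {
        "intra": bin_fractions(intra, edges),
        "inter": bin_fractions(inter, edges),
    }
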