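"""Group-level functional profiling: upstream-region extraction,
over-representation testing on user-supplied annotation maps, and
stress-response counting on expression matrices.

The enrichment statistic is the exact hypergeometric upper tail with
Benjamini-Hochberg adjustment; which term -> gene map is tested (motif
hits, GO terms, ...) is the caller's concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mir156 import revcomp_dna
from .model import GeneLocus

logger = logging.getLogger("sbpkit")


@dataclass
class UpstreamRegion:
    """The putative promoter window upstream of a gene's TSS.

    On the + strand the region is [TSS - far, TSS - near]; on the -
    strand the strand-reflected equivalent, with the sequence reported
    5'->3' on the gene's strand.  Truncated at chromosome ends; an
    ``empty`` region has nothing left after truncation.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    sequence: str

    @property
    def empty(self) -> bool:
        return self.sequence == ""


def extract_upstream(
    gene: GeneLocus,
    genome: Mapping[str, str],
    near: int = 100,
    far: int = 2000,
) -> UpstreamRegion:
    """Extract the [-far, -near] window upstream of the TSS (the gene
    feature's 5' end), strand-aware and truncated at chromosome ends."""
    chrom_seq = genome[gene.chromosome]
    if gene.strand == "+":
        tss = gene.start
        start = max(1, tss - far)
        end = tss - near
        if end < start:
            logger.info("gene %s: no upstream sequence to extract", gene.id)
            return UpstreamRegion(gene.id, gene.chromosome, 0, -1, "+", "")
        seq = chrom_seq[start - 1 : end].upper()
    else:
        tss = gene.end
        start = tss + near
        end = min(len(chrom_seq), tss + far)
        if end < start:
            logger.info("gene %s: no upstream sequence to extract", gene.id)
            return UpstreamRegion(gene.id, gene.chromosome, 0, -1, "-", "")
        seq = revcomp_dna(chrom_seq[start - 1 : end])
    if start == 1 or end == len(chrom_seq):
        logger.info("gene %s: upstream region truncated at chromosome end", gene.id)
    return UpstreamRegion(
        gene_id=gene.id, chromosome=gene.chromosome,
        start=start, end=end, strand=gene.strand, sequence=seq,
    )


@dataclass
class EnrichmentResult:
    term: str
    overlap: int
    selected_size: int
    annotated: int
    universe_size: int
    p_value: float
    adjusted_p: float


def enrich(
    selected: set[str],
    annotation_map: Mapping[str, set[str]],
    universe: set[str],
    min_support: int = 1,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per term, BH-adjusted.

    Terms annotating fewer than ``min_support`` universe genes are
    dropped before testing (a generic form of the minimum-support
    filtering applied to multi-species annotation sets).
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    M, N = len(universe), len(selected)
    rows = []
    for term in sorted(annotation_map):
        annotated = annotation_map[term] & universe
        n = len(annotated)
        if n < min_support:
            continue
        k = len(annotated & selected)
        p = float(hypergeom.sf(k - 1, M, n, N))
        p = min(p, 1.0)
        rows.append((term, k, n, p))
    if not rows:
        return []
    _, adj, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    return [
        EnrichmentResult(
            term=term, overlap=k, selected_size=N, annotated=n,
            universe_size=M, p_value=p, adjusted_p=float(q),
        )
        for (term, k, n, p), q in zip(rows, adj)
    ]


def stress_response_count(
    expression: pd.DataFrame,
    design: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    up_fold: float = 2.0,
    down_fold: float = 0.5,
) -> pd.DataFrame:
    """Per gene and condition, the number of treatment experiments whose
    value is at least double the matched control, or at most half.

    ``design`` maps condition -> (control columns, treatment columns);
    the two lists are matched positionally (experiment i compares
    treatment[i] to control[i], or to the single control when only one is
    given).  A zero control with nonzero treatment counts as responsive;
    zero against zero does not.  Both fold boundaries are inclusive.
    """
    counts = pd.DataFrame(
        0, index=expression.index, columns=sorted(design), dtype=int
    )
    for condition in sorted(design):
        controls, treatments = design[condition]
        for col in list(controls) + list(treatments):
            if col not in expression.columns:
                raise KeyError(f"design column {col!r} absent from matrix")
        if len(controls) == 1:
            controls = list(controls) * len(treatments)
        if len(controls) != len(treatments):
            raise ValueError(
                f"condition {condition}: control/treatment column counts differ"
            )
        for ctrl, treat in zip(controls, treatments):
            c = expression[ctrl].to_numpy(dtype=float)
            t = expression[treat].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                responsive = (t >= up_fold * c) | (t <= down_fold * c)
            # boundary semantics for zero controls
            responsive &= ~((c == 0) & (t == 0))
            responsive |= (c == 0) & (t > 0)
            # t <= down*c with c>0,t=0 is a valid response; c==0 handled above
            counts[condition] += responsive.astype(int)
    return counts


def log_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform for visualization export; negative values
    are rejected."""
    values = expression.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be >= 0")
    return pd.DataFrame(
        np.log2(values + 1.0), index=expression.index, columns=expression.columns
    )
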