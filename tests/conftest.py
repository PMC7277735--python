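"""Shared fixtures: one default synthetic genome (with its homology
table and miRNA predictions) is generated once per session and reused by
the recovery-style tests."""

from __future__ import annotations

import pytest

from sbpkit import internal_homology_search, predict_loci
from sbpkit.model import AnnotationSet, GeneLocus
from sbpkit.simulate import SimulationConfig, generate_genome

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def genome():
    """The reference study-condition genome: 2 chromosomes x 300 genes
    with 5 tandem, 3 segmental, 6 miRNA and 3 face-to-face events."""
    return generate_genome(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def homology(genome):
    """Internal all-vs-all homology at the stringent E threshold."""
    return internal_homology_search(genome.proteins).filtered(1e-10)


@pytest.fixture(scope="session")
def mirna_predictions(genome):
    return predict_loci(genome.genome, genome.annotation, genome.matures)


def make_annotation(
    n_genes: int,
    chromosome: str = "chr1",
    gene_length: int = 900,
    gap: int = 100,
    strand: str = "+",
) -> AnnotationSet:
    """A uniform toy annotation: n equally spaced genes on one chromosome."""
    genes = []
    pos = 1
    for i in range(n_genes):
        start = pos + gap
        end = start + gene_length - 1
        genes.append(
            GeneLocus(
                id=f"{chromosome}_g{i + 1}", chromosome=chromosome,
                start=start, end=end, strand=strand,
            )
        )
        pos = end
    return AnnotationSet(genes)
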