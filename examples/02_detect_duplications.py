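"""Detect tandem and segmental duplications on a synthetic genome.

Micro-fragments of up to 61 genes are built around every family gene;
two fragments sharing at least 10 homologous gene pairs are syntenic
(within one genome: a segmental duplication).  Tandem pairs are adjacent
paralogs, or paralogs separated by one non-homologous spacer gene.
"""

from sbpkit import (
    SimulationConfig,
    call_duplications,
    generate_genome,
    internal_homology_search,
    ks_binning,
    synteny_census,
)
from sbpkit.dupsynteny import attach_kaks

genome = generate_genome(SimulationConfig(seed=11))
homology = internal_homology_search(genome.proteins).filtered(1e-10)
print(f"homology: {len(homology)} hits at E <= 1e-10")

events, synteny_pairs, unclassified = call_duplications(
    genome.annotation, homology, min_pairs=10, window=30
)
events = attach_kaks(events, genome.annotation)

n_tandem = sum(e.kind == "tandem" for e in events)
n_segmental = sum(e.kind == "segmental" for e in events)
print(f"{n_tandem} tandem and {n_segmental} segmental duplication events; "
      f"{len(unclassified)} homologous family pairs with neither signature")
print(f"planted truth: {len(genome.truth.tandem_pairs)} tandem, "
      f"{len(genome.truth.segmental_blocks)} segmental block pair(s)")

census = synteny_census(synteny_pairs)
print(f"synteny relationships: {census.intra_total} intra-group, "
      f"{census.inter_total} inter-group")

bins = ks_binning(events, edges=(1.2, 2.0))
if bins["intra"]:
    frac = bins["intra"]["<1.2"]
    print(f"{frac:.0%} of intra-group duplications have Ks < 1.2 "
          f"(recent duplications sit below the older whole-genome "
          f"duplication era)")
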