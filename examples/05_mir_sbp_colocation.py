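"""miR156-SBP co-location, synteny, and face-to-face origin scan.

Co-location means a miR156 locus falls inside the genomic span of an SBP
gene's micro-fragment.  After excluding co-locations, miR156-anchored
windows are compared with SBP-anchored micro-fragments by the same
>= 10-homolog-pair rule.  The face-to-face scan looks for convergent
g1/g6 gene pairs across a short intergenic gap — the proposed substrate
for the origin of the miR156 hairpin.
"""

from sbpkit import (
    SimulationConfig,
    co_location,
    face_to_face_scan,
    generate_genome,
    internal_homology_search,
    make_micro_fragment,
    mature_scan,
    mir_sbp_synteny,
)

genome = generate_genome(SimulationConfig(seed=11))
homology = internal_homology_search(genome.proteins).filtered(1e-10)
hits = mature_scan(genome.genome, genome.matures)
print(f"{len(hits)} genomic miR156 matches (both strands, < 3 mismatches)")

fragments = [
    make_micro_fragment(g.id, genome.annotation)
    for g in genome.annotation.family_members()
]
colocated = {
    anchor for h in hits for anchor in co_location(h, fragments, genome.annotation)
}
print(f"{len(colocated)} SBP micro-fragments co-locate with a miR156 hit")

synteny = mir_sbp_synteny(hits, genome.annotation, homology)
print(f"{len(synteny)} miR156-SBP synteny relationships after excluding "
      f"co-locations")

pairs = face_to_face_scan(genome.annotation, group_a="g1", group_b="g6",
                          max_gap=8000)
for p in pairs:
    print(f"face-to-face pair {p.gene_a} (+) / {p.gene_b} (-), intergenic "
          f"gap {p.gap} nt: the convergent 3' ends flank the candidate "
          f"hairpin region {p.hairpin_region}")
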