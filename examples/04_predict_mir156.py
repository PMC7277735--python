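"""Predict miR156 loci and target sites.

Locus prediction: genome scan for near-matches to the reference mature
sequences (< 3 mismatches, >= 19 nt), +/-200 nt precursor extraction,
removal of hits inside protein-coding genes, and a stem-loop check of
the precursor by base-pair maximization.
"""

from sbpkit import SimulationConfig, generate_genome, predict_loci, target_scan
from sbpkit.mir156 import perfect_site_for

genome = generate_genome(SimulationConfig(seed=11))
result = predict_loci(genome.genome, genome.annotation, genome.matures)

print(f"{len(result['passed'])} candidate loci pass all filters, "
      f"{len(result['in_coding'])} removed inside coding genes, "
      f"{len(result['failed_hairpin'])} failed the stem-loop criteria")
best = result["passed"][0]
h = best.hairpin
print(f"example locus {best.hit.chromosome}:{best.hit.start}-{best.hit.end} "
      f"({best.hit.strand}), {best.hit.mismatches} mismatches to "
      f"{best.hit.mature_id}")
print(f"  {h.mature_paired}/{best.mature_length} mature bases paired to the "
      f"star arm; structure around the mature:")
lo = best.mature_offset
print("  " + h.structure.dotbracket[lo : lo + best.mature_length])

# target prediction: the complementarity expectation score (0 = perfect)
mature = genome.matures[0]
transcript = "C" * 40 + perfect_site_for(mature.sequence) + "C" * 40
sites = target_scan(mature, transcript, transcript_id="demo_mRNA")
site = min(sites, key=lambda s: s.expectation)
print(f"target site on demo_mRNA at {site.start}-{site.end}: "
      f"expectation {site.expectation} (0 means perfect complementarity; "
      f"psRNATarget-style default cut-off is 5)")
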