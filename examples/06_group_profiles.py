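"""Group-level profiling: upstream regions, enrichment, stress response.

Upstream windows ([-2000, -100] from the TSS, strand-aware) feed
whatever motif or binding-site scanner the user prefers; the enrichment
test is a generic hypergeometric over-representation test on a
term -> gene map; stress-response counting applies the two-fold /
half-fold rule per experiment.
"""

from sbpkit import (
    SimulationConfig,
    enrich,
    extract_upstream,
    generate_expression_matrix,
    generate_genome,
    log_matrix,
    stress_response_count,
)

genome = generate_genome(SimulationConfig(seed=11))
family = genome.annotation.family_members()

region = extract_upstream(family[0], genome.genome)
print(f"upstream region of {region.gene_id}: {region.chromosome}:"
      f"{region.start}-{region.end} ({region.strand}), "
      f"{len(region.sequence)} nt")

universe = {g.id for g in genome.annotation}
selected = {g.id for g in family}
# a toy annotation map: one term annotating mostly family genes
term_map = {"stress_inducible": set(list(selected)[:10]) | {"G00001"}}
for r in enrich(selected, term_map, universe):
    print(f"term {r.term}: overlap {r.overlap}/{r.annotated}, "
          f"p = {r.p_value:.3g} (hypergeometric upper tail), "
          f"BH-adjusted p = {r.adjusted_p:.3g}")

gene_ids = [g.id for g in family[:4]]
matrix, _ = generate_expression_matrix(
    gene_ids, ["cold", "heat"],
    {gene_ids[0]: [("cold", 2.5)], gene_ids[1]: [("heat", 0.4)]},
)
counts = stress_response_count(
    matrix,
    {"cold": (["cold_control"], ["cold_treat"]),
     "heat": (["heat_control"], ["heat_treat"])},
)
print("responsive experiments per gene and condition (ratio >= 2 or <= 0.5):")
print(counts)
print("log2(x+1) matrix head:")
print(log_matrix(matrix).head(2))
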