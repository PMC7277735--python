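# Methods

This note documents the models and procedures sbpkit implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Micro-fragment synteny and duplication classification

The unit of comparison is the *micro-fragment*: an anchor gene plus up
to `window` (default 30) coding genes on each side, truncated at
chromosome ends, so a fragment holds at most 61 genes.  Two fragments
are syntenic when they share at least `min_pairs` (default 10) distinct
homologous gene pairs at the homology stringency in use (E ≤ 1 × 10⁻¹⁰
by default).  Within one genome a syntenic fragment pair evidences a
segmental duplication; between genomes, shared ancestry — one code path
serves both, with a `same_species` flag on the result.

Support counting uses a one-to-one greedy maximum matching by
descending homology score: each gene contributes at most one pair, so a
single promiscuous gene cannot carry a block.  Collinear *order* within
the fragment pair is deliberately not required — the criterion is
co-occurrence counting, not MCScanX-style chaining — and this is the
main way the detector differs from chain-based collinearity tools.
Homologous pairs from any gene family count as support by default;
`family_only=True` restricts support to focal-family genes for users
who prefer the stricter reading.

Tandem duplications are homologous pairs that are adjacent on one
chromosome or separated by exactly one gene homologous to neither.
Tandem and segmental definitions are not mutually exclusive; tandem
takes precedence.  Homologous family pairs with neither signature are
reported as unclassified rather than silently counted.

Group-level accounting counts each synteny relationship once per
relationship in the group × group matrix and once *for each of the two
genes* in the gene-level incidence matrix (a gene in two syntenies has
an incidence row summing to 2).  Per-group inter-group shares are
percentages over partner groups and sum to 100 within a group.

## Ka/Ks estimation (NG86)

Divergence between duplicated CDSs is estimated with the classic
Nei–Gojobori (1986) method:

- *Sites.* For each codon, the synonymous-site count is the fraction of
  the nine possible point mutations (three per position) that preserve
  the encoded amino acid; mutations creating a stop codon count as
  nonsynonymous, so S + N = 3 × (counted codons) exactly.  Site counts
  are averaged over the two sequences.
- *Differences.* For each codon pair the synonymous/nonsynonymous
  difference counts are averaged with equal weight over all minimal
  mutational pathways (orders of the differing positions).  Pathways
  crossing a stop codon are dropped and the weights renormalized; in
  the rare case that every pathway crosses a stop, all pathways are
  used unweighted so the pair still contributes rather than being
  silently skipped.
- *Correction.* Jukes–Cantor: d = −¾ ln(1 − 4p/3) applied to
  ps = Sd/S and pn = Nd/N.  Proportions ≥ 3/4 raise a saturation error;
  the Ka/Ks ratio is reported as undefined (None) when Ks = 0.

Codon alignments are threaded from a protein alignment (BLOSUM62,
gap open 11, extend 1; a gap of length k costs open + k·extend);
columns containing a gap or stop codon are excluded from counting.
Only the standard genetic code is supported, pinned in
`sbpkit/data/genetic_code.json`.

NG86 is a deliberately transparent estimator: every piece (site
fractions, pathway averaging) is checkable against brute-force
enumeration, which the test suite does over all 61 × 61 sense-codon
pairs.  Model-averaged estimators give different per-pair values, but
the analyses built on top of Ks here depend only on coarse bins
(edges 1.2 and 2.0, following the practice of reading the bins against
known whole-genome-duplication eras), which NG86 resolves well at the
simulated divergences.  One-to-many Ks values for a gene are averaged
within a partner species and kept separate across species before
binning; empty bin categories are reported as undefined, never as 0.

## miR156 locus prediction

The homology route: reference mature sequences (the miR156 and miR157
families are treated as one, given their near-identity) are scanned
against the genome with an exhaustive ungapped Hamming scan of both
strands — every window matching a mature, or a ≥ `min_len` (19 nt)
prefix/suffix of it, with at most `max_mismatch` (2) mismatches is a
hit; overlapping hits for one mature on one strand are merged to the
best (fewest mismatches, then longest, then leftmost).  The exhaustive
scan replaces a seeded heuristic search: it is exact, and fast at the
scales involved.  Gapped matches are not considered.

Each hit is extended by `flank` (200) nt on both sides, truncated at
sequence ends, to form the candidate precursor (reported 5′→3′ on the
hit strand).  Candidates whose mature interval overlaps *any* annotated
gene by ≥ 1 nt are removed (the annotation defines "protein-coding";
the 1-nt rule is the strictest consistent reading).

Precursors are folded by base-pair maximization (Nussinov dynamic
program; canonical pairs plus G:U; minimum hairpin loop 3).  This is a
combinatorial surrogate for thermodynamic folding: it answers "can this
sequence form a stem-loop that carries the mature on one arm", not
"what is the minimum free energy".  The pass criteria, all exposed on
`HairpinCriteria` because published criteria sets vary:

- the mature must not pair with itself (self-pairing means it spans the
  terminal loop of its stem);
- the *star arm* is the side pairing the majority of mature bases;
  stray pairs to the opposite side — an artifact of maximizing pairs in
  random flanking sequence — count as unpaired;
- at least `min_mature_paired` (14) mature bases paired to the star
  arm; at most `max_star_mismatch` (6) unpaired mature bases; at most
  `max_loops_in_mature` (1) unpaired run inside the mature span.

These defaults are conventional plant-miRNA hairpin requirements; they
are a configurable operating point, not a canonical filter.

## miR156 target scoring

A site's *expectation* is the penalty sum of the best antiparallel
alignment of the mature to a transcript window (semi-global dynamic
program: mature fully aligned, transcript ends free): mismatch 1.0,
G:U wobble 0.5, gap 2.0 per position, with all penalties doubled over
mature positions 2–13 (the seed-proximal region).  Lower is better;
sites with expectation ≤ `max_expectation` (5.0) are reported, with
overlapping sites collapsed to the best.  On gap-free alignments the
expectation equals the plain per-position penalty sum, which the tests
pin down position by position.

## Co-location, miR156–SBP synteny, face-to-face origin scan

*Co-location* is the containment of a miR156 hit interval in the
genomic span (first gene start to last gene end) of an SBP-anchored
micro-fragment.  *miR156–SBP synteny* compares a miR156-anchored window
(the nearest ≤ 30 genes on each side of the hit; the miRNA itself is
not a coding gene) with every SBP-anchored fragment under the same
≥ 10-pair support rule, after removing pairs where the miR156
co-locates with the SBP fragment.

The *face-to-face* scan searches for one gene from each of two groups
(defaults g1 and g6) on the same chromosome, left gene on +, right gene
on −, so the 3′ ends converge, with an intergenic gap strictly below
`max_gap` (8000) nt.  The intergenic distance is downstream start −
upstream end − 1, the most conservative reading of "separated by"
(gene bodies, not TSSs).  The intergenic interval is attached as the
candidate hairpin region: under the inverted-duplication model of
miRNA origin, a convergent duplicate pair at short range is the
substrate from which a stem-loop precursor can arise.  Intervening
genes between the two are permitted; the rule constrains distance and
orientation only.

## Family identification and properties

Family membership is decided by a position-specific score matrix (PSSM)
over the 20 standard amino acids — a transparent surrogate for a
profile-HMM search.  The best ungapped window score is compared with a
threshold; `DomainModel.calibrate` sets the threshold midway between
the weakest known positive and the strongest known negative, and
`from_sequences` defaults to a fraction of the maximum achievable
score.  The PSSM threshold is the sole completeness criterion — there
is no secondary domain-structure validation step.

Group assignment is nearest-reference by optimal global alignment
score; exact ties between two labels are surfaced as ambiguous, never
silently broken, because group identity feeds every downstream count.

Protein properties: molecular weight is the sum of average residue
masses plus one water; the isoelectric point is found by bisection
(tolerance 10⁻⁴ pH) of a Henderson–Hasselbalch net-charge function
using the Bjellqvist pKa set (pinned in
`sbpkit/data/pka_bjellqvist.json`), so the net charge at the returned
pI is below 10⁻³ by construction.

The internal fallback homology search performs optimal global alignment
on candidate pairs selected by a shared-k-mer prefilter (k = 5, ≥ 8
shared words — the seeding idea of word-based search tools;
`prefilter_k=None` gives exhaustive all-vs-all).  Its E-value surrogate
is the Karlin–Altschul form K·m·n·exp(−λ·score) with the standard
gapped BLOSUM62/11/1 constants; it is a documented monotone transform
used only for thresholding, and no calibration against any particular
search engine is claimed.  Any engine's 12-column tabular output can be
substituted.

## Profiling

Upstream regions are the [−2000, −100] window from the TSS (the gene
feature's 5′ end; the annotation carries no separate TSS), strand
reflected on −, truncated at chromosome ends, and never overlapping the
gene body.  Over-representation is the exact hypergeometric upper tail
per term with Benjamini–Hochberg adjustment across terms; terms under a
minimum support are dropped before testing.  Stress-response counting
marks an experiment responsive when treatment ≥ 2 × control or ≤ ½ ×
control (both boundaries inclusive; a zero control with nonzero
treatment is responsive, zero against zero is not).  The visualization
export uses log₂(x + 1).

## The synthetic-data generator

`generate_genome` builds multi-chromosome gene orders (single-exon
genes, random sense-codon CDSs, normally distributed lengths and
intergenic gaps), labels a configurable fraction as family members
drawn from group-specific ancestors, and plants:

- tandem duplications: a diverged copy adjacent to the source or behind
  one fresh spacer gene;
- segmental blocks: a run of ≥ 61 genes copied elsewhere (same or
  different chromosome) with ⌈retention × length⌉ diverged homolog
  pairs retained in order, the central pair promoted to family anchors;
- miR156 loci: exact or mutated mature copies on either strand, inside
  or outside coding genes, with an optional inverted-repeat star arm so
  the locus passes (or, by design, fails) the hairpin criteria.
  Planted mismatches avoid the two outermost bases so that no
  sub-window of a designed 3-mismatch negative evades the filter;
- face-to-face pairs at exact intergenic gaps, including orientation
  and boundary (gap = 8000) negative controls;
- expression matrices with exact planted fold changes (noise, when
  requested, never touches planted cells).

Family structure: each group has an ancestral CDS carrying a
group-specific variant (30% amino-acid divergence) of a 50-residue
synthetic domain root with zinc-finger-like cysteine/histidine spacing
(`_DOMAIN_ROOT` is an invented stand-in, not a real profile).  Members
diverge mildly from their group ancestor, so within-group pairs are
strongly homologous while cross-group pairs share only the diverged
domain and fall below the E ≤ 10⁻¹⁰ threshold — which keeps family
genes from inflating fragment support counts.  The PSSM emitted with
the outputs is calibrated on the genome's own labelled proteins
(threshold midway between the weakest family protein and the strongest
background window): duplicate copies diverged to Ks ≈ 1 carry
nonsynonymous changes into the domain and can score well below a fixed
fraction of the maximum, so calibration on known positives/negatives —
the model's stated contract — is what keeps the separation exact.

`evolve_cds` applies random single-nucleotide substitutions —
synonymous ones while the NG86+JC Ks of the (input, current) pair is
below `target_ks`, nonsynonymous ones while Ka is below `target_ka` —
rejecting any substitution that creates a stop codon, so frame and
translatability are preserved.  The stopping rule is estimator-guided
by design: the generator's contract is "a pair whose corrected
divergence reaches the target", and the estimator's own path-counting
is independently verified against brute-force enumeration.  Targets
whose implied proportion of differences approaches the Jukes–Cantor
limit (p ≥ 0.74) are rejected as unreachable.

Default study conditions (the configuration the test suite and the
acceptance script use): 2 chromosomes × 300 genes, mean CDS 900 nt,
mean intergenic gap 2000 nt, family fraction 0.05 across 11 group
labels (g1–g9, ds, ms), 5 tandem events (alternating 0/1 spacers),
3 segmental blocks of 61 genes at retention 0.25 (16 retained pairs),
Ks targets cycling 0.3/0.5/1.0, 6 miR156 loci — four positives at
0/1/2/0 mismatches (one on the − strand) and two designed negatives
(one at 3 mismatches, one inside a coding gene) — and 3 face-to-face
pairs at gaps 6000/3000/8000, the last a deliberate boundary negative
under the strict < 8000 rule.  The family fraction is far above the
share of any real gene family; it is enriched so that grouping,
duplication and synteny behaviour can be exercised at desk scale.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: intron/exon structure, indels and
alignment uncertainty, substitution-rate heterogeneity among sites and
lineages, transposable elements, assembly gaps and unplaced scaffolds,
annotation errors, and codon-usage bias.  Recovery rates of 100% on
planted events are statements about the pipeline's correctness under
its stated definitions, not about sensitivity on real genomes.

## Determinism and problem sizes

All randomness flows from one seeded generator per run; identical
configurations produce byte-identical outputs, which the suite asserts
at the file level.  The test suite and acceptance script use the
default study conditions above (a ~2.3 Mb genome, ≈ 800 genes), 20
replicates × 300 codons for divergence recovery, 1000 random fragment
pairs for the order-shuffle specificity check, and 100 kb of random
sequence for the shuffled-mature check; the full suite runs in about a
minute on one CPU.

## Known limitations

- NG86 without rate correction underestimates Ks as divergence
  approaches saturation; bins above 2.0 should be read qualitatively.
- Base-pair maximization over-pairs relative to thermodynamic folding;
  the hairpin criteria compensate by requiring the pairing to be
  concentrated on one arm, but borderline real precursors would need a
  thermodynamic method.
- The E-value surrogate is monotone in score but not calibrated; users
  comparing against external search output should filter both through
  the same threshold semantics rather than mixing absolute values.
- The ≥ 10-pair co-occurrence rule without collinear ordering is more
  permissive than chained collinearity; on gene-dense regions of real
  genomes the strict `family_only` mode or a larger `min_pairs` may be
  appropriate.
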