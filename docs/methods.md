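# Methods

## Scope and model

`psychrocomp` re-implements, as one tested pipeline, the comparative-genomics
inference chain used to characterize cold/marine adaptation in a panel of
closely related bacterial genomes:

1. **Similarity search.** All deduced proteins of a focal genome are compared
   to every other genome's proteome with a local aligner; a hit exists when
   the Karlin–Altschul expectation E = K·m·n·exp(−λS) of the optimal local
   score S is at most the cutoff (default 1e-20, the value the original
   analysis used). m is the query length and n the total residue count of the
   subject proteome.
2. **Orthology and partitioning.** Two homology rules coexist, as in the
   original methodology. *Set construction* uses reciprocal best hits (RBH):
   gene a in genome A and gene b in genome B are orthologs when each is the
   other's first hit (minimum E, ties by bitscore then id) in both search
   directions. *Conservation accounting* ("conserved in" percentages) uses
   one-way presence: a gene is present in a target genome iff it has ≥1 hit
   at the cutoff. The focal genome's CDS set is partitioned by sequential
   deduction over a nested hierarchy of genome sets (full panel → inner
   clade → closest pair): CDS with RBH partners in every other genome of the
   full panel form the core (CDS_c); CDS with partners across the inner
   clade, minus the core, form the clade-shared set (CDS_4 for a 4-genome
   clade); similarly for the pair level (CDS_2); the remainder is
   strain-specific (CDS_1). The hierarchy is generalized to any number of
   strictly nested levels.
3. **Lateral-transfer calling.** Each focal CDS's hit list against a
   reference panel is filtered by configurable exclusion cases; the
   best-scoring survivor's genome is the putative origin. A gene is called
   laterally transferred when, for any case, that top match's lineage tags
   fall outside the case's scope (e.g. best match outside the genus after
   excluding the closest relatives, or outside marine gamma-proteobacteria
   after excluding the whole genus). Genes with no panel hit are reported as
   `no_hit`, never as lateral. Lineage membership is resolved from metadata
   tags, not from taxon-name parsing.
4. **Composition statistics.** Average amino-acid composition (ACAA) is the
   pooled percentage of each canonical residue over all residues of a protein
   set (not a mean of per-protein percentages); X/B/Z/U and stops are
   excluded from numerator and denominator. G+C and A+G content are pooled
   over concatenated CDS, excluding N. Cold-vs-warm group contrasts use a
   two-sided Welch t-test per feature (20 amino acids + GC + AG) with the
   genome as the sampling unit; deltas are cold − warm. Raw p-values are
   reported (no multiple-testing correction, matching the original
   presentation; Benjamini–Hochberg is available behind a flag). The
   GC–composition relationship is summarized per amino acid by the Pearson
   correlation and least-squares slope of composition against genome GC
   across genomes.
5. **Phylogenetics.** Kimura two-parameter distances
   d = −½ln(1−2P−Q) − ¼ln(1−2Q) from transition/transversion proportions,
   with pairwise or complete deletion of ambiguous sites; Saitou–Nei
   neighbor joining with deterministic lexicographic tie-breaking; bootstrap
   support as the fraction of column-resampled replicates containing each
   internal bipartition of the original tree.

## Aligner parameters

The built-in aligner is an exact affine-gap Smith–Waterman over BLOSUM62
(gap open 11, extend 1, BLAST-style gap cost open + k·extend), with E-value
constants K = 0.041, λ = 0.267 nats. Applying these ungapped-style constants
to gapped scores is a declared approximation: the original analysis delegated
the search to an external tool whose matrix and gap parameters it did not
record, and nothing downstream depends on calibrated E-values — only on the
thresholding behaviour at the 1e-20 cutoff, which tests exercise directly.
X scores as the worst-case substitution so it can never create similarity.
Externally produced 12-column hit tables can replace the built-in aligner
wholesale; the pipeline never mixes the two for one genome pair.

## Synthetic data: what it emulates and what it does not

The generator plants ground truth for every downstream stage. Its defaults
are the study conditions the pipeline is tested under: 17 genomes in a
17/4/2 nested hierarchy; 200 core, 100 clade-shared, 80 pair-shared families
plus 50 private families per genome; within-family divergence 0.15 expected
substitutions per site (applied independently from the family ancestor in
each genome); 10 laterally transferred genes per genome copied from a
4-genome foreign donor panel at divergence 0.05 from the donor ancestor,
far below the native within-family divergence so vertical/lateral truth is
unambiguous; a GC3 gradient of 0.35–0.65 across genomes; and the cold-genome
composition shift (percentage points) Ala −0.8, Pro −0.3, Arg −0.5,
Ile +0.6, Lys +0.4, Asn +0.4, compensated across the remaining residues.

Simulation is protein-level with reverse translation: replacement residues
are drawn from a genome-level target frequency vector (the uniform-usage
codon marginal of the standard code, tilted by shift/divergence for cold
genomes), so the expected realized cold−warm delta equals the configured
shift exactly — composition = (1−d)·ancestor + d·target. Synonymous codons
are then sampled with third positions weighted toward G/C (or A/T) to meet
each genome's GC3 target in expectation. A separate
`gc_coupled_composition` mode draws each genome's residues from the
amino-acid marginal of a codon model weighted by its GC target, which makes
the canonical GC–composition sign pattern (Arg/Pro/Ala/Gly positive,
Ile/Lys/Asn/Tyr negative) a pure consequence of codon structure; that mode
models composition, not orthology.

Protein lengths are drawn from a narrow normal (mean 150 aa, sd mean/8) with
a floor of 100 aa. The floor is a deliberate detectability choice: at a
strict E-cutoff, very short proteins cannot reach significance no matter how
conserved they are (a real property of threshold-based searches), and a
generator whose planted partition must be identifiable has to avoid them.
The 150-aa mean (real bacterial proteins average ~300 aa) keeps the
17-genome all-vs-all search a minutes-scale desk computation; family counts,
divergences and the cutoff are the stated study conditions and are not
scaled.

What the generator does **not** emulate: genome architecture (operons,
intergenic DNA, gene order), indels (families stay length-aligned),
paralogy and gene duplication, real codon-usage tables, rate heterogeneity
across sites or lineages, and compositional drift unrelated to habitat.
Passing the planted-truth tests therefore shows the inference chain is
correct under its own model assumptions — clean one-to-one orthology and
habitat-linked shifts — not that it is robust to paralogs, indel-rich
alignments or annotation noise in real genomes.

## Numerical and procedural choices

* **Determinism everywhere.** Hit ordering (E, then bitscore, then subject
  id), RBH construction, NJ join ties (lexicographic taxon pair) and
  alignment traceback (smallest endpoint, diagonal first) are all
  deterministically tie-broken; a pipeline rerun with the same config is
  byte-identical, and all randomness flows from the single config seed.
* **Welch, not pooled, t-test** — the unequal-variance default of the R
  `t.test` the original analysis cites. Group means weight genomes equally,
  not by proteome size.
* **Degenerate contrasts:** zero-variance groups with equal means give
  t = 0, p = 1; with distinct means, ±inf and p = 0.
* **K2P domain:** 1−2P−Q ≤ 0 or 1−2Q ≤ 0 raises a saturation error rather
  than returning NaN; bootstrap replicates that saturate count as not
  containing any bipartition.
* **Negative NJ branch estimates** are clamped to zero with the deficit
  moved to the sibling edge (the common convention), keeping printed trees
  additive in sum.
* **Core projection for scope="core" contrasts:** per-genome core CDS sets
  are obtained by mapping the focal genome's core through its RBH pairs,
  since a single-focal analysis has no other per-genome core definition.
* **Report precision:** percentages print with 1 decimal, p-values with 2,
  E-values in scientific notation — matching the original tables' precision.

## Problem sizes used by the test suite and acceptance script

The full-scale planted-truth run uses the default 17-genome configuration
above (≈5,100 CDS, ≈1.8 million pairwise protein alignments via a
numba-compiled score kernel; a few minutes on one core). Composition and
GC-correlation checks use 20-genome, 200–300-family collections. The null
calibration uses 2,000 label shuffles. Bootstrap defaults to 100 replicates
(the original trees used 3,000; the count is a config knob and affects only
support precision).

## Known limitations

* E-values are order-of-magnitude indicators, not calibrated to any external
  search tool; only thresholding behaviour is validated.
* The one-way presence rule and the RBH rule can disagree near the cutoff;
  both are exposed so the disagreement is inspectable.
* HGT calling is purely top-hit taxonomy: composition-based signals, island
  structure and mobile-element annotation are out of scope.
* The conservation matrix is computed for a configured genome subset (the
  inner clade by default) rather than all ordered pairs of the panel, which
  would double the alignment cost without changing any downstream stage.
* `partition_summary_from_shared_counts` assumes the shared-ortholog counts
  are taken over nested genome sets (counts non-decreasing inward), as in
  the original accounting.
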