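# Methods

This note records the models, algorithms, defaults and design choices
behind `edckit`, and what the synthetic tests do and do not demonstrate
about real data.

## Synthetic genomes (module `synthetic`)

The generator plants EDC-like genes with exact ground truth.

**Gene anatomy.** On the coding strand a SEDC locus is
`[non-coding exon] [intron] [ATG..stop]`; an SFTP locus splits its CDS into
two exons joined by a canonical GT..AG intron, cut at a codon boundary
after the S100-like block. The first intron always ends in `TAG`: the
final `AG` is the splice acceptor, and the triplet doubles as an in-frame
stop immediately upstream of the start codon. This guard pins the maximal
open reading frame to the planted ATG, making "exact CDS recovery" a
well-defined target. Intronless variants plant `TAA` in the same position
(stop guard without a spurious acceptor). Minus-strand genes are built on
the coding strand and reverse-complemented at assembly; all truth
coordinates are forward-strand, 0-based, half-open, with the stop codon
inside the CDS interval.

**Proteins.** Residues are drawn from the spec'd composition bias
(remainder uniform over the other residues); repeat arrays, the 34-residue
beta motif (1 or 4 copies), the S100-like block and optional
carboxy-terminal family motifs are planted verbatim. Reverse translation
uses uniform synonymous codons — no codon-usage table, since nothing
downstream depends on codon bias. Intergenic background is random DNA at
45% GC (a typical vertebrate value; configurable).

**Seed profiles.** The 34-column beta-motif seed alignment and the
S100-like seed are synthetic stand-ins authored for this package (files
named `*.synthetic.fasta`); they define a recognizable motif with
beta-strand-like alternation, not any organism's real motif. Consequences:
motif *detection machinery* is fully tested, but thresholds tuned on these
seeds say nothing about sensitivity on real CBP repertoires.

**Pseudogenes** carry one or more planted lesions (premature stop codon,
or single-base deletion causing a frameshift) at a codon drawn uniformly
from the CDS interior, excluding 8 codons at each terminus. The exclusion
is deliberate: a lesion in the extreme termini leaves no alignable
fragment on one side and is undetectable by homology in principle, so
including it would only measure an impossibility.

**Simulated evolution** (`evolve_species`) applies losses, tandem
duplications (copies renamed `genea`, `geneb`, …), strand inversions, then
substitutions. The raw substitution model (`mutate_sequence`) is i.i.d.
per site: mutate with probability *r*, new base uniform among the other
three. Its amino-acid identity expectation has an exact per-codon closed
form (`expected_aa_identity`), which the test suite checks by simulation.
Inside gene blocks, evolution protects start/stop codons, splice
dinucleotides and the 3-nt frame guard, and resamples substitutions that
would create an in-frame stop, so derived truth stays translatable; this
makes coding sequence mutate at a very slightly lower realized rate than
intergenic sequence, which is biologically the right direction anyway.

**Family expansions** (`simulate_family_expansion`) give each clade an
independent ancestor (shared ancestor mutated at `between_rate`) and each
copy an independent `within_rate` mutant of its clade ancestor, so
per-clade monophyly is true by construction; protein-level mutation is
i.i.d. per residue, uniform over the other 19.

## Translated search (module `search`)

Every scaffold is translated in six frames (stops as `*`, N-containing
codons as `X`) and each protein query is aligned locally against each
frame translation under BLOSUM62 with gap costs `open 11, extend 1`
(a gap of length *k* costs 11 + *k*). No low-complexity masking is applied
by default: EDC proteins are low-complexity, masking would remove the
signal.

The per-frame optimum is computed by full affine-gap Smith–Waterman
(numba-compiled three-matrix DP); additional non-overlapping HSPs come
from masking the matched target span and re-aligning. A seed-and-extend
heuristic was considered and rejected: the package promises *exact*
equality with the full-DP oracle, and an optimal local alignment need not
contain any exact word hit, so no word-seeded scheme can guarantee that.
At desk scale (scaffolds of 10^4–10^5 nt) full DP costs seconds.
`word_size` survives only as the minimum usable query length.

Scores are raw; there are no E-values. Karlin–Altschul calibration buys
nothing on single-scaffold searches and would make the reporting threshold
(default raw score 50) stochastic. The threshold is exposed in the config;
raising it never adds HSPs (monotonicity is a tested invariant).

## Gene prediction (module `predict`)

Prediction is homology-anchored, not ab initio. HSPs are merged into
candidate regions per (scaffold, strand) (merge distance 300 nt, padding
600 nt); each region is interpreted under the EDC grammar:

- **SEDC/CBP:** maximal ATG..stop ORFs (default minimum 30 residues) are
  enumerated; each HSP selects the ORF in its own reading frame with the
  largest overlap (at least half the HSP span), so tandem copies in one
  region each yield a model. The coding exon is taken to begin at the
  start codon; an upstream non-coding exon is attached when a canonical
  `AG` acceptor directly precedes the ATG with a `GT` donor at least 60 nt
  (default) further upstream, searched within 5,000 nt; otherwise the
  model is emitted single-exon and flagged `no_utr_intron`.
- **SFTP:** all (ATG, GT donor, AG acceptor) structures with first-exon
  length 150–450 nt, intron 60–2,000 nt, and a stop-free spliced
  translation are enumerated exhaustively and scored by the S100 profile
  match at the protein start plus (when a supporting homolog is available,
  as in the pipeline) the Smith–Waterman score of the spliced protein
  against it; ties prefer the shortest intron. With no surviving
  structure the model is returned `unclassified` with a `no_donor` or
  `no_two_exon_structure` diagnostic.
- **Pseudogenes:** the homolog is aligned to the region's coding-strand
  frame translations; the chain of alignment fragments is built greedily
  by score, each fragment required to cover at least 10 new homolog
  residues (repeat-rich queries spawn shifted-frame duplicates over ground
  already covered). A reading-frame change between consecutive fragments
  is a frameshift lesion; in-frame stop codons inside or between
  same-frame fragments are premature-stop lesions. Note the aligner
  *bridges* a premature stop with a pair of gaps rather than splitting the
  alignment — stops must be found by scanning the aligned span, not by
  counting fragments. A verdict additionally requires the chain score to
  reach 30% of the homolog's self-alignment score; weaker fragmented
  matches are low-complexity cross-hits, not pseudogenes.

Classification order in the pipeline: SFTP by query class; pseudogene
verdict; otherwise ORF models, re-labelled CBP when the translated product
carries at least one beta motif. GFF3 output is 1-based inclusive with
`gene_class`, flags, lesions and the protein recorded in column 9, which
makes the writer→reader→writer round trip byte-identical.

Incompleteness at assembly gaps: scaffold gap runs (≥10 N) are exposed on
locus maps; models over gaps are not specially truncated beyond what
alignment produces.

## Protein features (module `features`)

Composition is plain percentage per standard residue (X excluded from the
denominator). Bias labels use inclusive thresholds: any single residue
≥ 15% (cysteine ≥ 10%), combined G+S ≥ 40%. These are package defaults
chosen so that loricrin-like planting (G+S > 60%) and EDSPR-like planting
(P ≥ 15–20%) classify correctly with wide margins; real-data users should
treat them as starting points, not biology.

Tandem repeats: exhaustive scan over motif lengths 2–30 (default range
2–12) and all phases; a unit copy may differ from the array's first unit
by at most `max_mismatches_per_unit` substitutions (default 1); maximal
arrays are reported best-first (count, then span, then leftmost start,
then shortest motif); a trailing partial copy of at least half the motif
is flagged, not counted. Rotational phase of a repeat array is inherently
ambiguous (`KCVPVCPP` arrays may surface as an equal-count rotation when a
flanking residue happens to extend the rotated unit); callers comparing
motifs should compare arrays, not strings.

PSSMs are log2-odds against a uniform background (1/20), with pseudocount
0.5 applied to per-column residue *proportions* so that duplicating seed
rows leaves the matrix unchanged. The reporting threshold defaults to 60%
of the consensus self-score. CBP typing: non-overlapping motif placements,
greedy best-first; 4 motifs → `4B`; 1 motif → `type1` if the
amino-terminal arm is ≤ 15 residues else `type2` (the 15 sits in the empty
gap between the observed arm ranges of roughly 7–10 and ~40–100);
2–3 motifs is flagged anomalous and left unclassified. Terminal family
motifs are scanned only within a terminal window (default 50 residues).

## Orthology and synteny (module `orthology`)

All-vs-all protein Smith–Waterman scores feed reciprocal-best-hit calling;
exact score ties leave both genes unpaired and flagged ambiguous (the
honest answer when duplicates are indistinguishable). Co-ortholog
resolution: gene *b* joins gene *a*'s group when *a* is *b*'s unique
closest partner and *b*'s score to *a* is within 90% of *b*'s own best
score; groups of size >1 are `1:many` (symmetrically `many:1`); an
absolute floor (default raw score 50) leaves noise unmatched. The relative
threshold is anchored at each candidate's own best hit — anchoring it at
the source gene's best would make recovery of duplications depend on the
binomial spread of mutation counts between copies, i.e. on luck.

The synteny chain takes one representative pair per gene (highest score)
and computes the longest subsequence increasing in both species' gene
orders (O(n²) DP); off-chain matches are reported as breakpoints; a
matched gene whose strand differs between species stays in the chain with
an inversion flag. Genes at assembly gaps can be excluded from chain
scoring while remaining on the rendered maps. Maps render one row per
species — `gene(strand)`, `§` between scaffolds, `//` at within-scaffold
gaps — plus a TSV twin that round-trips byte-identically.

## Phylogenetics (module `phylo`)

The scientific claims this module serves are clade-membership claims, so
the machinery is distance-based and deterministic rather than a full
maximum-likelihood tree search:

- **Progressive alignment:** guide tree by neighbor joining on p-distances
  from pairwise global alignments; profile–profile global alignment with
  affine gaps (expected BLOSUM62 score between columns); sequences
  processed in lexicographic id order, so input order is irrelevant.
- **Distances:** pairwise deletion of gap columns. `poisson_corrected`:
  d = −ln(1 − p), capped at 10 with a warning when p ≥ 1. `jtt_like`:
  maximum-likelihood distance under the empirical JTT amino-acid model
  (eigendecomposition of the rate matrix, 1-D bounded likelihood
  optimization); the JTT constants ship as a data file.
- **Neighbor joining:** standard Q-matrix algorithm; ties broken by the
  lexicographically lowest index pair (required for determinism); negative
  branch lengths clamped to zero. On additive matrices the output tree's
  path-length metric reproduces the input exactly (within 1e-9) — the
  primary correctness anchor, plus a topology cross-check against
  scikit-bio's independent implementation in the tests.
- **Bootstrap:** column resampling, NJ per replicate, supports = % of
  replicates containing each internal split of the full-data tree,
  written onto internal node labels; deterministic given the seed. An
  alignment with no variable columns is returned flagged degenerate with
  zero supports rather than pretending a star has structure.
- **Monophyly:** a subset is monophyletic iff some edge bipartitions the
  leaves into exactly (subset, complement); the verdict carries that
  edge's bootstrap support. Trivial subsets are rejected.

For beta-motif phylogenies the "unambiguously aligned" region is
operationalized as columns with < 20% gaps and ≥ 50% modal-residue
agreement (`unambiguous_columns`), or an explicit user mask.

## Pipeline, configuration, determinism

`annotate` runs search → region merge → prediction → classification →
features (→ expression validation when transcripts are given: a protein is
`expressed` iff some transcript yields an HSP above threshold covering
≥ 50% of it). `run_comparison` adds RBH + synteny + per-family bootstrap
trees with monophyly verdicts. All parameters live in `RunConfig`
(YAML-loadable; unknown keys rejected; the effective config is echoed into
the output directory); every source of randomness flows from explicit
seeds, and identical configs produce byte-identical outputs. CLI exit
codes: 0 success, 2 validation error, 3 stage failure.

The standard demo uses 22 genes per species (all planted classes, both
strands, two pseudogenes), spacing 2,000 nt, substitution rate 0.05
between the two species plus one 1:2 duplication, one loss and one
inversion; the query panel is a third, outgroup-like species (the same
cluster independently diverged at rate 0.08 with no gene gains or losses),
mirroring how real EDC annotation uses a well-annotated reference species'
proteins. These sizes keep the full demo under two minutes on one CPU
while exercising every code path; they are the problem sizes the
acceptance script reports.

## What passing tests do and do not show

Planted-truth recovery shows the machinery is internally correct: exact
coordinate bookkeeping across strands and splicing, exact alignment
scores, correct relation and clade logic. It does not show field
performance on real genomes: real intergenic sequence has repeat
landscapes and GC structure the generator does not model; real divergence
is not i.i.d. per site; real splice sites have context beyond GT/AG; real
gene families blur the clean co-ortholog structure planted here. Headline
gene counts from real assemblies additionally depend on assembly
completeness and manual curation choices and are outside what this
package's synthetic evidence can establish.
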