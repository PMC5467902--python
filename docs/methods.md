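# Methods

`genomine` packages three desk-scale analyses used in bacterial genome
mining — regulatory-motif scanning, alignment-free proteome phylogeny,
and multi-source annotation reconciliation — together with a synthetic
data generator that plants ground truth for all of them. This note
records the models, the parameters that matter, and the design choices
made where more than one defensible convention exists.

## Degenerate-consensus motif scanning

**Model.** A binding site is modelled as an IUPAC degenerate consensus
with a mismatch budget, not a position-weight matrix: each pattern
position carries a set of admissible bases, and a window matches when
the number of positions outside their sets is at most the budget. The
built-in default is the *B. subtilis* Fur operator `TGATAATNATTATCA`
(15 bp, palindromic) with a budget of 2 — the parameters under which the
*L. sphaericus* 2362 Fur regulon was originally predicted.

**Search.** The scan is an exhaustive sliding window over both strands.
Earlier practice used short-sequence BLAST-n for this task; for a 15-mer
query over a single bacterial chromosome an exhaustive scan is complete
by construction, deterministic, and takes seconds (the window mismatch
counts are accumulated with a per-position lookup table over the byte-
encoded sequence, ~15 vectorized passes per strand). A palindromic
motif can match one physical window in both orientations; both hits are
kept at scan level and collapsed later.

**Filter and gene assignment.** A hit is retained when (a) it lies
wholly in intergenic space and (b) it sits on the 5' side of at least
one annotated gene whose strand-aware start is within the proximity
window (default 250 bp). It is assigned to *every* such gene, one output
row per assignment, which is how a palindromic site between divergently
transcribed genes legitimately yields two rows. Pseudogenes count as
ORFs for proximity — a repressor does not know the reading frame has
decayed. Per-orientation duplicates of a palindromic site are collapsed
to one physical site; each assignment is reported in the orientation
matching its gene's strand when that orientation was observed.

**Distance convention.** `distance_to_gene` is the number of bases
strictly between the hit boundary nearest the gene and the gene's
strand-aware start (adjacent = 0). Published tables rarely state this
arithmetic; the convention here is applied uniformly in the scanner, the
simulator's truth tables, and the built-in regulon reconstruction, so
distances are internally consistent throughout. Two documented switches
relax the defaults: `anchor="either"` qualifies hits by proximity to
either gene boundary rather than the start, and `permissive=True`
retains in-window hits that have no upstream gene (default strict mode
drops them).

**Ambiguity handling.** A pattern `N` matches every base, including an
ambiguous genome `N`. An ambiguous *genome* base matches only a pattern
`N`; this is deliberately conservative so assembly-gap runs of `N`
cannot produce hits.

**Coordinates.** Internally everything is 1-based inclusive on the
forward strand with an explicit strand field (the GFF3 convention);
BED6 export converts to 0-based half-open. Only the publication-style
report prints minus-orientation ranges with descending coordinates, and
it uses an ASCII hyphen. Scanning assumes a single linear contig; no
origin-spanning windows are generated.

## Composition-vector phylogeny

**Model.** Each proteome is summarized by its length-k peptide-string
frequencies. Windows are counted within proteins only (never across
boundaries) and windows containing non-standard residues
(B/J/O/U/X/Z) are skipped rather than expanded over their possible
readings — deterministic counts at the cost of a negligible fraction of
windows. The background expectation of each k-string is the
maximal-order Markov prediction from the two lengths below,

    p0(a1..ak) = p(a1..a(k-1)) * p(a2..ak) / p(a2..a(k-1)),

and the composition vector stores the relative deviations
`(p - p0)/p0` (0 where `p0` is 0). Subtracting the background removes
shared compositional signal that carries no phylogenetic information.
Pairwise dissimilarity is `D = (1 - C)/2`, where `C` is the cosine
correlation over the union of observed k-strings, so `D` lies in
[0, 1]: 0 for identical vectors, 0.5 for disjoint k-string supports,
1 for perfect anti-correlation. A proteome whose deviation vector is
identically zero (e.g. a homopolymer) has no direction and is rejected
rather than silently placed.

**Tree building.** Neighbor joining on the CV distance matrix, with
taxa presented in lexicographic order so that ties in the Q criterion
resolve identically across runs; the joining itself is scikit-bio's
implementation, which tests verify against the three-point closed form
and a brute-force minimum-evolution search over all topologies for up
to five taxa. Rooting is by outgroup (the root is placed on the edge to
the named leaf). NJ recovers additive matrices exactly, which is the
basis of the oracle tests; no bootstrap or likelihood machinery is
included.

**Choice of k.** For real bacterial proteomes (~10^6 residues) the
default is k = 6; published whole-proteome analyses report stable
topologies across k = 6-9, and 20^6 cells keep the vectors sparse but
well-populated at that size. The package's synthetic validation
proteomes are three orders of magnitude smaller (6,000 residues), so
tests exercise k = 4 and 5, where such proteomes still populate the
k-string space densely enough for stable topologies; the k-consistency
check (identical topologies at two adjacent k) is run at that scale.

## Annotation reconciliation

**Inputs.** Per-locus product strings from several pipelines (reference
source: `ncbi`) and pre-computed evidence rows — domain hits, best
reviewed database hits (with e-values), and regulon context. No live
database queries: the decision logic, not the lookup, is the procedure.

**Rules.** Products are normalized (lowercase, punctuation stripped,
whitespace collapsed) before comparison. The cascade, first match wins:

1. *consensus* — all sources agree: keep, unflagged.
2. *uninformative_vs_defined* — "hypothetical protein"-class calls
   (configurable lexicon plus DUF-only names) lose to a single
   well-defined alternative when a domain hit or reviewed best hit
   passes the e-value gate (strictly below 1e-6).
3. *general_vs_specific* — when one product's token set strictly
   contains every other's ("Iron Transporter" vs "Transporter"), the
   specific product wins given admissible evidence; regulon context is
   admissible here, as genomic neighbourhood is what distinguishes the
   specific reading.
4. *evidence_override* — when well-defined sources disagree with no
   subset relation and exactly one candidate differs from the reference
   call, a gated domain/reviewed hit promotes that candidate (this is
   the rule that re-annotates an "ABC Transporter Permease" carrying a
   single CryBP1 toxin domain at 2.9e-71 as an insecticidal toxin).
   With two or more distinct challengers the record stays unresolved —
   evidence rows are attached to the locus, not to a source, so the
   procedure cannot adjudicate between multiple challengers and keeping
   the reference call with a warning is the conservative outcome.
5. *unresolved* — keep the reference product, warn.

The discrepancy flag is defined as "final product differs from the NCBI
call after normalization" and is re-derived on every output, matching
the asterisk convention of curated supplementary tables. Identity and
coverage percentages of reviewed hits are carried as metadata but are
not admission thresholds; only the e-value gates admission. Evidence
support is existence-based at the locus level.

## Synthetic data

**Genomes.** Background sequence is i.i.d. with a specified GC
(default 0.373, a typical *Lysinibacillus* chromosome); genes are
non-overlapping spans with randomized strands and lengths, packed with
intergenic gaps sized to host the requested placements (an infeasible
packing is an error, not a silent adjustment). Planted sites are
instantiations of the motif with an exact number of mismatches applied
at constrained pattern positions, inserted on either strand at a
controlled placement: `upstream` at a given gap to a gene start,
`intragenic`, or `far` (intergenic, beyond the window of every gene).
The truth table's `expected_pass` is evaluated directly from the filter
predicates (budget 2, window 250) against the realized gene layout, so
it is independent of the scanner implementation.

By default the background is *scrubbed*: any window that would match
the motif within budget+1 mismatches in either orientation and is not a
planted site has one base re-randomized to force a mismatch, iterating
to a fixed point. Scrubbing makes the truth table exhaustive (planted
recovery can be asserted as set equality). Margin-level windows that
cannot be broken without touching protected bases are tolerated — the
hard guarantee is only that no unplanted window is within the budget
itself. With `scrub_background=False` spurious matches occur at the
analytically expected i.i.d. rate and consumers must re-validate extra
hits against the predicates.

What the generator does *not* emulate: codon structure (gene bodies are
background-distributed, genes are coordinates only), operons, indels,
dinucleotide bias, and mobile elements. Passing tests therefore
demonstrate correctness of the scanning and filtering logic, not
robustness to compositional structure in real chromosomes — for the
exhaustive scan this distinction is immaterial (completeness is
combinatorial, not statistical), but background hit *rates* observed on
synthetic genomes do not transfer to real ones.

**Proteomes.** A root proteome of i.i.d. residues evolves down a given
Newick tree; each branch applies a Poisson number of substitutions
(mean = branch length x rate scale x residue count) at uniformly chosen
sites, uniform over the 19 alternative residues. No rate matrix, no
indels, no site heterogeneity: topology recovery is what is tested, and
for that purpose a uniform model is sufficient and maximally legible.
The benchmark tree is six leaves with a near-clonal three-leaf clade
(0.02 substitutions/site internally) against three distant relatives —
the "tight toxic-lineage clade among outgroups" situation this
phylogeny method is typically asked to resolve.

**Validation problem sizes.** The standard validation chromosome is
100 kb / 30 genes / 12 planted sites covering every filter predicate
(mismatches 0-3; offsets 18-300 bp including a 250-bp boundary case;
intragenic and far controls). Scan completeness is checked against a
naive double-loop oracle on 200 seeded 5-kb genomes. The built-in
regulon reconstruction embeds the nine published Fur-box rows of the
*L. sphaericus* 2362 chromosome (seven physical sites) in a ~10-kb
synthetic chromosome with genes at the published distances; the
default-parameter pipeline reproduces all nine rows, including the
58-bp spacing upstream of the iron-dicitrate transporter gene.

## Known limitations

- The proximity filter anchors distance at gene starts; regulatory
  sites acting on internal promoters or read-through transcripts are
  out of model (the `anchor="either"` switch is a blunt alternative).
- Consensus-plus-budget scoring treats all mismatches equally; a PWM
  would weight them, and borderline sites (budget boundary) are
  all-or-nothing here.
- CV distances are dissimilarities, not evolutionary distances; branch
  lengths of the NJ tree have no substitutions-per-site interpretation.
- The reconciler's evidence model is existence-based per locus; it
  cannot arbitrate between two well-defined products each backed by
  separate strong evidence.
- Circular chromosomes are scanned linearly; a site spanning the origin
  would be missed unless the input is rotated.
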