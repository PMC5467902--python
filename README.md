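# genomine

Desk-scale bacterial genome mining: regulatory-motif scanning with an
intergenic/ORF-proximity filter, alignment-free whole-proteome
phylogeny, and rule-based reconciliation of multi-pipeline gene
annotations — plus a synthetic-data generator that plants ground truth
for all three. Built for bioinformaticians re-running or auditing
regulon predictions and annotation curation on newly sequenced
bacterial genomes, with *Lysinibacillus sphaericus* (a mosquitocidal
biocontrol agent) as the worked reference organism.

## What it computes

**Fur-regulon scanning.** The ferric-uptake regulator Fur represses
iron-acquisition genes by binding a conserved palindromic operator
("Fur box"); in *B. subtilis* the consensus is `TGATAATNATTATCA`. The
scanner slides this IUPAC consensus exhaustively over both strands of a
chromosome, keeps windows with at most *m* mismatches (default 2), and
then retains only hits that lie wholly in intergenic space on the 5'
side of a gene start within *w* bp (default 250). Each retained hit is
assigned to every qualifying gene — a palindromic site between
divergently transcribed genes yields one row per gene, exactly as
curated regulon tables print it.

**Composition-vector phylogeny.** Each proteome is reduced to the
frequencies of its length-k peptide strings; the background expectation
of each k-string is the Markov prediction from the two lengths below,
p0(a1..ak) = p(a1..a(k-1)) p(a2..ak) / p(a2..a(k-1)), and the vector of
relative deviations (p - p0)/p0 is compared between taxa by
D = (1 - C)/2 with C the cosine correlation. Neighbor joining on the
resulting distance matrix gives the tree (optionally rooted on an
outgroup). No markers, no alignment — usable across genomes with
different gene content.

**Annotation reconciliation.** Product calls from several annotation
pipelines (NCBI as reference, plus e.g. Prokka/RAST/KAAS) are merged by
an evidence-gated cascade: consensus kept; "hypothetical protein"-class
calls lose to a well-defined alternative backed by a domain or reviewed
hit with e-value < 1e-6; specific beats general ("Iron Transporter"
over "Transporter") given evidence; a single evidence-backed challenger
overrides the reference call; everything else stays unresolved with a
warning. Final calls that differ from NCBI carry an asterisk-style
discrepancy flag.

See `docs/methods.md` for conventions (coordinates, the distance
arithmetic, ambiguity handling) and limitations.

## Worked example

The package ships the nine published Fur-box rows of the
*L. sphaericus* 2362 chromosome (CP015224) and can rebuild a small
synthetic chromosome embedding their seven physical sites with target
genes at the published distances:

```python
from genomine.datasets import reconstruct_fur_genome
from genomine.motif import FUR_BOX
from genomine.scan import scan_and_filter
from genomine.report import publication_report

genome = reconstruct_fur_genome(seed=0)
hits = scan_and_filter(genome, FUR_BOX)   # defaults: 2 mismatches, 250 bp
print(publication_report(hits, genome))
```

prints (coordinates are synthetic; sequences, strands, and distances
are the published ones):

```
sequence	position	locus_tag	product	distance_bp
ttaatTGATAATCATTATCGttatt	506-520	A2J09_RS01965	iron ABC transporter substrate-binding protein	127
tttagTGATAATGATTATCAttttt	2438-2452	A2J09_RS04875	iron-dicitrate ABC transporter ATP-binding	58
aaaaaTGATAATCATTATCActaaa	2452-2438	A2J09_RS04870	Ferredoxin-NADP reductase 3	90
gaggaTGATAATCATTATCAtcaca	3616-3630	A2J09_RS04910	iron ABC transporter substrate-binding protein	52
gtgagTGATAATCATTATCAattaa	5439-5425	A2J09_RS07705	siderophore biosynthesis protein	42
acgtaTGATAATGATTATCAattac	6577-6563	A2J09_RS19865	ferrichrome ABC transporter substrate-binding protein	18
ttactTGATAATCATTATCAttatc	7805-7819	A2J09_RS20375	thioredoxin reductase	151
gataaTGATAATGATTATCAagtaa	7819-7805	A2J09_RS20370	alkaline phosphatase-like protein	122
gaaatTGATAATCATTATCAatata	9076-9090	A2J09_RS21310	Hypothetical protein	42
```

Nine rows from seven physical sites: each core is within the
two-mismatch budget (lowercase letters are 5-nt flanks; `A2J09_RS01965`
carries the single mismatched core `...TATCG`), descending position
ranges mark minus-orientation rows, and the two sites flanked by
divergent genes (`2438-2452` and `7805-7819`) are each reported twice,
once per regulated gene. The distance column is the gap in bp between
the box and the gene start — 58 bp upstream of the iron-dicitrate
transporter gene, for example.

The same stages run from the shell:

```sh
genomine simulate genome --spec spec.yaml --out-dir sim/
genomine scan --genome sim/genome.fasta --annotation sim/genome.gff3 \
              --motif fur_box --out-prefix hits
genomine phylo --proteomes proteomes/ --k 6 --outgroup StLB046 --out-prefix cv
genomine reconcile --annotations ann.tsv --evidence ev.tsv --out curated.tsv
```

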