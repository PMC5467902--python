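"""Synthetic genomes with planted motif sites and proteomes evolved on a tree.

The genome simulator emulates a low-GC bacterial chromosome (default GC
0.373): i.i.d. background sequence, non-overlapping gene features with
intergenic gaps, and motif instances planted at controlled mismatch
counts, strands, and distances to gene starts. Every planted site goes
into a ground-truth table whose ``expected_pass`` column is derived from
the filter rules (intergenic placement, mismatch budget 2, 250-bp
proximity window), so filter behaviour can be checked exactly.

By default the background is *scrubbed*: any background window that
would match the planted motif within budget+1 mismatches in either
orientation is re-randomized, so the truth table is exhaustive. With
``scrub_background=False`` spurious background matches may occur (their
expected rate is analytically small but not zero) and callers must
re-validate extra hits against the filter predicates.

The proteome simulator evolves a root proteome of i.i.d. residues down a
given tree, substituting sites as a Poisson process scaled by branch
length, with uniform replacement over the 19 alternative residues — a
deliberately minimal model, sufficient for topology-recovery tests.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio.tree import TreeNode

from .genome_io import GeneFeature, GenomeAnnotation
from .motif import FUR_BOX, IUPAC_SETS, ConsensusMotif, reverse_complement
from .phylogeny import Proteome
from .scan import _encode, _window_mismatches

#: Filter constants the truth table is derived against.
TRUTH_WINDOW = 250
TRUTH_BUDGET = 2

_AA = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(ValueError):
    """Infeasible simulation spec (packing, overlap, malformed tree)."""


@dataclass(frozen=True)
class PlantedSite:
    """One motif instance to plant.

    ``placement`` is ``upstream`` (at ``offset`` bases 5' of a gene
    start), ``intragenic`` (inside a gene body), or ``far`` (intergenic
    but beyond the proximity window of every gene).
    """

    mismatches: int = 0
    strand: str = "+"
    placement: str = "upstream"
    offset: int = 58
    gene_index: int | None = None
    core: str | None = None  # explicit pattern instantiation; random if None

    def __post_init__(self) -> None:
        if self.placement not in ("upstream", "intragenic", "far"):
            raise SimulationError(f"unknown placement {self.placement!r}")
        if self.strand not in ("+", "-"):
            raise SimulationError("strand must be '+' or '-'")
        if self.mismatches < 0 or self.offset < 0:
            raise SimulationError("mismatches and offset must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth for one planted site."""

    start: int
    end: int
    strand: str
    core: str
    mismatches: int
    placement: str
    offset: int
    gene: str
    expected_pass: bool


@dataclass
class GenomeSimSpec:
    """Parameters of one synthetic chromosome."""

    length: int = 100_000
    gc_fraction: float = 0.373
    gene_count: int = 30
    gene_length_range: tuple[int, int] = (300, 900)
    planted_motifs: list[PlantedSite] = field(default_factory=list)
    seed: int = 0
    scrub_background: bool = True


@dataclass
class TreeSimSpec:
    """Parameters of one proteome-evolution run."""

    newick_topology: str
    proteome_size: int = 50
    protein_length: int = 120
    substitution_rate_scale: float = 1.0
    seed: int = 0


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[p])) for p in pattern)


def _mutate(core: str, pattern: str, n: int, rng: np.random.Generator) -> str:
    """Introduce exactly n mismatches at pattern-constrained positions."""
    constrained = [j for j, p in enumerate(pattern) if len(IUPAC_SETS[p]) < 4]
    if n > len(constrained):
        raise SimulationError(f"cannot apply {n} mismatches: only {len(constrained)} constrained positions")
    out = list(core)
    for j in rng.choice(constrained, size=n, replace=False):
        alternatives = sorted(set("ACGT") - IUPAC_SETS[pattern[j]])
        out[j] = rng.choice(alternatives)
    return "".join(out)


def _background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def _layout_genes(spec: GenomeSimSpec, min_gaps: list[int], rng: np.random.Generator) -> list[GeneFeature]:
    lo, hi = spec.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.gene_count)
    leftover = spec.length - int(lengths.sum()) - sum(min_gaps)
    if leftover < 0:
        raise SimulationError(
            f"infeasible packing: need {spec.length - leftover} bp, have {spec.length}"
        )
    extra = rng.multinomial(leftover, [1 / len(min_gaps)] * len(min_gaps))
    genes: list[GeneFeature] = []
    pos = 1
    for i, glen in enumerate(lengths):
        pos += min_gaps[i] + int(extra[i])
        genes.append(
            GeneFeature(
                locus_tag=f"SIM_{i + 1:05d}",
                start=pos,
                end=pos + int(glen) - 1,
                strand=rng.choice(["+", "-"]),
                product=f"simulated protein {i + 1}",
            )
        )
        pos = genes[-1].end + 1
    return genes


def _expected_pass(start: int, end: int, mismatches: int, placement: str,
                   genes: list[GeneFeature]) -> bool:
    """Evaluate the filter predicates directly against the gene layout."""
    if placement == "intragenic" or mismatches > TRUTH_BUDGET:
        return False
    for g in genes:
        if g.strand == "+" and end < g.start and g.start - end - 1 <= TRUTH_WINDOW:
            return True
        if g.strand == "-" and start > g.end and start - g.end - 1 <= TRUTH_WINDOW:
            return True
    return False


def scrub_matches(
    seq: np.ndarray,
    motif: ConsensusMotif,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    margin: int = 1,
) -> np.ndarray:
    """Re-randomize background so no unplanted window matches within budget+margin.

    ``seq`` is a uint8 byte array of the chromosome; ``protected`` holds
    0-based [start, end) spans of planted cores, which are never touched.
    """
    threshold = motif.max_mismatches + margin
    m = len(motif)
    patterns = (motif.pattern, reverse_complement(motif.pattern))
    prot = np.zeros(len(seq), dtype=bool)
    for s, e in protected:
        prot[s:e] = True

    def _offending() -> tuple[set[int], set[int]]:
        codes = _encode(seq.tobytes().decode("ascii"))
        hard: set[int] = set()
        soft: set[int] = set()
        for pattern in patterns:
            mm = _window_mismatches(codes, pattern)
            for i in np.flatnonzero(mm <= threshold):
                i = int(i)
                if prot[i : i + m].all():
                    continue
                (hard if mm[i] <= motif.max_mismatches else soft).add(i)
        return hard, soft

    def _break_window(i: int) -> bool:
        """Mutate one base of window i so both orientations gain a mismatch
        there; returns False when no free position can be forced to mismatch
        (e.g. the only free offsets are unconstrained pattern positions)."""
        useful = []
        for j in range(i, i + m):
            if prot[j]:
                continue
            matching = IUPAC_SETS[patterns[0][j - i]] | IUPAC_SETS[patterns[1][j - i]]
            if chr(seq[j]) in matching and len(matching) < 4:
                useful.append((j, sorted(set("ACGT") - matching)))
        if not useful:
            return False
        j, choices = useful[int(rng.integers(len(useful)))]
        seq[j] = ord(rng.choice(choices))
        return True

    prev_soft: set[int] = set()
    for _ in range(50):
        hard, soft = _offending()
        # Hard windows (within budget: would be spurious hits) must go; soft
        # windows (within the safety margin only) are broken best-effort.
        if not hard and soft <= prev_soft:
            return seq
        stuck = [i for i in sorted(hard) if not _break_window(i)]
        if stuck:
            raise SimulationError(
                f"cannot scrub spurious match at 0-based position {stuck[0]}"
            )
        for i in sorted(soft):
            _break_window(i)
        prev_soft = soft
    raise SimulationError("background scrubbing did not converge")


def simulate_genome(
    spec: GenomeSimSpec, motif: ConsensusMotif = FUR_BOX
) -> tuple[GenomeAnnotation, list[TruthRecord]]:
    """Simulate one annotated chromosome with planted motif sites.

    Returns the annotation (FASTA/GFF3-writable) and the ground-truth
    table. Bit-reproducible for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    m = len(motif)
    upstream = [s for s in spec.planted_motifs if s.placement == "upstream"]
    far_sites = [s for s in spec.planted_motifs if s.placement == "far"]
    max_off = max((s.offset for s in upstream), default=0)
    interior = 2 * (max_off + m) + 100
    min_gaps = [interior] * spec.gene_count + [
        interior + (2 * TRUTH_WINDOW + (m + 20) * len(far_sites) + 100 if far_sites else 0)
    ]
    genes = _layout_genes(spec, min_gaps, rng)
    seq = _background(spec.length, spec.gc_fraction, rng)

    # assign planted sites to genes (round-robin unless pinned)
    next_gene = 0
    placements: list[tuple[PlantedSite, int, str]] = []  # (site, 0-based start, core)
    n_far_placed = 0
    for site in spec.planted_motifs:
        core = site.core or _instantiate(motif.pattern, rng)
        core = _mutate(core, motif.pattern, site.mismatches, rng)
        if site.placement == "far":
            anchor = genes[-1].end
            start0 = anchor + 2 * TRUTH_WINDOW + n_far_placed * (m + 20)  # 0-based
            n_far_placed += 1
        else:
            if site.gene_index is not None:
                gi = site.gene_index
            else:
                gi = next_gene
                next_gene = (next_gene + 1) % spec.gene_count
            g = genes[gi % spec.gene_count]
            if site.placement == "intragenic":
                if g.end - g.start + 1 < m + 20:
                    raise SimulationError(f"gene {g.locus_tag} too short for an intragenic site")
                start0 = g.start - 1 + (g.end - g.start + 1 - m) // 2
            elif g.strand == "+":
                start0 = g.start - site.offset - 1 - m  # hit end = g.start - offset - 1
            else:
                start0 = g.end + site.offset  # 0-based; 1-based start = g.end + offset + 1
        if start0 < 0 or start0 + m > spec.length:
            raise SimulationError("planted site falls outside the sequence")
        placements.append((site, start0, core))

    spans = sorted((s0, s0 + m) for _, s0, _ in placements)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise SimulationError("planted placements overlap")

    for site, start0, core in placements:
        inserted = core if site.strand == "+" else reverse_complement(core)
        seq[start0 : start0 + m] = np.frombuffer(inserted.encode("ascii"), dtype=np.uint8)

    if spec.scrub_background:
        seq = scrub_matches(seq, motif, [(s0, s0 + m) for _, s0, _ in placements], rng)

    annotation = GenomeAnnotation(
        sequence_id=f"simchr_seed{spec.seed}",
        sequence=seq.tobytes().decode("ascii"),
        features=genes,
    )
    truth = []
    for site, start0, core in placements:
        start, end = start0 + 1, start0 + m
        gene = ""
        if site.placement != "far":
            gi = next(
                (i for i, g in enumerate(genes)
                 if (site.placement == "intragenic" and g.start <= start and end <= g.end)
                 or (site.placement == "upstream" and (
                     (g.strand == "+" and end == g.start - site.offset - 1)
                     or (g.strand == "-" and start == g.end + site.offset + 1)))),
                None,
            )
            gene = genes[gi].locus_tag if gi is not None else ""
        truth.append(
            TruthRecord(
                start=start,
                end=end,
                strand=site.strand,
                core=core,
                mismatches=site.mismatches,
                placement=site.placement,
                offset=site.offset,
                gene=gene,
                expected_pass=_expected_pass(start, end, site.mismatches, site.placement, genes),
            )
        )
    truth.sort(key=lambda t: t.start)
    return annotation, truth


def write_truth_tsv(path: str | Path, truth: list[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tstrand\tcore\tmismatches\tplacement\toffset\tgene\texpected_pass\n")
        for t in truth:
            fh.write(
                f"{t.start}\t{t.end}\t{t.strand}\t{t.core}\t{t.mismatches}\t"
                f"{t.placement}\t{t.offset}\t{t.gene}\t{str(t.expected_pass).lower()}\n"
            )


def benchmark_planted_sites() -> list[PlantedSite]:
    """The standard planted-site panel used for filter validation.

    Twelve sites: nine upstream placements spanning mismatch counts 0-3
    at offsets {18, 42, 58, 151, 300} bp (the distances observed in the
    Fur regulon of L. sphaericus 2362, plus a 300-bp out-of-window
    control and a 250-bp boundary case), two intragenic controls, and
    one far-intergenic control. Expected filter outcomes cover every
    predicate: mismatch budget, intergenic placement, and proximity.
    """
    layout = [
        (0, "+", "upstream", 58),
        (1, "-", "upstream", 42),
        (2, "+", "upstream", 151),
        (3, "+", "upstream", 18),   # over budget: fails
        (0, "-", "upstream", 300),  # out of window: fails
        (2, "+", "upstream", 250),  # boundary: passes
        (1, "+", "upstream", 127),
        (0, "+", "upstream", 90),
        (2, "-", "upstream", 18),
        (0, "+", "intragenic", 0),  # fails: inside a gene
        (1, "-", "intragenic", 0),  # fails: inside a gene
        (0, "+", "far", 0),         # fails: no gene within window
    ]
    return [
        PlantedSite(mismatches=mm, strand=st, placement=pl, offset=off)
        for mm, st, pl, off in layout
    ]


def benchmark_genome_spec(seed: int = 0, **overrides) -> GenomeSimSpec:
    """100-kb, GC-0.373, 30-gene chromosome with the standard site panel."""
    params = dict(length=100_000, gc_fraction=0.373, gene_count=30,
                  planted_motifs=benchmark_planted_sites(), seed=seed)
    params.update(overrides)
    return GenomeSimSpec(**params)


#: Six-taxon validation tree: a near-clonal three-leaf clade (A, B, C;
#: 0.02 substitutions/site within) separated by a long stem from three
#: distant relatives, emulating a toxic-lineage clade among outgroups.
BENCHMARK_TREE = (
    "((A:0.02,(B:0.02,C:0.02):0.02):0.25,(D:0.3,(E:0.3,F:0.3):0.1):0.05);"
)


def benchmark_tree_spec(seed: int = 0, **overrides) -> TreeSimSpec:
    """50 x 120-residue proteomes evolved along :data:`BENCHMARK_TREE`."""
    params = dict(newick_topology=BENCHMARK_TREE, proteome_size=50,
                  protein_length=120, substitution_rate_scale=1.0, seed=seed)
    params.update(overrides)
    return TreeSimSpec(**params)


def simulate_proteomes(spec: TreeSimSpec) -> tuple[list[Proteome], TreeNode]:
    """Evolve a root proteome down ``spec.newick_topology``.

    Substitutions per branch are Poisson with mean
    ``branch_length * substitution_rate_scale * total_residues`` —
    branch lengths are expected substitutions per site when the rate
    scale is 1. Returns the leaf proteomes and the parsed true tree.
    """
    try:
        tree = TreeNode.read(_io.StringIO(spec.newick_topology))
    except Exception as exc:  # skbio raises several parse error types
        raise SimulationError(f"malformed Newick: {exc}") from exc
    tips = list(tree.tips())
    if len(tips) < 3:
        raise SimulationError("tree must have at least 3 leaves")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise SimulationError("branch lengths must be non-negative")
    rng = np.random.default_rng(spec.seed)
    n_res = spec.proteome_size * spec.protein_length
    alphabet = np.frombuffer(_AA.encode("ascii"), dtype=np.uint8)
    root_seq = rng.choice(alphabet, size=n_res)

    leaf_seqs: dict[str, np.ndarray] = {}

    def _evolve(node: TreeNode, parent_seq: np.ndarray) -> None:
        seq = parent_seq
        if node.length:
            seq = parent_seq.copy()
            n_sub = rng.poisson(node.length * spec.substitution_rate_scale * n_res)
            sites = rng.integers(0, n_res, size=n_sub)
            for s in sites:
                current = seq[s]
                choices = alphabet[alphabet != current]
                seq[s] = rng.choice(choices)
        if node.is_tip():
            leaf_seqs[node.name] = seq
        else:
            for child in node.children:
                _evolve(child, seq)

    for child in tree.children:
        _evolve(child, root_seq)

    proteomes = []
    for tip in tips:
        arr = leaf_seqs[tip.name].tobytes().decode("ascii")
        proteomes.append(
            Proteome(
                tip.name,
                [arr[i : i + spec.protein_length] for i in range(0, n_res, spec.protein_length)],
            )
        )
    return proteomes, tree
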