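"""Alignment-free whole-proteome phylogeny via composition vectors.

Each proteome is summarized by the frequencies of its overlapping
length-k peptide strings. The expected frequency of each k-string under a
maximal-order Markov background is predicted from the (k-1)- and
(k-2)-string frequencies,

    p0(a1..ak) = p(a1..a_{k-1}) * p(a2..ak) / p(a2..a_{k-1}),

and the composition vector holds the relative deviations
(p - p0)/p0. Subtracting the background suppresses the phylogenetically
uninformative signal shared by all proteomes of similar amino-acid
composition. Pairwise dissimilarity is D = (1 - C)/2, with C the cosine
correlation of two vectors over the union of their k-strings, and the
tree is built by neighbor joining.

This sidesteps marker-gene choice and alignment entirely, which is what
makes it usable across genomes with different gene content.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from .genome_io import read_fasta

#: The 20 standard amino acids; windows containing anything else are skipped.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class PhylogenyError(ValueError):
    """Degenerate proteome or invalid phylogeny input."""


@dataclass
class Proteome:
    """A predicted proteome: one taxon's protein sequences."""

    taxon_id: str
    sequences: list[str]

    def total_residues(self) -> int:
        return sum(len(s) for s in self.sequences)

    @classmethod
    def from_fasta(cls, path: str | Path, taxon_id: str | None = None) -> "Proteome":
        records = read_fasta(path)
        tid = taxon_id or Path(path).stem
        return cls(tid, [seq for _, seq in records])


@dataclass
class CompositionVector:
    """Normalized k-string frequency-deviation vector for one proteome."""

    taxon_id: str
    k: int
    components: dict[str, float] = field(default_factory=dict)

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.components.values()))


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix over an ordered taxon list."""

    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxon_ids), len(self.taxon_ids)):
            raise PhylogenyError("matrix shape does not match taxon list")
        if not np.allclose(v, v.T):
            raise PhylogenyError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise PhylogenyError("distance matrix diagonal must be zero")
        self.values = v

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxon_ids)}\n")
            for tid, row in zip(self.taxon_ids, self.values):
                fh.write(tid + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def kstring_counts(proteome: Proteome, k: int) -> Counter:
    """Count every overlapping k-residue window within each protein.

    Windows never span protein boundaries; windows containing a
    non-standard residue (B, J, O, U, X, Z, ...) are skipped rather than
    expanded, keeping counts deterministic.
    """
    if not 1 <= k <= 9:
        raise PhylogenyError(f"k must be in [1, 9], got {k}")
    counts: Counter = Counter()
    for seq in proteome.sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            window = s[i : i + k]
            if all(c in STANDARD_AA for c in window):
                counts[window] += 1
    return counts


def composition_vector(
    counts_k: Counter, counts_k1: Counter, counts_k2: Counter, *, taxon_id: str = "", k: int | None = None
) -> CompositionVector:
    """Build the background-subtracted deviation vector from raw counts.

    ``counts_k``, ``counts_k1``, ``counts_k2`` are k-, (k-1)- and
    (k-2)-string counts of the same proteome. For each observed k-string
    the component is (p - p0)/p0 with p0 the Markov prediction above;
    k-strings with zero predicted background get component 0.
    """
    if not counts_k:
        raise PhylogenyError("empty k-string counts: proteome too short for this k")
    if k is None:
        k = len(next(iter(counts_k)))
    if k < 3:
        raise PhylogenyError("composition vectors require k >= 3")
    tot_k = sum(counts_k.values())
    tot_k1 = sum(counts_k1.values())
    tot_k2 = sum(counts_k2.values())
    if tot_k1 == 0 or tot_k2 == 0:
        raise PhylogenyError("empty lower-order counts")
    components: dict[str, float] = {}
    for s, c in counts_k.items():
        prefix, suffix, middle = s[:-1], s[1:], s[1:-1]
        if counts_k1.get(prefix, 0) == 0 or counts_k1.get(suffix, 0) == 0:
            raise PhylogenyError(
                f"inconsistent counts: {s} observed but a (k-1)-substring is absent"
            )
        if counts_k2.get(middle, 0) == 0:
            raise PhylogenyError(
                f"inconsistent counts: {s} observed but its (k-2)-core is absent"
            )
        p = c / tot_k
        p0 = (
            (counts_k1[prefix] / tot_k1)
            * (counts_k1[suffix] / tot_k1)
            / (counts_k2[middle] / tot_k2)
        )
        components[s] = (p - p0) / p0 if p0 > 0 else 0.0
    return CompositionVector(taxon_id=taxon_id, k=k, components=components)


def proteome_vector(proteome: Proteome, k: int) -> CompositionVector:
    """Composition vector of a proteome at word length k (k >= 3)."""
    return composition_vector(
        kstring_counts(proteome, k),
        kstring_counts(proteome, k - 1),
        kstring_counts(proteome, k - 2),
        taxon_id=proteome.taxon_id,
        k=k,
    )


def cv_distance(a: CompositionVector, b: CompositionVector) -> float:
    """Dissimilarity D = (1 - C)/2 in [0, 1], C the cosine correlation.

    Identical vectors give 0; disjoint k-string supports (orthogonal
    vectors) give 0.5; perfectly anti-correlated vectors give 1.
    """
    if a.k != b.k:
        raise PhylogenyError(f"k mismatch: {a.k} vs {b.k}")
    na, nb = a.norm(), b.norm()
    if na == 0 or nb == 0:
        raise PhylogenyError("zero-norm composition vector (degenerate proteome)")
    smaller, larger = (a.components, b.components) if len(a.components) <= len(b.components) else (b.components, a.components)
    dot = sum(v * larger.get(s, 0.0) for s, v in smaller.items())
    c = dot / (na * nb)
    return (1.0 - max(-1.0, min(1.0, c))) / 2.0


def distance_matrix(vectors: list[CompositionVector]) -> DistanceMatrix:
    """All-pairs cv_distance matrix over a list of composition vectors."""
    n = len(vectors)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = cv_distance(vectors[i], vectors[j])
    return DistanceMatrix([v.taxon_id for v in vectors], values)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Unrooted neighbor-joining tree with branch lengths.

    On an additive matrix NJ recovers the generating topology and branch
    lengths exactly (up to floating-point tolerance). Taxa are presented
    to the joining in lexicographic order so that ties in the Q criterion
    resolve deterministically.
    """
    if len(d.taxon_ids) < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    order = sorted(range(len(d.taxon_ids)), key=lambda i: d.taxon_ids[i])
    ids = [d.taxon_ids[i] for i in order]
    values = d.values[np.ix_(order, order)]
    return nj(_SkbioDM(values, ids))


def root_with_outgroup(tree: TreeNode, taxon_id: str) -> TreeNode:
    """Root the tree on the edge leading to the outgroup leaf (idempotent)."""
    if taxon_id not in {t.name for t in tree.tips()}:
        raise PhylogenyError(f"outgroup {taxon_id!r} not present in tree")
    return tree.root_by_outgroup([taxon_id])


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
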