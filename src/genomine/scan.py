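"""Exhaustive motif scanning and the intergenic/ORF-proximity filter.

The scan slides the consensus over every window of the chromosome on both
strands and keeps windows within the mismatch budget. This is deliberately
exhaustive rather than heuristic (e.g. seeded short-read BLAST): for a
15-mer query an exhaustive scan is complete, deterministic, and fast
enough for a multi-megabase bacterial chromosome.

The downstream filter reproduces the regulon-prediction rule: a hit is
retained only if it lies wholly in intergenic space and within a fixed
window (default 250 bp) of the strand-aware start of an annotated ORF, on
the ORF's 5' (upstream) side. A palindromic site flanked by two
divergently transcribed genes yields one row per gene assignment.

Distance convention: ``distance_to_gene`` is the number of bases strictly
between the hit boundary nearest the gene and the gene's strand-aware
start (adjacent = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .genome_io import GeneFeature, GenomeAnnotation
from .motif import IUPAC_SETS, ConsensusMotif, reverse_complement

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}  # anything else -> 4 (ambiguous)


class FilterError(ValueError):
    """Invalid proximity-filter parameters."""


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on a genome.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates
    regardless of orientation; ``core`` and the flanks are read in hit
    orientation (reverse-complemented for minus-orientation hits).
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    core: str
    left_flank: str
    right_flank: str
    mismatches: int
    assigned_gene: str = ""
    distance_to_gene: int | None = None


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.uint8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _mismatch_lut(pattern: str) -> np.ndarray:
    """lut[j, code] == 1 iff genome base `code` mismatches pattern[j]."""
    lut = np.ones((len(pattern), 5), dtype=np.uint8)
    for j, pat in enumerate(pattern):
        for base, code in _BASE_CODE.items():
            if base in IUPAC_SETS[pat]:
                lut[j, code] = 0
        if pat == "N":
            lut[j, 4] = 0  # pattern N tolerates even an ambiguous genome base
    return lut


def _window_mismatches(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of every length-|pattern| window against pattern."""
    m = len(pattern)
    n_win = len(codes) - m + 1
    lut = _mismatch_lut(pattern)
    mm = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        mm += lut[j, codes[j : j + n_win]]
    return mm


def scan_genome(
    annotation: GenomeAnnotation,
    motif: ConsensusMotif,
    flank: int = 5,
) -> list[MotifHit]:
    """Find every window within the mismatch budget, on both strands.

    A window whose forward reading matches yields a '+' hit; a window
    whose reverse complement matches yields a '-' hit. For a palindromic
    motif the same window can yield both. Hits are sorted by start then
    strand; flanks are truncated at the sequence ends.
    """
    seq = annotation.sequence
    m = len(motif)
    if len(seq) < m:
        warnings.warn(f"sequence {annotation.sequence_id} shorter than motif; no hits")
        return []
    codes = _encode(seq)
    hits: list[MotifHit] = []
    for strand, pattern in (("+", motif.pattern), ("-", reverse_complement(motif.pattern))):
        mm = _window_mismatches(codes, pattern)
        for i in np.flatnonzero(mm <= motif.max_mismatches):
            i = int(i)
            start, end = i + 1, i + m  # 1-based inclusive
            window = seq[i : i + m]
            left = seq[max(0, i - flank) : i]
            right = seq[i + m : i + m + flank]
            if strand == "-":
                window = reverse_complement(window)
                left, right = reverse_complement(right), reverse_complement(left)
            hits.append(
                MotifHit(
                    sequence_id=annotation.sequence_id,
                    start=start,
                    end=end,
                    strand=strand,
                    core=window,
                    left_flank=left,
                    right_flank=right,
                    mismatches=int(mm[i]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _upstream_gap(hit_start: int, hit_end: int, gene: GeneFeature) -> int | None:
    """Bases between the hit and the gene's strand-aware start, if the hit
    lies on the gene's 5' side; None otherwise."""
    if gene.strand == "+":
        if hit_end < gene.start:
            return gene.start - hit_end - 1
        return None
    if hit_start > gene.end:
        return hit_start - gene.end - 1
    return None


def _boundary_gap(hit_start: int, hit_end: int, gene: GeneFeature) -> int | None:
    """Bases between the hit and the nearest gene boundary (None if overlapping)."""
    if hit_end < gene.start:
        return gene.start - hit_end - 1
    if hit_start > gene.end:
        return hit_start - gene.end - 1
    return None


def _overlaps_any_gene(hit: MotifHit, features: list[GeneFeature]) -> bool:
    return any(f.start <= hit.end and hit.start <= f.end for f in features)


def proximity_filter(
    hits: list[MotifHit],
    annotation: GenomeAnnotation,
    window: int = 250,
    anchor: str = "start",
    permissive: bool = False,
) -> list[MotifHit]:
    """Apply the intergenic / ORF-proximity rule and assign genes.

    Retains hits that (a) lie wholly in intergenic space and (b) are
    within ``window`` bases of an ORF. A hit is assigned to every gene
    whose strand-aware start it is upstream of within the window; one
    output row is produced per hit-gene assignment, so a palindromic site
    between divergent genes produces two rows. Per-orientation duplicates
    of a palindromic site are collapsed to one physical site, and each
    assignment is reported in the orientation matching its gene's strand
    when that orientation was observed.

    Parameters
    ----------
    window
        Maximum distance in bp (default 250).
    anchor
        ``"start"`` (default): qualification distance is measured to the
        gene's strand-aware start. ``"either"``: a hit also qualifies by
        proximity to either gene boundary, but assignment still requires
        the upstream side.
    permissive
        If True, a qualifying hit with no upstream gene within the window
        is retained unassigned; the default (strict) drops it.

    Pseudogenes count as ORFs: a regulator can still bind upstream of a
    decayed reading frame.
    """
    if window < 0:
        raise FilterError("window must be non-negative")
    if anchor not in ("start", "either"):
        raise FilterError("anchor must be 'start' or 'either'")
    features = annotation.features

    # group per-orientation scan hits into physical sites
    sites: dict[tuple[int, int], dict[str, MotifHit]] = {}
    for h in hits:
        sites.setdefault((h.start, h.end), {})[h.strand] = h

    out: list[MotifHit] = []
    for (start, end), by_strand in sorted(sites.items()):
        any_hit = next(iter(by_strand.values()))
        if _overlaps_any_gene(any_hit, features):
            continue  # not intergenic
        assignments: list[tuple[GeneFeature, int]] = []
        near_boundary: list[int] = []
        for gene in features:
            up = _upstream_gap(start, end, gene)
            bnd = _boundary_gap(start, end, gene)
            if bnd is not None and bnd <= window:
                near_boundary.append(bnd)
            qualify = bnd if anchor == "either" else up
            if up is not None and qualify is not None and qualify <= window:
                assignments.append((gene, up))
        if assignments:
            for gene, dist in sorted(assignments, key=lambda g: (g[1], g[0].locus_tag)):
                base = by_strand.get(gene.strand) or by_strand[sorted(by_strand)[0]]
                out.append(replace(base, assigned_gene=gene.locus_tag, distance_to_gene=dist))
        elif permissive and near_boundary:
            base = by_strand.get("+") or by_strand[sorted(by_strand)[0]]
            out.append(replace(base, distance_to_gene=min(near_boundary)))
    out.sort(key=lambda h: (h.start, h.strand, h.assigned_gene))
    return out


def scan_and_filter(
    annotation: GenomeAnnotation,
    motif: ConsensusMotif,
    window: int = 250,
    flank: int = 5,
    anchor: str = "start",
    permissive: bool = False,
) -> list[MotifHit]:
    """Convenience composition: exhaustive scan then proximity filter."""
    return proximity_filter(
        scan_genome(annotation, motif, flank=flank),
        annotation,
        window=window,
        anchor=anchor,
        permissive=permissive,
    )
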