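"""Built-in reference data: the published Fur regulon of L. sphaericus 2362.

``FUR_SITES_2362`` holds the nine reported Fur-box rows for the
*Lysinibacillus sphaericus* 2362 chromosome (RefSeq CP015224): flanked
site sequence as printed (lowercase 5-nt flanks, uppercase 15-nt core),
coordinate range (descending for minus-orientation rows), target locus
tag, product, and distance to the gene start in bp. Seven physical sites
underlie the nine rows: two palindromic sites sit between divergently
transcribed gene pairs and are reported once per orientation.

``reconstruct_fur_genome`` rebuilds a small SYNTHETIC chromosome that
embeds the seven physical sites with target genes placed at the reported
distances, so the full scan-and-filter pipeline can be exercised against
the published regulon without downloading the 4.7-Mb assembly. It is a
synthetic stand-in: coordinates are arbitrary, only the site sequences,
strand geometry, and distances are real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GeneFeature, GenomeAnnotation
from .motif import FUR_BOX, reverse_complement
from .simulate import scrub_matches


@dataclass(frozen=True)
class FurSiteRow:
    """One published Fur-box row (per hit-gene assignment)."""

    flanked_sequence: str  # lowercase flanks, uppercase core, hit orientation
    position: str  # "start-end", descending on minus orientation
    locus_tag: str
    product: str
    distance_bp: int
    is_pseudogene: bool = False

    @property
    def core(self) -> str:
        return self.flanked_sequence[5:-5].upper()

    @property
    def strand(self) -> str:
        a, b = (int(x) for x in self.position.split("-"))
        return "+" if a <= b else "-"


FUR_SITES_2362: list[FurSiteRow] = [
    FurSiteRow("tttagTGATAATGATTATCAttttt", "1030906-1030920", "A2J09_RS04875",
               "iron-dicitrate ABC transporter ATP-binding", 58),
    FurSiteRow("aaaaaTGATAATGATTATCActaaa", "1030920-1030906", "A2J09_RS04870",
               "Ferredoxin-NADP reductase 3", 90),
    FurSiteRow("gaggaTGATAATCATTATCAtcaca", "1038754-1038768", "A2J09_RS04910",
               "iron ABC transporter substrate-binding protein", 52),
    FurSiteRow("gtgagTGATAATCATTATCAattaa", "1584015-1584001", "A2J09_RS07705",
               "siderophore biosynthesis protein", 42),
    FurSiteRow("acgtaTGATAATGATTATCAattac", "4038130-4038116", "A2J09_RS19865",
               "ferrichrome ABC transporter substrate-binding protein", 18,
               is_pseudogene=True),
    FurSiteRow("ttactTGATAATCATTATCAttatc", "4142246-4142260", "A2J09_RS20375",
               "thioredoxin reductase", 151),
    FurSiteRow("gataaTGATAATGATTATCAagtaa", "4142260-4142246", "A2J09_RS20370",
               "alkaline phosphatase-like protein", 122),
    FurSiteRow("gaaatTGATAATCATTATCAatata", "4354641-4354655", "A2J09_RS21310",
               "Hypothetical protein", 42),
    FurSiteRow("ttaatTGATAATCATTATCGttatt", "422084-422097", "A2J09_RS01965",
               "iron ABC transporter substrate-binding protein", 127),
]


# Physical sites in chromosome coordinate order. Each entry: the
# forward-strand flanked sequence (from the plus-orientation row where one
# exists, else the reverse complement of the printed minus row), the gene
# assigned on the left (minus strand, with its distance) and/or on the
# right (plus strand, with its distance).
_PHYSICAL_SITES: list[dict] = [
    {"forward": "ttaatTGATAATCATTATCGttatt", "right": ("A2J09_RS01965", 127)},
    {"forward": "tttagTGATAATGATTATCAttttt",
     "left": ("A2J09_RS04870", 90), "right": ("A2J09_RS04875", 58)},
    {"forward": "gaggaTGATAATCATTATCAtcaca", "right": ("A2J09_RS04910", 52)},
    {"forward": reverse_complement("gtgagTGATAATCATTATCAattaa").lower(),
     "left": ("A2J09_RS07705", 42)},
    {"forward": reverse_complement("acgtaTGATAATGATTATCAattac").lower(),
     "left": ("A2J09_RS19865", 18)},
    {"forward": "ttactTGATAATCATTATCAttatc",
     "left": ("A2J09_RS20370", 122), "right": ("A2J09_RS20375", 151)},
    {"forward": "gaaatTGATAATCATTATCAatata", "right": ("A2J09_RS21310", 42)},
]

_PRODUCTS = {row.locus_tag: (row.product, row.is_pseudogene) for row in FUR_SITES_2362}

_GENE_LEN = 600
_BLOCK_GAP = 500


def reconstruct_fur_genome(seed: int = 0, gc_fraction: float = 0.373) -> GenomeAnnotation:
    """Synthetic chromosome embedding the seven published Fur sites.

    Target genes are placed on the published side and strand at the
    published distance from each site; intervening background is i.i.d.
    at the genome's GC and scrubbed of accidental near-matches so the
    pipeline's output on this chromosome is exactly the published nine
    hit-gene rows (with synthetic coordinates).
    """
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    features: list[GeneFeature] = []
    core_spans: list[tuple[int, int]] = []  # 0-based [start, end)
    pos = 0  # 0-based running length

    def background(n: int) -> str:
        probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
        return "".join(rng.choice(list("ACGT"), size=n, p=probs))

    def add(seq: str) -> None:
        nonlocal pos
        pieces.append(seq.upper())
        pos += len(seq)

    def add_gene(tag: str, strand: str) -> None:
        product, pseudo = _PRODUCTS[tag]
        features.append(
            GeneFeature(tag, pos + 1, pos + _GENE_LEN, strand, product, pseudo)
        )
        add(background(_GENE_LEN))

    add(background(_BLOCK_GAP))
    for site in _PHYSICAL_SITES:
        if "left" in site:
            tag, dist = site["left"]
            add_gene(tag, "-")  # minus gene: start codon at its right edge
            add(background(dist - 5))  # published distance counts from the core
        flanked = site["forward"]
        core_spans.append((pos, pos + len(flanked)))  # protect flanks too: they are printed data
        add(flanked)
        if "right" in site:
            tag, dist = site["right"]
            add(background(dist - 5))
            add_gene(tag, "+")
        add(background(_BLOCK_GAP))

    raw = np.frombuffer("".join(pieces).encode("ascii"), dtype=np.uint8).copy()
    clean = scrub_matches(raw, FUR_BOX, core_spans, rng)
    return GenomeAnnotation("synthetic_CP015224_fur_regulon",
                           clean.tobytes().decode("ascii"), features)
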