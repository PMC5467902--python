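"""Writers for scan results: publication-style TSV, BED6, and GFF3."""

from __future__ import annotations

from pathlib import Path

from .genome_io import GenomeAnnotation
from .scan import MotifHit

REPORT_COLUMNS = ("sequence", "position", "locus_tag", "product", "distance_bp")


def publication_report(hits: list[MotifHit], annotation: GenomeAnnotation) -> str:
    """Render filtered hits the way curated regulon tables print them.

    One row per hit-gene assignment: the site with lowercase flanks and
    an uppercase core (in hit orientation), the coordinate range printed
    descending for minus-orientation hits, the target locus tag and
    product, and the distance to the gene start in bp. Rows are ordered
    by forward-strand start, then orientation ('+' first). A hyphen
    separates coordinates (ASCII-safe).
    """
    products = {f.locus_tag: f.product for f in annotation.features}
    lines = ["\t".join(REPORT_COLUMNS)]
    for h in sorted(hits, key=lambda h: (h.start, h.strand, h.assigned_gene)):
        seq = h.left_flank.lower() + h.core.upper() + h.right_flank.lower()
        position = f"{h.start}-{h.end}" if h.strand == "+" else f"{h.end}-{h.start}"
        distance = "" if h.distance_to_gene is None else str(h.distance_to_gene)
        lines.append(
            "\t".join(
                [seq, position, h.assigned_gene, products.get(h.assigned_gene, ""), distance]
            )
        )
    return "\n".join(lines) + "\n"


def write_publication_report(
    path: str | Path, hits: list[MotifHit], annotation: GenomeAnnotation
) -> None:
    Path(path).write_text(publication_report(hits, annotation))


def write_bed6(path: str | Path, hits: list[MotifHit], name: str = "motif") -> None:
    """BED6 export: 0-based half-open coordinates, score = mismatch count."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.start, h.strand, h.assigned_gene)):
            fh.write(
                f"{h.sequence_id}\t{h.start - 1}\t{h.end}\t{name}\t{h.mismatches}\t{h.strand}\n"
            )


def write_hits_gff3(path: str | Path, hits: list[MotifHit], name: str = "motif") -> None:
    """GFF3 export of hits as TF_binding_site features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(sorted(hits, key=lambda h: (h.start, h.strand, h.assigned_gene)), 1):
            attrs = f"ID={name}_hit{i};Name={name};mismatches={h.mismatches}"
            if h.assigned_gene:
                attrs += f";assigned_gene={h.assigned_gene};distance={h.distance_to_gene}"
            fh.write(
                f"{h.sequence_id}\tgenomine\tTF_binding_site\t{h.start}\t{h.end}\t"
                f"{h.mismatches}\t{h.strand}\t.\t{attrs}\n"
            )
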