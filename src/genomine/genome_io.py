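"""Genome sequence / annotation I/O and the internal coordinate convention.

All coordinates inside the package are 1-based inclusive on the forward
strand, matching GFF3. Strand is always an explicit field; start <= end
always holds. BED6 export converts to 0-based half-open. Minus-strand
sites appear with descending coordinates only in the publication-style report,
never in the data model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import unquote

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AnnotationError(ValueError):
    """Malformed or inconsistent genome annotation input."""


@dataclass(frozen=True)
class GeneFeature:
    """One gene-level feature (ORF or pseudogene) of a bacterial annotation."""

    locus_tag: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive, >= start
    strand: str  # '+' or '-'
    product: str = ""
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"{self.locus_tag}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.locus_tag}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Strand-aware start coordinate (where transcription begins)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeAnnotation:
    """A genome sequence plus its ordered gene features."""

    sequence_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        length = len(self.sequence)
        for f in self.features:
            if f.locus_tag in seen:
                raise AnnotationError(f"duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)
            if f.end > length:
                raise AnnotationError(
                    f"{f.locus_tag} extends to {f.end} beyond sequence length {length}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(id, uppercased sequence), ...]``."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AnnotationError(f"{path}: no FASTA records found")
    for rid, seq in records:
        if not seq:
            raise AnnotationError(f"{path}: record {rid!r} has an empty sequence")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA; round-trips with read_fasta."""
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def _parse_gff_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = unquote(value.strip())
    return attrs


#: GFF3 feature types collapsed into one gene-level record per locus_tag.
_GENE_LEVEL_TYPES = {"gene", "pseudogene"}
_SUB_TYPES = {"CDS", "mRNA", "exon", "tRNA", "rRNA", "ncRNA"}


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read gene-level features from a GFF3 file.

    gene/pseudogene rows define the feature span; CDS rows contribute the
    ``product`` attribute and, for loci annotated only at CDS level, the
    span itself. Pseudogenes are retained with ``is_pseudogene=True``
    (a pseudogene can still be a regulatory target). One
    :class:`GeneFeature` is returned per locus_tag; a row without a
    locus_tag gets a synthetic tag with a warning.
    """
    spans: dict[str, dict] = {}
    order: list[str] = []
    synthetic = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            _, _, ftype, start_s, end_s, _, strand, _, attr_field = cols
            if ftype not in _GENE_LEVEL_TYPES and ftype not in _SUB_TYPES:
                continue
            attrs = _parse_gff_attributes(attr_field)
            tag = attrs.get("locus_tag")
            if tag is None:
                if ftype in _SUB_TYPES:
                    continue  # sub-feature without a tag cannot be attached
                synthetic += 1
                tag = f"GENOMINE_{synthetic:05d}"
                warnings.warn(
                    f"{path}:{lineno}: feature without locus_tag, using synthetic tag {tag}"
                )
            start, end = int(start_s), int(end_s)
            if strand not in ("+", "-"):
                strand = "+"
            entry = spans.get(tag)
            if entry is None:
                spans[tag] = entry = {
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "product": attrs.get("product", ""),
                    "pseudo": ftype == "pseudogene" or "pseudo" in attrs,
                    "gene_level_seen": ftype in _GENE_LEVEL_TYPES,
                }
                order.append(tag)
            else:
                if ftype in _GENE_LEVEL_TYPES:
                    if entry["gene_level_seen"]:
                        raise AnnotationError(f"{path}: duplicate locus_tag {tag}")
                    entry.update(start=start, end=end, strand=strand, gene_level_seen=True)
                else:
                    entry["start"] = min(entry["start"], start)
                    entry["end"] = max(entry["end"], end)
                if attrs.get("product"):
                    entry["product"] = attrs["product"]
                if ftype == "pseudogene" or "pseudo" in attrs:
                    entry["pseudo"] = True
    return [
        GeneFeature(
            locus_tag=tag,
            start=spans[tag]["start"],
            end=spans[tag]["end"],
            strand=spans[tag]["strand"],
            product=spans[tag]["product"],
            is_pseudogene=spans[tag]["pseudo"],
        )
        for tag in order
    ]


def write_gff3(path: str | Path, annotation_id: str, features: list[GeneFeature]) -> None:
    """Write gene-level features as GFF3 (inverse of read_gff3 at gene level)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda x: (x.start, x.end)):
            ftype = "pseudogene" if f.is_pseudogene else "gene"
            attrs = f"locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{annotation_id}\tgenomine\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def load_genome(fasta_path: str | Path, gff3_path: str | Path) -> GenomeAnnotation:
    """Load the first FASTA record plus its GFF3 features (single-contig)."""
    records = read_fasta(fasta_path)
    if len(records) > 1:
        warnings.warn(
            f"{fasta_path}: {len(records)} records; scanning uses the first contig only"
        )
    seq_id, seq = records[0]
    return GenomeAnnotation(seq_id, seq, read_gff3(gff3_path))


def intergenic_mask(annotation: GenomeAnnotation) -> list[tuple[int, int]]:
    """Maximal 1-based inclusive intervals covered by no gene feature.

    The mask and the features partition [1, L]: their union covers the
    whole sequence and they are disjoint. Returned intervals are sorted
    and pairwise non-adjacent.
    """
    length = len(annotation)
    mask: list[tuple[int, int]] = []
    cursor = 1
    for f in annotation.features:
        if f.start > cursor:
            mask.append((cursor, f.start - 1))
        cursor = max(cursor, f.end + 1)
    if cursor <= length:
        mask.append((cursor, length))
    return mask
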