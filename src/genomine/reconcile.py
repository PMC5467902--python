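"""Rule-based reconciliation of gene annotations from multiple pipelines.

Bacterial genomes annotated by several pipelines (NCBI PGAP, Prokka,
RAST, KAAS, ...) routinely disagree on gene products. This module merges
the per-gene calls into one curated product using an evidence-gated rule
cascade; evidence (domain hits, best reviewed database hit, regulon
context) is pre-computed upstream and consumed from TSV — no live
database queries. The reference source is ``ncbi``: the discrepancy flag
marks every final product that differs from the NCBI call, mirroring the
asterisk convention of curated supplementary tables.

Rule cascade (first match wins), with E_VALUE_GATE = 1e-6:

1. consensus            — all sources agree after normalization: keep.
2. uninformative_vs_defined — "hypothetical protein"-class calls lose to
   a single well-defined alternative, if a domain hit or reviewed best
   hit passes the e-value gate.
3. general_vs_specific  — a product whose token set strictly contains
   every other call's tokens wins ("Iron Transporter" over
   "Transporter"), given admissible evidence (domain architecture,
   reviewed hit, or regulon context).
4. evidence_override    — a single well-defined non-NCBI candidate backed
   by a gated domain/reviewed hit replaces the NCBI call.
5. unresolved           — keep the NCBI product and warn.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

E_VALUE_GATE = 1e-6

#: Products that carry no functional information.
UNINFORMATIVE_LEXICON = (
    "hypothetical protein",
    "uncharacterized protein",
    "unnamed protein",
    "unnamed protein product",
    "putative protein",
    "conserved hypothetical protein",
)

_DUF_ONLY = re.compile(r"^(duf\d+[ ,/-]*)+((domain|family)([ -]containing)?\s*protein)?$")

#: Reference annotation source; the discrepancy flag is relative to it.
REFERENCE_SOURCE = "ncbi"


class ReconcileError(ValueError):
    """Invalid reconciliation input."""


@dataclass(frozen=True)
class EvidenceItem:
    """One piece of pre-computed evidence attached to a locus."""

    kind: str  # domain_hit | reviewed_best_hit | regulon_context
    label: str
    evalue: float | None = None
    identity_pct: float | None = None
    coverage_pct: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("domain_hit", "reviewed_best_hit", "regulon_context"):
            raise ReconcileError(f"unknown evidence kind {self.kind!r}")
        if self.evalue is not None and self.evalue < 0:
            raise ReconcileError("e-value must be non-negative")

    @property
    def admissible(self) -> bool:
        """Sequence-similarity evidence must pass the e-value gate;
        regulon context has no e-value and is admissible as context."""
        if self.kind == "regulon_context":
            return True
        return self.evalue is not None and self.evalue < E_VALUE_GATE


@dataclass
class AnnotationRecord:
    """Per-gene products from several sources plus the reconciled call."""

    locus_tag: str
    source_annotations: dict[str, str]
    evidence: list[EvidenceItem] = field(default_factory=list)
    final_product: str = ""
    discrepancy_flag: bool = False
    rule_fired: str = ""


def normalize_product(product: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    p = re.sub(r"[^\w\s]", " ", product.lower())
    return re.sub(r"\s+", " ", p).strip()


def _tokens(product: str) -> frozenset[str]:
    return frozenset(normalize_product(product).split())


def classify_product(product: str, others: tuple[str, ...] = ()) -> str:
    """Classify a product string as uninformative, general, or specific.

    Uninformative is absolute (a configurable lexicon plus DUF-only
    names). General vs specific is relative: a product is *general* if
    its token set is a strict subset of some other product's tokens
    ("Transporter" is general next to "Iron Transporter"); otherwise it
    is specific.
    """
    if not product:
        raise ReconcileError("empty product string")
    norm = normalize_product(product)
    if norm in (normalize_product(u) for u in UNINFORMATIVE_LEXICON):
        return "uninformative"
    if _DUF_ONLY.match(norm):
        return "uninformative"
    mine = _tokens(product)
    for other in others:
        theirs = _tokens(other)
        if mine < theirs:
            return "general"
    return "specific"


def _admissible(evidence: list[EvidenceItem], kinds: tuple[str, ...]) -> list[EvidenceItem]:
    return [e for e in evidence if e.kind in kinds and e.admissible]


def reconcile(record: AnnotationRecord) -> AnnotationRecord:
    """Reconcile one record through the rule cascade (pure, idempotent).

    Returns a new record with ``final_product``, ``rule_fired`` and
    ``discrepancy_flag`` set; the flag is True iff the final product
    differs from the NCBI call (after normalization).
    """
    sources = record.source_annotations
    if not sources:
        raise ReconcileError(f"{record.locus_tag}: no source annotations")
    ref_product = sources.get(REFERENCE_SOURCE) or next(iter(sources.values()))

    def finish(product: str, rule: str) -> AnnotationRecord:
        return replace(
            record,
            final_product=product,
            rule_fired=rule,
            discrepancy_flag=normalize_product(product) != normalize_product(ref_product),
        )

    norms = {src: normalize_product(p) for src, p in sources.items()}
    if len(set(norms.values())) == 1:
        return finish(ref_product, "consensus")

    informative = {
        src: p for src, p in sources.items() if classify_product(p) != "uninformative"
    }
    if not informative:
        return finish(ref_product, "all_uninformative")

    distinct = {}  # normalized -> original (first seen wins for casing)
    for p in informative.values():
        distinct.setdefault(normalize_product(p), p)

    if len(informative) < len(sources) and len(distinct) == 1:
        # rule 2: uninformative vs one well-defined call
        winner = next(iter(distinct.values()))
        if _admissible(record.evidence, ("domain_hit", "reviewed_best_hit")):
            return finish(winner, "uninformative_vs_defined")
        warnings.warn(
            f"{record.locus_tag}: well-defined product lacks admissible evidence; "
            f"keeping {ref_product!r}"
        )
        return finish(ref_product, "unresolved")

    if len(distinct) > 1:
        # rule 3: a strictly most-specific product wins with evidence
        token_sets = {norm: frozenset(norm.split()) for norm in distinct}
        maximal = [
            norm
            for norm, toks in token_sets.items()
            if all(other == norm or ot < toks for other, ot in token_sets.items())
        ]
        if len(maximal) == 1:
            if _admissible(
                record.evidence, ("domain_hit", "reviewed_best_hit", "regulon_context")
            ):
                return finish(distinct[maximal[0]], "general_vs_specific")
            warnings.warn(
                f"{record.locus_tag}: specific product lacks admissible evidence; "
                f"keeping {ref_product!r}"
            )
            return finish(ref_product, "unresolved")

        # rule 4: a single well-defined challenger to the NCBI call
        ref_norm = normalize_product(ref_product)
        challengers = {n: p for n, p in distinct.items() if n != ref_norm}
        if len(challengers) == 1 and _admissible(
            record.evidence, ("domain_hit", "reviewed_best_hit")
        ):
            return finish(next(iter(challengers.values())), "evidence_override")

    warnings.warn(f"{record.locus_tag}: unresolved discrepancy; keeping {ref_product!r}")
    return finish(ref_product, "unresolved")


# ---------------------------------------------------------------------------
# TSV interfaces

def read_annotations_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    """Read (locus_tag, source, product) rows into locus -> source -> product."""
    table: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table.setdefault(row["locus_tag"], {})[row["source"]] = row["product"]
    if not table:
        raise ReconcileError(f"{path}: no annotation rows")
    return table


def read_evidence_tsv(path: str | Path) -> dict[str, list[EvidenceItem]]:
    """Read (locus_tag, kind, label, evalue, identity_pct, coverage_pct) rows."""

    def _num(value: str | None) -> float | None:
        return float(value) if value not in (None, "", "NA") else None

    table: dict[str, list[EvidenceItem]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table.setdefault(row["locus_tag"], []).append(
                EvidenceItem(
                    kind=row["kind"],
                    label=row.get("label", ""),
                    evalue=_num(row.get("evalue")),
                    identity_pct=_num(row.get("identity_pct")),
                    coverage_pct=_num(row.get("coverage_pct")),
                )
            )
    return table


def reconcile_tables(
    annotations: dict[str, dict[str, str]],
    evidence: dict[str, list[EvidenceItem]] | None = None,
) -> list[AnnotationRecord]:
    """Reconcile every locus of an annotations table."""
    evidence = evidence or {}
    return [
        reconcile(
            AnnotationRecord(
                locus_tag=tag,
                source_annotations=sources,
                evidence=evidence.get(tag, []),
            )
        )
        for tag, sources in sorted(annotations.items())
    ]


def write_curated_tsv(path: str | Path, records: list[AnnotationRecord]) -> None:
    """Write the curated table; the flag column carries '*' on discrepancy."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["locus_tag", "final_product", "flag", "rule_fired", "supporting_evidence"]
        )
        for r in records:
            support = ";".join(
                f"{e.kind}:{e.label}" + (f"({e.evalue:.2e})" if e.evalue is not None else "")
                for e in r.evidence
                if e.admissible
            )
            writer.writerow(
                [
                    r.locus_tag,
                    r.final_product,
                    "*" if r.discrepancy_flag else "",
                    r.rule_fired,
                    support,
                ]
            )
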