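"""Degenerate nucleotide consensus motifs and mismatch arithmetic.

A :class:`ConsensusMotif` is an IUPAC degenerate pattern (e.g. the 15-bp
Fur operator ``TGATAATNATTATCA`` from *Bacillus subtilis*) together with a
mismatch budget. Matching is set membership: a genome base matches a
pattern position iff it belongs to that position's IUPAC degeneracy set.
An ambiguous base (``N``) in the *genome* matches only a pattern ``N``;
this is deliberately conservative so that runs of ambiguity in an assembly
never produce spurious hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

#: IUPAC nucleotide degeneracy sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class MotifError(ValueError):
    """Invalid motif pattern or incompatible core sequence."""


@dataclass(frozen=True)
class ConsensusMotif:
    """An IUPAC degenerate consensus pattern with a mismatch budget.

    Parameters
    ----------
    pattern
        Non-empty string over the 15 IUPAC nucleotide codes.
    max_mismatches
        Number of mismatching positions tolerated for a retained hit.
    name
        Human-readable label used in reports and BED output.
    """

    pattern: str
    max_mismatches: int = 0
    name: str = "motif"

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if len(pat) < 1:
            raise MotifError("motif pattern must be non-empty")
        bad = set(pat) - set(IUPAC_SETS)
        if bad:
            raise MotifError(f"invalid IUPAC code(s) in pattern: {sorted(bad)}")
        if self.max_mismatches < 0:
            raise MotifError("max_mismatches must be non-negative")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)


#: The B. subtilis Fur high-affinity operator ("Fur box") with the
#: two-mismatch budget used for regulon scans.
FUR_BOX = ConsensusMotif("TGATAATNATTATCA", max_mismatches=2, name="fur_box")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Degenerate codes complement set-wise (R<->Y, S<->S, N<->N, ...), so
    ``reverse_complement`` is an involution on IUPAC strings.
    """
    s = seq.upper()
    bad = set(s) - set(IUPAC_SETS)
    if bad:
        raise MotifError(f"invalid IUPAC code(s) in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def is_palindromic(motif: ConsensusMotif) -> bool:
    """True iff the pattern equals its own reverse complement.

    Fur boxes are palindromic (the repressor binds as a dimer), which is
    why a single physical site can be reported in either orientation.
    """
    return reverse_complement(motif.pattern) == motif.pattern


def mismatch_count(core: str, motif: ConsensusMotif) -> int:
    """Number of positions of ``core`` outside the pattern's degeneracy sets.

    ``core`` must be an A/C/G/T string (case-insensitive) of the motif's
    length; an ``N`` base in the core is tolerated on input and counts as
    a mismatch at every non-``N`` pattern position.

    Raises
    ------
    MotifError
        If the lengths differ or ``core`` contains a non-nucleotide
        character.
    """
    c = core.upper()
    if len(c) != len(motif.pattern):
        raise MotifError(
            f"core length {len(c)} incompatible with pattern length {len(motif.pattern)}"
        )
    bad = set(c) - set("ACGTN")
    if bad:
        raise MotifError(f"non-nucleotide character(s) in core: {sorted(bad)}")
    mm = 0
    for base, pat in zip(c, motif.pattern):
        if base == "N":
            if pat != "N":
                mm += 1
        elif base not in IUPAC_SETS[pat]:
            mm += 1
    return mm


def load_motifs(path: str | Path) -> dict[str, ConsensusMotif]:
    """Load motif definitions from a YAML config.

    The file maps names to ``{pattern: ..., max_mismatches: ...}``
    entries::

        fur_box:
          pattern: TGATAATNATTATCA
          max_mismatches: 2

    Returns a dict of name -> :class:`ConsensusMotif`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise MotifError(f"motif config {path} is empty or not a mapping")
    motifs: dict[str, ConsensusMotif] = {}
    for name, entry in raw.items():
        if isinstance(entry, str):
            motifs[name] = ConsensusMotif(entry, 0, str(name))
        else:
            motifs[name] = ConsensusMotif(
                entry["pattern"], int(entry.get("max_mismatches", 0)), str(name)
            )
    return motifs


#: Motifs available by name on the command line without a config file.
BUILTIN_MOTIFS: dict[str, ConsensusMotif] = {FUR_BOX.name: FUR_BOX}
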