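"""Restriction enzyme definitions and IUPAC nucleotide utilities.

A type II restriction enzyme is modelled by its recognition sequence
(possibly degenerate, written in IUPAC codes) and the cut offset: the
number of top-strand bases 5' of the cut *within* the recognition
sequence.  For SbfI (CCTGCA^GG, cut offset 6) digestion leaves a 4-nt
TGCA overhang, so RAD reads from the right flank begin with the remnant
TGCAGG and reads from the left flank (read on the bottom strand) begin
with the same remnant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path

IUPAC: dict[str, frozenset[str]] = {
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


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_expansions(motif: str) -> list[str]:
    """All concrete ACGT words matching a degenerate IUPAC motif."""
    motif = motif.upper()
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
    return ["".join(w) for w in product(*(sorted(IUPAC[ch]) for ch in motif))]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: name, IUPAC recognition sequence, cut offset.

    ``cut_offset`` counts top-strand bases 5' of the cut inside the
    recognition sequence and must lie in [0, k].
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if len(rec) < 4:
            raise ValueError(f"{self.name}: recognition sequence must have length >= 4")
        bad = [ch for ch in rec if ch not in IUPAC]
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC code(s) {bad} in {rec!r}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"{self.name}: cut_offset {self.cut_offset} outside [0, {len(rec)}]")

    @property
    def k(self) -> int:
        """Recognition-sequence length."""
        return len(self.recognition)

    @property
    def palindromic(self) -> bool:
        """True iff the recognition sequence equals its own reverse complement."""
        return self.recognition == revcomp(self.recognition)

    def expansions(self) -> list[str]:
        return iupac_expansions(self.recognition)

    @property
    def remnant(self) -> str:
        """Recognition remnant retained at the 5' end of every RAD read.

        For a palindromic enzyme both flanks start with the last
        ``k - cut_offset``-complement... concretely: the right-flank read
        starts at position ``k - cut_offset`` of the recognition sequence,
        so the remnant is ``recognition[k - cut_offset:]``.
        """
        return self.recognition[self.k - self.cut_offset :]


SBFI = Enzyme("SbfI", "CCTGCAGG", 6)


def load_catalogue(path: str | Path | None = None) -> dict[str, Enzyme]:
    """Load an enzyme catalogue from a TSV (name, recognition, cut_offset).

    With no path, the bundled 18-enzyme catalogue is returned.
    """
    if path is None:
        src = resources.files("radsites").joinpath("data/enzymes.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    enzymes: dict[str, Enzyme] = {}
    reader = csv.reader(text.splitlines(), delimiter="\t")
    for row in reader:
        if not row or row[0].startswith("#"):
            continue
        name, recognition, cut_offset = row[0], row[1], int(row[2])
        enzymes[name] = Enzyme(name, recognition, cut_offset)
    return enzymes
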