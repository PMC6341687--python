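"""Exact in silico restriction digestion: enumerate recognition-site coordinates.

All occurrences of an enzyme's recognition sequence are reported,
including overlapping ones.  Palindromic sites are reported once with
strand '+'; for non-palindromic enzymes the reverse strand is scanned
too and hits reported with strand '-'.  Genome residues outside ACGT
never match, even where the IUPAC codes would be compatible: an
ambiguous residue is treated as absence of evidence for a cut site.
Coordinates are 0-based; BED output is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .enzymes import IUPAC, Enzyme, revcomp
from .io import read_fasta

SiteRecord = tuple[int, str]  # (start, strand)


def _motif_regex(motif: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all found
    classes = "".join(
        ch if len(IUPAC[ch]) == 1 else "[" + "".join(sorted(IUPAC[ch])) + "]" for ch in motif
    )
    return re.compile(f"(?=(?:{classes}))")


def find_sites(sequence: str, enzyme: Enzyme) -> list[SiteRecord]:
    """All recognition-site occurrences in one sequence, sorted by position.

    Returns (start, strand) pairs; start is the 0-based position of the
    first recognition base on the forward strand.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    hits = [(m.start(), "+") for m in _motif_regex(enzyme.recognition).finditer(seq)]
    if not enzyme.palindromic:
        rc = revcomp(enzyme.recognition)
        hits += [(m.start(), "-") for m in _motif_regex(rc).finditer(seq)]
        hits.sort()
    return hits


@dataclass
class RestrictionSiteMap:
    """Per-contig sorted cut-site coordinates for one enzyme."""

    enzyme: Enzyme
    sites: dict[str, list[SiteRecord]] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(len(v) for v in self.sites.values())

    def starts(self, contig: str) -> list[int]:
        return [s for s, _ in self.sites.get(contig, [])]

    def to_bed(self, path: str | Path) -> None:
        k = self.enzyme.k
        with open(path, "w") as handle:
            for contig, records in self.sites.items():
                for start, strand in records:
                    handle.write(
                        f"{contig}\t{start}\t{start + k}\t{self.enzyme.name}\t0\t{strand}\n"
                    )

    @classmethod
    def from_bed(cls, path: str | Path, enzyme: Enzyme) -> "RestrictionSiteMap":
        sites: dict[str, list[SiteRecord]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start = fields[0], int(fields[1])
            strand = fields[5] if len(fields) > 5 else "+"
            sites.setdefault(contig, []).append((start, strand))
        for records in sites.values():
            records.sort()
        return cls(enzyme=enzyme, sites=sites)


def digest_resource(
    resource: str | Path | dict[str, str] | Iterable[tuple[str, str]], enzyme: Enzyme
) -> RestrictionSiteMap:
    """Digest every contig of a FASTA path or {contig: sequence} dict."""
    if isinstance(resource, (str, Path)):
        contigs: dict[str, str] = read_fasta(resource)
    elif isinstance(resource, dict):
        contigs = resource
    else:
        contigs = dict(resource)
    if not contigs:
        raise ValueError("empty sequence resource")
    sites = {name: find_sites(seq, enzyme) for name, seq in contigs.items() if seq}
    if not sites:
        raise ValueError("resource contains no sequences")
    return RestrictionSiteMap(enzyme=enzyme, sites=sites)
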