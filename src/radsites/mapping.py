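"""Match mapped RAD-locus consensus sequences to cut-site coordinates.

RAD reads begin at the ligated overhang, so the consensus of a locus
abuts the cut position of its restriction site: for a site whose
recognition sequence of length ``k`` starts at ``s`` with cut offset
``c``, a right-flank locus is a forward-strand alignment starting near
``s + (k - c)`` and a left-flank locus is a reverse-strand alignment
ending near ``s + c``.  A small tolerance (default 2 bp) absorbs
soft-clipping slop.  Sites holding assigned loci are classified:

* scenario I   — exactly one left and one right locus;
* scenario II  — both sides occupied, three or more loci in total
  (allelic splits during assembly);
* scenario III — exactly one side occupied.

Mapped loci matching no site are paired into scenario IV when a forward
and a reverse locus imply coincident cut positions, else counted as
scenario V.  The empirical cut-site count is the number of sites in
scenarios I-III.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .digest import RestrictionSiteMap
from .enzymes import Enzyme, revcomp


@dataclass(frozen=True)
class LocusAlignment:
    """Primary alignment of one locus consensus; 0-based half-open."""

    locus_id: str
    mapped: bool
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    mapq: int = 0
    note: str = ""


def read_alignments(sam_path: str | Path, mapq_floor: int = 0) -> list[LocusAlignment]:
    """Read primary alignments from a SAM file.

    Secondary and supplementary records are excluded; unmapped records
    are kept with ``mapped=False``; records below ``mapq_floor`` are
    treated as unmapped.
    """
    alignments: list[LocusAlignment] = []
    record_no = 0
    try:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for rec in sam:
                record_no += 1
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.is_unmapped or rec.mapping_quality < mapq_floor:
                    alignments.append(LocusAlignment(rec.query_name, mapped=False))
                    continue
                alignments.append(
                    LocusAlignment(
                        locus_id=rec.query_name,
                        mapped=True,
                        contig=rec.reference_name,
                        start=rec.reference_start,
                        end=rec.reference_end,
                        strand="-" if rec.is_reverse else "+",
                        mapq=rec.mapping_quality,
                    )
                )
    except (ValueError, OSError) as exc:
        raise ValueError(
            f"malformed SAM input {sam_path} near record line {record_no + 1}: {exc}"
        ) from exc
    return alignments


def _find_all(haystack: str, needle: str, limit: int = 2) -> list[int]:
    hits: list[int] = []
    start = 0
    while len(hits) < limit:
        i = haystack.find(needle, start)
        if i < 0:
            break
        hits.append(i)
        start = i + 1
    return hits


def exact_map_loci(
    loci: Iterable[tuple[str, str]], genome: dict[str, str]
) -> list[LocusAlignment]:
    """Built-in exact mapper: a locus maps iff its consensus (or reverse
    complement) occurs exactly once in the genome.

    Multiple occurrences leave the locus unmapped with an ambiguity note.
    Intended for synthetic pipelines; real data goes through an external
    aligner and :func:`read_alignments`.
    """
    alignments: list[LocusAlignment] = []
    for locus_id, seq in loci:
        seq = seq.upper()
        rc = revcomp(seq)
        occurrences: list[tuple[str, int, str]] = []
        for contig, contig_seq in genome.items():
            occurrences += [(contig, i, "+") for i in _find_all(contig_seq, seq)]
            if rc != seq:
                occurrences += [(contig, i, "-") for i in _find_all(contig_seq, rc)]
            if len(occurrences) > 1:
                break
        if len(occurrences) == 1:
            contig, pos, strand = occurrences[0]
            alignments.append(
                LocusAlignment(locus_id, True, contig, pos, pos + len(seq), strand, mapq=60)
            )
        else:
            note = "ambiguous" if occurrences else "absent"
            alignments.append(LocusAlignment(locus_id, False, note=note))
    return alignments


@dataclass
class SiteAssignment:
    contig: str
    position: int
    left: list[str] = field(default_factory=list)
    right: list[str] = field(default_factory=list)

    @property
    def scenario(self) -> str:
        n_left, n_right = len(self.left), len(self.right)
        if n_left == 1 and n_right == 1:
            return "I"
        if n_left >= 1 and n_right >= 1 and n_left + n_right >= 3:
            return "II"
        return "III"


@dataclass
class ScenarioReport:
    """Scenario I-V classification of mapped loci against a site map."""

    sites: list[SiteAssignment]
    scenario_iv_groups: list[tuple[str, str]]  # (forward locus, reverse locus)
    scenario_v_loci: list[str]
    n_loci: int
    n_mapped: int

    @property
    def counts(self) -> dict[str, int]:
        c = {"I": 0, "II": 0, "III": 0}
        for site in self.sites:
            c[site.scenario] += 1
        c["IV"] = len(self.scenario_iv_groups)
        c["V"] = len(self.scenario_v_loci)
        return c

    @property
    def empirical_site_count(self) -> int:
        return sum(1 for s in self.sites if s.scenario in ("I", "II", "III"))

    @property
    def mapping_fraction(self) -> float:
        return self.n_mapped / self.n_loci if self.n_loci else 0.0

    def summary_frame(self) -> pd.DataFrame:
        counts = self.counts
        left = sum(len(s.left) for s in self.sites)
        right = sum(len(s.right) for s in self.sites)
        both = sum(1 for s in self.sites if s.left and s.right)
        one = sum(1 for s in self.sites if bool(s.left) != bool(s.right))
        return pd.DataFrame(
            [
                {
                    "n_loci": self.n_loci,
                    "n_mapped": self.n_mapped,
                    "mapped_pct": 100.0 * self.mapping_fraction,
                    "left_side_loci": left,
                    "right_side_loci": right,
                    "both_side_sites": both,
                    "one_side_sites": one,
                    "scenario_I": counts["I"],
                    "scenario_II": counts["II"],
                    "scenario_III": counts["III"],
                    "scenario_IV": counts["IV"],
                    "scenario_V": counts["V"],
                    "empirical_site_count": self.empirical_site_count,
                }
            ]
        )


def classify_sites(
    alignments: Sequence[LocusAlignment],
    site_map: RestrictionSiteMap,
    enzyme: Enzyme | None = None,
    tolerance: int = 2,
) -> ScenarioReport:
    """Assign mapped loci to cut sites and classify scenarios I-V.

    Each mapped locus is assigned to at most one site (the nearest whose
    expected cut-adjacent coordinate lies within ``tolerance``; ties go
    to the leftmost site).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    enzyme = enzyme or site_map.enzyme
    k, c = enzyme.k, enzyme.cut_offset

    # per-contig sorted anchors for each side
    anchors: dict[str, dict[str, tuple[list[int], list[int]]]] = {}
    assignments: dict[tuple[str, int], SiteAssignment] = {}
    for contig, records in site_map.sites.items():
        right_list: list[tuple[int, int]] = []
        left_list: list[tuple[int, int]] = []
        for s, strand in records:
            right_anchor = s + (k - c) if strand == "+" else s + c
            left_anchor = s + c if strand == "+" else s + (k - c)
            right_list.append((right_anchor, s))
            left_list.append((left_anchor, s))
        right_list.sort()
        left_list.sort()
        anchors[contig] = {
            "right": ([a for a, _ in right_list], [s for _, s in right_list]),
            "left": ([a for a, _ in left_list], [s for _, s in left_list]),
        }

    def nearest_site(contig: str, side: str, coord: int) -> int | None:
        if contig not in anchors:
            return None
        pos_list, site_list = anchors[contig][side]
        i = bisect_left(pos_list, coord)
        best: tuple[int, int, int] | None = None  # (distance, site, anchor)
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(pos_list):
                dist = abs(pos_list[j] - coord)
                if dist <= tolerance:
                    cand = (dist, site_list[j], pos_list[j])
                    if best is None or cand < best:
                        best = cand
        return None if best is None else best[1]

    unassigned: list[LocusAlignment] = []
    n_mapped = 0
    for aln in alignments:
        if not aln.mapped:
            continue
        n_mapped += 1
        if aln.strand == "+":
            site = nearest_site(aln.contig, "right", aln.start)
            side = "right"
        else:
            site = nearest_site(aln.contig, "left", aln.end)
            side = "left"
        if site is None:
            unassigned.append(aln)
            continue
        key = (aln.contig, site)
        entry = assignments.setdefault(key, SiteAssignment(aln.contig, site))
        getattr(entry, side).append(aln.locus_id)

    # pair leftover loci on inferred cut positions: forward start-(k-c) vs reverse end-c
    iv_groups: list[tuple[str, str]] = []
    v_loci: list[str] = []
    by_contig: dict[str, list[tuple[int, str, str]]] = {}
    for aln in unassigned:
        cut = aln.start - (k - c) if aln.strand == "+" else aln.end - c
        by_contig.setdefault(aln.contig, []).append((cut, aln.strand, aln.locus_id))
    for contig, items in by_contig.items():
        items.sort()
        open_fwd: list[tuple[int, str]] = []
        for cut, strand, locus_id in items:
            if strand == "+":
                open_fwd.append((cut, locus_id))
            else:
                match = next(
                    (i for i, (fcut, _fid) in enumerate(open_fwd) if abs(fcut - cut) <= tolerance),
                    None,
                )
                if match is not None:
                    iv_groups.append((open_fwd.pop(match)[1], locus_id))
                else:
                    v_loci.append(locus_id)
        v_loci.extend(fid for _cut, fid in open_fwd)

    sites_sorted = sorted(assignments.values(), key=lambda s: (s.contig, s.position))
    return ScenarioReport(
        sites=sites_sorted,
        scenario_iv_groups=iv_groups,
        scenario_v_loci=sorted(v_loci),
        n_loci=len(alignments),
        n_mapped=n_mapped,
    )


def locus_mapping_table(
    catalogue, alignments: Sequence[LocusAlignment]
) -> pd.DataFrame:
    """Per-locus table (locus id, individuals sharing it, mapped flag);
    the input to an external mapping-probability regression."""
    aln_by_id = {a.locus_id: a for a in alignments}
    rows = []
    for locus_id, _consensus in catalogue.consensus_fasta():
        if locus_id not in aln_by_id:
            raise ValueError(f"no alignment record for catalogue locus {locus_id}")
    by_locus = {f"locus_{loc.locus_id}": loc for loc in catalogue.loci}
    for locus_id, aln in aln_by_id.items():
        if locus_id not in by_locus:
            raise ValueError(f"alignment {locus_id} does not match any catalogue locus")
        rows.append(
            {
                "locus_id": locus_id,
                "n_individuals": by_locus[locus_id].n_individuals,
                "mapped": aln.mapped,
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "n_individuals", "mapped"])
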