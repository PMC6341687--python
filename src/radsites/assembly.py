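"""Simplified de novo assembly of single-end RAD reads into loci and a catalogue.

The algorithm mirrors the classic RADseq workflow: reads from one
individual are first dereplicated into *stacks* (piles of identical
reads); piles reaching depth ``m`` become primary stacks and the
remaining reads are attached to the nearest primary consensus within
``M`` mismatches or dropped.  Primary stacks are then greedily merged
into per-individual loci (Hamming distance <= ``M`` to the running
majority consensus), and per-individual consensus sequences are matched
across individuals into a catalogue within ``n`` mismatches.

This is a deliberately simplified, fully deterministic reimplementation
of the Stacks-style procedure: no deleveraging, no lumberjack-stack
removal, no gapped matching, exact tie-break rules throughout (depth
descending, then lexicographically smallest consensus; catalogue ties go
to the earliest-created entry; per-column majority ties resolve
A < C < G < T).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _enc(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _dec(arr: np.ndarray) -> str:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[arr].tobytes().decode("ascii")


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


@dataclass(frozen=True)
class AssemblyParams:
    """m: minimum stack depth; M: within-individual mismatch limit;
    n: across-individual mismatch limit."""

    m: int = 3
    M: int = 2
    n: int = 1

    def __post_init__(self) -> None:
        if self.m < 1 or self.M < 0 or self.n < 0:
            raise ValueError("require m >= 1, M >= 0, n >= 0")


#: The grid explored around the defaults: each of m/M/n moved one unit
#: up and down while holding the other two at their default.
PARAMETER_GRID: tuple[AssemblyParams, ...] = (
    AssemblyParams(2, 2, 1),
    AssemblyParams(3, 1, 1),
    AssemblyParams(3, 2, 0),
    AssemblyParams(3, 2, 1),
    AssemblyParams(3, 2, 2),
    AssemblyParams(3, 3, 1),
    AssemblyParams(4, 2, 1),
)


@dataclass
class Stack:
    """A pile of identical reads from one individual."""

    individual: str
    consensus: str
    depth: int
    members: list[str] = field(default_factory=list)


@dataclass
class StackResult:
    primary: list[Stack]
    # secondary reads that matched a primary stack: (sequence, count, stack index)
    assigned: list[tuple[str, int, int]]
    n_dropped: int
    n_short_discarded: int


def build_stacks(
    reads: Sequence[tuple[str, str]],
    params: AssemblyParams,
    individual: str = "",
    read_length: int | None = None,
) -> StackResult:
    """Dereplicate one individual's reads into primary stacks.

    Reads are trimmed to a common length (the modal input length unless
    ``read_length`` is given); shorter reads are discarded and counted.
    Piles with depth >= m are primary; every remaining read is assigned
    to the closest primary consensus within M mismatches (ties broken by
    higher depth, then lexicographically smaller consensus) or dropped.
    """
    if not reads:
        return StackResult([], [], 0, 0)
    if read_length is None:
        read_length = Counter(len(seq) for _rid, seq in reads).most_common(1)[0][0]
    kept: list[tuple[str, str]] = []
    n_short = 0
    for rid, seq in reads:
        if len(seq) < read_length:
            n_short += 1
        else:
            kept.append((rid, seq[:read_length].upper()))
    if n_short:
        logger.info("%s: discarded %d reads shorter than %d bp", individual, n_short, read_length)

    piles: dict[str, list[str]] = {}
    for rid, seq in kept:
        piles.setdefault(seq, []).append(rid)

    primary_items = sorted(
        ((seq, ids) for seq, ids in piles.items() if len(ids) >= params.m),
        key=lambda item: (-len(item[1]), item[0]),
    )
    primary = [
        Stack(individual=individual, consensus=seq, depth=len(ids), members=list(ids))
        for seq, ids in primary_items
    ]
    if not primary:
        logger.warning("%s: no pile reached depth m=%d", individual, params.m)
        return StackResult([], [], len(kept), n_short)

    cons_matrix = np.stack([_enc(s.consensus) for s in primary])
    depths = np.array([s.depth for s in primary])
    assigned: list[tuple[str, int, int]] = []
    n_dropped = 0
    for seq, ids in piles.items():
        if len(ids) >= params.m:
            continue
        dists = np.count_nonzero(cons_matrix != _enc(seq), axis=1)
        best = int(dists.min())
        if best > params.M:
            n_dropped += len(ids)
            continue
        tied = np.flatnonzero(dists == best)
        # highest depth, then lexicographically smallest consensus
        winner = min(tied, key=lambda i: (-depths[i], primary[i].consensus))
        assigned.append((seq, len(ids), int(winner)))
    return StackResult(primary, assigned, n_dropped, n_short)


@dataclass
class IndividualLocus:
    individual: str
    consensus: str
    counts: np.ndarray  # (4, read length) per-column base counts
    depth: int


def merge_stacks_to_loci(stacks: StackResult, params: AssemblyParams) -> list[IndividualLocus]:
    """Greedy depth-ordered merge of one individual's primary stacks.

    A stack joins the first existing locus whose current majority
    consensus is within Hamming distance M, else founds a new locus.
    Secondary reads assigned by :func:`build_stacks` travel with their
    stack into the locus base counts and depth.
    """
    if not stacks.primary:
        return []
    length = len(stacks.primary[0].consensus)
    extra: dict[int, list[tuple[str, int]]] = {}
    for seq, count, idx in stacks.assigned:
        extra.setdefault(idx, []).append((seq, count))

    order = sorted(
        range(len(stacks.primary)),
        key=lambda i: (-stacks.primary[i].depth, stacks.primary[i].consensus),
    )
    loci: list[dict] = []
    for idx in order:
        stack = stacks.primary[idx]
        arr = _enc(stack.consensus)
        target = None
        for locus in loci:
            if hamming(locus["consensus_arr"], arr) <= params.M:
                target = locus
                break
        if target is None:
            target = {
                "individual": stack.individual,
                "counts": np.zeros((4, length), dtype=np.int64),
                "depth": 0,
                "consensus_arr": arr.copy(),
            }
            loci.append(target)
        cols = np.arange(length)
        target["counts"][arr, cols] += stack.depth
        target["depth"] += stack.depth
        for seq, count in extra.get(idx, []):
            sarr = _enc(seq)
            target["counts"][sarr, cols] += count
            target["depth"] += count
        # per-column majority; argmax ties resolve to the smallest base index (A<C<G<T)
        target["consensus_arr"] = target["counts"].argmax(axis=0).astype(np.uint8)

    return [
        IndividualLocus(
            individual=locus["individual"],
            consensus=_dec(locus["consensus_arr"]),
            counts=locus["counts"],
            depth=int(locus["depth"]),
        )
        for locus in loci
    ]


def assemble_individual(
    reads: Sequence[tuple[str, str]],
    params: AssemblyParams,
    individual: str = "",
    read_length: int | None = None,
) -> list[IndividualLocus]:
    """Convenience wrapper: dereplicate then merge one individual's reads."""
    return merge_stacks_to_loci(
        build_stacks(reads, params, individual=individual, read_length=read_length), params
    )


@dataclass
class CatalogueLocus:
    locus_id: int
    consensus: str
    # per individual: summed per-column base counts and total depth
    members: dict[str, tuple[np.ndarray, int]]

    @property
    def n_individuals(self) -> int:
        return len(self.members)

    @property
    def depth(self) -> int:
        return sum(d for _c, d in self.members.values())


@dataclass
class RadCatalogue:
    loci: list[CatalogueLocus]
    params: AssemblyParams

    def __len__(self) -> int:
        return len(self.loci)

    def consensus_fasta(self) -> list[tuple[str, str]]:
        return [(f"locus_{loc.locus_id}", loc.consensus) for loc in self.loci]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": [f"locus_{loc.locus_id}" for loc in self.loci],
                "consensus": [loc.consensus for loc in self.loci],
                "n_individuals": [loc.n_individuals for loc in self.loci],
                "depth": [loc.depth for loc in self.loci],
            }
        )


def build_catalogue(
    per_individual_loci: Iterable[tuple[str, Sequence[IndividualLocus]]],
    params: AssemblyParams,
) -> RadCatalogue:
    """Match per-individual locus consensus sequences across individuals.

    Individuals are processed in input order; each locus joins the
    catalogue entry with minimum Hamming distance <= n (ties to the
    earliest-created entry), else founds a new entry whose consensus is
    fixed by the founding locus.
    """
    entries: list[CatalogueLocus] = []
    matrix: np.ndarray | None = None  # stacked entry consensus codes
    for individual, loci in per_individual_loci:
        for locus in loci:
            arr = _enc(locus.consensus)
            target = None
            if entries:
                assert matrix is not None
                dists = np.count_nonzero(matrix != arr, axis=1)
                best = int(dists.min())
                if best <= params.n:
                    target = entries[int(np.flatnonzero(dists == best)[0])]
            if target is None:
                target = CatalogueLocus(locus_id=len(entries), consensus=locus.consensus, members={})
                entries.append(target)
                matrix = (
                    arr[None, :] if matrix is None else np.vstack([matrix, arr[None, :]])
                )
            if individual in target.members:
                counts, depth = target.members[individual]
                target.members[individual] = (counts + locus.counts, depth + locus.depth)
            else:
                target.members[individual] = (locus.counts.copy(), locus.depth)
    return RadCatalogue(loci=entries, params=params)


def _column_calls(
    locus: CatalogueLocus, m: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column genotype summary over a catalogue locus.

    Returns (variant mask over columns, per-column heterozygote counts,
    per-column genotyped counts).  An individual is genotyped at a column
    when its depth is >= m; its called alleles are those with
    within-individual frequency >= 0.25; it is heterozygous when two or
    more alleles are called.  A column is variant when the union of
    called alleles across genotyped individuals has >= 2 members.
    """
    length = len(locus.consensus)
    het = np.zeros(length, dtype=np.int64)
    genotyped = np.zeros(length, dtype=np.int64)
    allele_seen = np.zeros((4, length), dtype=bool)
    for counts, _depth in locus.members.values():
        col_depth = counts.sum(axis=0)
        ok = col_depth >= m
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(col_depth > 0, counts / np.maximum(col_depth, 1), 0.0)
        called = (freqs >= 0.25) & ok[None, :]
        allele_seen |= called
        genotyped += ok.astype(np.int64)
        het += (called.sum(axis=0) >= 2).astype(np.int64)
    variant = allele_seen.sum(axis=0) >= 2
    return variant, het, genotyped


def assembly_stats(catalogue: RadCatalogue) -> dict[str, float]:
    """Catalogue summary: total loci, loci in >= 2 individuals, observed
    heterozygosity over variant columns, and mean depth per
    individual-locus.

    Observed heterozygosity is the mean over variant columns of the
    fraction of genotyped individuals called heterozygous; with no
    variant columns it is reported as 0 and flagged.
    """
    m = catalogue.params.m
    total = len(catalogue.loci)
    ge2 = sum(1 for loc in catalogue.loci if loc.n_individuals >= 2)
    fractions: list[float] = []
    depths: list[int] = []
    for locus in catalogue.loci:
        depths.extend(d for _c, d in locus.members.values())
        variant, het, genotyped = _column_calls(locus, m)
        for col in np.flatnonzero(variant):
            if genotyped[col] > 0:
                fractions.append(het[col] / genotyped[col])
    no_variants = not fractions
    if no_variants:
        logger.warning("catalogue has no variant columns; heterozygosity reported as 0")
    return {
        "total_loci": float(total),
        "loci_in_ge2_individuals": float(ge2),
        "observed_heterozygosity": float(np.mean(fractions)) if fractions else 0.0,
        "mean_depth": float(np.mean(depths)) if depths else 0.0,
        "no_variant_columns": float(no_variants),
    }
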