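"""Synthetic genomes, planted restriction sites and RAD reads with truth tables.

The generator emulates a single-digest RAD experiment: a background
genome of configurable composition (i.i.d. or Markov order 1-2),
recognition sites planted at known coordinates on a certified site-free
background, and per-individual single-end reads from both flanks of
every site.  Per site and individual, digestion succeeds with
probability ``digestion_prob``; a digested site yields Poisson
``coverage`` reads per flank.  Each read starts at the cut with the
retained recognition remnant at its 5' end (left-flank reads are
reverse-complemented), optionally carries one biallelic SNP per site
(genotypes drawn from Hardy-Weinberg at the given minor-allele
frequency, heterozygotes emitting alleles 50:50) and per-base
substitution errors.  Every read and every true locus position is
recorded in a truth table so each pipeline stage can be checked against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .digest import RestrictionSiteMap, find_sites
from .enzymes import SBFI, Enzyme, revcomp
from .io import write_fasta, write_fastq, write_sample_sheet

_BASES = "ACGT"


@dataclass
class GenomeSimSpec:
    """Background-genome specification.

    Provide either ``base_freqs`` (i.i.d. model, length-4, order of
    A,C,G,T) or ``transition`` (Markov model: shape (4,4) for order 1 —
    rows indexed by the previous base — or (16,4) for order 2, rows
    indexed by ``4*prev2 + prev1``).
    """

    length: int
    contig_count: int = 1
    base_freqs: Sequence[float] | None = None
    transition: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 80:
            raise ValueError("genome length must be at least 80 bp")
        if self.contig_count < 1:
            raise ValueError("contig_count must be >= 1")
        if self.base_freqs is not None and self.transition is not None:
            raise ValueError("give base_freqs or transition, not both")
        if self.base_freqs is not None:
            freqs = np.asarray(self.base_freqs, dtype=float)
            if freqs.shape != (4,) or np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0):
                raise ValueError("base_freqs must be 4 non-negative values summing to 1")
            self.base_freqs = freqs
        if self.transition is not None:
            trans = np.asarray(self.transition, dtype=float)
            if trans.shape not in ((4, 4), (16, 4)):
                raise ValueError("transition must have shape (4,4) or (16,4)")
            if np.any(trans < 0) or not np.allclose(trans.sum(axis=1), 1.0):
                raise ValueError("transition rows must be probability vectors")
            self.transition = trans


def _markov_sequence(n: int, trans: np.ndarray, rng: np.random.Generator) -> str:
    order = 1 if trans.shape[0] == 4 else 2
    cum_rows = np.cumsum(trans, axis=1).tolist()
    u = rng.random(n)
    out = bytearray(n)
    bases = b"ACGT"
    # warm up the chain from a uniform start
    prev2 = int(rng.integers(4))
    prev1 = int(rng.integers(4))
    for i in range(n):
        ctx = prev1 if order == 1 else prev2 * 4 + prev1
        row = cum_rows[ctx]
        x = u[i]
        if x < row[0]:
            b = 0
        elif x < row[1]:
            b = 1
        elif x < row[2]:
            b = 2
        else:
            b = 3
        out[i] = bases[b]
        prev2, prev1 = prev1, b
    return out.decode("ascii")


def simulate_genome(spec: GenomeSimSpec) -> dict[str, str]:
    """Generate a seeded background genome as {contig: sequence}."""
    rng = np.random.default_rng(spec.seed)
    lengths = [spec.length // spec.contig_count] * spec.contig_count
    lengths[-1] += spec.length - sum(lengths)
    genome: dict[str, str] = {}
    for i, n in enumerate(lengths, start=1):
        name = f"contig_{i}"
        if spec.transition is not None:
            genome[name] = _markov_sequence(n, spec.transition, rng)
        else:
            freqs = (
                np.asarray(spec.base_freqs)
                if spec.base_freqs is not None
                else np.full(4, 0.25)
            )
            codes = rng.choice(4, size=n, p=freqs)
            genome[name] = "".join(_BASES[c] for c in codes) if n < 1024 else (
                np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
            )
    return genome


def _scrub_occurrences(
    contig: bytearray,
    enzyme: Enzyme,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_rounds: int = 20,
) -> None:
    """Destroy recognition-site occurrences outside protected intervals by
    point mutation, re-scanning until clean."""
    k = enzyme.k
    planted_starts = {q for q, _ in protected}
    for _ in range(max_rounds):
        hits = [
            s
            for s, _strand in find_sites(contig.decode("ascii"), enzyme)
            if s not in planted_starts
        ]
        if not hits:
            return
        for s in hits:
            # mutate a base inside the occurrence but outside every planted window,
            # preferring the middle so single flips kill palindromic motifs too
            candidates = sorted(range(s, s + k), key=lambda p: abs(p - (s + k // 2)))
            pos = next(
                (p for p in candidates if all(not (q <= p < e) for q, e in protected)),
                None,
            )
            if pos is None:
                continue  # fully inside a planted window; re-scan will arbitrate
            old = chr(contig[pos])
            choices = [b for b in _BASES if b != old]
            contig[pos] = ord(choices[int(rng.integers(3))])
    raise RuntimeError("could not certify a site-free background after bounded retries")


def plant_sites(
    genome: dict[str, str],
    enzyme: Enzyme,
    n_sites: int | None = None,
    positions: dict[str, list[int]] | None = None,
    min_spacing: int = 200,
    margin: int = 100,
    seed: int = 0,
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Plant recognition sites on a certified site-free background.

    Either ``n_sites`` (random positions, proportional to contig length)
    or explicit per-contig ``positions`` must be given.  Positions keep
    ``min_spacing`` between sites and ``margin`` bp from contig ends.
    The result is certified by re-scan: an in silico digest of the
    returned genome yields exactly the planted set.

    Returns the modified genome and a sorted list of (contig, start).
    """
    if (n_sites is None) == (positions is None):
        raise ValueError("give exactly one of n_sites or positions")
    rng = np.random.default_rng(seed)
    k = enzyme.k
    contigs = {name: bytearray(seq.encode("ascii")) for name, seq in genome.items()}

    chosen: dict[str, list[int]] = {}
    if positions is not None:
        for name, pos_list in positions.items():
            if name not in contigs:
                raise ValueError(f"unknown contig {name!r}")
            pos_sorted = sorted(pos_list)
            length = len(contigs[name])
            for i, p in enumerate(pos_sorted):
                if p < margin or p + k + margin > length:
                    raise ValueError(f"position {p} violates the {margin} bp end margin")
                if i and p - pos_sorted[i - 1] < min_spacing:
                    raise ValueError("positions violate min_spacing")
            chosen[name] = pos_sorted
    else:
        names = list(contigs)
        lengths = np.array([len(contigs[n]) for n in names], dtype=float)
        if n_sites > 0:
            alloc = np.floor(lengths / lengths.sum() * n_sites).astype(int)
            while alloc.sum() < n_sites:
                alloc[int(np.argmax(lengths - alloc * min_spacing))] += 1
        else:
            alloc = np.zeros(len(names), dtype=int)
        for name, count in zip(names, alloc):
            length = len(contigs[name])
            lo, hi = margin, length - margin - k
            if count and hi <= lo:
                raise ValueError(f"contig {name} too short to plant sites")
            accepted: list[int] = []
            attempts = 0
            while len(accepted) < count:
                attempts += 1
                if attempts > 200 * max(count, 1):
                    raise ValueError("cannot satisfy min_spacing; genome too crowded")
                p = int(rng.integers(lo, hi + 1))
                if all(abs(p - q) >= min_spacing for q in accepted):
                    accepted.append(p)
            chosen[name] = sorted(accepted)

    for name, contig in contigs.items():
        protected = [(p, p + k) for p in chosen.get(name, [])]
        _scrub_occurrences(contig, enzyme, protected, rng)
        for p in chosen.get(name, []):
            expansions = enzyme.expansions()
            word = expansions[int(rng.integers(len(expansions)))]
            contig[p : p + k] = word.encode("ascii")
        # planting can create new overlapping occurrences at the edges
        _scrub_occurrences(contig, enzyme, protected, rng)

    out_genome = {name: contig.decode("ascii") for name, contig in contigs.items()}
    planted = sorted((name, p) for name, pos in chosen.items() for p in pos)
    observed = sorted(
        (name, s)
        for name, records in digest_sites(out_genome, enzyme).items()
        for s, _ in records
    )
    if observed != planted:
        raise RuntimeError("site planting failed certification re-scan")
    return out_genome, planted


def digest_sites(genome: dict[str, str], enzyme: Enzyme) -> dict[str, list[tuple[int, str]]]:
    return {name: find_sites(seq, enzyme) for name, seq in genome.items()}


def sites_to_map(sites: list[tuple[str, int]], enzyme: Enzyme) -> RestrictionSiteMap:
    """Convert a planted (contig, start) list to a RestrictionSiteMap."""
    mapping: dict[str, list[tuple[int, str]]] = {}
    for contig, start in sites:
        mapping.setdefault(contig, []).append((start, "+"))
    for records in mapping.values():
        records.sort()
    return RestrictionSiteMap(enzyme=enzyme, sites=mapping)


@dataclass
class RadSimSpec:
    """RAD read-simulation parameters.

    ``coverage`` is the Poisson mean reads per flank per individual per
    digested site; ``digestion_prob`` the per-site per-individual
    probability that digestion succeeds; ``snp_prob`` the probability a
    site carries one biallelic SNP in one of its flanks, with alternate
    allele frequency ``maf`` (genotypes drawn under Hardy-Weinberg).
    """

    n_individuals: int = 10
    read_length: int = 100
    coverage: float = 20.0
    error_rate: float = 0.001
    digestion_prob: float = 0.9
    snp_prob: float = 0.2
    maf: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if not 0 <= self.error_rate <= 1 or not 0 <= self.digestion_prob <= 1:
            raise ValueError("error_rate and digestion_prob must lie in [0, 1]")
        if not 0 <= self.snp_prob <= 1 or not 0 <= self.maf <= 0.5:
            raise ValueError("snp_prob in [0,1] and maf in [0, 0.5] required")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated RAD experiment."""

    enzyme: Enzyme
    read_length: int
    sites: list[tuple[str, int]]
    read_origins: pd.DataFrame  # read_id, individual, contig, site_start, side, allele
    locus_alignments: list[tuple[str, str, int, int, str]]  # id, contig, start, end, strand
    site_events: pd.DataFrame  # individual, contig, site_start, digested, reads_left, reads_right
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)

    def recoverable_sites(self, m: int) -> int:
        """Sites with at least one digested individual holding >= m reads
        on at least one flank (the most a depth-m assembler could use)."""
        ev = self.site_events
        ok = ev["digested"] & ((ev["reads_left"] >= m) | (ev["reads_right"] >= m))
        covered = ev.loc[ok, ["contig", "site_start"]].drop_duplicates()
        return len(covered)


def _true_flanks(
    genome: dict[str, str], contig: str, s: int, enzyme: Enzyme, read_length: int
) -> tuple[str, str]:
    k, c, L = enzyme.k, enzyme.cut_offset, read_length
    seq = genome[contig]
    if s + c - L < 0 or s + (k - c) + L > len(seq):
        raise ValueError(f"read length {L} exceeds flank availability at {contig}:{s}")
    right = seq[s + (k - c) : s + (k - c) + L]
    left = revcomp(seq[s + c - L : s + c])
    return left, right


def simulate_radseq(
    genome: dict[str, str],
    sites: list[tuple[str, int]],
    spec: RadSimSpec,
    enzyme: Enzyme = SBFI,
) -> tuple[dict[str, list[tuple[str, str]]], SimTruth]:
    """Simulate per-individual single-end RAD reads from planted sites.

    Returns ({individual: [(read id, sequence), ...]}, SimTruth).
    """
    rng = np.random.default_rng(spec.seed)
    k, c, L = enzyme.k, enzyme.cut_offset, spec.read_length
    if L < k:
        raise ValueError("read length must be at least the recognition length")

    # per-site SNP layout: (side, read offset >= cut_offset, alt base)
    snp_rows = []
    snp_by_site: dict[tuple[str, int], tuple[str, int, str]] = {}
    flank_cache: dict[tuple[str, int], tuple[str, str]] = {}
    for contig, s in sites:
        flank_cache[(contig, s)] = _true_flanks(genome, contig, s, enzyme, L)
        if rng.random() < spec.snp_prob:
            side = "L" if rng.random() < 0.5 else "R"
            offset = int(rng.integers(c, L))
            ref = flank_cache[(contig, s)][0 if side == "L" else 1][offset]
            alt = [b for b in _BASES if b != ref][int(rng.integers(3))]
            snp_by_site[(contig, s)] = (side, offset, alt)
            snp_rows.append(
                {"contig": contig, "site_start": s, "side": side, "offset": offset,
                 "ref": ref, "alt": alt}
            )

    individuals = [f"ind_{i+1:02d}" for i in range(spec.n_individuals)]
    # genotypes: number of alternate-allele copies per individual per SNP site
    genotypes = {
        key: rng.binomial(2, spec.maf, size=spec.n_individuals) for key in snp_by_site
    }

    reads_by_indiv: dict[str, list[tuple[str, str]]] = {ind: [] for ind in individuals}
    origin_rows = []
    event_rows = []
    for contig, s in sites:
        left, right = flank_cache[(contig, s)]
        snp = snp_by_site.get((contig, s))
        for ind_idx, ind in enumerate(individuals):
            digested = bool(rng.random() < spec.digestion_prob)
            n_left = int(rng.poisson(spec.coverage)) if digested else 0
            n_right = int(rng.poisson(spec.coverage)) if digested else 0
            event_rows.append(
                {"individual": ind, "contig": contig, "site_start": s,
                 "digested": digested, "reads_left": n_left, "reads_right": n_right}
            )
            if not digested:
                continue
            n_alt = int(genotypes[(contig, s)][ind_idx]) if snp else 0
            for side, count, template in (("L", n_left, left), ("R", n_right, right)):
                for serial in range(count):
                    allele = "ref"
                    seq = template
                    if snp and snp[0] == side and n_alt > 0:
                        emit_alt = n_alt == 2 or (n_alt == 1 and rng.random() < 0.5)
                        if emit_alt:
                            allele = "alt"
                            seq = seq[: snp[1]] + snp[2] + seq[snp[1] + 1 :]
                    n_err = int(rng.binomial(L, spec.error_rate))
                    if n_err:
                        pos = rng.choice(L, size=n_err, replace=False)
                        b = bytearray(seq.encode("ascii"))
                        for p in pos:
                            old = chr(b[p])
                            alts = [x for x in _BASES if x != old]
                            b[p] = ord(alts[int(rng.integers(3))])
                        seq = b.decode("ascii")
                    rid = f"{ind}|{contig}|{s}|{side}|{allele}|{serial}"
                    reads_by_indiv[ind].append((rid, seq))
                    origin_rows.append(
                        {"read_id": rid, "individual": ind, "contig": contig,
                         "site_start": s, "side": side, "allele": allele}
                    )

    locus_alignments = []
    for contig, s in sites:
        locus_alignments.append((f"{contig}:{s}:R", contig, s + (k - c), s + (k - c) + L, "+"))
        locus_alignments.append((f"{contig}:{s}:L", contig, s + c - L, s + c, "-"))

    origin_cols = ["read_id", "individual", "contig", "site_start", "side", "allele"]
    event_cols = ["individual", "contig", "site_start", "digested", "reads_left", "reads_right"]
    snp_cols = ["contig", "site_start", "side", "offset", "ref", "alt"]
    truth = SimTruth(
        enzyme=enzyme,
        read_length=L,
        sites=list(sites),
        read_origins=pd.DataFrame(origin_rows, columns=origin_cols),
        locus_alignments=locus_alignments,
        site_events=pd.DataFrame(event_rows, columns=event_cols),
        snps=pd.DataFrame(snp_rows, columns=snp_cols),
    )
    return reads_by_indiv, truth


def emit_truth(
    truth: SimTruth,
    genome: dict[str, str],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write truth files (BED sites, SAM of true locus alignments, TSV of
    read origins) that round-trip through the pipeline's readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bed": out / "truth_sites.bed",
        "sam": out / "truth_loci.sam",
        "tsv": out / "truth_reads.tsv",
    }
    sites_to_map([(c, s) for c, s in truth.sites], truth.enzyme).to_bed(paths["bed"])

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    with pysam.AlignmentFile(str(paths["sam"]), "wh", header=header) as sam:
        refs = {name: i for i, name in enumerate(genome)}
        for locus_id, contig, start, end, strand in truth.locus_alignments:
            a = pysam.AlignedSegment()
            a.query_name = locus_id
            a.flag = 16 if strand == "-" else 0
            a.reference_id = refs[contig]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{end - start}M"
            a.query_sequence = genome[contig][start:end]
            sam.write(a)

    truth.read_origins.to_csv(paths["tsv"], sep="\t", index=False)
    return paths


def write_cohort(
    reads_by_indiv: dict[str, list[tuple[str, str]]],
    out_dir: str | Path,
    gzip_fastq: bool = True,
) -> Path:
    """Write one FASTQ per individual plus a sample sheet; returns the
    sample-sheet path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ind, reads in reads_by_indiv.items():
        fq = out / (f"{ind}.fastq.gz" if gzip_fastq else f"{ind}.fastq")
        write_fastq(reads, fq)
        rows.append((ind, fq.name))
    sheet = out / "samples.tsv"
    write_sample_sheet(rows, sheet)
    return sheet


def write_genome(genome: dict[str, str], path: str | Path) -> None:
    write_fasta(genome, path)
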