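"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations (per-position
window scans, closed-form normal equations) that share no code with the
package paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

import radsites as r

# --- independent oracles ---------------------------------------------------

_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_ORACLE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}


def oracle_revcomp(motif: str) -> str:
    return "".join(_ORACLE_COMP[ch] for ch in reversed(motif))


def naive_find_sites(sequence: str, recognition: str, palindromic: bool) -> list[tuple[int, str]]:
    """O(L*k) per-position window scan; non-ACGT residues never match."""
    seq = sequence.upper()
    hits: list[tuple[int, str]] = []

    def scan(motif: str, strand: str) -> None:
        sets = [_ORACLE_IUPAC[ch] for ch in motif]
        k = len(motif)
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] in sets[j] for j in range(k)):
                hits.append((i, strand))

    scan(recognition, "+")
    if not palindromic:
        scan(oracle_revcomp(recognition), "-")
    return sorted(hits)


def ols_log10(x, y) -> tuple[float, float]:
    """Closed-form normal-equations OLS of log10(y) on log10(x)."""
    lx, ly = np.log10(np.asarray(x, float)), np.log10(np.asarray(y, float))
    n = len(lx)
    sx, sy, sxx, sxy = lx.sum(), ly.sum(), (lx * lx).sum(), (lx * ly).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return float(slope), float(intercept)


def random_sequence(rng: np.random.Generator, length: int, freqs=None, n_blocks: int = 0) -> str:
    """Seeded random ACGT sequence, optionally with N blocks inserted."""
    freqs = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
    codes = rng.choice(4, size=length, p=freqs)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
    seq = bytearray(seq.tobytes())
    for _ in range(n_blocks):
        start = int(rng.integers(0, max(length - 20, 1)))
        width = int(rng.integers(1, 20))
        seq[start : start + width] = b"N" * min(width, length - start)
    return seq.decode("ascii")


# --- shared simulated cohorts ----------------------------------------------


@pytest.fixture(scope="session")
def clean_cohort():
    """Error-free, complete-digestion, monomorphic cohort: the idealized
    condition where every planted site must be recovered as scenario I."""
    genome = r.simulate_genome(r.GenomeSimSpec(length=200_000, seed=41))
    genome, sites = r.plant_sites(genome, r.SBFI, n_sites=30, seed=42)
    spec = r.RadSimSpec(
        n_individuals=5, coverage=20, error_rate=0.0, digestion_prob=1.0,
        snp_prob=0.0, seed=43,
    )
    reads, truth = r.simulate_radseq(genome, sites, spec)
    return {
        "genome": genome,
        "sites": sites,
        "reads": reads,
        "truth": truth,
        "spec": spec,
        "site_map": r.sites_to_map(sites, r.SBFI),
    }


@pytest.fixture(scope="session")
def poly_cohort():
    """Polymorphic, error-free cohort for genotype/heterozygosity checks:
    every site carries one biallelic SNP at alternate-allele frequency 0.3."""
    genome = r.simulate_genome(r.GenomeSimSpec(length=400_000, seed=51))
    genome, sites = r.plant_sites(genome, r.SBFI, n_sites=50, seed=52)
    spec = r.RadSimSpec(
        n_individuals=20, coverage=20, error_rate=0.0, digestion_prob=1.0,
        snp_prob=1.0, maf=0.3, seed=53,
    )
    reads, truth = r.simulate_radseq(genome, sites, spec)
    return {
        "genome": genome,
        "sites": sites,
        "reads": reads,
        "truth": truth,
        "spec": spec,
        "site_map": r.sites_to_map(sites, r.SBFI),
    }
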