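"""Nucleotide-composition profiling and probabilistic restriction-site prediction.

Four composition models predict the per-position probability that a
restriction enzyme's recognition sequence occurs in a genome, from the
k-mer spectrum of any sequence resource (genome or transcriptome
assembly):

* ``gc``   — order 0 using GC content only: each G/C base weighted g/2,
  each A/T base (1-g)/2, with g the resource's GC fraction.
* ``mono`` — order-0 Markov (base frequencies): ``prod f(b_i)``.
* ``di``   — order-1 Markov: ``f(b1) * prod f(b_{i-1} b_i) / f(b_{i-1})``.
* ``tri``  — order-2 Markov:
  ``f(b1 b2) * prod f(b_{i-2} b_{i-1} b_i) / f(b_{i-2} b_{i-1})``.

Degenerate (IUPAC) recognition sequences are summed over their concrete
expansions.  Expected genome-wide counts multiply the per-position
probability by the number of positions, counting palindromic sites once
and non-palindromic sites on both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enzymes import Enzyme, revcomp

MODELS = ("gc", "mono", "di", "tri")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes A=0, C=1, G=2, T=3; anything else 4."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _word_index(word: str) -> int:
    idx = 0
    for ch in word:
        idx = idx * 4 + int(_CODE[ord(ch)])
    return idx


@dataclass
class CompositionProfile:
    """k-mer occurrence counts of a sequence resource for word lengths 1..max_order.

    Windows containing any non-ACGT residue are excluded entirely; words
    never span sequence boundaries.
    """

    counts: dict[int, np.ndarray]  # k -> length 4**k count vector
    positions_counted: dict[int, int]
    source_length: int

    @property
    def max_order(self) -> int:
        return max(self.counts)

    def frequencies(self, k: int) -> np.ndarray:
        if k not in self.counts:
            raise ValueError(f"profile holds orders {sorted(self.counts)}, not {k}")
        n = self.positions_counted[k]
        if n == 0:
            raise ValueError(f"no valid length-{k} windows in resource")
        return self.counts[k] / n

    def freq(self, word: str) -> float:
        """Frequency of a concrete ACGT word of any profiled length."""
        k = len(word)
        return float(self.frequencies(k)[_word_index(word)])

    @property
    def gc_fraction(self) -> float:
        f = self.frequencies(1)
        return float(f[1] + f[2])


def profile_composition(
    resource: dict[str, str] | Iterable[str] | str, max_order: int = 3
) -> CompositionProfile:
    """Count overlapping words of length 1..max_order across a sequence resource.

    ``resource`` may be a single sequence, an iterable of sequences, or a
    {name: sequence} dict.  Raises on an empty resource or one with no
    valid ACGT windows.
    """
    if not 1 <= max_order <= 3:
        raise ValueError("max_order must be in 1..3")
    if isinstance(resource, str):
        seqs: list[str] = [resource]
    elif isinstance(resource, dict):
        seqs = list(resource.values())
    else:
        seqs = list(resource)
    if not seqs:
        raise ValueError("empty sequence resource")

    counts = {k: np.zeros(4**k, dtype=np.int64) for k in range(1, max_order + 1)}
    positions = {k: 0 for k in range(1, max_order + 1)}
    total = 0
    for seq in seqs:
        total += len(seq)
        codes = encode(seq)
        valid = codes < 4
        code_k = codes.astype(np.int64)
        valid_k = valid
        for k in range(1, max_order + 1):
            if k > 1:
                code_k = code_k[:-1] * 4 + codes[k - 1 :]
                valid_k = valid_k[:-1] & valid[k - 1 :]
            if code_k.size:
                sel = code_k[valid_k]
                counts[k] += np.bincount(sel, minlength=4**k)
                positions[k] += int(sel.size)
    if positions[1] == 0:
        raise ValueError("resource contains no valid ACGT windows")
    return CompositionProfile(counts=counts, positions_counted=positions, source_length=total)


def _concrete_site_probability(profile: CompositionProfile, word: str, model: str) -> float:
    if model == "gc":
        g = profile.gc_fraction
        p = 1.0
        for b in word:
            p *= g / 2.0 if b in "GC" else (1.0 - g) / 2.0
        return p
    if model == "mono":
        f = profile.frequencies(1)
        p = 1.0
        for b in word:
            p *= float(f[_word_index(b)])
        return p
    if model == "di":
        p = profile.freq(word[0])
        for i in range(1, len(word)):
            ctx = profile.freq(word[i - 1])
            if ctx == 0.0:
                warnings.warn(f"zero-frequency context {word[i-1]!r}; probability set to 0")
                return 0.0
            p *= profile.freq(word[i - 1 : i + 1]) / ctx
        return p
    if model == "tri":
        p = profile.freq(word[:2])
        for i in range(2, len(word)):
            ctx = profile.freq(word[i - 2 : i])
            if ctx == 0.0:
                warnings.warn(f"zero-frequency context {word[i-2:i]!r}; probability set to 0")
                return 0.0
            p *= profile.freq(word[i - 2 : i + 1]) / ctx
        return p
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def site_probability(profile: CompositionProfile, enzyme: Enzyme | str, model: str) -> float:
    """Single-strand per-position probability of the recognition sequence.

    Degenerate recognition sequences sum over their IUPAC expansions.
    """
    motif = enzyme.recognition if isinstance(enzyme, Enzyme) else enzyme
    from .enzymes import iupac_expansions

    return float(sum(_concrete_site_probability(profile, w, model) for w in iupac_expansions(motif)))


def total_site_probability(profile: CompositionProfile, enzyme: Enzyme, model: str) -> float:
    """Per-position site probability with strand handling.

    Palindromic recognition sequences are counted once per position;
    non-palindromic ones accumulate forward plus reverse-complement
    probability.
    """
    p = site_probability(profile, enzyme, model)
    if not enzyme.palindromic:
        p += site_probability(profile, revcomp(enzyme.recognition), model)
    return p


def expected_site_count(p: float, genome_length: int, enzyme: Enzyme) -> float:
    """Expected number of sites in a genome of ``genome_length`` bp.

    ``p`` is the (strand-combined) per-position probability; the count is
    ``p * (G - k + 1)``.
    """
    if genome_length <= enzyme.k:
        raise ValueError(
            f"genome_length {genome_length} must exceed recognition length {enzyme.k}"
        )
    return p * (genome_length - enzyme.k + 1)


@dataclass(frozen=True)
class Prediction:
    enzyme: Enzyme
    model: str
    site_probability: float
    expected_count: float


def predict_table(
    resource: CompositionProfile | dict[str, str] | Iterable[str] | str,
    enzymes: Sequence[Enzyme],
    genome_length: int,
    models: Sequence[str] = MODELS,
) -> pd.DataFrame:
    """One prediction per (enzyme, model): per-position probability and
    expected genome-wide site count.

    ``site_probability`` in the output is the strand-combined probability
    used for the expectation.
    """
    if not enzymes:
        raise ValueError("at least one enzyme required")
    profile = (
        resource
        if isinstance(resource, CompositionProfile)
        else profile_composition(resource, max_order=3)
    )
    rows = []
    for enzyme in enzymes:
        for model in models:
            p = total_site_probability(profile, enzyme, model)
            rows.append(
                {
                    "enzyme": enzyme.name,
                    "model": model,
                    "site_probability": p,
                    "expected_count": expected_site_count(p, genome_length, enzyme),
                }
            )
    return pd.DataFrame(rows)
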