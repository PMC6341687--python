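"""File I/O helpers: FASTA/FASTQ (gzip-transparent), sample sheets."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered {name: sequence} dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open_text(path) as handle:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTQ as [(read id, sequence), ...]."""
    with open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    """Write reads with a constant phred quality."""
    with open_text(path, "wt") as handle:
        for rid, seq in reads:
            qual = chr(quality + 33) * len(seq)
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_sample_sheet(path: str | Path) -> list[tuple[str, Path]]:
    """Read a TSV sample sheet (individual id, FASTQ path); paths resolve
    relative to the sheet's directory."""
    path = Path(path)
    base = path.parent
    samples: list[tuple[str, Path]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        indiv, fq = line.split("\t")[:2]
        fq_path = Path(fq)
        if not fq_path.is_absolute():
            fq_path = base / fq_path
        samples.append((indiv, fq_path))
    if not samples:
        raise ValueError(f"empty sample sheet {path}")
    return samples


def write_sample_sheet(samples: Iterable[tuple[str, str | Path]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for indiv, fq in samples:
            handle.write(f"{indiv}\t{fq}\n")
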