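"""Quality filtering of raw amplicon reads.

Five filters are applied to each read, in a fixed order so that per-filter
attrition counts are deterministic:

1. ``mean_quality`` — arithmetic mean of all per-base Phred scores must be
   at least ``min_mean_quality`` (default 25; computed on the full read).
2. ``primer`` — the forward primer must match exactly at position 0
   (zero mismatches, no IUPAC expansion).
3. ``ambiguous`` — no ambiguous base (N) anywhere in the read.
4. ``homopolymer`` — no single-base run longer than ``max_homopolymer``
   (default 8).
5. ``length`` — at least ``min_length_bp`` (default 80), measured on the
   primer-trimmed sequence by default (configurable, since conventions
   differ on whether the minimum applies before or after trimming).

Retained reads are emitted with the primer removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import PairedFastaQualIterator
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "QCConfig",
    "QCReport",
    "FILTER_ORDER",
    "filter_read",
    "filter_batch",
    "read_fastq",
    "read_fasta_qual",
    "write_fastq",
    "write_fasta",
]

FILTER_ORDER = ("mean_quality", "primer", "ambiguous", "homopolymer", "length")


@dataclass
class Read:
    id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.id}: quality/sequence length mismatch "
                f"({len(self.qualities)} vs {len(self.sequence)})"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"{self.id}: negative quality score")


@dataclass
class QCConfig:
    min_mean_quality: float = 25.0
    forward_primer: str | None = None
    max_homopolymer: int = 8
    min_length_bp: int = 80
    allow_ambiguous: bool = False
    length_after_trim: bool = True

    def __post_init__(self):
        if self.min_mean_quality <= 0:
            raise ValueError("min_mean_quality must be positive")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")


@dataclass
class QCReport:
    total_in: int
    passed: int
    failed_by_filter: dict[str, int] = field(default_factory=dict)

    @property
    def retention_fraction(self) -> float:
        if self.total_in == 0:
            return 1.0
        return self.passed / self.total_in

    def __post_init__(self):
        if self.passed + sum(self.failed_by_filter.values()) != self.total_in:
            raise ValueError("QCReport counts do not conserve reads")


def longest_homopolymer(sequence: str) -> int:
    """Length of the longest run of one identical base."""
    best = run = 0
    prev = None
    for base in sequence:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def filter_read(read: Read, config: QCConfig) -> tuple[bool, str | None]:
    """Apply the five filters; return (passed, first-failing-filter-name)."""
    if len(read.sequence) == 0:
        return False, "length"
    mean_q = sum(read.qualities) / len(read.qualities)
    if mean_q < config.min_mean_quality:
        return False, "mean_quality"
    primer = config.forward_primer
    if primer and not read.sequence.startswith(primer):
        return False, "primer"
    if not config.allow_ambiguous and "N" in read.sequence:
        return False, "ambiguous"
    if longest_homopolymer(read.sequence) > config.max_homopolymer:
        return False, "homopolymer"
    trimmed_len = len(read.sequence) - (len(primer) if primer else 0)
    effective_len = trimmed_len if config.length_after_trim else len(read.sequence)
    if effective_len < config.min_length_bp:
        return False, "length"
    return True, None


def trim_primer(read: Read, config: QCConfig) -> Read:
    primer = config.forward_primer
    if not primer:
        return read
    k = len(primer)
    return Read(read.id, read.sequence[k:], list(read.qualities)[k:])


def filter_batch(reads: Iterable[Read], config: QCConfig) -> tuple[list[Read], QCReport]:
    """Filter a batch; retained reads are primer-trimmed, in input order."""
    retained: list[Read] = []
    failed = {name: 0 for name in FILTER_ORDER}
    total = 0
    for read in reads:
        total += 1
        ok, which = filter_read(read, config)
        if ok:
            retained.append(trim_primer(read, config))
        else:
            failed[which] += 1
    failed = {k: v for k, v in failed.items() if v}
    return retained, QCReport(total_in=total, passed=len(retained), failed_by_filter=failed)


# -- I/O -------------------------------------------------------------------

def _from_record(rec: SeqRecord) -> Read:
    return Read(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])


def read_fastq(path: str | Path) -> list[Read]:
    """Read Sanger/Phred+33 FASTQ."""
    return [_from_record(r) for r in SeqIO.parse(str(path), "fastq")]


def read_fasta_qual(fasta_path: str | Path, qual_path: str | Path) -> list[Read]:
    """Read paired FASTA + .qual files."""
    with open(fasta_path) as fa, open(qual_path) as qu:
        return [_from_record(r) for r in PairedFastaQualIterator(fa, qu)]


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
    rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    SeqIO.write((_to_record(r) for r in reads), str(path), "fastq")


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in reads),
        str(path), "fasta",
    )


def write_report(report: QCReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"total_in\t{report.total_in}\n")
        fh.write(f"passed\t{report.passed}\n")
        for name in FILTER_ORDER:
            fh.write(f"failed_{name}\t{report.failed_by_filter.get(name, 0)}\n")
        fh.write(f"retention_fraction\t{report.retention_fraction:.6f}\n")
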