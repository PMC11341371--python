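"""Genome and EPI pair-table I/O, window extraction, and dataset splitting.

Coordinates are 0-based half-open (BED convention) throughout.  Enhancer
windows are 3,000 bp and promoter windows 2,000 bp, the element sizes used
for sequence-only EPI classification; the promoter window is asymmetric
around the TSS (1,500 bp upstream, 500 bp downstream, in transcription
orientation).
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

ENHANCER_LEN = 3000
PROMOTER_LEN = 2000
PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500

PAIR_COLUMNS = [
    "enh_chrom", "enh_start", "enh_end",
    "prom_chrom", "prom_start", "prom_end",
    "label", "cell_line",
]

_VALID_BASES = frozenset("ACGTN")


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class PairTableError(ValueError):
    """Raised for malformed EPI pair tables; carries the offending line."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class EPIRecord:
    """One enhancer/promoter pair with its interaction label and cell line."""

    enhancer: GenomicInterval
    promoter: GenomicInterval
    label: int
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclasses.dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of a record collection."""

    train: list[EPIRecord]
    validation: list[EPIRecord]
    test: list[EPIRecord]
    seed: int

    def __iter__(self):
        yield from (self.train, self.validation, self.test)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record) FASTA file into ``{contig_id: UPPERCASE seq}``.

    Raises :class:`FastaFormatError` on empty files, duplicate contig ids,
    or sequences with characters outside ``{A,C,G,T,N}`` after upcasing.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise FastaFormatError(f"duplicate contig id {rec.id!r} in {path}")
            seq = str(rec.seq).upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FastaFormatError(
                    f"contig {rec.id!r} contains non-DNA characters {sorted(bad)}"
                )
            genome[rec.id] = seq
    if not genome:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    """Write a contig mapping to FASTA, wrapping lines at ``width``."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_interval(genome: Mapping[str, str], interval: GenomicInterval) -> str:
    """Slice a half-open interval; minus-strand intervals are reverse-complemented."""
    if interval.chrom not in genome:
        raise KeyError(f"unknown contig {interval.chrom!r}")
    contig = genome[interval.chrom]
    if interval.end > len(contig):
        raise IndexError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"exceeds contig length {len(contig)}"
        )
    seq = contig[interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


def promoter_interval(chrom: str, tss: int, strand: str) -> GenomicInterval:
    """The 2,000-bp promoter window around a TSS, in transcription orientation.

    Plus strand: ``[tss - 1500, tss + 500)``.  Minus strand the window is
    mirrored, ``[tss - 500, tss + 1500)``, and extraction reverse-complements
    it so "upstream" always means upstream of transcription.
    """
    if strand == "+":
        start, end = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    elif strand == "-":
        start, end = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0:
        raise IndexError(f"promoter window for tss={tss} ({strand}) underruns the contig")
    return GenomicInterval(chrom, start, end, strand)


def extract_promoter(genome: Mapping[str, str], chrom: str, tss: int, strand: str) -> str:
    """Extract the strand-aware 2,000-bp promoter window around ``tss``.

    No padding: a window overrunning the contig raises ``IndexError``.
    """
    return extract_interval(genome, promoter_interval(chrom, tss, strand))


def read_pairs(path: str | Path) -> list[EPIRecord]:
    """Read an EPI pair TSV (header required, columns as in PAIR_COLUMNS)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise PairTableError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            coords = {
                c: int(row[c])
                for c in ("enh_start", "enh_end", "prom_start", "prom_end")
            }
            label = int(row["label"])
            if label not in (0, 1):
                raise ValueError(f"label {label} not in {{0,1}}")
            rec = EPIRecord(
                enhancer=GenomicInterval(row["enh_chrom"], coords["enh_start"], coords["enh_end"]),
                promoter=GenomicInterval(row["prom_chrom"], coords["prom_start"], coords["prom_end"]),
                label=label,
                cell_line=str(row["cell_line"]),
            )
        except (ValueError, TypeError) as exc:
            raise PairTableError(f"{path}, line {line_no}: {exc}") from exc
        records.append(rec)
    return records


def write_pairs(records: Iterable[EPIRecord], path: str | Path) -> None:
    """Write records as the tab-separated pair table ``read_pairs`` accepts."""
    rows = [
        {
            "enh_chrom": r.enhancer.chrom,
            "enh_start": r.enhancer.start,
            "enh_end": r.enhancer.end,
            "prom_chrom": r.promoter.chrom,
            "prom_start": r.promoter.start,
            "prom_end": r.promoter.end,
            "label": r.label,
            "cell_line": r.cell_line,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def extract_pair_sequences(
    genome: Mapping[str, str], records: Sequence[EPIRecord]
) -> list[tuple[str, str]]:
    """Extract (enhancer_seq, promoter_seq) for every record."""
    return [
        (extract_interval(genome, r.enhancer), extract_interval(genome, r.promoter))
        for r in records
    ]


def _split_sizes(n: int, ratios: Sequence[float]) -> list[int]:
    # floor-then-distribute: floor each share, hand leftovers to the largest
    # fractional remainders (ties broken by split order).
    raw = [n * r for r in ratios]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split_dataset(
    records: Sequence[EPIRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    mode: str = "random",
) -> DatasetSplit:
    """Partition records into train/validation/test.

    ``mode='random'`` shuffles records with the seed; ``mode='by_chromosome'``
    assigns whole enhancer chromosomes to a single split (leakage guard),
    choosing the assignment greedily toward the target ratios.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    if len(records) < 3:
        raise ValueError("need at least 3 records to make 3 splits")
    rng = np.random.default_rng(seed)

    if mode == "random":
        order = rng.permutation(len(records))
        sizes = _split_sizes(len(records), ratios)
        bounds = np.cumsum([0] + sizes)
        parts = [
            [records[i] for i in order[bounds[j] : bounds[j + 1]]] for j in range(3)
        ]
    elif mode == "by_chromosome":
        groups: dict[str, list[EPIRecord]] = defaultdict(list)
        for r in records:
            groups[r.enhancer.chrom].append(r)
        chroms = sorted(groups)
        rng.shuffle(chroms)
        targets = [len(records) * x for x in ratios]
        parts = [[], [], []]
        counts = [0, 0, 0]
        for chrom in chroms:
            # put the chromosome where the deficit relative to target is largest
            j = int(np.argmax([t - c for t, c in zip(targets, counts)]))
            parts[j].extend(groups[chrom])
            counts[j] += len(groups[chrom])
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    return DatasetSplit(train=parts[0], validation=parts[1], test=parts[2], seed=seed)
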