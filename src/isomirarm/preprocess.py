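"""Raw-read cleanup: adapter trimming, length filtering, read collapsing.

Small-RNA inserts are shorter than the sequencing cycle count, so every
genuine insert is followed by (part of) the 3' adapter.  A read without
adapter evidence is therefore not "clean" and is discarded.  Clean reads are
length-filtered to the mature-miRNA envelope (18-25 nt by default), collapsed
to unique sequences with counts, and low-count singletons (count < 2) are
dropped before mapping.  Pre-collapsed (sequence, count) TSV input bypasses
adapter handling entirely.
"""
from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .mirbase import normalize_rna

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UniqueRead:
    """A distinct read sequence with its observed (collapsed) count."""

    sequence: str
    count: float  # integral in normal use; fractional only under multi-hit splitting

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")
        if self.count <= 0:
            raise ValueError(f"read {self.sequence!r}: nonpositive count {self.count}")


@dataclass
class Library:
    """A collapsed small-RNA read library with filtering bookkeeping.

    total_raw >= total_clean >= total_used: raw input reads, adapter-clean
    reads, and reads surviving the length and minimum-count filters.
    """

    name: str
    reads: list[UniqueRead] = field(default_factory=list)
    total_raw: int = 0
    total_clean: int = 0
    total_used: int = 0

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> str | None:
    """Return the insert preceding the leftmost 3' adapter occurrence.

    The adapter is detected either in full anywhere in the read (anything
    downstream is sequencing past the adapter and is ignored) or as a prefix
    of length >= ``min_overlap`` reaching the read's 3' end.  Matching is
    exact; ``None`` signals no adapter evidence (the read is not clean).
    An empty string return means the read was pure adapter.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read_n = normalize_rna(read)
    adapter_n = normalize_rna(adapter)
    n, a = len(read_n), len(adapter_n)
    for i in range(0, n - min_overlap + 1):
        tail = n - i
        if tail >= a:
            if read_n[i : i + a] == adapter_n:
                return read_n[:i]
        elif read_n[i:] == adapter_n[:tail]:
            return read_n[:i]
    return None


def collapse_and_filter(
    clean_reads: Iterable[str | tuple[str, float]],
    *,
    min_len: int = 18,
    max_len: int = 25,
    min_count: int = 2,
    name: str = "library",
    total_raw: int | None = None,
) -> Library:
    """Collapse adapter-clean reads to unique sequences and apply filters.

    Accepts plain sequences or pre-tallied ``(sequence, count)`` pairs.
    Length filtering happens first, then unique-sequence counts are tallied
    on the length-passed reads and sequences with count < ``min_count`` are
    removed.  Reads are returned sorted by descending count (ties broken
    alphabetically) for deterministic downstream output.
    """
    tally: Counter[str] = Counter()
    total_clean = 0
    for item in clean_reads:
        seq, cnt = (item, 1) if isinstance(item, str) else item
        seq = normalize_rna(seq)
        cnt = int(cnt)
        total_clean += cnt
        if min_len <= len(seq) <= max_len:
            tally[seq] += cnt
    reads = [
        UniqueRead(seq, cnt)
        for seq, cnt in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        if cnt >= min_count
    ]
    total_used = int(sum(r.count for r in reads))
    if total_clean == 0:
        logger.warning("library %s: no input reads", name)
    return Library(
        name=name,
        reads=reads,
        total_raw=total_clean if total_raw is None else total_raw,
        total_clean=total_clean,
        total_used=total_used,
    )


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    return "tsv"


def read_collapsed_tsv(path: str | Path) -> list[tuple[str, int]]:
    """Read a two-column (sequence, count) TSV; a header row is tolerated."""
    pairs: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: expected 2 columns, got {row!r}")
            try:
                cnt = int(row[1])
            except ValueError:
                continue  # header row
            pairs.append((row[0], cnt))
    return pairs


def write_collapsed_tsv(library: Library, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sequence", "count"])
        for r in library.reads:
            w.writerow([r.sequence, int(r.count)])


def write_summary_tsv(library: Library, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["library", "total_raw", "total_clean", "total_used", "unique_reads"])
        w.writerow([library.name, library.total_raw, library.total_clean, library.total_used, len(library)])


def load_reads(
    path: str | Path,
    *,
    fmt: str | None = None,
    adapter: str | None = None,
    min_overlap: int = 6,
    min_len: int = 18,
    max_len: int = 25,
    min_count: int = 2,
    name: str | None = None,
) -> Library:
    """Load a read library from FASTA, FASTQ or collapsed TSV.

    For FASTA/FASTQ with an ``adapter``, reads without adapter evidence are
    discarded (counted in ``total_raw`` only).  FASTQ quality scores are
    ignored.  TSV input is treated as already clean and collapsed.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    name = name or path.stem
    if fmt == "tsv":
        pairs = read_collapsed_tsv(path)
        return collapse_and_filter(
            pairs, min_len=min_len, max_len=max_len, min_count=min_count, name=name
        )
    raw = 0
    clean: list[str] = []
    for rec in SeqIO.parse(str(path), fmt):
        raw += 1
        seq = str(rec.seq)
        if adapter is not None:
            trimmed = trim_adapter(seq, adapter, min_overlap)
            if trimmed is None or not trimmed:
                continue
            clean.append(trimmed)
        else:
            clean.append(seq)
    return collapse_and_filter(
        clean, min_len=min_len, max_len=max_len, min_count=min_count, name=name, total_raw=raw
    )
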