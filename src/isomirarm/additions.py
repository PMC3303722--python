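"""Tabulation of 3'-end addition fragments recovered by trim-rescue mapping.

Every read rescued by 3' trimming carries a removed suffix — the putative
non-templated addition.  This module tallies those fragments, weighted by
read count, and reports each fragment's share of all addition events plus
the library-level addition rate (fraction of mapped reads carrying one).

The mapper's exact-match-first policy means an appended base that happens
to match the next templated hairpin base is never trimmed: such additions
are operationally invisible and are absent from this table by construction.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .mapping import MappedRead, MIN_MAPPED_LENGTH
from .mirbase import RNA_ALPHABET

logger = logging.getLogger(__name__)


@dataclass
class AdditionTable:
    """Per-fragment addition counts and percentages for one library."""

    table: pd.DataFrame  # columns: fragment, count, pct (of all addition reads)
    n_kinds: int  # distinct fragment sequences
    total_addition_count: float  # read-count-weighted addition events
    total_mapped_count: float  # read-count-weighted mapped reads
    addition_fraction: float  # total_addition_count / total_mapped_count


def tabulate_additions(mapped: Iterable[MappedRead]) -> AdditionTable:
    """Tally trimmed 3' fragments across mapped reads.

    Counts are read counts (``UniqueRead.count``-weighted), not unique-read
    counts; per-fragment percentage is of the total addition read count.
    Rows are ordered by descending percentage, ties broken alphabetically.
    """
    tally: Counter[str] = Counter()
    total_mapped = 0.0
    total_added = 0.0
    for mr in mapped:
        total_mapped += mr.count
        frag = mr.trimmed_fragment
        if not frag:
            continue
        assert set(frag) <= RNA_ALPHABET, f"non-nucleotide fragment {frag!r}"
        # a fragment longer than read length - 18 cannot survive trimming
        assert len(frag) <= len(mr.read.sequence) - MIN_MAPPED_LENGTH
        tally[frag] += mr.count
        total_added += mr.count
    if not tally:
        logger.warning("no trimmed reads: empty addition table")
        table = pd.DataFrame(columns=["fragment", "count", "pct"])
    else:
        rows = [
            {"fragment": frag, "count": cnt, "pct": 100.0 * cnt / total_added}
            for frag, cnt in tally.items()
        ]
        table = (
            pd.DataFrame(rows)
            .sort_values(["pct", "fragment"], ascending=[False, True], kind="stable")
            .reset_index(drop=True)
        )
    return AdditionTable(
        table=table,
        n_kinds=len(tally),
        total_addition_count=total_added,
        total_mapped_count=total_mapped,
        addition_fraction=(total_added / total_mapped) if total_mapped else 0.0,
    )


def combine_addition_tables(
    table_a: AdditionTable, table_b: AdditionTable, labels: tuple[str, str] = ("A", "B")
) -> pd.DataFrame:
    """Two-library fragment table: fragment, count/pct per library."""
    la, lb = labels
    a = table_a.table.rename(columns={"count": f"count_{la}", "pct": f"pct_{la}"})
    b = table_b.table.rename(columns={"count": f"count_{lb}", "pct": f"pct_{lb}"})
    merged = a.merge(b, on="fragment", how="outer").fillna(0.0)
    return (
        merged.sort_values([f"pct_{la}", "fragment"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
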