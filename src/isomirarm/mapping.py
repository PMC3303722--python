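"""Exact-substring mapping of collapsed reads onto pre-miRNA hairpins.

No mismatches are allowed anywhere: ambiguity between near-identical
paralogous matures is controlled by demanding perfect matches.  Because
non-templated nucleotides are frequently appended to a mature miRNA's 3'
end, a read with no perfect hit is rescued by trimming its 3'-terminal
nucleotide one at a time (down to 18 nt) until an exact match appears;
the removed suffix is retained as the read's addition fragment.

Mapped reads are assigned to annotated matures on the same hairpin when
their start offset is within +/-2 nt and end offset within +/-5 nt of the
reference span (wider shifts are treated as random matches).  Reads failing
every window can seed detection of an unannotated opposite-arm mature.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mirbase import MatureAnnotation, PreMiRNA, arm_of_span
from .preprocess import Library, UniqueRead

logger = logging.getLogger(__name__)

MIN_MAPPED_LENGTH = 18


@dataclass(frozen=True)
class MappedRead:
    """One exact placement of a (possibly 3'-trimmed) read on a hairpin."""

    read: UniqueRead
    premirna_id: str
    map_start: int  # 1-based inclusive, in hairpin coordinates
    map_end: int
    trimmed_fragment: str = ""
    count: float = 0.0  # read count attributed to this locus

    @property
    def mapped_sequence(self) -> str:
        """The read after 3' trimming (what actually matched the hairpin)."""
        n = len(self.read.sequence) - len(self.trimmed_fragment)
        return self.read.sequence[:n]

    @property
    def mapped_length(self) -> int:
        return self.map_end - self.map_start + 1


@dataclass
class IsomiR:
    """A distinct mapped variant of one mature miRNA.

    Offsets are read coordinate minus mature coordinate: negative start
    offsets start upstream of the reference 5' end, negative end offsets
    stop short of the reference 3' end.
    """

    mature_id: str
    premirna_id: str
    start_offset: int
    end_offset: int
    sequence: str
    count: float
    source: str = "mirbase"

    @property
    def offsets(self) -> tuple[int, int]:
        return (self.start_offset, self.end_offset)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_read(
    read: UniqueRead,
    hairpins: Mapping[str, PreMiRNA],
    *,
    min_trim_len: int = MIN_MAPPED_LENGTH,
    split_multihits: bool = False,
) -> list[MappedRead]:
    """Map one unique read, with iterative 3'-end trim rescue.

    The full-length read is searched against every hairpin; only if it has
    zero exact hits anywhere is the 3'-terminal nucleotide removed and the
    search repeated, stopping at the first (longest) length with at least one
    hit or when the trimmed read would drop below ``min_trim_len``.  All
    occurrences at the accepted length are returned; an empty list is the
    unmapped signal.

    A read hitting k loci contributes its full count to each by default;
    ``split_multihits`` divides the count by k instead.
    """
    seq = read.sequence
    for length in range(len(seq), min_trim_len - 1, -1):
        prefix = seq[:length]
        fragment = seq[length:]
        hits = [
            (hid, pos)
            for hid, hp in hairpins.items()
            for pos in _find_all(hp.sequence, prefix)
        ]
        if hits:
            count = read.count / len(hits) if split_multihits else read.count
            return [
                MappedRead(read, hid, pos + 1, pos + length, fragment, count)
                for hid, pos in hits
            ]
    return []


def map_library(
    library: Library,
    hairpins: Mapping[str, PreMiRNA],
    *,
    min_trim_len: int = MIN_MAPPED_LENGTH,
    split_multihits: bool = False,
) -> tuple[list[MappedRead], list[UniqueRead]]:
    """Map every unique read in a library; returns (mapped, unmapped)."""
    mapped: list[MappedRead] = []
    unmapped: list[UniqueRead] = []
    for read in library.reads:
        hits = map_read(
            read, hairpins, min_trim_len=min_trim_len, split_multihits=split_multihits
        )
        if hits:
            mapped.extend(hits)
        else:
            unmapped.append(read)
    return mapped, unmapped


def _pick_annotation(
    mr: MappedRead,
    candidates: Sequence[MatureAnnotation],
    max_start_offset: int,
    max_end_offset: int,
) -> tuple[MatureAnnotation, int, int] | None:
    eligible = []
    for ann in candidates:
        so = mr.map_start - ann.start
        eo = mr.map_end - ann.end
        if abs(so) <= max_start_offset and abs(eo) <= max_end_offset:
            eligible.append((abs(so), abs(eo), 0 if ann.arm == "5p" else 1, ann, so, eo))
    if not eligible:
        return None
    if len(eligible) > 1:
        logger.warning(
            "read %s on %s satisfies %d annotation windows; keeping closest",
            mr.read.sequence,
            mr.premirna_id,
            len(eligible),
        )
    eligible.sort(key=lambda t: t[:3])
    _, _, _, ann, so, eo = eligible[0]
    return ann, so, eo


def assign_isomirs(
    mapped: Iterable[MappedRead],
    annotations: Sequence[MatureAnnotation],
    *,
    max_start_offset: int = 2,
    max_end_offset: int = 5,
) -> tuple[list[IsomiR], list[MappedRead]]:
    """Assign mapped reads to mature annotations by offset windows.

    A read is an isomiR of a mature on the same hairpin iff |start offset|
    <= ``max_start_offset`` and |end offset| <= ``max_end_offset``.  When two
    annotations both accept a read the one with the smaller |start offset|
    wins (ties: smaller |end offset|, then the 5p arm).  Counts accumulate
    per distinct (mature, start offset, end offset); reads accepted by no
    annotation are returned for opposite-arm detection.
    """
    by_hairpin: dict[str, list[MatureAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_hairpin[ann.premirna_id].append(ann)

    acc: dict[tuple[str, int, int], IsomiR] = {}
    unassigned: list[MappedRead] = []
    for mr in mapped:
        pick = _pick_annotation(
            mr, by_hairpin.get(mr.premirna_id, ()), max_start_offset, max_end_offset
        )
        if pick is None:
            unassigned.append(mr)
            continue
        ann, so, eo = pick
        key = (ann.mature_id, so, eo)
        if key in acc:
            acc[key].count += mr.count
        else:
            acc[key] = IsomiR(
                mature_id=ann.mature_id,
                premirna_id=ann.premirna_id,
                start_offset=so,
                end_offset=eo,
                sequence=mr.mapped_sequence,
                count=mr.count,
                source=ann.source,
            )
    isomirs = sorted(acc.values(), key=lambda i: (i.mature_id, i.start_offset, i.end_offset))
    return isomirs, unassigned


@dataclass
class DetectedArm:
    """An opposite-arm mature inferred from unassigned reads."""

    annotation: MatureAnnotation
    defining_count: float  # count of the span-defining (most abundant) read
    total_count: float  # summed count of candidate reads on that arm
    n_reads: int


def detect_opposite_arm(
    unassigned: Iterable[MappedRead],
    annotations: Sequence[MatureAnnotation],
    hairpins: Mapping[str, PreMiRNA],
    *,
    min_count: float = 2,
) -> list[DetectedArm]:
    """Detect additional matures on arms that miRBase leaves unannotated.

    For each hairpin annotated on exactly one arm, unassigned reads whose
    span midpoint falls on the opposite arm are clustered; the most abundant
    read's span defines a new annotation (source ``"detected"``).  Clusters
    whose defining read count is below ``min_count`` are discarded.
    """
    arms_annotated: dict[str, set[str]] = defaultdict(set)
    for ann in annotations:
        arms_annotated[ann.premirna_id].add(ann.arm)

    by_target: dict[tuple[str, str], list[MappedRead]] = defaultdict(list)
    for mr in unassigned:
        hp = hairpins.get(mr.premirna_id)
        if hp is None:
            continue
        annotated = arms_annotated.get(mr.premirna_id, set())
        if len(annotated) != 1:
            continue  # both arms annotated (or hairpin unknown): nothing to detect
        missing = ({"5p", "3p"} - annotated).pop()
        if arm_of_span(mr.map_start, mr.map_end, hp.length) == missing:
            by_target[(mr.premirna_id, missing)].append(mr)

    detected: list[DetectedArm] = []
    for (hid, arm), reads in sorted(by_target.items()):
        defining = max(reads, key=lambda r: (r.count, -r.map_start, -r.map_end))
        if defining.count < min_count:
            continue
        ann = MatureAnnotation(
            mature_id=f"{hid}-{arm}",
            premirna_id=hid,
            start=defining.map_start,
            end=defining.map_end,
            arm=arm,
            source="detected",
        )
        detected.append(
            DetectedArm(
                annotation=ann,
                defining_count=defining.count,
                total_count=sum(r.count for r in reads),
                n_reads=len(reads),
            )
        )
    return detected


def expression_table(isomirs: Iterable[IsomiR]) -> pd.DataFrame:
    """Per-mature expression: the sum of all isomiR counts, plus type counts."""
    rows: dict[str, dict] = {}
    for iso in isomirs:
        row = rows.setdefault(
            iso.mature_id,
            {"mature_id": iso.mature_id, "premirna_id": iso.premirna_id,
             "expression": 0.0, "n_isomir_types": 0},
        )
        row["expression"] += iso.count
        row["n_isomir_types"] += 1
    df = pd.DataFrame(
        rows.values(), columns=["mature_id", "premirna_id", "expression", "n_isomir_types"]
    )
    return df.sort_values("expression", ascending=False, kind="stable").reset_index(drop=True)


def arm_expression(
    isomirs: Iterable[IsomiR], annotations: Sequence[MatureAnnotation]
) -> dict[tuple[str, str], float]:
    """Summed isomiR counts per (hairpin, arm)."""
    arm_of = {a.mature_id: (a.premirna_id, a.arm) for a in annotations}
    out: dict[tuple[str, str], float] = defaultdict(float)
    for iso in isomirs:
        key = arm_of.get(iso.mature_id)
        if key is None:
            raise KeyError(f"isomiR references unknown mature {iso.mature_id!r}")
        out[key] += iso.count
    return dict(out)


ISOMIR_COLUMNS = ["mature_id", "premirna_id", "start_offset", "end_offset", "sequence"]


def isomir_frame(
    isomirs_by_library: Mapping[str, Sequence[IsomiR]]
) -> pd.DataFrame:
    """Merge per-library isomiR lists into one table with count_<lib> columns."""
    merged: dict[tuple, dict] = {}
    for lib, isomirs in isomirs_by_library.items():
        for iso in isomirs:
            key = (iso.mature_id, iso.start_offset, iso.end_offset)
            row = merged.setdefault(
                key,
                {
                    "mature_id": iso.mature_id,
                    "premirna_id": iso.premirna_id,
                    "start_offset": iso.start_offset,
                    "end_offset": iso.end_offset,
                    "sequence": iso.sequence,
                },
            )
            row[f"count_{lib}"] = row.get(f"count_{lib}", 0.0) + iso.count
    cols = ISOMIR_COLUMNS + [f"count_{lib}" for lib in isomirs_by_library]
    df = pd.DataFrame(sorted(merged.values(), key=lambda r: (r["mature_id"], r["start_offset"], r["end_offset"])), columns=cols)
    for lib in isomirs_by_library:
        df[f"count_{lib}"] = df[f"count_{lib}"].fillna(0.0)
    return df
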