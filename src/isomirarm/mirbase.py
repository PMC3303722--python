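"""Hairpin / mature-miRNA annotation I/O.

Reads miRBase-style ``hairpin.fa`` and ``mature.fa`` files (first
whitespace-delimited header token is the record ID), locates mature miRNAs
inside their precursor hairpins by exact substring search, and assigns each
mature a 5p or 3p arm label with the midpoint rule: a mature whose span
midpoint lies strictly in the 5' half of the hairpin is a 5p-arm product,
otherwise 3p.  All coordinates are 1-based inclusive, matching the
``5p:17-39;3p:53-75`` notation used in published arm-selection tables.
"""
from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: suffixes that distinguish a mature ID from its hairpin ID (hsa-miR-423-5p -> hsa-mir-423)
_ARM_SUFFIX = re.compile(r"(-5p|-3p|\*)$", re.IGNORECASE)


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert DNA T to RNA U (canonical internal alphabet)."""
    return sequence.upper().replace("T", "U")


@dataclass(frozen=True)
class PreMiRNA:
    """A precursor miRNA hairpin: the mapping reference."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"hairpin {self.id!r}: empty sequence")
        bad = [i for i, c in enumerate(self.sequence) if c not in RNA_ALPHABET]
        if bad:
            pos = bad[0]
            raise ValueError(
                f"hairpin {self.id!r}: non-nucleotide character "
                f"{self.sequence[pos]!r} at position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Extract ``sequence[start..end]`` with 1-based inclusive coordinates."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"span {start}-{end} outside hairpin {self.id!r} (1..{self.length})")
        return self.sequence[start - 1 : end]


def arm_of_span(start: int, end: int, hairpin_length: int) -> str:
    """Arm label by the midpoint rule.

    5p if the span midpoint ``(start+end)/2`` is strictly left of the hairpin
    center ``(length+1)/2``; 3p otherwise (the exact-tie case falls to 3p and
    should be flagged by the caller via :func:`is_midpoint_tie`).
    """
    return "5p" if (start + end) / 2 < (hairpin_length + 1) / 2 else "3p"


def is_midpoint_tie(start: int, end: int, hairpin_length: int) -> bool:
    """True when the mature span is centered exactly on the hairpin midpoint."""
    return (start + end) / 2 == (hairpin_length + 1) / 2


@dataclass
class MatureAnnotation:
    """A mature miRNA located on its hairpin (1-based inclusive coordinates)."""

    mature_id: str
    premirna_id: str
    start: int
    end: int
    arm: str
    source: str = "mirbase"
    #: True if this arm is the miRBase-designated major product ("MA"), False for
    #: the minor product ("mi"), None when miRBase does not rank the arms.
    major: bool | None = None
    #: set when the arm label required the midpoint tie-break convention
    midpoint_tie: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mature_id!r}: arm must be '5p' or '3p', got {self.arm!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.mature_id!r}: invalid span {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_hairpins(path: str | Path) -> dict[str, PreMiRNA]:
    """Read a hairpin FASTA into an ordered ``{id: PreMiRNA}`` mapping.

    U/T are normalized to U and sequences are case-folded to uppercase.
    Raises ``ValueError`` on an empty file, duplicate record IDs, or
    non-nucleotide characters (reported with record ID and position).
    """
    hairpins: dict[str, PreMiRNA] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in hairpins:
            raise ValueError(f"duplicate hairpin ID {record.id!r} in {path}")
        hairpins[record.id] = PreMiRNA(record.id, normalize_rna(str(record.seq)))
    if not hairpins:
        raise ValueError(f"no FASTA records found in {path}")
    return hairpins


def _mature_base_id(mature_id: str) -> str:
    """hsa-miR-423-5p -> hsa-mir-423 (lowercase, arm suffix stripped)."""
    return _ARM_SUFFIX.sub("", mature_id).lower()


def _candidate_hairpins(mature_id: str, hairpins: Mapping[str, PreMiRNA]) -> list[PreMiRNA]:
    base = _mature_base_id(mature_id)
    out = []
    for hid, hp in hairpins.items():
        h = hid.lower()
        if h == base or h.startswith(base + "-"):
            out.append(hp)
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_matures(
    hairpins: Mapping[str, PreMiRNA],
    matures: str | Path | Sequence[tuple[str, str]],
) -> list[MatureAnnotation]:
    """Locate mature miRNAs within hairpins and assign arm labels.

    ``matures`` is a mature FASTA path (IDs prefix-matched to hairpin IDs), an
    annotation TSV path (explicit coordinates, overrides any search), or an
    in-memory sequence of ``(mature_id, sequence)`` pairs.

    Each mature sequence must occur exactly once in every hairpin it is matched
    to: absence and multiple occurrences are both errors (the latter requires
    TSV disambiguation).  A mature spanning the whole hairpin is rejected: its
    center is undefined relative to either arm.
    """
    if isinstance(matures, (str, Path)):
        path = Path(matures)
        with open(path) as fh:
            first = fh.read(1)
        if first != ">":
            return read_annotation_tsv(path, hairpins=hairpins)
        pairs = [
            (rec.id, normalize_rna(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
        ]
    else:
        pairs = [(mid, normalize_rna(seq)) for mid, seq in matures]

    annotations: list[MatureAnnotation] = []
    for mature_id, seq in pairs:
        candidates = _candidate_hairpins(mature_id, hairpins)
        if not candidates:
            raise ValueError(f"mature {mature_id!r}: no hairpin with a matching ID")
        found = False
        for hp in candidates:
            hits = _find_all(hp.sequence, seq)
            if not hits:
                continue
            if len(hits) > 1:
                raise ValueError(
                    f"mature {mature_id!r} occurs {len(hits)} times in hairpin "
                    f"{hp.id!r}; provide an explicit annotation TSV"
                )
            found = True
            start = hits[0] + 1
            end = hits[0] + len(seq)
            if start == 1 and end == hp.length:
                raise ValueError(
                    f"mature {mature_id!r} equals the whole hairpin {hp.id!r}; "
                    "arm is undefined"
                )
            tie = is_midpoint_tie(start, end, hp.length)
            if tie:
                logger.warning(
                    "mature %s centered exactly on hairpin %s midpoint; "
                    "assigned 3p by convention",
                    mature_id,
                    hp.id,
                )
            annotations.append(
                MatureAnnotation(
                    mature_id,
                    hp.id,
                    start,
                    end,
                    arm_of_span(start, end, hp.length),
                    source="mirbase",
                    midpoint_tie=tie,
                )
            )
        if not found:
            names = ", ".join(hp.id for hp in candidates)
            raise ValueError(f"mature {mature_id!r} not found in candidate hairpin(s): {names}")
    return annotations


ANNOTATION_COLUMNS = ["premirna_id", "mature_id", "start", "end", "arm", "source"]


def write_annotation_tsv(annotations: Iterable[MatureAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            w.writerow([a.premirna_id, a.mature_id, a.start, a.end, a.arm, a.source])


def read_annotation_tsv(
    path: str | Path, hairpins: Mapping[str, PreMiRNA] | None = None
) -> list[MatureAnnotation]:
    """Read an annotation TSV (header row required).

    When ``hairpins`` is given, spans are validated against hairpin bounds and
    arm labels against the midpoint rule (a mismatch is kept but logged, since
    an explicit TSV is authoritative).
    """
    annotations: list[MatureAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in ANNOTATION_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"annotation TSV {path}: missing column(s) {missing}")
        for row in reader:
            ann = MatureAnnotation(
                mature_id=row["mature_id"],
                premirna_id=row["premirna_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                arm=row["arm"],
                source=row["source"] or "mirbase",
            )
            if hairpins is not None:
                hp = hairpins.get(ann.premirna_id)
                if hp is None:
                    raise ValueError(f"annotation {ann.mature_id!r}: unknown hairpin {ann.premirna_id!r}")
                if ann.end > hp.length:
                    raise ValueError(
                        f"annotation {ann.mature_id!r}: span {ann.start}-{ann.end} exceeds "
                        f"hairpin length {hp.length}"
                    )
                expected = arm_of_span(ann.start, ann.end, hp.length)
                if expected != ann.arm:
                    logger.warning(
                        "annotation %s: declared arm %s disagrees with midpoint rule (%s)",
                        ann.mature_id,
                        ann.arm,
                        expected,
                    )
            annotations.append(ann)
    return annotations


_LOC_PART = re.compile(r"^(5p|3p|MA|mi):(\d+)-(\d+)$")


def parse_location(premirna_id: str, location: str) -> list[MatureAnnotation]:
    """Parse a published Location string such as ``"MA:14-36;mi:51-72"``.

    Explicit ``5p``/``3p`` tags name the arm directly; ``MA`` (major) / ``mi``
    (minor) tags carry the miRBase arm ranking, with the arm itself inferred
    from span order (the span starting first is the 5p arm).
    """
    spans = []
    for part in location.split(";"):
        m = _LOC_PART.match(part.strip())
        if not m:
            raise ValueError(f"{premirna_id}: cannot parse location part {part!r}")
        tag, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        spans.append((tag, start, end))
    spans.sort(key=lambda t: t[1])
    out = []
    for i, (tag, start, end) in enumerate(spans):
        if tag in ("5p", "3p"):
            arm = tag
            major = True if len(spans) == 1 else None
        else:
            if len(spans) != 2:
                raise ValueError(f"{premirna_id}: MA/mi tags need two spans, got {location!r}")
            arm = "5p" if i == 0 else "3p"
            major = tag == "MA"
        out.append(
            MatureAnnotation(f"{premirna_id}-{arm}", premirna_id, start, end, arm, major=major)
        )
    return out


def mirbase_major_arm(annotations: Sequence[MatureAnnotation]) -> str:
    """The miRBase-designated major arm of one hairpin's annotations.

    A single-arm annotation makes that arm the major one; for two-arm hairpins
    the ``major`` flag (MA/mi ranking) decides; without a ranking the call is
    ``"both-undetermined"``.
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    ranked = [a for a in annotations if a.major]
    if ranked:
        return ranked[0].arm
    arms = {a.arm for a in annotations}
    if len(arms) == 1:
        return next(iter(arms))
    return "both-undetermined"


def write_hairpin_fasta(hairpins: Mapping[str, PreMiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hp in hairpins.values():
            fh.write(f">{hp.id}\n{hp.sequence}\n")
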