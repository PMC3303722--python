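"""End-to-end orchestration of the two-library isomiR analysis.

Maps both collapsed libraries onto the hairpin reference, assigns isomiRs,
detects opposite-arm matures from the leftovers, and derives every summary
the analysis produces: per-mature expression, per-hairpin arm-count table,
arm-ratio records and preference calls, 3' addition tables, the categorical
KS screen, and the between-library normalization model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import armratio, kstest
from .additions import AdditionTable, combine_addition_tables, tabulate_additions
from .mapping import (
    DetectedArm,
    IsomiR,
    MappedRead,
    arm_expression,
    assign_isomirs,
    detect_opposite_arm,
    expression_table,
    isomir_frame,
    map_library,
)
from .mirbase import MatureAnnotation, PreMiRNA, mirbase_major_arm, write_annotation_tsv
from .normalize import NormalizationModel, fit_normalization
from .preprocess import Library

logger = logging.getLogger(__name__)


@dataclass
class LibraryResult:
    """Per-library mapping products and conservation bookkeeping."""

    library: Library
    mapped: list[MappedRead]
    unmapped_count: float
    isomirs: list[IsomiR]
    unassigned_count: float
    detected: list[DetectedArm]
    additions: AdditionTable
    expression: pd.DataFrame

    @property
    def assigned_count(self) -> float:
        return sum(i.count for i in self.isomirs)


@dataclass
class PipelineResult:
    labels: tuple[str, str]
    libs: dict[str, LibraryResult]
    annotations: list[MatureAnnotation]  # reference + merged detected
    detected_merged: list[MatureAnnotation]
    detected_crosstab: dict[str, list[str]]  # "a_only" / "b_only" / "shared" -> hairpin-arm keys
    arm_counts: pd.DataFrame  # premirna_id, N5p, N3p, T5p, T3p
    arm_table: pd.DataFrame  # arm_ratios output
    preference_calls: pd.DataFrame
    additions_combined: pd.DataFrame
    ks: pd.DataFrame
    normalization: NormalizationModel | None
    isomir_table: pd.DataFrame

    def conservation(self, label: str) -> tuple[float, float]:
        """(accounted reads, library total_used) for a conservation check."""
        lr = self.libs[label]
        return (
            lr.assigned_count + lr.unassigned_count + lr.unmapped_count,
            float(lr.library.total_used),
        )


def _process_library(
    library: Library,
    hairpins: Mapping[str, PreMiRNA],
    annotations: Sequence[MatureAnnotation],
    *,
    max_start_offset: int,
    max_end_offset: int,
    min_trim_len: int,
    split_multihits: bool,
    detect: bool,
    detect_min_count: float,
) -> tuple[list[MappedRead], float, list[IsomiR], list[MappedRead], list[DetectedArm]]:
    mapped, unmapped = map_library(
        library, hairpins, min_trim_len=min_trim_len, split_multihits=split_multihits
    )
    unmapped_count = sum(r.count for r in unmapped)
    isomirs, unassigned = assign_isomirs(
        mapped, annotations, max_start_offset=max_start_offset, max_end_offset=max_end_offset
    )
    detected: list[DetectedArm] = []
    if detect:
        detected = detect_opposite_arm(
            unassigned, annotations, hairpins, min_count=detect_min_count
        )
    return mapped, unmapped_count, isomirs, unassigned, detected


def run_pipeline(
    hairpins: Mapping[str, PreMiRNA],
    annotations: Sequence[MatureAnnotation],
    lib_a: Library,
    lib_b: Library,
    *,
    labels: tuple[str, str] | None = None,
    max_start_offset: int = 2,
    max_end_offset: int = 5,
    min_trim_len: int = 18,
    split_multihits: bool = False,
    detect: bool = True,
    detect_min_count: float = 2,
    min_arm_count: int = 10,
    fc_threshold: float = 3.0,
    ks_min_types: int = 8,
    ks_min_reads: float = 1000,
    ks_alpha: float = 0.001,
    normalize: bool = True,
) -> PipelineResult:
    """Run the full two-library analysis.

    ``labels`` name the two libraries in output columns; they default to the
    library names, with "N"/"T" (normal/tumor) being the conventional pair.
    """
    labels = labels or (lib_a.name or "N", lib_b.name or "T")
    la, lb = labels

    staged = {}
    for label, lib in ((la, lib_a), (lb, lib_b)):
        staged[label] = _process_library(
            lib,
            hairpins,
            annotations,
            max_start_offset=max_start_offset,
            max_end_offset=max_end_offset,
            min_trim_len=min_trim_len,
            split_multihits=split_multihits,
            detect=detect,
            detect_min_count=detect_min_count,
        )

    # merge per-library detections into one annotation set; on a span
    # disagreement the higher-count defining read wins
    best: dict[tuple[str, str], DetectedArm] = {}
    seen_in: dict[tuple[str, str], set[str]] = {}
    for label in (la, lb):
        for det in staged[label][4]:
            key = (det.annotation.premirna_id, det.annotation.arm)
            seen_in.setdefault(key, set()).add(label)
            if key not in best or det.defining_count > best[key].defining_count:
                best[key] = det
    detected_merged = [best[key].annotation for key in sorted(best)]
    crosstab = {"a_only": [], "b_only": [], "shared": []}
    for key in sorted(seen_in):
        libs_seen = seen_in[key]
        bucket = "shared" if len(libs_seen) == 2 else ("a_only" if la in libs_seen else "b_only")
        crosstab[bucket].append(f"{key[0]}:{key[1]}")

    all_annotations = list(annotations) + detected_merged

    lib_results: dict[str, LibraryResult] = {}
    for label, lib in ((la, lib_a), (lb, lib_b)):
        mapped, unmapped_count, isomirs, unassigned, _ = staged[label]
        if detected_merged:
            extra, unassigned = assign_isomirs(
                unassigned,
                detected_merged,
                max_start_offset=max_start_offset,
                max_end_offset=max_end_offset,
            )
            isomirs = sorted(
                isomirs + extra, key=lambda i: (i.mature_id, i.start_offset, i.end_offset)
            )
        lib_results[label] = LibraryResult(
            library=lib,
            mapped=mapped,
            unmapped_count=unmapped_count,
            isomirs=isomirs,
            unassigned_count=sum(mr.count for mr in unassigned),
            detected=staged[label][4],
            additions=tabulate_additions(mapped),
            expression=expression_table(isomirs),
        )

    # per-hairpin per-arm counts in arm-ratio layout (A -> "N5p"..., B -> "T...")
    arms_a = arm_expression(lib_results[la].isomirs, all_annotations)
    arms_b = arm_expression(lib_results[lb].isomirs, all_annotations)
    hairpin_ids = sorted({hid for hid, _ in set(arms_a) | set(arms_b)})
    arm_counts = pd.DataFrame(
        {
            "premirna_id": hairpin_ids,
            "N5p": [arms_a.get((h, "5p"), 0.0) for h in hairpin_ids],
            "N3p": [arms_a.get((h, "3p"), 0.0) for h in hairpin_ids],
            "T5p": [arms_b.get((h, "5p"), 0.0) for h in hairpin_ids],
            "T3p": [arms_b.get((h, "3p"), 0.0) for h in hairpin_ids],
        }
    )
    arm_table = armratio.arm_ratios(
        arm_counts, min_count=min_arm_count, fc_threshold=fc_threshold
    )
    by_hairpin: dict[str, list[MatureAnnotation]] = {}
    for ann in annotations:  # miRBase ranking comes from the reference set only
        by_hairpin.setdefault(ann.premirna_id, []).append(ann)
    major = {hid: mirbase_major_arm(anns) for hid, anns in by_hairpin.items()}
    calls = armratio.arm_preference_calls(arm_counts, major, lib_codes=(la, lb))

    ks = kstest.screen_all(
        lib_results[la].isomirs,
        lib_results[lb].isomirs,
        min_types=ks_min_types,
        min_reads=ks_min_reads,
        alpha=ks_alpha,
    )

    model = None
    if normalize:
        try:
            model = fit_normalization(lib_results[la].expression, lib_results[lb].expression)
        except ValueError as exc:
            logger.warning("normalization skipped: %s", exc)

    return PipelineResult(
        labels=labels,
        libs=lib_results,
        annotations=all_annotations,
        detected_merged=detected_merged,
        detected_crosstab=crosstab,
        arm_counts=arm_counts,
        arm_table=arm_table,
        preference_calls=armratio.calls_frame(calls),
        additions_combined=combine_addition_tables(
            lib_results[la].additions, lib_results[lb].additions, labels=labels
        ),
        ks=ks,
        normalization=model,
        isomir_table=isomir_frame(
            {la: lib_results[la].isomirs, lb: lib_results[lb].isomirs}
        ),
    )


def write_results(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the pipeline's tables as TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "isomirs": outdir / "isomirs.tsv",
        "arm_ratios": outdir / "arm_ratios.tsv",
        "preference_calls": outdir / "arm_preference_calls.tsv",
        "additions": outdir / "addition_fragments.tsv",
        "ks": outdir / "isomir_ks.tsv",
        "detected": outdir / "detected_annotations.tsv",
    }
    result.isomir_table.to_csv(paths["isomirs"], sep="\t", index=False)
    armratio.format_arm_ratio_table(result.arm_table).to_csv(
        paths["arm_ratios"], sep="\t", index=False
    )
    result.preference_calls.to_csv(paths["preference_calls"], sep="\t", index=False)
    result.additions_combined.to_csv(paths["additions"], sep="\t", index=False)
    result.ks.to_csv(paths["ks"], sep="\t", index=False)
    write_annotation_tsv(result.detected_merged, paths["detected"])
    return paths
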