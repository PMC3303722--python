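"""5p/3p arm-selection ratios, fold changes and arm-preference calls.

For each hairpin the per-arm expression (summed isomiR counts) in two
libraries N and T gives within-library arm ratios ``Ratio_N53p = N5p/N3p``
and ``Ratio_T53p = T5p/T3p``; their fold change (larger ratio over smaller)
measures how strongly arm selection differs between libraries.  Hairpins
with any arm count below 10 are excluded, and a fold change above 3 flags a
significant arm-selection shift.  Two further classifications compare the
observed major arm against the miRBase-designated major arm and between the
two libraries (a tissue switch).

Ratios use raw within-library counts: any monotone per-library scaling
(depth normalization included) cancels inside a within-library ratio.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["N5p", "N3p", "T5p", "T3p"]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding at report precision (banker-free)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1), np.where(num > 0, np.inf, np.nan))


def arm_ratios(
    counts: pd.DataFrame,
    *,
    min_count: int = 10,
    fc_threshold: float = 3.0,
) -> pd.DataFrame:
    """Compute per-hairpin arm ratios and between-library fold changes.

    ``counts`` needs columns premirna_id, N5p, N3p, T5p, T3p (libraries
    A = "N" and B = "T").  Ratios and fold change are kept at full precision;
    use :func:`format_arm_ratio_table` for report rounding.  A zero
    denominator yields an infinite ratio, which is excluded from the
    significance call; ``passes_count_filter`` requires every one of the four
    counts to reach ``min_count``.
    """
    df = counts.copy()
    for col in COUNT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"counts table missing column {col!r}")
    n5, n3 = df["N5p"].to_numpy(float), df["N3p"].to_numpy(float)
    t5, t3 = df["T5p"].to_numpy(float), df["T3p"].to_numpy(float)
    ratio_a = _ratio(n5, n3)
    ratio_b = _ratio(t5, t3)
    hi = np.maximum(ratio_a, ratio_b)
    lo = np.minimum(ratio_a, ratio_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / np.where(lo > 0, lo, 1), np.where(hi > 0, np.inf, np.nan))
    df["ratio_a"] = ratio_a
    df["ratio_b"] = ratio_b
    df["fold_change"] = fold
    df["passes_count_filter"] = (
        (n5 >= min_count) & (n3 >= min_count) & (t5 >= min_count) & (t3 >= min_count)
    )
    df["significant"] = (
        df["passes_count_filter"] & np.isfinite(fold) & (fold > fc_threshold)
    )
    return df


def format_arm_ratio_table(records: pd.DataFrame) -> pd.DataFrame:
    """Report-precision copy: ratios to 4 decimals, fold change to 2 (half-up)."""
    out = records.copy()
    for col in ("ratio_a", "ratio_b"):
        out[col] = out[col].map(lambda v: round_half_up(v, 4))
    out["fold_change"] = out["fold_change"].map(lambda v: round_half_up(v, 2))
    return out


def _major_arm(c5: float, c3: float) -> str:
    if c5 > c3:
        return "5p"
    if c3 > c5:
        return "3p"
    return "tie"


@dataclass
class ArmPreferenceCall:
    """Arm-preference classification of one hairpin."""

    premirna_id: str
    major_arm_a: str  # 5p / 3p / tie
    major_arm_b: str
    mirbase_major_arm: str  # 5p / 3p / both-undetermined
    exch_label: str  # library codes whose observed major arm contradicts miRBase
    tissue_switch: bool


def arm_preference_calls(
    counts: pd.DataFrame,
    mirbase_major: Mapping[str, str] | None = None,
    *,
    lib_codes: tuple[str, str] = ("N", "T"),
) -> list[ArmPreferenceCall]:
    """Observed-major-arm calls per hairpin, against miRBase and between libraries.

    Per library the observed major arm is the arm with the strictly larger
    count; a tie contributes nothing to either classification.  The exchange
    label collects the codes of libraries whose observed major arm contradicts
    the miRBase major arm (joined with ";", library A first); the tissue
    switch flag is set when the two libraries have different, non-tied major
    arms.
    """
    mirbase_major = mirbase_major or {}
    calls: list[ArmPreferenceCall] = []
    for row in counts.itertuples(index=False):
        major_a = _major_arm(row.N5p, row.N3p)
        major_b = _major_arm(row.T5p, row.T3p)
        if "tie" in (major_a, major_b):
            logger.info("hairpin %s: tied arm counts in at least one library", row.premirna_id)
        annotated = mirbase_major.get(row.premirna_id, "both-undetermined")
        codes = []
        if annotated in ("5p", "3p"):
            if major_a != "tie" and major_a != annotated:
                codes.append(lib_codes[0])
            if major_b != "tie" and major_b != annotated:
                codes.append(lib_codes[1])
        calls.append(
            ArmPreferenceCall(
                premirna_id=row.premirna_id,
                major_arm_a=major_a,
                major_arm_b=major_b,
                mirbase_major_arm=annotated,
                exch_label=";".join(codes),
                tissue_switch=(
                    major_a != "tie" and major_b != "tie" and major_a != major_b
                ),
            )
        )
    return calls


def mirbase_consistency(
    counts: pd.DataFrame,
    mirbase_major: Mapping[str, str],
    *,
    lib_codes: tuple[str, str] = ("N", "T"),
) -> list[ArmPreferenceCall]:
    """Arm-preference calls against the miRBase-designated major arm."""
    return arm_preference_calls(counts, mirbase_major, lib_codes=lib_codes)


def tissue_switch_calls(counts: pd.DataFrame) -> list[ArmPreferenceCall]:
    """Arm-preference calls between the two libraries (tissue switch)."""
    return arm_preference_calls(counts, None)


def calls_frame(calls: Sequence[ArmPreferenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "premirna_id": c.premirna_id,
                "major_arm_a": c.major_arm_a,
                "major_arm_b": c.major_arm_b,
                "mirbase_major_arm": c.mirbase_major_arm,
                "exch_label": c.exch_label,
                "tissue_switch": c.tissue_switch,
            }
            for c in calls
        ],
        columns=[
            "premirna_id",
            "major_arm_a",
            "major_arm_b",
            "mirbase_major_arm",
            "exch_label",
            "tissue_switch",
        ],
    )
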