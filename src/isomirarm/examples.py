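"""Published per-arm read-count tables from a paired gastric study.

A paired normal (N) / tumor (T) gastric small-RNA sequencing study reported
per-hairpin 5p/3p read counts in three tables: ten hairpins with strongly
inconsistent 5p/3p expression ratios between tissues, twenty-two hairpins
whose observed major arm contradicts the miRBase arm ranking, and five
hairpins whose major arm switches between the two tissues.  These counts
are the canonical worked example for the arm-ratio analysis: each row is
(pre-miRNA id, miRBase location string, N5p, N3p, T5p, T3p).

Location strings use the published encoding: explicit ``5p:``/``3p:`` tags,
or ``MA:``/``mi:`` for the miRBase major/minor ranking with the arm implied
by span order.
"""
from __future__ import annotations

import pandas as pd

from .mirbase import mirbase_major_arm, parse_location

#: hairpins with >3-fold inconsistent 5p/3p arm ratios between tissues
ARM_RATIO_ROWS: list[tuple[str, str, int, int, int, int]] = [
    ("hsa-mir-17", "MA:14-36;mi:51-72", 4767, 2266, 6656, 425),
    ("hsa-mir-511-1", "5p:16-36", 39, 903, 53, 147),
    ("hsa-mir-511-2", "5p:16-36", 39, 903, 53, 147),
    ("hsa-mir-423", "5p:17-39;3p:53-75", 20920, 8945, 1708, 6266),
    ("hsa-mir-30c-1", "MA:17-39;mi:56-77", 67040, 50, 8685, 64),
    ("hsa-mir-135b", "MA:16-38;mi:55-76", 360, 19, 171, 99),
    ("hsa-mir-376a-1", "mi:7-28;MA:44-64", 1646, 14, 569, 54),
    ("hsa-mir-376a-2", "3p:50-70", 428, 14, 99, 54),
    ("hsa-mir-335", "MA:16-38;mi:52-73", 3509, 110, 418, 264),
    ("hsa-mir-30b", "MA:17-38;mi:55-76", 50988, 51, 3931, 89),
]

#: hairpins whose observed major arm contradicts the miRBase ranking
ARM_EXCHANGE_ROWS: list[tuple[str, str, int, int, int, int]] = [
    ("hsa-mir-1277", "3p:47-68", 354, 172, 201, 56),
    ("hsa-mir-376a-2", "3p:50-70", 428, 14, 99, 54),
    ("hsa-mir-495", "3p:50-71", 35, 19, 12, 5),
    ("hsa-mir-1303", "3p:52-73", 19, 73, 12, 10),
    ("hsa-mir-1306", "3p:55-72", 94, 0, 31, 0),
    ("hsa-mir-496", "3p:56-77", 27, 0, 50, 0),
    ("hsa-mir-561", "3p:61-82", 231, 0, 40, 0),
    ("hsa-mir-659", "3p:61-82", 123, 0, 56, 0),
    ("hsa-mir-376b", "3p:62-83", 106, 9, 32, 83),
    ("hsa-mir-1307", "3p:80-101", 3512, 2369, 2002, 3544),
    ("hsa-mir-1273c", "5p:10-31", 0, 53, 0, 50),
    ("hsa-mir-511-1", "5p:16-36", 39, 903, 53, 147),
    ("hsa-mir-511-2", "5p:16-36", 39, 903, 53, 147),
    ("hsa-mir-1247", "5p:40-61", 67, 237, 17, 41),
    ("hsa-mir-374a", "MA:12-33;mi:42-63", 2275, 36122, 2017, 35147),
    ("hsa-mir-500a", "MA:13-35;mi:52-73", 215, 1907, 72, 1834),
    ("hsa-mir-625", "MA:15-35;mi:52-73", 333, 576, 87, 206),
    ("hsa-mir-136", "MA:15-37;mi:49-70", 1328, 621, 530, 652),
    ("hsa-mir-664", "mi:11-34;MA:49-71", 913, 271, 398, 98),
    ("hsa-mir-144", "mi:15-36;MA:52-71", 12406, 441, 1209, 113),
    ("hsa-mir-493", "mi:16-37;MA:57-78", 254, 248, 1744, 727),
    ("hsa-mir-376a-1", "mi:7-28;MA:44-64", 1646, 14, 569, 54),
]

#: hairpins whose major arm switches between normal and tumor tissue
TISSUE_SWITCH_ROWS: list[tuple[str, str, int, int, int, int]] = [
    ("hsa-mir-136", "MA:15-37;mi:49-70", 1328, 621, 530, 652),
    ("hsa-mir-361", "5p:6-27;3p:45-67", 1651, 2493, 1451, 1024),
    ("hsa-mir-423", "5p:17-39;3p:53-75", 20920, 8945, 1708, 6266),
    ("hsa-mir-376b", "3p:62-83", 106, 9, 32, 83),
    ("hsa-mir-1307", "3p:80-101", 3512, 2369, 2002, 3544),
]


def counts_frame(rows: list[tuple[str, str, int, int, int, int]]) -> pd.DataFrame:
    """Arm-count table (premirna_id, N5p, N3p, T5p, T3p) from example rows."""
    return pd.DataFrame(
        [(r[0], r[2], r[3], r[4], r[5]) for r in rows],
        columns=["premirna_id", "N5p", "N3p", "T5p", "T3p"],
    )


def major_arms(rows: list[tuple[str, str, int, int, int, int]]) -> dict[str, str]:
    """miRBase-designated major arm per hairpin, from the location strings."""
    return {
        premirna_id: mirbase_major_arm(parse_location(premirna_id, location))
        for premirna_id, location, *_ in rows
    }
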