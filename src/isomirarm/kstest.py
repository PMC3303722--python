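"""Categorical two-sample Kolmogorov-Smirnov comparison of isomiR patterns.

For one mature miRNA observed in two libraries, the union of its isomiR
variants — distinct (start offset, end offset) pairs — forms an ordered
categorical axis: types are sorted by ascending start offset then end
offset (the natural 5'-to-3' reading) and numbered 1..K.  Each library's
relative-abundance vector over that axis yields an empirical CDF, and the
KS statistic D is the maximum absolute CDF difference.  The p-value uses
the asymptotic two-sample Kolmogorov distribution with reads as the sample
units: effective size n_e = n_a*n_b/(n_a+n_b) and
lambda = (sqrt(n_e) + 0.12 + 0.11/sqrt(n_e)) * D.

With read counts in the thousands this treats every read as an independent
observation of a multinomial type, which makes the test anticonservative
for overdispersed data; screening therefore also requires more than eight
isomiR types and more than 1000 reads in both libraries, and a stringent
raw p < 0.001 cutoff is used by default (no multiplicity correction; a
Bonferroni option is available).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .mapping import IsomiR


@dataclass
class IsomiRTypeTable:
    """Union isomiR-type table for one mature miRNA in two libraries."""

    mature_id: str
    types: list[tuple[int, int]]  # canonical order: ascending (start, end) offset
    count_a: np.ndarray
    count_b: np.ndarray

    @property
    def k(self) -> int:
        return len(self.types)

    @property
    def type_ids(self) -> list[int]:
        return list(range(1, self.k + 1))

    @property
    def n_a(self) -> float:
        return float(self.count_a.sum())

    @property
    def n_b(self) -> float:
        return float(self.count_b.sum())

    @property
    def rel_a(self) -> np.ndarray:
        return self.count_a / self.n_a if self.n_a > 0 else np.zeros(self.k)

    @property
    def rel_b(self) -> np.ndarray:
        return self.count_b / self.n_b if self.n_b > 0 else np.zeros(self.k)


@dataclass
class KSResult:
    mature_id: str
    d_stat: float
    p_value: float
    n_effective: float
    k: int
    n_a: float
    n_b: float
    eligible: bool
    significant: bool


def build_type_table(
    isomirs_a: Sequence[IsomiR], isomirs_b: Sequence[IsomiR], mature_id: str | None = None
) -> IsomiRTypeTable:
    """Union the two libraries' isomiRs of one mature into an ordered table.

    Types present in only one library get a zero count in the other.  Raises
    if both collections are empty or reference different matures.
    """
    ids = {i.mature_id for i in isomirs_a} | {i.mature_id for i in isomirs_b}
    if not ids:
        raise ValueError("both isomiR collections are empty")
    if len(ids) > 1:
        raise ValueError(f"isomiRs reference multiple matures: {sorted(ids)}")
    mid = mature_id or next(iter(ids))
    ca: dict[tuple[int, int], float] = defaultdict(float)
    cb: dict[tuple[int, int], float] = defaultdict(float)
    for iso in isomirs_a:
        ca[iso.offsets] += iso.count
    for iso in isomirs_b:
        cb[iso.offsets] += iso.count
    types = sorted(set(ca) | set(cb))
    return IsomiRTypeTable(
        mature_id=mid,
        types=types,
        count_a=np.array([ca.get(t, 0.0) for t in types]),
        count_b=np.array([cb.get(t, 0.0) for t in types]),
    )


def ks_statistic(table: IsomiRTypeTable) -> float:
    """Max absolute difference of cumulative relative abundances."""
    return float(np.abs(np.cumsum(table.rel_a) - np.cumsum(table.rel_b)).max())


def kolmogorov_sf(lam: float) -> float:
    """Survival function of the Kolmogorov distribution, Q(lambda)."""
    return float(special.kolmogorov(lam))


def ks_compare(
    table: IsomiRTypeTable,
    *,
    alpha: float = 0.001,
    min_types: int = 8,
    min_reads: float = 1000,
) -> KSResult:
    """Categorical two-sample KS test on one type table.

    Eligibility requires strictly more than ``min_types`` isomiR types and
    strictly more than ``min_reads`` reads in both libraries; the
    ``significant`` flag is only set for eligible miRNAs with p < ``alpha``.
    """
    d = ks_statistic(table)
    n_a, n_b = table.n_a, table.n_b
    if n_a > 0 and n_b > 0:
        n_e = n_a * n_b / (n_a + n_b)
        lam = (math.sqrt(n_e) + 0.12 + 0.11 / math.sqrt(n_e)) * d
        p = min(1.0, max(0.0, kolmogorov_sf(lam)))
    else:
        n_e, p = 0.0, float("nan")
    eligible = table.k > min_types and n_a > min_reads and n_b > min_reads
    return KSResult(
        mature_id=table.mature_id,
        d_stat=d,
        p_value=p,
        n_effective=n_e,
        k=table.k,
        n_a=n_a,
        n_b=n_b,
        eligible=eligible,
        significant=bool(eligible and p < alpha),
    )


def screen_all(
    isomirs_a: Iterable[IsomiR],
    isomirs_b: Iterable[IsomiR],
    *,
    min_types: int = 8,
    min_reads: float = 1000,
    alpha: float = 0.001,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """KS-screen every mature observed in either library.

    All matures are reported with eligibility and significance flags; with
    ``bonferroni`` the alpha is divided by the number of eligible tests.
    """
    by_mature: dict[str, tuple[list[IsomiR], list[IsomiR]]] = defaultdict(lambda: ([], []))
    for iso in isomirs_a:
        by_mature[iso.mature_id][0].append(iso)
    for iso in isomirs_b:
        by_mature[iso.mature_id][1].append(iso)
    tables = [build_type_table(a, b, mature_id=mid) for mid, (a, b) in sorted(by_mature.items())]
    n_eligible = sum(
        1 for t in tables if t.k > min_types and t.n_a > min_reads and t.n_b > min_reads
    )
    effective_alpha = alpha / max(1, n_eligible) if bonferroni else alpha
    results = [
        ks_compare(t, alpha=effective_alpha, min_types=min_types, min_reads=min_reads)
        for t in tables
    ]
    df = pd.DataFrame(
        [
            {
                "mature_id": r.mature_id,
                "k": r.k,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "d_stat": r.d_stat,
                "p_value": r.p_value,
                "eligible": r.eligible,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["mature_id", "k", "n_a", "n_b", "d_stat", "p_value", "eligible", "significant"],
    )
    df.attrs["n_eligible"] = int(df["eligible"].sum()) if len(df) else 0
    df.attrs["n_significant"] = int(df["significant"].sum()) if len(df) else 0
    return df


def comparison_plot(table: IsomiRTypeTable, result: KSResult, path: str | Path) -> Path:
    """Write a per-miRNA comparison figure: abundance bars and CDF curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_bar, ax_cdf) = plt.subplots(1, 2, figsize=(9, 3.5))
    ids = table.type_ids
    width = 0.4
    ax_bar.bar([i - width / 2 for i in ids], table.rel_a, width=width, label="library A")
    ax_bar.bar([i + width / 2 for i in ids], table.rel_b, width=width, label="library B")
    ax_bar.set_xlabel("isomiR type ID")
    ax_bar.set_ylabel("relative abundance")
    ax_bar.set_title(table.mature_id)
    ax_bar.legend(frameon=False, fontsize=8)

    ax_cdf.step(ids, np.cumsum(table.rel_a), where="post", label="library A")
    ax_cdf.step(ids, np.cumsum(table.rel_b), where="post", label="library B")
    ax_cdf.set_xlabel("isomiR type ID")
    ax_cdf.set_ylabel("cumulative abundance")
    ax_cdf.set_title(f"D = {result.d_stat:.4f}, p = {result.p_value:.3g}")
    ax_cdf.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
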