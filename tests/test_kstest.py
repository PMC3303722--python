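import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isomirarm.kstest import (
    IsomiRTypeTable,
    build_type_table,
    comparison_plot,
    ks_compare,
    ks_statistic,
    screen_all,
)
from isomirarm.mapping import IsomiR


def _isomirs(offset_counts, mature="miR-x"):
    return [
        IsomiR(mature, "hp-x", so, eo, "A" * 20, cnt)
        for (so, eo), cnt in offset_counts.items()
    ]


def _table(count_a, count_b, mature="miR-x"):
    types = [(0, i) for i in range(len(count_a))]
    return IsomiRTypeTable(mature, types, np.asarray(count_a, float), np.asarray(count_b, float))


def kolmogorov_series(lam, terms=100000):
    """Direct evaluation of Q(lambda) = 2 sum_{j>=1} (-1)^(j-1) exp(-2 j^2 lam^2)."""
    if lam <= 0:
        return 1.0
    total = 0.0
    for j in range(1, terms + 1):
        term = (-1) ** (j - 1) * math.exp(-2.0 * j * j * lam * lam)
        total += term
        if abs(term) < 1e-18:
            break
    return min(1.0, max(0.0, 2.0 * total))


class TestBuildTypeTable:
    def test_union_order_and_abundances(self):
        a = _isomirs({(0, 0): 90, (1, 0): 10})
        b = _isomirs({(0, 0): 50, (0, -1): 50})
        table = build_type_table(a, b)
        assert table.types == [(0, -1), (0, 0), (1, 0)]
        assert table.type_ids == [1, 2, 3]
        assert table.rel_a.tolist() == pytest.approx([0.0, 0.9, 0.1])
        assert table.rel_b.tolist() == pytest.approx([0.5, 0.5, 0.0])
        assert table.rel_a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_collections_identical_abundances(self):
        a = _isomirs({(0, 0): 7, (0, 1): 3})
        table = build_type_table(a, _isomirs({(0, 0): 7, (0, 1): 3}))
        np.testing.assert_allclose(table.rel_a, table.rel_b)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_type_table([], [])

    def test_mixed_matures_rejected(self):
        with pytest.raises(ValueError, match="multiple matures"):
            build_type_table(_isomirs({(0, 0): 1}), _isomirs({(0, 0): 1}, mature="miR-y"))


class TestKsCompare:
    def test_identical_distributions(self):
        r = ks_compare(_table([50, 30, 20], [500, 300, 200]))
        assert r.d_stat == 0.0
        assert r.p_value == 1.0

    def test_maximal_separation(self):
        r = ks_compare(_table([5000, 0], [0, 5000]))
        assert r.d_stat == 1.0
        assert r.p_value < 1e-100

    def test_d_and_p_agree_with_series_oracle(self):
        table = _table([1000, 1000], [200, 1800])
        r = ks_compare(table)
        assert r.d_stat == pytest.approx(0.4)
        n_e = 2000 * 2000 / 4000
        lam = (math.sqrt(n_e) + 0.12 + 0.11 / math.sqrt(n_e)) * 0.4
        assert abs(r.p_value - kolmogorov_series(lam)) < 1e-6

    @pytest.mark.parametrize("shift", [10, 20, 40, 80])
    def test_small_d_p_values_match_series_to_1e6(self, shift):
        table = _table([1000, 1000], [1000 - shift, 1000 + shift])
        r = ks_compare(table)
        lam = (math.sqrt(r.n_effective) + 0.12 + 0.11 / math.sqrt(r.n_effective)) * r.d_stat
        assert abs(r.p_value - kolmogorov_series(lam)) < 1e-6

    def test_p_monotone_decreasing_in_d(self):
        ps = [
            ks_compare(_table([1000, 1000], [1000 - s, 1000 + s])).p_value
            for s in (10, 30, 60, 120, 240)
        ]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_eligibility_strict_inequalities(self):
        # exactly 8 types: ineligible; 9 types: eligible
        eight = ks_compare(_table([2000] * 8, [2000] * 8))
        nine = ks_compare(_table([2000] * 9, [2000] * 9))
        assert not eight.eligible and nine.eligible
        # exactly 1000 reads: ineligible
        at_floor = ks_compare(_table([100] * 10, [2000] * 10))
        assert at_floor.n_a == 1000 and not at_floor.eligible

    @settings(max_examples=60, derandomize=True)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 500)), min_size=2, max_size=12
        ).filter(lambda c: sum(a for a, _ in c) > 0 and sum(b for _, b in c) > 0),
        scale=st.integers(2, 50),
    )
    def test_d_bounded_and_scale_invariant(self, counts, scale):
        a = [c[0] for c in counts]
        b = [c[1] for c in counts]
        d = ks_statistic(_table(a, b))
        assert 0.0 <= d <= 1.0
        assert ks_statistic(_table([scale * v for v in a], b)) == pytest.approx(d)

    def test_canonical_order_deterministic_across_runs(self):
        a = _isomirs({(0, 0): 5, (-1, 2): 3, (2, -3): 2, (0, -1): 4})
        b = _isomirs({(1, 1): 6, (0, 0): 1})
        t1 = build_type_table(a, b)
        t2 = build_type_table(list(reversed(a)), list(reversed(b)))
        assert t1.types == t2.types == sorted(t1.types)
        assert ks_statistic(t1) == ks_statistic(t2)


class TestScreenAll:
    def _cohort(self, rng, n_null=10, n_shift=3, n=5000):
        base = np.array([0.30, 0.15, 0.12, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03])
        shifted = base.copy()
        shifted[0] -= 0.15
        shifted[7] += 0.15
        types = [(0, i - 5) for i in range(10)]
        a_list, b_list = [], []
        for i in range(n_null + n_shift):
            pb = base if i < n_null else shifted
            ca = rng.multinomial(n, base)
            cb = rng.multinomial(n, pb)
            mid = f"miR-{i:03d}"
            for t, c in zip(types, ca):
                if c:
                    a_list.append(IsomiR(mid, "hp", t[0], t[1], "A" * 20, int(c)))
            for t, c in zip(types, cb):
                if c:
                    b_list.append(IsomiR(mid, "hp", t[0], t[1], "A" * 20, int(c)))
        return a_list, b_list, n_null

    def test_shifted_patterns_detected(self, rng):
        a, b, n_null = self._cohort(rng)
        df = screen_all(a, b)
        shifted = df[df["mature_id"] >= f"miR-{n_null:03d}"]
        assert shifted["significant"].all()

    def test_summary_attrs_present(self, rng):
        a, b, _ = self._cohort(rng, n_null=2, n_shift=1)
        df = screen_all(a, b)
        assert df.attrs["n_eligible"] == len(df)
        assert df.attrs["n_significant"] == int(df["significant"].sum())

    def test_ineligible_never_significant(self):
        a = _isomirs({(0, i): 10 for i in range(-2, 3)})
        b = _isomirs({(0, i): 1000 for i in range(-2, 3)})
        df = screen_all(a, b)
        assert not df["eligible"].iloc[0] and not df["significant"].iloc[0]

    def test_bonferroni_tightens_alpha(self, rng):
        a, b, _ = self._cohort(rng, n_null=10, n_shift=0, n=2000)
        raw = screen_all(a, b, alpha=0.5)
        corrected = screen_all(a, b, alpha=0.5, bonferroni=True)
        assert corrected["significant"].sum() <= raw["significant"].sum()


def test_comparison_plot_writes_file(tmp_path):
    table = _table([900, 100], [500, 500])
    result = ks_compare(table)
    out = comparison_plot(table, result, tmp_path / "mir.png")
    assert out.exists() and out.stat().st_size > 0
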