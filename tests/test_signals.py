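"""Disproportionality statistics against direct-formula oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faers_signals.signals import (
    ContingencyTable,
    build_contingency,
    classify_signal,
    compute_bcpnn,
    compute_mgps,
    compute_prr,
    compute_ror,
    contingency_counts,
    rank_table,
    signal_metrics,
    signal_table,
)
from tests import oracles

NULL = ContingencyTable(10, 990, 100, 9900)
EXAMPLE = ContingencyTable(25, 75, 500, 9400)

cells = st.integers(min_value=1, max_value=10_000)


class TestFormulas:
    def test_null_table_is_unity(self):
        ror, _ = compute_ror(NULL)
        prr, chi2 = compute_prr(NULL)
        ic, *_ = compute_bcpnn(NULL)
        ebgm, _ = compute_mgps(NULL)
        assert ror == pytest.approx(1.0)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        assert ic == pytest.approx(0.0)
        assert ebgm == pytest.approx(1.0)

    def test_worked_example(self):
        ror, (lo, hi) = compute_ror(EXAMPLE)
        prr, chi2 = compute_prr(EXAMPLE)
        ic, *_ = compute_bcpnn(EXAMPLE)
        ebgm, ebgm05 = compute_mgps(EXAMPLE)
        assert ror == pytest.approx(6.2667, abs=1e-4)
        assert (lo, hi) == pytest.approx((3.950, 9.942), abs=1e-3)
        assert prr == pytest.approx(4.95, abs=1e-10)
        assert chi2 == pytest.approx(79.21, abs=0.005)
        assert ic == pytest.approx(2.2515, abs=1e-4)
        assert ebgm == pytest.approx(4.7619, abs=1e-4)
        assert ebgm05 == pytest.approx(3.002, abs=1e-3)

    def test_zero_a_cell_behaviour(self):
        t = ContingencyTable(0, 100, 100, 9800)
        ror, (lo, _) = compute_ror(t)
        assert math.isnan(ror) and math.isnan(lo)
        ic, e_ic, v_ic, ic025 = compute_bcpnn(t)
        assert ic == -math.inf
        assert math.isfinite(ic025) and ic025 < 0
        ebgm, ebgm05 = compute_mgps(t)
        assert ebgm == 0.0 and math.isnan(ebgm05)

    def test_degenerate_margins_not_evaluable(self):
        prr, chi2 = compute_prr(ContingencyTable(3, 0, 1, 0))
        assert math.isnan(chi2)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=300, deadline=None)
    def test_algebraic_identities(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ebgm, _ = compute_mgps(t)
        ic, *_ = compute_bcpnn(t)
        n = a + b + c + d
        assert ebgm == pytest.approx(a * n / ((a + c) * (a + b)), rel=1e-12)
        assert ic == pytest.approx(math.log2(ebgm), rel=1e-12)

    @given(a=st.integers(1, 500), k=st.integers(1, 20),
           b=st.integers(1, 5000))
    @settings(max_examples=200, deadline=None)
    def test_null_invariance(self, a, k, b):
        """Equal event rates under both drugs => every statistic is null."""
        t = ContingencyTable(a, b, k * a, k * b)
        ror, _ = compute_ror(t)
        prr, chi2 = compute_prr(t)
        ic, *_ = compute_bcpnn(t)
        ebgm, _ = compute_mgps(t)
        assert ror == pytest.approx(1.0, rel=1e-12)
        assert prr == pytest.approx(1.0, rel=1e-12)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert ebgm == pytest.approx(1.0, rel=1e-12)
        m = signal_metrics(t)
        assert not m.any_signal

    @given(a=st.integers(1, 200), b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_ror_prr_strictly_increasing_in_a(self, a, b, c, d):
        t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
        assert compute_ror(t2)[0] > compute_ror(t1)[0]
        assert compute_prr(t2)[0] > compute_prr(t1)[0]

    @given(a=st.integers(1, 200), db=st.integers(0, 5000),
           dc=st.integers(0, 5000), d=cells)
    @settings(max_examples=200, deadline=None)
    def test_ic_ebgm_increasing_when_margins_dominated(self, a, db, dc, d):
        """IC and EBGM rise with a while a is a minority of both margins.

        Unlike ROR/PRR this is not global: an extra co-occurrence also grows
        the event and drug margins, so for tables where ``a`` dominates a
        margin the relative reporting ratio can stall or fall.  With
        b, c >= 3a (the regime of a large reporting database) the increase
        is strict: d ln(EBGM)/da = 1/a + 1/n - 1/(a+b) - 1/(a+c) > 0.
        """
        b, c = 3 * a + db, 3 * a + dc
        t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
        assert compute_mgps(t2)[0] > compute_mgps(t1)[0]
        assert compute_bcpnn(t2)[0] > compute_bcpnn(t1)[0]

    def test_oracle_equivalence_random_tables(self):
        """1,000 random tables agree with the naive oracle to 10 sig digits."""
        rng = np.random.default_rng(42)
        cells = rng.integers(1, 10_001, size=(1000, 4))
        for a, b, c, d in cells.tolist():  # python ints: oracle stays exact
            t = ContingencyTable(a, b, c, d)
            ror, (lo, hi) = compute_ror(t)
            o_ror, o_lo, o_hi = oracles.ror_oracle(a, b, c, d)
            prr, chi2 = compute_prr(t)
            o_prr, o_chi2 = oracles.prr_oracle(a, b, c, d)
            ic, e_ic, v_ic, ic025 = compute_bcpnn(t)
            o_ic, o_e, o_v, o_ic025 = oracles.bcpnn_oracle(a, b, c, d)
            ebgm, ebgm05 = compute_mgps(t)
            o_ebgm, o_ebgm05 = oracles.mgps_oracle(a, b, c, d)
            for got, want in [(ror, o_ror), (lo, o_lo), (hi, o_hi),
                              (prr, o_prr), (chi2, o_chi2), (ic, o_ic),
                              (e_ic, o_e), (v_ic, o_v), (ic025, o_ic025),
                              (ebgm, o_ebgm), (ebgm05, o_ebgm05)]:
                assert got == pytest.approx(want, rel=1e-10)


class TestClassify:
    def test_null_table_fires_nothing(self):
        m = signal_metrics(NULL)
        assert not (m.ror_pos or m.prr_pos or m.bcpnn_pos or m.mgps_pos)
        assert not m.combined_signal and not m.any_signal

    def test_example_fires_ror_prr_mgps(self):
        m = signal_metrics(EXAMPLE)
        assert m.ror_pos and m.prr_pos and m.mgps_pos

    def test_min_case_gate_overrides_large_ror(self):
        flags = classify_signal(ror_lo=50.0, prr=100.0, chi2=500.0,
                                ic025=-1.0, ebgm05=1.0, n_cases=2)
        assert not flags["ror_pos"] and not flags["prr_pos"]

    def test_not_evaluable_flags_false(self):
        flags = classify_signal(float("nan"), float("nan"), float("nan"),
                                float("nan"), float("nan"), n_cases=10)
        assert not any(flags.values())


class TestContingencyConstruction:
    def test_two_report_enumeration(self, tmp_path):
        from faers_signals.ingest import CleanDataset
        ds = CleanDataset(
            reports=pd.DataFrame({"primaryid": ["1", "2"]}),
            drugs=pd.DataFrame(), events=pd.DataFrame(
                {"PRIMARYID": ["1", "2"], "PT": ["X", "Y"]}),
            therapies=pd.DataFrame(), indications=pd.DataFrame(),
            outcomes=pd.DataFrame(), target_ids=frozenset({"1"}),
            synonyms=("D",))
        t = build_contingency(ds, "X", "PT")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_duplicate_pt_rows_count_once(self):
        from faers_signals.ingest import CleanDataset
        ds = CleanDataset(
            reports=pd.DataFrame({"primaryid": ["1", "2"]}),
            drugs=pd.DataFrame(), events=pd.DataFrame(
                {"PRIMARYID": ["1", "1", "2"], "PT": ["X", "X", "Y"]}),
            therapies=pd.DataFrame(), indications=pd.DataFrame(),
            outcomes=pd.DataFrame(), target_ids=frozenset({"1"}),
            synonyms=("D",))
        assert build_contingency(ds, "X", "PT").a == 1

    def test_matches_brute_force_recount(self, dataset):
        counts = contingency_counts(dataset, "PT")
        events = list(zip(dataset.events["PRIMARYID"], dataset.events["PT"]))
        rng = np.random.default_rng(0)
        labels = rng.choice(counts.index.to_numpy(), size=8, replace=False)
        for label in labels:
            want = oracles.contingency_oracle(events, dataset.target_ids, label)
            row = counts.loc[label]
            assert (row["a"], row["b"], row["c"], row["d"]) == want

    def test_soc_level_counts_report_once_per_soc(self, dataset, soc_map):
        counts = contingency_counts(dataset, "SOC", soc_map)
        # a+c per SOC can never exceed the number of reports
        assert ((counts["a"] + counts["c"]) <= len(dataset.reports)).all()
        with pytest.raises(ValueError, match="missing from the SOC map"):
            contingency_counts(dataset, "SOC",
                               soc_map.iloc[: len(soc_map) // 2])

    def test_unknown_level_rejected(self, dataset):
        with pytest.raises(ValueError, match="unknown level"):
            contingency_counts(dataset, "HLGT")


class TestRankTable:
    def _results(self):
        df = pd.DataFrame({
            "a": [19, 20, 21, 21], "b": [1, 1, 1, 1], "c": [1, 1, 1, 1],
            "d": [1, 1, 1, 1],
            "ror": [1.0] * 4, "ror_lo": [0.5] * 4, "ror_hi": [2.0] * 4,
            "prr": [1.0] * 4, "chi2": [0.0] * 4, "ic": [0.0] * 4,
            "ic025": [-1.0] * 4, "ebgm": [1.0] * 4, "ebgm05": [0.5] * 4,
        }, index=["W", "Z", "B", "A"])
        return df

    def test_min_cases_filter(self):
        out = rank_table(self._results(), min_cases=20)
        assert set(out.index) == {"Z", "B", "A"}

    def test_tie_break_lexicographic(self):
        out = rank_table(self._results(), min_cases=0)
        assert list(out.index) == ["A", "B", "Z", "W"]

    def test_empty_input(self):
        assert rank_table(pd.DataFrame(columns=["a"]), min_cases=0).empty

    def test_unknown_sort_key(self):
        with pytest.raises(ValueError, match="sort key"):
            rank_table(self._results(), sort_key="banana")

    def test_display_rounding_half_away_from_zero(self):
        df = self._results().head(1).copy()
        df["ror"] = 2.345
        out = rank_table(df, min_cases=0)
        assert out["ror_disp"].iloc[0] == 2.35


def test_signal_table_flags_match_scalar_path(dataset):
    tbl = signal_table(dataset, "PT", min_cases=3)
    sample = tbl.sample(6, random_state=1)
    for label, row in sample.iterrows():
        m = signal_metrics(ContingencyTable(int(row["a"]), int(row["b"]),
                                            int(row["c"]), int(row["d"])))
        assert row["combined_signal"] == m.combined_signal
        assert row["any_signal"] == m.any_signal
        assert row["ror"] == pytest.approx(m.ror, rel=1e-12, nan_ok=True)
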