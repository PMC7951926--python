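"""Event aggregation, internal standardization and temporal profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

import arealrisk as ar


def ev(area, ts):
    return {"area_id": area, "timestamp": pd.Timestamp(ts)}


@pytest.fixture
def two_area_lattice():
    return ar.grid_lattice(1, 2)  # areas r0c0, r0c1


class TestAggregateEvents:
    def test_counts_per_area_year(self, two_area_lattice):
        events = [ev("r0c0", "2015-03-01 12:00")] * 3
        panel, excl = ar.aggregate_events(events, two_area_lattice, [2015])
        got = panel.set_index("area_id")["Y"]
        assert got["r0c0"] == 3 and got["r0c1"] == 0
        assert excl == 0

    def test_unknown_area_excluded_and_tallied(self, two_area_lattice):
        events = [ev("r0c0", "2015-06-01"), ev("Z", "2015-06-01")]
        panel, excl = ar.aggregate_events(events, two_area_lattice, [2015])
        assert excl == 1
        assert panel["Y"].sum() == 1

    def test_jan_first_midnight_counts_in_that_year(self, two_area_lattice):
        events = [ev("r0c0", "2016-01-01 00:00:00")]
        panel, _ = ar.aggregate_events(events, two_area_lattice, [2015, 2016])
        got = panel.set_index(["area_id", "year"])["Y"]
        assert got[("r0c0", 2016)] == 1 and got[("r0c0", 2015)] == 0

    def test_empty_event_list_warns_not_errors(self, two_area_lattice):
        with pytest.warns(UserWarning, match="empty"):
            panel, excl = ar.aggregate_events([], two_area_lattice, [2015])
        assert panel["Y"].sum() == 0 and excl == 0

    def test_permutation_invariance(self, two_area_lattice):
        rng = np.random.default_rng(0)
        events = [
            ev(rng.choice(["r0c0", "r0c1"]), f"2015-0{rng.integers(1,10)}-15")
            for _ in range(40)
        ]
        p1, _ = ar.aggregate_events(events, two_area_lattice, [2015])
        shuffled = [events[i] for i in rng.permutation(len(events))]
        p2, _ = ar.aggregate_events(shuffled, two_area_lattice, [2015])
        pd.testing.assert_frame_equal(p1, p2)

    def test_nonconsecutive_years_rejected(self, two_area_lattice):
        with pytest.raises(ValueError):
            ar.aggregate_events([], two_area_lattice, [2015, 2017])


class TestExpectedCounts:
    def test_pooled_rate_arithmetic(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "b"], "year": 2015, "Y": [2, 2], "N": [100, 300]}
        )
        out = ar.expected_counts(panel)
        assert np.allclose(out["E"], [1.0, 3.0])

    def test_y_proportional_to_n_gives_e_equal_y(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "b", "c"], "year": 2015, "Y": [1, 2, 3],
             "N": [100, 200, 300]}
        )
        out = ar.expected_counts(panel)
        assert np.allclose(out["E"], out["Y"])

    def test_two_year_pooling(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "b", "a", "b"], "year": [2015, 2015, 2016, 2016],
             "Y": [1, 1, 1, 1], "N": [100, 100, 100, 100]}
        )
        out = ar.expected_counts(panel)
        assert np.allclose(out["E"], 1.0)

    def test_sum_e_equals_sum_y(self, small_scenario):
        _, _, panel, _ = small_scenario
        assert np.isclose(panel["E"].sum(), panel["Y"].sum(), rtol=1e-12)

    def test_degenerate_rate_rejected(self):
        panel = pd.DataFrame(
            {"area_id": ["a"], "year": 2015, "Y": [0], "N": [100]}
        )
        with pytest.raises(ValueError, match="degenerate"):
            ar.expected_counts(panel)

    def test_nonpositive_population_rejected(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "b"], "year": 2015, "Y": [1, 1], "N": [100, 0]}
        )
        with pytest.raises(ValueError, match="population"):
            ar.expected_counts(panel)


class TestSir:
    def test_equal_observed_expected_gives_one(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "b"], "year": 2015, "Y": [3, 5], "E": [3.0, 5.0]}
        )
        out = ar.sir(panel)
        assert np.allclose(out["SIR"], 1.0)

    def test_hot_and_cold_classification(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "b", "c"], "year": 2015, "Y": [4, 0, 2],
             "E": [2.0, 3.0, 2.0]}
        )
        out = ar.sir(panel)
        assert np.allclose(out["SIR"], [2.0, 0.0, 1.0])
        assert list(ar.classify_sir(out["SIR"])) == ["hot", "cold", "null"]

    def test_zero_expected_identifies_cells(self):
        panel = pd.DataFrame(
            {"area_id": ["a", "b"], "year": 2015, "Y": [1, 1], "E": [1.0, 0.0]}
        )
        with pytest.raises(ValueError, match="b"):
            ar.sir(panel)

    def test_e_weighted_mean_sir_is_one(self, small_scenario):
        _, _, panel, _ = small_scenario
        weighted = (panel["SIR"] * panel["E"]).sum() / panel["E"].sum()
        assert np.isclose(weighted, 1.0, rtol=1e-12)


class TestTemporalProfile:
    def test_day_of_week_counts(self):
        # 2015-01-03 was a Saturday
        events = [ev("a", "2015-01-03 10:00")] * 5
        prof = ar.temporal_profile(events, "day_of_week")
        assert prof["Sat"] == 5
        assert prof.drop("Sat").sum() == 0
        assert list(prof.index) == ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]

    def test_hour_truncation(self):
        events = [ev("a", "2015-01-01 19:30"), ev("a", "2015-01-01 22:59")]
        prof = ar.temporal_profile(events, "hour_of_day")
        assert prof[19] == 1 and prof[22] == 1 and prof.sum() == 2
        assert len(prof) == 24

    def test_month_bins_canonical(self):
        events = [ev("a", "2015-05-10"), ev("a", "2015-05-11"), ev("a", "2015-12-01")]
        prof = ar.temporal_profile(events, "month_of_year")
        assert prof["May"] == 2 and prof["Dec"] == 1
        assert list(prof.index) == [
            "Jan", "Feb", "Mar", "Apr", "May", "Jun",
            "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
        ]

    def test_conservation_across_binnings(self):
        events = ar.simulate_events({2015: 30, 2016: 25}, ["a", "b"], seed=3)
        for binning in ("year", "month_of_year", "day_of_week", "hour_of_day"):
            assert ar.temporal_profile(events, binning).sum() == 55

    def test_unsupported_binning_rejected(self):
        with pytest.raises(ValueError):
            ar.temporal_profile([], "fortnight")


class TestStandardizationProperties:
    """Conservation laws hold for arbitrary valid panels."""

    @staticmethod
    def _panel(ys, ns):
        k = len(ys)
        return pd.DataFrame(
            {"area_id": [f"a{i}" for i in range(k)], "year": 2015,
             "Y": ys, "N": ns}
        )

    @given(
        ys=st.lists(st.integers(min_value=0, max_value=500), min_size=2,
                    max_size=30),
        ns=st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sum_e_equals_sum_y_for_any_panel(self, ys, ns):
        pops = ns.draw(
            st.lists(st.floats(min_value=1.0, max_value=1e6,
                               allow_nan=False),
                     min_size=len(ys), max_size=len(ys))
        )
        assume(sum(ys) > 0)
        panel = ar.expected_counts(self._panel(ys, pops))
        assert np.isclose(panel["E"].sum(), panel["Y"].sum(), rtol=1e-12)
        panel = ar.sir(panel)
        weighted = (panel["SIR"] * panel["E"]).sum() / panel["E"].sum()
        assert np.isclose(weighted, 1.0, rtol=1e-12)

    @given(n_events=st.integers(min_value=0, max_value=120),
           seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_profile_conservation_for_random_event_sets(self, n_events, seed):
        if n_events == 0:
            return
        events = ar.simulate_events({2016: n_events}, ["a", "b", "c"],
                                    seed=seed)
        for binning in ("year", "month_of_year", "day_of_week", "hour_of_day"):
            assert ar.temporal_profile(events, binning).sum() == n_events


class TestCsvRoundTrip:
    def test_events_and_panel(self, tmp_path, two_area_lattice):
        events = ar.simulate_events({2015: 10}, ["r0c0", "r0c1"], seed=1)
        p = tmp_path / "events.csv"
        events.to_csv(p, index=False)
        from arealrisk.standardize import read_events_csv, write_panel_csv, read_panel_csv

        back = read_events_csv(p)
        panel, _ = ar.aggregate_events(back, two_area_lattice, [2015])
        assert panel["Y"].sum() == 10
        panel["N"] = 100.0
        panel = ar.sir(ar.expected_counts(panel))
        out = tmp_path / "panel.csv"
        write_panel_csv(panel, out)
        again = read_panel_csv(out)
        assert np.allclose(again["SIR"], panel["SIR"])
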