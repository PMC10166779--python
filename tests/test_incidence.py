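"""Person-year attribution, AIR tables and Nelson-Aalen cumulative incidence."""

import numpy as np
import pytest

from lynchrisk import (
    CRC,
    cumulative_incidence,
    default_grid,
    incidence_table,
    person_years,
    single_organ,
)
from lynchrisk.cohort import organs_for_sex
from lynchrisk.incidence import AgeBand, _grid_edges

from conftest import make_carrier

GRID = default_grid()
EDGES = _grid_edges(GRID)


def brute_force_person_years(entry, stop, edges, step=1.0 / 365.0):
    """Day-resolution person-time counter (independent oracle)."""
    if stop <= entry:
        return np.zeros(len(edges) - 1)
    n_days = int(np.ceil((stop - entry) / step))
    starts = entry + step * np.arange(n_days)
    lengths = np.minimum(starts + step, stop) - starts
    bands = np.clip(np.searchsorted(edges, starts, side="right") - 1, -1, len(edges) - 1)
    py = np.zeros(len(edges) - 1)
    for b, ln in zip(bands, lengths):
        if 0 <= b < len(py):
            py[b] += ln
    return py


class TestPersonYears:
    def test_interval_arithmetic_example(self):
        py, band = person_years(make_carrier(incl=40.0, last=52.0), single_organ("colon"), GRID)
        expect = np.zeros(10)
        expect[[3, 4, 5]] = [5.0, 5.0, 2.0]  # [40,45) [45,50) [50,52)
        np.testing.assert_allclose(py, expect)
        assert band is None
        assert py.sum() == pytest.approx(12.0)

    def test_event_stops_person_time(self):
        carrier = make_carrier(incl=40.0, last=60.0,
                               events=[("colon", 47.0, "prospective")])
        py, band = person_years(carrier, single_organ("colon"), GRID)
        expect = np.zeros(10)
        expect[[3, 4]] = [5.0, 2.0]
        np.testing.assert_allclose(py, expect)
        assert band == 4  # [45,50)

    def test_grid_truncation_at_75(self):
        py, band = person_years(make_carrier(incl=73.0, last=79.0), single_organ("colon"), GRID)
        expect = np.zeros(10)
        expect[9] = 2.0
        np.testing.assert_allclose(py, expect)
        assert band is None

    def test_ineligible_carrier_contributes_nothing(self):
        carrier = make_carrier(incl=40.0, last=60.0,
                               events=[("colon", 38.0, "prevalent")])
        py, band = person_years(carrier, single_organ("colon"), GRID)
        assert py.sum() == 0.0 and band is None

    def test_event_in_other_group_organ_stops_group_time(self):
        carrier = make_carrier(incl=40.0, last=60.0,
                               events=[("rectum", 47.0, "prospective")])
        py, band = person_years(carrier, CRC, GRID)
        assert py.sum() == pytest.approx(7.0)
        assert band == 4

    def test_event_at_exactly_75_not_counted(self):
        carrier = make_carrier(incl=70.0, last=80.0,
                               events=[("colon", 75.0, "prospective")])
        py, band = person_years(carrier, single_organ("colon"), GRID)
        assert band is None
        assert py.sum() == pytest.approx(5.0)

    def test_matches_day_resolution_oracle_on_random_cohorts(self, rng):
        """Interval arithmetic vs brute-force day counting, 1000 small cohorts."""
        worst = 0.0
        for _ in range(1000):
            n = rng.integers(1, 6)
            for i in range(n):
                incl = float(rng.uniform(25.0, 80.0))
                last = incl + float(rng.uniform(0.0, 30.0))
                has_event = rng.random() < 0.3
                ev_age = float(rng.uniform(incl, last)) if has_event else np.inf
                events = (
                    [("colon", ev_age, "prospective")]
                    if has_event and ev_age > incl
                    else []
                )
                carrier = make_carrier(f"r{i}", incl=incl, last=last, events=events)
                py, _ = person_years(carrier, single_organ("colon"), GRID)
                stop = min(ev_age, last, 75.0)
                oracle = brute_force_person_years(max(incl, 25.0), stop, EDGES)
                worst = max(worst, float(np.abs(py - oracle).max()))
        assert worst <= 1.0 / 365.0 + 1e-9

    def test_partition_over_bands(self, sim_cohort):
        """Band person-years sum to the time from entry to stop, every carrier."""
        for rec in sim_cohort[:500]:
            py, _ = person_years(rec, single_organ("colon"), GRID)
            from lynchrisk import score_prospective_events

            scored = score_prospective_events(rec, single_organ("colon"))["colon"]
            if not scored.eligible:
                assert py.sum() == 0.0
                continue
            ev = scored.age_event if scored.age_event is not None else np.inf
            expect = max(
                0.0, min(ev, rec.age_last_obs, 75.0) - max(rec.age_inclusion, 25.0)
            )
            assert py.sum() == pytest.approx(expect, abs=1e-9)


class TestIncidenceTable:
    def test_hand_cohort_table(self, hand_cohort):
        """Matches the hand-computed colon person-time and event placement."""
        table = incidence_table(hand_cohort, [single_organ("colon")], GRID, by=())
        sub = table.set_index("age_lower")
        # first colon cancers: h02@47, h03@44, h07@47, h12@33 (h06 is ineligible)
        assert sub["n_events"].sum() == 4
        assert sub.loc[45.0, "n_events"] == 2
        assert sub.loc[40.0, "n_events"] == 1
        assert sub.loc[30.0, "n_events"] == 1
        # [40,45): h01 5 + h02 5 + h03 4 + h05 5 + h09 1 + h10 2.5
        assert sub.loc[40.0, "person_years"] == pytest.approx(22.5)
        # [70,75): h04 2 + h11 2
        assert sub.loc[70.0, "person_years"] == pytest.approx(4.0)

    def test_empty_cohort(self):
        table = incidence_table([], [single_organ("colon")], GRID)
        assert table["person_years"].sum() == 0
        assert table["n_events"].sum() == 0

    def test_table_equals_sum_of_record_level(self, sim_cohort):
        group = single_organ("colon")
        table = incidence_table(sim_cohort, [group], GRID, by=())
        py_sum = np.zeros(10)
        d_sum = np.zeros(10, int)
        for rec in sim_cohort:
            py, band = person_years(rec, group, GRID)
            py_sum += py
            if band is not None:
                d_sum[band] += 1
        sub = table[table["organ_set"] == "colon"].sort_values("age_lower")
        np.testing.assert_allclose(sub["person_years"].to_numpy(), py_sum, atol=1e-8)
        np.testing.assert_array_equal(sub["n_events"].to_numpy(), d_sum)

    def test_air_is_events_over_person_years(self, hand_cohort):
        table = incidence_table(hand_cohort, [single_organ("colon")], GRID, by=())
        sub = table[table["person_years"] > 0]
        np.testing.assert_allclose(
            sub["air"], sub["n_events"] / sub["person_years"]
        )

    def test_sex_restricted_group_excludes_other_sex(self, hand_cohort):
        table = incidence_table(
            hand_cohort, [single_organ("endometrium")], GRID, by=("sex",)
        )
        males = table[(table["sex"] == "M")]
        assert males["person_years"].sum() == 0.0


class TestCumulativeIncidence:
    def test_single_band_closed_form(self):
        # 10 identical carriers observed [25,30), one event rate 0.01/yr
        records = [
            make_carrier(f"c{i}", incl=25.0, last=30.0) for i in range(10)
        ]
        table = incidence_table(records, [single_organ("colon")], GRID, by=())
        table.loc[table["age_lower"] == 25.0, "n_events"] = 0
        # force AIR = 0.01 in the first band via synthetic PY/event counts
        table.loc[table["age_lower"] == 25.0, "person_years"] = 100.0
        table.loc[table["age_lower"] == 25.0, "n_events"] = 1
        curve = cumulative_incidence(table, "colon")
        assert curve.q[0] == 0.0  # Q(25) = 0
        assert curve.value_at(30.0) == pytest.approx(1 - np.exp(-0.05), abs=1e-12)

    def test_all_zero_events_gives_zero_curve_with_rule_of_three_bound(self, hand_cohort):
        records = [make_carrier(f"z{i}", incl=30.0, last=60.0) for i in range(20)]
        table = incidence_table(records, [single_organ("colon")], GRID, by=())
        curve = cumulative_incidence(table, "colon")
        assert np.all(curve.q == 0.0)
        assert np.all(curve.ci_low == 0.0)
        py_to_60 = 20 * 30.0
        assert curve.ci_high[-1] == pytest.approx(1 - np.exp(-3.0 / py_to_60))

    def test_event_with_zero_person_years_is_an_error(self, hand_cohort):
        table = incidence_table(hand_cohort, [single_organ("colon")], GRID, by=())
        table.loc[table["age_lower"] == 70.0, "n_events"] = 1
        table.loc[table["age_lower"] == 70.0, "person_years"] = 0.0
        with pytest.raises(ValueError, match="zero person-years"):
            cumulative_incidence(table, "colon")

    def test_hand_computable_hazard_on_integer_cohort(self, hand_cohort):
        """H(a) equals the hand sum of d_i/PY_i x width on a small cohort."""
        table = incidence_table(hand_cohort, [single_organ("colon")], GRID, by=())
        curve = cumulative_incidence(table, "colon")
        sub = table.sort_values("age_lower")
        h_hand = 0.0
        for py, d in zip(sub["person_years"], sub["n_events"]):
            h_hand += (d / py if py > 0 else 0.0) * 5.0
        assert curve.hazard[-1] == pytest.approx(h_hand, abs=1e-12)

    def test_monotone_and_ci_ordering(self, sim_cohort):
        table = incidence_table(sim_cohort, [single_organ("colon"), CRC], GRID)
        for key, _ in table.groupby(["organ_set", "gene", "sex"]):
            curve = cumulative_incidence(table, *key)
            assert np.all(np.diff(curve.q) >= -1e-12)
            assert np.all(curve.ci_low <= curve.q + 1e-12)
            assert np.all(curve.q <= curve.ci_high + 1e-12)
            assert curve.ci_high[-1] <= 1.0

    def test_group_bounds_max_group_sum(self, sim_cohort):
        """max over organs <= group curve <= sum over organs, at every age."""
        groups = [single_organ("colon"), single_organ("rectum"), CRC]
        table = incidence_table(sim_cohort, groups, GRID, by=("gene",))
        genes = table["gene"].unique()
        for gene in genes:
            qc = cumulative_incidence(table, "colon", gene).q
            qr = cumulative_incidence(table, "rectum", gene).q
            qg = cumulative_incidence(table, "colorectum", gene).q
            assert np.all(qg <= qc + qr + 1e-9)
            assert np.all(qg >= np.maximum(qc, qr) - 1e-9)

    def test_adding_events_never_decreases_q(self, hand_cohort):
        table = incidence_table(hand_cohort, [single_organ("colon")], GRID, by=())
        q0 = cumulative_incidence(table, "colon").q
        table2 = table.copy()
        table2.loc[table2["age_lower"] == 45.0, "n_events"] += 1
        q1 = cumulative_incidence(table2, "colon").q
        assert np.all(q1 >= q0 - 1e-12)


def test_grid_must_tile_without_gaps():
    with pytest.raises(ValueError):
        _grid_edges([AgeBand(25, 30), AgeBand(35, 40)])


def test_organs_for_sex():
    assert "prostate" not in organs_for_sex(CRC, "F")  # no-op for CRC
    from lynchrisk.cohort import GYNAE

    assert organs_for_sex(GYNAE, "M") == ()
    assert organs_for_sex(GYNAE, "F") == ("endometrium", "ovary")
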