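"""Movement filter: censoring, diel/season labels, step scales, ledger."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ducksel import movement
from ducksel.movement import (
    FilterLedger,
    assign_season,
    censor_initial,
    classify_diel,
    descriptive_table,
    round_trim,
    steps_and_scales,
)
from ducksel.solar import NoaaSolar, sunrise_sunset

UTC = timezone.utc


def make_fixes(records):
    df = pd.DataFrame(records, columns=["animal_id", "timestamp", "easting_km", "northing_km"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


class TestCensor:
    def test_first_four_days_removed(self):
        t0 = datetime(2015, 9, 1, tzinfo=UTC)
        fixes = make_fixes([("a", t0 + timedelta(hours=6 * i), 0.0, 0.0) for i in range(44)])
        out, info = censor_initial(fixes, days=4)
        assert (out["timestamp"] >= t0 + timedelta(days=4)).all()
        assert info["fixes_removed"] == 16  # 4 days x 4 fixes/day
        assert len(out) == 44 - 16

    def test_animal_failing_within_window_dropped(self):
        t0 = datetime(2015, 9, 1, tzinfo=UTC)
        fixes = make_fixes(
            [("ok", t0 + timedelta(days=d), 0.0, 0.0) for d in range(10)]
            + [("dead", t0 + timedelta(hours=h), 0.0, 0.0) for h in range(0, 72, 12)]
        )
        out, info = censor_initial(fixes, days=4)
        assert set(out["animal_id"]) == {"ok"}
        assert info["animals_marked"] == 2
        assert info["animals_censored"] == 1
        assert info["animals_analysed"] == 1

    def test_zero_days_is_identity(self):
        t0 = datetime(2015, 9, 1, tzinfo=UTC)
        fixes = make_fixes([("a", t0 + timedelta(days=d), 1.0, 2.0) for d in range(5)])
        out, info = censor_initial(fixes, days=0)
        pd.testing.assert_frame_equal(out, fixes)
        assert info["fixes_removed"] == 0

    def test_empty_input(self):
        out, info = censor_initial(make_fixes([]))
        assert out.empty and info["animals_marked"] == 0


class TestDiel:
    @staticmethod
    def fixed_solar(t):
        d = t.date()
        return (
            datetime(d.year, d.month, d.day, 11, 30, tzinfo=UTC),
            datetime(d.year, d.month, d.day, 23, 0, tzinfo=UTC),
        )

    def test_boundaries_around_sunrise(self):
        sunrise = datetime(2015, 10, 1, 11, 30, tzinfo=UTC)
        assert classify_diel(sunrise - timedelta(minutes=31), self.fixed_solar) == "nocturnal"
        assert classify_diel(sunrise - timedelta(minutes=29), self.fixed_solar) == "diurnal"

    def test_solar_noon_is_diurnal(self):
        assert classify_diel(datetime(2015, 10, 1, 17, 15, tzinfo=UTC), self.fixed_solar) == "diurnal"

    def test_after_sunset_margin_nocturnal(self):
        sunset = datetime(2015, 10, 1, 23, 0, tzinfo=UTC)
        assert classify_diel(sunset + timedelta(minutes=31), self.fixed_solar) == "nocturnal"
        assert classify_diel(sunset + timedelta(minutes=29), self.fixed_solar) == "diurnal"

    def test_year_of_labels_matches_independent_rule(self):
        # fixed per-date sunrise/sunset table at 42.3N; labels must equal an
        # independent inline evaluation of the shooting-time rule
        lat, lon = 42.3, -82.4
        table = {}
        d = date(2015, 1, 1)
        while d <= date(2015, 12, 31):
            table[d] = sunrise_sunset(d, lat, lon)
            d += timedelta(days=1)

        def provider(t):
            return table[t.date()]

        rng = np.random.default_rng(5)
        for _ in range(400):
            day = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
            t = datetime(day.year, day.month, day.day, tzinfo=UTC) + timedelta(
                minutes=float(rng.uniform(0, 24 * 60))
            )
            rise, setl = table[t.date()]
            expected = (
                "diurnal"
                if rise - timedelta(minutes=30) <= t <= setl + timedelta(minutes=30)
                else "nocturnal"
            )
            assert classify_diel(t, provider) == expected

    def test_polar_conditions_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            sunrise_sunset(date(2015, 6, 21), 80.0, 0.0)

    def test_noaa_provider_caches_per_date(self):
        solar = NoaaSolar(42.3, -82.4)
        t = datetime(2015, 10, 1, 15, 0, tzinfo=UTC)
        assert solar(t) == solar(t + timedelta(hours=2))


class TestSeasons:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (date(2015, 10, 1), "FIRST"),
            (date(2016, 1, 15), "POST"),
            (date(2015, 2, 15), "out_of_window"),
            (date(2014, 8, 27), "PRE"),  # window endpoints are inclusive
            (date(2014, 9, 26), "PRE"),
            (date(2014, 9, 27), "FIRST"),
            (date(2015, 11, 18), "SECOND"),
            (date(2016, 1, 31), "POST"),
            (date(2016, 2, 1), "out_of_window"),
        ],
    )
    def test_window_assignment(self, d, expected):
        assert assign_season(datetime(d.year, d.month, d.day, 12, tzinfo=UTC)) == expected


class TestStepsAndScales:
    def make_path(self, lengths):
        t0 = datetime(2015, 10, 1, tzinfo=UTC)
        x = np.concatenate([[0.0], np.cumsum(lengths)])
        return make_fixes(
            [("a", t0 + timedelta(hours=i), xi, 0.0) for i, xi in enumerate(x)]
        )

    def test_threshold_classes(self):
        steps, fixes, ledger = steps_and_scales(self.make_path([0.2, 9.6, 30.0]))
        assert list(steps["scale"]) == ["fine", "local", "relocation"]
        assert list(fixes["retained"]) == [False, False, True, False]
        assert ledger.total == 3 and ledger.local == 1

    def test_boundary_lengths_are_local(self):
        steps, _, _ = steps_and_scales(self.make_path([0.33, 25.0]))
        assert list(steps["scale"]) == ["local", "local"]

    def test_counts_match_brute_force(self, rng):
        lengths = np.concatenate(
            [rng.uniform(0, 0.33, 300), rng.uniform(0.33, 25, 150), rng.uniform(25, 60, 10)]
        )
        rng.shuffle(lengths)
        steps, _, ledger = steps_and_scales(self.make_path(lengths))
        fine = sum(1 for v in lengths if v < 0.33)
        reloc = sum(1 for v in lengths if v > 25)
        local = len(lengths) - fine - reloc
        assert (ledger.fine, ledger.relocation, ledger.local) == (fine, reloc, local)
        ledger.validate()

    @settings(max_examples=25, deadline=None)
    @given(
        theta=st.floats(0, 2 * np.pi),
        dx=st.floats(-100, 100),
        dy=st.floats(-100, 100),
    )
    def test_scales_invariant_to_rigid_motion(self, theta, dx, dy):
        fixes = self.make_path([0.2, 1.0, 5.0, 26.0, 0.4])
        xy = fixes[["easting_km", "northing_km"]].to_numpy()
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = fixes.copy()
        moved[["easting_km", "northing_km"]] = xy @ rot.T + [dx, dy]
        s1, _, _ = steps_and_scales(fixes)
        s2, _, _ = steps_and_scales(moved)
        assert list(s1["scale"]) == list(s2["scale"])

    def test_single_fix_animal_yields_no_steps(self):
        fixes = make_fixes([("a", datetime(2015, 10, 1, tzinfo=UTC), 0.0, 0.0)])
        steps, _, ledger = steps_and_scales(fixes)
        assert steps.empty and ledger.total == 0

    def test_non_monotone_timestamps_rejected(self):
        t0 = datetime(2015, 10, 1, tzinfo=UTC)
        fixes = make_fixes([("a", t0, 0, 0), ("a", t0, 1, 1)])
        with pytest.raises(ValueError, match="increasing"):
            movement._check_fixes(fixes)


class TestLedger:
    def test_conservation_identities_enforced(self):
        with pytest.raises(ValueError):
            FilterLedger(total=10, fine=5, relocation=1, local=3, final=3).validate()

    def test_from_counts_derives_dependents(self):
        led = FilterLedger.from_counts(total=100, fine=60, relocation=5, out_of_extent=7)
        assert led.local == 35 and led.final == 28


class TestDescriptiveTable:
    def test_means_and_display(self):
        t0 = datetime(2015, 9, 5, tzinfo=UTC)  # PRE season
        rows = []
        for i, k in enumerate([10, 20, 30]):
            for j in range(k):
                rows.append((f"a{i}", t0 + timedelta(minutes=j), 0.0, 0.0))
        fixes = make_fixes(rows)
        fixes["season"] = "PRE"
        fixes["diel"] = "diurnal"
        table = descriptive_table(fixes)
        row = table[(table.season == "PRE") & (table.diel == "diurnal")].iloc[0]
        assert row["ids"] == 3 and row["n"] == 60
        assert row["mean"] == pytest.approx(20.0)
        assert row["mean_display"] == "20"
        assert row["sd"] == pytest.approx(10.0)
        assert (row["min"], row["max"]) == (10, 30)

    def test_single_animal_stratum(self):
        t0 = datetime(2016, 1, 20, tzinfo=UTC)  # POST season
        fixes = make_fixes([("solo", t0 + timedelta(minutes=i), 0.0, 0.0) for i in range(7)])
        fixes["season"] = "POST"
        fixes["diel"] = "nocturnal"
        row = descriptive_table(fixes).set_index(["season", "diel"]).loc[("POST", "nocturnal")]
        assert row["mean"] == 7 and row["sd"] == 0.0 and row["min"] == row["max"] == 7

    def test_empty_stratum_rows_are_zero(self):
        fixes = make_fixes([])
        fixes["season"] = pd.Series(dtype=object)
        fixes["diel"] = pd.Series(dtype=object)
        table = descriptive_table(fixes)
        assert len(table) == 8 and (table["n"] == 0).all()


@pytest.mark.parametrize(
    "value,expected",
    [(30.245614, "30.25"), (37.9, "37.9"), (12.736842, "12.74"), (20.0, "20"), (13.855, "13.86")],
)
def test_round_trim(value, expected):
    assert round_trim(value) == expected
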