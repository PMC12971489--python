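import math

import numpy as np
import pandas as pd
import pytest

import syndyn as sd
from syndyn.observation import (
    NEW_COHORT,
    OTHER,
    STABLE_COHORT,
    CategoryCounts,
    PresenceTable,
    km_from_records,
    logrank,
    survival_records,
)
from syndyn.params import ImagingSchedule


def tracks_from_events(events, length=10.0):
    """Build a track table from (synapse_id, birth, stabilize, death) tuples."""
    rows = []
    for sid, birth, stab, death in events:
        rows.append(
            {
                "fish_id": "f1",
                "dendrite_id": "f1d1",
                "synapse_id": sid,
                "position_um": 1.0,
                "origin": "born" if birth > 0 else "initial_new",
                "t_birth_h": birth,
                "t_stabilize_h": stab,
                "t_death_h": death,
                "dendrite_length_um": length,
            }
        )
    return pd.DataFrame(rows)


def presence_from_patterns(patterns, times, length=10.0):
    """PresenceTable from {synapse_id: iterable of present times}."""
    rows = []
    for sid, present_at in patterns.items():
        for t in times:
            rows.append(
                {
                    "fish_id": "f1",
                    "dendrite_id": "f1d1",
                    "synapse_id": sid,
                    "time_h": float(t),
                    "present": int(t in present_at),
                }
            )
    lengths = pd.DataFrame(
        {"fish_id": ["f1"], "dendrite_id": ["f1d1"], "length_um": [length]}
    )
    columns = ["fish_id", "dendrite_id", "synapse_id", "time_h", "present"]
    data = pd.DataFrame(rows, columns=columns)
    return PresenceTable(data=data, lengths=lengths)


@pytest.fixture
def fate_times():
    return (0.0, 6.0, 12.0, 24.0, 48.0, 72.0)


class TestObserve:
    def test_interval_censored_new_synapse(self, fate_schedule):
        # born between 0 and 6, disappeared between 12 and 24
        tracks = tracks_from_events([("s1", 3.0, np.nan, 18.0)])
        pres = sd.observe(tracks, fate_schedule)
        got = pres.data.set_index("time_h")["present"]
        assert list(got[got == 1].index) == [6.0, 12.0]

    def test_no_death_present_from_birth(self, fate_schedule):
        tracks = tracks_from_events([("s1", 10.0, np.nan, np.nan)])
        pres = sd.observe(tracks, fate_schedule)
        got = pres.data.set_index("time_h")["present"]
        assert list(got[got == 1].index) == [12.0, 24.0, 48.0, 72.0]

    def test_unobservable_track_omitted(self, fate_schedule):
        tracks = tracks_from_events([("s1", 1.0, np.nan, 5.0),
                                     ("s2", 0.0, np.nan, np.nan)])
        pres = sd.observe(tracks, fate_schedule)
        assert set(pres.data["synapse_id"]) == {"s2"}

    def test_death_at_imaging_time_absent(self, fate_schedule):
        tracks = tracks_from_events([("s1", 0.0, np.nan, 24.0)])
        pres = sd.observe(tracks, fate_schedule)
        got = pres.data.set_index("time_h")["present"]
        assert got[24.0] == 0 and got[12.0] == 1

    def test_schedule_beyond_horizon_rejected(self, fate_schedule):
        tracks = tracks_from_events([("s1", 0.0, np.nan, np.nan)])
        with pytest.raises(ValueError, match="horizon"):
            sd.observe(tracks, fate_schedule, horizon=24.0)

    def test_every_synapse_has_all_times(self, theta_ctrl, fate_schedule):
        tracks = sd.simulate_dendrite(theta_ctrl, 3000.0, 72.0,
                                      np.random.default_rng(2))
        pres = sd.observe(tracks, fate_schedule)
        per = pres.data.groupby("synapse_id")["time_h"].count()
        assert (per == len(fate_schedule.times)).all()


class TestClassifyCohorts:
    def test_definitions(self, fate_times):
        pres = presence_from_patterns(
            {"a": {0.0, 6.0}, "b": {6.0, 12.0}, "c": {12.0}}, fate_times
        )
        labels = sd.classify_cohorts(pres).set_index("synapse_id")["cohort"]
        assert labels["a"] == STABLE_COHORT
        assert labels["b"] == NEW_COHORT
        assert labels["c"] == OTHER


class TestLifetimeCategories:
    def test_simple_categories(self, fate_times):
        pres = presence_from_patterns(
            {"a": {6.0, 12.0}, "b": set(fate_times)}, fate_times
        )
        counts = sd.lifetime_categories(pres)
        got = {
            (r.first_idx, r.last_idx): r.count
            for r in counts.counts.itertuples()
        }
        assert got == {(1, 2): 1, (0, 5): 1}

    def test_gap_splitting_with_warning(self, fate_times):
        pres = presence_from_patterns({"a": {0.0, 24.0}}, fate_times)
        with pytest.warns(UserWarning, match="split"):
            counts = sd.lifetime_categories(pres)
        got = {(r.first_idx, r.last_idx): r.count for r in counts.counts.itertuples()}
        assert got == {(0, 0): 1, (3, 3): 1}
        assert counts.total == 2

    def test_totals_match_observed(self, theta_ctrl, fate_schedule):
        tracks = sd.simulate_dendrite(theta_ctrl, 5000.0, 72.0,
                                      np.random.default_rng(4))
        pres = sd.observe(tracks, fate_schedule)
        counts = sd.lifetime_categories(pres)
        assert counts.total == pres.data["synapse_id"].nunique()

    def test_roundtrip_write(self, tmp_path, fate_times):
        pres = presence_from_patterns({"a": {0.0, 6.0}}, fate_times)
        counts = sd.lifetime_categories(pres)
        out = tmp_path / "categories.tsv"
        counts.write(out)
        back = pd.read_csv(out, sep="\t")
        assert list(back["first_h"]) == [0.0]
        assert list(back["last_h"]) == [6.0]


class TestWindowSummary:
    def test_three_synapse_example(self):
        pres = presence_from_patterns(
            {"A": {0.0, 24.0}, "B": {0.0}, "C": {24.0}}, (0.0, 24.0), length=10.0
        )
        ws = sd.window_summary(pres, 0.0, 24.0)
        assert (ws.newly_observed, ws.lost, ws.stable) == (1, 1, 1)
        assert ws.densities == (0.1, 0.1, 0.1)

    def test_empty_presence(self):
        pres = presence_from_patterns({}, (0.0, 24.0))
        ws = sd.window_summary(pres, 0.0, 24.0)
        assert (ws.newly_observed, ws.lost, ws.stable) == (0, 0, 0)

    def test_counts_identity(self, theta_ctrl, fate_schedule):
        tracks = sd.simulate_dendrite(theta_ctrl, 4000.0, 72.0,
                                      np.random.default_rng(8))
        pres = sd.observe(tracks, fate_schedule)
        w = pres.wide()
        for t_a, t_b in [(0.0, 24.0), (6.0, 48.0)]:
            ws = sd.window_summary(pres, t_a, t_b)
            assert ws.lost + ws.stable == int((w[t_a] > 0).sum())
            assert ws.newly_observed + ws.stable == int((w[t_b] > 0).sum())

    def test_simulated_turnover_fraction(self, theta_ctrl):
        # 24-h replaced fraction ~ 0.240 of the t=0 total
        schedule = ImagingSchedule((0.0, 24.0))
        tracks = sd.simulate_dendrite(theta_ctrl, 1e5, 24.0,
                                      np.random.default_rng(21))
        pres = sd.observe(tracks, schedule)
        ws = sd.window_summary(pres, 0.0, 24.0)
        n0 = ws.lost + ws.stable
        frac = ws.lost / n0
        expect = 1.0 - sd.survival_cohort(theta_ctrl, 24.0)
        se = math.sqrt(expect * (1 - expect) / n0)
        assert abs(frac - expect) < 4 * se

    def test_window_not_in_schedule(self, fate_times):
        pres = presence_from_patterns({"a": {0.0}}, fate_times)
        with pytest.raises(ValueError, match="13"):
            sd.window_summary(pres, 0.0, 13.0)

    def test_per_fish_table(self, theta_ctrl, fate_schedule):
        design = sd.SimDesign(3, 1, 500.0, 72.0, seed=5)
        pres = sd.observe(sd.simulate_study(theta_ctrl, design), fate_schedule)
        table = sd.window_summary_by(pres, 0.0, 24.0, by="fish_id")
        assert len(table) == 3
        assert (table["length_um"] == 500.0).all()


class TestSurvivalRecordsAndKM:
    def test_all_present_all_censored(self, fate_times):
        pres = presence_from_patterns(
            {f"s{i}": set(fate_times) for i in range(5)}, fate_times
        )
        km = sd.km_curve(pres, cohort=STABLE_COHORT)
        assert (km["survival"] == 1.0).all()
        assert km["censored"].iloc[-1] == 5

    def test_immediate_loss(self, fate_times):
        pres = presence_from_patterns({"a": {0.0}, "b": set(fate_times)},
                                      fate_times)
        km = sd.km_curve(pres, cohort=STABLE_COHORT)
        step = km.set_index("time")["survival"]
        assert step[6.0] == 0.5

    def test_new_cohort_rezeroed(self, fate_times):
        # new synapse present at 6 and 12, lost at 24: duration 24-6=18
        pres = presence_from_patterns({"a": {6.0, 12.0}}, fate_times)
        rec = survival_records(pres, cohort=NEW_COHORT)
        assert rec["duration"].iloc[0] == 18.0
        assert rec["observed"].iloc[0] == 1

    def test_km_equals_empirical_without_censoring(self, rng):
        # deaths at every time, none censored
        durations = rng.integers(1, 6, size=200).astype(float)
        observed = np.ones(200, dtype=int)
        km = km_from_records(durations, observed)
        for _, row in km.iterrows():
            frac = (durations > row["time"]).mean()
            assert row["survival"] == pytest.approx(frac, rel=1e-12)

    def test_km_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        durations = rng.integers(1, 8, size=300).astype(float)
        observed = rng.random(300) < 0.7
        km = km_from_records(durations, observed.astype(int))
        kmf = lifelines.KaplanMeierFitter().fit(durations, observed)
        for _, row in km.iterrows():
            ours = row["survival"]
            theirs = float(kmf.predict(row["time"]))
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_empty_cohort_error(self, fate_times):
        pres = presence_from_patterns({"a": {0.0, 6.0}}, fate_times)
        with pytest.raises(ValueError, match="empty"):
            survival_records(pres, cohort=NEW_COHORT)


class TestLogrank:
    @staticmethod
    def records(durations, observed):
        return pd.DataFrame({"duration": durations, "observed": observed})

    def test_identical_cohorts(self):
        rec = self.records([6.0, 12.0, 24.0, 72.0], [1, 1, 0, 0])
        res = logrank(rec, rec)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_degenerate(self):
        rec = self.records([72.0, 72.0], [0, 0])
        res = logrank(rec, rec)
        assert (res.chi_square, res.p_value) == (0.0, 1.0)

    def test_strong_separation(self, rng):
        # interval-censored exponential cohorts, hazards 0.25 vs 0.0006
        times = np.array([6.0, 12.0, 24.0, 48.0, 72.0])

        def censored(rate, n):
            raw = rng.exponential(1.0 / rate, size=n)
            idx = np.searchsorted(times, raw)
            obs = idx < len(times)
            dur = np.where(obs, times[np.minimum(idx, len(times) - 1)], times[-1])
            return self.records(dur, obs.astype(int))

        res = logrank(censored(0.25, 400), censored(0.0006, 400))
        assert res.p_value < 1e-4

    def test_empty_cohort_rejected(self):
        rec = self.records([6.0], [1])
        with pytest.raises(ValueError, match="empty"):
            logrank(rec, self.records([], []))

    def test_matches_lifelines(self, rng):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        a = self.records(rng.integers(1, 6, 80).astype(float), rng.random(80) < 0.8)
        b = self.records(rng.integers(1, 8, 60).astype(float), rng.random(60) < 0.6)
        ours = logrank(a, b)
        theirs = lifelines_stats.logrank_test(
            a["duration"], b["duration"], a["observed"], b["observed"]
        )
        assert ours.chi_square == pytest.approx(theirs.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-9)


class TestPresenceIO:
    def test_roundtrip(self, tmp_path, theta_ctrl, fate_schedule):
        tracks = sd.simulate_dendrite(theta_ctrl, 1000.0, 72.0,
                                      np.random.default_rng(6))
        pres = sd.observe(tracks, fate_schedule)
        p1, p2 = tmp_path / "presence.tsv", tmp_path / "dendrites.tsv"
        pres.write(p1, p2)
        back = PresenceTable.read(p1, p2)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True),
            pres.data.reset_index(drop=True),
            check_dtype=False,
        )
        assert back.total_length == pres.total_length

    def test_missing_column_named(self, tmp_path):
        p1 = tmp_path / "presence.tsv"
        p1.write_text("fish_id\tdendrite_id\tsynapse_id\ttime_h\nf1\td1\ts1\t0\n")
        p2 = tmp_path / "dendrites.tsv"
        p2.write_text("fish_id\tdendrite_id\tlength_um\nf1\td1\t10\n")
        with pytest.raises(ValueError, match="present"):
            PresenceTable.read(p1, p2)

    def test_invalid_present_values(self):
        data = pd.DataFrame(
            {"fish_id": ["f1"], "dendrite_id": ["d1"], "synapse_id": ["s1"],
             "time_h": [0.0], "present": [2]}
        )
        lengths = pd.DataFrame(
            {"fish_id": ["f1"], "dendrite_id": ["d1"], "length_um": [10.0]}
        )
        with pytest.raises(ValueError, match="0/1"):
            PresenceTable(data=data, lengths=lengths)


class TestModuleBridge:
    def test_category_frequencies_match_closed_form(self, theta_ctrl,
                                                    fate_schedule):
        # observe ∘ simulate -> lifetime_categories reproduces the expected
        # category densities within 4 binomial SE at L = 1e5 µm
        L = 1e5
        table = sd.expected_category_table(theta_ctrl, fate_schedule)
        for seed in range(3):
            tracks = sd.simulate_dendrite(theta_ctrl, L, 72.0,
                                          np.random.default_rng(100 + seed))
            counts = sd.lifetime_categories(sd.observe(tracks, fate_schedule))
            got = {
                (r.first_idx, r.last_idx): r.count
                for r in counts.counts.itertuples()
            }
            for cat, dens in table.items():
                expect = dens * L
                se = math.sqrt(expect)
                assert abs(got.get(cat, 0) - expect) < 4 * se, (seed, cat)

    def test_km_reproduces_cohort_survival(self, theta_ctrl, fate_schedule):
        tracks = sd.simulate_dendrite(theta_ctrl, 1e6, 72.0,
                                      np.random.default_rng(31))
        pres = sd.observe(tracks, fate_schedule)
        km = sd.km_curve(pres, fate_schedule, STABLE_COHORT)
        surv = km.set_index("time")["survival"]
        n = km["at_risk"].iloc[0]
        for t in fate_schedule.times[1:]:
            expect = sd.survival_cohort(theta_ctrl, t)
            se = math.sqrt(expect * (1 - expect) / n)
            assert abs(surv[t] - expect) < 4 * se
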