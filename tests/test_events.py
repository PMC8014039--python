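"""Gait event detection: YIN prior, IC/TC/MinRot, temporal parameters."""

import numpy as np
import pandas as pd
import pytest

from conftest import match_events
from strideforge.events import (
    GaitCycleTable,
    NoGaitPeriodicityError,
    detect_gait_events,
    detect_ic_tc,
    detect_midswing,
    detect_minrot,
    remove_invalid_strides,
    temporal_parameters,
    yin_period,
)


class TestYin:
    def test_sinusoid_period_estimate(self):
        fs = 500.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * t / 0.7)
        _, periods = yin_period(x, fs)
        assert np.abs(periods - 0.7).max() < 0.01

    def test_sinusoid_one_peak_per_period(self):
        fs = 500.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * t / 0.7)
        peaks = detect_midswing(x, fs)
        spacing = np.diff(peaks) / fs
        assert np.abs(spacing - 0.7).max() < 0.02

    def test_constant_signal_no_periodicity(self):
        with pytest.raises(NoGaitPeriodicityError, match="period"):
            yin_period(np.full(10000, 2.0), 500.0)

    def test_aperiodic_noise_no_periodicity(self):
        rng = np.random.default_rng(0)
        with pytest.raises(NoGaitPeriodicityError):
            detect_midswing(rng.normal(size=10000), 500.0)


class TestEventDetection:
    def test_midswing_matches_planted_events(self, clean_session):
        _, recs, _, truth = clean_session
        fs = recs["left"].fs
        peaks = detect_midswing(recs["left"].gyr[:, 2], fs)
        det = peaks / fs
        matched, n_det, n_truth = match_events(det, truth.events["left"]["midswing"], 0.010)
        assert matched == n_det == n_truth

    def test_ic_tc_within_10ms_of_planted(self, clean_session):
        _, recs, _, truth = clean_session
        rec = recs["left"]
        fs = rec.fs
        ms = detect_midswing(rec.gyr[:, 2], fs)
        cyc = detect_ic_tc(rec.gyr[:, 2], ms)
        cyc = cyc[cyc.valid]
        for col, key in (("ic_idx", "ic"), ("tc_idx", "tc")):
            det = cyc[col].to_numpy() / fs
            matched, n_det, n_truth = match_events(det, truth.events["left"][key], 0.010)
            assert matched == n_det == n_truth

    def test_monotone_cycle_flagged_missing_minima(self):
        x = np.concatenate([np.linspace(0, 1, 500), np.linspace(1, 2, 500)])
        cyc = detect_ic_tc(x, np.array([0, 999]))
        assert not cyc.valid.iloc[0]
        assert cyc.reason.iloc[0] == "missing minima"

    def test_translation_invariance_of_ic_tc(self):
        rng = np.random.default_rng(1)
        wave = np.sin(np.linspace(0, 2 * np.pi, 400)) - 2 * np.exp(
            -0.5 * ((np.arange(400) - 120) / 10.0) ** 2
        ) - 1.5 * np.exp(-0.5 * ((np.arange(400) - 260) / 10.0) ** 2)
        two = np.tile(wave, 3)
        ms = np.array([0, 400, 800])
        cyc = detect_ic_tc(two, ms)
        offs_ic = cyc.ic_idx.to_numpy() - ms[:-1]
        offs_tc = cyc.tc_idx.to_numpy() - ms[:-1]
        assert len(set(offs_ic)) == 1 and len(set(offs_tc)) == 1


class TestMinRot:
    def test_planted_static_window_contains_minrot(self, clean_session):
        _, recs, _, truth = clean_session
        rec = recs["left"]
        table = detect_gait_events(recs)
        left = table.for_foot("left")
        windows = truth.static_windows["left"]
        hits = 0
        for _, row in left.iterrows():
            if row.minrot_idx < 0:
                continue
            t_mr = row.minrot_idx / rec.fs
            if any(a - 0.002 <= t_mr <= b + 0.002 for a, b in windows):
                hits += 1
        assert hits == (left.minrot_idx >= 0).sum()

    def test_constant_norm_ties_to_earliest(self):
        gyr = np.ones((100, 3))
        assert detect_minrot(gyr, 10, 50) == 10

    def test_single_sample_stance(self):
        gyr = np.random.default_rng(0).normal(size=(100, 3))
        assert detect_minrot(gyr, 42, 42) == 42

    def test_empty_window_raises(self):
        with pytest.raises(ValueError, match="stance"):
            detect_minrot(np.ones((10, 3)), 5, 3)


class TestTemporalParameters:
    def _steps(self, events, fs=100.0):
        return pd.DataFrame(
            [dict(foot=f, ic_idx=int(ic * fs), tc_idx=int(tc * fs),
                  midswing_idx=0, minrot_idx=0)
             for f, ic, tc in events]
        )

    def test_contact_time_direct(self):
        df = temporal_parameters(
            self._steps([("left", 10.00, 10.25), ("right", 10.35, 10.60),
                         ("left", 10.70, 10.95)]), fs=100.0)
        assert df.ct.iloc[0] == pytest.approx(0.25)

    def test_worked_example_flt_stp_str_swt(self):
        df = temporal_parameters(
            self._steps([("left", 10.00, 10.25), ("right", 10.35, 10.60),
                         ("left", 10.70, 10.95), ("right", 11.05, 11.30)]),
            fs=100.0)
        row = df.iloc[0]
        assert row.flt == pytest.approx(0.10)
        assert row.stp == pytest.approx(0.35)
        assert row["str"] == pytest.approx(0.70)
        assert row.swt == pytest.approx(0.45)

    def test_incomplete_trailing_steps_flagged(self):
        df = temporal_parameters(
            self._steps([("left", 1.0, 1.2), ("right", 1.4, 1.6),
                         ("left", 1.8, 2.0)]), fs=100.0)
        assert not df.valid.iloc[-1] and not df.valid.iloc[-2]
        assert (df.reason.iloc[-2:] == "incomplete").all()

    def test_same_foot_twice_flags_missed_contralateral(self):
        df = temporal_parameters(
            self._steps([("left", 1.0, 1.2), ("left", 1.7, 1.9),
                         ("right", 2.1, 2.3), ("left", 2.5, 2.7),
                         ("right", 2.9, 3.1)]), fs=100.0)
        assert (df.reason.iloc[:2] == "missed contralateral step").all()

    def test_step_and_stride_identities(self, processed_clean):
        # STP_i + STP_{i+1} = STR_i and CT_i + FLT_i = STP_i exactly
        df = processed_clean.table.df
        stp = df.stp.to_numpy()
        for i in range(len(df) - 2):
            if np.isfinite(df["str"].iloc[i]):
                assert stp[i] + stp[i + 1] == pytest.approx(df["str"].iloc[i], abs=1e-12)
        ok = np.isfinite(df.flt)
        assert np.allclose((df.ct + df.flt)[ok], df.stp[ok], atol=1e-12)

    def test_detected_stride_matches_planted_period(self, clean_session, processed_clean):
        scenario, _, _, truth = clean_session
        valid = processed_clean.table.valid()
        planted = np.diff(truth.events["left"]["ic"]).mean()
        assert np.abs(valid["str"].to_numpy() - planted).max() < 2 / 500.0 + 1e-9


class TestStrideValidity:
    def _table(self, rows):
        df = pd.DataFrame(rows)
        df["valid"] = True
        df["reason"] = ""
        return GaitCycleTable(df=df, fs=500.0)

    def test_rejection_rules(self):
        table = self._table([
            dict(foot="left", ic_idx=0, tc_idx=1, **{"str": 0.30, "flt": 0.05}),
            dict(foot="left", ic_idx=0, tc_idx=1, **{"str": 2.60, "flt": 0.05}),
            dict(foot="left", ic_idx=0, tc_idx=1, **{"str": 0.80, "flt": 0.0}),
            dict(foot="left", ic_idx=0, tc_idx=1, **{"str": 0.80, "flt": 0.05}),
            dict(foot="left", ic_idx=0, tc_idx=1, **{"str": 0.37, "flt": 0.01}),
            dict(foot="left", ic_idx=0, tc_idx=1, **{"str": 2.50, "flt": 0.01}),
        ])
        out = remove_invalid_strides(table)
        assert list(out.df.reason) == ["too short", "too long", "no flight", "", "", ""]
        assert list(out.df.valid) == [False, False, False, True, True, True]
        assert out.rejections == {"too short": 1, "too long": 1, "no flight": 1}

    def test_event_recall_perfect_on_clean_session(self, clean_session):
        _, recs, _, truth = clean_session
        table = detect_gait_events(recs)
        fs = table.fs
        for foot in ("left", "right"):
            det = table.for_foot(foot)
            for col, key in (("ic_idx", "ic"), ("tc_idx", "tc")):
                d = det[col].to_numpy() / fs
                matched, n_det, n_truth = match_events(d, truth.events[foot][key], 0.010)
                assert matched == n_det == n_truth
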