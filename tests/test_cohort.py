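"""Synthetic cohort generator: determinism, conservation, calibration recovery."""

import numpy as np
import pandas as pd
import pytest

from gazeclass import calibration
from gazeclass.battery import default_battery
from gazeclass.cohort import (
    ASD,
    TD,
    LOW_AVAILABILITY_VALUES,
    default_params,
    draw_attention_profile,
    generate_cohort,
    simulate_fixation_table,
)
from gazeclass.exceptions import ConfigurationError


class TestDefaultParams:
    def test_group_sizes(self):
        p = default_params()
        assert p.n_td == 35
        assert p.n_asd == 26

    def test_targets_come_from_printed_table(self):
        p = default_params()
        assert p.target_mean(TD, "G.people") == 67.2
        assert p.target_mean(ASD, "B.eyes") == 46.7

    def test_low_availability_values(self):
        p = default_params()
        am = p.groups[ASD].availability
        assert am.low_values == (60.0, 58.0, 53.0, 52.0, 31.0)
        assert round(am.low_probability * 26) == 5
        assert p.groups[TD].availability.low_probability == 0

    def test_invalid_targets_rejected(self):
        p = default_params()
        bad = dict(p.targets)
        bad[(ASD, "A")] = [("eyes", 120.0, 5.0), ("mouth", 10.0, 5.0)]
        with pytest.raises(ConfigurationError):
            p.replace(targets=bad)


class TestAttentionProfile:
    def _params_with_latents(self, latents):
        p = default_params()
        return p.replace(latents={**p.latents, **latents})

    def test_zero_sd_is_exact(self, battery):
        """With sigma=0 and full availability the profile equals the latents."""
        p = self._params_with_latents({(ASD, "A"): [("eyes", 60.0, 0.0), ("mouth", 20.0, 0.0)]})
        per_aoi, out = draw_attention_profile(
            p, ASD, battery[0], np.random.default_rng(0), availability=100.0
        )
        assert per_aoi.tolist() == [60.0, 20.0]
        assert out == 20.0

    def test_conservation_when_targets_fill_duration(self, battery):
        p = self._params_with_latents({(ASD, "A"): [("eyes", 70.0, 0.0), ("mouth", 30.0, 0.0)]})
        per_aoi, out = draw_attention_profile(
            p, ASD, battery[0], np.random.default_rng(0), availability=100.0
        )
        assert per_aoi.sum() == 100.0
        assert out == 0.0

    def test_rescale_when_sum_exceeds_availability(self, battery):
        """80+40 latent at 90% availability rescales proportionally to 60/30."""
        p = self._params_with_latents({(ASD, "A"): [("eyes", 80.0, 0.0), ("mouth", 40.0, 0.0)]})
        per_aoi, out = draw_attention_profile(
            p, ASD, battery[0], np.random.default_rng(0), availability=90.0
        )
        assert per_aoi == pytest.approx([60.0, 30.0])
        assert out == pytest.approx(0.0)


class TestCalibration:
    def test_beta_availability_moment_match(self):
        a, b = calibration.beta_availability_params(95.3, 5.5)
        lo, hi = calibration.AVAILABILITY_LO, calibration.AVAILABILITY_HI
        mean = lo + (hi - lo) * a / (a + b)
        var = (hi - lo) ** 2 * a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(95.3, abs=1e-9)
        assert np.sqrt(var) == pytest.approx(5.5, abs=1e-9)

    def test_infeasible_availability_rejected(self):
        with pytest.raises(ConfigurationError):
            calibration.beta_availability_params(95.0, 12.0)

    def test_calibrate_stimulus_recovers_moments(self):
        """The fitted latents reproduce the requested post-process moments."""
        mus, sigmas = calibration.calibrate_stimulus(
            [21.9], [15.3], 97.2, 3.1, n_mc=40_000, maxiter=800
        )
        rng = np.random.default_rng(99)
        av = calibration.draw_normal_availability(97.2, 3.1, 100_000, rng)
        q = calibration.clip_rescale(mus[:, None] + sigmas[:, None] * rng.standard_normal((1, 100_000)), av)
        assert q.mean() == pytest.approx(21.9, abs=0.5)
        assert q.std() == pytest.approx(15.3, rel=0.05)

    def test_shipped_latents_reproduce_printed_moments(self, fixtures):
        """Spot-check the packaged calibration table against its targets."""
        p = default_params()
        rng = np.random.default_rng(1234)
        for item in ("B.eyes", "D.eyes", "G.people"):
            stim, aoi = item.split(".")
            for group, mcol, scol in ((ASD, "asd_mean", "asd_sd"), (TD, "td_mean", "td_sd")):
                rows = p.latents[(group, stim)]
                mus = np.array([r[1] for r in rows])
                sigmas = np.array([r[2] for r in rows])
                gp = p.groups[group]
                av = calibration.draw_normal_availability(
                    gp.availability.mean, gp.availability.sd, 120_000, rng
                )
                q = calibration.clip_rescale(
                    mus[:, None] + sigmas[:, None] * rng.standard_normal((len(mus), 120_000)), av
                )
                i = [r[0] for r in rows].index(aoi)
                assert q[i].mean() == pytest.approx(fixtures.table2.loc[item, mcol], abs=1.0)
                assert q[i].std() == pytest.approx(fixtures.table2.loc[item, scol], rel=0.12)


class TestGenerateCohort:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        from gazeclass.cohort import write_cohort_csvs

        p = default_params(seed=11)
        for d in ("a", "b"):
            participants, gaze = generate_cohort(p)
            write_cohort_csvs(participants, gaze, tmp_path / d)
        a = (tmp_path / "a" / "gaze.csv").read_bytes()
        b = (tmp_path / "b" / "gaze.csv").read_bytes()
        assert a == b
        pa = (tmp_path / "a" / "participants.csv").read_bytes()
        pb = (tmp_path / "b" / "participants.csv").read_bytes()
        assert pa == pb

    def test_sample_schedule(self, default_cohort, battery):
        _, _, gaze = default_cohort
        counts = gaze.groupby(["participant_id", "stimulus_id"]).size().unstack()
        for stim in battery:
            assert (counts[stim.stimulus_id] == stim.n_samples).all()
        t = gaze[gaze["stimulus_id"] == "A"].groupby("participant_id")["t_ms"]
        assert (t.apply(lambda s: (np.diff(s) == 20).all())).all()

    def test_conservation_partition(self, default_cohort, battery):
        """valid-in-AoI + valid-out + invalid = scheduled samples, exactly."""
        _, _, gaze = default_cohort
        spec = {s.stimulus_id: s for s in battery}
        for (pid, sid), sub in list(gaze.groupby(["participant_id", "stimulus_id"]))[:40]:
            stim = spec[sid]
            valid = sub["valid"].to_numpy(dtype=bool)
            x = sub["x_px"].to_numpy(float)
            y = sub["y_px"].to_numpy(float)
            in_aoi = np.zeros(len(sub), dtype=bool)
            for aoi in stim.aois:
                in_aoi |= valid & aoi.contains(x, y)
            n_out = (valid & ~in_aoi).sum()
            assert in_aoi.sum() + n_out + (~valid).sum() == stim.n_samples

    def test_invalid_samples_have_no_coordinates(self, default_cohort):
        _, _, gaze = default_cohort
        bad = gaze[gaze["valid"] == 0]
        assert bad["x_px"].isna().all() and bad["y_px"].isna().all()

    def test_low_availability_participants_present(self, default_fixation_table):
        _, table = default_fixation_table
        assert table.n_excluded == 5
        got = sorted(table.excluded["availability"])
        # realised availability fluctuates binomially around the configured values
        for got_v, want_v in zip(got, sorted(LOW_AVAILABILITY_VALUES)):
            assert got_v == pytest.approx(want_v, abs=2.0)

    def test_srs_missingness_among_included(self, default_cohort, default_fixation_table):
        _, participants, _ = default_cohort
        _, table = default_fixation_table
        inc = participants.loc[table.included.index.intersection(participants.index)]
        asd = inc[inc["group"] == ASD]
        assert asd["srs_total"].notna().sum() == 17
        assert asd["fsiq"].notna().all()
        td = inc[inc["group"] == TD]
        assert td["srs_total"].notna().all()
        assert td["fsiq"].isna().all()

    def test_srs_range(self, default_cohort):
        _, participants, _ = default_cohort
        srs = participants["srs_total"].dropna()
        assert ((srs >= 0) & (srs <= 195)).all()


class TestFastPathEquivalence:
    def test_fast_path_deterministic(self):
        p = default_params(seed=5)
        _, t1 = simulate_fixation_table(p)
        _, t2 = simulate_fixation_table(p)
        pd.testing.assert_frame_equal(t1.included, t2.included)

    def test_fast_path_matches_stream_distribution(self):
        """Count-level and stream-level paths agree on group means (same law)."""
        p = default_params(seed=21)
        _, table_fast = simulate_fixation_table(p, seed=21)
        participants, gaze = generate_cohort(p, seed=22)
        from gazeclass.metrics import compute_fixation_table

        table_stream = compute_fixation_table(gaze)
        for item in ("A.eyes", "G.people"):
            a = table_fast.included[item].mean()
            b = table_stream.included[item].mean()
            # two independent n=56 cohorts; SDs are ~15-30 points
            assert a == pytest.approx(b, abs=18.0)

    def test_recovery_at_moderate_n(self):
        """Group means recover the calibration targets at n=500 per group."""
        p = default_params(seed=7)
        p = p.replace(
            groups={
                ASD: p.groups[ASD].__class__(**{**p.groups[ASD].__dict__, "n": 500}),
                TD: p.groups[TD].__class__(**{**p.groups[TD].__dict__, "n": 500}),
            }
        )
        participants, table = simulate_fixation_table(p)
        inc = participants.loc[table.included.index]
        for group in (ASD, TD):
            ids = inc.index[inc["group"] == group]
            for item in ("A.eyes", "B.eyes", "H.geometry"):
                got = table.included.loc[ids, item].mean()
                assert got == pytest.approx(p.target_mean(group, item), abs=3.0)
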