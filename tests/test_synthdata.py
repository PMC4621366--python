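"""Synthetic-patient generator tests: determinism, designed structure."""

import numpy as np
import pytest

from doanet import emd, sampen
from doanet.synthdata import (
    DEFAULT_EFFECT_PROFILE,
    VITAL_CHANNELS,
    ChannelEffect,
    LatentTrajectory,
    generate_eeg,
    generate_patient,
    generate_rater_scores,
    generate_trajectory,
    generate_vitals,
    inject_artifact,
    load_patient_dir,
    write_patient_dir,
)


def _plateau(state: float, n_windows: int) -> LatentTrajectory:
    return LatentTrajectory(
        times=np.arange(1, n_windows + 1) * 5.0,
        state=np.full(n_windows, float(state)),
    )


class TestTrajectory:
    def test_shape_and_surgical_phases(self):
        traj = generate_trajectory(500.0, seed=1)
        assert traj.n == 100
        assert traj.state[0] >= 80.0  # starts awake
        assert traj.state.min() <= 40.0  # reaches anesthesia
        assert np.all((traj.state >= 0) & (traj.state <= 100))

    def test_minimum_duration(self):
        traj = generate_trajectory(50.0, seed=7)
        assert traj.n == 10
        with pytest.raises(ValueError):
            generate_trajectory(49.0, seed=7)

    def test_deterministic_under_seed(self):
        a = generate_trajectory(300.0, seed=3)
        b = generate_trajectory(300.0, seed=3)
        np.testing.assert_array_equal(a.state, b.state)
        c = generate_trajectory(300.0, seed=4)
        assert not np.array_equal(a.state, c.state)


class TestEEG:
    def test_entropy_tracks_consciousness(self):
        """Windowed SampEn of the generated EEG increases with the
        latent state: awake EEG is more irregular."""
        means = []
        for state in (10.0, 50.0, 90.0):
            eeg = generate_eeg(_plateau(state, 30), seed=11)
            filt = emd.filter_signal(eeg)
            means.append(sampen.windowed_entropy(filt)["sampen"].mean())
        assert means[0] < means[1] < means[2]

    def test_zero_state_still_finite_signal(self):
        eeg = generate_eeg(_plateau(0.0, 5), seed=2)
        assert np.all(np.isfinite(eeg))
        assert eeg.std() > 0

    def test_bit_identical_under_seed(self):
        lat = _plateau(60.0, 8)
        np.testing.assert_array_equal(generate_eeg(lat, 5), generate_eeg(lat, 5))

    def test_length_contract(self):
        lat = _plateau(60.0, 8)
        assert generate_eeg(lat, 0).size == 8 * 625


class TestVitals:
    def test_designed_dominant_channel_has_highest_correlation(self):
        traj = generate_trajectory(500.0, seed=1)
        vitals = generate_vitals(traj, seed=1)  # default: EMG gain 16x others
        corrs = {
            ch: abs(np.corrcoef(vitals[ch], traj.state)[0, 1])
            for ch in VITAL_CHANNELS
        }
        assert max(corrs, key=corrs.get) == "emg"

    def test_zero_gains_decorrelate(self):
        traj = generate_trajectory(500.0, seed=2)
        profile = {ch: ChannelEffect(gain=0.0, noise_sd=2.0) for ch in VITAL_CHANNELS}
        vitals = generate_vitals(traj, seed=2, effect_profile=profile)
        for ch in VITAL_CHANNELS:
            assert abs(np.corrcoef(vitals[ch], traj.state)[0, 1]) < 0.3

    def test_physiological_clipping(self):
        traj = _plateau(100.0, 50)
        profile = dict(DEFAULT_EFFECT_PROFILE)
        profile["hr"] = ChannelEffect(gain=5.0, noise_sd=1.0)  # drives HR past 180
        vitals = generate_vitals(traj, seed=3, effect_profile=profile)
        assert vitals["hr"].max() == 180.0

    def test_incomplete_profile_rejected(self):
        traj = _plateau(50.0, 10)
        with pytest.raises(ValueError, match="missing channels"):
            generate_vitals(traj, seed=0, effect_profile={"emg": ChannelEffect(1, 1)})


class TestRaters:
    def test_zero_noise_reproduces_latent(self):
        traj = generate_trajectory(200.0, seed=4)
        scores = generate_rater_scores(traj, seed=4, noise_sd=0.0)
        for c in ("r1", "r2", "r3", "r4", "r5"):
            np.testing.assert_allclose(scores[c], traj.state)

    def test_average_beats_any_single_rater(self):
        """Averaging 5 independent raters cancels noise: over 20 seeds
        the mean rater RMSE beats every individual rater's RMSE."""
        mean_rmse, single_rmse = [], []
        for seed in range(20):
            traj = generate_trajectory(250.0, seed=seed)
            scores = generate_rater_scores(traj, seed=seed)
            cols = [f"r{j}" for j in range(1, 6)]
            avg = scores[cols].mean(axis=1)
            mean_rmse.append(np.sqrt(np.mean((avg - traj.state) ** 2)))
            single_rmse.append(
                np.mean(
                    [np.sqrt(np.mean((scores[c] - traj.state) ** 2)) for c in cols]
                )
            )
        assert np.mean(mean_rmse) < np.mean(single_rmse)

    def test_clipped_to_score_range(self):
        scores = generate_rater_scores(_plateau(99.0, 40), seed=1, noise_sd=30.0)
        assert scores[[f"r{j}" for j in range(1, 6)]].to_numpy().max() <= 100.0


class TestArtifact:
    def test_only_selected_windows_touched(self):
        eeg = generate_eeg(_plateau(70.0, 6), seed=8)
        cont = inject_artifact(eeg, [3], seed=8)
        mask = np.ones(eeg.size, dtype=bool)
        mask[3 * 625 : 4 * 625] = False
        np.testing.assert_array_equal(cont[mask], eeg[mask])
        assert not np.array_equal(cont[~mask], eeg[~mask])

    def test_burst_amplitude_contract(self):
        eeg = generate_eeg(_plateau(70.0, 6), seed=8)
        cont = inject_artifact(eeg, [2], amplitude=15.0, seed=8)
        sl = slice(2 * 625, 3 * 625)
        assert np.sqrt(np.mean(cont[sl] ** 2)) >= 10 * np.sqrt(np.mean(eeg[sl] ** 2))

    def test_out_of_range_window_rejected(self):
        eeg = generate_eeg(_plateau(70.0, 4), seed=8)
        with pytest.raises(IndexError):
            inject_artifact(eeg, [4], seed=8)

    def test_band_reconstruction_attenuates_burst(self):
        """The burst lives above the 0.8-32 Hz band, so the IMF 2-6
        reconstruction strips most of its power (periodogram check)."""
        from scipy.signal import periodogram

        eeg = generate_eeg(_plateau(70.0, 3), seed=9)
        cont = inject_artifact(eeg, [1], seed=9)
        seg = cont[625:1250]
        rec, _ = emd.band_reconstruct(emd.decompose(seg))
        f, p_raw = periodogram(seg, fs=125.0)
        _, p_rec = periodogram(rec, fs=125.0)
        hf = f >= 40.0
        assert p_rec[hf].sum() < 0.1 * p_raw[hf].sum()


class TestPatientRoundTrip:
    def test_full_determinism(self):
        a = generate_patient(150.0, seed=21)
        b = generate_patient(150.0, seed=21)
        np.testing.assert_array_equal(a.eeg, b.eeg)
        assert a.vitals.equals(b.vitals)
        assert a.rater_scores.equals(b.rater_scores)

    def test_write_then_load(self, tmp_path):
        p = generate_patient(100.0, seed=13, artifact_windows=[5])
        out = write_patient_dir(p, tmp_path / "pt")
        assert {f.name for f in out.iterdir()} == {
            "eeg.csv",
            "vitals.csv",
            "raters.csv",
            "meta.json",
        }
        q = load_patient_dir(out)
        assert q.seed == 13
        assert q.artifact_windows == [5]
        np.testing.assert_allclose(q.eeg, p.eeg, rtol=1e-6)
        np.testing.assert_allclose(q.latent.state, p.latent.state, atol=1e-5)
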