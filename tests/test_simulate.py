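"""Synthetic-data generators: ground-truth statistics and determinism."""

import numpy as np
import pytest

from sptkin import (
    HillSimParams,
    QpcrSimParams,
    SensorgramSimParams,
    TrackSimParams,
    simulate_qpcr,
    simulate_rate_curve,
    simulate_sensorgram,
    simulate_tracks,
)
from sptkin.simulate import hill_rate


class TestTrackSimulation:
    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrackSimParams(diffusion_constants=(0.1, 0.2), fractions=(0.5, 0.6))
        with pytest.raises(ValueError, match=">= 0"):
            TrackSimParams(diffusion_constants=(-0.1,), fractions=(1.0,))
        with pytest.raises(ValueError):
            TrackSimParams(diffusion_constants=(0.1,), fractions=(1.0,), n_tracks=0)

    def test_zero_diffusion_zero_noise_gives_static_tracks(self):
        params = TrackSimParams(
            diffusion_constants=(0.0,), fractions=(1.0,), n_tracks=20,
            localization_sigma=0.0, seed=0,
        )
        ts = simulate_tracks(params)
        for t in ts.tracks:
            assert np.all(t.x == t.x[0])
            assert np.all(t.y == t.y[0])

    def test_one_frame_msd_matches_4_d_dt(self):
        """Mean squared one-frame step converges to 4·D·Δt (no noise)."""
        d, dt = 0.1, 0.024
        params = TrackSimParams(
            diffusion_constants=(d,), fractions=(1.0,), n_tracks=12000,
            frame_interval=dt, localization_sigma=0.0, seed=1,
        )
        ts = simulate_tracks(params)
        sq = np.concatenate([
            np.diff(t.x) ** 2 + np.diff(t.y) ** 2 for t in ts.tracks
        ])
        assert len(sq) >= 1e5
        assert np.mean(sq) == pytest.approx(4 * d * dt, rel=0.02)

    def test_localization_error_inflates_msd(self):
        """With noise the apparent one-frame MSD is 4·D·Δt + 4·σ²."""
        d, dt, sigma = 0.05, 0.024, 0.03
        params = TrackSimParams(
            diffusion_constants=(d,), fractions=(1.0,), n_tracks=12000,
            frame_interval=dt, localization_sigma=sigma, seed=2,
        )
        ts = simulate_tracks(params)
        sq = np.concatenate([
            np.diff(t.x) ** 2 + np.diff(t.y) ** 2 for t in ts.tracks
        ])
        assert np.mean(sq) == pytest.approx(4 * d * dt + 4 * sigma**2, rel=0.02)

    def test_state_occupancies_match_fractions(self):
        params = TrackSimParams(
            diffusion_constants=(0.5, 0.05, 0.005), fractions=(0.5, 0.3, 0.2),
            n_tracks=5000, seed=3,
        )
        ts = simulate_tracks(params)
        labels = np.array([t.state_label for t in ts.tracks])
        occ = np.bincount(labels, minlength=3) / len(labels)
        np.testing.assert_allclose(occ, [0.5, 0.3, 0.2], atol=0.02)

    def test_fixed_seed_is_bit_reproducible(self):
        params = TrackSimParams(
            diffusion_constants=(0.2,), fractions=(1.0,), n_tracks=50, seed=9,
        )
        a, b = simulate_tracks(params), simulate_tracks(params)
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)

    def test_track_lengths_respect_minimum_and_mean(self):
        params = TrackSimParams(
            diffusion_constants=(0.1,), fractions=(1.0,), n_tracks=5000,
            track_length_mean=12.0, min_track_length=5, seed=4,
        )
        lengths = np.array([len(t) for t in simulate_tracks(params).tracks])
        assert lengths.min() >= 5
        assert lengths.mean() == pytest.approx(12.0, rel=0.05)

    def test_confinement_keeps_tracks_inside_radius(self):
        params = TrackSimParams(
            diffusion_constants=(1.0,), fractions=(1.0,), n_tracks=100,
            localization_sigma=0.0, confinement_radius=0.5,
            track_length_model="fixed", track_length_mean=50, seed=5,
        )
        for t in simulate_tracks(params).tracks:
            assert np.all(np.hypot(t.x, t.y) <= 0.5 + 1e-9)


class TestSensorgramSimulation:
    def test_noiseless_matches_closed_form_everywhere(self):
        p = SensorgramSimParams(ka=7.42e4, kd=0.16, analyte_conc=2e-6, rmax=1.0)
        sg = simulate_sensorgram(p)
        kobs = p.ka * p.analyte_conc + p.kd
        assert kobs == pytest.approx(0.3084)
        req = p.rmax * p.analyte_conc / (p.analyte_conc + p.kd / p.ka)
        t_a, y_a = sg.segment("association")
        np.testing.assert_allclose(y_a, req * (1 - np.exp(-kobs * t_a)), rtol=0, atol=1e-14)
        # dissociation decays exponentially from its first stored sample
        t_d, y_d = sg.segment("dissociation")
        np.testing.assert_allclose(y_d, y_d[0] * np.exp(-p.kd * t_d), rtol=1e-12)
        dt = 1.0 / p.sample_rate
        assert y_d[0] == pytest.approx(y_a[-1] * np.exp(-p.kd * dt), rel=1e-12)

    def test_association_plateau_is_equilibrium_response(self):
        p = SensorgramSimParams(ka=1e5, kd=0.1, analyte_conc=5e-6, rmax=2.0,
                                t_assoc=2000.0)
        sg = simulate_sensorgram(p)
        req = p.rmax * p.analyte_conc / (p.analyte_conc + p.kd / p.ka)
        _, y_a = sg.segment("association")
        assert y_a[-1] == pytest.approx(req, rel=1e-9)

    def test_zero_kd_dissociation_is_constant(self):
        p = SensorgramSimParams(ka=1e5, kd=0.0, analyte_conc=1e-6)
        sg = simulate_sensorgram(p)
        _, y_d = sg.segment("dissociation")
        assert np.all(y_d == y_d[0])

    def test_phase_boundaries_recorded_in_order(self):
        sg = simulate_sensorgram(SensorgramSimParams(ka=1e5, kd=0.1, analyte_conc=1e-6))
        a0, a1 = sg.phases["association"]
        d0, d1 = sg.phases["dissociation"]
        assert 0 == a0 < a1 == d0 < d1 == len(sg.t)


class TestRateCurveSimulation:
    def test_zero_substrate_gives_background(self):
        p = HillSimParams(vmax=0.02, k_half=0.5, n_h=1.2, background_rate=0.004)
        df = simulate_rate_curve(p)
        v0 = df.loc[df["substrate_mM"] == 0.0, "rate_nmol_min"].iloc[0]
        assert v0 == pytest.approx(0.004)

    def test_half_saturation_gives_half_vmax(self):
        p = HillSimParams(vmax=0.04, k_half=0.5, n_h=2.0,
                          substrate_grid=(0.5,), background_rate=0.0)
        df = simulate_rate_curve(p)
        assert df["rate_nmol_min"].iloc[0] == pytest.approx(0.02)

    def test_hill_with_unit_coefficient_equals_michaelis_menten(self):
        grid = (0.1, 0.3, 1.0, 2.0, 5.0)
        p = HillSimParams(vmax=0.03, k_half=0.7, n_h=1.0, substrate_grid=grid)
        df = simulate_rate_curve(p)
        s = np.asarray(grid)
        mm = 0.03 * s / (0.7 + s)
        np.testing.assert_allclose(df["rate_nmol_min"].to_numpy(), mm, rtol=1e-12)

    def test_hill_rate_is_monotone_in_substrate(self):
        s = np.linspace(0, 5, 50)
        v = hill_rate(s, 0.023, 0.5, 0.97)
        assert np.all(np.diff(v) > 0)


class TestQpcrSimulation:
    def test_unit_ratio_gives_equal_ct(self):
        p = QpcrSimParams(true_copy_ratio=1.0, noise_sd=0.0, replicates=1)
        df = simulate_qpcr(p)
        ct_t = df.loc[df["target"] == "target", "ct"].iloc[0]
        ct_r = df.loc[df["target"] == "reference", "ct"].iloc[0]
        assert ct_t == pytest.approx(ct_r)

    def test_one_doubling_shifts_ct_by_minus_one(self):
        p = QpcrSimParams(true_copy_ratio=2.0, efficiency_target=2.0,
                          efficiency_ref=2.0, noise_sd=0.0, replicates=1)
        df = simulate_qpcr(p)
        ct_t = df.loc[df["target"] == "target", "ct"].iloc[0]
        ct_r = df.loc[df["target"] == "reference", "ct"].iloc[0]
        assert ct_t - ct_r == pytest.approx(-1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            QpcrSimParams(true_copy_ratio=0.0)
        with pytest.raises(ValueError, match=r"\(1, 2\]"):
            QpcrSimParams(true_copy_ratio=1.0, efficiency_target=2.5)
        with pytest.raises(ValueError):
            QpcrSimParams(true_copy_ratio=1.0, replicates=0)
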