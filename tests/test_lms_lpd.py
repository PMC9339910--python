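import math

import numpy as np
import pytest

from polstim.frame_codec import make_dot_trajectory
from polstim.lms_lpd import (
    LocalMotionEstimate,
    SpikeTrain,
    VectorField,
    circular_mean,
    contrast_tuning,
    estimate_local_motion,
    interpolate_vector_field,
    latency_corrected_lpd,
    lms,
    normalise_field,
    polarisation_tuning,
    sector_rate,
    spike_motion_directions,
)
from polstim.simulators import H1Model, simulate_h1_spikes

OMEGA = 720.0  # deg/s for the standard 2 Hz dot


def traj_pair(sample_rate=1000.0, n_cycles=10):
    return (
        make_dot_trajectory("CW", sample_rate, n_cycles=n_cycles),
        make_dot_trajectory("CCW", sample_rate, n_cycles=n_cycles),
    )


def simulate_pair(model, contrast=1.0, location=(0.0, 0.0), seed=0, n_cycles=10,
                  dolp=0.0, aop_deg=None):
    traj_cw, traj_ccw = traj_pair(n_cycles=n_cycles)
    rng = np.random.default_rng(seed)
    s_cw = simulate_h1_spikes(traj_cw, location, contrast, model,
                              dolp=dolp, aop_deg=aop_deg, rng=rng)
    s_ccw = simulate_h1_spikes(traj_ccw, location, contrast, model,
                               dolp=dolp, aop_deg=aop_deg, rng=rng)
    return s_cw, s_ccw, traj_cw, traj_ccw


class TestSpikeTrain:
    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SpikeTrain(np.array([0.2, 0.1]))

    def test_empty_ok(self):
        assert len(SpikeTrain(np.array([]))) == 0


class TestSpikeMotionDirections:
    def test_no_spikes(self):
        traj = make_dot_trajectory("CW", 1000.0)
        th, dropped = spike_motion_directions(SpikeTrain(np.array([])), traj)
        assert len(th) == 0 and dropped == 0

    def test_tangent_at_origin_ccw(self):
        traj = make_dot_trajectory("CCW", 1000.0)
        th, _ = spike_motion_directions(SpikeTrain(np.array([0.0])), traj)
        assert th[0] == pytest.approx(90.0)

    def test_outside_span_dropped_and_counted(self):
        traj = make_dot_trajectory("CW", 1000.0, n_cycles=2)  # 1 s
        th, dropped = spike_motion_directions(
            SpikeTrain(np.array([-0.5, 0.5, 7.0])), traj
        )
        assert len(th) == 1 and dropped == 2

    def test_uniform_raster_uniform_histogram(self, rng):
        traj = make_dot_trajectory("CW", 1000.0, n_cycles=10)
        times = np.sort(rng.uniform(0, traj.duration, 4000))
        th, _ = spike_motion_directions(SpikeTrain(np.unique(times)), traj)
        counts, _ = np.histogram(th, bins=8, range=(0, 360))
        expected = len(th) / 8
        chi2 = np.sum((counts - expected) ** 2 / expected)
        assert chi2 < 24.3  # chi2(7 dof) at p = 0.001


class TestCircularMean:
    def test_symmetric_triplet(self):
        mean, r = circular_mean([10.0, 20.0, 30.0])
        assert mean == pytest.approx(20.0)
        assert 0 < r <= 1

    def test_antipodal_undefined(self):
        mean, r = circular_mean([0.0, 180.0])
        assert math.isnan(mean) and r == 0.0

    def test_single_angle(self):
        mean, r = circular_mean([123.0])
        assert mean == pytest.approx(123.0)
        assert r == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            circular_mean([])

    def test_against_brute_force_oracle(self, rng):
        for _ in range(1000):
            angles = rng.uniform(0, 360, rng.integers(1, 30))
            mean, r = circular_mean(angles)
            # independent oracle: explicit unit-vector summation loop
            sx = sum(math.cos(math.radians(a)) for a in angles)
            sy = sum(math.sin(math.radians(a)) for a in angles)
            r_oracle = math.hypot(sx, sy) / len(angles)
            assert r == pytest.approx(r_oracle, abs=1e-12)
            if r_oracle > 1e-9:
                mean_oracle = math.degrees(math.atan2(sy, sx)) % 360
                diff = abs((mean - mean_oracle + 180) % 360 - 180)
                assert diff < 1e-9


class TestLatencyCorrection:
    def test_equal_inputs(self):
        assert latency_corrected_lpd(30.0, 30.0) == pytest.approx(30.0)

    @pytest.mark.parametrize("theta,delta", [(0, 30), (135, 89), (300, 45)])
    def test_symmetric_offsets_cancel(self, theta, delta):
        out = latency_corrected_lpd((theta + delta) % 360, (theta - delta) % 360)
        assert abs((out - theta + 180) % 360 - 180) < 1e-9

    def test_antipodal_rejected(self):
        with pytest.raises(ValueError, match="antipodal"):
            latency_corrected_lpd(0.0, 180.0)

    def test_simulated_latency_phase_lag(self):
        # latency 20 ms at 720 deg/s: single-direction estimates offset
        # by ~14.4 deg in opposite senses; the resultant cancels the lag
        model = H1Model(theta_pref=135.0, latency=0.020, baseline_rate=20,
                        gain=80, seed=2)
        s_cw, s_ccw, t_cw, t_ccw = simulate_pair(model, seed=2, n_cycles=40)
        est = estimate_local_motion(s_cw, s_ccw, t_cw, t_ccw)
        lag = OMEGA * 0.020
        assert est.lpd_cw == pytest.approx(135.0 - lag, abs=6.0)
        assert est.lpd_ccw == pytest.approx(135.0 + lag, abs=6.0)
        assert abs((est.lpd - 135.0 + 180) % 360 - 180) < 5.0


class TestSectorRate:
    def test_no_spikes_zero(self):
        traj = make_dot_trajectory("CW", 1000.0)
        assert sector_rate(SpikeTrain(np.array([])), traj, 0.0) == 0.0

    def test_full_circle_equals_mean_rate(self, rng):
        traj = make_dot_trajectory("CW", 1000.0)
        times = np.unique(np.sort(rng.uniform(0, traj.duration, 200)))
        rate = sector_rate(SpikeTrain(times), traj, 0.0, halfwidth_deg=180.0)
        assert rate == pytest.approx(len(times) / traj.duration, rel=0.01)

    def test_homogeneous_poisson_any_sector(self, rng):
        traj = make_dot_trajectory("CW", 1000.0, n_cycles=40)  # 20 s
        n = rng.poisson(10.0 * traj.duration)
        times = np.unique(np.sort(rng.uniform(0, traj.duration, n)))
        for centre in (0, 90, 210):
            rate = sector_rate(SpikeTrain(times), traj, centre)
            # ~50 expected spikes in sector: 4 sd tolerance
            assert rate == pytest.approx(10.0, abs=4 * np.sqrt(10.0 / 5.0))


class TestLms:
    def test_pure_preferred(self):
        assert lms(20, 20, 0, 0) == 20.0

    def test_untuned(self):
        assert lms(7, 7, 7, 7) == 0.0

    def test_mean_of_differences(self):
        assert lms(10, 20, 0, 0) == 15.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            lms(-1, 0, 0, 0)


class TestEstimateLocalMotion:
    def test_recovery_at_rf_centre(self):
        model = H1Model(theta_pref=45.0, baseline_rate=20, gain=80, seed=3)
        ests = []
        for seed in range(20):
            s_cw, s_ccw, t_cw, t_ccw = simulate_pair(model, seed=seed)
            ests.append(estimate_local_motion(s_cw, s_ccw, t_cw, t_ccw))
        lpd_err = np.median(
            [abs((e.lpd - 45.0 + 180) % 360 - 180) for e in ests]
        )
        assert lpd_err < 5.0
        # generative LMS: preferred-sector rate (baseline + gain * sector
        # mean of cos) minus the anti-sector rate, which rectifies to 0
        # here (baseline 20 < gain * cos everywhere in the anti sector)
        mean_cos = np.sin(np.pi / 4) / (np.pi / 4)  # sector average of cos
        expected = 20 + 80 * mean_cos
        assert np.mean([e.lms for e in ests]) == pytest.approx(expected, rel=0.15)

    def test_untuned_neuron_lms_near_zero(self):
        # the estimated LPD is fit on the same spikes, so single-trial
        # LMS carries a small positive selection bias; the mean must
        # still sit within 2 sd of zero (the paper-scale criterion)
        model = H1Model(theta_pref=0.0, baseline_rate=30, gain=0, seed=4)
        vals = []
        for seed in range(15):
            s_cw, s_ccw, t_cw, t_ccw = simulate_pair(model, contrast=1.0, seed=seed)
            vals.append(estimate_local_motion(s_cw, s_ccw, t_cw, t_ccw).lms)
        assert abs(np.mean(vals)) <= 2 * np.std(vals)

    def test_doubling_gain_doubles_lms(self):
        res = {}
        for gain in (40, 80):
            model = H1Model(theta_pref=90.0, baseline_rate=100, gain=gain)
            vals = []
            for seed in range(12):
                s_cw, s_ccw, t_cw, t_ccw = simulate_pair(model, seed=seed,
                                                         n_cycles=20)
                vals.append(estimate_local_motion(s_cw, s_ccw, t_cw, t_ccw).lms)
            res[gain] = np.mean(vals)
        assert res[80] / res[40] == pytest.approx(2.0, rel=0.15)


class TestTuningCurves:
    @staticmethod
    def lms_records(model, contrasts, n_animals=3, n_trials=2, **sim_kw):
        records = []
        for animal in range(n_animals):
            for contrast in contrasts:
                for trial in range(n_trials):
                    seed = hash((animal, contrast, trial)) % (2**32)
                    s_cw, s_ccw, t_cw, t_ccw = simulate_pair(
                        model, contrast=contrast, seed=seed, **sim_kw
                    )
                    est = estimate_local_motion(s_cw, s_ccw, t_cw, t_ccw)
                    records.append(
                        {"animal": animal, "contrast": contrast, "lms": est.lms}
                    )
        return records

    def test_v_shaped_contrast_tuning(self):
        # baseline > gain keeps the rate un-rectified at every contrast,
        # so LMS is exactly proportional to contrast^2
        model = H1Model(theta_pref=0.0, baseline_rate=100, gain=80)
        records = self.lms_records(model, (-1.0, -0.5, 0.0, 0.5, 1.0))
        curve = contrast_tuning(records)
        lms_by_c = dict(zip(curve["contrast"], curve["lms_mean"]))
        assert min(lms_by_c, key=lms_by_c.get) == 0.0
        assert lms_by_c[-1.0] > lms_by_c[-0.5] > lms_by_c[0.0]
        assert lms_by_c[1.0] > lms_by_c[0.5] > lms_by_c[0.0]
        # contrast-squared gain: |c| = 1 responses ~4x the |c| = 0.5 ones
        assert lms_by_c[1.0] / lms_by_c[0.5] == pytest.approx(4.0, rel=0.3)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 contrast levels"):
            contrast_tuning([{"animal": 0, "contrast": 1.0, "lms": 5.0}])

    def test_within_animal_averaging_first(self):
        # one animal contributes many trials: cross-animal mean must not
        # be dominated by it
        records = [
            {"animal": 0, "contrast": 1.0, "lms": 10.0},
            {"animal": 1, "contrast": 1.0, "lms": 20.0},
            {"animal": 1, "contrast": 1.0, "lms": 20.0},
            {"animal": 1, "contrast": 1.0, "lms": 20.0},
            {"animal": 0, "contrast": 0.0, "lms": 0.0},
            {"animal": 1, "contrast": 0.0, "lms": 0.0},
        ]
        curve = contrast_tuning(records)
        row = curve[curve["contrast"] == 1.0].iloc[0]
        assert row["lms_mean"] == pytest.approx(15.0)  # not 17.5
        assert row["n_animals"] == 2

    def test_polarisation_blind_neuron_flat_aop_curve(self):
        model = H1Model(theta_pref=0.0, baseline_rate=20, gain=80,
                        polarisation_sensitive=False)
        records = []
        for animal in range(3):
            for aop in (None, 0.0, 45.0, 90.0, 135.0):
                seed = hash((animal, aop)) % (2**32)
                s_cw, s_ccw, t_cw, t_ccw = simulate_pair(
                    model, contrast=1.0, seed=seed, dolp=1.0, aop_deg=aop
                )
                est = estimate_local_motion(s_cw, s_ccw, t_cw, t_ccw)
                records.append(
                    {"animal": animal, "contrast": 1.0, "aop": aop, "lms": est.lms}
                )
        curve = polarisation_tuning(records)
        means = curve["lms_mean"].to_numpy()
        assert (means.max() - means.min()) / means.mean() < 0.25

    def test_polarisation_sensitive_variant_modulates(self):
        model = H1Model(theta_pref=0.0, baseline_rate=10, gain=120,
                        polarisation_sensitive=True, phi_max=0.0, ps=4.0)
        vals = {}
        for aop in (0.0, 90.0):
            trial_lms = []
            for seed in range(6):
                s_cw, s_ccw, t_cw, t_ccw = simulate_pair(
                    model, contrast=1.0, seed=seed, dolp=1.0, aop_deg=aop
                )
                trial_lms.append(
                    estimate_local_motion(s_cw, s_ccw, t_cw, t_ccw).lms
                )
            vals[aop] = np.mean(trial_lms)
        assert vals[0.0] > 1.5 * vals[90.0]


class TestVectorField:
    def uniform_field(self, lpd=30.0, lms_val=10.0):
        az = np.linspace(-120, 30, 6)
        el = np.linspace(-75, 75, 6)
        return VectorField(
            azimuths=az, elevations=el,
            lpd=np.full((6, 6), lpd), lms=np.full((6, 6), lms_val),
        )

    def test_uniform_field_interpolates_uniform(self):
        out = interpolate_vector_field(self.uniform_field(), step_deg=15.0)
        assert np.allclose(out.lpd, 30.0)
        assert np.allclose(out.lms, 10.0)

    def test_nodes_reproduced_exactly(self, rng):
        az = np.linspace(-120, 30, 6)
        el = np.linspace(-75, 75, 6)
        fld = VectorField(
            azimuths=az, elevations=el,
            lpd=rng.uniform(0, 360, (6, 6)), lms=rng.uniform(1, 20, (6, 6)),
        )
        out = interpolate_vector_field(fld, step_deg=15.0)
        ia = np.searchsorted(out.azimuths, az)
        ie = np.searchsorted(out.elevations, el)
        diff = (out.lpd[np.ix_(ie, ia)] - fld.lpd + 180) % 360 - 180
        assert np.allclose(diff, 0.0, atol=1e-9)
        assert np.allclose(out.lms[np.ix_(ie, ia)], fld.lms, atol=1e-9)

    def test_linear_component_field_reproduced(self):
        az = np.linspace(-120, 30, 6)
        el = np.linspace(-75, 75, 6)
        azg, elg = np.meshgrid(az, el)
        u = 0.05 * azg + 2.0
        v = 0.02 * elg - 1.0
        fld = VectorField(
            azimuths=az, elevations=el,
            lpd=np.rad2deg(np.arctan2(v, u)) % 360, lms=np.hypot(u, v),
        )
        out = interpolate_vector_field(fld, step_deg=15.0)
        azf, elf = np.meshgrid(out.azimuths, out.elevations)
        uf = out.lms * np.cos(np.deg2rad(out.lpd))
        vf = out.lms * np.sin(np.deg2rad(out.lpd))
        assert np.allclose(uf, 0.05 * azf + 2.0, atol=1e-9)
        assert np.allclose(vf, 0.02 * elf - 1.0, atol=1e-9)

    def test_too_few_nodes_rejected(self):
        fld = VectorField(
            azimuths=np.array([0.0, 10, 20]), elevations=np.array([0.0, 10, 20]),
            lpd=np.zeros((3, 3)), lms=np.ones((3, 3)),
        )
        with pytest.raises(ValueError, match="4x4"):
            interpolate_vector_field(fld)

    def test_normalise_field(self):
        ref = self.uniform_field(lms_val=40.0)
        other = self.uniform_field(lms_val=10.0)
        out = normalise_field({"NP": ref, "pol": other}, reference="NP")
        assert np.allclose(out["NP"].lms, 1.0)
        assert np.allclose(out["pol"].lms, 0.25)

    def test_normalise_missing_reference(self):
        with pytest.raises(ValueError, match="reference"):
            normalise_field({"pol": self.uniform_field()}, reference="NP")

    def test_normalise_zero_reference_rejected(self):
        z = self.uniform_field(lms_val=0.0)
        with pytest.raises(ValueError, match="positive"):
            normalise_field({"NP": z}, reference="NP")
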