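"""Absorbance-dynamics statistic: control envelope, flagging, the
discrimination probability, band summaries, and candidate-band scans."""

import numpy as np
import pytest

from mbspec import synth
from mbspec.dynamics import (
    MARKER_BANDS,
    band_summary,
    control_envelope,
    discrimination_probability,
    dynamics_vector,
    flag_altered,
    scan_candidate_bands,
    summary_table,
)
from mbspec.preprocess import preprocess_set, group_mean
from mbspec.spectra import Region, SpectrumSet, SpectrumError


def control_like(n, noise_sd=0.004, seed=0, jitter=False):
    """Spectra drawn from the control generative profile."""
    noise = synth.NoiseModel(
        additive_sd=noise_sd,
        amplitude_jitter_cv=0.05 if jitter else 0.0,
        center_jitter_sd=0.2 if jitter else 0.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    prof = synth.make_group_profile("control")
    return SpectrumSet(
        [
            synth.synth_spectrum(prof, noise, sample_id=f"s{i}", rng=rng)
            for i in range(n)
        ]
    )


class TestControlEnvelope:
    def test_identical_controls_floor_the_sd(self, pp_config):
        # identical controls: SD degenerates to ~0 (fp residue only) and the
        # flooring rule keeps the stored SD at or above the floor everywhere
        controls = control_like(3, noise_sd=0.0)
        env = control_envelope(controls, pp_config)
        assert env.sd_dynamics.max() < 1e-15
        assert np.all(env.sd_dynamics >= env.sd_floor)

    def test_mean_of_two_controls_is_halfway(self, pp_config):
        controls = control_like(2, noise_sd=0.004, seed=3)
        env = control_envelope(controls, pp_config)
        d = [dynamics_vector(s, pp_config).absorbance for s in controls]
        np.testing.assert_allclose(env.mean_dynamics, (d[0] + d[1]) / 2, atol=1e-15)

    def test_mean_dynamics_commutes_with_group_mean(self, pp_config):
        controls = control_like(4, noise_sd=0.004, seed=4)
        env = control_envelope(controls, pp_config)
        mean_spec = group_mean(controls, "control")
        np.testing.assert_allclose(
            env.mean_dynamics, dynamics_vector(mean_spec, pp_config).absorbance, atol=1e-10
        )

    def test_single_control_rejected(self, pp_config):
        with pytest.raises(SpectrumError, match="2 control"):
            control_envelope(control_like(1), pp_config)

    def test_grid_is_excised_fingerprint(self, pp_config):
        env = control_envelope(control_like(2), pp_config)
        assert env.grid[0] == 800.0 and env.grid[-1] == 1800.0
        assert not ((env.grid >= 1350) & (env.grid <= 1500)).any()
        assert len(env.grid) == 850


class TestFlagging:
    def test_noiseless_control_patient_raises_no_flags(self, pp_config):
        # identical noiseless controls: SD is exactly the floor (zero), and a
        # patient drawn from the same profile deviates nowhere
        controls = control_like(3, noise_sd=0.0)
        env = control_envelope(controls, pp_config)
        patient = control_like(1, noise_sd=0.0)[0]
        flags = flag_altered(patient, env, k=2.0, config=pp_config)
        assert not flags.any()

    def test_threshold_arithmetic_at_exactly_one_wavenumber(self, pp_config):
        # a patient whose absorbance carries one extra narrow feature is
        # flagged only around that feature, nowhere else
        controls = control_like(8, noise_sd=0.004, seed=5)
        env = control_envelope(controls, pp_config)
        patient = control_like(1, noise_sd=0.0)[0]
        bump = 0.05 * np.exp(-((patient.wavenumbers - 1000.0) ** 2) / (2 * 3.0**2))
        patient = patient.with_absorbance(patient.absorbance + bump)
        flags = flag_altered(patient, env, k=2.0, config=pp_config)
        flagged_nu = env.grid[flags]
        assert flagged_nu.size > 0
        assert np.all(np.abs(flagged_nu - 1000.0) < 20.0)

    def test_grid_mismatch_rejected(self, pp_config):
        env = control_envelope(control_like(2), pp_config)
        short = control_like(1, seed=9)[0].slice(Region(800, 1200))
        with pytest.raises(SpectrumError):
            flag_altered(short, env, 2.0, pp_config)


class TestDiscriminationProbability:
    def test_trivial_extremes(self, pp_config):
        controls = control_like(6, seed=10)
        env = control_envelope(controls, pp_config)
        patients = control_like(1, seed=11)
        prof = discrimination_probability(patients, env, k=1e9, config=pp_config)
        np.testing.assert_array_equal(prof.probability, 0.0)
        prof2 = discrimination_probability(patients, env, k=0.0, config=pp_config)
        # |dev| > 0 almost surely at every wavenumber
        assert prof2.probability.min() >= 99.9

    def test_probability_invariant_to_patient_order(self, pp_config):
        controls = control_like(6, seed=12)
        env = control_envelope(controls, pp_config)
        patients = control_like(5, seed=13)
        reversed_patients = SpectrumSet(list(patients)[::-1])
        a = discrimination_probability(patients, env, config=pp_config)
        b = discrimination_probability(reversed_patients, env, config=pp_config)
        np.testing.assert_array_equal(a.probability, b.probability)

    def test_probability_bounds_and_flag_consistency(self, default_cohort, pp_config):
        controls = preprocess_set(default_cohort.select("control"), pp_config, average=False)
        env = control_envelope(controls, pp_config)
        patients = preprocess_set(
            SpectrumSet([s for s in default_cohort if s.group != "control"]),
            pp_config,
        )
        prof = discrimination_probability(patients, env, config=pp_config)
        assert prof.probability.min() >= 0 and prof.probability.max() <= 100
        np.testing.assert_allclose(prof.probability, 100 * prof.flagged.mean(axis=0))

    def test_power_is_monotone_in_injected_magnitude(self, pp_config):
        band = synth.SIGNATURE_BAND
        power = []
        for mag in (0.0, 1.0, 2.0, 5.0):
            cohort = synth.synth_cohort(
                {"control": 4, "classic": 8},
                synth.NoiseModel(seed=21),
                replicates=3,
                signature=(band, mag) if mag else None,
            )
            controls = preprocess_set(cohort.select("control"), pp_config, average=False)
            env = control_envelope(controls, pp_config)
            patients = preprocess_set(
                SpectrumSet([s for s in cohort if s.group != "control"]), pp_config
            )
            prof = discrimination_probability(patients, env, config=pp_config)
            power.append(prof.probability[band.mask(prof.grid)].mean())
        assert all(b >= a for a, b in zip(power, power[1:]))
        assert power[-1] == 100.0


class TestBandSummaries:
    def make_profile(self, grid, prob):
        from mbspec.dynamics import DynamicsProfile

        prob = np.asarray(prob, dtype=float)
        return DynamicsProfile(
            grid=np.asarray(grid, dtype=float),
            probability=prob,
            per_group={"classic": prob},
            flagged=np.atleast_2d(prob > 50),
            groups=np.array(["classic"]),
            sample_ids=np.array(["p0"]),
            k_threshold=2.0,
        )

    def test_constant_probability_collapses_range(self):
        prof = self.make_profile([1000, 1001, 1002], [70, 70, 70])
        s = band_summary(prof, (Region(1000, 1002),))[0]
        assert s.prob_min == s.prob_max == 70

    def test_min_max_range_cell(self):
        prof = self.make_profile([1000, 1001], [60, 100])
        s = band_summary(prof, (Region(1000, 1001),))[0]
        assert (s.prob_min, s.prob_max) == (60, 100)
        table = summary_table([s])
        assert table.iloc[0]["all_MB"] == "60-100"

    def test_band_off_grid_errors(self):
        prof = self.make_profile([1000, 1001], [0, 0])
        with pytest.raises(SpectrumError):
            band_summary(prof, (Region(1500, 1501),))

    def test_scan_empty_when_probability_zero(self):
        prof = self.make_profile(np.arange(1000, 1050), np.zeros(50))
        assert scan_candidate_bands(prof) == []

    def test_scan_finds_single_plateau_endpoints(self):
        grid = np.arange(1000, 1050)
        prob = np.zeros(50)
        prob[10:21] = 90.0
        prof = self.make_profile(grid, prob)
        found = scan_candidate_bands(prof, threshold=80.0)
        assert len(found) == 1
        assert (found[0].region.lo, found[0].region.hi) == (1010.0, 1020.0)

    def test_scan_covers_injected_band(self, default_cohort, pp_config):
        controls = preprocess_set(default_cohort.select("control"), pp_config, average=False)
        env = control_envelope(controls, pp_config)
        patients = preprocess_set(
            SpectrumSet([s for s in default_cohort if s.group != "control"]), pp_config
        )
        prof = discrimination_probability(patients, env, config=pp_config)
        regions = [(s.region.lo, s.region.hi) for s in scan_candidate_bands(prof)]
        assert any(lo <= 1714 and hi >= 1716 for lo, hi in regions)

    def test_marker_band_list_is_on_grid(self, pp_config):
        env = control_envelope(control_like(2), pp_config)
        for band in MARKER_BANDS:
            assert band.mask(env.grid).any()
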