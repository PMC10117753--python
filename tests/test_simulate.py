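"""Synthetic cohort generator: determinism, spectral fidelity, coupling,
TCD behaviour, artifact injection, recovery after declamping."""

import numpy as np
import pytest
from scipy import stats

from qeegmon.montage import BIPOLAR_CHANNELS, bipolar_derive
from qeegmon.simulate import (CohortSpec, PatientScenario, draw_scenarios,
                              inject_artifact, iter_cohort, simulate_patient)
from qeegmon.spectral import BANDS, band_power, epoch_qeeg, welch_estimate


def alpha_ratio(rec, window_base, window_test, electrodes):
    """Hemisphere alpha-power ratio between two windows (sum over electrodes)."""
    fs = rec.sampling_rate
    def power(window):
        i0, i1 = (int(t * fs) for t in window)
        return sum(
            band_power(welch_estimate(rec.channel(e)[i0:i1], fs), BANDS["alpha"])
            for e in electrodes
        )
    return power(window_test) / power(window_base)


class TestScenarioValidation:
    def test_label_follows_severity(self):
        sc = PatientScenario("P1", 55.0, 0.6, 0.2, 0.2, 60.0, 185.0, "left")
        assert sc.ischemic
        sc2 = PatientScenario("P1", 55.0, 0.5, 0.2, 0.2, 60.0, 185.0, "left")
        assert not sc2.ischemic  # boundary: exactly 50% drop is non-ischemic

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            PatientScenario("P1", 55.0, 0.2, 0.0, 0.0, 100.0, 50.0, "left")

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="ischemic_fraction"):
            CohortSpec(n_patients=10, ischemic_fraction=1.5)
        with pytest.raises(ValueError, match="sampling_rate"):
            CohortSpec(sampling_rate=50.0)
        with pytest.raises(ValueError, match="finite"):
            CohortSpec(band_power_profile={"delta": np.nan, "theta": 1,
                                          "alpha": 1, "beta": 1})


class TestCohortStructure:
    @pytest.mark.parametrize("n,frac,expected", [
        (63, 20 / 63, 20),  # the reference cohort: 20 ischemic / 43 not
        (55, 17 / 55, 17),  # the minimum powered sample: 17 / 38
        (10, 0.5, 5),
    ])
    def test_exact_ischemic_count(self, n, frac, expected):
        spec = CohortSpec(n_patients=n, ischemic_fraction=frac, seed=3)
        scenarios = draw_scenarios(spec, np.random.default_rng(3))
        assert sum(s.ischemic for s in scenarios) == expected
        assert all(s.ischemic == (s.rho > 0.5) for s in scenarios)

    def test_seeded_determinism_bit_identical(self):
        spec = CohortSpec(n_patients=3, ischemic_fraction=0.4, seed=21,
                          duration=190.0, declamp_time=185.0)
        first = list(iter_cohort(spec))
        second = list(iter_cohort(spec))
        for (s1, r1, t1), (s2, r2, t2) in zip(first, second):
            assert s1 == s2
            assert np.array_equal(r1.data, r2.data)
            assert t1.vmca_at == t2.vmca_at

    def test_monotone_coupling_over_cohort(self):
        spec = CohortSpec(n_patients=63, seed=5)
        scenarios = draw_scenarios(spec, np.random.default_rng(5))
        rho = [s.rho for s in scenarios]
        a = [s.alpha_attenuation for s in scenarios]
        assert stats.spearmanr(rho, a).statistic > 0


class TestTcdTrace:
    def test_drop_with_noise_bound(self, short_spec):
        sc = PatientScenario("P1", 50.0, 0.6, 0.2, 0.2, 60.0, 185.0, "left")
        _, trace = simulate_patient(sc, short_spec, np.random.default_rng(0))
        for tp in ("T1", "T2", "T3"):
            ratio = trace.vmca_at[tp] / trace.baseline_vmca
            assert 0.37 <= ratio <= 0.43  # 0.4 * (1 +/- 3% noise)
        from qeegmon.detect import label_from_tcd
        assert label_from_tcd(trace, "T1").ischemic

    def test_noise_free_tcd_is_exact(self):
        spec = CohortSpec(seed=1, duration=190.0, declamp_time=185.0,
                          tcd_noise=0.0)
        sc = PatientScenario("P1", 50.0, 0.3, 0.0, 0.0, 60.0, 185.0, "left")
        _, trace = simulate_patient(sc, spec, np.random.default_rng(0))
        assert trace.vmca_at["T2"] == pytest.approx(35.0)

    def test_gold_counts_match_ground_truth(self):
        spec = CohortSpec(n_patients=12, ischemic_fraction=1 / 3, seed=9,
                          duration=190.0, declamp_time=185.0)
        from qeegmon.detect import label_from_tcd
        labels = []
        truth = []
        for sc, _, trace in iter_cohort(spec):
            labels.append(label_from_tcd(trace, "T1").ischemic)
            truth.append(sc.ischemic)
        assert labels == truth
        assert sum(labels) == 4


class TestSpectralBehaviour:
    def test_no_ischemia_identity(self, quiet_patient):
        # rho = a = d = 0: post-clamp band powers equal pre-clamp ones
        _, rec, _ = quiet_patient
        ratio = alpha_ratio(rec, (10.0, 50.0), (70.0, 110.0),
                            ("Fp1", "F3", "C3", "P3"))
        assert ratio == pytest.approx(1.0, rel=0.10)

    def test_half_alpha_attenuation_at_t2(self, short_spec):
        # a = 0.5: surgical-hemisphere alpha power at T2 is half of baseline;
        # averaged over replicate patients to beat the Welch variance of
        # single 10-s epochs
        left = ("Fp1", "F3", "F7", "C3", "P3", "T3", "T5", "O1")
        ratios = []
        for k in range(4):
            sc = PatientScenario(f"P{k}", 55.0, 0.7, 0.5, 0.0, 60.0, 185.0,
                                 "left")
            rec, _ = simulate_patient(sc, short_spec,
                                      np.random.default_rng(800 + k))
            ratios.append(alpha_ratio(rec, (50.0, 60.0), (110.0, 120.0), left))
        assert np.mean(ratios) == pytest.approx(0.5, rel=0.15)

    def test_contralateral_hemisphere_untouched(self, ischemic_patient):
        _, rec, _ = ischemic_patient
        right = ("Fp2", "F4", "F8", "C4", "P4", "T4", "T6", "O2")
        ratio = alpha_ratio(rec, (50.0, 60.0), (110.0, 120.0), right)
        assert ratio == pytest.approx(1.0, rel=0.2)

    def test_pre_clamp_band_powers_match_profile(self, quiet_patient, short_spec):
        _, rec, _ = quiet_patient
        for electrode in ("F3", "C4", "O1"):
            est = welch_estimate(rec.channel(electrode)[: int(50 * 256)], 256.0)
            for band, target in short_spec.band_power_profile.items():
                measured = band_power(est, BANDS[band])
                assert measured == pytest.approx(target, rel=0.15)

    def test_recovery_after_declamp(self, short_spec):
        # values return to baseline once the clamp is released
        spec = CohortSpec(seed=1, duration=260.0, clamp_time=60.0,
                          declamp_time=200.0)
        sc = PatientScenario("P1", 55.0, 0.8, 0.3, 0.45, 60.0, 200.0, "left")
        rec, _ = simulate_patient(sc, spec, np.random.default_rng(31))
        left = ("Fp1", "F3", "F7", "C3", "P3", "T3", "T5", "O1")
        during = alpha_ratio(rec, (20.0, 55.0), (120.0, 155.0), left)
        after = alpha_ratio(rec, (20.0, 55.0), (215.0, 250.0), left)
        assert during < 0.85
        assert after == pytest.approx(1.0, rel=0.12)

    def test_ischemic_ra_adr_decline_on_surgical_side(self, ischemic_patient):
        _, rec, _ = ischemic_patient
        baseline = epoch_qeeg(rec, "left", "TB")
        at_t2 = epoch_qeeg(rec, "left", "T2")
        n_ra_down = sum(t.ra < b.ra for b, t in zip(baseline, at_t2))
        n_adr_down = sum(t.adr < b.adr for b, t in zip(baseline, at_t2))
        assert n_ra_down == 8
        assert n_adr_down == 8


class TestArtifactInjection:
    def test_unknown_electrode_named_in_error(self, quiet_patient):
        _, rec, _ = quiet_patient
        with pytest.raises(KeyError, match="Cz"):
            inject_artifact(rec, "Cz-T3", (0.0, 1.0))

    def test_empty_window_is_identity(self, quiet_patient):
        _, rec, _ = quiet_patient
        out = inject_artifact(rec, "F7-T3", (10.0, 10.0))
        assert np.array_equal(out.data, rec.data)

    def test_artifact_is_local_and_large(self, quiet_patient):
        _, rec, _ = quiet_patient
        clamp = rec.event_time("clamp")
        window = (clamp + 110.0, clamp + 120.0)
        out = inject_artifact(rec, "F7-T3", window)
        fs = rec.sampling_rate
        i0, i1 = int(window[0] * fs), int(window[1] * fs)
        # amplitude reaches >= 5x the channel SD on the touched electrode
        delta = out.channel("F7") - rec.channel("F7")
        assert np.abs(delta[i0:i1]).max() >= 5 * rec.channel("F7").std()
        # confined to the window ...
        assert np.array_equal(delta[:i0], np.zeros(i0))
        # ... and to the pair: all other electrodes bit-identical
        for e in rec.labels:
            if e not in ("F7", "T3"):
                assert np.array_equal(out.channel(e), rec.channel(e))

    def test_artifact_depresses_ra_on_touched_channel_only(self, quiet_patient):
        _, rec, _ = quiet_patient
        clamp = rec.event_time("clamp")
        out = inject_artifact(rec, "F7-T3", (clamp + 110.0, clamp + 120.0))
        clean = {q.channel.index: q.ra for q in epoch_qeeg(rec, "left", "T3")}
        dirty = {q.channel.index: q.ra for q in epoch_qeeg(out, "left", "T3")}
        assert dirty[4] < clean[4]  # F7-T3 is channel 4
        assert dirty[5] == pytest.approx(clean[5], rel=0.02)  # C3-P3 untouched
        # contralateral side is bit-identical
        contra_clean = epoch_qeeg(rec, "right", "T3")
        contra_dirty = epoch_qeeg(out, "right", "T3")
        for a, b in zip(contra_clean, contra_dirty):
            assert a.ra == b.ra


class TestIschemicDeclineProbability:
    def test_ra_adr_decline_probability_at_default_coupling(self):
        """Across a default cohort, ischemic patients' RA and ADR at T1-T3
        fall below baseline in >= 95% of channel observations (checked as a
        one-sided binomial bound on the pooled proportion)."""
        from qeegmon.pipeline import patient_qeeg_frames

        spec = CohortSpec(n_patients=63, ischemic_fraction=20 / 63, seed=1,
                          duration=190.0, declamp_time=185.0)
        declines = []
        for sc, rec, _ in iter_cohort(spec):
            if not sc.ischemic:
                continue
            _, changes = patient_qeeg_frames(sc, rec)
            declines.extend(changes["pct_change"] < 0)
        p_hat = np.mean(declines)
        se = np.sqrt(0.95 * 0.05 / len(declines))
        assert p_hat >= 0.95 - 1.645 * se
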