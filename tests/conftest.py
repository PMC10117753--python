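import numpy as np
import pytest

from qeegmon.recording import ELECTRODES_1020, EEGRecording
from qeegmon.simulate import CohortSpec, PatientScenario, simulate_patient


@pytest.fixture(scope="session")
def short_spec() -> CohortSpec:
    """Cohort spec trimmed to the minimum duration that still reaches T3."""
    return CohortSpec(seed=7, duration=190.0, declamp_time=185.0)


@pytest.fixture(scope="session")
def quiet_patient(short_spec):
    """A non-ischemic patient (no alpha/delta modulation at all)."""
    scenario = PatientScenario(
        patient_id="P00", vmca_baseline=55.0, rho=0.0,
        alpha_attenuation=0.0, delta_augmentation=0.0,
        clamp_time=60.0, declamp_time=185.0, surgical_side="left",
    )
    rec, trace = simulate_patient(scenario, short_spec,
                                  np.random.default_rng(11))
    return scenario, rec, trace


@pytest.fixture(scope="session")
def ischemic_patient(short_spec):
    """A clearly ischemic patient: half the alpha power, +50% delta."""
    scenario = PatientScenario(
        patient_id="P01", vmca_baseline=60.0, rho=0.7,
        alpha_attenuation=0.5, delta_augmentation=0.5,
        clamp_time=60.0, declamp_time=185.0, surgical_side="left",
    )
    rec, trace = simulate_patient(scenario, short_spec,
                                  np.random.default_rng(12))
    return scenario, rec, trace


def sine_recording(freq: float, amplitude: float, fs: float = 256.0,
                   duration: float = 30.0, electrode: str = "Fp1") -> EEGRecording:
    """Recording with a pure sinusoid on one electrode, zeros elsewhere."""
    n = int(duration * fs)
    t = np.arange(n) / fs
    data = np.zeros((len(ELECTRODES_1020), n))
    data[list(ELECTRODES_1020).index(electrode)] = amplitude * np.sin(2 * np.pi * freq * t)
    return EEGRecording(labels=list(ELECTRODES_1020), sampling_rate=fs,
                        data=data, events=[(duration / 2, "clamp")])
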