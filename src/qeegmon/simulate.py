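"""Synthetic intraoperative EEG + TCD cohort generator.

Emulates carotid-endarterectomy monitoring under total intravenous
anesthesia: a 16-electrode 10-20 scalp EEG sampled at 256 Hz, a carotid
clamp event that attenuates alpha power and augments delta power on the
surgical hemisphere, and recovery after declamping. Ischemia severity is
driven by the fractional drop ``rho`` of the middle-cerebral-artery
velocity (V-MCA); a patient is ground-truth ischemic when ``rho > 0.5``,
mirroring the TCD gold standard (decline of more than 50% from baseline).

Each monopolar channel is a sum of independent band-limited Gaussian
processes (delta 1-4, theta 4-8, alpha 8-13, beta 13-20 Hz) scaled to a
baseline band-power profile, plus 1/f (pink) background noise at -10 dB
relative to the total rhythmic power. After the clamp, on surgical-side
electrodes only, the alpha component ramps to ``(1 - a)`` times its
baseline power and the delta component to ``(1 + d)`` times baseline over
a 5-s raised-cosine transition, returning to baseline after declamping.

The attenuation/augmentation factors are coupled to severity through a
noisy piecewise-linear map (see :func:`couple`) whose constants were
chosen so that a default cohort reproduces the qualitative clinical
regime: relative-alpha decline cut-offs near -15%, alpha-delta-ratio
cut-offs near -25%, high but imperfect AUCs, and false calls concentrated
near the 50% V-MCA boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .recording import ELECTRODES_1020, EEGRecording, TCDTrace

__all__ = [
    "PatientScenario", "CohortSpec", "STRONG_COUPLING",
    "couple", "draw_scenarios", "simulate_patient", "simulate_cohort",
    "iter_cohort", "inject_artifact",
]

_LEFT = ("Fp1", "F3", "F7", "C3", "P3", "T3", "T5", "O1")
_RIGHT = ("Fp2", "F4", "F8", "C4", "P4", "T4", "T6", "O2")

_BAND_EDGES = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 13.0), "beta": (13.0, 20.0)}

_RAMP = 5.0  # seconds, raised-cosine transition after clamp/declamp


@dataclass
class PatientScenario:
    """Ground truth for one simulated patient."""

    patient_id: str
    vmca_baseline: float          # cm/s
    rho: float                    # fractional V-MCA drop, 0..0.95
    alpha_attenuation: float      # a in [0, 1]
    delta_augmentation: float     # d in [0, 3]
    clamp_time: float             # s
    declamp_time: float           # s
    surgical_side: str            # "left" | "right"
    artifact_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 0.95:
            raise ValueError(f"rho must be in [0, 0.95], got {self.rho}")
        if not 0 <= self.alpha_attenuation <= 1:
            raise ValueError("alpha_attenuation must be in [0, 1]")
        if not 0 <= self.delta_augmentation <= 3:
            raise ValueError("delta_augmentation must be in [0, 3]")
        if not 0 < self.clamp_time < self.declamp_time:
            raise ValueError("need declamp_time > clamp_time > 0")
        if self.vmca_baseline <= 0:
            raise ValueError("vmca_baseline must be positive")
        if self.surgical_side not in ("left", "right"):
            raise ValueError("surgical_side must be 'left' or 'right'")

    @property
    def ischemic(self) -> bool:
        """Ground-truth label; follows the TCD criterion rho > 0.5."""
        return self.rho > 0.5


#: Deterministic, strongly separated coupling for validation studies: every
#: ischemic patient gets maximal alpha loss / delta gain, every non-ischemic
#: patient none, so the downstream calibration must reach perfect accuracy.
STRONG_COUPLING: dict[str, float] = dict(
    rho0=0.5, k_a=20.0, a_max=0.9, sigma_a=0.0,
    k_d=20.0, d_max=2.0, sigma_d=0.0,
)


@dataclass
class CohortSpec:
    """Configuration of a simulated cohort.

    The defaults define the reference study conditions: 63 patients of whom
    20 are ischemic, 256 Hz sampling, clamp at 60 s and declamp at 300 s,
    and a band-power profile typical of propofol anesthesia (delta-dominant
    with a preserved anteriorized alpha rhythm).
    """

    n_patients: int = 63
    ischemic_fraction: float = 20 / 63
    seed: int = 0
    duration: float = 330.0          # s
    sampling_rate: float = 256.0     # Hz
    clamp_time: float = 60.0         # s
    declamp_time: float = 300.0      # s
    band_power_profile: dict[str, float] = field(
        default_factory=lambda: {"delta": 30.0, "theta": 15.0,
                                 "alpha": 20.0, "beta": 10.0})  # uV^2
    pink_fraction: float = 0.1       # pink power / total rhythmic power
    # severity -> (alpha attenuation, delta augmentation) coupling
    rho0: float = 0.5
    k_a: float = 3.6
    a_max: float = 0.30
    sigma_a: float = 0.04
    k_d: float = 3.6
    d_max: float = 0.45
    sigma_d: float = 0.06
    tcd_noise: float = 0.03          # multiplicative V-MCA noise bound
    artifact_rate: float = 0.0       # fraction of patients with an artifact
    vmca_baseline_range: tuple[float, float] = (40.0, 70.0)  # cm/s

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if not 0 < self.ischemic_fraction < 1:
            raise ValueError("ischemic_fraction must be in (0, 1)")
        k = round(self.n_patients * self.ischemic_fraction)
        if k < 1 or k > self.n_patients - 1:
            raise ValueError("cohort needs at least one patient of each class")
        if self.sampling_rate < 70:
            raise ValueError("sampling_rate must be >= 70 Hz (2 x 35 Hz)")
        if not 0 < self.clamp_time < self.declamp_time:
            raise ValueError("need declamp_time > clamp_time > 0")
        if self.duration < self.clamp_time + 120:
            raise ValueError("duration must cover clamp_time + 120 s")
        for band, p in self.band_power_profile.items():
            if not np.isfinite(p) or p <= 0:
                raise ValueError(f"band power for {band!r} must be finite "
                                 f"and positive, got {p}")
        if not 0 <= self.tcd_noise < 0.5:
            raise ValueError("tcd_noise must be in [0, 0.5)")

    @property
    def n_ischemic(self) -> int:
        return round(self.n_patients * self.ischemic_fraction)

    def with_coupling(self, **kwargs) -> "CohortSpec":
        """Copy of the spec with coupling constants replaced."""
        return replace(self, **kwargs)


def couple(rho: float, spec: CohortSpec, rng: np.random.Generator) -> tuple[float, float]:
    """Map severity ``rho`` to (alpha attenuation, delta augmentation).

    Both factors rise linearly once ``rho`` exceeds ``rho0``, saturate at
    ``a_max`` / ``d_max``, and carry additive Gaussian noise so the two
    groups overlap near the 50% V-MCA boundary.
    """
    a = float(np.clip(spec.k_a * (rho - spec.rho0), 0, spec.a_max))
    d = float(np.clip(spec.k_d * (rho - spec.rho0), 0, spec.d_max))
    if spec.sigma_a > 0:
        a += rng.normal(0, spec.sigma_a)
    if spec.sigma_d > 0:
        d += rng.normal(0, spec.sigma_d)
    return float(np.clip(a, 0, 1)), float(np.clip(d, 0, 3))


def draw_scenarios(spec: CohortSpec, rng: np.random.Generator) -> list[PatientScenario]:
    """Draw the cohort's ground-truth scenarios.

    Exactly ``round(n_patients * ischemic_fraction)`` patients receive a
    severity ``rho`` above 0.5 (uniform on [0.55, 0.85]); the rest draw
    uniformly from [0.05, 0.45], keeping both groups clear of the boundary
    so the TCD noise cannot flip a gold label.
    """
    k = spec.n_ischemic
    rho = np.concatenate([
        rng.uniform(0.55, 0.85, size=k),
        rng.uniform(0.05, 0.45, size=spec.n_patients - k),
    ])
    rng.shuffle(rho)
    width = len(str(spec.n_patients))
    scenarios = []
    for i, r in enumerate(rho):
        a, d = couple(float(r), spec, rng)
        side = "left" if rng.random() < 0.5 else "right"
        artifacts: list[str] = []
        if spec.artifact_rate > 0 and rng.random() < spec.artifact_rate:
            pair = _LEFT if side == "left" else _RIGHT
            j = int(rng.integers(0, len(pair) - 1))
            artifacts.append(f"{pair[j]}-{pair[j + 1]}")
        scenarios.append(PatientScenario(
            patient_id=f"P{i + 1:0{width}d}",
            vmca_baseline=float(rng.uniform(*spec.vmca_baseline_range)),
            rho=float(r),
            alpha_attenuation=a,
            delta_augmentation=d,
            clamp_time=spec.clamp_time,
            declamp_time=spec.declamp_time,
            surgical_side=side,
            artifact_channels=artifacts,
        ))
    return scenarios


def _band_limited_noise(n: int, fs: float, low: float, high: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [low, high] Hz (FFT shaping)."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spectrum = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    mask = (freqs >= low) & (freqs <= high)
    spectrum *= mask
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


_PINK_LOW, _PINK_HIGH = 0.5, 35.0


def _welch_band_gain(lo_src: float, hi_src: float, lo_dst: float, hi_dst: float,
                     fs: float, window_sec: float = 2.0) -> float:
    """Expected fraction of a flat [lo_src, hi_src] Hz process's power that a
    Hann-window Welch estimate attributes to the [lo_dst, hi_dst] Hz band.

    Welch smears the true PSD with the window's power kernel, so a few
    percent of each rhythmic component leaks past its band edges. The
    generator inverts this linear map (see :func:`_calibrated_powers`) so
    that *measured* band powers match the requested profile.
    """
    n = int(round(window_sec * fs))
    w = np.hanning(n)
    pad = 8
    kernel = np.abs(np.fft.rfft(w, n * pad)) ** 2
    kernel /= kernel.sum()
    df = fs / (n * pad)
    freqs = np.arange(kernel.size) * df
    # distribute source power uniformly and convolve with the (symmetric) kernel
    src = ((freqs >= lo_src) & (freqs < hi_src)).astype(float)
    sym_kernel = np.concatenate([kernel[::-1], kernel[1:]])
    sym_kernel /= sym_kernel.sum()
    centre = kernel.size - 1
    full = np.convolve(src, sym_kernel)
    smeared = full[centre : centre + src.size]
    dst = (freqs >= lo_dst) & (freqs < hi_dst)
    return float(smeared[dst].sum() / src.sum())


def _calibrated_powers(profile: dict[str, float], pink_power: float,
                       fs: float) -> dict[str, float]:
    """Component variances such that expected Welch band powers (2-s Hann
    windows) of rhythm + pink match the profile. Solves the 4x4 linear
    leakage system; raises if the profile is infeasible."""
    bands = list(_BAND_EDGES)
    gain = np.array([[_welch_band_gain(*_BAND_EDGES[src], *_BAND_EDGES[dst], fs)
                      for src in bands] for dst in bands])
    target = np.array([
        profile[b] - pink_power * _pink_band_fraction(*_BAND_EDGES[b])
        for b in bands
    ])
    powers = np.linalg.solve(gain, target)
    if np.any(powers <= 0):
        raise ValueError("band_power_profile infeasible: a component power "
                         "would be non-positive after noise calibration")
    return dict(zip(bands, powers))


def _pink_band_fraction(low: float, high: float) -> float:
    """Fraction of unit-variance pink-noise power inside [low, high] Hz.

    The pink generator has PSD proportional to ``1/max(f, 1)`` on
    [0.5, 35] Hz, so band fractions have a closed form used to scale the
    rhythmic components such that total band powers hit the profile.
    """
    def cumulative(f: float) -> float:
        f = min(max(f, _PINK_LOW), _PINK_HIGH)
        return (f - _PINK_LOW) if f <= 1.0 else (1.0 - _PINK_LOW) + np.log(f)
    norm = cumulative(_PINK_HIGH)
    return (cumulative(high) - cumulative(low)) / norm


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise band-limited to 0.5-35 Hz."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spectrum = (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    mask = (freqs >= 0.5) & (freqs <= 35.0)
    amp = np.zeros_like(freqs)
    amp[mask] = 1.0 / np.sqrt(np.maximum(freqs[mask], 1.0))
    x = np.fft.irfft(spectrum * amp, n=n)
    return x / x.std()


def _gain_envelope(t: np.ndarray, clamp: float, declamp: float,
                   target_gain: float) -> np.ndarray:
    """Amplitude envelope: 1 before clamp, ``target_gain`` during clamping,
    1 again after declamp, with raised-cosine ramps of 5 s."""
    def ramp(t0: float) -> np.ndarray:
        u = np.clip((t - t0) / _RAMP, 0.0, 1.0)
        return 0.5 * (1 - np.cos(np.pi * u))
    return 1.0 + (target_gain - 1.0) * (ramp(clamp) - ramp(declamp))


def simulate_patient(scenario: PatientScenario, spec: CohortSpec,
                     rng: np.random.Generator) -> tuple[EEGRecording, TCDTrace]:
    """Generate one patient's EEG recording and TCD trace.

    Surgical-side electrodes have their alpha component scaled to
    ``(1 - a)`` times baseline power and delta to ``(1 + d)`` times during
    the clamp interval; the contralateral hemisphere and the theta/beta/pink
    components are untouched. V-MCA at T1/T2/T3 equals
    ``baseline * (1 - rho)`` with multiplicative noise bounded by
    ``spec.tcd_noise``.
    """
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    surgical = _LEFT if scenario.surgical_side == "left" else _RIGHT

    gain_a = _gain_envelope(t, scenario.clamp_time, scenario.declamp_time,
                            np.sqrt(1.0 - scenario.alpha_attenuation))
    gain_d = _gain_envelope(t, scenario.clamp_time, scenario.declamp_time,
                            np.sqrt(1.0 + scenario.delta_augmentation))

    pink_power = spec.pink_fraction * sum(spec.band_power_profile.values())
    comp_power = _calibrated_powers(spec.band_power_profile, pink_power, fs)
    data = np.empty((len(ELECTRODES_1020), n))
    for i, electrode in enumerate(ELECTRODES_1020):
        x = np.sqrt(pink_power) * _pink_noise(n, fs, rng)
        for band, (low, high) in _BAND_EDGES.items():
            comp = (np.sqrt(comp_power[band])
                    * _band_limited_noise(n, fs, low, high, rng))
            if electrode in surgical:
                if band == "alpha":
                    comp = comp * gain_a
                elif band == "delta":
                    comp = comp * gain_d
            x += comp
        data[i] = x

    rec = EEGRecording(
        labels=list(ELECTRODES_1020), sampling_rate=fs, data=data,
        events=[(scenario.clamp_time, "clamp"),
                (scenario.declamp_time, "declamp")],
        side=scenario.surgical_side, patient_id=scenario.patient_id,
    )

    for pair in scenario.artifact_channels:
        t3 = scenario.clamp_time + 120.0
        rec = inject_artifact(rec, pair, (t3 - 10.0, t3))

    vmca = {}
    for tp in ("T1", "T2", "T3"):
        noise = rng.uniform(-spec.tcd_noise, spec.tcd_noise) if spec.tcd_noise else 0.0
        vmca[tp] = scenario.vmca_baseline * (1.0 - scenario.rho) * (1.0 + noise)
    trace = TCDTrace(patient_id=scenario.patient_id,
                     baseline_vmca=scenario.vmca_baseline, vmca_at=vmca)
    return rec, trace


def iter_cohort(spec: CohortSpec) -> Iterator[tuple[PatientScenario, EEGRecording, TCDTrace]]:
    """Stream the cohort one patient at a time (constant memory).

    Deterministic given ``spec.seed``: each patient draws from an
    independent child stream spawned from the cohort seed, so the same
    spec always yields bit-identical data.
    """
    root = np.random.SeedSequence(spec.seed)
    scen_rng = np.random.default_rng(root.spawn(1)[0])
    scenarios = draw_scenarios(spec, scen_rng)
    streams = root.spawn(len(scenarios) + 1)[1:]
    for scenario, stream in zip(scenarios, streams):
        rec, trace = simulate_patient(scenario, spec, np.random.default_rng(stream))
        yield scenario, rec, trace


def simulate_cohort(spec: CohortSpec) -> list[tuple[PatientScenario, EEGRecording, TCDTrace]]:
    """Materialize the whole cohort as a list (see :func:`iter_cohort`)."""
    return list(iter_cohort(spec))


def inject_artifact(rec: EEGRecording, channel: str,
                    time_window: tuple[float, float]) -> EEGRecording:
    """Return a copy of ``rec`` with an electrode artifact on one pair.

    Emulates the high-amplitude low-frequency transient produced by
    touching the electrode cap: a 1.5-Hz oscillation under a Hann envelope,
    confined to ``time_window``, added to both electrodes of the bipolar
    pair (at 8x and 3x the channel standard deviation, so it does not
    cancel in the bipolar derivation). All other electrodes are untouched;
    an empty window returns the recording unchanged.

    ``channel`` is an electrode-pair name such as ``"F7-T3"``.
    """
    try:
        first, second = channel.split("-")
    except ValueError:
        raise ValueError(f"channel must look like 'F7-T3', got {channel!r}") from None
    for label in (first, second):
        if label not in rec.labels:
            raise KeyError(f"electrode {label!r} not present in recording")

    out = rec.copy()
    start, end = time_window
    if end <= start:
        return out
    fs = rec.sampling_rate
    i0 = max(0, int(round(start * fs)))
    i1 = min(rec.n_samples, int(round(end * fs)))
    if i1 <= i0:
        return out
    seg_t = np.arange(i1 - i0) / fs
    envelope = np.hanning(i1 - i0)
    wave = np.sin(2 * np.pi * 1.5 * seg_t) * envelope
    for label, factor in ((first, 8.0), (second, 3.0)):
        idx = rec.labels.index(label)
        out.data[idx, i0:i1] += factor * rec.data[idx].std() * wave
    return out
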