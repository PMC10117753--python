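# Methods

## The monitoring problem

During carotid endarterectomy (CEA) the internal carotid artery is clamped,
which can drop cerebral perfusion on the surgical hemisphere enough to cause
ischemia. Two quantitative-EEG (QEEG) trend statistics are sensitive to this:
cortical hypoperfusion attenuates fast alpha activity and augments slow delta
activity, so the **relative alpha percentage**

RA = 100 · P(8–13 Hz) / P(1–20 Hz)

and the **alpha–delta ratio**

ADR = P(8–13 Hz) / P(1–4 Hz)

both fall. The package expresses each statistic as a signed percent change
from the pre-clamp baseline at three protocol time points (30 s, 1 min and
2 min after clamping), calibrates a decline cut-off per bipolar channel by
ROC against a transcranial-Doppler (TCD) gold standard — middle cerebral
artery velocity (V-MCA) falling to strictly below 50% of baseline — and
summarizes agreement with sensitivity, specificity, predictive values and
Cohen's kappa from the 2×2 contingency table.

## Spectral estimation

* Band edges follow standard clinical convention: delta 1–4, theta 4–8,
  alpha 8–13, beta 13–20 Hz; the RA denominator band is 1–20 Hz.
* Each bipolar series (first electrode minus second, eight
  mirror-symmetric anterior-to-posterior pairs per hemisphere) is band-pass
  filtered at 1.0–35 Hz with a 4th-order zero-phase Butterworth filter,
  matching the analog corners of the monitoring hardware without phase
  distortion.
* The PSD is a Welch estimate with 2-s Hann windows at 50% overlap over a
  10-s epoch ending at each time point (the baseline epoch ends at the
  clamp instant). Band power is the trapezoidal integral of the PSD with
  linearly interpolated band edges, so disjoint bands tile the 1–20 Hz
  total exactly.
* **Estimator variance.** A band of width *B* Hz estimated from *T* seconds
  of Gaussian EEG has roughly 2·*B*·*T* degrees of freedom; at *B* = 5 Hz
  (alpha) and *T* = 10 s the band-power SD is ≈ 14%, giving a per-channel
  RA percent-change noise of ≈ 12–15% and a larger one for ADR (the 3-Hz
  delta band is noisier). This floor, not the generator, limits single-cell
  diagnostic accuracy, which is why trend monitors average over time; the
  stability and fidelity tests therefore use longer (≥ 50 s) windows or
  averages over electrodes/patients when they need to see through the
  estimator noise.

## ROC calibration and agreement

Every observed percent change is a candidate threshold; a case is positive
when its change is at or below the threshold (the achieved cut-off is
inclusive). The optimal cut-off maximizes the Youden index
J = sensitivity + specificity − 1, with ties broken toward higher
sensitivity — a monitor should not miss ischemia. AUC is the trapezoidal
area under the empirical curve (equal to the Mann–Whitney statistic with
tie correction); its 95% CI uses the closed-form Hanley–McNeil standard
error rather than bootstrap so results are exactly reproducible. Reported
percents are rounded half-up to 1 decimal and kappa/AUC to 3 decimals,
matching clinical statistics software.

Published accuracy tables for this protocol can be verified exactly:
because the ischemic/non-ischemic group sizes (20/43) are known, printed
sensitivity and specificity determine the 2×2 table (tp = half-up
round(sens/100 × 20), tn = round(spec/100 × 43)), from which PPV, NPV and
kappa follow. `verify_printed_metrics` recomputes all 48 published cells;
45 reproduce exactly at printed precision and three (RA1 at T1 and RA8 at
T3, NPV 95.7 vs computed 95.1; RA6 at T2, kappa 0.747 vs computed 0.666)
are internally inconsistent as printed — apparent misprints, reported as
mismatches rather than silently corrected.

## The synthetic cohort generator

No public intraoperative EEG+TCD dataset accompanies this protocol, so the
generator produces cohorts with the statistical structure the analysis
assumes.

* **Signal model.** Each of the 16 monopolar 10-20 electrodes carries a sum
  of four independent band-limited Gaussian processes plus 1/f (pink)
  background noise at −10 dB relative to total rhythmic power, band-limited
  to 0.5–35 Hz. The default band-power profile (delta 30, theta 15,
  alpha 20, beta 10 µV² per channel) is delta-dominant with a preserved
  alpha rhythm, as seen under propofol-based total intravenous anesthesia;
  no published per-band amplitudes exist for this protocol, so the profile
  is a simulator choice. Because Welch windowing smears a few percent of
  each component past its band edges, component variances are obtained by
  inverting the deterministic 4×4 band-leakage gain matrix of the 2-s Hann
  kernel, so *measured* pre-clamp band powers match the profile (residual
  bias ≤ ~3%).
* **Clamp dynamics.** From the clamp event, surgical-side electrodes ramp
  the alpha component to (1 − a) × baseline power and delta to
  (1 + d) × baseline over a 5-s raised-cosine transition; both return to
  baseline after declamping. The contralateral hemisphere is untouched.
  Defaults: clamp at 60 s, declamp at 300 s, 256 Hz, 330 s duration.
* **Severity coupling.** Ischemia severity is the fractional V-MCA drop ρ;
  ground truth is ischemic iff ρ > 0.5. Non-ischemic patients draw
  ρ ~ U[0.05, 0.45] and ischemic ρ ~ U[0.55, 0.85] (exactly
  round(n × ischemic fraction) ischemic per cohort), keeping both groups
  clear of the boundary so the ≤ 3% multiplicative TCD noise cannot flip a
  gold label. The coupling a = clip(k_a(ρ − 0.5), 0, a_max) + N(0, σ_a)
  (and likewise d) uses defaults k_a = k_d = 3.6, a_max = 0.30,
  d_max = 0.45, σ_a = 0.04, σ_d = 0.06. These were calibrated once, by
  band-power algebra and a design simulation, so that a default cohort
  reproduces the clinical regime reported for this protocol: near-boundary
  ischemic patients show RA declines of about −20% (saturating near −36%),
  RA Youden cut-offs land in the −10 to −25% range with AUCs around
  0.90–0.97, ADR cut-offs are deeper (−20 to −45%) with somewhat lower
  AUCs, and false calls concentrate near the 50% V-MCA boundary. A steeper
  deterministic preset (`STRONG_COUPLING`, σ = 0, saturated effects) gives
  complete separation and is used to validate that the calibration
  recovers perfect accuracy when the signal is unambiguous.
* **Artifacts.** An electrode-touch artifact is modelled as a 1.5-Hz
  oscillation under a Hann envelope added to both electrodes of one
  bipolar pair at 8× and 3× the channel SD (unequal, so the bipolar
  difference does not cancel); it inflates delta and depresses RA on the
  touched channel only, emulating the false positives such artifacts cause
  clinically.
* **Determinism.** Each patient consumes an independent child stream
  spawned from the cohort seed; identical spec + seed gives bit-identical
  cohorts and byte-identical pipeline CSVs.

### What the generator does not emulate

Anesthetic-depth dynamics (burst suppression, BIS), emboli signatures in
TCD, chronic infarct asymmetries, eye-blink/EMG artifacts, electrode
impedance drift, and continuous V-MCA traces (only the four protocol
values are produced). Passing tests therefore show that the analysis
recovers the planted spectral structure under realistic estimator noise —
not that the specific clinical cut-off values transfer to real patients,
which requires the original recordings.

## Numerical and design choices

* EDF+ output is written by a small built-in 16-bit EDF+C writer (one-second
  records, annotations channel carrying clamp/declamp); reading goes
  through MNE, which doubles as an independent round-trip check. Round-trip
  error is bounded by half a quantization step of the per-channel physical
  range.
* The published channel-pair scheme lists pair 2 as F3-C3/F4-C3; the right
  side is implemented as F4-C4, treating F4-C3 as a typographical error
  (every other pair is mirror-symmetric across the midline).
* Gold-standard boundary: a decline of exactly 50% is non-ischemic (strict
  inequality); a percent change exactly at the cut-off classifies positive.
* The gold label defaults to the T1 V-MCA value and is configurable; the
  clinical grouping time point is not further specified by the protocol.
* Degenerate epochs (zero total or delta power) raise errors rather than
  returning infinities; zero-denominator accuracy metrics are NaN-flagged.
* Problem sizes in the test suite and acceptance script are desk-scale by
  design: recordings are trimmed to 190 s (clamp at 60 s, declamp at
  185 s — still covering T3 plus the baseline epoch), parameter-recovery
  cohorts use 200 patients, and fidelity checks average a handful of
  replicate patients.

## Known limitations

* Per-cell cut-offs carry the full Welch noise of single 10-s epochs; a
  clinical deployment would average trends over longer windows.
* The Hanley–McNeil CI is slightly conservative for heavily tied data.
* The generator's hemispheres are spatially unstructured (independent
  electrodes); no volume-conduction correlation is modelled, so bipolar
  derivations have twice the monopolar power rather than a realistic
  spatial covariance.
* kappa/PPV/NPV reconstruction assumes the published group sizes are exact.
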