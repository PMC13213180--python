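# hreflex

Analysis of soleus H-reflex and M-wave **recruitment curves** at reduced EMG
sampling rates, built for closed-loop evoked-potential conditioning setups
where the stimulation target must be derived from the curves in (pseudo-)real
time.

Electrical stimulation of the tibial nerve evokes two EMG responses in the
soleus: the direct motor response (M-wave, ~6–20 ms latency) and the
monosynaptic Hoffmann reflex (H-reflex, ~28–45 ms). Ramping the stimulation
intensity *s* and measuring each response's mean rectified value (MRV) inside
a fixed post-stimulus window yields two recruitment curves:

- M-wave — saturating logistic: `M(s) = M_max / (1 + exp(-b_m (s - c_m)))`
- H-reflex — "hill" curve, the product of a rising and a falling sigmoid:
  `H(s) = h · σ(b_r (s - c_r)) · σ(-b_f (s - c_f))`

From the fitted curves six parameters are extracted — normalized curve MSEs,
`H_max`, `M_max`, the stimulation intensities at `H_max` and at `M_threshold`
(operationalized as 5 % of `M_max`) — plus the **target stimulation
intensity**: the smallest *s* where the fitted M-wave reaches 10 % of
`M_max`, flagged if the H-reflex there is below 75 % of `H_max`.

The scientific question the package addresses: portable acquisition systems
(EEG-headset class) sample EMG at 320–640 Hz instead of the laboratory's
3200 Hz — do the recruitment-curve parameters that define the stimulation
target survive that degradation? The package provides:

- `hreflex.simulate` — synthetic recruitment-curve runs with known
  ground-truth recruitment functions (stimulus artifact + exponential decay
  tail, sharp biphasic M-wave, ~100 Hz H-reflex wavelet, band-limited
  background EMG, multiplicative trial-to-trial variability, background-EMG
  trigger gating);
- `hreflex.preprocess` — Butterworth filtering, anti-alias low-pass +
  integer decimation with floor-mapped trigger indices (deliberately keeping
  the trigger-quantization jitter of a low-rate system), 600 ms epoching;
- `hreflex.delineate` — artifact blanking, exponential-decay removal, MRV
  measurement with investigator-style fixed windows or automated whole-run
  window delineation (per-latency-bin model comparison);
- `hreflex.fit` — scikit-learn-style `LogisticRecruitment` /
  `HillRecruitment` estimators, multi-start bounded least squares, parameter
  extraction, target intensity;
- `hreflex.stats` — Friedman test with Kendall's *w* (= χ²/(N(k−1))) and an
  exact small-sample mode, Tukey-style post-hoc on ranks, ICC (two-way,
  absolute agreement, single measurement), TOST equivalence by 90 % CI
  inclusion, Bland–Altman limits of agreement;
- `hreflex.pipeline` / CLI — the full multi-rate pseudo-online experiment.

## Worked example

```python
import numpy as np
from hreflex import (
    RecruitmentTruth, SweepProtocol, WaveformSpec,
    generate_run, downsample_run, manual_windows, measure_run,
    fit_recruitment, extract_params, target_intensity,
)

truth = RecruitmentTruth()          # logistic M-wave + bell-shaped H-reflex
protocol = SweepProtocol()          # 1 mA steps, 4 trials/step, 3200 Hz
wspec = WaveformSpec()              # 5 uV noise, 15% trial-to-trial CV

run = generate_run(truth, protocol, wspec, subject_id="S00", seed=42)

for rate in (3200, 640):
    degraded = run if rate == run.fs else downsample_run(run, rate)
    data = measure_run(degraded, manual_windows())
    curves = fit_recruitment(data)
    params = extract_params(curves, data)
    target, flags = target_intensity(curves, data)
    print(f"{rate:>5} Hz: Hmax {params.h_max:6.1f} uV @ {params.stim_at_hmax:.2f} mA | "
          f"Mmax {params.m_max:6.1f} uV, threshold @ {params.stim_at_mthreshold:.2f} mA | "
          f"target {target:.2f} mA {flags}")
```

prints

```
 3200 Hz: Hmax  133.7 uV @ 17.00 mA | Mmax  320.2 uV, threshold @ 17.44 mA | target 18.66 mA []
  640 Hz: Hmax  131.0 uV @ 16.99 mA | Mmax  299.7 uV, threshold @ 17.30 mA | target 18.58 mA []
```

The ground-truth H-reflex peak for this subject lies at 16.99 mA: the fitted
`stim@Hmax` recovers it to within 0.01 mA at the full rate, and the 5×
downsampled copy of the same recording lands within 0.01 mA of the full-rate
answer even though `Mmax` itself is attenuated by the anti-alias filtering —
the target-defining intensities are robust to reduced resolution while the
amplitude parameters are not. A full cohort experiment (21 subjects × 6
rates × 2 delineation methods, with the Friedman/ICC/TOST battery and a
summary report) is one call:

```sh
hreflex run --subjects 21 --seed 1 --out results/experiment
```

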