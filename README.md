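# mmrbss

Subtraction-free extraction of the auditory mismatch response (MMR) from
multichannel MEG oddball recordings, by **weighted time-delayed blind
source separation** (weighted-BSS_T/k), together with the full
component-evaluation framework needed to judge what a decomposition
actually recovered, and a synthetic oddball simulator with exported
ground truth.

## The problem

In an oddball paradigm, rare "deviant" tones interrupt a train of
repeated "standard" tones. The MMR — the brain's change-detection
response, ~100–250 ms post-stimulus over bilateral temporal cortex — is
conventionally obtained by subtracting the standard event-related field
from the deviant one, x̄_sub(n) = x̄_dev(n) − x̄_std(n). Subtraction adds
the noise of both conditions and conflates the MMR with differential
neural adaptation of the obligatory M100 response. Since the
memory-comparison account places the MMR only in deviant epochs, only
deviant epochs should be needed to isolate it.

## The method

For sensor data x(n) = A s(n) with mixing matrix A and sources s,
BSS_T/k finds one orthogonal rotation that jointly (approximately)
diagonalizes time-lagged correlation matrices of the sphered data at the
fractional delays

    τ_m = [f_s / f_p] / m,   m = 1 … k,

where f_s is the sampling rate and f_p the stimulus presentation rate
(at f_s = 1000 Hz, f_p = 2 Hz, k = 8: τ = 500, 250, 166, 125, 100, 83,
71, 62 ms). The joint diagonalization uses Jacobi-style sweeps of
closed-form Givens rotations. Responses that repeat with the stimulus
period are thereby concentrated into few components.

The *weighted* variant makes the randomly occurring deviant response
periodic and salient before decomposing:

1. **Deviant concatenation** — deviant epochs are placed end-to-end as
   new raw data with period equal to the epoch length;
2. **Window weighting** — a rectangular window multiplies samples inside
   the MMR time range [n₁, n₂] (default 96–276 ms) by 1.0 and all other
   samples by 0.2, repeated over every concatenated epoch.

Each component q is scored against a **reference standard** x̄_Ref (the
subtraction waveform restricted to MMR sensors and the MMR window, both
selected by a spatio-temporal cluster permutation test) with two
similarities:

- **C_max** — maximal |cosine| between the component's mixing column and
  the reference spatial pattern across window times (spatial match,
  in [0, 1]);
- **M_max** — maximal scalar projection (X_l, Y_l)/‖X_l‖ of the
  back-projected component waveform Y onto each reference sensor
  waveform X_l (temporal match, carries amplitude in fT/cm).

Both are z-scored over the pooled components of all methods compared;
components above z = 1.65 on either axis are *salient* (major / minor /
pseudo by quadrant). Salient components are cumulatively back-projected
in PCA order; the increment of the mean projection M_ave per added
component is its relative contribution RC(c), fitted by RC ≈ β e^(−αc),
and the number of components with fitted RC ≥ 5% is the *dominant
count* — the headline quantity: weighted-BSS_T/k concentrates the MMR
into one to three dominant components where infomax ICA spreads it over
many minor ones.

## Worked example

```python
import numpy as np
from mmrbss import (OddballDesign, SourceModel, simulate_recording,
                    RunConfig, run_methods)

design = OddballDesign(min_deviants=40, seed=1)   # 2 Hz oddball, 20% deviants
model = SourceModel.default(n_channels=24, design=design, snr=5.0)
raw, truth = simulate_recording(design, model)

results = run_methods(raw, RunConfig(seed=1),
                      combos=[("weighted", "bsstk"), ("weighted", "ica")])
bundle = results["bundles"]["weighted-bsstk"]
print(bundle["decomposition"].summary())
```

```
Decomposition Results
======================================================
method:            bsstk
channels:          24
components:        24
samples:           24000
delays (ms):       500, 250, 166, 125, 100, 83, 71, 62
sweeps:            100 (converged=False)
off-diag criterion: 1.598e+00
top components by sensor variance:
  #0     33.31 %
  ...
```

(Non-convergence at the 1e−8 rad angle tolerance is normal for noisy
data — the criterion has plateaued; it is a logged warning, not an
error.) The component table shows one component towering over the rest:

```
 component    C_max      M_max       z_M       z_C quadrant
         0 0.982401 471.096522  6.649792  2.871906       RU
         9 0.328206  13.778613 -0.149206 -0.271656       LL
        20 0.345934  10.318954 -0.200641 -0.186467       LL
```

Component 0 is a *major* (RU) component: its mixing column has cosine
0.96 with the planted MMR topography, and the contribution profile gives
`dominant_count == 1` — the MMR in a single component. The same weighted
data under the infomax adapter yields 3 salient components, none in the
RU quadrant: the response is fragmented, exactly the contrast the
weighted approach is designed to expose.

A thin CLI wraps the same stages:

```bash
mmrbss simulate --out subj.h5 --seed 3 --n-channels 204
mmrbss decompose --method bsstk --approach weighted subj.h5 decomp.h5
mmrbss run subj.h5 --out results/
```

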