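# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mmrbss`. Notation: sensor data x(n) ∈ ℝ^N (N planar
gradiometer channels, fT/cm), sampled at f_s; stimuli presented at rate
f_p with onset asynchrony SOA = 1/f_p; epochs span −100…500 ms around
onset.

## 1. Signal model and the two approaches

The package assumes the instantaneous linear mixture x(n) = A s(n). Two
structural assumptions justify the weighted approach: (i) the mismatch
response (MMR) occurs only in deviant epochs and only inside a window
[n₁, n₂] after onset; (ii) obligatory responses (M100 onset and offset)
repeat nearly identically in every epoch and therefore correlate highly
with themselves across stimulus periods. Under (i)–(ii), concatenating
deviant epochs makes the MMR periodic, and down-weighting the non-MMR
time (gain 0.2 outside [n₁, n₂], 1.0 inside) suppresses the correlation
between the MMR and the M100 offset that intrudes into the window, so a
second-order method keyed to the stimulus period can isolate the MMR.

The *subtraction* approach is retained as the reference path: epochs are
low-pass filtered (30 Hz, zero-phase Butterworth, order 4), averaged per
condition, and differenced deviant − standard. In the subtraction path
the filter precedes averaging; in the weighted path the filter is
applied to the (back-projected) source signals after decomposition,
before the weighted-epoch average. Both placements are arguments, not
hard-coded.

## 2. BSS_T/k

Pipeline: sphere → lagged correlations → joint diagonalization.

- **Delay schedule.** τ_m = trunc(trunc(f_s/f_p)/m), m = 1…k (default
  k = 8). Truncation, not nearest-integer rounding, is the default
  because it reproduces the canonical delay table at f_s = 1000 Hz,
  f_p = 2 Hz (…, τ₃ = 166, …, τ₈ = 62); `rounding="nearest"` is
  available. k must not exceed the period in samples.
- **Sphering.** Eigendecomposition of the sample covariance;
  eigenvalues below 1e−10 × the largest are dropped (spatially filtered
  real data are rank-deficient; synthetic data are usually full rank).
  Channel means are *not* removed by default (`center=True` available);
  oddball MEG data are high-passed upstream.
- **Lagged correlations.** R(τ) from the overlapping-segment estimator
  with denominator = number of overlapping samples, symmetrized as
  (R + Rᵀ)/2 and scaled to unit Frobenius norm so every lag carries the
  same weight in the joint criterion. The normalization is a package
  choice (the originating literature does not pin it down);
  `normalize_lags=False` disables it.
- **Joint diagonalization.** Jacobi sweeps over all index pairs with the
  closed-form Givens angle (for the pair (p,q): stack
  g_i = [M_i,pp − M_i,qq, 2 M_i,pq], form G = Σ g_i g_iᵀ, rotate by
  θ = ½ atan2(2G₁₂, G₁₁ − G₂₂ + r), r = ‖·‖). The summed squared
  off-diagonal criterion is recorded per sweep and is non-increasing.
  Convergence: all sweep angles < 1e−8 rad, or 100 sweeps. On noisy
  (not exactly diagonalizable) data the criterion plateaus above zero
  and the angle tolerance is typically not reached — this is logged as
  a warning, never raised.
- **Conventions.** Component sign: the largest-|entry| element of each
  mixing column is made positive. Order: as produced by the rotation
  (no reordering). These make decompositions reproducible bit-for-bit.

The infomax comparison is a thin adapter around
`mne.preprocessing.infomax` (extended infomax, seeded), sharing the
sphering, sign and order conventions. It is deliberately not
reimplemented.

## 3. Reference standard

Per-subject difference ERFs are tested against zero with a
spatio-temporal cluster permutation: one-sample t at every
(channel, time); two-sided cluster-forming threshold at p = 0.01 with
df = n_subjects − 1; supra-threshold samples clustered over the combined
graph (spatial sensor adjacency × temporal succession), positive and
negative clusters separately; cluster mass = signed sum of member
t-values; null = maximum |mass| over 1024 random sign-flips of subjects;
p = (1 + #{null ≥ |mass|}) / (1 + n_perm) (the +1 avoids zero p).
Cluster *selection* for the reference is an explicit argument
(`reference_from_clusters`), mirroring the fact that physiological
plausibility, not rank order, decides which clusters define the MMR.
The reference x̄_Ref is then the difference ERF restricted to the
selected L sensors and the window — no rescaling.

## 4. Component evaluation

- **C_max**: for each window time, |cos| between the reference column
  and the mixing column restricted to the L reference channels (the
  restriction is required by dimensional consistency), maximized over
  the window. Invariant to rescaling of the column; in [0, 1].
- **M_max**: per reference sensor l, M_l = (X_l, Y_l)/‖X_l‖ — the
  *uncentered* inner-product projection, implemented exactly as the
  defining formula even though it resembles a Pearson coefficient; a
  mean-centered variant sits behind `centered=True`. The maximum is
  taken *signed* (anti-correlated components are informative); an
  absolute-value mode exists.
- **z-scores** pool C_max and M_max over all components of all methods
  run in the comparison (2–4 methods; 204 × 4 = 816 at full scale),
  using the population SD. Quadrants at z > 1.65: RU major, LU minor,
  RL pseudo, LL inconsequential; salient = not LL.
- **PCA of salient points** (2-D): center = centroid; PC1 sign fixed
  toward positive z_M so the slope sign is meaningful; variance
  fraction λ₁/(λ₁+λ₂); cumulation order = descending PC1 projection,
  ties broken by descending z_M then component index. With fewer than
  5 points a warning is logged (the summary is unstable).
- **Contribution.** For c = 1…#end, the first c ordered salient
  components are back-projected together, the approach's ERF rebuilt,
  restricted by the reference, and M averaged over the L sensors
  (M_ave). RC(c) = (M_ave(c) − M_ave(c−1)) / M_ave(q_all). For the
  subtraction approach the denominator equals the reference's mean
  self-projection (full reconstruction reproduces the reference
  exactly, so Σ RC = 1 over a full ordering); for the weighted approach
  the denominator is the M_ave of the full weighted reconstruction —
  exact reference recovery is not guaranteed there, and this choice is
  the package's. RC is fitted by β e^(−αc) (nonlinear least squares,
  log-linear initialization on positive values; α unconstrained). The
  dominant count is the largest c with fitted value ≥ 0.05 — i.e. the
  last component at-or-above threshold, 0 ("none") if even c = 1 falls
  below; a non-decaying fit is capped at #end.

## 5. Synthetic data

The simulator emulates the study conditions: 500 ms SOA (f_p = 2 Hz),
100 ms tones, 80/20 standard/deviant drawn i.i.d. until ≥150 deviants,
f_s = 1000 Hz, 204 channels on a planar grid layout. Sources:

| source | gating | time course | default amplitude |
|---|---|---|---|
| M100 left / right | both | Gaussian onset deflection peaking 100 ms post-onset plus offset deflection peaking 100 ms post-offset (200 ms post-onset, inside the MMR window) | 80 fT/cm peak; ×0.7 in standard epochs (repetition suppression) |
| MMR | deviant-only | Gaussian peaking at 150 ms, hard-zeroed outside 96–276 ms | snr × noise SD (50 fT/cm at snr = 5) |
| alpha | both | 10 Hz sinusoid, fresh random phase each trial | 12 fT/cm |

plus 1/f background (one-pole-filtered white noise, 15 fT/cm RMS) and
white sensor noise (10 fT/cm SD). Topographies are unit-norm Gaussian
blobs over the layout; the MMR topography is a left-heavy bilateral
mixture deliberately overlapping the M100 patterns, so spatial overlap —
the condition that makes the separation problem hard — is present. The
adaptation magnitude is a free parameter: no quantitative model of
repetition suppression is assumed. Ground truth (events, mixing,
sources, MMR index) is always returned and written beside simulated
data.

What the simulator does **not** model: head geometry and forward
fields, sensor physics and cross-talk, eye/cardiac artifacts,
trial-to-trial latency jitter, or correlated inter-regional dynamics.
Passing tests therefore demonstrate the algorithmic claims (periodicity
exploitation, window weighting, scoring) under the stated assumptions,
not performance on raw laboratory data.

## 6. Problem sizes and determinism

All randomness flows from seeded `numpy` generators; pipelines are
deterministic given a config (whose hash is embedded in outputs). The
test suite runs the stochastic suites at reduced scale as the package's
own sizes: 16–24 channels and 20–40 deviants for pipeline tests, a
12×30 sensor-time grid with 10 subjects × 1024 permutations × 200
repetitions for the family-wise-error simulation, and 10 seeds of the
24-channel end-to-end comparison; the printed-constant checks (delay
table, window gains) and the 204-channel component-count checks run at
full scale. The acceptance script runs the full default design (204
channels, ≥150 deviants).

## 7. Known limitations

- Orthogonal joint diagonalization only; no non-orthogonal variants.
- The rectangular window causes spectral ringing; alternative window
  shapes are possible by constructing `WindowSpec`-like gains upstream,
  but only the rectangular form is built in.
- The epoch length (600 ms), not the SOA (500 ms), sets the
  concatenation period, so the delay schedule's fundamental T = f_s/f_p
  is 100 ms short of the true concatenated period; this mirrors the
  published procedure and the lag set still brackets the relevant
  periodicities.
- Group statistics beyond the cluster test (rmANOVA, post-hoc
  contrasts) are out of scope; users apply standard tools to the
  exported tables.
- FIF reading requires `mne` and a stim channel with the
  standard-vs-deviant convention described in `io.py`.
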