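# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic validation does and does not establish.

## Synthetic data model

**MVAR cohorts** (`synthgen.simulate_mvar_cohort`).  Each participant's
epochs are drawn from a stable MVAR(p) process (default p = 2, 6 channels,
250 Hz, 200 epochs × 300 samples).  Channels default to a mild AR(1)
self-coefficient of 0.3 with unit innovation SD.  A planted edge
`source → target` in band *b* places a damped oscillator on the source
channel — an AR(2) pair (2ρ cos θ, −ρ²) with pole radius ρ = 0.8 at the
band's centre frequency θ = 2πf₀/fs — plus a lag-1 cross-coefficient
(default 0.4) into the target.  The oscillator concentrates the source's
power inside the band; the cross-transfer itself is broadband, which is why
ground-truth matrices mark the carried pair in *every* band while the edge's
designated band is where detection power peaks.  Each participant carries an
edge with probability `edge_prevalence` (default 0.9), and all nonzero
coefficients are jittered by a multiplicative Gaussian factor (SD 10%,
re-drawn until the companion spectral radius is < 1) so the binomial group
statistics see realistic between-participant variability.  Unstable planted
coefficient sets are rejected outright.

**Toy source meshes** (`simulate_vertex_fra`).  A 2-D grid graph (default
20×20, 4-connectivity, 6.2 mm spacing — the vertex spacing of a downsampled
template cortical surface, at desk scale) with rectangular atlas labels.
The "image" condition adds a Hann-profile activation of amplitude *a*·σ on a
connected vertex patch inside a time window; the "fixation-cross" condition
is i.i.d. Gaussian noise, so the expected contrast equals the planted signal
exactly.  The generator does not emulate spatial noise correlations, 1/f
spectra, or inter-run head-position differences; SCPT calibration results on
it therefore certify the permutation machinery, not robustness to
structured MEG noise.

**Behaviour tables** (`simulate_target_trials`).  Amplitude and RT are
jointly Gaussian with the requested correlation; amplitudes are N(10, 1) so
that mean-|activity| amplitude extraction stays linear in the latent value
and the planted r survives the pipeline.  RT defaults (489 ± 197 ms) mirror
typical search-response latencies.  A configurable fraction of trials
violates the correctness bounds (fixation offset > 1.7°, response lag
> 500 ms).  Truncating RTs at 1 s removes ~0.5% of trials at these moments
and attenuates r negligibly.

## Statistical conventions

* **Window arithmetic.**  Epoching uses inclusive endpoints with
  nearest-sample rounding ([−0.4, 0.3] s at 1000 Hz → 701 samples); analysis
  windows use a floor rule (first 200 ms at 1017.25 Hz → 203 samples).
* **Baseline standardization.**  Per-channel baseline means are subtracted
  first; the divisor is the *population* SD (ddof = 0) of the demeaned
  baseline pooled across channels.  This order makes the operation
  idempotent and scale-equivariant; an epoch whose baseline carries no
  within-channel variation is degenerate and rejected.
* **Epoch cap.**  cap = floor(min count × 1.1).  Thinning is deterministic:
  the `count − cap` drops are spread evenly (drop j removes index
  floor((j+1)·count/n_drop) − 1), which removes exactly every third epoch at
  50% overshoot and is reproducible.
* **SCPT.**  Cluster-forming threshold: two-sided pointwise t at p = 0.05
  (df = runs − 1) — conventional, configurable.  Spatiotemporal connectivity
  is (same vertex, adjacent samples) ∪ (adjacent vertices, same sample);
  positive and negative effects cluster separately; mass is Σ|t|.  The null
  permutes run signs; p = (1 + #{null ≥ mass})/(1 + n_perm).  Cluster
  geometry and masses are cross-checked against MNE's implementation in the
  test suite.  The 15% label rule is inclusive (exactly 15% is kept); the
  20 ms duration rule is strict.
* **MVAR estimation.**  One model per participant/condition; regression rows
  pool epochs and never cross epoch boundaries.  σ²ₘ is the residual
  variance with ddof = N·p.  Order selection minimizes
  HQ(p) = ln det Σₚ + 2pN² ln(ln T)/T with all candidates scored on the
  common sample trimmed at p_max.  Surrogate refits accumulate Gram matrices
  in float32 (with float64 solves); the user-facing fit is float64
  throughout — the float32 path is for the ~10⁵ surrogate refits a cohort
  analysis needs and matches the float64 edge decisions.
* **Diagnostics.**  Whiteness: Li–McLeod portmanteau on within-epoch
  residual autocovariances, χ² with N²(h − p) df (h = 20 default).
  Consistency compares stacked auto/cross-covariances (lags 0–10) of the
  data against data simulated from the fitted model:
  100·(1 − ‖R_sim − R_data‖/‖R_data‖).  First-differencing is applied only
  when a majority of channels test non-stationary (ADF + KPSS, "auto" mode):
  differencing an already-stationary VAR induces a non-invertible MA
  component and biases the fit.  The stationarity tests run on the first
  three epochs per channel (median p) — the per-epoch outcome is
  exchangeable and the diagnostic would otherwise dominate runtime.
* **GPDC.**  Baccalá's generalized PDC with modulus and square root, so the
  column normalization Σₘ GPDC²ₘₙ(f) = 1 holds identically; the DTFT uses
  e^(−i2πfk/fs) with f in Hz.  Band averages take the inclusive integer
  1-Hz bins (alpha 8–13 Hz = 6 bins; shared endpoints belong to both
  neighbouring bands).
* **Surrogates.**  Time samples are permuted independently within each
  epoch and channel — this destroys auto- and cross-correlation while
  keeping amplitude distributions.  Per surrogate the maximum GPDC over all
  ordered channel pairs is recorded per frequency bin; a band's threshold is
  the mean over its bins of the 99.99th percentile across surrogates.
  Unstable surrogate refits are skipped and counted.
* **Group inference.**  Exact integer-arithmetic Binomial(n, ½) upper
  tails; significance is strict (p < α).  At n = 31 and α = 0.001 an edge
  needs ≥ 25 carriers; group significance is impossible below 12
  participants (2⁻ⁿ > 0.001), which is why the demo pipeline defaults to 12.
  Condition contrasts subtract group-mean thresholded strengths on the
  union ROI set (ROIs absent from a condition contribute zeros).
* **Node degree.**  Degree = in + out significant edges.  The null
  redistributes each band's edge budget uniformly over ordered off-diagonal
  pairs and records the maximum degree per randomization; a ROI is a hub
  when its degree is nonzero and reaches the 95th percentile in ≥ 1 band.
  A degree-preserving rewiring null is deliberately *not* offered: in+out
  degree is invariant under it, so that null cannot discriminate anything.

## Problem sizes

Simulation-based checks run at desk scale on one CPU: cohorts of 31
participants × 200 epochs × 300 samples with 200 surrogates for edge
recovery (50 for the repeated null-calibration runs — fewer surrogates
*lower* the threshold, so a clean null under them is the conservative
direction); 20×20 meshes, 30 runs and 500 permutations × 200 repetitions for
cluster-test calibration; 10⁵ randomizations for degree nulls (the
redistribution null is exchangeable, so percentiles stabilize well below
that).  The permutation count for a single exploratory cluster test defaults
to 500–1000; published-grade analyses would raise it (and the surrogate and
randomization counts) by an order of magnitude without any code change.

## Known limitations

* The mesh generator's noise is white in space and time; SCPT's false-alarm
  calibration on it does not speak to spatially correlated noise, where
  cluster-forming-threshold choice matters more.
* Surrogate shuffling is maximally destructive (it whitens each channel);
  gentler nulls (phase randomization, circular shifts) would preserve
  autospectra and give higher thresholds for strongly autocorrelated data.
* The consistency statistic uses covariances up to lag 10; models whose
  inadequacy lives only at longer lags can score deceptively well.
* Pooled (cross-participant) amplitude–RT correlation is implemented; a
  within-participant variant is a natural extension and the function accepts
  any pre-grouped trial table.
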