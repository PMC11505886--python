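# Methods

## The model in brief

EEG is treated as a sequence of four microstate classes A–D.  Per class,
functional connectivity is estimated as theta-band phase locking between
all channel pairs, giving one weighted network per class per subject.
Each network is then characterized four ways: graph topology (clustering
Cp, characteristic path length Lp, global/local efficiency Eg/Eloc,
small-worldness Sw), synchronizability (the Laplacian eigenratio
M = λ₂/λ_max), linear controllability of each node (average and modal),
and a pinning-control gain per node.  Group inference compares each
(state, metric) cell between cohorts with Welch t-tests.

## Synthetic cohorts and what they do (and do not) emulate

The generator produces 60-channel, 500 Hz recordings (20 s per subject,
35 subjects per group by default) on a deterministic sunflower-spiral
montage with named regions (frontal-left/medial/right, central, parietal,
occipital).  Its components:

- **State sequence.** A 4-state Markov chain with geometric dwell times;
  the default mean dwell of 80 ms matches typical microstate run lengths.
  The chain's self-transition probability is derived from the dwell mean
  (`p_self = 1 − 1/(dwell·fs)`), off-diagonal mass uniform.
- **Topography carrier.** The active class's unit-norm template modulated
  by a 10 Hz carrier.  Putting the topography *outside* the theta band is
  deliberate: a narrow 4–7 Hz filter has a ≳300 ms impulse response that
  would smear 80 ms microstates beyond recognition, so segmentation runs
  on the broad band while phase analysis runs on theta.  The canonical
  templates are two diagonal anterior–posterior gradients (A, B), a
  frontal–occipital gradient (C) and a frontal-medial focus (D),
  constructed so all pairwise |spatial correlations| stay below 0.7.
- **Theta coupling component.** Equal amplitude on every channel; each
  channel's phase deviates from a common carrier by slow Gaussian jitter
  (sd `jitter_sd`, low-passed at 1 Hz) scaled by (1 − g), where
  g ∈ [0, 1] is the class- and region-specific coupling strength.  With
  jitter alone the pairwise PLV has the closed form
  `exp(−((1−g_i)² + (1−g_j)²)·σ²/2)`, which anchors the quantitative
  recovery tests.  An optional per-channel frequency drift (evenly spaced
  offsets within ±`drift_spread` Hz) makes uncoupled pairs decorrelate
  deterministically — used in the coupling-recovery checks, off by
  default in cohorts.
- **Group effect.** The SZ-like group scales transitions *into* state D
  by the occurrence multiplier (renormalizing rows), lowering D's
  occurrence and coverage while leaving dwell roughly unchanged, and
  scales frontal-channel coupling by the coupling multiplier.  Defaults
  are 0.7 for both.
- **Noise.** White Gaussian, i.i.d. across channels, with
  `sd = amplitude/(snr·√(2N))`, i.e. `snr` is the ratio of total signal
  RMS to total noise RMS.  Default snr = 5.

Not emulated: volume conduction (no forward model), 1/f background,
artifacts, per-subject template variability, and any nonstationarity
beyond the Markov switching.  Passing tests therefore demonstrate that
the *pipeline* recovers planted structure under controlled conditions,
not that real clinical EEG would behave this way.

## Numerical and design choices

- **Filters.** Odd-length Hamming windowed-sinc FIR, 1 Hz transition
  width (1651 taps at 500 Hz), applied once via FFT convolution with
  group-delay compensation — exactly zero-phase for the symmetric kernel.
  Edges are reflect-padded by one filter length.  Artifact removal and
  surface-Laplacian hooks exist as no-ops (synthetic data need neither).
- **GFP peaks.** A peak satisfies v[i−1] < v[i] ≥ v[i+1] (plateaus keep
  their first sample; constant series have no peaks); peaks closer than
  `min_distance` (default 5 samples = 10 ms at 500 Hz) are thinned,
  keeping the larger.
- **Clustering.** Modified k-means over GFP-normalized peak maps pooled
  across both groups: assignment maximizes squared spatial correlation,
  centroids are the dominant eigenvector of the GFP²-weighted scatter of
  assigned maps (both polarity-free), 50 restarts keep the solution with
  the highest GFP²-weighted global explained variance.  Cluster-to-class
  naming solves an optimal assignment against the four canonical
  synthetic axes by |correlation|; with real data a published canonical
  map set would be needed instead.
- **Backfitting.** Every sample labeled independently by maximal
  |spatial correlation|; optional minimum-duration smoothing (relabel
  runs shorter than a threshold to the neighbor with higher fit
  correlation) is off by default as the least interpretive choice.
  Temporal parameters use the standard definitions: coverage = sample
  fraction, occurrence = runs/s, duration = mean run length,
  contribution = share of summed GFP.
- **Phases and PLV.** Analytic-signal phase computed once on the
  continuous theta-filtered signal (restricting to class samples
  afterwards avoids concatenation discontinuities).  One second at each
  edge and samples with vanishing analytic amplitude (< 1e−12 µV) are
  masked.  Classes with fewer than 100 valid samples yield networks
  flagged unreliable and excluded from group statistics (PLV bias scales
  as 1/√Len).  The 0.55 display threshold affects figures only; all
  analyses use the full weighted matrix.
- **Topology.** Distances d = 1/w on positive edges; Lp averages finite
  pairwise distances (disconnected graphs are flagged); Eg averages 1/d;
  clustering uses Onnela's geometric-mean triangle form; Eloc averages
  the neighborhood-subgraph efficiency.  Sw normalizes against
  weight-permutation surrogates (default 100; 20 in the cohort pipeline):
  PLV graphs are complete, so degree-preserving rewiring is vacuous and
  permuting edge weights is the natural null that preserves topology and
  the weight distribution.
- **Controllability.** The improper Gramian integral only converges for a
  Hurwitz system, so the connectivity matrix is first normalized as
  `A_s = A/(1 + λ_max(A)) − I` (the convention of the linear
  network-controllability literature); the applied transform is recorded
  in the results.  AC uses the symmetric closed form
  `ac_k = Σ_i V²_ki/(−2μ_i)`; a per-node Lyapunov solver remains as an
  independent route.  MC scales the spectrum into (−1, 1) by
  `1 + max|λ|` before evaluating `Σ_j (1 − λ_j²)v_ij²`.
- **Pinning control.** Importance `d_i = p_i^a·q_i^b` with p = strength,
  q = betweenness on d = 1/w plus a 1/n offset (complete similarity
  graphs leave many exact-zero betweenness values that negative exponents
  cannot absorb), a = b = −1/2.  The program —
  minimize λ_max(A − diag(k)) s.t. 0 ≤ k_i ≤ cs,
  cs − ε ≤ Σ d_i² k_i ≤ cs + ε — is convex; it is solved by SLSQP on a
  log-sum-exp smoothing of the spectral objective (β = 100 then 2000,
  analytic gradient −Σ_j w_j v_ij²), then the exact λ_max at the optimum
  is reported.  Infeasible budget windows raise an error stating the
  achievable interval.  Defaults cs = 2, ε = 0.2.  The stability-margin
  comparison against λ_min(A) is reported post hoc, not enforced.  Gains
  at exactly 1.4 fall in the second tier; ranking ties break by channel
  index.  The pipeline optimizes gains on the group-average network per
  class (per-subject gains are available through the library).
- **Statistics.** Welch t-test by default (equal-variance form by flag),
  Cohen's d on the pooled SD, Pearson correlations with the t-transform
  p-value.  No multiple-comparison correction by default — mirroring the
  source analysis — with BH-FDR available and its on/off state recorded
  in the report; a warning is logged when it is off.
- **Seeding.** One master `SeedSequence` (the synthetic config seed)
  spawns, in fixed order, the per-subject streams, the k-means restarts
  and the surrogate null; identical config + seed reproduces the report
  bundle byte-for-byte.

## Problem sizes in the validation runs

Kernel oracles run at n ≤ 8 nodes (grid search for pinning at n = 4,
step 0.05).  Ground-truth recovery uses 200 noisy peak maps, one 20 s
default-condition recording for backfit accuracy, and a 24-channel,
20 s single-state recording for coupling recovery.  The planted-effect
contrast runs the full study conditions (35 subjects per group,
60 channels, 20 s).  Null calibration uses twenty 19-channel,
10-per-group, 8 s cohorts; with ~64 correlated test cells per cohort the
rejection fraction is compared with a widened binomial band around
α = 0.05 rather than the i.i.d. band.

## Known limitations

- Microstate count is fixed at 4; no model-order selection.
- Backfitting labels all samples (no GFP-peak-only interpolation option).
- The pinning importance vectors (P, Q) and the control-strength scale
  are free parameters; node rankings, though not the optimizer itself,
  depend on these choices.
- Sw's null model is weight permutation; other nulls (e.g.,
  strength-sequence-preserving simulated annealing) are not implemented.
- Connectivity is PLV only (no wPLI/coherence), and volume conduction —
  the main confound PLV inherits on real scalp data — is neither
  simulated nor corrected.
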