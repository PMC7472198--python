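# Methods notes

This note documents the modeling choices, numerical conventions, and the
synthetic study design behind `braingp`, in the spirit of a package
methods appendix. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The package assumes that (i) local field potentials at nearby locations
are correlated, with similarity falling off smoothly in MNI space, and
(ii) different people's brains share correlational structure, so
correlations estimated in some patients carry information about the
same location pairs in others. Under those assumptions, activity across
model locations is treated as jointly Gaussian with correlation matrix
K̂, and the reconstruction at unobserved locations is the conditional
mean K̂_{βα} K̂_{αα}⁻¹ y. Only the conditional mean is produced;
posterior variance maps are out of scope, as is absolute-voltage
recovery (K̂ is a correlation, not covariance, matrix — outputs are in
z units).

### Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `lambda_width` | 20 | mm² | RBF spatial smoothing scale; weight exp(−d²/λ), no factor of 2. Larger λ generalizes further from electrodes at the cost of spatial resolution. |
| `ridge` | 1e-5 | correlation scale | conditioning of K̂ before inversion; bounds the smallest eigenvalue below by ridge/(1+ridge). |
| `tolerance` (partition) | 0.5 | mm | electrode-to-model-row matching; locations originate from the same tables, so matches are near-exact. |
| `chunk_size` | 10 000 | timepoints | piecewise evaluation of the conditional mean; results are exactly chunk-size-invariant, so this is purely a memory knob. |
| notch | 60 ± 0.5 Hz, order 4 | — | Butterworth band-stop, applied forward-backward (zero phase) so cross-electrode correlations are not distorted; harmonics are not filtered by default but `extra_notch_hz` allows it. |
| target rate | 250 | Hz | common samplerate after polyphase downsampling. |
| kurtosis threshold | 10 | excess (Fisher) kurtosis | electrode exclusion on the maximum across sessions, computed on notched, downsampled data; Gaussian channels score ≈ 0. |

### Conventions worth knowing

- **Fisher z everywhere correlations are averaged**: across sessions
  (patient matrices), across patients (the numerator/denominator merge),
  and across sessions of held-out accuracy. Correlations are clipped to
  ±(1 − 1e-6) before the transform so |r| = 1 stays finite.
- **Pair sums and symmetrization.** The expansion sums over unordered
  electrode pairs j < i, which leaves the raw target-pair sums
  asymmetric; both orderings are accumulated (num ← num + numᵀ), which
  cancels in the ratio. Accumulator diagonals are kept at zero and the
  model diagonal is set to exactly 1 at materialization, so the
  diagonal pair sums are never consumed.
- **Merging is a sum**, hence associative, commutative, and exactly
  subtractable — the across-patient cross-validation holds a patient out
  by summing the other patients' terms, and a provenance log records
  which patients entered each model.
- **Conditioning.** The z-space weighted average does not guarantee a
  positive semi-definite K̂. `condition_matrix` floors negative
  eigenvalues at zero (renormalizing the diagonal), then applies
  K ← (K + ridge·I)/(1 + ridge). With PSD input and ridge 0 it is the
  identity. The inverse in the reconstruction is always a Cholesky
  solve, never an explicit inverse.
- **Voxel grids.** Voxel centers sit at origin + spacing·index; the
  20-mm-radius neighborhoods used by density and information maps are
  closed balls on voxel-center-to-electrode Euclidean distance. The
  4-mm MNI152 brain mask is obtained from the template bundled with
  nilearn (no download); a rectangular unmasked grid (`VoxelMap.box`)
  serves tests and synthetic studies whose coordinates are not brain-
  shaped.
- **NaN policy at ingestion**: sessions containing non-finite samples
  are rejected with an error by default; `drop_nan_rows=True` drops the
  offending rows with a logged count. Silent imputation would bias
  correlations.
- **Broadband power** is the mean height over the 50-point log-frequency
  grid of a robust line (IRLS, Tukey bisquare, tol 1e-8, ≤ 50
  iterations) fitted to log wavelet power vs log frequency; natural
  logs throughout (a fixed log base only rescales the series). The
  "fourth-order" Morlet wavelet is realized as 4 cycles. The
  time-resolved variant uses non-overlapping 1-s windows by default; the
  wavelet transform is computed once per session and averaged within
  windows, so windows may be shorter than the longest wavelet. A
  degenerate (constant) spectrum yields slope 0 and level equal to the
  constant.

## The synthetic study

Real multi-patient clinical cohorts are not distributable with the
package, so all quantitative claims are made on simulated data with a
known generating correlation matrix K_true:

- **Ground truth**: M = 40 candidate locations uniform in a 60-mm cube;
  K_true = 0.84·exp(−d²/(2·25²)) + 0.15·(rank-3 random correlation)
  + 0.01·I. The Gaussian term realizes the smoothness assumption at a
  25-mm scale (neighboring locations correlate ≈ 0.8); the low-rank term
  adds non-spatial shared structure; the jitter guarantees positive
  definiteness. The 60-mm cube keeps every pairwise distance ≤ ~104 mm
  so all RBF weight products stay numerically positive at λ = 20 mm² —
  the simulated cohort behaves like a densely sampled region rather than
  a whole head.
- **Patients**: 8 patients × 12 electrodes, each subset spatially
  clustered (random anchor plus a random draw from its nearest
  neighbors), mimicking grids/strips where a location's nearest
  neighbors tend to belong to the same patient. Sessions are zero-mean
  multivariate Gaussian draws (T = 5000 at a nominal 250 Hz) from
  K_true restricted to the subset — so the correlation model is exactly
  matched by default.
- **Contaminants** (off by default, switched on where the test needs
  them): spike channels get 1% of samples replaced by ±20 SD values,
  which drives moment-formula excess kurtosis far beyond the exclusion
  threshold; line noise adds a shared 60 Hz sinusoid.

What passing tests on this generator do show: the estimator recovers a
shared smooth correlation structure from sparse heterogeneous coverage,
pooled models beat single-patient models, reconstruction converges to
the closed-form conditional-correlation bound, and the preprocessing
correctly flags the injected artifact types. What they do not show:
robustness to 1/f spectra and nonstationarity (an optional 1/f-shaped
variant of the generator exercises the spectral code path, not the
model-recovery claims), volume conduction, re-referencing effects, or
performance at whole-brain inter-electrode distances where RBF coverage
is extremely sparse.

## Design choices that were genuinely open

- The kernel is the Gaussian RBF exp(−d²/λ) with λ in mm² and no factor
  of 2; λ is fixed, not learned (cross-validating λ is a documented
  non-goal).
- "Mean height" of the broadband fit is the fitted line averaged over
  the frequency grid (equivalently its value at the mean log frequency);
  an intercept-at-1-Hz reading would differ by a constant and is
  available by combining the fitted slope and level.
- Within- vs across-patient accuracies are aggregated per patient in z
  space before the paired t-test; electrode-level records keep
  per-session correlations so other aggregations remain possible.
- Information scores assign each patient's mean accuracy to all of that
  patient's electrodes and average over electrodes within 20 mm of each
  voxel — so patients with more nearby electrodes weigh more. Ties at a
  top-fraction cutoff are all included (deterministic, may slightly
  exceed the nominal fraction).
- Recording formats (CSV pair / HDF5), the model file layout, and the
  NIfTI map output are artifact choices; vendor EEG formats are
  upstream conversions.

## Problem sizes

The test suite and acceptance script run cohorts of 8 patients × 12
electrodes × 5000 timepoints (five seeds), single-cohort smoke runs, and
T = 10 000 draws for the convergence checks — sizes chosen so the entire
verification cycle completes in minutes on a single CPU while leaving
the stochastic assertions comfortable margins. The implementation
itself is vectorized over electrodes and chunked over time, and has no
intrinsic limits near these sizes.

## Known limitations

- K̂ estimated through the RBF expansion is near-singular when
  electrodes are dense relative to λ; reconstruction quality then hinges
  on the ridge. The default 1e-5 is conservative; raise it if
  `reconstruct_timeseries` reports a singular observed block.
- Locations with no RBF coverage from any patient pair produce an
  explicit zero-denominator error at materialization rather than a
  silent extrapolation.
- The conditional mean shrinks variance (reconstructed columns have
  variance ≤ 1 in z units); downstream analyses sensitive to amplitude
  should use the observed channels or re-standardize explicitly.
- Session boundaries are hard: z-scoring, correlation, and
  reconstruction never mix sessions, and sessions are never
  concatenated.
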