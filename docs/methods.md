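# Methods

## Forward model

Each region of an N-node parcellation is a Stuart–Landau oscillator (the
normal form of a supercritical Hopf bifurcation) written in Cartesian
coordinates, coupled by a linear difference scheme through the structural
connectome and driven by additive Gaussian noise. The difference coupling
`Σ_i C_ij (x_i − x_j)` vanishes identically when all nodes share a state,
so a synchronized noiseless network evolves exactly as N uncoupled nodes —
a property the test suite exploits as an integrator oracle.

Parameters and defaults:

| parameter | meaning | default | notes |
|---|---|---|---|
| `a_j` | node bifurcation parameter (dimensionless) | −0.02 for calibration | a<0 noise-driven, a>0 limit cycle of radius √a |
| `ω_j` | intrinsic angular frequency (rad/s) | U(0.05, 0.25) | maps to 0.008–0.04 Hz, inside the BOLD band |
| `G` | global coupling (dimensionless) | calibrated | scales a connectome normalized to max 0.2 |
| `β` | model noise std | 0.02 | documented model-level default |
| `σ` | noise amplitude injected per Euler substep | 0.01 | used for synthetic generation; `sigma=None` falls back to β |
| `tr` | saved-sample interval (s) | 0.72 | HCP repetition time |
| `n_substeps` | Euler substeps per saved sample | 10 | dt = tr/n_substeps |
| `n_discard` | transient saved samples dropped | 100 | so a W-sample window needs 100+W saved steps |

Two noise scalars coexist deliberately: the model definition carries
β = 0.02 while the synthetic-generation protocol injects σ = 0.01 per
Euler–Maruyama substep. Only one is active in any run (`SimulationConfig.sigma`,
with `None` deferring to `HopfParams.beta`); both are exposed because the
two conventions describe the same additive-noise term at different stages of
the workflow.

Integration is explicit Euler–Maruyama,
`state += dt·drift + σ·√dt·N(0,1)`, with the initial state and all noise
drawn from a single seeded generator in a fixed order (initial x and y
first, then per-substep noise), so every run is bit-reproducible. A guard
aborts with the substep index if any coordinate exceeds 1e6. The saved-sample
interval is interpreted as the scan TR; "time steps" throughout the package
mean saved samples, not integration substeps.

Numerical accuracy: the explicit Euler step inflates the limit-cycle radius
by ≈ dt·ω²/(4r). At the default dt = 0.072 s and ω ≤ 0.25 rad/s this bias
is ~2e-3 at worst — irrelevant next to σ-driven variability — but tests that
assert the continuous-model radius √a to 1e-3 use 100 substeps per sample.

## Observables

Band-pass filtering is a zero-phase (forward–backward) second-order
Butterworth at 0.008–0.08 Hz, the standard resting-state band; the
forward–backward pass squares the magnitude response, which the test suite
checks against the analytic transfer function. Static FC is plain Pearson
correlation. Phase FCD follows the instantaneous-phase construction: per
sample, a coherence frame `cos(φ_i − φ_j)` from the Hilbert analytic
signal; frames are compared by cosine similarity of their strict upper
triangles (the diagonal is identically one and carries no information),
yielding a T×T FCD matrix. No frames are trimmed by default; a
`trim_frames` option removes Hilbert edge transients when wanted, and
property tests assert only on interior frames.

Distribution-level comparison uses the two-sample Kolmogorov–Smirnov
statistic on FCD values pooled across subjects of a group (upper triangles
concatenated into one sample). Pooling makes the sweep objective a scalar
and uses all data symmetrically; a per-subject-then-aggregate variant was
considered and rejected as it requires an extra, unspecified aggregation
rule.

Intrinsic frequencies are estimated per node as the within-band peak of a
Welch periodogram (segment length min(T, 256), 50% overlap), then averaged
across subjects and converted to rad/s.

## Calibration of G

The sweep fixes `a_j = −0.02` (just below the bifurcation, where FCD
statistics are most sensitive to coupling), simulates a group of
pseudo-subjects per grid value, and minimizes the pooled-FCD KS distance to
the reference sample. The KS-vs-G curve is smoothed by a least-squares
degree-8 polynomial — fitted after rescaling the grid to [−1, 1], because
the raw monomial basis is ill-conditioned at that degree — and evaluated
densely at 0.001 spacing; the argmin is `g_opt`. With fewer than degree+1
grid points the degree drops to n−1 with a warning.

Desk-scale self-consistency study: a 10-region random connectome, reference
group of 20 pseudo-subjects × 300 samples generated at G* = 1.0, grid 0–2
in steps of 0.1. Across seed families this design recovers G* within 0.2
(typically within 0.1); smaller designs (6 subjects × 150 samples) show
recovery errors up to ~0.4 and are used only where the test merely asks for
the argmin on a coarse 3-point grid.

## Synthetic data

Training windows follow the generation protocol: per sample, `a_j ~ U(−1,1)`
and `ω_j ~ U(0.05, 0.25)` per node, initial state uniform in [−1, 1],
σ = 0.01, 100 transient samples discarded, the last W samples kept — so a
50-sample window runs 150 saved steps. Samples are integrated in vectorized
batches of up to 1024 independent runs.

Pseudo-cohorts emulate a multi-condition study: cohort c draws each
subject's a-vector i.i.d. per node from `N(mean_c, spread²)` truncated to
[−1, 1], with per-subject ω and a scan length uniform over `T_range`, so
variable-length windowing is exercised. The generating truth is returned
for recovery quantification. The default two-cohort study uses means −0.10
(rest-like) and +0.05 (task-like) — a 0.15 separation, the qualitative
rest-below-task ordering — with spread 0.05 (3× separation-to-spread) and
150 subjects per cohort, enough for the individual-level classifier to be
meaningfully compared against chance + 5 binomial standard errors on the
held-out fifth.

What the generator does *not* emulate: hemodynamic convolution, task-block
timing, scanner drift/motion artifacts, inter-subject connectome
variability (all cohorts share one connectome), or regional heterogeneity
beyond (a, ω). Passing tests therefore demonstrate internal consistency of
the inverse method under the model's own assumptions, not robustness to
empirical confounds.

Window→image conversion clips values to [−1, 1] and maps them linearly to
indices 0–255 of a frozen 256-entry palette shipped as CSV (a perceptually
uniform sequential map, with duplicate quantized RGB rows nudged so the
lookup is strictly invertible up to the (max−min)/255 quantization step).
The palette id is recorded in the model contract so image-trained models
reject mismatched inputs.

## Inverse models and training

Both regressors are built on a compact numpy layer stack written for this
package (im2col convolutions with hand-derived backward passes, Adam,
one-cycle learning-rate schedule). Training is CPU-sized and exactly
reproducible: split, initialization and batch order all derive from the
config seed.

- `sequence`: a temporal convolutional network — stacked dilated causal 1-D
  convolutions (kernel 5; dilations 1,2,4,8 at the tiny preset, doubled
  further until the receptive field covers W), ReLU, global average pooling
  over time, linear head to N outputs. Nodes enter as input channels.
- `image`: the palette-rendered window (3×N×W, values/255) through a
  patchified stem (2×2, stride 2) and two 3×3 convolution stages, global
  average pooling, linear head.

Protocol: seeded 80/20 train/validation split, MSE loss, Adam, batch 16,
base learning rate 3e-4, one-cycle schedule (25% cosine warm-up from
lr/25, cosine anneal to lr/1e4), fixed epoch count, final-epoch weights
kept (no early stopping, no validation-best selection). The quality metric
is the normalized RMSE, `100·RMSE/(a_max − a_min)` on the [−1, 1] prior
support; the constant prior-mean predictor scores `100/(2√3) ≈ 28.87` on
uniform labels and is the floor any useful model must beat.

Desk-scale working point: N = 10 regions, S = 2000 samples, W = 50, tiny
sequence preset, 12 epochs — about half a minute on one CPU, reaching
validation nRMSE ≈ 14–17 depending on seed. The fixed-budget comparison
(S = 2000, W = 50 versus S = 500, W = 200 at equal S·N·W, 8 epochs, 3
seeds) consistently favors more samples over longer windows. These problem
sizes are the package's chosen desk-scale study conditions; the same code
scales to larger S, W, N and the `small` presets unchanged.

## Inference pipeline

Per scan: amplitude normalization (one scalar per scan — the scan-wide
maximum absolute value — preserving relative regional amplitudes, which is
an explicit interpretation of "maximum amplitude 1"; per-node normalization
would discard amplitude cues that carry a-information), then non-overlapping
windows of length W with the trailing remainder dropped, then element-wise
averaging of a subject's windows, then one prediction per subject. A
`average_windows=False` toggle predicts per window and averages predictions
instead, exposed for sensitivity checks only; the default follows the
average-then-predict order.

## Statistics

Group level: node-mean values per subject, all pairwise two-sided
Mann–Whitney–Wilcoxon tests (scipy's exact/asymptotic switching with
midrank tie handling), Benjamini–Hochberg adjustment applied jointly across
all pairs, significance bands `****` ≤ 1e-4, `***` ≤ 1e-3, `**` ≤ 0.01,
`*` ≤ 0.05, else `ns`. Individual level: linear-kernel SVM (C = 1.0, fixed
for reproducibility) on standardized features, stratified 80/20 split,
stratified 10-fold CV on the training portion only, confusion matrix kept
as raw held-out counts (row-normalize for recall in displays). Permutation
feature importance shuffles each feature 10 times on the held-out set and
reports the mean and std accuracy drop. Network activation averages
subject-level predictions per cohort, subtracts the rest cohort row, and
averages nodes within each network of the region→network map; the shipped
DK80 table (62 cortical regions assigned to the seven canonical cortical
networks plus 18 subcortical regions) is an editable default whose
anatomical assignment is documentation rather than tested behavior — tests
use synthetic maps.

## Degenerate inputs and tie-breaks

Connectomes must be square and nonnegative; they are symmetrized as
(M+Mᵀ)/2, diagonal-zeroed, and rejected if nothing remains to normalize.
Zero-variance nodes fail static FC by name; zero-norm coherence frames fail
the FCD with a degenerate-frame error; empty samples fail the KS distance.
Spectral peak ties resolve to the lowest frequency (argmax convention), and
the polynomial argmin resolves to the leftmost dense-grid point.

## Known limitations

- The explicit Euler scheme is first-order; the radius bias noted above
  grows with ω·dt, so heavy oversampling of fast oscillators needs more
  substeps.
- Calibration assumes the reference and sweep share ω and the connectome;
  with synthetic references this holds by construction, with empirical data
  it is the usual modeling assumption.
- The tiny presets trade accuracy for CPU time; validation nRMSE ≈ 14 at
  desk scale is far from what large training sets and wider backbones reach,
  and the image approach only overtakes the sequence approach at training
  budgets beyond desk scale.
- Pseudo-cohort classification accuracy depends on the separation/spread
  ratio chosen for the generator; it validates the pipeline, not any
  empirical effect size.
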