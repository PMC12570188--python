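# Methods

This note records the modelling assumptions, numerical conventions and open
design choices behind `rhythmmap`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

Recordings are truncated at 60 s and segmented with a 20 s window and 5 s
stride (75% overlap); a window is emitted only when it fits entirely inside
the truncated recording, so a 60 s strip yields exactly
floor((60 − 20)/5) + 1 = 9 snippets. For interval-series payloads a snippet
holds the RR intervals fully contained in its time span.

**Quality gating.** Clinical practice delegates snippet grading to signal
-quality software whose exact rule is proprietary to each package; our
default backend grades a waveform snippet `excellent` when the mean
per-beat Pearson correlation with the median beat template is ≥ 0.95 and
the implied heart rate lies in 30–220 bpm, `unreadable` below 3 detectable
beats, `acceptable` otherwise. The backend is pluggable
(`preprocessing.QUALITY_BACKENDS`), as is the R-peak detector. Interval-only
recordings carry no waveform to judge and pass by convention. Only
`excellent` snippets reach the feature table.

**HRV panel.** All indices are computed from the NN intervals in
milliseconds per their published definitions (`hrv.py`); estimators that
are undefined on a given series return NaN rather than raising, so short
snippets naturally produce missing values for the fragile estimators
(DFA needs ≥ 16 beats, multifractal DFA ≥ 20 — a 20 s snippet holds
~25). Conventions worth making explicit:

* Percentiles (Prc20/Prc80) use linear interpolation between order
  statistics.
* MadNN is the median absolute deviation scaled by 1.4826 (normal
  consistency).
* pNN50/pNN20 count *strict* exceedances of the 50/20 ms thresholds.
* HTI and the Shannon entropy bin the intervals at the conventional
  1/128 s width; TINN is the baseline width of the best least-squares
  triangular fit to that histogram.
* HF power integrates a Welch periodogram of the tachogram cubically
  resampled at 4 Hz over 0.15–0.40 Hz; HFn divides by LF + HF power.
* The Poincaré asymmetry decomposition (SD1d, SD2d, SD2a, C1d, C2d, Cd)
  follows the deceleration/acceleration partition of short- and long-term
  variance; Guzik's index sums line-of-identity distances of
  decelerations, Porta's index counts accelerations among off-identity
  points.
* DFA α₁ fits log F(s) over window sizes 4–16 beats. At these scales the
  estimator runs slightly above the asymptotic exponent (white noise
  measures ~0.6, not 0.5); this bias is shared by standard HRV
  implementations and is irrelevant downstream, where only the relative
  ordering of rhythms matters. The multifractal summaries (Width, Peak,
  Mean, Max, Delta, Asymmetry, Fluctuation) are defined in the
  `_mfdfa_alpha1` docstring.

**Column filtering.** Columns with > 30% missingness are dropped first
(correlation estimates on mostly-missing columns are untrustworthy); the
survivors are scanned greedily in panel order and a column is dropped when
its pairwise-complete |Pearson r| with an already-retained column exceeds
0.9 — the earlier column wins, which makes the audit deterministic.
Remaining missing cells are imputed with the training-column median, then
z-scored; the (median, mean, SD) triples are stored with the model and
re-applied verbatim to screening data.

## GTM

The latent grid is K nodes on [−1, 1]² (8 × 8 by default); the basis is S
Gaussian RBFs on a uniform center grid (3 × 3) plus a constant bias, with
σ = 0.8 × the distance between adjacent centers. Interpreting the "width
0.8" as a multiple of center spacing is the dominant convention in
reference GTM implementations; an absolute width is available via
`RBFBasis(absolute_width=...)`. Node priors are uniform 1/K.

**Initialization** is deterministic PCA: W solves the least squares problem
Φ W ≈ x̄ + U diag(√λ₁, √λ₂) Vᵀ with (λᵢ, vᵢ) the leading eigenpairs of the
data covariance and U the node grid; eigenvector signs are fixed by the
largest-magnitude loading. β⁻¹ starts at max(λ₃, (half the minimum distance
between distinct initial reference vectors)²), falling back to λ₂/2 when
fewer than three positive eigenvalues exist. Deterministic initialization
makes training seed-free; a random-init option sits behind an explicit
seed.

**EM.** The E-step computes responsibilities with log-sum-exp
stabilization; the M-step solves (ΦᵀGΦ + (α/β)I) W = ΦᵀRᵀX and then
updates β⁻¹ as the responsibility-weighted mean squared residual. With
α > 0 this is MAP estimation: the quantity EM ascends — and what
`loglik_trace` stores and the stopping rule watches — is the penalized
log-likelihood ℓ − (α/2)‖W‖²_F, which reduces to the plain log-likelihood
at α = 0. Convergence is declared when the relative change drops below
1e-5 (200 iterations maximum). One consequence of the ridge worth knowing:
reference vectors are shrunk slightly toward the origin, visibly so for
data placed at large radii (the planted-recovery unit test therefore uses a
small α).

Features are standardized before training (the GTM's isotropic noise model
assumes comparable scales); whether the original clinical analysis did so
is not recorded, and the choice is kept in model metadata.

**Serialization** is a two-file archive: a JSON manifest (shapes,
hyperparameters, trace, column names, standardizer, magnification field)
plus `W.csv` written at 17 significant digits, which round-trips float64
exactly — reloading reproduces responsibilities bit for bit.

## Magnification factors

MF_k = √det(J_kᵀJ_k) with J_k = Wᵀ(∂Φ/∂u) evaluated analytically at node
u_k (Gaussian derivative −((u − μ)/σ²)Φ; zero for the bias). The field is
evaluated exactly at the nodes because the downstream KNN constraint
operates on nodes; a finer mesh would be a rendering option only.
Determinants below −1e-12 raise (numerical fault); tiny negatives clamp to
zero. Everything lives in the standardized data space the model was trained
in, so MF scales as c² when W is scaled by c.

## Macroclusters

Each node becomes a point (u₁, u₂, MF) in R³. Because MF is unbounded while
the latent coordinates are order 1, the default scaling min-maxes every
coordinate to [0, 1] ("none" and "zscore" are available; whether the
original analysis scaled is unrecorded). A k = 5 nearest-neighbour search
(Euclidean, distance ties to the lower node index) is union-symmetrized
into the constraint graph. Agglomerative clustering of the reference
vectors then proceeds under the Ward criterion — variance-minimizing
linkage is the common default for constrained agglomeration and produces
compact regions — with merges restricted to graph-adjacent cluster pairs.
When the graph has more components than the requested M, the remaining
merges join the closest clusters outright and each relaxation is logged.
Final labels are renumbered 1..M by smallest member node (labels are
1-based in all reports; node and snippet indices are 0-based internally).
M = 5 and k = 5 are configuration knobs, deliberately manual.

A known behaviour on sharply clustered data: latent nodes that no data
occupy carry reference vectors interpolating smoothly between the occupied
regions (the RBF map is global and smooth). These "bridge" nodes can form
phantom clusters that consume the cluster budget, occasionally causing two
true data clusters to merge while a sparse region keeps its own label. On
the planted five-blob benchmark (separation 8 SD) recovery is typically
good but varies with the random fixture (adjusted Rand ~0.7–1.0 across
fixture seeds; ~0.92 at the default fixture); the constraint graph
mitigates but cannot always veto such merges because at k = 5 it usually
stays fully connected.

## Screening

Per ECG: average the snippet responsibility rows (arithmetic mean — each
snippet counts equally), total the resulting node distribution per
macrocluster, assign the argmax cluster (ties to the lowest id), and map
to a diagnosis through the cluster's label. Cluster labels are the majority
diagnosis of the training snippets that mode-project into the cluster, with
ties broken toward the higher-risk label (af > possible_af > normal) —
the estimator is deliberately simple and the full composition fractions are
exported so users can re-label. Snippets failing quality are excluded from
aggregation, mirroring training; an ECG with no usable snippets is flagged
`unscreenable`. Probability mass is conserved at every stage (node
distribution and cluster totals each sum to 1).

## The synthetic generators

`simulate_rr_series` emulates the *RR statistics* of three regimes, not ECG
morphology (no P waves or fibrillatory waves — a stated non-goal):

* **normal**: RR(t) = mean_rr + A sin(2π·0.25 Hz·t) + ε,
  ε ~ N(0, rr_jitter²), defaults mean_rr = 0.85 s, rr_jitter = 0.02 s. The
  sinusoid mimics respiratory sinus arrhythmia. Its amplitude is tied to
  the jitter, A = 2·rr_jitter (0.04 s at the defaults), so that a
  zero-jitter specification degenerates exactly to a constant series —
  the contract the dispersion-feature sanity checks rely on.
* **af**: RR ~ mean_rr + Uniform(−rr_jitter, rr_jitter) i.i.d., defaults
  0.70 s ± 0.20 s — irregularly irregular, near-zero lag-1 autocorrelation.
* **paroxysmal**: a per-beat two-state Markov chain, P(normal→af) = 0.02
  and P(af→normal) = 0.05 per beat, started from its stationary
  distribution (~28.6% AF — an opportunistic recording catches a patient at
  a random phase). Every beat carries its generating state.

All intervals are floored at 0.25 s by resampling (physiological
plausibility). `simulate_feature_blobs` provides an abstract Gaussian
-mixture fixture with unit within-cluster SD and a minimum pairwise center
distance equal to `separation`.

What the generators do *not* emulate — waveform noise and artefacts,
ectopy, rate trends, device-specific filtering — bounds what passing tests
show: they validate the pipeline's statistical machinery, not clinical
performance on real strips.

## End-to-end behaviour and known limitations

On the standard synthetic corpus (40 ECGs per class, 60 s each) the
pipeline separates pure sinus rhythm from sustained AF essentially
perfectly, and the measured overall accuracy lands around 0.70–0.75
(recompute with `scripts/acceptance.py`). The shortfall is concentrated
entirely in the paroxysmal class, and it is structural rather than a
fitting defect: averaging snippet responsibilities assigns an ECG to the
macrocluster of its *dominant* snippet type, so a paroxysmal recording
whose AF burden within the captured 60 s is low is screened as normal. At
the default switching rates the mean sojourns are ~42 s in sinus rhythm and
~14 s in AF, so fewer than two-thirds of paroxysmal recordings are even in
principle identifiable as mixed by a plurality-of-snippets rule — an
intrinsic ceiling of the averaging rule at these dynamics, not something a
better fit can cross. Detecting paroxysmal AF from a short opportunistic
strip is exactly the hard clinical problem; a screening rule sensitive to
*any* AF-typical snippet (rather than the average) would trade specificity
for paroxysmal recall and is left as future work.

Other limitations: the Gaussian noise model is outlier-sensitive (a
heavy-tailed variant would be the remedy); the number of macroclusters and
the neighbourhood size are manual choices; quality grading is a stand-in
for whatever grader a deployment uses; and problem sizes in the test suite
(50 random EM fits at N = 30, the 120-ECG corpus, 500-point blob fixtures)
are chosen to exercise every claim while keeping the default run fast.
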