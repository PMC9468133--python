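# Methods

## Data model

A dentition is a labeled 3D point set in millimetres. The default protocol
covers 28 teeth (FDI positions 1–7, no wisdom teeth) with 130 crown and
140 root landmarks, 270 in total. Root landmarks are fixed per tooth:
LM-1 in the root-canal centre at the cemento-enamel junction line, LM-2–LM-4
at 2 mm apical steps along the canal, LM-5 at the apex; multi-rooted teeth
are treated as one merged root. The per-tooth *crown* allocation is not
canonical — published totals fix only the sums — so the default allocation
(upper jaw: molars 6, premolars 5, canines and incisors 3; lower jaw:
molars 7, premolars 5, canines 3, central incisors 4, lateral incisors 3)
is a documented, configurable stand-in chosen to respect cusp/edge/fissure
counts per tooth class and to sum to exactly 130. No symmetric per-class
allocation can reach 130 (parity), so the two jaws necessarily differ.

Partial configurations (crowns only, one tooth absent) are first-class:
every operation works on the label subset that is present. Coordinates are
serialized at 4 decimal places (0.1 µm), far below scan accuracy.

## Tooth axis

The axis of a tooth is the 3D least-squares line through LM-1…LM-4, in the
*orthogonal* (total least squares) sense: the dominant right singular
vector of the centred points, anchored at their centroid, sign-fixed
coronal→apical. Coordinate-wise regression of two coordinates on a third
would make the axis depend on an arbitrary frame choice; the orthogonal fit
is frame-equivariant, which the test suite asserts under random rigid
motions. LM-5 is carried in the data model but excluded from the fit.
Landmarks whose centred coordinate matrix has dominant singular value below
1e-9 mm are rejected as degenerate.

Accuracy measures between a predicted and an actual axis: angle α =
arccos |d̂_pred · d̂_act| (degrees, in [0, 90]); Distance A and Distance B
are the perpendicular distances of the predicted LM-1 and LM-4 to the
actual axis line. An alternative reading of Distance A — between the two
axes' intersections with the CEJL plane rather than from the predicted
LM-1 — exists; the point-to-line definition is implemented.

## Shape model

Per jaw (132 / 138 labels): generalized Procrustes alignment removes
translation and rotation only. Scale is retained throughout — centroid
size is preserved per individual per iteration (asserted in tests) —
because jaw size is biologically informative, not nuisance. Rotations are
Kabsch solutions with reflections forbidden; the mean is initialized from
the first individual (deterministic) and iterated until its RMS change is
below 1e-7 mm (cap 100 iterations; typically < 10).

PCA of the aligned coordinate vectors uses the thin SVD; eigenvalues are
sample-covariance eigenvalues (n−1 divisor). Modes are retained until the
cumulative explained variance reaches `variance_fraction` (default 0.98);
eigenvalues below 1e-12 of the largest are always discarded as numerical
null space. The 0.98 default drops the near-null modes that arise from the
linearization of rotation in GPA, which otherwise destabilize low-noise
inference. A combined two-jaw model (270 labels) is available by passing
`jaw=None`; per-jaw models are the default because evaluation is reported
per jaw.

## Missing-landmark inference

Given an observation (crown landmarks, possibly minus one tooth), the
unobserved coordinates are inferred under the probabilistic-PCA view of the
model: x_obs = x̄_obs + P_obs s + ε with ε isotropic, sd `noise_sd_mm`
(default 0.3 mm, the order of combined scan and landmark-placement error).
The posterior mean of the scores is the ridge-regularized projection

    s* = (Λ⁻¹ + P_obsᵀ P_obs / σ²)⁻¹ P_obsᵀ (x_obs − x̄_obs) / σ².

Pose and scores are estimated by alternation: the observation is first
rigidly posed onto the mean shape's observed block (rotation + translation,
no scaling, ≥ 3 non-collinear landmarks required), scores are solved in
closed form, the observation is re-posed onto the current reconstruction,
and so on until the score change falls below 1e-10 (cap 50 iterations).
The refinement matters: a single pose-then-project pass lets the rigid fit
absorb part of the shape deformation visible on the crown block, which
biases the inferred root axes by ~0.5° on noiseless test populations;
alternation reduces this below 0.03°. The procedure is deterministic.

Scores are optionally clamped: if the total Mahalanobis norm
√(Σ s_j²/λ_j) exceeds `max_mahalanobis` (default 3√m), they are shrunk
radially onto the cap, keeping reconstructions inside the plausible shape
population. An unregularized least-squares projection
(`method="projection"`) is available for comparison. With zero retained
modes the reconstruction is the posed mean shape — this is also the
explicit "mean-shape baseline" used in evaluation, the no-information
reference any useful model must beat.

## Evaluation protocol

Leave-one-out cross-validation: for each case, a model is trained on all
other cases (leakage-free by construction; each result records its training
fold), the held-out case's crown landmarks form the observation, and
predicted root landmarks are scored against the actual ones. Scenarios:

* *full dentition* — all 14 crowns of the jaw observed; all 14 teeth
  evaluated;
* *missing tooth* — one tooth's crowns additionally removed; by default the
  removed tooth is evaluated (optionally all 14). Run for every tooth, this
  yields 14 scenarios per jaw.

Summaries give per-tooth and pooled per-jaw mean ± sd (n−1 divisor); for
n = 1 the sd is reported as 0 with an explicit flag so report tables stay
total. Scenario differences use two-sided paired t-tests on (individual,
tooth) pairs, Holm-adjusted over the family of all compared teeth × 3
metrics of a jaw (42 tests for a full comparison); the family size is a
documented choice, configurable by slicing the inputs. Degenerate
zero-variance differences are reported (t = 0, p = 1 if the mean difference
is also zero; t = ±∞, p = 0 otherwise) rather than raised.

## Synthetic populations

The generator emulates exactly the structure the model assumes:
individual = template + Σ_j s_j·mode_j + noise, then an optional random
rigid motion. The template places the 14 tooth centres of each jaw on a
parabolic arch (width 60 mm, depth 45 mm), arranges crown landmarks in
class-specific rings around each crown, and lays root landmarks along a
tooth-local, buccally inclined axis with the exact 2 mm LM spacing; it is
exactly mirror-symmetric about the midsagittal plane. Deformation modes are
parametric fields — arch width, whole-tooth inclination, arch depth, root
flare, left/right inclination asymmetry, arch curvature — orthonormalized
in that order. Inclination and arch fields move crowns and roots of a tooth
coherently, so crowns genuinely predict roots (the identifiability property
the method rests on); the root-flare field moves roots only and represents
variation crowns cannot see, keeping the prediction task honest. Score sds
default to (8, 6, 5, 4, 3, 2) mm in configuration-vector norm, i.e. about
0.1–0.5 mm RMS per landmark; landmark noise is iid isotropic. These scales
are plausible-magnitude choices — no empirical shape spectrum for such a
cohort is available — and results on them must not be read as estimates of
any clinical population.

Benchmark presets (fixed seeds, overridable): `smoke` n=10, 2 modes;
`default` n=30, 4 modes, noise 0.05 mm; `paper_scale` n=71, 6 modes, noise
0.15 mm. The `default` preset is the standard benchmark for parameter-
recovery claims: model LOOCV mean angle error beats the mean-shape baseline
in every tested seed, and removing one tooth's crowns barely changes
accuracy (missing/full angle ratio ≈ 1.0). What passing these tests does
*not* show: performance on real dentitions, whose shape variation is richer
than six smooth fields, whose landmark errors are anisotropic and
operator-dependent, and which include pathologies the generator never
emulates (orthodontic-appliance artifacts are explicitly out of scope).

## Problem sizes and numerical choices

The shipped evaluations use the preset sizes above (LOOCV on n = 30 with
~400-coordinate per-jaw models runs in seconds; the full 14-scenario sweep
for both jaws in about half a minute). Ties and degenerate inputs are
handled explicitly: coincident root landmarks raise a degenerate-axis
error, collinear observations cannot be posed, empty observations are
rejected (no silent mean fallback), and all stochastic paths are driven by
a single integer seed, making every pipeline run bit-reproducible.

## Known limitations

* Landmark-level only: no root surface reconstruction, mesh handling,
  segmentation or scan superimposition.
* The crown-landmark allocation is a stand-in (totals are fixed, per-tooth
  counts are not); models built under a different allocation are not
  interchangeable (the model file records a protocol hash).
* The posterior inference assumes isotropic landmark noise and a Gaussian
  low-rank shape prior; systematic landmarking bias violates both.
* Multi-rooted teeth are represented by one merged axis by design.
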