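# Methods

## The estimand and the procedure

The object of inference is geometric structure in a perceptual space:
the distance between two perceptual categories, and the dispersion (polygon
area) of a group of categories. Rather than fitting one MDS solution to the
grand-mean dissimilarity matrix, the pipeline fits a classical MDS solution
to each participant's own matrix and computes every geometric statistic
*inside* each participant's solution. The per-participant values are then an
ordinary sample, so standard inferential tests apply. Averaging happens, if
at all, only at the very end and only for display.

The key property motivating this order of operations is that an MDS solution
is identified only up to rotation, reflection and translation. Distances and
shoelace areas are invariant under exactly those transformations, so
per-participant statistics are unaffected by each solution's arbitrary
orientation. Element-wise averaging of raw coordinates is *not* invariant:
solutions in different orientations partially cancel and the mean
configuration shrinks toward the origin (with 25 random orientations the
mean triangle retains under ten percent of the true area in our
simulations). The package therefore averages raw coordinates only for
plotting, exactly as practised, and offers `align="procrustes"` (rigid
alignment to the first solution, no scaling) for a faithful mean picture.

## Sensitivity front end

For an unordered pair {A, B} and one participant:

* hit rate H = P(respond "different" | trial presented A and B, either order);
* false-alarm rate FA = P(respond "different" | trial presented AA or BB),
  pooling both members' same-trials;
* d′ = z(H) − z(FA), the yes/no-style sensitivity index.

The same–different literature contains several d′ models (differencing,
independent observation, ...). The yes/no form is used because it is the
simplest defensible estimator, is monotone in the underlying discriminability
either way, and requires no assumption about how listeners combine the two
observation intervals. No alternative model is offered; fitting one without
knowing the response strategy would imply precision the data do not support.

Extreme rates are corrected by clamping to [1/2N, 1 − 1/2N] (N = trials
behind the rate; the conventional choice), or optionally by the log-linear
(count + 0.5)/(N + 1) rule. Two consequences matter downstream:

* **Saturation.** With n trials per pair, d̂′ cannot exceed
  z(1 − 1/2n) − z(FA_min). At the reference design's 10 different trials per
  pair this cap is ≈ 4, and the cap's *expectation* binds much earlier: true
  d′ above ≈ 2.5 is systematically underestimated. Highly discriminable
  pairs therefore compress, the d′ matrix becomes less Euclidean, and the
  2-D embedding redistributes that distortion into all distances. The
  per-solution diagnostics (`n_negative_eigenvalues`, `negative_share`)
  surface this; a warning fires when the most negative eigenvalue exceeds
  10% of the largest positive one.
* **Noise inflation.** Estimation noise in the matrix spreads the embedded
  points apart, biasing short distances upward. The bias vanishes with trial
  count: in the simulated parameter-recovery check, mean per-participant
  distances are within 2% of latent values at 2,000 trials per pair, but
  inflate by ~10% for the shortest distances at 400.

Negative d̂′ values (possible by sampling noise) are floored at 0 with a
warning before the matrix is built, since the embedding expects
non-negative dissimilarities; participants missing any pair after filtering
are excluded entirely, with a warning, so every retained participant
contributes a complete matrix.

## Classical MDS

Standard Torgerson/Gower principal coordinates: B = −½ J (D∘D) J with
J = I − 11ᵀ/n; eigendecompose B; coordinates are the top-k eigenvectors
scaled by √λ. Numerical conventions, chosen for reproducibility:

* dimensions with non-positive eigenvalues are zero-filled and counted;
* each coordinate column's sign is fixed so its largest-magnitude entry is
  positive (eigensolver output order breaks exact ties);
* k = 2 by default (the planar solution the geometry statistics assume);
  1 ≤ k ≤ n − 1 enforced.

When D is Euclidean and planar the embedding reproduces all pairwise
distances to ~1e-14 (verified over 1,000 random 6-point configurations).

## Geometry

Distance is the Euclidean norm of the coordinate difference. Areas use the
surveyor's (shoelace) formula; for triangles the vertex order is irrelevant,
for n ≥ 4 the vertices are ordered by angle about their centroid (ties by
radius) and the resulting boundary is validated by an O(n²) closed-segment
intersection test over non-adjacent edge pairs — replacing the manual
plot-inspection step with an automated, validated one. The angular sort is
guaranteed for star-shaped point sets, which covers every configuration at
the n ≤ 8 sizes used in practice; a failed validation raises an error naming
the crossing edges rather than returning a wrong area.

Collinearity: when the largest triangle among a group's points is below
1e-12 × (diameter)², the group is declared collinear and its area is 0 with
a warning, never an exception — an inherent blind spot of area-based
dispersion (a perfectly linear but widely spread group has zero area).
Degenerate groups do occur in fitted solutions, e.g. when a pair's d̂′ is
floored to 0 and two objects coincide.

## Inference

`compare()` wraps two-sided t-tests at α = 0.05 with a 95% CI of the mean
difference: Welch (default), pooled-variance Student, and paired. Any other
procedure can be plugged in as a callable; Holm/Bonferroni adjustment is
available for families of comparisons. No adjustment is applied by default.

**Which test matches which design.** Two statistics computed from the *same*
participants are not independent samples. Sharing an object couples them
positively (shared same-trials enter both false-alarm rates); even disjoint
groups are coupled negatively through the joint embedding (truncating a
noisy 6-point matrix to two dimensions trades one group's apparent spread
against the other's — measured correlation ≈ −0.15 in the replicate
studies). An unpaired test on within-participant statistics is therefore
mis-calibrated in either direction; the paired t-test conditions the
coupling away and is the design-appropriate choice, and the replicate-study
calibration bears this out (rejection rate 0.046 at nominal 0.05 over
10,000 null studies for paired-within; 0.05 for Welch-between on
independent cohorts; ≈ 0.063 for the mismatched Welch-within combination,
which remains available precisely to demonstrate the hazard).

## Synthetic studies

The generator emulates a 6-object AX discrimination study: 60 same + 150
different base trials per participant plus 15 extra same trials per object
(300 trials, 150/150 same/different after balancing), 25 participants,
7,500 trials in total; counts that do not divide evenly are spread
round-robin with the remainder logged. Each participant perceives the latent
configuration moved by a random rigid motion (rotation, reflection,
translation) plus iid Gaussian jitter per object (default SD 0.15 p.u.,
about 10% of within-group distances). Responses follow a signal-detection
model: a pair at perceived distance d has true d′ = scale × d (scale 1 by
default — within-group separations ≈ 1.2–1.9 p.u. land in the
well-estimated d′ range, between-group separations ≈ 2.5–4.5 deliberately
exercise the saturation regime described above); P("different") is
Φ(d′ − c) on different trials and Φ(−c) on same trials with criterion
c = scale/2, so the yes/no estimator is unbiased for d′ by construction.
Reaction times are uniform on (400, 1500) ms, inside the filter window; an
optional contamination fraction falls outside (300, 2300) ms to exercise
the filter. All randomness flows through named streams keyed by
(seed, participant, stage), so studies are byte-identical across runs and
independent of evaluation order.

What the generator does **not** emulate: acoustic or phonetic structure of
the stimuli, sequential effects (fatigue, adaptation, order biases),
response-time models, non-Gaussian participant heterogeneity, and
criterion drift. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated response model, not robustness to
these real-data features.

Replicate-study experiments (`mdsinfer.experiments`) draw per-(participant,
pair) response *counts* from the binomial model instead of materialising
individual trial rows; with exchangeable trials and no sequential structure
the two routes are distributionally identical (cross-checked in the test
suite), and the count route is what makes 10,000-study calibration runs
take seconds. Their null configuration is two congruent triangles offset
horizontally (equal latent areas, congruent latent distances, side lengths
≈ 1.4–1.6 p.u.), with a reduced 240-trial design (8 different trials per
pair, 20 same per object) so that estimation noise is realistic; effects
are injected by dilating the second triangle about its centroid (area
scales with the square of the dilation).

## Problem sizes and defaults used in the shipped checks

Reconstruction: 1,000 random planar 6-point configurations. Geometry
invariance: 1,000 random rigid motions; simplicity: 900 random point sets,
n = 3…8. Reflection safety: 25 participants, zero jitter, exact (infinite
trial) matrices. Calibration: 10,000 replicate null studies (paired,
within), 4,000 (Welch, between); power: 400 studies per effect level at
dilations 1.3, 1.6, 2.0. d′ recovery: one pair, true d′ = 1.5, 10,000
trials per kind (estimate within ±0.05).

## Known limitations

* Within-participant comparisons depend on the paired test for calibration;
  the unpaired variants are provided for fidelity to common practice but are
  not recommended for same-participant designs.
* d′ saturation bounds the measurable range; very discriminable pairs need
  prohibitive trial counts and their distances compress in the embedding.
* The area statistic is blind to collinear dispersion and, like all of the
  geometry, is defined for k = 2 embeddings only.
* The angular vertex sort can in principle fail for strongly non-star-shaped
  point sets at large n; it is validated on every call and fails loudly.
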