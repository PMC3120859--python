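# Methods

`rhizotrack` reconstructs single-nucleus dynamics in a growing plant root
tip from light-sheet time-lapse stacks: deconvolution, depth-normalized
segmentation, rigid registration, assignment-energy tracking by simulated
annealing, cell-division detection, and velocity-field kinematics. Because
no public dataset accompanies this problem, the package carries a
first-class synthetic generator whose defaults encode the measured
statistics of the system it emulates; every downstream stage is validated
by parameter recovery against that generator.

## The synthetic root

Nuclei are packed into a capped cylinder (hemispherical tip at the origin,
axis along +y/gravity) by hard-core dart throwing calibrated so the mean
nearest-neighbour distance equals the requested spacing (10 µm default,
matching the ~10 µm inter-nuclear separation of an *Arabidopsis* root tip
meristem). Dynamics per 10-minute step:

* **Longitudinal stretch** `v_m = E · max(0, m − m₀)` with
  `E = 5.0×10⁻⁴ (µm/min)/µm` early, declining to `2.3×10⁻⁵` late
  (switch at 21 h) and onset `m₀ = 90 µm` from the tip.
* **Rigid rotation** about the root axis at `ω` rad/min (no twist, no
  shear); the default is set so the spatial mean of `ρ·v_θ` is the
  measured 0.017 µm/min at the default geometry.
* **Jitter**: each nucleus fluctuates about a tether point advected by
  the deterministic drift: `u ← 0.85·u + step`, with step magnitudes
  gamma-distributed and scaled so the *realized* per-step displacement
  has mean 1.1 µm (SD ≈ 0.75 µm). Two deliberate choices here. First,
  the magnitude family is a generator choice — an isotropic Gaussian step
  cannot reproduce mean 1.1 *and* SD 0.8 (it pins mean/SD ≈ 2.4); a gamma
  magnitude with an isotropic direction reproduces the mean exactly and
  the SD nearly. Second, steps are *not* accumulated as a free random
  walk: at 1.1 µm per step a random walk spreads inter-nuclear distances
  so widely that within ~2.5 h a third of the nuclei become optically
  unresolvable, contradicting the maintained ~10 µm packing of the real
  tissue over 29 h. The tether (relaxation 0.85/step, stationary
  excursion ≈ 2.6 µm RMS) models sub-cellular confinement while keeping
  the per-step displacement statistics.
* **Divisions** occur at a Gaussian rate profile in `m` (centre 150 µm,
  σ 35 µm) so events cluster 100–200 µm from the tip. The default peak
  rate (1.5×10⁻³ /nucleus/min) is a desk-scale choice that yields ~10²
  events in a typical 50-frame run — enough for stable statistics; the
  source system's absolute rate is not published. Daughters separate
  symmetrically in opposite directions along a sampled axis (80%
  longitudinal / 12% circumferential / 8% radial, ±0.25 rad noise) with
  magnitudes `N(2.6, 0.6²)` µm, then keep separating through the ~30 min
  cytokinesis window toward the 10 µm cell spacing — mirroring the
  observation that nuclear separation is trackable *during* cytokinesis.
  The marker brightens up to 5× just before the split, drops to half
  after it and recovers over 30 min; daughter lateral size falls by 20%.

### Forward imaging model

Each nucleus renders as an anisotropic Gaussian (intrinsic ~2 µm SD
convolved with a 1 µm lateral / 1.78 µm axial PSF — the 4.2 µm FWHM
excitation sheet dominates axially). Attenuation is exponential in the
two tissue path lengths (collection axis +z, sheet axis −x), calibrated
to 60%/35% deficits at full root diameter, and is applied **per voxel**:
depth varies across a nucleus, and a flat per-nucleus factor would leave
a spurious gradient after depth normalization that skews measured
centroids by ~0.2 µm. Poisson shot noise (500 counts per unit intensity
over a 2-count background) and Gaussian read noise (σ=3) complete the
model. Not modelled: optical wave effects, sheet-scanning geometry,
photobleaching (none was detected in the source system), stage error.

### What the generator does not emulate

Real stacks contain autofluorescence structure, a cortex with depleted
marker, segmentation-relevant debris, and nuclei of varying shape.
Passing recovery tests on this generator demonstrates that the analysis
chain is unbiased and correctly calibrated under the stated statistics —
not that it would reach the same error rates on real data.

## Deconvolution

Richardson–Lucy (Poisson EM) with the PSF measured from (synthetic) bead
stacks; fixed 30 iterations, constant background from the 1st intensity
percentile subtracted first, reflective padding around the
frequency-domain convolutions. Flux is conserved to <1% and the Poisson
likelihood is non-decreasing per iteration. We implement the iteration
in-package because the boundary/background contract above is part of the
pipeline's behaviour; `skimage.restoration.richardson_lucy` serves as an
independent cross-check in the test suite.

## Segmentation

The convex hull of supra-threshold voxels approximates the root
boundary; per-voxel optical depths to the hull along +z and −x feed a
least-squares quadratic fit of log maximum intensity, which flattens the
depth-dependent intensity decay (correction clipped to [0.05, 1]).
Extraction uses an increasing geometric series of global thresholds with
26-connected components classified by ranges on voxel count, mean
intensity, lateral size/eccentricity and axial size plus a
single-axial-maximum test; accepted voxels are masked from higher
thresholds. Numerical choices that proved load-bearing:

* The series is anchored at the **median local-maximum intensity**, not
  the stack max: 5× pre-division intensity spikes otherwise push every
  level above the dim, freshly separated daughters. The series spans
  0.18–6× the anchor over 24 levels so bright spiking nuclei still
  isolate at the top.
* Criteria ranges ship calibrated on the synthetic fixtures (the source
  method's ranges were trained on hand-labelled nuclei and are not
  published). Two presets: the default for raw 2 µm stacks, and
  `SegmentationCriteria.deconvolved()` for 1.5×1.5×2 µm deconvolved
  stacks, whose tight size/eccentricity maxima reject the ~5 µm dumbbell
  of an unresolved daughter pair so that a higher threshold can split it.
* A final **relaxed fallback pass** accepts leftover blobs that still
  hold an unclaimed intensity peak: an unresolved pair then yields one
  oversized record rather than a detection gap. Those records carry the
  very artifact signature the division classifier is trained to reject.
* Accepted centroids are re-estimated by two iterations of a symmetric
  spherical-window (r = 2.8 µm) centre of mass with background-relative
  weights: hard-threshold supports lose flank voxels toward neighbours,
  and the symmetric window removes the resulting ~0.1–0.3 µm truncation
  bias.

"Lateral size"/"axial size" are twice the intensity-weighted RMS extent
in the (x, y) plane / along z (with a half-voxel variance floor);
"lateral eccentricity" derives from the 2×2 lateral second-moment
eigenvalues. The axial-maximum test smooths the per-slice maximum profile
with a 3-point window and rejects components with a second peak of ≥6–10%
prominence (preset-dependent).

## Registration and the root frame

Image-based rigid registration is an iterated Gauss–Newton (Lucas–Kanade)
minimization of the summed squared intensity difference over axis-angle +
translation, coarse-to-fine over a 3-level pyramid, with backtracking
line search and a validity mask that excludes voxels within two voxels
of out-of-bounds samples (edge gradient cliffs otherwise dominate the
normal equations). It mirrors the instrument's tip-tracking loop:
translations are what a stage would apply; rotations are estimated but
not applied.

Point-cloud refinement aligns consecutive frames' segmented centroids by
trimmed ICP: nearest-neighbour correspondences (keeping pairs within 2×
the median distance), closed-form Kabsch update, iterated to a fixed
point. The closed-form update replaces literal gradient descent on the
same mean-squared-displacement objective; each round solves that
iteration's minimization exactly. In the pipeline the refinement is
**translation-only** and each raw frame pair is aligned before
accumulating corrections — aligning against an already-shifted frame
grows the relative offset past the inter-nuclear distance and corrupts
the correspondences. Rotations stay out of the refinement deliberately:
the root's own rigid rotation is physical signal that inter-frame
alignment would silently absorb.

The root frame (m, ρ, θ) is anchored per frame: axis = principal
component of the centroid cloud (oriented tip-to-base), tip origin 10 µm
distal of the 1st-percentile projection, both smoothed over 5 frames;
θ = 0 toward the objective (+z), π/2 toward the laser (−x), reported as 0
on the axis.

## Tracking

Identity assignments form a forest scored in µm²: squared displacement
per link plus a penalty per skipped frame (one skip allowed); per node,
λ·[f(n_parents) + g(n_children)] with f(1)=g(1)=0, terminal penalties
f(0)=g(0)=25 µm² (their sum centred in the admissible window
d²_max=25 < f(0)+g(0) ≤ d²_nn=100, and waived at the observation
window's first/last frames — otherwise every true trajectory endpoint is
penalized), a finite fusion penalty f(2)=60 µm², and a branching term
g(2) built to be negligible for true divisions: per daughter a quadratic
hinge on | |Δ| − 2.6 µm | beyond a 0.6 µm dead-band (κ=4), plus
25·(1+cos φ)/2 on the inter-daughter angle. The hinge/cosine bodies are
this package's choice — the published description fixes their roles and
calibration anchors but not their functional forms.

Optimization: greedy nearest-neighbour initialization (link if within
d_nn and energy-reducing, ties by record index), then Metropolis
annealing. Move targets are drawn proportionally to their energy
contribution (Fenwick tree, +0.5 µm² floor so zero-energy nodes stay
reachable); kinds are cut/add/change with a second serial move (p=0.5)
targeting a node touched by the first. Temperature starts at 25 µm²
(the order of the dominant f(0) barrier; the true critical temperature
of the source system is not recoverable), equilibrates for up to 5000
moves and cools exponentially to 0.1 µm² over 200 moves/record.
Incremental energies are verified against full recomputation every 10⁴
moves; the lowest-energy configuration ever visited is returned via an
operation journal. On random toy instances (no gaps) annealing reaches
the exhaustively enumerated global optimum — without gaps the energy
separates over consecutive frame pairs, which is what makes exact
enumeration tractable as an oracle.

## Division detection

Candidates are every forest branch point **plus** every trajectory that
appears at an interior frame within d_nn of a continuing one. The second
class matters at desk-scale resolution: daughters born ~5 µm apart are
often segmented as one blob for a frame or two, so the split surfaces as
a new trajectory beside an existing one rather than as a branch. Features
per candidate: parent lateral size and maximum intensity over the three
frames up to the branch, both daughters' over the three frames after,
trajectory durations, daughter displacement magnitudes, inter-daughter
angle cosine, and the imputation count. A class-weighted RBF-kernel SVM
on standardized features (5-fold stratified CV for the report) separates
true divisions — pre-division intensity spike, size drop, recovery —
from resolution artifacts. On synthetic runs the training labels come
from the ground-truth lineage (the stand-in for manual annotation),
matched in the registered frame. A third candidate class covers a
trajectory that ends while two fresh ones appear nearby (both daughters
unresolved briefly). The decision threshold is set on out-of-fold
scores to reach 92% sensitivity: a missed division is gone for good,
while a spurious event is absorbed by the downstream statistics.

The per-division displacement statistic uses the *sharp* subset of
accepted events — actual forest branches with both displacements within
d_max — because appearance-class events measure the blob-to-daughter
jump at the (later) optical split, not the cytokinesis displacement.
Each sharp event contributes half its inter-daughter separation:
daughters part symmetrically in opposite directions, so this equals the
mean parent-to-daughter magnitude while the parent-centroid error
cancels and the daughter errors halve.

## Kinematics

Velocities are per-step finite differences in cylindrical components
attributed to the step midpoint, division-adjacent steps excluded (the
parent trajectory 3 frames back, daughters 3 frames forward — daughters
still drift apart through cytokinesis). Binned fields use medians and
quartiles per 5 µm bin with a 36-sample mask; the expansion slope is the
least-squares line of v_m on m over 80–300 µm; rotation/twist/shear are
the spatial mean of ρ·v_θ and regression slopes with 95% intervals.
For weak gradients (the late-window expansion is ~20x below the early
one) velocities can be computed over longer lags or whole trajectories
(one endpoint sample per trajectory): the tethered jitter is bounded, so
its contribution to a lag-L velocity falls roughly as 1/L while drift
persists. Even so, trajectory fragmentation caps the attainable slope
precision at desk scale — the late-window estimate carries a standard
error comparable to half its value.
The mean non-dividing step displacement removes the fitted drift
(stretch slope and mean rotation) and keeps only steps between compact
blobs (lateral size below the record population's median + 2.5 robust
SD — oversized blobs are unresolved pairs whose centroid jumps) and
below d_max = 5 µm. Trajectory frequency splitting is an exact DFT
partition at 0.23 hr⁻¹ (low band includes the mean; the two bands sum to
the input to numerical precision); gapped trajectories are linearly
interpolated onto the uniform grid first, with interpolated samples
flagged.

## Pipeline presets and problem sizes

Two imaging configurations ship as defaults of the analysis entry point:

* **Kinematics runs** (expansion, rotation): 2 µm voxels, no
  deconvolution. At the 10 µm packing with no divisions, raw stacks
  segment with ≤1% error and sub-0.25 µm centroid RMS; skipping the EM
  step keeps a 50-frame run ≈ 2 minutes.
* **Division runs**: 1.5×1.5×2 µm voxels, 30 EM iterations,
  `SegmentationCriteria.deconvolved()`. Freshly separated daughters sit
  at the resolution limit; the finer sampling and deconvolution roughly
  double same-frame daughter resolvability.

Synthetic studies use a thin root (radius 15 µm, length 340 µm →
~240 nuclei) so the 80–300 µm fit region is covered at a few hundred
nuclei per frame; the real organ's 50–75 µm radius would hold thousands
of nuclei per frame and push a single tracking run far past interactive
time without changing which properties are exercised.

## Known limitations

* At 1.5–2 µm voxels, ~10–15% of divisions (mostly collection-axis
  oriented) are unresolvable at the division frame and are recovered
  late or not at all; recovery on the division fixture is ~65–70%,
  at the lower edge of what the source system achieved on real data
  with 0.465 µm pixels.
* The measured division displacement carries a ~+8% bias from centroid
  noise on dim, truncated daughter blobs even after refinement.
* The late-window expansion slope (2.3×10⁻⁵ (µm/min)/µm) is ~20× weaker
  than the early one; at desk-scale sample sizes its estimate carries a
  relative standard error of tens of percent, so late-window recovery is
  reported with wide uncertainty.
* The annealer's energy is calibrated for ~10 µm packing and ~1 µm
  steps; densities or motilities far outside that regime need new
  penalty constants.
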