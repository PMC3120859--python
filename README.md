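# rhizotrack

Quantifying cellular dynamics in a growing plant root tip from
light-sheet fluorescence time-lapse imaging: nucleus segmentation with
tissue-depth intensity normalization, rigid registration, nuclear
identity tracking by simulated annealing, cell-division detection, and
velocity-field kinematics in a tip-anchored cylindrical frame. The
package targets 3D stacks of a nuclear-localized marker (e.g.
H2B-fused fluorescent protein) acquired every ~10 minutes over hours to
days, and ships a first-class synthetic-root generator so the entire
chain can be developed and validated by parameter recovery without any
acquired data.

## The analysis in brief

A root tip is modelled in cylindrical coordinates *(m, ρ, θ)* anchored
at the tip: *m* is the distance from the tip along the principal axis,
*ρ* the radial distance, *θ* the azimuth measured from the objective
axis. Per 10-minute interval the pipeline:

1. **Deconvolves** each stack by Richardson–Lucy (Poisson EM, fixed
   iteration count) with a PSF measured from bead stacks.
2. **Segments** nuclei: the convex hull of supra-threshold voxels
   approximates the root boundary; log maximum intensity is fit by least
   squares to a second-order polynomial in the two optical depths
   (collection and sheet axes) and divided out; an increasing series of
   global thresholds extracts 26-connected blobs classified by ranges on
   voxel count, intensity, lateral/axial size, eccentricity and a
   single-axial-maximum test — accepted voxels are masked from higher
   thresholds.
3. **Registers** consecutive frames (Lucas–Kanade rigid image alignment
   for tip tracking; trimmed-ICP translation refinement of the segmented
   centroids).
4. **Tracks** nuclear identities as a forest minimizing the assignment
   energy

   *E = Σ<sub>links</sub> |Δx|² + gaps + λ Σ<sub>i</sub> [f(n<sub>prev</sub>) + g(n<sub>next</sub>)]*  (µm²),

   where f(1)=g(1)=0, the terminal penalties satisfy
   d²<sub>max</sub> < f(0)+g(0) ≤ d²<sub>nn</sub>, fusions carry a finite
   penalty, and the branching term g(2) is negligible exactly for true
   divisions (symmetric anti-parallel daughter displacements of ~2.6 µm).
   Minimization: greedy nearest-neighbour initialization, then Metropolis
   simulated annealing with energy-biased move targeting and exponential
   cooling.
5. **Detects divisions** by classifying branch candidates with an SVM
   over size/intensity time courses (pre-division intensity spike, size
   drop, recovery), trajectory durations and displacement geometry.
6. **Measures kinematics**: binned velocity fields, the longitudinal
   expansion slope of v<sub>m</sub> vs m, rigid-rotation/twist/shear
   statistics, per-trajectory frequency splitting at 0.23 hr⁻¹, and the
   non-dividing per-step displacement with collective drift removed.

See `docs/methods.md` for the model details, calibrated defaults and
known limitations.

## Worked example

```python
import numpy as np
from rhizotrack.synthetic import simulate_root, evolve, KinematicsParams, DivisionModel
from rhizotrack.pipeline import run_synthetic_analysis
from rhizotrack.kinematics import fit_expansion, rotation_and_shear

# a small root: ~90 nuclei, 16 frames at 10-minute steps
root = simulate_root(radius=15.0, length=160.0, spacing=10.0, seed=7)
evolve(
    root,
    KinematicsParams(expansion_rate_early=5.0e-4, expansion_onset_m=40.0,
                     rotation_rate=1.5e-3),
    DivisionModel(rate_peak=0.0),
    n_steps=15,
    seed=8,
)

result = run_synthetic_analysis(root, seed=7)
velocities = result.velocity_samples()
fit = fit_expansion(velocities, fit_range=(50.0, 150.0))
rotation = rotation_and_shear(velocities)

print(f"records: {len(result.records)}  trajectories: {len(result.trajectories.trajectories)}")
print(f"expansion slope: {fit.slope:.2e} (µm/min)/µm  [generator: 5.0e-04]")
print(f"mean rho*v_theta: {rotation['mean_rho_v_theta'][0]:.4f} µm/min")
```

Output:

```
records: 1673  trajectories: 154
expansion slope: 4.97e-04 (µm/min)/µm  [generator: 5.0e-04]
mean rho*v_theta: 0.0162 µm/min
```

The simulated root stretches along its axis at 5.0×10⁻⁴ (µm/min)/µm
beyond 40 µm from the tip and rotates rigidly at 1.5×10⁻³ rad/min; after
rendering ~90 nuclei per frame into noisy attenuated stacks, segmenting,
tracking and transforming into the root frame, the fitted expansion
slope lands within 1% of the setpoint and the mean angular velocity
component within ~8% (the sampled nuclei sit at a mean radius of
~11 µm, so 1.5×10⁻³ rad/min corresponds to ≈0.017 µm/min).

## Command line

```bash
rhizotrack simulate --radius 15 --length 340 --steps 30 out/sim
rhizotrack deconvolve --psf psf.tif --iters 30 in.tif out.tif
rhizotrack segment out/sim/stack_0000.tif records.csv
rhizotrack track records.csv out/tracking
rhizotrack kinematics records.csv out/tracking/forest.json kin.json
rhizotrack run config.yaml --seed 7      # full pipeline from a YAML config
```

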