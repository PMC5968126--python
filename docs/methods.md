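# Methods

`fibrofocal` studies how left-atrial patchy fibrosis degrades the
non-invasive localization of focal atrial tachycardia (FAT) sources from
body-surface P-wave integral maps (BSPiM). The package chains four layers:
cellular/tissue electrophysiology, stochastic fibrosis generation, a
forward body-surface model, and a clustering/classification pipeline. This
note documents the models, the calibrated constants, the numerical choices,
and what the synthetic data can and cannot show.

## Membrane models

**Myocyte.** The Courtemanche–Ramirez–Nattel (CRN) human atrial model: 12
membrane currents, 15 gating variables, intracellular Na+/K+/Ca2+ handling
with SR uptake/release. Regional electrophysiological heterogeneity is
expressed as multiplicative factors on the maximum conductances of I_to,
I_CaL and I_Kr in eleven labelled atrial regions (RA, PM, CT/BB, TVR, RAA,
LA, FO, MVR, LAA, PV, CS); the factor table lives in
`src/fibrofocal/data/ionic_constants.yaml` together with every other model
constant. Validation is emergent rather than copied: the resting state
drifts < 0.01 mV over 1 s without stimulation, and the base model's APD90
at BCL 1000 ms is 302 ms, matching the canonical formulation. The test
suite additionally checks the implementation current-by-current against an
independently coded transcription at clamped voltages.

**Fibroblast.** The active MacCannell fibroblast: exactly four currents
(time- and voltage-dependent K+ current I_Kv, inward rectifier I_K1, Na+/K+
pump, background Na+), fixed intracellular concentrations, Cm = 6.3 pF. Its
stable resting potential, found by root-finding on the total current, is
−49.1 mV — some 32 mV above the myocyte — which is what makes
fibroblast–myocyte coupling depolarize neighbouring myocytes.

**Integration.** Rush–Larsen exponential updates for all gates, forward
Euler for concentrations and voltage, dt = 0.02 ms by default (gates remain
in [0,1] by construction; dt ≤ 0.05 ms enforced). Single-cell pacing uses a
rectangular 2 ms stimulus at twice the diastolic threshold found by
bisection. AP metrics: RMP is the pre-upstroke plateau, APDx runs from the
time of maximum dV/dt to repolarization to RMP + (1 − x/100)·amplitude,
with linear interpolation at the crossing.

## Tissue model

The monodomain reaction–diffusion equation is solved on a voxel lattice
(0.3 mm spacing, the slab geometry is 50 × 50 × 0.3 mm) with Godunov
operator splitting: one membrane (reaction) step, then one explicit
7-point finite-difference diffusion step with harmonic-mean face
conductivities and no-flux boundaries. Local activation time (LAT) is the
first upward crossing of −40 mV. The explicit diffusion step is stable for
the default dt by a margin of ten.

**Calibration (all values frozen in the constants file).**

* `diffusion_scale = 104.58` maps the regional conductivity σ_l to the
  longitudinal diffusion coefficient so that a planar wave crosses the
  homogeneous LA slab in 59.0 ms (CV ≈ 0.85 m/s) — the tissue-level anchor
  of the study; the slab anchor wins over the nominal regional CV table.
* Fibrotic voxels use MacCannell kinetics and a conductivity of
  `0.285 × σ_l(LA)` along the host fiber direction. This value was
  calibrated against the fibroblast-barrier anchors — a 0.3 mm transverse
  barrier delays the slab crossing by ≈ 3 ms (+5 %), 0.6 mm by ≈ 12 ms
  (+20 %), and 0.9 mm blocks — and then frozen (measured: 61.4 ms, 71.4 ms,
  block).
* Fibrotic tissue has its own transverse-to-longitudinal ratio
  `fib_anisotropy = 0.07`. This is the one place where the design was
  genuinely open: with isotropic fibrotic conductivity no parameter choice
  reproduces both the barrier delays (which need longitudinal transmission)
  and the conduction-channel experiments (which need weak lateral loading,
  or every channel below 4 mm rests at −53 mV and blocks). Preferentially
  disrupted side-to-side coupling is the classical picture of interstitial
  fibrosis. With 0.07 the 1.2 mm channel blocks and the 1.5/1.8/2.4/2.7 mm
  delays order as 84.5 > 63.7 > 56.1 ≥ 55.1 ms with exit amplitude
  increasing in width.
* `fib_current_scale` (fibroblast membrane-current density per voxel,
  representing fibroblast density) remains 1.0.

**Equilibration.** Myocytes rest near −81 mV, fibroblasts near −49 mV, so
mixed tissue must be relaxed to its coupled resting state before
stimulation; otherwise the initial transient alone depolarizes narrow
channels by tens of mV. Barrier and channel layouts are invariant along one
lattice axis, so the equilibrium is relaxed on a one-voxel-thick profile
for 200 ms (converged to < 5 µV against 400 ms) and tiled — orders of
magnitude cheaper than relaxing the full slab and exactly equal for these
geometries (asserted in the tests).

**Control AP provenance.** The printed control AP (RMP −79.9 mV, peak
0.73 mV, amplitude 80.66 mV, APD90 252 ms) is a tissue measurement: an
isolated CRN cell peaks at +28 mV. The package therefore provides both
protocols: isolated-cell pacing (RMP −79.2 mV, APD90 238.6 ms at dt
0.02 ms) and a plane-wave-paced healthy strip (RMP −79.4 mV, amplitude
82.8 mV, APD90 263.6 ms after 20 beats at BCL 500 ms). The two bracket the
printed APD90 at about ±5 %, which we take as the model-level agreement
limit of an independent reimplementation; no parameter is tuned against it.

## Patchy fibrosis generation

Elements (voxels or surface vertices) are seeded — 50 seeds split equally
across the pulmonary-vein ostia, coronary sinus, fossa-ovalis ring and
posterior LA wall (the stated regions; the stated-but-unquantified
"different proportions" default to equal weights) — and grown by frontier
expansion. Every newly added contour element is reverted to healthy with
probability `drop_prob = 0.3` (the published description randomizes the
contour without giving a probability; 0.3 produces ragged contours with
occasional enclosed healthy islands and is frozen). Reverted sites adjacent
to older fibrosis are not retried, which is what leaves islands. The final
frontier batch is trimmed so the achieved fraction lands on the growth
target to within one element. Growth targets 2 / 12 / 18 / 28 / 40 % of the
LA volume define stages I–V; stages nest within a case (each grown from the
previous stage's set). Stage labels follow the Utah quartiles
(I < 8.1 % ≤ II < 16 % ≤ III < 21 % ≤ IV), with the top quartile split into
two growth targets (IV, V) and band edges resolving upward. Everything is
deterministic given (mesh, seeds, parameters, rng seed).

## Synthetic atlas and activation surrogate

The organ-scale anatomy is deliberately schematic: two ellipsoidal
icosphere shells (LA ≈ 28 × 25 × 22 mm semi-axes, RA slightly smaller)
carrying per-vertex region labels as angular caps/bands (four PV ostia,
LAA, MVR, FO disc + conducting rim, CS, posterior wall; CT/BB, RAA, TVR, PM
on the right), joined by three explicit inter-atrial connection edges
(Bachmann's bundle, fossa-ovalis rim, coronary sinus). The FO disc itself
is non-conducting (regional σ_l = 0). The torso is an ellipsoidal
Fibonacci-lattice "electrode vest" (default 14,157 nodes). 57 ectopic foci
(19 primary) are placed deterministically by farthest-point sampling within
regions, covering both atria.

Activation is an eikonal first-arrival problem solved by fast marching on
the triangle mesh: per-vertex speeds follow the regional longitudinal CVs
(0.633 m/s generic atrium up to 1.154 m/s pectinate muscles), treated
isotropically on the surface. The fibrosis rules are calibrated from the
slab layer, not re-fitted: conducting fibrotic vertices travel at 0.5× the
local speed (the 0.85 → 0.50 m/s channel observation) and vertices at ≥ 2
rings from the nearest healthy vertex block entirely (the surface analogue
of the ≥ 0.9 mm transmural block). A focus inside a blocked zone does not
capture and its run is excluded — on this atlas exclusions appear at stages
4–5, in the spirit (not the exact counts) of the original exclusions.

The fast-marching update is the two-point virtual-source-on-edge solve
(equivalent to the classical planar update on acute triangles, with the
causality guard and a Dijkstra fallback), followed by Gauss–Seidel sweeps
to a fixed point. The front-curvature error near the source would exceed
2 % on its own, so sources are initialized exactly within at most 12 rings
of slowness-homogeneous neighbourhood using the chord length corrected by
the vertex-normal rotation (arc = chord·(θ/2)/sin(θ/2), exact on spheres
and second-order on smooth surfaces). On an icosphere (subdivision 4) the
maximum relative error against the closed-form great-circle solution is
below 1.7 % across slowness scalings.

## Forward body-surface model

The heterogeneous-torso bidomain projection is replaced by an
infinite-homogeneous-conductor current-dipole sum: each surface triangle
contributes −σ·A·∇V, and the composition of the dipole kernel with the
per-face gradient operator collapses into one dense electrodes × vertices
lead-field matrix. Absolute potentials are nominal; the spatial pattern
structure the pipeline consumes is preserved, and linearity/superposition
hold to machine precision. Electrode potentials are referenced to their
zero mean at every sample.

Per-run transmembrane movies are the paced LA AP template shifted by the
local activation time, sampled at 1 kHz, with the AP excursion scaled by
0.58 on conducting fibrotic vertices (the printed amplitude-reduction class
80.66 → 46.63 mV) and flat at rest on blocked/unreached vertices. The
P-wave window is depolarization only — [0, max LAT + 30 ms]. This matters:
integrating the full AP cancels the depolarization integral against
repolarization and buries the map in noise (integral SNR ≈ 1), whereas the
physiological P wave is the depolarization signal.

Noise and integration follow the study's calibration: white Gaussian noise
with one third of the mean signal power (power ratio 3 ⇒ SNR 10·log10(3) =
4.77 dB; the printed absolute powers, 0.003 mW ↔ −55.2 dBW, are treated as
nominal — only the ratio has physical effect), Savitzky–Golay smoothing
(window 21 samples, order 3; unstated in the source, standard defaults),
trapezoidal time integration per electrode, and normalization of each map
to [−1, 1] by its maximum absolute value.

## Localization pipeline

1. **Electrode reduction** — the torso nodes are partitioned into 256
   spatially contiguous, size-balanced patches (deterministic k-means
   tessellation of the coordinates; 14,157/256 ≈ 55 nodes per patch) and
   one seeded-random representative per patch becomes an electrode.
2. **Clustering** — Ward variance-minimizing agglomerative clustering of
   the BSPiMs, cut at exactly K clusters for K = 2…10 (a distance-threshold
   mode would give the same cuts; exact-K is implemented).
3. **Cluster → region association** — every focus accumulates the cluster
   labels of its runs. The atria are tessellated into geodesic-Voronoi
   patches around the foci; foci are graph-adjacent when their patches
   share a border. Metrics: persistence |labels(x)|/K ∈ [1/K, 1];
   OR = % of foci with more than one label; CR = % of foci not isolated
   from their class in the ectopic graph (the node-based reading that
   reproduces the worked example 17/19 = 89.4 %; the cluster-based variant
   is reported as a secondary output); mean ± sd region area with
   multiply-labelled foci double-counted.
4. **Electrode selection** — a single global χ² ranking of electrodes
   against the cluster labels (features min-max rescaled to [0, 1] for
   scoring only), truncated to N = 2…256; a single ranking makes the
   selected sets nested by construction.
5. **Classification** — RBF-kernel SVM with per-feature standardization,
   stratified 4-fold cross-validation, and an inner 3-fold grid search over
   C ∈ {0.1, 1, 10, 100} and kernel widths; a `fast` mode (fixed C = 10,
   γ = 'scale') exists for large grids. Classes smaller than the fold count
   are merged into their nearest class by centroid with a warning.

## What the synthetic data shows — and what it does not

The generator reproduces the statistical structure of the original
dataset: 57/19 focus sets, 5 cases × 5 nested fibrosis stages spanning
2–40 % burden, fibrosis-induced slowing/block perturbing the activation
maps, exclusion of buried foci, and the bookkeeping identities
(475 candidates, M0 = 57, M2 = 190). On it, the pipeline reproduces the
study's qualitative findings: no-fibrosis accuracy ≥ 0.90 up to K = 6 with
256 electrodes, chance-level accuracy under label permutation, overlap (OR)
growing with fibrosis level and K, region areas shrinking with K, and
accuracy degrading (weakly) from M1 to M5 at high K. It cannot reproduce
the printed per-cell accuracy table or the exact 54 exclusions — those
depend on the original 754k-node anatomy, its fiber fields, and its 25
specific fibrosis distributions. Geometry-bound numbers from this package
are properties of the surrogate atlas, not of any patient anatomy.

## Problem sizes and determinism

Default sizes: slab 167 × 167 × 1 voxels; atlas subdivision 4
(2,562 vertices per atrium) with a 14,157-node torso; the test suite runs
the geometry layers at subdivision 3 with a 3,000-node torso. Every
stochastic step (seeding, growth, noise, representative sampling, fold
shuffling) takes an explicit integer seed carried by `ExperimentConfig`,
which serializes to YAML losslessly and stamps outputs with its content
hash. Known limitations: no fiber-direction anisotropy on the atlas
surface, no atrial repolarization signal, no baseline wander or QRS
overlap, a single AP template for all regions in the forward model, and an
electrode vest that is a mathematical ellipsoid rather than a torso scan.
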