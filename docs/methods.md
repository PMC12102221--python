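# Methods

## Scope and data model

`lcnpipe` analyzes single-channel 3D fluorescence stacks of FITC-stained,
optically cleared bone in which the lacuno-canalicular network (LCN)
appears bright on a dark mineralized-matrix background. Volumes are
indexed `(z, y, x)`; voxel `i` along an axis of pitch `p` sits at the
physical position `i·p` µm. Intensities live in `[0, 1]`: integer TIFF
data is divided by its dtype maximum at read time, because every contrast
stage assumes a unit histogram interval. All micrometre parameters are
converted to voxels with round-half-up, and each conversion is logged.

## Preprocessing chain

The chain is a fixed composition; each intensity stage maps `[0, 1]` into
`[0, 1]` and only the resampling stage changes the grid.

| stage | parameter (default) | notes |
| --- | --- | --- |
| brightness | kernel 50 µm, stride 8 µm, saturation 0.35 % | per-slice sliding-window quantile stretch; window bounds bilinearly interpolated between window centers |
| denoise | σ = 3.25 × pixel size in µm, in **pixels** | 2D per slice (`gauss_dims: 3` switches to volumetric); at 0.2 µm pixels this is σ = 0.65 px, sub-pixel smoothing |
| normalize | — | global affine min→0, max→1; a constant stack is an error |
| CLAHE | kernel 6 µm, clip limit 0.01 | per slice, square tiles; kernels larger than the slice fall back to one tile (logged) |
| sigmoid | gain 10, cutoff `auto` | `out = 1/(1+exp(gain·(cutoff−in)))`; `auto` = midpoint of the stack's robust `[p1, p99]` range, i.e. image specific |
| resample | 0.4 µm isotropic | trilinear; new shape per axis = `round(extent/0.4)` |
| binarize | threshold 0.6, inclusive `>=` | requires an isotropic grid |

Two protocol parameters (CLAHE clip limit, sigmoid gain) have no stated
value; the defaults above are common normalized choices and both are
exposed in the configuration, which serializes losslessly to YAML.

**Low-signal guard.** Brightness windows and CLAHE slices whose robust
dynamic range (0.5–99.5 percentile spread) falls below
`min_signal_range_fraction` (default 0.2) of the robust stack range are
left unchanged. This extends the degenerate-window rule (a constant
window stretches as identity) to near-degenerate ones: without it, a
structure-free z-slice — common in sparse volumes — is stretched and
equalized into full-scale noise and then binarizes as foreground
(measured on phantoms: foreground fraction 6 % against a 1.5 % truth,
Dice 0.42 versus 0.92 with the guard). Real cortical-bone stacks are
dense enough that the guard rarely triggers; set the fraction to 0 to
disable it.

## Lacuna identification

On the isotropic binary mask, the Euclidean distance transform (EDT)
separates the two structure classes: lacunae are thick (interior EDT well
above the canalicular radius), canaliculi thin. Calibration values are in
voxels at the 0.4 µm working pitch, so the seed threshold of 5 voxels is
a 2.0 µm half-width; they are logged in µm as well.

1. Seeds: voxels with EDT ≥ 5; 26-connected seed components smaller than
   25 voxels are discarded.
2. Growth: each candidate grows by 1-voxel geodesic dilation steps inside
   the mask. A candidate stops growing once a step would add less than
   `limit_fraction` (0.1) of its current volume, with a minimum of
   `dilation_dist` (2) steps. While the label climbs through the lacuna
   body each step adds a large relative shell (≈ 3/r per step), so growth
   runs to the mask boundary; once only canaliculi remain to creep into,
   the relative growth collapses and the label freezes. The same rule is
   the anti-merge guard: two lacunae bridged by a canaliculus never meet.
   Voxels claimed by several candidates in one step go to the nearest
   seed centroid (ties: lower label id).
3. Opening: each label is finished with a morphological opening (ball of
   radius `dilation_dist`). Lacunae are smooth convex bodies and
   canaliculi are thin, so the opening releases the one-to-two voxels of
   canalicular bite swallowed during the final growth steps back to the
   canalicular compartment without changing the body. The erosion half
   treats the outside of the stack as foreground so lacunae cut by a
   stack face keep their face contact; seed-core voxels are never
   released. On phantoms this step moves the total canalicular length
   bias from about −8 % to about −1 %.

The per-step growth-saturation rule in step 2 is this package's
interpretation of the "limit fraction for dilation" calibration value: applying
a 10 % per-step cap literally from the first step would stop all growth
immediately (one dilation shell of a seeded core is 25–40 % of its
volume) and leave every lacuna rind inside the canalicular mask, where it
skeletonizes into closed-surface artifacts.

Per-lacuna outputs: centroid (µm), volume (voxels and µm³), and an
`edge_touching` flag set when any labeled voxel lies on a stack face.
The `exclude_touching` edge policy drops flagged lacunae from the count,
mirroring manual counting, which skips potentially incomplete cells at
image borders; the default `include_all` counts everything the
segmentation sees.

## Skeletonization and pruning

The canalicular compartment (mask minus lacuna labels) is thinned with
3D medial-axis skeletonization (topology preserving, 26-connected
foreground / 6-connected background). Terminal branches shorter than
`skeleton_prune_um` (1.0 µm, ≈ 2.5 voxels) that do not come within 2
voxels of a lacuna are thinning artifacts and are removed, isolated
single voxels included; the volume is re-thinned after each prune round
until stable. The pruning length is deliberately below any plausible
canaliculus so only artifacts are affected.

## Graph construction

Skeleton voxels are classified by 26-neighbor count: 1 → end voxel,
≥ 3 → junction voxel; 26-adjacent junction voxels merge into one branch
node at their centroid. Every identified lacuna is one node at its
centroid, attached or not. Skeleton voxels 26-adjacent to a lacuna are
absorbed into that lacuna's node; terminal and junction voxels attach
within a Chebyshev radius of 2 voxels instead, because thinning retracts
tube tips by roughly their radius and forks hugging a lacuna surface are
attachment artifacts — ordinary through-path voxels keep the strict rule
so traced edge lengths are not truncated. A voxel adjacent to two
lacunae goes to the nearer centroid, ties to the lower label id.

Edges are traced along degree-2 voxel chains between node voxels; their
geodesic length is the chamfer sum of inter-voxel steps (1, √2, √3 ×
pitch), with no spline smoothing. Pure cycles without any node voxel
promote one voxel to a branch node carrying a self-loop. Degree counts
self-loops twice; the clustering coefficient *cc* is computed on the
simple graph (parallel edges collapsed, self-loops dropped) as closed
neighbor pairs over all neighbor pairs, 0 for degree < 2.

Node classes partition the network: end (degree 1), tree (*cc* = 0),
cluster (*cc* > 0.5), and an explicit intermediate class
(0 < *cc* ≤ 0.5) so proportions always sum to one.

## Morphometry and distances

* lacuna density = N / ROI volume, reported per mm³ (the ROI is the full
  stack volume);
* total canalicular length = Σ edge geodesic lengths; mean length =
  total / number of edges; canalicular density = total length / volume
  (µm⁻²);
* **d_L**: per lacuna, the Euclidean centroid-to-centroid distance to the
  nearest other lacuna (a surface-to-surface variant is not provided —
  centroids are robust to dilation settings);
* **d_LC**: the mean, over matrix voxels (complement of the LCN mask), of
  the EDT distance to the nearest LCN voxel; zero only when the LCN
  fills the stack;
* **d_net**: per lacuna, the shortest network path to the nearest other
  lacuna. Paths are measured centroid to centroid: each edge contributes
  its skeleton length plus the straight span from any terminal node's
  position (lacuna or branch-cluster centroid) to the path's end voxel.
  Every edge weight therefore bounds the Euclidean distance between its
  node positions from above, and d_net ≥ d_L holds exactly (polygon
  inequality). An edge measured only between lacuna *surfaces* can be
  shorter than the centroid separation of two large nearby lacunae,
  which is why the plain edge-sum definition is not used. Disconnected
  lacunae report d_net as missing (not infinite) and their number is
  logged.

## Phantom generator

The generator emulates the acquisition: ellipsoidal lacunae (random
orientation; long semi-axis 3.5–5.0 µm, short semi-axes 2.8–3.6 µm,
matching murine cortical lacunae of ~7–10 µm length and ~5.5–7 µm width)
packed without overlap (center spacing above the sum of long semi-axes)
in a (100, 40, 40) µm domain — 14 lacunae ≈ 9 × 10⁴ mm⁻³, a realistic
murine density. Each lacuna is connected to its 2 nearest neighbors by a
jittered-polyline canaliculus (radius 0.6 µm, chosen so tubes survive
0.4 µm resampling; two perpendicular control-point offsets of up to 8 %
of the chord) and topped up with blind canaliculi (5–10 µm) to a
Poisson-distributed dendricity of mean 8. Note the short semi-axis floor
is also a detectability condition: the reference calibration seeds
lacunae at EDT ≥ 5 voxels = 2.0 µm, so a minor radius near 2 µm erodes
below the 25-voxel minimum and is invisible to the method by design.

The continuous scene is rasterized on an anisotropic grid
((1.0, 0.2, 0.2) µm by default, so the resampling stage genuinely
matters), blurred with an anisotropic Gaussian point-spread stand-in
((0.4, 0.2, 0.2) µm), multiplied by a smooth linear shading field
(±10 %), and degraded with additive Gaussian noise (SD 0.02) before
clipping to `[0, 1]`. Background is 0.08, foreground 1.0. Lacunae are
placed either clearly interior (≥ 2 µm face clearance) or clearly
protruding (≥ 1 µm past a face, flagged `edge_touching`), so the truth
flag is unambiguous under blur. All randomness flows from one integer
seed through `numpy.random.Generator`; a seed reproduces the stack bit
for bit.

**What the phantom does not emulate:** physically correct optics
(diffraction side lobes, depth-dependent aberration), photobleaching,
autofluorescent matrix texture, osteocyte bodies or dendrite branching
*within* a canaliculus, partially stained networks, and real lacunar
density/dendricity heterogeneity. Phantoms are also sparser than dense
cortical LCN. Passing the oracle tests therefore shows that the chain
recovers known geometry under controlled degradation — not that its
absolute accuracy on real tissue matches these figures.

**Aging degradation** removes canaliculi with probability
`1 − keep_fraction`, shortens survivors to `length_scale` of their arc
length by retracting the distal end toward the lacuna of origin (for
lacuna–lacuna canaliculi the retained end is chosen at random), and can
remove lacunae with their incident canaliculi. The retraction-from-one-
end model mirrors dendrite retraction; shrinking toward the polyline
midpoint instead would detach both ends and turn every surviving
connector into a floating fragment with two new end nodes, *raising* the
node count under aging — the opposite of the degeneration signature the
model exists to emulate.

`truth_metrics` computes densities, arc lengths and graph summaries
analytically from the generative model and is exact by construction; all
pipeline-accuracy statements are phrased against it.

## Agreement statistics

Differences are oriented manual − automated, so a pipeline that counts
edge cells a manual reader skips yields a negative Bland-Altman mean
difference. SDs use the n−1 denominator; SEM = SD/√n. The percentage
error is absolute, `|auto − manual|/manual × 100` (the signed mean is
also emitted); pairs with a zero manual count are excluded and counted.
The Wilcoxon matched-pairs statistic W is the sum of positive-difference
ranks with average ranks for ties and zero differences dropped; the
two-sided p-value is exact — full enumeration of the 2ⁿ sign patterns,
which remains valid under ties — for effective n ≤ 12, and a normal
approximation with continuity correction otherwise (the rank-based
variance Σr²/4 is tie-corrected automatically). All-zero differences
return W = 0, p = 1.

## Validation studies and problem sizes

The oracle studies (shared by the test suite and
`scripts/acceptance.py`) use full-default phantoms — raw stacks of
100 × 200 × 200 voxels resampled to 250 × 100 × 100 — for single-phantom
recovery, and (50, 30, 30) µm 5-lacuna phantoms for baseline/degraded
aging pairs, sizes at which one phantom costs a few seconds end to end.
Recovery is scored against the *detectable* truth count (lacunae whose
EDT-eroded core clears the minimum seed size; under the default geometry
that is all of them). One caveat the studies surface: because the
sigmoid cutoff is image specific, mild degradation occasionally shifts
the binarization enough to offset a small d_LC increase, so the aging
signature holds in the large majority of seeded pairs rather than
universally; density and node-count directions are far more robust.

## Degenerate inputs and tie-breaks

Empty masks yield empty labelings, skeletons and graphs (not errors);
an empty graph reports its mean degree as missing. A single lacuna has
missing d_L/d_net. Constant stacks fail at normalization with an
explicit error. The binarization comparison is inclusive (≥). Nearest-
seed contests and nearest-centroid attachment both break ties toward the
lower label id. µm→voxel conversion rounds half up everywhere.
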