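# Methods

This note documents the models and procedures implemented in
`testisquant`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions shared by all stages.

## Geometry conventions

Spatial axis order is `(z, y, x)` everywhere; the channel axis is the
leading axis of a stack and never mixed with the spatial axes. Voxel
indices are 0-based and the centre of voxel `(i, j, k)` sits at physical
position `(i·dz, j·dy, k·dx)` µm. All centroids, radii and distances are
in micrometres; committing to one convention removes half-voxel drift
between the generator, the segmentation and the classifiers. The default
sampling of the synthetic scenes is `1.0 × 0.31 × 0.31` µm `(z, y, x)`, a
typical confocal z-step and in-plane pixel size; real data must carry
its own voxel size (explicit argument > embedded TIFF metadata > error —
never a silent default).

## Synthetic scenes

`make_nuclei_scene` renders nuclei as uniform spheres (default radius
2 µm) convolved with an isotropic Gaussian (default σ = 0.5 µm) over a
constant background (default 10 AU), with Poisson shot noise applied to
the expected intensity (Gaussian read noise and noise-free rendering are
options), quantized to 16 bits. Marker channels render flagged cells at
the full base intensity (default 300 AU) and unflagged cells dimmed by
the marker contrast (default 10×), so positivity is recoverable by
thresholding but not trivially binary. Marker flags are assigned as
exact counts (`round(fraction × n)`), making flag-recovery tests exact.

Niche scenes add a spherical hub blob (default radius 8–10 µm) placed a
quarter of the way along x (the "apical tip"), with:

* `n_gsc` Vasa⁺ cells pinned to the hub contact sphere on a randomly
  rotated Fibonacci lattice. The lattice guarantees near-even spacing,
  so the placed GSCs always satisfy the mutual "singleness" rule that
  the classifier enforces; rejection sampling cannot guarantee this at
  realistic GSC counts (9 cells on a ~12 µm sphere).
* `n_cysc` Zfh-1⁺ cells at surface-to-surface gaps drawn from 1–7 µm,
  safely inside the 10 µm gate.
* bulk cells kept >12 µm from the hub surface so they can never gate as
  niche cells.

Spermatid bundles are rendered as 4×4×4 lattices (64 nuclei, 2 µm
spacing, ±0.3 µm jitter, random rotation) of small (1 µm) nuclei; the
lattice geometry keeps every nearest-neighbour pair under the 3 µm
single-linkage default, so a canonical bundle is always one cluster.

`make_coloc_pair` builds channel B as `ρ·A + √(1−ρ²)·ε` from
standard-normal voxel fields and rescales each channel affinely to the
16-bit range; Pearson r is invariant under positive affine maps, so the
sample correlation converges to ρ (calibration: mean r̂ within 0.02 of ρ
over 50 replicates at 10⁵ voxels).

`make_ic_scene` renders each individualization complex as two bead
chains (bead radius 1 µm, spacing 0.2 µm, arm length 8 µm) meeting at a
vertex with the requested angle; bead radius must span the 1 µm z-step
or oblique arms dash into fragments across slices. Ground truth stores
the three landmark points per complex.

What the generator does **not** emulate: realistic point-spread
functions (the blur is an isotropic Gaussian), cyst membranes, antibody
penetration gradients, tissue autofluorescence structure, optical
attenuation with depth, and touching/overlapping nuclei beyond what the
minimum-separation parameter allows. Passing recovery tests therefore
demonstrates correctness of the measurement chain under the stated
forward model, not performance on degraded real-world stacks.

## Segmentation

`preprocess` smooths the nuclear channel with a physical-units Gaussian
(default σ = 1.0 µm, converted per-axis through the voxel size) and
thresholds globally (Otsu by default; a constant channel raises a
degenerate-histogram error rather than producing an arbitrary mask).

`label_nuclei` computes the Euclidean distance transform with per-axis
sampling equal to the voxel size — handling anisotropy without
resampling the volume — takes distance-map maxima as watershed seeds,
and floods the negated distance map constrained to the mask. Defaults:
minimum peak separation 4 µm (≈ one nuclear diameter), minimum
component volume 30 µm³ (≈ a 1.9 µm-radius sphere; removes debris).
Two numerical details matter:

* The EDT of a symmetric object has plateau ties that survive the
  maximum filter, yielding duplicate seeds inside one nucleus; seeds are
  therefore suppressed greedily in physical coordinates (deepest first,
  minimum separation enforced exactly). Seed order also fixes watershed
  tie-breaks deterministically.
* The size filter relabels components consecutively, so `n_labels` is
  always the count and label arrays are stable across runs.

On noise-free scenes with centre separation ≥ 4 nuclear radii the count
equals ground truth exactly and agrees voxel-for-voxel with a
brute-force nearest-true-centre assignment; under Poisson noise at the
default intensities the count stays within ±5% over 20 seeds.

## Cell classification

Marker positivity is mean cell intensity above a per-channel cutoff.
Since visual scoring is not reproducible, the cutoff is explicit; a
helper derives it as background mean + 3×SD. Note the relevant scale is
the *label-averaged* intensity: a watershed label extends to the Otsu
boundary, so a cell rendered at 300 AU averages ≈ 140 AU over its label.
Demo configurations place the cutoff (120 AU) between the
dimmed-negative (~30 AU) and positive plateaus.

Hub distance is surface-to-surface: the distance transform of the hub
mask sampled at the cell centroid, minus the cell's equivalent spherical
radius (negative values mean overlap). GSC = Vasa⁺ ∧ hub distance ≤
`contact_tol_um` ∧ no other Vasa⁺ centroid within `singleness_dist_um`
(default 8 µm = twice the nominal nuclear diameter, a proxy for "not
inside a multi-cell cyst"). CySC = Zfh-1⁺ ∧ hub distance strictly
< 10 µm, exactly as the operational definition states. The library
default `contact_tol_um` is 0.5 µm ("contacting"); the demo manifest
uses 2.0 µm because both the hub and the nucleus surface radii are
estimated from thresholded masks and each carries roughly a voxel of
error — with the tight default, a truly touching cell can fail the gate
by measurement noise alone.

Bundles: single-linkage clustering of nuclear centroids at 3 µm;
clusters with ≥ 48 nuclei (¾ of the canonical 64) count as bundles, so
a few segmentation misses do not drop a bundle.

## Colocalization

Voxel-wise Pearson r over the whole volume by default (an optional mask
restricts to e.g. tissue foreground and is recorded in the result). The
sums run in double precision with an explicit two-pass mean; 16-bit
integer inputs cannot trigger catastrophic cancellation. A channel that
is constant within the mask raises an error instead of returning NaN.
Per-genotype aggregation is the arithmetic mean ± SEM of per-image r
values. Costes randomization and Manders coefficients are out of scope.

## Individualization-complex angles

`association_angle` is the vertex angle between the rays
vertex→actin-landmark and vertex→nucleus-landmark, computed from the
normalized dot product in physical coordinates (so voxel anisotropy
cannot bias it), reported in (0, 180]. `extract_ic_landmarks` automates
what is otherwise an interactive angle-tool measurement: each channel is
lightly smoothed (0.4 µm) and Otsu-thresholded; connected components
(26-connectivity, ≥30 voxels) are reduced to intensity-weighted
principal axes; each actin component is paired with the nuclear
component whose axis endpoint approaches closest; the vertex is the
midpoint of the two mutually closest endpoints. The reported angle is
computed from the fitted axis *directions* (proximal→distal), which is
robust to vertex-localization error — using the vertex point itself
would add a one-sided bias near 180° because any noise can only shrink
an angle at the upper bound. Recovery on synthetic complexes is within
±2° at 90°–180°; the residual error (~0.4° per arm) is dominated by the
coarse 1 µm z-sampling. This automated extraction is a methodological
substitute for interactive measurement and is validated only on
synthetic ground truth.

## Fertility and statistics

Fertility: 0 offspring/day → Infertile, more than 30 → Fertile,
otherwise Subfertile. The printed rule leaves exactly 30 unassigned;
this package classifies 30 as Subfertile (conservative) and exposes the
boundary. SEM is SD(ddof=1)/√n and is undefined (NaN) for n = 1.

Group comparisons default to Welch's t-test (Satterthwaite df) for two
groups and one-way ANOVA with Tukey's HSD (statsmodels) for three or
more; which test a figure used is recorded in the output. Star notation
uses strict inequalities; a p exactly on a threshold gets the weaker
annotation. When every group has zero within-group variance the test
statistic is 0/0; the wrappers then return p = 1 for identical means
and p = 0 otherwise, so degenerate-but-clear synthetic data yields
definite answers instead of NaN. Null calibration: both wrappers reject
5% ± 1.5% of null datasets at α = 0.05 over 1000 seeded simulations
(Tukey measured as family-wise error across all pairs).

## Pipeline

One stack = one biological replicate = one row in group summaries. A run
is driven by a YAML `RunConfig`; all parameters (including defaults) are
written to `run_log.json`, so a run is reproducible from its log alone.
Stage failures are logged with stack id and stage name and do not abort
the run. The demo study uses 36×160×160-voxel stacks (35×49×49 µm) with
9/2/9 ground-truth GSCs across three pseudo-genotypes and 12 males per
genotype in the fertility table — small enough to run in seconds per
stack while leaving every classifier decision non-trivial.

## Known limitations

* The watershed assumes roughly convex, sphere-like nuclei; elongated
  spermatid nuclei are counted via clustering, not shape-segmented.
* Marker thresholds are global per channel; depth-dependent attenuation
  in thick real stacks would need per-slice normalization, which is not
  implemented.
* Hub detection returns the single largest component; fragmented hub
  staining would be under-segmented.
* IC landmark extraction assumes arms are straight and resolvable as one
  component per channel; curved or touching complexes are out of scope.
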