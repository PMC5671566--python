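# Methods

`somaburst` segments neuronal somata (cell bodies) in 3-D fluorescence
microscopy stacks. Somata in such data are solid, roughly ellipsoidal, of
similar peak intensity, frequently touching, and surrounded by thin
neurites; intensity alone cannot separate a touching pair, so the method
works on the *Euclidean distance transform* (EDT) of the binarized
foreground instead. The pipeline is

1. isotropic resampling,
2. multi-scale LoG foreground enhancement + Otsu binarization + cleanup,
3. EDT + H-dome regional-maxima seed detection,
4. distance-map Rayburst surface sampling per seed,
5. direct least-squares ellipsoid fitting and label assembly.

All internal units are voxels of the isotropic working grid; axis order is
(z, y, x) throughout.

## Foreground enhancement

The background estimate is `I_bg = I − Σ_i K_σ(i) * I` and the enhanced
foreground `I_fg = I − max(I_bg, 0)`, where `K_σ = −∇²G_σ` is the
*blob-enhancing* Laplacian-of-Gaussian kernel (positive central response on
bright blobs). With this sign convention the summed responses are large
inside somata, `I_bg` approximates the smooth background there, and
subtracting its positive part cancels the background while preserving the
somata; with the opposite sign convention the same formulas suppress
exactly the structures of interest, so the blob-enhancing sign is the only
one consistent with the procedure's purpose. `I_fg ≤ I` holds everywhere by
construction.

Sigmas are chosen from the soma radius: a scale σ responds most strongly to
blobs of radius ≈ σ√3, and the interior of a soma much larger than the
largest scale is locally flat (response ≈ 0), leaving only an enhanced rim
that hole-filling must close — fragile under noise. The default set
(1, 2, 3, 4) suits radii up to ≈ 7 voxels; the phantom-field configuration
(`phantom.field_pipeline_config`) uses (2, 4, 6, 8) for its radius 6–12
somata. No scale normalization is applied across sigmas. Convolution uses
reflect boundaries to avoid dark-rim artifacts.

Binarization is Otsu's threshold on a 256-bin histogram of the enhanced
volume, applied per stack (volumetric, not per slice). Note the maximizer
of the between-class variance is a *plateau* whenever bins between the
modes are empty; any cut in the plateau induces the same partition, which
is the well-defined object. Cleanup fills enclosed cavities (6-connected
background) and removes 26-connected components below `min_region_size`
(default 200 voxels).

## Seed detection

The EDT assigns each foreground voxel its distance to the nearest
background voxel; the volume is treated as padded with background so
border-clipped somata still receive finite distances (they can be excluded
at evaluation time instead). Soma centres are regional maxima of this map.
Shallow spurious maxima ("jitter") — from rough mask surfaces and from the
saddle structure between touching somata — are suppressed with the H-dome
transform `dmap − R(dmap − h; dmap)` (greyscale reconstruction by dilation,
26-connected): a maximum survives only if its dome reaches the jitter
height `h` (default 1 voxel; useful range roughly 0–2 depending on soma
radius). Each surviving maximum plateau yields one seed at the plateau
centroid (snapped into the plateau if it is non-convex).

## Rayburst sampling on the distance map

From each seed, a near-uniform core of `n_rays` (default 258) unit
directions is cast. The core is the smallest geodesic icosahedron
tessellation (10f² + 2 vertices) with at least the requested count,
decimated to the exact count by farthest-point selection over *antipodal
vertex pairs*, which keeps the core exactly antipodally symmetric and
balanced (Σ directions ≈ 0); the nearest-neighbour angular gap ratio stays
under 2.

Along a ray the distance profile `d(t)` is sampled by trilinear
interpolation every `ray_step` (0.5) voxels. Each ray stops at the first
of:

- **background**: `d` falls to 0.5 voxel — the material boundary between
  the last foreground and first background voxel centre of a digital
  surface — with the exact radius refined by linear interpolation between
  samples. (Stopping at `d = 0` instead would systematically overshoot the
  surface by up to a voxel, because the interpolated EDT reaches zero only
  at the first background voxel centre.)
- **distance increase**: `d` rises by more than 1e−3 after having strictly
  decreased at least once — the ray has crossed the regional minimum in the
  neck between touching somata; the stop is the local-minimum sample. The
  rule is armed only after a strict decrease so rays are not killed while
  leaving the seed's maximum plateau.
- **max range** (default 60 voxels).

A ray also records an *inner* boundary: the first point where a monotone
decrease ends in a flat step (|Δd| ≤ 1e−3) — the transition out of the
soma's private distance basin into the shared region of a touching pair.
Where no such transition exists the inner boundary coincides with the
outer one. After casting, rays whose outer radius exceeds
`alpha_clip × median(inner radii)` (default α = 2) are clipped back to
that bound: runaway rays that escaped through a thin bridge or along a
neurite are fixed by the ensemble's order statistics, and the clip is a
no-op on isolated somata where inner ≈ outer.

## Ellipsoid fitting

The outer-boundary point cloud is fitted with a quadric
`ax² + by² + cz² + dxy + exz + fyz + px + qy + rz + k = 0` by direct
constrained least squares. Points are shifted/scaled per axis into [0, 1]
(scale = per-axis range; degenerate axes keep scale 1). With design matrix
`D` (rows `x² y² z² xy xz yz x y z 1`) and scatter matrix `S = DᵀD`
partitioned into S₁ (6×6), S₂ (6×4), S₃ (4×4), the quadratic part solves
`M a₁ = λ a₁` with `M = C₁⁻¹(S₁ − S₂S₃⁻¹S₂ᵀ)`, where C₁ encodes the
invariant condition `4J − I² = 1` (I = tr Q, J = Σ principal 2×2 minors of
the quadratic form Q) — a sufficient condition for the quadric to be an
ellipsoid. The linear part follows as `a₂ = −S₃⁻¹S₂ᵀa₁` (the transpose is
forced by the block shapes).

Classically `a₁` is the eigenvector of the unique positive eigenvalue.
Two degeneracies require a refinement:

- on (near-)exact data the relevant eigenvalue collapses to ~0, since
  `λ · a₁ᵀC₁a₁ = ‖Da‖²` and the residual vanishes;
- genuinely elongated ellipsoids (axis ratio > 2) have `4J − I² < 0` —
  e.g. diag(1, 1, 10) gives −60 — and therefore live outside the set the
  constraint can represent, although they are perfectly real ellipsoids.

The implemented selection is: among eigenvectors whose completed
coefficient vector describes a real ellipsoid (definite quadratic form,
opposite-sign centred constant), take the smallest algebraic residual
`‖Da‖`. This coincides with the positive-eigenvalue rule whenever that rule
applies and recovers exact data to machine precision at any axis ratio.
Coefficients are normalized to constraint value +1 when the invariant is
positive, otherwise to quadric value −1 at the centre; both conventions fix
the interior-negative sign. The same centre-value normalization is used
after mapping the coefficients back to the original frame (the invariant is
not preserved under anisotropic scaling, but the zero set is).

Centre, semi-axes and orientation come from the gradient-zero linear system
and the eigendecomposition of the quadratic form; the surface area uses
Thomsen's approximation (p = 1.6075, max error ≈ 1.06%) since no closed
form exists. Segmentation voxels are the voxel centres with negative
quadric value, clipped to the stack.

## Pipeline assembly

Candidates are processed in descending peak-distance order. A candidate
whose position already lies inside a generated segment is skipped. After
fitting, a segment is dropped if

- its largest semi-axis exceeds `max_axis_factor` (1.5) times the largest
  sampled outer radius — an ellipsoid is only trusted where its surface was
  actually sampled; fits of cylinder-like clouds (neurite tubes) otherwise
  extrapolate far beyond their data and masquerade as somata; or
- its voxelized volume is below `volume_threshold` — set from the smallest
  expected soma volume for the dataset at hand (default 4200 voxels for
  somata of radius ≥ ~10; 400 for the phantom-field scale).

Voxels claimed by several ellipsoids go to the segment in whose interior
they lie deepest (most negative quadric value normalized by the value at
the centre). The pipeline has no stochastic component: identical input and
configuration reproduce the label volume bit for bit.

## Evaluation

Localization: greedy one-to-one centroid matching in ascending distance
order; a pair matches iff distance < Rc (strict), with Rc the mean soma
radius. Recall = matched/truth and precision = matched/predicted in the
standard convention; the report also carries the swapped labelling, which
some of the literature prints, under `*_as_printed`. Segmentation overlap
is `|Seg ∩ GT| / ((|Seg| + |GT|)/2)` — algebraically the Dice coefficient.
Volume and area ratios compare the fitted ellipsoid's analytic volume/area
against the truth voxel count and a marching-cubes surface area of the
truth set. Truth somata touching the stack border can be excluded
(`exclude_border_truth`) to mirror the usual broken-soma exclusion.

## Synthetic phantoms

The generator emulates soma-scale fluorescence content: solid ellipsoids at
peak intensity ~200 over background 20, with a 1-voxel linear soft edge
(so binarization is realistic rather than trivially exact); declared
touching pairs with centre separation a fraction (0.75–0.8) of the summed
radii, producing genuine necks; thin tubes (radius 2) as neurite-like
distractors that create false seed candidates; additive Gaussian noise;
optional 4× axial anisotropy. Truth labels assign contested pair voxels to
the soma with the smaller axes-normalized radius. It does **not** model a
PSF, photon noise, intensity inhomogeneity within a soma, or non-ellipsoidal
cell shapes — passing tests demonstrate correct mechanics of the method
under its own geometric assumptions, not performance on real tissue.

The fixed suite: S1 single ball r = 8; S2 rotated ellipsoid (10, 8, 7);
S3 touching equal pair r = 8 at 0.75 separation; S4 unequal pair (10, 6) at
0.8; S5 a 20-soma field (seed 42) with three touching pairs, fourteen
singles with the largest semi-axis U(6, 12) and mild eccentricity
(0.8–1.0×), two tubes, noise σ = 20 (10% of soma intensity); S6 the same
field sampled at (4, 1, 1) relative voxel size, mirroring a 0.5 × 0.5 ×
2.0 μm acquisition. Problem sizes (96×168×168 field, 258 rays, 50 EDT
oracle masks ≤ 20³, 100 ellipsoid fits) keep a full verification run at
about ten seconds on one CPU while leaving every mechanism — touching
separation, jitter suppression, tube rejection, anisotropy — exercised.

## Known limitations

- Non-ellipsoidal (bent, lobed) somata are approximated by their best
  ellipsoid; strongly elongated somata can yield multiple seeds.
- Somata touching with a very large contact area may merge into a single
  distance maximum and be segmented as one.
- The inner-boundary fix is an order-statistic heuristic (α·median); a
  seed sitting on a thick neurite junction can still produce a plausible
  small ellipsoid that only the volume threshold can reject.
- Voxel sizes are taken from configuration, never parsed from TIFF tags.
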