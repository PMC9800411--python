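# Methods

## Measurement model

The measurand is the anatomical form change of a skeletal specimen after
water embedding, expressed as the mean absolute distance (MAD) between the
dry and hydrated surface models of the same specimen after best-fit rigid
superimposition.  The dry model is always the fixed reference; the hydrated
model is transformed onto it.  For a measurement area *R* (a contiguous
patch of triangles on the reference mesh),

MAD(R) = mean over reference vertices v ∈ R of |d(v)|,

where d(v) is the signed Euclidean distance from v to the superimposed test
surface: |d| is the exact point-to-surface distance, and the sign is that of
(closest point − v)·n̂(v) with n̂ the outward vertex normal — positive where
the hydrated surface lies outside the dry one (red in the distance maps),
negative inside (blue).  Vertices whose closest point lies further than
`d_max` or on a boundary edge of the other model have no corresponding
surface and are excluded (grey in the maps).  `d_max` defaults to 5 mm: far
above any plausible hydration deviation (reported maxima are ~2 mm) yet
small enough to reject non-homologous surface.

Sampling at reference-mesh vertices (rather than face centroids or dense
resampling) is a deliberate choice: at scan-resolution meshes (0.3 mm) any
protocol-sized patch contains thousands of vertices, so vertex sampling
oversamples the patch adequately.  A symmetrised (both-ways) variant is not
the default but the one-way field can be computed in either direction.

## Registration

Superimposition is landmark initialisation (closed-form Kabsch fit on ≥3
non-collinear homologous points; optional Umeyama scaling for diagnostics)
followed by iterative closest point.  Defaults mirror the measurement
protocol: 100% point sampling of the source vertices, 100% estimated
overlap (trimming disabled, though retain-best-fraction trimming exists for
generality), point-to-plane metric, 50 iterations.

Two interpretation choices deserve note:

- *Exact nearest neighbour search* is implemented as the exact closest
  point on the target **surface** (point-to-triangle), not the nearest
  vertex: vertex snapping biases distances upward by a fraction of the edge
  length.  Queries prune candidate triangles with a k-d tree over triangle
  centroids — the distance to the nearest soup vertex is an upper bound on
  the surface distance, so every triangle that can host the true closest
  point lies within (bound + max circumradius) of the query — and evaluate
  exact point-triangle distances on the survivors.  Ties resolve to the
  lowest face index.  Zero-area triangles are excluded from correspondence.
- *Point-to-plane* residuals use the target's area-weighted vertex normals
  interpolated barycentrically at the closest point; the rigid increment
  solves the small-angle linearisation by 6×6 least squares and is
  re-orthonormalised through the rotation exponential map.

Early stopping (rms improvement < 1e-6 mm) is an optimisation only; with
the fixed iteration budget it changes results by less than the tolerance.
Point-to-point rms is non-increasing exactly; point-to-plane may fluctuate
within the linearisation tolerance and is asserted never to worsen by more
than 1e-6 mm per iteration.  Superimposition can be restricted to a
reference area on either mesh (sampling restriction on the source,
correspondence restriction on the target).  A registration whose final rms
exceeds its initial rms is treated as diverged; in batch runs the pair is
excluded with a log record rather than aborting the study.

## Regions

Measurement areas follow the protocol's "circular area of a fixed triangle
count": from the face nearest a seed point, faces are admitted in ascending
Euclidean centroid-to-seed distance among faces edge-adjacent to the current
patch, until exactly *n* triangles are selected.  This matches a ball-pick
in a mesh editor; geodesic growth would differ only on strongly curved
patches.  Ties in distance break on centroid coordinates lexicographically
and then on face index, which makes growth deterministic *and* invariant to
face reordering.  The protocol count of 10,000 triangles is tied to 0.3 mm
meshes; on coarser meshes the pipeline keeps the patch *area* equivalent
(10,000 × the 0.3 mm triangle area ≈ 390 mm²) via `region_triangle_count`.

Hand-painted reference areas are ingested as face-id masks (largest
connected component kept, discards counted).  Regions transfer across a
superimposed pair by selecting faces whose centroids project onto the
region (closest point on the source surface falls on a region face) within
a cutoff; the nearby-patch alternative was rejected because it inflates the
set by a one-ring of neighbours even for identical meshes.

## Statistics

The analysis layer reproduces the study design: descriptives as median/IQR
(linear-interpolation quartiles)/range; Kruskal–Wallis (tie-corrected H,
χ² approximation, k−1 df) across measurement areas for the unpaired
dry-vs-wet contrasts, followed when significant by Dunn's pairwise z tests
with the published tie-corrected pooled-variance formula and Bonferroni
adjustment over all pairs (this may differ slightly from SPSS's variant on
ties-heavy data); Friedman's test (within-specimen ranks, tie-corrected,
χ², k−1 df) for the paired embedding-time contrast; Spearman rank
correlation (t approximation) for volume–effect association, computed only
over specimens whose dry model is watertight since enclosed volume requires
a closed surface.  All tests are two-sided at α = 0.05.  Degenerate inputs
are defined, not errors: all-identical data gives statistic 0 and p = 1.
Box-plot summaries follow the figure convention of flagging points further
from the *median* than 1.5×IQR (3×IQR for extremes).  Normality testing is
not implemented; the pipeline is nonparametric by design.

## Synthetic specimens

Real specimens are not publicly deposited, so the generator emulates the
study's geometric and statistical structure rather than any individual
anatomy:

- **Skull** — a closed, watertight shell from a subdivided icosahedron
  scaled to semi-axes 85×70×60 mm, with two lateral zygoma-analogue bumps
  and a flattened forehead plateau realised as smooth radial features.
  True arch handles attached only at their ends would change the genus and
  break the closed-form ground truth; the bump realisation keeps the shell
  watertight while preserving what matters downstream: identifiable zygoma
  regions with a doubled hydration effect.
- **Mandible** — an open C-shaped swept surface (horizontal circular arc,
  chin anterior), elliptical cross-section growing into two tall ramus
  plates at the ends; condylar cuts open by default, cappable for volume
  work.  Arch width 110 mm between labelled ramus tips.

Hydration is an analytic displacement field: skull mode is an outward
normal offset (`enlargement`, default 0.2 mm) doubled under Gaussian blends
at the zygoma analogues; mandible mode adds a bilateral lateral expansion
of the rami (default 1.0 mm, smoothstep-weighted along the arch and
saturated under the ramus measurement areas) and an arch "flattening" that
rotates the arms about a vertical hinge at the chin (default factor 0.016,
i.e. ~1.8 mm at the ramus tips).  Every field is projected orthogonal to
the six linearised rigid-body modes in the surface-normal metric — the
component a point-to-plane best fit would remove — so the ground-truth
expected MAD of a region, mean |d·n̂| over its vertices, is well defined
independently of the superimposition.  A by-product matching the physical
observations: after projection the chin shifts inward, so the lingual chin
area carries a large deviation while the buccal chin (where enlargement and
shift oppose) carries the smallest — the ordering BC < LR/LL < LC < BR/BL.

Default magnitudes are calibrated so synthetic studies land in the reported
ranges (pooled regional medians ≈ 0.2 mm for skulls, ≈ 0.54 mm for
mandibles, ≈ 0.05 mm for the 5- vs 15-minute embedding contrast, maxima
just under 2 mm); this is emulation of the study conditions, not
reproduction of its data.  Per-specimen variability enters as a log-normal
scale on the deformation magnitudes (SD 0.35, chosen to give IQR-to-median
ratios comparable to those reported) and a 2% Gaussian jitter of the base
shape.  Scanner noise is zero-mean Gaussian along the vertex normals
(default SD 0.035 mm, between the reported dry/wet precisions of
0.031/0.040 mm); in-plane jitter is excluded since structured-light scan
noise is predominantly radial.  Misalignment draws a uniform rotation axis,
uniform angle and uniform translation within bounds (defaults 5°, 5 mm)
about the centroid.  All randomness flows from a single integer seed
through `numpy.random.default_rng` (PCG64), giving bitwise reproducibility
for a fixed seed.

The generator does **not** emulate: real cranial topology (foramina, inner
tables, sutures), spatially correlated scanner error, stitching artefacts,
or the physics of water absorption.  Passing tests therefore demonstrate
that the pipeline measures known deformations correctly under realistic
noise and misalignment — not that real bone deforms as modelled.

## Numerical choices and problem sizes

- Millimetres and 0-based indexing everywhere; STL read welds coincident
  vertices at 1e-9 mm (far below the 0.3 mm feature scale); distance maps
  clamp at ±1 mm (skull) / ±2 mm (mandible) by default, matching the
  reported deviation ranges; the scale is overridable since colour-scale
  bounds are a presentation choice, not part of the measurement.
- The first-order expectation mean |d·n̂| agrees with the exact
  point-to-surface distance to second order in |d|/r (surface curvature
  radius r); at the default mandible magnitudes (1 mm displacements on
  6 mm cross-section rims) this amounts to ~2–3% on the ramus areas, which
  is why tests check registration neutrality (pipeline vs direct
  measurement of the clean pair, 2%) separately from ground-truth accuracy
  (0.05 mm absolute under noise).
- Tests and the acceptance script generate meshes at 1.5–2.0 mm target edge
  length with the protocol-area-equivalent region sizes, and synthetic
  studies of 16 specimens per arm; the generator's default edge length
  remains 0.3 mm.  Deformation, noise and misalignment magnitudes are never
  reduced in tests.
- Icosphere subdivision depth is chosen as the nearest power-of-4 level to
  the requested edge length, so realised mean edges track the target within
  roughly a factor of 1.4.

## Known limitations

- "Estimated overlap" is read as retain-best-fraction trimming; commercial
  superimposition tools do not document the internal meaning of that
  setting, so other readings (e.g. robust kernels) are possible.
- Dunn's SE convention may differ from SPSS in ties-heavy data.
- Regional MAD expectations are first-order in the displacement field (see
  above); exact expectations would require surface-offset integrals.
- Skull synthetic studies show less between-area dispersion than real
  skulls (the real deformation field is rougher than a two-bump model), so
  pooled IQRs run below the reported ones while medians match.
- The mandible volume–MAD correlation is only available when models are
  generated watertight (capped condylar cuts).
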