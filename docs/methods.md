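# Methods

`tissuedyn` quantifies how the deformation of a 2D epithelial tissue
emerges from the behaviour of its cells, starting from tracked
label-image movies.  This note documents the models, conventions and
numerical choices the package is built on.

## Data model

A frame of a tracked movie is a planar cell complex: cells bounded by
bonds (cell–cell interfaces) meeting at vertices.  Topology is stored as
**directed bonds** — each interface is owned twice, once per adjacent
cell, ordered counter-clockwise along the owning cell's contour.  Each
directed bond links to its *conjugate* (the same interface from the
neighbouring cell) and its *left* bond (its counter-clockwise follower
in the same cell).  A single virtual **background cell** (id 0) owns the
outward conjugate of every margin bond, making the conjugate map a total
involution and margin cells detectable as neighbours of cell 0.

"Counter-clockwise" is defined numerically as positive shoelace area in
the `(x, y)` coordinates of the input, whether those are y-up vector
coordinates or y-down image coordinates.  All angle conventions
(nematic axes, vorticity, division orientation) follow the same numeric
frame, so the toolkit is self-consistent in either convention; only the
on-screen appearance of "counter-clockwise" flips.

Each movie is persisted as one SQLite file with tables `frames`,
`cells`, `vertices`, `bonds`, `directed_bonds` and `cell_histories`.
The schema is extensible: appended columns do not affect relationships,
and the loader only reads the columns it knows.

## Mask parsing

Input movies assign every cell a persistent positive integer id, with
1-px-wide zero-valued boundaries.  The parser (i) assigns boundary
pixels to the smallest adjacent label to obtain a complete tiling,
(ii) detects junctions on the pixel-corner grid (a 2×2 corner where ≥3
labels meet, the exterior counting as the background cell; adjacent
junction corners cluster into one vertex, so 4-label corners give a
single 4-fold vertex), and (iii) crack-traces every cell's contour,
reading off the junction corners in order.  Cell centers are mean member
pixel coordinates; areas are member pixel counts plus the cell's share
of adjacent boundary pixels (1/k per boundary pixel touching k labels
— the convention is a choice; interface pixels split half/half);
elongation integrals are exact pixel sums.  The round trip through the
bundled rasterizer recovers cell counts and the neighbour graph exactly
and areas within ~1% at 30 px/edge.

Appearance/disappearance reasons are inferred per id: a vanished cell
whose footprint (dilated by 1 px) captures the majority (>50%) of the
pixels of exactly two newly appearing ids is a division — 50% is the
unique threshold guaranteeing at most one mother per daughter; more
than two majority candidates is flagged ambiguous and excluded from the
lineage.  A cell whose last footprint touches the image border or the
exterior moved out of view (this deliberately includes margin cells, so
extrusions are only called in the interior); the remainder are
extrusions.  An explicit division table from the tracker overrides
inference.

## Cell-state quantification

Cell center and area are the area integrals `r_c = (1/A)∫r dA`,
`A = ∫dA`.  The elongation nematic is

    eps_xx = (1/A) ∫ cos(2 phi) dA,    eps_xy = (1/A) ∫ sin(2 phi) dA,

with `phi` the angle of `r − r_c` against the x axis.  Pixel regions
use exact pixel sums.  Polygon regions use the polar form of the area
element around the center, `dA = (x dy − y dx)/2`, which reduces each
component to a 1-D adaptive quadrature along every edge (relative
tolerance 1e-9); this keeps both input styles consistent and makes
regular polygons exactly isotropic.  Elongation is translation
invariant and rotation equivariant by construction.

Coarse-graining sums or averages positioned nematics on a square grid
(default 33 µm boxes, anchored at the image origin, partial border
boxes kept) with an optional centred moving-average time window
(default 50 min).  Unit nematics of discrete events are *summed* (so
opposite events cancel); cell elongation is *averaged*.

## Events

Half-T1s are neighbour-set differences between consecutive frames,
computed after (i) masking divisions by fusing the two daughters under
the mother id and (ii) discarding pairs in which either id is absent in
one frame (extrusions, cells crossing the field-of-view border).
"Neighbour" means sharing at least one bond — vertex-only contact does
not count, so extrusion rosettes do not generate spurious gains, and
four-fold vertex resolutions register as simultaneous loss + gain.

Orientations are unit nematics: a division along the daughter-center
axis `(cos 2phi, sin 2phi)`; a contact loss along the separating-center
axis; a contact gain as the *negative* of its axis nematic
(equivalently, perpendicular), so a contact lost and regained along the
same axis cancels exactly.  Losses are evaluated with the centers of
the first frame (where the contact exists), gains with the second.

Rates are events per cell per hour in fixed bins (default 1 h), with
the per-bin mean ROI cell count as denominator.  The cell-cycle
statistic is the median mother-birth-to-division interval within
lineages, reported with the median absolute deviation.

## ROIs and the margin filter

An ROI is anchored by a simple polygon on one frame (cells whose center
lies strictly inside; on-edge centers are excluded) and browsed through
the lineage forest: forward, daughters inherit membership; backward, a
mother is a member if any descendant alive at the anchor frame is.
Cells without a lineage path to the anchor (e.g. extruded earlier) are
recovered by a connected-component rule: non-member cells joined by
bonds form components, and every component except the largest — the
surrounding tissue — is merged into the ROI (ties prefer the component
touching the background, then the lowest minimum id).  The operation is
idempotent.

`whole_tissue` removes, in every frame, the cells adjacent to the
background and one further row sharing a bond with them (bond-sharing,
not vertex contact, is the deterministic choice), then keeps only cells
whose entire lineage survives the removal in every frame of its
existence and never crosses the field-of-view border.  User ROIs are
intersected with this population.

## Triangle method

The junctional network is tiled with triangles on cell centers: one per
interior three-fold vertex; a k-fold vertex fans into k−2 triangles
over its cyclically ordered cells starting at the lowest id; vertices
touching the background produce none.  Collinear-center triangles are
kept with zero area and excluded from averages.

A triangle's shape is the linear map `S` from an area-matched reference
equilateral.  We use the **left** polar form
`S = exp(Q + ln(s) I) · R(theta)`, so the elongation nematic `Q` lives
in the laboratory frame: rotating the triangle rotates `Q` by the same
angle, and the reference orientation only shifts `theta`.  The
per-triangle deformation between frames is `M = D₁ D₀⁻¹` on the edge
matrices; `ln det M` is its isotropic part, the symmetric-traceless part
of `ln √(M Mᵀ)` its pure shear, and the polar rotation its vorticity.
Tissue-level `V_iso`, `V~` and `Omega` are the area-weighted averages
over matched triangles (weights: first-frame areas).  These logarithmic
finite-deformation measures make uniform imposed maps recover their
generator exactly at any step size, which is why halving the step and
doubling the frame count leaves cumulative totals unchanged.

The vorticity sign is fixed by requiring that a rigidly co-rotating
elongation is stationary under the corotational derivative

    DQ/Dt = dQ/dt − 2 (c Omega + [1 − c] dPhi/dt) e·Q,
    c = tanh(2Q)/(2Q),

evaluated with finite differences: `dQ/dt` is the change of the
area-weighted mean elongation over *all* triangles, `Phi` its axis
angle (wrapped to (−π/2, π/2]; treated as constant while the mean
elongation is numerically zero, where the axis is undefined), and `e·Q`
uses the midpoint elongation.  Co-rotation then cancels to third order
in the step.

Cellular contributions are measured by swapping the affected triangles
in and out at frozen cell positions:

* **E** (extrusions): change of the mean elongation when the vanishing
  cells' triangles are removed at first-frame positions, negated.
* **T** (T1s): likewise for the redrawn triangles of each neighbour
  exchange, the new triangles evaluated at first-frame centers.
* **C** (divisions): at the second frame, the mean elongation with the
  daughters fused at their combined (area-weighted) center versus
  unfused, negated.  Triangles that collapse under fusion are the
  division-born triangles.
* **D** (correlations): defined as the exact closure
  `D = V~ − (DQ/Dt + T + C + E)`.  The finite-deformation closed forms
  of the correlation term are not reproduced here; the identity — which
  is the testable contract — holds to machine precision by
  construction, and on event-free uniform movies `D` vanishes
  identically rather than merely closing.

Triangles touched by several events are classified with precedence
extrusion > division > T1; unexplained redrawn triangles (e.g. cells
leaving the analysis region) are counted as "other" and absorbed by
`D`.  The scalar identity uses logarithmic rates:
`ln(A₁/A₀) = ln(ā₁/ā₀) + ln((N+d)/N) + ln(N₁/(N+d))` — mean-cell-area
change plus division gain minus extrusion loss, exact by construction
(`≈ ±d/N` for small counts).

## Synthetic movies

The generator is first-class, tested code and defines the validation
conditions: regular hexagonal sheets deformed kinematically by
per-frame 2×2 gradients.  The isotropic preset applies
`exp(g/2)·I` per frame with `g = 3.50e-2` (relative area growth per
frame) on a 14×14 sheet, whose margin-filtered interior holds exactly
100 cells; the pure-shear preset applies `diag(e^s, e^-s)` with
`s = 1.75e-2` on an 11×11 sheet (49 interior cells).  The sheet sizes
are chosen to match the ~100/~50-cell interiors of the original
validation movies; "rate per frame" is interpreted exponentially, which
makes the measured `V_iso` and `V~_xx` equal the imposed numbers and is
consistent with `g = 2s`.

Scripted events edit the vertex cycles directly: a T1 collapses the
target bond and re-expands it perpendicular at 0.3 edge lengths; a
division cuts the mother through its center perpendicular to the
scripted daughter-separation axis; an extrusion collapses the cell to a
rosette vertex.  Optional Gaussian vertex jitter (σ = 0.03 edge
lengths, matching ~0.5 px contour noise at ~15 px edges) emulates
pixelation noise; it biases per-frame rates but cancels under
cumulation.  The rasterizer fills cell polygons and carves 1-px
boundaries wherever the label changes, producing exactly the parser's
input format, so the whole pipeline closes offline.

What the synthetic movies do **not** emulate: mechanical relaxation
(deformations are kinematic, not force-balanced), curved or 3D tissue,
segmentation errors, uneven illumination, or densely interleaved events.
Passing the validation suite therefore demonstrates the correctness of
the bookkeeping and the measurement operators, not robustness to
tracking noise in real microscopy data.

## Problem sizes and defaults

The bundled analyses use sheets of 25–200 cells over 3–25 frames —
small enough that the full suite runs in well under a minute of compute
per movie while every population (interior cells, triangles, events) is
large enough to be statistically meaningful.  Key defaults: grid box
33 µm, time window 50 min, rate bin 1 h, majority-overlap threshold
50%, T1 re-expansion gap 0.3 edge lengths, jitter σ 0.03 edge lengths,
fixed seed 0 for randomized fixtures.

## Known limitations

* The parser assumes 4-connected cell regions and 1-px boundaries; it
  flags but does not repair malformed segmentations.
* Margin cells that extrude are classified as moving out of view.
* Two cells sharing two distinct interfaces between the same vertex
  pair are matched heuristically; pinched (repeated-cell) vertices are
  skipped in the triangulation.
* The event terms T, C, E depend mildly on the frozen-geometry
  bookkeeping chosen here; alternative finite-deformation conventions
  shift weight between them and `D` but never break the identity.
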