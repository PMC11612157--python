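# Methods

This package is a complete in-silico reconstruction of a DMD-projector
microscopy workflow for patterned optogenetic control of engineered cell
cultures, together with the virtual culture used to exercise it.  This note
documents the models, the parameters that matter, what the synthetic test bed
does and does not emulate, and the design choices made where the design was
genuinely open.

## Projection geometry

The DMD is modeled as a 1080×1920 array of micromirrors whose PWM duty
cycles (fractions in [0, 1]) set the time-averaged projected intensity.
Duty → irradiance is taken as exactly linear with a single scalar calibration
`max_irradiance` (μW/cm² at duty 1): PWM is time-division, so average power
is linear in duty by construction.  No gamma, no per-pixel flat-field; an
optional Gaussian blur (σ in camera px, default 0) can model illumination
bleed-through between neighbouring regions but is off by default.

The optical train maps DMD pixels to camera pixels.  We model this as an
8-degree-of-freedom planar homography rather than an affinity: projective
subsumes affine, costs nothing extra to estimate from ≥ 4 fiducials, and
covers keystone-type distortions of a tilted projection path.  Estimation is
the normalized direct linear transform (points centred and scaled to RMS
distance √2, then a total-least-squares fit), as implemented by
`skimage.transform.ProjectiveTransform`; no RANSAC, since calibration
fiducials are clean by construction — the estimator accepts a pre-filtered
correspondence set.  Calibration projects a grid of full-on disks (one
corner disk enlarged ×1.5 to break the 180° symmetry of a regular grid),
Otsu-thresholds the camera frame, orders the intensity-weighted centroids
row-major, and fits.  Grid-row clustering assumes the residual rotation is
small relative to the grid pitch (a few degrees), which holds for a roughly
aligned instrument.

Pattern pre-correction inverse-warps the camera-space target into DMD space
with bilinear interpolation (for each DMD pixel, sample the target at its
forward-projected camera position), clipping duties to [0, 1] and zeroing
regions that fall outside the target.  Because the DMD samples the camera
plane more finely than the camera in the default geometry, the
correct-then-project round trip is sharp: binary shapes return with IoU ≥
0.98 (in practice 1.0) and mean absolute duty error ≪ 0.02.

## Extremal-region segmentation

Candidate cell regions are the nodes of a max-tree (component tree) of the
image quantized to 256 gray levels with 4-connectivity; for dark-on-bright
material the image is inverted first.  Nodes outside an area gate
(default 20–10 000 px) remain in the tree for nesting but are ineligible as
cells.  Internally the tree stores an Euler-tour pixel ordering so any
node's pixel set is a contiguous slice — feature extraction and rendering
are O(region area).

Each eligible node is described by 9 features: area, perimeter, compactness
4πA/P², bounding-box fill ratio, major/minor axis ratio from second moments,
mean interior intensity, interior intensity variance, boundary contrast
(|interior mean − immediate-exterior ring mean|), and the node's normalized
gray level.  The upstream tool this reconstructs does not publish its exact
feature list; this set is a shape+texture mix computable from tree statistics
and sufficient to separate cells from noise and from loose/tight nested
variants on the synthetic fixtures.

Scoring is a linear SVM on standardized features with the hinge objective
averaged per sample (C scaled by 1/n), which makes the decision boundary
invariant to duplicating the training set; decision values are calibrated to
[0, 1] likelihoods by a logistic (Platt) fit.  Training examples are
harvested from labeled fixtures: positives are nodes with IoU ≥ 0.7 against
a ground-truth cell; negatives IoU ≤ 0.5.  The negative band deliberately
includes loose-fitting ancestors of true cells — with negatives restricted
to IoU ≤ 0.2 the classifier has no gradient across the nesting chain and the
selection stage systematically prefers the larger, looser region of each
chain (object-level precision at IoU 0.7 drops from 1.0 to ~0.73 on the
30-disk fixture).  Both gates are parameters.

The final mask is the optimal antichain of the tree: maximize the sum of
(likelihood − threshold) over selected nodes subject to no node being an
ancestor of another, solved exactly by the bottom-up recursion
value(node) = max(own score, Σ value(children)).  Exactness is verified
against exhaustive antichain enumeration on random trees.  Raising the
threshold can only shrink the selected set (monotonicity), and selected
regions are pixel-disjoint by construction.

## Tracking

Identities across frames are propagated by Hungarian assignment on centroid
distances, gated at a maximum physical displacement (default 20 μm), with
unmatched detections opening new tracks and unmatched tracks surviving
`lost_patience` frames before closing.  Ties break deterministically by
lowest (track id, label).  Divisions start a new track for the daughter;
lineage reconstruction and gap-closing optimization are out of scope.  The
source method being reconstructed is not publicly specified beyond
"tracking"; nearest-centroid bipartite matching is the stated choice and is
validated on simulations with known identities (100% identity accuracy when
motility is low relative to cell spacing and division/death are off).

## The virtual culture

Each agent carries a photoswitch activity A ∈ [0, 1] obeying
dA/dt = k_on·I·(1−A) − k_off·A with local irradiance I.  The update uses the
exact exponential solution over each time step and the exact time integral
of A feeds the dose, so the seconds-scale switch kinetics are handled
without stiffness at the 5-minute default step (steps are capped at
10 min).  Defaults: k_off = ln 2 / 17 s⁻¹ (dark-reversion half-life 17 s,
the one directly anchored kinetic constant) and k_on = 10⁻³
(μW/cm²)⁻¹s⁻¹, which puts the activation half-saturation near 41 μW/cm² so
that working irradiances (175–260 μW/cm²) sit at A_ss ≈ 0.8–0.86.

Death is dose accumulation with a hard tolerance: dD/dt = dose_scale · A
only while I > θ_I (default 35 μW/cm²; below it exposure is exactly
harmless, making the dark and low-intensity controls absolute rather than
statistical).  Each cell draws a lognormal death threshold (median 1,
σ = 0.1).  When D crosses the threshold the cell commits to apoptosis
(crossing time interpolated within the step), becomes SYTOX-positive after a
0.5 h lag, loses GFP with a 3 h half-life from commitment, and is scored
dead 2 h after SYTOX onset.  `dose_scale` = 0.286 h⁻¹ is the one calibrated
constant: with ~50 cells in the top decile of a gradient at 175 μW/cm², the
expected minimum threshold is ≈ 0.80 of the median (minimum of ~50 lognormal
draws), activity is ≈ 0.80, and onset = 0.80/(0.286·0.80) + 0.5 ≈ 4 h —
the earliest-onset anchor.  These constants were set from this closed-form
argument, not fitted to simulation output; all of them live in one config
block and none besides the 17 s half-life should be read as an empirical
value.

Viable cells do Brownian motion (default D = 0.5 μm²/min, reflective field
boundaries) and divide at Poisson rate ln 2 / 14 h when fewer than 5
neighbours lie within 15 μm (contact inhibition); committed cells stop
moving.  Light-insensitive co-culture cells skip the photoswitch and death
model entirely.  An antibiotic-shielding flag zeroes the death hazard.

Rendering draws each agent as a Gaussian blob scaled by its reporter level
(GFP for viable circuit-bearing cells, SYTOX from onset, a constitutive
far-red nuclear marker for insensitive cells), brightfield as an inverted
density map, with Poisson shot noise plus Gaussian read noise on a constant
offset, to 16-bit range.  All randomness flows from the seed given at
initialization; identical config + seed reproduces frame stacks bit-for-bit.

What the generator does **not** emulate: cell morphology (blobs, not
segmentable shapes with texture), directed migration and crowding mechanics,
the intracellular caspase cascade (death is a two-parameter dose model),
reporter maturation kinetics, focus drift, illumination non-uniformity, and
3D geometry.  Passing tests therefore demonstrate the correctness and
robustness of the computational stack under controlled conditions, not
performance on real microscopy data.

## The closed-loop game

Nine independent cultures are the stage positions.  Each position is imaged
as a 192-px view of the full ~2.2 mm low-magnification field
(11.55 μm/px): pattern features must stay large relative to cell migration,
as they are on the bench, so the scaled-down camera keeps the physical pixel
size of a heavily binned sensor rather than shrinking the field itself.
Positions are seeded at graded densities (480 down to 250 cells) so the
dynamic mapping has a confluence ladder to exploit: each move is bound to
the unassigned position with the highest current confluence (GFP coverage
after thresholding and morphological closing), ties to the lowest id.

Symbols are an annulus (outer radius 35% of the FOV, stroke 15%) and a
cross (arm half-length 35%, stroke 15%), drawn in camera space, pre-corrected
through the homography estimated by the in-loop calibration routine, and
projected at 260 μW/cm² for 5 h per turn.  Move detection works on the
positive difference of consecutive SYTOX acquisitions: the point-like
stained nuclei are smoothed (σ 4 px) into a dead-cell density map,
Otsu-thresholded, closed, and all components of meaningful size kept (a
sparsely stained stroke fragments into arcs).  Classification is by
normalized template correlation against ideal ring and cross masks centred
at the known projection centre, with the Euler number (ring ⇒ one hole) as
a ±0.1 bias rather than a decisive rule — a gap in the ring or an
accidental hole in a lumpy cross would otherwise flip the call.  A
detection-free guard (density maximum below 20 robust σ of the smoothed
difference) returns "none" on unilluminated positions.  Because cells that
commit late in a turn convert to SYTOX during the next one, players scan
only positions not yet attributed on their private board.

Players reconstruct the opponent's play exclusively from these detections —
the handler never shares its board.  A detection mismatch is logged and, by
default, corrected from ground truth so long matches stay robust
(strict mode aborts instead; a third mode lets the wrong belief persist,
which the fault-injection test uses to show that decisions really flow from
the images).  The perfect player is full minimax (win > tie > loss,
shallower wins and deeper losses preferred, lowest-index tie-break);
perfect-vs-perfect therefore ties from every opening, giving the 9-move,
9·5 + 5 = 50 h reference match.  The documented `blunder1` script
(cross plays cells 1, 6, 2) blocks circle's first column threat but
concedes a double threat, so circle completes a line on the game's 7th
executed move: 7·5 + 5 = 40 h.  The suboptimal policy that produced the
original shorter match is not specified anywhere; this script is the
package's own documented stand-in.

## Problem sizes and numerical choices

Desk-scale defaults were chosen so the full suite and the acceptance script
run comfortably on one CPU: 192-px position cameras, 250–480 cells per
position, 10-minute integration steps inside matches (the exact exponential
photoswitch update makes results step-size-insensitive for piecewise-
constant light), 500-cell gradient fields at 192 px, and 5 seeded replicates
where medians are reported.  Quantization is 256 gray levels; warps are
bilinear with clipping; degenerate inputs (collinear fiducials, singular
homographies, empty cultures, blank frames) raise typed errors or return
empty results as documented per function.

## Known limitations

* The homography is planar: field curvature and chromatic effects are out of
  scope, as is any per-pixel vignetting model.
* Segmentation quality claims are fixture-bound; the 9-feature set and the
  antichain objective are reconstructions of an unpublished design, verified
  against their own brute-force oracles rather than against the original
  implementation.
* Move detection assumes symbols centred in the position FOV and one move
  per turn; it has no appearance model for debris or stage drift.
* The culture model's dose–response constants (all but the 17 s half-life)
  are free parameters of the virtual culture, reported above and in the
  default config, and should not be quoted as measured biology.
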