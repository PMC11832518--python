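# Methods

This note documents the model behind `ewmnkit`, the parameter defaults and
why they were chosen, what the synthetic-data generators emulate (and do
not), and the numerical choices a user may need to know about. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Geometric model

**Frames.** Coordinates are right-handed with gravity along −z; the
configured `zero_direction` (default +x) is the antero-posterior (AP) axis
of the prone reference posture ("zero position") and must be horizontal.
Each trunk segment's orientation is a unit vector read in spherical
coordinates: `theta` in [0, 360), counter-clockwise viewed from above from
the reference direction, and `phi` in [−90, +90], positive upward. The
per-segment systems of reference never rotate — only their origins
translate with the joints — so all angles are computed directly in the
global frame (frame-parallelism). Frames are 0-based and all intervals are
half-open `[start, end)`.

**Chain.** The trunk is a single chain of rigid segments ordered posterior
to anterior (default: pelvis, torso, head over four keypoints), each with
a nominal rest length. Segment directions are measured per frame as
normalized joint differences, so measured lengths are free to vary —
nothing downstream assumes the rest lengths exactly.

**Heavy/light hierarchy.** The base of support orders the segments from
heavy (nearest the supporting girdle) to light. Hindquarters support roots
the chain at the tail-base joint (pelvis heaviest); forequarters support
reverses the permutation exactly. `both` resolves to a configurable
policy, hindquarters by default, because the early-emerging modules pivot
on the hind legs; a dominant-girdle rule can be substituted. `none`
(airborne) retains the last grounded base and flags the frame — how the
hierarchy should be rooted during genuinely airborne phases (stotting,
tumbling) is left flagged rather than resolved, and the first frame of a
record cannot be airborne without an explicit initial base.

**Carried-along (body-relative) description.** For each segment, the
minimal rotation taking the zero direction onto its heavy neighbour's
current direction is inverted before reading the spherical coordinates.
In zero position body-relative equals absolute; a light segment rigidly
carried by its heavy neighbour keeps constant body-relative coordinates.
When the heavy neighbour is antiparallel to the zero direction the minimal
rotation is undefined; the tie-break is a half-turn about the vertical
axis (preserving horizontal-plane semantics) and those frames carry an
`antiparallel` flag. Composing the heavy rotation with the body-relative
direction reproduces the absolute direction to better than 1e−9 on
noise-free input (tested).

**Quantization.** Angles are additionally stored on the standard
45-degree grid (22.5 available via the `quantum` parameter), with
nearest-multiple rounding and ties toward zero; raw degrees are kept
alongside so no information is lost.

**Forward kinematics.** Joints are chained from the root joint outward:
`p_next = p + (L + ext) · u`. The per-segment, per-frame extension term
`ext` models **forward transport of a sub-chain** as axial lengthening at
the transported segment's heavy joint (anatomically, soft-tissue extension
between metameres — a neck stretch carries the head forward while heavier
joints stay put). This keeps the shared-keypoint chain intact, makes
per-segment forward recruitment renderable, and makes it recoverable from
keypoints: the transported segment is the heaviest one whose proximal
joint translated, every lighter joint being carried along. Transport of
the heaviest segment is translation of the root itself (whole-body
progression).

## Segmentation

**Immobility.** Per-keypoint speeds come from smoothed first differences;
a bout is a maximal run in which every tracked keypoint's speed stays
below the threshold, kept only if it lasts the minimum duration (which
must span at least 2 frames). The default symmetric smoothing
(Savitzky–Golay, 0.25 s window, order 3) blurs bout boundaries by roughly
half a window; passing `smooth_window_s=0` gives exact boundaries (up to
the one-frame central-difference stencil) on noise-free input.

**Single movements.** Body-relative angle traces are unwrapped, smoothed
with the same filter, and differentiated. Movement bouts are seeded where
angular speed crosses the threshold (default 10 deg/s), grown with 20%
hysteresis, then expanded outward to the surrounding rest points (a 5%
floor) so amplitudes are read where the trace is flat — with the
minimum-jerk profiles the simulator uses, the amplitude error of this
scheme is far below one degree at zero noise. The minimum amplitude
defaults to a quarter quantum (11.25°): small enough to keep genuine
low-amplitude movement "buds", large enough to suppress tracker jitter;
sub-amplitude flicker is counted in a discard log, never silently
dropped. What amplitude should "count" toward recruitment is not a
settled biological constant — it is a parameter, reported with results.

**Classification.** With ranges `r_theta`, `r_phi` over a bout and the
plane tolerance of half a quantum (±22.5°): horizontal-plane movement
keeps `phi` flat *and near zero* (a flat but elevated `phi` is a cone
about the vertical); vertical-plane movement keeps `theta` flat; when both
vary, a small-circle fit on the direction sphere (smallest-eigenvector
axis, residual < 8°) separates conical from mixed, and mixed bouts fall
back to the nearer plane with a `mixed` flag. Signs follow the direction
of change (left = counter-clockwise from above, up = increasing
elevation). When angular and translational criteria are both met the
angular classification takes precedence and the bout is flagged mixed.
Rotatory movement (rotation of a segment about its own long axis) is
unobservable from single point keypoints per joint and is reported as
such, never guessed.

**Snout contact.** Distance from the snout keypoint to the nearest arena
surface (planes, or 2-D polylines via shapely), thresholded (default 2 cm
for a rat-scale arena) and debounced by a minimum dwell. Without a snout
keypoint, contact is unknown and the two vertical modules merge into an
unresolved label that the grammar checkers exclude and note.

## Grammar

The six spatial modules are ordered `horizontal_on_hindlegs < forward <
vertical_snout_contact < vertical_free < {horizontal_on_forelegs,
vertical_on_forelegs}`; the last two form a concurrent tier, mutually
unordered, both requiring the free-vertical module. The support module is
separate.

**Build-up.** Recruitment within every module runs antero-posteriorly
(head first); on the forelegs the mechanical hierarchy reverses but
recruitment still runs along the AP axis. A primitive violates
`AP_within_module` when its segment's anterior neighbour has not yet
appeared in that module, and `module_order` when it is the segment's first
appearance in a module whose predecessor that segment has not yet visited
*within the current sequence* — the bookkeeping resets at each qualifying
immobility bout, because warm-up is performed de novo after extensive
immobility. A carried-along (chord-member) excursion does not count as the
segment "having moved": a body-relative change is required. Exhaustion of
a plane before the transition to the next is typical rather than law, so
it is reported descriptively (repetition counts are visible in the event
table), not enforced.

**Narrowing.** `LIFO_narrowing`: higher modules must disappear first, so a
module's last occurrence after the last occurrence of any lower module is
a violation (time-reversing a build-up-compliant sequence always passes —
a tested duality). `PA_support`: support inactivation events must run
tail-to-head; violations cite the offending support event. In adult,
"implicated" behavior where modules lawfully interleave, the checkers
report violations descriptively; a non-compliant report is a description
of the sequence, not a pathology verdict.

**Warm-up extraction and ontogeny.** Immobility bouts at or above the
reset duration partition a session; each sequence runs from a bout's
offset to the next qualifying bout, and its peak primitive is the maximum
under (module rank, then caudal recruitment depth). Daily peaks form the
ontogenetic matrix; collinearity (terminal addition) holds when the peak
keys are non-decreasing across days, and regressions are listed.

## Metrics

**Stereotypy triplet.** Active modules; AP extent (segments recruited in
the most advanced module); predictability = 1 − the first-order Markov
entropy rate of the (segment, module) symbol sequence, Laplace-smoothed,
normalized by log of the observed alphabet size — so the score is
invariant to relabeling, 1 for a deterministic alternation in the long
run, and near 0 for an iid-uniform sequence. A single-symbol sequence is
perfectly predictable by convention and flagged degenerate. No canonical
estimator exists for this quantity; first-order Markov with Laplace
smoothing is the simplest one with the right limits, and the window over
which modules count as "available" is a parameter reported with every
result rather than a built-in time constant.

**Recruitment delays.** For each module and adjacent AP pair, the
cumulative amplitude the anterior segment performed in that module before
the posterior segment's first primitive there (degrees for angular
modules, path length for forward transport). A never-recruited posterior
segment leaves a censored entry whose value is a lower bound. Delays are
additive over concatenated windows (tested).

**Attended space.** Radius of gyration and convex-hull area of the
reference-keypoint path over non-overlapping windows (≥ 1 s), with a
Kendall-tau trend over windows; windows with fewer than three distinct
points get zero hull area and a degenerate flag.

**Rigid-trunk path kinematics.** Speed from smoothed differences;
curvature as turning of the direction of progression per unit arc length,
computed on an arc-length-resampled path (step = median per-frame
displacement) to avoid speed–curvature coupling; body rotation rate from
the unwrapped heading; and the heading–progression interval (the
rigid-trunk analogue of delayed caudal recruitment) as the smallest angle
between trunk orientation and direction of progression. Curvature and the
interval are masked below a speed floor — 10% of the session median speed
by default — where the direction of progression is noise; pivoting remains
defined at zero speed because it comes from the heading alone. On sampled
circles the estimator reproduces 1/r within 2% at 100 Hz (tested).

**Immobility alignment.** The immobility spot is the mean centroid within
the bout (no other definition is standard). Distance-to-spot traces are
aligned on bout onset and offset, optionally rescaled to [0, 1] before
averaging, with per-trace Kendall taus as the monotonicity statistic.

**Traveling waves.** Instantaneous phase per segment from the analytic
signal (Hilbert transform) of the zero-meaned lateral bending — no
periodicity or symmetry assumed; relative phase is the circular mean of
adjacent instantaneous phase differences; with S segments spanning the
body and mean adjacent lag δ, the wavelength is 360/(S·δ) body lengths. A
mean lag under 2° is reported as a standing wave (infinite wavelength).
Near-zero-variance segments are excluded and listed; 5% of samples at each
edge are trimmed against Hilbert edge effects. Phases are invariant to
amplitude scaling within 1° (tested).

## Simulators: what they emulate, and what they do not

**Warm-up generator.** The `stage` parameter (0–1) is the fraction of the
bauplan unlocked: one module per quarter stage up to the fourth
(horizontal, forward, vertical with contact, vertical free — stage 1 stops
at the fourth, matching the canonical infant/recovery progression; the
foreleg tier is checked by the grammar but not generated, since it
requires a forequarters weight shift outside the rendered scenario).
Within each module, recruited segment count and amplitude grow linearly
with stage from one quantum toward the module maximum ("buds" growing into
full-blown movements); each recruitment step is repeated (default twice,
out and back). Movements are rendered with minimum-jerk interpolation
between quantized targets — the within-movement velocity profile is not
biologically specified; minimum-jerk is the standard smooth choice and is
documented so segmentation tolerances are meaningful. Pauses are
log-normal (mean 0.7 s, floored at 0.45 s — a synthetic choice, as no
empirical pause distribution is established). A wall plane is placed where
the snout sits at the onset of contact-vertical work and the generator
retreats from it (a lawful forward-module event) before free-vertical
work, so the contact/no-contact split of the vertical modules is
reproduced in the rendering. Keypoint noise is Gaussian, default zero.
Default frame rate 50 Hz, immobility prelude 10 s.

What the generator does **not** emulate: limb/footfall kinematics (support
is a flag channel, not rendered feet), rotatory (long-axis) movement,
postural drift during pauses, occlusion-like structured tracking error,
and the adult interleaved ("implicated") regime. Passing the zero-noise
recovery tests therefore shows the pipeline is exact on its own model
class; it does not bound errors on real tracking data, where smoothing
windows and amplitude thresholds must earn their keep.

**Fly session.** Scripted phases at 30 Hz in a 30 mm circular arena:
straight bouncing runs (20 mm/s, 300 s), an inward spiral whose radius
shrinks monotonically onto the immobility spot while the winding rate
rises (240 s) — so distance-to-spot falls while curvature grows — pivoting
in place (90 deg/s, 60 s), complete immobility of exactly 600 s (the
canonical ten-minute bout), then the mirror-image build-up. The
heading–progression interval is inflated (up to 35°) during the spiral
phases. The session is a clean caricature: real sessions have bursts and
variability rather than monotone profiles, and the immobility here is
perfectly frozen.

**Traveling wave.** Segment k bends as `A sin(2π f t − 2π k/(S·λ))` plus
optional Gaussian noise; the script (including the implied adjacent lag)
is returned as ground truth.

**Violation injector.** Minimal edits each creating exactly one violation:
moving a caudal segment's first in-module movement ahead of its anterior
neighbour's (AP), moving the most anterior segment's first appearance in a
module ahead of its first appearance in the previous module (module
order), or re-appending a higher-module primitive to a narrowing-ordered
sequence (LIFO — inject into a time-reversed build-up). Support-folding
violations are constructed directly on support-event lists in the tests
rather than through the injector, since support events are not
primitives. All generators and the injector are deterministic given a
seed (single seeded stream; independent sub-streams are unnecessary at the
current scale).

## Numerical choices and degenerate inputs

- Missing keypoints: linear interpolation across gaps up to 5 frames;
  longer gaps keep their frames invalid, and segmentation treats invalid
  frames as record boundaries instead of inventing motion across them.
- Zero-length segments flag the frame invalid; they never raise mid-run.
- Savitzky–Golay smoothing everywhere differentiation happens; window
  0.25 s, order 3, never narrower than 5 frames unless disabled.
- Bout expansion floor 5% of the speed threshold; hysteresis 20%.
- Cone-fit residual tolerance 8°; plane tolerance half a quantum.
- Quantization ties round toward zero; theta sectors wrap modulo
  360/quantum, phi sectors do not wrap.
- Predictability uses log2 and clips to [0, 1] against smoothing-induced
  drift just outside the interval.
- `attended_space` hull areas use Qhull; collinear windows degrade to zero
  area with a flag instead of raising.

## Problem sizes used in the bundled checks

The test suite and acceptance script run entirely on generated data:
1000-pose oracles for the mechanical-hierarchy and round-trip checks; 200
rendered warm-up sequences (five stages × forty seeds, ~15–60 s of
50 Hz data each) for recovery and soundness; 100 seeds × 5 edits for the
injection benchmark; a single 1800 s, 30 Hz fly session; and 20–30 s
traveling-wave records at 100 Hz. These sizes give stable statistics for
every quantity checked while keeping a full run in the low minutes on one
CPU.

## Known limitations

- Conical movements are classified but mapped to the nearest plane module
  with a flag, since the module taxonomy is defined on plane movements.
- The carried-along construction uses the minimal (geodesic) rotation of
  the heavy neighbour; for large out-of-plane excursions this is one of
  several defensible conventions, and rigid co-rotation invariance is
  exact only where the heavy segment's motion is itself a single rotation
  from zero position (always true segment-wise in the renderer).
- Forward transport of a non-root segment is modelled as axial extension;
  organisms also achieve it by limb-driven translation, which this trunk
  model cannot distinguish from root transport.
- The fly pipeline assumes a planar rigid trunk; no attempt is made to
  detect articulated movement in fly data.
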