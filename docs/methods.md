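# Methods

This note documents the models, default parameters and design choices
behind the `remyelin` analysis chain and its synthetic-data generator.
Coordinates are micrometres, right-handed, origin at one corner of the
imaged field at the pial surface, z increasing with depth; intervals are
half-open.

## The study conditions the generator encodes

The default configuration describes a 3-week cuprizone demyelination with
9 weeks of recovery, imaged weekly (sessions at weeks 0–12) in a
425 × 425 × 300 μm cortical volume divided into three 100-μm depth zones.

**Demography.** Baseline oligodendrocyte counts per zone default to
(17, 40, 79) cells — density rises steeply with depth.  The middle-zone
value interpolates between the superficial and deep densities.  Per-mouse
counts are Poisson; positions are uniform in x-y and uniform within the
zone in depth.

**Loss.** Each baseline cell carries an independent weekly loss hazard
{wk 1: 0.01, wk 2: 0.03, wk 3: 0.35, wk 4: 0.70, wk 5: 0.69}: most
destruction follows cuprizone withdrawal, and the cumulative loss is 94.2%
of baseline by the end of week 5 (the "loss phase").  Control cohorts have
zero hazard.

**Addition.** New cells appear per zone at weekly rates that burst early
in recovery and decay to ~3.5% of baseline per week (shape
[4, 12, 11, 8, 6, 5, 4, 3.7, 3.5] over recovery weeks 1–9), normalized to
zone-specific cumulative totals of 79.4% / 55.8% / 49.7% of the zone
baseline — regeneration is efficient superficially and impaired at depth;
the zone-weighted, volume-wide cumulative addition is 55.2%.  Weekly
counts use error-diffusion rounding (the cumulative count stays the
nearest integer to the cumulative schedule, residual initialized at 1/2):
the schedule is the modeled condition, and independent per-week rounding
would add dispersion that swamps the small top zone (~17 cells).  Only
placement is random: each new cell is displaced from a uniformly chosen
same-zone baseline cell by a radial kernel r = 12 + Lognormal(mean 18 μm,
log-sd 0.6) (mean ≈ 30 μm) in a uniform 3-D direction, resampled to stay
in the volume and zone.  The kernel floor reflects that regenerated cells
occupy distinctly new positions, well separated from the ~10 μm
registration-wobble scale; its exact shape is a free choice of the
generator.

**Noise.** Every session carries a rigid drift vector (per-axis SD 3 μm)
plus i.i.d. detection jitter (per-axis SD 2 μm).  With both set to zero,
every downstream stage recovers ground truth exactly (tested).

**What the generator does not emulate:** intensity images, detection
failures (dropouts), segmentation errors, vasculature or anatomical
heterogeneity, cell migration (somata are static between appearance and
loss), and axon degeneration.  Passing the recovery tests therefore shows
the analysis chain is unbiased under the modeled noise, not that it is
robust to segmentation artifacts in real imagery.

## Tracking

Drift between consecutive sessions is removed iteratively: mutual-nearest
neighbor matching within 15 μm, subtraction of the matched pairs' mean
displacement, re-matching, until the drift vector changes by < 0.1 μm or
10 iterations.  The iteration resolves the circularity that the mean
movement vector presupposes known correspondences; when matching is
correct it converges to exactly that vector.  The 15 μm default match
radius sits above the registration wobble and below typical inter-cell
spacing (≈ 40 μm at the deep-zone density); it is configurable.

Tracks chain correspondences across sessions.  A track unmatched for one
session remains eligible for re-joining at the next (single-dropout
tolerance); loss is confirmed by absence through the end of the series.
Fates follow first/last appearance vs the baseline and final sessions:
stable, lost, new, new_then_lost.  Zone membership is frozen per track and
estimated from the mean drift-corrected position over the track's observed
sessions — somata are static, so averaging is an estimator of the same
(first-seen) position with less boundary-crossing noise than a single
jittered session.  The depth "binning between planes parallel to the pia"
is implemented directly as half-open plane binning.

Rates divide fate-event counts per interval by baseline count × interval
weeks.  Zone-resolved recovery fractions are pooled over mice
(Σ final counts / Σ baselines): with ~17 baseline cells per mouse in the
top zone, a mean of per-mouse ratios would be dominated by
small-denominator noise.  Volume-wide loss/addition fractions are averaged
over mice.

## Morphometry

Traces are smoothed with a centered moving average (window 3 points,
endpoints fixed) before arc-length measurement; for collinear, evenly
spaced samples the length is preserved exactly.  Sheath-dynamics labels
use a ±2 μm per-interval threshold (no numeric threshold is standard; the
value is configurable and sits above tracing noise).  Mature-morphology
comparisons use day 12–14 snapshots, when newly formed cells have reached
their stable form.

The synthetic arbor draws per-cell sheath counts Normal(53, 8)
(between-cell SD, not SEM) and sheath lengths Lognormal with mean 62.6 μm
and between-sheath SD 25 μm (right-skewed; gamma available), midpoints
uniform in an axially symmetric arbor ellipsoid (r_xy 76 μm, r_z 30 μm),
orientations azimuthally uniform with a small Normal(0, 0.1) z-slope, and
attachment points uniform along the internode.  The regenerated-cell
preset is (51 sheaths, 72.3 μm, r_xy 85 μm).

**Hodges–Ajne:** m = the minimum, over open half-planes through the
origin, of points in the half-plane; exact tail probability
2^(1−n)(n−2m)C(n,m) for m < n/3, otherwise a cached, seeded Monte-Carlo
null of m under uniformity.  **Kuiper two-sample:** V = D⁺ + D⁻ evaluated
on the pooled circular sample with tied angles processed jointly (so
identical samples give exactly V = 0); p from the asymptotic series with
the effective-sample-size correction, or a seeded permutation null when
the effective n < 8.  Note that fully separated point masses give V = 1
(D⁺ = 1, D⁻ = 0): V = 2 is not attainable for probability CDFs.  Both
tests analyze the x-y projection only; solid-angle statistics are out of
scope.

## Territory

The containment ellipsoid is centered at the mean of all sheath sample
points (centering at the soma would push territory volume above the pia)
and searched on a 1-μm radius grid, minimizing r_xy² · r_z subject to
containment ≥ 80%, ties toward smaller r_xy then r_z.  The search bound
matters: the optimal r_xy can exceed the furthest point's distance
(widening r_xy relaxes the radial term and lets r_z shrink), so the grid
extends until the volume provably exceeds that of a known feasible corner
solution; a brute-force oracle cross-checks the search in the tests.  The
printed membership inequality is the standard normalized quadratic form;
radii below the 1 μm search step are not considered (prevents degenerate
zero-volume fits).

Rasterization stamps condition-mean model ellipsoids at soma positions
onto an anisotropic grid (1 μm in x-y, 3 μm in z — a 100-μm zone is 33
slices), counting multiplicity and clipping at the volume boundary.
Overlap = occupied-voxel intersection / baseline occupancy, scaled by
n_baseline / n_recovery; the literal bookkeeping form
"((recovery − baseline) ≤ 0) + baseline" is available behind
`literal_formula=True` but is not a proportion as written (its Boolean is
1 wherever both grids are empty), so the intersection reading — the stated
intent — is the default.  The random-placement null redraws recovery
centers uniformly in the volume with the same cell count.

## Internode fates

Axon fields are smooth, non-parallel 3-D curves (direction random walk,
angular step SD 0.03/2 μm), carrying runs of 1–3 consecutive internodes
(run-length probabilities 0.57 / 0.23 / 0.20, giving 65% of internodes at
least one neighbor) separated by node gaps of 0.5–3 μm within runs and
bare stretches of 25–80 μm between runs.  Runs are always emitted whole
and the polyline is extended to cover the realized arc: truncating runs at
a fixed axon length would bias the surviving run-length mix toward
singletons and distort the neighbor-class distribution.  The arc midpoint
is anchored uniformly in the field so window inclusion is symmetric along
the arc.

Cuprizone fields destroy baseline internodes with probability 0.844;
destroyed internodes are replaced with probability 0.35 (isolated) or 0.73
(≥ 1 neighbor) — neighbor-conditional replacement — by a new-cell sheath
drawn as a sub-interval with coverage uniform in [0.55, 0.95] (a
sub-interval can never collide with neighboring final-session sheaths,
which would be invalid tracing).  Novel internodes appear on bare
stretches at 47.6% of the baseline count (25.8% in control, where
destruction is 0.9% and nothing is replaced).

Classification: stable = same owner overlapping at the final session;
replaced = union of regenerated-owner overlaps ≥ 50% of the baseline
interval (single-sheath mode available); otherwise lost; final sheaths not
acting as replacements are novel, and owners known to neither population
are undefined.  Neighbor gaps are measured end-to-end along the axon arc
(nodes are axonal-domain structures, not 3-D chords).  A replaced
internode's identity maps to the largest-overlap new sheath (ties to the
lower id).  Analysis windows are 100³ μm cubes drawn by seeded uniform
sampling; an internode is included if any part of its arc passes through
the window, with neighbor context taken from the full axon.

Node detection from intensity profiles (pitch ≤ 0.5 μm) finds local
minima between two local maxima that dip below the flanking internode
floor; the gap spans between the nearest flanking samples at or above the
mid-reference level (halfway between dip and lower peak), and a node is
called iff the gap is < 5 μm.

## Nodal domains

Nodal puncta are placed with an 8-μm hard core in a 135 × 135 × 30 μm
field; each non-AIS punctum receives 0/1/2 paranodal partners at 0.8–3 μm
per the condition preset (control: 0.85/0.10/0.05 for 2/1/0; cuprizone
4 wk: 0.45/0.25/0.30; 6 wk: 0.10/0.15/0.75 — paranodes strip
progressively), plus 20% stray paranodal puncta kept ≥ 4.5 μm from any
nodal punctum so ground-truth classes stay exact.  15% of nodal structures
are elongated AIS-like objects (8–25 μm).

Classification counts paranodal puncta within 3.5 μm (count-within-radius,
not two-sided flanking geometry — matching the stated procedure over the
schematic); a paranodal punctum may serve several nodal puncta, with an
exclusivity mode for sensitivity analysis.  The AIS size filter excludes
structures longer than 6 μm (AIS are the elongated ones; cutoff and
direction configurable).  The rotation null turns the paranodal channel
90° about the bounding-box center of the combined field — points may leave
the field and simply stop pairing.

## Problem sizes and reproducibility

Default analyses use 6 virtual mice (~820 baseline cells), five axon
fields of 250 axons (~1100 windowed baseline internodes), and 200 traced
morphologies — sizes at which binomial counting error sits well inside the
reported tolerances while a full run stays in seconds.  All randomness
flows from one integer seed through deterministic substreams
(`numpy.random.SeedSequence`); re-running any stage or the full pipeline
with the same seed is byte-identical.

## Known limitations

- The matcher can occasionally fuse a newly appeared cell with a track
  that vanished at the same transition within the match radius; at default
  densities this biases volume-wide loss by ≲ 0.5 percentage points.
- Replacement geometry in the generator is a sub-interval of the baseline
  internode; real replacement sheaths can overhang into node gaps.
- Sheath thickness / g-ratio and 3-D orientation statistics are out of
  scope, as are image-domain steps (segmentation, registration).
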