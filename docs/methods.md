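# Methods

This note documents what the checks actually compute, the tunable
parameters and their defaults, what the synthetic fixtures do and do not
emulate, and the numerical choices made where the design was open.

## Inputs and coordinate conventions

Two paired datasets are read: the original and the on-table-adapted plan,
each one DICOM RT Plan plus one RT Structure Set. Everything is kept in the
DICOM patient coordinate system in millimetres; contours are taken verbatim
from `ContourData` (z = third coordinate), never resampled. Per-segment
monitor units are cumulative-meterset-weight differences scaled by the beam
meterset, under a step-and-shoot assumption: segment *j* spans control
points (j, j+1) and uses the leaf positions in force at control point *j*.
The two MLC banks are identified among the beam-limiting devices by their
leaf boundaries; the bank with the smaller first boundary is "stack A".
The machine description (34 leaf pairs per stack, 8.3 mm leaf width at
isocenter, banks offset by half a leaf width) is configuration, not
hard-coded: `MLCGeometryConfig`.

DICOM has no standard attribute for the *priority* of a relative-electron-
density override. The reader accepts the convention the fixture writer
uses — `ROIObservationDescription` containing `DENSITY_PRIORITY=<n>` on the
RT ROI observation — and falls back to observation order otherwise.

## Volumes, gaps, density overrides

Volume is slice-prism summation: per contoured slice, polygon areas are
combined with even-odd nesting (a polygon contained in an odd number of
larger polygons on the same slice is a hole) and multiplied by the slice
spacing; no end-cap correction is applied. The spacing is inferred per
structure as the mode of its consecutive z-differences (ties broken toward
the smaller value), because adapted structure sets may be cropped or use a
different grid; a structure with a single slice falls back to
`default_slice_spacing_mm` (3 mm, a typical MR slice thickness). The same
convention on both plans makes volume *differences* insensitive to the
choice.

A volume change above `volume_diff_percent` (default 30 %) raises one
alert per structure — per structure rather than per plan, favouring
sensitivity. A structure present only in the original set is a deletion.
A consecutive z-step larger than `gap_factor` (1.5) times the structure's
nominal spacing reports the intermediate grid positions as missing slices;
1.5 is robust to floating-point jitter yet catches any single-slice
deletion. Density overrides are reported priority-descending and are purely
informational; values outside (0, 3] relative electron density are marked
extreme (0 itself — air — is flagged as worth a glance).

## Target-chain consistency

Structure names are matched case-insensitively against configurable
patterns (`^gtv(.*)$`, `^ctv(.*)$`, `^ptv(.*)$`); the captured suffix
groups members into chains (GTV2/CTV2/PTV2). Because targets are
recontoured and margins re-applied at every adapted fraction, members of a
chain should change volume together. Three rules flag a chain
(weight 2):

1. **Sign mismatch** — PTV and GTV (or CTV) changed in opposite directions,
   either direction.
2. **Spread** — two members' percentage changes differ by more than
   `target_spread_points` (10 percentage points). The published threshold
   phrase "volume changes do not differ by more than 10 %" is read as a
   percentage-point spread: comparing raw cc changes across structures
   that differ in size by an order of magnitude would make the rule
   vacuous for exactly the incidents it is meant to catch.
3. **Frozen PTV** — GTV or CTV changed while the PTV did not (margin
   expansion skipped, or the wrong PTV expanded). "Did not change" means
   |Δ| ≤ `target_zero_tol_points` (0.5 percentage points), so float noise
   and trivial recontouring cannot trigger it — while a genuine 1–2 %
   recontour of the GTV over an untouched PTV does, which is precisely the
   reused-PTV failure pattern.

Single-member chains are reported as not checkable. For reassurance the
equivalent-sphere margin (3V/4π)^⅓(outer) − (3V/4π)^⅓(inner) is shown for
the innermost-member→PTV pair of both plans; it is exact for spheres and a
useful sanity figure otherwise, not a reconstruction of the true 3D margin
(no distance transform is attempted).

## MLC complexity

The half-leaf-offset double stack is converted to an artificial single
stack on rows at half-leaf pitch: each row is covered by exactly one leaf
pair of each bank, and its opening is the intersection
[max(left_A, left_B), min(right_A, right_B)] — the minimum united opening.
Edge half-rows covered by only one bank are treated as blocked. Segment
area is the sum of open row rectangles; subsegments are connected
components of open rows, adjacent rows being connected iff their x-intervals
overlap with positive length; the per-beam union area merges the segments'
row intervals. The effective MU of beam *i* is

    effMU_i = Σ_j MU_ij · AA_ij / U(AA_ij),

the MU-weighted mean segment area normalized by the union area — an
open-field-equivalent MU. The division by U is required on dimensional
grounds (without it the quantity has units of MU·cm⁴); effMU_i ≤ the beam's
MU, with equality exactly when every segment opens the full union.

Alerts: more than `small_area_frac_percent` (10 %) of a plan's segments
under `small_area_cm2` (1 cm²) weighs "fraction % − 10"; more than
`low_mu_frac_percent` (5 %) under `low_mu` (5 MU) weighs 1; a total-MU
change beyond `mu_diff_percent` (10 %) weighs "|Δ %| − 10" with the
absolute value taken — a decrease is as suspicious as an increase. The
segment alerts are evaluated on the adapted (deliverable) plan; both plans'
complexity summaries appear in the report. The area and MU criteria keep
separate thresholds and weights (10 % area / 5 % MU) rather than being
merged into a single 10 % rule. Formula weights are
kept as real numbers; no rounding is applied, which makes fractional
traffic-light totals possible.

## Alerts and the traffic light

Fixed weights: wrong patient (name *or* ID) 10, wrong plan label 10,
deleted structure 5, volume difference 3, inconsistent target chain 2,
low-MU segments 1, structure gap 5. Identity comparison is case-sensitive
after whitespace normalization. The traffic light is green at total 0,
orange for totals in (0, 9], red above 9. Totals strictly between 0 and 1
(reachable only through a fractional MU weight) are shown orange rather
than green: a raised alert must never be invisible, and the design goal is
sensitivity — the light is advisory, a red fraction may still be treated
after review.

## Synthetic fixtures

`fixture_forge` generates valid, minimal RT Plan/RT Structure Set pairs
from analytic primitives: spheres, cylinders and boxes sampled as 72-gon
contours on a 1 mm (configurable) slice grid; target chains as concentric
spheres GTV(r), CTV(r+m₁), PTV(r+m₁+m₂); beams as rectangular MLC openings
(both banks set identically, so the requested rectangle is quantized to
leaf rows). The adapted pair is the original with benign recontouring
noise — an in-plane scaling drawn uniformly within ±2 % volume change,
*one draw per chain* so chain members move together as they do when a
target is recontoured and margins re-applied — plus the injected faults.
The ±2 % default keeps faults isolable; clinical recontouring can
intentionally change volumes by tens of percent, so passing specificity on
these fixtures demonstrates correct wiring of thresholds, not the clinical
false-positive rate. Other simplifications: no realistic anatomy, no
intentional contour gaps, identical leaf patterns between original and
adapted plans unless a fault modifies them, a single beam by default, and
no dose grids at all. Coordinates and MU weights are rounded to what the
DICOM decimal-string encoding carries (10⁻⁶ mm; cumulative weights to
10⁻⁸), and the recorded ground truth is the rounded model, so read-back is
exact. UIDs are derived from the seed via SHA-256, making output
byte-identical per seed.

Each of the eleven fault kinds (delete_slice, delete_structure,
wrong_margin, skip_margin_expansion, inflate_wrong_ptv, scale_volume,
rename_patient, rename_plan, add_small_segment, add_low_mu_segment,
scale_total_mu) maps to exactly one expected alert code. Fault-added
segments keep their stated MU ("pinned"); a total-MU fault rescales the
remaining segments, so a 0.66 cm²/302.6 MU segment and a +10.1 % total can
coexist exactly. Expected alert codes are derived from the generator's own
shoelace-area bookkeeping, independent of the checking code. The
nine-member `incident_suite()` reproduces the failure patterns this kind
of check catches in clinical adaptive workflows: four target/margin
irregularities (including the −21 %-PTV with
+32 %/+16 % GTV/CTV chain, and a margin of 3 mm instead of 5 mm shrinking
a small PTV by ≈55 %), four accidental missing slices (three in CTV/GTV,
one in bowel), and the over-modulated plan above.

## Numerical choices and degenerate inputs

Contours need ≥ 3 vertices and must be simple (validated through the
polygon library); degenerate contours in a file are skipped with a logged
warning. Zero original volume makes a percentage change undefined: the
entry is flagged and alerted. A beam whose segments never open has
undefined effMU (reported as such, no alert). Leaf pairs with
left > right are rejected at read time, as are non-monotone cumulative
weights. Tolerances: 10⁻⁶ mm/MU for round-trips, 10⁻⁹ for interval
arithmetic tie-breaks (a zero-length row opening is closed).

## Problem sizes in the test and acceptance runs

The bundled suites use one-chain fixtures (spheres of 5–8 mm GTV radius at
1 mm slicing, a 12–18 mm OAR) and a 10-pair reduced MLC geometry for the
rasterization oracles: 20 random fixtures per fault kind for sensitivity,
50 fault-free fixtures for specificity, 100 random apertures against the
0.1 mm pixel-counting/flood-fill oracle. The acceptance script uses 5
fixtures per fault kind and 20 fault-free fixtures. These sizes give exact
expectations (100 % detection on constructed faults) while keeping a full
run in the low minutes on one core.

## Known limitations

Volume differences, not dose, are checked; contour plausibility against
anatomy, deformable-registration quality, deliverability (leaf speeds,
interdigitation) and dosimetric uncertainty modelling are out of scope.
The single-stack conversion assumes the half-leaf-offset double-stack
geometry; other MLCs would need their own `MLCGeometryConfig` and possibly
a different conversion. The report replaces the original PDF layout with
JSON (schema shipped) and plain text; a PDF renderer is an extension point.
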