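# apart

Automated per-fraction plan checks for online-adaptive MR-guided
radiotherapy.

On an MR-Linac the treatment plan is re-optimized every day with the patient
on the table: targets and organs at risk are recontoured, margins
re-applied, densities overridden where the electron-density map is off, and
the plan re-optimized — all under time pressure, and without any possibility
of a pre-treatment measurement. The vendor's secondary dose calculation
verifies that the *dose* of the adapted plan is computed correctly, but it
is blind to bad *input*: a deleted contour slice, a forgotten margin
expansion, an override applied to the wrong structure, or a plan that became
excessively modulated. This package implements the complementary check: it
compares the original and the adapted plan pair (DICOM RT Plan + RT
Structure Set each) and reports every irregularity as a weighted alert,
aggregated into a green/orange/red traffic light for the physicist who has
to approve the fraction in minutes.

## Checks and scoring

* **Identity** — patient name, patient ID and plan label must match between
  original and adapted plan (weight 10 each for patient / plan mismatch).
* **Structures** — structure-by-structure volume comparison (|ΔV| > 30 % →
  weight 3 per structure), deleted structures (weight 5), missing interior
  slices detected from each structure's own z-spacing (weight 5), and a
  listing of all relative-electron-density overrides with their priorities.
* **Target chains** — GTV/CTV/PTV families (grouped by name suffix) must
  change volume together: a sign flip between PTV and GTV/CTV, a spread of
  more than 10 percentage points between members, or a frozen PTV under an
  edited GTV/CTV flags the chain (weight 2). For reassurance the
  equivalent-sphere expansion radius r(V) = (3V/4π)^⅓ is reported for both
  plans.
* **MLC complexity** — the double-stack MLC (two banks offset by half a
  leaf width) is reduced to a single artificial stack by intersecting the
  two banks' openings on half-leaf-pitch rows. Per beam *i* the effective MU

      effMU_i = Σ_j MU_ij · AA_ij / U(AA_ij)

  is computed, where AA_ij is the open area of segment *j* and U(AA_ij) the
  union of the beam's segment areas. The plan-level statistics cover
  segment/subsegment counts, the smallest-area and lowest-MU segments, the
  fraction of segments under 1 cm² (> 10 % → weight "fraction % − 10") or
  under 5 MU (> 5 % → weight 1), and the total-MU change (|Δ| > 10 % →
  weight "|Δ %| − 10").

Total weight 0 → **green**; up to 9 → **orange**; above 9 → **red**. All
thresholds and weights live in a config file (`CheckConfig`).

Because clinical DICOM cannot ship with a test suite, the package includes
`apart.fixture_forge`: a deterministic generator of valid paired RT
Plan/Structure Set files built from analytic shapes, with eleven injectable
fault kinds (each mapped to the alert it must raise) and a nine-member
incident suite reproducing the failure patterns observed in clinical use.

## Worked example

Generate a fixture pair in which one interior CTV slice was "accidentally"
deleted during recontouring, then check it:

```python
from apart.fixture_forge import (FixtureSpec, ChainSpec, StructureSpec,
                                 FaultSpec, generate_pair)

spec = FixtureSpec(
    seed=11,
    chains=[ChainSpec(gtv_radius=8.0, ctv_margin=3.0, ptv_margin=5.0)],
    structures=[StructureSpec("Liver", center=(40.0, 0.0, 0.0), size=(20.0,))],
    faults=[FaultSpec("delete_slice", {"name": "CTV"})],
)
generate_pair(spec, "demo")
```

```
$ apart check --original-plan demo/orig_plan.dcm --original-rs demo/orig_rs.dcm \
              --adapted-plan demo/adapted_plan.dcm --adapted-rs demo/adapted_rs.dcm
TRAFFIC LIGHT: ORANGE (total weight 5)

Patient: DOE^JANE (PAT0001)  Plan: ABD_SBRT_A
Total MU: 200.0 -> 200.0 (+0.0%)

Alerts (1):
  [STRUCTURE_GAP] weight 5: CTV: missing slice(s) at z = 0

Volume table (cc):
  structure                 original   adapted   delta %
  GTV                           2.13      2.10      -1.5
  CTV                           5.56      5.10      -8.2
  PTV                          17.12     16.86      -1.5
  Liver                        33.45     33.45      -0.0

Complexity (original): 4 segments, 4 subsegments
  smallest segment: 7.47 cm² at 50.0 MU
  lowest-MU segment: 40.0 MU at 13.28 cm²
  beam B1: effMU 125.2, union 20.75 cm², MU 200.0
...
```

The deleted slice at z = 0 is found from the CTV's own nominal slice
spacing (a step larger than 1.5× the spacing flags the missing positions)
and carries weight 5 → orange: the fraction needs review before treatment.
The benign ±2 % recontouring noise on the other structures stays well below
every threshold. Exit code is 0/1/2 for green/orange/red, ≥ 3 for errors,
so the tool can sit in a scripted workflow. `--format json` emits the full
machine-readable report (validated against the shipped schema) instead.

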