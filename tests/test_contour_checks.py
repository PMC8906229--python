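"""Volume computation, structure matching, gaps and density overrides."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

from apart.config import CheckConfig
from apart.contour_checks import (
    VolumeEntry,
    density_override_report,
    detect_gaps,
    match_structures,
    nominal_spacing,
    structure_volume,
    volume_diff_table,
)
from apart.model import Contour, PlanIdentity, Structure, StructureSet


def square(side, z, cx=0.0, cy=0.0):
    h = side / 2.0
    return Contour(
        z=z,
        vertices=np.array(
            [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
        ),
    )


def sphere_structure(radius, spacing, n, name="S"):
    contours = []
    k = int(math.floor((radius - 1e-9) / spacing))
    for i in range(-k, k + 1):
        z = i * spacing
        r = math.sqrt(radius**2 - z**2)
        if r < 0.3:
            continue
        theta = 2 * np.pi * np.arange(n) / n
        contours.append(
            Contour(z=z, vertices=np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        )
    return Structure(name, 1, contours)


def test_prism_volume():
    s = Structure("box", 1, [square(10.0, float(z)) for z in range(10)])
    assert structure_volume(s, 1.0) == pytest.approx(1.0, rel=1e-9)


def test_triangle_slice_volume():
    tri = Contour(z=0.0, vertices=np.array([[0, 0], [10, 0], [0, 10]], float))
    s = Structure("tri", 1, [tri])
    assert structure_volume(s, 3.0) == pytest.approx(0.150, rel=1e-9)


def test_sphere_volume_close_to_analytic():
    s = sphere_structure(20.0, 1.0, 40)
    v = structure_volume(s, 1.0)
    assert v == pytest.approx(33.510, rel=0.02)


def test_volume_invariant_under_translation_and_rotation():
    s = sphere_structure(12.0, 1.0, 48)
    v0 = structure_volume(s, 1.0)
    angle = 0.7
    rot = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    moved = Structure(
        "moved",
        1,
        [Contour(z=c.z, vertices=c.vertices @ rot.T + [31.5, -17.2]) for c in s.contours],
    )
    assert structure_volume(moved, 1.0) == pytest.approx(v0, rel=1e-6)


def test_holes_subtracted_on_same_slice():
    outer = square(20.0, 0.0)
    hole = square(10.0, 0.0)
    s = Structure("ring", 1, [outer, hole])
    # 400 - 100 mm² over one 1 mm slice
    assert structure_volume(s, 1.0) == pytest.approx(0.300, rel=1e-9)
    # island inside the hole is added back (even-odd nesting)
    island = square(4.0, 0.0)
    s2 = Structure("ring2", 1, [outer, hole, island])
    assert structure_volume(s2, 1.0) == pytest.approx(0.316, rel=1e-9)


@pytest.mark.parametrize(
    "builder",
    [
        lambda: sphere_structure(10.0, 0.5, 90),
        lambda: Structure("box", 1, [square(14.0, 0.5 * z) for z in range(20)]),
    ],
)
def test_volume_against_voxelization_oracle(builder):
    """Convex fixtures: slice-prism volume vs 0.5 mm in-plane point counting."""
    import shapely

    s = builder()
    spacing = nominal_spacing(s)
    v = structure_volume(s, spacing)
    step = 0.5
    grid = np.arange(-20.0, 20.0, step) + step / 2.0
    xx, yy = np.meshgrid(grid, grid)
    voxel = 0.0
    for z in s.z_positions:
        poly = Polygon(s.contours_at(z)[0].vertices)
        inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).sum()
        voxel += inside * step * step * spacing
    assert v == pytest.approx(voxel / 1000.0, rel=0.01)


def test_match_structures():
    def ss(names):
        return StructureSet(
            PlanIdentity("A^B", "1", "P"),
            [
                Structure(n, i + 1, [square(10.0, 0.0), square(10.0, 1.0)])
                for i, n in enumerate(names)
            ],
        )

    orig = ss(["Duodenum", "GTV", "PTV"])
    same = ss(["duodenum", "gtv", "ptv"])  # case-insensitive
    matched, deleted, new = match_structures(orig, same)
    assert len(matched) == 3 and not deleted and not new

    adapted = ss(["GTV", "PTV", "PTV_opt"])
    matched, deleted, new = match_structures(orig, adapted)
    assert deleted == ["Duodenum"]
    assert new == ["PTV_opt"]
    assert sorted(m[0] for m in matched) == ["GTV", "PTV"]


def test_volume_diff_alerts():
    def one(name, side_orig, side_adapted):
        o = Structure(name, 1, [square(side_orig, float(z)) for z in range(10)])
        a = Structure(name, 1, [square(side_adapted, float(z)) for z in range(10)])
        orig = StructureSet(PlanIdentity("A^B", "1", "P"), [o])
        adapted = StructureSet(PlanIdentity("A^B", "1", "P"), [a])
        return volume_diff_table(orig, adapted, [(name, name)])

    # 20% change: below the 30% threshold
    entries, alerts = one("a", 10.0, 10.0 * math.sqrt(1.2))
    assert entries[0].delta_percent == pytest.approx(20.0, abs=1e-6)
    assert alerts == []
    # 35% change: one alert, weight 3
    entries, alerts = one("b", 10.0, 10.0 * math.sqrt(1.35))
    assert entries[0].delta_percent == pytest.approx(35.0, abs=1e-6)
    assert [a.weight for a in alerts] == [3.0]


def test_volume_entry_consistency_and_undefined():
    e = VolumeEntry("x", 10.0, 13.5)
    assert e.delta_cc == pytest.approx(3.5, abs=1e-9)
    assert e.delta_percent == pytest.approx(35.0, abs=1e-9)
    z = VolumeEntry("y", 0.0, 2.0)
    assert z.undefined and z.delta_percent is None


@pytest.mark.parametrize(
    "zs,expected_nominal,expected_missing",
    [
        ([0, 1, 2, 3, 4], 1.0, []),
        ([0, 1, 3, 4], 1.0, [2.0]),
        ([0, 2, 4, 8, 10], 2.0, [6.0]),
    ],
)
def test_detect_gaps(zs, expected_nominal, expected_missing):
    s = Structure("s", 1, [square(10.0, float(z)) for z in zs])
    report = detect_gaps(s)
    assert report.nominal_spacing == pytest.approx(expected_nominal)
    assert report.missing_z == pytest.approx(expected_missing)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    spacing=st.floats(0.5, 5.0),
    n_slices=st.integers(3, 30),
    z0=st.floats(-50.0, 50.0),
)
def test_equal_spacing_never_gaps(spacing, n_slices, z0):
    s = Structure(
        "s", 1, [square(10.0, z0 + i * spacing) for i in range(n_slices)]
    )
    assert not detect_gaps(s).has_gap


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    n_slices=st.integers(4, 25),
    hole=st.integers(1, 23),
    spacing=st.sampled_from([1.0, 2.0, 3.0]),
)
def test_single_deleted_interior_slice_always_found(n_slices, hole, spacing):
    hole = 1 + hole % (n_slices - 2)  # interior index
    zs = [i * spacing for i in range(n_slices) if i != hole]
    s = Structure("s", 1, [square(10.0, z) for z in zs])
    report = detect_gaps(s)
    assert report.missing_z == pytest.approx([hole * spacing])


def test_density_override_report_sorting_and_extremes():
    counter = iter(range(1, 100))

    def struct(name, override):
        return Structure(name, next(counter), [square(8.0, 0.0), square(8.0, 1.0)],
                         density_override=override)

    ss = StructureSet(
        PlanIdentity("A^B", "1", "P"),
        [
            struct("air_cavity", (0.0, 1)),
            struct("stent", (2.0, 2)),
            struct("plain", None),
        ],
    )
    rows = density_override_report(ss)
    assert [r["name"] for r in rows] == ["stent", "air_cavity"]  # priority desc
    assert rows[1]["extreme"] is True  # density 0.0 flagged
    assert rows[0]["extreme"] is False

    empty = StructureSet(PlanIdentity("A^B", "1", "P"), [struct("plain", None)])
    assert density_override_report(empty) == []
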