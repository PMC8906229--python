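"""Double-stack aperture conversion, areas, subsegments, effMU and alerts."""

import numpy as np
import pytest

from apart.model import Beam, MLCGeometry, MLCSegment, Plan, PlanIdentity, ValidationError
from apart.mlc_complexity import (
    aperture_area,
    combine_stacks,
    count_subsegments,
    effective_mu,
    mu_comparison,
    segment_stats,
    union_area,
)

from conftest import (
    mask_area_cm2,
    mask_components,
    random_segment,
    segment_pixel_mask,
)


def uniform_segment(mu, left, right, geometry):
    pairs = [(left, right)] * geometry.n_pairs
    return MLCSegment(mu=mu, stack_a=pairs, stack_b=list(pairs), geometry=geometry)


def banded_segment(mu, intervals_by_row, geometry):
    """Open the given x-interval on selected leaf pairs of both stacks."""
    def stack():
        return [intervals_by_row.get(i, (0.0, 0.0)) for i in range(geometry.n_pairs)]

    return MLCSegment(mu=mu, stack_a=stack(), stack_b=stack(), geometry=geometry)


class TestCombineStacks:
    def test_fully_open_stacks_give_fully_open_rows(self, small_geometry):
        aperture = combine_stacks(uniform_segment(10, -50.0, 50.0, small_geometry))
        assert all(r.open for r in aperture.rows)
        assert all(r.x_left == -50.0 and r.x_right == 50.0 for r in aperture.rows)
        # rows tile the covered field at half-leaf pitch without overlap
        heights = [r.height for r in aperture.rows]
        assert np.allclose(heights, small_geometry.stack_offset)
        for a, b in zip(aperture.rows, aperture.rows[1:]):
            assert a.y_high == pytest.approx(b.y_low)

    def test_row_interval_is_intersection(self, small_geometry):
        seg = uniform_segment(10, -10.0, 10.0, small_geometry)
        seg.stack_b = [(-5.0, 15.0)] * small_geometry.n_pairs
        aperture = combine_stacks(seg)
        assert all(
            (r.x_left, r.x_right) == (-5.0, 10.0) for r in aperture.rows if r.open
        )

    def test_disjoint_leaf_pairs_close_the_row(self, small_geometry):
        seg = uniform_segment(10, -10.0, -2.0, small_geometry)
        seg.stack_b = [(3.0, 10.0)] * small_geometry.n_pairs
        aperture = combine_stacks(seg)
        assert not any(r.open for r in aperture.rows)

    def test_symmetric_in_stack_order(self):
        geometry = MLCGeometry(n_pairs=10, leaf_width=8.3, stack_offset=0.0)
        rng = np.random.default_rng(5)
        for _ in range(10):
            seg = random_segment(rng, geometry)
            swapped = MLCSegment(
                mu=seg.mu, stack_a=seg.stack_b, stack_b=seg.stack_a,
                geometry=geometry,
            )
            rows = [(r.x_left, r.x_right) for r in combine_stacks(seg).rows]
            rows_swapped = [
                (r.x_left, r.x_right) for r in combine_stacks(swapped).rows
            ]
            assert rows == rows_swapped


class TestAreas:
    def test_single_open_row_area(self, small_geometry):
        aperture = combine_stacks(
            banded_segment(10, {4: (0.0, 10.0)}, small_geometry)
        )
        # a single opened pair of each stack overlaps in one half-leaf row
        assert aperture_area(aperture) == pytest.approx(0.415, abs=1e-9)

    def test_closed_aperture_zero_area(self, small_geometry):
        aperture = combine_stacks(uniform_segment(10, 0.0, 0.0, small_geometry))
        assert aperture_area(aperture) == 0.0

    def test_area_matches_rasterization_oracle(self, small_geometry):
        rng = np.random.default_rng(42)
        for _ in range(25):
            seg = random_segment(rng, small_geometry)
            mask, h, dx = segment_pixel_mask(seg)
            expected = mask_area_cm2(mask, h, dx)
            got = aperture_area(combine_stacks(seg))
            assert got == pytest.approx(expected, rel=0.005, abs=1e-6)


class TestSubsegments:
    def test_contiguous_opening_is_one(self, small_geometry):
        seg = banded_segment(10, {3: (-10.0, 10.0), 4: (-8.0, 12.0)}, small_geometry)
        assert count_subsegments(combine_stacks(seg)) == 1

    def test_row_gap_splits_components(self, small_geometry):
        seg = banded_segment(
            10, {2: (-10.0, 10.0), 6: (-10.0, 10.0)}, small_geometry
        )
        assert count_subsegments(combine_stacks(seg)) == 2

    def test_disjoint_intervals_on_adjacent_rows_split(self, small_geometry):
        seg = banded_segment(
            10, {3: (-10.0, -5.0), 4: (5.0, 10.0)}, small_geometry
        )
        # adjacent open rows but their x-intervals do not overlap
        assert count_subsegments(combine_stacks(seg)) >= 2

    def test_counts_match_flood_fill_oracle(self, small_geometry):
        rng = np.random.default_rng(99)
        for _ in range(25):
            seg = random_segment(rng, small_geometry)
            mask, _, _ = segment_pixel_mask(seg)
            assert count_subsegments(combine_stacks(seg)) == mask_components(mask)


class TestUnionArea:
    def test_single_segment_union_is_its_area(self, small_geometry):
        a = combine_stacks(uniform_segment(10, -20.0, 20.0, small_geometry))
        assert union_area([a]) == pytest.approx(aperture_area(a))

    def test_idempotent_for_identical_segments(self, small_geometry):
        a = combine_stacks(uniform_segment(10, -20.0, 20.0, small_geometry))
        b = combine_stacks(uniform_segment(20, -20.0, 20.0, small_geometry))
        assert union_area([a, b]) == pytest.approx(aperture_area(a))

    def test_row_disjoint_segments_add(self, small_geometry):
        a = combine_stacks(banded_segment(10, {2: (-10.0, 10.0)}, small_geometry))
        b = combine_stacks(banded_segment(10, {6: (-15.0, 5.0)}, small_geometry))
        assert union_area([a, b]) == pytest.approx(
            aperture_area(a) + aperture_area(b)
        )

    def test_monotone_in_segment_set(self, small_geometry):
        rng = np.random.default_rng(7)
        segs = [random_segment(rng, small_geometry) for _ in range(5)]
        apertures = [combine_stacks(s) for s in segs]
        areas = [union_area(apertures[: k + 1]) for k in range(5)]
        assert all(b >= a - 1e-12 for a, b in zip(areas, areas[1:]))

    def test_union_matches_rasterization_oracle(self, small_geometry):
        rng = np.random.default_rng(11)
        segs = [random_segment(rng, small_geometry) for _ in range(4)]
        masks = [segment_pixel_mask(s) for s in segs]
        combined = np.logical_or.reduce([m for m, _, _ in masks])
        expected = mask_area_cm2(combined, masks[0][1], masks[0][2])
        got = union_area([combine_stacks(s) for s in segs])
        assert got == pytest.approx(expected, rel=0.005, abs=1e-6)


class TestEffectiveMU:
    def test_single_segment_equals_its_mu(self, small_geometry):
        beam = Beam("b", [uniform_segment(100.0, -20.0, 20.0, small_geometry)])
        assert effective_mu(beam) == pytest.approx(100.0)

    def test_identical_segments_add(self, small_geometry):
        beam = Beam(
            "b",
            [
                uniform_segment(50.0, -20.0, 20.0, small_geometry),
                uniform_segment(50.0, -20.0, 20.0, small_geometry),
            ],
        )
        assert effective_mu(beam) == pytest.approx(100.0)

    def test_disjoint_equal_area_segments_halve(self, small_geometry):
        beam = Beam(
            "b",
            [
                banded_segment(50.0, {2: (-10.0, 10.0)}, small_geometry),
                banded_segment(50.0, {6: (-10.0, 10.0)}, small_geometry),
            ],
        )
        assert effective_mu(beam) == pytest.approx(50.0)

    def test_bounded_by_beam_mu(self, small_geometry):
        rng = np.random.default_rng(3)
        for _ in range(20):
            segs = [random_segment(rng, small_geometry) for _ in range(4)]
            beam = Beam("b", segs)
            eff = effective_mu(beam)
            if eff is None:
                continue
            assert eff <= beam.mu + 1e-9

    def test_closed_beam_undefined(self, small_geometry):
        beam = Beam("b", [uniform_segment(10.0, 0.0, 0.0, small_geometry)])
        assert effective_mu(beam) is None


def plan_of(segments, geometry):
    beams = [Beam("B1", segments)]
    return Plan(
        PlanIdentity("A^B", "1", "P"), beams, sum(s.mu for s in segments)
    )


class TestSegmentStats:
    def test_clean_plan_no_alerts(self, small_geometry):
        plan = plan_of(
            [uniform_segment(50.0, -20.0, 20.0, small_geometry) for _ in range(4)],
            small_geometry,
        )
        report, alerts = segment_stats(plan)
        assert report.frac_small_area == 0.0
        assert report.frac_low_mu == 0.0
        assert alerts == []

    def test_one_small_segment_in_five_weighs_ten(self, small_geometry):
        """20% of segments below 1 cm² -> formula weight 20 - 10 = 10."""
        small = banded_segment(302.6, {4: (0.0, 66.0 / 4.15)}, small_geometry)
        segs = [
            uniform_segment(50.0, -20.0, 20.0, small_geometry) for _ in range(4)
        ] + [small]
        report, alerts = segment_stats(plan_of(segs, small_geometry))
        assert report.frac_small_area == pytest.approx(20.0)
        assert report.min_area_segment[0] == pytest.approx(0.66, abs=1e-6)
        assert report.min_area_segment[1] == pytest.approx(302.6)
        assert [(a.code.value, a.weight) for a in alerts] == [
            ("SMALL_SEGMENTS", pytest.approx(10.0))
        ]

    def test_low_mu_fraction_above_five_percent_weighs_one(self, small_geometry):
        segs = [
            uniform_segment(40.0, -20.0, 20.0, small_geometry) for _ in range(7)
        ] + [uniform_segment(3.0, -20.0, 20.0, small_geometry)]
        report, alerts = segment_stats(plan_of(segs, small_geometry))
        assert report.frac_low_mu == pytest.approx(12.5)
        assert [(a.code.value, a.weight) for a in alerts] == [
            ("LOW_MU_SEGMENTS", 1.0)
        ]


class TestMUComparison:
    def mini_plan(self, total, small_geometry):
        return plan_of([uniform_segment(total, -20.0, 20.0, small_geometry)],
                       small_geometry)

    def test_ten_point_one_percent_increase(self, small_geometry):
        delta, alerts = mu_comparison(
            self.mini_plan(100.0, small_geometry),
            self.mini_plan(110.1, small_geometry),
        )
        assert delta == pytest.approx(10.1)
        assert [a.weight for a in alerts] == [pytest.approx(0.1)]

    def test_equal_totals_no_alert(self, small_geometry):
        delta, alerts = mu_comparison(
            self.mini_plan(150.0, small_geometry),
            self.mini_plan(150.0, small_geometry),
        )
        assert delta == 0.0 and alerts == []

    def test_decrease_uses_absolute_value(self, small_geometry):
        delta, alerts = mu_comparison(
            self.mini_plan(200.0, small_geometry),
            self.mini_plan(160.0, small_geometry),
        )
        assert delta == pytest.approx(-20.0)
        assert [a.weight for a in alerts] == [pytest.approx(10.0)]

    def test_zero_original_total_rejected(self, small_geometry):
        plan = plan_of([uniform_segment(0.0, -20.0, 20.0, small_geometry)],
                       small_geometry)
        with pytest.raises(ValidationError):
            mu_comparison(plan, self.mini_plan(100.0, small_geometry))
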