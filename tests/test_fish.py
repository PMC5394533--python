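"""FISH positive-cell calling, ROI counting, and area fractions."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon

from oracles import brute_force_calls, crossing_number_contains
from stressmyelin.fish import (
    FishField,
    InvalidRoiError,
    Roi,
    area_fraction,
    call_positive_cells,
    compare_groups,
    count_in_roi,
    square_roi,
    summarize_counts,
)
from stressmyelin.synthetic import gen_fish_field


def _field(nuclei_rows, spot_rows, roi=None, **kw):
    return FishField(
        nuclei=pd.DataFrame(nuclei_rows, columns=["x", "y", "eq_diameter"]),
        spots=pd.DataFrame(spot_rows, columns=["x", "y", "channel"]),
        roi=roi or square_roi("fmi", center=(0.0, 0.0)),
        **kw,
    )


def _random_field(rng, n_nuclei=60, n_spots=150, side=200.0):
    nuclei = pd.DataFrame(
        {
            "x": rng.uniform(0, side, n_nuclei),
            "y": rng.uniform(0, side, n_nuclei),
            "eq_diameter": rng.uniform(4, 12, n_nuclei),
        }
    )
    spots = pd.DataFrame(
        {
            "x": rng.uniform(0, side, n_spots),
            "y": rng.uniform(0, side, n_spots),
            "channel": rng.choice(["target", "control"], n_spots),
        }
    )
    return FishField(
        nuclei=nuclei, spots=spots, roi=Roi("custom", shapely.box(0, 0, side, side))
    )


class TestCallPositiveCells:
    def test_spot_at_nucleus_center_is_positive(self):
        f = _field([[0.0, 0.0, 8.0]], [[0.0, 0.0, "target"]])
        assert call_positive_cells(f).tolist() == [True]

    def test_vicinity_boundary_is_inclusive(self):
        # eq_diameter 10 -> calling disc radius 10: spot at exactly 10.0 is
        # positive, at 10.01 negative
        f = _field([[0.0, 0.0, 10.0]], [[10.0, 0.0, "target"]])
        assert call_positive_cells(f).tolist() == [True]
        f = _field([[0.0, 0.0, 10.0]], [[10.01, 0.0, "target"]])
        assert call_positive_cells(f).tolist() == [False]

    def test_wrong_channel_does_not_call(self):
        f = _field([[0.0, 0.0, 8.0]], [[0.0, 0.0, "control"]])
        assert call_positive_cells(f).tolist() == [False]
        assert call_positive_cells(f, channel="control").tolist() == [True]

    def test_empty_spot_list_all_negative(self):
        f = _field([[0.0, 0.0, 8.0], [5.0, 5.0, 6.0]], [])
        assert call_positive_cells(f).tolist() == [False, False]

    def test_one_spot_can_mark_several_nuclei(self):
        f = _field([[0.0, 0.0, 8.0], [3.0, 0.0, 8.0]], [[1.5, 0.0, "target"]])
        assert call_positive_cells(f).tolist() == [True, True]

    def test_matches_brute_force_oracle_on_random_fields(self, rng):
        for _ in range(20):
            f = _random_field(rng)
            fast = call_positive_cells(f)
            slow = brute_force_calls(f.nuclei, f.spots)
            assert (fast == slow).all()

    def test_invariant_under_rigid_translation(self, rng):
        f = _random_field(rng)
        shifted = FishField(
            nuclei=f.nuclei.assign(x=f.nuclei.x + 123.4, y=f.nuclei.y - 77.7),
            spots=f.spots.assign(x=f.spots.x + 123.4, y=f.spots.y - 77.7),
            roi=f.roi,
        )
        assert (call_positive_cells(f) == call_positive_cells(shifted)).all()

    def test_adding_spots_never_turns_calls_off(self, rng):
        f = _random_field(rng)
        base = call_positive_cells(f)
        extra = pd.concat(
            [f.spots, f.spots.assign(x=f.spots.x + 1.0)], ignore_index=True
        )
        denser = FishField(nuclei=f.nuclei, spots=extra, roi=f.roi)
        more = call_positive_cells(denser)
        assert (more | ~base).all()  # base implies more


class TestCountInRoi:
    def test_nucleus_on_roi_edge_is_counted(self):
        roi = Roi("custom", shapely.box(0, 0, 100, 100))
        f = _field([[0.0, 50.0, 8.0]], [[0.0, 50.0, "target"]], roi=roi)
        assert count_in_roi(f, call_positive_cells(f)) == 1

    def test_positive_cells_outside_roi_not_counted(self):
        roi = Roi("custom", shapely.box(0, 0, 10, 10))
        f = _field([[50.0, 50.0, 8.0]], [[50.0, 50.0, "target"]], roi=roi)
        assert count_in_roi(f, call_positive_cells(f)) == 0

    def test_membership_matches_crossing_number_oracle(self, rng):
        # non-convex polygon
        verts = [(0, 0), (100, 0), (100, 100), (50, 40), (0, 100)]
        poly = Polygon(verts)
        pts = rng.uniform(-10, 110, size=(1000, 2))
        ours = shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])
        theirs = np.array(
            [crossing_number_contains(verts, x, y, eps=1e-9) for x, y in pts]
        )
        assert (ours == theirs).all()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(InvalidRoiError):
            Roi("bad", Polygon([(0, 0), (1, 1), (2, 2)]))


class TestSummarizeCounts:
    def _fields_with_counts(self, counts, animal="a1", group="HC"):
        roi = Roi("custom", shapely.box(0, 0, 100, 100))
        fields = []
        for img, c in enumerate(counts, start=1):
            xy = [(5.0 + 3 * (i % 30), 5.0 + 5 * (i // 30)) for i in range(c)]
            nuclei = [[x, y, 8.0] for x, y in xy]
            spots = [[x, y, "target"] for x, y in xy]
            fields.append(
                _field(nuclei, spots, roi=roi, animal_id=animal, group=group,
                       image_index=img)
            )
        return fields

    def test_four_image_mean(self):
        out = summarize_counts(self._fields_with_counts([40, 44, 46, 50]))
        assert out["mean_count"].iloc[0] == 45.0
        assert out["n_images"].iloc[0] == 4

    def test_single_image_is_its_own_mean(self):
        out = summarize_counts(self._fields_with_counts([7]))
        assert out["mean_count"].iloc[0] == 7.0

    def test_no_fields_rejected(self):
        with pytest.raises(ValueError):
            summarize_counts([])

    def test_group_comparison_runs_on_animal_means(self):
        fields = []
        for i, c in enumerate([45, 44, 47]):
            fields += self._fields_with_counts([c, c], animal=f"hc{i}", group="HC")
        for i, c in enumerate([38, 40, 39]):
            fields += self._fields_with_counts([c, c], animal=f"cs{i}", group="CSD")
        res = compare_groups(summarize_counts(fields))
        assert res.df == 4  # n = animals per group, not images
        assert res.t < 0


class TestAreaFraction:
    def test_uniform_zero_image_is_zero_percent(self):
        img = np.zeros((700, 700))
        assert area_fraction(img, 1.0, (0, 0, 600), method="fixed:1") == 0.0

    def test_half_filled_binary_image_is_fifty_percent(self):
        img = np.zeros((600, 600))
        img[:300, :] = 1.0
        assert area_fraction(img, 1.0, (0, 0, 600), method="fixed:0.5") == 50.0

    def test_painted_fraction_recovered_within_one_point(self, rng):
        img = np.zeros((600, 600))
        mask = rng.random((600, 600)) < 0.237
        img[mask] = 100.0
        est = area_fraction(img, 1.0, (0, 0, 600), method="fixed:50")
        assert est == pytest.approx(100 * mask.mean(), abs=1.0)

    def test_otsu_separates_bimodal_blob(self, rng):
        img = rng.normal(10, 1, (600, 600))
        img[100:300, 100:300] += 200.0  # bright square blob, 1/9 of the box
        est = area_fraction(img, 1.0, (0, 0, 600), method="otsu")
        assert est == pytest.approx(100 * (200 * 200) / (600 * 600), abs=1.0)

    def test_box_outside_image_rejected(self):
        with pytest.raises(InvalidRoiError):
            area_fraction(np.zeros((100, 100)), 1.0, (0, 0, 600))

    def test_micron_box_maps_through_pixel_size(self):
        img = np.zeros((1200, 1200))
        img[:600, :] = 5.0  # with 0.5 um pixels the 600 um box is 1200 px
        est = area_fraction(img, 0.5, (0, 0, 600), method="fixed:1")
        assert est == 50.0


class TestControlChannelProperty:
    def test_control_positive_fractions_match_between_groups(self):
        # housekeeping-style channel: every cell is positive in both groups,
        # so group fractions differ by far less than 2 percentage points
        fields, _ = gen_fish_field(n_animals=2, n_images=2, seed=3)
        fracs = {"HC": [], "CSD": []}
        for f in fields:
            calls = call_positive_cells(f, channel="control")
            fracs[f.group].append(calls.mean())
        diff = abs(np.mean(fracs["HC"]) - np.mean(fracs["CSD"]))
        assert diff < 0.02
        assert np.mean(fracs["HC"]) > 0.99
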