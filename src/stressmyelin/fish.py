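"""FISH positive-cell calling and area-fraction quantification.

A cell (DAPI nucleus) counts as expressing a transcript when at least one
same-channel fluorescent spot lies in, or in close vicinity of, its nucleus
— operationalized as the closed disc of twice the nuclear equivalent
diameter, concentric with the nucleus (radius = eq_diameter for the default
disc factor of 2). Positive nuclei are counted inside a user-supplied ROI
polygon (nucleus-center membership, boundary inclusive), up to four images
per area are averaged per animal, and group inference runs on per-animal
means. Dense signals (housekeeping controls such as Ubc) are quantified as
the thresholded area fraction inside a consistently positioned square.

Coordinates are μm, origin top-left, y increasing downward; 16 μm sections
are treated as projected planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .inference import TTestResult, student_t_test

__all__ = [
    "Roi",
    "FishField",
    "InvalidRoiError",
    "square_roi",
    "call_positive_cells",
    "count_in_roi",
    "summarize_counts",
    "compare_groups",
    "area_fraction",
]

# Default square boxes (side in μm) from the quantification protocol.
DEFAULT_BOX_SIDES = {"fmi": 600.0, "M1": 700.0, "ubc": 600.0}


class InvalidRoiError(ValueError):
    pass


@dataclass
class Roi:
    """Named region of interest: a simple polygon in μm."""

    name: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise InvalidRoiError(f"ROI {self.name!r} is degenerate or self-intersecting")


def square_roi(name: str, side: float | None = None, center: tuple = (0.0, 0.0)) -> Roi:
    """Axis-aligned square ROI; side defaults by region name (fmi 600, M1 700)."""
    if side is None:
        side = DEFAULT_BOX_SIDES.get(name)
        if side is None:
            raise InvalidRoiError(f"no default box side for region {name!r}")
    cx, cy = center
    h = side / 2.0
    return Roi(name=name, polygon=shapely.box(cx - h, cy - h, cx + h, cy + h))


@dataclass
class FishField:
    """One imaged field: nuclei (x, y, eq_diameter), spots (x, y, channel),
    the ROI, and its provenance (animal, group, image index 1..4)."""

    nuclei: pd.DataFrame
    spots: pd.DataFrame
    roi: Roi
    animal_id: str = "a0"
    group: str = "HC"
    image_index: int = 1

    def __post_init__(self) -> None:
        if not 1 <= int(self.image_index) <= 4:
            raise ValueError("image_index must be 1..4")
        if (self.nuclei.get("eq_diameter", pd.Series(dtype=float)) <= 0).any():
            raise ValueError("nucleus eq_diameter must be > 0")


def call_positive_cells(
    field: FishField, channel: str = "target", disc_factor: float = 2.0
) -> np.ndarray:
    """Boolean per nucleus: positive iff ≥1 same-channel spot lies within the
    closed disc of diameter ``disc_factor`` × eq_diameter centered on the
    nucleus (boundary inclusive). A spot may mark several crowded nuclei."""
    nuclei = field.nuclei
    spots = field.spots[field.spots["channel"] == channel]
    if len(nuclei) == 0:
        return np.zeros(0, dtype=bool)
    if len(spots) == 0:
        return np.zeros(len(nuclei), dtype=bool)
    nxy = nuclei[["x", "y"]].to_numpy(float)
    sxy = spots[["x", "y"]].to_numpy(float)
    radius = disc_factor / 2.0 * nuclei["eq_diameter"].to_numpy(float)
    d2 = ((nxy[:, None, :] - sxy[None, :, :]) ** 2).sum(axis=2)
    return (d2 <= radius[:, None] ** 2).any(axis=1)


def count_in_roi(field: FishField, calls: np.ndarray) -> int:
    """Number of positive nuclei whose centers fall inside or on the
    boundary of the field's ROI polygon."""
    poly = field.roi.polygon
    if not poly.is_valid or poly.area <= 0:
        raise InvalidRoiError(f"ROI {field.roi.name!r} is degenerate")
    calls = np.asarray(calls, dtype=bool)
    if calls.shape[0] != len(field.nuclei):
        raise ValueError("calls length does not match nuclei")
    if not calls.any():
        return 0
    pos = field.nuclei.loc[calls]
    inside = shapely.intersects_xy(poly, pos["x"].to_numpy(float), pos["y"].to_numpy(float))
    return int(inside.sum())


def summarize_counts(
    fields: list[FishField], channel: str = "target", disc_factor: float = 2.0
) -> pd.DataFrame:
    """Per animal × region: mean positive-cell count over its images.

    Returns a DataFrame with columns animal_id, region, group, mean_count,
    n_images. Each animal contributes one value per region (the mean over
    the 1–4 images present); group tests then run on per-animal means.
    """
    if not fields:
        raise ValueError("no fields supplied")
    rows = []
    for f in fields:
        calls = call_positive_cells(f, channel=channel, disc_factor=disc_factor)
        rows.append(
            {
                "animal_id": f.animal_id,
                "region": f.roi.name,
                "group": f.group,
                "image_index": f.image_index,
                "count": count_in_roi(f, calls),
            }
        )
    per_image = pd.DataFrame(rows)
    dup = per_image.duplicated(subset=["animal_id", "region", "image_index"])
    if dup.any():
        raise ValueError("duplicate image_index for an animal/region")
    out = (
        per_image.groupby(["animal_id", "region", "group"], sort=False)["count"]
        .agg(mean_count="mean", n_images="size")
        .reset_index()
    )
    if (out["n_images"] > 4).any():
        raise ValueError("more than 4 images for an animal/region")
    return out


def compare_groups(summary: pd.DataFrame, region: str | None = None) -> TTestResult:
    """Student t-test of CSD vs HC on per-animal mean counts (n = animals)."""
    if region is not None:
        summary = summary[summary["region"] == region]
    a = summary.loc[summary["group"] == "CSD", "mean_count"].to_numpy(float)
    b = summary.loc[summary["group"] == "HC", "mean_count"].to_numpy(float)
    return student_t_test(a, b)


def area_fraction(
    image: np.ndarray,
    pixel_size: float,
    box: tuple = (0.0, 0.0, 600.0),
    method: str = "otsu",
) -> float:
    """Percent of pixels at or above threshold inside a square box.

    ``box`` is (x0, y0, side) in μm with (x0, y0) the top-left corner;
    ``method`` is "otsu" or "fixed:<value>". Returns a percentage in
    [0, 100]. The box must lie within the image bounds.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D intensity grid")
    x0, y0, side = box
    j0, j1 = int(round(x0 / pixel_size)), int(round((x0 + side) / pixel_size))
    i0, i1 = int(round(y0 / pixel_size)), int(round((y0 + side) / pixel_size))
    if i0 < 0 or j0 < 0 or i1 > image.shape[0] or j1 > image.shape[1] or i1 <= i0 or j1 <= j0:
        raise InvalidRoiError("box exceeds image bounds")
    patch = image[i0:i1, j0:j1]
    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(patch)
    elif method.startswith("fixed:"):
        thr = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return float(100.0 * (patch >= thr).mean())
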