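"""File formats and run configuration.

Text formats throughout: TSV for matrices and result tables, CSV for point
and Ct tables, JSON for ROIs, truth tables, and result bundles. Every
result JSON embeds the configuration hash so mixed-provenance outputs are
detectable by the report stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from .array_de import ExpressionMatrix
from .fish import Roi
from .stereology import FiberPhantom


class ParseError(ValueError):
    pass


# ------------------------------------------------------------------ expression


def read_expression_tsv(path, groups_path=None) -> ExpressionMatrix | pd.DataFrame:
    """Expression TSV: first column fragment id, header row of sample ids.

    With ``groups_path`` (CSV sample,group) an ExpressionMatrix is
    returned; otherwise the raw DataFrame.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df.index.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate fragment id {dup!r}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            frag = df.index[bad][0]
            raise ParseError(f"{path}: non-numeric value in column {col!r} at fragment {frag!r}")
        if numeric.isna().any():
            frag = df.index[numeric.isna()][0]
            raise ParseError(f"{path}: missing value in column {col!r} at fragment {frag!r}")
        df[col] = numeric
    if groups_path is None:
        return df
    return ExpressionMatrix(values=df, groups=read_group_map(groups_path))


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="fragment_id")


def read_group_map(path) -> pd.Series:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ParseError(f"{path}: expected columns sample,group")
    return df.set_index("sample")["group"]


def write_group_map(groups: pd.Series, path) -> None:
    groups.rename("group").rename_axis("sample").reset_index().to_csv(path, index=False)


def read_annotation(path) -> pd.Series:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["gene", "category"]:
        raise ParseError(f"{path}: expected columns gene,category")
    return df.set_index("gene")["category"]


def write_annotation(annotation: pd.Series, path) -> None:
    annotation.rename("category").rename_axis("gene").reset_index().to_csv(path, index=False)


# ------------------------------------------------------------------ qPCR / FISH


def read_ct_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample", "group", "gene", "replicate", "ct"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_points_csv(path) -> pd.DataFrame:
    """Nuclei or spot table; must carry x and y columns (μm)."""
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ParseError(f"{path}: expected x,y columns")
    return df


def read_roi_json(path) -> Roi:
    with open(path) as fh:
        obj = json.load(fh)
    if "vertices" not in obj:
        raise ParseError(f"{path}: ROI JSON needs a 'vertices' list")
    return Roi(name=obj.get("name", "custom"), polygon=Polygon(obj["vertices"]))


def write_roi_json(roi: Roi, path) -> None:
    verts = [list(xy) for xy in np.asarray(roi.polygon.exterior.coords)[:-1]]
    with open(path, "w") as fh:
        json.dump({"name": roi.name, "vertices": verts}, fh, indent=1)


# ------------------------------------------------------------------ phantoms


def read_phantom_csv(path) -> FiberPhantom:
    """Fiber polylines as (fiber_id, vertex_index, x, y, z) rows."""
    df = pd.read_csv(path)
    needed = {"fiber_id", "vertex_index", "x", "y", "z"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(needed)}")
    df = df.sort_values(["fiber_id", "vertex_index"], kind="mergesort")
    pts = df[["x", "y", "z"]].to_numpy(float)
    fid = df["fiber_id"].to_numpy()
    same = fid[1:] == fid[:-1]  # consecutive vertices of one polyline
    if not same.any():
        raise ParseError(f"{path}: no fiber segments")
    segments = np.stack([pts[:-1][same], pts[1:][same]], axis=1)
    length = float(np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1).sum())
    return FiberPhantom(segments=segments, true_total_length=length)


def write_phantom_csv(phantom: FiberPhantom, path) -> None:
    rows = []
    for fid, seg in enumerate(phantom.segments):
        rows.append({"fiber_id": fid, "vertex_index": 0, "x": seg[0, 0], "y": seg[0, 1], "z": seg[0, 2]})
        rows.append({"fiber_id": fid, "vertex_index": 1, "x": seg[1, 0], "y": seg[1, 1], "z": seg[1, 2]})
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------------ truth/json


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ------------------------------------------------------------------ run config


@dataclass
class RunConfig:
    """Pipeline configuration; every parameter is serialized into each
    results file for full provenance."""

    seed: int = 0
    out_dir: str = "results"
    # array stage inputs + parameters
    expression: str | None = None
    groups: str | None = None
    annotation: str | None = None
    fdr_alpha: float = 0.05
    fc_threshold: float = 1.20
    lowess_span: float = 0.05
    linearity_r2: float = 0.99
    window: int = 8
    grid_size: int = 40
    # qPCR
    ct: str | None = None
    reference_gene: str = "Gapdh"
    control_group: str = "HC"
    # FISH
    nuclei: str | None = None
    spots: str | None = None
    roi: str | None = None
    disc_factor: float = 2.0
    n_images: int = 4
    # stereology
    phantom: str | None = None
    phantom_roi: str | None = None  # falls back to `roi` when unset
    dx: float = 200.0
    dy: float = 100.0
    radius: float = 5.0
    guard: float = 2.0
    thickness: float = 16.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            obj = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**obj)
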