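"""Calibrated mask and table I/O.

A :class:`SegmentationMask` is the raw input of the whole pipeline: a binary
pixel grid (foreground = invasive melanoma, as produced by a two-class
segmentation network) together with its physical calibration in microns per
pixel.  Polygon annotations (GeoJSON, coordinates in mm) are an alternate
representation and can be rasterized to the same type.

All downstream geometry is done in millimetres; the calibration convention is
that pixel ``(i, j)`` (row, col) has its centre at physical coordinates
``((j + 0.5) * mpp_x / 1000, (i + 0.5) * mpp_y / 1000)`` mm, with y increasing
downward.  Anisotropic pixels (``mpp_x != mpp_y``) are supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import CalibrationError, MaskFormatError, SchemaError

__all__ = [
    "SegmentationMask",
    "RegionSet",
    "read_mask",
    "rasterize_regions",
    "write_morphometrics_table",
    "read_morphometrics_table",
    "read_cohort_table",
    "write_cohort_table",
]

#: TIFF resolution tags are trusted only inside this window (µm / pixel).
PLAUSIBLE_MPP = (0.1, 10.0)

#: Mandatory columns of a cohort table.
COHORT_REQUIRED = (
    "case_id",
    "time_os",
    "event_os",
    "time_mss",
    "event_mss",
    "age",
    "sex",
    "site",
)

#: Optional clinical columns kept when present.
COHORT_OPTIONAL = (
    "area",
    "perimeter",
    "major",
    "dbt",
    "ni",
    "breslow",
    "ajcc_stage",
    "subtype",
    "ulceration",
    "vascular_invasion",
    "mitotic_rate_ge1",
    "regression",
    "microsatellitosis",
    "perineural",
    "til_status",
    "braf",
)

_NUMERIC_COLS = ("time_os", "event_os", "time_mss", "event_mss", "age",
                 "area", "perimeter", "major", "dbt", "ni", "breslow")

#: Categorical levels treated as missing on read.
_MISSING_TOKENS = {"unknown", "not stated", "na", "n/a", ""}


@dataclass
class SegmentationMask:
    """Binary segmentation of one whole-slide image, with calibration.

    Parameters
    ----------
    pixels : ndarray of bool, shape (rows, cols)
        True where the pixel is invasive melanoma.
    mpp_x, mpp_y : float
        Microns per pixel along image x (columns) and y (rows); must be > 0.
    case_id : str
        Case identifier used to join against the cohort table.
    """

    pixels: np.ndarray
    mpp_x: float
    mpp_y: float
    case_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise MaskFormatError(
                f"mask must be a non-empty 2-D grid, got shape {self.pixels.shape}")
        self.pixels = self.pixels.astype(bool)
        for name, v in (("mpp_x", self.mpp_x), ("mpp_y", self.mpp_y)):
            if not np.isfinite(v) or v <= 0:
                raise CalibrationError(f"{name} must be positive, got {v!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    @property
    def pixel_area_mm2(self) -> float:
        """Physical area of one pixel in mm²."""
        return (self.mpp_x / 1000.0) * (self.mpp_y / 1000.0)


@dataclass
class RegionSet:
    """Polygon representation of the segmentation, in mm coordinates.

    ``polygons`` is a list of (outer_ring, holes) pairs; rings are sequences
    of (x, y) vertices in mm.  Closure is implicit: the last vertex is joined
    back to the first (a repeated closing vertex is tolerated and dropped).
    Outer rings must enclose positive area (counter-clockwise in the
    y-down convention used here is not enforced; |area| > 0 is).
    """

    case_id: str
    polygons: list = field(default_factory=list)


def read_mask(path: str | Path, mpp_x: float | None = None,
              mpp_y: float | None = None, case_id: str | None = None) -> SegmentationMask:
    """Read an 8-bit single-channel PNG/TIFF mask; any nonzero pixel is tumour.

    Calibration is taken from explicit arguments; for TIFFs, resolution tags
    are used when *both* are present and plausible (0.1–10 µm/px) and no
    explicit value is given.  Missing or non-positive calibration raises
    :class:`CalibrationError` naming the offending value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    if case_id is None:
        case_id = path.stem

    tag_x = tag_y = None
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            res_x = page.tags.get("XResolution")
            res_y = page.tags.get("YResolution")
            unit = page.tags.get("ResolutionUnit")
            if res_x is not None and res_y is not None and unit is not None:
                per_unit = {2: 25400.0, 3: 10000.0}.get(int(unit.value))  # inch / cm -> µm
                if per_unit is not None:
                    def _mpp(tag):
                        num, den = tag.value if isinstance(tag.value, tuple) else (tag.value, 1)
                        return per_unit * den / num if num else None
                    tag_x, tag_y = _mpp(res_x), _mpp(res_y)
                    ok = all(v is not None and PLAUSIBLE_MPP[0] <= v <= PLAUSIBLE_MPP[1]
                             for v in (tag_x, tag_y))
                    if not ok:
                        tag_x = tag_y = None
    else:
        with Image.open(path) as im:
            if im.mode not in ("L", "1", "P", "I", "I;16"):
                raise MaskFormatError(
                    f"{path.name}: expected a single-channel mask, got mode {im.mode!r}")
            arr = np.asarray(im.convert("I"))

    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise MaskFormatError(
            f"{path.name}: expected a single-channel mask, got shape {arr.shape}")

    mpp_x = mpp_x if mpp_x is not None else tag_x
    mpp_y = mpp_y if mpp_y is not None else tag_y
    if mpp_x is None or mpp_y is None:
        raise CalibrationError(
            f"{path.name}: no calibration supplied and no plausible TIFF resolution tags")
    return SegmentationMask(arr > 0, float(mpp_x), float(mpp_y), case_id)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a mask as 8-bit PNG (0/255) plus a calibration sidecar JSON."""
    path = Path(path)
    Image.fromarray(np.where(mask.pixels, 255, 0).astype(np.uint8), mode="L").save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"case_id": mask.case_id, "mpp_x": mask.mpp_x, "mpp_y": mask.mpp_y}))


def _ring_array(ring: Sequence[Sequence[float]]) -> np.ndarray:
    pts = np.asarray(ring, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise MaskFormatError(f"polygon ring needs >=3 (x, y) vertices, got {pts.shape}")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        raise MaskFormatError("polygon ring degenerate after dropping closing vertex")
    return pts


def read_regions_geojson(path: str | Path, case_id: str | None = None) -> RegionSet:
    """Read Polygon/MultiPolygon GeoJSON with coordinates in mm."""
    path = Path(path)
    obj = json.loads(path.read_text())
    geoms = []
    if obj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in obj["features"]]
    elif obj.get("type") == "Feature":
        geoms = [obj["geometry"]]
    else:
        geoms = [obj]
    polys = []
    for g in geoms:
        if g["type"] == "Polygon":
            rings = [g["coordinates"]]
        elif g["type"] == "MultiPolygon":
            rings = g["coordinates"]
        else:
            raise MaskFormatError(f"unsupported GeoJSON geometry {g['type']!r}")
        for poly in rings:
            outer = _ring_array(poly[0])
            holes = [_ring_array(h) for h in poly[1:]]
            polys.append((outer, holes))
    return RegionSet(case_id or path.stem, polys)


def rasterize_regions(regions: RegionSet, mpp_x: float, mpp_y: float) -> SegmentationMask:
    """Rasterize mm-space polygons onto a pixel grid.

    A pixel is foreground iff its centre lies inside an outer ring and outside
    that ring's holes.  The grid covers the regions' bounding box plus a
    1-pixel margin.
    """
    from shapely.geometry import Polygon as ShPolygon
    from shapely.ops import unary_union
    import shapely

    if mpp_x <= 0 or mpp_y <= 0:
        raise CalibrationError(f"mpp must be positive, got ({mpp_x}, {mpp_y})")
    if not regions.polygons:
        raise MaskFormatError("empty region set")
    shapes = []
    for outer, holes in regions.polygons:
        p = ShPolygon(_ring_array(outer), [_ring_array(h) for h in holes])
        if not p.is_valid:
            p = p.buffer(0)
        shapes.append(p)
    geom = unary_union(shapes)
    if geom.area <= 0:
        raise MaskFormatError("degenerate (zero-area) region set")

    sx, sy = mpp_x / 1000.0, mpp_y / 1000.0  # mm per pixel
    minx, miny, maxx, maxy = geom.bounds
    col0 = int(np.floor(minx / sx)) - 1
    row0 = int(np.floor(miny / sy)) - 1
    ncol = int(np.ceil(maxx / sx)) + 1 - col0 + 1
    nrow = int(np.ceil(maxy / sy)) + 1 - row0 + 1
    cols = (np.arange(ncol) + col0 + 0.5) * sx
    rows = (np.arange(nrow) + row0 + 0.5) * sy
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(nrow, ncol)
    return SegmentationMask(inside, mpp_x, mpp_y, regions.case_id)


# ---------------------------------------------------------------------------
# tables

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_morphometrics_table(records, path: str | Path) -> None:
    """Write per-case morphometrics as CSV/TSV.

    Lengths are rounded to 3 decimal places (mm / mm²), the nodularity index
    to 4; internal computation is full precision and only serialization rounds.
    """
    path = Path(path)
    rows = []
    for r in records:
        rows.append({
            "case_id": r.case_id,
            "area_mm2": round(r.area, 3),
            "perimeter_mm": round(r.perimeter, 3),
            "major_mm": round(r.major_axis, 3),
            "dbt_mm": round(r.minor_axis, 3),
            "ni": round(r.nodularity_index, 4),
            "n_components": r.n_components,
            "largest_fraction": round(r.largest_component_fraction, 4),
        })
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_morphometrics_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("case_id", "area_mm2", "perimeter_mm", "major_mm", "dbt_mm", "ni"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    return df


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a per-case cohort table (CSV/TSV) with survival endpoints.

    Mandatory columns: ``case_id, time_os, event_os, time_mss, event_mss,
    age, sex, site``.  Unknown categorical levels ("Unknown", "Not stated",
    "NA" ...) become missing values; the row is retained.  A non-numeric
    survival time raises :class:`SchemaError` with its row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"case_id": str})
    for col in COHORT_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    for col in df.columns:
        if df[col].dtype == object and col != "case_id":
            low = df[col].astype(str).str.strip().str.lower()
            df.loc[low.isin(_MISSING_TOKENS), col] = np.nan
    for col in _NUMERIC_COLS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if col.startswith(("time_", "event_")) and bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}")
        df[col] = coerced
    for col in ("time_os", "time_mss"):
        if (df[col].dropna() < 0).any():
            raise SchemaError(f"{path.name}: negative survival time in {col!r}")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)
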