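"""Regions of interest, cropping, density filtering and rasterization.

An ROI is either an axis-aligned rectangle or a simple polygon, in nm.
Channels belonging to one image are always cropped with the identical ROI,
and analyses that randomize molecular positions can refine a loose
user-drawn ROI down to the minimum bounding polygon of the molecules so
that randomization does not spread molecules over a larger area than they
truly occupy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import Point, Polygon, box

from .tables import LocalizationTable

__all__ = [
    "RegionOfInterest",
    "RasterImage",
    "crop_to_roi",
    "minimum_bounding_polygon",
    "density_filter",
    "rasterize",
    "raster_occupied_points",
]


class DegenerateGeometryError(ValueError):
    """Fewer than 3 non-collinear points, or an ROI without area."""


@dataclass
class RegionOfInterest:
    """A rectangle or simple polygon in nm.

    Construct with :meth:`rectangle` or :meth:`polygon`.  ``refined`` marks
    ROIs produced by :func:`minimum_bounding_polygon`.
    """

    shape: Polygon
    refined: bool = False

    @classmethod
    def rectangle(cls, xmin: float, ymin: float, xmax: float, ymax: float
                  ) -> "RegionOfInterest":
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("rectangle must have positive extent")
        return cls(shape=box(xmin, ymin, xmax, ymax))

    @classmethod
    def polygon(cls, vertices: Sequence[Sequence[float]],
                refined: bool = False) -> "RegionOfInterest":
        poly = Polygon(np.asarray(vertices, dtype=float))
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValueError("polygon must have positive area")
        return cls(shape=poly, refined=refined)

    @property
    def area(self) -> float:
        return float(self.shape.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return tuple(float(v) for v in self.shape.bounds)

    @property
    def is_rectangle(self) -> bool:
        return self.shape.equals(box(*self.shape.bounds))

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.shape.exterior.coords[:-1], dtype=float)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boundary-inclusive point-in-region test for an (n, 2) array."""
        xy = np.asarray(xy, dtype=float)
        if self.is_rectangle:
            xmin, ymin, xmax, ymax = self.bounds
            return ((xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
                    & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax))
        prepared = self.shape
        return np.array([prepared.covers(Point(p)) for p in xy], dtype=bool)

    def to_dict(self) -> dict:
        """JSON-serializable description (rectangle or vertex list)."""
        if self.is_rectangle:
            xmin, ymin, xmax, ymax = self.bounds
            return {"type": "rectangle",
                    "bounds": [xmin, ymin, xmax, ymax],
                    "refined": self.refined}
        return {"type": "polygon",
                "vertices": self.vertices.tolist(),
                "refined": self.refined}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionOfInterest":
        if d["type"] == "rectangle":
            roi = cls.rectangle(*d["bounds"])
        else:
            roi = cls.polygon(d["vertices"])
        roi.refined = bool(d.get("refined", False))
        return roi

    @classmethod
    def from_table(cls, table: LocalizationTable, pad: float = 0.0
                   ) -> "RegionOfInterest":
        """Bounding rectangle of a table's molecules, optionally padded."""
        xmin, ymin, xmax, ymax = table.bounds()
        return cls.rectangle(xmin - pad, ymin - pad, xmax + pad, ymax + pad)


@dataclass
class RasterImage:
    """Count-per-pixel rendering of a point set.

    ``grid[i, j]`` counts molecules in the half-open pixel
    ``[y0 + i*s, y0 + (i+1)*s) × [x0 + j*s, x0 + (j+1)*s)`` — row index is
    y, column index is x, matching image conventions.  Counts saturate at
    65535 (16-bit) with a warning.
    """

    pixel_size: float
    grid: np.ndarray
    origin: tuple[float, float]

    @property
    def total(self) -> int:
        return int(self.grid.sum())

    def to_tiff(self, path) -> str:
        import tifffile
        tifffile.imwrite(path, self.grid.astype(np.uint16))
        return str(path)


def raster_occupied_points(table: LocalizationTable,
                           roi: RegionOfInterest,
                           pixel_size: float = 20.0) -> LocalizationTable:
    """Binarize a point set onto a raster and return occupied-pixel centres.

    The raster-parity representation of a localization image: every pixel
    holding at least one molecule contributes one point at its centre.
    Repeat detections of one fluorophore collapse onto few pixels, which
    is what makes raster-based spatial statistics sensitive to
    oversampling where exact point statistics are not.
    """
    img = rasterize(table, pixel_size=pixel_size, roi=roi)
    iy, ix = np.nonzero(img.grid)
    x0, y0 = img.origin
    return LocalizationTable(
        x=x0 + (ix + 0.5) * pixel_size,
        y=y0 + (iy + 0.5) * pixel_size,
        channel_id=f"{table.channel_id}_raster",
    )


def crop_to_roi(tables: Sequence[LocalizationTable], roi: RegionOfInterest
                ) -> list[LocalizationTable]:
    """Crop 1–3 channels jointly with the identical ROI (boundary-inclusive).

    Emits a warning when a channel ends up empty.
    """
    if roi.area <= 0:
        raise ValueError("ROI must have positive area")
    out = []
    for t in tables:
        kept = t.subset(roi.contains(t.xy))
        if kept.n == 0:
            warnings.warn(
                f"ROI contains no molecules of channel {t.channel_id!r}",
                stacklevel=2)
        out.append(kept)
    return out


def minimum_bounding_polygon(table: LocalizationTable) -> RegionOfInterest:
    """Convex hull of the molecules, as a refined randomization region.

    Estimates the true area occupied by the labelled molecules so that
    Monte-Carlo randomization does not place points over a larger area than
    the molecules actually cover.  The convex hull is used as the polygon
    class: it is parameter-free and deterministic.  A concave (alpha-shape)
    refinement is a possible extension point.
    """
    if table.n < 3:
        raise DegenerateGeometryError("need at least 3 points")
    pts = table.xy
    try:
        hull = ConvexHull(pts)
    except Exception as exc:
        raise DegenerateGeometryError(f"degenerate geometry: {exc}") from exc
    return RegionOfInterest.polygon(pts[hull.vertices], refined=True)


def density_filter(table: LocalizationTable, k: int, max_knn_distance: float
                   ) -> LocalizationTable:
    """Remove molecules in low-density regions.

    Keeps exactly the molecules whose distance to their k-th nearest
    same-channel neighbour (excluding themselves) is ≤ ``max_knn_distance``.
    Filtering sparse background enhances subsequent analysis of clustered
    molecules.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.n <= k:
        raise ValueError("table must contain more than k molecules")
    tree = cKDTree(table.coords)
    # k+1 because the query returns the point itself at distance 0
    dist, _ = tree.query(table.coords, k=k + 1)
    return table.subset(dist[:, k] <= max_knn_distance)


def rasterize(table: LocalizationTable, pixel_size: float = 20.0,
              roi: Optional[RegionOfInterest] = None) -> RasterImage:
    """Bin molecules into a count-per-pixel grid (default 20 nm pixels).

    Bins are half-open ``[i*s, (i+1)*s)`` anchored at the ROI minimum
    corner; molecules exactly on the maximum edge fall into the last pixel,
    so the grid sum always equals the number of in-ROI molecules.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if roi is None:
        if table.n == 0:
            raise ValueError("cannot infer a raster extent from an empty table")
        roi = RegionOfInterest.from_table(table)
    xmin, ymin, xmax, ymax = roi.bounds
    nx = max(1, int(np.ceil((xmax - xmin) / pixel_size)))
    ny = max(1, int(np.ceil((ymax - ymin) / pixel_size)))
    inside = ((table.x >= xmin) & (table.x <= xmax)
              & (table.y >= ymin) & (table.y <= ymax))
    ix = np.floor((table.x[inside] - xmin) / pixel_size).astype(int)
    iy = np.floor((table.y[inside] - ymin) / pixel_size).astype(int)
    np.clip(ix, 0, nx - 1, out=ix)
    np.clip(iy, 0, ny - 1, out=iy)
    grid = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(grid, (iy, ix), 1)
    if grid.max(initial=0) > 65535:
        warnings.warn("pixel counts exceed 65535; 16-bit output will clip",
                      stacklevel=2)
    return RasterImage(pixel_size=float(pixel_size), grid=grid,
                       origin=(xmin, ymin))
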