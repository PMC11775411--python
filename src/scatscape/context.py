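"""Habitat context around scat points and wildland-urban interface rasters.

Three questions about each scat location: what land cover surrounds it
(class proportions within buffer radii chosen from carnivore home-range
sizes: 1000/1500/2000/3500/4500 m), how far it lies from the nearest
forest edge (signed: positive inside forest), and where in the landscape
forest co-occurs with agriculture and built-up land within a 150 m
neighborhood — the interface zones where carnivore-human encounters
concentrate.

Raster semantics throughout: a cell belongs to a circle iff its center
does (inclusive boundary), which keeps every operation exactly
reproducible by brute-force cell enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import ttest_ind

from .landscape import circular_mask
from .raster import CategoricalRaster

BUFFER_RADII = (1000.0, 1500.0, 2000.0, 3500.0, 4500.0)
MAJOR_CLASSES = ("forest", "agriculture", "built_up")


def buffer_composition(
    r: CategoricalRaster,
    points: pd.DataFrame,
    radii: tuple[float, ...] = BUFFER_RADII,
    classes: tuple[str, ...] = MAJOR_CLASSES,
) -> pd.DataFrame:
    """Land-cover proportions within circular buffers around each point.

    ``points`` is indexed by point id with columns x, y. Proportions are
    class cells over all non-nodata cells in the circle; the reported
    classes need not sum to 1 (other classes exist). Buffers reaching past
    the raster edge use the available cells and emit a truncation warning.
    """
    xmin, xmax, ymin, ymax = r.extent
    rows = []
    for pid, pt in points.iterrows():
        for radius in radii:
            if radius <= 0:
                raise ValueError("buffer radii must be positive")
            if (pt["x"] - radius < xmin or pt["x"] + radius > xmax
                    or pt["y"] - radius < ymin or pt["y"] + radius > ymax):
                warnings.warn(
                    f"buffer r={radius:g} around point {pid} truncated at "
                    "the raster edge")
            mask = circular_mask(r, pt["x"], pt["y"], radius) & r.valid_mask()
            total = int(mask.sum())
            for cls in classes:
                code = r.code_of(cls)
                prop = (np.nan if total == 0
                        else float((r.data[mask] == code).sum()) / total)
                rows.append({"point": pid, "radius": radius,
                             "class": cls, "proportion": prop})
    return pd.DataFrame(rows)


def _forest_edge_segments(
    r: CategoricalRaster, forest: int
) -> list[tuple[float, float, float, float]]:
    """Cell-face segments (x0, y0, x1, y1) between forest and other classes.

    Faces against nodata or the raster border are not edges: the boundary
    sought is between forest and another mapped land-use type.
    """
    nr, nc = r.shape
    is_f = (r.data == forest) & r.valid_mask()
    other = (~(r.data == forest)) & r.valid_mask()
    c = r.cell_size
    segs: list[tuple[float, float, float, float]] = []
    # vertical faces between horizontally adjacent cells
    vert = (is_f[:, :-1] & other[:, 1:]) | (other[:, :-1] & is_f[:, 1:])
    for i, j in np.argwhere(vert):
        x = r.xll + (j + 1) * c
        y0 = r.yll + (nr - i - 1) * c
        segs.append((x, y0, x, y0 + c))
    # horizontal faces between vertically adjacent cells
    horiz = (is_f[:-1, :] & other[1:, :]) | (other[:-1, :] & is_f[1:, :])
    for i, j in np.argwhere(horiz):
        y = r.yll + (nr - i - 1) * c
        x0 = r.xll + j * c
        segs.append((x0, y, x0 + c, y))
    return segs


def _point_segment_distance(px, py, x0, y0, x1, y1) -> float:
    dx, dy = x1 - x0, y1 - y0
    t = ((px - x0) * dx + (py - y0) * dy) / (dx * dx + dy * dy)
    t = min(1.0, max(0.0, t))
    return float(np.hypot(px - (x0 + t * dx), py - (y0 + t * dy)))


def distance_to_forest_edge(
    r: CategoricalRaster,
    x: float,
    y: float,
    forest: int | str = "forest",
) -> float:
    """Signed distance (m) from a point to the nearest forest edge.

    Positive inside forest, negative outside; 0 exactly on an edge face.
    NaN (with a warning) when the raster contains no forest/other boundary.
    """
    code = r.code_of(forest)
    segs = _forest_edge_segments(r, code)
    if not segs:
        warnings.warn("raster has no forest edge (no forest, or all forest)")
        return float("nan")
    d = min(_point_segment_distance(x, y, *s) for s in segs)
    if d == 0.0:
        return 0.0
    row, col = r.cell_at(x, y)
    inside = r.data[row, col] == code
    return d if inside else -d


# ---------------------------------------------------------------------------
# interface (wildland-urban) rasters
# ---------------------------------------------------------------------------

@dataclass
class InterfaceRaster:
    """Binary interface grids with their areas and landscape shares."""

    focal: dict[str, np.ndarray]  # per-class focal presence
    fa: np.ndarray  # forest-agriculture interface
    fb: np.ndarray  # forest-built-up interface
    fab: np.ndarray  # forest-agriculture-built-up interface
    areas_ha: dict[str, float]
    percent: dict[str, float]


def _disk_footprint(radius: float, cell_size: float) -> np.ndarray:
    k = int(np.floor(radius / cell_size))
    off = np.arange(-k, k + 1)
    dr, dc = np.meshgrid(off, off, indexing="ij")
    return (dr ** 2 + dc ** 2) * cell_size ** 2 <= radius ** 2


def focal_presence(
    r: CategoricalRaster, cls: int | str, radius: float
) -> np.ndarray:
    """1 where the class occurs at any cell center within ``radius``."""
    code = r.code_of(cls)
    binary = (r.data == code) & r.valid_mask()
    return ndimage.binary_dilation(binary, structure=_disk_footprint(
        radius, r.cell_size))


def interface_rasters(
    r: CategoricalRaster,
    radius: float = 150.0,
    classes: tuple[str, str, str] = MAJOR_CLASSES,
) -> InterfaceRaster:
    """Forest-agriculture, forest-built-up and combined interface layers.

    Each class's binary layer is turned into a focal-presence layer over a
    circular neighborhood, and the interfaces are the cellwise products
    (intersections): FA = forest x agriculture, FB = forest x built-up,
    FAB = FA x FB.
    """
    if radius < r.cell_size:
        raise ValueError("focal radius must be at least one cell")
    forest_cls, agri_cls, built_cls = classes
    focal = {c: focal_presence(r, c, radius) for c in classes}
    fa = focal[forest_cls] & focal[agri_cls]
    fb = focal[forest_cls] & focal[built_cls]
    fab = fa & fb
    valid = r.valid_mask()
    cell_ha = r.cell_size ** 2 / 1e4
    landscape_ha = float(valid.sum()) * cell_ha
    areas = {name: float((grid & valid).sum()) * cell_ha
             for name, grid in (("FA", fa), ("FB", fb), ("FAB", fab))}
    percent = {k: (100.0 * v / landscape_ha if landscape_ha else np.nan)
               for k, v in areas.items()}
    return InterfaceRaster(focal=focal, fa=fa, fb=fb, fab=fab,
                           areas_ha=areas, percent=percent)


# ---------------------------------------------------------------------------
# cattle vs non-cattle scat context
# ---------------------------------------------------------------------------

def cattle_context_comparison(
    r: CategoricalRaster,
    points: pd.DataFrame,
    radius: float = 1000.0,
    classes: tuple[str, ...] = MAJOR_CLASSES,
) -> pd.DataFrame:
    """Compare land cover around scats with vs without cattle in the diet.

    ``points`` needs columns x, y and a boolean ``contains_cattle``. Per
    class: mean percent cover within ``radius`` for each group, their
    difference, and a Welch two-sample t-test (p is NaN when either group
    has < 2 points or both groups are constant).
    """
    comp = buffer_composition(r, points, radii=(radius,), classes=classes)
    comp = comp.merge(points["contains_cattle"], left_on="point",
                      right_index=True)
    rows = []
    for cls, grp in comp.groupby("class", sort=False):
        with_c = grp.loc[grp["contains_cattle"], "proportion"] * 100
        without = grp.loc[~grp["contains_cattle"], "proportion"] * 100
        if len(with_c) >= 2 and len(without) >= 2 and (
                with_c.var() > 0 or without.var() > 0):
            stat, p = ttest_ind(with_c, without, equal_var=False)
        else:
            stat, p = np.nan, np.nan
        rows.append({
            "class": cls,
            "mean_with_cattle": with_c.mean(),
            "mean_without_cattle": without.mean(),
            "difference": with_c.mean() - without.mean(),
            "t": stat, "p": p,
            "n_with": len(with_c), "n_without": len(without),
        })
    return pd.DataFrame(rows).set_index("class")
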