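"""Class-level forest-fragmentation metrics and the median-rank classifier.

Patches are maximal 8-connected components of one land-cover class. Six
class metrics, computed per analysis unit (whole raster, named masks, or
circular buffers around points):

PD   patch density, patches per 100 ha of the unit
ED   edge density, m of class edge per ha
MPA  mean patch area, ha
MSI  mean shape index, mean over patches of 0.25 * perimeter / sqrt(area)
     (1 for a square, larger for irregular shapes)
MCA  mean core area, ha; a core cell's center lies more than the edge
     depth (default 100 m) from every cell center outside its patch
ENN  mean Euclidean nearest-neighbor distance between same-class patches,
     center-to-center between their boundary cells (missing if < 2 patches)

Perimeter counts every cell face adjacent to a different class, nodata, or
the raster/unit boundary, so clipped analysis units have closed outlines.

Units are then ranked per metric in the direction of increasing
fragmentation (PD, ED, MSI, ENN ascending; MPA and MCA inverted, since
smaller patches and cores mean more fragmentation), the median of the six
ranks is taken, and units are split into low / moderate / high
fragmentation tertiles of the median rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .raster import CategoricalRaster

EIGHT = np.ones((3, 3), dtype=int)
METRICS = ("PD", "ED", "MPA", "MSI", "MCA", "ENN")
#: metrics where a LARGER value means MORE fragmentation
_ASCENDING = {"PD": True, "ED": True, "MPA": False,
              "MSI": True, "MCA": False, "ENN": True}


@dataclass
class PatchSet:
    """Labeled patches of one class: label image plus a per-patch table."""

    cls_code: int
    labels: np.ndarray  # 0 = background
    cell_size: float
    table: pd.DataFrame  # index patch_id; n_cells, area_m2, perimeter_m

    @property
    def n_patches(self) -> int:
        return len(self.table)


def _face_counts(labels: np.ndarray) -> np.ndarray:
    """Per-label count of cell faces against anything not in the label."""
    n = int(labels.max())
    padded = np.pad(labels, 1)
    faces = np.zeros(n + 1, dtype=int)
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor = np.roll(padded, shift, axis=ax)
        mask = (padded > 0) & (padded != neighbor)
        faces += np.bincount(padded[mask], minlength=n + 1)
    return faces


def delineate_patches(r: CategoricalRaster, cls: int | str) -> PatchSet:
    """8-connected patches of one class with cell counts and perimeters."""
    code = r.code_of(cls)
    mask = (r.data == code) & r.valid_mask()
    labels, n = ndimage.label(mask, structure=EIGHT)
    cells = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    faces = _face_counts(labels)[1:]
    table = pd.DataFrame({
        "n_cells": cells.astype(int),
        "area_m2": cells * r.cell_size ** 2,
        "perimeter_m": faces * r.cell_size,
    }, index=pd.RangeIndex(1, n + 1, name="patch_id"))
    return PatchSet(code, labels, r.cell_size, table)


def core_cell_count(ps: PatchSet, patch_id: int, edge_depth: float) -> int:
    """Cells whose center is > edge_depth from every center outside the patch."""
    mask = ps.labels == patch_id
    if mask.all():
        return int(mask.sum())  # no outside cells exist in the raster
    dist = ndimage.distance_transform_edt(mask, sampling=ps.cell_size)
    return int((dist > edge_depth).sum())


def _boundary_cells(mask: np.ndarray) -> np.ndarray:
    """Row/col indices of cells on the mask's edge (incl. raster border)."""
    interior = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~interior)


def nearest_neighbor_distances(ps: PatchSet) -> pd.Series:
    """Per patch: min center-to-center distance to the nearest other patch."""
    ids = list(ps.table.index)
    if len(ids) < 2:
        return pd.Series(np.nan, index=ps.table.index, name="enn_m")
    pts = {pid: _boundary_cells(ps.labels == pid) * ps.cell_size
           for pid in ids}
    out = pd.Series(np.inf, index=ps.table.index, name="enn_m")
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = float(cdist(pts[a], pts[b]).min())
            if d < out[a]:
                out[a] = d
            if d < out[b]:
                out[b] = d
    return out


def class_metrics(
    ps: PatchSet,
    landscape_area_ha: float,
    edge_depth: float = 100.0,
) -> pd.Series:
    """The six class metrics for one analysis unit (NaN where undefined)."""
    if landscape_area_ha <= 0:
        raise ValueError("landscape_area_ha must be positive")
    if ps.n_patches == 0:
        return pd.Series(np.nan, index=list(METRICS))
    areas_ha = ps.table["area_m2"] / 1e4
    perims = ps.table["perimeter_m"]
    core_ha = pd.Series(
        [core_cell_count(ps, pid, edge_depth) * ps.cell_size ** 2 / 1e4
         for pid in ps.table.index], index=ps.table.index)
    msi = 0.25 * perims / np.sqrt(ps.table["area_m2"])
    enn = nearest_neighbor_distances(ps)
    return pd.Series({
        "PD": ps.n_patches / landscape_area_ha * 100.0,
        "ED": float(perims.sum()) / landscape_area_ha,
        "MPA": float(areas_ha.mean()),
        "MSI": float(msi.mean()),
        "MCA": float(core_ha.mean()),
        "ENN": float(enn.mean()) if ps.n_patches >= 2 else np.nan,
    })


# ---------------------------------------------------------------------------
# analysis units / scales
# ---------------------------------------------------------------------------

def circular_mask(r: CategoricalRaster, x: float, y: float,
                  radius: float) -> np.ndarray:
    """Cells whose center lies within ``radius`` of planar point (x, y)."""
    cx, cy = r.cell_centers()
    return (cx - x) ** 2 + (cy - y) ** 2 <= radius ** 2


def clip_raster(r: CategoricalRaster, mask: np.ndarray) -> CategoricalRaster:
    """Raster restricted to a unit: outside cells become nodata."""
    data = np.where(mask, r.data, r.nodata)
    return CategoricalRaster(data=data, cell_size=r.cell_size, xll=r.xll,
                             yll=r.yll, nodata=r.nodata, legend=dict(r.legend))


def metrics_at_scales(
    r: CategoricalRaster,
    cls: int | str,
    units: dict[str, np.ndarray] | None = None,
    points: pd.DataFrame | None = None,
    buffer_radius: float = 1000.0,
    edge_depth: float = 100.0,
) -> pd.DataFrame:
    """Class metrics per analysis unit.

    Units may be named boolean masks and/or point buffers (``points`` needs
    columns x, y; each point becomes a circular unit of ``buffer_radius``).
    With neither given, the single unit is the whole raster. The landscape
    area of a unit is its non-nodata cell area inside the raster.
    """
    all_units: dict[str, np.ndarray] = {}
    if units:
        all_units.update(units)
    if points is not None:
        for pid, row in points.iterrows():
            all_units[str(pid)] = circular_mask(r, row["x"], row["y"],
                                                buffer_radius)
    if not all_units:
        all_units["whole"] = np.ones(r.shape, dtype=bool)

    rows = {}
    for name, mask in all_units.items():
        area_ha = float((mask & r.valid_mask()).sum()) * r.cell_size ** 2 / 1e4
        if area_ha == 0:
            rows[name] = pd.Series(np.nan, index=list(METRICS))
            continue
        clipped = clip_raster(r, mask)
        ps = delineate_patches(clipped, cls)
        rows[name] = class_metrics(ps, area_ha, edge_depth=edge_depth)
    out = pd.DataFrame(rows).T
    out.index.name = "unit"
    return out


# ---------------------------------------------------------------------------
# median-rank fragmentation classifier
# ---------------------------------------------------------------------------

def fragmentation_ranks(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-metric fragmentation ranks (average ranks on ties, NaN kept)."""
    ranks = {}
    for m in METRICS:
        v = rows[m].to_numpy(dtype=float)
        if not _ASCENDING[m]:
            v = -v
        ranks[m] = rankdata(v, method="average", nan_policy="omit")
    return pd.DataFrame(ranks, index=rows.index)


def classify_fragmentation(rows: pd.DataFrame) -> pd.DataFrame:
    """Median-rank classification of units into low/moderate/high.

    Each unit's six metric ranks are reduced to their median (ignoring
    missing metrics); units are split into equal-count tertiles of the
    median rank, with tied medians kept together in the lower class.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 units to classify")
    ranks = fragmentation_ranks(rows)
    median = ranks.median(axis=1, skipna=True)
    med = median.to_numpy()
    labels = np.empty(len(rows), dtype=object)
    if len(np.unique(med[~np.isnan(med)])) <= 1:
        # fully degenerate: no gradient to split on
        labels[:] = "moderate"
    else:
        order = np.argsort(med, kind="stable")
        classes = ("low", "moderate", "high")
        for gi, grp in enumerate(np.array_split(order, 3)):
            labels[grp] = classes[gi]
        # ties spanning a tertile boundary all take the lower class
        rank_of = {"low": 0, "moderate": 1, "high": 2}
        for value in np.unique(med[~np.isnan(med)]):
            tied = np.where(med == value)[0]
            if len(tied) > 1:
                lowest = min(labels[tied], key=lambda c: rank_of[c])
                labels[tied] = lowest
    out = ranks.copy()
    out["median_rank"] = median
    out["frag_class"] = labels
    return out
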