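"""Independent brute-force re-implementations used as test oracles.

Everything here is written with plain Python loops and explicit
enumeration — deliberately naive, sharing no code path with the package —
so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math
from collections import deque


# ---------------------------------------------------------------------------
# patch delineation and class metrics
# ---------------------------------------------------------------------------

def flood_fill_patches(grid, cls, nodata=-9999):
    """8-connected components of one class as lists of (row, col) sets."""
    nr, nc = len(grid), len(grid[0])
    seen = set()
    patches = []
    for i in range(nr):
        for j in range(nc):
            if grid[i][j] != cls or grid[i][j] == nodata or (i, j) in seen:
                continue
            comp = set()
            queue = deque([(i, j)])
            seen.add((i, j))
            while queue:
                a, b = queue.popleft()
                comp.add((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        na, nb = a + da, b + db
                        if (0 <= na < nr and 0 <= nb < nc
                                and (na, nb) not in seen
                                and grid[na][nb] == cls):
                            seen.add((na, nb))
                            queue.append((na, nb))
            patches.append(comp)
    return patches


def patch_perimeter(cells, grid_shape):
    """Cell-face count between the patch and anything else (incl. border)."""
    nr, nc = grid_shape
    faces = 0
    for (i, j) in cells:
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if not (0 <= ni < nr and 0 <= nj < nc) or (ni, nj) not in cells:
                faces += 1
    return faces


def patch_core_cells(cells, grid_shape, cell_size, edge_depth):
    """Cells whose center is > edge_depth from every in-raster center
    outside the patch, by exhaustive pairwise distances."""
    nr, nc = grid_shape
    outside = [(i, j) for i in range(nr) for j in range(nc)
               if (i, j) not in cells]
    if not outside:
        return set(cells)
    core = set()
    for (i, j) in cells:
        dmin = min(math.hypot(i - a, j - b) for a, b in outside) * cell_size
        if dmin > edge_depth:
            core.add((i, j))
    return core


def enn_distances(patches, cell_size):
    """Per patch: min center-to-center distance to any other patch's cells."""
    out = []
    for i, p in enumerate(patches):
        best = math.inf
        for k, q in enumerate(patches):
            if k == i:
                continue
            for (a, b) in p:
                for (c, d) in q:
                    dist = math.hypot(a - c, b - d) * cell_size
                    if dist < best:
                        best = dist
        out.append(best)
    return out


def class_metrics(grid, cls, cell_size, landscape_area_ha, edge_depth=100.0,
                  nodata=-9999):
    """All six class metrics by exhaustive enumeration. NaN where undefined."""
    nan = float("nan")
    shape = (len(grid), len(grid[0]))
    patches = flood_fill_patches(grid, cls, nodata)
    if not patches:
        return dict(PD=nan, ED=nan, MPA=nan, MSI=nan, MCA=nan, ENN=nan)
    areas = [len(p) * cell_size ** 2 for p in patches]
    perims = [patch_perimeter(p, shape) * cell_size for p in patches]
    cores = [len(patch_core_cells(p, shape, cell_size, edge_depth))
             * cell_size ** 2 for p in patches]
    msi = [0.25 * pr / math.sqrt(a) for pr, a in zip(perims, areas)]
    n = len(patches)
    enn = (sum(enn_distances(patches, cell_size)) / n if n >= 2 else nan)
    return {
        "PD": n / landscape_area_ha * 100.0,
        "ED": sum(perims) / landscape_area_ha,
        "MPA": sum(areas) / n / 1e4,
        "MSI": sum(msi) / n,
        "MCA": sum(cores) / n / 1e4,
        "ENN": enn,
    }


# ---------------------------------------------------------------------------
# median-rank classifier
# ---------------------------------------------------------------------------

def _avg_ranks(values):
    """Average ranks (1-based) of a list, ties averaged, None skipped."""
    idx = [i for i, v in enumerate(values) if v is not None]
    ranks = [None] * len(values)
    ordered = sorted(idx, key=lambda i: values[i])
    k = 0
    while k < len(ordered):
        m = k
        while (m + 1 < len(ordered)
               and values[ordered[m + 1]] == values[ordered[k]]):
            m += 1
        avg = (k + m) / 2 + 1
        for t in range(k, m + 1):
            ranks[ordered[t]] = avg
        k = m + 1
    return ranks


def median_rank_classes(metric_rows):
    """(ranks, medians, classes) for a list of {metric: value} dicts.

    Fragmentation direction: PD, ED, MSI, ENN as-is; MPA, MCA negated.
    Classes: equal-count tertiles of the median rank, ties to the lower
    class; all-tied medians degenerate to 'moderate'.
    """
    inverted = {"MPA", "MCA"}
    metrics = ["PD", "ED", "MPA", "MSI", "MCA", "ENN"]
    per_metric = {}
    for m in metrics:
        vals = []
        for row in metric_rows:
            v = row.get(m)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                vals.append(None)
            else:
                vals.append(-v if m in inverted else v)
        per_metric[m] = _avg_ranks(vals)
    medians = []
    for i in range(len(metric_rows)):
        rs = sorted(r[i] for r in per_metric.values() if r[i] is not None)
        k = len(rs)
        medians.append((rs[k // 2] if k % 2 else
                        (rs[k // 2 - 1] + rs[k // 2]) / 2) if k else None)
    uniq = sorted({m for m in medians if m is not None})
    n = len(metric_rows)
    if len(uniq) <= 1:
        classes = ["moderate"] * n
    else:
        order = sorted(range(n), key=lambda i: (medians[i], i))
        sizes = [(n + 2) // 3, (n + 1) // 3, n // 3]
        classes = [None] * n
        pos = 0
        for label, size in zip(("low", "moderate", "high"), sizes):
            for i in order[pos:pos + size]:
                classes[i] = label
            pos += size
        for value in uniq:
            tied = [i for i in range(n) if medians[i] == value]
            if len(tied) > 1:
                lowest = min((classes[i] for i in tied),
                             key=["low", "moderate", "high"].index)
                for i in tied:
                    classes[i] = lowest
    return per_metric, medians, classes


# ---------------------------------------------------------------------------
# focal / buffer raster operations
# ---------------------------------------------------------------------------

def focal_presence(grid, cls, radius, cell_size, nodata=-9999):
    """Per cell: does the class occur at any cell center within radius?"""
    nr, nc = len(grid), len(grid[0])
    out = [[False] * nc for _ in range(nr)]
    targets = [(i, j) for i in range(nr) for j in range(nc)
               if grid[i][j] == cls]
    for i in range(nr):
        for j in range(nc):
            for (a, b) in targets:
                if math.hypot(i - a, j - b) * cell_size <= radius:
                    out[i][j] = True
                    break
    return out


def circle_cells(nr, nc, cell_size, xll, yll, x, y, radius):
    """Cells whose center lies within radius of point (x, y)."""
    cells = set()
    for i in range(nr):
        for j in range(nc):
            cx = xll + (j + 0.5) * cell_size
            cy = yll + (nr - i - 0.5) * cell_size
            if math.hypot(cx - x, cy - y) <= radius:
                cells.add((i, j))
    return cells


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

def filter_chain_presence(counts, control_row, taxon_of, threshold=0.01):
    """Presence dict-of-dicts by direct rule application.

    ``counts``: {sample: {otu: reads}}; ``control_row``: {otu: reads};
    ``taxon_of``: {otu: taxon label or None for OTUs to discard}.
    """
    t = max(control_row.values()) if control_row else 0
    presence = {}
    for sample, row in counts.items():
        pooled = {}
        for otu, reads in row.items():
            if reads <= t:
                continue
            taxon = taxon_of.get(otu)
            if taxon is None:
                continue
            pooled[taxon] = pooled.get(taxon, 0) + reads
        total = sum(pooled.values())
        presence[sample] = {tax: (total > 0 and reads / total > threshold)
                            for tax, reads in pooled.items()}
    return presence
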