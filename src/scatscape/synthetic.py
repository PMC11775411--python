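"""Deterministic synthetic inputs for every pipeline stage.

Three families of generators:

* diet fixtures reconstructed from the published leopard / leopard-cat
  diet-composition tables (percent occurrence and frequency of occurrence
  with known totals N = 37 and N = 76), turned into occurrence counts and a
  randomized presence matrix;
* scat metabarcoding simulators: multinomial read counts over each scat's
  true prey taxa plus sub-threshold contaminant OTUs and a leaky negative
  control, and BLAST-style hit tables with a controllable discordant
  fraction;
* categorical land-cover rasters with known patch geometry (ground-truth
  inventory) for oracle-testing the fragmentation metrics.

Everything is driven by explicit seeds: same seed, same output.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up
from .filters import RANKS, CountTable
from .raster import CategoricalRaster

PREDATOR_SPECIES = {
    "leopard": "Panthera pardus",
    "leopardcat": "Prionailurus bengalensis",
}

#: per-fixture totals: (scats genotyped, total prey items)
FIXTURE_TOTALS = {"leopard": (20, 37), "leopardcat": (26, 76)}

_GROUP_CLASS = {
    "ungulate": "Mammalia", "carnivore": "Mammalia", "primate": "Mammalia",
    "rodent": "Mammalia", "shrew": "Mammalia", "bird": "Aves",
    "fish": "Actinopteri",
}

DEFAULT_LEGEND = {
    "forest": 1, "agriculture": 2, "built_up": 3, "other": 4, "water": 5,
}


@dataclass
class DietTruth:
    """Known dietary composition: the generating truth for simulations.

    ``catalog`` is indexed by taxon and carries common_name, group, origin,
    mass_kg and the integer occurrence ``count`` per taxon. ``n_total_items``
    is N, the total prey occurrences over all scats.
    """

    predator: str
    catalog: pd.DataFrame
    n_scats: int
    n_total_items: int

    def __post_init__(self) -> None:
        counts = self.catalog["count"]
        if int(counts.sum()) != self.n_total_items:
            raise ValueError(
                f"occurrence counts sum to {counts.sum()}, "
                f"expected N={self.n_total_items}")
        if (counts < 1).any():
            raise ValueError("every reconstructed count must be >= 1")
        if (counts > self.n_scats).any():
            raise ValueError("a taxon cannot occur in more scats than exist")


@dataclass
class SimulationConfig:
    """Knobs of the read-count simulator."""

    seed: int = 0
    reads_per_scat: int = 10_000
    noise_taxa: int = 0
    noise_fraction: float = 0.0  # total read share of all noise taxa
    control_contamination: int = 5  # max leaked reads per OTU in the control
    presence_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.reads_per_scat < 100:
            raise ValueError(
                "reads_per_scat < 100: threshold and abundance rules are "
                "meaningless at that depth")
        if not 0 <= self.noise_fraction <= 0.05:
            raise ValueError("noise_fraction must lie in [0, 0.05]")
        if self.noise_taxa:
            per_taxon = self.noise_fraction / self.noise_taxa
            if per_taxon >= self.presence_threshold:
                warnings.warn(
                    f"per-noise-taxon share {per_taxon:.3f} is not below the "
                    f"presence threshold; noise may survive filtering")


def lineage_for(taxon: str, group: str) -> str:
    """Plausible 7-rank lineage string for a fixture prey taxon.

    Genus-level prey ("Mus spp.") keep the table label at the species slot
    so that species-level consensus reproduces the table's taxon names.
    """
    genus = taxon.split()[0]
    cls = _GROUP_CLASS[group]
    return ";".join(["Animalia", "Chordata", cls, f"{cls}-order",
                     f"{genus}idae", genus, taxon])


def _load_fixture_table(table_id: str) -> pd.DataFrame:
    ref = importlib.resources.files("scatscape.data") / f"{table_id}_diet.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def fixture_from_tables(
    table_id: str, seed: int = 0
) -> tuple[DietTruth, pd.DataFrame]:
    """Reconstruct a diet fixture from the bundled published-table TSVs.

    Per-taxon occurrence counts are ``round_half_up(%PO x N / 100)`` and are
    checked to (a) re-sum exactly to N and (b) agree with
    ``round_half_up(%FO x n_scats / 100)`` — one occurrence is one scat
    containing the taxon. A seeded random assignment then scatters each
    taxon's occurrences over distinct scats; scat-level co-occurrence is not
    identifiable from the published aggregates, so it is randomized.
    """
    if table_id not in FIXTURE_TOTALS:
        raise KeyError(f"unknown fixture {table_id!r}")
    n_scats, n_total = FIXTURE_TOTALS[table_id]
    tab = _load_fixture_table(table_id)
    counts = tab["po_percent"].map(lambda p: int(round_half_up(p * n_total / 100)))
    fo_counts = tab["fo_percent"].map(
        lambda p: int(round_half_up(p * n_scats / 100)))
    if not (counts == fo_counts).all():
        raise ValueError(f"{table_id}: %PO and %FO reconstructions disagree")
    if int(counts.sum()) != n_total:
        raise ValueError(
            f"{table_id}: reconstructed counts sum to {counts.sum()}, "
            f"not N={n_total}")
    catalog = tab.set_index("taxon").assign(count=counts.to_numpy())
    truth = DietTruth(table_id, catalog, n_scats, n_total)

    rng = np.random.default_rng(seed)
    prefix = {"leopard": "leo", "leopardcat": "lc"}[table_id]
    scats = [f"{prefix}{i + 1:02d}" for i in range(n_scats)]
    presence = pd.DataFrame(False, index=scats, columns=catalog.index)
    for taxon, c in catalog["count"].items():
        chosen = rng.choice(n_scats, size=int(c), replace=False)
        presence.iloc[chosen, presence.columns.get_loc(taxon)] = True
    presence.index.name = "scat"
    presence.columns.name = "taxon"
    return truth, presence


# ---------------------------------------------------------------------------
# read-count simulation
# ---------------------------------------------------------------------------

def simulate_scat_counts(
    truth: DietTruth,
    presence: pd.DataFrame,
    cfg: SimulationConfig,
) -> tuple[CountTable, dict[str, str]]:
    """Multinomial read counts per scat over its true prey plus noise OTUs.

    Each scat's ``reads_per_scat`` reads are split multinomially: the scat's
    true taxa share ``1 - noise_fraction`` equally, and ``noise_taxa``
    contaminant OTUs share ``noise_fraction`` equally. A scat with no true
    prey yields only predator-host reads (blocked but never fully removed in
    real assays). A negative-control sample carries uniform leaked reads of
    at most ``control_contamination`` per OTU. Returns the count table and
    the otu_id -> lineage map of the generating truth.

    Noise lineages are vertebrate but use a dummy class/genus namespace
    disjoint from real prey, so they can only be removed by the abundance
    rule, never by name collision.
    """
    rng = np.random.default_rng(cfg.seed)
    host = PREDATOR_SPECIES[truth.predator]
    otu_of = {t: f"otu_{i:03d}" for i, t in enumerate(presence.columns)}
    lineages = {
        otu_of[t]: lineage_for(t, truth.catalog.at[t, "group"])
        for t in presence.columns
    }
    host_otu = "otu_host"
    lineages[host_otu] = ";".join(
        ["Animalia", "Chordata", "Mammalia", "Carnivora", "Felidae",
         host.split()[0], host])
    noise_otus = [f"noise_{i:02d}" for i in range(cfg.noise_taxa)]
    for i, otu in enumerate(noise_otus):
        lineages[otu] = ";".join(
            ["Animalia", "Chordata", "Synthetica", "Synthorder",
             f"Noisidae{i}", f"Noisus{i}", f"Noisus{i} synthetica"])

    columns = list(otu_of.values()) + noise_otus + [host_otu]
    samples = list(presence.index) + ["NEG"]
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample"),
                          columns=columns)
    for scat in presence.index:
        true_taxa = list(presence.columns[presence.loc[scat]])
        p = np.zeros(len(columns))
        if true_taxa:
            share = (1.0 - cfg.noise_fraction) / len(true_taxa)
            for t in true_taxa:
                p[columns.index(otu_of[t])] = share
            for otu in noise_otus:
                p[columns.index(otu)] = cfg.noise_fraction / len(noise_otus)
        else:
            p[columns.index(host_otu)] = 1.0
        p /= p.sum()
        counts.loc[scat] = rng.multinomial(cfg.reads_per_scat, p)

    counts.loc["NEG"] = rng.integers(
        0, cfg.control_contamination + 1, size=len(columns))
    meta = pd.DataFrame(
        {"predator": host, "is_control": False}, index=counts.index)
    meta.loc["NEG", ["predator", "is_control"]] = ["", True]
    return CountTable(counts, meta), lineages


def simulate_hit_table(
    assignment_truth: dict[str, str],
    n_hits: int = 50,
    discordant_fraction: float = 0.0,
    seed: int = 0,
    identity: tuple[float, float] = (97.5, 100.0),
    coverage: tuple[float, float] = (90.0, 100.0),
) -> pd.DataFrame:
    """BLAST-style hit rows per query OTU with a known discordance level.

    ``round((1 - discordant_fraction) * n_hits)`` hits carry the true
    lineage; the remainder carry a sibling species under the same genus.
    Identities and coverages are drawn uniformly from the given ranges, so
    setting a range below the 97/85 cutoffs makes hits fail the screen.
    """
    if not 0 <= discordant_fraction <= 1:
        raise ValueError("discordant_fraction must lie in [0, 1]")
    if n_hits > 50:
        raise ValueError("n_hits capped at 50 (the BLAST return limit used)")
    rng = np.random.default_rng(seed)
    rows = []
    for otu_id, lineage in assignment_truth.items():
        parts = lineage.split(";")
        sibling = ";".join(parts[:-1] + [parts[-1] + " (sibling)"])
        n_true = int(round_half_up((1 - discordant_fraction) * n_hits))
        for k in range(n_hits):
            rows.append({
                "otu_id": otu_id,
                "lineage": lineage if k < n_true else sibling,
                "pident": rng.uniform(*identity),
                "qcovs": rng.uniform(*coverage),
            })
    return pd.DataFrame(rows, columns=["otu_id", "lineage", "pident", "qcovs"])


# ---------------------------------------------------------------------------
# landscape simulation
# ---------------------------------------------------------------------------

@dataclass
class Placement:
    """One painted patch: a rectangle or ellipse of a single class."""

    cls: str
    shape: str  # 'rect' | 'ellipse'
    row: int
    col: int
    height: int  # rows (rect) or semi-axis in rows (ellipse)
    width: int

    def footprint(self, nrows: int, ncols: int) -> np.ndarray:
        m = np.zeros((nrows, ncols), dtype=bool)
        if self.shape == "rect":
            m[self.row:self.row + self.height, self.col:self.col + self.width] = True
        elif self.shape == "ellipse":
            rr, cc = np.ogrid[:nrows, :ncols]
            m[((rr - self.row) / max(self.height, 1e-9)) ** 2
              + ((cc - self.col) / max(self.width, 1e-9)) ** 2 <= 1.0] = True
        else:
            raise ValueError(f"unknown placement shape {self.shape!r}")
        return m


@dataclass
class LandscapeSpec:
    """Grid dimensions, legend and the ordered list of patch placements."""

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    background: str = "other"
    class_codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    placements: list[Placement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        codes = list(self.class_codes.values())
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be distinct")
        for p in self.placements:
            if p.cls not in self.class_codes:
                raise ValueError(f"placement class {p.cls!r} not in legend")
            if p.shape == "rect":
                if (p.row < 0 or p.col < 0
                        or p.row + p.height > self.n_rows
                        or p.col + p.width > self.n_cols):
                    raise ValueError("rect placement outside grid")


def _mask_perimeter_cells(mask: np.ndarray) -> int:
    """Number of unit cell faces between mask and its complement/border."""
    padded = np.pad(mask, 1)
    faces = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        faces += int((padded & ~np.roll(padded, (dr, dc), (0, 1))).sum())
    return faces


def simulate_landscape(
    spec: LandscapeSpec,
) -> tuple[CategoricalRaster, pd.DataFrame]:
    """Paint the placements onto the grid; later placements overwrite earlier.

    Returns the raster and a ground-truth inventory with one row per
    realized patch (8-connected component of the union of same-class
    surviving footprints): class, n_cells, area_m2, perimeter_m. A placement
    fully overwritten by later paint triggers a warning.
    """
    from scipy import ndimage

    bg = spec.class_codes[spec.background]
    grid = np.full((spec.n_rows, spec.n_cols), bg, dtype=int)
    footprints = []
    for p in spec.placements:
        m = p.footprint(spec.n_rows, spec.n_cols)
        grid[m] = spec.class_codes[p.cls]
        footprints.append((p, m))

    for p, m in footprints:
        if m.any() and not (grid[m] == spec.class_codes[p.cls]).any():
            warnings.warn(f"placement {p} fully overwritten by later paint")

    rows = []
    eight = np.ones((3, 3), dtype=int)
    placed = sorted({p.cls for p in spec.placements})
    for cls in placed:
        survives = grid == spec.class_codes[cls]
        intended = np.zeros_like(survives)
        for p, m in footprints:
            if p.cls == cls:
                intended |= m
        mask = survives & intended
        labels, n = ndimage.label(mask, structure=eight)
        for pid in range(1, n + 1):
            pm = labels == pid
            rows.append({
                "class": cls,
                "n_cells": int(pm.sum()),
                "area_m2": float(pm.sum()) * spec.cell_size ** 2,
                "perimeter_m": _mask_perimeter_cells(pm) * spec.cell_size,
            })
    raster = CategoricalRaster(
        data=grid, cell_size=spec.cell_size, legend=dict(spec.class_codes))
    return raster, pd.DataFrame(
        rows, columns=["class", "n_cells", "area_m2", "perimeter_m"])


def random_raster(
    n_rows: int,
    n_cols: int,
    n_classes: int = 3,
    cell_size: float = 30.0,
    seed: int = 0,
    p_nodata: float = 0.0,
) -> CategoricalRaster:
    """Uniform random class grid — the workhorse of the oracle tests."""
    rng = np.random.default_rng(seed)
    data = rng.integers(1, n_classes + 1, size=(n_rows, n_cols))
    if p_nodata > 0:
        data[rng.random((n_rows, n_cols)) < p_nodata] = -9999
    legend = {f"class_{c}": c for c in range(1, n_classes + 1)}
    return CategoricalRaster(data=data, cell_size=cell_size, nodata=-9999,
                             legend=legend)


# ---------------------------------------------------------------------------
# model-layer simulators (for the statistical recovery checks)
# ---------------------------------------------------------------------------

def simulate_reliance_gradient(
    n_scats: int = 60, n_taxa: int = 16, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Presence matrix with a known domestic-reliance gradient.

    Scat i's probability of containing each domestic taxon rises linearly
    along the gradient g_i in [0, 1] while wild-taxon probabilities fall.
    Each taxon sits in its own prey group (as if distinct orders), so the
    group x origin indicator matrix keeps one column per taxon and the
    gradient stays resolvable. Returns (presence, catalog, gradient).
    """
    rng = np.random.default_rng(seed)
    g = np.linspace(0, 1, n_scats)
    half = n_taxa // 2
    taxa = [f"dom_{i}" for i in range(half)] + \
           [f"wild_{i}" for i in range(n_taxa - half)]
    catalog = pd.DataFrame({
        "group": [f"order_{i}" for i in range(n_taxa)],
        "origin": ["domestic"] * half + ["wild"] * (n_taxa - half),
        "mass_kg": 1.0,
    }, index=pd.Index(taxa, name="taxon"))
    prob = np.empty((n_scats, n_taxa))
    prob[:, :half] = 0.02 + 0.96 * g[:, None]
    prob[:, half:] = 0.98 - 0.96 * g[:, None]
    presence = pd.DataFrame(rng.random((n_scats, n_taxa)) < prob,
                            index=[f"s{i:03d}" for i in range(n_scats)],
                            columns=catalog.index)
    return presence, catalog, g


def simulate_model_dataset(
    kind: str = "patch_predator",
    n: int = 46,
    effect: float = 0.0,
    sigma: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Scored dataset for regression/ANOVA recovery simulations.

    ``patch_predator``: pc1 = effect * I(leopard) + patch offsets + noise,
    predictors patch (6 levels) and predator (2 levels).
    ``disturbance``: pc1 = effect * forest_prop + noise, predictors
    forest_prop, edge_dist, frag_level; effect = 0 gives a pure-noise null.
    """
    rng = np.random.default_rng(seed)
    if kind == "patch_predator":
        patches = np.array(["SH", "NJ", "CH", "PH", "ID", "NK"])
        patch = rng.choice(patches, size=n)
        predator = rng.choice(["leopard", "leopardcat"], size=n)
        offsets = dict(zip(patches, rng.normal(0, 0.5, size=len(patches))))
        pc1 = (effect * (predator == "leopard")
               + np.array([offsets[p] for p in patch])
               + rng.normal(0, sigma, size=n))
        return pd.DataFrame({"pc1": pc1, "patch": patch, "predator": predator})
    if kind == "disturbance":
        forest = rng.uniform(0, 1, size=n)
        edge = rng.normal(0, 200, size=n)
        frag = rng.choice(["low", "moderate", "high"], size=n)
        pc1 = effect * forest + rng.normal(0, sigma, size=n)
        return pd.DataFrame({"pc1": pc1, "forest_prop": forest,
                             "edge_dist": edge, "frag_level": frag})
    raise ValueError(f"unknown dataset kind {kind!r}")
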