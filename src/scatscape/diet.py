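"""Dietary composition statistics from a scats x prey presence matrix.

Definitions, with s_i the number of scats containing taxon i, N = sum(s_i)
the total prey occurrences, and n the number of scats:

* percent occurrence       PO_i = 100 * s_i / N
* frequency of occurrence  FO_i = 100 * s_i / n
* standardized Levins niche breadth
      B    = 1 / sum(p_i^2),  p_i = s_i / N
      Bsta = (B - 1) / (N - 1)
  where the normalizing "n" of the textbook formula is taken as the total
  number of prey items ingested (N), not the number of taxa — the reading
  consistent with the definition "n is the total number of prey items
  ingested" and the one that reproduces the published values (0.18 for the
  leopard, 0.07 for the leopard cat). The taxon-count alternative is
  available via ``n_mode="taxa"``.

A "prey item" is one taxon present in one scat; multiplicity within a scat
is not counted, matching how occurrence tables total their N.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import round_half_up


def _check(pm: pd.DataFrame) -> None:
    if pm.size == 0:
        raise ValueError("presence matrix is empty")


def occurrences(pm: pd.DataFrame) -> pd.Series:
    """Per-taxon occurrence counts s_i (scats containing the taxon)."""
    _check(pm)
    return pm.sum(axis=0).astype(int)


def percent_occurrence(pm: pd.DataFrame) -> pd.Series:
    """PO_i = 100 * s_i / N, full precision (round only for display)."""
    s = occurrences(pm)
    n_total = int(s.sum())
    if n_total == 0:
        raise ValueError("presence matrix has no occurrences")
    return 100.0 * s / n_total


def frequency_occurrence(pm: pd.DataFrame) -> pd.Series:
    """FO_i = 100 * (scats containing taxon i) / (total scats)."""
    s = occurrences(pm)
    return 100.0 * s / len(pm)


def levins_standardized(pm: pd.DataFrame, n_mode: str = "occurrences") -> float:
    """Standardized Levins dietary niche breadth in [0, 1].

    0 marks a perfect specialist (all occurrences in one taxon), 1 a
    perfect generalist (occurrences spread evenly with one per item).
    """
    s = occurrences(pm)
    s = s[s > 0]
    n_total = int(s.sum())
    if n_total < 2:
        raise ValueError("niche breadth undefined for N < 2 occurrences")
    p = s / n_total
    b = 1.0 / float((p ** 2).sum())
    if n_mode == "occurrences":
        denom = n_total - 1
    elif n_mode == "taxa":
        denom = len(s) - 1
    else:
        raise ValueError(f"unknown n_mode {n_mode!r}")
    if denom == 0:
        return 0.0
    return (b - 1.0) / denom


def group_composition(pm: pd.DataFrame, catalog: pd.DataFrame) -> dict:
    """PO aggregated by prey group and by domestic/wild origin.

    ``catalog`` must be indexed by taxon with columns ``group`` and
    ``origin`` covering every presence column. Also reports how many scats
    contain at least one domestic taxon (a fixture-dependent quantity:
    it depends on scat-level co-occurrence, not just the marginals).
    """
    _check(pm)
    missing = [t for t in pm.columns if t not in catalog.index]
    if missing:
        raise KeyError(f"taxa missing from catalog: {missing}")
    s = occurrences(pm)
    n_total = int(s.sum())
    group_po = (100.0 * s.groupby(catalog.loc[s.index, "group"].to_numpy()).sum()
                / n_total)
    origin_po = (100.0 * s.groupby(catalog.loc[s.index, "origin"].to_numpy()).sum()
                 / n_total)
    domestic_taxa = [t for t in pm.columns
                     if catalog.at[t, "origin"] == "domestic"]
    scats_with_domestic = int(pm[domestic_taxa].any(axis=1).sum())
    return {
        "group_po": group_po.rename_axis("group"),
        "origin_po": origin_po.rename_axis("origin"),
        "scats_with_domestic": scats_with_domestic,
    }


def diet_profile(pm: pd.DataFrame, catalog: pd.DataFrame,
                 ndigits: int = 2) -> pd.DataFrame:
    """Per-taxon table in the layout of published diet-composition tables:
    occurrences, %PO, %FO (half-up rounded) and approximate prey mass."""
    s = occurrences(pm)
    po = percent_occurrence(pm)
    fo = frequency_occurrence(pm)
    out = pd.DataFrame({
        "s": s,
        "po_percent": po.map(lambda v: round_half_up(v, ndigits)),
        "fo_percent": fo.map(lambda v: round_half_up(v, ndigits)),
    })
    for col in ("group", "origin", "mass_kg"):
        if col in catalog.columns:
            out[col] = catalog.reindex(out.index)[col]
    out.index.name = "taxon"
    return out
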