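"""Taxonomy assignment and the scat-metabarcoding filter chain.

The chain turns a denoised scats x OTU read-count table plus a BLAST-style
hit table into a presence/absence matrix of prey taxa:

1. consensus taxonomy per OTU from its database hits (identity/coverage
   screen, then the deepest rank where one taxon holds a qualifying
   majority of the surviving hits);
2. a minimum read threshold taken from the negative-control sample;
3. removal of non-vertebrate, family-level-only, unassigned, and
   predator-self OTUs;
4. presence if a taxon's relative read abundance in the scat strictly
   exceeds 1% (OTUs pooled to their assigned taxon first).

Defaults follow the common vertebrate 12S metabarcoding practice: 97%
identity, 85% query coverage, 51% consensus over at most 50 hits, and a
1% relative-abundance presence rule.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
VERTEBRATE_PHYLUM = "Chordata"


def split_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon-delimited kingdom->species lineage path."""
    return tuple(part.strip() for part in lineage.split(";"))


@dataclass(frozen=True)
class TaxAssignment:
    """Consensus taxonomy for one OTU."""

    otu_id: str
    lineage: tuple[str, ...]  # path down to the achieved rank
    rank: str  # 'species' | 'genus' | 'family' | 'unassigned'
    consensus: float | None  # fraction of surviving hits agreeing, or None

    @property
    def taxon(self) -> str | None:
        """Name at the achieved rank (presence-matrix column label)."""
        if self.rank == "unassigned":
            return None
        return self.lineage[-1]

    @property
    def is_vertebrate(self) -> bool:
        return (len(self.lineage) > 1
                and self.lineage[1] == VERTEBRATE_PHYLUM)


@dataclass
class CountTable:
    """Samples x OTU integer read counts with per-sample metadata.

    ``meta`` is indexed like ``counts`` and carries at least ``predator``;
    ``is_control`` flags the negative-control sample of the run.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the same sample index")
        if "is_control" not in self.meta.columns:
            self.meta = self.meta.assign(is_control=False)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def control_ids(self) -> list[str]:
        return list(self.meta.index[self.meta["is_control"]])

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.meta.copy())


# ---------------------------------------------------------------------------
# consensus taxonomy
# ---------------------------------------------------------------------------

#: index into RANKS of the deepest rank tried, in descending depth
_CONSENSUS_RANKS = (("species", 7), ("genus", 6), ("family", 5))


def consensus_assign_one(
    hits: pd.DataFrame,
    otu_id: str,
    max_hits: int = 50,
    min_consensus: float = 0.51,
    min_identity: float = 97.0,
    min_coverage: float = 85.0,
) -> TaxAssignment:
    """Assign one OTU from its hit rows (columns lineage/pident/qcovs)."""
    ok = hits[(hits["pident"] >= min_identity) & (hits["qcovs"] >= min_coverage)]
    ok = ok.sort_values("pident", ascending=False, kind="stable").head(max_hits)
    if ok.empty:
        return TaxAssignment(otu_id, (), "unassigned", None)
    paths = [split_lineage(ln) for ln in ok["lineage"]]
    n = len(paths)
    for rank_name, depth in _CONSENSUS_RANKS:
        prefixes = Counter(p[:depth] for p in paths if len(p) >= depth)
        if not prefixes:
            continue
        best, count = prefixes.most_common(1)[0]
        if count / n >= min_consensus:
            return TaxAssignment(otu_id, best, rank_name, count / n)
    return TaxAssignment(otu_id, (), "unassigned", None)


def consensus_assign(
    hit_table: pd.DataFrame,
    otu_ids: list[str] | None = None,
    **kwargs,
) -> dict[str, TaxAssignment]:
    """Consensus taxonomy for every OTU in a long-format hit table.

    ``hit_table`` has columns ``otu_id``, ``lineage`` (semicolon path),
    ``pident`` and ``qcovs`` (percent). OTUs listed in ``otu_ids`` but
    absent from the table come back unassigned.
    """
    out: dict[str, TaxAssignment] = {}
    for otu_id, grp in hit_table.groupby("otu_id", sort=False):
        out[str(otu_id)] = consensus_assign_one(grp, str(otu_id), **kwargs)
    for otu_id in otu_ids or []:
        if otu_id not in out:
            out[otu_id] = TaxAssignment(otu_id, (), "unassigned", None)
    return out


# ---------------------------------------------------------------------------
# count-table filters
# ---------------------------------------------------------------------------

def control_threshold_filter(table: CountTable) -> CountTable:
    """Zero every count at or below the negative-control maximum.

    The threshold T is the largest per-OTU read count observed in the
    control sample; entries <= T anywhere in the table are set to zero
    (reads that low are indistinguishable from carry-over contamination).
    The control row is removed and all-zero OTU columns are dropped.
    """
    controls = table.control_ids
    if not controls:
        warnings.warn("no negative control flagged; threshold defaults to 0")
        threshold = 0
    else:
        threshold = int(table.counts.loc[controls].to_numpy().max())
    counts = table.counts.drop(index=controls)
    counts = counts.where(counts > threshold, 0)
    counts = counts.loc[:, counts.any(axis=0)]
    meta = table.meta.drop(index=controls)
    logger.info("control threshold T=%d; %d OTUs retained", threshold,
                counts.shape[1])
    return CountTable(counts, meta)


def drop_coarse_and_offtarget(
    assignments: dict[str, TaxAssignment],
    table: CountTable,
) -> CountTable:
    """Remove OTUs that cannot be interpreted as prey.

    Drops columns that are unassigned, resolved only to family, or not
    vertebrate, and zeroes predator-self reads (e.g. leopard DNA inside a
    leopard scat — host DNA survives blocking oligos at low levels).
    ``meta['predator']`` must hold the predator's species name as used in
    the hit-table lineages.
    """
    keep = []
    for otu in table.counts.columns:
        a = assignments.get(str(otu))
        if a is None:
            raise KeyError(f"OTU {otu!r} has no taxonomy assignment")
        if a.rank in ("unassigned", "family") or not a.is_vertebrate:
            continue
        keep.append(otu)
    counts = table.counts[keep].copy()

    host_reads = 0
    for sample, predator in table.meta["predator"].items():
        for otu in keep:
            a = assignments[str(otu)]
            if predator and a.taxon == predator:
                host_reads += int(counts.at[sample, otu])
                counts.at[sample, otu] = 0
    if host_reads:
        logger.info("removed %d predator-self reads", host_reads)
    counts = counts.loc[:, counts.any(axis=0)]
    return CountTable(counts, table.meta.copy())


def to_presence(
    table: CountTable,
    assignments: dict[str, TaxAssignment],
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Collapse OTUs to taxa and threshold relative abundance into presence.

    OTUs sharing an assigned taxon (e.g. several OTUs resolved to the genus
    *Mus*) are pooled before thresholding, because diet tables report prey
    at that rank. A taxon is present in a scat iff its pooled reads exceed
    ``threshold`` of the scat's retained reads (strictly greater).
    """
    taxa = {otu: assignments[str(otu)].taxon for otu in table.counts.columns}
    if any(t is None for t in taxa.values()):
        bad = [o for o, t in taxa.items() if t is None]
        raise ValueError(f"unassigned OTUs reached presence step: {bad}")
    pooled = table.counts.T.groupby(table.counts.columns.map(taxa)).sum().T
    totals = pooled.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} scat(s) with zero retained reads; "
            "their presence rows are all-absent")
    rel = pooled.div(totals.where(~empty, 1), axis=0)
    presence = rel > threshold
    presence = presence.loc[:, presence.any(axis=0)]
    presence.index.name = "scat"
    presence.columns.name = "taxon"
    return presence


def filter_chain(
    table: CountTable,
    assignments: dict[str, TaxAssignment],
    presence_threshold: float = 0.01,
) -> pd.DataFrame:
    """Full order-fixed chain: control threshold -> taxonomy drop -> presence."""
    t = control_threshold_filter(table)
    t = drop_coarse_and_offtarget(assignments, t)
    return to_presence(t, assignments, threshold=presence_threshold)
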