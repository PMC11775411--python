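#!/usr/bin/env python
"""Simulate scat metabarcoding reads over the leopard diet truth, run the
full filter chain (consensus taxonomy, control threshold, taxonomy drop,
>1% presence rule), and measure how reliably the known presence matrix is
recovered under contaminant noise.

Writes results/metabarcoding/: a simulated count table, the filtered
presence matrix, and a recovery summary.
"""

import json
import warnings
from pathlib import Path

from scatscape import filters
from scatscape import synthetic as synth

OUT = Path("results/metabarcoding")
OUT.mkdir(parents=True, exist_ok=True)

truth, pm_true = synth.fixture_from_tables("leopard", seed=1)
cfg = synth.SimulationConfig(seed=1, reads_per_scat=10_000,
                             noise_taxa=5, noise_fraction=0.02,
                             control_contamination=5)
table, lineages = synth.simulate_scat_counts(truth, pm_true, cfg)
hits = synth.simulate_hit_table(lineages, discordant_fraction=0.1, seed=2)
assignments = filters.consensus_assign(hits, otu_ids=list(table.counts.columns))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pm = filters.filter_chain(table, assignments)

table.counts.to_csv(OUT / "counts_leopard.tsv", sep="\t")
pm.astype(int).to_csv(OUT / "presence_filtered.tsv", sep="\t")

exact = pm.reindex(columns=pm_true.columns, fill_value=False).equals(pm_true)
print(f"simulated {table.counts.shape[0] - 1} scats x "
      f"{table.counts.shape[1]} OTUs at {cfg.reads_per_scat} reads/scat "
      f"({cfg.noise_taxa} noise OTUs sharing {cfg.noise_fraction:.0%} of reads)")
print(f"single-run recovery of the generating presence matrix: "
      f"{'exact' if exact else 'NOT exact'}")

ok = 0
reps = 100
for rep in range(reps):
    c = synth.SimulationConfig(seed=100 + rep, reads_per_scat=2000,
                               noise_taxa=5, noise_fraction=0.02)
    t, _ = synth.simulate_scat_counts(truth, pm_true, c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = filters.filter_chain(t, assignments)
    ok += out.reindex(columns=pm_true.columns, fill_value=False).equals(pm_true)
print(f"recovery across {reps} replicates with sub-threshold noise: "
      f"{ok}/{reps}")

(OUT / "recovery.json").write_text(json.dumps({
    "single_run_exact": bool(exact),
    "replicates": reps,
    "replicates_recovered": int(ok),
}, indent=2))
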