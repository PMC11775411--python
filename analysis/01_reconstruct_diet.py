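#!/usr/bin/env python
"""Reconstruct both predators' diet profiles from the published tables and
compute the occurrence statistics and niche breadth.

Writes results/diet/: per-predator profile TSVs and a summary JSON.
"""

import json
from pathlib import Path

from scatscape import diet
from scatscape import synthetic as synth
from scatscape._util import round_half_up

OUT = Path("results/diet")
OUT.mkdir(parents=True, exist_ok=True)

summary = {}
for predator in ("leopard", "leopardcat"):
    truth, pm = synth.fixture_from_tables(predator, seed=1)
    profile = diet.diet_profile(pm, truth.catalog)
    profile.to_csv(OUT / f"profile_{predator}.tsv", sep="\t")
    comp = diet.group_composition(pm, truth.catalog)
    bsta = diet.levins_standardized(pm)
    summary[predator] = {
        "n_scats": truth.n_scats,
        "n_prey_items": truth.n_total_items,
        "n_taxa": int(len(profile)),
        "levins_bsta": round_half_up(bsta, 2),
        "group_po": comp["group_po"].round(2).to_dict(),
        "origin_po": comp["origin_po"].round(2).to_dict(),
    }
    print(f"{predator}: {len(profile)} prey taxa, "
          f"N={truth.n_total_items} items over {truth.n_scats} scats; "
          f"Bsta={bsta:.2f}")
    top = profile.sort_values("po_percent", ascending=False).head(3)
    for taxon, row in top.iterrows():
        print(f"  {taxon}: PO {row.po_percent}%, FO {row.fo_percent}%")

(OUT / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
print(f"\nThe leopard diet is ungulate-dominated "
      f"({summary['leopard']['group_po']['ungulate']}% PO, "
      f"{summary['leopard']['origin_po']['domestic']}% domestic); the "
      f"leopard cat is a rodent specialist "
      f"({summary['leopardcat']['group_po']['rodent']}% PO) with a much "
      f"narrower niche (Bsta {summary['leopardcat']['levins_bsta']} vs "
      f"{summary['leopard']['levins_bsta']}).")
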