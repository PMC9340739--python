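#!/usr/bin/env python
"""Four-perspective emission accounting and net-flow patterns.

Allocates each year's anthropogenic emissions to the income, production,
final-sale and consumption perspectives, computes pairwise net flows, and
writes the region-by-region matrices to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pahflow import WorldSpec, generate_world
from pahflow.inventory import split_anthropogenic
from pahflow.mrio import four_perspectives, net_flows

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

world = generate_world(WorldSpec(seed=SEED))
rows = []
for y, sl in enumerate(world.slices):
    anthro, _ = split_anthropogenic(sl.inventory)
    qs = four_perspectives(sl.table, anthro.E)
    total = anthro.E.sum()
    spread = max(abs(qs[p].total - total) for p in qs) / total
    print(f"year {y}: all four perspectives account for {total:.1f} "
          f"(max relative spread {spread:.1e})")
    for p, q in qs.items():
        pd.DataFrame(q.Qmat, index=q.region_labels, columns=q.region_labels).to_csv(
            OUT / f"Q_{p}_y{y}.csv", float_format="%.6g")
        if p == "production":
            continue
        nf = net_flows(q)
        rows.append({
            "year": y, "perspective": p,
            "total_net_inflow": nf.total_net_inflow,
            "importers": ",".join(q.region_labels[i] for i in nf.importers),
            "exporters": ",".join(q.region_labels[i] for i in nf.exporters),
        })
        print(f"  {p:12s}: net inflow {nf.total_net_inflow:8.1f}; "
              f"importers {rows[-1]['importers']}, exporters {rows[-1]['exporters']}")

df = pd.DataFrame(rows)
df.to_csv(OUT / "net_flows.csv", index=False, float_format="%.6g")

y0 = df[df.year == 0].set_index("perspective")["total_net_inflow"]
print(f"consumption-based net flow ({y0['consumption']:.0f}) exceeds final-sale "
      f"({y0['sale']:.0f}) and income ({y0['income']:.0f}): the downstream end of "
      "the supply chain moves the most embodied emissions, as designed.")
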