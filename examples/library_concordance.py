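"""Cross-library SNV concordance and panel recall on synthetic calls.

Three libraries observe the same genome with independent small call
dropout; the overlap diagram regions and the recall against a
down-sampled "panel" are computed from call identities alone.
"""

import numpy as np

from aneukit.concordance import overlap_variants, panel_recall
from aneukit.simulate import SimParams, make_genome_model, simulate_variant_reads

params = SimParams(seed=4, variant_call_dropout=0.05)
model = make_genome_model(params)
reads = simulate_variant_reads(model)

sets = {lib: {r.key for r in recs} for lib, recs in reads.items()}
regions = overlap_variants(sets)

print("overlap regions (exactly these libraries):")
for combo in sorted(regions, key=lambda c: (len(c), sorted(c))):
    print(f"  {' & '.join(sorted(combo)):<20}{regions[combo]:>8,}")

rng = np.random.default_rng(4)
panel = {k for k in sorted(sets["STD"], key=lambda k: (k.chrom, k.pos))
         if rng.random() < 0.01}
union = sets["STD"] | sets["LFR1"] | sets["LFR2"]
report = panel_recall(union, panel)
print(f"\npanel recall (union of libraries vs {report.n_panel} panel sites): "
      f"{report.recall:.2f}")

# With 5 % per-library dropout most variants land in the triple
# intersection, and the union recovers nearly every panel site — the
# signature of reproducible call sets.
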