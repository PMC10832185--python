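"""Score functional states with gene panels: Z heatmap values and AUC.

Fold changes at each culture day are Z-scored per gene across days, averaged
within each panel category and integrated over the actual day values.  A
positive AUC marks a rising program (disease-associated microglia, astrocyte
activation), a negative AUC a falling one (homeostatic, neurotransmitter
receptors).
"""

import pandas as pd

import gliostate as gs

counts, truth = gs.simulate_counts(gs.default_design(seed=1))
norm = gs.housekeeping_normalize(counts, truth.housekeeping_genes)

lfc = pd.DataFrame({
    cond: gs.log2_fold_changes(norm, (cond, "DIV0")).table["log2fc"]
    for cond in ("DIV1", "DIV3", "DIV6", "DIV9", "DIV14")
})
z = gs.zscore_rows(lfc, cap=6.0)           # per-gene Z across days, capped at +/-6
times = {c: float(c[3:]) for c in lfc.columns}

auc = gs.category_auc(z, gs.emit_panels(truth), times)
print(auc.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
# dam / astrocyte_activation integrate positive (rising over the 14 days),
# homeostatic / neurotransmitter_receptor negative; acute_injury is small
# because its day-1 pulse contributes little area after it resolves.
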