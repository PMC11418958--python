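"""Hexokinase isoform usage by cell type in a synthetic single-cell matrix.

Generates sparse binarizable counts with cell-type-dependent isoform
probabilities, tabulates the fraction of cells of each type expressing
each isoform, and computes the non-neuronal share of HK2-expressing
cells plus a regional HK1/HK2 ratio correlation.
"""

import numpy as np
import pandas as pd

from neuroglyc import expression as ex
from neuroglyc import synth

expr, truth = synth.gen_expression_matrix(synth.ExpressionConfig(seed=0))

table = ex.celltype_isoform_fractions(expr)
print("fraction of cells expressing each isoform:")
print(table.pivot(index="cell_type", columns="isoform",
                  values="fraction").round(3).to_string())

share = ex.class_share_of_expressing(expr, "HK2")
print(f"\nnon-neuronal share of HK2-expressing cells: {share:.1%}")
print("Microglia are the only type where HK2 outnumbers HK1 -- the "
      "cell-type signature of the white-matter HK2 enrichment.")

rng = np.random.default_rng(1)
delta = pd.DataFrame({"region": [f"region{i:02d}" for i in range(48)],
                      "delta": rng.normal(0, 1, 48)})
regional = synth.gen_regional_expression(delta, target_r=-0.63, seed=2)
r = ex.regional_ratio_correlation(regional, delta, "HK1", "HK2")
print(f"\nregional HK1/HK2 ratio vs metabolic change: r = {r:.2f} "
      "(regions with relatively more HK2 change more)")
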