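"""Negative-binomial Wald differential expression on simulated counts.

Builds an 8-sample, 2-condition count matrix where 5 of 200 genes are
planted at a 4-fold up-shift, then prints the top of the DE table.

Run:  python examples/02_differential_expression.py
"""

import numpy as np
import pandas as pd

from mrgrn import CountMatrix, DeThresholds, run_de

rng = np.random.default_rng(0)
n_genes, fold_shift = 200, 4.0
mu = np.full(n_genes, 150.0)
mu_case = mu.copy()
mu_case[:5] *= fold_shift
r = 1 / 0.1  # dispersion 0.1: variance = mu + 0.1 mu^2

cols, meta_rows = {}, []
for cond, m in (("control", mu), ("case", mu_case)):
    for i in range(4):
        sid = f"{cond}_{i}"
        cols[sid] = rng.negative_binomial(r, r / (r + m))
        meta_rows.append((sid, "colon", cond, "B1"))

cm = CountMatrix(
    pd.DataFrame(cols, index=[f"g{i:03d}" for i in range(n_genes)]),
    pd.DataFrame(meta_rows, columns=["sample_id", "tissue", "condition", "batch"])
    .set_index("sample_id"),
)

det, summary = run_de(cm, DeThresholds(alpha=0.05))
print(det.sort_values("padj").head(7).round(4))
print(
    f"\n{summary['n_up']} up / {summary['n_down']} down of "
    f"{summary['n_tested']} tested genes at padj < 0.05"
)
print("log2fc ~ 2 for the five planted genes: the 4-fold shift is recovered.")
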