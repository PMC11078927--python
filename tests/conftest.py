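"""Shared fixtures: programmatic count matrices and tiny networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrgrn.io import CountMatrix, EdgeRecord


def nb_count_matrix(
    n_genes: int,
    n_rep: int,
    seed: int,
    mu: float = 200.0,
    alpha: float = 0.1,
    case_log2fc: np.ndarray | None = None,
    tissue: str = "colon",
) -> CountMatrix:
    """Two-condition NB count matrix; case means shifted gene-wise by
    2**case_log2fc (variance = mu + alpha mu^2)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    mu_ctrl = np.full(n_genes, float(mu))
    shift = np.zeros(n_genes) if case_log2fc is None else np.asarray(case_log2fc, float)
    mu_case = mu_ctrl * 2.0**shift
    r = 1.0 / alpha
    cols, rows = {}, []
    for i in range(n_rep):
        sid = f"control_{i}"
        cols[sid] = rng.negative_binomial(r, r / (r + mu_ctrl))
        rows.append((sid, tissue, "control", "B1"))
    for i in range(n_rep):
        sid = f"case_{i}"
        cols[sid] = rng.negative_binomial(r, r / (r + mu_case))
        rows.append((sid, tissue, "case", "B1"))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "tissue", "condition", "batch"]
    ).set_index("sample_id")
    return CountMatrix(pd.DataFrame(cols, index=genes), meta)


def edges(*pairs, mode: str = "activation", source: str = "test") -> list[EdgeRecord]:
    """Shorthand: edges(("A","B"), ("B","C")) -> EdgeRecord list."""
    return [
        EdgeRecord(a, b, mode=mode, sources=frozenset({source})) for a, b in pairs
    ]


@pytest.fixture
def small_counts() -> CountMatrix:
    """4 genes x 4 samples with a clear case-vs-control contrast."""
    counts = pd.DataFrame(
        {
            "c1": [100, 50, 10, 0],
            "c2": [110, 55, 12, 0],
            "k1": [400, 52, 11, 0],
            "k2": [420, 51, 9, 0],
        },
        index=["gUp", "gFlat", "gLow", "gZero"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "k1", "k2"],
            "tissue": ["colon"] * 4,
            "condition": ["control", "control", "case", "case"],
            "batch": ["B1"] * 4,
        }
    ).set_index("sample_id")
    return CountMatrix(counts, meta)
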