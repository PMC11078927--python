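"""Simplified negative-binomial differential expression for two-group designs.

The stage mirrors the standard count-based DE contract: median-of-ratios
size factors, a per-gene NB dispersion, a Wald test on the log2 fold change
(case vs control) against the normal reference, and Benjamini-Hochberg
adjustment. It deliberately omits dispersion-trend shrinkage, independent
filtering and outlier handling; the normal reference makes it a
large-sample test (see docs/methods.md for the implications at small n).

The NB is parameterized as variance = mu + alpha * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = [
    "DeThresholds",
    "estimate_size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "classify_degs",
    "run_de",
]

DISPERSION_FLOOR = 1e-8
LOG2 = np.log(2.0)


@dataclass
class DeThresholds:
    """Cutoffs for calling a gene differentially expressed.

    alpha is the adjusted-p cutoff; fc_threshold the |log2 fold change|
    cutoff (0 by default: the network stage consumes every adjusted-p
    significant gene, while volcano-style reporting may use a stricter
    fold-change filter).
    """

    alpha: float = 0.05
    fc_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be >= 0")


def _conditions_of(cm: CountMatrix, groups=None) -> pd.Series:
    if groups is None:
        groups = cm.sample_meta.loc[cm.sample_ids, "condition"]
    elif isinstance(groups, dict):
        groups = pd.Series({s: groups[s] for s in cm.sample_ids})
    else:
        groups = pd.Series(groups).loc[cm.sample_ids]
    return groups


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over reference genes g of counts[g, j] / geomean_k counts[g, k],
    where reference genes have strictly positive counts in every sample.
    """
    counts = cm.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "pseudo-reference fallback is disabled"
        )
    ref = counts[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def estimate_dispersions(cm: CountMatrix, sf: pd.Series, groups=None) -> pd.Series:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    Within each condition, alpha_c = (var_c - mean_c) / mean_c^2; the
    per-gene estimate pools the conditions by their degrees of freedom and
    is floored at 1e-8 (genes whose sample variance does not exceed the
    mean, including constant genes, sit at the floor).
    """
    groups = _conditions_of(cm, groups)
    y = cm.counts.to_numpy(dtype=float) / sf.loc[cm.sample_ids].to_numpy()
    num = np.zeros(y.shape[0])
    den = 0.0
    for cond in sorted(set(groups)):
        mask = (groups == cond).to_numpy()
        n_c = int(mask.sum())
        if n_c < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
        sub = y[:, mask]
        mean_c = sub.mean(axis=1)
        var_c = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_c = (var_c - mean_c) / mean_c**2
        alpha_c = np.where(np.isfinite(alpha_c), alpha_c, 0.0)
        num += (n_c - 1) * alpha_c
        den += n_c - 1
    alpha = num / den
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=cm.gene_ids, name="dispersion")


def nb_wald_test(
    cm: CountMatrix, sf: pd.Series, disp: pd.Series, groups=None
) -> pd.DataFrame:
    """Two-group NB Wald test; returns the per-gene DE table.

    Group means are fitted on size-factor-normalized counts; the fold
    change uses a +0.5 pseudocount; SE(log2fc) comes from the NB
    information at the fitted means, Var(K_ij) = mu + alpha mu^2; the
    two-sided p is read off the normal reference. Genes with zero counts
    everywhere are reported as untested (p undefined).
    """
    groups = _conditions_of(cm, groups)
    present = set(groups)
    if present != {"control", "case"}:
        raise ValueError(
            f"exactly the conditions 'control' and 'case' are required, got {sorted(present)}"
        )
    s = sf.loc[cm.sample_ids].to_numpy(dtype=float)
    counts = cm.counts.to_numpy(dtype=float)
    y = counts / s
    alpha = disp.loc[cm.gene_ids].to_numpy(dtype=float)
    mask_case = (groups == "case").to_numpy()
    mask_ctrl = ~mask_case
    n_case, n_ctrl = int(mask_case.sum()), int(mask_ctrl.sum())

    m_ctrl = y[:, mask_ctrl].mean(axis=1)
    m_case = y[:, mask_case].mean(axis=1)
    base_mean = y.mean(axis=1)

    q_ctrl = m_ctrl + 0.5
    q_case = m_case + 0.5
    log2fc = np.log2(q_case / q_ctrl)

    # Var(mean of normalized counts) from the NB model at the fitted means:
    # Var(K_ij / s_j) = q / s_j + alpha q^2
    inv_s_ctrl = (1.0 / s[mask_ctrl]).sum()
    inv_s_case = (1.0 / s[mask_case]).sum()
    var_ctrl = (q_ctrl * inv_s_ctrl + alpha * q_ctrl**2 * n_ctrl) / n_ctrl**2
    var_case = (q_case * inv_s_case + alpha * q_case**2 * n_case) / n_case**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_case / q_case**2 + var_ctrl / q_ctrl**2) / LOG2
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    untested = counts.sum(axis=1) == 0
    p = np.where(untested, np.nan, p)
    log2fc = np.where(untested, 0.0, log2fc)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "dispersion": alpha,
            "p": p,
            "padj": np.nan,
            "status": np.where(untested, "untested", "ns"),
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Undefined entries (NaN) are excluded from m and stay NaN; adjusted
    values are monotone in rank and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    vals = p[defined]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[defined] = result
    return out


def classify_degs(
    det: pd.DataFrame, thresholds: DeThresholds | None = None
) -> tuple[pd.DataFrame, dict]:
    """Fill up/down/ns calls and return the summary {n_up, n_down, n_tested}.

    up   iff padj < alpha and log2fc > fc_threshold
    down iff padj < alpha and log2fc < -fc_threshold
    """
    thresholds = thresholds or DeThresholds()
    det = det.copy()
    tested = det["p"].notna()
    sig = tested & (det["padj"] < thresholds.alpha)
    up = sig & (det["log2fc"] > thresholds.fc_threshold)
    down = sig & (det["log2fc"] < -thresholds.fc_threshold)
    det.loc[tested, "status"] = "ns"
    det.loc[up, "status"] = "up"
    det.loc[down, "status"] = "down"
    det.loc[~tested, "status"] = "untested"
    summary = {
        "n_up": int(up.sum()),
        "n_down": int(down.sum()),
        "n_tested": int(tested.sum()),
    }
    return det, summary


def run_de(
    cm: CountMatrix,
    thresholds: DeThresholds | None = None,
    groups=None,
) -> tuple[pd.DataFrame, dict]:
    """Convenience: size factors -> dispersions -> Wald -> BH -> calls."""
    thresholds = thresholds or DeThresholds()
    sf = estimate_size_factors(cm)
    disp = estimate_dispersions(cm, sf, groups)
    det = nb_wald_test(cm, sf, disp, groups)
    det["padj"] = bh_adjust(det["p"].to_numpy())
    return classify_degs(det, thresholds)
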