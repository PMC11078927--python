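"""ddCt relative quantification of qPCR data and the unpaired t-test.

Relative expression follows the classic 2^(-ddCt) scheme: per animal,
dCt = Ct_target - Ct_housekeeping; ddCt references the arithmetic mean of
the control group's dCt (so the control group's mean relative expression
is 1 by construction); rq = 2^(-ddCt). Group comparison uses the
pooled-variance (Student) unpaired two-sided t-test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct_relative_expression", "two_group_ttest", "qpcr_gene_summary"]


def ddct_relative_expression(
    table: pd.DataFrame, housekeeping: str, target: str
) -> pd.DataFrame:
    """Per-animal dCt, ddCt and rq = 2^(-ddCt) for one target gene.

    ``table`` columns: animal_id, group (control/case), gene, ct. Animals
    carrying the target but missing a housekeeping Ct are excluded with a
    warning; the run fails if no control animal remains (the ddCt
    reference would be undefined).
    """
    tgt = table[table["gene"] == target].set_index("animal_id")
    hk = table[table["gene"] == housekeeping].set_index("animal_id")
    if tgt.empty:
        raise ValueError(f"no Ct rows for target gene {target!r}")
    rows = []
    for animal, row in tgt.iterrows():
        if animal not in hk.index:
            warnings.warn(
                f"animal {animal!r} lacks a {housekeeping} Ct and was excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "animal_id": animal,
                "group": row["group"],
                "dct": float(row["ct"]) - float(hk.loc[animal, "ct"]),
            }
        )
    res = pd.DataFrame(rows, columns=["animal_id", "group", "dct"])
    control = res.loc[res["group"] == "control", "dct"]
    if control.empty:
        raise ValueError(f"no control animals with both {target} and {housekeeping} Ct")
    ref = control.mean()
    res["ddct"] = res["dct"] - ref
    res["rq"] = 2.0 ** (-res["ddct"])
    res.insert(1, "gene", target)
    return res


def two_group_ttest(x, y) -> dict:
    """Pooled-variance unpaired two-sided t-test.

    Returns {"t", "df", "p"} with df = n_x + n_y - 2. Degenerate inputs
    (zero pooled variance) give p = 1 for equal means and p = 0 (with a
    warning) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    nx_, ny = x.size, y.size
    df = nx_ + ny - 2
    sp2 = ((nx_ - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return {"t": 0.0, "df": df, "p": 1.0}
        warnings.warn(
            "zero pooled variance with unequal means: degenerate t-test",
            stacklevel=2,
        )
        return {"t": float(np.sign(diff)) * np.inf, "df": df, "p": 0.0}
    t = diff / np.sqrt(sp2 * (1.0 / nx_ + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p)}


def qpcr_gene_summary(
    table: pd.DataFrame, housekeeping: str, targets: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal rq for each target plus group means +/- SEM and p.

    Returns (per_animal, per_gene) frames; per_gene has control/case mean
    rq, SEM and the pooled-t p-value on rq.
    """
    per_animal = []
    summaries = []
    for gene in targets:
        rel = ddct_relative_expression(table, housekeeping, gene)
        per_animal.append(rel)
        ctrl = rel.loc[rel["group"] == "control", "rq"].to_numpy()
        case = rel.loc[rel["group"] == "case", "rq"].to_numpy()
        row = {
            "gene": gene,
            "control_mean_rq": float(ctrl.mean()) if ctrl.size else np.nan,
            "control_sem_rq": float(ctrl.std(ddof=1) / np.sqrt(ctrl.size))
            if ctrl.size > 1
            else np.nan,
            "case_mean_rq": float(case.mean()) if case.size else np.nan,
            "case_sem_rq": float(case.std(ddof=1) / np.sqrt(case.size))
            if case.size > 1
            else np.nan,
        }
        if ctrl.size >= 2 and case.size >= 2:
            row["p"] = two_group_ttest(ctrl, case)["p"]
        else:
            row["p"] = np.nan
        summaries.append(row)
    return (
        pd.concat(per_animal, ignore_index=True),
        pd.DataFrame(
            summaries,
            columns=[
                "gene",
                "control_mean_rq",
                "control_sem_rq",
                "case_mean_rq",
                "case_sem_rq",
                "p",
            ],
        ),
    )
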