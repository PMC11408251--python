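"""Two-group differential expression with Benjamini-Hochberg FDR.

The retrieval contrast (reactivated vs non-reactivated animals) is tested
gene-by-gene with the pooled-variance t-test on log2-scale expression; the
log2 fold change is the difference of group means, and q-values come from
the Benjamini-Hochberg step-up adjustment over the whole tested family.

Fold changes are also reported on a signed linear scale: the convention is
``fc_linear = sign(log2fc) * 2**|log2fc|``, so a halving is written -2.0
rather than 0.5 and |fc_linear| >= 1 always holds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = ["differential_expression", "bh_fdr", "volcano_classify", "signed_linear_fc"]


def bh_fdr(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped to <= 1, where (i)
    indexes the ascending sort of the m p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def signed_linear_fc(log2fc: np.ndarray | float) -> np.ndarray | float:
    """Signed linear fold change: sign(log2fc) * 2**|log2fc| (1.0 at zero)."""
    lf = np.asarray(log2fc, dtype=float)
    out = np.where(lf >= 0, 2.0**lf, -(2.0 ** (-lf)))
    return out if out.ndim else float(out)


def differential_expression(
    expr: ExpressionMatrix,
    groups: pd.Series | None = None,
    case_label: str = "React-30",
    control_label: str = "NR",
    log_transform_counts: bool = False,
) -> pd.DataFrame:
    """Per-gene t-test and BH FDR between two animal groups.

    ``groups`` defaults to the matrix's own sample group labels. Expression
    is assumed to already be on a log2-like scale; pass
    ``log_transform_counts=True`` to apply log2(x + 1) to raw counts first.
    Genes with zero variance in both groups are flagged (``tested`` False)
    and excluded from the BH family (their p and q are NaN).

    Returns a DataFrame indexed by gene id with columns ``symbol``,
    ``log2fc``, ``fc_linear``, ``p``, ``q``, ``tested``.
    """
    if groups is None:
        groups = expr.groups
    if groups is None:
        raise ValueError("no group labels: pass `groups` or use a matrix with groups")
    groups = groups.reindex(expr.sample_ids)
    for label in (case_label, control_label):
        if not (groups == label).any():
            raise ValueError(f"group label {label!r} absent from sample metadata")
    case_ids = expr.sample_ids[(groups == case_label).to_numpy()]
    ctrl_ids = expr.sample_ids[(groups == control_label).to_numpy()]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    xa = expr.values.loc[:, case_ids].to_numpy(dtype=float)
    xb = expr.values.loc[:, ctrl_ids].to_numpy(dtype=float)
    if log_transform_counts:
        if np.any(xa < 0) or np.any(xb < 0):
            raise ValueError("raw counts must be non-negative")
        xa = np.log2(xa + 1.0)
        xb = np.log2(xb + 1.0)
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    tested = (np.var(xa, axis=1) > 0) | (np.var(xb, axis=1) > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    p = np.where(tested, p, np.nan)
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = bh_fdr(p[tested])
    out = pd.DataFrame(index=expr.feature_ids)
    out["symbol"] = expr.symbols
    out["log2fc"] = log2fc
    out["fc_linear"] = signed_linear_fc(log2fc)
    out["p"] = p
    out["q"] = q
    out["tested"] = tested
    return out


def volcano_classify(
    de_table: pd.DataFrame, log2fc_cut: float = 0.38, p_cut: float = 0.05
) -> tuple[pd.Series, int, int]:
    """Label genes up / down / ns by strict fold-change and p thresholds.

    ``up`` requires log2fc > log2fc_cut and p < p_cut; ``down`` the mirror
    image; everything else (including boundary values, per the strict
    inequalities) is ``ns``. Returns (labels, n_up, n_down).
    """
    if log2fc_cut <= 0 or p_cut <= 0:
        raise ValueError("thresholds must be positive")
    lf = de_table["log2fc"].to_numpy(dtype=float)
    p = de_table["p"].to_numpy(dtype=float)
    sig = p < p_cut  # NaN compares False
    up = sig & (lf > log2fc_cut)
    down = sig & (lf < -log2fc_cut)
    labels = pd.Series(
        np.where(up, "up", np.where(down, "down", "ns")), index=de_table.index, name="label"
    )
    return labels, int(up.sum()), int(down.sum())
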