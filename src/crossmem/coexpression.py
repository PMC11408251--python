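"""Co-expression screening around a target probe.

Every other probe on the array is correlated with the target probe across
subjects; probes exceeding an absolute-correlation threshold form the
target's co-expression neighbourhood, reported both at probe level and
collapsed to unique genes (a gene is a hit if any of its probes passes; the
reported r for a multi-probe gene is its largest-|r| probe).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import _pearson_rows
from .containers import ExpressionMatrix

__all__ = ["coexpression_screen"]


def coexpression_screen(
    expr: ExpressionMatrix, target_probe: str, abs_r_min: float = 0.6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of all probes against one target probe.

    Returns ``(probe_table, gene_table)``: the probe table has one row per
    retained probe (|r| > abs_r_min, strict; the target itself excluded)
    with columns ``symbol``, ``r``, ``p``; the gene table collapses probes
    to unique non-empty symbols keeping each gene's largest-|r| probe.

    Raises
    ------
    KeyError
        If the target probe is absent.
    ValueError
        If the target probe has zero variance or fewer than 3 samples.
    """
    if target_probe not in expr.feature_ids:
        raise KeyError(f"target probe {target_probe!r} not in matrix")
    if expr.n_samples < 3:
        raise ValueError("co-expression screen needs at least 3 samples")
    y = expr.values.loc[target_probe].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError(f"target probe {target_probe!r} is constant")
    x = expr.values.to_numpy(dtype=float)
    r, p = _pearson_rows(x, y)
    table = pd.DataFrame(
        {"symbol": expr.symbols, "r": r, "p": p}, index=expr.feature_ids
    )
    table = table.drop(index=target_probe)
    probe_table = table[np.abs(table["r"]) > abs_r_min].copy()
    probe_table = probe_table.sort_values("r", key=np.abs, ascending=False)
    genes = probe_table[probe_table["symbol"].astype(str).str.len() > 0]
    gene_table = genes.reset_index(names="probe").groupby("symbol", sort=False).head(1)
    gene_table = gene_table.set_index("symbol")
    return probe_table, gene_table
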