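"""Cross-species matching, direction consistency and threshold gates.

Human probe-level symptom correlations and mouse gene-level retrieval fold
changes are joined on case-insensitive gene symbols. Each probe x gene pair
becomes an integration record carrying both effects, its sign quadrant and a
consistency flag (same nonzero sign on both axes). Three selection gates are
provided:

``hybrid``
    effect-size screen: |human r| > r_min AND mouse q < q_max, consistency
    not required — used to characterise the joint sign distribution.
``strict``
    the candidate-gene gate: adds |linear FC| > fc_min and requires a
    consistent direction.
``broad``
    significance-based overlap: human p < p_max AND mouse q < q_alt,
    consistency not required, with one-pass outlier exclusion on the
    standardized mouse fold-change axis.

A final curation step keeps genes whose case-control contrast is itself
significant with a direction matching the symptom correlation (a gene
negatively correlated with severity must be lower in patients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdSpec",
    "match_symbols",
    "classify_direction",
    "build_integration_records",
    "select_overlap",
    "exclude_outliers",
    "cross_species_concordance",
    "curate_three_way",
]

GATES = ("hybrid", "strict", "broad")


@dataclass(frozen=True)
class ThresholdSpec:
    """Thresholds of the integration gates (all inequalities strict)."""

    human_abs_r_min: float = 0.40
    human_p_max: float = 0.05
    mouse_q_max: float = 0.001
    mouse_abs_fc_min: float = 1.36
    mouse_q_alt: float = 0.05
    case_control_p_max: float = 0.05
    outlier_sd: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "human_abs_r_min",
            "human_p_max",
            "mouse_q_max",
            "mouse_abs_fc_min",
            "mouse_q_alt",
            "case_control_p_max",
            "outlier_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.human_abs_r_min >= 1:
            raise ValueError("human_abs_r_min must be < 1")


def match_symbols(
    human_symbols: pd.Series, mouse_symbols: pd.Series | list[str]
) -> pd.Index:
    """Case-insensitive gene-symbol universe shared by both species.

    Symbols are compared upper-cased (human ``PDE4B`` matches mouse
    ``Pde4b``); features without a symbol are dropped. Returns the sorted
    upper-case universe; raises on an empty intersection with a diagnostic
    listing the most frequent unmatched symbols.
    """
    h = pd.Series(human_symbols).dropna().astype(str)
    m = pd.Series(mouse_symbols).dropna().astype(str)
    h = h[h.str.len() > 0].str.upper()
    m = m[m.str.len() > 0].str.upper()
    common = pd.Index(sorted(set(h) & set(m)))
    if len(common) == 0:
        top_h = h.value_counts().index[:5].tolist()
        top_m = m.value_counts().index[:5].tolist()
        raise ValueError(
            "no gene symbols shared between species; "
            f"top human symbols: {top_h}, top mouse symbols: {top_m}"
        )
    return common


def classify_direction(human_r: float, mouse_log2fc: float) -> tuple[str, bool]:
    """Sign quadrant and consistency of one human/mouse effect pair.

    Consistent iff both effects are nonzero and share a sign. A zero on
    either axis is degenerate: not consistent, quadrant named by the nonzero
    sign (or the down-down placeholder when both are zero).
    """
    if np.isnan(human_r) or np.isnan(mouse_log2fc):
        raise ValueError("classify_direction requires finite inputs")
    sh = np.sign(human_r)
    sm = np.sign(mouse_log2fc)
    hu = "up" if sh > 0 else "down"
    mu = "up" if sm > 0 else "down"
    quadrant = f"{hu}-{mu}"
    consistent = bool(sh != 0 and sm != 0 and sh == sm)
    return quadrant, consistent


def build_integration_records(
    assoc: pd.DataFrame, de_table: pd.DataFrame
) -> pd.DataFrame:
    """Join probe-level human associations with mouse DE on gene symbol.

    ``assoc`` must carry ``symbol``, ``pearson_r``, ``pearson_p`` (one row
    per probe); ``de_table`` carries ``symbol``, ``log2fc``, ``fc_linear``,
    ``p``, ``q`` (one row per mouse gene). A human gene with several probes
    yields one record per probe, all mapped to the same mouse gene. Records
    with an undefined effect on either axis are flagged ``degenerate`` and
    excluded from counts downstream.

    Returns one row per probe x mouse-gene match with columns
    ``gene_symbol`` (upper-case key), ``human_probe``, ``human_r``,
    ``human_p``, ``mouse_log2fc``, ``mouse_fc_linear``, ``mouse_p``,
    ``mouse_q``, ``quadrant``, ``consistent``, ``degenerate``.
    """
    universe = match_symbols(assoc["symbol"], de_table["symbol"])
    h = assoc.copy()
    h["gene_symbol"] = h["symbol"].astype(str).str.upper()
    h = h[h["gene_symbol"].isin(universe)]
    m = de_table.copy()
    m["gene_symbol"] = m["symbol"].astype(str).str.upper()
    m = m[m["gene_symbol"].isin(universe)]
    # one mouse row per symbol: RNA-seq tables are gene-level already; if
    # duplicated, keep the most significant entry
    m = m.sort_values("p").groupby("gene_symbol", sort=False).head(1)
    m = m.set_index("gene_symbol")
    rec = pd.DataFrame(
        {
            "gene_symbol": h["gene_symbol"].to_numpy(),
            "human_probe": h.index.to_numpy(),
            "human_r": h["pearson_r"].to_numpy(dtype=float),
            "human_p": h["pearson_p"].to_numpy(dtype=float),
        }
    )
    rec["mouse_log2fc"] = m["log2fc"].reindex(rec["gene_symbol"]).to_numpy(dtype=float)
    rec["mouse_fc_linear"] = m["fc_linear"].reindex(rec["gene_symbol"]).to_numpy(dtype=float)
    rec["mouse_p"] = m["p"].reindex(rec["gene_symbol"]).to_numpy(dtype=float)
    rec["mouse_q"] = m["q"].reindex(rec["gene_symbol"]).to_numpy(dtype=float)
    hr = rec["human_r"].to_numpy()
    mf = rec["mouse_log2fc"].to_numpy()
    degenerate = ~np.isfinite(hr) | ~np.isfinite(mf) | (hr == 0) | (mf == 0)
    quadrant = np.where(
        np.where(np.isfinite(hr), hr, 0) > 0, "up", "down"
    ).astype(object)
    quadrant = quadrant + "-" + np.where(np.where(np.isfinite(mf), mf, 0) > 0, "up", "down")
    consistent = ~degenerate & (np.sign(hr) == np.sign(mf))
    rec["quadrant"] = quadrant
    rec["consistent"] = consistent
    rec["degenerate"] = degenerate
    return rec


def exclude_outliers(
    values: np.ndarray | pd.Series, k_sd: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass upper outlier exclusion at mean + k_sd * sd.

    Returns (boolean keep mask, integer positions excluded). With fewer
    than 3 values, zero spread, or k_sd = inf nothing is excluded.
    """
    v = np.asarray(values, dtype=float)
    keep = np.ones(v.shape, dtype=bool)
    if v.size < 3 or not np.isfinite(k_sd):
        return keep, np.array([], dtype=int)
    sd = v.std(ddof=0)
    if sd == 0:
        return keep, np.array([], dtype=int)
    keep = v <= v.mean() + k_sd * sd
    return keep, np.where(~keep)[0]


def select_overlap(
    records: pd.DataFrame, spec: ThresholdSpec | None = None, gate: str = "strict"
) -> pd.DataFrame:
    """Apply one of the integration gates to a record table.

    See the module docstring for gate semantics; all comparisons are strict.
    An empty input yields an empty output. The returned frame carries a
    ``passed_stage`` column naming the gates each record cleared.
    """
    if spec is None:
        spec = ThresholdSpec()
    if gate not in GATES:
        raise ValueError(f"gate must be one of {GATES}, got {gate!r}")
    if len(records) == 0:
        out = records.copy()
        out["passed_stage"] = pd.Series(dtype=object)
        return out
    ok = ~records["degenerate"].to_numpy(dtype=bool)
    abs_r = np.abs(records["human_r"].to_numpy(dtype=float))
    q = records["mouse_q"].to_numpy(dtype=float)
    if gate == "hybrid":
        mask = ok & (abs_r > spec.human_abs_r_min) & (q < spec.mouse_q_max)
        stages = "human_threshold,mouse_threshold"
    elif gate == "strict":
        mask = (
            ok
            & (abs_r > spec.human_abs_r_min)
            & (q < spec.mouse_q_max)
            & (np.abs(records["mouse_fc_linear"].to_numpy(dtype=float)) > spec.mouse_abs_fc_min)
            & records["consistent"].to_numpy(dtype=bool)
        )
        stages = "human_threshold,mouse_threshold,overlap"
    else:  # broad
        mask = (
            ok
            & (records["human_p"].to_numpy(dtype=float) < spec.human_p_max)
            & (q < spec.mouse_q_alt)
        )
        stages = "human_threshold,mouse_threshold"
    out = records[mask].copy()
    if gate == "broad" and len(out) >= 3:
        fc = out["mouse_fc_linear"].to_numpy(dtype=float)
        z = (fc - fc.mean()) / fc.std(ddof=0) if fc.std(ddof=0) > 0 else np.zeros_like(fc)
        keep, _ = exclude_outliers(z, spec.outlier_sd)
        out = out[keep]
    out["passed_stage"] = stages
    return out


def cross_species_concordance(
    records: pd.DataFrame, fold_change_axis: str = "linear"
) -> dict:
    """Concordance of human and mouse effects over a record set.

    Both axes are z-standardized across records (the human axis is the
    symptom correlation coefficient, the mouse axis the signed fold change
    — linear by default, ``fold_change_axis="log2"`` for the log scale) and
    their Pearson correlation reported, together with the consistent
    fraction and the 2x2 sign-quadrant counts. Degenerate records are
    dropped first; fewer than 3 usable records is an error.
    """
    if fold_change_axis not in ("linear", "log2"):
        raise ValueError("fold_change_axis must be 'linear' or 'log2'")
    rec = records[~records["degenerate"].astype(bool)]
    if len(rec) < 3:
        raise ValueError("need at least 3 non-degenerate records")
    hx = rec["human_r"].to_numpy(dtype=float)
    mx = rec["mouse_fc_linear" if fold_change_axis == "linear" else "mouse_log2fc"].to_numpy(
        dtype=float
    )
    hz = (hx - hx.mean()) / hx.std(ddof=0)
    mz = (mx - mx.mean()) / mx.std(ddof=0)
    r, p = stats.pearsonr(hz, mz)
    counts = rec["quadrant"].value_counts().to_dict()
    quadrants = {q: int(counts.get(q, 0)) for q in ("up-up", "down-down", "up-down", "down-up")}
    return {
        "pearson_r": float(r),
        "p": float(p),
        "consistent_fraction": float(rec["consistent"].mean()),
        "quadrant_counts": quadrants,
        "n": int(len(rec)),
    }


def curate_three_way(
    overlap: pd.DataFrame,
    case_control: pd.DataFrame,
    spec: ThresholdSpec | None = None,
) -> pd.DataFrame:
    """Final curation against the case-control contrast.

    Keeps records from the strict gate whose probe shows a case-control
    p < threshold AND whose patients-vs-controls direction matches the
    symptom-correlation direction (negative correlation with severity must
    pair with lower expression in patients). Probes absent from the
    case-control table are flagged in ``curation_note`` and excluded.
    """
    if spec is None:
        spec = ThresholdSpec()
    out = overlap.copy()
    if len(out) == 0:
        out["cc_p"] = pd.Series(dtype=float)
        out["cc_direction"] = pd.Series(dtype=float)
        out["curation_note"] = pd.Series(dtype=object)
        return out
    probes = out["human_probe"]
    present = probes.isin(case_control.index).to_numpy()
    cc_p = case_control["p"].reindex(probes).to_numpy(dtype=float)
    cc_dir = case_control["direction"].reindex(probes).to_numpy(dtype=float)
    human_sign = np.sign(out["human_r"].to_numpy(dtype=float))
    keep = present & (cc_p < spec.case_control_p_max) & (cc_dir == human_sign)
    out["cc_p"] = cc_p
    out["cc_direction"] = cc_dir
    out["curation_note"] = np.where(present, "", "missing_from_case_control")
    out = out[keep].copy()
    out["passed_stage"] = out["passed_stage"].astype(str) + ",case_control"
    return out
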