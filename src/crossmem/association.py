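"""Per-feature association of expression with symptom severity and diagnosis.

Correlation screens relate each probe's expression to a continuous symptom
score (Pearson, optionally confirmed by Spearman); case-control contrasts
use the pooled-variance two-sample t-test with an optional one-way ANCOVA
adjusting for a covariate such as age. Subjects with a missing phenotype are
dropped pairwise-complete and the number actually used is recorded per
feature. All p-values are two-tailed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "correlate_with_phenotype",
    "partial_correlation",
    "case_control_tests",
]


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of ``x`` against ``y`` and its two-tailed p.

    Rows with zero variance (or if ``y`` has zero variance) yield NaN.
    p-values come from the exact null distribution via
    t = r*sqrt(df/(1-r^2)) with df = n - 2.
    """
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    ssx = np.einsum("ij,ij->i", xc, xc)
    ssy = float(yc @ yc)
    denom = np.sqrt(ssx * ssy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ yc) / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 0.0))
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df)))
    return r, p


def correlate_with_phenotype(
    expr: ExpressionMatrix,
    pheno: pd.DataFrame,
    phenotype_name: str,
    methods: tuple[str, ...] = ("pearson", "spearman"),
) -> pd.DataFrame:
    """Correlate every feature with one phenotype across aligned subjects.

    Subjects are matched by id between the expression columns and the
    phenotype index; subjects with a missing phenotype value are dropped and
    ``n_used`` records how many remained. Spearman is computed by rank
    transformation followed by the same Pearson machinery.

    Returns a DataFrame indexed by feature id with columns ``symbol``,
    ``pearson_r``, ``pearson_p`` (and ``spearman_rho``, ``spearman_p`` if
    requested), ``n_used`` and ``defined`` (False for zero-variance
    features, whose statistics are NaN and which downstream screens skip).
    """
    if phenotype_name not in pheno.columns:
        raise KeyError(f"phenotype {phenotype_name!r} not in phenotype table")
    unknown = set(methods) - {"pearson", "spearman"}
    if unknown:
        raise ValueError(f"unknown correlation methods: {sorted(unknown)}")
    subjects = expr.sample_ids.intersection(pheno.index)
    y_full = pheno.loc[subjects, phenotype_name].astype(float)
    keep = y_full.notna()
    subjects = subjects[keep.to_numpy()]
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects with a non-missing phenotype")
    y = y_full[keep].to_numpy()
    x = expr.values.loc[:, subjects].to_numpy(dtype=float)

    out = pd.DataFrame(index=expr.feature_ids)
    out["symbol"] = expr.symbols
    if "pearson" in methods:
        r, p = _pearson_rows(x, y)
        out["pearson_r"] = r
        out["pearson_p"] = p
    if "spearman" in methods:
        xr = stats.rankdata(x, axis=1)
        yr = stats.rankdata(y)
        rho, p = _pearson_rows(xr, yr)
        out["spearman_rho"] = rho
        out["spearman_p"] = p
    out["n_used"] = len(subjects)
    row_var = np.var(x, axis=1)
    out["defined"] = row_var > 0
    return out


def partial_correlation(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualized on the covariates (plus intercept) by
    least squares and the residuals correlated; the p-value uses
    df = n - 2 - k, k the number of covariates.

    Raises
    ------
    ValueError
        If the covariate design is rank-deficient (collinear columns, named
        in the message when available) or n <= k + 2.
    """
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        c = covariates.to_numpy(dtype=float)
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] == 1 and c.shape[1] > 1:
            c = c.T
        names = [f"covariate_{i}" for i in range(c.shape[1])]
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    n, k = c.shape[0], c.shape[1]
    if not (len(xv) == len(yv) == n):
        raise ValueError("x, y and covariates must have equal length")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), c])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = np.ones((n, 1))
        for j in range(k):
            cand = np.column_stack([cur, c[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(names[j])
            else:
                cur = cand
        raise ValueError(f"collinear covariate columns: {bad}")
    coef_x, *_ = np.linalg.lstsq(design, xv, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, yv, rcond=None)
    rx = xv - design @ coef_x
    ry = yv - design @ coef_y
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # residuals at numerical-noise level mean the variable is fully
    # explained by the covariates: the partial correlation is zero
    tot_x = float(((xv - xv.mean()) ** 2).sum())
    tot_y = float(((yv - yv.mean()) ** 2).sum())
    if sx <= 1e-12 * max(tot_x, 1e-300) or sy <= 1e-12 * max(tot_y, 1e-300):
        return 0.0, 1.0
    r = float(rx @ ry / np.sqrt(sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def case_control_tests(
    expr: ExpressionMatrix,
    pheno: pd.DataFrame,
    group_col: str = "diagnosis",
    case_label: str = "PTSD",
    control_label: str = "control",
    covariate: str | None = None,
) -> pd.DataFrame:
    """Pooled-variance t-test (and optional ANCOVA) per feature.

    The t statistic is signed as cases minus controls; ``direction`` is the
    sign of the case-control mean difference. With ``covariate`` given, a
    one-way ANCOVA fits expression ~ group + covariate per feature and
    reports the group-term F with (1, n - 3) degrees of freedom.

    Returns a DataFrame indexed by feature id with columns ``symbol``,
    ``t_statistic``, ``p``, ``direction`` and, when a covariate is supplied,
    ``ancova_F``, ``ancova_p``.
    """
    subjects = expr.sample_ids.intersection(pheno.index)
    g = pheno.loc[subjects, group_col]
    case_ids = subjects[(g == case_label).to_numpy()]
    ctrl_ids = subjects[(g == control_label).to_numpy()]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError(
            f"each group needs >=2 subjects (got {len(case_ids)} {case_label!r}, "
            f"{len(ctrl_ids)} {control_label!r})"
        )
    xa = expr.values.loc[:, case_ids].to_numpy(dtype=float)
    xb = expr.values.loc[:, ctrl_ids].to_numpy(dtype=float)
    t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    out = pd.DataFrame(index=expr.feature_ids)
    out["symbol"] = expr.symbols
    out["t_statistic"] = t
    out["p"] = p
    out["direction"] = np.sign(diff).astype(int)
    if covariate is not None:
        used = case_ids.append(ctrl_ids)
        cov = pheno.loc[used, covariate].astype(float).to_numpy()
        if np.any(~np.isfinite(cov)):
            raise ValueError(f"covariate {covariate!r} has missing values")
        grp = np.concatenate([np.ones(len(case_ids)), np.zeros(len(ctrl_ids))])
        design = np.column_stack([np.ones(len(used)), grp, cov])
        yv = expr.values.loc[:, used].to_numpy(dtype=float).T  # n x features
        n = design.shape[0]
        xtx_inv = np.linalg.inv(design.T @ design)
        beta = xtx_inv @ design.T @ yv
        resid = yv - design @ beta
        df_resid = n - 3
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df_resid
        se_g = np.sqrt(sigma2 * xtx_inv[1, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            t_g = np.where(se_g > 0, beta[1] / np.where(se_g > 0, se_g, 1.0), np.nan)
        f_g = t_g**2
        out["ancova_F"] = f_g
        out["ancova_p"] = np.where(np.isnan(f_g), np.nan, stats.f.sf(f_g, 1, df_resid))
    return out
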