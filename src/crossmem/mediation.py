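"""Candidate-gene CpG tripartite screen and mediation analysis.

The tripartite screen asks, for every CpG of the candidate gene, whether
its methylation level correlates with both symptom severity and the gene's
mRNA expression, and whether the three pairwise correlation signs are
mutually compatible (sign(meth~expr) * sign(expr~symptom) =
sign(meth~symptom), all nonzero).

Mediation then quantifies the indirect path methylation -> expression ->
symptom with the product-of-coefficients approach: OLS fits give the
a-path (M ~ X), b and c' (Y ~ X + M) and the total effect c (Y ~ X);
indirect = a*b with a Sobel normal-theory test and a nonparametric
case-resampling bootstrap confidence interval (percentile by default,
bias-corrected-and-accelerated optional). For OLS on complete data the
decomposition c = c' + a*b is an algebraic identity.

Because published mediation tables often mix raw and standardized scales,
``mediate_both_scales`` reports both parameterizations side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

__all__ = [
    "MediationResult",
    "tripartite_screen",
    "mediation_analysis",
    "mediate_both_scales",
]


@dataclass(frozen=True)
class MediationResult:
    """Path coefficients and indirect-effect inference of one X -> M -> Y model."""

    a: float
    a_se: float
    a_p: float
    b: float
    b_se: float
    b_p: float
    c_prime: float
    c_prime_se: float
    c_prime_p: float
    c_total: float
    c_total_se: float
    c_total_p: float
    indirect: float
    indirect_se: float
    indirect_p: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_boot: int
    seed: int
    n: int
    standardized: bool

    @property
    def complete_mediation(self) -> bool:
        """Indirect effect significant while the direct path is not (at 0.05)."""
        return self.indirect_p < 0.05 and self.c_prime_p >= 0.05


def _corr_and_p(r: np.ndarray, n: int) -> np.ndarray:
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 0.0))
    return np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1, 0.0, 2 * stats.t.sf(np.abs(t), df)))


def tripartite_screen(
    meth: pd.DataFrame,
    expr: pd.Series,
    symptom: pd.Series,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-CpG tripartite correlation screen.

    ``meth`` is CpGs x subjects (beta values in [0, 1]); ``expr`` and
    ``symptom`` are per-subject vectors. Subjects are aligned by id and
    restricted to complete cases across expression and symptom. A site is
    ``selected`` iff both of its correlations (methylation~symptom and
    methylation~expression) have p < alpha — by default uncorrected, with
    ``bh_correct=True`` applying BH within each 125-site family —
    and ``compatible`` iff the three correlation signs are mutually
    compatible and all nonzero. Constant CpG columns are flagged
    (``defined`` False) and never selected.

    Returns a DataFrame indexed by CpG id with columns ``r_meth_symptom``,
    ``p_meth_symptom``, ``r_meth_expr``, ``p_meth_expr``,
    ``r_expr_symptom``, ``p_expr_symptom``, ``selected``, ``compatible``,
    ``defined``, ``n_used``.
    """
    subjects = meth.columns.intersection(expr.index).intersection(symptom.index)
    e = expr.loc[subjects].astype(float)
    s = symptom.loc[subjects].astype(float)
    complete = e.notna() & s.notna()
    subjects = subjects[complete.to_numpy()]
    if len(subjects) < 3:
        raise ValueError("need at least 3 complete-case subjects")
    x = meth.loc[:, subjects].to_numpy(dtype=float)
    if np.nanmin(x) < 0 or np.nanmax(x) > 1:
        raise ValueError("methylation beta values must lie in [0, 1]")
    ev = e.loc[subjects].to_numpy()
    sv = s.loc[subjects].to_numpy()
    n = len(subjects)

    from .association import _pearson_rows

    r_ms, p_ms = _pearson_rows(x, sv)
    r_me, p_me = _pearson_rows(x, ev)
    r_es = float(np.corrcoef(ev, sv)[0, 1])
    p_es = float(_corr_and_p(np.array([r_es]), n)[0])

    defined = np.var(x, axis=1) > 0
    ps, pe = p_ms.copy(), p_me.copy()
    if bh_correct:
        ps[defined] = bh_fdr(ps[defined])
        pe[defined] = bh_fdr(pe[defined])
    selected = defined & (ps < alpha) & (pe < alpha)
    signs_ok = (np.sign(r_me) != 0) & (np.sign(r_ms) != 0) & (np.sign(r_es) != 0)
    compatible = defined & signs_ok & (np.sign(r_me) * np.sign(r_es) == np.sign(r_ms))
    out = pd.DataFrame(index=meth.index)
    out["r_meth_symptom"] = r_ms
    out["p_meth_symptom"] = p_ms
    out["r_meth_expr"] = r_me
    out["p_meth_expr"] = p_me
    out["r_expr_symptom"] = r_es
    out["p_expr_symptom"] = p_es
    out["selected"] = selected
    out["compatible"] = compatible
    out["defined"] = defined
    out["n_used"] = n
    return out


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple-regression slope, SE and two-tailed p (intercept included)."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    t = beta / se if se > 0 else np.inf
    return beta, se, float(2 * stats.t.sf(abs(t), n - 2))


def _ols_two(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Y ~ 1 + X + M: returns (c', SE, p, b, SE, p)."""
    n = len(x)
    design = np.column_stack([np.ones(n), x, m])
    xtx = design.T @ design
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    dof = n - 3
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta[1], se[1], float(p[1]), beta[2], se[2], float(p[2])


def _boot_indirect(
    x: np.ndarray, m: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized case-resampling bootstrap of the indirect effect a*b."""
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sxm / sxx
        det = sxx * smm - sxm * sxm
        b = (sxx * smy - sxm * sxy) / det
        ab = a * b
    return ab[np.isfinite(ab)]


def mediation_analysis(
    x_meth: np.ndarray | pd.Series,
    m_expr: np.ndarray | pd.Series,
    y_symptom: np.ndarray | pd.Series,
    n_boot: int = 5000,
    seed: int = 0,
    standardize: bool = False,
    ci_method: str = "percentile",
    ci_level: float = 0.95,
) -> MediationResult:
    """Product-of-coefficients mediation of X on Y through M.

    Complete cases only (rows with any missing value dropped; at least 10
    required). The indirect effect a*b carries a Sobel standard error
    sqrt(a^2 SE_b^2 + b^2 SE_a^2) with a normal-theory two-tailed p, and a
    case-resampling bootstrap CI whose randomness is fully determined by
    ``seed``. ``standardize=True`` z-scores X, M and Y first, putting all
    paths on the correlation-like scale.

    Raises ``ValueError`` on X-M collinearity (|corr| == 1) or n < 10.
    """
    if ci_method not in ("percentile", "bca"):
        raise ValueError("ci_method must be 'percentile' or 'bca'")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    x = np.asarray(x_meth, dtype=float).ravel()
    m = np.asarray(m_expr, dtype=float).ravel()
    y = np.asarray(y_symptom, dtype=float).ravel()
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must have equal length")
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[keep], m[keep], y[keep]
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")
    if np.var(x) == 0 or np.var(m) == 0:
        raise ValueError("X and M must be non-constant")
    r_xm = float(np.corrcoef(x, m)[0, 1])
    if abs(r_xm) >= 1.0 - 1e-12:
        raise ValueError("X and M are perfectly collinear")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)

    a, a_se, a_p = _ols_slope(x, m)
    c, c_se, c_p = _ols_slope(x, y)
    c_prime, cp_se, cp_p, b, b_se, b_p = _ols_two(x, m, y)
    indirect = a * b
    sobel_se = float(np.sqrt(a * a * b_se * b_se + b * b * a_se * a_se))
    if sobel_se > 0:
        indirect_p = float(2 * stats.norm.sf(abs(indirect) / sobel_se))
    else:
        indirect_p = 0.0 if indirect != 0 else 1.0

    rng = np.random.default_rng(seed)
    boots = _boot_indirect(x, m, y, n_boot, rng)
    alpha = 1.0 - ci_level
    if ci_method == "percentile":
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    else:
        # BCa: bias correction from the bootstrap distribution, acceleration
        # from the jackknife of the indirect effect
        z0 = stats.norm.ppf(np.clip(np.mean(boots < indirect), 1e-9, 1 - 1e-9))
        jack = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            ai, *_ = _ols_slope(x[mask], m[mask])
            _, _, _, bi, *_ = _ols_two(x[mask], m[mask], y[mask])
            jack[i] = ai * bi
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
        acc = num / den if den > 0 else 0.0
        zlo, zhi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
        p_lo = stats.norm.cdf(z0 + (z0 + zlo) / (1 - acc * (z0 + zlo)))
        p_hi = stats.norm.cdf(z0 + (z0 + zhi) / (1 - acc * (z0 + zhi)))
        lo, hi = np.quantile(boots, [p_lo, p_hi])
    return MediationResult(
        a=a, a_se=a_se, a_p=a_p,
        b=b, b_se=b_se, b_p=b_p,
        c_prime=c_prime, c_prime_se=cp_se, c_prime_p=cp_p,
        c_total=c, c_total_se=c_se, c_total_p=c_p,
        indirect=indirect, indirect_se=sobel_se, indirect_p=indirect_p,
        ci_low=float(lo), ci_high=float(hi), ci_method=ci_method,
        n_boot=n_boot, seed=seed, n=n, standardized=standardize,
    )


def mediate_both_scales(
    x_meth, m_expr, y_symptom, n_boot: int = 5000, seed: int = 0, ci_method: str = "percentile"
) -> dict[str, MediationResult]:
    """Raw-scale and fully standardized mediation fits of the same data."""
    return {
        "raw": mediation_analysis(
            x_meth, m_expr, y_symptom, n_boot=n_boot, seed=seed, standardize=False,
            ci_method=ci_method,
        ),
        "standardized": mediation_analysis(
            x_meth, m_expr, y_symptom, n_boot=n_boot, seed=seed, standardize=True,
            ci_method=ci_method,
        ),
    }
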