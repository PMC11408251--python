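"""Tripartite CpG screen and product-of-coefficients mediation."""

import numpy as np
import pandas as pd
import pytest

from crossmem import (
    mediation_analysis,
    simulate_mediation_cohort,
    tripartite_screen,
)


def _screen_inputs(meth_rows, expr, symptom):
    n = len(expr)
    subjects = [f"s{j}" for j in range(n)]
    meth = pd.DataFrame(
        meth_rows, index=[f"cg{i}" for i in range(len(meth_rows))], columns=subjects
    )
    return meth, pd.Series(expr, index=subjects), pd.Series(symptom, index=subjects)


def test_screen_sign_compatibility_rule(rng):
    """meth positively tracks expression while expression (and methylation)
    negatively track symptoms -> compatible."""
    n = 40
    latent = rng.normal(size=n)
    expr = 2.0 * latent + 0.2 * rng.normal(size=n)
    symptom = -3.0 * expr + rng.normal(size=n)
    meth = 1 / (1 + np.exp(-(0.8 * latent + 0.2 * rng.normal(size=n))))
    m, e, s = _screen_inputs([meth], expr, symptom)
    row = tripartite_screen(m, e, s).iloc[0]
    assert row["r_meth_expr"] > 0 and row["r_meth_symptom"] < 0 and row["r_expr_symptom"] < 0
    assert row["selected"] and row["compatible"]


def test_screen_incompatible_signs_flagged(rng):
    """A frustrated sign triple (meth up with expression, down with
    symptoms, while expression and symptoms correlate positively) is
    selected but flagged incompatible."""
    n = 300
    corr = np.array([[1.0, 0.6, -0.6], [0.6, 1.0, 0.1], [-0.6, 0.1, 1.0]])
    latent = rng.multivariate_normal(np.zeros(3), corr, size=n)
    meth = 1 / (1 + np.exp(-latent[:, 0]))
    expr, symptom = latent[:, 1], latent[:, 2]
    m, e, s = _screen_inputs([meth], expr, symptom)
    row = tripartite_screen(m, e, s).iloc[0]
    assert row["r_meth_expr"] > 0 and row["r_meth_symptom"] < 0 and row["r_expr_symptom"] > 0
    assert row["selected"]
    assert not row["compatible"]


def test_null_site_rarely_selected(rng):
    n = 48
    expr = rng.normal(size=n)
    symptom = rng.normal(size=n)
    meths = rng.uniform(0.1, 0.9, size=(125, n))
    m, e, s = _screen_inputs(meths, expr, symptom)
    table = tripartite_screen(m, e, s)
    assert table["selected"].sum() <= 4  # ~0.3 expected under the null


def test_constant_cpg_flagged_not_selected(rng):
    n = 20
    m, e, s = _screen_inputs([np.full(n, 0.5)], rng.normal(size=n), rng.normal(size=n))
    row = tripartite_screen(m, e, s).iloc[0]
    assert not row["defined"] and not row["selected"]


def test_screen_beta_range_validated(rng):
    m, e, s = _screen_inputs([rng.normal(size=12)], rng.normal(size=12), rng.normal(size=12))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        tripartite_screen(m, e, s)


def test_planted_mediator_site_selected(small_bundle):
    patients = small_bundle.phenotypes.index[
        small_bundle.phenotypes["diagnosis"] == "PTSD"
    ]
    expr = np.log2(
        small_bundle.human_expr.values.loc[small_bundle.truth["target_probe"], patients]
    )
    table = tripartite_screen(
        small_bundle.methylation.loc[:, patients],
        expr,
        small_bundle.phenotypes.loc[patients, "reexperiencing"],
    )
    row = table.loc[small_bundle.truth["mediator_cpg"]]
    assert row["selected"] and row["compatible"]


# --- mediation ---


def test_noiseless_outcome_recovers_paths_exactly(rng):
    """Y exactly b*M + c'*X: b and c' recovered exactly and the
    decomposition identity gives indirect = c - c'."""
    n = 40
    x = rng.normal(size=n)
    m = 2.0 * x + 0.5 * rng.normal(size=n)  # noise in M keeps X, M independent columns
    y = -1.5 * m + 0.7 * x
    res = mediation_analysis(x, m, y, n_boot=200, seed=1)
    assert res.b == pytest.approx(-1.5, abs=1e-10)
    assert res.c_prime == pytest.approx(0.7, abs=1e-10)
    assert res.indirect == pytest.approx(res.c_total - res.c_prime, abs=1e-10)


def test_decomposition_identity_on_random_data(rng):
    for _ in range(25):
        n = int(rng.integers(12, 60))
        x = rng.normal(size=n)
        m = rng.normal(size=n) + 0.3 * x
        y = rng.normal(size=n) + 0.2 * m - 0.1 * x
        res = mediation_analysis(x, m, y, n_boot=10, seed=0)
        assert res.c_total == pytest.approx(res.c_prime + res.indirect, abs=1e-8)


def test_parameter_recovery_within_three_se():
    x, m, y = simulate_mediation_cohort(n=32, a=2.0, b=-1.5, cprime=0.0, seed=42)
    res = mediation_analysis(x, m, y, n_boot=1000, seed=0)
    assert abs(res.a - 2.0) < 3 * res.a_se
    assert abs(res.b + 1.5) < 3 * res.b_se
    assert abs(res.c_prime) < 3 * res.c_prime_se


def test_independent_mediator_gives_null_a_and_ci_covering_zero():
    covered = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        m = rng.normal(size=40)
        y = 0.5 * m + rng.normal(size=40)
        res = mediation_analysis(x, m, y, n_boot=500, seed=seed)
        if res.ci_low <= 0.0 <= res.ci_high:
            covered += 1
    assert covered >= 8


def test_bootstrap_reproducible_with_seed():
    x, m, y = simulate_mediation_cohort(n=32, a=1.0, b=1.0, seed=5)
    r1 = mediation_analysis(x, m, y, n_boot=500, seed=77)
    r2 = mediation_analysis(x, m, y, n_boot=500, seed=77)
    assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
    r3 = mediation_analysis(x, m, y, n_boot=500, seed=78)
    assert (r1.ci_low, r1.ci_high) != (r3.ci_low, r3.ci_high)


def test_matches_pingouin_cross_check():
    pingouin = pytest.importorskip("pingouin")
    x, m, y = simulate_mediation_cohort(n=60, a=1.2, b=-0.8, cprime=0.3, seed=9)
    res = mediation_analysis(x, m, y, n_boot=500, seed=0)
    df = pd.DataFrame({"X": x, "M": m, "Y": y})
    pg = pingouin.mediation_analysis(data=df, x="X", m="M", y="Y", n_boot=500, seed=0)
    pg = pg.set_index("path")
    assert res.a == pytest.approx(float(pg.loc["M ~ X", "coef"]), rel=1e-6)
    assert res.c_total == pytest.approx(float(pg.loc["Total", "coef"]), rel=1e-6)
    assert res.c_prime == pytest.approx(float(pg.loc["Direct", "coef"]), rel=1e-6)
    assert res.indirect == pytest.approx(float(pg.loc["Indirect", "coef"]), rel=1e-6)
    # pingouin's "Y ~ M" row is the unadjusted regression; its conditional
    # b-path is recoverable as indirect / a
    assert res.b == pytest.approx(float(pg.loc["Indirect", "coef"]) / res.a, rel=1e-6)


def test_sobel_and_bootstrap_agree_at_large_n():
    x, m, y = simulate_mediation_cohort(n=500, a=2.0, b=-1.5, seed=3)
    res = mediation_analysis(x, m, y, n_boot=2000, seed=0)
    assert res.indirect_p < 0.001
    assert res.ci_high < 0  # CI excludes zero on the same side
    assert res.ci_low <= res.indirect <= res.ci_high


def test_standardized_scale_indirect_matches_correlation_algebra():
    x, m, y = simulate_mediation_cohort(n=200, a=2.0, b=-1.5, seed=8)
    res = mediation_analysis(x, m, y, n_boot=100, seed=0, standardize=True)
    # standardized a-path equals corr(X, M)
    assert res.a == pytest.approx(float(np.corrcoef(x, m)[0, 1]), abs=1e-10)


def test_collinear_mediator_rejected(rng):
    x = rng.normal(size=20)
    with pytest.raises(ValueError, match="collinear"):
        mediation_analysis(x, 2 * x, rng.normal(size=20), n_boot=10, seed=0)


def test_too_few_cases_rejected(rng):
    with pytest.raises(ValueError, match="at least 10"):
        mediation_analysis(
            rng.normal(size=5), rng.normal(size=5), rng.normal(size=5), n_boot=10, seed=0
        )


def test_bca_interval_available():
    x, m, y = simulate_mediation_cohort(n=32, a=2.0, b=-1.5, seed=11)
    res = mediation_analysis(x, m, y, n_boot=500, seed=0, ci_method="bca")
    assert res.ci_method == "bca"
    assert res.ci_low < res.ci_high
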