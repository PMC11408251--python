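"""Symbol matching, direction consistency, gates and curation."""

import numpy as np
import pandas as pd
import pytest

from crossmem import (
    ThresholdSpec,
    build_integration_records,
    classify_direction,
    cross_species_concordance,
    curate_three_way,
    exclude_outliers,
    match_symbols,
    select_overlap,
)


def _records(human_r, mouse_lfc, human_p=None, mouse_q=None):
    """Minimal record table from effect vectors."""
    hr = np.asarray(human_r, dtype=float)
    mf = np.asarray(mouse_lfc, dtype=float)
    n = len(hr)
    degenerate = (hr == 0) | (mf == 0) | ~np.isfinite(hr) | ~np.isfinite(mf)
    rec = pd.DataFrame(
        {
            "gene_symbol": [f"G{i}" for i in range(n)],
            "human_probe": [f"p{i}" for i in range(n)],
            "human_r": hr,
            "human_p": human_p if human_p is not None else np.full(n, 0.001),
            "mouse_log2fc": mf,
            "mouse_fc_linear": np.sign(mf) * 2.0 ** np.abs(mf),
            "mouse_p": np.full(n, 1e-6),
            "mouse_q": mouse_q if mouse_q is not None else np.full(n, 1e-6),
        }
    )
    rec["quadrant"] = [
        ("up" if r > 0 else "down") + "-" + ("up" if f > 0 else "down")
        for r, f in zip(hr, mf)
    ]
    rec["consistent"] = ~degenerate & (np.sign(hr) == np.sign(mf))
    rec["degenerate"] = degenerate
    return rec


def test_cross_species_symbol_case_matching():
    universe = match_symbols(
        pd.Series(["PDE4B", "RAP1A", "ONLYHUMAN"]), pd.Series(["Pde4b", "Rap1a", "Onlymouse"])
    )
    assert list(universe) == ["PDE4B", "RAP1A"]


def test_toy_symbol_lists_intersection():
    uni = match_symbols(pd.Series(list("ABCDE")), pd.Series(["c", "e", "x", "y", "z"]))
    assert list(uni) == ["C", "E"]


def test_empty_intersection_raises_with_diagnostic():
    with pytest.raises(ValueError, match="no gene symbols shared"):
        match_symbols(pd.Series(["A", "B"]), pd.Series(["X", "Y"]))


def test_classify_direction_quadrants():
    assert classify_direction(-0.46, -0.485) == ("down-down", True)
    assert classify_direction(0.5, 0.4) == ("up-up", True)
    assert classify_direction(0.5, -0.4) == ("up-down", False)
    assert classify_direction(0.5, 0.0) == ("up-down", False)  # degenerate
    with pytest.raises(ValueError):
        classify_direction(np.nan, 0.2)


def test_random_sign_pairs_match_enumeration(rng):
    """1000 random sign pairs: quadrant counts equal a brute-force table."""
    hr = rng.choice([-1.0, 1.0], size=1000) * rng.uniform(0.1, 1, size=1000)
    mf = rng.choice([-1.0, 1.0], size=1000) * rng.uniform(0.1, 2, size=1000)
    counts = {}
    for r, f in zip(hr, mf):
        q, _ = classify_direction(r, f)
        counts[q] = counts.get(q, 0) + 1
    brute = {
        "up-up": int(np.sum((hr > 0) & (mf > 0))),
        "up-down": int(np.sum((hr > 0) & (mf < 0))),
        "down-up": int(np.sum((hr < 0) & (mf > 0))),
        "down-down": int(np.sum((hr < 0) & (mf < 0))),
    }
    assert counts == brute


def test_multi_probe_gene_maps_each_probe():
    assoc = pd.DataFrame(
        {"symbol": ["PDE4B", "PDE4B", "RAP1A"], "pearson_r": [-0.5, -0.3, 0.2],
         "pearson_p": [0.01, 0.1, 0.3]},
        index=["p1", "p2", "p3"],
    )
    de = pd.DataFrame(
        {"symbol": ["Pde4b", "Rap1a"], "log2fc": [-0.6, 0.5],
         "fc_linear": [-1.52, 1.41], "p": [1e-5, 1e-4], "q": [1e-4, 1e-3]},
        index=["g1", "g2"],
    )
    rec = build_integration_records(assoc, de)
    assert len(rec) == 3
    pde = rec[rec["gene_symbol"] == "PDE4B"]
    assert set(pde["human_probe"]) == {"p1", "p2"}
    assert (pde["mouse_log2fc"] == -0.6).all()
    assert pde["consistent"].all()


def test_overlap_boundary_is_strict():
    rec = _records([0.40, 0.41], [-1.0, 1.0])
    rec.loc[0, "human_r"] = 0.40
    out = select_overlap(rec, gate="hybrid")
    assert list(out["gene_symbol"]) == ["G1"]


def test_empty_tables_give_empty_selection():
    rec = _records([], [])
    assert len(select_overlap(rec, gate="strict")) == 0
    assert len(select_overlap(rec, gate="broad")) == 0


def test_strict_gate_requires_consistency_and_fc():
    spec = ThresholdSpec()
    rec = _records(
        human_r=[-0.6, -0.6, -0.6, 0.6],
        mouse_lfc=[-0.6, 0.6, -0.2, 0.6],  # |FC|: 1.52, 1.52, 1.15, 1.52
    )
    out = select_overlap(rec, spec, gate="strict")
    assert sorted(out["gene_symbol"]) == ["G0", "G3"]


def test_planted_truth_recovered_at_huge_effects(small_bundle):
    """Near-noiseless route: records built from the bundle's own tables with
    generous effects select exactly the planted shared-direction genes."""
    from crossmem import correlate_with_phenotype, differential_expression, normalize_microarray

    human = normalize_microarray(small_bundle.human_expr)
    assoc = correlate_with_phenotype(human, small_bundle.phenotypes, "reexperiencing")
    de = differential_expression(small_bundle.mouse_expr)
    rec = build_integration_records(assoc, de)
    out = select_overlap(rec, ThresholdSpec(), gate="strict")
    selected = set(out["gene_symbol"]) - {small_bundle.truth["target_symbol"]}
    truth = set(small_bundle.truth["signal_genes"])
    # default regime: high but not perfect power; no null should enter
    assert len(selected & truth) >= 0.7 * len(truth)
    assert len(selected - truth) == 0


def test_exclude_outliers_cases():
    v = np.ones(5)
    keep, excluded = exclude_outliers(v, 10)
    assert keep.all() and excluded.size == 0

    base = np.random.default_rng(0).normal(size=200)
    spiked = np.append(base, base.mean() + 50 * base.std())
    # oracle: direct mean/sd check with the spike included
    above = spiked > spiked.mean() + 10 * spiked.std()
    assert above[-1] and above.sum() == 1
    keep, excluded = exclude_outliers(spiked, 10)
    assert list(excluded) == [200]

    keep, excluded = exclude_outliers(spiked, np.inf)
    assert keep.all()


def test_concordance_identical_axes_r_one():
    rec = _records([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
    out = cross_species_concordance(rec, fold_change_axis="log2")
    assert out["pearson_r"] == pytest.approx(1.0)
    assert out["consistent_fraction"] == 1.0
    assert out["quadrant_counts"]["up-up"] == 3


def test_concordance_all_down_down():
    rec = _records([-0.3, -0.5, -0.7], [-1.0, -0.5, -2.0])
    out = cross_species_concordance(rec)
    assert out["consistent_fraction"] == 1.0
    assert out["quadrant_counts"]["down-down"] == 3


def test_concordance_requires_three_records():
    with pytest.raises(ValueError):
        cross_species_concordance(_records([0.5, 0.4], [1.0, 1.0]))


def test_independent_axes_give_half_consistency(rng):
    """Across 20 seeds, independent effect signs give ~50% consistency."""
    fracs = []
    for _ in range(20):
        hr = rng.normal(size=500)
        mf = rng.normal(size=500)
        fracs.append(cross_species_concordance(_records(hr, mf))["consistent_fraction"])
    se = np.sqrt(0.25 / (20 * 500))
    assert abs(np.mean(fracs) - 0.5) < 4 * se


def test_consistent_fraction_invariant_under_joint_sign_flip(rng):
    hr = rng.normal(size=100)
    mf = rng.normal(size=100)
    f1 = cross_species_concordance(_records(hr, mf))["consistent_fraction"]
    f2 = cross_species_concordance(_records(-hr, -mf))["consistent_fraction"]
    assert f1 == f2


def test_gates_are_monotone_in_thresholds(rng):
    hr = rng.uniform(-1, 1, size=300)
    mf = rng.normal(size=300)
    hp = rng.uniform(0, 0.2, size=300)
    mq = rng.uniform(0, 0.01, size=300)
    rec = _records(hr, mf, human_p=hp, mouse_q=mq)
    loose = ThresholdSpec()
    for tight in (
        ThresholdSpec(human_abs_r_min=0.6),
        ThresholdSpec(mouse_q_max=1e-4),
        ThresholdSpec(mouse_abs_fc_min=2.0),
    ):
        for gate in ("hybrid", "strict"):
            a = set(select_overlap(rec, loose, gate=gate)["gene_symbol"])
            b = set(select_overlap(rec, tight, gate=gate)["gene_symbol"])
            assert b <= a


def test_curation_direction_rule():
    rec = _records([-0.5, -0.5], [-1.0, -1.0])
    cc = pd.DataFrame(
        {"p": [0.03, 0.01], "direction": [-1, 1]}, index=["p0", "p1"]
    )
    out = curate_three_way(select_overlap(rec, gate="strict"), cc)
    # gene 0: lower in patients matching negative correlation -> retained;
    # gene 1: higher in patients despite negative correlation -> excluded
    assert list(out["gene_symbol"]) == ["G0"]
    assert out["passed_stage"].iloc[0].endswith("case_control")


def test_curation_keeps_only_direction_consistent_half():
    rec = _records([-0.5] * 10, [-1.0] * 10)
    cc = pd.DataFrame(
        {"p": [0.01] * 10, "direction": [-1] * 5 + [1] * 5},
        index=[f"p{i}" for i in range(10)],
    )
    out = curate_three_way(select_overlap(rec, gate="strict"), cc)
    assert sorted(out["gene_symbol"]) == [f"G{i}" for i in range(5)]


def test_curation_missing_probe_excluded():
    rec = _records([-0.5], [-1.0])
    cc = pd.DataFrame({"p": [0.01], "direction": [-1]}, index=["other"])
    out = curate_three_way(select_overlap(rec, gate="strict"), cc)
    assert len(out) == 0
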