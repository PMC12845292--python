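"""Differential-expression tests: exact binomial, NB Wald, BH, set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferromir.datagen import SimConfig, gen_count_matrix
from ferromir.diffexp import (
    DESet,
    ac_exact_test,
    bh_adjust,
    call_de,
    fe_responsive_sets,
    log2_fold_change,
    median_of_ratios_size_factors,
    nb_wald_test,
    normalize_cpm,
    threshold_calls,
)


# ---------------------------------------------------------------------------
# normalization and fold-change


def test_cpm_single_column_and_scale_invariance():
    m = pd.DataFrame({"s1": [2, 3, 5]})
    out = normalize_cpm(m)
    assert list(out["s1"]) == [2e5, 3e5, 5e5]
    two = pd.DataFrame({"s1": [2, 3, 5], "s2": [4, 6, 10]})
    n = normalize_cpm(two)
    assert np.allclose(n["s1"], n["s2"])
    assert np.allclose(n.sum(axis=0), 1e6, rtol=1e-6)
    z = pd.DataFrame({"s1": [1, 1], "s2": [0, 0]})
    with pytest.raises(ValueError):
        normalize_cpm(z)


def test_all_zero_feature_stays_zero():
    m = pd.DataFrame({"s1": [0, 10], "s2": [0, 20]})
    out = normalize_cpm(m)
    assert (out.iloc[0] == 0).all()


@pytest.mark.parametrize(
    "a, b, c, expected",
    [(5, 5, 1, 0.0), (0, 0, 1, 0.0), (1, 7, 1, 2.0)],
)
def test_log2_fold_change_examples(a, b, c, expected):
    assert log2_fold_change(a, b, c) == pytest.approx(expected)


def test_log2_fold_change_validation():
    with pytest.raises(ValueError):
        log2_fold_change(1, 2, pseudocount=0)
    with pytest.raises(ValueError):
        log2_fold_change(-1, 2)


def test_median_of_ratios_recovers_depth_ratio():
    rng = np.random.default_rng(0)
    base = rng.poisson(100, size=500).astype(float) + 1
    m = pd.DataFrame({"s1": base, "s2": base * 2.0})
    sf = median_of_ratios_size_factors(m)
    assert sf["s2"] / sf["s1"] == pytest.approx(2.0, rel=1e-6)


# ---------------------------------------------------------------------------
# exact binomial test


@pytest.mark.parametrize(
    "xa, xb, expected",
    [(5, 5, 1.0), (0, 10, 2 * 0.5**10), (10, 0, 2 * 0.5**10), (0, 0, 1.0)],
)
def test_ac_exact_examples(xa, xb, expected):
    assert ac_exact_test(xa, xb, 1e6, 1e6) == pytest.approx(expected)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    xa=st.integers(0, 200),
    xb=st.integers(0, 200),
    na=st.integers(1, 10**7),
    nb=st.integers(1, 10**7),
)
def test_ac_exact_exchange_symmetry(xa, xb, na, nb):
    assert ac_exact_test(xa, xb, na, nb) == pytest.approx(
        ac_exact_test(xb, xa, nb, na), rel=1e-9
    )


def test_ac_exact_validation():
    with pytest.raises(ValueError):
        ac_exact_test(-1, 0, 1, 1)
    with pytest.raises(ValueError):
        ac_exact_test(0, 0, 0, 1)


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_example_and_degenerate_cases():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        bh_adjust([1.5])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_never_decreases_and_bounded(ps):
    q = bh_adjust(ps)
    assert (q >= np.asarray(ps) - 1e-12).all()
    assert (q <= 1 + 1e-12).all()
    order = np.argsort(ps)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# NB Wald test


def test_identical_replicates_give_null_result():
    lfc, p = nb_wald_test([10, 12, 11], [10, 12, 11], [1e6] * 3, [1e6] * 3)
    assert lfc == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_all_zero_feature_returns_null():
    lfc, p = nb_wald_test([0, 0], [0, 0], [1e6] * 2, [1e6] * 2)
    assert (lfc, p) == (0.0, 1.0)


def test_wald_requires_replicates():
    with pytest.raises(ValueError):
        nb_wald_test([5], [5, 6], [1e6], [1e6] * 2)


def test_null_type_one_error_in_band():
    data, _ = gen_count_matrix(SimConfig(seed=11, n_features=2000, dispersion=0.1))
    de = call_de(data, "FeD_L", "CK_L", assay="mRNA")
    frac = float((de.table["p"] <= 0.05).mean())
    assert 0.03 <= frac <= 0.07


def _balanced_effects(n_planted, magnitude, group="FeD_L"):
    eff = {}
    for i in range(n_planted):
        sign = 1.0 if i < n_planted // 2 else -1.0
        eff[f"feat{i:04d}"] = {group: sign * magnitude}
    return eff


def test_power_at_planted_lfc_two():
    eff = _balanced_effects(500, 2.0)
    data, _ = gen_count_matrix(
        SimConfig(seed=12, n_features=2000, dispersion=0.1, effect_table=eff)
    )
    de = call_de(data, "FeD_L", "CK_L", assay="mRNA", norm="median-of-ratios")
    planted = [f"feat{i:04d}" for i in range(500)]
    assert de.table.loc[planted, "called"].mean() >= 0.95


def test_lfc_recovery_within_tenth():
    eff = _balanced_effects(500, 1.0)
    data, _ = gen_count_matrix(
        SimConfig(seed=13, n_features=2000, dispersion=0.1, effect_table=eff)
    )
    de = call_de(data, "FeD_L", "CK_L", assay="mRNA", norm="median-of-ratios")
    up = [f"feat{i:04d}" for i in range(250)]
    down = [f"feat{i:04d}" for i in range(250, 500)]
    assert de.table.loc[up, "lfc"].mean() == pytest.approx(1.0, abs=0.1)
    assert de.table.loc[down, "lfc"].mean() == pytest.approx(-1.0, abs=0.1)


def test_bh_fdr_controlled_empirically():
    fdps = []
    for run in range(20):
        eff = _balanced_effects(200, 2.0)
        data, _ = gen_count_matrix(
            SimConfig(seed=100 + run, n_features=2000, dispersion=0.1, effect_table=eff)
        )
        de = call_de(data, "FeD_L", "CK_L", assay="mRNA", norm="median-of-ratios")
        called = set(de.up) | set(de.down)
        truth = {f"feat{i:04d}" for i in range(200)}
        if called:
            fdps.append(len(called - truth) / len(called))
    assert np.mean(fdps) <= 0.10


# ---------------------------------------------------------------------------
# calling semantics


def test_threshold_semantics_inclusive_boundaries():
    lfc = np.array([0.4, 0.5, 0.5, -0.5, 2.0])
    p = np.array([0.001, 0.05, 0.051, 0.05, 0.05])
    called = threshold_calls(lfc, p, alpha=0.05, lfc_min=0.5)
    assert list(called) == [False, True, False, True, True]


def test_call_de_assay_thresholds_and_validation():
    data, _ = gen_count_matrix(SimConfig(seed=14, n_features=100))
    mi = call_de(data, "FeD_L", "CK_L", assay="miRNA")
    assert mi.lfc_min == 0.5 and not mi.use_adjusted
    mr = call_de(data, "FeD_L", "CK_L", assay="mRNA")
    assert mr.lfc_min == 1.0 and mr.use_adjusted
    with pytest.raises(ValueError):
        call_de(data, "FeD_L", "CK_L", assay="protein")
    with pytest.raises(ValueError):
        call_de(data, "FeD_X", "CK_L")


def test_called_features_satisfy_their_thresholds():
    eff = _balanced_effects(50, 1.5)
    data, _ = gen_count_matrix(
        SimConfig(seed=15, n_features=300, dispersion=0.1, effect_table=eff)
    )
    de = call_de(data, "FeD_L", "CK_L", assay="miRNA")
    t = de.table
    for f in de.up | de.down:
        assert abs(t.loc[f, "lfc"]) >= 0.5
        assert t.loc[f, "p"] <= 0.05
    assert not (de.up & de.down)


# ---------------------------------------------------------------------------
# Fe-responsive set algebra


def _mkdeset(contrast, up, down):
    feats = sorted(up | down)
    table = pd.DataFrame(
        {"lfc": 0.0, "p": 0.0, "q": 0.0, "called": True},
        index=pd.Index(feats, name="feature"),
    )
    return DESet(contrast=contrast, table=table, up=set(up), down=set(down))


def test_opposite_trend_hand_example():
    de = {
        "FeD_L_vs_CK_L": _mkdeset("FeD_L_vs_CK_L", {"a", "b", "c"}, set()),
        "RE_L_vs_FeD_L": _mkdeset("RE_L_vs_FeD_L", set(), {"b", "c", "d"}),
        "Fol_L_vs_FeD_L": _mkdeset("Fol_L_vs_FeD_L", set(), {"c", "d"}),
    }
    sets = fe_responsive_sets(de, "L")
    assert sets.pattern_a == {"c"}
    assert sets.pattern_b == set()
    assert sets.down_after_resupply == {"b", "c", "d"}


def test_disjoint_inputs_give_empty_patterns():
    de = {
        "FeD_R_vs_CK_R": _mkdeset("FeD_R_vs_CK_R", {"a"}, {"z"}),
        "RE_R_vs_FeD_R": _mkdeset("RE_R_vs_FeD_R", {"b"}, {"y"}),
        "Fol_R_vs_FeD_R": _mkdeset("Fol_R_vs_FeD_R", {"c"}, {"x"}),
    }
    sets = fe_responsive_sets(de, "R")
    assert sets.pattern_a == set() and sets.pattern_b == set()


def test_pattern_b_mirrors_pattern_a_under_relabeling():
    up, dn = {"a", "b"}, {"p", "q"}
    de_fwd = {
        "FeD_L_vs_CK_L": _mkdeset("FeD_L_vs_CK_L", up, dn),
        "RE_L_vs_FeD_L": _mkdeset("RE_L_vs_FeD_L", dn, up),
        "Fol_L_vs_FeD_L": _mkdeset("Fol_L_vs_FeD_L", dn, up),
    }
    de_mirror = {
        "FeD_L_vs_CK_L": _mkdeset("FeD_L_vs_CK_L", dn, up),
        "RE_L_vs_FeD_L": _mkdeset("RE_L_vs_FeD_L", up, dn),
        "Fol_L_vs_FeD_L": _mkdeset("Fol_L_vs_FeD_L", up, dn),
    }
    a = fe_responsive_sets(de_fwd, "L")
    b = fe_responsive_sets(de_mirror, "L")
    assert a.pattern_a == b.pattern_b and a.pattern_b == b.pattern_a


def test_missing_contrast_rejected_and_ck_baseline_switch():
    de = {"FeD_L_vs_CK_L": _mkdeset("FeD_L_vs_CK_L", {"a"}, set())}
    with pytest.raises(ValueError):
        fe_responsive_sets(de, "L")
    de.update(
        {
            "RE_L_vs_CK_L": _mkdeset("RE_L_vs_CK_L", set(), {"a"}),
            "Fol_L_vs_CK_L": _mkdeset("Fol_L_vs_CK_L", set(), {"a"}),
        }
    )
    sets = fe_responsive_sets(de, "L", resupply_baseline="CK")
    assert sets.pattern_a == {"a"}
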