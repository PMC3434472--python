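"""Evaluation statistics: ANOVA, t/LSD, Holm, grouping, order machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from _oracles import oracle_anova
from cresstex import evaluation as ev


def _balanced_234(seed=7, n_per_cell=5):
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(2):
        for b in range(3):
            for c in range(4):
                for _ in range(n_per_cell):
                    rows.append(dict(
                        A=f"a{a}", B=f"b{b}", C=f"c{c}",
                        y=rng.normal(0.5 * a + 0.2 * b + 0.1 * c + 0.3 * a * b, 1.0),
                    ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Factorial ANOVA
# ---------------------------------------------------------------------------

def test_anova_matches_projection_oracle():
    df = _balanced_234()
    tab = ev.factorial_anova(df, "y", ["A", "B", "C"])
    ref = oracle_anova(df, "y", ["A", "B", "C"])
    assert set(tab.effects) == set(ref) - {"Residual"}
    for eff in tab.effects:
        assert tab.F(eff) == pytest.approx(ref[eff]["F"], abs=1e-8)
        assert tab.p(eff) == pytest.approx(ref[eff]["p"], abs=1e-8)
    assert tab.residual_df == ref["Residual"]["df"]


def test_anova_one_factor_equals_t_squared():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 9)
    b = rng.normal(0.8, 1, 9)
    df = pd.DataFrame(dict(g=["a"] * 9 + ["b"] * 9, y=np.concatenate([a, b])))
    tab = ev.factorial_anova(df, "y", ["g"])
    t, p = ev.two_sample_t(a, b)
    assert tab.F("g") == pytest.approx(t * t, rel=1e-10)
    assert tab.p("g") == pytest.approx(p, rel=1e-10)


def test_anova_balanced_decomposition_sums_to_total():
    df = _balanced_234(seed=11)
    tab = ev.factorial_anova(df, "y", ["A", "B", "C"])
    y = df["y"].to_numpy()
    total = float(((y - y.mean()) ** 2).sum())
    ss = sum(float(tab.table.loc[e, "sum_sq"]) for e in tab.effects)
    assert ss + tab.residual_df * tab.residual_ms == pytest.approx(total, rel=1e-9)


def test_anova_constant_response_degenerate():
    df = pd.DataFrame(dict(g=["a", "a", "b", "b"], y=[2.0] * 4))
    tab = ev.factorial_anova(df, "y", ["g"])
    assert tab.F("g") == 0.0
    assert tab.p("g") == 1.0
    assert float(tab.table.loc["g", "sum_sq"]) == 0.0


def test_anova_errors():
    df = pd.DataFrame(dict(g=["a", "a", "b"], y=[1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="no data"):
        ev.factorial_anova(df.assign(y=np.nan), "y", ["g"])
    with pytest.raises(ValueError, match="level"):
        ev.factorial_anova(df.assign(g="a"), "y", ["g"])
    with pytest.raises(ValueError, match="at least one factor"):
        ev.factorial_anova(df, "y", [])
    empty_cell = pd.DataFrame(dict(
        A=["a", "a", "b", "b"], B=["x", "x", "y", "y"], y=[1.0, 2.0, 3.0, 4.0]
    ))
    with pytest.raises(ValueError, match="not estimable"):
        ev.factorial_anova(empty_cell, "y", ["A", "B"])
    saturated = pd.DataFrame(dict(g=["a", "b"], y=[1.0, 2.0]))
    with pytest.raises(ValueError, match="saturated"):
        ev.factorial_anova(saturated, "y", ["g"])


def test_anova_tolerates_hazardous_factor_names():
    # "C" and "Sum" are live identifiers inside a patsy formula
    df = _balanced_234().rename(columns={"A": "C", "B": "Sum", "C": "Q"})
    tab = ev.factorial_anova(df, "y", ["C", "Sum", "Q"])
    ref = oracle_anova(df, "y", ["C", "Sum", "Q"])
    for eff in tab.effects:
        assert tab.F(eff) == pytest.approx(ref[eff]["F"], abs=1e-8)


# ---------------------------------------------------------------------------
# t-test and LSD
# ---------------------------------------------------------------------------

def test_two_sample_t_identical_samples():
    t, p = ev.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0
    assert p == 1.0


def test_two_sample_t_textbook_case():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([3.0, 4.0, 5.0, 6.0])
    t, p = ev.two_sample_t(a, b)
    # pooled sd^2 = 5/3, se = sqrt(5/3 * 1/2), t = -2 / se
    se = np.sqrt((5 / 3) * 0.5)
    assert t == pytest.approx(-2 / se)
    assert p == pytest.approx(2 * stats.t.sf(2 / se, 6))


def test_two_sample_t_errors():
    with pytest.raises(ValueError, match="n >= 2"):
        ev.two_sample_t([1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="pooled variance"):
        ev.two_sample_t([1.0, 1.0], [1.0, 1.0])


def test_lsd_reduces_to_pooled_t_in_two_cell_design():
    rng = np.random.default_rng(21)
    df = pd.DataFrame(dict(
        g=["a"] * 6 + ["b"] * 6, y=rng.normal([0] * 6 + [1] * 6, 1.0)
    ))
    tab = ev.factorial_anova(df, "y", ["g"])
    # LSD must use residual MS; in a two-cell one-factor model that's the
    # pooled variance, so LSD == pooled t-test
    t_lsd, p_lsd = ev.lsd_posthoc(tab, df, "y", "g", "a", "b")
    t, p = ev.two_sample_t(df[df.g == "a"].y, df[df.g == "b"].y)
    assert t_lsd == pytest.approx(t, rel=1e-9)
    assert p_lsd == pytest.approx(p, rel=1e-9)


def test_lsd_equal_means_and_missing_group():
    df = pd.DataFrame(dict(g=["a", "a", "b", "b"], y=[1.0, 2.0, 1.0, 2.0]))
    tab = ev.factorial_anova(df, "y", ["g"])
    t, p = ev.lsd_posthoc(tab, df, "y", "g", "a", "b")
    assert t == 0.0 and p == 1.0
    with pytest.raises(ValueError, match="absent"):
        ev.lsd_posthoc(tab, df, "y", "g", "a", "zzz")


# ---------------------------------------------------------------------------
# Holm correction
# ---------------------------------------------------------------------------

def test_holm_single_p():
    reject, _ = ev.holm_correction([0.04], alpha=0.05)
    assert reject.tolist() == [True]


def test_holm_105_copies_none_rejected():
    reject, _ = ev.holm_correction([0.04] * 105, alpha=0.05)
    assert not reject.any()  # 0.04 > 0.05 / 105


def test_holm_step_down_thresholds():
    # thresholds 0.05/3, 0.05/2, 0.05/1 = 0.0167, 0.025, 0.05
    reject, adj = ev.holm_correction([0.001, 0.01, 0.03], alpha=0.05)
    assert reject.tolist() == [True, True, True]
    assert np.all(np.diff(np.sort(adj)) >= 0)
    # smallest p (0.018) misses the first threshold 0.05/3, so the
    # step-down stops immediately and nothing is rejected
    reject2, _ = ev.holm_correction([0.02, 0.018, 0.03], alpha=0.05)
    assert reject2.tolist() == [False, False, False]


def test_holm_input_validation():
    with pytest.raises(ValueError):
        ev.holm_correction([0.5, 1.2])
    with pytest.raises(ValueError):
        ev.holm_correction([0.5, np.nan])
    reject, adj = ev.holm_correction([])
    assert reject.size == 0 and adj.size == 0


@given(seed=st.integers(0, 500), m=st.integers(1, 30))
def test_holm_dominates_bonferroni(seed, m):
    p = np.random.default_rng(seed).uniform(0, 1, m)
    holm, _ = ev.holm_correction(p, alpha=0.05)
    bonf = p <= 0.05 / m
    assert np.all(holm[bonf])  # every Bonferroni rejection is a Holm rejection


# ---------------------------------------------------------------------------
# Variable grouping
# ---------------------------------------------------------------------------

def test_group_duplicate_columns_share_component():
    rng = np.random.default_rng(2)
    x = rng.normal(size=100)
    feats = pd.DataFrame(dict(u=x, v=x.copy(), w=rng.normal(size=100)))
    g = ev.correlate_and_group(feats, rng.normal(size=100))
    assert g.corr.loc["u", "v"] == pytest.approx(1.0)
    assert {"u", "v"} in g.components
    assert g.labels["w"] == "intermediate"


def test_group_independent_noise_is_singletons():
    rng = np.random.default_rng(4)
    feats = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
    g = ev.correlate_and_group(feats, rng.normal(size=200))
    assert all(len(c) == 1 for c in g.components)


def test_group_evaporation_labels():
    rng = np.random.default_rng(8)
    evap = rng.normal(size=300)
    shared = rng.normal(size=300)
    feats = pd.DataFrame(dict(
        g2a=evap + 0.3 * rng.normal(size=300),
        g2b=evap + 0.3 * rng.normal(size=300),
        g1a=shared + 0.3 * rng.normal(size=300),
        g1b=shared + 0.3 * rng.normal(size=300),
    ))
    g = ev.correlate_and_group(feats, evap)
    assert g.labels["g2a"] == g.labels["g2b"] == "II"
    assert g.labels["g1a"] == g.labels["g1b"] == "I"


def test_group_zero_variance_dropped_with_warning_and_min_rows():
    feats = pd.DataFrame(dict(a=[1.0, 2.0, 3.0, 4.0], b=[5.0] * 4,
                              c=[2.0, 1.0, 4.0, 3.0]))
    with pytest.warns(UserWarning, match="zero-variance"):
        g = ev.correlate_and_group(feats, np.arange(4.0))
    assert "b" not in g.corr.columns
    with pytest.raises(ValueError, match=">= 3"):
        ev.correlate_and_group(feats.head(2), np.arange(2.0))


# ---------------------------------------------------------------------------
# Processing-order machinery
# ---------------------------------------------------------------------------

def _order_frame(slope=0.0, seed=0, n_days=6):
    rng = np.random.default_rng(seed)
    rows = []
    for day in range(1, n_days + 1):
        for order in range(1, 7):
            for _ in range(3):
                rows.append(dict(
                    day=day, processing_order=order,
                    y=10 + 0.5 * day + slope * order + rng.normal(0, 0.3),
                ))
    return pd.DataFrame(rows)


def test_order_test_detects_injected_trend_not_null():
    assert ev.processing_order_test(_order_frame(slope=1.0), "y") < 1e-6
    # under the null a single draw should rarely be extreme; use a mild bound
    assert ev.processing_order_test(_order_frame(slope=0.0, seed=5), "y") > 0.001


def test_order_test_constant_response_and_errors():
    df = _order_frame().assign(y=3.0)
    assert ev.processing_order_test(df, "y") == 1.0
    with pytest.raises(ValueError, match="no control data"):
        ev.processing_order_test(df.assign(y=np.nan), "y")
    single = df[df.processing_order == 1]
    with pytest.raises(ValueError, match="order levels"):
        ev.processing_order_test(single, "y")
    with pytest.raises(ValueError, match="mode"):
        ev.processing_order_test(df, "y", mode="log")


def test_order_test_subtract_mode():
    p = ev.processing_order_test(_order_frame(slope=1.0), "y", mode="subtract")
    assert p < 1e-6


def test_order_correction_removes_exact_trend():
    order = np.tile(np.arange(1, 7), 4).astype(float)
    y = 5.0 + 2.0 * order
    corrected, slope = ev.order_correction(y, order)
    assert slope == pytest.approx(2.0)
    np.testing.assert_allclose(corrected, np.full_like(y, 5.0 + 2.0 * order.mean()))
    assert corrected.mean() == pytest.approx(y.mean())  # grand mean preserved


def test_order_correction_idempotent_and_residual_slope_zero():
    rng = np.random.default_rng(12)
    order = np.tile(np.arange(1, 7), 10).astype(float)
    y = rng.normal(0, 1, order.size) + 0.4 * order
    once, _ = ev.order_correction(y, order)
    _, refit = ev.order_correction(once, order)
    assert abs(refit) <= 1e-10
    twice, _ = ev.order_correction(once, order)
    np.testing.assert_allclose(twice, once, atol=1e-12)


def test_order_correction_single_level_errors():
    with pytest.raises(ValueError, match="distinct"):
        ev.order_correction([1.0, 2.0], [3, 3])


# ---------------------------------------------------------------------------
# Effect vs evaporation correlation
# ---------------------------------------------------------------------------

def test_effect_vs_evaporation_extremes_and_errors():
    evap = np.array([14.0, 18.0, 21.0, 25.0])
    r, _ = ev.effect_vs_evaporation(evap * 2 - 3, evap)
    assert r == pytest.approx(1.0)
    orth = np.array([1.0, -1.0, -1.0, 1.0])
    evap2 = np.array([-3.0, -1.0, 1.0, 3.0])
    r2, _ = ev.effect_vs_evaporation(orth, evap2)
    assert r2 == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="length"):
        ev.effect_vs_evaporation([1, 2, 3], [1, 2])
    with pytest.raises(ValueError, match=">= 3"):
        ev.effect_vs_evaporation([1, 2], [1, 2])
    with pytest.raises(ValueError, match="variance"):
        ev.effect_vs_evaporation([1.0, 1.0, 1.0], [1, 2, 3])


def test_effect_vs_evaporation_recovers_correlation():
    rng = np.random.default_rng(6)
    rs = []
    for _ in range(200):
        x = rng.normal(size=8)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=8)
        r, _ = ev.effect_vs_evaporation(y, x)
        rs.append(r)
    assert np.median(rs) == pytest.approx(0.8, abs=0.1)
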