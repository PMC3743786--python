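"""Comparative Ct, Welch/paired t, Mann-Whitney, Tukey-Kramer, and the
fold-change + Welch candidate screen, each checked against an independent
oracle (closed forms, exhaustive enumeration, or the studentized-range
distribution directly)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import stdtr
from scipy.stats import studentized_range

from mirprof import (
    CtMeasurement,
    mann_whitney,
    paired_t,
    relative_expression,
    screen_candidates,
    tukey_kramer,
    welch_t,
)
from mirprof.stats import group_tests


# ----------------------------------------------------------- oracles

def welch_oracle(a, b):
    """Closed-form Welch t with Satterthwaite df; p from the t CDF."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * (1 - stdtr(df, abs(t)))
    return t, p


def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating every assignment of the
    pooled values to the two groups."""
    a, b = list(a), list(b)
    pooled = a + b

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + 0.5 * sum(
            1 for x in group_a for y in group_b if x == y
        )

    u_obs = u_stat(a, b)
    mean_u = len(a) * len(b) / 2.0
    total = 0
    as_extreme = 0
    for idx in itertools.combinations(range(len(pooled)), len(a)):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            as_extreme += 1
    return as_extreme / total


# ----------------------------------------------------------- comparative Ct

def test_ddct_closed_form():
    ms = [
        CtMeasurement("cal", (28.0,), (20.0,)),
        CtMeasurement("s1", (25.0,), (20.0,)),
    ]
    out = {r.sample_id: r for r in relative_expression(ms, "cal")}
    assert out["s1"].ddct == pytest.approx(-3.0)
    assert out["s1"].rq == pytest.approx(8.0)
    assert out["cal"].rq == 1.0


def test_all_samples_identical_to_calibrator_have_rq_one():
    ms = [CtMeasurement(f"s{i}", (24.0, 24.2), (19.9, 20.1)) for i in range(4)]
    assert all(r.rq == pytest.approx(1.0) for r in relative_expression(ms, "s0"))


def test_missing_or_invalid_ct_rejected():
    with pytest.raises(ValueError):
        CtMeasurement("s", (float("nan"),), (20.0,))
    with pytest.raises(ValueError):
        CtMeasurement("s", (), (20.0,))
    with pytest.raises(ValueError):
        relative_expression([CtMeasurement("s", (25.0,), (20.0,))], "absent")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(shift=st.floats(min_value=-5, max_value=5, allow_nan=False))
def test_rq_invariant_to_constant_ct_shift(shift):
    base = [("cal", 28.0, 20.0), ("s1", 25.0, 21.0), ("s2", 30.0, 19.5)]
    plain = relative_expression(
        [CtMeasurement(s, (t,), (r,)) for s, t, r in base], "cal"
    )
    shifted = relative_expression(
        [CtMeasurement(s, (t + shift,), (r + shift,)) for s, t, r in base], "cal"
    )
    for x, y in zip(plain, shifted):
        assert y.rq == pytest.approx(x.rq, rel=1e-9)


# ------------------------------------------------------------------ Welch

def test_welch_identical_groups():
    t, p = welch_t((1, 2, 3), (1, 2, 3))
    assert t == 0.0 and p == pytest.approx(1.0)


def test_welch_agrees_with_closed_form_oracle():
    a, b = (10, 11, 12), (20, 21, 22)
    t, p = welch_t(a, b)
    t0, p0 = welch_oracle(a, b)
    assert t == pytest.approx(t0, abs=1e-9)
    assert p == pytest.approx(p0, abs=1e-9)


def test_welch_symmetry_and_errors():
    a, b = (1.0, 2.0, 4.0), (3.0, 5.0, 9.0)
    t_ab, p_ab = welch_t(a, b)
    t_ba, p_ba = welch_t(b, a)
    assert t_ab == pytest.approx(-t_ba)
    assert p_ab == pytest.approx(p_ba)
    with pytest.raises(ValueError):
        welch_t((1, 1, 1), (2, 2, 2))
    with pytest.raises(ValueError):
        welch_t((1,), (2, 3))


def test_welch_p_monotone_in_effect_size():
    a = (0.0, 1.0, 2.0)
    ps = [welch_t(a, tuple(x + d for x in a))[1] for d in (0.5, 1.0, 2.0, 4.0)]
    assert all(x > y for x, y in zip(ps, ps[1:]))


# ----------------------------------------------------------------- paired

def test_paired_t_matches_one_sample_oracle():
    pairs = [(1, 2), (2, 3), (3, 5)]
    diffs = np.array([x - y for x, y in pairs], float)
    t0 = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(len(diffs)))
    p0 = 2 * (1 - stdtr(len(diffs) - 1, abs(t0)))
    t, p = paired_t(pairs)
    assert t == pytest.approx(t0, abs=1e-9)
    assert p == pytest.approx(p0, abs=1e-9)


def test_paired_t_degenerate_and_symmetric_cases():
    with pytest.raises(ValueError):
        paired_t([(1, 1), (2, 2), (3, 3)])  # zero-variance differences
    t, p = paired_t([(1, 0), (0, 1), (2, 1), (1, 2)])  # differences +1,-1,+1,-1
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


# ----------------------------------------------------------- Mann-Whitney

def test_mw_small_sample_exact_p():
    u, p = mann_whitney((1, 2), (3, 4))
    assert u == 0.0
    assert p == pytest.approx(2 / 6)


def test_mw_single_tied_values():
    u, p = mann_whitney((5.0,), (5.0,))
    assert u == 0.5
    assert p == 1.0


@pytest.mark.parametrize("n_a,n_b,seed", [(2, 3, 0), (3, 3, 1), (4, 4, 2), (5, 5, 3), (4, 6, 4)])
def test_mw_exact_equals_exhaustive_enumeration(n_a, n_b, seed):
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(1.0, n_a + n_b + 1.0))  # tie-free
    a, b = vals[:n_a], vals[n_a:]
    _, p = mann_whitney(a, b, exact=True)
    assert p == pytest.approx(mw_exact_oracle(a, b), abs=1e-12)


def test_mw_exact_and_asymptotic_agree_at_moderate_n():
    rng = np.random.default_rng(6)
    vals = rng.permutation(np.arange(1.0, 13.0))
    a, b = vals[:6], vals[6:]
    _, p_exact = mann_whitney(a, b, exact=True)
    _, p_asym = mann_whitney(a, b, exact=False)
    assert abs(p_exact - p_asym) < 0.05


def test_mw_symmetry():
    a, b = (1.0, 4.0, 6.0), (2.0, 3.0, 9.0, 11.0)
    u_ab, p_ab = mann_whitney(a, b)
    u_ba, p_ba = mann_whitney(b, a)
    assert u_ab + u_ba == pytest.approx(len(a) * len(b))
    assert p_ab == pytest.approx(p_ba)


# ----------------------------------------------------------- Tukey-Kramer

def test_tukey_identical_groups_give_p_one():
    table = tukey_kramer([(1, 2, 3), (1, 2, 3), (1, 2, 3)])
    assert table["p_value"].tolist() == pytest.approx([1.0, 1.0, 1.0])


def test_tukey_separated_group_detected():
    table = tukey_kramer([(0, 1), (0, 1), (10, 11)], names=["a", "b", "c"])
    p = {(r.group_a, r.group_b): r.p_value for r in table.itertuples()}
    assert p[("a", "b")] > 0.05
    assert p[("a", "c")] < 0.05
    assert p[("b", "c")] < 0.05


def test_tukey_two_groups_matches_studentized_range():
    a, b = (1.0, 3.0, 4.0), (6.0, 7.0, 9.0)
    table = tukey_kramer([a, b])
    arrs = [np.asarray(a), np.asarray(b)]
    df = sum(x.size for x in arrs) - 2
    mse = sum((x.size - 1) * x.var(ddof=1) for x in arrs) / df
    se = math.sqrt(mse / 2 * (1 / arrs[0].size + 1 / arrs[1].size))
    q = abs(arrs[0].mean() - arrs[1].mean()) / se
    p0 = studentized_range.sf(q, 2, df)
    assert table["p_value"].iloc[0] == pytest.approx(p0, abs=1e-9)


def test_tukey_input_validation():
    with pytest.raises(ValueError):
        tukey_kramer([(1, 2)])
    with pytest.raises(ValueError):
        tukey_kramer([(1, 2), (3,)])
    with pytest.raises(ValueError):
        tukey_kramer([(1, 1), (2, 2)])


# ------------------------------------------------------------------ screen

def _matrix(rng, n_features, fold_features=(), fold=4.0, sigma=0.25, n_per=3):
    cols = [f"c{i}" for i in range(n_per)] + [f"n{i}" for i in range(n_per)]
    log2 = rng.normal(10.0, sigma, size=(n_features, 2 * n_per))
    for f in fold_features:
        log2[f, :n_per] += math.log2(fold)
    expr = pd.DataFrame(2.0 ** log2, index=[f"f{i}" for i in range(n_features)], columns=cols)
    labels = {c: ("cancer" if c.startswith("c") else "control") for c in cols}
    return expr, labels


def test_screen_selects_planted_upregulated_feature():
    rng = np.random.default_rng(8)
    expr, labels = _matrix(rng, 20, fold_features=[0], fold=4.0)
    res = screen_candidates(expr, labels)
    row = res[res.feature_id == "f0"].iloc[0]
    assert row.selected and row.direction == "up"
    assert row.fold_change == pytest.approx(4.0, rel=0.4)
    # per-feature Welch oracle on log2 values
    a = np.log2(expr.loc["f0", ["c0", "c1", "c2"]].astype(float))
    b = np.log2(expr.loc["f0", ["n0", "n1", "n2"]].astype(float))
    _, p0 = welch_oracle(a, b)
    assert row.p_value == pytest.approx(p0, abs=1e-9)


def test_fold_gate_blocks_significant_small_folds():
    rng = np.random.default_rng(9)
    expr, labels = _matrix(rng, 5, fold_features=[0], fold=1.5, sigma=0.02)
    res = screen_candidates(expr, labels)
    row = res[res.feature_id == "f0"].iloc[0]
    assert row.p_value < 0.05 and not row.selected


def test_screen_null_selection_bounded_by_alpha():
    rng = np.random.default_rng(10)
    expr, labels = _matrix(rng, 1000)
    res = screen_candidates(expr, labels)
    n_alpha = 0.05 * 1000
    assert res.selected.sum() <= n_alpha + 3 * math.sqrt(1000 * 0.05 * 0.95)


def test_screen_requires_two_samples_per_class():
    rng = np.random.default_rng(11)
    expr, _ = _matrix(rng, 5)
    labels = {"c0": "cancer", "c1": "cancer", "c2": "cancer", "n0": "control"}
    with pytest.raises(ValueError):
        screen_candidates(expr[["c0", "c1", "c2", "n0"]], labels)


def test_group_tests_long_table():
    rng = np.random.default_rng(12)
    expr, _ = _matrix(rng, 3)
    groups = {"c0": "g1", "c1": "g1", "c2": "g2", "n0": "g2", "n1": "g3", "n2": "g3"}
    out = group_tests(expr, groups, "mannwhitney")
    assert set(out.comparison) == {"g1 vs g2", "g1 vs g3", "g2 vs g3"}
    assert ((out.p_value >= 0) & (out.p_value <= 1)).all()
    out_t = group_tests(expr, groups, "tukey")
    assert len(out_t) == 9
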