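"""Agreement metrics: ICC, bimodality, stability, attrition, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from delphiset import (
    SimConfig,
    attrition_compare,
    bimodality_flag,
    experience_regression,
    icc_two_way_random,
    score_change_stats,
    sd_change,
    simulate_round1,
    simulate_round2,
    summarize_item,
)
from conftest import make_panel


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _hand_icc21(mat):
    """Independent oracle: explicit two-way ANOVA sums of squares."""
    n, k = mat.shape
    grand = mat.sum() / (n * k)
    ss_rows = sum(k * (mat[i].sum() / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (mat[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_tot = sum((mat[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def test_icc_matches_hand_computed_anova():
    mat = np.array(
        [
            [9.0, 8.0, 7.0],
            [5.0, 6.0, 4.0],
            [2.0, 3.0, 2.0],
            [7.0, 7.0, 6.0],
        ]
    )
    res = icc_two_way_random(mat)
    assert res.estimate == pytest.approx(_hand_icc21(mat), abs=1e-10)


def test_icc_and_ci_match_pingouin_on_random_matrices():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(42)
    for trial in range(5):
        n, k = rng.integers(5, 15), rng.integers(3, 8)
        mat = rng.integers(1, 10, size=(n, k)).astype(float)
        if np.ptp(mat) == 0:
            continue
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": mat.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        # rows 1 and 4 are the two-way random absolute-agreement forms
        for form, row_idx in (("single", 1), ("average", 4)):
            mine = icc_two_way_random(mat, form=form)
            row = ref.iloc[row_idx]
            assert mine.estimate == pytest.approx(row["ICC"], abs=1e-8)
        # CI compared on the single-measure form only: the average-measure
        # step-up is numerically singular when the lower bound nears -1/(k-1)
        single = icc_two_way_random(mat, form="single")
        lo, hi = ref.iloc[1]["CI95"]  # pingouin rounds its CI to 2 decimals
        assert single.ci_low == pytest.approx(lo, abs=0.006)
        assert single.ci_high == pytest.approx(hi, abs=0.006)


def test_perfect_agreement_gives_icc_of_one():
    col = np.array([1.0, 5.0, 9.0, 3.0])
    mat = np.column_stack([col, col, col])
    res = icc_two_way_random(mat)
    assert res.estimate == pytest.approx(1.0)
    assert res.ms_error == pytest.approx(0.0)
    assert res.ms_raters == pytest.approx(0.0)


def test_constant_matrix_is_undefined_not_one():
    with pytest.raises(ValueError, match="undefined"):
        icc_two_way_random(np.full((4, 3), 5.0))


def test_icc_invariant_to_shift_and_relabeling():
    rng = np.random.default_rng(1)
    mat = rng.integers(1, 10, size=(8, 5)).astype(float)
    base = icc_two_way_random(mat).estimate
    assert icc_two_way_random(mat + 3.0).estimate == pytest.approx(base)
    perm_rows = mat[rng.permutation(8)]
    perm_cols = perm_rows[:, rng.permutation(5)]
    assert icc_two_way_random(perm_cols).estimate == pytest.approx(base)


def test_listwise_deletion_drops_incomplete_raters():
    mat = np.array([[9.0, 8.0, np.nan], [5.0, 6.0, 4.0], [2.0, 3.0, 2.0], [7.0, 7.0, 6.0]])
    res = icc_two_way_random(mat, missing_policy="listwise")
    assert res.n_raters == 2
    assert res.estimate == pytest.approx(icc_two_way_random(mat[:, :2]).estimate)


def test_icc_recovers_variance_ratio_in_continuous_mode():
    # sigma_mu^2 = 4, sigma_rater^2 = 0.5, sigma_eps^2 = 1 -> ICC = 4/5.5
    rng = np.random.default_rng(99)
    estimates = []
    for seed in range(10):
        mu = tuple(rng.normal(5.0, 2.0, size=60))
        cfg = SimConfig(
            mu=mu,
            sigma_rater=np.sqrt(0.5),
            sigma_noise=1.0,
            continuous_mode=True,
            seed=seed,
        )
        sim = simulate_round1(cfg)
        estimates.append(icc_two_way_random(sim.panel.score_matrix()).estimate)
    assert np.mean(estimates) == pytest.approx(4 / 5.5, abs=0.05)


# ---------------------------------------------------------------------------
# bimodality
# ---------------------------------------------------------------------------

def test_bimodality_examples():
    from delphiset import ItemSummary

    assert not bimodality_flag(ItemSummary("a", 45, 95.56, 0.00))
    assert bimodality_flag(ItemSummary("b", 45, 45.00, 45.00))


@given(st.lists(st.integers(1, 9), min_size=1, max_size=50))
def test_bimodality_impossible_when_high_band_exceeds_60(scores):
    s = summarize_item(scores)
    if s.pct_7to9 > 60:
        assert not bimodality_flag(s)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def test_identical_rounds_have_zero_change(tiny_panel):
    r2 = make_panel(
        tiny_panel.score_matrix().T.to_numpy(), round_label="round2"
    )
    rep = score_change_stats(tiny_panel, r2)
    assert (rep.per_item["mean_abs_change"] == 0).all()
    assert (rep.per_item["pct_small"] == 0).all()
    assert (rep.per_item["pct_large"] == 0).all()
    assert rep.overall_mean == 0


def test_single_large_change_is_counted():
    mat1 = np.full((10, 2), 6)
    mat2 = mat1.copy()
    mat2[0, 0] = 9  # one rater moves one item by 3
    rep = score_change_stats(
        make_panel(mat1), make_panel(mat2, round_label="round2")
    )
    item = rep.per_item.loc["i01"]
    assert item["pct_large"] == pytest.approx(10.0)
    assert item["pct_small"] == pytest.approx(0.0)
    assert item["mean_abs_change"] == pytest.approx(0.3)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20)
def test_change_stats_equal_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    mat1 = rng.integers(1, 10, size=(6, 4))
    mat2 = rng.integers(1, 10, size=(6, 4))
    rep = score_change_stats(make_panel(mat1), make_panel(mat2, round_label="round2"))
    diffs = np.abs(mat2 - mat1)
    for j, item_id in enumerate(sorted(rep.per_item.index)):
        d = diffs[:, j]
        assert rep.per_item.loc[item_id, "mean_abs_change"] == pytest.approx(d.mean())
        assert rep.per_item.loc[item_id, "pct_small"] == pytest.approx(
            100 * np.count_nonzero((d >= 1) & (d <= 2)) / d.size
        )
        assert rep.per_item.loc[item_id, "pct_large"] == pytest.approx(
            100 * np.count_nonzero(d >= 3) / d.size
        )


def test_sd_change_identity_and_full_convergence():
    s1 = [2, 4, 6, 8]
    assert sd_change(s1, s1) == pytest.approx((np.std(s1, ddof=1), np.std(s1, ddof=1), 0.0))
    sd1, sd2, dsd = sd_change(s1, [5, 5, 5, 5])
    assert sd2 == 0 and dsd == pytest.approx(-sd1)
    with pytest.raises(ValueError):
        sd_change([5], [5, 5])


def test_stronger_convergence_shrinks_item_sds():
    deltas = {}
    for w in (0.0, 0.8):
        vals = []
        for seed in range(20):
            cfg = SimConfig(n_raters=20, n_items=12, convergence_w=w, dropout_p=0.0, seed=seed)
            sim = simulate_round1(cfg)
            r2 = simulate_round2(cfg, sim.panel, sim.panel.item_ids)
            rep = score_change_stats(sim.panel, r2)
            vals.append(rep.per_item["delta_sd"].mean())
        deltas[w] = np.mean(vals)
    assert deltas[0.8] < deltas[0.0]


# ---------------------------------------------------------------------------
# attrition
# ---------------------------------------------------------------------------

def test_identical_constant_groups_compare_as_equal():
    means = {f"r{i}": 7.0 for i in range(6)}
    res = attrition_compare(means, ["r0", "r1", "r2"], ["r3", "r4", "r5"])
    assert res.difference == 0 and res.p_value == 1.0


def test_welch_matches_textbook_formula():
    rng = np.random.default_rng(3)
    a = rng.normal(7.1, 1.1, size=40)
    b = rng.normal(8.5, 0.3, size=5)
    means = {f"a{i}": v for i, v in enumerate(a)} | {f"b{i}": v for i, v in enumerate(b)}
    res = attrition_compare(means, [f"a{i}" for i in range(40)], [f"b{i}" for i in range(5)])
    # independent textbook computation
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (b.mean() - a.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    assert res.t_statistic == pytest.approx(t, abs=1e-8)
    assert res.p_value == pytest.approx(p, abs=1e-8)
    assert res.mean_nonresponders == pytest.approx(b.mean())


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        attrition_compare({"a": 7.0}, ["a"], [])


def test_informative_dropout_raises_nonresponder_means():
    gaps = []
    for seed in range(60):
        cfg = SimConfig(seed=seed)
        sim = simulate_round1(cfg)
        r2 = simulate_round2(cfg, sim.panel, sim.panel.item_ids)
        dropped = sorted(set(sim.panel.rater_ids) - set(r2.rater_ids))
        kept = sorted(r2.rater_ids)
        if not dropped:
            continue
        res = attrition_compare(sim.panel.rater_means().to_dict(), kept, dropped)
        gaps.append(res.difference)
    assert np.mean(gaps) > 0


# ---------------------------------------------------------------------------
# experience regression
# ---------------------------------------------------------------------------

def test_constant_change_has_zero_slope():
    change = {f"r{i}": 0.7 for i in range(8)}
    bands = {f"r{i}": ["lt5", "5to10", "10to20", "gt20"][i % 4] for i in range(8)}
    assert experience_regression(change, bands).slope == pytest.approx(0.0)


def test_exactly_linear_change_recovers_slope():
    bands = {f"r{i}": ["lt5", "5to10", "10to20", "gt20"][i % 4] for i in range(12)}
    change = {r: 0.2 + 0.15 * ["lt5", "5to10", "10to20", "gt20"].index(b) for r, b in bands.items()}
    res = experience_regression(change, bands)
    assert res.slope == pytest.approx(0.15)
    assert res.intercept == pytest.approx(0.2)


def test_regression_matches_normal_equations_oracle():
    rng = np.random.default_rng(7)
    bands_list = ["lt5", "5to10", "10to20", "gt20"]
    bands = {f"r{i}": bands_list[rng.integers(4)] for i in range(30)}
    change = {r: float(rng.normal(0.7, 0.3)) for r in bands}
    res = experience_regression(change, bands)
    raters = sorted(bands)
    x = np.array([bands_list.index(bands[r]) for r in raters], dtype=float)
    y = np.array([change[r] for r in raters])
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert res.intercept == pytest.approx(beta[0], abs=1e-10)
    assert res.slope == pytest.approx(beta[1], abs=1e-10)


def test_categorical_coding_returns_band_contrasts():
    bands = {f"r{i}": ["lt5", "5to10", "10to20", "gt20"][i % 4] for i in range(16)}
    change = {r: 0.5 + 0.1 * (i % 4) for i, r in enumerate(sorted(bands))}
    res = experience_regression(change, bands, coding="categorical")
    assert res.coding == "categorical"
    assert res.coefficients is not None and len(res.coefficients) == 4


def test_single_band_rejected():
    with pytest.raises(ValueError):
        experience_regression({"a": 0.5, "b": 0.6}, {"a": "lt5", "b": "lt5"})
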