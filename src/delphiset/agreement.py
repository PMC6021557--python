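"""Agreement and stability statistics for rating panels.

The headline statistic is the intraclass correlation from a two-way
random-effects ANOVA in which the candidate items are the targets and
the panelists are the raters, both treated as random samples.  The
default form is the single-measure absolute-agreement coefficient
(ICC(2,1) in the Shrout-Fleiss taxonomy),

    ICC(2,1) = (MS_I - MS_E) / (MS_I + (k-1) MS_E + k (MS_R - MS_E) / n)

with n items, k raters, and MS_I / MS_R / MS_E the item, rater, and
residual mean squares.  Its 95% confidence interval uses the standard
F-based construction with a Satterthwaite-approximated denominator
degree of freedom.  The average-measure form ICC(2,k) is also exposed.

Supporting statistics quantify movement between rounds: per-item mean
absolute score change, the share of raters changing by 1-2 points and
by >= 3 points, per-item SD change, bimodality of the rating
distribution, a responder/nonresponder comparison of round-1 means
(attrition), and a regression of score change on length of experience.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ItemSummary
from .types import EXPERIENCE_BANDS, RatingsPanel

__all__ = [
    "ICCResult",
    "StabilityReport",
    "AttritionResult",
    "RegressionResult",
    "icc_two_way_random",
    "bimodality_flag",
    "score_change_stats",
    "sd_change",
    "attrition_compare",
    "experience_regression",
]


@dataclass(frozen=True)
class ICCResult:
    """A two-way random-effects intraclass correlation with its 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    ms_items: float
    ms_raters: float
    ms_error: float
    n_items: int
    n_raters: int
    form: str


@dataclass
class StabilityReport:
    """Between-round score movement, per item, per rater, and overall.

    ``per_item`` columns: n_pairs, mean_abs_change, pct_small (changed
    by 1 or 2 points), pct_large (changed by >= 3), sd_round1,
    sd_round2, delta_sd, large_change_flag (mean |change| >= 3).
    ``per_rater`` columns: n_items, mean_abs_change.
    ``overall_mean``/``overall_sd`` summarize the per-rater means.
    """

    per_item: pd.DataFrame
    per_rater: pd.DataFrame
    overall_mean: float
    overall_sd: float


@dataclass(frozen=True)
class AttritionResult:
    mean_responders: float
    sd_responders: float
    mean_nonresponders: float
    sd_nonresponders: float
    difference: float
    t_statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    stderr: float
    p_value: float
    intercept: float
    coding: str
    coefficients: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def _two_way_anova(matrix: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (items, raters, error) of a complete two-way layout."""
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    ss_items = k * np.sum((row_means - grand) ** 2)
    ss_raters = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((matrix - grand) ** 2)
    ss_error = ss_total - ss_items - ss_raters
    return (
        ss_items / (n - 1),
        ss_raters / (k - 1),
        max(ss_error, 0.0) / ((n - 1) * (k - 1)),
    )


def icc_two_way_random(
    matrix,
    missing_policy: str = "listwise",
    form: str = "single",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way random-effects ICC (absolute agreement) of an items x raters matrix.

    Parameters
    ----------
    matrix
        Items-by-raters score matrix (ndarray or DataFrame, e.g. from
        ``RatingsPanel.score_matrix()``).  NaN marks a missing rating.
    missing_policy
        ``"listwise"`` drops raters (columns) with any missing score,
        reflecting a panel design in which raters score every item;
        ``"complete"`` requires an already-complete matrix.
    form
        ``"single"`` for ICC(2,1) (default), ``"average"`` for ICC(2,k).
    """
    mat = np.asarray(matrix, dtype=float)
    if missing_policy == "listwise":
        mat = mat[:, ~np.isnan(mat).any(axis=0)]
    elif missing_policy != "complete":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if np.isnan(mat).any():
        raise ValueError("matrix has missing cells after missing-data handling")
    n, k = mat.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 items and 2 raters; got {n} x {k}")
    if np.ptp(mat) == 0:
        raise ValueError("all scores identical: total variance is zero, ICC undefined")

    ms_i, ms_r, ms_e = _two_way_anova(mat)
    denom_single = ms_i + (k - 1) * ms_e + k * (ms_r - ms_e) / n
    icc_single = (ms_i - ms_e) / denom_single

    # F-based CI for ICC(2,1) with Satterthwaite df (McGraw & Wong case 2A)
    r = icc_single
    if ms_e > 0 and r < 1:
        a = k * r / (n * (1 - r))
        b = 1 + k * r * (n - 1) / (n * (1 - r))
        v = (a * ms_r + b * ms_e) ** 2 / (
            (a * ms_r) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (ms_i - f_l * ms_e) / (
            f_l * (k * ms_r + (k * n - k - n) * ms_e) + n * ms_i
        )
        hi = n * (f_u * ms_i - ms_e) / (
            k * ms_r + (k * n - k - n) * ms_e + n * f_u * ms_i
        )
    else:
        lo = hi = icc_single  # degenerate: no residual variance

    if form == "single":
        est, ci_low, ci_high = icc_single, lo, hi
    elif form == "average":
        # Spearman-Brown step-up of the single-measure form and its bounds
        def step_up(x: float) -> float:
            return k * x / (1 + (k - 1) * x)

        est = (ms_i - ms_e) / (ms_i + (ms_r - ms_e) / n)
        ci_low, ci_high = step_up(lo), step_up(hi)
    else:
        raise ValueError(f"unknown form {form!r}")

    return ICCResult(
        estimate=float(est),
        ci_low=float(min(ci_low, est)),
        ci_high=float(max(ci_high, est)),
        ms_items=float(ms_i),
        ms_raters=float(ms_r),
        ms_error=float(ms_e),
        n_items=n,
        n_raters=k,
        form=f"two-way random, {'single measure' if form == 'single' else 'average measure'}, absolute agreement",
    )


# ---------------------------------------------------------------------------
# bimodality
# ---------------------------------------------------------------------------

def bimodality_flag(summary: ItemSummary, band_threshold: float = 40.0) -> bool:
    """True when both rating bands exceed the threshold (>40% at 7-9 and >40% at 1-3).

    Such a split signals an irreconcilable difference of opinion rather
    than mere spread.  Since the two bands partition at most 100% of
    raters, a flag is impossible whenever either band exceeds 60%.
    """
    return summary.pct_7to9 > band_threshold and summary.pct_1to3 > band_threshold


# ---------------------------------------------------------------------------
# between-round stability
# ---------------------------------------------------------------------------

def score_change_stats(round1: RatingsPanel, round2: RatingsPanel) -> StabilityReport:
    """Between-round change statistics over raters present in both rounds.

    Differences are paired per (rater, item); a pair exists only when
    both rounds observed the score.  An item is flagged unstable when
    its mean absolute change is >= 3 points.
    """
    merged = round1.scores.merge(
        round2.scores,
        on=["participant_id", "item_id"],
        suffixes=("_r1", "_r2"),
    )
    if merged.empty:
        raise ValueError("no overlapping (rater, item) pairs between rounds")
    merged["abs_change"] = (merged["score_r2"] - merged["score_r1"]).abs()

    rows = []
    for item_id, grp in merged.groupby("item_id", sort=True):
        d = grp["abs_change"].to_numpy()
        n = d.size
        s1 = round1.scores_for_item(item_id)
        s2 = round2.scores_for_item(item_id)
        sd1 = float(np.std(s1, ddof=1)) if s1.size > 1 else float("nan")
        sd2 = float(np.std(s2, ddof=1)) if s2.size > 1 else float("nan")
        rows.append(
            {
                "item_id": item_id,
                "n_pairs": n,
                "mean_abs_change": float(d.mean()),
                "pct_small": 100.0 * np.count_nonzero((d >= 1) & (d <= 2)) / n,
                "pct_large": 100.0 * np.count_nonzero(d >= 3) / n,
                "sd_round1": sd1,
                "sd_round2": sd2,
                "delta_sd": sd2 - sd1,
                "large_change_flag": bool(d.mean() >= 3),
            }
        )
    per_item = pd.DataFrame(rows).set_index("item_id")

    per_rater = (
        merged.groupby("participant_id")["abs_change"]
        .agg(n_items="size", mean_abs_change="mean")
        .sort_index()
    )
    rater_means = per_rater["mean_abs_change"].to_numpy()
    return StabilityReport(
        per_item=per_item,
        per_rater=per_rater,
        overall_mean=float(rater_means.mean()),
        overall_sd=float(rater_means.std(ddof=1)) if rater_means.size > 1 else float("nan"),
    )


def sd_change(
    round1_scores: Sequence[float], round2_scores: Sequence[float]
) -> tuple[float, float, float]:
    """Per-item sample SDs in each round and their change (round 2 - round 1)."""
    s1 = np.asarray(round1_scores, dtype=float)
    s2 = np.asarray(round2_scores, dtype=float)
    if s1.size < 2 or s2.size < 2:
        raise ValueError("need at least 2 scores per round to compute an SD")
    sd1 = float(s1.std(ddof=1))
    sd2 = float(s2.std(ddof=1))
    return sd1, sd2, sd2 - sd1


# ---------------------------------------------------------------------------
# attrition
# ---------------------------------------------------------------------------

def attrition_compare(
    rater_means: Mapping[str, float],
    responder_ids: Iterable[str],
    nonresponder_ids: Iterable[str],
    equal_var: bool = False,
) -> AttritionResult:
    """Compare round-1 mean scores of round-2 responders vs nonresponders.

    Uses Welch's unequal-variance t test by default (``equal_var=True``
    switches to the pooled test).  When both groups are constant and
    equal the comparison is vacuous and p is reported as 1.
    """
    resp = np.array([rater_means[r] for r in responder_ids], dtype=float)
    nonresp = np.array([rater_means[r] for r in nonresponder_ids], dtype=float)
    if resp.size == 0 or nonresp.size == 0:
        raise ValueError("both responder and nonresponder groups must be nonempty")
    diff = float(nonresp.mean() - resp.mean())
    if resp.std() == 0 and nonresp.std() == 0:
        t_stat, p = (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
    else:
        t_stat, p = stats.ttest_ind(nonresp, resp, equal_var=equal_var)
    return AttritionResult(
        mean_responders=float(resp.mean()),
        sd_responders=float(resp.std(ddof=1)) if resp.size > 1 else float("nan"),
        mean_nonresponders=float(nonresp.mean()),
        sd_nonresponders=float(nonresp.std(ddof=1)) if nonresp.size > 1 else float("nan"),
        difference=diff,
        t_statistic=float(t_stat),
        p_value=float(p),
        method="pooled t" if equal_var else "Welch t",
    )


# ---------------------------------------------------------------------------
# change vs experience
# ---------------------------------------------------------------------------

def experience_regression(
    mean_abs_change: Mapping[str, float],
    experience_band: Mapping[str, str],
    coding: str = "ordinal",
) -> RegressionResult:
    """OLS of per-rater mean absolute score change on length of experience.

    With ``coding="ordinal"`` (default) the four experience bands are
    coded 0-3 in increasing order and a single slope is fitted; with
    ``coding="categorical"`` the bands enter as dummy contrasts against
    the least-experienced band and the reported p value is the overall
    F test.
    """
    raters = sorted(set(mean_abs_change) & set(experience_band))
    if not raters:
        raise ValueError("no raters with both a change score and an experience band")
    y = np.array([mean_abs_change[r] for r in raters], dtype=float)
    bands = [experience_band[r] for r in raters]
    if len(set(bands)) < 2:
        raise ValueError("need at least 2 distinct experience bands")

    if coding == "ordinal":
        x = np.array([EXPERIENCE_BANDS.index(b) for b in bands], dtype=float)
        res = stats.linregress(x, y)
        return RegressionResult(
            slope=float(res.slope),
            stderr=float(res.stderr),
            p_value=float(res.pvalue),
            intercept=float(res.intercept),
            coding="ordinal",
        )
    if coding == "categorical":
        import statsmodels.api as sm

        dummies = pd.get_dummies(
            pd.Categorical(bands, categories=EXPERIENCE_BANDS), drop_first=True, dtype=float
        )
        model = sm.OLS(y, sm.add_constant(dummies)).fit()
        coefs = {name: float(v) for name, v in model.params.items()}
        return RegressionResult(
            slope=float("nan"),
            stderr=float("nan"),
            p_value=float(model.f_pvalue),
            intercept=coefs.get("const", float("nan")),
            coding="categorical",
            coefficients=coefs,
        )
    raise ValueError(f"unknown coding {coding!r}")
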