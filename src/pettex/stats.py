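"""Two-group cohort statistics: conventional metrics, normality-gated tests,
greedy correlation-based feature elimination, Bonferroni gate, fold changes.

Notes on test choice: for two independent groups a signed-rank test is
ill-defined without pairing, so non-normal features are compared with the
unpaired Wilcoxon rank-sum (Mann-Whitney) test: exact for n <= 10 without
ties, otherwise the normal approximation with tie correction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

#: Conventional response metrics: always tested, reported separately, and
#: never subjected to the correlation filter.
CONVENTIONAL_METRICS = ("vol_cal", "delta_vol", "vol_met", "met_mean", "met_max")


# --------------------------------------------------------------------------
# conventional metrics


def caliper_volume(length: float, width: float) -> float:
    """Caliper tumor volume: length x width^2 / 2 (mm^3)."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    if width > length:
        warnings.warn("width > length; swapping to keep length >= width")
        length, width = width, length
    return length * width * width / 2.0


def delta_vol(baseline: float, final: float) -> float:
    """Percent caliper-volume growth: 100 x (final - baseline) / baseline."""
    if baseline <= 0:
        raise ValueError("baseline volume must be > 0")
    return 100.0 * (final - baseline) / baseline


def fold_change(treated_value: float, control_value: float) -> float:
    """(treated - control) / control; 0 = no change, +1 = doubling, -1 = halving."""
    if control_value == 0:
        raise ValueError("undefined fold change: control value is 0")
    return (treated_value - control_value) / control_value


def bonferroni_threshold(alpha_family: float = 0.05, m: int = 1) -> tuple[float, float]:
    """Family-wise alpha / m; returns (raw, rounded to one significant figure)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    raw = alpha_family / m
    exponent = math.floor(math.log10(raw))
    rounded = round(raw / 10 ** exponent) * 10 ** exponent
    return raw, float(rounded)


# --------------------------------------------------------------------------
# feature testing


@dataclass
class FeatureTestResult:
    feature: str
    normality: str  # both_normal | not_normal
    shapiro_p: tuple[float, float]  # (treated, control)
    test_used: str  # welch_t | rank_test
    p_raw: float
    fold_change: float
    treated_center: float
    control_center: float
    treated_sd: float
    control_sd: float
    significant_bonferroni: bool = False


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant sample: treat as decisively non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def _rank_test_p(a: np.ndarray, b: np.ndarray) -> float:
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_feature(values_treated, values_control,
                    alpha_normality: float = 0.05,
                    fold_change_center: str = "mean",
                    feature: str = "") -> FeatureTestResult:
    """Shapiro-Wilk gate per group, then Welch t or Mann-Whitney, plus fold change."""
    a = np.asarray(values_treated, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 subjects per group")

    if len(a) < 3 or len(b) < 3:
        warnings.warn("fewer than 3 subjects per group: skipping normality "
                      "test, using rank test")
        sw = (0.0, 0.0)
        both_normal = False
    else:
        sw = (_shapiro_p(a), _shapiro_p(b))
        both_normal = sw[0] > alpha_normality and sw[1] > alpha_normality

    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        log.warning("feature %r constant and identical in both groups; p = 1", feature)
        p = 1.0
        test_used = "rank_test"
    elif both_normal:
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        test_used = "welch_t"
    else:
        p = _rank_test_p(a, b)
        test_used = "rank_test"

    center = np.mean if fold_change_center == "mean" else np.median
    ca, cb = float(center(a)), float(center(b))
    fc = fold_change(ca, cb) if cb != 0 else float("nan")
    if cb == 0:
        log.warning("feature %r: control center is 0; fold change undefined (NaN)", feature)

    return FeatureTestResult(
        feature=feature,
        normality="both_normal" if both_normal else "not_normal",
        shapiro_p=sw,
        test_used=test_used,
        p_raw=p,
        fold_change=fc,
        treated_center=ca,
        control_center=cb,
        treated_sd=float(a.std(ddof=1)),
        control_sd=float(b.std(ddof=1)),
    )


# --------------------------------------------------------------------------
# correlation filter


def correlation_filter(table: pd.DataFrame, cutoff: float = 0.8
                       ) -> tuple[list[str], list[tuple[str | None, str, float]]]:
    """Greedy pairwise elimination at |Pearson r| > cutoff over pooled subjects.

    While any off-diagonal |r| exceeds the cutoff, the pair with the largest
    |r| is found and the member with the larger mean absolute correlation to
    the remaining features is dropped (ties: the lexicographically later
    name).  Zero-variance features are dropped first.  Returns
    (retained, dropped_pairs) with dropped_pairs entries (kept, dropped, r);
    zero-variance drops carry kept=None and r=nan.
    """
    if table.shape[0] < 3:
        raise ValueError("need >= 3 subjects for the correlation filter")
    if table.shape[1] < 2:
        raise ValueError("need >= 2 features")

    dropped: list[tuple[str | None, str, float]] = []
    active = list(table.columns)
    for col in list(active):
        if table[col].std() == 0:
            warnings.warn(f"zero-variance feature {col!r} dropped before filtering")
            dropped.append((None, col, float("nan")))
            active.remove(col)
    if not active:
        raise ValueError("all features are constant")

    data = table[active].to_numpy(dtype=float)
    corr = np.corrcoef(data, rowvar=False)
    if corr.ndim == 0:  # single remaining feature
        return active, dropped
    np.fill_diagonal(corr, 0.0)
    names = list(active)

    while len(names) > 1:
        acorr = np.abs(corr)
        idx = np.unravel_index(np.argmax(acorr), acorr.shape)
        r_max = acorr[idx]
        if r_max <= cutoff:
            break
        a, b = idx
        mean_a = acorr[a].sum() / (len(names) - 1)
        mean_b = acorr[b].sum() / (len(names) - 1)
        if mean_a > mean_b:
            drop, keep = a, b
        elif mean_b > mean_a:
            drop, keep = b, a
        else:  # tie: drop the lexicographically later name
            drop, keep = (a, b) if names[a] > names[b] else (b, a)
        dropped.append((names[keep], names[drop], float(corr[a, b])))
        corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
        names.pop(drop)

    return names, dropped


# --------------------------------------------------------------------------
# study driver


@dataclass
class StatsConfig:
    alpha_family: float = 0.05
    alpha_normality: float = 0.05
    corr_cutoff: float = 0.8
    fold_change_center: str = "mean"
    # optional explicit texture-feature panel; None = all non-conventional columns
    features: list[str] | None = None


@dataclass
class StudySummary:
    retained_features: list[str]
    dropped_pairs: list[tuple[str | None, str, float]]
    results: list[FeatureTestResult]  # retained texture features
    conventional_results: list[FeatureTestResult]
    bonferroni_threshold: float
    bonferroni_threshold_raw: float
    category_tally: dict[str, int] = field(default_factory=dict)

    def result(self, feature: str) -> FeatureTestResult:
        for r in self.results + self.conventional_results:
            if r.feature == feature:
                return r
        raise KeyError(feature)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for r in self.conventional_results + self.results:
            rows.append({
                "feature": r.feature,
                "kind": "conventional" if r.feature in CONVENTIONAL_METRICS else "texture",
                "treated_center": r.treated_center,
                "treated_sd": r.treated_sd,
                "control_center": r.control_center,
                "control_sd": r.control_sd,
                "fold_change": r.fold_change,
                "p_raw": r.p_raw,
                "test": r.test_used,
                "significant": r.significant_bonferroni,
            })
        return pd.DataFrame(rows)

    def fold_change_plot_data(self, category: dict[str, str] | None = None) -> pd.DataFrame:
        rows = [{
            "feature": r.feature,
            "category": (category or {}).get(r.feature, ""),
            "fold_change": r.fold_change,
            "significant": r.significant_bonferroni,
        } for r in self.results]
        return pd.DataFrame(rows)


def run_study(table: pd.DataFrame, config: StatsConfig | None = None,
              category: dict[str, str] | None = None) -> StudySummary:
    """Filter, test and gate a cohort table.

    ``table`` must carry a ``group`` column with values treated/control;
    conventional metrics (vol_cal, delta_vol, vol_met, met_mean, met_max)
    are tested and reported separately, exempt from the correlation filter.
    """
    config = config or StatsConfig()
    if "group" not in table.columns:
        raise ValueError("table needs a 'group' column")
    groups = set(table["group"])
    if groups != {"treated", "control"}:
        raise ValueError(f"groups must be treated/control, got {sorted(groups)}")
    tmask = table["group"] == "treated"
    if tmask.sum() < 2 or (~tmask).sum() < 2:
        raise ValueError("need >= 2 subjects per group")

    meta_cols = {"group", "subject_id"}
    conventional = [c for c in CONVENTIONAL_METRICS if c in table.columns]
    if config.features is not None:
        texture = [c for c in config.features if c in table.columns]
    else:
        texture = [c for c in table.columns
                   if c not in meta_cols and c not in conventional]

    def _test(name: str) -> FeatureTestResult:
        return compare_feature(table.loc[tmask, name], table.loc[~tmask, name],
                               alpha_normality=config.alpha_normality,
                               fold_change_center=config.fold_change_center,
                               feature=name)

    conventional_results = [_test(c) for c in conventional]

    if texture:
        retained, dropped = correlation_filter(table[texture], cutoff=config.corr_cutoff)
    else:
        warnings.warn("no texture features to analyze; conventional metrics only")
        retained, dropped = [], []

    m = max(len(retained), 1)
    thr_raw, thr = bonferroni_threshold(config.alpha_family, m)

    results = []
    for name in retained:
        r = _test(name)
        r.significant_bonferroni = r.p_raw < thr
        results.append(r)
    for r in conventional_results:
        r.significant_bonferroni = r.p_raw < thr

    tally: dict[str, int] = {}
    if category:
        for name in retained:
            cat = category.get(name, "unknown")
            tally[cat] = tally.get(cat, 0) + 1

    return StudySummary(
        retained_features=retained,
        dropped_pairs=dropped,
        results=results,
        conventional_results=conventional_results,
        bonferroni_threshold=thr,
        bonferroni_threshold_raw=thr_raw,
        category_tally=tally,
    )
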