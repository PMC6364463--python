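"""Two-group inference over the feature grid and ROC cutoff analysis.

``compare_groups`` runs one two-sided two-sample t-test per
(phase, feature, filter) cell — Welch's unequal-variance form by default —
and adjusts the raw p-values jointly across all cells actually tested with
the Benjamini-Hochberg step-up FDR procedure.  With two phases, five
features and three filter channels that family is 30 tests.

``roc_analysis`` characterizes selected cells with an empirical ROC curve,
high grade as the positive class.  If a feature is *lower* in high-grade
lesions (as entropy is), the score orientation is flipped so AUC >= 0.5 and
the flip is recorded in ``positive_direction``.  The operating cutoff
maximizes Youden's J = sensitivity + specificity - 1, reported as the
midpoint between the adjacent observed feature values; J-ties resolve to the
candidate cutoff nearest the midpoint of the two group medians.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from ctta.features import FEATURE_NAMES
from ctta.filtering import FILTER_LEVELS
from ctta.io import GROUPS, PHASES

COMPARISON_COLUMNS = [
    "phase",
    "feature",
    "filter",
    "mean_low",
    "sd_low",
    "mean_high",
    "sd_high",
    "t_statistic",
    "p_raw",
    "p_adjusted",
    "significant",
]

ROC_COLUMNS = [
    "phase",
    "feature",
    "filter",
    "auc",
    "cutoff",
    "sensitivity",
    "specificity",
    "positive_direction",
]


def _cell_values(features: pd.DataFrame, phase: str, feature: str, level: str):
    cell = features[(features["phase"] == phase) & (features["filter"] == level)]
    out = {}
    for group in GROUPS:
        vals = cell.loc[cell["group"] == group, feature].to_numpy(dtype=np.float64)
        out[group] = vals[np.isfinite(vals)]  # degenerate subjects report NaN
    return out["low"], out["high"]


def compare_groups(
    features: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Group-comparison table over the full phase x feature x filter grid.

    One Welch t-test per cell (``equal_var=True`` switches to the pooled
    Student form), BH adjustment across the cells actually tested.  Cells
    with fewer than two finite values in either group are excluded with a
    warning and shrink the BH family accordingly.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rows = []
    for phase in PHASES:
        for feature in FEATURE_NAMES:
            for level in FILTER_LEVELS:
                low, high = _cell_values(features, phase, feature, level)
                if len(low) < 2 or len(high) < 2:
                    import warnings

                    warnings.warn(
                        f"cell ({phase}, {feature}, {level}) has <2 usable "
                        "values per group; excluded from testing",
                        stacklevel=2,
                    )
                    continue
                t_stat, p_raw = sps.ttest_ind(low, high, equal_var=equal_var)
                rows.append(
                    {
                        "phase": phase,
                        "feature": feature,
                        "filter": level,
                        "mean_low": low.mean(),
                        "sd_low": low.std(ddof=1),
                        "mean_high": high.mean(),
                        "sd_high": high.std(ddof=1),
                        "t_statistic": float(t_stat),
                        "p_raw": float(p_raw),
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no testable cells in the feature table")
    table["p_adjusted"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    return table.loc[:, COMPARISON_COLUMNS]


def _roc_points(labels: np.ndarray, scores: np.ndarray):
    """Empirical ROC (FPR, TPR) over all observed thresholds, AUC by trapezoid."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def empirical_auc(negatives: np.ndarray, positives: np.ndarray) -> float:
    """Trapezoidal AUC of the empirical ROC, positives scoring high.

    Equals the Mann-Whitney concordance probability with ties counted 1/2.
    """
    negatives = np.asarray(negatives, dtype=np.float64)
    positives = np.asarray(positives, dtype=np.float64)
    labels = np.r_[np.zeros(len(negatives)), np.ones(len(positives))]
    _, _, auc = _roc_points(labels, np.r_[negatives, positives])
    return auc


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values over one joint family."""
    _, p_adj, _, _ = multipletests(np.asarray(p_values), method="fdr_bh")
    return p_adj


def _youden_cutoff(low: np.ndarray, high: np.ndarray, flipped: bool):
    """Best Youden-J cutoff; candidates are midpoints between adjacent values.

    Classification rule in original feature units: positive (high grade) when
    value > cutoff, or value < cutoff if the orientation was flipped.
    """
    pooled = np.unique(np.concatenate([low, high]))
    if len(pooled) < 2:
        raise ValueError("degenerate scores: a cutoff needs >= 2 distinct values")
    candidates = 0.5 * (pooled[:-1] + pooled[1:])
    best = None
    median_mid = 0.5 * (np.median(low) + np.median(high))
    for cut in candidates:
        if flipped:
            sens = float((high < cut).mean())
            spec = float((low >= cut).mean())
        else:
            sens = float((high > cut).mean())
            spec = float((low <= cut).mean())
        j = sens + spec - 1.0
        key = (round(j, 12), -abs(cut - median_mid))
        if best is None or key > best[0]:
            best = (key, float(cut), sens, spec)
    _, cutoff, sens, spec = best
    return cutoff, sens, spec


def roc_analysis(
    features: pd.DataFrame,
    selected: list[tuple[str, str, str]],
) -> pd.DataFrame:
    """ROC characterization of selected (phase, feature, filter) cells."""
    rows = []
    for phase, feature, level in selected:
        low, high = _cell_values(features, phase, feature, level)
        if len(low) == 0 or len(high) == 0:
            raise ValueError(
                f"cell ({phase}, {feature}, {level}) lacks one of the classes"
            )
        auc = empirical_auc(low, high)
        flipped = auc < 0.5
        if flipped:
            auc = empirical_auc(-low, -high)
        cutoff, sens, spec = _youden_cutoff(low, high, flipped)
        rows.append(
            {
                "phase": phase,
                "feature": feature,
                "filter": level,
                "auc": auc,
                "cutoff": cutoff,
                "sensitivity": sens,
                "specificity": spec,
                "positive_direction": (
                    "high-grade-low-values" if flipped else "high-grade-high-values"
                ),
            }
        )
    return pd.DataFrame(rows, columns=ROC_COLUMNS)


def significant_cells(comparison: pd.DataFrame) -> list[tuple[str, str, str]]:
    """The FDR-significant (phase, feature, filter) cells of a comparison table."""
    sig = comparison[comparison["significant"]]
    return list(zip(sig["phase"], sig["feature"], sig["filter"]))
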