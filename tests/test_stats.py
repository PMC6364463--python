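import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctta.features import FEATURE_NAMES
from ctta.filtering import FILTER_LEVELS
from ctta.io import PHASES
from ctta.stats import (
    bh_adjust,
    compare_groups,
    empirical_auc,
    roc_analysis,
    significant_cells,
)


def bh_stepup_oracle(p):
    """Independent BH step-up: sort, scale by m/rank, enforce monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def pair_count_auc(negatives, positives):
    """O(n^2) Mann-Whitney concordance with ties counted 1/2."""
    wins = ties = 0
    for x in positives:
        for y in negatives:
            wins += x > y
            ties += x == y
    return (wins + 0.5 * ties) / (len(positives) * len(negatives))


def feature_table(rng, n_low=10, n_high=10, shift=None):
    """A synthetic feature table over the full grid; optional per-cell shifts."""
    rows = []
    for group, n in (("low", n_low), ("high", n_high)):
        for i in range(n):
            for phase in PHASES:
                for level in FILTER_LEVELS:
                    rec = {"subject_id": f"{group}-{i}", "group": group,
                           "phase": phase, "filter": level, "n_voxels": 1000}
                    for feat in FEATURE_NAMES:
                        delta = 0.0
                        if group == "high" and shift:
                            delta = shift.get((phase, feat, level), 0.0)
                        rec[feat] = rng.normal(delta, 1.0)
                    rows.append(rec)
    return pd.DataFrame(rows)


class TestWelch:
    def test_textbook_example(self, rng):
        """A={1..5}, B={2..6}: equal variances s^2=2.5, se=1, so t=-1, df=8."""
        table = feature_table(rng, n_low=5, n_high=5)
        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        cell = (table["phase"] == "corticomedullary") & (table["filter"] == "none")
        table.loc[cell & (table["group"] == "low"), "entropy"] = a
        table.loc[cell & (table["group"] == "high"), "entropy"] = b
        row = compare_groups(table).query(
            "phase == 'corticomedullary' and feature == 'entropy' and filter == 'none'"
        ).iloc[0]
        assert row["t_statistic"] == pytest.approx(-1.0, abs=1e-12)
        assert row["p_raw"] == pytest.approx(2 * sps.t.sf(1.0, df=8), rel=1e-10)
        assert row["mean_low"] == pytest.approx(3.0)
        assert row["sd_high"] == pytest.approx(np.sqrt(2.5))

    def test_identical_groups_give_t_zero_p_one(self, rng):
        table = feature_table(rng, n_low=6, n_high=6)
        # one value per subject, constant across that subject's six cells
        vals = np.repeat([1.0, 4.0, 2.0, 8.0, 5.0, 7.0], len(PHASES) * len(FILTER_LEVELS))
        for group in ("low", "high"):
            table.loc[table["group"] == group, "entropy"] = vals
        out = compare_groups(table)
        ent = out[out["feature"] == "entropy"]
        assert np.allclose(ent["t_statistic"], 0.0)
        assert np.allclose(ent["p_raw"], 1.0)

    def test_welch_equals_student_for_equal_variance_equal_n(self, rng):
        table = feature_table(rng, n_low=7, n_high=7)
        welch = compare_groups(table, equal_var=False)
        student = compare_groups(table, equal_var=True)
        # equal n: the t statistics coincide exactly
        np.testing.assert_allclose(
            welch["t_statistic"], student["t_statistic"], rtol=1e-12
        )
        # shifted-copy groups: variances equal, so even the p values coincide
        shifted = table.copy()
        low_vals = shifted.loc[shifted["group"] == "low", "sd"].to_numpy()
        shifted.loc[shifted["group"] == "high", "sd"] = low_vals + 1.0
        w = compare_groups(shifted, equal_var=False).query("feature == 'sd'")
        s = compare_groups(shifted, equal_var=True).query("feature == 'sd'")
        np.testing.assert_allclose(w["p_raw"], s["p_raw"], rtol=1e-10)

    def test_grid_shape_and_p_value_invariants(self, rng):
        out = compare_groups(feature_table(rng))
        assert len(out) == len(PHASES) * len(FEATURE_NAMES) * len(FILTER_LEVELS) == 30
        assert ((out["p_adjusted"] >= out["p_raw"] - 1e-15)
                & (out["p_raw"] >= 0) & (out["p_adjusted"] <= 1)).all()

    def test_degenerate_cell_excluded_with_warning(self, rng):
        table = feature_table(rng, n_low=5, n_high=5)
        # leave only one usable high-grade kurtosis value in one cell
        cell = ((table["phase"] == "nephrographic") & (table["filter"] == "fine")
                & (table["group"] == "high"))
        table.loc[cell, "kurtosis"] = np.nan
        table.loc[table.index[cell][0], "kurtosis"] = 2.0
        with pytest.warns(UserWarning, match="excluded"):
            out = compare_groups(table)
        assert len(out) == 29


class TestBH:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=30) ** rng.uniform(0.3, 3.0)
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_monotone_and_never_decreases_raw_p(self, rng):
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestROC:
    def test_perfect_separation(self, rng):
        table = feature_table(
            rng, shift={(ph, "entropy", lev): 100.0 for ph in PHASES for lev in FILTER_LEVELS}
        )
        out = roc_analysis(table, [("corticomedullary", "entropy", "none")]).iloc[0]
        assert out["auc"] == 1.0
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_small_example_auc_three_quarters(self):
        # pairs: (0.35 vs 0.1) +, (0.35 vs 0.4) -, (0.8 vs 0.1) +, (0.8 vs 0.4) +
        assert empirical_auc([0.1, 0.4], [0.35, 0.8]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pair_count_concordance(self, seed):
        rng = np.random.default_rng(seed)
        neg = rng.integers(0, 6, size=rng.integers(2, 10)).astype(float)
        pos = rng.integers(0, 6, size=rng.integers(2, 10)).astype(float)
        assert empirical_auc(neg, pos) == pytest.approx(pair_count_auc(neg, pos), abs=1e-12)

    def test_random_labels_give_half(self, rng):
        n = 2000
        scores = rng.normal(size=2 * n)
        auc = empirical_auc(scores[:n], scores[n:])
        assert abs(auc - 0.5) < 3 / np.sqrt(n)

    def test_orientation_flip_recorded_for_low_value_positive_feature(self, rng):
        table = feature_table(
            rng, shift={(ph, "entropy", lev): -3.0 for ph in PHASES for lev in FILTER_LEVELS}
        )
        out = roc_analysis(table, [("nephrographic", "entropy", "fine")]).iloc[0]
        assert out["positive_direction"] == "high-grade-low-values"
        assert out["auc"] >= 0.5

    def test_cutoff_is_midpoint_in_separation_gap(self, rng):
        table = feature_table(rng, n_low=3, n_high=3)
        cell = (table["phase"] == "corticomedullary") & (table["filter"] == "none")
        table.loc[cell & (table["group"] == "low"), "entropy"] = [1.0, 2.0, 3.0]
        table.loc[cell & (table["group"] == "high"), "entropy"] = [5.0, 6.0, 7.0]
        out = roc_analysis(table, [("corticomedullary", "entropy", "none")]).iloc[0]
        assert out["cutoff"] == pytest.approx(4.0)  # midpoint of 3 and 5
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_one_class_input_rejected(self, rng):
        table = feature_table(rng)
        table = table[table["group"] == "low"]
        with pytest.raises(ValueError, match="class"):
            roc_analysis(table, [("corticomedullary", "entropy", "none")])

    def test_significant_cells_roundtrip(self, rng):
        shift = {(ph, "entropy", lev): 50.0 for ph in PHASES for lev in FILTER_LEVELS}
        table = feature_table(rng, n_low=15, n_high=15, shift=shift)
        comparison = compare_groups(table)
        cells = significant_cells(comparison)
        assert set(c[1] for c in cells) == {"entropy"}
        roc = roc_analysis(table, cells)
        assert (roc["auc"] == 1.0).all()
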