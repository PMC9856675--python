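import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import rtspect as r
from rtspect.stats import factorial_anova, rank_activations, tukey_contrasts


def _planted_table(n_per_cat=12, effect=2.0, seed=0):
    """Null table plus an (electrode, band, category)-specific shift —
    a pure three-way interaction pattern."""
    tab = r.simulate_null_table(n_per_cat, seed=seed)
    spots = {("E01", "alpha", "fast"), ("E05", "beta", "medium"),
             ("E09", "beta", "slow")}
    mask = tab.apply(lambda row: (row["electrode"], row["band"],
                                  row["category"]) in spots, axis=1)
    tab.loc[mask, "activation"] += effect
    return tab


def test_report_covers_all_seven_effects():
    rep = factorial_anova(r.simulate_null_table(6, seed=1))
    assert list(rep.table["effect"]) == [
        "electrode", "band", "category", "electrode*band",
        "electrode*category", "band*category", "electrode*band*category"]
    assert (rep.table["F"] >= 0).all()
    assert rep.table[["df1", "df2"]].gt(0).all().all()


def test_planted_three_way_interaction_detected():
    rep = factorial_anova(_planted_table())
    assert rep.p("electrode*band*category") < 0.01


def test_balanced_closed_form_matches_wald_engine():
    """Two independent computations of the same fixed-effects ANOVA: the
    closed-form balanced path and the sum-coded type-III Wald path."""
    tab = _planted_table(n_per_cat=5, seed=2)
    small = tab[tab["electrode"].isin([f"E{i:02d}" for i in range(8)])]
    rep_closed = factorial_anova(small, random_intercept=None)
    # drop one row to force the Wald engine, then put it back via weights:
    # instead, call the engine directly on the same balanced data
    from rtspect.stats import _codes, _wald_anova
    rep_wald = _wald_anova(small.copy(), _codes(small), None)
    merged = rep_closed.table.merge(rep_wald, on="effect",
                                    suffixes=("_c", "_w"))
    assert np.allclose(merged["F_c"], merged["F_w"], rtol=1e-8)
    assert (merged["df1_c"] == merged["df1_w"]).all()
    assert (merged["df2_c"] == merged["df2_w"]).all()


def test_anova_matches_statsmodels_oracle():
    """Independent cross-check of the fixed-effects factorial F statistics
    against statsmodels OLS + anova_lm on a small balanced table."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    tab = _planted_table(n_per_cat=4, seed=3)
    small = tab[tab["electrode"].isin(["E00", "E01", "E02"])].copy()
    rep = factorial_anova(small, random_intercept=None)
    m = smf.ols("activation ~ C(electrode) * C(band) * C(category)",
                data=small).fit()
    aov = sm.stats.anova_lm(m, typ=2)  # equals type III on balanced data
    name_map = {
        "electrode": "C(electrode)", "band": "C(band)",
        "category": "C(category)",
        "electrode*band": "C(electrode):C(band)",
        "electrode*category": "C(electrode):C(category)",
        "band*category": "C(band):C(category)",
        "electrode*band*category": "C(electrode):C(band):C(category)",
    }
    for eff, sm_name in name_map.items():
        ours = float(rep.table.set_index("effect").loc[eff, "F"])
        theirs = float(aov.loc[sm_name, "F"])
        assert ours == pytest.approx(theirs, rel=1e-6), eff


def test_empty_cell_raises_with_cell_name():
    tab = r.simulate_null_table(4, seed=4)
    tab = tab[~((tab.electrode == "E07") & (tab.band == "beta")
                & (tab.category == "slow"))]
    with pytest.raises(ValueError, match="E07"):
        factorial_anova(tab)


def test_random_intercept_changes_category_stratum():
    """With a per-sample intercept the category effect is tested in the
    between-sample stratum (small denominator df)."""
    tab = r.simulate_null_table(8, seed=5)
    rep_mixed = factorial_anova(tab, random_intercept="sample")
    rep_fixed = factorial_anova(tab, random_intercept=None)
    df2_mixed = int(rep_mixed.table.set_index("effect").loc["category", "df2"])
    df2_fixed = int(rep_fixed.table.set_index("effect").loc["category", "df2"])
    assert df2_mixed == 8 * 3 - 3
    assert df2_fixed > df2_mixed


# --------------------------------------------------------------------------
# Tukey

def _toy_groups():
    return {
        "fast": np.array([1.0, 1.2, 0.9, 1.1, 1.3]),
        "medium": np.array([1.8, 2.0, 2.2, 1.9, 2.1]),
        "slow": np.array([1.4, 1.5, 1.6, 1.45, 1.55]),
    }


def _toy_table():
    rows = []
    for cat, vals in _toy_groups().items():
        for i, v in enumerate(vals):
            rows.append((i, "", cat, "E00", "alpha", v))
    return pd.DataFrame(rows, columns=["sample", "subject", "category",
                                       "electrode", "band", "activation"])


def test_tukey_z_ratios_match_hand_computation():
    """z ratios and adjusted p against a direct pooled-variance
    computation (1e-6)."""
    rep = tukey_contrasts(_toy_table(), {"electrode": "E00", "band": "alpha"})
    groups = _toy_groups()
    df_err = sum(len(v) - 1 for v in groups.values())
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_err
    for _, row in rep.iterrows():
        c1, c2 = row["pair"].split("-")
        g1, g2 = groups[c1], groups[c2]
        se = np.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
        z = (g1.mean() - g2.mean()) / se
        assert row["z_ratio"] == pytest.approx(z, abs=1e-6)
        q = abs(z) * np.sqrt(2)
        p = sstats.studentized_range.sf(q, 3, df_err)
        assert row["p_adjusted"] == pytest.approx(p, abs=1e-6)


def test_tukey_pair_order_and_columns():
    rep = tukey_contrasts(_toy_table())
    assert list(rep["pair"]) == ["fast-medium", "fast-slow", "medium-slow"]
    assert {"mean_1", "mean_2", "z_ratio", "p_adjusted"} <= set(rep.columns)


def test_tukey_adjusted_p_dominates_unadjusted():
    rng = np.random.default_rng(6)
    rows = []
    for i, cat in enumerate(("fast", "medium", "slow")):
        for j, v in enumerate(rng.normal(i * 0.1, 1, 20)):
            rows.append((j, "", cat, "E00", "alpha", v))
    tab = pd.DataFrame(rows, columns=["sample", "subject", "category",
                                      "electrode", "band", "activation"])
    rep = tukey_contrasts(tab)
    assert (rep["p_adjusted"] >= rep["p_unadjusted"] - 1e-12).all()


def test_tukey_identical_groups():
    vals = np.array([1.0, 1.1, 0.9, 1.05])
    rows = []
    for cat in ("fast", "medium"):
        for i, v in enumerate(vals):
            rows.append((i, "", cat, "E00", "alpha", v))
    tab = pd.DataFrame(rows, columns=["sample", "subject", "category",
                                      "electrode", "band", "activation"])
    rep = tukey_contrasts(tab)
    assert rep["z_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert rep["p_adjusted"].iloc[0] > 0.99


def test_tukey_singleton_group_rejected():
    tab = _toy_table()
    tab = tab[~((tab.category == "slow") & (tab["sample"] > 0))]
    with pytest.raises(ValueError):
        tukey_contrasts(tab)


# --------------------------------------------------------------------------
# ranking

def test_ranking_recovers_well_separated_tiers():
    """Electrode means at 1/5/10 (SD 0.1) must map exactly to the
    low/relevant/high tiers."""
    rng = np.random.default_rng(7)
    rows = []
    tier_truth = {}
    for ei in range(21):
        level = ei % 3
        center = (1.0, 5.0, 10.0)[level]
        tier_truth[f"E{ei:02d}"] = ("low", "relevant", "high")[level]
        for s in range(4):
            rows.append((s, "", "fast", f"E{ei:02d}", "alpha",
                         rng.normal(center, 0.1)))
    tab = pd.DataFrame(rows, columns=["sample", "subject", "category",
                                      "electrode", "band", "activation"])
    rep = rank_activations(tab, seed=0)
    for _, row in rep.iterrows():
        assert row["tier"] == tier_truth[row["electrode"]]


def test_ranking_degenerate_values_rejected():
    rows = [(s, "", "fast", f"E{e}", "alpha", 1.0)
            for s in range(3) for e in range(6)]
    tab = pd.DataFrame(rows, columns=["sample", "subject", "category",
                                      "electrode", "band", "activation"])
    with pytest.raises(ValueError):
        rank_activations(tab)


def test_ranking_grain_band_by_category(montage64):
    tab = r.simulate_null_table(4, seed=8)
    rep = rank_activations(tab, seed=0)
    assert set(rep.groupby(["band", "category"]).size()) == {64}
    assert set(rep["tier"]) <= {"low", "relevant", "high"}
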