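"""Factorial analysis of saliency activation tables.

The activation table has one row per (sample, electrode, band) with the
sample's response-speed category. The model is the full factorial
activation ~ electrode * band * category (3 mains, 3 two-way and 1
three-way interaction). With the default random intercept per sample the
design is a split plot: category varies between samples and is tested
against the samples-within-category stratum, while electrode, band and all
interactions vary within samples and are tested against the within-sample
residual after absorbing per-sample means. Fully balanced tables use
closed-form sums of squares; otherwise a sum-to-zero-coded type-III Wald
path is used. Tukey HSD contrasts compare the three categories within an
electrode and/or band cell, and a univariate 3-component Gaussian mixture
ranks electrodes into low/relevant/high activation tiers per band and
category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.mixture import GaussianMixture

__all__ = [
    "factorial_anova",
    "tukey_contrasts",
    "rank_activations",
    "simulate_null_table",
    "render_effect",
]

_FACTORS = ("electrode", "band", "category")
_EFFECTS = (
    ("electrode",), ("band",), ("category",),
    ("electrode", "band"), ("electrode", "category"), ("band", "category"),
    ("electrode", "band", "category"),
)

_PAIR_ORDER = (("fast", "medium"), ("fast", "slow"), ("medium", "slow"))


@dataclass
class AnovaReport:
    """Per-effect F statistics; ``table`` has effect/F/df1/df2/p columns."""

    table: pd.DataFrame

    def p(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "p"])

    def __str__(self) -> str:
        return "\n".join(render_effect(r) for _, r in self.table.iterrows())


def render_effect(row) -> str:
    return (f"{row['effect']}: F ({int(row['df1'])}, {int(row['df2'])}) = "
            f"{row['F']:.2f}, p = {row['p']:.3g}")


def _check_cells(df: pd.DataFrame) -> None:
    counts = df.groupby(list(_FACTORS), observed=True).size()
    levels = [df[f].unique() for f in _FACTORS]
    full = np.prod([len(lv) for lv in levels])
    if len(counts) < full:
        have = set(counts.index)
        for e in levels[0]:
            for b in levels[1]:
                for c in levels[2]:
                    if (e, b, c) not in have:
                        raise ValueError(
                            f"empty cell: electrode={e!r}, band={b!r}, category={c!r}")


def _codes(df):
    out = {}
    for f in _FACTORS:
        levels = sorted(df[f].unique())
        idx = {v: i for i, v in enumerate(levels)}
        out[f] = (np.array([idx[v] for v in df[f]]), len(levels))
    return out


# --------------------------------------------------------------------------
# closed-form path (balanced designs)

def _balanced_anova(df, codes, grouping):
    y = df["activation"].to_numpy(dtype=float)
    (ia, a), (ib, b), (ic, c) = (codes[f] for f in _FACTORS)
    n_cell = len(y) // (a * b * c)
    cell_sum = np.zeros((a, b, c))
    np.add.at(cell_sum, (ia, ib, ic), y)
    M = cell_sum / n_cell
    grand = M.mean()
    mA = M.mean(axis=(1, 2)) - grand
    mB = M.mean(axis=(0, 2)) - grand
    mC = M.mean(axis=(0, 1)) - grand
    mAB = M.mean(axis=2) - grand - mA[:, None] - mB[None, :]
    mAC = M.mean(axis=1) - grand - mA[:, None] - mC[None, :]
    mBC = M.mean(axis=0) - grand - mB[:, None] - mC[None, :]
    mABC = (M - grand - mA[:, None, None] - mB[None, :, None] - mC[None, None, :]
            - mAB[:, :, None] - mAC[:, None, :] - mBC[None, :, :])
    ss = {
        ("electrode",): n_cell * b * c * np.sum(mA**2),
        ("band",): n_cell * a * c * np.sum(mB**2),
        ("category",): n_cell * a * b * np.sum(mC**2),
        ("electrode", "band"): n_cell * c * np.sum(mAB**2),
        ("electrode", "category"): n_cell * b * np.sum(mAC**2),
        ("band", "category"): n_cell * a * np.sum(mBC**2),
        ("electrode", "band", "category"): n_cell * np.sum(mABC**2),
    }
    dfs = {
        ("electrode",): a - 1,
        ("band",): b - 1,
        ("category",): c - 1,
        ("electrode", "band"): (a - 1) * (b - 1),
        ("electrode", "category"): (a - 1) * (c - 1),
        ("band", "category"): (b - 1) * (c - 1),
        ("electrode", "band", "category"): (a - 1) * (b - 1) * (c - 1),
    }
    ss_total = np.sum((y - y.mean())**2)
    ss_model = sum(ss.values())

    rows = []
    if grouping is not None:
        g = df[grouping].to_numpy()
        gser = pd.DataFrame({"g": g, "y": y, "c": ic})
        per = gser.groupby("g", sort=True).agg(m=("y", "mean"), n=("y", "size"),
                                               c=("c", "first"))
        rows_per = per["n"].to_numpy()
        cat_mean = np.array([per["m"][per["c"] == k].mean() for k in range(c)])
        ss_subj = float(np.sum(rows_per * (per["m"].to_numpy()
                                           - cat_mean[per["c"].to_numpy()])**2))
        df_subj = len(per) - c
        if df_subj <= 0:
            grouping = None  # singleton groups: fixed-effects fallback
        else:
            ss_err_within = ss_total - ss_model - ss_subj
            df_err_within = (len(y) - 1 - df_subj
                             - sum(dfs.values()))
            for eff in _EFFECTS:
                if eff == ("category",):
                    F = (ss[eff] / dfs[eff]) / (ss_subj / df_subj)
                    d2 = df_subj
                else:
                    F = (ss[eff] / dfs[eff]) / (ss_err_within / df_err_within)
                    d2 = df_err_within
                rows.append(("*".join(eff), max(F, 0.0), dfs[eff], d2,
                             sstats.f.sf(max(F, 0.0), dfs[eff], d2)))
    if grouping is None:
        ss_err = ss_total - ss_model
        df_err = len(y) - a * b * c
        if df_err <= 0:
            raise ValueError("no residual degrees of freedom (one row per cell)")
        for eff in _EFFECTS:
            F = (ss[eff] / dfs[eff]) / (ss_err / df_err)
            rows.append(("*".join(eff), max(F, 0.0), dfs[eff], df_err,
                         sstats.f.sf(max(F, 0.0), dfs[eff], df_err)))
    return rows


# --------------------------------------------------------------------------
# type-III Wald path (unbalanced designs)

def _sum_contrast(levels: int) -> np.ndarray:
    C = np.vstack([np.eye(levels - 1), -np.ones(levels - 1)])
    return C


def _design(codes, effects):
    """Sum-to-zero-coded design columns per effect."""
    mats = {}
    for f in _FACTORS:
        idx, L = codes[f]
        mats[f] = _sum_contrast(L)[idx]  # (n, L-1)
    blocks = {}
    for eff in effects:
        X = mats[eff[0]]
        for f in eff[1:]:
            X = (X[:, :, None] * mats[f][:, None, :]).reshape(len(X), -1)
        blocks[eff] = X
    return blocks


def _wald_anova(df, codes, grouping):
    y = df["activation"].to_numpy(dtype=float)
    n = len(y)
    rows = []
    within_effects = [e for e in _EFFECTS if e != ("category",)]

    if grouping is not None:
        g = df[grouping].to_numpy()
        per = pd.DataFrame({"g": g, "y": y,
                            "c": codes["category"][0]}).groupby("g", sort=True)
        gm = per["y"].mean()
        gn = per["y"].size()
        gc = per["c"].first()
        c = codes["category"][1]
        if (gn.to_numpy() == 1).all() or len(gm) <= c:
            grouping = None
        else:
            # between stratum: one-way ANOVA on sample means, weighted by rows
            w = gn.to_numpy(dtype=float)
            m = gm.to_numpy()
            cat = gc.to_numpy()
            grand = np.average(m, weights=w)
            cat_means = np.array([np.average(m[cat == k], weights=w[cat == k])
                                  for k in range(c)])
            ss_c = float(np.sum(w * (cat_means[cat] - grand)**2))
            ss_subj = float(np.sum(w * (m - cat_means[cat])**2))
            df_subj = len(m) - c
            F = (ss_c / (c - 1)) / (ss_subj / df_subj)
            rows.append(("category", max(F, 0.0), c - 1, df_subj,
                         sstats.f.sf(max(F, 0.0), c - 1, df_subj)))
            # within stratum: absorb per-sample means
            y_w = y - gm.loc[g].to_numpy()
            blocks = _design(codes, within_effects)
            Xw = np.concatenate([blocks[e] for e in within_effects], axis=1)
            means = pd.DataFrame(Xw).groupby(g).transform("mean").to_numpy()
            Xw = Xw - means
            rows.extend(_wald_tests(Xw, y_w, within_effects, blocks,
                                    extra_df=len(gm)))
            report = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])
            eff_order = ["*".join(e) for e in _EFFECTS]
            return report.set_index("effect").loc[eff_order].reset_index()

    blocks = _design(codes, _EFFECTS)
    X = np.concatenate([np.ones((n, 1))]
                       + [blocks[e] for e in _EFFECTS], axis=1)
    rows = _wald_tests(X, y, _EFFECTS, blocks, extra_df=0, has_intercept=True)
    report = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])
    return report


def _wald_tests(X, y, effects, blocks, extra_df=0, has_intercept=False):
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ Xty
    resid = y - X @ beta
    df_err = n - np.linalg.matrix_rank(XtX) - extra_df + (0 if has_intercept else 0)
    if df_err <= 0:
        raise ValueError("design is rank deficient: no residual df")
    s2 = float(resid @ resid) / df_err
    rows = []
    start = 1 if has_intercept else 0
    for eff in effects:
        q = blocks[eff].shape[1]
        sl = slice(start, start + q)
        start += q
        b = beta[sl]
        V = XtX_inv[sl, sl] * s2
        try:
            F = float(b @ np.linalg.solve(V, b)) / q
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"rank-deficient design for effect {eff}") from exc
        rows.append(("*".join(eff), max(F, 0.0), q, df_err,
                     sstats.f.sf(max(F, 0.0), q, df_err)))
    return rows


def factorial_anova(table: pd.DataFrame,
                    random_intercept: str | None = "sample") -> AnovaReport:
    """Full-factorial ANOVA of activation ~ electrode * band * category.

    ``random_intercept`` names a grouping column ("sample" by default,
    "subject" for a subject-level intercept, None for pure fixed effects).
    Raises on empty cells or rank-deficient designs.
    """
    df = table.copy()
    for f in _FACTORS:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    _check_cells(df)
    codes = _codes(df)
    if random_intercept is not None and random_intercept not in df.columns:
        raise ValueError(f"grouping column {random_intercept!r} not in table")

    counts = df.groupby(list(_FACTORS), observed=True).size().to_numpy()
    balanced = counts.min() == counts.max()
    if balanced and random_intercept is not None:
        # balanced split-plot additionally needs equal rows per group and
        # equal groups per category
        g = df.groupby(random_intercept, observed=True)
        sizes = g.size().to_numpy()
        gcat = g["category"].first()
        per_cat = gcat.value_counts().to_numpy()
        balanced = (sizes.min() == sizes.max()
                    and per_cat.min() == per_cat.max())
    if balanced:
        rows = _balanced_anova(df, codes, random_intercept)
        report = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])
    else:
        report = _wald_anova(df, codes, random_intercept)
    return AnovaReport(table=report)


# --------------------------------------------------------------------------
# Tukey HSD posthoc contrasts

def tukey_contrasts(table: pd.DataFrame, cell: dict | None = None) -> pd.DataFrame:
    """All pairwise category contrasts within an electrode and/or band cell.

    ``cell`` maps factor name to level, e.g. {"electrode": "TP7"} or
    {"electrode": "AF4", "band": "beta"}; None uses the whole table.
    Returns one row per contrast with group means, z ratio (estimate / SE)
    and the studentized-range-adjusted p (family = the contrasts within
    this cell).
    """
    df = table
    cell = cell or {}
    for k, v in cell.items():
        if k not in df.columns:
            raise ValueError(f"unknown factor {k!r}")
        df = df[df[k] == v]
    groups = {c: df.loc[df["category"] == c, "activation"].to_numpy(dtype=float)
              for c in sorted(df["category"].unique())}
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 categories in the cell")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("singleton group in cell; cannot estimate variance")
    df_err = sum(len(v) - 1 for v in groups.values())
    mse = sum(((v - v.mean())**2).sum() for v in groups.values()) / df_err

    ordered = [p for p in _PAIR_ORDER if p[0] in groups and p[1] in groups]
    for c1 in groups:
        for c2 in groups:
            if c1 < c2 and (c1, c2) not in ordered and (c2, c1) not in ordered:
                ordered.append((c1, c2))
    rows = []
    for c1, c2 in ordered:
        g1, g2 = groups[c1], groups[c2]
        diff = g1.mean() - g2.mean()
        se = np.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
        z = diff / se if se > 0 else 0.0
        q = abs(z) * np.sqrt(2.0)
        p_adj = float(sstats.studentized_range.sf(q, k, df_err))
        p_unadj = float(2 * sstats.t.sf(abs(z), df_err))
        rows.append({**cell, "pair": f"{c1}-{c2}",
                     "mean_1": float(g1.mean()), "mean_2": float(g2.mean()),
                     "estimate": float(diff), "se": float(se),
                     "z_ratio": float(z), "df": df_err,
                     "p_unadjusted": min(p_unadj, 1.0),
                     "p_adjusted": min(p_adj, 1.0)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# GMM activation ranking

def rank_activations(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Tier electrodes (low / relevant / high) per band and category.

    Activation is averaged over rows per electrode within each (band,
    category) slice; a 3-component univariate Gaussian mixture clusters the
    electrode means and tiers are named by ascending component mean.
    """
    tiers = ("low", "relevant", "high")
    rows = []
    for (band, cat), sub in table.groupby(["band", "category"], observed=True):
        means = sub.groupby("electrode", observed=True)["activation"].mean()
        vals = means.to_numpy(dtype=float)
        if len(np.unique(vals)) < 3:
            raise ValueError(
                f"degenerate activation distribution in band={band!r}, "
                f"category={cat!r}: fewer than 3 distinct electrode means")
        gm = GaussianMixture(n_components=3, covariance_type="spherical",
                             n_init=10, random_state=seed,
                             reg_covar=1e-10).fit(vals[:, None])
        comp = gm.predict(vals[:, None])
        order = np.argsort(gm.means_[:, 0])
        tier_of = {int(order[i]): tiers[i] for i in range(3)}
        for el, v, c in zip(means.index, vals, comp):
            rows.append({"band": band, "category": cat, "electrode": el,
                         "mean_activation": float(v), "tier": tier_of[int(c)]})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# helpers

def simulate_null_table(n_per_category: int = 10, electrodes=None,
                        bands=("alpha", "beta", "gamma"),
                        categories=("fast", "medium", "slow"),
                        seed: int = 0) -> pd.DataFrame:
    """An activation table with i.i.d. noise and no planted effects, for
    calibration studies: ``n_per_category`` samples per category, each with
    one row per (electrode, band)."""
    if electrodes is None:
        electrodes = [f"E{i:02d}" for i in range(64)]
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for cat in categories:
        for _ in range(n_per_category):
            acts = rng.standard_normal(len(electrodes) * len(bands))
            i = 0
            for el in electrodes:
                for band in bands:
                    rows.append((sid, "", cat, el, band, acts[i]))
                    i += 1
            sid += 1
    return pd.DataFrame(rows, columns=["sample", "subject", "category",
                                       "electrode", "band", "activation"])
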