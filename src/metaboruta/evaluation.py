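"""Quantitative evaluation of selected metabolites.

For each selected metabolite in a pairwise comparison:

* **Δ%** — relative concentration difference between the two groups,
  computed on *pre-adjustment* concentrations against the symmetric mean:
  Δ% = 100·(x̄₂ − x̄₁) / ((x̄₁ + x̄₂)/2).  Negative ⇔ the second-listed
  group is lower.  The symmetric denominator bounds |Δ%| by 200 and keeps
  the statistic antisymmetric in the group order.
* **Mann-Whitney U** and its two-sided p-value on residuals (exact null
  distribution for small tie-free samples, normal approximation with tie
  and continuity correction otherwise).
* **ROC-AUC** — the normalized U statistic, oriented so AUC >= 0.5
  (direction-free discrimination; the direction is carried by Δ%).
* **MDG** (mean decrease Gini) and model-level **OOB error** from a
  1,000-tree random forest grown on the selected metabolites only.  MDG is
  reported on the R randomForest scale: per-tree sum of sample-weighted
  impurity decreases, averaged over trees, times the sample count.
* Bonferroni significance at alpha / n_tests where n_tests is the number
  of metabolites that survived QC (not the number selected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .adjust import ResidualMatrix
from .panel import ComparisonSpec, MetabolitePanel

#: largest n1*n2 for which the exact MWU null distribution is used
_EXACT_LIMIT = 400


@dataclass
class MWUResult:
    U: float
    p: float
    method: str  # "exact" | "asymptotic"

    def __iter__(self):
        return iter((self.U, self.p))


@dataclass
class EvaluationTable:
    """Per-metabolite statistics plus the model-level forest summary."""

    metabolites: pd.DataFrame
    oob_error: float
    misclassified: list[str]
    comparison: ComparisonSpec
    n_tests: int
    alpha: float


def delta_percent(values_g1, values_g2) -> float:
    """Relative concentration difference (%) against the symmetric mean."""
    m1 = float(np.nanmean(np.asarray(values_g1, dtype=float)))
    m2 = float(np.nanmean(np.asarray(values_g2, dtype=float)))
    denom = (m1 + m2) / 2.0
    if denom <= 0:
        warnings.warn("non-positive mean concentration; delta percent undefined")
        return float("nan")
    return 100.0 * (m2 - m1) / denom


def mwu_test(values_g1, values_g2) -> MWUResult:
    """Mann-Whitney U (oriented as #pairs g1 > g2, ties count 1/2) and
    two-sided p-value.

    Exact null distribution when n1*n2 <= 400 and there are no ties,
    otherwise normal approximation with tie and continuity correction.
    """
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size * y.size <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
    )
    return MWUResult(U=float(res.statistic), p=float(res.pvalue), method=method)


def roc_auc(values_g1, values_g2) -> float:
    """Direction-free ROC-AUC = max(U, n1·n2 − U) / (n1·n2), in [0.5, 1]."""
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one value")
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    n = x.size * y.size
    return max(u, n - u) / n


def bonferroni_flag(p: float, n_tests: int, alpha: float = 0.05) -> bool:
    """True when p clears the Bonferroni-corrected threshold alpha/n_tests."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return bool(p < alpha / n_tests)


def _mean_decrease_gini(rf: RandomForestClassifier, n_samples: int) -> np.ndarray:
    """Per-feature impurity decrease on the R randomForest scale."""
    per_tree = np.array(
        [t.tree_.compute_feature_importances(normalize=False) for t in rf.estimators_]
    )
    return per_tree.mean(axis=0) * n_samples


def rf_evaluate(
    X_selected, y, n_trees: int = 1000, seed: int = 0
) -> tuple[pd.Series, float, list[str]]:
    """Grow a forest on the selected metabolites; report MDG, OOB error and
    the out-of-bag misclassified sample ids."""
    if isinstance(X_selected, pd.DataFrame):
        ids = list(map(str, X_selected.index))
        names = list(map(str, X_selected.columns))
        x = X_selected.to_numpy(dtype=float)
    else:
        x = np.asarray(X_selected, dtype=float)
        ids = [str(i) for i in range(x.shape[0])]
        names = [f"f{j}" for j in range(x.shape[1])]
    y = np.asarray(y)
    if x.shape[1] < 1:
        raise ValueError("need at least one selected metabolite")
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")
    if np.ptp(x, axis=0).min() == 0:
        warnings.warn("constant metabolite among the selected features")

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(x, y)
    mdg = pd.Series(_mean_decrease_gini(rf, x.shape[0]), index=names, name="mdg")
    votes = rf.oob_decision_function_
    if (np.nansum(votes, axis=1) == 0).any():
        warnings.warn("some samples never out-of-bag; grow more trees")
    pred = rf.classes_[np.nanargmax(np.nan_to_num(votes), axis=1)]
    wrong = pred != y
    return mdg, float(wrong.mean()), [ids[i] for i in np.flatnonzero(wrong)]


def within_group_correlations(
    residuals: ResidualMatrix,
    metabolites,
    group: str,
    flag_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix among selected metabolites within one
    group's samples, plus a boolean flag matrix for |r| >= threshold."""
    sub = residuals.subset_groups([group])
    if len(sub.sample_ids) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 samples")
    frame = sub.residuals[list(metabolites)]
    corr = frame.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    constant = frame.std(ddof=1) == 0
    for name in corr.index[constant]:
        corr.loc[name, :] = np.nan
        corr.loc[:, name] = np.nan
    flags = corr.abs() >= flag_threshold
    np.fill_diagonal(flags.values, False)
    return corr, flags


def evaluate_comparison(
    panel: MetabolitePanel,
    residuals: ResidualMatrix,
    comparison: ComparisonSpec,
    selected: list[str],
    n_tests: int,
    alpha: float = 0.05,
    n_trees: int = 1000,
    seed: int = 0,
) -> EvaluationTable:
    """Full per-metabolite evaluation for one pairwise or multi-class
    comparison.

    Δ% uses raw concentrations; MWU/AUC/forest use residuals.  For a
    multi-class comparison the rank statistics are NA (they are two-group
    quantities) and only MDG / OOB are reported.
    """
    if not selected:
        raise ValueError("no selected metabolites to evaluate")
    sub = residuals.subset_groups(comparison.groups)
    y = sub.groups().to_numpy()
    x_sel = sub.residuals[selected]
    mdg, oob, misclassified = rf_evaluate(x_sel, y, n_trees=n_trees, seed=seed)

    rows = []
    pairwise = comparison.mode == "pairwise"
    if pairwise:
        g1, g2 = comparison.groups
        raw = panel.biological()
        mask1 = raw.sample_meta["group"] == g1
        mask2 = raw.sample_meta["group"] == g2
        rmask1 = sub.sample_meta["group"] == g1
        rmask2 = sub.sample_meta["group"] == g2
    for name in selected:
        row = {
            "metabolite": name,
            "analyte_class": panel.metabolite_meta.loc[name, "analyte_class"]
            if name in panel.metabolite_meta.index
            else "NA",
            "mdg": float(mdg[name]),
        }
        if pairwise:
            c1 = raw.concentrations.loc[mask1, name].dropna()
            c2 = raw.concentrations.loc[mask2, name].dropna()
            r1 = sub.residuals.loc[rmask1, name].dropna()
            r2 = sub.residuals.loc[rmask2, name].dropna()
            mwu = mwu_test(r1, r2)
            row.update(
                delta_percent=delta_percent(c1, c2),
                auc=roc_auc(r1, r2),
                mwu_U=mwu.U,
                mwu_p=mwu.p,
                mwu_method=mwu.method,
                bonferroni_significant=bonferroni_flag(mwu.p, n_tests, alpha),
            )
        else:
            row.update(
                delta_percent=np.nan, auc=np.nan, mwu_U=np.nan, mwu_p=np.nan,
                mwu_method="NA", bonferroni_significant=False,
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("metabolite")
    table = table.sort_values("mdg", ascending=False, kind="stable")
    return EvaluationTable(
        metabolites=table,
        oob_error=oob,
        misclassified=misclassified,
        comparison=comparison,
        n_tests=n_tests,
        alpha=alpha,
    )
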