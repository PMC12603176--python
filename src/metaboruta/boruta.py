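"""All-relevant feature selection with shadow features (Boruta-style).

The selector answers "which metabolites carry *any* information about the
class label", not "which minimal subset predicts best".  Each iteration:

1. Every surviving real feature gets a *shadow* copy — the same values,
   independently permuted across samples — so shadows share the marginal
   distribution of the data but are independent of the label by
   construction.
2. A random-forest classifier is fit on [real | shadow] and impurity
   (Gini) importances are read off.
3. A real feature scores a *hit* when its importance exceeds the
   ``perc``-percentile of the shadow importances (default 100 = the best
   shadow).

Under the null a feature hits with probability 1/2 per iteration, so hit
counts are binomial.  After a burn-in, two-sided binomial tests with
multiple-testing correction promote features to Confirmed (hits
significantly above n/2) or demote them to Rejected (significantly below);
rejected features and their shadows leave the model.  Features still
undecided at ``max_iter`` remain Tentative.

The whole procedure is deterministic given ``BorutaParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"

#: iterations accumulated before the first binomial test (matches the
#: canonical implementations' warm-up).
_BURN_IN = 5


@dataclass
class BorutaParams:
    """Tuning knobs of one selector run.

    ``perc`` is the shadow-importance percentile a real feature must beat
    (100 = the maximum shadow, the strictest choice).  With
    ``two_step_correction`` the acceptance/rejection tests use
    Benjamini-Hochberg FDR plus an alpha/n_iterations bound; without it, a
    plain Bonferroni correction over the still-tentative features.
    """

    max_iter: int = 100
    alpha: float = 0.05
    perc: float = 100.0
    n_trees: int = 500
    two_step_correction: bool = True
    max_depth: int | None = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.perc <= 100:
            raise ValueError("perc must be in (0, 100]")


@dataclass
class BorutaDecision:
    """Outcome of one selector run."""

    status: dict[str, str]
    hits: dict[str, int]
    n_iterations_tested: dict[str, int]
    converged_at: int  # iteration at which no Tentative remained (or max_iter)

    def features_with(self, status: str) -> list[str]:
        return [f for f, s in self.status.items() if s == status]

    @property
    def confirmed(self) -> list[str]:
        return self.features_with(CONFIRMED)

    @property
    def tentative(self) -> list[str]:
        return self.features_with(TENTATIVE)

    @property
    def rejected(self) -> list[str]:
        return self.features_with(REJECTED)


def _permute_columns(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each column; preserves every column's multiset."""
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = x[rng.permutation(x.shape[0]), j]
    return out


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level alpha."""
    adj = stats.false_discovery_control(pvals, method="bh")
    return adj <= alpha


def run_boruta(X, y, params: BorutaParams | None = None) -> BorutaDecision:
    """Run the shadow-feature selector on features ``X`` and labels ``y``.

    Parameters
    ----------
    X
        DataFrame (or 2-D array) of predictors, samples x features.
        Features containing NA are dropped with a warning before the run.
    y
        Class labels, one per sample; >= 2 classes with >= 2 samples each.
    """
    params = params or BorutaParams()
    if isinstance(X, pd.DataFrame):
        names = list(map(str, X.columns))
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(x.shape[1])]
    y = np.asarray(y)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 samples each")

    na_cols = np.isnan(x).any(axis=0)
    if na_cols.any():
        import warnings

        warnings.warn(
            f"dropping {int(na_cols.sum())} NA-bearing feature(s): "
            f"{[names[j] for j in np.flatnonzero(na_cols)][:5]}"
        )
        keep = ~na_cols
        x = x[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in X")
    if x.shape[1] == 0:
        raise ValueError("no usable features remain")

    rng = np.random.default_rng(params.seed)
    m = x.shape[1]
    status = np.full(m, TENTATIVE, dtype=object)
    hits = np.zeros(m, dtype=int)
    trials = np.zeros(m, dtype=int)
    converged_at = params.max_iter

    for it in range(1, params.max_iter + 1):
        undecided = status == TENTATIVE
        if not undecided.any():
            converged_at = it - 1
            break
        active = status != REJECTED  # confirmed features stay in the model
        xa = x[:, active]
        shadows = _permute_columns(xa, rng)
        design = np.hstack([xa, shadows])

        rf = RandomForestClassifier(
            n_estimators=params.n_trees,
            max_features="sqrt",
            max_depth=params.max_depth,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(design, y)
        imp = rf.feature_importances_
        n_active = xa.shape[1]
        threshold = np.percentile(imp[n_active:], params.perc)

        active_idx = np.flatnonzero(active)
        hit_now = imp[:n_active] > threshold
        for k, j in enumerate(active_idx):
            if status[j] == TENTATIVE:
                trials[j] += 1
                if hit_now[k]:
                    hits[j] += 1

        if it < _BURN_IN:
            continue

        tent = np.flatnonzero(status == TENTATIVE)
        p_acc = stats.binom.sf(hits[tent] - 1, trials[tent], 0.5)
        p_rej = stats.binom.cdf(hits[tent], trials[tent], 0.5)
        if params.two_step_correction:
            acc = _bh_reject(p_acc, params.alpha) & (p_acc <= params.alpha / it)
            rej = _bh_reject(p_rej, params.alpha) & (p_rej <= params.alpha / it)
        else:
            k = len(tent)
            acc = p_acc * k < params.alpha
            rej = p_rej * k < params.alpha
        status[tent[acc]] = CONFIRMED
        status[tent[rej & ~acc]] = REJECTED

    return BorutaDecision(
        status=dict(zip(names, status)),
        hits=dict(zip(names, hits.tolist())),
        n_iterations_tested=dict(zip(names, trials.tolist())),
        converged_at=converged_at,
    )
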