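"""Stability validation of the feature selection.

A single selector run on 24 (or 36) animals is fragile, so every selection
is re-run under a grid of perturbations: each biological sample is held out
in turn (leave-one-out) and the selector is repeated with ``n_seeds``
different random seeds on the remaining samples, giving
``n_seeds x N`` runs (120 for a 12-vs-12 pairwise comparison with 5 seeds,
180 for the 3x12 multi-class setup).  A metabolite's retention count is the
number of runs in which it was Confirmed; categories:

* ``highly_reliable``   — Confirmed in every run (100%),
* ``moderately_reliable`` — Confirmed in >= 90% of runs,
* ``unstable``          — anything less.

Each run's seed is derived from (base seed, seed index, held-out sample
id), so any individual run can be reproduced in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjust import ResidualMatrix
from .boruta import BorutaParams, run_boruta
from .panel import ComparisonSpec

HIGHLY_RELIABLE = "highly_reliable"
MODERATELY_RELIABLE = "moderately_reliable"
UNSTABLE = "unstable"


@dataclass(frozen=True)
class ReliabilityThresholds:
    high: float = 1.00
    moderate: float = 0.90


@dataclass
class StabilityReport:
    """Per-metabolite retention over all validation runs, plus the run log."""

    counts: pd.DataFrame  # retained, total_runs, retention_frac, category
    run_log: pd.DataFrame  # held_out_sample, seed_index, run_seed, n_confirmed, confirmed
    comparison: ComparisonSpec
    n_seeds: int
    skipped_runs: int = 0

    @property
    def total_runs(self) -> int:
        return int(self.counts["total_runs"].iloc[0]) if len(self.counts) else 0

    def selected(self, category: str = MODERATELY_RELIABLE) -> list[str]:
        """Metabolites at or above the given reliability category."""
        order = {HIGHLY_RELIABLE: 2, MODERATELY_RELIABLE: 1, UNSTABLE: 0}
        floor = order[category]
        keep = self.counts["category"].map(order) >= floor
        return list(self.counts.index[keep])

    def confirmed_at_least_once(self) -> list[str]:
        return list(self.counts.index[self.counts["retained"] > 0])


def classify_reliability(
    retained: int, total_runs: int, thresholds: ReliabilityThresholds | None = None
) -> str:
    """Map a retention count onto its reliability category."""
    thr = thresholds or ReliabilityThresholds()
    if not 0 <= retained <= total_runs or total_runs <= 0:
        raise ValueError(f"invalid retention {retained}/{total_runs}")
    frac = retained / total_runs
    if frac >= thr.high:
        return HIGHLY_RELIABLE
    if frac >= thr.moderate:
        return MODERATELY_RELIABLE
    return UNSTABLE


def run_seed(base_seed: int, seed_index: int, held_out: str) -> int:
    """Stable per-run seed from (base seed, seed index, held-out sample id)."""
    key = f"{base_seed}:{seed_index}:{held_out}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def run_validation(
    residuals: ResidualMatrix,
    comparison: ComparisonSpec,
    params: BorutaParams | None = None,
    n_seeds: int = 5,
    thresholds: ReliabilityThresholds | None = None,
) -> StabilityReport:
    """Leave-one-out x multi-seed selector validation for one comparison.

    Runs the selector ``n_seeds`` times for every held-out sample; a run
    that would leave a class with fewer than 2 samples is skipped (logged
    and excluded from the run total).
    """
    params = params or BorutaParams()
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    sub = residuals.subset_groups(comparison.groups)
    y_all = sub.groups()
    sample_ids = list(sub.sample_ids)
    if len(set(y_all)) < 2:
        raise ValueError("comparison needs samples from >= 2 groups")

    rows = []
    log = []
    counts = pd.Series(0, index=sub.metabolites, dtype=int)
    skipped = 0
    for seed_index in range(n_seeds):
        for held_out in sample_ids:
            keep = [s for s in sample_ids if s != held_out]
            y = y_all.loc[keep]
            if y.value_counts().min() < 2:
                skipped += 1
                log.append(
                    {
                        "held_out_sample": held_out,
                        "seed_index": seed_index,
                        "run_seed": -1,
                        "n_confirmed": -1,
                        "confirmed": "SKIPPED: class below 2 samples",
                    }
                )
                continue
            seed = run_seed(params.seed, seed_index, held_out)
            run_params = BorutaParams(
                max_iter=params.max_iter,
                alpha=params.alpha,
                perc=params.perc,
                n_trees=params.n_trees,
                two_step_correction=params.two_step_correction,
                max_depth=params.max_depth,
                seed=seed,
            )
            decision = run_boruta(sub.residuals.loc[keep], y.to_numpy(), run_params)
            confirmed = decision.confirmed
            counts.loc[counts.index.intersection(confirmed)] += 1
            log.append(
                {
                    "held_out_sample": held_out,
                    "seed_index": seed_index,
                    "run_seed": seed,
                    "n_confirmed": len(confirmed),
                    "confirmed": ";".join(sorted(confirmed)),
                }
            )

    total = n_seeds * len(sample_ids) - skipped
    thr = thresholds or ReliabilityThresholds()
    table = pd.DataFrame(
        {
            "retained": counts,
            "total_runs": total,
            "retention_frac": counts / total if total else np.nan,
        }
    )
    table["category"] = [
        classify_reliability(int(r), total, thr) if total else UNSTABLE
        for r in table["retained"]
    ]
    return StabilityReport(
        counts=table,
        run_log=pd.DataFrame(log),
        comparison=comparison,
        n_seeds=n_seeds,
        skipped_runs=skipped,
    )
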