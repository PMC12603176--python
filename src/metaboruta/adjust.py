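"""Covariate residualization of metabolite concentrations.

Each metabolite is regressed, by ordinary least squares over the pooled
biological samples of *all* groups jointly, on sex (0/1 contrast) and
carcass weight:

    y_i = b0 + b_w * w_i + b_s * s_i + e_i

and the residuals e_i replace the concentrations for all downstream
analysis.  Group labels never enter the design matrix, so breed signal
survives residualization while sex/weight confounding is removed.  The fit
is on raw concentrations by default (a log10 option exists for sensitivity
checks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MetabolitePanel


@dataclass
class ResidualMatrix:
    """Per-sample x metabolite OLS residuals plus the fitted coefficients.

    QC replicate rows are excluded.  ``residuals`` keeps the panel's sample
    and metabolite axes; NA concentrations give NA residuals.  Dropped
    design terms (constant weight, single sex level) have NaN coefficients.
    """

    residuals: pd.DataFrame
    coefficients: pd.DataFrame  # columns: beta0, beta_w, beta_s
    sample_meta: pd.DataFrame
    sex_coding: dict[str, int]
    log_transformed: bool = False

    @property
    def sample_ids(self) -> pd.Index:
        return self.residuals.index

    @property
    def metabolites(self) -> pd.Index:
        return self.residuals.columns

    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    def subset_groups(self, groups) -> "ResidualMatrix":
        keep = self.sample_meta["group"].isin(groups)
        return ResidualMatrix(
            self.residuals.loc[keep],
            self.coefficients,
            self.sample_meta.loc[keep],
            self.sex_coding,
            self.log_transformed,
        )


def sex_contrast(sex: pd.Series) -> tuple[np.ndarray, dict[str, int]]:
    """Map free-string sex labels onto a 0/1 contrast (sorted order: first=0)."""
    levels = sorted(sex.unique())
    if len(levels) > 2:
        raise ValueError(f"sex has {len(levels)} levels, expected at most 2: {levels}")
    coding = {lvl: i for i, lvl in enumerate(levels)}
    return sex.map(coding).to_numpy(dtype=float), coding


def fit_and_residualize(
    panel: MetabolitePanel, log10_transform: bool = False
) -> ResidualMatrix:
    """Fit the sex + carcass-weight model per metabolite; return residuals.

    Pooled fit across all biological samples (never per group).  Rows with
    a missing concentration are excluded from that metabolite's fit and get
    NA residuals.  Rank-deficient terms (constant weight, one sex level)
    are dropped with a warning and a NaN coefficient.
    """
    bio = panel.biological()
    meta = bio.sample_meta
    w = meta["carcass_weight"].to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValueError("carcass_weight missing for one or more biological samples")
    s, coding = sex_contrast(meta["sex"])

    use_w = np.ptp(w) > 0
    use_s = len(coding) == 2
    if not use_w:
        warnings.warn("carcass_weight is constant; weight term dropped")
    if not use_s:
        warnings.warn("sex has a single level; sex term dropped")

    cols = [np.ones_like(w)]
    labels = ["beta0"]
    if use_w:
        cols.append(w)
        labels.append("beta_w")
    if use_s:
        cols.append(s)
        labels.append("beta_s")
    design = np.column_stack(cols)

    y = bio.concentrations.to_numpy(dtype=float)
    if log10_transform:
        y = np.log10(y)
    n, m = y.shape
    resid = np.full((n, m), np.nan)
    coef = np.full((m, 3), np.nan)
    col_pos = {lab: i for i, lab in enumerate(labels)}

    ok_all = ~np.isnan(y)
    complete = ok_all.all(axis=0)
    if complete.any():
        # one shared lstsq for all fully observed metabolites
        beta, *_ = np.linalg.lstsq(design, y[:, complete], rcond=None)
        resid[:, complete] = y[:, complete] - design @ beta
        for lab, i in col_pos.items():
            coef[complete, {"beta0": 0, "beta_w": 1, "beta_s": 2}[lab]] = beta[i]
    for j in np.flatnonzero(~complete):
        ok = ok_all[:, j]
        if ok.sum() <= design.shape[1]:
            warnings.warn(
                f"metabolite {bio.metabolites[j]!r}: too few observations to fit; all-NA residuals"
            )
            continue
        beta, *_ = np.linalg.lstsq(design[ok], y[ok, j], rcond=None)
        resid[ok, j] = y[ok, j] - design[ok] @ beta
        for lab, i in col_pos.items():
            coef[j, {"beta0": 0, "beta_w": 1, "beta_s": 2}[lab]] = beta[i]

    return ResidualMatrix(
        residuals=pd.DataFrame(resid, index=bio.sample_ids, columns=bio.metabolites),
        coefficients=pd.DataFrame(
            coef, index=bio.metabolites, columns=["beta0", "beta_w", "beta_s"]
        ),
        sample_meta=meta.copy(),
        sex_coding=coding,
        log_transformed=log10_transform,
    )
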