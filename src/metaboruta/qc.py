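"""Quality-control filtering of a metabolite panel.

Three-step metabolite screen, applied in fixed precedence so each excluded
metabolite carries exactly one reason:

1. ``CV`` — intraplate coefficient of variation across the QC replicate
   injections above ``cv_max`` (default 20%), or CV undefined.
2. ``LOD_QC`` — QC replicate concentrations below the metabolite's limit of
   detection (all replicates by default; configurable to "any").
3. ``LOD_SAMPLES`` — more than ``lod_sample_frac`` (default 30%) of the
   biological samples below the LOD.
4. ``NA_ZERO`` — more than ``na_zero_frac`` (default 30%) of the biological
   samples missing or exactly zero.  Missing and zero are distinct
   measurement outcomes but count toward the same rule.

Samples are never removed here.  A separate advisory screen scores each
biological sample's robust distance from the panel centroid and flags
outliers; removal requires an explicit downstream decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MetabolitePanel

REASONS = ("CV", "LOD_QC", "LOD_SAMPLES", "NA_ZERO", "none")


class QCConfigError(ValueError):
    """QC filtering requested with inputs that cannot support it."""


class UndefinedCVError(ValueError):
    """CV cannot be computed (fewer than 2 replicates, or zero mean)."""


@dataclass
class QCThresholds:
    """Cutoffs of the metabolite screen; ``None`` disables a rule."""

    cv_max: float | None = 20.0
    lod_qc_rule: str | None = "all"  # "all" | "any" | None
    lod_sample_frac: float | None = 0.30
    na_zero_frac: float | None = 0.30
    outlier_cutoff: float = 3.5


@dataclass
class QCReport:
    """Per-metabolite filter statistics plus advisory sample-outlier flags."""

    metabolites: pd.DataFrame  # cv_percent, frac_below_lod_qc, frac_na_zero,
    #                            frac_below_lod_samples, excluded, reason
    outlier_samples: list[dict] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return int((~self.metabolites["excluded"]).sum())

    @property
    def n_excluded(self) -> int:
        return int(self.metabolites["excluded"].sum())

    def reason_counts(self) -> dict[str, int]:
        sub = self.metabolites[self.metabolites["excluded"]]
        return sub["reason"].value_counts().to_dict()


def compute_cv(qc_values) -> float:
    """Percent coefficient of variation of QC replicate concentrations.

    CV% = 100 * sd / mean with the sample (n-1) standard deviation.
    """
    vals = np.asarray(qc_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise UndefinedCVError(f"need >= 2 non-missing replicates, got {vals.size}")
    mean = vals.mean()
    if mean <= 0:
        raise UndefinedCVError("replicate mean is not positive")
    return float(100.0 * vals.std(ddof=1) / mean)


def apply_filters(
    panel: MetabolitePanel, thresholds: QCThresholds | None = None
) -> tuple[MetabolitePanel, QCReport]:
    """Screen every metabolite; return the cleaned panel and a full report.

    The report covers every input metabolite exactly once; the cleaned
    panel keeps all rows (QC replicates included) and drops only the
    excluded metabolite columns.  Values below the LOD in retained
    metabolites are kept as reported (no imputation).
    """
    thr = thresholds or QCThresholds()
    qc = panel.qc_rows()
    if thr.cv_max is not None and len(qc) < 2:
        raise QCConfigError(
            "CV filtering needs >= 2 QC replicate rows; disable cv_max or add QC rows"
        )
    bio = panel.concentrations.loc[~panel.qc_mask()]
    lod = panel.metabolite_meta["lod"]

    rows = []
    for name in panel.metabolites:
        cv = np.nan
        cv_failed = False
        if thr.cv_max is not None:
            try:
                cv = compute_cv(qc[name])
                cv_failed = cv > thr.cv_max
            except UndefinedCVError:
                cv_failed = True
        qvals = qc[name].to_numpy(dtype=float) if len(qc) else np.array([])
        below_qc = qvals < lod[name]
        frac_below_lod_qc = float(below_qc.mean()) if qvals.size else np.nan
        bvals = bio[name].to_numpy(dtype=float)
        ok = ~np.isnan(bvals)
        frac_below_lod_samples = float((bvals[ok] < lod[name]).mean()) if ok.any() else 1.0
        frac_na_zero = float((~ok | (np.nan_to_num(bvals, nan=1.0) == 0)).mean())

        reason = "none"
        if cv_failed:
            reason = "CV"
        elif thr.lod_qc_rule is not None and qvals.size:
            hit = below_qc.all() if thr.lod_qc_rule == "all" else below_qc.any()
            if hit:
                reason = "LOD_QC"
        if reason == "none" and thr.lod_sample_frac is not None:
            if frac_below_lod_samples > thr.lod_sample_frac:
                reason = "LOD_SAMPLES"
        if reason == "none" and thr.na_zero_frac is not None:
            if frac_na_zero > thr.na_zero_frac:
                reason = "NA_ZERO"

        rows.append(
            {
                "metabolite": name,
                "cv_percent": cv,
                "frac_below_lod_qc": frac_below_lod_qc,
                "frac_below_lod_samples": frac_below_lod_samples,
                "frac_na_zero": frac_na_zero,
                "excluded": reason != "none",
                "reason": reason,
            }
        )
    table = pd.DataFrame(rows).set_index("metabolite")
    keep = table.index[~table["excluded"]]
    clean = panel.subset_metabolites(keep)
    report = QCReport(metabolites=table, outlier_samples=flag_outlier_samples(
        clean, cutoff=thr.outlier_cutoff))
    return clean, report


def flag_outlier_samples(panel: MetabolitePanel, cutoff: float = 3.5) -> list[dict]:
    """Advisory outlier screen on the biological samples.

    Each metabolite is scaled to zero mean / unit variance; a sample's score
    is the robust z (median/MAD) of its Euclidean distance from the
    centroid in that scaled space.  Scores above ``cutoff`` flag the sample.
    All-missing samples are flagged unconditionally.
    """
    bio = panel.concentrations.loc[~panel.qc_mask()]
    if len(bio) < 3:
        raise QCConfigError("outlier screen needs >= 3 biological samples")
    x = bio.to_numpy(dtype=float)
    all_na = np.isnan(x).all(axis=1)

    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    # NA cells contribute nothing to a sample's distance
    d = np.sqrt(np.nansum(z**2, axis=1))

    med = np.median(d[~all_na]) if (~all_na).any() else 0.0
    mad = np.median(np.abs(d[~all_na] - med)) if (~all_na).any() else 0.0
    denom = 1.4826 * mad
    if denom == 0:
        scores = np.zeros_like(d)
    else:
        scores = (d - med) / denom

    flags = []
    for i, sid in enumerate(bio.index):
        if all_na[i]:
            flags.append({"sample_id": sid, "score": np.inf, "reason": "all values missing"})
        elif scores[i] > cutoff:
            flags.append({"sample_id": sid, "score": float(scores[i]), "reason": "distance"})
    return flags
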