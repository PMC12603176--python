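"""Core data containers for a targeted metabolite concentration panel.

A panel is a samples x metabolites matrix of absolute concentrations (µM)
plus per-sample metadata (group label, sex, carcass weight, QC-replicate
flag) and per-metabolite metadata (analyte class, limit of detection).
Quality-control replicate rows live in the same matrix, flagged by
``is_qc``; they carry no group label semantics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Analyte subclasses of a Biocrates-p180-style targeted panel.
ANALYTE_CLASSES = ("AA", "AC", "BA", "hexose", "LysoPC", "PC", "SM")

SAMPLE_META_COLUMNS = ("group", "sex", "carcass_weight", "is_qc")
METABOLITE_META_COLUMNS = ("analyte_class", "lod")


class PanelValidationError(ValueError):
    """A panel violates a structural invariant."""


class PanelFormatError(ValueError):
    """An input file does not conform to the expected tabular layout."""


@dataclass
class MetabolitePanel:
    """Concentration matrix with sample and metabolite metadata.

    Parameters
    ----------
    concentrations
        DataFrame of non-negative concentrations (µM), indexed by sample id,
        one column per metabolite. NA is a legal value and is distinct from
        zero (zeros are real measured concentrations).
    sample_meta
        DataFrame indexed by sample id with columns ``group``, ``sex``,
        ``carcass_weight`` (kg) and ``is_qc`` (bool).
    metabolite_meta
        DataFrame indexed by metabolite name with columns ``analyte_class``
        and ``lod`` (limit of detection, µM).
    """

    concentrations: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        conc, smeta, mmeta = self.concentrations, self.sample_meta, self.metabolite_meta
        if not conc.index.equals(smeta.index):
            raise PanelValidationError(
                "concentration rows and sample metadata indexes differ"
            )
        if not conc.columns.equals(mmeta.index):
            raise PanelValidationError(
                "concentration columns and metabolite metadata indexes differ"
            )
        if conc.index.has_duplicates:
            dups = conc.index[conc.index.duplicated()].unique().tolist()
            raise PanelValidationError(f"duplicate sample ids: {dups}")
        if conc.columns.has_duplicates:
            dups = conc.columns[conc.columns.duplicated()].unique().tolist()
            raise PanelValidationError(f"duplicate metabolite names: {dups}")
        missing = [c for c in SAMPLE_META_COLUMNS if c not in smeta.columns]
        if missing:
            raise PanelValidationError(f"sample metadata lacks columns: {missing}")
        missing = [c for c in METABOLITE_META_COLUMNS if c not in mmeta.columns]
        if missing:
            raise PanelValidationError(f"metabolite metadata lacks columns: {missing}")
        vals = conc.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise PanelValidationError("negative concentration encountered")
        w = smeta["carcass_weight"].to_numpy(dtype=float)
        if np.any(w[~np.isnan(w)] <= 0):
            raise PanelValidationError("carcass_weight must be positive")
        if (mmeta["lod"].to_numpy(dtype=float) < 0).any():
            raise PanelValidationError("lod must be non-negative")

    # -- views -------------------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.concentrations.index

    @property
    def metabolites(self) -> pd.Index:
        return self.concentrations.columns

    @property
    def n_samples(self) -> int:
        return int((~self.sample_meta["is_qc"].astype(bool)).sum())

    @property
    def n_qc(self) -> int:
        return int(self.sample_meta["is_qc"].astype(bool).sum())

    def qc_mask(self) -> np.ndarray:
        return self.sample_meta["is_qc"].astype(bool).to_numpy()

    def qc_rows(self) -> pd.DataFrame:
        """Concentrations of the QC replicate rows only."""
        return self.concentrations.loc[self.qc_mask()]

    def biological(self) -> "MetabolitePanel":
        """Panel restricted to the non-QC (biological) samples."""
        keep = ~self.qc_mask()
        return MetabolitePanel(
            self.concentrations.loc[keep],
            self.sample_meta.loc[keep],
            self.metabolite_meta,
        )

    def groups(self) -> list[str]:
        """Distinct group labels of the biological samples, in order of appearance."""
        g = self.sample_meta.loc[~self.qc_mask(), "group"]
        return list(dict.fromkeys(g))

    def subset_metabolites(self, names) -> "MetabolitePanel":
        names = [n for n in self.metabolites if n in set(names)]
        return MetabolitePanel(
            self.concentrations[names],
            self.sample_meta,
            self.metabolite_meta.loc[names],
        )

    def subset_groups(self, groups) -> "MetabolitePanel":
        keep = self.sample_meta["group"].isin(groups) & ~self.qc_mask()
        return MetabolitePanel(
            self.concentrations.loc[keep],
            self.sample_meta.loc[keep],
            self.metabolite_meta,
        )


@dataclass(frozen=True)
class ComparisonSpec:
    """A breed comparison: which groups, in which order.

    The group order fixes the sign convention of the relative concentration
    difference: Δ% = 100·(x̄₂ − x̄₁) / mean(x̄₁, x̄₂), so Δ% < 0 means the
    second-listed group has the lower mean concentration.
    """

    mode: str  # "pairwise" | "multiclass"
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("pairwise", "multiclass"):
            raise ValueError(f"unknown comparison mode: {self.mode!r}")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("comparison groups must be distinct")
        if self.mode == "pairwise" and len(self.groups) != 2:
            raise ValueError("pairwise comparison needs exactly 2 groups")
        if self.mode == "multiclass" and len(self.groups) < 3:
            raise ValueError("multiclass comparison needs >= 3 groups")

    @property
    def label(self) -> str:
        return "-".join(self.groups)

    def check_against(self, panel: MetabolitePanel) -> None:
        present = set(panel.groups())
        missing = [g for g in self.groups if g not in present]
        if missing:
            raise PanelValidationError(
                f"comparison groups not present in panel: {missing}"
            )

    @staticmethod
    def pairwise(g1: str, g2: str) -> "ComparisonSpec":
        return ComparisonSpec("pairwise", (g1, g2))

    @staticmethod
    def multiclass(groups) -> "ComparisonSpec":
        return ComparisonSpec("multiclass", tuple(groups))
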