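"""Reading and writing panels and result tables.

Primary on-disk layout is wide UTF-8 TSV (CSV accepted by extension or an
explicit dialect): one row per sample, metadata columns first
(``sample_id``, ``group``, ``sex``, ``carcass_weight``, ``is_qc``), then one
column per metabolite.  Metabolite metadata (``name``, ``analyte_class``,
``lod``) lives in a sidecar table.  NA and zero are distinct: zeros are
measured concentrations, NA tokens (``""``, ``NA``, ``<LOD`` by default)
parse to missing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    METABOLITE_META_COLUMNS,
    MetabolitePanel,
    PanelFormatError,
)

_META_COLS = ["sample_id", "group", "sex", "carcass_weight", "is_qc"]
_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


@dataclasses.dataclass(frozen=True)
class Dialect:
    """Tabular dialect of a panel file."""

    sep: str = "\t"
    na_tokens: tuple[str, ...] = ("", "NA", "NaN", "<LOD")
    float_precision: int = 6

    @staticmethod
    def for_path(path) -> "Dialect":
        return Dialect(sep="," if str(path).endswith(".csv") else "\t")


def _parse_float_column(raw: pd.Series, column: str,
                        na_tokens: tuple[str, ...] = ()) -> pd.Series:
    if na_tokens:
        raw = raw.mask(raw.astype(str).str.strip().isin(na_tokens))
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PanelFormatError(
            f"cannot parse value {raw.iloc[row]!r} in column {column!r}, row {row + 1}"
        )
    return out


def _parse_bool_column(raw: pd.Series, column: str) -> pd.Series:
    def one(v, i):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUE_TOKENS:
            return True
        if s in _FALSE_TOKENS:
            return False
        raise PanelFormatError(
            f"cannot parse boolean {v!r} in column {column!r}, row {i + 1}"
        )

    return pd.Series([one(v, i) for i, v in enumerate(raw)], index=raw.index)


def read_panel(path, meta_path=None, dialect: Dialect | None = None) -> MetabolitePanel:
    """Read a wide panel table (plus optional metabolite-metadata sidecar).

    Every input row becomes a panel row (QC replicates included); rows are
    never silently dropped.  Without a sidecar, analyte classes default to
    ``"AA"`` and LODs to 0 (no LOD-based filtering possible).

    Raises
    ------
    PanelFormatError
        Missing metadata column, or an unparseable numeric/boolean cell
        (the error names the offending row and column).
    """
    path = Path(path)
    dialect = dialect or Dialect.for_path(path)
    # NA tokens are resolved per column below: numeric columns map them to
    # missing, while group/sex keep their literal strings
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLS if c not in raw.columns]
    if missing:
        raise PanelFormatError(f"panel file lacks metadata columns: {missing}")
    metabolite_names = [c for c in raw.columns if c not in _META_COLS]
    if not metabolite_names:
        raise PanelFormatError("panel file contains no metabolite columns")

    sample_ids = raw["sample_id"].astype(str)
    smeta = pd.DataFrame(
        {
            "group": raw["group"].astype(str),
            "sex": raw["sex"].astype(str),
            "carcass_weight": _parse_float_column(
                raw["carcass_weight"], "carcass_weight", dialect.na_tokens
            ),
            "is_qc": _parse_bool_column(raw["is_qc"], "is_qc"),
        }
    )
    smeta.index = pd.Index(sample_ids, name="sample_id")

    conc = pd.DataFrame(index=smeta.index)
    for name in metabolite_names:
        conc[name] = _parse_float_column(raw[name], name, dialect.na_tokens).to_numpy()

    if meta_path is not None:
        mmeta = read_metabolite_meta(meta_path, dialect)
        missing = [n for n in metabolite_names if n not in mmeta.index]
        if missing:
            raise PanelFormatError(
                f"metabolite metadata lacks entries for: {missing[:5]}"
            )
        mmeta = mmeta.loc[metabolite_names]
    else:
        mmeta = pd.DataFrame(
            {"analyte_class": "AA", "lod": 0.0},
            index=pd.Index(metabolite_names, name="name"),
        )
    return MetabolitePanel(conc, smeta, mmeta)


def read_metabolite_meta(path, dialect: Dialect | None = None) -> pd.DataFrame:
    path = Path(path)
    dialect = dialect or Dialect.for_path(path)
    raw = pd.read_csv(path, sep=dialect.sep, na_values=list(dialect.na_tokens))
    need = ["name", *METABOLITE_META_COLUMNS]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise PanelFormatError(f"metabolite metadata lacks columns: {missing}")
    mmeta = raw.set_index("name")[list(METABOLITE_META_COLUMNS)]
    mmeta["lod"] = _parse_float_column(mmeta["lod"].astype(object), "lod").to_numpy()
    return mmeta


def write_panel(panel: MetabolitePanel, path, meta_path=None,
                dialect: Dialect | None = None) -> None:
    """Write a panel as a wide table, optionally with its metadata sidecar."""
    path = Path(path)
    dialect = dialect or Dialect.for_path(path)
    out = panel.sample_meta.copy()
    out.insert(0, "sample_id", panel.sample_ids)
    out["is_qc"] = out["is_qc"].map(lambda b: "true" if b else "false")
    body = panel.concentrations.copy()
    frame = pd.concat([out.reset_index(drop=True), body.reset_index(drop=True)], axis=1)
    _write_frame(frame, path, dialect)
    if meta_path is not None:
        mm = panel.metabolite_meta.copy()
        mm.insert(0, "name", mm.index)
        _write_frame(mm.reset_index(drop=True), Path(meta_path), dialect)


def write_table(rows, path, dialect: Dialect | None = None, sort_by=None) -> None:
    """Write any tabular result as TSV with a deterministic layout.

    Floats are rendered at the dialect's fixed precision, missing values as
    the literal token ``NA``.  When ``sort_by`` is given rows are sorted on
    those columns (ties broken by original order) so repeated runs emit
    byte-identical files.
    """
    frame = pd.DataFrame(rows)
    if frame.shape[1] == 0:
        raise ValueError("refusing to write a table with no columns")
    if sort_by:
        frame = frame.sort_values(list(sort_by), kind="stable")
    _write_frame(frame.reset_index(drop=True), Path(path), dialect or Dialect())


def _write_frame(frame: pd.DataFrame, path: Path, dialect: Dialect) -> None:
    fmt = f"%.{dialect.float_precision}g"
    frame.to_csv(
        path,
        sep=dialect.sep,
        index=False,
        na_rep="NA",
        float_format=fmt,
        lineterminator="\n",
    )
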