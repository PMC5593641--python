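"""Per-cell data model, CSV dialect, log transform and cohort splitting.

The unit of observation throughout the package is one imaged cell nucleus:
its identity (patient, specimen phase, imaging frame), the tissue compartment
of the frame it was segmented from, its pathological/Gleason labels inherited
from the tissue of origin, and nonnegative nuclear fluorescence intensities
for a marker panel on a 12-bit scale.

Tables are plain CSV (UTF-8, comma separated, header row, "." decimal) with a
JSON provenance sidecar recording seeds, transforms and filters applied.
Category tokens come from closed vocabularies; note that the compartment token
for cultured cells is the literal string ``NA``, so CSV parsing must not treat
it as missing data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "COMPARTMENTS",
    "PATH_CATEGORIES",
    "GLEASON_GROUPS",
    "PANEL_I",
    "PANEL_II",
    "CORE_COLUMNS",
    "ParseError",
    "DefinitionError",
    "ConfigurationError",
    "CellTable",
    "read_cell_table",
    "write_cell_table",
    "log_transform",
    "split_development_validation",
    "filter_compartment",
]

PHASES = ("biopsy1", "biopsy2", "prostatectomy", "culture")

#: Imaging-frame tissue compartments: pure epithelium (E), epithelium with a
#: minor stromal border (E+s), mixed epithelium/stroma (ES), pure stroma (S).
#: Cultured cells have no tissue compartment and carry the token "NA".
COMPARTMENTS = ("E", "E+s", "ES", "S", "NA")

#: Pathological categories: benign (B), atypical small acinar proliferation
#: (ASAP), adenocarcinoma (AC), extensive adenocarcinoma (LAC) at biopsy, and
#: Stage II / Stage III disease at prostatectomy.
PATH_CATEGORIES = ("B", "ASAP", "AC", "LAC", "StageII", "StageIII", "unknown")

#: Gleason groups: benign/no score, 6 (3+3), 7 (3+4), 7 (4+3).
GLEASON_GROUPS = ("B", "G33", "G34", "G43", "unknown")

PANEL_I = ("DAPI", "AMACR", "5mC", "5hmC")
PANEL_II = ("DAPI", "SAFB", "H3K9me3", "H3K27me3", "nAR")

CORE_COLUMNS = (
    "cell_id",
    "patient_id",
    "phase",
    "frame_id",
    "compartment",
    "path_category",
    "gleason_group",
)

#: Optional boolean bookkeeping columns (12-bit ceiling clipping at
#: generation; floor clamping at log transform).
FLAG_COLUMNS = ("clipped", "clamped")

_CATEGORY_VOCAB = {
    "phase": PHASES,
    "compartment": COMPARTMENTS,
    "path_category": PATH_CATEGORIES,
    "gleason_group": GLEASON_GROUPS,
}


class ParseError(ValueError):
    """A cell-table file violates the documented schema."""


class DefinitionError(ValueError):
    """An operation was called with arguments outside its definition."""


class ConfigurationError(ValueError):
    """A configuration object violates its own invariants."""


@dataclass
class CellTable:
    """An ordered collection of per-cell records sharing one marker set.

    Parameters
    ----------
    data:
        One row per cell. Must contain :data:`CORE_COLUMNS`, one float column
        per marker, and optionally the boolean flag columns.
    marker_names:
        Ordered marker list; fixes the column order of the intensity block.
    provenance:
        Free-form metadata (source, seed, transforms/filters applied). The key
        ``log_transformed`` marks tables whose intensity columns hold natural
        log intensities (which may legitimately be negative).
    """

    data: pd.DataFrame
    marker_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marker_names = tuple(self.marker_names)
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"missing required columns: {missing}")
        missing_markers = [m for m in self.marker_names if m not in self.data.columns]
        if missing_markers:
            raise ParseError(f"missing marker columns: {missing_markers}")
        for col, vocab in _CATEGORY_VOCAB.items():
            bad = ~self.data[col].isin(vocab)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"unknown {col} token {self.data[col].iloc[row]!r} at row {row}"
                )
        values = self.data[list(self.marker_names)].to_numpy()
        if not np.isfinite(values).all():
            row = int(np.flatnonzero(~np.isfinite(values).all(axis=1))[0])
            raise ParseError(f"non-finite intensity at row {row}")
        if not self.is_log and (values < 0).any():
            row = int(np.flatnonzero((values < 0).any(axis=1))[0])
            raise ParseError(f"negative intensity at row {row}")
        dup = self.data.duplicated(subset=["patient_id", "phase", "cell_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ParseError(f"duplicate (patient_id, phase, cell_id) at row {row}")

    # -- accessors ---------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def is_log(self) -> bool:
        return bool(self.provenance.get("log_transformed", False))

    def intensity_matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """Float matrix of shape (n_cells, n_markers) in marker order."""
        markers = self.marker_names if markers is None else tuple(markers)
        unknown = [m for m in markers if m not in self.marker_names]
        if unknown:
            raise DefinitionError(f"markers not in table: {unknown}")
        return self.data[list(markers)].to_numpy(dtype=float)

    def with_provenance(self, **entries) -> "CellTable":
        return CellTable(self.data, self.marker_names, {**self.provenance, **entries})

    def copy(self) -> "CellTable":
        return CellTable(self.data.copy(), self.marker_names, dict(self.provenance))

    def equals(self, other: "CellTable") -> bool:
        return (
            self.marker_names == other.marker_names
            and self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        )


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".prov.json")


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table as CSV plus a JSON provenance sidecar."""
    path = Path(path)
    cols = list(CORE_COLUMNS) + list(table.marker_names) + [
        c for c in FLAG_COLUMNS if c in table.data.columns
    ]
    table.data[cols].to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(table.provenance, indent=2, default=str))


def read_cell_table(path: str | Path, markers: Sequence[str] | None = None) -> CellTable:
    """Read a cell-table CSV written by :func:`write_cell_table`.

    ``keep_default_na`` is disabled so the culture-compartment token ``NA``
    survives parsing. Marker columns are every non-core, non-flag column
    unless ``markers`` narrows the selection.
    """
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {missing}")
    inferred = [c for c in df.columns if c not in CORE_COLUMNS and c not in FLAG_COLUMNS]
    marker_names = tuple(markers) if markers is not None else tuple(inferred)
    for col in marker_names:
        if col not in df.columns:
            raise ParseError(f"{path}: missing marker column {col!r}")
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"{path}: non-numeric intensity in {col!r} at row {row}")
        df[col] = numeric.astype(float)
    for col in FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    prov_path = _sidecar(path)
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    provenance.setdefault("source", str(path))
    return CellTable(df, marker_names, provenance)


def log_transform(table: CellTable, floor: float = 1.0) -> CellTable:
    """Replace every intensity v by ln(max(v, floor)).

    Channel intensities are strongly right-skewed, so the whole analysis
    (PCA, logistic scoring, k-NN metric) operates on natural-log intensities.
    Zero or sub-floor intensities are clamped to ``floor`` (default 1 unit on
    the 12-bit scale) rather than dropped, preserving the cell counts that the
    composition stage reports; clamped cells are flagged.
    """
    if floor <= 0:
        raise DefinitionError(f"floor must be positive, got {floor}")
    if table.is_log:
        raise DefinitionError("table is already log-transformed")
    df = table.data.copy()
    values = table.intensity_matrix()
    clamped = (values < floor).any(axis=1)
    df[list(table.marker_names)] = np.log(np.maximum(values, floor))
    df["clamped"] = clamped
    return CellTable(
        df,
        table.marker_names,
        {
            **table.provenance,
            "log_transformed": True,
            "log_floor": floor,
            "n_clamped": int(clamped.sum()),
        },
    )


def split_development_validation(
    table: CellTable,
    development_patients: Iterable[str],
    validation_patients: Iterable[str],
) -> tuple[CellTable, CellTable]:
    """Partition a cohort by patient into development and validation tables.

    The split is by patient, never by cell, so no information leaks between
    model development and validation. Patients in neither set are dropped.
    """
    dev = set(development_patients)
    val = set(validation_patients)
    overlap = dev & val
    if overlap:
        raise DefinitionError(f"patient sets overlap: {sorted(overlap)}")
    dev_df = table.data[table.data["patient_id"].isin(dev)].reset_index(drop=True)
    val_df = table.data[table.data["patient_id"].isin(val)].reset_index(drop=True)
    return (
        CellTable(dev_df, table.marker_names, {**table.provenance, "split": "development"}),
        CellTable(val_df, table.marker_names, {**table.provenance, "split": "validation"}),
    )


def filter_compartment(table: CellTable, compartments: Iterable[str]) -> CellTable:
    """Retain only cells whose frame compartment is in ``compartments``.

    Cultured cells (compartment ``NA``) are excluded unless ``NA`` is listed
    explicitly. Row order is preserved.
    """
    comps = set(compartments)
    if not comps:
        raise DefinitionError("empty compartment selection")
    unknown = comps - set(COMPARTMENTS)
    if unknown:
        raise DefinitionError(f"unknown compartments: {sorted(unknown)}")
    df = table.data[table.data["compartment"].isin(comps)].reset_index(drop=True)
    return CellTable(
        df,
        table.marker_names,
        {**table.provenance, "compartment_filter": sorted(comps)},
    )
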