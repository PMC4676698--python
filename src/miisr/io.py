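"""Reading, scaling, filtering and writing molecular position files.

Localization microscopes export per-molecule position tables in a handful
of vendor dialects.  This module standardizes them into
:class:`~miisr.tables.LocalizationTable` records — x/y/z in nanometres,
photon count and localization precision — applying linear pixel→nm and
intensity→photon scaling plus quality filters identically to every record.

Vendor column layouts drift across instrument-software versions, so the
dialects are shipped as configurable column-map presets; ``generic_tabular``
with an explicit column map is the documented fallback.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .tables import STANDARD_COLUMNS, LocalizationTable

__all__ = ["ConversionSpec", "DIALECT_PRESETS", "read_positions", "write_positions"]


class FormatError(ValueError):
    """A position file does not match the declared dialect."""


# Column-map presets: standard field -> 0-based column index in the export.
# The vendor layouts are presets, not guarantees; validate against real
# exports and fall back to generic_tabular with an explicit map when needed.
DIALECT_PRESETS: dict[str, dict[str, Optional[int]]] = {
    # Leica GSD ASCII export: x, y, z, intensity, precision
    "leica_gsd": {"x": 0, "y": 1, "z": 2, "photons": 3, "precision": 4},
    # Zeiss ELYRA text export (trimmed): x, y, precision, photons
    "zeiss_elyra": {"x": 0, "y": 1, "z": None, "photons": 3, "precision": 2},
    # QuickPALM results table: x, y, z, intensity
    "quickpalm": {"x": 0, "y": 1, "z": 2, "photons": 3, "precision": None},
    # Standardized layout written by write_positions
    "miisr": {"x": 0, "y": 1, "z": 2, "photons": 3, "precision": 4},
}


@dataclass
class ConversionSpec:
    """How to interpret and filter a raw position file.

    Parameters
    ----------
    pixel_to_nm : float
        Linear scale applied to x/y/z (nm per source unit; 1.0 when the
        file is already in nm).
    intensity_to_photons : float
        Linear scale from the file's intensity units to photon counts.
    min_photons : float
        Records with fewer photons are discarded (0 keeps everything).
    max_precision : float
        Records with a worse (larger) localization precision are discarded
        (``inf`` keeps everything).  Records with no precision value are
        kept: they simply cannot contribute to precision-based statistics.
    dialect : str
        One of ``DIALECT_PRESETS`` or ``"generic_tabular"``.
    column_map : mapping, optional
        Required for ``generic_tabular``: standard field name → column
        index.  ``x`` and ``y`` are mandatory; ``z``, ``photons`` and
        ``precision`` may be omitted or ``None``.
    has_header : bool
        Whether the first line of the file is a header row.
    """

    pixel_to_nm: float = 1.0
    intensity_to_photons: float = 1.0
    min_photons: float = 0.0
    max_precision: float = np.inf
    dialect: str = "miisr"
    column_map: Optional[Mapping[str, Optional[int]]] = None
    has_header: bool = True

    def __post_init__(self) -> None:
        if self.pixel_to_nm < 0 or self.intensity_to_photons < 0:
            raise ValueError("scale factors must be >= 0")
        if self.dialect == "generic_tabular":
            if self.column_map is None:
                raise ValueError("generic_tabular requires an explicit column_map")
        elif self.dialect not in DIALECT_PRESETS:
            raise ValueError(f"unknown dialect {self.dialect!r}")

    def resolved_columns(self) -> dict[str, Optional[int]]:
        cmap = dict(self.column_map) if self.dialect == "generic_tabular" \
            else dict(DIALECT_PRESETS[self.dialect])
        for key in ("x", "y"):
            if cmap.get(key) is None:
                raise FormatError(f"column map lacks mandatory column {key!r}")
        for key in ("z", "photons", "precision"):
            cmap.setdefault(key, None)
        return cmap


def read_positions(path, spec: ConversionSpec,
                   channel_id: Optional[str] = None) -> LocalizationTable:
    """Read one position file into a standardized nm-unit table.

    Scaling (``pixel_to_nm``, ``intensity_to_photons``) is applied linearly
    and identically to every record, then records failing ``min_photons``
    or ``max_precision`` are removed.  A missing z column is filled with 0
    and flagged via ``has_z=False``.

    Raises
    ------
    FileNotFoundError
        The path does not exist.
    FormatError
        Mandatory columns are missing (the error names the column).
    ValueError
        A cell cannot be parsed as a number (the error names the row).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    cmap = spec.resolved_columns()
    try:
        df = pd.read_csv(path, sep="\t", header=0 if spec.has_header else None,
                         dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise IOError(f"cannot read {path}: {exc}") from exc
    if df.shape[1] <= max(i for i in cmap.values() if i is not None):
        missing = [k for k, i in cmap.items()
                   if i is not None and i >= df.shape[1]]
        raise FormatError(
            f"{path}: file has {df.shape[1]} columns; missing {missing}")

    def column(key: str) -> Optional[np.ndarray]:
        idx = cmap[key]
        if idx is None:
            return None
        raw = df.iloc[:, idx].to_numpy()
        out = np.empty(len(raw), dtype=float)
        for row, cell in enumerate(raw):
            try:
                out[row] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} in data row "
                    f"{row + 1}, column {key!r}") from None
        return out

    x = column("x") * spec.pixel_to_nm
    y = column("y") * spec.pixel_to_nm
    z = column("z")
    has_z = z is not None
    if has_z:
        z = z * spec.pixel_to_nm
    photons = column("photons")
    if photons is not None:
        photons = photons * spec.intensity_to_photons
    precision = column("precision")

    keep = np.ones(x.size, dtype=bool)
    if photons is not None and spec.min_photons > 0:
        keep &= photons >= spec.min_photons
    if precision is not None and np.isfinite(spec.max_precision):
        # no-precision records are kept (NaN comparisons are False)
        keep &= ~(precision > spec.max_precision)

    table = LocalizationTable(
        x=x[keep], y=y[keep],
        z=None if not has_z else z[keep],
        photons=None if photons is None else photons[keep],
        precision=None if precision is None else precision[keep],
        channel_id=channel_id or os.path.splitext(os.path.basename(path))[0],
        has_z=has_z,
    )
    return table


def write_positions(table: LocalizationTable, path) -> str:
    """Write a table in the standardized five-column tab-delimited layout.

    Columns: X coordinate, Y coordinate, Z coordinate, # Photons,
    Precision of detection — all in nm, photons as counts.  Missing photon
    or precision data is written as NaN.  Lossless to float64 precision
    (values are written with repr-round-trip formatting).
    """
    path = os.fspath(path)
    n = table.n
    nan = np.full(n, np.nan)
    df = pd.DataFrame({
        STANDARD_COLUMNS[0]: table.x,
        STANDARD_COLUMNS[1]: table.y,
        STANDARD_COLUMNS[2]: table.z,
        STANDARD_COLUMNS[3]: table.photons if table.photons is not None else nan,
        STANDARD_COLUMNS[4]: table.precision if table.precision is not None else nan,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path
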