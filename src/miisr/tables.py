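"""Per-molecule localization tables.

The fundamental container of the package: one :class:`LocalizationTable`
per colour channel, holding molecular positions in nanometres together with
optional photon counts and per-molecule localization precision.  Row order
carries no meaning; every operation in the package is permutation-invariant
up to re-ordering of its per-molecule outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["LocalizationTable"]

STANDARD_COLUMNS = (
    "X coordinate",
    "Y coordinate",
    "Z coordinate",
    "# Photons",
    "Precision of detection",
)


@dataclass
class LocalizationTable:
    """Molecular positions for one colour channel, in nanometres.

    Parameters
    ----------
    x, y : ndarray of float
        Lateral coordinates in nm.
    z : ndarray of float, optional
        Axial coordinates in nm.  Stored as zeros when the source file had
        no Z column; ``has_z`` records whether real axial data is present.
    photons : ndarray of float, optional
        Detected photons per molecule (``None`` when not exported).
    precision : ndarray of float, optional
        Per-molecule localization precision in nm (``None`` when absent).
    channel_id : str
        Label identifying the colour channel.
    has_z : bool
        True when the z column carries measured values.
    """

    x: np.ndarray
    y: np.ndarray
    z: Optional[np.ndarray] = None
    photons: Optional[np.ndarray] = None
    precision: Optional[np.ndarray] = None
    channel_id: str = "channel"
    has_z: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.z is None:
            self.z = np.zeros_like(self.x)
            self.has_z = False
        else:
            self.z = np.asarray(self.z, dtype=float).ravel()
        for name in ("photons", "precision"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).ravel())
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n = self.x.size
        for name in ("y", "z"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name!r} length mismatch")
        for name in ("photons", "precision"):
            v = getattr(self, name)
            if v is not None and v.size != n:
                raise ValueError(f"column {name!r} length mismatch")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                and np.isfinite(self.z).all()):
            raise ValueError("coordinates must be finite")
        if self.photons is not None and np.nanmin(self.photons, initial=0) < 0:
            raise ValueError("photon counts must be >= 0")
        if self.precision is not None and np.nanmin(self.precision, initial=0) < 0:
            raise ValueError("precision must be >= 0")

    # -- basic views ---------------------------------------------------
    def __len__(self) -> int:
        return self.x.size

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def is_3d(self) -> bool:
        return self.has_z

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of lateral coordinates."""
        return np.column_stack([self.x, self.y])

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) or (n, 3) coordinate array depending on ``has_z``."""
        if self.has_z:
            return np.column_stack([self.x, self.y, self.z])
        return self.xy

    def subset(self, index) -> "LocalizationTable":
        """Return a new table keeping rows selected by a mask or index array."""
        index = np.asarray(index)
        return LocalizationTable(
            x=self.x[index],
            y=self.y[index],
            z=self.z[index],
            photons=None if self.photons is None else self.photons[index],
            precision=None if self.precision is None else self.precision[index],
            channel_id=self.channel_id,
            has_z=self.has_z,
        )

    def with_coords(self, xy: np.ndarray, z: Optional[np.ndarray] = None
                    ) -> "LocalizationTable":
        """Copy of the table with replaced coordinates (metadata carried over)."""
        xy = np.asarray(xy, dtype=float)
        return LocalizationTable(
            x=xy[:, 0],
            y=xy[:, 1],
            z=self.z.copy() if z is None else np.asarray(z, dtype=float),
            photons=None if self.photons is None else self.photons.copy(),
            precision=None if self.precision is None else self.precision.copy(),
            channel_id=self.channel_id,
            has_z=self.has_z,
        )

    def mean_precision(self) -> float:
        """Mean per-molecule precision σ_c of the channel, in nm.

        Molecules lacking a precision value are excluded.  Raises when the
        channel carries no precision data at all; callers needing a default
        must supply one explicitly.
        """
        if self.precision is None:
            raise ValueError(
                f"channel {self.channel_id!r} has no precision column; "
                "supply sigma explicitly")
        vals = self.precision[np.isfinite(self.precision)]
        if vals.size == 0:
            raise ValueError("no finite precision values")
        return float(vals.mean())

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the molecule positions, nm."""
        if self.n == 0:
            raise ValueError("empty table has no bounds")
        return (float(self.x.min()), float(self.y.min()),
                float(self.x.max()), float(self.y.max()))
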