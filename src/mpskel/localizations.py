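"""The localization table — the pipeline's universal currency.

One row per detected molecule: integer id, camera frame (>= 1), x/y/z in nm,
and a ground-truth ring label (``truth_ring``; -1 means background or
unknown).  Real data never carry ``truth_ring`` information; the synthetic
generators fill it so tests can audit every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["LocalizationTable", "COLUMNS"]

COLUMNS = ("id", "frame", "x_nm", "y_nm", "z_nm", "truth_ring")


@dataclass(frozen=True)
class LocalizationTable:
    id: np.ndarray
    frame: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    z_nm: np.ndarray
    truth_ring: np.ndarray
    extras: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        n = len(self.id)
        arrays = {
            "id": np.asarray(self.id, dtype=np.int64),
            "frame": np.asarray(self.frame, dtype=np.int64),
            "x_nm": np.asarray(self.x_nm, dtype=float),
            "y_nm": np.asarray(self.y_nm, dtype=float),
            "z_nm": np.asarray(self.z_nm, dtype=float),
            "truth_ring": np.asarray(self.truth_ring, dtype=np.int64),
        }
        for name, arr in arrays.items():
            if arr.ndim != 1 or arr.size != n:
                raise InvalidArgumentError(f"column {name!r} must be 1D of common length")
            object.__setattr__(self, name, arr)
        if n and np.any(arrays["frame"] < 1):
            raise InvalidArgumentError("frame stamps must be >= 1")
        for name in ("x_nm", "y_nm", "z_nm"):
            if n and not np.all(np.isfinite(arrays[name])):
                raise InvalidArgumentError(f"non-finite values in column {name!r}")
        if self.extras is not None and len(self.extras) != n:
            raise InvalidArgumentError("extras must have one row per localization")

    def __len__(self) -> int:
        return self.id.size

    @property
    def xyz(self) -> np.ndarray:
        """``(n, 3)`` coordinate array in nm."""
        return np.column_stack([self.x_nm, self.y_nm, self.z_nm])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in COLUMNS})
        if self.extras is not None:
            df = pd.concat([df, self.extras.reset_index(drop=True)], axis=1)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LocalizationTable":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise InvalidArgumentError(f"missing columns: {missing}")
        extra_cols = [c for c in df.columns if c not in COLUMNS]
        extras = df[extra_cols].reset_index(drop=True) if extra_cols else None
        return cls(*(df[c].to_numpy() for c in COLUMNS), extras=extras)

    @classmethod
    def from_arrays(
        cls,
        x_nm: np.ndarray,
        y_nm: np.ndarray,
        z_nm: np.ndarray,
        frame: np.ndarray | int = 1,
        truth_ring: np.ndarray | int = -1,
    ) -> "LocalizationTable":
        """Build a table from coordinate arrays, broadcasting scalar frame/label."""
        x_nm = np.asarray(x_nm, dtype=float)
        n = x_nm.size
        return cls(
            id=np.arange(n, dtype=np.int64),
            frame=np.broadcast_to(np.asarray(frame, dtype=np.int64), n).copy(),
            x_nm=x_nm,
            y_nm=np.asarray(y_nm, dtype=float),
            z_nm=np.asarray(z_nm, dtype=float),
            truth_ring=np.broadcast_to(np.asarray(truth_ring, dtype=np.int64), n).copy(),
        )

    def take(self, index: np.ndarray) -> "LocalizationTable":
        """Row subset by positional index (keeps original ids)."""
        index = np.asarray(index)
        extras = self.extras.iloc[index].reset_index(drop=True) if self.extras is not None else None
        return LocalizationTable(
            *(getattr(self, c)[index] for c in COLUMNS), extras=extras
        )

    def equals(self, other: "LocalizationTable") -> bool:
        return all(np.array_equal(getattr(self, c), getattr(other, c)) for c in COLUMNS)
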