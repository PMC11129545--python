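"""List-mode event container: the interchange format of the pipeline.

Events are frame-stamped pixel hits with a deposited energy and an optional
truth tag (simulator provenance).  Stored column-wise as numpy arrays;
serialized to HDF5 or CSV with identical columns.

Truth tag convention: 0 = other/unknown, 1 = Compton background, Z >= 2 =
XRF from the element with that atomic number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["ListMode", "TRUTH_OTHER", "TRUTH_COMPTON"]

TRUTH_OTHER = 0
TRUTH_COMPTON = 1

_COLUMNS = ("frame", "module", "row", "col", "energy", "truth")
_DTYPES = {
    "frame": np.int64,
    "module": np.int16,
    "row": np.int16,
    "col": np.int16,
    "energy": np.float64,
    "truth": np.int16,
}


@dataclass
class ListMode:
    frame: np.ndarray
    module: np.ndarray
    row: np.ndarray
    col: np.ndarray
    energy: np.ndarray
    truth: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in _COLUMNS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=_DTYPES[name]))
        n = len(self.frame)
        if any(len(getattr(self, c)) != n for c in _COLUMNS):
            raise ValueError("list-mode columns must have equal length")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def empty(cls, meta: dict | None = None) -> "ListMode":
        return cls(*(np.empty(0, dtype=_DTYPES[c]) for c in _COLUMNS), meta=dict(meta or {}))

    def sorted_by_frame(self) -> "ListMode":
        order = np.lexsort((self.col, self.row, self.module, self.frame))
        return self.select(order)

    def select(self, index) -> "ListMode":
        return ListMode(*(getattr(self, c)[index] for c in _COLUMNS), meta=dict(self.meta))

    @classmethod
    def concatenate(cls, parts: list["ListMode"], meta: dict | None = None) -> "ListMode":
        if not parts:
            return cls.empty(meta)
        cols = [np.concatenate([getattr(p, c) for p in parts]) for c in _COLUMNS]
        return cls(*cols, meta=dict(meta or parts[0].meta))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in _COLUMNS})

    # -- IO -----------------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            for c in _COLUMNS:
                fh.create_dataset(c, data=getattr(self, c))
            fh.attrs["meta"] = json.dumps(self.meta, default=float)

    @classmethod
    def from_hdf5(cls, path) -> "ListMode":
        with h5py.File(path, "r") as fh:
            cols = [fh[c][...] for c in _COLUMNS]
            meta = json.loads(fh.attrs.get("meta", "{}"))
        return cls(*cols, meta=meta)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "ListMode":
        d = pd.read_csv(path)
        return cls(*(d[c].to_numpy() for c in _COLUMNS), meta=dict(meta or {}))
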