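"""Detector-side list-mode processing.

Two stages precede any imaging: per-pixel two-point energy calibration
(Am-241 at 59.54 keV and Co-57 at 122 keV in flat-field irradiation) and
charge-sharing discrimination (CSD), which rejects every event that has a
same-frame neighbor within the surrounding 3 x 3 pixel region of its own
module.  CSD rejects whole sharing clusters — no summation correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .listmode import ListMode

__all__ = [
    "PixelCalibration",
    "fit_two_point_calibration",
    "apply_calibration",
    "csd_filter",
    "accumulate_spectrum",
    "CAL_ENERGIES",
]

CAL_ENERGIES = (59.54, 122.0)  # keV: Am-241 and Co-57 photopeaks


@dataclass
class PixelCalibration:
    """Per-pixel linear ADC-to-keV maps, one set of arrays per module."""

    gain: dict[int, np.ndarray]  # keV per ADC unit, (pixels, pixels)
    offset: dict[int, np.ndarray]  # keV
    dead: dict[int, np.ndarray]  # bool mask
    source_energies: tuple[float, float] = CAL_ENERGIES

    def modules(self):
        return sorted(self.gain)

    def to_csv(self, path, module: int) -> None:
        g, o, d = self.gain[module], self.offset[module], self.dead[module]
        rows, cols = np.meshgrid(range(g.shape[0]), range(g.shape[1]), indexing="ij")
        pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "gain": g.ravel(),
                "offset": o.ravel(),
                "dead": d.ravel().astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, paths: dict[int, str]) -> "PixelCalibration":
        gain, offset, dead = {}, {}, {}
        for m, p in paths.items():
            d = pd.read_csv(p)
            n = int(d.row.max()) + 1
            for name, store in (("gain", gain), ("offset", offset), ("dead", dead)):
                a = np.zeros((n, n))
                a[d.row, d.col] = d[name]
                store[m] = a.astype(bool) if name == "dead" else a
        return cls(gain, offset, dead)


def _peak_centroid(centers: np.ndarray, counts: np.ndarray, idx: int, half: int = 3) -> float:
    lo, hi = max(idx - half, 0), min(idx + half + 1, len(counts))
    w = counts[lo:hi]
    return float(np.sum(centers[lo:hi] * w) / np.sum(w))


def fit_two_point_calibration(
    spectra: np.ndarray,
    bin_centers: np.ndarray,
    source_energies: tuple[float, float] = CAL_ENERGIES,
    min_prominence: float = 5.0,
    min_separation_bins: int = 8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit per-pixel gain/offset from flat-field two-source spectra.

    ``spectra`` has shape (rows, cols, nbins) in raw ADC bins.  For each
    pixel the two most prominent peaks are located (highest bin, then the
    highest outside its exclusion zone), refined to a +-3 bin centroid, and
    mapped in increasing order onto the two source energies.  Pixels where
    either peak is below ``min_prominence`` counts are flagged dead.

    Returns ``(gain, offset, dead)`` arrays.
    """
    e_lo, e_hi = sorted(source_energies)
    rows, cols, _ = spectra.shape
    gain = np.ones((rows, cols))
    offset = np.zeros((rows, cols))
    dead = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            y = spectra[r, c].astype(float)
            i1 = int(np.argmax(y))
            masked = y.copy()
            masked[max(i1 - min_separation_bins, 0): i1 + min_separation_bins + 1] = 0.0
            i2 = int(np.argmax(masked))
            if y[i1] < min_prominence or masked[i2] < min_prominence:
                dead[r, c] = True
                continue
            c1 = _peak_centroid(bin_centers, y, i1)
            c2 = _peak_centroid(bin_centers, y, i2)
            a_lo, a_hi = sorted((c1, c2))
            g = (e_hi - e_lo) / (a_hi - a_lo)
            gain[r, c] = g
            offset[r, c] = e_lo - g * a_lo
    return gain, offset, dead


def apply_calibration(events: ListMode, cal: PixelCalibration) -> ListMode:
    """Convert raw ADC amplitudes to keV; events in dead pixels are dropped."""
    for m in np.unique(events.module):
        if int(m) not in cal.gain:
            raise KeyError(f"no calibration for module {int(m)}")
    g = np.empty(len(events))
    b = np.empty(len(events))
    alive = np.ones(len(events), dtype=bool)
    for m in np.unique(events.module):
        sel = events.module == m
        g[sel] = cal.gain[int(m)][events.row[sel], events.col[sel]]
        b[sel] = cal.offset[int(m)][events.row[sel], events.col[sel]]
        alive[sel] = ~cal.dead[int(m)][events.row[sel], events.col[sel]]
    out = events.select(alive)
    out.energy = g[alive] * events.energy[alive] + b[alive]
    out.meta["calibrated"] = True
    return out


def csd_filter(events: ListMode) -> ListMode:
    """Charge-sharing discrimination.

    Within each (frame, module) an event survives iff no other event of
    that frame and module lies within its 3 x 3 neighborhood (Chebyshev
    distance <= 1).  Whole clusters are rejected; survivors are returned
    unmodified.  Idempotent by construction.
    """
    n = len(events)
    if n == 0:
        return events.select(np.zeros(0, dtype=bool))
    key = events.frame.astype(np.int64) * 1024 + events.module.astype(np.int64)
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]
    starts = np.flatnonzero(np.concatenate([[True], sorted_key[1:] != sorted_key[:-1]]))
    bounds = np.append(starts, n)
    keep = np.ones(n, dtype=bool)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a == 1:
            continue
        idx = order[a:b]
        r, c = events.row[idx].astype(int), events.col[idx].astype(int)
        dr = np.abs(r[:, None] - r[None, :])
        dc = np.abs(c[:, None] - c[None, :])
        near = (np.maximum(dr, dc) <= 1)
        np.fill_diagonal(near, False)
        keep[idx[near.any(axis=1)]] = False
    out = events.select(keep)
    out.meta["csd"] = True
    return out


def accumulate_spectrum(
    events: ListMode,
    bin_width: float = 0.25,
    e_max: float = 160.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram deposited energies; returns ``(bin_edges, counts)``.

    Total counts equal the number of events (energies outside the range are
    clipped into the edge bins so nothing is lost).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, e_max + bin_width, bin_width)
    e = np.clip(events.energy, edges[0], edges[-1] - bin_width / 2)
    counts, _ = np.histogram(e, bins=edges)
    return edges, counts
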