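"""Image formation: views -> merged back-projected profile -> elemental map.

At each scan position the 96 pinhole views of the illuminated line are
split by subdetector region, back-projected through their pinholes onto the
beam line (which performs the necessary inversions and flips implicitly),
merged into a per-row energy spectrum, collapsed over columns, and the net
XRF counts per row are extracted in a 3 keV window around the K-alpha line
with a linear sideband background fit.  Scanning line-by-line assembles the
2D elemental image; no attenuation correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from . import physics as ph
from .geometry import ScanPlan, SystemGeometry
from .listmode import ListMode

__all__ = [
    "ViewStack",
    "BackprojectedProfile",
    "XFETImage",
    "split_views",
    "merge_views",
    "collapse_columns",
    "net_xrf",
    "assemble_image",
    "form_images",
]


@dataclass
class ViewStack:
    """Events partitioned by pinhole view (disjoint by construction)."""

    events: ListMode
    view_id: np.ndarray  # per event; all >= 0
    n_views: int
    n_dropped: int  # events outside every subdetector region

    def view(self, i: int) -> ListMode:
        return self.events.select(self.view_id == i)

    def counts_per_view(self) -> np.ndarray:
        return np.bincount(self.view_id, minlength=self.n_views)


@dataclass
class BackprojectedProfile:
    """Row x column x energy histogram of merged views, object coordinates."""

    counts: np.ndarray  # (n_rows, n_cols, n_e)
    row_edges: np.ndarray  # object mm along the beam
    col_edges: np.ndarray  # object mm along the axial direction
    energy_edges: np.ndarray  # keV
    x_pos: float  # scan position this profile belongs to

    @property
    def row_centers(self):
        return 0.5 * (self.row_edges[:-1] + self.row_edges[1:])

    @property
    def energy_centers(self):
        return 0.5 * (self.energy_edges[:-1] + self.energy_edges[1:])

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class XFETImage:
    """2D net-XRF map (rows along the beam, columns = scan positions)."""

    counts: np.ndarray  # (n_rows, n_positions) net XRF counts
    sigma: np.ndarray  # background-σ companion grid, same shape
    element: str
    row_edges: np.ndarray  # object mm along the beam
    positions: np.ndarray  # scan positions, mm
    window: float = 3.0
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.counts.shape

    def voxel_of(self, x_mm: float, y_mm: float) -> tuple[int, int]:
        """Image voxel (row, col) of an object point (x = scan, y = beam)."""
        row = int(np.clip(np.searchsorted(self.row_edges, y_mm, side="right") - 1, 0, self.shape[0] - 1))
        col = int(np.argmin(np.abs(self.positions - x_mm)))
        return row, col

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.counts.astype(np.float32))

    def to_csv(self, path, sigma_path=None) -> None:
        pd.DataFrame(self.counts, columns=[f"{x:g}" for x in self.positions]).to_csv(path, index=False)
        if sigma_path:
            pd.DataFrame(self.sigma, columns=[f"{x:g}" for x in self.positions]).to_csv(sigma_path, index=False)


def split_views(events: ListMode, geometry: SystemGeometry) -> ViewStack:
    """Partition calibrated, CSD-filtered events into the 96 pinhole views.

    Events landing outside every assigned subdetector region are dropped
    and counted.
    """
    vid = geometry.view_of(events.module, events.row, events.col)
    inside = vid >= 0
    return ViewStack(
        events=events.select(inside),
        view_id=vid[inside],
        n_views=len(geometry.pinholes),
        n_dropped=int((~inside).sum()),
    )


def merge_views(
    stack: ViewStack,
    geometry: SystemGeometry,
    x_pos: float | None = None,
    axial: float = 0.0,
    row_mm: float = 1.0,
    e_bin: float = 0.25,
    e_max: float = 160.0,
) -> BackprojectedProfile:
    """Back-project every view onto the beam line and merge row-wise.

    Each event's pixel center is traced back through its pinhole; the point
    of closest approach to the beam line gives its object-space beam depth
    (row) and axial offset (column).  The pinhole optics invert and minify
    each view, so this single geometric rule realizes all the per-module
    inversions and panel flips at once.  Rows bin the 20 mm field of view at
    ``row_mm`` (1 mm = 2 detector pixels through the 1:2 minification);
    out-of-field values are clipped into the edge bins so counts are
    conserved exactly.
    """
    ev = stack.events
    if x_pos is None:
        x_pos = float(ev.meta.get("x_pos", 0.0))
    fov = geometry.config.fov_diameter
    row_edges = np.arange(-fov / 2, fov / 2 + row_mm / 2, row_mm)
    col_edges = row_edges.copy()
    e_edges = np.arange(0.0, e_max + e_bin, e_bin)
    counts = np.zeros((len(row_edges) - 1, len(col_edges) - 1, len(e_edges) - 1))
    line_o = np.array([x_pos, 0.0, axial])
    line_d = np.array([0.0, 1.0, 0.0])
    for view in range(stack.n_views):
        sel = stack.view_id == view
        if not sel.any():
            continue
        pin = geometry.pinholes[view]
        mod = geometry.modules[pin.module]
        r = ev.row[sel].astype(float) + 0.5
        c = ev.col[sel].astype(float) + 0.5
        pix = (
            mod.center
            + ((r - mod.pixels / 2.0) * mod.pitch)[:, None] * mod.row_dir
            + ((c - mod.pixels / 2.0) * mod.pitch)[:, None] * mod.col_dir
        )
        d = pin.center - pix
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        # closest approach between the back-projected ray and the beam line
        w0 = pix - line_o
        b = d @ line_d
        denom = 1.0 - b**2
        w0_d = np.einsum("ij,ij->i", w0, d)
        t = np.where(np.abs(denom) > 1e-12, ((w0 @ line_d) * b - w0_d) / denom, 0.0)
        q = pix + t[:, None] * d
        y_obj = q[:, 1]
        z_obj = q[:, 2] - axial
        ri = np.clip(np.digitize(y_obj, row_edges) - 1, 0, counts.shape[0] - 1)
        ci = np.clip(np.digitize(z_obj, col_edges) - 1, 0, counts.shape[1] - 1)
        ei = np.clip(np.digitize(ev.energy[sel], e_edges) - 1, 0, counts.shape[2] - 1)
        np.add.at(counts, (ri, ci, ei), 1)
    return BackprojectedProfile(counts, row_edges, col_edges, e_edges, float(x_pos))


def collapse_columns(profile: BackprojectedProfile) -> np.ndarray:
    """Sum the profile horizontally; returns per-row spectra (rows, n_e)."""
    return profile.counts.sum(axis=1)


def net_xrf(
    spectrum: np.ndarray,
    energy_edges: np.ndarray,
    line_energy: float,
    window: float = 3.0,
    sideband: float = 2.0,
) -> tuple[float, float]:
    """Windowed net XRF counts above a linearly fitted sideband background.

    A ``window`` keV interval is centered on the line; ``sideband`` keV
    strips on each side (excluding the window) anchor a straight-line
    least-squares background fit.  Net = window counts minus the integrated
    fit; sigma combines Poisson counting in the window with the fit's
    propagated uncertainty.
    """
    centers = 0.5 * (energy_edges[:-1] + energy_edges[1:])
    in_win = np.abs(centers - line_energy) <= window / 2.0
    off = np.abs(centers - line_energy)
    in_sb = (off > window / 2.0) & (off <= window / 2.0 + sideband)
    lo_sb = in_sb & (centers < line_energy)
    hi_sb = in_sb & (centers > line_energy)
    if not lo_sb.any() or not hi_sb.any():
        raise ValueError("sidebands must flank the window on both sides")
    x, y = centers[in_sb], spectrum[in_sb].astype(float)
    X = np.stack([np.ones_like(x), x], axis=1)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    var_y = np.maximum(y, 1.0)  # Poisson variance per sideband bin
    cov = xtx_inv @ X.T @ np.diag(var_y) @ X @ xtx_inv
    s = np.array([in_win.sum(), centers[in_win].sum()])
    background = float(s @ beta)
    w_counts = float(spectrum[in_win].sum())
    var_b = float(s @ cov @ s)
    net = w_counts - background
    sigma = float(np.sqrt(max(w_counts, 1.0) + var_b))
    return net, sigma


def assemble_image(
    profiles: list[BackprojectedProfile],
    plan: ScanPlan,
    element: str,
    window: float = 3.0,
    sideband: float = 2.0,
) -> XFETImage:
    """Stack per-position net-XRF row vectors into the 2D elemental image.

    Column j of the image is the net-XRF profile of scan position j.  The
    positions of the scan plan must each be covered by exactly one profile;
    gaps raise an error naming the missing positions.  No attenuation
    correction is applied.
    """
    by_x = {round(p.x_pos, 6): p for p in profiles}
    missing = [x for x in plan.positions if round(float(x), 6) not in by_x]
    if missing:
        raise ValueError(f"missing profiles for scan positions {missing}")
    e0 = ph.line_energy(element, "Ka")
    first = by_x[round(float(plan.positions[0]), 6)]
    n_rows = first.counts.shape[0]
    img = np.zeros((n_rows, len(plan.positions)))
    sig = np.zeros_like(img)
    for j, x in enumerate(plan.positions):
        prof = by_x[round(float(x), 6)]
        rows = collapse_columns(prof)
        for i in range(n_rows):
            img[i, j], sig[i, j] = net_xrf(rows[i], prof.energy_edges, e0, window, sideband)
    return XFETImage(
        img, sig, ph.element_symbol(element), first.row_edges,
        np.asarray(plan.positions, dtype=float), window,
        meta={"sideband": sideband, "line_keV": e0},
    )


def form_images(
    listmodes: list[ListMode],
    geometry: SystemGeometry,
    plan: ScanPlan,
    elements: list[str],
    window: float = 3.0,
    sideband: float = 2.0,
    csd: bool = True,
) -> dict[str, XFETImage]:
    """Full processing chain from per-position list mode to elemental maps."""
    from .events import csd_filter

    profiles = []
    for lm in listmodes:
        clean = csd_filter(lm) if csd else lm
        stack = split_views(clean, geometry)
        profiles.append(merge_views(stack, geometry, axial=plan.axial))
    return {
        el: assemble_image(profiles, plan, el, window, sideband) for el in elements
    }
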