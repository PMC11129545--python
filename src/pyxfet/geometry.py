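"""Hexagonal detector ring, 96-pinhole compound-eye aperture, scan planning.

Coordinate convention (right handed): ``x`` is the lateral scan axis, ``y``
the pencil-beam axis, ``z`` the axial (ring/phantom cylinder) axis.  The six
detector panels surround the object with normals at 60 degree increments
about ``z``; the beam enters and leaves through the hexagon's vertices.
Distances in mm.

Each panel carries four 20 mm x 20 mm CdTe modules (80 x 80 pixels at
250 um pitch) in a 2 x 2 layout and sixteen 1 mm knife-edge pinholes.  Each
pinhole owns a 1 cm x 1 cm non-multiplexed subdetector region; with the 1:2
minification the pinhole plane sits at two thirds of the detector distance
from the axis, just inside the 14 mm collimator.  The two lower (low-``z``)
modules of every panel are mounted physically inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeometryConfig",
    "DetectorModule",
    "Pinhole",
    "SystemGeometry",
    "ScanPlan",
    "build_geometry",
    "default_geometry",
    "project_point",
    "backproject_pixel",
    "geometric_sensitivity",
    "trace_to_detector",
    "view_orientation",
    "make_scan_plan",
]


@dataclass
class GeometryConfig:
    """Buildable description of the system; defaults model the benchtop rig."""

    panel_spacing: float = 82.0  # distance between opposite detector panels, mm
    collimator_thickness: float = 14.0  # mm
    n_panels: int = 6
    modules_per_panel: int = 4  # 2 x 2
    pixels: int = 80  # per module side
    pitch: float = 0.25  # mm
    pinholes_per_panel: int = 16  # 4 x 4, aligned with subdetector centers
    pinhole_diameter: float = 1.0  # mm
    minification: float = 2.0  # object : image
    acceptance_half_angle: float = 50.0  # degrees, knife-edge opening
    fov_diameter: float = 20.0  # mm
    fov_axial: float = 18.0  # mm
    aimed_pinholes: bool = False  # aperture disks normal to panel by default
    inverted_modules: str = "bottom"  # low-z half of each panel

    @classmethod
    def from_yaml(cls, path) -> "GeometryConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class DetectorModule:
    id: int
    panel: int
    center: np.ndarray  # 3D, mm
    row_dir: np.ndarray  # unit vector of increasing row index
    col_dir: np.ndarray  # unit vector of increasing column index
    normal: np.ndarray  # outward panel normal
    pixels: int
    pitch: float
    inverted: bool

    @property
    def side(self) -> float:
        return self.pixels * self.pitch


@dataclass
class Pinhole:
    id: int
    panel: int
    center: np.ndarray
    axis: np.ndarray  # unit vector, from object side toward the detector
    diameter: float
    half_angle: float  # degrees
    module: int  # assigned subdetector module
    region: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    minification: float


@dataclass
class ScanPlan:
    positions: np.ndarray  # lateral (x) beam positions, mm
    step: float  # mm
    dwell: float  # s per position
    beam_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    beam_diameter: float = 1.0  # mm
    axial: float = 0.0  # z of the beam line


class SystemGeometry:
    """Fully placed ring geometry with vectorized lookup arrays."""

    def __init__(self, config: GeometryConfig):
        self.config = config
        c = config
        self.detector_distance = c.panel_spacing / 2.0
        m = c.minification
        if m <= 1:
            raise ValueError("minification must exceed 1 (object larger than image)")
        # object-to-pinhole = m * pinhole-to-detector, both summing to the
        # detector distance
        self.pinhole_distance = self.detector_distance * m / (m + 1.0)
        self.focal_length = self.detector_distance - self.pinhole_distance
        inner = self.detector_distance - c.collimator_thickness
        if not (inner - 1e-9 <= self.pinhole_distance <= self.detector_distance):
            raise ValueError("derived pinhole plane falls outside the collimator")

        region_extent = c.fov_diameter / m  # mm on the detector
        spacing = 2 * c.pixels * c.pitch / int(round(np.sqrt(c.pinholes_per_panel)))
        if region_extent > spacing + 1e-9:
            raise ValueError(
                f"subdetector regions of {region_extent:g} mm overlap "
                f"({spacing:g} mm spacing): lower the FOV or raise the minification"
            )
        self.region_px = int(round(region_extent / c.pitch))

        ang = np.deg2rad(60.0 * np.arange(c.n_panels))
        self.panel_normals = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
        self.panel_tangents = np.stack([-np.sin(ang), np.cos(ang), np.zeros_like(ang)], axis=1)
        zhat = np.array([0.0, 0.0, 1.0])

        side = c.pixels * c.pitch  # 20 mm
        self.modules: list[DetectorModule] = []
        self.pinholes: list[Pinhole] = []
        for p in range(c.n_panels):
            n, t = self.panel_normals[p], self.panel_tangents[p]
            # modules: 2 x 2; index 0,1 = upper (high z), 2,3 = lower, inverted
            for mi in range(c.modules_per_panel):
                zrow, tcol = divmod(mi, 2)
                cz = side / 2 if zrow == 0 else -side / 2
                ct = -side / 2 if tcol == 0 else side / 2
                inverted = (zrow == 1) if c.inverted_modules == "bottom" else False
                sgn = -1.0 if inverted else 1.0
                self.modules.append(
                    DetectorModule(
                        id=p * c.modules_per_panel + mi,
                        panel=p,
                        center=self.detector_distance * n + ct * t + cz * zhat,
                        row_dir=sgn * -zhat,  # row 0 at the local top
                        col_dir=sgn * t,
                        normal=n,
                        pixels=c.pixels,
                        pitch=c.pitch,
                        inverted=inverted,
                    )
                )
            # pinholes: 4 x 4, one per subdetector region
            grid = np.sqrt(c.pinholes_per_panel)
            if grid != int(grid):
                raise ValueError("pinholes_per_panel must be a square number")
            grid = int(grid)
            offsets = (np.arange(grid) - (grid - 1) / 2.0) * spacing  # region centers
            scale = self.pinhole_distance / self.detector_distance
            for iz, rz in enumerate(offsets[::-1]):  # high z first
                for it, rt in enumerate(offsets):
                    center = self.pinhole_distance * n + rt * scale * t + rz * scale * zhat
                    axis = n.copy()
                    if c.aimed_pinholes:
                        axis = center / np.linalg.norm(center)
                    det_point = self.detector_distance * n + rt * t + rz * zhat
                    mod = self._module_at(p, det_point)
                    r, cc = self._pixel_coords(mod, det_point)
                    half = self.region_px / 2.0
                    region = (
                        int(round(r - half)),
                        int(round(r + half)),
                        int(round(cc - half)),
                        int(round(cc + half)),
                    )
                    self.pinholes.append(
                        Pinhole(
                            id=len(self.pinholes),
                            panel=p,
                            center=center,
                            axis=axis,
                            diameter=c.pinhole_diameter,
                            half_angle=c.acceptance_half_angle,
                            module=mod.id,
                            region=region,
                            minification=m,
                        )
                    )
        self._freeze_arrays()
        self.validate()

    # -- construction helpers ------------------------------------------------

    def _module_at(self, panel: int, point: np.ndarray) -> DetectorModule:
        for mod in self.modules[panel * self.config.modules_per_panel:
                                (panel + 1) * self.config.modules_per_panel]:
            r, c = self._pixel_coords(mod, point)
            if -1e-6 <= r <= mod.pixels + 1e-6 and -1e-6 <= c <= mod.pixels + 1e-6:
                return mod
        raise ValueError("detector point outside every module of the panel")

    def _pixel_coords(self, mod: DetectorModule, point: np.ndarray):
        d = point - mod.center
        return (
            float(d @ mod.row_dir / mod.pitch + mod.pixels / 2.0),
            float(d @ mod.col_dir / mod.pitch + mod.pixels / 2.0),
        )

    def _freeze_arrays(self) -> None:
        # panel-local 4x4 candidate lookup for fast ray tracing: pinhole
        # centers lie on a regular grid in each panel's pinhole plane
        grid = int(round(np.sqrt(self.config.pinholes_per_panel)))
        scale = self.pinhole_distance / self.detector_distance
        spacing = 2 * self.config.pixels * self.config.pitch / grid * scale
        self.grid_n = grid
        self.grid_spacing = spacing
        self.grid_origin = -(grid - 1) / 2.0 * spacing
        self.pin_lookup = np.full((self.config.n_panels, grid, grid), -1, dtype=int)
        for p in self.pinholes:
            tan = self.panel_tangents[p.panel]
            u = float(p.center @ tan)
            v = float(p.center[2])
            iu = int(round((u - self.grid_origin) / spacing))
            iv = int(round((v - self.grid_origin) / spacing))
            self.pin_lookup[p.panel, iu, iv] = p.id
        self.ph_centers = np.array([p.center for p in self.pinholes])
        self.ph_axes = np.array([p.axis for p in self.pinholes])
        self.ph_panel = np.array([p.panel for p in self.pinholes])
        self.ph_module = np.array([p.module for p in self.pinholes])
        self.ph_region = np.array([p.region for p in self.pinholes])
        self.ph_radius = np.array([p.diameter / 2.0 for p in self.pinholes])
        self.mod_centers = np.array([m.center for m in self.modules])
        self.mod_row_dir = np.array([m.row_dir for m in self.modules])
        self.mod_col_dir = np.array([m.col_dir for m in self.modules])
        self.mod_normal = np.array([m.normal for m in self.modules])
        self.mod_panel = np.array([m.panel for m in self.modules])

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        c = self.config
        if len(self.modules) != c.n_panels * c.modules_per_panel:
            raise ValueError("module count mismatch")
        if len(self.pinholes) != c.n_panels * c.pinholes_per_panel:
            raise ValueError("pinhole count mismatch")
        # subdetector regions must tile without overlap
        seen = set()
        for p in self.pinholes:
            r0, r1, c0, c1 = p.region
            if not (0 <= r0 < r1 <= c.pixels and 0 <= c0 < c1 <= c.pixels):
                raise ValueError(f"region of pinhole {p.id} leaves its module")
            for key in ((p.module, r, cc) for r in range(r0, r1) for cc in range(c0, c1)):
                if key in seen:
                    raise ValueError("overlapping subdetector regions")
                seen.add(key)

    # -- event-side lookups --------------------------------------------------

    def view_of(self, module: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """Pinhole/view id for detector pixels; -1 outside every region."""
        module = np.asarray(module)
        row, col = np.asarray(row), np.asarray(col)
        out = np.full(module.shape, -1, dtype=int)
        for p in self.pinholes:
            r0, r1, c0, c1 = p.region
            hit = (module == p.module) & (row >= r0) & (row < r1) & (col >= c0) & (col < c1)
            out[hit] = p.id
        return out

    def export_csv(self, pinhole_path, module_path) -> None:
        pd.DataFrame(
            [
                {
                    "id": p.id, "panel": p.panel, "module": p.module,
                    "x": p.center[0], "y": p.center[1], "z": p.center[2],
                    "ax": p.axis[0], "ay": p.axis[1], "az": p.axis[2],
                    "diameter_mm": p.diameter,
                    "row0": p.region[0], "row1": p.region[1],
                    "col0": p.region[2], "col1": p.region[3],
                }
                for p in self.pinholes
            ]
        ).to_csv(pinhole_path, index=False)
        pd.DataFrame(
            [
                {
                    "id": m.id, "panel": m.panel, "inverted": m.inverted,
                    "x": m.center[0], "y": m.center[1], "z": m.center[2],
                }
                for m in self.modules
            ]
        ).to_csv(module_path, index=False)


def build_geometry(config: GeometryConfig | None = None) -> SystemGeometry:
    return SystemGeometry(config or GeometryConfig())


_DEFAULT: SystemGeometry | None = None


def default_geometry() -> SystemGeometry:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = build_geometry()
    return _DEFAULT


# ---------------------------------------------------------------------------
# projection


def project_point(p, pinhole: Pinhole, geometry: SystemGeometry):
    """Ideal central projection of an object point through a pinhole.

    Returns ``(module_id, row, col)`` with continuous pixel coordinates, or
    ``None`` when the point lies outside the pinhole's acceptance cone or its
    image misses the assigned module.
    """
    p = np.asarray(p, dtype=float)
    to_ph = pinhole.center - p
    dist = np.linalg.norm(to_ph)
    if dist == 0:
        return None
    cos = float(to_ph @ pinhole.axis / dist)
    if cos < np.cos(np.deg2rad(pinhole.half_angle)):
        return None
    mod = geometry.modules[pinhole.module]
    denom = float(to_ph @ mod.normal)
    if denom <= 0:
        return None
    # detector plane: x . normal = detector_distance
    t = (geometry.detector_distance - p @ mod.normal) / denom
    hit = p + t * to_ph
    r, c = geometry._pixel_coords(mod, hit)
    if not (0 <= r <= mod.pixels and 0 <= c <= mod.pixels):
        return None
    return mod.id, r, c


def backproject_pixel(module_id, row, col, pinhole: Pinhole, geometry: SystemGeometry):
    """Ray from a detector pixel center back through the pinhole center.

    Returns ``(origin, direction)`` with the origin at the pinhole and the
    unit direction pointing into the object space.
    """
    mod = geometry.modules[int(module_id)]
    pix = (
        mod.center
        + (np.asarray(row, dtype=float) - mod.pixels / 2.0 + 0.5)[..., None] * mod.pitch * mod.row_dir
        + (np.asarray(col, dtype=float) - mod.pixels / 2.0 + 0.5)[..., None] * mod.pitch * mod.col_dir
    )
    d = pinhole.center - pix
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    return pinhole.center, d


def view_orientation(module: DetectorModule, geometry: SystemGeometry):
    """Row/column flip flags that bring a module's view to the common frame.

    The common frame is defined by the upper-left module of panel 0: object
    ``+z`` decreasing row index, object ``+y`` (the beam direction as seen
    from panel 0) increasing column index.  Flags are derived from the
    projection geometry itself, not stored.
    """
    ref = geometry.modules[0]
    zhat = np.array([0.0, 0.0, 1.0])
    dz_ref = float(ref.row_dir @ -zhat)
    dz = float(module.row_dir @ -zhat)
    flip_row = (dz > 0) != (dz_ref > 0)
    # the beam axis seen from this panel runs along the panel tangent; a
    # pinhole inverts it, so the sign of col_dir . tangent fixes the flip
    tan_ref = geometry.panel_tangents[ref.panel]
    tan = geometry.panel_tangents[module.panel]
    proj_ref = float(ref.col_dir @ tan_ref)
    proj = float(module.col_dir @ tan)
    # opposite panels view the object from reversed tangents
    opposite = float(tan @ tan_ref) < 0
    flip_col = ((proj > 0) != (proj_ref > 0)) ^ opposite
    return flip_row, flip_col


# ---------------------------------------------------------------------------
# sensitivity


def trace_to_detector(origins, dirs, geometry: SystemGeometry):
    """Trace rays through the aperture to their assigned subdetector regions.

    Vectorized over rays (origins may be a single point or one per ray);
    loops over the 96 pinholes.  Returns ``(pinhole_id, module_id, row, col)``
    arrays with id -1 (and NaN pixel coordinates) for rays accepted by no
    pinhole.  A ray is accepted when it crosses a pinhole's aperture disk
    travelling outward and its continuation lands inside that pinhole's
    assigned subdetector region.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    n = len(dirs)
    origins = np.broadcast_to(np.atleast_2d(np.asarray(origins, dtype=float)), (n, 3))
    cand = np.full(n, -1, dtype=int)
    t_cand = np.full(n, np.inf)
    t_first = np.full(n, np.inf)  # first outward collimator-plane crossing
    inside = np.ones(n, dtype=bool)  # origin inside the aperture ring
    r_ap = geometry.ph_radius.max()
    # stage 1: nearest-pinhole candidate per panel via the 4x4 grid
    for p in range(geometry.config.n_panels):
        nrm = geometry.panel_normals[p]
        tan = geometry.panel_tangents[p]
        inside &= origins @ nrm < geometry.pinhole_distance + 1e-9
        denom = dirs @ nrm
        fwd = denom > 1e-12
        t = np.where(fwd, (geometry.pinhole_distance - origins @ nrm) / np.where(fwd, denom, 1.0), np.inf)
        t_first = np.minimum(t_first, np.where(fwd & (t > 0), t, np.inf))
        ok = fwd & (t > 0) & (t < t_cand)
        if not ok.any():
            continue
        pt = origins[ok] + t[ok, None] * dirs[ok]
        u = pt @ tan
        v = pt[:, 2]
        iu = np.clip(np.round((u - geometry.grid_origin) / geometry.grid_spacing).astype(int),
                     0, geometry.grid_n - 1)
        iv = np.clip(np.round((v - geometry.grid_origin) / geometry.grid_spacing).astype(int),
                     0, geometry.grid_n - 1)
        pid = geometry.pin_lookup[p, iu, iv]
        cu = geometry.grid_origin + iu * geometry.grid_spacing
        cv = geometry.grid_origin + iv * geometry.grid_spacing
        near = (pid >= 0) & ((u - cu) ** 2 + (v - cv) ** 2 <= (2.0 * r_ap) ** 2)
        idx = np.flatnonzero(ok)[near]
        cand[idx] = pid[near]
        t_cand[idx] = t[idx]
    # a photon is only transmitted if its origin lies inside the ring and
    # its pinhole crossing is its first collimator-plane crossing (otherwise
    # it enters tungsten first); the ring is convex, so this is exact
    cand = np.where(inside & (t_cand <= t_first + 1e-6), cand, -1)
    # stage 2: exact aperture-disk test of the candidate, then the region
    hit_id = np.full(n, -1, dtype=int)
    mod_id = np.full(n, -1, dtype=int)
    row = np.full(n, np.nan)
    col = np.full(n, np.nan)
    sel = np.flatnonzero(cand >= 0)
    if len(sel) == 0:
        return hit_id, mod_id, row, col
    pid = cand[sel]
    o, d = origins[sel], dirs[sel]
    centers = geometry.ph_centers[pid]
    axes = geometry.ph_axes[pid]
    denom = np.einsum("ij,ij->i", d, axes)
    ok = denom > 1e-12
    t = np.einsum("ij,ij->i", centers - o, axes) / np.where(ok, denom, 1.0)
    pt = o + t[:, None] * d
    ok &= (t > 0) & (np.linalg.norm(pt - centers, axis=1) <= geometry.ph_radius[pid])
    # continue to the detector plane of the assigned module
    mid = geometry.ph_module[pid]
    nrm = geometry.mod_normal[mid]
    denom2 = np.einsum("ij,ij->i", d, nrm)
    ok &= denom2 > 1e-12
    t2 = (geometry.detector_distance - np.einsum("ij,ij->i", o, nrm)) / np.where(ok, denom2, 1.0)
    hit = o + t2[:, None] * d
    rel = hit - geometry.mod_centers[mid]
    pitch = geometry.config.pitch
    half = geometry.config.pixels / 2.0
    r = np.einsum("ij,ij->i", rel, geometry.mod_row_dir[mid]) / pitch + half
    c = np.einsum("ij,ij->i", rel, geometry.mod_col_dir[mid]) / pitch + half
    reg = geometry.ph_region[pid]
    ok &= (r >= reg[:, 0]) & (r < reg[:, 1]) & (c >= reg[:, 2]) & (c < reg[:, 3])
    idx = sel[ok]
    hit_id[idx] = pid[ok]
    mod_id[idx] = mid[ok]
    row[idx] = r[ok]
    col[idx] = c[ok]
    return hit_id, mod_id, row, col


def isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    s = np.sqrt(1.0 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def geometric_sensitivity(
    p,
    geometry: SystemGeometry,
    n_samples: int = 100_000,
    seed: int = 0,
    chunk: int = 200_000,
):
    """Monte-Carlo geometric sensitivity (accepted fraction) from a point.

    Fraction of isotropically emitted photons that pass through any pinhole
    aperture and land inside its assigned subdetector region.  Reproducible
    for a fixed seed.  Returns ``(sensitivity, mc_standard_error)``.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        dirs = isotropic_directions(m, rng)
        hits += int((trace_to_detector(p, dirs, geometry)[0] >= 0).sum())
        done += m
    frac = hits / n_samples
    se = np.sqrt(max(frac * (1 - frac), 1e-30) / n_samples)
    return frac, se


def analytic_sensitivity(p, geometry: SystemGeometry) -> float:
    """Solid-angle sum  sum_i A_i cos(theta_i) / (4 pi d_i^2)  over pinholes."""
    p = np.asarray(p, dtype=float)
    to_ph = geometry.ph_centers - p
    d = np.linalg.norm(to_ph, axis=1)
    cos = np.einsum("ij,ij->i", to_ph, geometry.ph_axes) / d
    a = np.pi * geometry.ph_radius**2
    vis = cos > 0
    return float(np.sum(a[vis] * cos[vis] / (4 * np.pi * d[vis] ** 2)))


# ---------------------------------------------------------------------------
# scan planning


def make_scan_plan(
    n_positions: int,
    step: float = 0.5,
    dwell: float = 600.0,
    beam_direction=(0.0, 1.0, 0.0),
    axial: float = 0.0,
) -> ScanPlan:
    """Lateral scan positions symmetric about the phantom axis.

    The span is ``(n-1) * step``; the benchtop protocol uses 37 positions at
    0.5 mm for an 18 mm span across the 19 mm phantom.
    """
    if n_positions < 1:
        raise ValueError("need at least one position")
    if step <= 0 or dwell <= 0:
        raise ValueError("step and dwell must be positive")
    x = (np.arange(n_positions) - (n_positions - 1) / 2.0) * step
    d = np.asarray(beam_direction, dtype=float)
    return ScanPlan(x, float(step), float(dwell), d / np.linalg.norm(d), axial=axial)
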