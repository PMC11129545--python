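"""Analytic phantom description and the two shipped phantom studies.

The phantom is a 19 mm diameter x 10 mm acrylic cylinder (axis along ``z``)
with four PTFE tubes (4.7 mm outer / 3 mm inner diameter, 8 mm tall) whose
centers sit 5.5 mm from the axis at 90 degree spacing.  Study I fills them
with water and three Gd concentrations; study II with Gd:La mixtures.

Rays are traced analytically against the finite cylinders; all lengths mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics import WATER, PMMA, PTFE, MaterialMixture, solution

__all__ = [
    "Tube",
    "PhantomSpec",
    "phantom_study_I",
    "phantom_study_II",
    "ray_segments",
    "path_lengths",
]

_TUBE_ANGLES = (0.0, 90.0, 180.0, 270.0)  # degrees from +x, at 5.5 mm offset


@dataclass
class Tube:
    center: tuple[float, float]  # (x, y), mm
    fill: MaterialMixture
    outer_diameter: float = 4.7
    inner_diameter: float = 3.0
    height: float = 8.0
    wall: MaterialMixture = field(default_factory=lambda: PTFE)


@dataclass
class PhantomSpec:
    body_diameter: float = 19.0
    body_height: float = 10.0
    body: MaterialMixture = field(default_factory=lambda: PMMA)
    tubes: list[Tube] = field(default_factory=list)
    name: str = "phantom"

    def __post_init__(self):
        rb = self.body_diameter / 2.0
        for t in self.tubes:
            r = np.hypot(*t.center) + t.outer_diameter / 2.0
            if r > rb + 1e-9 or t.height > self.body_height + 1e-9:
                raise ValueError("tube extends beyond the phantom body")

    def elements(self) -> list[str]:
        """Solute elements present in any fill, with max concentration first."""
        conc: dict[str, float] = {}
        for t in self.tubes:
            for sym, c in t.fill.solute_mg_ml:
                conc[sym] = max(conc.get(sym, 0.0), c)
        return sorted(conc, key=conc.get, reverse=True)

    def material_at(self, point) -> MaterialMixture | None:
        x, y, z = point
        for t in self.tubes:
            if abs(z) <= t.height / 2.0:
                r = np.hypot(x - t.center[0], y - t.center[1])
                if r <= t.inner_diameter / 2.0:
                    return t.fill
                if r <= t.outer_diameter / 2.0:
                    return t.wall
        if abs(z) <= self.body_height / 2.0 and np.hypot(x, y) <= self.body_diameter / 2.0:
            return self.body
        return None


def _tube_positions(offset: float = 5.5):
    ang = np.deg2rad(_TUBE_ANGLES)
    return [(offset * np.cos(a), offset * np.sin(a)) for a in ang]


def phantom_study_I() -> PhantomSpec:
    """Detection-limit study: water and Gd at 3, 0.6 and 0.1 mg/mL."""
    pos = _tube_positions()
    fills = [
        solution({"Gd": 3.0}),
        solution({"Gd": 0.6}),
        solution({"Gd": 0.1}),
        WATER,
    ]
    return PhantomSpec(tubes=[Tube(p, f) for p, f in zip(pos, fills)], name="study_I")


def phantom_study_II() -> PhantomSpec:
    """Two-element study: Gd:La at 3:6, 3:3 and 6:3 mg/mL plus water."""
    pos = _tube_positions()
    fills = [
        solution({"Gd": 3.0, "La": 6.0}),
        solution({"Gd": 3.0, "La": 3.0}),
        solution({"Gd": 6.0, "La": 3.0}),
        WATER,
    ]
    return PhantomSpec(tubes=[Tube(p, f) for p, f in zip(pos, fills)], name="study_II")


# ---------------------------------------------------------------------------
# ray tracing


def _cyl_interval(o, d, cx, cy, radius, half_height):
    """Entry/exit parameters of rays against a finite z-aligned cylinder.

    Vectorized over rays; returns (tin, tout) with tin > tout meaning a miss.
    """
    o = np.atleast_2d(o).astype(float)
    d = np.atleast_2d(d).astype(float)
    ox, oy, oz = o[:, 0] - cx, o[:, 1] - cy, o[:, 2]
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    a = dx**2 + dy**2
    b = ox * dx + oy * dy
    c = ox**2 + oy**2 - radius**2
    tin = np.full(len(o), np.inf)
    tout = np.full(len(o), -np.inf)
    quad = a > 1e-14
    disc = b**2 - a * c
    hit = quad & (disc > 0)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tin = np.where(hit, (-b - sq) / a, tin)
        tout = np.where(hit, (-b + sq) / a, tout)
    # vertical rays: inside or outside for all t
    vert = ~quad
    inside = vert & (c <= 0)
    tin = np.where(inside, -np.inf, tin)
    tout = np.where(inside, np.inf, tout)
    # z slab
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-half_height - oz) / dz
        t2 = (half_height - oz) / dz
    zin = np.where(np.abs(dz) > 1e-14, np.minimum(t1, t2), -np.inf)
    zout = np.where(np.abs(dz) > 1e-14, np.maximum(t1, t2), np.inf)
    flat_out = (np.abs(dz) <= 1e-14) & (np.abs(oz) > half_height)
    zin = np.where(flat_out, np.inf, zin)
    zout = np.where(flat_out, -np.inf, zout)
    return np.maximum(tin, zin), np.minimum(tout, zout)


def ray_segments(phantom: PhantomSpec, origin, direction):
    """Ordered material segments along a ray.

    Returns a list of ``(material, t_entry, t_exit)`` covering the ray's
    intersection with the body for ``t >= 0``; contiguous, non-overlapping.
    An empty list means the ray misses the phantom.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    b_in, b_out = _cyl_interval(o, d, 0.0, 0.0, phantom.body_diameter / 2.0,
                                phantom.body_height / 2.0)
    t0, t1 = max(float(b_in[0]), 0.0), float(b_out[0])
    if t1 <= t0:
        return []
    cuts = {t0, t1}
    for t in phantom.tubes:
        for radius in (t.outer_diameter / 2.0, t.inner_diameter / 2.0):
            ci, co = _cyl_interval(o, d, t.center[0], t.center[1], radius, t.height / 2.0)
            for v in (float(ci[0]), float(co[0])):
                if t0 < v < t1:
                    cuts.add(v)
    ts = sorted(cuts)
    segments = []
    for a, b in zip(ts[:-1], ts[1:]):
        mid = o + 0.5 * (a + b) * d
        mat = phantom.material_at(mid)
        if mat is None:
            continue
        if segments and segments[-1][0] is mat:
            segments[-1] = (mat, segments[-1][1], b)
        else:
            segments.append((mat, a, b))
    return segments


def path_lengths(phantom: PhantomSpec, origins, directions, t_start=0.0):
    """Per-material path lengths for a batch of rays (vectorized).

    Returns ``{material: lengths_mm}`` for the body and every distinct tube
    wall/fill material.  ``t_start`` clips the rays (e.g. 0 for photons
    born inside the phantom).
    """
    o = np.atleast_2d(origins).astype(float)
    d = np.atleast_2d(directions).astype(float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    lo = np.broadcast_to(np.asarray(t_start, dtype=float), (len(o),))
    b_in, b_out = _cyl_interval(o, d, 0.0, 0.0, phantom.body_diameter / 2.0,
                                phantom.body_height / 2.0)
    b_in = np.maximum(b_in, lo)
    body_len = np.clip(b_out - b_in, 0.0, None)
    out: dict[MaterialMixture, np.ndarray] = {}
    outer_total = np.zeros(len(o))
    for t in phantom.tubes:
        oi, oo = _cyl_interval(o, d, t.center[0], t.center[1], t.outer_diameter / 2.0,
                               t.height / 2.0)
        oi, oo = np.maximum(oi, b_in), np.minimum(oo, b_out)
        l_outer = np.clip(oo - oi, 0.0, None)
        ii, io = _cyl_interval(o, d, t.center[0], t.center[1], t.inner_diameter / 2.0,
                               t.height / 2.0)
        ii, io = np.maximum(ii, b_in), np.minimum(io, b_out)
        l_inner = np.clip(io - ii, 0.0, None)
        outer_total += l_outer
        out[t.wall] = out.get(t.wall, 0.0) + (l_outer - l_inner)
        out[t.fill] = out.get(t.fill, 0.0) + l_inner
    out[phantom.body] = out.get(phantom.body, 0.0) + body_len - outer_total
    return out
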