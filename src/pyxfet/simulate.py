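"""Seeded Monte-Carlo forward simulation of one pencil-beam scan position.

The chain per position:

1. the polychromatic pencil beam is attenuated analytically along its path
   through the phantom;
2. expected K-line emissions per depth bin are computed for every solute
   element (photoelectric interaction restricted to spectrum bins above the
   K edge, times the K-shell fraction, fluorescence yield and branching);
3. emission counts are Poisson-sampled and each photon is emitted
   isotropically, tested against all 96 pinhole apertures, attenuated along
   its exit path, absorbed in 1 mm of CdTe with the photoelectric
   probability, blurred by the energy response and optionally split by
   charge sharing;
4. single-scatter Compton background photons are sampled along the beam
   from the Klein-Nishina distribution and transported identically;
5. events are stamped with frames from a Poisson process at the configured
   frame rate.

Only single interactions are simulated (no multiple scatter, no collimator
penetration); the downstream background subtraction is empirical anyway.
Everything is reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import physics as ph
from .geometry import ScanPlan, SystemGeometry, isotropic_directions, trace_to_detector
from .listmode import TRUTH_COMPTON, ListMode
from .phantom import PhantomSpec, path_lengths

__all__ = [
    "DetectorResponseModel",
    "apply_response",
    "simulate_charge_sharing",
    "xrf_yield_per_path",
    "simulate_position",
    "simulate_scan",
]

_MEC2 = 510.99895  # keV


@dataclass
class DetectorResponseModel:
    """Energy resolution, charge sharing and readout framing of one module.

    FWHM anchors are the measured CdTe values; between anchors the FWHM is
    linearly interpolated, outside them it is held flat.
    """

    fwhm_anchors: tuple[tuple[float, float], ...] = ((35.0, 0.5), (60.0, 0.88), (122.0, 1.02))
    charge_sharing_prob: float = 0.3
    frame_rate: float = 2000.0  # frames per second
    threshold: float = 4.0  # keV, low-energy discriminator
    cdte_thickness: float = 0.1  # cm
    escape_peaks: bool = True  # model Cd/Te K-fluorescence escape

    def __post_init__(self):
        e = [a for a, _ in self.fwhm_anchors]
        w = [b for _, b in self.fwhm_anchors]
        if sorted(e) != list(e) or sorted(w) != list(w) or min(w) <= 0:
            raise ValueError("FWHM anchors must be increasing in energy and width")
        if not 0.0 <= self.charge_sharing_prob <= 1.0:
            raise ValueError("sharing probability must be in [0, 1]")

    def fwhm(self, e_kev):
        e = np.asarray(e_kev, dtype=float)
        xs = np.array([a for a, _ in self.fwhm_anchors])
        ys = np.array([b for _, b in self.fwhm_anchors])
        return np.interp(e, xs, ys)  # np.interp clamps outside the anchors

    def efficiency(self, e_kev):
        """Photoelectric absorption probability of the CdTe slab."""
        mu = ph.linear_attenuation(ph.CDTE, e_kev, "photoelectric")
        return 1.0 - np.exp(-mu * self.cdte_thickness)


def escape_probabilities(e_kev: np.ndarray):
    """Cd/Te K-fluorescence escape channels for photopeak events in CdTe.

    For a photon photoelectrically absorbed in the detector, the struck
    atom may emit a K X-ray that leaves the crystal, recording the photon
    at the deposited energy E - E_fluorescence instead of E.  The escape
    fraction uses the standard semi-infinite-slab expectation

        P = 0.5 * [1 - r ln(1 + 1/r)],    r = mu(E_fl) / mu(E),

    weighted by the atom's photoelectric share, its K-shell fraction,
    fluorescence yield and line branching.  This is what puts the Cd and
    Te escape satellites into measured CdTe spectra, and it removes ~4%
    more La Kalpha photopeak events (33.3 keV, just above the Te K edge)
    than Gd Kalpha ones.

    Returns ``(probs, lines)``: per-photon probabilities of shape
    ``(n, n_channels)`` and the escaping line energies.
    """
    e = np.atleast_1d(np.asarray(e_kev, dtype=float))
    mu_in = ph.linear_attenuation(ph.CDTE, e)
    comp = dict(ph.CDTE.composition)
    tau = {
        sym: frac * ph.cross_section_table(sym)(e, "photoelectric")
        for sym, frac in comp.items()
    }
    tau_tot = sum(tau.values())
    probs, lines = [], []
    for sym in ("Cd", "Te"):
        edge = ph.k_edge(sym)
        xs = ph.cross_section_table(sym)
        jump = float(xs(edge * (1 + 1e-6), "photoelectric") / xs(edge * (1 - 1e-6), "photoelectric"))
        k_frac = 1.0 - 1.0 / jump
        share = np.where((e > edge) & (tau_tot > 0), tau[sym] / np.where(tau_tot > 0, tau_tot, 1.0), 0.0)
        for line in ("Ka", "Kb"):
            e_fl = ph.line_energy(sym, line)
            r = ph.linear_attenuation(ph.CDTE, e_fl) / mu_in
            p_geom = 0.5 * (1.0 - r * np.log1p(1.0 / r))
            p = share * k_frac * ph.fluorescence_yield(sym) * ph.k_line_fraction(sym, line) * p_geom
            probs.append(np.where(e > e_fl, p, 0.0))
            lines.append(e_fl)
    return np.stack(probs, axis=1), np.array(lines)


def _apply_escape(e: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace a random subset of deposited energies by their escape-reduced value."""
    if len(e) == 0:
        return e
    probs, lines = escape_probabilities(e)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(e))
    out = e.copy()
    chosen = np.full(len(e), -1)
    for ch in range(cum.shape[1] - 1, -1, -1):
        chosen = np.where(u < cum[:, ch], ch, chosen)
    hit = chosen >= 0
    out[hit] = e[hit] - lines[chosen[hit]]
    return out


def apply_response(e_true, response: DetectorResponseModel, rng: np.random.Generator):
    """Gaussian energy blur with the response model's FWHM."""
    e = np.asarray(e_true, dtype=float)
    if np.any(e <= 0):
        raise ValueError("true energy must be positive")
    sigma = response.fwhm(e) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    out = rng.normal(e, sigma)
    return float(out) if np.isscalar(e_true) else out


def simulate_charge_sharing(event: dict, sharing_prob: float, rng: np.random.Generator,
                            pixels: int = 80) -> list[dict]:
    """Split one event's charge with a neighbor with the given probability.

    With probability ``sharing_prob`` the deposited energy is divided
    (uniform fraction) between the pixel and one of its valid 8-neighbors,
    both in the same frame; otherwise the event is returned unchanged.
    """
    if not 0.0 <= sharing_prob <= 1.0:
        raise ValueError("sharing probability must be in [0, 1]")
    if rng.random() >= sharing_prob:
        return [dict(event)]
    r, c = int(event["row"]), int(event["col"])
    neighbors = [
        (r + dr, c + dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0) and 0 <= r + dr < pixels and 0 <= c + dc < pixels
    ]
    nr, nc = neighbors[rng.integers(len(neighbors))]
    u = rng.random()
    first = dict(event, energy=event["energy"] * u)
    second = dict(event, row=nr, col=nc, energy=event["energy"] * (1 - u))
    return [first, second]


def _share_batch(row, col, energy, prob, rng, pixels=80):
    """Vectorized charge sharing; returns (row, col, energy, parent_index)."""
    n = len(row)
    share = rng.random(n) < prob
    idx = np.arange(n)
    if not share.any():
        return row, col, energy, idx
    ns = int(share.sum())
    u = rng.random(ns)
    offs = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)])
    pick = rng.integers(8, size=ns)
    nr = row[share] + offs[pick, 0]
    nc = col[share] + offs[pick, 1]
    # events on the detector edge: re-pick among valid neighbors
    bad = (nr < 0) | (nr >= pixels) | (nc < 0) | (nc >= pixels)
    while bad.any():
        pick = rng.integers(8, size=int(bad.sum()))
        nr[bad] = row[share][bad] + offs[pick, 0]
        nc[bad] = col[share][bad] + offs[pick, 1]
        bad = (nr < 0) | (nr >= pixels) | (nc < 0) | (nc >= pixels)
    e_first = energy.copy()
    e_first[share] = energy[share] * u
    row2 = np.concatenate([row, nr])
    col2 = np.concatenate([col, nc])
    energy2 = np.concatenate([e_first, energy[share] * (1 - u)])
    parent = np.concatenate([idx, idx[share]])
    return row2, col2, energy2, parent


# ---------------------------------------------------------------------------
# beam physics along the path


def _beam_grid(phantom: PhantomSpec, x_pos: float, axial: float, step: float):
    """Depth bin centers (y, mm) of the beam chord through the body."""
    r = phantom.body_diameter / 2.0
    if abs(x_pos) >= r:
        return np.empty(0), 0.0
    half = float(np.sqrt(r**2 - x_pos**2))
    n = max(int(np.ceil(2 * half / step)), 1)
    edges = np.linspace(-half, half, n + 1)
    return 0.5 * (edges[:-1] + edges[1:]), (edges[1] - edges[0])


def _transmission(phantom: PhantomSpec, x_pos: float, axial: float,
                  y_centers: np.ndarray, dy: float, energies: np.ndarray):
    """Beam survival at each depth bin center for each spectrum energy."""
    mu = {}  # material -> linear attenuation per energy, 1/mm
    mats = []
    for y in y_centers:
        m = phantom.material_at((x_pos, y, axial)) or phantom.body
        mats.append(m)
        if m not in mu:
            mu[m] = ph.linear_attenuation(m, energies) / 10.0
    mu_path = np.stack([mu[m] for m in mats])  # (nbins, nE)
    att = np.cumsum(mu_path * dy, axis=0) - 0.5 * mu_path * dy  # to bin centers
    return np.exp(-att), mats


def xrf_yield_per_path(
    phantom: PhantomSpec,
    x_pos: float,
    spectrum: ph.BeamSpectrum,
    element: str | int,
    axial: float = 0.0,
    depth_step: float = 0.25,
    line: str = "Ka",
):
    """Expected K-line photons per incident beam photon, by beam depth.

    Returns ``(y_centers_mm, yield_per_bin)``.  The yield at each depth bin
    is the surviving spectral fluence above the element's K edge times the
    element's photoelectric mass-interaction probability in that bin, the
    K-shell fraction of it, the fluorescence yield and the line branching.
    An element absent from every fill gives an all-zero profile.
    """
    y, dy = _beam_grid(phantom, x_pos, axial, depth_step)
    if len(y) == 0:
        return y, np.zeros(0)
    sym = ph.element_symbol(element)
    energies = spectrum.centers
    trans, mats = _transmission(phantom, x_pos, axial, y, dy, energies)
    edge = ph.k_edge(sym)
    xs = ph.cross_section_table(sym)
    above = energies > edge
    tau = np.where(above, xs(np.clip(energies, edge * (1 + 1e-6), None), "photoelectric"), 0.0)
    jump = float(
        xs(edge * (1 + 1e-6), "photoelectric") / xs(edge * (1 - 1e-6), "photoelectric")
    )
    k_fraction = 1.0 - 1.0 / jump  # share of photoelectric events in the K shell
    conc = np.array([m.mass_fraction(sym) * m.density for m in mats])  # g/cm^3
    w = spectrum.fluence[None, :] * trans * tau[None, :]  # per bin, per energy
    per_bin = w.sum(axis=1) * conc * (dy / 10.0) * k_fraction
    return y, per_bin * ph.fluorescence_yield(sym) * ph.k_line_fraction(sym, line)


def _compton_weights(phantom, x_pos, axial, y, dy, spectrum):
    """Joint (depth, energy) expected single-scatter weights per photon."""
    energies = spectrum.centers
    trans, mats = _transmission(phantom, x_pos, axial, y, dy, energies)
    mu_inc = np.stack([ph.linear_attenuation(m, energies, "incoherent") / 10.0 for m in mats])
    return spectrum.fluence[None, :] * trans * mu_inc * dy, energies


def _sample_kn_cos(e_kev: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample Klein-Nishina scattering cosines."""
    out = np.empty(len(e_kev))
    todo = np.arange(len(e_kev))
    k = e_kev / _MEC2
    while len(todo):
        c = rng.uniform(-1.0, 1.0, len(todo))
        kk = k[todo]
        ratio = 1.0 / (1.0 + kk * (1.0 - c))  # E'/E
        f = ratio**2 * (ratio + 1.0 / ratio - (1.0 - c**2))
        accept = rng.random(len(todo)) * 2.0 < f
        out[todo[accept]] = c[accept]
        todo = todo[~accept]
    return out


def _rotate_from_axis(axis: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Directions at polar angle arccos(cos_t), azimuth phi about ``axis``.

    ``axis`` may be a single vector or one unit vector per sample.
    """
    a = np.atleast_2d(np.asarray(axis, dtype=float))
    if len(a) == 1:
        a = np.broadcast_to(a, (len(cos_t), 3))
    helper = np.where(np.abs(a[:, 1:2]) > 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(a, u)
    s = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    return cos_t[:, None] * a + (s * np.cos(phi))[:, None] * u + (s * np.sin(phi))[:, None] * v


def _emit_into_cones(
    lam_b: np.ndarray,
    y_centers: np.ndarray,
    dy: float,
    x_pos: float,
    axial: float,
    beam_radius: float,
    geometry: SystemGeometry,
    rng: np.random.Generator,
):
    """Sample isotropic emissions, tracing only those aimed at an aperture.

    Photons are detectable only through the 96 pinholes, so the isotropic
    Poisson emission of each depth bin is split by superposition into 96
    independent streams aimed at cones that enclose each aperture disk (with
    margin for the emission jitter inside the bin and beam cross-section)
    plus an untraced remainder.  Every traced photon still gets an exact
    position and an exact aperture-disk test, so the detected event stream
    is distributed identically to brute-force isotropic emission; only the
    photons that geometrically cannot reach a detector are never built.

    Returns ``(positions, directions, n_emitted_total)``.
    """
    nb = len(y_centers)
    centers = np.stack(
        [np.full(nb, x_pos), y_centers, np.full(nb, axial)], axis=1
    )  # (nb, 3)
    diff = geometry.ph_centers[None, :, :] - centers[:, None, :]  # (nb, 96, 3)
    dist = np.linalg.norm(diff, axis=2)
    margin = dy / 2.0 + beam_radius
    sin_enc = np.clip((geometry.ph_radius[None, :] + margin) / (dist - margin), 0.0, 1.0)
    cos_enc = np.sqrt(1.0 - sin_enc**2)
    p_cone = 0.5 * (1.0 - cos_enc)  # solid-angle fraction of each cone
    n_bi = rng.poisson(lam_b[:, None] * p_cone)  # (nb, 96)
    n_rest = rng.poisson(lam_b * np.clip(1.0 - p_cone.sum(axis=1), 0.0, None))
    total_emitted = int(n_bi.sum() + n_rest.sum())
    if n_bi.sum() == 0:
        return np.empty((0, 3)), np.empty((0, 3)), total_emitted
    bi, pi = np.nonzero(n_bi)
    counts = n_bi[bi, pi]
    b_idx = np.repeat(bi, counts)
    p_idx = np.repeat(pi, counts)
    n = len(b_idx)
    yy = y_centers[b_idx] + rng.uniform(-dy / 2, dy / 2, n)
    rr = beam_radius * np.sqrt(rng.random(n))
    aa = rng.uniform(0, 2 * np.pi, n)
    pos = np.stack([x_pos + rr * np.cos(aa), yy, axial + rr * np.sin(aa)], axis=1)
    axis = diff[b_idx, p_idx]
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    c_lo = cos_enc[b_idx, p_idx]
    cos_t = c_lo + rng.random(n) * (1.0 - c_lo)  # uniform in the cone
    phi = rng.uniform(0, 2 * np.pi, n)
    dirs = _rotate_from_axis(axis, cos_t, phi)
    return pos, dirs, total_emitted


# ---------------------------------------------------------------------------
# transport of emitted photons


def _transport(
    positions: np.ndarray,
    directions: np.ndarray,
    energies: np.ndarray,
    truth: np.ndarray,
    phantom: PhantomSpec,
    geometry: SystemGeometry,
    response: DetectorResponseModel,
    rng: np.random.Generator,
):
    """Common pinhole transport: acceptance, attenuation, detection, blur."""
    hit, mod, row, col = trace_to_detector(positions, directions, geometry)
    acc = hit >= 0
    if not acc.any():
        return (np.empty(0, int),) * 3 + (np.empty(0), np.empty(0, int), np.empty(0, int))
    pos, d, e, tr = positions[acc], directions[acc], energies[acc], truth[acc]
    mod, row, col = mod[acc], row[acc], col[acc]
    # exit attenuation through the phantom
    mu_len = np.zeros(len(e))
    for mat, lengths in path_lengths(phantom, pos, d).items():
        mu_len += ph.linear_attenuation(mat, e) * lengths / 10.0
    keep = rng.random(len(e)) < np.exp(-mu_len)
    keep &= rng.random(len(e)) < response.efficiency(e)
    mod, row, col, e, tr = mod[keep], row[keep], col[keep], e[keep], tr[keep]
    if response.escape_peaks:
        e = _apply_escape(e, rng)
    row_i = np.clip(np.floor(row).astype(int), 0, geometry.config.pixels - 1)
    col_i = np.clip(np.floor(col).astype(int), 0, geometry.config.pixels - 1)
    # charge sharing happens pre-blur; energies split, then each deposit is
    # blurred independently by the readout
    row_s, col_s, e_s, parent = _share_batch(
        row_i, col_i, e, response.charge_sharing_prob, rng, geometry.config.pixels
    )
    mod_s, tr_s = mod[parent], tr[parent]
    e_meas = apply_response(np.clip(e_s, 1e-6, None), response, rng)
    ok = e_meas > response.threshold
    return mod_s[ok], row_s[ok], col_s[ok], e_meas[ok], tr_s[ok], parent[ok]


def simulate_position(
    phantom: PhantomSpec,
    x_pos: float,
    geometry: SystemGeometry,
    spectrum: ph.BeamSpectrum,
    dwell: float,
    flux: float,
    response: DetectorResponseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    include_compton: bool = True,
    compton_scale: float = 1.0,
    axial: float = 0.0,
    beam_diameter: float = 1.0,
    depth_step: float = 0.25,
) -> ListMode:
    """Simulate the list-mode data of one beam position.

    ``flux`` is the number of beam photons per second through the 1 mm
    aperture (a configuration choice: the bench value is not published, so
    every downstream claim is ratio- or shape-based).  ``compton_scale``
    thins the single-scatter background by that factor (variance reduction;
    1.0 is analog).  Fully reproducible for a fixed seed.
    """
    if flux <= 0 or dwell <= 0:
        raise ValueError("flux and dwell must be positive")
    response = response or DetectorResponseModel()
    rng = np.random.default_rng(seed)
    n_photons = flux * dwell

    y, dy = _beam_grid(phantom, x_pos, axial, depth_step)
    chunks = []
    emitted: dict[str, int] = {}
    if len(y):
        # --- XRF ---
        for sym in phantom.elements():
            for line in ("Ka", "Kb"):
                yc, lam = xrf_yield_per_path(
                    phantom, x_pos, spectrum, sym, axial, depth_step, line
                )
                pos, dirs, total = _emit_into_cones(
                    n_photons * lam, yc, dy, x_pos, axial, beam_diameter / 2.0,
                    geometry, rng,
                )
                emitted[f"{sym}_{line}"] = total
                if len(pos) == 0:
                    continue
                e0 = np.full(len(pos), ph.line_energy(sym, line))
                tr = np.full(len(pos), ph.atomic_number(sym), dtype=int)
                chunks.append(
                    _transport(pos, dirs, e0, tr, phantom, geometry, response, rng)
                )
        # --- Compton background ---
        if include_compton and compton_scale > 0:
            w, energies = _compton_weights(phantom, x_pos, axial, y, dy, spectrum)
            lam_tot = float(w.sum()) * n_photons * compton_scale
            n_sc = int(rng.poisson(lam_tot))
            emitted["compton"] = n_sc
            if n_sc:
                flat = (w / w.sum()).ravel()
                pick = rng.choice(len(flat), size=n_sc, p=flat)
                bi, ei = np.unravel_index(pick, w.shape)
                e_in = energies[ei] + rng.uniform(-0.5, 0.5, n_sc) * np.diff(
                    spectrum.edges
                ).mean()
                yy = y[bi] + rng.uniform(-dy / 2, dy / 2, n_sc)
                rr = beam_diameter / 2.0 * np.sqrt(rng.random(n_sc))
                aa = rng.uniform(0, 2 * np.pi, n_sc)
                pos = np.stack(
                    [x_pos + rr * np.cos(aa), yy, axial + rr * np.sin(aa)], axis=1
                )
                cos_t = _sample_kn_cos(e_in, rng)
                phi = rng.uniform(0, 2 * np.pi, n_sc)
                dirs = _rotate_from_axis(np.array([0.0, 1.0, 0.0]), cos_t, phi)
                e_sc = e_in / (1.0 + e_in / _MEC2 * (1.0 - cos_t))
                tr = np.full(n_sc, TRUTH_COMPTON, dtype=int)
                chunks.append(
                    _transport(pos, dirs, e_sc, tr, phantom, geometry, response, rng)
                )

    mod = np.concatenate([c[0] for c in chunks]) if chunks else np.empty(0, int)
    row = np.concatenate([c[1] for c in chunks]) if chunks else np.empty(0, int)
    col = np.concatenate([c[2] for c in chunks]) if chunks else np.empty(0, int)
    e = np.concatenate([c[3] for c in chunks]) if chunks else np.empty(0)
    tr = np.concatenate([c[4] for c in chunks]) if chunks else np.empty(0, int)

    # frames: each physical photon gets an arrival time from the Poisson
    # process; charge-sharing partners share their parent's frame
    frames = np.empty(len(e), dtype=np.int64)
    start = 0
    for c in chunks:
        n_here = len(c[3])
        parents = c[5]
        n_parents = int(parents.max()) + 1 if n_here else 0
        t = rng.uniform(0.0, dwell, n_parents)
        frames[start : start + n_here] = np.floor(t[parents] * response.frame_rate)
        start += n_here

    lm = ListMode(
        frames, mod, row, col, e, tr,
        meta={
            "x_pos": float(x_pos),
            "axial": float(axial),
            "dwell": float(dwell),
            "flux": float(flux),
            "seed": int(seed) if np.isscalar(seed) else None,
            "phantom": phantom.name,
            "emitted": emitted,
            "compton_scale": float(compton_scale),
            "frame_rate": float(response.frame_rate),
        },
    )
    return lm.sorted_by_frame()


def simulate_scan(
    phantom: PhantomSpec,
    plan: ScanPlan,
    geometry: SystemGeometry,
    spectrum: ph.BeamSpectrum,
    flux: float,
    response: DetectorResponseModel | None = None,
    seed: int = 0,
    **kwargs,
) -> list[ListMode]:
    """Simulate every position of a scan plan; one child seed per position."""
    seeds = np.random.SeedSequence(seed).spawn(len(plan.positions))
    out = []
    for x, s in zip(plan.positions, seeds):
        lm = simulate_position(
            phantom, float(x), geometry, spectrum, plan.dwell, flux,
            response, seed=s, axial=plan.axial, **kwargs,
        )
        lm.meta["scan_seed"] = int(seed)
        out.append(lm)
    return out
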