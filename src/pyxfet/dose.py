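"""Dose accounting for the pencil-beam acquisition.

Two layers: exact arithmetic on a known dose rate (rate x dwell x
positions), and a seeded kerma-approximation Monte-Carlo estimator of the
dose rate itself for a given spectrum, phantom and beam flux, with optional
low-energy spectrum filtering.  Secondary electrons deposit locally; below
90 keV at these geometries that approximation is benign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import physics as ph
from .phantom import PhantomSpec

__all__ = [
    "DoseReport",
    "dose_per_position",
    "total_dose",
    "mc_dose_rate",
    "phantom_mass",
    "mu_en_approx",
]

KEV_TO_J = 1.602176634e-16
_MEC2 = 510.99895


@dataclass
class DoseReport:
    dose_rate_cgy_min: float
    dwell_min: float
    n_positions: int
    per_position_cgy: float
    total_cgy: float
    filter_kev: float | None = None

    @classmethod
    def build(cls, rate: float, dwell_min: float, n_positions: int,
              filter_kev: float | None = None) -> "DoseReport":
        per = dose_per_position(rate, dwell_min)
        return cls(rate, dwell_min, n_positions, per,
                   total_dose(per, n_positions), filter_kev)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def dose_per_position(rate_cgy_min: float, dwell_min: float) -> float:
    """Dose per scan position, cGy = rate x dwell."""
    if rate_cgy_min < 0 or dwell_min < 0:
        raise ValueError("rate and dwell must be nonnegative")
    return rate_cgy_min * dwell_min


def total_dose(per_position_cgy: float, n_positions: int) -> float:
    """Total scan dose, cGy (8.8 cGy x 37 positions ~ 326 cGy)."""
    if n_positions < 0:
        raise ValueError("position count must be nonnegative")
    return per_position_cgy * n_positions


def phantom_mass(phantom: PhantomSpec) -> float:
    """Total phantom mass in grams (body minus tube bores, plus tubes)."""
    rb = phantom.body_diameter / 2.0
    v_body = np.pi * rb**2 * phantom.body_height  # mm^3
    mass = 0.0
    v_removed = 0.0
    for t in phantom.tubes:
        ro, ri = t.outer_diameter / 2.0, t.inner_diameter / 2.0
        v_o = np.pi * ro**2 * t.height
        v_i = np.pi * ri**2 * t.height
        v_removed += v_o
        mass += t.wall.density * (v_o - v_i) + t.fill.density * v_i
    mass += phantom.body.density * (v_body - v_removed)
    return mass / 1000.0  # mm^3 * g/cm^3 -> g


def _kn_transfer_fraction(e_kev):
    """Mean fraction of photon energy given to the Compton electron."""
    e = np.atleast_1d(np.asarray(e_kev, dtype=float))
    cos = np.linspace(-1.0, 1.0, 201)[None, :]
    k = (e / _MEC2)[:, None]
    ratio = 1.0 / (1.0 + k * (1.0 - cos))
    dsdc = ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos**2))
    frac = np.trapezoid(dsdc * (1.0 - ratio), cos, axis=1) / np.trapezoid(dsdc, cos, axis=1)
    return frac if np.ndim(e_kev) else float(frac[0])


def mu_en_approx(material: ph.MaterialMixture, e_kev):
    """Approximate mass energy-absorption coefficient, cm^2/g.

    Photoelectric events deposit everything locally; incoherent events
    deposit the Klein-Nishina mean electron energy; coherent events deposit
    nothing.  This is the same physics the MC estimator implements, written
    as a closed-form expectation — it serves as its deterministic oracle.
    """
    tau = ph.mass_attenuation(material, e_kev, "photoelectric")
    inc = ph.mass_attenuation(material, e_kev, "incoherent")
    return tau + inc * _kn_transfer_fraction(e_kev)


def mc_dose_rate(
    spectrum: ph.BeamSpectrum,
    phantom: PhantomSpec,
    flux: float,
    filter_below: float | None = None,
    n_histories: int = 50_000,
    seed: int = 0,
    beam_diameter: float = 1.0,
    max_bounces: int = 200,
) -> float:
    """Monte-Carlo phantom dose rate in cGy/min (kerma approximation).

    Photons are sampled from the (optionally low-energy-truncated) spectrum
    and delta-tracked through the heterogeneous phantom.  Photoelectric
    absorption deposits the full photon energy; Compton scattering deposits
    the electron share and follows the scattered photon; coherent scattering
    deposits nothing and continues the photon unchanged (its deflection is
    predominantly forward at these energies).

    Filtering removes photons from the same source: the effective photon
    rate is ``flux`` times the fluence fraction the filter retains, so a
    filtered beam can only deliver less dose than the unfiltered one.
    """
    if n_histories < 1:
        raise ValueError("need at least one history")
    mass = phantom_mass(phantom)
    if mass <= 0:
        raise ValueError("phantom mass must be positive")
    rng = np.random.default_rng(seed)
    retained = 1.0
    sp = spectrum
    if filter_below is not None:
        retained = float(spectrum.fluence[spectrum.centers >= filter_below].sum()
                         / spectrum.fluence.sum())
        sp = spectrum.filtered_below(filter_below)
    mats = [phantom.body] + [m for t in phantom.tubes for m in (t.wall, t.fill)]

    def mu_of(mat, e, kind="total"):
        return ph.linear_attenuation(mat, e, kind) / 10.0  # 1/mm

    e = sp.sample(n_histories, rng)
    rr = beam_diameter / 2.0 * np.sqrt(rng.random(n_histories))
    aa = rng.uniform(0, 2 * np.pi, n_histories)
    # start just upstream of the body surface (delta-tracking from farther
    # away would waste steps on virtual collisions outside the phantom)
    y0 = -(phantom.body_diameter / 2.0 + 0.1)
    pos = np.stack([rr * np.cos(aa), np.full(n_histories, y0), rr * np.sin(aa)], axis=1)
    d = np.tile(np.array([0.0, 1.0, 0.0]), (n_histories, 1))
    alive = np.ones(n_histories, dtype=bool)
    deposited = 0.0
    for _ in range(max_bounces):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        ee = e[idx]
        mu_maj = np.max([mu_of(m, ee) for m in mats], axis=0)
        step = rng.exponential(1.0 / mu_maj)
        pos[idx] += step[:, None] * d[idx]
        # escape: outside an enclosing sphere, or leaving the body forever
        r = np.linalg.norm(pos[idx], axis=1)
        gone = r > 1.5 * phantom.body_diameter
        here = [phantom.material_at(p) for p in pos[idx]]
        mu_here = np.array([mu_of(m, ev) if m else 0.0 for m, ev in zip(here, ee)])
        real = rng.random(len(idx)) < mu_here / mu_maj
        for j, (i, m, is_real) in enumerate(zip(idx, here, real)):
            if gone[j]:
                alive[i] = False
                continue
            if not is_real or m is None:
                continue
            ev = e[i]
            tau = mu_of(m, ev, "photoelectric")
            inc = mu_of(m, ev, "incoherent")
            tot = mu_of(m, ev)
            u = rng.random() * tot
            if u < tau:  # photoelectric: local absorption
                deposited += ev
                alive[i] = False
            elif u < tau + inc:  # Compton: deposit electron share, follow photon
                cos_t = _sample_kn_cos_scalar(ev, rng)
                e_sc = ev / (1.0 + ev / _MEC2 * (1.0 - cos_t))
                deposited += ev - e_sc
                e[i] = e_sc
                phi = rng.uniform(0, 2 * np.pi)
                d[i] = _deflect(d[i], cos_t, phi)
                if e_sc < 1.0:
                    deposited += e_sc  # below the table range: absorb locally
                    alive[i] = False
            # coherent: no deposit, direction kept (forward approximation)
    gray_per_photon = deposited / n_histories * KEV_TO_J / (mass / 1000.0)
    return gray_per_photon * flux * retained * 60.0 * 100.0  # -> cGy/min


def _sample_kn_cos_scalar(e_kev: float, rng) -> float:
    k = e_kev / _MEC2
    while True:
        c = rng.uniform(-1.0, 1.0)
        ratio = 1.0 / (1.0 + k * (1.0 - c))
        f = ratio**2 * (ratio + 1.0 / ratio - (1.0 - c**2))
        if rng.random() * 2.0 < f:
            return c


def _deflect(d, cos_t, phi):
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[1]) > 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    s = np.sqrt(max(1.0 - cos_t**2, 0.0))
    return cos_t * d + s * np.cos(phi) * u + s * np.sin(phi) * v
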