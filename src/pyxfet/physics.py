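"""Atomic-physics tables, materials and the polychromatic source model.

Everything downstream (forward simulation, dosimetry, quantification) pulls
element constants and mass-interaction coefficients from here.  The numeric
content lives in three CSV fixtures under :mod:`pyxfet.data` (see
``make_tables.py`` there for how they were produced); this module only loads,
interpolates and combines them.

Energies are keV throughout, mass-interaction coefficients cm^2/g,
densities g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EmissionLine",
    "CrossSectionTable",
    "MaterialMixture",
    "BeamSpectrum",
    "element_symbol",
    "atomic_number",
    "line_energy",
    "k_edge",
    "fluorescence_yield",
    "k_line_fraction",
    "cross_section_table",
    "mass_attenuation",
    "photoelectric_edge_ratio",
    "simulate_source_spectrum",
    "spectrum_fraction_above",
    "material",
    "solution",
    "WATER",
    "PMMA",
    "PTFE",
    "CDTE",
]


class LookupError_(KeyError):
    """Unknown element, line label or material."""


def _data_path(name: str):
    return resources.files("pyxfet.data").joinpath(name)


@lru_cache(maxsize=1)
def _elements() -> pd.DataFrame:
    with resources.as_file(_data_path("elements.csv")) as p:
        return pd.read_csv(p).set_index("symbol")


@lru_cache(maxsize=1)
def _lines() -> pd.DataFrame:
    with resources.as_file(_data_path("lines.csv")) as p:
        return pd.read_csv(p)


@lru_cache(maxsize=1)
def _xs() -> pd.DataFrame:
    with resources.as_file(_data_path("xs_tables.csv")) as p:
        return pd.read_csv(p)


def element_symbol(element: str | int) -> str:
    """Resolve an element given as symbol or atomic number Z."""
    el = _elements()
    if isinstance(element, str):
        if element not in el.index:
            raise LookupError_(f"element {element!r} not in embedded tables")
        return element
    match = el.index[el["Z"] == int(element)]
    if len(match) == 0:
        raise LookupError_(f"Z={element} not in embedded tables")
    return str(match[0])


def atomic_number(element: str | int) -> int:
    return int(_elements().loc[element_symbol(element), "Z"])


def atomic_mass(element: str | int) -> float:
    return float(_elements().loc[element_symbol(element), "atomic_mass"])


@dataclass(frozen=True)
class EmissionLine:
    """One intensity-weighted K emission line of an element."""

    element: int  # atomic number Z
    line_label: str  # "Ka" or "Kb"
    energy: float  # keV
    relative_intensity: float  # fraction of the total K emission
    fluorescence_yield: float  # omega_K

    def __post_init__(self):
        assert 0.0 <= self.fluorescence_yield <= 1.0
        assert 0.0 <= self.relative_intensity <= 1.0


_LABELS = {"Ka": "Ka", "Kalpha": "Ka", "Kα": "Ka", "Kb": "Kb", "Kbeta": "Kb", "Kβ": "Kb"}


def _line_row(element: str | int, label: str) -> pd.Series:
    sym = element_symbol(element)
    if label not in _LABELS:
        raise LookupError_(f"unsupported line label {label!r}")
    lab = _LABELS[label]
    d = _lines()
    row = d[(d.symbol == sym) & (d.line == lab)]
    if row.empty:
        raise LookupError_(f"no {lab} line tabulated for {sym}")
    return row.iloc[0]


def emission_line(element: str | int, label: str) -> EmissionLine:
    r = _line_row(element, label)
    return EmissionLine(
        element=atomic_number(element),
        line_label=r.line,
        energy=float(r.energy_keV),
        relative_intensity=float(r.rel_intensity),
        fluorescence_yield=float(r.fluorescence_yield),
    )


def line_energy(element: str | int, label: str = "Ka") -> float:
    """Tabulated intensity-weighted K-line energy, keV."""
    return float(_line_row(element, label).energy_keV)


def k_line_fraction(element: str | int, label: str = "Ka") -> float:
    """Fraction of the element's K emission carried by the given line."""
    return float(_line_row(element, label).rel_intensity)


def fluorescence_yield(element: str | int) -> float:
    """K-shell fluorescence yield omega_K."""
    sym = element_symbol(element)
    d = _lines()
    row = d[d.symbol == sym]
    if row.empty:
        raise LookupError_(f"no fluorescence yield tabulated for {sym}")
    return float(row.iloc[0].fluorescence_yield)


def k_edge(element: str | int) -> float:
    """K-shell binding energy, keV."""
    return float(_elements().loc[element_symbol(element), "k_edge_keV"])


# ---------------------------------------------------------------------------
# cross sections


@dataclass
class CrossSectionTable:
    """Per-element mass-interaction coefficients on an energy grid.

    Interpolation is log-log and edge-aware: the grid carries nodes an
    epsilon below and above each absorption edge, and interpolation never
    bridges the discontinuity.
    """

    element: str
    energy: np.ndarray  # keV, strictly increasing
    photoelectric: np.ndarray
    incoherent: np.ndarray
    coherent: np.ndarray
    k_edge: float

    @property
    def total(self) -> np.ndarray:
        return self.photoelectric + self.incoherent + self.coherent

    def _interp(self, e, values) -> np.ndarray:
        e = np.asarray(e, dtype=float)
        if np.any(e < self.energy[0]) or np.any(e > self.energy[-1]):
            raise ValueError(
                f"energy outside table grid [{self.energy[0]:.3g}, "
                f"{self.energy[-1]:.3g}] keV for {self.element}"
            )
        return np.exp(np.interp(np.log(e), np.log(self.energy), np.log(values)))

    def __call__(self, e, kind: str = "total"):
        values = {
            "total": self.total,
            "photoelectric": self.photoelectric,
            "incoherent": self.incoherent,
            "compton": self.incoherent,
            "coherent": self.coherent,
            "rayleigh": self.coherent,
        }[kind]
        return self._interp(e, values)


@lru_cache(maxsize=None)
def cross_section_table(element: str | int) -> CrossSectionTable:
    sym = element_symbol(element)
    d = _xs()[_xs().symbol == element_symbol(element)].sort_values("energy_keV")
    return CrossSectionTable(
        element=sym,
        energy=d.energy_keV.to_numpy(),
        photoelectric=d.photoelectric.to_numpy(),
        incoherent=d.incoherent.to_numpy(),
        coherent=d.coherent.to_numpy(),
        k_edge=k_edge(sym),
    )


def photoelectric_edge_ratio(element_a: str | int, element_b: str | int) -> float:
    """Ratio of photoelectric coefficients just above each element's own K edge.

    Evaluated as the limit from above at each K edge, per unit mass.  For
    (La, Gd) this is ~1.5, the factor the two-element phantom study leans on.
    """
    out = []
    for el in (element_a, element_b):
        t = cross_section_table(el)
        if not (t.energy[0] < t.k_edge < t.energy[-1]):
            raise LookupError_(f"no in-range K edge for {element_symbol(el)}")
        out.append(float(t(t.k_edge * (1 + 1e-6), "photoelectric")))
    return out[0] / out[1]


# ---------------------------------------------------------------------------
# materials


@dataclass(frozen=True)
class MaterialMixture:
    """Homogeneous mixture described by elemental mass fractions."""

    name: str
    composition: tuple[tuple[str, float], ...]  # (symbol, mass fraction)
    density: float  # g/cm^3
    solute_mg_ml: tuple[tuple[str, float], ...] = ()  # bookkeeping for solutions

    def __post_init__(self):
        fracs = np.array([f for _, f in self.composition])
        if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-3:
            raise ValueError(f"mass fractions of {self.name} must be >=0 and sum to 1")
        if abs(fracs.sum() - 1.0) > 1e-12:
            object.__setattr__(
                self,
                "composition",
                tuple((s, f / fracs.sum()) for s, f in self.composition),
            )
        if self.density <= 0:
            raise ValueError("density must be positive")

    def mass_fraction(self, element: str | int) -> float:
        sym = element_symbol(element)
        return dict(self.composition).get(sym, 0.0)


def _mix(name, comp: dict[str, float], rho, solutes=()) -> MaterialMixture:
    return MaterialMixture(name, tuple(sorted(comp.items())), rho, tuple(solutes))


WATER = _mix("water", {"H": 0.1119, "O": 0.8881}, 1.0)
# acrylic body is PMMA (C5O2H8) at the stated 1.18 g/cm^3
PMMA = _mix("pmma", {"C": 0.5998, "H": 0.0805, "O": 0.3196}, 1.18)
# tube walls are PTFE (C2F4); wall density is a declared default
PTFE = _mix("ptfe", {"C": 0.2402, "F": 0.7598}, 2.2)
CDTE = _mix("cdte", {"Cd": 0.4681, "Te": 0.5319}, 5.85)
_REGISTRY = {m.name: m for m in (WATER, PMMA, PTFE, CDTE)}


def material(name: str) -> MaterialMixture:
    key = name.lower()
    if key in _REGISTRY:
        return _REGISTRY[key]
    if key == "acrylic":
        return PMMA
    if key == "teflon":
        return PTFE
    sym = element_symbol(name.capitalize() if name.islower() else name)
    rho = float(_elements().loc[sym, "density_g_cm3"])
    return _mix(sym, {sym: 1.0}, rho)


def solution(solutes_mg_ml: dict[str, float], solvent: MaterialMixture = WATER) -> MaterialMixture:
    """Dilute aqueous solution of one or more elements at mg/mL.

    Density is taken as the solvent's (dilute limit; concentrations here are
    a few mg/mL so the error is <1%).
    """
    for c in solutes_mg_ml.values():
        if c < 0:
            raise ValueError("concentrations must be nonnegative")
    total = sum(solutes_mg_ml.values()) / 1000.0 / solvent.density
    comp = {sym: f * (1 - total) for sym, f in solvent.composition}
    for el, c in solutes_mg_ml.items():
        sym = element_symbol(el)
        comp[sym] = comp.get(sym, 0.0) + c / 1000.0 / solvent.density
    label = "+".join(f"{s}{c:g}" for s, c in sorted(solutes_mg_ml.items()))
    return _mix(f"{solvent.name}+{label}mg/mL", comp, solvent.density,
                tuple(sorted((element_symbol(e), float(c)) for e, c in solutes_mg_ml.items())))


def mass_attenuation(mat: MaterialMixture, e, kind: str = "total"):
    """Mass attenuation coefficient of a mixture, cm^2/g (mixture rule)."""
    e = np.asarray(e, dtype=float)
    out = np.zeros_like(e)
    for sym, frac in mat.composition:
        out = out + frac * cross_section_table(sym)(e, kind)
    return out if out.ndim else float(out)


def linear_attenuation(mat: MaterialMixture, e, kind: str = "total"):
    """Linear attenuation coefficient, 1/cm."""
    return mass_attenuation(mat, e, kind) * mat.density


# ---------------------------------------------------------------------------
# source spectrum


@dataclass
class BeamSpectrum:
    """Polychromatic beam spectrum as relative fluence per energy bin."""

    edges: np.ndarray  # keV, bin edges, length n+1
    fluence: np.ndarray  # per bin, normalized to 1
    kvp: float
    anode: str = "Mo"
    window: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def fraction_above(self, e_kev: float) -> float:
        return spectrum_fraction_above(self, e_kev)

    def mean_energy(self) -> float:
        return float(np.sum(self.centers * self.fluence) / np.sum(self.fluence))

    def energy_fraction_below(self, e_kev: float) -> float:
        """Fluence-energy-weighted fraction carried by photons below e_kev."""
        w = self.centers * self.fluence
        return float(w[self.centers < e_kev].sum() / w.sum())

    def filtered_below(self, threshold: float | None) -> "BeamSpectrum":
        """Remove all bins whose centers lie strictly below ``threshold``."""
        if threshold is None:
            return self
        f = np.where(self.centers < threshold, 0.0, self.fluence)
        s = f.sum()
        if s == 0:
            raise ValueError("filter removed the entire spectrum")
        return BeamSpectrum(self.edges.copy(), f / s, self.kvp, self.anode, self.window)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n photon energies (uniform within bins)."""
        idx = rng.choice(len(self.fluence), size=n, p=self.fluence / self.fluence.sum())
        lo, hi = self.edges[idx], self.edges[idx + 1]
        return lo + rng.random(n) * (hi - lo)

    def to_csv(self, path) -> None:
        pd.DataFrame({"energy_keV": self.centers, "fluence": self.fluence}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kvp=None, anode="", window="") -> "BeamSpectrum":
        d = pd.read_csv(path)
        c = d.energy_keV.to_numpy()
        step = np.diff(c).mean()
        edges = np.concatenate([[c[0] - step / 2], c + step / 2])
        f = d.fluence.to_numpy().astype(float)
        return cls(edges, f / f.sum(), kvp or float(edges[-1]), anode, window)


def simulate_source_spectrum(
    kvp: float,
    anode: str | int = "Mo",
    window_material: str = "Be",
    window_um: float = 254.0,
    characteristic_fraction: float = 0.25,
    bin_width: float = 0.1,
) -> BeamSpectrum:
    """Analytic tube spectrum: Kramers continuum + anode K lines + window.

    The continuum is the thick-target Kramers form, fluence per bin
    proportional to Z*(kVp - E)/E, filtered by the exit window's attenuation.
    Anode characteristic K lines are added only when kVp exceeds the anode
    K edge, carrying ``characteristic_fraction`` of the total exit fluence
    (split Ka:Kb by the tabulated branching).  The result is normalized to
    unit total fluence.

    The default characteristic fraction makes the spectrum's fluence-energy
    fraction below 21 keV exceed one half, matching the qualitative property
    of the measured 90 kVp Mo spectrum this models.
    """
    if kvp <= 0:
        raise ValueError("kVp must be positive")
    anode_sym = element_symbol(anode)
    z = atomic_number(anode_sym)
    edges = np.arange(1.0, kvp + bin_width / 2, bin_width)
    if edges[-1] < kvp:
        edges = np.append(edges, kvp)
    centers = 0.5 * (edges[:-1] + edges[1:])
    cont = z * np.clip(kvp - centers, 0.0, None) / centers
    win = material(window_material)
    trans = np.exp(-mass_attenuation(win, centers) * win.density * window_um * 1e-4)
    cont = cont * trans
    cont /= cont.sum()

    fluence = cont.copy()
    if kvp > k_edge(anode_sym) and characteristic_fraction > 0:
        fluence = cont * (1 - characteristic_fraction)
        for lab in ("Ka", "Kb"):
            e0 = line_energy(anode_sym, lab)
            if e0 >= kvp:
                continue
            i = int(np.searchsorted(edges, e0) - 1)
            t = float(np.exp(-mass_attenuation(win, e0) * win.density * window_um * 1e-4))
            fluence[i] += characteristic_fraction * k_line_fraction(anode_sym, lab) * t
        fluence /= fluence.sum()
    return BeamSpectrum(edges, fluence, float(kvp), anode_sym, f"{window_material} {window_um:g}um")


def spectrum_fraction_above(spectrum: BeamSpectrum, e_kev: float) -> float:
    """Fraction of total fluence in bins whose centers lie above e_kev."""
    total = spectrum.fluence.sum()
    return float(spectrum.fluence[spectrum.centers > e_kev].sum() / total)
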