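"""Materials, photon interaction coefficients and the Ir-192 emission spectrum.

Coefficient tables (mass attenuation ``mu/rho`` split into photoelectric,
incoherent/Compton and coherent/Rayleigh channels, plus the mass
energy-absorption coefficient ``muen/rho``) are shipped as plain-text package
data on a common log-uniform energy grid spanning 1-1400 keV and interpolated
log-log in energy.  See the data-file headers and ``docs/methods.md`` for
provenance.

The in-memory containers are deliberately plain: :class:`XsTable` is a bundle
of validated numpy arrays, :class:`EmissionSpectrum` a list of discrete lines.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "Material",
    "XsTable",
    "EmissionSpectrum",
    "CHANNELS",
    "lookup_mu",
    "mixture_table",
    "sample_emission",
    "load_table",
    "load_material",
    "load_spectrum",
    "available_materials",
    "form_factor_squared",
]

#: channel name -> column attribute of :class:`XsTable`
CHANNELS = ("total", "photoelectric", "compton", "rayleigh", "muen")

#: element symbol -> (Z, A); covers every shipped composition
ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "P": (15, 30.974),
    "S": (16, 32.06), "Ar": (18, 39.948), "Ca": (20, 40.078),
    "Cr": (24, 51.996), "Mn": (25, 54.938), "Fe": (26, 55.845),
    "Ni": (28, 58.693), "Mo": (42, 95.95), "Ir": (77, 192.217),
    "Pb": (82, 207.2),
}

ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 1400.0


class MaterialDataError(ValueError):
    """A shipped or user-supplied table violates a physical invariant."""


@dataclass(frozen=True)
class Material:
    """A named medium: elemental mass fractions and a nominal density."""

    name: str
    composition: tuple[tuple[str, float], ...]
    density: float  # g/cm3

    def __post_init__(self):
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise MaterialDataError(
                f"mass fractions of {self.name!r} sum to {total}, not 1")
        if self.density <= 0:
            raise MaterialDataError(f"density of {self.name!r} must be > 0")
        for sym, _ in self.composition:
            if sym not in ELEMENTS:
                raise MaterialDataError(f"unknown element {sym!r}")


@dataclass
class XsTable:
    """Photon interaction coefficients of one material on an energy grid.

    All coefficients are mass coefficients in cm2/g; energies in keV.
    """

    material: str
    energy_grid: np.ndarray
    mu_rho_photoelectric: np.ndarray
    mu_rho_compton: np.ndarray
    mu_rho_rayleigh: np.ndarray
    mu_rho_total: np.ndarray
    muen_rho: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energy_grid, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise MaterialDataError(
                f"{self.material}: energy grid must be strictly increasing")
        if e[0] > ENERGY_MIN_KEV + 1e-9 or e[-1] < ENERGY_MAX_KEV - 1e-9:
            raise MaterialDataError(
                f"{self.material}: grid [{e[0]}, {e[-1]}] keV does not span "
                f"[{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
        cols = (self.mu_rho_photoelectric, self.mu_rho_compton,
                self.mu_rho_rayleigh, self.mu_rho_total, self.muen_rho)
        for c in cols:
            if np.asarray(c).shape != e.shape:
                raise MaterialDataError(f"{self.material}: ragged columns")
            if np.any(np.asarray(c) <= 0):
                raise MaterialDataError(
                    f"{self.material}: coefficients must be > 0")
        part = (self.mu_rho_photoelectric + self.mu_rho_compton
                + self.mu_rho_rayleigh)
        if np.any(np.abs(part / self.mu_rho_total - 1.0) > 5e-3):
            raise MaterialDataError(
                f"{self.material}: partial coefficients do not sum to the "
                "total within 0.5%")
        if np.any(self.muen_rho > self.mu_rho_total * (1 + 1e-12)):
            raise MaterialDataError(
                f"{self.material}: muen/rho exceeds mu/rho")

    def _column(self, channel: str) -> np.ndarray:
        try:
            return {
                "total": self.mu_rho_total,
                "photoelectric": self.mu_rho_photoelectric,
                "compton": self.mu_rho_compton,
                "rayleigh": self.mu_rho_rayleigh,
                "muen": self.muen_rho,
            }[channel]
        except KeyError:
            raise ValueError(
                f"unknown channel {channel!r}; expected one of {CHANNELS}"
            ) from None

    def lookup(self, energy, channel: str = "total"):
        """Log-log interpolated coefficient; exact at grid nodes."""
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energy_grid[0]) or np.any(e > self.energy_grid[-1]):
            raise ValueError(
                f"energy {energy} keV outside the tabulated range "
                f"[{self.energy_grid[0]:g}, {self.energy_grid[-1]:g}] keV "
                f"for material {self.material!r}")
        col = self._column(channel)
        out = np.exp(np.interp(np.log(e), np.log(self.energy_grid),
                               np.log(col)))
        return float(out) if np.isscalar(energy) else out

    def resample(self, energy_grid: np.ndarray) -> "XsTable":
        """Log-log resampling onto a new grid (used for mixing)."""
        return XsTable(
            material=self.material,
            energy_grid=np.asarray(energy_grid, dtype=float),
            mu_rho_photoelectric=self.lookup(energy_grid, "photoelectric"),
            mu_rho_compton=self.lookup(energy_grid, "compton"),
            mu_rho_rayleigh=self.lookup(energy_grid, "rayleigh"),
            mu_rho_total=self.lookup(energy_grid, "total"),
            muen_rho=self.lookup(energy_grid, "muen"),
        )


@dataclass(frozen=True)
class EmissionSpectrum:
    """Discrete photon emission spectrum (line energies and yields)."""

    lines: tuple[tuple[float, float], ...]  # (keV, photons per decay)
    total_yield: float = field(default=0.0)

    def __post_init__(self):
        if not self.lines:
            raise MaterialDataError("emission spectrum has no lines")
        for e, i in self.lines:
            if i <= 0:
                raise MaterialDataError(f"non-positive intensity at {e} keV")
            if not (ENERGY_MIN_KEV < e < ENERGY_MAX_KEV):
                raise MaterialDataError(
                    f"line energy {e} keV outside ({ENERGY_MIN_KEV}, "
                    f"{ENERGY_MAX_KEV}) keV")
        s = sum(i for _, i in self.lines)
        if self.total_yield == 0.0:
            object.__setattr__(self, "total_yield", s)
        elif abs(self.total_yield - s) > 1e-6 * s:
            raise MaterialDataError(
                "total_yield does not equal the sum of line intensities")

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.lines])

    @property
    def mean_energy(self) -> float:
        """Intensity-weighted mean line energy, keV."""
        e, i = self.energies, self.intensities
        return float((e * i).sum() / i.sum())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def lookup_mu(table: XsTable, energy, channel: str = "total"):
    """Interpolated mass coefficient (cm2/g) at ``energy`` keV."""
    return table.lookup(energy, channel)


def mixture_table(components: list[tuple[XsTable, float]],
                  name: str = "mixture") -> XsTable:
    """Mass-fraction-weighted mixture of component tables.

    Components are resampled onto the first component's grid; every
    coefficient of the result is the weighted sum of the components'.
    """
    if not components:
        raise ValueError("mixture needs at least one component")
    total = sum(w for _, w in components)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mixture fractions sum to {total}, not 1")
    grid = components[0][0].energy_grid
    acc = {c: np.zeros_like(grid) for c in CHANNELS}
    for tab, w in components:
        t = tab if tab.energy_grid is grid or (
            len(tab.energy_grid) == len(grid)
            and np.allclose(tab.energy_grid, grid)) else tab.resample(grid)
        acc["photoelectric"] += w * t.mu_rho_photoelectric
        acc["compton"] += w * t.mu_rho_compton
        acc["rayleigh"] += w * t.mu_rho_rayleigh
        acc["total"] += w * t.mu_rho_total
        acc["muen"] += w * t.muen_rho
    return XsTable(
        material=name, energy_grid=grid.copy(),
        mu_rho_photoelectric=acc["photoelectric"],
        mu_rho_compton=acc["compton"],
        mu_rho_rayleigh=acc["rayleigh"],
        mu_rho_total=acc["total"],
        muen_rho=acc["muen"],
    )


def sample_emission(spectrum: EmissionSpectrum, rng: np.random.Generator,
                    size=None):
    """Sample line energies with probability proportional to intensity."""
    p = spectrum.intensities / spectrum.intensities.sum()
    out = rng.choice(spectrum.energies, size=size, p=p)
    return float(out) if size is None else out


# ---------------------------------------------------------------------------
# Package-data loaders
# ---------------------------------------------------------------------------

def _data_path(fname: str):
    return importlib.resources.files("brachymc").joinpath("data", fname)


def available_materials() -> list[str]:
    root = importlib.resources.files("brachymc").joinpath("data")
    return sorted(p.name[:-4] for p in root.iterdir()
                  if p.name.endswith(".txt") and "spectrum" not in p.name)


def _parse_header(text: str) -> dict:
    meta = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if ":" in body:
            key, _, val = body.partition(":")
            key = key.strip()
            if key in ("material", "density_g_cm3", "composition", "spectrum",
                       "total_yield_per_decay"):
                meta[key] = val.strip()
    return meta


@lru_cache(maxsize=None)
def load_table(name: str) -> XsTable:
    """Load a shipped coefficient table by material name (cached)."""
    try:
        text = _data_path(f"{name}.txt").read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no shipped coefficient table for {name!r}; available: "
            f"{available_materials()}") from None
    arr = np.loadtxt(text.splitlines())
    return XsTable(
        material=name, energy_grid=arr[:, 0],
        mu_rho_photoelectric=arr[:, 1], mu_rho_compton=arr[:, 2],
        mu_rho_rayleigh=arr[:, 3], mu_rho_total=arr[:, 4], muen_rho=arr[:, 5],
    )


@lru_cache(maxsize=None)
def load_material(name: str) -> Material:
    text = _data_path(f"{name}.txt").read_text()
    meta = _parse_header(text)
    comp = tuple(
        (tok.split(":")[0], float(tok.split(":")[1]))
        for tok in meta["composition"].split())
    return Material(name=name, composition=comp,
                    density=float(meta["density_g_cm3"]))


@lru_cache(maxsize=None)
def load_spectrum(name: str = "ir192") -> EmissionSpectrum:
    text = _data_path(f"{name}_spectrum.txt").read_text()
    meta = _parse_header(text)
    arr = np.loadtxt(text.splitlines())
    lines = tuple((float(e), float(i)) for e, i in arr)
    return EmissionSpectrum(
        lines=lines, total_yield=float(meta["total_yield_per_decay"]))


# ---------------------------------------------------------------------------
# Atomic form factors (coherent-scattering angular shape)
# ---------------------------------------------------------------------------

_TF_LENGTH = 0.4685  # Thomas-Fermi screening radius prefactor, Angstrom


def form_factor_squared(material: Material, x: np.ndarray) -> np.ndarray:
    """Squared molecular form factor at momentum transfer ``x`` (1/Angstrom).

    Independent-atom sum of screened (Thomas-Fermi-like) atomic form factors
    F(x, Z) = Z [1 + (4 pi a_TF x)^2]^(-3/2); only the *shape* matters (it
    normalizes away in sampling), the coherent cross section itself comes
    from the shipped tables.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for sym, w in material.composition:
        z, a = ELEMENTS[sym]
        n = w / a
        atf = _TF_LENGTH * z ** (-1.0 / 3.0)
        f = z * (1.0 + (4.0 * np.pi * atf * x) ** 2) ** -1.5
        out += n * f * f
    return out
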