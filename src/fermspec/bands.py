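"""Pure-component band models and Beer-Lambert superposition.

Mid-infrared absorption bands of small molecules in aqueous or dry-film
samples are well approximated by Gaussian or Lorentzian profiles
parameterised by centre wavenumber, full width at half maximum (FWHM) and
peak height.  A component (glucose, citric acid, water, lipid, ...) is a
named list of such bands; a spectrum of a mixture is the concentration-
weighted sum of the component spectra (Beer-Lambert law).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Band:
    """One vibrational band.

    ``height`` is the peak absorbance (AU) contributed when the parent
    component is present at its library reference concentration, undiluted,
    at unit pathlength factor.
    """

    center: float  # cm^-1
    fwhm: float  # cm^-1
    height: float  # AU at the component's reference concentration
    shape: str = "gaussian"  # or "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.height < 0:
            raise ValueError("height must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate the band on a wavenumber grid."""
        x = (np.asarray(grid, dtype=float) - self.center) / self.fwhm
        if self.shape == "gaussian":
            return self.height * np.exp(-4.0 * np.log(2.0) * x * x)
        return self.height / (1.0 + 4.0 * x * x)


def build_pure_spectrum(bands: list[Band], grid: np.ndarray) -> np.ndarray:
    """Additive superposition of band profiles on ``grid``.

    An isolated band contributes exactly ``height`` at its centre and
    ``height / 2`` at ``center +/- fwhm / 2``.  Bands centred outside the
    grid raise a warning and contribute only their tail.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavenumber grid")
    d = np.diff(grid)
    if grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("grid must be strictly monotone")
    out = np.zeros_like(grid)
    lo, hi = min(grid[0], grid[-1]), max(grid[0], grid[-1])
    for band in bands:
        if not (lo <= band.center <= hi):
            warnings.warn(
                f"band centred at {band.center:g} cm^-1 lies outside the grid "
                f"[{lo:g}, {hi:g}]; only its tail contributes",
                stacklevel=2,
            )
        out += band.profile(grid)
    return out


@dataclass
class ComponentLibrary:
    """Named pure components with band lists, molar masses and the
    reference concentrations (g/L) at which band heights are defined.

    Components without a reference concentration (water, background) are
    added to synthetic spectra at a fixed weight rather than scaled by a
    profile concentration.
    """

    components: dict[str, list[Band]] = field(default_factory=dict)
    molar_mass: dict[str, float] = field(default_factory=dict)
    reference_concentration: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, bands in self.components.items():
            if not bands:
                raise ValueError(f"component {name!r} has no bands")
        for name, m in self.molar_mass.items():
            if m <= 0:
                raise ValueError(f"molar mass of {name!r} must be positive")

    def spectrum(self, name: str, grid: np.ndarray) -> np.ndarray:
        if name not in self.components:
            raise KeyError(f"component {name!r} not in library")
        return build_pure_spectrum(self.components[name], grid)

    def molar(self, name: str, grams_per_liter: float) -> float:
        """Convert g/L to mol/L using the stored molar mass."""
        return grams_per_liter / self.molar_mass[name]


def default_library() -> ComponentLibrary:
    """Band library for fungal fermentation supernatants.

    Glucose: pyranose-ring / C-O fingerprint bands at 1200-900 cm^-1 with
    FWHM 30-40 cm^-1 and the principal peak at 1035 cm^-1.  Citric acid:
    acid C=O stretch at 1725 cm^-1 plus C-O/C-C bands at 1500-1000 cm^-1.
    Water: broad O-H stretch / bend / libration bands (FWHM 100-400 cm^-1).
    Lipid: C-H stretch, ester C=O and acyl-chain bands.  ``background``
    lumps the remaining medium constituents (yeast extract, salts) into a
    few very broad weak bands.

    Heights are calibrated so that undiluted glucose at its 80 g/L
    reference gives a 0.5 AU peak at 1035 cm^-1 — a plausible mid-range
    absorbance for a transmission/ATR measurement.
    """
    g = "gaussian"
    return ComponentLibrary(
        components={
            "glucose": [
                Band(1035.0, 35.0, 0.50, g),
                Band(1080.0, 35.0, 0.40, g),
                Band(1150.0, 30.0, 0.25, g),
                Band(995.0, 30.0, 0.20, g),
                Band(920.0, 40.0, 0.10, g),
            ],
            "citric_acid": [
                Band(1725.0, 45.0, 0.45, g),
                Band(1400.0, 40.0, 0.20, g),
                Band(1220.0, 40.0, 0.15, g),
                Band(1140.0, 35.0, 0.10, g),
                Band(1080.0, 35.0, 0.08, g),
            ],
            "water": [
                Band(3300.0, 400.0, 1.10, g),
                Band(2110.0, 250.0, 0.18, g),
                Band(1635.0, 120.0, 0.75, g),
                Band(580.0, 200.0, 0.55, g),
            ],
            "lipid": [
                Band(2925.0, 40.0, 0.30, g),
                Band(2855.0, 35.0, 0.20, g),
                Band(1745.0, 30.0, 0.35, g),
                Band(1460.0, 35.0, 0.12, g),
                Band(1160.0, 60.0, 0.10, g),
                Band(720.0, 25.0, 0.04, g),
            ],
            "background": [
                Band(1450.0, 900.0, 0.060, g),
                Band(1550.0, 120.0, 0.030, g),
                Band(1060.0, 500.0, 0.040, g),
            ],
        },
        molar_mass={"glucose": 180.16, "citric_acid": 192.12, "water": 18.015},
        reference_concentration={"glucose": 80.0, "citric_acid": 80.0},
    )
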