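"""Synthetic spectra acquisition: ATR and dry-film (HTS) measurement models.

A measured spectrum of one technical replicate is

    A(nu) = m * [ sum_c conc_c / (dilution * ref_c) * s_c(nu) ]  (+ water)
            + baseline(nu) + eps(nu)

where ``s_c`` is the pure-component spectrum at the library reference
concentration ``ref_c``, ``m`` is a per-replicate multiplicative pathlength
factor (mean 1), ``baseline`` a random quadratic drift and ``eps`` white
noise.  The two acquisition modes differ in their defaults:

* ATR: liquid on a crystal — water bands dominate, pathlength is controlled
  (no jitter), no dilution.
* HTS: 10x-diluted samples dried to films on a silicon microplate — water
  essentially absent, but film formation is irreproducible, giving a
  substantial multiplicative pathlength spread between replicates.

Medium constituents other than water (glucose, citric acid, background)
are diluted together with the sample; water, being the solvent, is not.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bands import ComponentLibrary, default_library
from .dataset import SpectralDataset
from .design import screening_design
from .kinetics import FermentationProfile

REFERENCE_COLUMNS = [
    "sample_id",
    "strain",
    "temperature",
    "day",
    "well_replicate",
    "sample_type",
    "glucose",
    "citric_acid",
]


@dataclass
class AcquisitionConfig:
    """Instrument/measurement settings for one synthetic acquisition run."""

    mode: str = "HTS"  # "ATR" or "HTS"
    grid_start: float = 4000.0  # cm^-1 (presentation order; stored ascending)
    grid_end: float = 500.0
    grid_spacing: float = 2.0
    dilution_factor: float = 10.0
    pathlength_jitter_sd: float = 0.10  # relative multiplicative sd
    baseline_drift_amplitude: float = 0.005  # AU
    noise_sd: float = 2e-4  # AU, typical 100%-line noise of a 64-scan measurement
    include_water: bool = False
    water_weight: float = 1.0
    background_weight: float = 1.0
    biological_cv: float = 0.02  # relative well-to-well concentration spread
    reference_noise_sd: float = 0.0  # optional additive "HPLC error", g/L
    technical_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ATR", "HTS"):
            raise ValueError("mode must be 'ATR' or 'HTS'")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.technical_replicates < 1:
            raise ValueError("technical_replicates must be >= 1")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")

    @classmethod
    def atr(cls, seed: int = 0, **overrides) -> "AcquisitionConfig":
        """Liquid-on-crystal defaults: water included, no dilution or jitter."""
        cfg = cls(
            mode="ATR",
            dilution_factor=1.0,
            pathlength_jitter_sd=0.0,
            baseline_drift_amplitude=0.01,
            noise_sd=2e-4,
            include_water=True,
            seed=seed,
        )
        return replace(cfg, **overrides)

    @classmethod
    def hts(cls, seed: int = 0, **overrides) -> "AcquisitionConfig":
        """Dry-film defaults: 10x dilution, 10% pathlength spread, no water."""
        cfg = cls(mode="HTS", seed=seed)
        return replace(cfg, **overrides)

    def grid(self) -> np.ndarray:
        """Strictly increasing wavenumber grid."""
        lo = min(self.grid_start, self.grid_end)
        hi = max(self.grid_start, self.grid_end)
        n = int(round((hi - lo) / self.grid_spacing)) + 1
        return lo + self.grid_spacing * np.arange(n)


def synthesize_dataset(
    library: ComponentLibrary | None,
    profiles: list[FermentationProfile],
    acq: AcquisitionConfig,
    design: pd.DataFrame | None = None,
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Generate spectra plus a reference-concentration table for a design.

    ``profiles`` must cover every (strain, temperature, day >= 1) in the
    design; medium samples (day 0) use the day-0 profile of their
    temperature.  Per-sample biological variability is applied to the
    concentrations *before* the spectra are computed, and the reference
    table records those actual concentrations (an optional additive
    reference-measurement noise can be enabled via
    ``acq.reference_noise_sd``).  Deterministic given ``acq.seed``.

    Returns ``(dataset, references)`` where ``references`` has one row per
    sample (not per technical replicate).
    """
    library = library if library is not None else default_library()
    if design is None:
        design = screening_design(include_biomass=False)
    design = design[design["sample_type"].isin(["medium", "supernatant"])]
    for comp in ("glucose", "citric_acid"):
        if comp not in library.components:
            raise KeyError(f"profiles require component {comp!r} missing from library")

    grid = acq.grid()
    pure = {name: library.spectrum(name, grid) for name in library.components}
    ref_conc = library.reference_concentration

    prof_map: dict[tuple, FermentationProfile] = {
        (p.strain, p.temperature, p.day): p for p in profiles
    }
    day0_by_temp: dict[float, FermentationProfile] = {}
    for p in profiles:
        if p.day == 0:
            day0_by_temp.setdefault(p.temperature, p)

    rng = np.random.default_rng(acq.seed)
    rows, ref_rows, spectra = [], [], []
    for sample in design.itertuples(index=False):
        if sample.sample_type == "medium":
            prof = day0_by_temp.get(sample.temperature)
            if prof is None:
                raise KeyError(f"no day-0 profile for temperature {sample.temperature}")
        else:
            key = (sample.strain, sample.temperature, sample.day)
            prof = prof_map.get(key)
            if prof is None:
                raise KeyError(f"no fermentation profile for condition {key}")

        bio = 1.0 + acq.biological_cv * rng.standard_normal(2)
        bio = np.clip(bio, 0.0, None)
        glucose = prof.glucose * bio[0]
        citric = prof.citric_acid * bio[1]

        # diluted component weights (water is the solvent, never diluted)
        signal = (
            glucose / (acq.dilution_factor * ref_conc["glucose"]) * pure["glucose"]
            + citric / (acq.dilution_factor * ref_conc["citric_acid"]) * pure["citric_acid"]
        )
        if "background" in pure:
            signal = signal + acq.background_weight / acq.dilution_factor * pure["background"]
        if acq.include_water:
            signal = signal + acq.water_weight * pure["water"]

        u = np.linspace(-1.0, 1.0, grid.size)
        for tech in range(1, acq.technical_replicates + 1):
            m = max(0.05, 1.0 + acq.pathlength_jitter_sd * rng.standard_normal())
            coeffs = rng.uniform(-1.0, 1.0, 3) * (acq.baseline_drift_amplitude / 3.0)
            baseline = coeffs[0] + coeffs[1] * u + coeffs[2] * u * u
            eps = rng.normal(0.0, acq.noise_sd, grid.size) if acq.noise_sd > 0 else 0.0
            spectra.append(m * signal + baseline + eps)
            rows.append(
                {
                    "spectrum_id": f"{sample.sample_id}_t{tech}",
                    "sample_id": sample.sample_id,
                    "strain": sample.strain,
                    "temperature": sample.temperature,
                    "day": sample.day,
                    "well_replicate": sample.well_replicate,
                    "technical_replicate": tech,
                    "sample_type": sample.sample_type,
                }
            )
        if acq.reference_noise_sd > 0:
            glucose = max(0.0, glucose + rng.normal(0.0, acq.reference_noise_sd))
            citric = max(0.0, citric + rng.normal(0.0, acq.reference_noise_sd))
        ref_rows.append(
            {
                "sample_id": sample.sample_id,
                "strain": sample.strain,
                "temperature": sample.temperature,
                "day": sample.day,
                "well_replicate": sample.well_replicate,
                "sample_type": sample.sample_type,
                "glucose": glucose,
                "citric_acid": citric,
            }
        )

    ds = SpectralDataset(
        grid=grid,
        absorbance=np.vstack(spectra),
        metadata=pd.DataFrame(rows),
    )
    references = pd.DataFrame(ref_rows, columns=REFERENCE_COLUMNS)
    return ds, references
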