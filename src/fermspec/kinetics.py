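"""Fermentation concentration profiles for the synthetic benchmark.

The generator mimics a 12-day batch cultivation of oleaginous filamentous
fungi on a glucose-rich medium: glucose is consumed from 80 g/L down to
single-digit g/L, and one acid-producing strain excretes citric acid that
rises during the first days and then plateaus around 7.5 g/L.

Functional forms are deliberately simple and smooth:

* glucose(t) = floor + (g0 - floor) * exp(-uptake_rate * t)   (monotone decay)
* citric(t)  = min(acid_yield * consumed(t), acid_plateau)    (producers only)

i.e. the acid tracks a fixed fraction of the glucose consumed until it
saturates at the plateau, after which it remains stable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FermentationProfile:
    """Reference concentrations for one (strain, temperature, day)."""

    strain: str
    temperature: float  # degrees C
    day: int  # 0 = starting growth medium
    glucose: float  # g/L
    citric_acid: float  # g/L

    def __post_init__(self) -> None:
        if self.glucose < 0 or self.citric_acid < 0:
            raise ValueError("concentrations must be non-negative")


def simulate_fermentation(
    initial_glucose: float = 80.0,
    uptake_rate: float = float(np.log(10.0) / 12.0),
    acid_yield: float = 0.15,
    acid_plateau: float = 7.5,
    producer: bool = True,
    days: int = 12,
    glucose_floor: float = 0.0,
    strain: str = "strain",
    temperature: float = 30.0,
) -> list[FermentationProfile]:
    """Daily glucose/citric-acid profiles for one cultivation condition.

    Parameters
    ----------
    initial_glucose : g/L at day 0 (the starting growth medium).
    uptake_rate : 1/day exponential decay rate of glucose towards
        ``glucose_floor``.  The default empties 80 g/L to 8 g/L by day 12.
    acid_yield : g citric acid produced per g glucose consumed, before the
        plateau is reached.
    acid_plateau : g/L ceiling at which citric acid stabilises (reached
        around day 5-6 with the defaults).
    producer : whether this strain excretes citric acid at all.
    days : final cultivation day (profiles cover day 0 .. days).

    Returns
    -------
    list of :class:`FermentationProfile`, one per day including day 0.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    for name, v in [
        ("initial_glucose", initial_glucose),
        ("uptake_rate", uptake_rate),
        ("acid_yield", acid_yield),
        ("acid_plateau", acid_plateau),
        ("glucose_floor", glucose_floor),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    profiles = []
    for day in range(days + 1):
        glucose = glucose_floor + (initial_glucose - glucose_floor) * np.exp(
            -uptake_rate * day
        )
        consumed = initial_glucose - glucose
        citric = min(acid_yield * consumed, acid_plateau) if producer else 0.0
        profiles.append(
            FermentationProfile(strain, temperature, day, float(glucose), float(citric))
        )
    return profiles


def default_profiles(
    strains: tuple[str, ...] = ("M. circinelloides", "U. isabellina", "P. glabrum"),
    temperatures: tuple[float, ...] = (20.0, 30.0),
    producer_strain: str = "P. glabrum",
    initial_glucose: float = 80.0,
    days: int = 12,
) -> list[FermentationProfile]:
    """Profiles for the full screening design (3 strains x 2 temperatures).

    Uptake rates vary modestly by strain and temperature (faster at 30 degC)
    so conditions are distinguishable, as in a real screen.  The producer
    strain plateaus at 7.5 g/L citric acid at 20 degC and 6.5 g/L at 30 degC.
    """
    strain_factor = {s: f for s, f in zip(strains, (1.0, 0.95, 1.05))}
    temp_factor = {temperatures[0]: 0.90, temperatures[1]: 1.10}
    plateau = {temperatures[0]: 7.5, temperatures[1]: 6.5}
    base_rate = np.log(10.0) / days
    out: list[FermentationProfile] = []
    for strain in strains:
        for temp in temperatures:
            out.extend(
                simulate_fermentation(
                    initial_glucose=initial_glucose,
                    uptake_rate=base_rate
                    * strain_factor.get(strain, 1.0)
                    * temp_factor.get(temp, 1.0),
                    acid_plateau=plateau.get(temp, 7.5),
                    producer=(strain == producer_strain),
                    days=days,
                    strain=strain,
                    temperature=temp,
                )
            )
    return out
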