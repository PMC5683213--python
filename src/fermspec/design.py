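"""Sampling design of the high-throughput fungal screening study.

Three oleaginous fungi (M. circinelloides, U. isabellina, P. glabrum) are
cultivated at 20 and 30 degC in microtiter deep-well plates for 12 days.
Each day, the supernatant of three parallel wells (biological replicates)
per strain and temperature is sampled, giving 3 x 2 x 12 x 3 = 216
supernatant samples, plus 6 starting-growth-medium samples (three bottles
per temperature).  Every sample is measured in three technical replicates,
giving 648 supernatant and 18 medium spectra.  Biomass is sampled from the
same wells except for the two slow-growing strain/temperature combinations
on day 1 (210 samples, 630 spectra).
"""
from __future__ import annotations

import pandas as pd

STRAINS = ("M. circinelloides", "U. isabellina", "P. glabrum")
STRAIN_CODES = {"M. circinelloides": "Mc", "U. isabellina": "Ui", "P. glabrum": "Pg"}
TEMPERATURES = (20.0, 30.0)
DAYS = tuple(range(1, 13))
WELLS = (1, 2, 3)
PRODUCER_STRAIN = "P. glabrum"
#: strain/temperature combinations with no biomass sample on day 1
BIOMASS_DAY1_OMITTED = (("U. isabellina", 20.0), ("P. glabrum", 20.0))

SAMPLE_COLUMNS = ["sample_id", "strain", "temperature", "day", "well_replicate", "sample_type"]


def screening_design(include_biomass: bool = False) -> pd.DataFrame:
    """Sample-level design table (one row per physical sample, no spectra).

    Returns a DataFrame with columns ``sample_id, strain, temperature, day,
    well_replicate, sample_type``.  Medium rows have ``day == 0`` and a
    missing strain.  With ``include_biomass`` the 210-sample biomass design
    is appended.
    """
    rows = []
    for temp in TEMPERATURES:
        for well in WELLS:
            rows.append(
                {
                    "sample_id": f"med_{temp:g}C_b{well}",
                    "strain": pd.NA,
                    "temperature": temp,
                    "day": 0,
                    "well_replicate": well,
                    "sample_type": "medium",
                }
            )
    for strain in STRAINS:
        code = STRAIN_CODES[strain]
        for temp in TEMPERATURES:
            for day in DAYS:
                for well in WELLS:
                    rows.append(
                        {
                            "sample_id": f"sup_{code}_{temp:g}C_d{day:02d}_w{well}",
                            "strain": strain,
                            "temperature": temp,
                            "day": day,
                            "well_replicate": well,
                            "sample_type": "supernatant",
                        }
                    )
    if include_biomass:
        for strain in STRAINS:
            code = STRAIN_CODES[strain]
            for temp in TEMPERATURES:
                for day in DAYS:
                    if day == 1 and (strain, temp) in BIOMASS_DAY1_OMITTED:
                        continue
                    for well in WELLS:
                        rows.append(
                            {
                                "sample_id": f"bio_{code}_{temp:g}C_d{day:02d}_w{well}",
                                "strain": strain,
                                "temperature": temp,
                                "day": day,
                                "well_replicate": well,
                                "sample_type": "biomass",
                            }
                        )
    df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    if df["sample_id"].duplicated().any():
        raise AssertionError("design produced duplicate sample ids")
    return df


def design_counts(include_biomass: bool = True, technical_replicates: int = 3) -> dict:
    """Printed totals of the design: samples and spectra per sample type."""
    design = screening_design(include_biomass=include_biomass)
    counts = design["sample_type"].value_counts().to_dict()
    out = {}
    for stype in ("medium", "supernatant", "biomass"):
        if stype in counts:
            out[f"{stype}_samples"] = int(counts[stype])
            out[f"{stype}_spectra"] = int(counts[stype] * technical_replicates)
    return out
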