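"""Core container for stacks of infrared spectra with per-spectrum metadata."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Metadata columns every dataset carries.  ``spectrum_id`` is unique per row;
#: ``sample_id`` is shared by technical replicates of one physical sample.
METADATA_COLUMNS = (
    "spectrum_id",
    "sample_id",
    "strain",
    "temperature",
    "day",
    "well_replicate",
    "technical_replicate",
    "sample_type",
)


@dataclass
class SpectralDataset:
    """Spectra on a shared wavenumber grid.

    Parameters
    ----------
    grid : ndarray, shape (p,)
        Wavenumbers in cm^-1, strictly increasing.  FTIR files are
        conventionally written high-to-low; flip before constructing
        (the readers in :mod:`fermspec.io` do this automatically).
    absorbance : ndarray, shape (n, p)
        Absorbance in AU, one row per spectrum.  No missing values.
    metadata : DataFrame, n rows
        One row per spectrum; see :data:`METADATA_COLUMNS`.
    """

    grid: np.ndarray
    absorbance: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.grid.ndim != 1 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 1-D array of wavenumbers")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError(
                "grid must be strictly increasing; reverse a descending grid "
                "(and the absorbance columns) before constructing"
            )
        if self.absorbance.shape[1] != self.grid.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {self.grid.size} points"
            )
        if len(self.metadata) != self.absorbance.shape[0]:
            raise ValueError(
                f"metadata has {len(self.metadata)} rows but absorbance has "
                f"{self.absorbance.shape[0]} spectra"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains NaN or infinite values")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.size

    def with_values(
        self,
        absorbance: np.ndarray | None = None,
        grid: np.ndarray | None = None,
        metadata: pd.DataFrame | None = None,
    ) -> "SpectralDataset":
        """Return a new dataset with some fields replaced (others shared)."""
        return SpectralDataset(
            grid=self.grid if grid is None else grid,
            absorbance=self.absorbance if absorbance is None else absorbance,
            metadata=self.metadata if metadata is None else metadata,
        )

    def subset(self, mask_or_indices) -> "SpectralDataset":
        """Select spectra by boolean mask or integer indices."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectralDataset(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
        )
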