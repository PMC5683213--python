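"""Spectral preprocessing: region selection, baseline offset, Savitzky-Golay
derivatives, technical-replicate averaging, SNV and EMSC normalisation.

Two frozen plans mirror the supernatant analysis tracks:

* ``atr_media`` — 1900-700 cm^-1 region, per-spectrum baseline offset.
  ATR pathlength is controlled, so nothing more is needed.
* ``hts_media`` — 1900-700 cm^-1 region, Savitzky-Golay second derivative
  (window 15 points, polynomial order 2), then averaging of technical
  replicates.  Differentiation removes additive baselines and averaging
  damps the film-to-film pathlength spread of dry-film measurements.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .dataset import SpectralDataset


def select_region(ds: SpectralDataset, low: float, high: float) -> SpectralDataset:
    """Keep grid points inside ``[low, high]`` inclusive (either order).

    Spectroscopic convention quotes regions high-to-low ("1900-700");
    both orders are accepted.
    """
    lo, hi = (low, high) if low <= high else (high, low)
    mask = (ds.grid >= lo) & (ds.grid <= hi)
    if not mask.any():
        raise ValueError(
            f"region [{lo:g}, {hi:g}] cm^-1 does not overlap the grid "
            f"[{ds.grid[0]:g}, {ds.grid[-1]:g}]"
        )
    return ds.with_values(grid=ds.grid[mask], absorbance=ds.absorbance[:, mask])


def baseline_offset(ds: SpectralDataset) -> SpectralDataset:
    """Subtract each spectrum's minimum so its minimum becomes exactly 0."""
    mins = ds.absorbance.min(axis=1, keepdims=True)
    return ds.with_values(absorbance=ds.absorbance - mins)


def savitzky_golay(
    ds: SpectralDataset, window: int, polyorder: int, deriv: int = 0
) -> SpectralDataset:
    """Savitzky-Golay smoothing / differentiation on a uniform grid.

    Each point is replaced by the value (or ``deriv``-th derivative, taken
    with respect to wavenumber, i.e. scaled by the grid spacing) of a local
    least-squares polynomial of order ``polyorder`` fitted over a centred
    window of ``window`` grid points.  The ``(window - 1) / 2`` edge points
    on each side, whose windows are incomplete, are dropped rather than
    padded: padding invents data and biases derivatives near region edges.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if deriv < 0 or deriv > polyorder:
        raise ValueError("deriv must satisfy 0 <= deriv <= polyorder")
    spacing = np.diff(ds.grid)
    if not np.allclose(spacing, spacing[0], rtol=1e-8, atol=0.0):
        raise ValueError(
            "Savitzky-Golay requires a uniformly spaced grid; interpolate "
            "onto a uniform grid first"
        )
    if ds.n_points < window:
        raise ValueError("fewer grid points than the filter window")
    out = savgol_filter(
        ds.absorbance, window, polyorder, deriv=deriv, delta=float(spacing[0]), axis=1
    )
    half = window // 2
    return ds.with_values(grid=ds.grid[half:-half], absorbance=out[:, half:-half])


def average_technical_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Average spectra sharing a ``sample_id``; one output spectrum each.

    Metadata is collapsed to one row per sample with the technical
    replicate field cleared and ``spectrum_id`` set to the sample id.
    """
    if "sample_id" not in ds.metadata.columns:
        raise ValueError("metadata lacks a sample_id column")
    sample_ids = ds.metadata["sample_id"]
    order = sample_ids.drop_duplicates().tolist()
    rows, spectra = [], []
    groups = ds.metadata.groupby("sample_id", sort=False).indices
    for sid in order:
        idx = groups[sid]
        spectra.append(ds.absorbance[idx].mean(axis=0))
        row = ds.metadata.iloc[idx[0]].copy()
        row["spectrum_id"] = sid
        row["technical_replicate"] = pd.NA
        rows.append(row)
    meta = pd.DataFrame(rows).reset_index(drop=True)
    return ds.with_values(absorbance=np.vstack(spectra), metadata=meta)


def snv(ds: SpectralDataset) -> SpectralDataset:
    """Standard normal variate: centre each spectrum to mean 0, scale to
    unit standard deviation (ddof=1).  Removes per-spectrum affine
    (pathlength + offset) effects."""
    if ds.n_points < 3:
        raise ValueError("SNV needs at least 3 grid points")
    mean = ds.absorbance.mean(axis=1, keepdims=True)
    sd = ds.absorbance.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a zero-variance spectrum")
    return ds.with_values(absorbance=(ds.absorbance - mean) / sd)


def emsc(ds: SpectralDataset, reference_spectrum: np.ndarray) -> SpectralDataset:
    """Extended multiplicative signal correction against a reference.

    Each spectrum ``x`` is regressed on ``{reference, 1, u, u^2}`` (``u`` the
    wavenumber scaled to [-1, 1]); the corrected spectrum is
    ``(x - b0 - b1*u - b2*u^2) / m`` with ``m`` the reference coefficient.
    """
    reference = np.asarray(reference_spectrum, dtype=float)
    if reference.shape != ds.grid.shape:
        raise ValueError("reference spectrum must be on the dataset grid")
    if ds.n_points < 4:
        raise ValueError("EMSC needs at least 4 grid points")
    u = 2.0 * (ds.grid - ds.grid.mean()) / (ds.grid[-1] - ds.grid[0])
    design = np.column_stack([reference, np.ones_like(u), u, u * u])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("degenerate EMSC regression (reference collinear with baseline)")
    coef, *_ = np.linalg.lstsq(design, ds.absorbance.T, rcond=None)
    m = coef[0]
    if np.any(np.abs(m) < 1e-12):
        raise ValueError("EMSC multiplicative coefficient is (near) zero")
    baseline = design[:, 1:] @ coef[1:]
    corrected = (ds.absorbance - baseline.T) / m[:, None]
    return ds.with_values(absorbance=corrected)


@dataclass(frozen=True)
class PreprocessPlan:
    """An ordered preprocessing recipe: region -> baseline -> derivative ->
    normalisation -> replicate averaging."""

    name: str = "custom"
    region: tuple[float, float] = (1900.0, 700.0)
    baseline: str = "none"  # "offset" or "none"
    sg_window: int | None = None  # odd, in grid points
    sg_polyorder: int = 2
    sg_deriv: int = 2
    average_replicates: bool = False
    normalization: str = "none"  # "none", "snv" or "emsc"

    def __post_init__(self) -> None:
        if self.baseline not in ("offset", "none"):
            raise ValueError("baseline must be 'offset' or 'none'")
        if self.normalization not in ("none", "snv", "emsc"):
            raise ValueError("normalization must be 'none', 'snv' or 'emsc'")
        if self.sg_window is not None:
            if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
                raise ValueError("sg_window must be odd and > sg_polyorder")
            if self.sg_deriv > self.sg_polyorder:
                raise ValueError("sg_deriv must be <= sg_polyorder")

    def apply(
        self, ds: SpectralDataset, emsc_reference: np.ndarray | None = None
    ) -> SpectralDataset:
        ds = select_region(ds, *self.region)
        if self.baseline == "offset":
            ds = baseline_offset(ds)
        if self.sg_window is not None:
            ds = savitzky_golay(ds, self.sg_window, self.sg_polyorder, self.sg_deriv)
        if self.normalization == "snv":
            ds = snv(ds)
        elif self.normalization == "emsc":
            if emsc_reference is None:
                raise ValueError("EMSC plan requires a reference spectrum")
            ds = emsc(ds, emsc_reference)
        if self.average_replicates:
            ds = average_technical_replicates(ds)
        return ds

    def describe(self) -> dict:
        """Plain-dict snapshot for manifests and provenance sidecars."""
        return {
            "name": self.name,
            "region_cm1": list(self.region),
            "baseline": self.baseline,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder if self.sg_window else None,
            "sg_deriv": self.sg_deriv if self.sg_window else None,
            "normalization": self.normalization,
            "average_replicates": self.average_replicates,
        }


ATR_MEDIA = PreprocessPlan(name="atr_media", baseline="offset")
HTS_MEDIA = PreprocessPlan(name="hts_media", sg_window=15, average_replicates=True)

PLANS = {p.name: p for p in (ATR_MEDIA, HTS_MEDIA)}
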