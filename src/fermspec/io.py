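"""File formats: wide-CSV spectra, metadata/reference CSV, JCAMP-DX (read),
JSON model documents and run manifests.

The primary exchange format is a wide CSV — first column the wavenumber,
one column per spectrum named by its spectrum id — which keeps a
hundreds-of-spectra dataset in a single human-readable file.  Descending
(instrument-convention) wavenumber order is accepted on read and is the
default on write; internally grids are always strictly increasing.
"""
from __future__ import annotations

import datetime
import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import PLSRModel
from .dataset import METADATA_COLUMNS, SpectralDataset


def write_spectra_csv(ds: SpectralDataset, path, descending: bool = True) -> None:
    """Write a dataset as wide CSV (column per spectrum).

    ``descending=True`` emits the conventional high-to-low wavenumber order.
    Metadata is not embedded; write it alongside with
    :func:`write_metadata_csv`.
    """
    ids = ds.metadata["spectrum_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError("spectrum_id values must be unique to write wide CSV")
    df = pd.DataFrame(ds.absorbance.T, columns=ids.tolist())
    df.insert(0, "wavenumber", ds.grid)
    if descending:
        df = df.iloc[::-1]
    df.to_csv(path, index=False)


def read_spectra_csv(path, metadata_path=None) -> SpectralDataset:
    """Read a wide-CSV spectra file (ascending or descending wavenumbers).

    If ``metadata_path`` is given, rows are matched to metadata by
    ``spectrum_id`` (the column headers); otherwise a minimal metadata
    table is reconstructed from the headers.  The original on-disk order is
    recorded in ``dataset.metadata.attrs["source_order"]``.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavenumber column plus >=1 spectrum")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data line {bad + 2}"
            )
    grid = df.iloc[:, 0].to_numpy(dtype=float)
    if pd.Series(grid).duplicated().any():
        raise ValueError(f"{path}: duplicated wavenumber rows")
    d = np.diff(grid)
    if np.all(d > 0):
        order = "ascending"
    elif np.all(d < 0):
        order = "descending"
        df = df.iloc[::-1]
        grid = grid[::-1]
    else:
        raise ValueError(f"{path}: wavenumber column is not monotone")

    ids = [str(c) for c in df.columns[1:]]
    if metadata_path is not None:
        meta = read_metadata_csv(metadata_path)
        meta = meta.set_index("spectrum_id").loc[ids].reset_index()
    else:
        meta = pd.DataFrame({"spectrum_id": ids})
        for col in METADATA_COLUMNS:
            if col not in meta.columns:
                meta[col] = pd.NA
        meta["sample_id"] = meta["spectrum_id"]
    ds = SpectralDataset(
        grid=grid, absorbance=df.iloc[:, 1:].to_numpy(dtype=float).T, metadata=meta
    )
    ds.metadata.attrs["source_order"] = order
    return ds


def write_metadata_csv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


def read_metadata_csv(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "spectrum_id" not in meta.columns:
        raise ValueError(f"{path}: metadata must contain a spectrum_id column")
    for col in ("day", "well_replicate", "technical_replicate"):
        if col in meta.columns:
            meta[col] = meta[col].astype("Int64")
    return meta


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only, uncompressed forms)

_SQZ_DIF_CHARS = set("@ABCDEFGHIabcdefghiJKLMNOPQRjklmnopqr%")


def _parse_labels(text: str) -> dict[str, str]:
    labels: dict[str, str] = {}
    current = None
    for line in text.splitlines():
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            current = key.strip().upper().replace(" ", "")
            labels[current] = value.strip()
        elif current is not None:
            labels[current] += "\n" + line
    return labels


def read_jcamp(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a single spectrum from an uncompressed JCAMP-DX file.

    Supports ``##XYDATA=(X++(Y..Y))`` and ``##XYPOINTS=(XY..XY)`` in AFFN
    (plain decimal) form.  SQZ/DIF/PAC-compressed ordinates are rejected
    with an explicit message.  Returns ``(wavenumbers, absorbance)`` in
    ascending wavenumber order.
    """
    text = Path(path).read_text()
    labels = _parse_labels(text)
    for required in ("TITLE", "XUNITS", "YUNITS"):
        if required not in labels:
            raise ValueError(f"{path}: missing required JCAMP label ##{required}=")

    if "XYDATA" in labels:
        body = labels["XYDATA"].split("\n")
        header, lines = body[0], [ln for ln in body[1:] if ln.strip()]
        if "X++" not in header.replace(" ", ""):
            raise ValueError(f"{path}: unsupported XYDATA variant {header!r}")
        for required in ("NPOINTS", "FIRSTX", "LASTX", "XFACTOR", "YFACTOR"):
            if required not in labels:
                raise ValueError(f"{path}: missing required JCAMP label ##{required}=")
        # AFFN (whitespace-separated) and PAC (sign-delimited) numbers
        number = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")
        joined = " ".join(lines)
        leftover = number.sub("", joined)
        if any(c in _SQZ_DIF_CHARS for c in leftover):
            raise ValueError(
                f"{path}: SQZ/DIF-compressed JCAMP ordinates are not supported; "
                "export the file in AFFN (plain decimal) form"
            )
        xfac, yfac = float(labels["XFACTOR"]), float(labels["YFACTOR"])
        npoints = int(float(labels["NPOINTS"]))
        ys = []
        for ln in lines:
            vals = [float(v) for v in number.findall(ln)]
            if len(vals) < 2:
                raise ValueError(f"{path}: XYDATA line with no ordinates: {ln!r}")
            ys.append([v * yfac for v in vals[1:]])
        firstx, lastx = float(labels["FIRSTX"]), float(labels["LASTX"])
        y = np.array([v for line in ys for v in line])
        if y.size != npoints:
            raise ValueError(
                f"{path}: NPOINTS={npoints} but {y.size} ordinates were read"
            )
        x = np.linspace(firstx, lastx, npoints)
    elif "XYPOINTS" in labels:
        body = labels["XYPOINTS"].split("\n")
        pairs = " ".join(ln for ln in body[1:] if ln.strip())
        pairs = pairs.replace(";", " ").replace(",", " ")
        vals = [float(v) for v in pairs.split()]
        if len(vals) % 2:
            raise ValueError(f"{path}: XYPOINTS has an odd number of values")
        x = np.array(vals[0::2])
        y = np.array(vals[1::2])
    else:
        raise ValueError(f"{path}: missing required JCAMP label ##XYDATA= or ##XYPOINTS=")

    order = np.argsort(x)
    return x[order], y[order]


def write_jcamp(path, x: np.ndarray, y: np.ndarray, title: str = "spectrum") -> None:
    """Write one spectrum as a minimal AFFN XYPOINTS JCAMP-DX file."""
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##NPOINTS={len(x)}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [f"{xi:.6f}, {yi:.8g}" for xi, yi in zip(x, y)]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Model serialisation and run manifests


def save_model(model: PLSRModel, path, plan: dict | None = None, analyte: str | None = None) -> None:
    """Serialise a fitted PLS1 model to a JSON document."""
    doc = {
        "format": "fermspec-plsr",
        "version": 1,
        "analyte": analyte,
        "plan": plan,
        "n_components": model.n_components,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "x_weights": model.x_weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "grid": None if model.grid is None else model.grid.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> tuple[PLSRModel, dict]:
    """Load a model document; returns (model, document-metadata)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "fermspec-plsr":
        raise ValueError(f"{path}: not a fermspec PLSR model document")
    model = PLSRModel(
        n_components=doc["n_components"],
        x_mean=np.asarray(doc["x_mean"], dtype=float),
        y_mean=float(doc["y_mean"]),
        x_weights=np.asarray(doc["x_weights"], dtype=float),
        x_loadings=np.asarray(doc["x_loadings"], dtype=float),
        x_scores=np.empty((0, doc["n_components"])),
        y_loadings=np.asarray(doc["y_loadings"], dtype=float),
        grid=None if doc.get("grid") is None else np.asarray(doc["grid"], dtype=float),
    )
    return model, {k: doc.get(k) for k in ("analyte", "plan", "version")}


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, command: str, params: dict, inputs: list, outputs: list) -> None:
    """Record a run: parameters plus SHA-256 digests of inputs and outputs."""
    from . import __version__

    manifest = {
        "command": command,
        "fermspec_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": params,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
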