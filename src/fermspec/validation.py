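"""Validation schemes for calibration models.

Replicates of one cultivation condition (same strain, temperature and day)
share correlated biology and measurement artefacts, so random-split
cross-validation leaks information.  Here CV folds are *segments* defined
by the experimental grouping — supernatant spectra per (strain,
temperature, day), starting-growth-medium spectra per temperature — and
independent-test validation holds out an entire strain x temperature
condition (by default the citric-acid producer at 30 degC).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import (
    ValidationMetrics,
    compute_metrics,
    fit_plsr,
    select_a_opt,
)
from .dataset import SpectralDataset
from .design import PRODUCER_STRAIN
from .preprocess import PLANS, PreprocessPlan

SEGMENT_KEYS = ("strain", "temperature", "day", "sample_type")


@dataclass
class SegmentAssignment:
    """Cross-validation segment label per spectrum."""

    labels: pd.Series  # aligned with the metadata index
    keys: tuple[str, ...] = SEGMENT_KEYS

    @property
    def n_segments(self) -> int:
        return self.labels.nunique()

    def ordered_segments(self) -> list[str]:
        return sorted(self.labels.unique())


def build_segments(metadata: pd.DataFrame) -> SegmentAssignment:
    """Group spectra into CV segments by cultivation condition.

    Supernatant (and biomass) spectra are grouped per (strain, temperature,
    day); starting-growth-medium spectra per temperature.  All technical
    and biological replicates of a condition land in the same segment.
    """
    missing = [k for k in SEGMENT_KEYS if k not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks segment key columns: {missing}")
    labels = []
    for row in metadata.itertuples(index=False):
        if row.sample_type == "medium":
            labels.append(f"med|{row.temperature:g}")
        else:
            labels.append(
                f"{row.sample_type[:3]}|{row.strain}|{row.temperature:g}|d{row.day:02d}"
            )
    return SegmentAssignment(labels=pd.Series(labels, index=metadata.index))


@dataclass
class CVResult:
    """Pooled segmented cross-validation output."""

    rmsecv: np.ndarray  # (A_max,), pooled over held-out predictions
    rmsecv_se: np.ndarray  # (A_max,), segment-level standard error of RMSECV
    predictions: np.ndarray  # (n, A_max) held-out predictions
    segment_labels: np.ndarray  # (n,)
    n_segments: int


def segmented_cross_validation(
    X: np.ndarray,
    y: np.ndarray,
    segments: SegmentAssignment | pd.Series,
    a_max: int,
) -> CVResult:
    """Leave-one-segment-out CV of PLS1 over component counts 1..a_max.

    For every held-out segment a model is fitted on the remaining segments
    (centring recomputed on the training fold only) and the held-out
    spectra are predicted for each component count.  RMSECV is pooled over
    all held-out predictions.  Folds iterate in sorted segment order, so
    the procedure is fully deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    labels = segments.labels if isinstance(segments, SegmentAssignment) else segments
    labels = np.asarray(labels)
    if labels.size != X.shape[0] or y.size != X.shape[0]:
        raise ValueError("X, y and segment labels must be aligned")
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise ValueError("segmented CV needs at least 2 segments")
    if a_max < 1:
        raise ValueError("a_max must be >= 1")

    n = X.shape[0]
    preds = np.full((n, a_max), np.nan)
    covered = np.zeros(n, dtype=bool)
    for seg in unique:
        test = labels == seg
        train = ~test
        if not train.any():
            raise ValueError(f"segment {seg!r} contains every sample")
        # leakage guard: a condition must never straddle train and test
        assert not np.any(test & train)
        model = fit_plsr(X[train], y[train], a_max)
        for a in range(1, a_max + 1):
            preds[test, a - 1] = model.predict(X[test], a)
        covered |= test
    assert covered.all(), "every spectrum must be held out exactly once"

    resid2 = (preds - y[:, None]) ** 2
    rmsecv = np.sqrt(resid2.mean(axis=0))
    # segment-level spread of the fold MSEs, propagated to the RMSE scale
    seg_mse = np.stack([resid2[labels == seg].mean(axis=0) for seg in unique])
    se_mse = seg_mse.std(axis=0, ddof=1) / np.sqrt(len(unique))
    rmsecv_se = se_mse / (2.0 * np.maximum(rmsecv, 1e-12))
    return CVResult(
        rmsecv=rmsecv,
        rmsecv_se=rmsecv_se,
        predictions=preds,
        segment_labels=labels,
        n_segments=len(unique),
    )


def independent_test_split(
    metadata: pd.DataFrame,
    holdout_strain: str | None,
    holdout_temperature: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Hold out every supernatant spectrum of one strain x temperature.

    Returns (train_indices, test_indices) into the metadata rows.  Medium
    spectra always stay in the training portion (inclusion of media in a
    model is decided upstream).  Passing ``None`` for both keys yields an
    empty test set.
    """
    if holdout_strain is None and holdout_temperature is None:
        idx = np.arange(len(metadata))
        return idx, np.array([], dtype=int)
    test = (
        (metadata["strain"] == holdout_strain)
        & (metadata["temperature"] == holdout_temperature)
        & (metadata["sample_type"] != "medium")
    ).to_numpy()
    if not test.any():
        raise ValueError(
            f"holdout condition ({holdout_strain!r}, {holdout_temperature!r}) "
            "not present in the metadata"
        )
    return np.flatnonzero(~test), np.flatnonzero(test)


@dataclass
class CalibrationReport:
    """Everything needed to reproduce and audit one calibration run."""

    analyte: str
    mode: str
    scheme: str  # "CV" or "ITV"
    metrics: ValidationMetrics
    rmsecv_curve: list[float]
    n_segments: int
    n_segments_design: int
    n_train: int
    n_test: int
    plan: dict
    predictions: pd.DataFrame = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "mode": self.mode,
            "scheme": self.scheme,
            "metrics": self.metrics.as_dict(),
            "rmsecv_curve": list(map(float, self.rmsecv_curve)),
            "n_segments": self.n_segments,
            "n_segments_design": self.n_segments_design,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "plan": self.plan,
        }


def _align_reference(metadata: pd.DataFrame, references: pd.DataFrame, analyte: str):
    if analyte not in references.columns:
        raise ValueError(f"analyte {analyte!r} not in the reference table")
    lookup = references.set_index("sample_id")[analyte]
    missing = set(metadata["sample_id"]) - set(lookup.index)
    if missing:
        raise ValueError(f"reference table lacks samples: {sorted(missing)[:5]} ...")
    return metadata["sample_id"].map(lookup).to_numpy(dtype=float)


def run_workflow(
    dataset: SpectralDataset,
    references: pd.DataFrame,
    analyte: str,
    mode: str,
    scheme: str = "CV",
    a_max: int = 10,
    tolerance: float = 0.02,
    holdout: tuple[str, float] | None = (PRODUCER_STRAIN, 30.0),
    producer_strain: str = PRODUCER_STRAIN,
    include_media: bool | None = None,
    reference_scale: float | None = None,
    plan: PreprocessPlan | None = None,
) -> CalibrationReport:
    """Full calibration workflow for one analyte and acquisition mode.

    Applies the mode's frozen preprocessing plan, restricts the spectra per
    the analyte rule (glucose: all strains, media excluded; citric acid:
    producer strain only, media included — both overridable via
    ``include_media``), then runs segmented CV and, for ``scheme="ITV"``,
    refits on the training portion (component count chosen by CV inside the
    training set) and evaluates on the held-out condition.
    """
    if analyte not in ("glucose", "citric_acid"):
        raise ValueError("analyte must be 'glucose' or 'citric_acid'")
    if scheme not in ("CV", "ITV"):
        raise ValueError("scheme must be 'CV' or 'ITV'")
    if plan is None:
        plan = PLANS["atr_media" if mode.upper() == "ATR" else "hts_media"]
    ds = plan.apply(dataset)
    n_segments_design = build_segments(ds.metadata).n_segments

    if include_media is None:
        include_media = analyte == "citric_acid"
    meta = ds.metadata
    keep = meta["sample_type"].isin(["supernatant"] + (["medium"] if include_media else []))
    if analyte == "citric_acid":
        keep &= (meta["strain"] == producer_strain) | (meta["sample_type"] == "medium")
    ds = ds.subset(keep.to_numpy())

    y = _align_reference(ds.metadata, references, analyte)
    X = ds.absorbance
    segments = build_segments(ds.metadata)

    if scheme == "CV":
        cv = segmented_cross_validation(X, y, segments, a_max)
        a_opt = select_a_opt(cv.rmsecv, tolerance)
        y_pred = cv.predictions[:, a_opt - 1]
        metrics = compute_metrics(y, y_pred, reference_scale, a_opt)
        pred_df = ds.metadata[["spectrum_id", "sample_id"]].copy()
        pred_df["segment"] = cv.segment_labels
        pred_df["y_true"] = y
        pred_df["y_pred"] = y_pred
        return CalibrationReport(
            analyte=analyte,
            mode=mode.upper(),
            scheme="CV",
            metrics=metrics,
            rmsecv_curve=cv.rmsecv.tolist(),
            n_segments=cv.n_segments,
            n_segments_design=n_segments_design,
            n_train=X.shape[0],
            n_test=0,
            plan=plan.describe(),
            predictions=pred_df,
        )

    if holdout is None:
        raise ValueError("ITV scheme requires a holdout condition")
    train_idx, test_idx = independent_test_split(ds.metadata, *holdout)
    if test_idx.size == 0:
        raise ValueError("ITV holdout selected no spectra")
    X_tr, y_tr = X[train_idx], y[train_idx]
    inner = segmented_cross_validation(
        X_tr, y_tr, segments.labels.iloc[train_idx], a_max
    )
    a_opt = select_a_opt(inner.rmsecv, tolerance)
    model = fit_plsr(X_tr, y_tr, a_opt)
    y_pred = model.predict(X[test_idx])
    metrics = compute_metrics(y[test_idx], y_pred, reference_scale, a_opt)
    pred_df = ds.metadata.iloc[test_idx][["spectrum_id", "sample_id"]].copy()
    pred_df["segment"] = segments.labels.iloc[test_idx].to_numpy()
    pred_df["y_true"] = y[test_idx]
    pred_df["y_pred"] = y_pred
    return CalibrationReport(
        analyte=analyte,
        mode=mode.upper(),
        scheme="ITV",
        metrics=metrics,
        rmsecv_curve=inner.rmsecv.tolist(),
        n_segments=inner.n_segments,
        n_segments_design=n_segments_design,
        n_train=int(train_idx.size),
        n_test=int(test_idx.size),
        plan=plan.describe(),
        predictions=pred_df.reset_index(drop=True),
    )
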