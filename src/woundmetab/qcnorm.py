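"""QC-based feature filtering and QC-anchored LOESS drift correction.

Pooled QC injections monitor instrument performance over the run.  Features
are kept only if (i) they are detected in at least 80% of QCs and (ii)
their QC relative standard deviation is at most 25% (both configurable).
Run-order drift is then removed per feature by regressing QC intensity on
injection order (locally weighted, tricube, degree 1) and dividing every
injection by the fitted trend, rescaled to the median fitted QC level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import FeatureTable, ValidationError


def qc_stats(table: FeatureTable) -> pd.DataFrame:
    """Per-feature QC presence fraction and QC RSD (%).

    RSD uses the sample (n-1) standard deviation over non-missing QC
    intensities and is NaN when fewer than 2 QC values are available.
    """
    qc = table.intensities[:, table.qc_mask()]
    if qc.shape[1] == 0:
        raise ValidationError("table contains no QC samples")
    present = ~np.isnan(qc)
    n_present = present.sum(axis=1)
    presence = n_present / qc.shape[1]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(present, qc, np.nan), axis=1)
        sd = np.full(qc.shape[0], np.nan)
        enough = n_present >= 2
        if enough.any():
            sd[enough] = np.nanstd(qc[enough], axis=1, ddof=1)
        rsd = np.where(enough & (mean > 0), sd / mean * 100.0, np.nan)
    return pd.DataFrame(
        {"qc_presence_fraction": presence, "qc_rsd": rsd},
        index=pd.Index(table.feature_ids, name="feature_id"),
    )


def qc_presence_filter(table: FeatureTable, min_fraction: float = 0.80) -> FeatureTable:
    """Keep features detected in at least ``min_fraction`` of QC injections."""
    stats = qc_stats(table)
    keep = (stats["qc_presence_fraction"] >= min_fraction).to_numpy()
    return table.subset_features(keep)


def qc_rsd_filter(table: FeatureTable, max_rsd_pct: float = 25.0,
                  keep: str = "below") -> FeatureTable:
    """Keep features whose QC RSD is at most ``max_rsd_pct`` percent.

    ``keep="below"`` (default, standard QC practice) retains precise
    features (RSD <= threshold, boundary retained); ``keep="above"``
    inverts the rule for the literal reading of the source protocol.
    """
    if keep not in ("below", "above"):
        raise ValidationError(f"keep must be 'below' or 'above', got {keep!r}")
    stats = qc_stats(table)
    rsd = stats["qc_rsd"].to_numpy()
    if np.isnan(rsd).any():
        bad = [fid for fid, v in zip(table.feature_ids, rsd) if np.isnan(v)]
        raise ValidationError(
            f"features with < 2 QC values reached the RSD filter (apply the "
            f"presence filter first): {bad[:5]}"
        )
    mask = rsd <= max_rsd_pct if keep == "below" else rsd > max_rsd_pct
    return table.subset_features(mask)


@dataclass
class LoessReport:
    """Bookkeeping from drift correction."""

    n_features_in: int = 0
    n_dropped_nonpositive_fit: int = 0
    dropped_feature_ids: list[str] = field(default_factory=list)
    qc_count: int = 0
    used_linear_fallback: bool = False


def _fit_trend(x_qc: np.ndarray, y_qc: np.ndarray, x_all: np.ndarray,
               span: float, min_qc_for_loess: int) -> np.ndarray:
    """Fitted drift trend at every injection position."""
    if x_qc.size < min_qc_for_loess:
        slope, intercept = np.polyfit(x_qc, y_qc, 1)
        return intercept + slope * x_all
    fitted = sm.nonparametric.lowess(
        y_qc, x_qc, frac=span, it=0, xvals=x_all, is_sorted=False,
    )
    return np.asarray(fitted, dtype=float)


def loess_drift_correct(
    table: FeatureTable,
    span: float = 0.75,
    min_qc_for_loess: int = 7,
) -> tuple[FeatureTable, LoessReport]:
    """Divide out per-feature run-order drift anchored on QC injections.

    For each feature the QC intensities are regressed on injection order
    (LOESS, degree 1, tricube weights, no robustness iterations; an
    ordinary least-squares line when fewer than ``min_qc_for_loess`` QC
    points are available).  Corrected intensity is
    ``raw * reference / fitted`` with the reference the median fitted
    value at QC positions, so corrected values stay on the original
    scale.  Features whose fitted trend is nonpositive anywhere a
    measurement exists are dropped and counted in the report.
    """
    qc_mask = table.qc_mask()
    n_qc = int(qc_mask.sum())
    if n_qc < 4:
        raise ValidationError(f"drift correction needs >= 4 QC samples, found {n_qc}")

    orders = table.injection_orders().astype(float)
    x_all = orders
    report = LoessReport(
        n_features_in=table.shape[0],
        qc_count=n_qc,
        used_linear_fallback=n_qc < min_qc_for_loess,
    )

    corrected = np.full_like(table.intensities, np.nan)
    keep = np.ones(table.shape[0], dtype=bool)
    for i, fid in enumerate(table.feature_ids):
        row = table.intensities[i]
        qc_vals = row[qc_mask]
        ok = ~np.isnan(qc_vals)
        x_qc = x_all[qc_mask][ok]
        y_qc = qc_vals[ok]
        if x_qc.size < 2:
            keep[i] = False
            report.dropped_feature_ids.append(fid)
            continue
        fitted = _fit_trend(x_qc, y_qc, x_all, span, min_qc_for_loess)
        measured = ~np.isnan(row)
        if np.any(fitted[measured] <= 0):
            keep[i] = False
            report.n_dropped_nonpositive_fit += 1
            report.dropped_feature_ids.append(fid)
            continue
        reference = float(np.median(fitted[qc_mask]))
        corrected[i] = row * reference / fitted
    out = table.with_intensities(corrected).subset_features(keep)
    return out, report
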