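"""QC-driven preprocessing for LC-MS feature tables.

The chain mirrors common practice for multi-batch plasma metabolomics:

1. ``filter_features`` — drop features whose HSQC (human-serum QC) replicate
   coefficient of variation is >= ``cv_max`` (default 0.3) or whose mean
   HSQC intensity is <= ``intensity_min`` (default 1e5). Both inequalities
   are strict in the keep direction (CV < 0.3, intensity > 1e5).
2. ``normalize_batchwise`` — divide each feature within each batch by the
   batch's HSQC median for that feature, removing multiplicative batch
   effects. A per-ten-sample variant is available as an alternative mode.
3. ``log_autoscale`` — natural log then per-feature standardization to zero
   mean / unit variance over biological samples (autoscaling).
4. ``impute_missing`` — replace missing cells by the feature mean over
   observed biological samples. Run last, so imputed values equal the
   feature's post-transform mean.

``preprocess`` composes the four steps; the whole chain is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureTable, RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "QcFilterReport",
    "compute_feature_cv",
    "filter_features",
    "normalize_batchwise",
    "log_autoscale",
    "impute_missing",
    "preprocess",
]


@dataclass
class QcFilterReport:
    """Per-feature QC decisions: CVs, pooled HSQC mean intensity, verdict."""

    table: pd.DataFrame  # index: feature id; columns: cv_<batch>..., cv_mean,
    #                      mean_intensity, passed, reason

    @property
    def kept(self) -> list[str]:
        return self.table.index[self.table["passed"]].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def compute_feature_cv(table: FeatureTable) -> pd.DataFrame:
    """Per-feature, per-batch CV over HSQC replicate injections.

    CV = sample (n-1) standard deviation / mean of that batch's HSQC
    intensities. Batches with fewer than two HSQC injections get NaN.
    """
    hsqc = table.role_mask("hsqc")
    if not hsqc.any():
        raise ValueError("table contains no HSQC samples; cannot compute QC CVs")
    batches = table.batches()
    out = pd.DataFrame(index=pd.Index(table.feature_ids, name="feature_id"),
                       columns=batches, dtype=float)
    batch_arr = np.asarray(table.batch)
    for b in batches:
        rows = table.intensities[hsqc & (batch_arr == b)]
        if rows.shape[0] < 2:
            out[b] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(rows, axis=0)
            sd = np.nanstd(rows, axis=0, ddof=1)
        cv = np.where(mean != 0, sd / mean, np.nan)
        out[b] = cv
    return out


def filter_features(
    table: FeatureTable, cv_max: float = 0.3, intensity_min: float = 1e5
) -> tuple[FeatureTable, QcFilterReport]:
    """Keep features reproducible in QC: mean per-batch HSQC CV < ``cv_max``
    and mean HSQC intensity > ``intensity_min`` (both strict)."""
    cv_table = compute_feature_cv(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv_mean = cv_table.mean(axis=1, skipna=True)
        hsqc_mean = np.nanmean(table.intensities[table.role_mask("hsqc")], axis=0)
    cv_ok = (cv_mean < cv_max).to_numpy() & cv_mean.notna().to_numpy()
    int_ok = hsqc_mean > intensity_min
    passed = cv_ok & int_ok

    reasons = np.where(
        passed, "",
        np.where(~cv_ok & ~int_ok, "cv>=cv_max;intensity<=intensity_min",
                 np.where(~cv_ok, "cv>=cv_max", "intensity<=intensity_min")))
    report = cv_table.add_prefix("cv_")
    report["cv_mean"] = cv_mean
    report["mean_intensity"] = hsqc_mean
    report["passed"] = passed
    report["reason"] = reasons
    rep = QcFilterReport(report)
    if not passed.any():
        raise ValueError(
            "QC filtering removed every feature; review cv_max/intensity_min")
    kept = [f for f, ok in zip(table.feature_ids, passed) if ok]
    return table.subset_features(kept), rep


def normalize_batchwise(table: FeatureTable, mode: str = "batch") -> FeatureTable:
    """Divide each feature, within each batch, by the batch HSQC median.

    Falls back to the batch median over biological samples when the HSQC
    median is missing or zero. ``mode='per10'`` instead normalizes each run
    of ten consecutive samples by its nearest HSQC injection (alternative
    strategy; batch-wise is the default).
    """
    if mode not in ("batch", "per10"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    X = table.intensities.copy()
    batch_arr = np.asarray(table.batch)
    hsqc = table.role_mask("hsqc")
    bio = table.role_mask("biological")
    for b in table.batches():
        in_batch = batch_arr == b
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X[in_batch & hsqc], axis=0) if (in_batch & hsqc).any() \
                else np.full(table.n_features, np.nan)
            fallback = np.nanmedian(X[in_batch & bio], axis=0) if (in_batch & bio).any() \
                else np.full(table.n_features, np.nan)
        med = np.where(np.isfinite(med) & (med != 0), med, fallback)
        bad = ~np.isfinite(med) | (med == 0)
        if bad.any():
            logger.warning("batch %s: %d features have no usable normalizer; "
                           "values left unscaled", b, int(bad.sum()))
            med = np.where(bad, 1.0, med)
        if mode == "per10":
            idx = np.flatnonzero(in_batch)
            for start in range(0, len(idx), 10):
                seg = idx[start:start + 10]
                seg_h = [i for i in seg if hsqc[i]]
                if seg_h:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        seg_med = np.nanmedian(X[seg_h], axis=0)
                    seg_med = np.where(np.isfinite(seg_med) & (seg_med != 0),
                                       seg_med, med)
                else:
                    seg_med = med
                X[seg] = X[seg] / seg_med
        else:
            X[in_batch] = X[in_batch] / med
    out = FeatureTable(
        sample_ids=list(table.sample_ids), feature_ids=list(table.feature_ids),
        intensities=X, batch=list(table.batch), role=list(table.role),
        class_label=table.class_label, stage_t=table.stage_t,
        stage_n=table.stage_n, mutation=table.mutation,
        transformed=table.transformed)
    return out


def log_autoscale(table: FeatureTable) -> FeatureTable:
    """Natural log then autoscale each feature to mean 0 / sd 1 over
    biological samples. Constant features (sd == 0) are dropped with a
    warning rather than divided by zero."""
    X = table.intensities
    finite = np.isfinite(X)
    if np.any(finite & (X <= 0)):
        i, j = np.argwhere(finite & (X <= 0))[0]
        raise ValueError(
            f"non-positive intensity at sample {table.sample_ids[i]!r}, "
            f"feature {table.feature_ids[j]!r}; log transform undefined")
    logged = np.where(finite, np.log(np.where(finite, X, 1.0)), np.nan)
    bio = table.role_mask("biological")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(logged[bio], axis=0)
        sd = np.nanstd(logged[bio], axis=0, ddof=1)
    keep = np.isfinite(sd) & (sd > 0)
    if not keep.all():
        dropped = [f for f, k in zip(table.feature_ids, keep) if not k]
        logger.warning("dropping %d constant/degenerate features: %s",
                       len(dropped), dropped[:10])
    scaled = (logged[:, keep] - mean[keep]) / sd[keep]
    out = FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_ids=[f for f, k in zip(table.feature_ids, keep) if k],
        intensities=scaled, batch=list(table.batch), role=list(table.role),
        class_label=table.class_label, stage_t=table.stage_t,
        stage_n=table.stage_n, mutation=table.mutation, transformed=True)
    return out


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Replace missing cells by the feature mean over observed biological
    samples; observed values are untouched."""
    X = table.intensities.copy()
    bio = table.role_mask("biological")
    observed = np.isfinite(X[bio])
    if not observed.any(axis=0).all():
        j = int(np.flatnonzero(~observed.any(axis=0))[0])
        raise ValueError(
            f"feature {table.feature_ids[j]!r} has no observed biological "
            "values; cannot impute")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(X[bio], axis=0)
    missing = ~np.isfinite(X)
    X[missing] = np.broadcast_to(means, X.shape)[missing]
    out = FeatureTable(
        sample_ids=list(table.sample_ids), feature_ids=list(table.feature_ids),
        intensities=X, batch=list(table.batch), role=list(table.role),
        class_label=table.class_label, stage_t=table.stage_t,
        stage_n=table.stage_n, mutation=table.mutation,
        transformed=table.transformed)
    return out


def preprocess(
    table: FeatureTable,
    cv_max: float = 0.3,
    intensity_min: float = 1e5,
    mode: str = "batch",
) -> tuple[FeatureTable, QcFilterReport]:
    """Full chain: filter -> batch-normalize -> log+autoscale -> impute."""
    filtered, report = filter_features(table, cv_max=cv_max,
                                       intensity_min=intensity_min)
    normalized = normalize_batchwise(filtered, mode=mode)
    scaled = log_autoscale(normalized)
    return impute_missing(scaled), report
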