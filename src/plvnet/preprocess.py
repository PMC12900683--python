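"""Resting-state EEG cleaning chain.

Order of operations: drop auxiliary channels → 1–30 Hz band-pass →
48–52 Hz notch → mastoid re-referencing → artifact-component removal
(ICA backend) → ±70 μV segment rejection → minimum-retention rule.
Filters are 4th-order Butterworth applied forward–backward (zero phase);
the contracts are stated as attenuation behaviour, so any compliant
realisation passes the same tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .core import DataError, Recording

__all__ = [
    "PreprocessConfig",
    "drop_channels",
    "bandpass_filter",
    "notch_filter",
    "rereference",
    "remove_artifact_components",
    "reject_amplitude",
    "enforce_retention",
    "RetentionError",
    "preprocess",
]

log = logging.getLogger(__name__)


class RetentionError(ValueError):
    """Raised when a subject retains too little clean data."""


@dataclass
class PreprocessConfig:
    """All cleaning thresholds, surfaced so none is hard-coded downstream."""

    bandpass: tuple[float, float] = (1.0, 30.0)
    notch: tuple[float, float] = (48.0, 52.0)
    reference: Sequence[str] = ("M1", "M2")
    drop: Sequence[str] = ("VEOG", "HEOG")
    amp_threshold: float = 70.0     # μV
    min_retained: float = 300.0     # seconds, strictly exceeded to pass
    segment_len: float = 1.0        # seconds per rejection window
    ica_corr_threshold: float = 0.7

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not lo < hi:
            raise DataError("bandpass low must be < high")
        if self.amp_threshold <= 0 or self.min_retained <= 0 or self.segment_len <= 0:
            raise DataError("thresholds must be positive")


def drop_channels(rec: Recording, labels: Sequence[str]) -> Recording:
    """Remove the named rows, preserving the order of the rest.

    Labels not present are skipped with a warning; removing every channel
    is an error.
    """
    labels = list(labels)
    missing = [l for l in labels if l not in rec.labels]
    if missing:
        warnings.warn(f"channels not present, skipped: {missing}")
    keep = [i for i, l in enumerate(rec.labels) if l not in labels]
    if not keep:
        raise DataError("drop_channels would remove every channel")
    return Recording(data=rec.data[keep], fs=rec.fs,
                     labels=[rec.labels[i] for i in keep], space=rec.space,
                     retained_mask=rec.retained_mask)


def _sos_filtfilt(rec: Recording, sos: np.ndarray) -> Recording:
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(data=filtered, fs=rec.fs, labels=list(rec.labels),
                     space=rec.space, retained_mask=rec.retained_mask)


def bandpass_filter(rec: Recording, low: float, high: float,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, per row."""
    nyq = rec.fs / 2
    if not 0 < low < high:
        raise DataError("need 0 < low < high")
    if high >= nyq:
        raise DataError(f"band edge {high} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs,
                        output="sos")
    return _sos_filtfilt(rec, sos)


def notch_filter(rec: Recording, band: tuple[float, float] = (48.0, 52.0),
                 order: int = 4) -> Recording:
    """Zero-phase Butterworth band-stop (≥ 20 dB at the band centre)."""
    low, high = band
    nyq = rec.fs / 2
    if not 0 < low < high < nyq:
        raise DataError(f"stop band {band} must lie within (0, {nyq})")
    sos = signal.butter(order, [low, high], btype="bandstop", fs=rec.fs,
                        output="sos")
    return _sos_filtfilt(rec, sos)


def rereference(rec: Recording, reference_labels: Sequence[str]) -> Recording:
    """Subtract the mean of the reference rows from every row.

    Reference rows are retained in the output so later stages can still
    drop or inspect them.
    """
    idx = []
    for lab in reference_labels:
        if lab not in rec.labels:
            raise DataError(f"reference channel {lab!r} not in recording")
        idx.append(rec.labels.index(lab))
    ref = rec.data[idx].mean(axis=0)
    return Recording(data=rec.data - ref[None, :], fs=rec.fs,
                     labels=list(rec.labels), space=rec.space,
                     retained_mask=rec.retained_mask)


def remove_artifact_components(rec: Recording,
                               artifact_templates: dict[str, np.ndarray] | None,
                               corr_threshold: float = 0.7,
                               random_state: int = 0,
                               ) -> tuple[Recording, list[dict]]:
    """Zero independent components correlated with artifact templates.

    The recording is decomposed with FastICA; any component whose absolute
    Pearson correlation with a template time series reaches
    ``corr_threshold`` is removed before reconstruction.  Returns the
    cleaned recording and a per-component report.  With no templates the
    input is returned unchanged (with a warning).
    """
    if not artifact_templates:
        warnings.warn("no artifact templates supplied; recording unchanged")
        return rec.copy(), []
    if rec.n_channels < 2:
        raise DataError("component removal needs at least 2 channels")

    from sklearn.decomposition import FastICA

    X = rec.data.T  # samples × channels
    mean = X.mean(axis=0)
    ica = FastICA(n_components=rec.n_channels, random_state=random_state,
                  max_iter=1000, whiten="unit-variance")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = ica.fit_transform(X - mean)  # samples × components
    except Exception as exc:  # pragma: no cover - backend failure path
        raise DataError(f"ICA decomposition failed: {exc}") from exc

    report: list[dict] = []
    removed: list[int] = []
    for k in range(S.shape[1]):
        comp = S[:, k]
        best_name, best_r = "", 0.0
        for name, tpl in artifact_templates.items():
            tpl = np.asarray(tpl, dtype=float)
            if tpl.shape != comp.shape:
                raise DataError(f"template {name!r} length mismatch")
            if comp.std() == 0 or tpl.std() == 0:
                continue
            r = float(np.corrcoef(comp, tpl)[0, 1])
            if abs(r) > abs(best_r):
                best_name, best_r = name, r
        hit = abs(best_r) >= corr_threshold
        if hit:
            removed.append(k)
        report.append({"component": k, "template": best_name,
                       "corr": best_r, "removed": hit})

    S_clean = S.copy()
    S_clean[:, removed] = 0.0
    X_clean = S_clean @ ica.mixing_.T + mean
    cleaned = Recording(data=X_clean.T, fs=rec.fs, labels=list(rec.labels),
                        space=rec.space, retained_mask=rec.retained_mask)
    log.info("ICA removed %d/%d components", len(removed), S.shape[1])
    return cleaned, report


def reject_amplitude(rec: Recording, threshold: float = 70.0,
                     segment_len: float = 1.0) -> tuple[Recording, np.ndarray]:
    """Mask out fixed-length segments containing any |amplitude| > threshold.

    The recording is split into consecutive windows of ``segment_len``
    seconds (a final partial window is kept as its own segment); a window
    is rejected if any sample on any row exceeds the threshold.  Returns
    the recording with retained samples concatenated (its
    ``retained_mask`` covers the output samples) together with the
    full-length boolean mask over the input samples.
    """
    if threshold <= 0:
        raise DataError("threshold must be > 0")
    seg = int(round(segment_len * rec.fs))
    if seg < 1:
        raise DataError("segment shorter than one sample")
    T = rec.n_samples
    mask = np.ones(T, dtype=bool)
    for start in range(0, T, seg):
        stop = min(start + seg, T)
        if np.abs(rec.data[:, start:stop]).max() > threshold:
            mask[start:stop] = False
    out = Recording(data=rec.data[:, mask], fs=rec.fs, labels=list(rec.labels),
                    space=rec.space,
                    retained_mask=np.ones(int(mask.sum()), dtype=bool))
    return out, mask


def enforce_retention(rec: Recording, min_retained: float = 300.0) -> Recording:
    """Pass the recording through iff it retains strictly more than
    ``min_retained`` seconds; otherwise raise :class:`RetentionError`.

    The rule is strict ("exceeding"): exactly ``min_retained`` seconds is
    an exclusion.
    """
    if rec.retained_mask is None:
        raise DataError("enforce_retention requires a retained_mask "
                        "(run reject_amplitude first)")
    kept = rec.retained_seconds
    if kept > min_retained:
        return rec
    raise RetentionError(
        f"only {kept:.1f} s retained; need strictly more than {min_retained:.0f} s"
    )


def preprocess(rec: Recording, config: PreprocessConfig | None = None,
               artifact_templates: dict[str, np.ndarray] | None = None,
               ) -> tuple[Recording, dict]:
    """Run the full cleaning chain and return (recording, report).

    Region-space recordings skip channel dropping and re-referencing
    (those are sensor-montage operations) but receive the same filtering
    and rejection.  Raises :class:`RetentionError` when the subject fails
    the minimum-retention rule; the report is attached to the exception's
    ``report`` attribute in that case.
    """
    cfg = config or PreprocessConfig()
    report: dict = {"n_channels_in": rec.n_channels,
                    "duration_in": rec.duration}

    out = rec
    if rec.space == "sensor":
        to_drop = [l for l in cfg.drop if l in out.labels]
        if to_drop:
            out = drop_channels(out, to_drop)
        report["dropped"] = to_drop
    out = bandpass_filter(out, *cfg.bandpass)
    if cfg.notch[1] < out.fs / 2:
        out = notch_filter(out, cfg.notch)
        report["notch"] = list(cfg.notch)
    if rec.space == "sensor" and all(l in out.labels for l in cfg.reference):
        out = rereference(out, cfg.reference)
        report["reference"] = list(cfg.reference)
    if artifact_templates:
        out, ica_report = remove_artifact_components(
            out, artifact_templates, corr_threshold=cfg.ica_corr_threshold)
        report["ica"] = ica_report
    out, _ = reject_amplitude(out, cfg.amp_threshold, cfg.segment_len)
    report["retained_seconds"] = out.retained_seconds
    try:
        out = enforce_retention(out, cfg.min_retained)
        report["excluded"] = False
    except RetentionError as exc:
        report["excluded"] = True
        exc.report = report
        raise
    return out, report
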