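"""Reading, writing and preprocessing of two-channel CTG records.

A cardiotocographic (CTG) record carries a fetal heart rate channel (FHR,
beats/min) and a uterine contraction channel (UC, mmHg or arbitrary units),
conventionally sampled at 4 Hz. Clinical traces are contaminated by sensor
contact loss (abrupt drops/spikes) and missing stretches; preprocessing is

1. sliding-median outlier correction — a sample is replaced by the median
   over the centred 10-s window whenever it falls outside
   ``(1 ± outlier_factor) * median``,
2. excision of missing-data runs longer than ``gap_max_s`` (shorter runs are
   filled from the local median),
3. a causal 6th-order Butterworth band-pass (0.004-0.5 Hz), which also
   detrends the baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any

import numpy as np
import pandas as pd
from scipy import signal


class Label(str, Enum):
    VAGINAL = "vaginal"
    CESAREAN = "cesarean"
    UNKNOWN = "unknown"


class CTGFormatError(ValueError):
    """Malformed input record (missing channel, length mismatch, ...)."""


class EmptyRecordError(ValueError):
    """Record contains no usable samples."""


@dataclass
class CTGRecord:
    """Two aligned equal-length channels with label and metadata."""

    record_id: str
    fhr: np.ndarray
    uc: np.ndarray
    fs: float
    label: Label = Label.UNKNOWN
    meta: dict[str, Any] = field(default_factory=dict)
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        if self.fhr.shape != self.uc.shape or self.fhr.ndim != 1:
            raise CTGFormatError(
                f"channels must be 1-D and equal length, got "
                f"{self.fhr.shape} vs {self.uc.shape}"
            )
        if self.fs <= 0:
            raise CTGFormatError(f"sampling rate must be positive, got {self.fs}")
        if isinstance(self.label, str) and not isinstance(self.label, Label):
            self.label = Label(self.label)

    def __len__(self) -> int:
        return self.fhr.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the three preprocessing steps.

    ``median_window_s`` / ``outlier_factor``: centred window length and the
    multiplicative band of the sliding-median rule. ``gap_max_s``: missing
    runs longer than this are excised. ``band_low_hz``/``band_high_hz``/
    ``filter_order``: Butterworth band-pass (order = order of the band-pass
    transfer function). ``median_floor``: absolute floor on |median| so the
    multiplicative rule stays defined near zero.
    """

    median_window_s: float = 10.0
    outlier_factor: float = 0.33
    gap_max_s: float = 10.0
    band_low_hz: float = 0.004
    band_high_hz: float = 0.5
    filter_order: int = 6
    median_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.median_window_s > 0 and 0 < self.outlier_factor < 1):
            raise ValueError("median_window_s > 0 and 0 < outlier_factor < 1 required")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low_hz < band_high_hz")


def read_record(path, dialect: str = "csv", label: str | None = None) -> CTGRecord:
    """Read a CTG record from ``path``.

    ``csv``: header ``time,fhr,uc`` (time in seconds); sampling rate inferred
    from the time column. ``wfdb``: a PhysioNet-style record with two signals
    (requires the optional :mod:`wfdb` package). The label may be supplied
    explicitly or through a ``label`` column/metadata field; otherwise it is
    ``unknown``.
    """
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"time", "fhr", "uc"} - set(df.columns)
        if missing:
            raise CTGFormatError(f"CSV missing column(s): {sorted(missing)}")
        t = df["time"].to_numpy(dtype=float)
        if t.size < 2:
            raise CTGFormatError("need at least 2 samples to infer sampling rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise CTGFormatError("time column is not uniformly sampled")
        fs = 1.0 / dt[0]
        lab = label or (str(df["label"].iloc[0]) if "label" in df.columns else "unknown")
        rid = str(getattr(path, "stem", None) or path)
        return CTGRecord(rid, df["fhr"].to_numpy(float), df["uc"].to_numpy(float),
                         fs=fs, label=Label(lab))
    if dialect == "wfdb":
        try:
            import wfdb  # type: ignore
        except ImportError as e:  # pragma: no cover - optional dependency
            raise ImportError(
                "reading WFDB records requires the optional 'wfdb' package "
                "(pip install wfdb)"
            ) from e
        rec = wfdb.rdrecord(str(path))
        if rec.p_signal is None or rec.p_signal.shape[1] < 2:
            raise CTGFormatError("WFDB record must contain two signals (FHR, UC)")
        return CTGRecord(rec.record_name, rec.p_signal[:, 0], rec.p_signal[:, 1],
                         fs=float(rec.fs), label=Label(label or "unknown"))
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_record(rec: CTGRecord, path) -> None:
    """Write a record as ``time,fhr,uc[,label]`` CSV (round-trips with read)."""
    t = np.arange(len(rec)) / rec.fs
    df = pd.DataFrame({"time": t, "fhr": rec.fhr, "uc": rec.uc})
    if rec.label is not Label.UNKNOWN:
        df["label"] = rec.label.value
    # %.17g is round-trippable for IEEE doubles
    df.to_csv(path, index=False, float_format="%.17g")


def _window_median(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Median over the centred window (truncated at edges), ignoring NaNs."""
    half = max(int(round(window_s * fs)) // 2, 1)
    n = x.size
    med = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices -> NaN
        for i in range(n):
            med[i] = np.nanmedian(x[max(0, i - half): min(n, i + half + 1)])
    return med


def _nan_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal non-finite run."""
    bad = ~np.isfinite(x)
    runs: list[tuple[int, int]] = []
    i = 0
    n = x.size
    while i < n:
        if bad[i]:
            j = i
            while j < n and bad[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def correct_outliers(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Sliding-median outlier correction.

    At each sample the median over the centred ``median_window_s`` window is
    computed (ignoring non-finite values); samples strictly outside
    ``[(1-f)*m, (1+f)*m]`` and short non-finite runs are replaced by that
    median. The multiplicative band is taken about the median with half-width
    ``f * max(|m|, median_floor)`` so the rule stays defined for near-zero or
    negative medians. Non-finite runs longer than ``gap_max_s`` are left in
    place for :func:`remove_long_gaps`.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if x.size < max(int(round(cfg.median_window_s * fs)), 2):
        raise ValueError("series shorter than the median window")
    med = _window_median(x, fs, cfg.median_window_s)
    halfband = cfg.outlier_factor * np.maximum(np.abs(med), cfg.median_floor)
    lo, hi = med - halfband, med + halfband
    out = x.copy()
    finite = np.isfinite(x)
    viol = finite & np.isfinite(med) & ((x < lo) | (x > hi))
    out[viol] = med[viol]
    # fill short non-finite runs only; long ones are the gap markers
    max_gap = int(round(cfg.gap_max_s * fs))
    for start, length in _nan_runs(x):
        if length <= max_gap:
            sl = slice(start, start + length)
            out[sl] = med[sl]
    return out


def remove_long_gaps(
    x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Excise non-finite runs longer than ``gap_max_s``; fill shorter ones.

    Returns the (possibly shortened) series and a log of excised intervals as
    ``(start_s, length_s)`` in the original time base. Flanking segments are
    concatenated.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if x.size == 0 or not np.isfinite(x).any():
        raise EmptyRecordError("record entirely missing")
    max_gap = int(round(cfg.gap_max_s * fs))
    runs = _nan_runs(x)
    log = [(s / fs, ln / fs) for s, ln in runs if ln > max_gap]
    keep = np.ones(x.size, dtype=bool)
    for s, ln in runs:
        if ln > max_gap:
            keep[s: s + ln] = False
    y = x[keep]
    if _nan_runs(y):  # short runs remain: fill from the local median
        med = _window_median(y, fs, cfg.median_window_s)
        bad = ~np.isfinite(y)
        y = y.copy()
        y[bad] = med[bad]
    return y, log


def _design_sos(fs: float, cfg: PreprocessConfig) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 < cfg.band_low_hz < cfg.band_high_hz < nyq):
        raise ValueError(
            f"band edges ({cfg.band_low_hz}, {cfg.band_high_hz}) must lie "
            f"strictly inside (0, {nyq})"
        )
    # butter(N, btype='band') yields a transfer function of order 2N; an
    # order-6 band-pass therefore uses N = 3 sections per edge.
    n = max(cfg.filter_order // 2, 1)
    return signal.butter(n, [cfg.band_low_hz, cfg.band_high_hz],
                         btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Causal Butterworth band-pass; removes DC/baseline, preserves length.

    Forward-only (no zero-phase filtering). The filter state is initialised
    to the step steady state of the first sample, which suppresses the large
    start-up transient a raw baseline (e.g. 140 bpm) would otherwise excite
    while keeping the filter causal.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    sos = _design_sos(fs, cfg)
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def bandpass_gain(freq_hz: float, fs: float, cfg: PreprocessConfig | None = None) -> float:
    """Analytic magnitude response of the preprocessing filter at ``freq_hz``."""
    cfg = cfg or PreprocessConfig()
    sos = _design_sos(fs, cfg)
    _, h = signal.sosfreqz(sos, worN=[2 * np.pi * freq_hz / fs])
    return float(np.abs(h[0]))


def preprocess(rec: CTGRecord, cfg: PreprocessConfig | None = None) -> CTGRecord:
    """Outlier correction, long-gap excision, band-pass — in that order.

    Both channels are processed with the same configuration; gaps are excised
    at the union of the two channels' long-gap masks so the channels stay
    aligned. The gap log is stored in ``meta['gap_log']``.
    """
    cfg = cfg or PreprocessConfig()
    if len(rec) == 0:
        raise EmptyRecordError("empty record")
    fhr = correct_outliers(rec.fhr, rec.fs, cfg)
    uc = correct_outliers(rec.uc, rec.fs, cfg)
    # align the channels: a long gap in either channel is excised from both
    joint = np.where(~np.isfinite(fhr) | ~np.isfinite(uc), np.nan, 0.0)
    max_gap = int(round(cfg.gap_max_s * rec.fs))
    runs = _nan_runs(joint)
    log = [(s / rec.fs, ln / rec.fs) for s, ln in runs if ln > max_gap]
    keep = np.ones(len(rec), dtype=bool)
    for s, ln in runs:
        if ln > max_gap:
            keep[s: s + ln] = False
    fhr, uc = fhr[keep], uc[keep]
    for ch in (fhr, uc):  # fill any short runs that survived
        bad = ~np.isfinite(ch)
        if bad.any():
            med = _window_median(ch, rec.fs, cfg.median_window_s)
            ch[bad] = med[bad]
    if fhr.size < int(round(cfg.median_window_s * rec.fs)):
        raise EmptyRecordError("record too short after gap removal")
    fhr = bandpass(fhr, rec.fs, cfg)
    uc = bandpass(uc, rec.fs, cfg)
    out = replace(rec, fhr=fhr, uc=uc, preprocessed=True,
                  meta={**rec.meta, "gap_log": log})
    return out
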