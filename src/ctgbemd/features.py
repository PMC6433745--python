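"""Hilbert time-frequency features of bivariate IMFs.

Each real-valued IMF channel is lifted to its analytic signal
``x + jH(x)``; modulus, unwrapped angle and phase derivative give the
instantaneous amplitude A(t), phase phi(t) and frequency f(t) (rad/s). The
two channels of one bivariate IMF are then combined into joint estimates

    A_multi(t) = sqrt(A_F^2 + A_U^2)
    f_multi(t) = (A_F^2 f_F + A_U^2 f_U) / (A_F^2 + A_U^2)

and summarised by eight scalars per IMF:

    mjia   mean of A_multi
    mmam   mean of dA_multi/dt  (AM drift)
    vmam   variance of dA_multi/dt about mmam
    wmf    weighted mean frequency, sum(A f^2)/sum(A f), per channel
    me     log mean squared IMF amplitude, per channel
    psi    phase synchronization index between the channels' phases,
           the circular resultant length of the phase difference, in [0, 1]

With five IMFs this yields the canonical 40-feature vector per record.
Features are computed over interior samples (5% trimmed at each end by
default) to suppress Hilbert/spline edge artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bemd import IMFSet

#: per-IMF feature stems, in canonical order
FEATURE_STEMS = ("mjia", "mmam", "vmam", "wmf_fhr", "wmf_uc", "me_fhr", "me_uc", "psi")


def feature_names(n_imfs: int = 5) -> list[str]:
    """Canonical feature-column order: ``{stem}_{imf}`` for imf = 1..M."""
    return [f"{stem}_{m}" for m in range(1, n_imfs + 1) for stem in FEATURE_STEMS]


@dataclass
class AnalyticIMF:
    """Instantaneous amplitude / unwrapped phase / frequency of one channel."""

    ia: np.ndarray      # >= 0, signal units
    ip: np.ndarray      # radians, unwrapped
    ifreq: np.ndarray   # rad/s
    degenerate: bool = False


def analytic(x: np.ndarray, fs: float) -> AnalyticIMF:
    """Analytic-signal estimates for one real IMF channel.

    Instantaneous frequency is the derivative of the unwrapped phase by
    central differences (one-sided at the ends), in rad/s. Negative samples
    are retained. An all-zero input is flagged degenerate with zero phase.
    """
    x = np.asarray(x, float)
    if x.size < 16:
        raise ValueError("series too short for a stable Hilbert estimate")
    if not np.any(x):
        z = np.zeros_like(x)
        return AnalyticIMF(ia=z, ip=z.copy(), ifreq=z.copy(), degenerate=True)
    a = hilbert(x)
    ia = np.abs(a)
    ip = np.unwrap(np.angle(a))
    ifreq = np.gradient(ip) * fs
    return AnalyticIMF(ia=ia, ip=ip, ifreq=ifreq)


def joint_amplitude(ia_f: np.ndarray, ia_u: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean norm of the two channels' amplitudes."""
    ia_f, ia_u = np.asarray(ia_f, float), np.asarray(ia_u, float)
    if ia_f.shape != ia_u.shape:
        raise ValueError("length mismatch between channels")
    return np.hypot(ia_f, ia_u)


def joint_frequency(ia_f: np.ndarray, if_f: np.ndarray,
                    ia_u: np.ndarray, if_u: np.ndarray) -> np.ndarray:
    """Amplitude-squared-weighted mean of the channel instantaneous frequencies.

    Samples where both amplitudes vanish are undefined and returned as NaN
    (callers exclude them from means).
    """
    arrs = [np.asarray(a, float) for a in (ia_f, if_f, ia_u, if_u)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("length mismatch")
    ia_f, if_f, ia_u, if_u = arrs
    w_f, w_u = ia_f ** 2, ia_u ** 2
    den = w_f + w_u
    out = np.full(den.shape, np.nan)
    ok = den > 0
    out[ok] = (w_f[ok] * if_f[ok] + w_u[ok] * if_u[ok]) / den[ok]
    return out


def mjia(a_multi: np.ndarray) -> float:
    """Mean of the joint instantaneous amplitude."""
    a = np.asarray(a_multi, float)
    if a.size == 0:
        raise ValueError("empty series")
    return float(a.mean())


def mmam(a_multi: np.ndarray, fs: float) -> float:
    """Mean of the joint-amplitude derivative (units/s).

    Discrete convention: mean of the first differences scaled by fs, which
    telescopes to ``(a[-1] - a[0]) * fs / (N - 1)``.
    """
    a = np.asarray(a_multi, float)
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.diff(a).mean() * fs)


def vmam(a_multi: np.ndarray, fs: float) -> float:
    """Population variance of the joint-amplitude derivative about its mean."""
    a = np.asarray(a_multi, float)
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    d = np.diff(a) * fs
    return float(np.mean((d - d.mean()) ** 2))


def wmf(ia: np.ndarray, ifreq: np.ndarray) -> float:
    """Weighted mean frequency sum(A f^2)/sum(A f), rad/s.

    The weighting is amplitude times frequency (as defined, not the
    conventional amplitude-squared). Undefined (NaN) when the denominator
    sum(A f) is not positive; imputed downstream.
    """
    ia, ifreq = np.asarray(ia, float), np.asarray(ifreq, float)
    if ia.shape != ifreq.shape:
        raise ValueError("length mismatch")
    den = float(np.sum(ia * ifreq))
    if den <= 0:
        return float("nan")
    return float(np.sum(ia * ifreq ** 2) / den)


def me(x: np.ndarray) -> float:
    """Log mean squared IMF amplitude (natural log); NaN for an all-zero IMF."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty series")
    msq = float(np.mean(x ** 2))
    if msq <= 0:
        return float("nan")
    return float(np.log(msq))


def psi(ip_f: np.ndarray, ip_u: np.ndarray) -> float:
    """Phase synchronization index: circular resultant length of the phase
    difference, ``(1/T) sqrt((sum cos d)^2 + (sum sin d)^2)``, clipped to
    [0, 1]. 1 means the phase difference is constant (perfect locking); for
    i.i.d. uniform phase differences it decays like 1/sqrt(T).
    """
    ip_f, ip_u = np.asarray(ip_f, float), np.asarray(ip_u, float)
    if ip_f.shape != ip_u.shape:
        raise ValueError("length mismatch")
    d = ip_f - ip_u
    r = np.hypot(np.cos(d).sum(), np.sin(d).sum()) / d.size
    return float(np.clip(r, 0.0, 1.0))


def _interior(n: int, trim_frac: float) -> slice:
    k = int(np.floor(n * trim_frac))
    return slice(k, n - k if k else n)


def extract_features(imfs: IMFSet, n_imfs: int = 5, trim_frac: float = 0.05,
                     record_id: str | None = None, label=None) -> pd.Series:
    """The 8 x ``n_imfs`` named scalar features of one decomposition.

    IMFs beyond those available (or degenerate channels) yield NaN entries,
    to be imputed at the pipeline level from training medians. Returned as a
    Series in canonical column order; ``record_id``/``label`` are attached in
    ``.attrs`` when given.
    """
    values: dict[str, float] = {name: float("nan") for name in feature_names(n_imfs)}
    for m in range(1, min(n_imfs, imfs.n_imfs) + 1):
        f = analytic(imfs.channel(m, "fhr"), imfs.fs)
        u = analytic(imfs.channel(m, "uc"), imfs.fs)
        sl = _interior(len(f.ia), trim_frac)
        a_multi = joint_amplitude(f.ia[sl], u.ia[sl])
        values[f"mjia_{m}"] = mjia(a_multi)
        values[f"mmam_{m}"] = mmam(a_multi, imfs.fs)
        values[f"vmam_{m}"] = vmam(a_multi, imfs.fs)
        values[f"wmf_fhr_{m}"] = wmf(f.ia[sl], f.ifreq[sl])
        values[f"wmf_uc_{m}"] = wmf(u.ia[sl], u.ifreq[sl])
        values[f"me_fhr_{m}"] = me(imfs.channel(m, "fhr")[sl])
        values[f"me_uc_{m}"] = me(imfs.channel(m, "uc")[sl])
        if f.degenerate or u.degenerate:
            values[f"psi_{m}"] = float("nan")
        else:
            values[f"psi_{m}"] = psi(f.ip[sl], u.ip[sl])
    s = pd.Series(values, index=feature_names(n_imfs), dtype=float)
    s.attrs["record_id"] = record_id
    s.attrs["label"] = label
    return s
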