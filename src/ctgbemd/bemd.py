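"""Bivariate empirical mode decomposition (BEMD) of a complex two-channel signal.

The two CTG channels are combined into one complex series
``z(t) = F(t) + jU(t)`` and decomposed into complex intrinsic mode functions
(IMFs) by directional-projection sifting: the signal is projected onto K
directions ``theta_k = 2*pi*k/K`` of the unit circle, the maxima of each real
projection are spline-interpolated (in the complex plane) into directional
envelopes, and the envelope mean is subtracted until the remainder qualifies
as an IMF. Decomposing both channels jointly aligns the scales: the m-th IMF
carries matched frequency content in the real (FHR) and imaginary (UC) parts,
which a channel-by-channel univariate EMD does not guarantee.

The decomposition is complete by construction:
``z(t) = sum_m gamma_m(t) + r(t)`` with residual (trend) ``r(t)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.linalg import solve_banded
from scipy.signal import find_peaks

MIN_SIFT_LENGTH = 8


class DecompositionError(ValueError):
    pass


@dataclass(frozen=True)
class SiftConfig:
    """Sifting parameters.

    ``n_directions``: number K of projection directions on the unit circle.
    ``max_imfs``: M, maximum number of IMFs to extract. ``stop_rule``:
    'rilling' stops a sift when the normalised envelope mean |m(t)|/a(t) is
    below ``theta1`` on at least (1 - alpha) of samples and below ``theta2``
    everywhere (a(t) = mean directional envelope modulus); 'fixed_iters' runs
    ``fixed_iters`` subtractions.
    """

    n_directions: int = 64
    max_imfs: int = 5
    spline: Literal["cubic"] = "cubic"
    boundary: Literal["mirror"] = "mirror"
    stop_rule: Literal["rilling", "fixed_iters"] = "rilling"
    theta1: float = 0.05
    theta2: float = 0.50
    alpha: float = 0.05
    fixed_iters: int = 10
    max_sift_iters: int = 50

    def __post_init__(self) -> None:
        if self.n_directions < 4:
            raise ValueError("need at least 4 projection directions")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if not self.theta1 < self.theta2:
            raise ValueError("theta1 < theta2 required")


@dataclass
class BivariateSignal:
    """Complex two-channel signal: real part FHR, imaginary part UC."""

    z: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=complex)
        if self.z.size < MIN_SIFT_LENGTH:
            raise DecompositionError(
                f"signal too short to sift ({self.z.size} < {MIN_SIFT_LENGTH})"
            )
        if not np.all(np.isfinite(self.z.real) & np.isfinite(self.z.imag)):
            raise DecompositionError("signal must be finite")

    @classmethod
    def from_channels(cls, fhr: np.ndarray, uc: np.ndarray, fs: float) -> "BivariateSignal":
        fhr = np.asarray(fhr, float)
        uc = np.asarray(uc, float)
        if fhr.shape != uc.shape:
            raise DecompositionError("channels must have equal length")
        return cls(fhr + 1j * uc, fs)


@dataclass
class IMFSet:
    """Ordered complex IMFs plus the residual trend from one BEMD run."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    fs: float
    config: SiftConfig = field(default_factory=SiftConfig)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.residual if self.imfs else self.residual

    def channel(self, m: int, which: str) -> np.ndarray:
        """Real-valued IMF m (1-based) of channel 'fhr' or 'uc'."""
        g = self.imfs[m - 1]
        return g.real if which == "fhr" else g.imag


def project(z: np.ndarray, theta: float) -> np.ndarray:
    """Directional projection Re(e^{-j*theta} z(t))."""
    return (np.asarray(z, complex) * np.exp(-1j * theta)).real


def _mirror_knots(idx: np.ndarray, vals: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two outermost knots about each endpoint (0 and n-1)."""
    t = idx.astype(float)
    lt, lv = -t[:2][::-1], vals[:2][::-1]
    rt, rv = 2.0 * (n - 1) - t[-2:][::-1], vals[-2:][::-1]
    tt = np.concatenate([lt, t, rt])
    vv = np.concatenate([lv, vals, rv])
    order = np.argsort(tt, kind="stable")
    tt, vv = tt[order], vv[order]
    # a knot exactly on an endpoint mirrors onto itself; drop duplicates
    keep = np.concatenate([[True], np.diff(tt) > 0])
    return tt[keep], vv[keep]


def _natural_cubic(tt: np.ndarray, vv: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Natural cubic spline through (tt, vv) evaluated at x (vv may be complex).

    Lean banded-system implementation: envelope construction dominates the
    sifting cost and the generic interpolator class overhead is avoided.
    """
    m = tt.size
    if m == 2:
        return vv[0] + (vv[1] - vv[0]) * (x - tt[0]) / (tt[1] - tt[0])
    h = np.diff(tt)
    dv = np.diff(vv) / h
    # second-derivative system, natural ends (M_0 = M_{m-1} = 0)
    ab = np.zeros((3, m - 2))
    ab[0, 1:] = h[1:-1]
    ab[1] = 2.0 * (h[:-1] + h[1:])
    ab[2, :-1] = h[1:-1]
    rhs = 6.0 * (dv[1:] - dv[:-1])
    M = np.zeros(m, dtype=vv.dtype)
    M[1:-1] = solve_banded((1, 1), ab, rhs)
    seg = np.clip(np.searchsorted(tt, x, side="right") - 1, 0, m - 2)
    dx = x - tt[seg]
    b = dv - h * (2.0 * M[:-1] + M[1:]) / 6.0
    c = M[:-1] / 2.0
    d = (M[1:] - M[:-1]) / (6.0 * h)
    return vv[seg] + dx * (b[seg] + dx * (c[seg] + dx * d[seg]))


def _spline_envelope(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    tt, vv = _mirror_knots(idx, vals, n)
    return _natural_cubic(tt, vv, np.arange(n, dtype=float))


def directional_envelopes(z: np.ndarray, cfg: SiftConfig | None = None) -> np.ndarray:
    """Complex envelopes of the K directional projections.

    For each direction, the local maxima of the projection are located and the
    complex samples of z at those times are cubic-spline interpolated (mirror
    boundary). Directions whose projection has fewer than two maxima are
    skipped. Returns an array of shape (n_usable, len(z)); n_usable may be
    less than K.
    """
    cfg = cfg or SiftConfig()
    z = np.asarray(z, complex)
    n = z.size
    envs = []
    for k in range(1, cfg.n_directions + 1):
        theta = 2.0 * np.pi * k / cfg.n_directions
        p = project(z, theta)
        idx, _ = find_peaks(p)
        if idx.size < 2:
            continue
        envs.append(_spline_envelope(idx, z[idx], n))
    return np.array(envs) if envs else np.empty((0, n), complex)


def local_mean(z: np.ndarray, cfg: SiftConfig | None = None) -> np.ndarray:
    """Arithmetic mean of all usable directional envelopes."""
    envs = directional_envelopes(z, cfg)
    if envs.shape[0] < 2:
        raise DecompositionError("fewer than 2 usable projection directions")
    return envs.mean(axis=0)


def _mean_and_amplitude(z: np.ndarray, cfg: SiftConfig) -> tuple[np.ndarray, np.ndarray, int]:
    envs = directional_envelopes(z, cfg)
    k = envs.shape[0]
    if k < 2:
        return np.zeros_like(z), np.zeros(z.size), k
    return envs.mean(axis=0), np.abs(envs).mean(axis=0), k


def sift(z: np.ndarray, cfg: SiftConfig | None = None) -> tuple[np.ndarray, np.ndarray, bool]:
    """Extract one IMF from z by iterated envelope-mean subtraction.

    Returns ``(imf, z - imf, hit_iter_cap)``. Sifting stops per
    ``cfg.stop_rule``; if ``max_sift_iters`` is exceeded the current remainder
    is returned with the warning flag set.
    """
    cfg = cfg or SiftConfig()
    d = np.asarray(z, complex).copy()
    if cfg.stop_rule == "fixed_iters":
        for _ in range(cfg.fixed_iters):
            m, _, k = _mean_and_amplitude(d, cfg)
            if k < 2:
                break
            d = d - m
        return d, z - d, False
    tiny = np.finfo(float).tiny
    for _ in range(cfg.max_sift_iters):
        m, a, k = _mean_and_amplitude(d, cfg)
        if k < 2:
            break
        sx = np.abs(m) / np.maximum(a, tiny)
        if np.mean(sx < cfg.theta1) >= 1.0 - cfg.alpha and np.all(sx < cfg.theta2):
            break
        d = d - m
    else:
        warnings.warn("sift hit max_sift_iters before the stop rule fired")
        return d, z - d, True
    return d, z - d, False


def _siftable(z: np.ndarray, cfg: SiftConfig) -> bool:
    """At least two directions with >= 2 projection maxima."""
    usable = 0
    for k in range(1, cfg.n_directions + 1):
        theta = 2.0 * np.pi * k / cfg.n_directions
        idx, _ = find_peaks(project(z, theta))
        if idx.size >= 2:
            usable += 1
            if usable >= 2:
                return True
    return False


def bemd(sig: BivariateSignal | np.ndarray, cfg: SiftConfig | None = None,
         fs: float | None = None) -> IMFSet:
    """Full bivariate EMD: up to ``max_imfs`` complex IMFs plus residual.

    Extraction stops early when the running residual yields fewer than two
    maxima in every projection direction (a monotonic/trend residual). The
    completeness identity ``z = sum(imfs) + residual`` holds exactly by
    construction.
    """
    cfg = cfg or SiftConfig()
    if isinstance(sig, BivariateSignal):
        z, fs_ = sig.z, sig.fs
    else:
        z = np.asarray(sig, complex)
        fs_ = fs if fs is not None else 1.0
        BivariateSignal(z, fs_)  # validate
    imfs: list[np.ndarray] = []
    warns: list[str] = []
    residual = z.copy()
    for m in range(cfg.max_imfs):
        if not _siftable(residual, cfg):
            break
        with warnings.catch_warnings(record=True) as wlog:
            warnings.simplefilter("always")
            imf, residual, capped = sift(residual, cfg)
        if capped:
            warns.append(f"IMF {m + 1}: sift iteration cap reached")
        if not np.any(imf):
            break
        imfs.append(imf)
    return IMFSet(imfs=imfs, residual=residual, fs=fs_, config=cfg, warnings_=warns)


# ---------------------------------------------------------------------------
# univariate EMD (for channel-by-channel comparison runs)


def _real_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return _spline_envelope(idx, x[idx], x.size).real


def _emd_mean_amp(x: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    mx, _ = find_peaks(x)
    mn, _ = find_peaks(-x)
    if mx.size < 2 or mn.size < 2:
        return None
    upper = _real_envelope(x, mx)
    lower = _real_envelope(x, mn)
    return (upper + lower) / 2.0, np.abs(upper - lower) / 2.0


def emd_univariate(x: np.ndarray, cfg: SiftConfig | None = None) -> tuple[list[np.ndarray], np.ndarray]:
    """Classical single-channel EMD with the same stop rules as :func:`sift`.

    Local mean = average of the maxima and minima spline envelopes. Provided
    for comparing joint (mode-aligned) against independent channel-by-channel
    decompositions; not used by the feature pipeline.
    """
    cfg = cfg or SiftConfig()
    x = np.asarray(x, float)
    tiny = np.finfo(float).tiny
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(cfg.max_imfs):
        if _emd_mean_amp(residual) is None:
            break
        d = residual.copy()
        for _ in range(cfg.max_sift_iters):
            ma = _emd_mean_amp(d)
            if ma is None:
                break
            m, a = ma
            sx = np.abs(m) / np.maximum(a, tiny)
            if cfg.stop_rule == "rilling" and \
                    np.mean(sx < cfg.theta1) >= 1.0 - cfg.alpha and np.all(sx < cfg.theta2):
                break
            d = d - m
        imfs.append(d)
        residual = residual - d
    return imfs, residual
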