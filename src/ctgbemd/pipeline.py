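"""Feature normalization, ranking, collinearity diagnostics and class balancing.

Everything here operates on a :class:`FeatureMatrix` (records x features with
0/1 labels; vaginal = 0, cesarean = 1 project-wide). Normalization is the
mean/range scaling ``(x - mean) / (max - min)`` with parameters learned on
training rows only. Feature ranking is linear-SVM recursive feature
elimination (smallest squared weight removed each round). Collinearity is
diagnosed with Belsley condition indices and variance-decomposition
proportions. Class imbalance is handled by SMOTE oversampling of the minority
class combined with random undersampling of the majority class; the default
operating point (over 400%, under 100%) yields an exactly balanced training
set with the minority grown to five times its original size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

VAGINAL, CESAREAN = 0, 1


@dataclass
class FeatureMatrix:
    """Records x features with binary labels and per-feature scaling state."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    normalized: bool = False
    normalization_params: pd.DataFrame | None = None  # rows: mean, max, min

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one label per row")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("one name per feature column required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_col: str = "label") -> "FeatureMatrix":
        cols = [c for c in df.columns if c not in (label_col, "record_id")]
        return cls(df[cols].to_numpy(float), df[label_col].to_numpy(int), cols)


def impute_train_median(X: np.ndarray, train_rows: np.ndarray) -> np.ndarray:
    """Replace non-finite entries with the training-row median per feature."""
    X = np.array(X, dtype=float, copy=True)
    med = np.nanmedian(np.where(np.isfinite(X[train_rows]), X[train_rows], np.nan), axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    bad = ~np.isfinite(X)
    X[bad] = np.broadcast_to(med, X.shape)[bad]
    return X


def normalize(fm: FeatureMatrix, fit_rows: np.ndarray | None = None) -> FeatureMatrix:
    """Mean/range scaling with parameters learned on ``fit_rows``.

    Columns constant on the fit subset carry no information and cannot be
    scaled; they are dropped with a warning.
    """
    rows = np.arange(fm.X.shape[0]) if fit_rows is None else np.asarray(fit_rows)
    sub = fm.X[rows]
    mean, mx, mn = sub.mean(axis=0), sub.max(axis=0), sub.min(axis=0)
    rng = mx - mn
    keep = rng > 0
    if not keep.all():
        dropped = [n for n, k in zip(fm.feature_names, keep) if not k]
        warnings.warn(f"dropping constant feature(s) on the fit subset: {dropped}")
    Xn = (fm.X[:, keep] - mean[keep]) / rng[keep]
    names = [n for n, k in zip(fm.feature_names, keep) if k]
    params = pd.DataFrame([mean[keep], mx[keep], mn[keep]],
                          index=["mean", "max", "min"], columns=names)
    return FeatureMatrix(Xn, fm.y.copy(), names, normalized=True,
                         normalization_params=params)


def apply_normalization(X: np.ndarray, params: pd.DataFrame) -> np.ndarray:
    """Apply previously learned scaling parameters to new rows."""
    mean = params.loc["mean"].to_numpy()
    rng = (params.loc["max"] - params.loc["min"]).to_numpy()
    return (np.asarray(X, float) - mean) / rng


@dataclass
class RFEResult:
    elimination_order: list[str]          # first removed ... last survivor
    criterion_history: list[float] = field(default_factory=list)
    subset_metrics: pd.DataFrame | None = None

    def ranking(self) -> list[str]:
        """Features from most to least important (reverse elimination)."""
        return list(reversed(self.elimination_order))


def rfe_rank(X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None,
             step: int = 1, C: float = 1.0) -> RFEResult:
    """Linear-SVM recursive feature elimination.

    At each round a hard/soft-margin linear SVM is fit on the surviving
    features; the feature with the smallest squared weight is removed (ties
    broken toward the lowest feature index). With ``step = 1`` this performs
    exactly p - 1 fits for p features.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    p = X.shape[1]
    names = feature_names or [f"f{i}" for i in range(p)]
    remaining = list(range(p))
    order: list[str] = []
    crit: list[float] = []
    while len(remaining) > 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, remaining], y)
        w2 = np.ravel(clf.coef_) ** 2
        j = int(np.argmin(w2))  # argmin returns the first (lowest-index) tie
        order.append(names[remaining[j]])
        crit.append(float(w2[j]))
        del remaining[j]
    order.append(names[remaining[0]])
    return RFEResult(elimination_order=order, criterion_history=crit)


@dataclass
class CollinearityReport:
    condition_indices: np.ndarray       # ascending, >= 1
    vdp: np.ndarray                     # (n_indices, n_features), cols sum to 1
    flagged: list[list[str]]
    feature_names: list[str]


def belsley(X: np.ndarray, feature_names: list[str] | None = None,
            cond_threshold: float = 30.0, vdp_threshold: float = 0.5) -> CollinearityReport:
    """Belsley collinearity diagnostics via SVD of the column-equilibrated matrix.

    Columns are scaled to unit Euclidean norm; condition indices are
    sigma_max / sigma_i; the variance-decomposition proportion of coefficient
    j on singular value i is ``(v_ji / s_i)^2`` normalised over i. A near
    dependency is flagged when a condition index exceeds ``cond_threshold``
    and at least two coefficients have proportions above ``vdp_threshold``
    there. Exact rank deficiency shows up as an infinite condition index.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    names = feature_names or [f"f{i}" for i in range(p)]
    if n <= p:
        warnings.warn("fewer rows than features; diagnostics may be unstable")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero column(s) cannot be equilibrated")
    Xs = X / norms
    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    tol = s[0] * max(n, p) * np.finfo(float).eps
    with np.errstate(divide="ignore"):
        cond = np.where(s > tol, s[0] / np.maximum(s, np.finfo(float).tiny), np.inf)
    # phi[i, j]: contribution of singular direction i to var(b_j)
    inv_s = np.where(s > tol, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    phi = (Vt * inv_s[:, None]) ** 2
    exact = s <= tol
    if exact.any():
        # an exactly dependent direction absorbs the full variance share of
        # the coefficients it involves
        phi[exact] = (np.abs(Vt[exact]) > np.sqrt(np.finfo(float).eps)).astype(float) * 1e30
    colsum = phi.sum(axis=0)
    vdp = phi / np.where(colsum > 0, colsum, 1.0)
    order = np.argsort(cond)
    cond, vdp = cond[order], vdp[order]
    flagged: list[list[str]] = []
    for i in range(cond.size):
        if cond[i] > cond_threshold:
            grp = [names[j] for j in range(p) if vdp[i, j] > vdp_threshold]
            if len(grp) >= 2:
                flagged.append(grp)
    return CollinearityReport(cond, vdp, flagged, names)


def smote_balance(X: np.ndarray, y: np.ndarray, over_pct: int = 400,
                  under_pct: int = 100, k: int = 5, seed: int | None = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE oversampling of the minority class + majority undersampling.

    For every minority sample, ``over_pct / 100`` synthetic points are drawn
    on the segments toward randomly chosen members of its k nearest minority
    neighbours (uniform interpolation fraction). The majority class is then
    randomly undersampled to ``under_pct / 100`` times the grown minority
    size; the default (400, 100) therefore returns equal class counts with
    the minority at five times its original size. Training rows only — never
    apply to test data.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    mino = classes[np.argmin(counts)]
    majo = classes[1] if mino == classes[0] else classes[0]
    Xm = X[y == mino]
    n_min = Xm.shape[0]
    k_eff = k
    if n_min < k + 1:
        k_eff = max(n_min - 1, 1)
        warnings.warn(f"minority class too small for k={k}; using k={k_eff}")
    n_new_per = over_pct // 100
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    _, nbrs = nn.kneighbors(Xm)  # col 0 is the point itself
    synth = []
    for i in range(n_min):
        for _ in range(n_new_per):
            j = nbrs[i, rng.integers(1, k_eff + 1)]
            u = rng.uniform()
            synth.append(Xm[i] + u * (Xm[j] - Xm[i]))
    X_min = np.vstack([Xm] + [np.asarray(synth)]) if synth else Xm
    n_keep = int(round(under_pct / 100 * X_min.shape[0]))
    Xj = X[y == majo]
    if n_keep < Xj.shape[0]:
        idx = rng.choice(Xj.shape[0], size=n_keep, replace=False)
        Xj = Xj[idx]
    X_out = np.vstack([X_min, Xj])
    y_out = np.concatenate([np.full(X_min.shape[0], mino), np.full(Xj.shape[0], majo)])
    return X_out, y_out
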