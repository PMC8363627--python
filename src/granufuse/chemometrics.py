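"""PCA and NIPALS partial least squares with chemometric diagnostics.

The model family here is the standard single-response PLS1 used throughout
process chemometrics: both blocks are autoscaled (mean 0, unit n-1 standard
deviation per column), successive latent variables maximize the X--y
covariance of the deflated blocks, and the model is summarized by

* ``R^2  = 1 - SSE/SST`` on fitted values,
* ``Q^2  = 1 - prod_a (PRESS_a / SS_{a-1})`` by cross-validation, where
  ``PRESS_a`` is the predicted residual sum of squares at component depth
  ``a`` and ``SS_{a-1}`` the residual sum of squares entering component ``a``
  on the full data,
* per-variable VIP scores (mean of squared VIPs is 1 by construction),
* ``Accuracy`` = fraction of predictions within a stated deviation
  (boundary inclusive), and ``RMSEP`` = root mean squared prediction error,
* Hotelling T^2 with the F-distribution 95% limit for score-space
  outlier/coverage diagnostics.

Component signs are fixed deterministically (largest-magnitude weight or
loading entry positive) so results are reproducible across runs and row
orderings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_EPS = np.finfo(float).eps


class RankError(ValueError):
    """More components requested than the (effective) rank of scaled X."""


@dataclass
class ScalingModel:
    """Per-column mean/sd of a training block; constant columns are dropped."""

    mean: np.ndarray
    std: np.ndarray
    columns: list[str]
    dropped: list[str] = field(default_factory=list)

    def apply(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = self._take(X)
        return (X - self.mean) / self.std

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.std + self.mean

    def _take(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.rename(columns=str)
            missing = [c for c in self.columns if c not in X.columns]
            if missing:
                raise ValueError(f"input lacks training columns: {missing}")
            return X[self.columns].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.columns) + len(self.dropped):
            if X.shape[1] == len(self.columns):
                return X
            raise ValueError(
                f"expected {len(self.columns) + len(self.dropped)} columns, "
                f"got {X.shape[1]}"
            )
        if self.dropped:
            # unnamed input with the original width: drop by stored position
            keep = [i for i, flag in enumerate(self._keep_flags) if flag]
            return X[:, keep]
        return X

    _keep_flags: list[bool] = field(default_factory=list)


def autoscale_fit(X: np.ndarray | pd.DataFrame) -> ScalingModel:
    """Column-wise centering/unit-variance scaling (n-1 denominator).

    Constant columns cannot be scaled; they are dropped with a warning and
    recorded on the returned model.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        names = [f"x{i}" for i in range(arr.shape[1])]
    if arr.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 rows")
    mean = arr.mean(axis=0)
    std = arr.std(axis=0, ddof=1)
    keep = std > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"constant columns dropped before scaling: {dropped}")
    sm = ScalingModel(mean=mean[keep], std=std[keep],
                      columns=[n for n, k in zip(names, keep) if k],
                      dropped=dropped)
    sm._keep_flags = list(keep)
    return sm


def autoscale_apply(sm: ScalingModel, X) -> np.ndarray:
    return sm.apply(X)


def _fix_sign(vec: np.ndarray) -> float:
    """Return +-1 making the largest-magnitude entry of ``vec`` positive."""
    j = int(np.argmax(np.abs(vec)))
    return -1.0 if vec[j] < 0 else 1.0


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    n_components: int
    loadings: np.ndarray          # (p, A), orthonormal columns
    scores: np.ndarray            # (n, A)
    explained: np.ndarray         # variance fraction per component
    scaler: ScalingModel
    t2_limit: float               # Hotelling 95% limit on the A components

    def project(self, X) -> np.ndarray:
        return self.scaler.apply(X) @ self.loadings


def fit_pca(X, n_components: int, alpha: float = 0.05) -> PCAModel:
    """PCA of the autoscaled matrix via singular value decomposition."""
    scaler = autoscale_fit(X)
    Xs = scaler.apply(X)
    n, p = Xs.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise RankError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    signs = np.array([_fix_sign(Vt[a]) for a in range(len(s))])
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    A = n_components
    scores = U[:, :A] * s[:A]
    explained = (s ** 2 / (s ** 2).sum())[:A]
    _, limit = hotelling_t2(scores, A, alpha=alpha)
    return PCAModel(A, Vt[:A].T, scores, explained, scaler, limit)


def hotelling_t2(scores: np.ndarray, n_components: int | None = None,
                 alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Per-row Hotelling T^2 on (centered) score columns plus its limit.

    T^2_i = sum_a t_ia^2 / var(t_a);
    limit = A (N^2 - 1) / (N (N - A)) * F_{1-alpha}(A, N - A).
    """
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    A = n_components or T.shape[1]
    T = T[:, :A]
    n = T.shape[0]
    if n <= A:
        raise ValueError(f"need more rows ({n}) than components ({A})")
    var = T.var(axis=0, ddof=1)
    if np.any(var <= 0):
        # all-identical scores on a component: that direction carries no
        # distance information
        var = np.where(var > 0, var, np.inf)
    t2 = (T ** 2 / var).sum(axis=1)
    fcrit = stats.f.ppf(1.0 - alpha, A, n - A)
    limit = A * (n ** 2 - 1) / (n * (n - A)) * fcrit
    return t2, float(limit)


# ---------------------------------------------------------------------------
# PLS (NIPALS, single response)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Single-y NIPALS PLS model on autoscaled blocks.

    Matrices follow the usual chemometric naming: X-weights ``W`` (columns
    unit norm), X-loadings ``P``, y-loadings ``c``, scores ``T``, transformed
    weights ``Wstar = W (P'W)^-1`` such that ``T = Xs @ Wstar``, and the
    pooled regression vector ``B = Wstar @ c`` on scaled data.
    """

    n_components: int
    W: np.ndarray
    P: np.ndarray
    c: np.ndarray
    T: np.ndarray
    Wstar: np.ndarray
    B: np.ndarray
    x_scaler: ScalingModel
    y_mean: float
    y_std: float
    r2x: np.ndarray            # explained X-variance fraction per component
    r2y: np.ndarray            # explained y-variance fraction per component
    columns: list[str]

    # -- prediction / projection -------------------------------------------
    def predict(self, Xnew, n_components: int | None = None) -> np.ndarray:
        """Predicted response in original units."""
        A = n_components or self.n_components
        Xs = self.x_scaler.apply(Xnew)
        b = self.Wstar[:, :A] @ self.c[:A]
        return self.y_mean + self.y_std * (Xs @ b)

    def predict_depths(self, Xnew) -> np.ndarray:
        """Predictions at every component depth 1..A, shape (n, A)."""
        Xs = self.x_scaler.apply(Xnew)
        Bs = np.cumsum(self.Wstar * self.c[None, :], axis=1)
        return self.y_mean + self.y_std * (Xs @ Bs)

    def project(self, Xnew) -> np.ndarray:
        """Score matrix of new rows in the model's latent space."""
        return self.x_scaler.apply(Xnew) @ self.Wstar

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "n_components": self.n_components,
            "W": self.W.tolist(), "P": self.P.tolist(), "c": self.c.tolist(),
            "T": self.T.tolist(), "Wstar": self.Wstar.tolist(),
            "B": self.B.tolist(),
            "x_mean": self.x_scaler.mean.tolist(),
            "x_std": self.x_scaler.std.tolist(),
            "x_columns": self.x_scaler.columns,
            "x_dropped": self.x_scaler.dropped,
            "y_mean": self.y_mean, "y_std": self.y_std,
            "r2x": self.r2x.tolist(), "r2y": self.r2y.tolist(),
            "columns": self.columns,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        scaler = ScalingModel(mean=np.array(d["x_mean"]),
                              std=np.array(d["x_std"]),
                              columns=list(d["x_columns"]),
                              dropped=list(d["x_dropped"]))
        return cls(
            n_components=d["n_components"],
            W=np.array(d["W"]), P=np.array(d["P"]), c=np.array(d["c"]),
            T=np.array(d["T"]), Wstar=np.array(d["Wstar"]),
            B=np.array(d["B"]), x_scaler=scaler,
            y_mean=d["y_mean"], y_std=d["y_std"],
            r2x=np.array(d["r2x"]), r2y=np.array(d["r2y"]),
            columns=list(d["columns"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PLSModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit_pls(X, y, n_components: int) -> PLSModel:
    """Fit a single-response PLS model by the (non-iterative) NIPALS sequence.

    Per component: ``w = X'y / ||X'y||``; ``t = Xw``; ``p = X't / t't``;
    ``c = y't / t't``; then X and y are deflated by the rank-one fits.
    Requesting more components than the effective rank of scaled X raises
    :class:`RankError`.
    """
    columns = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) \
        else [f"x{i}" for i in range(np.atleast_2d(X).shape[1])]
    x_scaler = autoscale_fit(X)
    Xs = x_scaler.apply(X)
    yarr = np.asarray(y, dtype=float).ravel()
    if yarr.size != Xs.shape[0]:
        raise ValueError("X and y row counts differ")
    y_mean = float(yarr.mean())
    y_std = float(yarr.std(ddof=1))
    if y_std <= 0:
        raise ValueError("response is constant")
    ys = (yarr - y_mean) / y_std

    n, p = Xs.shape
    A = int(n_components)
    if not 1 <= A <= min(n - 1, p):
        raise RankError(f"n_components must be in [1, {min(n - 1, p)}], got {A}")

    ssx_total = float((Xs ** 2).sum())
    ssy_total = float((ys ** 2).sum())
    Xa, ya = Xs.copy(), ys.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    c = np.zeros(A)
    T = np.zeros((n, A))
    r2x = np.zeros(A)
    r2y = np.zeros(A)
    tol = max(n, p) * _EPS * max(1.0, np.linalg.norm(Xs))
    for a in range(A):
        cov = Xa.T @ ya
        nrm = np.linalg.norm(cov)
        if nrm <= tol:
            raise RankError(
                f"scaled X exhausted after {a} components; cannot extract "
                f"{A} (covariance with y vanished)"
            )
        w = cov / nrm
        w *= _fix_sign(w)
        t = Xa @ w
        tt = float(t @ t)
        if tt <= tol ** 2:
            raise RankError(f"degenerate score on component {a + 1}")
        pvec = Xa.T @ t / tt
        cval = float(ya @ t) / tt
        Xa -= np.outer(t, pvec)
        ya = ya - cval * t
        W[:, a], P[:, a], c[a], T[:, a] = w, pvec, cval, t
        r2x[a] = tt * float(pvec @ pvec) / ssx_total
        r2y[a] = cval ** 2 * tt / ssy_total

    Wstar = W @ np.linalg.inv(P.T @ W)
    B = Wstar @ c
    return PLSModel(A, W, P, c, T, Wstar, B, x_scaler, y_mean, y_std,
                    r2x, r2y, columns)


def pls_predict(model: PLSModel, Xnew) -> np.ndarray:
    return model.predict(Xnew)


def pls_project(model: PLSModel, Xnew) -> np.ndarray:
    return model.project(Xnew)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def r2(y_obs, y_fit) -> float:
    """Coefficient of determination: 1 - SSE / SST."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_fit = np.asarray(y_fit, dtype=float).ravel()
    sse = float(((y_obs - y_fit) ** 2).sum())
    sst = float(((y_obs - y_obs.mean()) ** 2).sum())
    return 1.0 - sse / sst


def rmsep(y_obs, y_pred) -> float:
    """Root mean square error of prediction."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def accuracy(y_obs, y_pred, deviation: float) -> float:
    """Fraction of predictions with |error| <= deviation (inclusive bound)."""
    if deviation < 0:
        raise ValueError("deviation must be >= 0")
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    return float(np.mean(np.abs(y_pred - y_obs) <= deviation))


def cv_folds(n: int, folds: int, seed: int | None = 0) -> np.ndarray:
    """Venetian-blind fold assignment after a seeded shuffle.

    Rows are shuffled once, then dealt to folds in rotation, giving folds of
    near-equal size whose composition is reproducible from the seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot make {folds} non-empty folds from {n} rows")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    fold_id[order] = np.arange(n) % folds
    return fold_id


def q2_cv(X, y, n_components: int, folds: int = 7, seed: int | None = 0,
          fold_id: np.ndarray | None = None) -> dict:
    """Cumulative Q^2 by the product formula, with the per-component ledger.

    ``PRESS_a`` sums squared cross-validated errors of the depth-``a``
    prediction (each fold's model refit without that fold); ``SS_a`` is the
    residual sum of squares after ``a`` components of the full-data fit
    (``SS_0`` is the total sum of squares about the mean).  Both are in
    original response units, so each ratio PRESS_a / SS_{a-1} is scale-free.

    Returns a dict with ``q2`` (cumulative), ``q2_per_depth``, ``press``,
    ``ss`` (length A+1, starting at SS_0) and ``fold_id``.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.atleast_2d(X))
    yarr = np.asarray(y, dtype=float).ravel()
    n = len(yarr)
    A = int(n_components)
    if fold_id is None:
        fold_id = cv_folds(n, folds, seed)
    else:
        fold_id = np.asarray(fold_id, dtype=int)
    preds = np.full((n, A), np.nan)
    for f in np.unique(fold_id):
        test = fold_id == f
        train = ~test
        if test.sum() == 0 or train.sum() == 0:
            raise ValueError(f"fold {f} leaves an empty partition")
        sub = fit_pls(Xdf.iloc[np.where(train)[0]], yarr[train], A)
        preds[test] = sub.predict_depths(Xdf.iloc[np.where(test)[0]])
    press = ((yarr[:, None] - preds) ** 2).sum(axis=0)

    full = fit_pls(Xdf, yarr, A)
    depth_fit = full.predict_depths(Xdf)
    ss = np.empty(A + 1)
    ss[0] = float(((yarr - yarr.mean()) ** 2).sum())
    for a in range(1, A + 1):
        ss[a] = float(((yarr - depth_fit[:, a - 1]) ** 2).sum())
    ratios = press / ss[:-1]
    q2_per_depth = 1.0 - np.cumprod(ratios)
    return {
        "q2": float(q2_per_depth[-1]),
        "q2_per_depth": q2_per_depth,
        "press": press,
        "ss": ss,
        "fold_id": fold_id,
    }


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_k = sqrt( K * sum_a SSY_a (w_ak / ||w_a||)^2 / sum_a SSY_a ), where
    SSY_a is the y-variance explained by component a.  The mean of squared
    VIPs equals 1 (weights have unit norm).
    """
    K = model.W.shape[0]
    ssy = model.r2y  # proportional to explained SSY; the constant cancels
    wnorm2 = (model.W ** 2) / (model.W ** 2).sum(axis=0)
    num = (wnorm2 * ssy[None, :]).sum(axis=1)
    return np.sqrt(K * num / ssy.sum())


def select_n_lv(X, y, a_max: int, folds: int = 7, delta: float = 0.01,
                seed: int | None = 0) -> tuple[int, pd.DataFrame]:
    """Choose the number of latent variables by the R^2/Q^2 plateau rule.

    The chosen A is the smallest depth where adding one more component
    increases *both* cumulative R^2 and Q^2 by less than ``delta``; if no
    plateau occurs the maximum depth is kept.  The full per-depth ledger is
    returned for reporting.
    """
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    yarr = np.asarray(y, dtype=float).ravel()
    full = fit_pls(X, yarr, a_max)
    depth_fit = full.predict_depths(X)
    r2s = np.array([r2(yarr, depth_fit[:, a]) for a in range(a_max)])
    cv = q2_cv(X, yarr, a_max, folds=folds, seed=seed)
    q2s = cv["q2_per_depth"]
    ledger = pd.DataFrame({
        "A": np.arange(1, a_max + 1),
        "R2": r2s,
        "Q2": q2s,
        "dR2": np.diff(r2s, prepend=np.nan),
        "dQ2": np.diff(q2s, prepend=np.nan),
    })
    chosen = a_max
    for a in range(a_max - 1):
        if (r2s[a + 1] - r2s[a] < delta) and (q2s[a + 1] - q2s[a] < delta):
            chosen = a + 1
            break
    return chosen, ledger
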