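"""The three BP regression models and their shared numerics.

* :func:`pls_fit` / :func:`pls_predict` — partial least squares by
  iterative covariance-maximizing projection with deflation, on
  autoscaled X and y. Each component's weight vector is the normalized
  cross-covariance ``w_i = X_i' y_i / ||X_i' y_i||``; scores, loadings and
  coefficients follow, and both X and y are deflated before the next
  component. With as many components as columns this reproduces ordinary
  least squares.
* :func:`lwpls_predict` — just-in-time locally weighted PLS: for each
  query, training samples are weighted by a similarity that decays
  exponentially in Mahalanobis distance from the query, the weighted
  component equations are iterated, and the query is projected alongside.
* :func:`gpr_fit` / :func:`gpr_predict` — Gaussian process regression
  with an RBF kernel (length scale initialized at 1) contaminated with
  white noise (noise level initialized at 1) on standardized inputs;
  hyper-parameters are optionally refined by maximizing the log marginal
  likelihood.

The default latent dimension is ``D = 2`` for both PLS variants
(selectable by cross-validated R²; see :func:`r2_cv`).
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as spla
from scipy import optimize as spopt

from .errors import (
    DegenerateComponentError,
    InvalidArgumentError,
    InvalidCovarianceError,
    NoNeighborsError,
    NumericalError,
    UnstableLocalFitError,
)

__all__ = [
    "DEFAULT_COMPONENTS",
    "PLSModel",
    "LWPLSQuery",
    "GPRModel",
    "pls_fit",
    "pls_predict",
    "r2_cv",
    "mahalanobis_distance",
    "similarity_weights",
    "lwpls_predict",
    "gpr_fit",
    "gpr_predict",
    "save_model",
    "load_model",
]

DEFAULT_COMPONENTS = 2
_EPS = 1e-12


def _standardize_fit(A: np.ndarray):
    center = A.mean(axis=0)
    scale = A.std(axis=0, ddof=0)
    scale = np.where(scale < _EPS, 1.0, scale)
    return center, scale


# ---------------------------------------------------------------------------
# PLS


@dataclass
class PLSModel:
    """Fitted PLS regression: weights W, loadings P, coefficients q and
    the autoscaling parameters, plus the final residuals for diagnostics."""

    W: np.ndarray
    Pload: np.ndarray
    q: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    E: np.ndarray
    f: np.ndarray

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def coef_(self) -> np.ndarray:
        """Regression vector in standardized space: B = W (P'W)^-1 q."""
        PW = self.Pload.T @ self.W
        return self.W @ np.linalg.solve(PW, self.q)


def pls_fit(X: np.ndarray, y: np.ndarray, D: int = DEFAULT_COMPONENTS) -> PLSModel:
    """Fit PLS with ``D`` latent components on autoscaled X, y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise InvalidArgumentError("X and y lengths differ")
    if D < 1 or D > p:
        raise InvalidArgumentError(f"D must lie in [1, {p}]")
    if n <= D:
        raise InvalidArgumentError("need more samples than components")
    x_center, x_scale = _standardize_fit(X)
    y_center, y_scale = float(y.mean()), float(y.std(ddof=0))
    if y_scale < _EPS:
        y_scale = 1.0
    Xi = (X - x_center) / x_scale
    yi = (y - y_center) / y_scale

    W = np.empty((p, D))
    P = np.empty((p, D))
    q = np.empty(D)
    for i in range(D):
        cov = Xi.T @ yi
        nrm = np.linalg.norm(cov)
        if nrm < _EPS:
            raise DegenerateComponentError(
                f"y orthogonal to remaining X at component {i + 1}"
            )
        w = cov / nrm
        t = Xi @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise DegenerateComponentError(f"vanishing score at component {i + 1}")
        pvec = Xi.T @ t / tt
        qi = float(yi @ t) / tt
        Xi = Xi - np.outer(t, pvec)
        yi = yi - t * qi
        W[:, i], P[:, i], q[i] = w, pvec, qi
    return PLSModel(
        W=W, Pload=P, q=q,
        x_center=x_center, x_scale=x_scale,
        y_center=y_center, y_scale=y_scale,
        E=Xi, f=yi,
    )


def pls_predict(model: PLSModel, x: np.ndarray) -> np.ndarray | float:
    """Predict targets for one query vector or a matrix of queries."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.x_center.size:
        raise InvalidArgumentError(
            f"expected {model.x_center.size} features, got {X.shape[1]}"
        )
    Z = (X - model.x_center) / model.x_scale
    yhat = model.y_center + model.y_scale * (Z @ model.coef_)
    return float(yhat[0]) if single else yhat


def r2_cv(
    X: np.ndarray,
    y: np.ndarray,
    D_candidates=(1, 2, 3, 4),
    folds: int = 5,
    seed: int = 0,
) -> dict[int, float]:
    """Cross-validated coefficient of determination per candidate D:
    ``1 - sum (y_i - yhat_cv,i)^2 / sum (y_i - ybar)^2`` over seeded
    shuffled K folds."""
    from sklearn.model_selection import KFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise InvalidArgumentError("folds must be at least 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < _EPS:
        raise InvalidArgumentError("constant y: cross-validated R2 undefined")
    out: dict[int, float] = {}
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    for D in D_candidates:
        yhat = np.empty_like(y)
        for train, test in splits:
            m = pls_fit(X[train], y[train], D=D)
            yhat[test] = pls_predict(m, X[test])
        out[int(D)] = 1.0 - float(np.sum((y - yhat) ** 2)) / sst
    return out


# ---------------------------------------------------------------------------
# Mahalanobis similarity and LW-PLS


def _inv_covariance(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidArgumentError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise InvalidArgumentError("S must be symmetric")
    eig = np.linalg.eigvalsh(S)
    tol = 1e-8 * max(1.0, float(np.abs(eig).max()))
    if eig.min() < -tol:
        raise InvalidCovarianceError("S has negative eigenvalues beyond tolerance")
    p = S.shape[0]
    cond_bad = eig.min() <= tol
    if cond_bad:
        S = S + (1e-8 * np.trace(S) / p) * np.eye(p)
    return np.linalg.pinv(S)


def mahalanobis_distance(
    xi: np.ndarray, xj: np.ndarray, S: np.ndarray, S_inv: np.ndarray | None = None
) -> float:
    """sqrt((xi - xj)' S^-1 (xi - xj)); a regularized pseudo-inverse is
    used when S is singular or near-singular."""
    d = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    Si = _inv_covariance(S) if S_inv is None else S_inv
    val = float(d @ Si @ d)
    return float(np.sqrt(max(val, 0.0)))


def similarity_weights(
    Xt: np.ndarray,
    xr: np.ndarray,
    S: np.ndarray,
    phi: float = 1.0,
    stabilize: bool = False,
) -> np.ndarray:
    """Diagonal of the similarity matrix U: ``u_i = exp(-d_i / (sigma_d * phi))``
    with d_i the Mahalanobis distance of training row i from the query and
    sigma_d the standard deviation of those distances (the usual
    localization normalization; phi > 0 tunes how sharply weights decay).

    With ``stabilize`` the exponent is shifted by the minimum distance,
    which rescales every weight by the same constant: the weighted
    component equations are invariant to that scaling, but the weights can
    no longer underflow for queries far from all training rows.
    """
    if phi <= 0:
        raise InvalidArgumentError("phi must be positive")
    Xt = np.asarray(Xt, dtype=float)
    Si = _inv_covariance(S)
    diffs = Xt - np.asarray(xr, dtype=float)
    d = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diffs, Si, diffs), 0.0))
    sigma = float(d.std(ddof=0))
    if sigma < _EPS:
        u = np.ones_like(d)
    else:
        shift = d.min() if stabilize else 0.0
        u = np.exp(-(d - shift) / (sigma * phi))
    if not np.any(u > 1e-12):
        raise NoNeighborsError("all similarity weights underflowed")
    return u


@dataclass
class LWPLSQuery:
    """Training context for locally weighted PLS predictions.

    ``S`` (the covariance for the distance metric) defaults to the
    covariance of the training features. Inputs are autoscaled once at
    construction so the weighted component equations operate on the same
    scale as the global PLS model.
    """

    Xt: np.ndarray
    yt: np.ndarray
    phi: float = 1.0
    D: int = DEFAULT_COMPONENTS
    S: np.ndarray | None = None
    #: with strict off, queries whose locality weights sum below D + 1 are
    #: still predicted (the estimate shrinks toward the local weighted
    #: mean) instead of raising; used by rolling evaluation where distant
    #: queries are the norm early in a subject's record
    strict: bool = True
    _x_center: np.ndarray = field(init=False, repr=False)
    _x_scale: np.ndarray = field(init=False, repr=False)
    _y_center: float = field(init=False, repr=False)
    _y_scale: float = field(init=False, repr=False)
    _Z: np.ndarray = field(init=False, repr=False)
    _z_y: np.ndarray = field(init=False, repr=False)
    _S_std: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.Xt = np.asarray(self.Xt, dtype=float)
        self.yt = np.asarray(self.yt, dtype=float).ravel()
        m, p = self.Xt.shape
        if self.yt.size != m:
            raise InvalidArgumentError("Xt and yt lengths differ")
        if m < self.D + 1:
            raise InvalidArgumentError("need at least D + 1 training samples")
        if self.phi <= 0:
            raise InvalidArgumentError("phi must be positive")
        if self.S is None:
            self.S = np.cov(self.Xt, rowvar=False) if m > 1 else np.eye(p)
            self.S = np.atleast_2d(self.S)
        self._x_center, self._x_scale = _standardize_fit(self.Xt)
        self._y_center = float(self.yt.mean())
        self._y_scale = float(self.yt.std(ddof=0)) or 1.0
        self._Z = (self.Xt - self._x_center) / self._x_scale
        self._z_y = (self.yt - self._y_center) / self._y_scale
        # distance metric in standardized coordinates (same Mahalanobis
        # distances as in raw coordinates under the matching covariance)
        self._S_std = self.S / np.outer(self._x_scale, self._x_scale)


def lwpls_predict(query: LWPLSQuery, xr: np.ndarray) -> float:
    """Locally weighted PLS estimate at request ``xr``.

    Builds the similarity diagonal U from Mahalanobis distances, centers
    X and y on their U-weighted means, iterates the weighted component
    equations with deflation while projecting the centered request
    alongside, and returns the weighted-mean target plus the accumulated
    score-times-coefficient sum.
    """
    xr = np.asarray(xr, dtype=float)
    if xr.size != query.Xt.shape[1]:
        raise InvalidArgumentError("query dimension mismatch")
    zr = (xr - query._x_center) / query._x_scale
    try:
        u = similarity_weights(query._Z, zr, query._S_std, phi=query.phi)
    except NoNeighborsError:
        if query.strict:
            raise
        u = similarity_weights(
            query._Z, zr, query._S_std, phi=query.phi, stabilize=True
        )
    # A query sitting exactly on a training sample (weight 1) degenerates
    # gracefully to that sample's target, so the effective-size guard only
    # applies away from the training set.
    if query.strict and float(u.max()) < 1.0 - 1e-12 and float(u.sum()) < query.D + 1:
        raise UnstableLocalFitError(
            f"effective local sample size {u.sum():.3g} < D + 1 = {query.D + 1}"
        )
    usum = float(u.sum())
    xw = (u @ query._Z) / usum
    yw = float(u @ query._z_y) / usum
    X0 = query._Z - xw
    y0 = query._z_y - yw
    x0r = zr - xw

    yhat = yw
    for _ in range(query.D):
        cov = X0.T @ (u * y0)
        nrm = np.linalg.norm(cov)
        if nrm < _EPS:
            break  # remaining weighted covariance exhausted
        w = cov / nrm
        t = X0 @ w
        tut = float(t @ (u * t))
        if tut < _EPS:
            break
        pvec = X0.T @ (u * t) / tut
        qa = float(y0 @ (u * t)) / tut
        tr = float(x0r @ w)
        yhat += tr * qa
        X0 = X0 - np.outer(t, pvec)
        y0 = y0 - t * qa
        x0r = x0r - tr * pvec
    return query._y_center + query._y_scale * yhat


# ---------------------------------------------------------------------------
# Gaussian process regression


@dataclass
class GPRModel:
    """Fitted GP with RBF + white-noise kernel on autoscaled inputs."""

    Xtrain: np.ndarray  # standardized
    alpha_vec: np.ndarray
    rbf_scale: float
    signal_var: float
    noise_level: float
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    optimize_flag: bool
    log_marginal_likelihood: float
    _chol: np.ndarray = field(repr=False, default=None)


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = np.sum(A * A, axis=1)[:, None]
    bb = np.sum(B * B, axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * (A @ B.T), 0.0)


def _chol_with_jitter(K: np.ndarray):
    jitters = (0.0, 1e-10, 1e-8, 1e-6)
    scale = float(np.mean(np.diag(K)))
    for j in jitters:
        try:
            return spla.cholesky(K + j * scale * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
        except spla.LinAlgError:  # pragma: no cover - alias on some scipys
            continue
    raise NumericalError("kernel factorization failed after jitter escalation")


def gpr_fit(
    X: np.ndarray,
    y: np.ndarray,
    optimize: bool = True,
    rbf_scale: float = 1.0,
    signal_var: float = 1.0,
    noise_level: float = 1.0,
    bounds: tuple[float, float] = (1e-3, 1e3),
    maxiter: int = 50,
) -> GPRModel:
    """Fit the GP. With ``optimize`` on (default) the three kernel
    hyper-parameters are refined by L-BFGS-B on the log marginal
    likelihood (analytic gradients, log-parameterization, box bounds),
    starting from the stated initial values."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise InvalidArgumentError("X and y lengths differ")
    x_center, x_scale = _standardize_fit(X)
    y_center = float(y.mean())
    y_scale = float(y.std(ddof=0)) or 1.0
    Z = (X - x_center) / x_scale
    z_y = (y - y_center) / y_scale
    n = Z.shape[0]
    D2 = _sq_dists(Z, Z)

    def neg_lml(theta: np.ndarray):
        ls, sv, nl = np.exp(theta)
        E = np.exp(-D2 / (2.0 * ls * ls))
        K = sv * E + nl * np.eye(n)
        L = _chol_with_jitter(K)
        alpha = spla.cho_solve((L, True), z_y)
        lml = (
            -0.5 * float(z_y @ alpha)
            - float(np.sum(np.log(np.diag(L))))
            - 0.5 * n * np.log(2.0 * np.pi)
        )
        Kinv = spla.cho_solve((L, True), np.eye(n))
        A = np.outer(alpha, alpha) - Kinv
        dK_ls = sv * E * (D2 / (ls * ls))
        dK_sv = sv * E
        dK_nl = nl * np.eye(n)
        grad = 0.5 * np.array(
            [np.sum(A * dK_ls), np.sum(A * dK_sv), np.sum(A * dK_nl)]
        )
        return -lml, -grad

    theta0 = np.log([rbf_scale, signal_var, noise_level])
    if optimize:
        lo, hi = np.log(bounds[0]), np.log(bounds[1])
        res = spopt.minimize(
            neg_lml,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * 3,
            options={"maxiter": maxiter},
        )
        theta = res.x
    else:
        theta = theta0
    ls, sv, nl = np.exp(theta)
    E = np.exp(-D2 / (2.0 * ls * ls))
    K = sv * E + nl * np.eye(n)
    L = _chol_with_jitter(K)
    alpha = spla.cho_solve((L, True), z_y)
    lml = (
        -0.5 * float(z_y @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    return GPRModel(
        Xtrain=Z,
        alpha_vec=alpha,
        rbf_scale=float(ls),
        signal_var=float(sv),
        noise_level=float(nl),
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        optimize_flag=bool(optimize),
        log_marginal_likelihood=lml,
        _chol=L,
    )


def gpr_predict(
    model: GPRModel, x: np.ndarray, return_sd: bool = False
):
    """Posterior mean (and optionally SD) at one query or a matrix of
    queries, de-standardized to mmHg."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xq = np.atleast_2d(x)
    if Xq.shape[1] != model.x_center.size:
        raise InvalidArgumentError("query dimension mismatch")
    Zq = (Xq - model.x_center) / model.x_scale
    D2 = _sq_dists(Zq, model.Xtrain)
    Kstar = model.signal_var * np.exp(-D2 / (2.0 * model.rbf_scale**2))
    mean_std = Kstar @ model.alpha_vec
    mean = model.y_center + model.y_scale * mean_std
    if not return_sd:
        return float(mean[0]) if single else mean
    v = spla.solve_triangular(model._chol, Kstar.T, lower=True)
    var = model.signal_var - np.sum(v * v, axis=0)
    sd = model.y_scale * np.sqrt(np.maximum(var, 0.0))
    if single:
        return float(mean[0]), float(sd[0])
    return mean, sd


# ---------------------------------------------------------------------------
# JSON persistence


def _enc(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=float)
    return {
        "shape": list(a.shape),
        "data": base64.b64encode(a.tobytes()).decode("ascii"),
    }


def _dec(d: dict) -> np.ndarray:
    a = np.frombuffer(base64.b64decode(d["data"]), dtype=float)
    return a.reshape(d["shape"]).copy()


def save_model(model, path) -> None:
    """Serialize a PLSModel or GPRModel to JSON (scalars + base64 arrays)."""
    if isinstance(model, PLSModel):
        payload = {
            "kind": "pls",
            "W": _enc(model.W), "Pload": _enc(model.Pload), "q": _enc(model.q),
            "x_center": _enc(model.x_center), "x_scale": _enc(model.x_scale),
            "y_center": model.y_center, "y_scale": model.y_scale,
            "E": _enc(model.E), "f": _enc(model.f),
        }
    elif isinstance(model, GPRModel):
        payload = {
            "kind": "gpr",
            "Xtrain": _enc(model.Xtrain), "alpha_vec": _enc(model.alpha_vec),
            "rbf_scale": model.rbf_scale, "signal_var": model.signal_var,
            "noise_level": model.noise_level,
            "x_center": _enc(model.x_center), "x_scale": _enc(model.x_scale),
            "y_center": model.y_center, "y_scale": model.y_scale,
            "optimize_flag": model.optimize_flag,
            "log_marginal_likelihood": model.log_marginal_likelihood,
            "chol": _enc(model._chol),
        }
    else:
        raise InvalidArgumentError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Inverse of :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.get("kind")
    if kind == "pls":
        return PLSModel(
            W=_dec(payload["W"]), Pload=_dec(payload["Pload"]), q=_dec(payload["q"]),
            x_center=_dec(payload["x_center"]), x_scale=_dec(payload["x_scale"]),
            y_center=payload["y_center"], y_scale=payload["y_scale"],
            E=_dec(payload["E"]), f=_dec(payload["f"]),
        )
    if kind == "gpr":
        return GPRModel(
            Xtrain=_dec(payload["Xtrain"]), alpha_vec=_dec(payload["alpha_vec"]),
            rbf_scale=payload["rbf_scale"], signal_var=payload["signal_var"],
            noise_level=payload["noise_level"],
            x_center=_dec(payload["x_center"]), x_scale=_dec(payload["x_scale"]),
            y_center=payload["y_center"], y_scale=payload["y_scale"],
            optimize_flag=payload["optimize_flag"],
            log_marginal_likelihood=payload["log_marginal_likelihood"],
            _chol=_dec(payload["chol"]),
        )
    raise InvalidArgumentError(f"unknown model kind {kind!r}")
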