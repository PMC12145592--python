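"""Orthogonal-scores partial least squares (PLS1/PLS2) with LOO cross-validation.

The decomposition extracts components sequentially: the a-th weight vector is
the dominant left singular vector of X_a' Y_a (for a single response this is
the normalized covariance vector), the score is t_a = X_a w_a, and both X and
Y are deflated by the rank-one score approximation — the classical
orthogonal-scores variant, in which training scores are mutually orthogonal.
Regression coefficients for any truncation a follow from
B_a = W_a (P_a' W_a)^{-1} Q_a'.

Multi-response (PLS2) fitting is the default; because the coefficient stack
is kept for every component count 1..A, each response can still be truncated
at its own cross-validated component count ("evaluated individually") without
refitting.  Weight vectors are sign-normalized (largest-magnitude element
positive), making fits bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateResponseError,
    DimensionError,
    ParameterError,
)


@dataclass
class PLSModel:
    """Fitted orthogonal-scores PLS model.

    ``coefs`` has shape (A, p, m): ``coefs[a-1]`` are the regression
    coefficients using the first a components.  ``selected`` holds the
    per-response component counts chosen by cross-validation (defaults to A).
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray      # p x A
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # m x A
    scores: np.ndarray       # n x A (training scores)
    coefs: np.ndarray        # A x p x m
    n_components: int
    selected: np.ndarray     # m, per-response component counts
    response_names: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_responses(self) -> int:
        return self.y_loadings.shape[0]

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "coefs": self.coefs.tolist(),
            "n_components": self.n_components,
            "selected": self.selected.tolist(),
            "response_names": self.response_names,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=np.asarray(d["y_mean"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            coefs=np.asarray(d["coefs"], dtype=float),
            n_components=int(d["n_components"]),
            selected=np.asarray(d["selected"], dtype=int),
            response_names=list(d.get("response_names", [])),
            provenance=dict(d.get("provenance", {})),
        )


def save_model(model: PLSModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), sort_keys=True))


def load_model(path) -> PLSModel:
    try:
        return PLSModel.from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParameterError(f"cannot load model file {path}: {exc}") from exc


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    response_names: list[str] | None = None,
    provenance: dict | None = None,
) -> PLSModel:
    """Fit an orthogonal-scores PLS model on centered copies of X and Y.

    If the X-Y covariance is exhausted before ``n_components`` (e.g. a
    noiseless low-rank relationship), extraction stops early and the
    coefficient stack repeats its last entry, which leaves predictions
    unchanged for larger component counts.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise DimensionError("X and Y must have the same number of rows")
    m = Y.shape[1]
    a_bound = min(n - 1, p)
    if not (1 <= n_components <= a_bound):
        raise ParameterError(
            f"n_components must be in [1, min(n-1, p)] = [1, {a_bound}]"
        )
    if np.any(Y.std(axis=0) == 0):
        raise DegenerateResponseError("a response column has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xa = X - x_mean
    Ya = Y - y_mean
    cov0 = np.linalg.norm(Xa.T @ Ya)

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    T = np.zeros((n, n_components))
    a_eff = 0
    for a in range(n_components):
        M = Xa.T @ Ya
        if m == 1:
            nrm = np.linalg.norm(M[:, 0])
            if nrm <= 1e-13 * max(cov0, 1e-300):
                break
            w = M[:, 0] / nrm
        else:
            u, s, _ = np.linalg.svd(M, full_matrices=False)
            if s[0] <= 1e-13 * max(cov0, 1e-300):
                break
            w = u[:, 0]
        # sign convention: largest-magnitude element positive
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p_a = (Xa.T @ t) / tt
        q_a = (Ya.T @ t) / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t
        Xa = Xa - np.outer(t, p_a)
        Ya = Ya - np.outer(t, q_a)
        a_eff += 1
    if a_eff == 0:
        raise DegenerateResponseError("X carries no covariance with Y")

    coefs = np.zeros((n_components, p, m))
    for a in range(1, a_eff + 1):
        Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
        coefs[a - 1] = Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)
    for a in range(a_eff, n_components):
        coefs[a] = coefs[a_eff - 1]

    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coefs=coefs,
        n_components=n_components,
        selected=np.full(m, n_components, dtype=int),
        response_names=list(response_names or [f"y{j}" for j in range(m)]),
        provenance=dict(provenance or {}),
    )


def predict_pls(
    model: PLSModel,
    X_new: np.ndarray,
    components_per_response: np.ndarray | int | None = None,
) -> np.ndarray:
    """Predict responses for preprocessed spectra.

    X_new is centered with the model's training mean (never its own), and
    response j uses the coefficient stack truncated at its selected
    component count.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_channels:
        raise DimensionError(
            f"X_new has {X_new.shape[1]} channels, model expects {model.n_channels}"
        )
    m = model.n_responses
    if components_per_response is None:
        comps = model.selected
    elif np.isscalar(components_per_response):
        comps = np.full(m, int(components_per_response), dtype=int)
    else:
        comps = np.asarray(components_per_response, dtype=int)
        if comps.shape != (m,):
            raise DimensionError("components_per_response must have one entry per response")
    if np.any(comps < 1) or np.any(comps > model.n_components):
        raise ParameterError("component counts must be in [1, n_components]")
    Xc = X_new - model.x_mean
    out = np.empty((X_new.shape[0], m))
    for j in range(m):
        out[:, j] = Xc @ model.coefs[comps[j] - 1][:, j] + model.y_mean[j]
    return out


@dataclass
class CVResult:
    """Leave-one-out RMSECV for every (response, component count) pair."""

    rmsecv: np.ndarray          # m x A
    a_values: np.ndarray        # 1..A
    selected: np.ndarray        # m
    response_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.rmsecv < 0) or not np.all(np.isfinite(self.rmsecv)):
            raise ParameterError("RMSECV values must be finite and >= 0")


def select_components(rmsecv: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Per response, the smallest component count within ``tol`` of the minimum."""
    rmsecv = np.atleast_2d(np.asarray(rmsecv, dtype=float))
    selected = np.empty(rmsecv.shape[0], dtype=int)
    for j in range(rmsecv.shape[0]):
        row = rmsecv[j]
        selected[j] = int(np.flatnonzero(row <= row.min() + tol)[0]) + 1
    return selected


def loo_cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    a_max: int = 20,
    response_names: list[str] | None = None,
) -> CVResult:
    """Leave-one-out cross-validation over component counts 1..a_max.

    Every fold refits the model from scratch on the remaining n-1 samples —
    including re-centering, so the left-out sample never leaks into the
    centering step — and predicts the held-out sample at every component
    count from the fold's coefficient stack.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    if n < 5:
        raise ParameterError("LOO cross-validation needs n >= 5")
    if not (1 <= a_max <= min(n - 2, p)):
        raise ParameterError(f"a_max must be in [1, min(n-2, p)] = [1, {min(n - 2, p)}]")
    preds = np.empty((n, a_max, m))
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        model = fit_pls(X[rest], Y[rest], a_max)
        Xc = X[i] - model.x_mean
        for a in range(1, a_max + 1):
            preds[i, a - 1] = Xc @ model.coefs[a - 1] + model.y_mean
    err = preds - Y[:, None, :]
    rmsecv = np.sqrt(np.mean(err**2, axis=0)).T  # m x A
    return CVResult(
        rmsecv=rmsecv,
        a_values=np.arange(1, a_max + 1),
        selected=select_components(rmsecv),
        response_names=list(response_names or [f"y{j}" for j in range(m)]),
    )


def fit_pls_with_cv(
    X: np.ndarray,
    Y: np.ndarray,
    a_max: int = 20,
    response_names: list[str] | None = None,
    pls2: bool = True,
    provenance: dict | None = None,
) -> tuple[PLSModel, CVResult]:
    """Fit with LOO-tuned per-response component counts.

    With ``pls2=False`` each response is fitted and cross-validated by its
    own single-response (PLS1) model; the returned model stacks the
    per-response coefficient vectors.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    a_max = min(a_max, X.shape[0] - 2, X.shape[1])
    if pls2:
        cv = loo_cross_validate(X, Y, a_max, response_names)
        model = fit_pls(X, Y, a_max, response_names, provenance)
        model.selected = cv.selected.copy()
        return model, cv
    m = Y.shape[1]
    models, rows = [], []
    for j in range(m):
        cv_j = loo_cross_validate(X, Y[:, j], a_max)
        rows.append(cv_j.rmsecv[0])
        models.append(fit_pls(X, Y[:, j], a_max))
    rmsecv = np.vstack(rows)
    selected = select_components(rmsecv)
    coefs = np.stack(
        [np.concatenate([mj.coefs[a] for mj in models], axis=1) for a in range(a_max)]
    )
    model = PLSModel(
        x_mean=models[0].x_mean,
        y_mean=np.array([mj.y_mean[0] for mj in models]),
        weights=models[0].weights,
        x_loadings=models[0].x_loadings,
        y_loadings=np.vstack([mj.y_loadings for mj in models]),
        scores=models[0].scores,
        coefs=coefs,
        n_components=a_max,
        selected=selected,
        response_names=list(response_names or [f"y{j}" for j in range(m)]),
        provenance=dict(provenance or {}, mode="pls1-per-response"),
    )
    cv = CVResult(rmsecv=rmsecv, a_values=np.arange(1, a_max + 1),
                  selected=selected, response_names=model.response_names)
    return model, cv
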