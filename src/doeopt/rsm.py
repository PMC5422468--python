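"""Stage 2: second-order response-surface fitting and optimization.

Fits the full quadratic model

    Y = b0 + sum_i b_i X_i + sum_{i<j} b_ij X_i X_j + sum_i b_ii X_i^2

by OLS on coded factors, evaluates it at arbitrary points, locates its
stationary point by canonical analysis (x_s = -1/2 B^{-1} b where B is the
symmetric quadratic-form matrix), and finds the constrained maximum over a
coded box by a dense grid sweep followed by local polish.  The grid stage
guarantees globality over the box — the fitted surface may be a saddle, in
which case the constrained maximum lies on the boundary and a purely local
optimizer could miss it.

A structural note on Box-Behnken designs with a single center run: every
edge run of a k=3 BBD satisfies x1^2 + x2^2 + x3^2 = 2, so the constant
direction of the model is estimable only through the center run, whose
leverage is therefore exactly 1 and whose fitted value equals its observed
value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .designs import Design

__all__ = [
    "QuadraticFit",
    "StationaryPointResult",
    "OptimumResult",
    "quadratic_model_matrix",
    "fit_quadratic",
    "predict",
    "stationary_point",
    "constrained_optimum",
]


def _term_names(factor_names: list[str]) -> list[str]:
    k = len(factor_names)
    names = ["(intercept)"] + list(factor_names)
    names += [
        f"{factor_names[i]}:{factor_names[j]}"
        for i, j in itertools.combinations(range(k), 2)
    ]
    names += [f"{n}^2" for n in factor_names]
    return names


def quadratic_model_matrix(X: np.ndarray) -> np.ndarray:
    """Model matrix of the full second-order polynomial in coded factors.

    Column order: intercept, linear terms, pairwise interactions (i<j),
    squared terms.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols.extend(X[:, i] for i in range(k))
    cols.extend(X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2))
    cols.extend(X[:, i] ** 2 for i in range(k))
    return np.column_stack(cols)


@dataclass
class QuadraticFit:
    factor_names: list[str]
    beta0: float
    linear: np.ndarray  # b_i
    interactions: dict[tuple[str, str], float]  # b_ij, i<j
    quadratics: np.ndarray  # b_ii
    fitted_values: np.ndarray
    residuals: np.ndarray
    leverages: np.ndarray
    r_squared: float
    response_name: str
    design: Design | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def quadratic_form(self) -> np.ndarray:
        """Symmetric matrix B with b_ii on the diagonal, b_ij/2 off it."""
        B = np.diag(self.quadratics.astype(float))
        for (a, b), v in self.interactions.items():
            i, j = self.factor_names.index(a), self.factor_names.index(b)
            B[i, j] = B[j, i] = v / 2.0
        return B

    def coefficients(self) -> pd.Series:
        """All 10 (for k=3) coefficients in model-matrix order."""
        vals = [self.beta0, *self.linear]
        vals += [self.interactions[p] for p in sorted_pairs(self.factor_names)]
        vals += list(self.quadratics)
        return pd.Series(vals, index=_term_names(self.factor_names))


def sorted_pairs(names: list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(names, 2))


def fit_quadratic(design: Design, responses) -> QuadraticFit:
    """OLS fit of the full second-order model on coded columns."""
    y = np.asarray(
        responses.to_numpy() if hasattr(responses, "to_numpy") else responses,
        dtype=float,
    )
    if y.size == 0:
        raise ValueError("response set is empty")
    if y.shape[0] != design.n_runs:
        raise ValueError(f"{y.shape[0]} responses for a {design.n_runs}-run design")
    k = design.k
    M = quadratic_model_matrix(design.matrix)
    p = M.shape[1]
    if design.n_runs < p:
        raise ValueError(
            f"quadratic model has {p} parameters but the design has only "
            f"{design.n_runs} runs"
        )
    if np.linalg.matrix_rank(M) < p:
        names = _term_names(design.factor_names)
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(M, j, axis=1))
            == np.linalg.matrix_rank(M)
        ]
        raise ValueError(f"design cannot identify model terms: {bad}")

    res = sm.OLS(y, M).fit()
    beta = np.asarray(res.params)
    # hat diagonal via the thin QR of the model matrix
    Q, _ = np.linalg.qr(M)
    lev = np.sum(Q**2, axis=1)
    pairs = sorted_pairs(design.factor_names)
    n_int = len(pairs)
    name = getattr(responses, "name", None) or "response"
    return QuadraticFit(
        factor_names=list(design.factor_names),
        beta0=float(beta[0]),
        linear=beta[1 : 1 + k].copy(),
        interactions={p_: float(v) for p_, v in zip(pairs, beta[1 + k : 1 + k + n_int])},
        quadratics=beta[1 + k + n_int :].copy(),
        fitted_values=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        leverages=lev,
        r_squared=float(res.rsquared),
        response_name=str(name),
        design=design,
    )


def predict(fit: QuadraticFit, coded_point, extrapolate: bool = False):
    """Evaluate the fitted polynomial at one point or an array of points.

    Points outside [-1, 1]^k are refused unless ``extrapolate`` is set —
    the model is an interpolating surface over the design region.
    """
    pts = np.atleast_2d(np.asarray(coded_point, dtype=float))
    if pts.shape[1] != fit.k:
        raise ValueError(f"expected {fit.k}-vector points, got shape {pts.shape}")
    if not extrapolate and np.any(np.abs(pts) > 1.0 + 1e-12):
        raise ValueError(
            "point outside the coded cube [-1,1]^k; pass extrapolate=True "
            "to evaluate the model outside the design region"
        )
    # evaluate through the same model-matrix route the fit used, so design
    # rows reproduce the stored fitted values
    coef = np.concatenate(
        [
            [fit.beta0],
            fit.linear,
            [fit.interactions[p] for p in sorted_pairs(fit.factor_names)],
            fit.quadratics,
        ]
    )
    vals = quadratic_model_matrix(pts) @ coef
    return float(vals[0]) if np.ndim(coded_point) == 1 else vals


@dataclass
class StationaryPointResult:
    coded_point: np.ndarray
    eigenvalues: np.ndarray  # ascending
    nature: str  # "maximum" | "minimum" | "saddle"
    predicted_response: float
    inside_design_cube: bool


def stationary_point(fit: QuadraticFit, singular_tol: float = 1e-10) -> StationaryPointResult:
    """Canonical analysis: solve grad Y = 0 and classify the critical point.

    x_s = -1/2 B^{-1} b; the eigenvalues of B give the nature (all negative
    -> maximum, all positive -> minimum, mixed -> saddle).
    """
    B = fit.quadratic_form
    scale = max(np.abs(B).max(), 1.0)
    if abs(np.linalg.det(B)) <= singular_tol * scale**fit.k:
        raise ValueError(
            "quadratic form is singular (ridge system); use constrained_optimum"
        )
    xs = -0.5 * np.linalg.solve(B, fit.linear)
    eig = np.sort(np.linalg.eigvalsh(B))
    if np.all(eig < 0):
        nature = "maximum"
    elif np.all(eig > 0):
        nature = "minimum"
    else:
        nature = "saddle"
    value = float(fit.beta0 + xs @ fit.linear + xs @ B @ xs)
    return StationaryPointResult(
        coded_point=xs,
        eigenvalues=eig,
        nature=nature,
        predicted_response=value,
        inside_design_cube=bool(np.all(np.abs(xs) <= 1.0)),
    )


@dataclass
class OptimumResult:
    coded_point: np.ndarray
    predicted_response: float
    on_boundary: np.ndarray  # per-coordinate bool
    natural_point: dict[str, float] | None = None


def constrained_optimum(
    fit: QuadraticFit,
    bounds: list[tuple[float, float]] | None = None,
    sense: str = "max",
    grid_step: float = 0.01,
) -> OptimumResult:
    """Global optimum of the fitted surface over a coded box.

    Dense per-axis grid sweep (deterministic; ties broken by smallest
    Euclidean norm of the coded point) followed by L-BFGS-B polish within
    the same bounds.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    if bounds is None:
        bounds = [(-1.0, 1.0)] * fit.k
    if len(bounds) != fit.k:
        raise ValueError("one (low, high) bound pair per factor required")
    for lo, hi in bounds:
        if not lo < hi:
            raise ValueError("degenerate bounds")
    sign = -1.0 if sense == "max" else 1.0
    B = fit.quadratic_form
    b = fit.linear

    axes = [
        np.linspace(lo, hi, int(round((hi - lo) / grid_step)) + 1) for lo, hi in bounds
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    vals = fit.beta0 + pts @ b + np.einsum("ni,ij,nj->n", pts, B, pts)
    best = vals.min() if sense == "min" else vals.max()
    near = np.flatnonzero(np.abs(vals - best) <= 1e-9 * max(abs(best), 1.0))
    start = pts[near[np.argmin(np.einsum("ij,ij->i", pts[near], pts[near]))]]

    def neg(x):
        return sign * (fit.beta0 + x @ b + x @ B @ x)

    def grad(x):
        return sign * (b + 2.0 * B @ x)

    res = minimize(neg, start, jac=grad, method="L-BFGS-B", bounds=bounds)
    x = np.clip(res.x, [lo for lo, _ in bounds], [hi for _, hi in bounds])
    value = float(fit.beta0 + x @ b + x @ B @ x)
    grid_value = float(best)
    if (sense == "max" and grid_value > value) or (sense == "min" and grid_value < value):
        x, value = start, grid_value  # polish never worsens the grid answer
    on_boundary = np.array(
        [abs(xi - lo) < 1e-9 or abs(xi - hi) < 1e-9 for xi, (lo, hi) in zip(x, bounds)]
    )
    return OptimumResult(coded_point=x, predicted_response=value, on_boundary=on_boundary)
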