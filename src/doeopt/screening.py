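"""Stage 1: first-order screening analysis of two-level designs.

Fits Y = b0 + sum_i b_i X_i by ordinary least squares on the coded
columns, computes per-factor main effects (mean at +1 minus mean at -1),
and selects the active subset either with Lenth's pseudo standard error
(the standard significance test for unreplicated two-level screens) or by
simply taking the m largest effects.

On an orthogonal balanced design the half-effects coincide with the
saturated OLS slopes; on a non-orthogonal matrix they do not, so both are
reported and model reduction is always done by refitting on the reduced
column set rather than by zeroing coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designs import Design

__all__ = [
    "FirstOrderFit",
    "EffectTable",
    "fit_first_order",
    "main_effects",
    "lenth_pse",
    "select_significant",
]


@dataclass
class FirstOrderFit:
    intercept: float
    coefficients: pd.Series  # per selected factor
    fitted_values: np.ndarray
    residuals: np.ndarray
    r_squared: float
    dof_residual: int
    response_name: str
    aliased_factors: list[str] | None = None  # set when a pinv fit was forced

    def summary_dict(self) -> dict:
        return {
            "response": self.response_name,
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "r_squared": self.r_squared,
            "dof_residual": self.dof_residual,
        }


@dataclass
class EffectTable:
    """Per-factor contrast estimates from a two-level screen.

    ``table`` columns: mean_plus, mean_minus, main_effect, half_effect,
    rank (1 = largest |effect|), significant, method.
    """

    table: pd.DataFrame
    method: str | None = None

    @property
    def effects(self) -> pd.Series:
        return self.table["main_effect"]

    def significant_factors(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _align(design: Design, responses) -> np.ndarray:
    y = np.asarray(
        responses.to_numpy() if hasattr(responses, "to_numpy") else responses,
        dtype=float,
    )
    if y.size == 0:
        raise ValueError("response set is empty")
    if y.shape[0] != design.n_runs:
        raise ValueError(
            f"{y.shape[0]} responses for a {design.n_runs}-run design"
        )
    return y


def fit_first_order(
    design: Design,
    responses,
    factors_subset: list[str] | None = None,
    allow_aliased: bool = False,
) -> FirstOrderFit:
    """OLS fit of the response on intercept + selected coded columns.

    Solves the full normal equations (QR under the hood), so non-orthogonal
    matrices are handled correctly.  R^2 = 1 - SS_res / SS_tot (centered).

    A rank-deficient column selection (e.g. duplicated columns in a
    transcribed matrix) raises by default, naming the dependent columns;
    with ``allow_aliased=True`` the minimum-norm least-squares solution is
    returned instead and the aliased columns are recorded on the fit.  The
    intercept is unaffected by aliasing whenever all columns are balanced
    (it is then the grand mean of the responses).
    """
    y = _align(design, responses)
    names = factors_subset if factors_subset is not None else list(design.factor_names)
    missing = [n for n in names if n not in design.factor_names]
    if missing:
        raise KeyError(f"unknown factors: {missing}")
    idx = [design.factor_names.index(n) for n in names]
    X = design.matrix[:, idx]
    if len(names) + 1 > design.n_runs:
        raise ValueError(
            f"{len(names) + 1} parameters exceed {design.n_runs} runs"
        )
    M = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(M)
    aliased = None
    if rank < M.shape[1]:
        dep = _dependent_columns(M, ["(intercept)"] + names)
        if not allow_aliased:
            raise ValueError(f"rank-deficient design columns: {dep}")
        aliased = dep
    res = sm.OLS(y, M).fit()  # pinv solve: minimum-norm under aliasing
    name = getattr(responses, "name", None) or "response"
    return FirstOrderFit(
        intercept=float(res.params[0]),
        coefficients=pd.Series(res.params[1:], index=names),
        fitted_values=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        r_squared=float(res.rsquared),
        dof_residual=int(design.n_runs - rank),
        response_name=str(name),
        aliased_factors=aliased,
    )


def _dependent_columns(M: np.ndarray, names: list[str]) -> list[str]:
    # name columns whose removal restores full rank
    dep = []
    for j in range(M.shape[1]):
        rest = np.delete(M, j, axis=1)
        if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(M):
            dep.append(names[j])
    return dep


def main_effects(design: Design, responses) -> EffectTable:
    """Main-effect contrasts: mean response at +1 minus mean at -1.

    Requires a pure two-level design (every entry +-1).
    """
    y = _align(design, responses)
    X = design.matrix
    if not np.all(np.isin(X, (-1.0, 1.0))):
        raise ValueError("main effects require a two-level (+-1) design")
    rows = {}
    for j, name in enumerate(design.factor_names):
        plus = y[X[:, j] == 1].mean()
        minus = y[X[:, j] == -1].mean()
        rows[name] = {
            "mean_plus": plus,
            "mean_minus": minus,
            "main_effect": plus - minus,
            "half_effect": (plus - minus) / 2.0,
        }
    tab = pd.DataFrame.from_dict(rows, orient="index")
    order = tab["main_effect"].abs().rank(ascending=False, method="first")
    tab["rank"] = order.astype(int)
    tab["significant"] = False
    tab["method"] = ""
    return EffectTable(table=tab)


def lenth_pse(effects: np.ndarray) -> float:
    """Lenth's pseudo standard error of a vector of effect estimates.

    s0 = 1.5 * median|e|; PSE = 1.5 * median of |e| restricted to
    |e| < 2.5 * s0.
    """
    e = np.abs(np.asarray(effects, dtype=float))
    if e.size == 0:
        raise ValueError("no effects")
    s0 = 1.5 * np.median(e)
    kept = e[e < 2.5 * s0]
    if kept.size == 0:
        kept = e
    return float(1.5 * np.median(kept))


def select_significant(
    effects: EffectTable,
    method: str = "lenth_pse",
    alpha_or_m: float | int = 0.05,
) -> list[str]:
    """Mark and return the active factors.

    - lenth_pse: |effect| > t(alpha/2, d) * PSE with d = k/3;
    - top_m: the m largest |effect|.
    Annotates ``effects.table`` in place.
    """
    tab = effects.table
    k = len(tab)
    if k == 0:
        raise ValueError("empty effect table")
    if method == "top_m":
        m = int(alpha_or_m)
        if m > k:
            raise ValueError(f"cannot select top {m} of {k} factors")
        chosen = tab["main_effect"].abs().nlargest(m).index
        tab["significant"] = tab.index.isin(chosen)
    elif method == "lenth_pse":
        alpha = float(alpha_or_m)
        pse = lenth_pse(tab["main_effect"].to_numpy())
        d = k / 3.0
        margin = stats.t.ppf(1.0 - alpha / 2.0, d) * pse
        tab["significant"] = tab["main_effect"].abs() > margin
    else:
        raise ValueError(f"unknown selection method {method!r}")
    tab["method"] = method
    effects.method = method
    sig = tab[tab["significant"]]
    return list(sig["main_effect"].abs().sort_values(ascending=False).index)
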