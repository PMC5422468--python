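"""Two-level Plackett-Burman and three-level Box-Behnken design matrices.

Plackett-Burman (PB) designs are saturated two-level screening arrays: n
runs support up to n-1 factors, every column is balanced (equal counts of
-1 and +1) and every pair of columns is orthogonal, so main effects are
estimated free of each other (interactions are aliased).  Box-Behnken
designs (BBD) are three-level response-surface arrays whose non-center runs
sit at the midpoints of the edges of the factor cube (two coordinates at
+-1, the rest 0), plus center runs.

Construction follows the classical recipes: Hadamard doubling for run
counts that are powers of two, cyclic first-row generators for n = 12, 20,
24.  `validate_design` audits balance and orthogonality of any design,
which matters here because printed matrices from the literature are not
always the orthogonal arrays they claim to be.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from . import gsh_study

__all__ = [
    "Design",
    "ValidityReport",
    "generate_plackett_burman",
    "generate_box_behnken",
    "validate_design",
    "load_fixture",
    "read_design_csv",
    "read_responses_csv",
    "FIXTURE_NAMES",
]

PB_SUPPORTED_RUNS = (8, 12, 16, 20, 24)

# Classical cyclic first rows (the final all-minus row is appended).
_PB_GENERATORS = {
    12: "++-+++---+-",
    20: "++--++++-+-+----++-",
    24: "+++++-+-++--++--+-+----",
}


@dataclass
class Design:
    """A coded design matrix with run and factor labels.

    matrix is n_runs x k; standard coded levels are -1/0/+1 but fractional
    levels are permitted (family="custom").
    """

    family: str  # "plackett_burman" | "box_behnken" | "custom"
    matrix: np.ndarray
    factor_names: list[str]
    run_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.factor_names):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.factor_names)} factor names were given"
            )
        if not self.run_ids:
            self.run_ids = [str(i + 1) for i in range(self.matrix.shape[0])]
        if len(self.run_ids) != self.matrix.shape[0]:
            raise ValueError("run_ids length must equal the number of runs")

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.factor_names)
        df.insert(0, "run_id", self.run_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ValidityReport:
    """Balance/orthogonality audit of a coded design matrix."""

    factor_names: list[str]
    column_means: np.ndarray
    balanced: np.ndarray  # per-column bool
    pairwise_inner_products: np.ndarray  # k x k, symmetric
    orthogonal: bool
    offending_pairs: list[tuple[str, str, float]]
    condition_number: float

    def summary(self) -> str:
        lines = [
            f"orthogonal: {self.orthogonal}",
            f"all columns balanced: {bool(np.all(self.balanced))}",
            f"condition number: {self.condition_number:.4g}",
        ]
        for a, b, ip in self.offending_pairs:
            lines.append(f"  non-orthogonal pair: {a} x {b} (inner product {ip:g})")
        return "\n".join(lines)


def generate_plackett_burman(n_runs: int, n_factors: int) -> Design:
    """Saturated two-level screening design with `n_factors` columns.

    The first `n_factors` columns of the saturated (n_runs - 1)-column
    array are returned; every column is balanced and all pairs orthogonal.
    """
    if n_runs not in PB_SUPPORTED_RUNS:
        raise ValueError(
            f"unsupported run count {n_runs}; supported sizes: {PB_SUPPORTED_RUNS}"
        )
    if n_factors < 1:
        raise ValueError("n_factors must be at least 1")
    if n_factors > n_runs - 1:
        raise ValueError(
            f"a {n_runs}-run Plackett-Burman design supports at most "
            f"{n_runs - 1} factors, got {n_factors}"
        )

    if n_runs in _PB_GENERATORS:
        gen = np.array([1 if c == "+" else -1 for c in _PB_GENERATORS[n_runs]])
        k = n_runs - 1
        rows = [np.roll(gen, i) for i in range(k)]
        rows.append(-np.ones(k, dtype=int))
        full = np.array(rows)
    else:
        # powers of two: drop the leading all-ones column of a (normalized)
        # Hadamard matrix
        full = hadamard(n_runs)[:, 1:]

    matrix = full[:, :n_factors].astype(float)
    names = [f"x{i + 1}" for i in range(n_factors)]
    return Design("plackett_burman", matrix, names)


def generate_box_behnken(k: int, n_center: int = 1) -> Design:
    """Box-Behnken design for k factors with `n_center` center runs.

    4*C(k,2) edge runs (each pair of factors at the four +-1 sign
    combinations, all others 0) followed by the center runs.
    """
    if k < 3:
        raise ValueError("Box-Behnken designs are undefined for k < 3")
    if n_center < 1:
        raise ValueError("need at least one center run")

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        for si, sj in itertools.product((-1, 1), repeat=2):
            row = np.zeros(k)
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend(np.zeros(k) for _ in range(n_center))
    names = [f"x{i + 1}" for i in range(k)]
    return Design("box_behnken", np.array(rows), names)


def validate_design(design: Design, tol: float = 1e-9) -> ValidityReport:
    """Audit column balance and pairwise orthogonality of coded columns.

    A column is balanced when its mean is zero and it is not constant
    (a constant column is flagged unbalanced, not raised).  Orthogonality
    is judged on raw inner products of the coded columns.
    """
    X = design.matrix
    if X.size == 0:
        raise ValueError("empty design")
    means = X.mean(axis=0)
    constant = X.ptp(axis=0) < tol if hasattr(X, "ptp") else np.ptp(X, axis=0) < tol
    balanced = (np.abs(means) < tol) & ~constant
    G = X.T @ X
    offending = []
    for i in range(design.k):
        for j in range(i + 1, design.k):
            if abs(G[i, j]) > tol:
                offending.append(
                    (design.factor_names[i], design.factor_names[j], float(G[i, j]))
                )
    with np.errstate(divide="ignore"):
        cond = float(np.linalg.cond(X)) if np.linalg.matrix_rank(X) == design.k else np.inf
    return ValidityReport(
        factor_names=list(design.factor_names),
        column_means=means,
        balanced=balanced,
        pairwise_inner_products=G,
        orthogonal=not offending,
        offending_pairs=offending,
        condition_number=cond,
    )


FIXTURE_NAMES = ("gsh_pb16", "gsh_bbd13", "gsh_factors_pb", "gsh_factors_bbd")


def load_fixture(name: str):
    """Return a bundled study object by name.

    - "gsh_pb16": the 16-run, 14-factor screening design, verbatim as
      printed (non-orthogonal; family "custom"), with its responses
      attached as ``design.responses``.
    - "gsh_bbd13": the 13-run Box-Behnken design with responses attached.
    - "gsh_factors_pb" / "gsh_factors_bbd": factor definitions
      (:class:`~doeopt.coding.Factor` lists) for the two stages.
    """
    from .coding import Factor  # local import to avoid a cycle

    if name == "gsh_pb16":
        d = Design(
            "custom",
            np.array(gsh_study.PB_MATRIX, dtype=float),
            list(gsh_study.PB_FACTOR_NAMES),
        )
        d.responses = pd.Series(
            gsh_study.PB_RESPONSES, index=d.run_ids, name="gsh", dtype=float
        )
        return d
    if name == "gsh_bbd13":
        d = Design(
            "box_behnken",
            np.array(gsh_study.BBD_MATRIX, dtype=float),
            list(gsh_study.BBD_FACTOR_NAMES),
        )
        d.responses = pd.Series(
            gsh_study.BBD_RESPONSES, index=d.run_ids, name="gsh", dtype=float
        )
        return d
    if name == "gsh_factors_pb":
        return [
            Factor(name=n, low=lo, high=hi, units=u)
            for n, (lo, hi, u) in gsh_study.PB_FACTOR_LEVELS.items()
        ]
    if name == "gsh_factors_bbd":
        return [
            Factor(name=n, low=lo, mid=mid, high=hi, units=u)
            for n, (lo, mid, hi, u) in gsh_study.BBD_FACTOR_LEVELS.items()
        ]
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


def read_design_csv(path, family: str = "custom") -> Design:
    """Read a design from CSV (columns: run_id, then factor names)."""
    df = pd.read_csv(path)
    if "run_id" not in df.columns:
        raise ValueError(f"{path}: expected a 'run_id' column")
    factor_names = [c for c in df.columns if c != "run_id"]
    return Design(
        family,
        df[factor_names].to_numpy(dtype=float),
        factor_names,
        [str(r) for r in df["run_id"]],
    )


def read_responses_csv(path, column: str | None = None) -> pd.Series:
    """Read run-aligned responses from CSV (columns: run_id, response...)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: response file is empty")
    if "run_id" not in df.columns:
        raise ValueError(f"{path}: expected a 'run_id' column")
    value_cols = [c for c in df.columns if c != "run_id"]
    if not value_cols:
        raise ValueError(f"{path}: no response column found")
    col = column or value_cols[0]
    return pd.Series(
        df[col].to_numpy(dtype=float), index=[str(r) for r in df["run_id"]], name=col
    )
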