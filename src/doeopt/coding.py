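"""Coded-level <-> natural-unit mapping for design factors.

A factor's chosen low/mid/high levels map to coded -1/0/+1.  When the
three levels are evenly spaced this is the usual linear rescale; when they
are not (e.g. supplement concentrations chosen on a roughly geometric grid
such as 0.02 / 0.1 / 0.5 %), a single linear map cannot place the middle
level at 0, so two modes are offered:

- ``piecewise_linear`` (default): linear within [low, mid] and within
  [mid, high] separately, so coded -1/0/+1 hit the three levels exactly;
- ``log``: linear in log(natural value), for strictly positive levels.

Both are strictly monotone and exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import yaml

__all__ = ["Factor", "code_value", "decode_value", "factors_from_config", "decode_point"]


@dataclass
class Factor:
    """A named design variable with its coded-level mapping.

    Two-level (screening) factors carry no mid level; three-level factors
    need mid for the 0 code to be defined.
    """

    name: str
    low: float
    high: float
    mid: float | None = None
    units: str = ""
    scale_mode: str = "piecewise_linear"  # or "log"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.mid is not None and not (self.low < self.mid < self.high):
            raise ValueError(f"{self.name}: mid must lie strictly between low and high")
        if self.scale_mode not in ("piecewise_linear", "log"):
            raise ValueError(f"{self.name}: unknown scale_mode {self.scale_mode!r}")
        if self.scale_mode == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log scaling requires positive levels")


def code_value(factor: Factor, natural: float, extrapolate: bool = False) -> float:
    """Map a natural-unit value to its coded level (low -> -1, high -> +1)."""
    if not extrapolate and not (factor.low <= natural <= factor.high):
        raise ValueError(
            f"{factor.name}: value {natural} outside [{factor.low}, {factor.high}] "
            "(pass extrapolate=True to allow)"
        )
    if factor.scale_mode == "log":
        lo, hi = math.log(factor.low), math.log(factor.high)
        x = math.log(natural)
        if factor.mid is None:
            return -1.0 + 2.0 * (x - lo) / (hi - lo)
        mid = math.log(factor.mid)
        return _piecewise(x, lo, mid, hi)
    if factor.mid is None:
        return -1.0 + 2.0 * (natural - factor.low) / (factor.high - factor.low)
    return _piecewise(natural, factor.low, factor.mid, factor.high)


def decode_value(factor: Factor, coded: float, extrapolate: bool = False) -> float:
    """Exact inverse of :func:`code_value` for the same scale mode."""
    if not extrapolate and not (-1.0 <= coded <= 1.0):
        raise ValueError(
            f"{factor.name}: coded level {coded} outside [-1, 1] "
            "(pass extrapolate=True to allow)"
        )
    if factor.scale_mode == "log":
        lo, hi = math.log(factor.low), math.log(factor.high)
        if factor.mid is None:
            x = lo + (coded + 1.0) * (hi - lo) / 2.0
        else:
            x = _piecewise_inv(coded, lo, math.log(factor.mid), hi)
        return math.exp(x)
    if factor.mid is None:
        return factor.low + (coded + 1.0) * (factor.high - factor.low) / 2.0
    return _piecewise_inv(coded, factor.low, factor.mid, factor.high)


def _piecewise(x: float, lo: float, mid: float, hi: float) -> float:
    if x <= mid:
        return (x - mid) / (mid - lo)
    return (x - mid) / (hi - mid)


def _piecewise_inv(c: float, lo: float, mid: float, hi: float) -> float:
    if c <= 0:
        return mid + c * (mid - lo)
    return mid + c * (hi - mid)


def decode_point(factors: list[Factor], coded: "list[float]", extrapolate: bool = False) -> dict[str, float]:
    """Decode a coded point into a {factor: natural value} mapping."""
    if len(factors) != len(coded):
        raise ValueError("coded point dimension does not match number of factors")
    return {
        f.name: decode_value(f, float(c), extrapolate=extrapolate)
        for f, c in zip(factors, coded)
    }


def factors_from_config(source) -> list[Factor]:
    """Build factors from a YAML/JSON mapping or list of mappings.

    Each entry: name, low, high, optional mid, units, scale_mode.
    `source` may be a path, a YAML string, or an already-parsed structure.
    """
    if isinstance(source, (list, dict)):
        data = source
    else:
        text = source.read_text() if hasattr(source, "read_text") else str(source)
        try:
            with open(text) as fh:  # a path
                data = yaml.safe_load(fh)
        except (OSError, ValueError):
            data = yaml.safe_load(text)
    if isinstance(data, dict):
        data = [{"name": k, **v} for k, v in data.items()]
    return [Factor(**entry) for entry in data]
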