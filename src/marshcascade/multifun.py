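"""Multifunctionality metrics: standardization, averaged index, and
Hill-number summaries (effective number of functions, effective
multifunctionality).

The averaged index follows the percent-of-max convention (each function
scaled to 100 at its maximum observed value); the Hill-number metrics use
the 0-1 convention (0 = no function, 1 = maximum observed level). For a
plot with standardized profile F_1..F_k the relative contributions are
p_i = F_i / sum(F), and the effective number of functions of order q is

    N^q = (sum_i p_i^q)^(1/(1-q))        q >= 0, q != 1
    N^1 = exp(-sum_i p_i ln p_i)         (the q -> 1 limit)

N^0 counts the functions with a positive contribution; increasing q
upweights high-performing functions. Effective multifunctionality is
qM_ef = N^q * A with A the arithmetic mean of the standardized profile.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .functions import (
    ABOVEGROUND_FUNCTIONS,
    BELOWGROUND_FUNCTIONS,
    FUNCTION_COLUMNS,
)

__all__ = [
    "DEFAULT_Q_GRID",
    "standardize",
    "average_index",
    "effective_number",
    "effective_multifunctionality",
    "multifunctionality_table",
]

#: Orders used by default: 1..5 plus the q = 0 count.
DEFAULT_Q_GRID: tuple[int, ...] = (0, 1, 2, 3, 4, 5)

_MODES = {"percent_of_max": 100.0, "unit_interval": 1.0}


def standardize(matrix: pd.DataFrame, mode: str = "percent_of_max",
                columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Columnwise standardization of a function matrix.

    ``percent_of_max`` rescales each function to percent of its maximum
    observed value; ``unit_interval`` to the 0-1 scale. Non-numeric columns
    (e.g. ``treatment``) are carried through untouched. Columns whose
    maximum is not positive cannot be scaled and are set to 0 with a
    warning.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown standardization mode {mode!r}")
    scale = _MODES[mode]
    if columns is None:
        columns = [c for c in matrix.columns
                   if pd.api.types.is_numeric_dtype(matrix[c])]
    out = matrix.copy()
    for col in columns:
        top = matrix[col].max()
        if not top > 0:
            warnings.warn(f"column {col!r} has non-positive maximum; "
                          "standardized to 0", RuntimeWarning, stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = matrix[col] / top * scale
    return out


def _subset_columns(subset: str) -> tuple[str, ...]:
    if subset == "all":
        return FUNCTION_COLUMNS
    if subset == "above":
        return ABOVEGROUND_FUNCTIONS
    if subset == "below":
        return BELOWGROUND_FUNCTIONS
    raise ValueError(f"unknown subset {subset!r}")


def average_index(std: pd.DataFrame, subset: str = "all") -> pd.Series:
    """Unweighted mean multifunctionality index per plot over the selected
    function subset (``all``, ``above``, or ``below``)."""
    cols = _subset_columns(subset)
    missing = [c for c in cols if c not in std.columns]
    if missing:
        raise KeyError(f"standardized matrix lacks columns {missing}")
    return std[list(cols)].mean(axis=1).rename(f"avg_index_{subset}")


def _relative_proportions(values: Sequence[float]) -> np.ndarray:
    f = np.asarray(values, dtype=float)
    if np.any(f < 0):
        raise ValueError("effective number requires non-negative values; "
                         "shift negative columns first")
    total = f.sum()
    if total <= 0:
        raise ValueError("effective number undefined for an all-zero profile")
    return f / total


def effective_number(values: Sequence[float], q: float) -> float:
    """Effective number of functions N^q for one plot's standardized
    profile. Zero-valued functions contribute p_i = 0 and drop out of the
    sums, so N^0 counts the functions provided at a positive level."""
    if q < 0:
        raise ValueError("order q must be non-negative")
    p = _relative_proportions(values)
    p = p[p > 0]
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def effective_multifunctionality(values: Sequence[float], q: float) -> float:
    """qM_ef = N^q * A, with A the arithmetic mean of the standardized
    profile (zeros included)."""
    a = float(np.mean(np.asarray(values, dtype=float)))
    return effective_number(values, q) * a


def _shift_nonnegative(std: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    """Shift any column with negative entries up to min 0 (the relative-
    proportion formula requires non-negative values)."""
    out = std.copy()
    for col in cols:
        low = out[col].min()
        if low < 0:
            warnings.warn(f"column {col!r} shifted by {-low:.4g} to "
                          "non-negative before Hill computation",
                          RuntimeWarning, stacklevel=3)
            out[col] = out[col] - low
    return out


def multifunctionality_table(matrix: pd.DataFrame,
                             q_grid: Sequence[float] = DEFAULT_Q_GRID,
                             index_mode: str = "percent_of_max",
                             hill_mode: str = "unit_interval") -> pd.DataFrame:
    """Tidy per-plot multifunctionality summary from a raw function matrix.

    Columns: ``treatment``; ``avg_index`` (and above/below splits when the
    biomass split columns are present) on the ``index_mode`` scale; and for
    every order q in ``q_grid`` the effective number ``N_q{q}`` and
    effective multifunctionality ``M_ef_q{q}`` on the ``hill_mode`` scale.
    """
    std_idx = standardize(matrix, mode=index_mode)
    std_hill = standardize(matrix, mode=hill_mode)
    std_hill = _shift_nonnegative(std_hill, FUNCTION_COLUMNS)

    out = pd.DataFrame(index=matrix.index)
    if "treatment" in matrix.columns:
        out["treatment"] = matrix["treatment"]
    out["avg_index"] = average_index(std_idx, "all")
    if all(c in matrix.columns for c in ("aboveground_biomass",
                                         "belowground_biomass")):
        out["avg_index_above"] = average_index(std_idx, "above")
        out["avg_index_below"] = average_index(std_idx, "below")

    profiles = std_hill[list(FUNCTION_COLUMNS)].to_numpy()
    for q in q_grid:
        tag = f"{q:g}"
        nq = np.array([effective_number(row, q) for row in profiles])
        a = profiles.mean(axis=1)
        out[f"N_q{tag}"] = nq
        out[f"M_ef_q{tag}"] = nq * a
    return out
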