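"""TOPSIS: ranking alternatives by closeness to the ideal solution.

The decision matrix is column-normalised (vector normalisation by default:
each column divided by its Euclidean norm, signs preserved so that negative
energies stay negative), weighted, and compared against the ideal point A+
(best weighted value per criterion in its stated direction) and anti-ideal
point A-.  Each alternative's Minkowski distances d+ and d- to the two
points (exponent s, default 2 = Euclidean) combine into the closeness
coefficient

    C_i = d-_i / (d+_i + d-_i)  in [0, 1],

and alternatives are ranked by decreasing C_i, ties broken stably by input
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core_io import (
    ConfigError,
    DataDomainError,
    DecisionMatrix,
    Direction,
)

__all__ = [
    "TOPSISResult",
    "normalize",
    "ideal_points",
    "minkowski_distance",
    "rank",
    "result_table",
    "plot_closeness",
]


@dataclass(frozen=True)
class TOPSISResult:
    """All intermediate and final quantities of one TOPSIS run."""

    alternatives: tuple[str, ...]
    normalized: np.ndarray
    weighted: np.ndarray
    ideal: np.ndarray
    anti_ideal: np.ndarray
    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray
    ranking: tuple[int, ...]      # row indices, best first
    ranks: tuple[int, ...]        # competition rank per row (ties share)
    s: float

    @property
    def ranked_alternatives(self) -> tuple[str, ...]:
        return tuple(self.alternatives[i] for i in self.ranking)

    @property
    def best(self) -> str:
        return self.alternatives[self.ranking[0]]


def normalize(dm: DecisionMatrix | np.ndarray,
              method: Literal["vector", "minmax"] = "vector") -> np.ndarray:
    """Column-normalise raw criterion values.

    Vector normalisation divides each column by its Euclidean norm,
    preserving sign; an all-zero column is left at zero with a warning.
    Min-max normalisation maps each column onto [0, 1] (offered for
    sensitivity analysis; constant columns map to 0).
    """
    x = dm.values if isinstance(dm, DecisionMatrix) else np.asarray(
        dm, dtype=float)
    if method == "vector":
        norms = np.sqrt((x ** 2).sum(axis=0))
        zero = norms == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} all-zero column(s) left at 0",
                          stacklevel=2)
        safe = np.where(zero, 1.0, norms)
        return x / safe
    if method == "minmax":
        lo, hi = x.min(axis=0), x.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (x - lo) / span
    raise ConfigError(f"unknown normalization {method!r}")


def ideal_points(weighted: np.ndarray,
                 directions: Sequence[Direction],
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (A+) and anti-ideal (A-) points of the weighted matrix.

    For a benefit column A+ takes the maximum, for a cost column the
    minimum; A- is the opposite.  With energies kept negative, "minimum"
    correctly selects the most negative (strongest) weighted value.
    """
    v = np.asarray(weighted, dtype=float)
    if v.shape[1] != len(directions):
        raise ConfigError(
            f"{len(directions)} directions for {v.shape[1]} columns")
    hi, lo = v.max(axis=0), v.min(axis=0)
    benefit = np.array([d == "benefit" for d in directions])
    a_plus = np.where(benefit, hi, lo)
    a_minus = np.where(benefit, lo, hi)
    return a_plus, a_minus


def minkowski_distance(row: np.ndarray, point: np.ndarray,
                       s: float = 2.0) -> float:
    """Minkowski distance (sum |x_j - y_j|^s)^(1/s); requires s >= 1."""
    if s < 1:
        raise DataDomainError(f"Minkowski exponent must be >= 1, got {s}")
    diff = np.abs(np.asarray(row, dtype=float) - np.asarray(point, dtype=float))
    if np.isinf(s):
        return float(diff.max())
    return float((diff ** s).sum() ** (1.0 / s))


def rank(dm: DecisionMatrix,
         weights: Sequence[float] | None = None,
         s: float = 2.0,
         normalization: Literal["vector", "minmax"] = "vector",
         ) -> TOPSISResult:
    """Run the full TOPSIS pipeline on a decision matrix.

    ``weights`` defaults to the weights carried by the matrix criteria; it
    must be positive and sum to 1.  When every alternative coincides with
    both ideal points (d+ + d- = 0) closeness is defined as 0.5 with a
    warning, preserving tie semantics without a division by zero.
    """
    if weights is None:
        w = dm.weights
        if w is None:
            raise ConfigError("no weights supplied and criteria carry none")
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (len(dm.criteria),):
        raise ConfigError(
            f"{w.size} weights for {len(dm.criteria)} criteria")
    if not np.all(w > 0):
        raise ConfigError("weights must be strictly positive")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ConfigError(f"weights sum to {w.sum():.6f}, expected 1")
    if s < 1:
        raise DataDomainError(f"Minkowski exponent must be >= 1, got {s}")

    r = normalize(dm, method=normalization)
    v = r * w
    a_plus, a_minus = ideal_points(v, dm.directions)
    d_plus = np.array([minkowski_distance(row, a_plus, s) for row in v])
    d_minus = np.array([minkowski_distance(row, a_minus, s) for row in v])
    total = d_plus + d_minus
    degenerate = total == 0
    if degenerate.any():
        warnings.warn("alternatives coincide with both ideal points; "
                      "closeness set to 0.5", stacklevel=2)
    closeness = np.where(degenerate, 0.5,
                         d_minus / np.where(degenerate, 1.0, total))
    order = tuple(sorted(range(len(closeness)),
                         key=lambda i: (-closeness[i], i)))
    # competition ranking: equal closeness shares the best rank
    ranks = [0] * len(order)
    for pos, idx in enumerate(order):
        if pos > 0 and closeness[idx] == closeness[order[pos - 1]]:
            ranks[idx] = ranks[order[pos - 1]]
        else:
            ranks[idx] = pos + 1
    return TOPSISResult(
        alternatives=dm.alternatives,
        normalized=r, weighted=v, ideal=a_plus, anti_ideal=a_minus,
        d_plus=d_plus, d_minus=d_minus, closeness=closeness,
        ranking=order, ranks=tuple(ranks), s=float(s),
    )


def result_table(dm: DecisionMatrix, res: TOPSISResult):
    """Ranked results as a pandas DataFrame (best alternative first)."""
    import pandas as pd

    rows = []
    for i in res.ranking:
        row = {"alternative": dm.alternatives[i]}
        row.update({c.name: dm.values[i, j]
                    for j, c in enumerate(dm.criteria)})
        row.update({"d_plus": res.d_plus[i], "d_minus": res.d_minus[i],
                    "closeness": res.closeness[i], "rank": res.ranks[i]})
        rows.append(row)
    return pd.DataFrame(rows)


def plot_closeness(res: TOPSISResult, ax=None, title: str | None = None):
    """Bar plot of closeness coefficients in ranked order (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    labels = [res.alternatives[i] for i in res.ranking]
    ax.bar(labels, [res.closeness[i] for i in res.ranking])
    ax.set_ylabel("closeness coefficient")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.tick_params(axis="x", rotation=45)
    return ax
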