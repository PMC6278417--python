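"""Analytic Hierarchy Process: priority weights, consistency, group aggregation.

Criteria weights are derived from positive reciprocal pairwise-comparison
matrices (PCMs) on the Saaty 1-9 scale.  The default priority method is the
principal right eigenvector, computed by deterministic power iteration from
the uniform vector; the row geometric mean is available as an alternative
(the two agree to many digits for near-consistent matrices).

Judgment quality is summarised by the consistency ratio

    CR = CI / RI_n,   CI = (lambda_max - n) / (n - 1),

where RI_n is Saaty's random index for order n.  CR < 0.1 is the customary
acceptance threshold.

Several experts' matrices are merged by aggregation of individual judgments
(AIJ): the element-wise geometric mean, which is the unique aggregation
preserving reciprocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .core_io import (
    ConfigError,
    FormatError,
    NumericError,
    PairwiseComparisonMatrix,
)

__all__ = [
    "RANDOM_INDEX",
    "AHPResult",
    "derive_weights",
    "consistency_ratio",
    "aggregate_aij",
]

#: Saaty random consistency indices for matrix orders 1..10.
RANDOM_INDEX: Mapping[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

Method = Literal["eigenvector", "row_geometric_mean"]


@dataclass(frozen=True)
class AHPResult:
    """Priority vector with its consistency diagnostics."""

    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    method: Method
    labels: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "weights": [float(w) for w in self.weights],
            "labels": list(self.labels),
            "lambda_max": float(self.lambda_max),
            "ci": float(self.ci),
            "cr": float(self.cr),
            "method": self.method,
        }


def _power_iteration(a: np.ndarray, tol: float = 1e-12,
                     max_iter: int = 100_000) -> np.ndarray:
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        v = a @ w
        v /= v.sum()
        if np.max(np.abs(v - w) / np.maximum(v, 1e-300)) < tol:
            return v
        w = v
    raise NumericError(
        f"power iteration did not converge in {max_iter} iterations")


def derive_weights(pcm: PairwiseComparisonMatrix,
                   method: Method = "eigenvector",
                   random_index: Mapping[int, float] | None = None,
                   ) -> AHPResult:
    """Derive the priority vector and consistency diagnostics of one PCM.

    lambda_max is estimated as the mean over i of ``(A w)_i / w_i`` — the
    exact principal eigenvalue at the eigenvector fixed point and the
    standard estimator for the geometric-mean vector.  For n <= 2 any
    reciprocal matrix is consistent, so CI = CR = 0 by definition.  Orders
    above 10 need a caller-supplied ``random_index``.
    """
    a = pcm.entries
    n = pcm.n
    ri_table = random_index if random_index is not None else RANDOM_INDEX
    if method == "eigenvector":
        w = _power_iteration(a)
    elif method == "row_geometric_mean":
        w = np.exp(np.mean(np.log(a), axis=1))
        w = w / w.sum()
    else:
        raise ConfigError(f"unknown AHP method {method!r}")

    lambda_max = float(np.mean((a @ w) / w))
    if n <= 2:
        ci = cr = 0.0
    else:
        ci = (lambda_max - n) / (n - 1)
        if n not in ri_table:
            raise ConfigError(
                f"no random index for order n={n}; supply random_index")
        ri = ri_table[n]
        cr = ci / ri if ri > 0 else 0.0
    return AHPResult(weights=w, lambda_max=lambda_max, ci=ci, cr=cr,
                     method=method, labels=pcm.labels)


def consistency_ratio(pcm: PairwiseComparisonMatrix,
                      method: Method = "eigenvector",
                      random_index: Mapping[int, float] | None = None,
                      ) -> float:
    """Consistency ratio CI/RI of one PCM with the configured method."""
    return derive_weights(pcm, method=method, random_index=random_index).cr


def aggregate_aij(pcms: Sequence[PairwiseComparisonMatrix],
                  ) -> PairwiseComparisonMatrix:
    """Merge expert PCMs by element-wise geometric mean (AIJ).

    All matrices must share order and labels.  Reciprocity is preserved:
    if every input satisfies ``a_ji = 1/a_ij`` so does the aggregate,
    because geometric means commute with reciprocals.
    """
    if not pcms:
        raise ConfigError("aggregate_aij needs at least one matrix")
    first = pcms[0]
    for k, p in enumerate(pcms[1:], start=2):
        if p.n != first.n:
            raise FormatError(
                f"matrix {k} has order {p.n}, expected {first.n}")
        if p.labels != first.labels:
            raise FormatError(
                f"matrix {k} labels {p.labels} differ from {first.labels}")
    logs = np.mean([np.log(p.entries) for p in pcms], axis=0)
    return PairwiseComparisonMatrix(first.labels, np.exp(logs))
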