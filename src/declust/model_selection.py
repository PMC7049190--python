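"""Choosing the number of cancer subtypes with a BIC curve.

For each candidate K the model is fit and scored with

    BIC(K) = log(MSE) * n_samples + log(n_samples) * K

where MSE is the mean squared log-reconstruction error (sum divided by
genes x samples).  Two heuristics are read off the curve -- the argmin
and the elbow (maximum discrete curvature) -- and when they disagree the
midpoint, rounded down toward fewer subtypes, is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .core_model import DeclustError, ExpressionMatrix, MarkerSet

__all__ = ["BicCurve", "SubtypeSelection", "compute_bic",
           "select_num_subtypes", "fit_k_range"]


@dataclass
class BicCurve:
    """BIC and mean-MSE values over an increasing grid of subtype numbers."""

    k_values: list[int]
    mse_values: list[float]
    bic_values: list[float]

    def __post_init__(self) -> None:
        if not (len(self.k_values) == len(self.mse_values) == len(self.bic_values)):
            raise DeclustError("BIC curve fields have differing lengths")
        if any(b >= a for a, b in zip(self.k_values[1:], self.k_values)):
            raise DeclustError("k_values must be strictly increasing")


class SubtypeSelection(NamedTuple):
    selected: int
    k_min: int
    k_elbow: int


def compute_bic(mse_mean: float, n_samples: int, n_subtypes: int) -> float:
    """Evaluate log(MSE)*n + log(n)*K for one candidate subtype number."""
    if mse_mean <= 0:
        raise DeclustError(
            "mean MSE must be positive: a numerically perfect fit makes log(MSE) "
            "undefined; add noise/jitter to the data or treat BIC as -inf explicitly")
    if n_samples < 2:
        raise DeclustError("need at least 2 samples")
    if n_subtypes < 1:
        raise DeclustError("n_subtypes must be >= 1")
    return math.log(mse_mean) * n_samples + math.log(n_samples) * n_subtypes


def select_num_subtypes(curve: BicCurve) -> SubtypeSelection:
    """Pick the subtype number from a BIC curve.

    ``k_min`` is the argmin of the curve (ties to the smallest K).
    ``k_elbow`` maximizes the discrete second forward difference
    BIC(k-1) - 2 BIC(k) + BIC(k+1) over interior points (ties to the
    smallest K); on a curve whose argmin is the first point the elbow
    coincides with it.  If the two disagree, the midpoint rounded down
    (parsimony) is returned.
    """
    ks = list(curve.k_values)
    bic = np.asarray(curve.bic_values, dtype=float)
    if len(ks) < 3:
        raise DeclustError("need at least 3 points on the BIC curve")
    k_min = ks[int(np.argmin(bic))]
    curvature = bic[:-2] - 2.0 * bic[1:-1] + bic[2:]
    k_elbow = ks[1 + int(np.argmax(curvature))]
    if k_min == ks[0]:
        # monotone-increasing start: no interior knee precedes the minimum
        k_elbow = k_min
    if k_min == k_elbow:
        selected = k_min
    else:
        selected = (k_min + k_elbow) // 2
    return SubtypeSelection(selected=selected, k_min=k_min, k_elbow=k_elbow)


def fit_k_range(observed: ExpressionMatrix, markers: MarkerSet,
                k_values: Optional[Sequence[int]] = None,
                config=None, return_states: bool = False):
    """Fit the model over a range of subtype numbers and build the BIC curve.

    Returns (curve, selection) or (curve, selection, states) where
    ``states`` maps K to the fitted state.
    """
    from .optimizer import OptimizerConfig, run_declust

    config = config or OptimizerConfig()
    if k_values is None:
        k_values = range(1, 11)
    k_values = [int(k) for k in k_values]
    n = observed.n_samples
    size = observed.n_genes * n
    states = {}
    mses, bics = [], []
    for k in k_values:
        state = run_declust(observed, markers, k, config)
        states[k] = state
        mse_mean = state.objective / size
        mses.append(mse_mean)
        bics.append(compute_bic(mse_mean, n, k))
    curve = BicCurve(k_values, mses, bics)
    selection = select_num_subtypes(curve)
    if return_states:
        return curve, selection, states
    return curve, selection
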