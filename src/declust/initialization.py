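"""Marker-based initialization of compartment fractions.

Immune and stromal abundances are assumed proportional to the linear-scale
geometric mean of their marker genes' expression:

    f_j^immune  = exp(mean log immune-marker expression in sample j) * C_immune
    f_j^stromal = exp(mean log stromal-marker expression in sample j) * C_stromal
    f_j^cancer  = 1 - f_j^immune - f_j^stromal

The two proportionality constants are chosen by a 10x10 grid search over
the feasible region (all implied fractions on the simplex), scoring each
candidate pair with a single non-iterated pass of the two optimization
layers.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_model import (
    CompartmentFractions,
    DeclustError,
    ExpressionMatrix,
    MarkerSet,
)

logger = logging.getLogger(__name__)

__all__ = ["ScalingConstants", "init_fractions_from_markers",
           "grid_search_constants", "marker_scores"]

N_GRID = 10
# implied immune+stromal fraction must leave at least this much cancer
MIN_CANCER_FRACTION = 0.01


@dataclass
class ScalingConstants:
    """Marker-score-to-fraction proportionality constants."""

    c_immune: float
    c_stromal: float

    def __post_init__(self) -> None:
        if self.c_immune <= 0 or self.c_stromal <= 0:
            raise DeclustError("scaling constants must be positive")


def marker_scores(observed: ExpressionMatrix, markers: MarkerSet,
                  min_markers: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mean log expression of immune and stromal markers.

    Markers absent from the matrix are dropped (with a log message);
    fewer than ``min_markers`` surviving markers of either class is an error.
    """
    present = markers.restrict_to(observed)
    for name, before, after in (("immune", markers.immune_genes, present.immune_genes),
                                ("stromal", markers.stromal_genes, present.stromal_genes)):
        missing = len(before) - len(after)
        if missing:
            logger.info("dropped %d %s markers absent from the matrix", missing, name)
        if len(after) < min_markers:
            raise DeclustError(
                f"only {len(after)} {name} markers found in the matrix (need >= {min_markers})")
    idx = {g: i for i, g in enumerate(observed.gene_ids)}
    imm_rows = [idx[g] for g in present.immune_genes]
    str_rows = [idx[g] for g in present.stromal_genes]
    return (observed.values[imm_rows].mean(axis=0),
            observed.values[str_rows].mean(axis=0))


def init_fractions_from_markers(observed: ExpressionMatrix, markers: MarkerSet,
                                constants: ScalingConstants,
                                return_meta: bool = False):
    """Initial compartment fractions from marker scores and scaling constants.

    Implied fractions that leave the simplex are projected back (clipped
    at zero and renormalized); whether any projection occurred is
    reported in the optional metadata.
    """
    s_imm, s_str = marker_scores(observed, markers)
    fi = np.exp(s_imm) * constants.c_immune
    fs = np.exp(s_str) * constants.c_stromal
    fc = 1.0 - fi - fs
    raw = np.column_stack([fc, fi, fs])
    clipped = bool(np.any(raw < 0) or np.any(raw > 1))
    if clipped:
        logger.warning("marker-implied fractions left the simplex for %d samples; projected",
                       int(np.any(raw < 0, axis=1).sum()))
    fractions = CompartmentFractions.from_array(raw, list(observed.sample_ids),
                                                project=True)
    if return_meta:
        return fractions, {"clipped": clipped}
    return fractions


_GRID_CACHE: dict = {}


def _cache_key(observed, markers, n_subtypes, config):
    h = hashlib.sha1(np.ascontiguousarray(observed.values).tobytes()).hexdigest()
    return (h, tuple(markers.immune_genes), tuple(markers.stromal_genes),
            n_subtypes, config.seed, config.grid_maxiter, config.kmeans_restarts)


def grid_search_constants(observed: ExpressionMatrix, markers: MarkerSet,
                          n_subtypes: int,
                          config=None) -> tuple[ScalingConstants, list[dict]]:
    """Choose (C_immune, C_stromal) by exhaustive search over a 10x10 grid.

    Each axis spans (0, c_max] where c_max makes the largest implied
    single-compartment fraction equal 1; grid points sit at the 10 bin
    centers.  Pairs driving any sample's immune+stromal fraction above
    ``1 - MIN_CANCER_FRACTION`` are infeasible and skipped.  Every
    feasible pair is scored with one non-iterated optimization pass; the
    pair with the smallest objective wins.  Results are cached per
    (matrix, markers, K, optimizer settings).

    Returns the winning constants and the list of evaluated grid points
    (dicts with c_immune, c_stromal, objective).
    """
    from .optimizer import OptimizerConfig, single_pass_objective

    config = config or OptimizerConfig()
    if n_subtypes < 1:
        raise DeclustError("n_subtypes must be >= 1")
    key = _cache_key(observed, markers, n_subtypes, config)
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]

    s_imm, s_str = marker_scores(observed, markers)
    a = np.exp(s_imm)
    b = np.exp(s_str)
    ci_max = 1.0 / a.max()
    cs_max = 1.0 / b.max()
    ci_grid = ci_max * (np.arange(1, N_GRID + 1) - 0.5) / N_GRID
    cs_grid = cs_max * (np.arange(1, N_GRID + 1) - 0.5) / N_GRID

    budget = 1.0 - MIN_CANCER_FRACTION
    evaluated: list[dict] = []
    best = None
    for ci in ci_grid:
        for cs in cs_grid:
            if np.any(a * ci + b * cs > budget):
                continue
            fi = a * ci
            fs = b * cs
            fractions = CompartmentFractions.from_array(
                np.column_stack([1.0 - fi - fs, fi, fs]),
                list(observed.sample_ids))
            obj = single_pass_objective(observed, fractions, n_subtypes, config)
            evaluated.append({"c_immune": float(ci), "c_stromal": float(cs),
                              "objective": float(obj)})
            if best is None or obj < best[0]:
                best = (obj, ci, cs)
    if best is None:
        raise DeclustError(
            "no feasible (C_immune, C_stromal) grid pair: marker-implied fractions "
            "exceed the simplex everywhere; inspect the marker lists and input scale")
    result = (ScalingConstants(float(best[1]), float(best[2])), evaluated)
    _GRID_CACHE[key] = result
    logger.info("grid search evaluated %d feasible pairs; best objective %.6g",
                len(evaluated), best[0])
    return result
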