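"""Comparator strategies and recovery metrics for simulation benchmarks.

Two baselines are provided for subtype discovery on bulk mixtures:

* ``bulk`` -- K-means applied directly to the observed mixture, ignoring
  compartment heterogeneity;
* ``two_step`` -- reference-based removal of the immune and stromal
  signal from each sample (linear-scale subtraction and division by the
  cancer fraction), quantile normalization, then K-means on the
  estimated cancer expression.

Recovery of a simulated ground truth is scored on three axes: fraction
accuracy (per-compartment across-sample Pearson correlation), clustering
accuracy (best-permutation agreement via optimal assignment, with the
adjusted Rand index alongside), and profile accuracy (across-gene
Pearson correlation of matched compartment profiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import adjusted_rand_score

from .core_model import (
    CompartmentFractions,
    DeclustError,
    DimensionMismatchError,
    ExpressionMatrix,
    SubtypeAssignment,
)
from .optimizer import FitState, OptimizerConfig, init_subtypes
from .simulator import SimulatedDataset

logger = logging.getLogger(__name__)

__all__ = ["EvaluationReport", "two_step_cancer_profile", "quantile_normalize",
           "baseline_cluster", "estimate_fractions_nnls", "clustering_accuracy",
           "evaluate_recovery", "summarize_reports"]


@dataclass
class EvaluationReport:
    """Recovery metrics for one fitted dataset (NaN where not applicable)."""

    clustering_accuracy: float
    adjusted_rand_index: float
    fraction_accuracy: float = float("nan")
    profile_accuracy: float = float("nan")
    fraction_correlations: dict = field(default_factory=dict)
    profile_correlations: dict = field(default_factory=dict)
    profile_correlations_spearman: dict = field(default_factory=dict)
    label_permutation: Optional[tuple] = None


def two_step_cancer_profile(observed: ExpressionMatrix,
                            ref_immune_profile: np.ndarray,
                            ref_stromal_profile: np.ndarray,
                            fractions: CompartmentFractions,
                            median_match: bool = True,
                            return_meta: bool = False):
    """Per-sample cancer expression by subtracting reference non-cancer signal.

    Works on the linear scale:

        E_cancer = (o_mix - refE_immune * f_immune - refE_stromal * f_stromal)
                   / f_cancer

    With ``median_match`` the (log-scale) reference profiles are first
    rescaled so the median of their linear-scale matrix matches that of
    the observed linear-scale matrix, accommodating references measured
    on a different scale.  Negative subtracted values are floored at a
    small positive epsilon before returning to log scale.
    """
    ref_imm = np.asarray(ref_immune_profile, dtype=float).ravel()
    ref_str = np.asarray(ref_stromal_profile, dtype=float).ravel()
    if ref_imm.size != observed.n_genes or ref_str.size != observed.n_genes:
        raise DimensionMismatchError("reference profiles missing genes of the matrix")
    if fractions.n_samples != observed.n_samples:
        raise DimensionMismatchError("fractions and matrix disagree on sample count")
    if np.any(fractions.f_cancer < 0.01 - 1e-12):
        raise DeclustError("two-step subtraction requires f_cancer >= 0.01")

    o_lin = np.exp(observed.values)
    ref_lin = np.column_stack([np.exp(ref_imm), np.exp(ref_str)])
    if median_match:
        scale = np.median(o_lin) / np.median(ref_lin)
        ref_lin = ref_lin * scale
    cancer_lin = (o_lin - ref_lin[:, [0]] * fractions.f_immune
                  - ref_lin[:, [1]] * fractions.f_stromal) / fractions.f_cancer
    eps = 1e-6 * np.median(o_lin)
    floored = int(np.sum(cancer_lin < eps))
    if floored:
        logger.debug("two-step subtraction floored %d negative entries", floored)
    cancer_lin = np.clip(cancer_lin, eps, None)
    result = ExpressionMatrix(np.log(cancer_lin), list(observed.gene_ids),
                              list(observed.sample_ids))
    if return_meta:
        return result, {"n_floored": floored}
    return result


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values, assigned back by within-column rank.
    """
    v = matrix.values
    order = np.argsort(v, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(v.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows, axis=0)
    reference = np.sort(v, axis=0).mean(axis=1)
    return ExpressionMatrix(reference[ranks], list(matrix.gene_ids),
                            list(matrix.sample_ids))


def baseline_cluster(matrix: ExpressionMatrix, n_subtypes: int,
                     mode: str = "bulk",
                     config: Optional[OptimizerConfig] = None) -> SubtypeAssignment:
    """K-means subtyping of a genes x samples matrix.

    ``bulk`` clusters the matrix as-is; ``two_step`` quantile-normalizes
    columns first (the input is then typically an estimated cancer
    matrix).  K-means settings (restarts, seed) are shared with the main
    optimizer.
    """
    config = config or OptimizerConfig()
    if mode not in ("bulk", "two_step"):
        raise DeclustError("mode must be 'bulk' or 'two_step'")
    if mode == "two_step":
        matrix = quantile_normalize(matrix)
    return init_subtypes(matrix.values, n_subtypes, config)


def estimate_fractions_nnls(observed: ExpressionMatrix,
                            ref_cancer_profile: np.ndarray,
                            ref_immune_profile: np.ndarray,
                            ref_stromal_profile: np.ndarray) -> CompartmentFractions:
    """Reference-based fraction estimates by per-sample non-negative least
    squares on the linear scale, normalized to the simplex.

    This is the plain reference-based comparator used to feed the
    two-step strategy with estimated (rather than true) fractions.
    """
    A = np.column_stack([np.exp(np.asarray(p, dtype=float).ravel())
                         for p in (ref_cancer_profile, ref_immune_profile,
                                   ref_stromal_profile)])
    if A.shape[0] != observed.n_genes:
        raise DimensionMismatchError("reference profiles missing genes of the matrix")
    o_lin = np.exp(observed.values)
    out = np.empty((observed.n_samples, 3))
    for j in range(observed.n_samples):
        w, _ = nnls(A, o_lin[:, j])
        if w.sum() <= 0:
            w = np.array([1.0, 0.0, 0.0])
        out[j] = w / w.sum()
    # keep downstream division by f_cancer well defined: floor f_cancer
    # and rescale the non-cancer part so rows stay on the simplex
    low = out[:, 0] < 0.01
    if np.any(low):
        out[low, 1:] *= ((1.0 - 0.01) / out[low, 1:].sum(axis=1))[:, None]
        out[low, 0] = 0.01
    return CompartmentFractions.from_array(out, list(observed.sample_ids))


def clustering_accuracy(true_labels: np.ndarray, est_labels: np.ndarray
                        ) -> tuple[float, tuple, float]:
    """Best-permutation agreement between two labelings.

    Builds the contingency table and solves the optimal one-to-one label
    matching (Hungarian algorithm); returns (accuracy, permutation, ARI)
    where ``permutation[c]`` is the true label (0-based) matched to
    estimated label c.
    """
    t = np.asarray(true_labels, dtype=int).ravel()
    e = np.asarray(est_labels, dtype=int).ravel()
    if t.size != e.size:
        raise DimensionMismatchError("label vectors differ in length")
    kt, ke = t.max() + 1, e.max() + 1
    k = max(kt, ke)
    cont = np.zeros((k, k))
    np.add.at(cont, (t, e), 1)
    rows, cols = linear_sum_assignment(-cont)
    acc = float(cont[rows, cols].sum() / t.size)
    perm = tuple(int(rows[list(cols).index(c)]) for c in range(k))
    return acc, perm, float(adjusted_rand_score(t, e))


def _safe_pearson(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(pearsonr(x, y).statistic)


def evaluate_recovery(truth: SimulatedDataset,
                      estimate: Union[FitState, SubtypeAssignment]
                      ) -> EvaluationReport:
    """Score an estimate (full fit or bare assignment) against ground truth."""
    true_assign = truth.true_assignment
    if isinstance(estimate, SubtypeAssignment):
        est_assign, state = estimate, None
    else:
        est_assign, state = estimate.assignment, estimate
    if est_assign.n_samples != true_assign.n_samples:
        raise DimensionMismatchError("estimate and truth disagree on sample count")

    acc, perm, ari = clustering_accuracy(true_assign.zero_based(),
                                         est_assign.zero_based())
    report = EvaluationReport(clustering_accuracy=acc, adjusted_rand_index=ari,
                              label_permutation=perm)
    if state is None:
        return report

    tf = truth.true_fractions.as_array()
    ef = state.fractions.as_array()
    names = ("cancer", "immune", "stromal")
    report.fraction_correlations = {
        n: _safe_pearson(tf[:, c], ef[:, c]) for c, n in enumerate(names)}
    report.fraction_accuracy = float(np.mean(
        [report.fraction_correlations[n] for n in names]))

    tp, ep = truth.true_profiles, state.profiles
    if tp.n_genes == ep.n_genes:
        k = min(tp.n_subtypes, ep.n_subtypes)
        cancer_p, cancer_s = [], []
        for c in range(k):
            tcol = tp.cancer_profiles[:, perm[c]] if perm[c] < tp.n_subtypes else None
            if tcol is None:
                continue
            ecol = ep.cancer_profiles[:, c]
            cancer_p.append(_safe_pearson(tcol, ecol))
            cancer_s.append(float(spearmanr(tcol, ecol).statistic))
        report.profile_correlations = {
            "cancer": float(np.nanmean(cancer_p)),
            "immune": _safe_pearson(tp.immune_profile, ep.immune_profile),
            "stromal": _safe_pearson(tp.stromal_profile, ep.stromal_profile),
        }
        report.profile_correlations_spearman = {
            "cancer": float(np.nanmean(cancer_s)),
            "immune": float(spearmanr(tp.immune_profile, ep.immune_profile).statistic),
            "stromal": float(spearmanr(tp.stromal_profile, ep.stromal_profile).statistic),
        }
        report.profile_accuracy = float(np.mean(
            [report.profile_correlations[n] for n in names]))
    return report


def summarize_reports(reports: list[EvaluationReport]) -> dict:
    """Mean of each metric over per-replicate reports."""
    def mean_of(attr):
        vals = [v for r in reports if not np.isnan(v := getattr(r, attr))]
        return float(np.mean(vals)) if vals else float("nan")

    return {
        "clustering_accuracy": mean_of("clustering_accuracy"),
        "adjusted_rand_index": mean_of("adjusted_rand_index"),
        "fraction_accuracy": mean_of("fraction_accuracy"),
        "profile_accuracy": mean_of("profile_accuracy"),
        "n_replicates": len(reports),
    }
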