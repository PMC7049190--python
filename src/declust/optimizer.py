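"""Two-layer block-coordinate optimization of the mixture model.

The model has three groups of unknowns: per-sample compartment fractions
(group A), per-sample subtype labels (group B), and per-gene compartment
reference profiles (group C).  The inner layer alternates profile
estimation (C) with exact subtype reassignment (B) at fixed fractions;
the outer layer alternates the inner layer with per-sample fraction
optimization (A).  Every accepted step leaves the summed squared
log-reconstruction error non-increasing.

Profile updates solve, per gene, a box-constrained minimization of the
squared log-reconstruction error.  Because the problem is separable
across genes, all genes are advanced simultaneously by a damped Newton
iteration with analytic per-gene gradients and Hessians; a step is
accepted for a gene only if it improves that gene's objective, so
per-gene descent holds by construction.  Fraction updates use the same
scheme across samples in the two free coordinates of the simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from .core_model import (
    CompartmentFractions,
    CompartmentProfiles,
    DeclustError,
    ExpressionMatrix,
    MarkerSet,
    SubtypeAssignment,
    linear_mixture,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerConfig",
    "FitState",
    "fit_single_subtype",
    "init_subtypes",
    "optimize_profiles",
    "reassign_subtypes",
    "run_inner_loop",
    "optimize_fractions",
    "run_declust",
    "single_pass_objective",
]

# absolute slack allowed on "non-increasing" objective comparisons
DESCENT_SLACK = 1e-9


@dataclass
class OptimizerConfig:
    """Tunable knobs of the block-coordinate optimizer.

    Iteration caps and tolerances govern the two convergence loops;
    ``profile_bounds_pad`` widens the per-gene box constraints beyond the
    observed log-expression range; the seed drives K-means restarts.
    """

    max_inner_iter: int = 20
    max_outer_iter: int = 10
    rel_tol_inner: float = 1e-6
    rel_tol_outer: float = 1e-5
    kmeans_restarts: int = 25
    seed: int = 0
    profile_bounds_pad: float = 2.0
    profile_maxiter: int = 60
    fraction_maxiter: int = 60
    grid_maxiter: int = 12

    def __post_init__(self) -> None:
        if self.max_inner_iter < 1 or self.max_outer_iter < 1:
            raise DeclustError("iteration caps must be >= 1")
        if self.rel_tol_inner <= 0 or self.rel_tol_outer <= 0:
            raise DeclustError("tolerances must be positive")
        if self.kmeans_restarts < 1:
            raise DeclustError("kmeans_restarts must be >= 1")


@dataclass
class FitState:
    """Joint optimizer state plus bookkeeping."""

    profiles: CompartmentProfiles
    fractions: CompartmentFractions
    assignment: SubtypeAssignment
    objective: float
    inner_iterations: int = 0
    outer_iterations: int = 0
    inner_converged: bool = False
    outer_converged: bool = False
    history: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# raw-array objective helpers

def _objective_matrix(O: np.ndarray, cancer: np.ndarray, immune: np.ndarray,
                      stromal: np.ndarray, frac: np.ndarray,
                      labels0: np.ndarray) -> np.ndarray:
    mix = linear_mixture(cancer, immune, stromal, frac, labels0)
    r = O - np.log(mix)
    return r * r


def _objective(O, cancer, immune, stromal, frac, labels0) -> float:
    return float(_objective_matrix(O, cancer, immune, stromal, frac, labels0).sum())


def _state_objective(observed: ExpressionMatrix, profiles: CompartmentProfiles,
                     fractions: CompartmentFractions,
                     assignment: SubtypeAssignment) -> float:
    return _objective(observed.values, profiles.cancer_profiles,
                      profiles.immune_profile, profiles.stromal_profile,
                      fractions.as_array(), assignment.zero_based())


# --------------------------------------------------------------------------
# profile optimization (group C)

def _solve_profiles_batched(O: np.ndarray, frac: np.ndarray, labels0: np.ndarray,
                            n_subtypes: int, warm: np.ndarray, bounds_pad: float,
                            maxiter: int, ftol: float = 1e-15,
                            gtol: float = 1e-10) -> tuple[np.ndarray, int]:
    """Minimize the squared log-reconstruction error over per-gene profiles.

    All genes are solved simultaneously by a damped (Levenberg-style)
    Newton iteration with analytic per-gene gradients and (K+2)x(K+2)
    Hessians; steps are clipped to per-gene box constraints and accepted
    gene-wise only when they improve that gene's objective, so descent
    holds per gene by construction.  ``warm`` and the returned array are
    (genes, K+2): K cancer columns, then immune, then stromal.
    Returns (solution, n_stalled_genes).
    """
    G, S = O.shape
    P = n_subtypes + 2
    # weight matrix: row c gives each sample's loading on profile column c
    W = np.zeros((P, S))
    for k in range(n_subtypes):
        W[k, labels0 == k] = frac[labels0 == k, 0]
    W[n_subtypes] = frac[:, 1]
    W[n_subtypes + 1] = frac[:, 2]

    lo = O.min(axis=1) - bounds_pad
    hi = O.max(axis=1) + bounds_pad
    theta = np.clip(warm, lo[:, None], hi[:, None])
    eye = np.eye(P)

    def obj_only(th):
        m = np.exp(th) @ W
        r = O - np.log(m)
        return np.sum(r * r, axis=1)

    # second starting point: linear-scale least squares (design shared
    # across genes); exact at zero noise and a strong basin for genes
    # whose compartments differ by orders of magnitude
    try:
        U = np.linalg.lstsq(W.T, np.exp(O).T, rcond=None)[0].T
        with np.errstate(divide="ignore", invalid="ignore"):
            cand0 = np.log(U)
        cand0 = np.where(np.isfinite(cand0), cand0, theta)
        cand0 = np.clip(cand0, lo[:, None], hi[:, None])
        better = obj_only(cand0) < obj_only(theta)
        theta[better] = cand0[better]
    except np.linalg.LinAlgError:
        pass

    def obj_grad_hess(th):
        s = np.exp(th)[:, :, None] * W[None, :, :]        # (G, P, S)
        m = s.sum(axis=1)                                  # (G, S)
        r = O - np.log(m)
        q = s / m[:, None, :]                              # component shares
        f = np.sum(r * r, axis=1)
        qr = np.einsum("gps,gs->gp", q, r)
        grad = -2.0 * qr
        H = 2.0 * np.einsum("gps,gqs->gpq", q * (1.0 + r)[:, None, :], q)
        H[:, np.arange(P), np.arange(P)] -= 2.0 * qr
        return f, grad, H

    f, grad, H = obj_grad_hess(theta)
    lam = np.full(G, 1e-8)
    stalled = np.zeros(G, dtype=bool)
    for _ in range(maxiter):
        work = (np.max(np.abs(grad), axis=1) >= gtol) & ~stalled
        if not np.any(work):
            break
        improved_any = np.zeros(G, dtype=bool)
        f_old = f.copy()
        active = work.copy()
        for _attempt in range(8):
            idx = np.where(active)[0]
            if idx.size == 0:
                break
            Hd = H[idx] + lam[idx, None, None] * eye
            try:
                step = np.linalg.solve(Hd, -grad[idx, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                lam[idx] = np.minimum(lam[idx] * 10.0, 1e12)
                continue
            cand = np.clip(theta[idx] + step, lo[idx, None], hi[idx, None])
            f_cand = obj_only_rows(cand, W, O, idx)
            ok = f_cand < f[idx]
            good = idx[ok]
            theta[good] = cand[ok]
            f[good] = f_cand[ok]
            improved_any[good] = True
            lam[good] = np.maximum(lam[good] * 0.3, 1e-10)
            bad = idx[~ok]
            lam[bad] = np.minimum(lam[bad] * 10.0, 1e12)
            active[:] = False
            active[bad] = lam[bad] < 1e12
        stalled = work & ~improved_any
        if not np.any(improved_any):
            break
        # relative-improvement stop (analogue of an ftol criterion)
        if np.max(f_old - f) <= ftol * max(1.0, float(f.sum())):
            break
        f, grad, H = obj_grad_hess(theta)

    worse = obj_only(theta) > obj_only(np.clip(warm, lo[:, None], hi[:, None])) \
        + DESCENT_SLACK
    if np.any(worse):   # cannot happen by construction; belt and braces
        theta[worse] = np.clip(warm, lo[:, None], hi[:, None])[worse]
        logger.debug("profile solve reverted %d genes", int(worse.sum()))
    return theta, int(stalled.sum())


def obj_only_rows(th_rows: np.ndarray, W: np.ndarray, O: np.ndarray,
                  idx: np.ndarray) -> np.ndarray:
    m = np.exp(th_rows) @ W
    r = O[idx] - np.log(m)
    return np.sum(r * r, axis=1)


def _profiles_from_theta(theta: np.ndarray, n_subtypes: int,
                         gene_ids: list[str]) -> CompartmentProfiles:
    return CompartmentProfiles(theta[:, :n_subtypes], theta[:, n_subtypes],
                               theta[:, n_subtypes + 1], list(gene_ids))


_SINGLE_SUBTYPE_CACHE: dict = {}


def fit_single_subtype(observed: ExpressionMatrix, fractions: CompartmentFractions,
                       config: Optional[OptimizerConfig] = None,
                       maxiter: Optional[int] = None, ftol: float = 1e-14,
                       gtol: float = 1e-10) -> CompartmentProfiles:
    """Fit the K=1 model: one cancer profile plus immune and stromal profiles.

    When fractions are degenerate (e.g. all samples pure cancer) the
    unidentifiable compartments simply keep their warm-start values, which
    are the per-gene means of the observed log expression.  Results are
    cached on (data, fractions, solver settings): the K=1 fit does not
    depend on the candidate subtype number, so the scaling-constant grid
    search reuses it across K.
    """
    import hashlib

    config = config or OptimizerConfig()
    O = observed.values
    frac = fractions.as_array()
    if frac.shape[0] != observed.n_samples:
        raise DeclustError("fractions and observed matrix disagree on sample count")
    maxiter = maxiter or config.profile_maxiter
    key = (hashlib.sha1(np.ascontiguousarray(O).tobytes()).hexdigest(),
           hashlib.sha1(np.ascontiguousarray(frac).tobytes()).hexdigest(),
           config.profile_bounds_pad, maxiter, ftol, gtol)
    if key in _SINGLE_SUBTYPE_CACHE:
        theta = _SINGLE_SUBTYPE_CACHE[key]
    else:
        warm = np.repeat(O.mean(axis=1)[:, None], 3, axis=1)
        labels0 = np.zeros(observed.n_samples, dtype=int)
        theta, _ = _solve_profiles_batched(O, frac, labels0, 1, warm,
                                           config.profile_bounds_pad,
                                           maxiter, ftol, gtol)
        if len(_SINGLE_SUBTYPE_CACHE) > 512:
            _SINGLE_SUBTYPE_CACHE.clear()
        _SINGLE_SUBTYPE_CACHE[key] = theta
    return _profiles_from_theta(theta, 1, observed.gene_ids)


def optimize_profiles(observed: ExpressionMatrix, fractions: CompartmentFractions,
                      assignment: SubtypeAssignment,
                      warm_start_profiles: CompartmentProfiles,
                      config: Optional[OptimizerConfig] = None,
                      maxiter: Optional[int] = None) -> CompartmentProfiles:
    """Update all compartment profiles at fixed fractions and assignment.

    Gene-wise problems are independent; subtypes with no member samples
    keep their warm-start column (their gradient is identically zero).
    """
    config = config or OptimizerConfig()
    K = warm_start_profiles.n_subtypes
    if assignment.labels.size and assignment.labels.max() > K:
        raise DeclustError("assignment labels exceed the number of subtype profiles")
    labels0 = assignment.zero_based()
    empty = [k + 1 for k in range(K) if not np.any(labels0 == k)]
    if empty:
        logger.warning("subtypes with no member samples kept at warm start: %s", empty)
    warm = np.column_stack([warm_start_profiles.cancer_profiles,
                            warm_start_profiles.immune_profile,
                            warm_start_profiles.stromal_profile])
    theta, _ = _solve_profiles_batched(observed.values, fractions.as_array(),
                                       labels0, K, warm,
                                       config.profile_bounds_pad,
                                       maxiter or config.profile_maxiter)
    for k in (np.asarray(empty) - 1):
        # unidentifiable column: return the warm start verbatim (unclipped)
        theta[:, k] = warm[:, k]
    return _profiles_from_theta(theta, K, observed.gene_ids)


# --------------------------------------------------------------------------
# subtype assignment (group B)

def init_subtypes(residuals: np.ndarray, n_subtypes: int,
                  config: Optional[OptimizerConfig] = None) -> SubtypeAssignment:
    """Initial subtype labels by K-means clustering of residual expression.

    Samples (columns of the residual matrix) are the observations.
    Labels are renumbered by descending cluster size and returned 1-based.
    """
    config = config or OptimizerConfig()
    residuals = np.asarray(residuals, dtype=float)
    n_samples = residuals.shape[1]
    if n_subtypes > n_samples:
        raise DeclustError("more subtypes than samples")
    if n_subtypes == 1:
        return SubtypeAssignment(np.ones(n_samples, dtype=int), 1)
    km = KMeans(n_clusters=n_subtypes, n_init=config.kmeans_restarts,
                random_state=config.seed)
    raw = km.fit_predict(residuals.T)
    return SubtypeAssignment(_relabel_by_size(raw) + 1, n_subtypes)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber 0-based labels so cluster 0 is the largest, ties by old index."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = np.empty(int(uniq.max()) + 1, dtype=int)
    for new, old in enumerate(order):
        mapping[old] = new
    return mapping[labels]


def _per_sample_errors_by_subtype(O, cancer, immune, stromal, frac):
    """(K, samples) matrix of per-sample squared errors under each label."""
    K = cancer.shape[1]
    base = (np.exp(immune)[:, None] * frac[:, 1]
            + np.exp(stromal)[:, None] * frac[:, 2])
    errs = np.empty((K, O.shape[1]))
    for k in range(K):
        mix = np.exp(cancer[:, k])[:, None] * frac[:, 0] + base
        r = O - np.log(mix)
        errs[k] = np.sum(r * r, axis=0)
    return errs


def reassign_subtypes(observed: ExpressionMatrix, profiles: CompartmentProfiles,
                      fractions: CompartmentFractions) -> SubtypeAssignment:
    """Exactly optimal per-sample subtype labels by exhaustive enumeration.

    Ties are broken toward the lowest subtype index, so the result is
    deterministic and the total objective can never increase.
    """
    errs = _per_sample_errors_by_subtype(observed.values, profiles.cancer_profiles,
                                         profiles.immune_profile,
                                         profiles.stromal_profile,
                                         fractions.as_array())
    return SubtypeAssignment(np.argmin(errs, axis=0) + 1, profiles.n_subtypes)


# --------------------------------------------------------------------------
# fraction optimization (group A)

_FRACTION_EPS = 1e-9


def _project_triangle(x: np.ndarray) -> np.ndarray:
    """Project (samples, 2) points onto {fi, fs >= eps, fi + fs <= 1 - eps}."""
    x = np.clip(x, _FRACTION_EPS, None)
    s = x.sum(axis=1)
    over = s > 1.0 - _FRACTION_EPS
    if np.any(over):
        excess = (s[over] - (1.0 - _FRACTION_EPS)) / 2.0
        x[over] -= excess[:, None]
        x = np.clip(x, _FRACTION_EPS, None)
        s = x.sum(axis=1)
        over = s > 1.0 - _FRACTION_EPS
        x[over] *= ((1.0 - _FRACTION_EPS) / s[over])[:, None]
    return x


def optimize_fractions(observed: ExpressionMatrix, profiles: CompartmentProfiles,
                       assignment: SubtypeAssignment,
                       warm_start_fractions: CompartmentFractions,
                       config: Optional[OptimizerConfig] = None,
                       maxiter: Optional[int] = None, ftol: float = 1e-15,
                       gtol: float = 1e-10) -> CompartmentFractions:
    """Update per-sample compartment fractions at fixed profiles and labels.

    In the free coordinates x = (f_immune, f_stromal) with
    f_cancer = 1 - f_immune - f_stromal, the linear-scale mixture is
    linear in x, so each sample is a tiny 2-parameter problem solved by a
    damped Newton iteration with analytic Hessians; steps are projected
    onto the feasible triangle and accepted per sample only when they
    improve, so per-sample descent and the simplex constraint hold by
    construction.
    """
    config = config or OptimizerConfig()
    O = observed.values
    labels0 = assignment.zero_based()
    Ec = np.exp(profiles.cancer_profiles[:, labels0])      # genes x samples
    A1 = np.exp(profiles.immune_profile)[:, None] - Ec     # d mix / d f_immune
    A2 = np.exp(profiles.stromal_profile)[:, None] - Ec
    S = O.shape[1]
    maxit = maxiter or config.fraction_maxiter

    def per_sample(x):
        mix = Ec + A1 * x[:, 0] + A2 * x[:, 1]
        r = O - np.log(mix)
        return mix, r, np.sum(r * r, axis=0)

    warm_frac = warm_start_fractions.as_array()
    x = _project_triangle(warm_frac[:, 1:].copy())
    mix, r, f = per_sample(x)
    lam = np.full(S, 1e-8)
    for _ in range(maxit):
        q1, q2 = A1 / mix, A2 / mix
        g1 = -2.0 * np.sum(r * q1, axis=0)
        g2 = -2.0 * np.sum(r * q2, axis=0)
        if max(np.max(np.abs(g1)), np.max(np.abs(g2))) < gtol:
            break
        w = 1.0 + r
        h11 = 2.0 * np.sum(q1 * q1 * w, axis=0) + lam
        h22 = 2.0 * np.sum(q2 * q2 * w, axis=0) + lam
        h12 = 2.0 * np.sum(q1 * q2 * w, axis=0)
        det = h11 * h22 - h12 * h12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d1 = (-g1 * h22 + g2 * h12) / det
        d2 = (-g2 * h11 + g1 * h12) / det
        improved = np.zeros(S, dtype=bool)
        step = np.column_stack([d1, d2])
        scale = 1.0
        x_new, f_new = x.copy(), f.copy()
        remaining = np.ones(S, dtype=bool)
        for _bt in range(8):
            cand = _project_triangle(x + scale * step)
            _, _, f_c = per_sample(cand)
            ok = remaining & (f_c <= f - 1e-18)
            x_new[ok] = cand[ok]
            f_new[ok] = f_c[ok]
            improved |= ok
            remaining &= ~ok
            if not np.any(remaining):
                break
            scale *= 0.5
        lam = np.where(improved, np.maximum(lam * 0.3, 1e-10), lam * 10.0)
        gain = f - f_new
        x, f = x_new, f_new
        mix, r, f = per_sample(x)
        if not np.any(improved) or np.max(gain) <= ftol * max(1.0, float(f.sum())):
            break

    full = np.column_stack([1.0 - x.sum(axis=1), x])
    _, _, f_warm = per_sample(_project_triangle(warm_frac[:, 1:].copy()))
    worse = f > f_warm + DESCENT_SLACK
    if np.any(worse):   # defensive; acceptance is per sample already
        full[worse] = warm_frac[worse]
        logger.debug("fraction solve reverted %d samples", int(worse.sum()))
    return CompartmentFractions.from_array(full,
                                           list(warm_start_fractions.sample_ids),
                                           project=True)


# --------------------------------------------------------------------------
# inner loop (groups B and C at fixed A)

def _repair_empty_subtypes(O, theta, n_subtypes, frac, labels0):
    """Re-seed cancer-profile columns of empty subtypes from the worst sample.

    Returns (theta, labels0, repaired_flag).
    """
    present = np.unique(labels0)
    missing = [k for k in range(n_subtypes) if k not in present]
    if not missing:
        return theta, labels0, False
    cancer = theta[:, :n_subtypes]
    errs = _per_sample_errors_by_subtype(O, cancer, theta[:, n_subtypes],
                                         theta[:, n_subtypes + 1], frac)
    cur = errs[labels0, np.arange(O.shape[1])]
    order = np.argsort(-cur)
    theta = theta.copy()
    for rank, k in enumerate(missing):
        j = order[rank % order.size]
        other = (np.exp(theta[:, n_subtypes]) * frac[j, 1]
                 + np.exp(theta[:, n_subtypes + 1]) * frac[j, 2])
        fc = max(frac[j, 0], 1e-3)
        seed_profile = np.log(np.clip((np.exp(O[:, j]) - other) / fc, 1e-8, None))
        theta[:, k] = seed_profile
    return theta, labels0, True


def run_inner_loop(observed: ExpressionMatrix, fractions: CompartmentFractions,
                   n_subtypes: int, config: Optional[OptimizerConfig] = None,
                   warm_state: Optional[FitState] = None,
                   profile_maxiter: Optional[int] = None,
                   max_iter: Optional[int] = None,
                   ftol: float = 1e-14, gtol: float = 1e-10) -> FitState:
    """Alternate profile estimation and subtype reassignment at fixed fractions.

    Without a warm state the loop starts from the K=1 fit: its residual
    matrix is clustered by K-means to yield initial labels, and its
    profiles (cancer column replicated K times) seed the first profile
    update.  With a warm state (outer iterations after the first) the
    previous labels and profiles are reused directly.
    """
    config = config or OptimizerConfig()
    O = observed.values
    frac = fractions.as_array()
    gene_ids = observed.gene_ids

    if warm_state is not None and warm_state.profiles.n_subtypes == n_subtypes:
        labels0 = warm_state.assignment.zero_based()
        theta = np.column_stack([warm_state.profiles.cancer_profiles,
                                 warm_state.profiles.immune_profile,
                                 warm_state.profiles.stromal_profile])
    else:
        p1 = fit_single_subtype(observed, fractions, config,
                                maxiter=profile_maxiter, ftol=ftol, gtol=gtol)
        mix1 = linear_mixture(p1.cancer_profiles, p1.immune_profile,
                              p1.stromal_profile, frac,
                              np.zeros(O.shape[1], dtype=int))
        residuals = O - np.log(mix1)
        labels0 = init_subtypes(residuals, n_subtypes, config).zero_based()
        theta = np.column_stack([np.repeat(p1.cancer_profiles, n_subtypes, axis=1),
                                 p1.immune_profile, p1.stromal_profile])

    maxit = max_iter if max_iter is not None else config.max_inner_iter
    pmaxiter = profile_maxiter or config.profile_maxiter
    history = []
    objective = _objective(O, theta[:, :n_subtypes], theta[:, n_subtypes],
                           theta[:, n_subtypes + 1], frac, labels0)
    converged = False
    it = 0
    for it in range(1, maxit + 1):
        theta, _ = _solve_profiles_batched(O, frac, labels0, n_subtypes, theta,
                                           config.profile_bounds_pad, pmaxiter,
                                           ftol, gtol)
        errs = _per_sample_errors_by_subtype(O, theta[:, :n_subtypes],
                                             theta[:, n_subtypes],
                                             theta[:, n_subtypes + 1], frac)
        new_labels0 = np.argmin(errs, axis=0)

        theta2, labels2, repaired = _repair_empty_subtypes(
            O, theta, n_subtypes, frac, new_labels0)
        if repaired:
            errs2 = _per_sample_errors_by_subtype(O, theta2[:, :n_subtypes],
                                                  theta2[:, n_subtypes],
                                                  theta2[:, n_subtypes + 1], frac)
            labels2 = np.argmin(errs2, axis=0)
            theta2, _ = _solve_profiles_batched(O, frac, labels2, n_subtypes,
                                                theta2, config.profile_bounds_pad,
                                                pmaxiter, ftol, gtol)
            obj2 = _objective(O, theta2[:, :n_subtypes], theta2[:, n_subtypes],
                              theta2[:, n_subtypes + 1], frac, labels2)
            obj1 = float(errs[new_labels0, np.arange(O.shape[1])].sum())
            if obj2 <= obj1 + DESCENT_SLACK:
                theta, new_labels0 = theta2, labels2

        new_objective = _objective(O, theta[:, :n_subtypes], theta[:, n_subtypes],
                                   theta[:, n_subtypes + 1], frac, new_labels0)
        history.append(new_objective)
        labels_unchanged = np.array_equal(new_labels0, labels0)
        rel_change = abs(objective - new_objective) / max(abs(objective), 1e-30)
        labels0 = new_labels0
        objective = new_objective
        if labels_unchanged and rel_change < config.rel_tol_inner:
            converged = True
            break

    profiles = _profiles_from_theta(theta, n_subtypes, gene_ids)
    assignment = SubtypeAssignment(labels0 + 1, n_subtypes)
    return FitState(profiles=profiles, fractions=fractions, assignment=assignment,
                    objective=objective, inner_iterations=it,
                    inner_converged=converged, history=history)


# --------------------------------------------------------------------------
# one-pass fit used by the scaling-constant grid search

def single_pass_objective(observed: ExpressionMatrix,
                          fractions: CompartmentFractions, n_subtypes: int,
                          config: Optional[OptimizerConfig] = None) -> float:
    """Objective after one non-iterated pass of the two optimization layers.

    Runs the K=1 fit, K-means label initialization, a single profile
    update, a single exact reassignment and a single fraction update --
    no iteration, few solver iterations, few K-means restarts -- and
    returns the resulting summed squared error.  The point is a cheap
    but consistent ranking of candidate scaling constants, not a
    converged fit.
    """
    from dataclasses import replace as _replace

    config = config or OptimizerConfig()
    config = _replace(config, kmeans_restarts=min(config.kmeans_restarts, 5))
    state = run_inner_loop(observed, fractions, n_subtypes, config,
                           profile_maxiter=config.grid_maxiter, max_iter=1,
                           ftol=1e-10, gtol=1e-8)
    new_frac = optimize_fractions(observed, state.profiles, state.assignment,
                                  fractions, config, maxiter=config.grid_maxiter,
                                  ftol=1e-10, gtol=1e-8)
    return _state_objective(observed, state.profiles, new_frac, state.assignment)


# --------------------------------------------------------------------------
# full pipeline

def run_declust(observed: ExpressionMatrix, markers: MarkerSet, n_subtypes: int,
                config: Optional[OptimizerConfig] = None,
                constants=None) -> FitState:
    """Full two-layer fit for a fixed number of cancer subtypes.

    Determines the marker-to-fraction scaling constants by grid search
    (unless ``constants`` is supplied), initializes fractions from marker
    expression, then alternates the inner layer (profiles + labels) with
    per-sample fraction optimization until the relative objective change
    drops below ``rel_tol_outer``.
    """
    from .initialization import grid_search_constants, init_fractions_from_markers

    config = config or OptimizerConfig()
    if constants is None:
        constants, grid = grid_search_constants(observed, markers, n_subtypes, config)
    else:
        grid = None
    fractions = init_fractions_from_markers(observed, markers, constants)

    state: Optional[FitState] = None
    objective = np.inf
    outer_history = []
    converged = False
    it = 0
    for it in range(1, config.max_outer_iter + 1):
        state = run_inner_loop(observed, fractions, n_subtypes, config,
                               warm_state=state)
        fractions = optimize_fractions(observed, state.profiles, state.assignment,
                                       fractions, config)
        new_objective = _state_objective(observed, state.profiles, fractions,
                                         state.assignment)
        outer_history.append(new_objective)
        rel_change = abs(objective - new_objective) / max(abs(objective), 1e-30)
        objective = new_objective
        if it > 1 and rel_change < config.rel_tol_outer:
            converged = True
            break
    if not converged:
        logger.warning("outer loop hit the iteration cap (%d) before converging",
                       config.max_outer_iter)

    state.fractions = fractions
    state.objective = objective
    state.outer_iterations = it
    state.outer_converged = converged
    state.history = outer_history
    state.metadata = {
        "constants": {"c_immune": float(constants.c_immune),
                      "c_stromal": float(constants.c_stromal)},
        "seed": config.seed,
        "n_subtypes": n_subtypes,
        "outer_history": [float(v) for v in outer_history],
        "outer_converged": converged,
        "grid": grid,
    }
    return state
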