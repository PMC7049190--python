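"""Core mixture model: domain containers, reconstruction, objective, residuals.

Each bulk tumor sample is modeled as a mixture of three cellular
compartments -- cancer, immune and stromal cells -- where the cancer
compartment additionally carries one of K discrete molecular subtypes.
All expression values are stored on natural-log scale, but mixing of
compartments happens on the original (linear) scale:

    exp(o_ij) ~ exp(E_i^subtype(j)) * f_j^cancer
              + exp(E_i^immune)     * f_j^immune
              + exp(E_i^stromal)    * f_j^stromal

where ``o_ij`` is the observed log expression of gene i in sample j,
``E`` are per-gene log-scale compartment reference profiles shared across
the cohort, and ``f_j`` is the per-sample compartment fraction vector on
the probability simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIMPLEX_TOL = 1e-8

__all__ = [
    "DeclustError",
    "DimensionMismatchError",
    "SimplexError",
    "EmptyFilterError",
    "ExpressionMatrix",
    "CompartmentFractions",
    "CompartmentProfiles",
    "SubtypeAssignment",
    "MarkerSet",
    "reconstruct_mixture",
    "compute_mse",
    "compute_residuals",
    "filter_low_variance_genes",
    "project_to_simplex",
]


class DeclustError(ValueError):
    """Base class for model-contract violations."""


class DimensionMismatchError(DeclustError):
    """Shapes of jointly used containers are inconsistent."""


class SimplexError(DeclustError):
    """A fraction vector violates the probability-simplex constraint."""


class EmptyFilterError(DeclustError):
    """A filtering step removed every gene."""


def _default_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i + 1}" for i in range(n)]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of natural-log-scale expression values."""

    values: np.ndarray
    gene_ids: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionMismatchError("expression values must be 2-D (genes x samples)")
        if not np.all(np.isfinite(self.values)):
            raise DeclustError("expression matrix contains non-finite entries")
        n_genes, n_samples = self.values.shape
        if self.gene_ids is None:
            self.gene_ids = _default_ids("gene", n_genes)
        if self.sample_ids is None:
            self.sample_ids = _default_ids("sample", n_samples)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.gene_ids) != n_genes:
            raise DimensionMismatchError("gene_ids length does not match row count")
        if len(self.sample_ids) != n_samples:
            raise DimensionMismatchError("sample_ids length does not match column count")
        if len(set(self.gene_ids)) != n_genes:
            raise DeclustError("gene identifiers are not unique")
        if len(set(self.sample_ids)) != n_samples:
            raise DeclustError("sample identifiers are not unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to rows where ``keep`` is True."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_genes,):
            raise DimensionMismatchError("gene mask has wrong length")
        ids = [g for g, k in zip(self.gene_ids, keep) if k]
        return ExpressionMatrix(self.values[keep], ids, list(self.sample_ids))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def project_to_simplex(arr: np.ndarray) -> np.ndarray:
    """Clip negative entries at 0 and renormalize rows to sum to 1."""
    arr = np.clip(np.asarray(arr, dtype=float), 0.0, None)
    sums = arr.sum(axis=-1, keepdims=True)
    if np.any(sums <= 0):
        raise SimplexError("cannot project an all-zero fraction vector")
    return arr / sums


@dataclass
class CompartmentFractions:
    """Per-sample (cancer, immune, stromal) proportions on the simplex."""

    f_cancer: np.ndarray
    f_immune: np.ndarray
    f_stromal: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.f_cancer = np.asarray(self.f_cancer, dtype=float).ravel()
        self.f_immune = np.asarray(self.f_immune, dtype=float).ravel()
        self.f_stromal = np.asarray(self.f_stromal, dtype=float).ravel()
        n = self.f_cancer.size
        if self.f_immune.size != n or self.f_stromal.size != n:
            raise DimensionMismatchError("fraction vectors have differing lengths")
        if self.sample_ids is None:
            self.sample_ids = _default_ids("sample", n)
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) != n:
            raise DimensionMismatchError("sample_ids length does not match fractions")
        arr = self.as_array()
        if np.any(arr < -SIMPLEX_TOL) or np.any(arr > 1 + SIMPLEX_TOL):
            raise SimplexError("fractions outside [0, 1]")
        if np.any(np.abs(arr.sum(axis=1) - 1.0) > SIMPLEX_TOL):
            raise SimplexError("fractions do not sum to 1 within tolerance")

    @property
    def n_samples(self) -> int:
        return self.f_cancer.size

    def as_array(self) -> np.ndarray:
        """(samples, 3) array in (cancer, immune, stromal) column order."""
        return np.column_stack([self.f_cancer, self.f_immune, self.f_stromal])

    @classmethod
    def from_array(cls, arr: np.ndarray, sample_ids: list[str] | None = None,
                   project: bool = False) -> "CompartmentFractions":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise DimensionMismatchError("fraction array must be (samples, 3)")
        if project:
            arr = project_to_simplex(arr)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], sample_ids)


@dataclass
class CompartmentProfiles:
    """Cohort-level log-scale reference profiles for all compartments.

    ``cancer_profiles`` is genes x K (one column per cancer subtype);
    immune and stromal compartments get a single shared profile each.
    """

    cancer_profiles: np.ndarray
    immune_profile: np.ndarray
    stromal_profile: np.ndarray
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.cancer_profiles = np.asarray(self.cancer_profiles, dtype=float)
        if self.cancer_profiles.ndim == 1:
            self.cancer_profiles = self.cancer_profiles[:, None]
        self.immune_profile = np.asarray(self.immune_profile, dtype=float).ravel()
        self.stromal_profile = np.asarray(self.stromal_profile, dtype=float).ravel()
        g = self.cancer_profiles.shape[0]
        if self.immune_profile.size != g or self.stromal_profile.size != g:
            raise DimensionMismatchError("profile gene counts are inconsistent")
        if self.cancer_profiles.shape[1] < 1:
            raise DeclustError("need at least one cancer subtype profile")
        for a in (self.cancer_profiles, self.immune_profile, self.stromal_profile):
            if not np.all(np.isfinite(a)):
                raise DeclustError("profiles contain non-finite values")
        if self.gene_ids is None:
            self.gene_ids = _default_ids("gene", g)
        self.gene_ids = list(self.gene_ids)
        if len(self.gene_ids) != g:
            raise DimensionMismatchError("gene_ids length does not match profiles")

    @property
    def n_genes(self) -> int:
        return self.cancer_profiles.shape[0]

    @property
    def n_subtypes(self) -> int:
        return self.cancer_profiles.shape[1]


@dataclass
class SubtypeAssignment:
    """Per-sample cancer subtype labels in 1..K (1-based)."""

    labels: np.ndarray
    n_subtypes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        self.n_subtypes = int(self.n_subtypes)
        if self.n_subtypes < 1:
            raise DeclustError("n_subtypes must be >= 1")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.n_subtypes):
            raise DeclustError("subtype labels must lie in 1..K")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def zero_based(self) -> np.ndarray:
        return self.labels - 1


@dataclass
class MarkerSet:
    """Immune and stromal marker gene lists used for fraction initialization."""

    immune_genes: list[str] = field(default_factory=list)
    stromal_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.immune_genes = list(dict.fromkeys(self.immune_genes))
        self.stromal_genes = list(dict.fromkeys(self.stromal_genes))
        overlap = set(self.immune_genes) & set(self.stromal_genes)
        if overlap:
            raise DeclustError(f"marker lists overlap: {sorted(overlap)[:5]} ...")

    def restrict_to(self, matrix: ExpressionMatrix) -> "MarkerSet":
        """Intersect marker lists with the genes present in ``matrix``."""
        present = set(matrix.gene_ids)
        return MarkerSet(
            [g for g in self.immune_genes if g in present],
            [g for g in self.stromal_genes if g in present],
        )


# --- array-level fast paths shared by the optimizer ----------------------

def linear_mixture(cancer: np.ndarray, immune: np.ndarray, stromal: np.ndarray,
                   frac: np.ndarray, labels0: np.ndarray) -> np.ndarray:
    """Linear-scale mixture matrix (genes x samples) from raw arrays.

    ``frac`` is (samples, 3) in (cancer, immune, stromal) order;
    ``labels0`` holds 0-based subtype indices.
    """
    ec = np.exp(cancer[:, labels0])           # genes x samples
    return (ec * frac[:, 0]
            + np.exp(immune)[:, None] * frac[:, 1]
            + np.exp(stromal)[:, None] * frac[:, 2])


def _check_shapes(observed: ExpressionMatrix, profiles: CompartmentProfiles,
                  fractions: CompartmentFractions, assignment: SubtypeAssignment) -> None:
    if profiles.n_genes != observed.n_genes:
        raise DimensionMismatchError("profiles and observed matrix disagree on gene count")
    if fractions.n_samples != observed.n_samples:
        raise DimensionMismatchError("fractions and observed matrix disagree on sample count")
    if assignment.n_samples != observed.n_samples:
        raise DimensionMismatchError("assignment and observed matrix disagree on sample count")
    if assignment.n_subtypes > profiles.n_subtypes or (
            assignment.labels.size and assignment.labels.max() > profiles.n_subtypes):
        raise DeclustError("assignment labels exceed the number of subtype profiles")


def reconstruct_mixture(profiles: CompartmentProfiles, fractions: CompartmentFractions,
                        assignment: SubtypeAssignment) -> ExpressionMatrix:
    """Reconstruct the expected log-scale bulk matrix from model components.

    Mixing is performed on the linear scale, so every reconstructed
    linear-scale value is a convex combination of the three compartments'
    linear-scale values for that gene.
    """
    if fractions.n_samples != assignment.n_samples:
        raise DimensionMismatchError("fractions and assignment disagree on sample count")
    if assignment.labels.size and assignment.labels.max() > profiles.n_subtypes:
        raise DeclustError("assignment labels exceed the number of subtype profiles")
    mix = linear_mixture(profiles.cancer_profiles, profiles.immune_profile,
                         profiles.stromal_profile, fractions.as_array(),
                         assignment.zero_based())
    return ExpressionMatrix(np.log(mix), list(profiles.gene_ids),
                            list(fractions.sample_ids))


def compute_residuals(observed: ExpressionMatrix, profiles: CompartmentProfiles,
                      fractions: CompartmentFractions,
                      assignment: SubtypeAssignment) -> np.ndarray:
    """Residual log expression: observed minus reconstructed, genes x samples."""
    _check_shapes(observed, profiles, fractions, assignment)
    recon = reconstruct_mixture(profiles, fractions, assignment)
    return observed.values - recon.values


def compute_mse(observed: ExpressionMatrix, profiles: CompartmentProfiles,
                fractions: CompartmentFractions, assignment: SubtypeAssignment,
                variant: str = "sum") -> float:
    """Squared log-scale reconstruction error.

    ``variant="sum"`` returns the plain sum of squared residuals (the
    quantity the optimizer minimizes); ``variant="mean"`` divides by
    genes x samples (the quantity fed to the BIC).
    """
    r = compute_residuals(observed, profiles, fractions, assignment)
    total = float(np.sum(r * r))
    if variant == "sum":
        return total
    if variant == "mean":
        return total / r.size
    raise ValueError(f"unknown MSE variant: {variant!r}")


def filter_low_variance_genes(observed: ExpressionMatrix,
                              threshold: float = 0.5) -> ExpressionMatrix:
    """Drop genes whose log-scale standard deviation is below ``threshold``.

    The standard deviation uses the unbiased (n-1) denominator; genes at
    exactly the threshold are retained.
    """
    if observed.n_genes < 1:
        raise DeclustError("expression matrix has no genes")
    if observed.n_samples < 2:
        raise DeclustError("need at least 2 samples to compute a standard deviation")
    sd = observed.values.std(axis=1, ddof=1)
    keep = sd >= threshold
    if not np.any(keep):
        raise EmptyFilterError(
            "variance filter removed every gene; lower the threshold or check the input scale")
    return observed.subset_genes(keep)
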