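# declust

Reference-profile-free deconvolution of bulk tumor transcriptomes with
joint cancer cell-intrinsic subtyping.

Solid tumor tissue is a mixture of cancer, immune and stromal cells, so
expression-based molecular subtyping of bulk samples is confounded by
varying microenvironment content, and classical deconvolution methods
need reference expression profiles that are rarely available for the
tumor type at hand.  `declust` addresses both problems at once: from a
single genes × samples log-scale expression matrix (plus two marker gene
lists used only for initialization) it jointly estimates

1. per-sample compartment fractions (f_cancer, f_immune, f_stromal),
2. a cancer cell-intrinsic subtype label per sample, and
3. cohort-level reference expression profiles for the immune and stromal
   compartments and for each of K cancer subtypes.

It is aimed at computational oncology groups who want cancer-intrinsic
subtypes and tumor-type-specific microenvironment profiles from bulk
cohorts (TCGA-style) without external signature matrices.

## Model

Mixing is linear on the original scale while fitting is done on the log
scale:

    exp(o_ij) ≈ exp(E_i^subtype(j)) f_j^cancer
              + exp(E_i^immune)     f_j^immune
              + exp(E_i^stromal)    f_j^stromal

    SSE = Σ_ij ( o_ij − log reconstruction_ij )²

Unknowns are estimated by a two-layer block-coordinate scheme — an inner
layer alternating per-gene profile fits (damped Newton, analytic
Hessians) with exactly optimal per-sample subtype reassignment, and an
outer layer alternating the inner layer with per-sample fraction fits on
the simplex.  Fractions are initialized from immune/stromal marker
expression through two scaling constants chosen by a 10×10 grid search;
the number of subtypes is chosen from a BIC curve,
BIC(K) = log(MSE)·n + log(n)·K, combining the curve's argmin and elbow.
Every accepted step is non-increasing in SSE, and a fixed seed makes
runs bit-reproducible.  See `docs/methods.md` for assumptions,
parameters and numerical details.

The package also ships the full simulation framework used to validate
the method (correlated compartment reference profiles, subtype-
conditional simplex fractions, log-normal or negative-binomial noise,
full ground truth) and the comparator strategies (direct bulk K-means;
reference-based two-step subtraction + K-means) with recovery metrics.

## Worked example

```python
from declust import OptimizerConfig, SimulationConfig, run_declust, simulate_dataset
from declust.baselines import evaluate_recovery

# synthetic cohort: 300 genes x 60 samples, 3 subtypes, noise sd 0.3
ds = simulate_dataset(SimulationConfig(n_genes=300, n_samples=60,
                                       n_subtypes=3, noise_level=0.3, seed=7))
state = run_declust(ds.observed, ds.markers, n_subtypes=3,
                    config=OptimizerConfig(seed=7))
report = evaluate_recovery(ds, state)
print(state.metadata["constants"])
print(report.clustering_accuracy, report.fraction_accuracy, report.profile_accuracy)
print(state.fractions.as_array()[:3].round(4))
```

prints

```
{'c_immune': 0.0029382757494835652, 'c_stromal': 0.0026269820948797607}
1.0 0.9917 0.9549
[[0.5557 0.3657 0.0787]
 [0.6815 0.1674 0.1511]
 [0.8124 0.1488 0.0388]]
```

i.e. the grid search picked the two marker-scaling constants shown; all
60 samples were assigned to their true subtype (clustering accuracy 1.0
up to label permutation); the estimated fractions correlate with the
simulated truth at 0.992 averaged over the three compartments (the first
three samples' cancer/immune/stromal rows are shown — truth for sample 1
is 0.611/0.323/0.066); and the inferred compartment profiles correlate
with the true ones at 0.955 averaged over compartments.

The same pipeline is available from the shell:

```
declust simulate --outdir sim/ --n-genes 300 --n-samples 60 --noise-level 0.3 --seed 7
declust fit --expression sim/observed.tsv \
            --immune-markers sim/markers_immune.txt \
            --stromal-markers sim/markers_stromal.txt \
            --n-subtypes 3 --outdir fit/ --seed 7
declust evaluate --truth-dir sim/ --estimate-dir fit/
```

`declust fit` without `--n-subtypes` scans a K range, writes the BIC
curve and picks K automatically; `declust select-k` emits just the
curve; `declust baseline` runs the K-means comparators.  Real matrices
are accepted as TSV/CSV with a `--scale natural|log2|linear`
declaration; for TCGA-style input, filter low-variability genes first
(`--variance-filter 0.5`).

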