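"""Reading and writing the plain-text formats used by the pipeline.

Expression matrices are tab- or comma-delimited genes x samples tables
(first column gene identifiers, header row sample identifiers); marker
lists are one gene symbol per line; results and metadata round-trip
through TSV and JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core_model import (
    CompartmentFractions,
    CompartmentProfiles,
    DeclustError,
    ExpressionMatrix,
    MarkerSet,
    SubtypeAssignment,
)
from .model_selection import BicCurve
from .optimizer import FitState
from .simulator import SimulatedDataset, SimulationConfig

logger = logging.getLogger(__name__)

__all__ = ["read_expression_matrix", "read_marker_list", "read_marker_set",
           "write_declust_result", "read_declust_result",
           "write_simulated_dataset", "read_simulated_dataset"]

LN2 = float(np.log(2.0))


def read_expression_matrix(path, declared_scale: str = "natural") -> ExpressionMatrix:
    """Parse an expression table and convert to natural-log scale.

    ``declared_scale`` is one of ``natural`` (stored as-is), ``log2``
    (multiplied by ln 2) or ``linear`` (transformed as log(x + 1)).
    Duplicate gene identifiers keep the maximum-variance row; duplicate
    sample identifiers are an error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    samples = header.split(sep)[1:]
    dups = [s for s in set(samples) if samples.count(s) > 1]
    if dups:
        raise DeclustError(f"duplicate sample identifiers in {path.name}: "
                           f"{sorted(dups)[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DeclustError(f"non-numeric cells in {path.name}: {exc}") from None
    if np.any(pd.isna(values)):
        raise DeclustError(f"missing values in {path.name}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("%d duplicate gene ids in %s; keeping max-variance rows",
                       n_dup, path.name)
        df = df.assign(_var=values.var(axis=1))
        df = (df.sort_values("_var", ascending=False)
              .groupby(level=0, sort=False).head(1)
              .drop(columns="_var"))
        df = df.loc[~df.index.duplicated()]
        values = df.to_numpy(dtype=float)

    if declared_scale == "natural":
        pass
    elif declared_scale == "log2":
        values = values * LN2
    elif declared_scale == "linear":
        if np.any(values < 0):
            raise DeclustError("linear-scale input contains negative values")
        values = np.log(values + 1.0)
    else:
        raise DeclustError(f"unknown scale declaration: {declared_scale!r}")
    return ExpressionMatrix(values, [str(g) for g in df.index],
                            [str(s) for s in df.columns])


def read_marker_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_marker_set(immune_path, stromal_path) -> MarkerSet:
    return MarkerSet(read_marker_list(immune_path), read_marker_list(stromal_path))


def _write_fractions(fractions: CompartmentFractions, path: Path) -> None:
    pd.DataFrame({"sample": fractions.sample_ids,
                  "f_cancer": fractions.f_cancer,
                  "f_immune": fractions.f_immune,
                  "f_stromal": fractions.f_stromal}).to_csv(path, sep="\t",
                                                            index=False)


def _write_profiles(profiles: CompartmentProfiles, path: Path) -> None:
    cols = {"gene": profiles.gene_ids,
            "immune": profiles.immune_profile,
            "stromal": profiles.stromal_profile}
    for k in range(profiles.n_subtypes):
        cols[f"subtype_{k + 1}"] = profiles.cancer_profiles[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_declust_result(state: FitState, curve: Optional[BicCurve], outdir,
                         selection=None) -> Path:
    """Write fractions, subtype labels, profiles, BIC curve and metadata.

    All files are TSV except ``metadata.json``; every numeric table
    round-trips through :func:`read_declust_result`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fractions(state.fractions, outdir / "fractions.tsv")
    pd.DataFrame({"sample": state.fractions.sample_ids,
                  "subtype": state.assignment.labels}).to_csv(
        outdir / "subtypes.tsv", sep="\t", index=False)
    _write_profiles(state.profiles, outdir / "profiles.tsv")
    if curve is not None:
        pd.DataFrame({"K": curve.k_values, "mse_mean": curve.mse_values,
                      "bic": curve.bic_values}).to_csv(
            outdir / "bic_curve.tsv", sep="\t", index=False)
    meta = {"version": __version__,
            "objective": float(state.objective),
            "n_subtypes": int(state.assignment.n_subtypes),
            "outer_iterations": int(state.outer_iterations),
            "outer_converged": bool(state.outer_converged)}
    meta.update({k: v for k, v in state.metadata.items() if k != "grid"})
    if selection is not None:
        meta["selected_k"] = int(selection.selected)
        meta["k_min"] = int(selection.k_min)
        meta["k_elbow"] = int(selection.k_elbow)
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_declust_result(outdir) -> dict:
    """Read back a result directory written by :func:`write_declust_result`."""
    outdir = Path(outdir)
    fr = pd.read_csv(outdir / "fractions.tsv", sep="\t")
    fractions = CompartmentFractions(fr["f_cancer"].to_numpy(),
                                     fr["f_immune"].to_numpy(),
                                     fr["f_stromal"].to_numpy(),
                                     fr["sample"].astype(str).tolist())
    su = pd.read_csv(outdir / "subtypes.tsv", sep="\t")
    pr = pd.read_csv(outdir / "profiles.tsv", sep="\t")
    sub_cols = [c for c in pr.columns if c.startswith("subtype_")]
    profiles = CompartmentProfiles(pr[sub_cols].to_numpy(),
                                   pr["immune"].to_numpy(),
                                   pr["stromal"].to_numpy(),
                                   pr["gene"].astype(str).tolist())
    meta = json.loads((outdir / "metadata.json").read_text())
    assignment = SubtypeAssignment(su["subtype"].to_numpy(), len(sub_cols))
    out = {"fractions": fractions, "assignment": assignment,
           "profiles": profiles, "metadata": meta}
    curve_path = outdir / "bic_curve.tsv"
    if curve_path.exists():
        cv = pd.read_csv(curve_path, sep="\t")
        out["curve"] = BicCurve(cv["K"].tolist(), cv["mse_mean"].tolist(),
                                cv["bic"].tolist())
    return out


def write_simulated_dataset(dataset: SimulatedDataset, outdir) -> Path:
    """Write a simulated cohort (observed matrix + full ground truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.observed.to_dataframe().to_csv(outdir / "observed.tsv", sep="\t")
    _write_fractions(dataset.true_fractions, outdir / "true_fractions.tsv")
    pd.DataFrame({"sample": dataset.true_fractions.sample_ids,
                  "subtype": dataset.true_assignment.labels}).to_csv(
        outdir / "true_subtypes.tsv", sep="\t", index=False)
    _write_profiles(dataset.true_profiles, outdir / "true_profiles.tsv")
    (outdir / "markers_immune.txt").write_text(
        "\n".join(dataset.markers.immune_genes) + "\n")
    (outdir / "markers_stromal.txt").write_text(
        "\n".join(dataset.markers.stromal_genes) + "\n")
    cfg = asdict(dataset.config)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, default=list))
    return outdir


def read_simulated_dataset(outdir) -> SimulatedDataset:
    """Read back a simulated cohort directory (subtype variants are not
    stored on disk and come back as None)."""
    outdir = Path(outdir)
    observed = read_expression_matrix(outdir / "observed.tsv")
    fr = pd.read_csv(outdir / "true_fractions.tsv", sep="\t")
    fractions = CompartmentFractions(fr["f_cancer"].to_numpy(),
                                     fr["f_immune"].to_numpy(),
                                     fr["f_stromal"].to_numpy(),
                                     fr["sample"].astype(str).tolist())
    su = pd.read_csv(outdir / "true_subtypes.tsv", sep="\t")
    pr = pd.read_csv(outdir / "true_profiles.tsv", sep="\t")
    sub_cols = [c for c in pr.columns if c.startswith("subtype_")]
    profiles = CompartmentProfiles(pr[sub_cols].to_numpy(),
                                   pr["immune"].to_numpy(),
                                   pr["stromal"].to_numpy(),
                                   pr["gene"].astype(str).tolist())
    markers = MarkerSet(read_marker_list(outdir / "markers_immune.txt"),
                        read_marker_list(outdir / "markers_stromal.txt"))
    cfg_raw = json.loads((outdir / "config.json").read_text())
    config = SimulationConfig(**cfg_raw)
    assignment = SubtypeAssignment(su["subtype"].to_numpy(), len(sub_cols))
    return SimulatedDataset(observed=observed, true_profiles=profiles,
                            true_fractions=fractions, true_assignment=assignment,
                            markers=markers, config=config)
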