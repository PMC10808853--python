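"""Report bundles: the standard result tables as CSV plus diagnostic plots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import UncertaintyResults

__all__ = ["write_report", "plot_prediction_range", "plot_precision_profile"]


def plot_precision_profile(results: UncertaintyResults, ax=None):
    """Reproducibility SD and RSD as functions of concentration."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    prof = results.profile
    x = np.linspace(results.model.x.min() / 2, results.model.x.max() * 1.05, 300)
    ax.plot(x, prof.sd(x), label="sigma(x)")
    ax2 = ax.twinx()
    ax2.plot(x, prof.rsd(np.maximum(x, 1e-12)), ls="--", color="C1", label="RSD(x) [%]")
    ax.set_xlabel(f"concentration [{results.units}]")
    ax.set_ylabel(f"reproducibility SD [{results.units}]")
    ax2.set_ylabel("RSD [%]")
    ax.set_title("Precision profile sqrt(C + P x^2)")
    return ax


def plot_prediction_range(results: UncertaintyResults, k: float = 2.0,
                          measured: Sequence[float] = (), bias_corrected: bool = True,
                          ax=None):
    """Data, mean curve and prediction band; optional interval constructions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rng = results.prediction_range(k=k, bias_corrected=bias_corrected)
    study = results.model.study
    ax.scatter(study.data["known_x"], study.data["y"], marker="D", s=18,
               color="k", zorder=3, label="validation results")
    hi = study.data["known_x"].max() * 1.15
    y = np.linspace(0, hi, 400)
    ax.plot(y, rng.curve.predict(y), color="C0", label="mean curve")
    ax.plot(y, rng.f_upper(y), "--", color="C0", label=f"prediction range (k={k:g})")
    ax.plot(y, rng.f_lower(y), "--", color="C0")
    for ym in measured:
        iv = rng.invert(float(ym))
        ax.axhline(ym, color="C3", lw=0.8)
        upper = iv.upper if np.isfinite(iv.upper) else hi
        ax.plot([iv.lower, upper], [0, 0], color="C3", lw=4, solid_capstyle="butt")
    ax.set_xlabel(f"measurand / known concentration [{results.units}]")
    ax.set_ylabel(f"measurement result [{results.units}]")
    ax.set_ylim(bottom=0)
    ax.legend(fontsize=8)
    return ax


def write_report(results: UncertaintyResults, outdir, measured: Sequence[float] = (),
                 k: float = 2.0, bias_corrected: bool = True,
                 concentrations: Sequence[float] | None = None) -> dict[str, Path]:
    """Write variance/precision/uncertainty tables (CSV) and plots (SVG).

    Returns the mapping of artefact name to path.  Footnote-style warnings
    (boundary zeros, truncated or unbounded limits) are appended to notes.txt.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if concentrations is None:
        concentrations = sorted(results.model.study.levels)
    paths: dict[str, Path] = {}

    tables = {
        "variance_components": results.variance_table(),
        "precision": results.precision_table(concentrations),
        "expanded_uncertainty": results.expanded_uncertainty_table(concentrations, k=k),
    }
    if len(measured):
        tables["uncertainty_intervals"] = results.uncertainty_table(
            measured, k=k, bias_corrected=bias_corrected
        )
    for name, frame in tables.items():
        paths[name] = outdir / f"{name}.csv"
        frame.to_csv(paths[name], index=False)

    fig, ax = plt.subplots(figsize=(6, 4))
    plot_precision_profile(results, ax=ax)
    paths["precision_profile_plot"] = outdir / "precision_profile.svg"
    fig.savefig(paths["precision_profile_plot"], bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    plot_prediction_range(results, k=k, measured=measured, bias_corrected=bias_corrected, ax=ax)
    paths["prediction_range_plot"] = outdir / "prediction_range.svg"
    fig.savefig(paths["prediction_range_plot"], bbox_inches="tight")
    plt.close(fig)

    notes = []
    for name, tv in results.components.items():
        if tv.const == 0.0:
            notes.append(f"boundary zero: constant component of {name!r}")
        if tv.prop == 0.0:
            notes.append(f"boundary zero: proportional component of {name!r}")
    if "uncertainty_intervals" in tables:
        t = tables["uncertainty_intervals"]
        for _, row in t.iterrows():
            if row["truncated_low"]:
                notes.append(f"lower limit truncated at 0 for ym={row['measured']:g}")
            if row["unbounded_high"]:
                notes.append(f"no finite upper limit for ym={row['measured']:g}")
    if not results.converged:
        notes.append("WARNING: REML fit did not converge; results are indicative only")
    paths["notes"] = outdir / "notes.txt"
    paths["notes"].write_text("\n".join(notes) + "\n")
    paths["summary"] = outdir / "summary.txt"
    paths["summary"].write_text(results.summary() + "\n")
    return paths
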