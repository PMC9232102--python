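"""Figure rendering and machine-readable summary validation for a pipeline run."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import MembindError

__all__ = ["render_report", "validate_summary", "ReportError"]


class ReportError(MembindError):
    """A required stage output is missing from the bundle."""


#: Minimal schema of summary.json: required keys and their types.
SUMMARY_SCHEMA = {
    "config_hash": str,
    "seed": int,
    "status": str,
    "stages": dict,
}


def validate_summary(summary: dict) -> None:
    """Validate a summary dict against the shipped schema; raise on failure."""
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ReportError(f"summary missing required key '{key}'")
        if not isinstance(summary[key], typ):
            raise ReportError(
                f"summary key '{key}' has type {type(summary[key]).__name__}, "
                f"expected {typ.__name__}")
    for name, stage in summary["stages"].items():
        if not isinstance(stage, dict):
            raise ReportError(f"stage '{name}' entry is not an object")


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def render_report(bundle_dir: str | Path, threshold: float = 0.8) -> dict:
    """Render figures from a pipeline output directory.

    Produces the 2D distance/orientation density heat map, the z-density
    profile line plot, the per-residue normalised-contact bar profile with
    the hotspot threshold line, and (for ≥2 replicates) the convergence
    curve.  Returns {figure name: path}.  Missing stage outputs raise
    :class:`ReportError` listing the absent artifacts.
    """
    bundle = Path(bundle_dir)
    summary_path = bundle / "summary.json"
    required = [summary_path, bundle / "density2d.csv",
                bundle / "normalized_contacts.csv"]
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise ReportError(f"missing stage outputs: {', '.join(missing)}")
    with open(summary_path) as fh:
        summary = json.load(fh)
    validate_summary(summary)

    figures: dict = {}

    dens = _read_csv(bundle / "density2d.csv")
    z = np.sort(dens["zdist"].unique())
    t = np.sort(dens["theta"].unique())
    grid = dens.pivot_table(index="zdist", columns="theta",
                            values="density").to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(t, z, grid, shading="nearest", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="density of states")
    ax.set_xlabel("orientation angle θ (deg)")
    ax.set_ylabel("protein–membrane z distance (nm)")
    path = bundle / "density2d.png"
    fig.savefig(path, dpi=120, bbox_inches="tight"); plt.close(fig)
    figures["density2d"] = str(path)

    zprof = bundle / "zprofile.csv"
    if zprof.exists():
        prof = _read_csv(zprof)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for col in prof.columns[1:]:
            ax.plot(prof["z"], prof[col], label=col)
        ax.set_xlabel("z relative to membrane COM (nm)")
        ax.set_ylabel("number density (nm$^{-3}$)")
        ax.legend(fontsize=7)
        path = bundle / "zprofile.png"
        fig.savefig(path, dpi=120, bbox_inches="tight"); plt.close(fig)
        figures["zprofile"] = str(path)

    norm = _read_csv(bundle / "normalized_contacts.csv")
    fig, ax = plt.subplots(figsize=(6, 3.5))
    group = next((c for c in norm.columns if "POP2" in c), norm.columns[-1])
    ax.bar(norm["residue"], norm[group], width=1.0, color="firebrick")
    ax.axhline(threshold, color="k", linestyle="--", linewidth=0.8,
               label=f"hotspot threshold {threshold}")
    ax.set_xlabel("residue")
    ax.set_ylabel(f"normalised {group} contacts")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    path = bundle / "contacts_profile.png"
    fig.savefig(path, dpi=120, bbox_inches="tight"); plt.close(fig)
    figures["contacts_profile"] = str(path)

    conv = bundle / "convergence.csv"
    if conv.exists():
        curve = _read_csv(conv)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.errorbar(curve["k"], curve["mean_correlation"],
                    yerr=curve["sd_correlation"], marker="o", capsize=3)
        ax.set_xlabel("replicates per subset (k)")
        ax.set_ylabel("Pearson r between disjoint subsets")
        ax.set_ylim(0, 1.02)
        path = bundle / "convergence.png"
        fig.savefig(path, dpi=120, bbox_inches="tight"); plt.close(fig)
        figures["convergence"] = str(path)

    return figures
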