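"""Write pipeline outputs: density/staging CSVs, metadata, heat maps.

Numeric CSVs use a fixed 12-significant-digit format so that two runs from
the same seed produce byte-identical files.  Positions are reported 1-based
(1..N); stages 0-based (0..N, stage 0 = no events yet); both conventions are
stated in every output header.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sequence import (
    PositionalDensity,
    SequencePosterior,
    cumulative_density,
    positional_density,
)

_FLOAT_FMT = "%.12g"


def density_to_frame(density: PositionalDensity) -> pd.DataFrame:
    """Positional density as a DataFrame (rows = events, columns pos_1..pos_N)."""
    cols = [f"pos_{p}" for p in range(1, density.n_events + 1)]
    df = pd.DataFrame(density.matrix, columns=cols)
    df.insert(0, "event", density.events)
    if density.modality_of:
        df.insert(1, "modality", [density.modality_of[e] for e in density.events])
    return df


def frame_to_density(df: pd.DataFrame) -> PositionalDensity:
    """Inverse of :func:`density_to_frame`."""
    pos_cols = [c for c in df.columns if c.startswith("pos_")]
    modality = (
        dict(zip(df["event"], df["modality"])) if "modality" in df.columns else None
    )
    return PositionalDensity(
        df[pos_cols].to_numpy(dtype=float), df["event"].tolist(), modality
    )


def write_samples(posterior: SequencePosterior, path: str) -> None:
    """Serialize posterior samples, one permutation per row (event indices)."""
    with open(path, "w") as fh:
        fh.write("# one post-burn-in MCMC sample per row: event index at positions 1..N\n")
        np.savetxt(fh, posterior.samples, fmt="%d", delimiter=",")


def read_samples(path: str) -> np.ndarray:
    return np.loadtxt(path, dtype=int, delimiter=",", comments="#", ndmin=2)


def density_from_samples(path: str, events: list[str],
                         modality_of: dict[str, str] | None = None) -> PositionalDensity:
    """Recompute the positional density exactly from serialized samples."""
    samples = read_samples(path)
    post = SequencePosterior(
        samples=samples, log_likelihoods=np.zeros(len(samples)),
        n_iterations=len(samples), burn_in=0, acceptance_rate=1.0,
    )
    return positional_density(post, events, modality_of)


@dataclass
class ProgressionResults:
    """Everything :func:`write_progression_report` needs from a fitted run."""

    density: PositionalDensity
    staging: pd.DataFrame           # subject_id, risk_group, stage, log_likelihood
    posterior: SequencePosterior | None = None
    seed: int | None = None
    config: dict[str, Any] | None = None
    fold_assignments: dict[str, Any] | None = None
    cv_summary: dict[str, Any] | None = None


def write_progression_report(results: ProgressionResults, out_dir: str) -> dict[str, str]:
    """Write the standard output bundle; returns {artifact: path}.

    Artifacts: positional density CSV, cumulative abnormality CSV, staging
    CSV, run metadata JSON, posterior samples CSV (when available), and
    PNG heat maps of the positional density and cumulative abnormality.
    """
    if results.density is None or results.staging is None:
        raise ValidationError("results must contain a density and staging table")
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    header = (
        "# rows: events (display order by posterior mean position); "
        "columns pos_1..pos_N are 1-based sequence positions\n"
    )
    dens = density_to_frame(results.density)
    order = results.density.display_order
    dens = dens.iloc[order].reset_index(drop=True)
    paths["density"] = os.path.join(out_dir, "positional_density.csv")
    with open(paths["density"], "w") as fh:
        fh.write(header)
        dens.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")

    cum = cumulative_density(results.density)
    cum_df = pd.DataFrame(
        cum, columns=[f"pos_{p}" for p in range(1, results.density.n_events + 1)]
    )
    cum_df.insert(0, "event", results.density.events)
    cum_df = cum_df.iloc[order].reset_index(drop=True)
    paths["cumulative"] = os.path.join(out_dir, "cumulative_abnormality.csv")
    with open(paths["cumulative"], "w") as fh:
        fh.write(header)
        cum_df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")

    paths["staging"] = os.path.join(out_dir, "staging.csv")
    with open(paths["staging"], "w") as fh:
        fh.write("# stage is 0-based: 0 = no events yet, N = all events occurred\n")
        results.staging.to_csv(fh, index=False, float_format=_FLOAT_FMT,
                               lineterminator="\n")

    meta = {
        "seed": results.seed,
        "config": results.config,
        "fold_assignments": results.fold_assignments,
        "cv_summary": results.cv_summary,
        "n_events": results.density.n_events,
        "position_convention": "1-based (1..N)",
        "stage_convention": "0-based (0..N)",
    }
    paths["metadata"] = os.path.join(out_dir, "run_metadata.json")
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=_jsonable)

    if results.posterior is not None:
        paths["samples"] = os.path.join(out_dir, "posterior_samples.csv")
        write_samples(results.posterior, paths["samples"])

    paths.update(_write_heatmaps(results.density, out_dir))
    return paths


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def _write_heatmaps(density: PositionalDensity, out_dir: str) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = density.display_order
    labels = [density.events[i] for i in order]
    paths = {}
    for name, mat, title in (
        ("density_heatmap", density.matrix[order], "Positional density"),
        ("cumulative_heatmap", cumulative_density(density)[order], "Cumulative abnormality"),
    ):
        fig, ax = plt.subplots(
            figsize=(6, max(3, 0.22 * density.n_events + 1.2))
        )
        im = ax.imshow(mat, aspect="auto", cmap="Reds", vmin=0, vmax=1)
        ax.set_yticks(range(len(labels)), labels=labels, fontsize=6)
        ax.set_xlabel("sequence position (1..N)")
        ax.set_xticks(range(density.n_events),
                      labels=[str(p + 1) for p in range(density.n_events)], fontsize=6)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="posterior proportion")
        fig.tight_layout()
        path = os.path.join(out_dir, f"{name}.png")
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths[name] = path
    return paths
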