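"""Metrics, snapshot and manifest serialization.

Metrics tables are CSV with a fixed 50-column schema: ``generation``,
``mean_payoff``, then ``count_0..count_15`` (agents per strategy),
``payoff_0..payoff_15`` (per-strategy mean payoff, empty where the
strategy is absent) and ``srac_0..srac_15`` (SRAC agents per strategy).
Floats are written with full precision so a read-back reproduces the run
exactly.  A JSON manifest (config + seed + package version) written beside
the outputs makes every run directory reproducible from the manifest
alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .simulation import (
    GenerationMetrics,
    GridSnapshot,
    N_STRATEGIES,
    SimulationConfig,
)

__all__ = [
    "metrics_to_dataframe",
    "write_metrics",
    "read_metrics",
    "write_snapshot",
    "read_snapshot",
    "write_manifest",
    "read_manifest",
    "METRICS_COLUMNS",
]

_S = range(N_STRATEGIES)
METRICS_COLUMNS = (
    ["generation", "mean_payoff"]
    + [f"count_{k}" for k in _S]
    + [f"payoff_{k}" for k in _S]
    + [f"srac_{k}" for k in _S]
)


def metrics_to_dataframe(metrics: Sequence[GenerationMetrics]) -> pd.DataFrame:
    if len(metrics) == 0:
        raise ValueError("cannot serialize an empty metrics list")
    rows = []
    for m in metrics:
        row = {"generation": m.generation, "mean_payoff": m.mean_payoff}
        row.update({f"count_{k}": int(m.strategy_counts[k]) for k in _S})
        row.update({f"payoff_{k}": m.per_strategy_mean_payoff[k] for k in _S})
        row.update({f"srac_{k}": int(m.srac_counts_by_strategy[k]) for k in _S})
        rows.append(row)
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics(metrics: Sequence[GenerationMetrics], path: str | Path) -> Path:
    """Write the per-generation metrics table as CSV (stable column order)."""
    path = Path(path)
    df = metrics_to_dataframe(metrics)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_metrics(path: str | Path) -> list[GenerationMetrics]:
    """Inverse of :func:`write_metrics`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != METRICS_COLUMNS:
        raise ValueError(f"unexpected metrics columns in {path}")
    out = []
    for _, row in df.iterrows():
        out.append(GenerationMetrics(
            generation=int(row["generation"]),
            strategy_counts=np.array([int(row[f"count_{k}"]) for k in _S]),
            mean_payoff=float(row["mean_payoff"]),
            per_strategy_mean_payoff=np.array(
                [float(row[f"payoff_{k}"]) for k in _S]
            ),
            srac_counts_by_strategy=np.array([int(row[f"srac_{k}"]) for k in _S]),
        ))
    return out


def write_snapshot(snapshot: GridSnapshot, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, snapshot.matrix, fmt="%d", delimiter=",")
    return path


def read_snapshot(path: str | Path, generation: int) -> GridSnapshot:
    matrix = np.loadtxt(path, dtype=np.int64, delimiter=",")
    return GridSnapshot(generation=generation, matrix=np.atleast_2d(matrix))


def render_snapshot(snapshot: GridSnapshot, path: str | Path) -> Path:
    """Optional PNG render of a strategy grid (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(snapshot.matrix, cmap="tab20", vmin=0, vmax=15,
                   interpolation="nearest")
    ax.set_title(f"generation {snapshot.generation}")
    fig.colorbar(im, ax=ax, label="strategy index")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def write_manifest(config: SimulationConfig, path: str | Path,
                   extra: dict | None = None) -> Path:
    path = Path(path)
    manifest = {
        "software": "sracipd",
        "version": __version__,
        "config": config.to_dict(),
    }
    if extra:
        manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_manifest(path: str | Path) -> SimulationConfig:
    manifest = json.loads(Path(path).read_text())
    return SimulationConfig.from_dict(manifest["config"])
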