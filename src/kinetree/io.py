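"""Reaction-table I/O and report writing."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RowValidationError, SchemaError
from .substrate import POSITIONS
from .training import Ensemble, ReactionDataset

REACTION_COLUMNS = ["ligand_id", "substituent", "position", "k_obs", "temperature_K"]


def read_reaction_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a reaction CSV.

    Required columns: ligand_id, substituent, position (meta|para),
    k_obs (> 0), temperature_K (> 0).  Errors cite the offending row
    (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in REACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"reaction table {path} is missing columns: {missing}")
    for i, row in enumerate(df.itertuples(), start=1):
        if row.position not in POSITIONS:
            raise RowValidationError(
                f"row {i}: position {row.position!r} not in {POSITIONS}", row=i
            )
        if not np.isfinite(row.k_obs) or row.k_obs <= 0:
            raise RowValidationError(
                f"row {i}: k_obs must be positive, got {row.k_obs}", row=i
            )
        if not np.isfinite(row.temperature_K) or row.temperature_K <= 0:
            raise RowValidationError(
                f"row {i}: temperature_K must be positive, got {row.temperature_K}",
                row=i,
            )
    return df[REACTION_COLUMNS + [c for c in df.columns if c not in REACTION_COLUMNS]]


def write_reaction_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def ligand_decomposition_summary(
    ensemble: Ensemble, dataset: ReactionDataset
) -> pd.DataFrame:
    """Distribution of fitted dG_L per ligand across ensemble members.

    One row per ligand with min/q1/median/q3/max of the member-wise mean
    dG_L, sorted by ascending median (the boxplot ordering).
    """
    member_dgl = pd.DataFrame(
        {
            i: p.groupby("ligand_id")["dG_L"].mean()
            for i, p in enumerate(ensemble.member_predictions(dataset))
        }
    )
    stats = member_dgl.quantile([0.0, 0.25, 0.5, 0.75, 1.0], axis=1).T
    stats.columns = ["min", "q1", "median", "q3", "max"]
    return stats.sort_values("median").reset_index()


def write_report(
    ensemble: Ensemble, dataset: ReactionDataset, out_dir: str | Path
) -> dict[str, Path]:
    """Write per-reaction ensemble predictions and the per-ligand summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pred = ensemble.predict(dataset)
    pred_path = out_dir / "predictions.csv"
    pred.to_csv(pred_path, index=False)
    summary_path = out_dir / "ligand_dG_L_summary.csv"
    ligand_decomposition_summary(ensemble, dataset).to_csv(summary_path, index=False)
    return {"predictions": pred_path, "ligand_summary": summary_path}
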