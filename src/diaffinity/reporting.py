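"""Packaged evaluation tables and their recomputed summary statistics.

Five benchmark tables ship with the package as CSV transcriptions of the
published evaluation of the DIA models:

* ``table1`` — 33 complexes with experimental dG and the cross-validated
  predictions of all six models.  (The accompanying text refers to 34
  complexes; only 33 rows are printed, so 33 are packaged.)
* ``table3`` — binding free energies of three non-active GPCR ligands
  (alprenolol, fenoterol, cetirizine) docked into the benchmark proteins,
  with per-row differences against each protein's original ligand; rows
  where the pocket could not accommodate the ligand are empty (N.D.).
* ``table4_thrombin`` / ``table4_hiv`` / ``table4_trypsin`` — same-target
  subsets with predictions of the ligand-entropy and weighted models.

Aggregates are always recomputed from the printed dG columns, not from the
printed per-row error columns, which occasionally differ in the last digit
from the column arithmetic (rounding of unpublished extra decimals).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .models import EvaluationReport, evaluation_report

__all__ = ["TABLE_IDS", "load_fixture", "evaluate_fixture", "difference_summary"]

TABLE_IDS = ("table1", "table3", "table4_thrombin", "table4_hiv", "table4_trypsin")


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one packaged benchmark table as a DataFrame."""
    if table_id not in TABLE_IDS:
        raise ValueError(f"unknown table {table_id!r}; expected one of {TABLE_IDS}")
    with resources.files("diaffinity.data").joinpath(f"{table_id}.csv").open() as fh:
        return pd.read_csv(fh)


def evaluate_fixture(table_id: str, model_column: str) -> EvaluationReport:
    """Recompute error/correlation statistics for one model column.

    Statistics (mean absolute error, SD of the differences, Pearson r,
    Spearman rho with average ranks) are computed from the dG columns at
    full precision; comparisons against the printed values belong to the
    caller, rounded to the table's printed decimals.
    """
    df = load_fixture(table_id)
    if model_column not in df.columns:
        raise ValueError(
            f"{table_id} has no column {model_column!r}; available: "
            f"{[c for c in df.columns if c not in ('complex_id', 'dg_exptl')]}"
        )
    sub = df[["complex_id", "dg_exptl", model_column]].dropna()
    return evaluation_report(
        sub[model_column].to_numpy(), sub["dg_exptl"].to_numpy(), sub["complex_id"].tolist()
    )


def difference_summary(column: str, table_id: str = "table3") -> dict:
    """Mean difference and fraction-weaker for one non-active ligand column.

    The difference is (original-ligand dG) - (non-active dG): negative means
    the non-active compound binds more weakly than the original ligand.
    N.D. rows (empty cells) are excluded.  Returns ``mean_difference``,
    ``fraction_weaker`` (in [0, 1]), ``n`` and ``mean_dg``.
    """
    df = load_fixture(table_id)
    diff_col = f"{column}_diff"
    if diff_col not in df.columns:
        raise ValueError(f"{table_id} has no difference column for {column!r}")
    diffs = df[diff_col].dropna().to_numpy(dtype=float)
    if diffs.size == 0:
        raise ValueError(f"{column}: all rows are N.D.")
    dgs = df[column].dropna().to_numpy(dtype=float)
    return {
        "mean_difference": float(diffs.mean()),
        "fraction_weaker": float(np.mean(diffs < 0)),
        "n": int(diffs.size),
        "mean_dg": float(dgs.mean()),
    }
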