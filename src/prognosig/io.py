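"""Reading and writing the pipeline's tab-separated interchange files.

The on-disk conventions follow the usual public-repository tab dumps:

* expression: genes (or probes) in rows, samples in columns; the first
  column holds the gene/probe identifier and the header row holds sample
  identifiers.
* clinical: one sample per row; the first column is the sample identifier,
  the remaining columns are outcome and covariate fields.

Both readers are gzip-transparent (pandas infers compression from the
extension) and tolerant of Windows line endings and quoted fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DataError",
    "read_expression",
    "read_clinical",
    "write_expression",
    "write_clinical",
    "reconcile_samples",
]

#: clinical columns required by the survival stages
SURVIVAL_COLUMNS = ("dfs_event", "dfs_time", "os_event", "os_time")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_expression(path, *, allow_duplicate_ids: bool = False) -> pd.DataFrame:
    """Read a gene-by-sample expression TSV into a float DataFrame.

    Parameters
    ----------
    path:
        TSV file; first column gene/probe id, header row sample ids.
    allow_duplicate_ids:
        Permit duplicated row identifiers (needed for probe-level matrices
        that will be collapsed with a probe map). Duplicate *sample*
        columns are always rejected.
    """
    # pandas silently renames duplicated header fields; check the raw header
    header = pd.read_csv(path, sep="\t", header=None, nrows=1).iloc[0].astype(str)
    dup_cols = header.iloc[1:][header.iloc[1:].duplicated()].unique()
    if len(dup_cols):
        raise DataError(f"duplicated sample columns: {', '.join(dup_cols)}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not allow_duplicate_ids:
        dup_rows = df.index[df.index.duplicated()].unique()
        if len(dup_rows):
            raise DataError(
                "duplicated gene identifiers (pass a probe map to collapse "
                f"them): {', '.join(dup_rows[:5])}"
            )
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise DataError(
                    f"non-numeric expression value at gene {row!r}, sample {col!r}"
                ) from None
        raise
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read a per-sample clinical TSV indexed by sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise DataError(f"duplicated sample ids in clinical table: {', '.join(dup)}")
    return df


def write_expression(expr: pd.DataFrame, path, *, id_label: str = "gene_id") -> None:
    # %.17g guarantees binary round-trip of float64 values
    expr.to_csv(path, sep="\t", index_label=id_label, float_format="%.17g")


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class ReconcileReport:
    """Samples dropped while aligning expression and clinical tables."""

    expression_only: list = field(default_factory=list)
    clinical_only: list = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.expression_only) + len(self.clinical_only)


def reconcile_samples(
    expr: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, ReconcileReport]:
    """Restrict both tables to their common samples, reporting the drops."""
    common = [s for s in expr.columns if s in clinical.index]
    report = ReconcileReport(
        expression_only=[s for s in expr.columns if s not in clinical.index],
        clinical_only=[s for s in clinical.index if s not in set(expr.columns)],
    )
    if not common:
        raise DataError("expression and clinical tables share no samples")
    return expr[common], clinical.loc[common], report
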