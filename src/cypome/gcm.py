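"""The Genome-CYP Matrix (GCM): CYP-name × genome counts at family or subfamily level.

Rows are CYP names (C_i), columns are genomes; element counts are numbers of
classified protein sequences, recovered through cluster membership.  G_ci is
the number of genomes carrying C_i and G_t the number of genomes in the run.
Novel-group placeholder rows (NF…) sort after known families.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Level = Literal["family", "subfamily"]


def _row_sort_key(name: str) -> tuple[int, str]:
    return (1 if name.startswith("NF") else 0, name)


@dataclass
class GCM:
    """Genome-CYP count matrix with named rows (CYPs) and columns (genomes)."""

    level: Level
    table: pd.DataFrame  # rows: CYP names, cols: genome ids, int counts

    @property
    def cyp_names(self) -> list[str]:
        return list(self.table.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.table.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.table.to_numpy()

    @property
    def g_ci(self) -> pd.Series:
        """Number of genomes carrying each CYP."""
        return (self.table > 0).sum(axis=1)

    @property
    def g_t(self) -> int:
        """Number of genomes in the dataset."""
        return self.table.shape[1]

    @property
    def n_cyps(self) -> int:
        return self.table.shape[0]

    def total(self) -> int:
        return int(self.table.to_numpy().sum())


def build_gcm(
    per_sequence: pd.DataFrame,
    level: Level,
    genome_ids: Sequence[str] | None = None,
) -> GCM:
    """Count classified sequences per CYP name and genome.

    ``per_sequence`` is the propagated classification table (columns
    ``genome`` and ``family``/``subfamily``).  ``genome_ids`` fixes the column
    set so genomes without any CYP appear as all-zero columns; by default the
    columns are the genomes present in the table.  Rows/columns are sorted by
    name (novel NF rows last).  An empty table yields a 0-row GCM.
    """
    if level not in ("family", "subfamily"):
        raise ValueError(f"level must be family or subfamily, got {level!r}")
    if genome_ids is None:
        genome_ids = sorted(per_sequence["genome"].unique()) if len(per_sequence) else []
    genome_ids = list(genome_ids)
    if len(per_sequence) == 0:
        table = pd.DataFrame(np.zeros((0, len(genome_ids)), dtype=int), columns=genome_ids)
        return GCM(level=level, table=table)
    counts = (
        per_sequence.groupby([level, "genome"], sort=False).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=genome_ids, fill_value=0)
    counts = counts.loc[sorted(counts.index, key=_row_sort_key)]
    counts.index.name = None
    counts.columns.name = None
    return GCM(level=level, table=counts.astype(int))


def export_numeric_csv(gcm: GCM, path: str | Path) -> None:
    """Write the GCM as CSV: first column CYP name, then one column per genome."""
    out = gcm.table.copy()
    out.insert(0, "CYP", out.index)
    out.to_csv(path, index=False)


def read_numeric_csv(path: str | Path, level: Level = "family") -> GCM:
    """Round-trip reader for :func:`export_numeric_csv` output."""
    df = pd.read_csv(path)
    df = df.set_index("CYP")
    df.index.name = None
    return GCM(level=level, table=df.astype(int))
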