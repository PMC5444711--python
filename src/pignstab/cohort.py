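"""Expression-cohort container and gene-panel definitions.

The central in-memory object is :class:`ExpressionCohort`: a log2-scale
gene-by-sample expression matrix (a :class:`pandas.DataFrame` with gene
symbols as the index) together with a per-sample disease-subtype label.
Subtypes follow the MDS risk ladder used throughout the package:
``Control`` and the lower-risk subtypes ``RA``/``RARS`` versus the
higher-risk ``RAEB1``/``RAEB2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBTYPES: tuple[str, ...] = ("Control", "RA", "RARS", "RAEB1", "RAEB2")

#: Binary risk stratification: normal controls and low-risk subtypes versus
#: the high-risk excess-blast subtypes.
RISK_OF_SUBTYPE: dict[str, str] = {
    "Control": "low",
    "RA": "low",
    "RARS": "low",
    "RAEB1": "high",
    "RAEB2": "high",
}


@dataclass(frozen=True)
class GenePanel:
    """A named, ordered list of gene symbols (e.g. the CIN70 signature)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        seen = set()
        for g in self.genes:
            if g in seen:
                raise ValueError(f"panel {self.name!r} lists {g!r} twice")
            seen.add(g)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GenePanel":
        """Load a panel from a one-symbol-per-line text file ('#' comments)."""
        path = Path(path)
        genes = [
            line.strip()
            for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(name or path.stem, tuple(genes))


def _packaged_panel(filename: str, name: str) -> GenePanel:
    ref = resources.files("pignstab.data") / filename
    genes = [
        line.strip()
        for line in ref.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GenePanel(name, tuple(genes))


def cin70_panel() -> GenePanel:
    """The packaged 70-gene chromosomal-instability signature."""
    return _packaged_panel("cin70_panel.txt", "CIN70")


def gpi_panel() -> GenePanel:
    """The packaged GPI-anchor biosynthesis panel (PIG family + GPAA1 + PGAP)."""
    return _packaged_panel("gpi_panel.txt", "GPI")


@dataclass
class ExpressionCohort:
    """Gene-by-sample log2 expression matrix with subtype labels.

    Parameters
    ----------
    matrix
        DataFrame, rows = gene symbols (unique), columns = sample ids.
    labels
        Series indexed by sample id with subtype values.
    """

    matrix: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dups)[:5]}")
        self.labels = self.labels.reindex(self.matrix.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])[:5]
            raise ValueError(f"samples without a subtype label: {missing}")
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        unknown = set(self.labels) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtype labels: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    def risk(self) -> pd.Series:
        """Per-sample binary risk stratum, a pure function of subtype."""
        return self.labels.map(RISK_OF_SUBTYPE).rename("risk")

    def classes(self, scheme: str = "low-high") -> pd.Series:
        """Class labels for classification: ``low-high`` (binary) or ``subtype``."""
        if scheme == "low-high":
            return self.risk()
        if scheme == "subtype":
            return self.labels
        raise ValueError(f"unknown class scheme {scheme!r}")

    # ---- I/O ------------------------------------------------------------

    def to_files(self, matrix_tsv: str | Path, labels_csv: str | Path) -> None:
        """Write the matrix as genes x samples TSV and the labels as CSV."""
        self.matrix.to_csv(matrix_tsv, sep="\t", index_label="gene")
        self.labels.rename("subtype").to_csv(labels_csv, index_label="sample")

    @classmethod
    def from_files(
        cls, matrix_tsv: str | Path, labels_csv: str | Path
    ) -> "ExpressionCohort":
        matrix = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
        labels = pd.read_csv(labels_csv, index_col=0).iloc[:, 0]
        return cls(matrix, labels)

    def subset_genes(self, genes: Sequence[str]) -> pd.DataFrame:
        """Submatrix for the given genes, silently keeping only those present."""
        present = [g for g in genes if g in self.matrix.index]
        return self.matrix.loc[present]


def overlapping_genes(panels: Iterable[GenePanel]) -> list[str]:
    """Gene symbols shared between any two of the given panels."""
    seen: dict[str, str] = {}
    shared: list[str] = []
    for panel in panels:
        for g in panel.genes:
            if g in seen and seen[g] != panel.name:
                shared.append(g)
            seen.setdefault(g, panel.name)
    return shared
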