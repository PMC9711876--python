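"""Expression-matrix and gene-panel containers and I/O.

The scoring machinery is rank based and unit agnostic: any abundance unit
that is a strictly monotone transform of TPM (counts-per-million, log-TPM,
...) yields identical scores. The container therefore only enforces
non-negativity and completeness, not a particular normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PANEL_RESOURCE = "default_panel.txt"


@dataclass(frozen=True)
class GenePanel:
    """An ordered signature gene list (default: 10 canonical AR target genes).

    The shipped default panel is a stand-in built from widely used canonical
    AR target genes; any panel of >= 2 distinct symbols is accepted.
    """

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a gene panel needs at least 2 genes")
        normalized = [g.strip().upper() for g in self.genes]
        if len(set(normalized)) != len(normalized):
            raise ValueError("panel genes must be distinct (case-insensitive)")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance matrix.

    ``data`` has gene symbols as index and sample labels as columns. Values
    must be non-negative and complete; gene symbols must be unique after
    case-normalisation.
    """

    data: pd.DataFrame
    _upper_index: pd.Index = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise ValueError("expression matrix has no genes")
        self.data.index = self.data.index.astype(str).str.strip()
        self.data.columns = self.data.columns.astype(str)
        upper = self.data.index.str.upper()
        if upper.has_duplicates:
            dups = upper[upper.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after case-normalisation: {dups}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.data.values < 0).any():
            raise ValueError("expression values must be non-negative")
        self._upper_index = upper

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_values(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return self.data[sample_id]

    def resolve_genes(self, symbols) -> tuple[list[str], list[str]]:
        """Match symbols against matrix genes, case-insensitively.

        Returns (matched matrix gene ids, unmatched query symbols); matched
        ids are in query order and use the matrix's own spelling.
        """
        if not hasattr(self, "_lookup"):
            object.__setattr__(self, "_lookup", dict(zip(self._upper_index, self.data.index)))
        lookup = self._lookup
        matched, unmatched = [], []
        for sym in symbols:
            key = sym.strip().upper()
            if key in lookup:
                matched.append(lookup[key])
            else:
                unmatched.append(sym)
        return matched, unmatched


def read_expression_matrix(
    path: str | Path, *, sep: str | None = None, missing: str = "error"
) -> ExpressionMatrix:
    """Read a delimited gene-by-sample table (first column = gene symbol).

    ``missing`` is ``"error"`` (default) or ``"zero"`` (impute, logged).
    The delimiter is sniffed from the extension unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    n_missing = int(frame.isna().sum().sum())
    if n_missing:
        if missing == "zero":
            logger.warning("imputing %d missing expression entries as zero", n_missing)
            frame = frame.fillna(0.0)
        else:
            raise ValueError(f"{path}: {n_missing} missing entries (missing='error')")
    return ExpressionMatrix(frame.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, *, sep: str = "\t") -> None:
    matrix.data.to_csv(path, sep=sep, index_label="gene")


def read_gene_panel(path: str | Path) -> GenePanel:
    """Read a panel file: one symbol per line, ``#`` starts a comment."""
    genes = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    if not genes:
        raise ValueError(f"{path}: no genes found")
    return GenePanel(tuple(genes))


def default_panel() -> GenePanel:
    """The shipped stand-in panel of 10 canonical AR target genes."""
    text = resources.files("arascore.data").joinpath(DEFAULT_PANEL_RESOURCE).read_text()
    genes = [ln.split("#", 1)[0].strip() for ln in text.splitlines()]
    return GenePanel(tuple(g for g in genes if g))
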