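"""In-memory containers shared across pipeline stages.

Expression data travel as a features x samples matrix plus a per-feature
gene-symbol annotation; phenotypes, association results, differential
expression and integration records are plain :class:`pandas.DataFrame`
objects with documented column names (see each producing function).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Phenotype table column names recognised throughout the package.
PHENOTYPE_COLUMNS = (
    "diagnosis",
    "reexperiencing",
    "avoidance",
    "hyperarousal",
    "trait_anxiety",
    "state_anxiety",
    "depression",
    "age",
)


@dataclass
class ExpressionMatrix:
    """Features x samples expression matrix with feature annotations.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (probe id for human arrays, gene id
        for mouse RNA-seq) with one column per sample.
    symbols
        Gene symbol per feature, indexed like ``values``. Human arrays use
        upper-case symbols (``PDE4B``), mouse uses mixed case (``Pde4b``);
        cross-species matching is case-insensitive downstream.
    groups
        Optional sample -> group label mapping (e.g. ``NR`` /
        ``React-30`` for the mouse retrieval contrast).
    """

    values: pd.DataFrame
    symbols: pd.Series
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated feature ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicated sample ids: {list(dups[:5])}")
        self.symbols = self.symbols.reindex(self.values.index)
        if self.groups is not None:
            missing = self.values.columns.difference(self.groups.index)
            if len(missing):
                raise ValueError(f"samples without group label: {list(missing[:5])}")
            self.groups = self.groups.reindex(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def equals(self, other: "ExpressionMatrix") -> bool:
        same = self.values.equals(other.values) and self.symbols.equals(other.symbols)
        if self.groups is None or other.groups is None:
            return same and self.groups is None and other.groups is None
        return same and self.groups.equals(other.groups)
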