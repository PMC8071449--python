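"""Gene x sample count matrix container.

The same container holds bulk RNA-seq counts (samples = replicates of cell
clones) and single-cell counts (samples = cells).  Counts are non-negative
integers; gene and sample identifiers must be unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate {what}: {dups[:10]}")


@dataclass
class CountMatrix:
    """Non-negative integer count matrix with genes in rows.

    Parameters
    ----------
    counts:
        DataFrame indexed by gene symbol with one column per sample (or cell).
    condition:
        Optional mapping sample -> group label (e.g. clone name).  Required by
        the differential-expression stage; single-cell matrices instead carry
        a separate cell-annotation table.
    """

    counts: pd.DataFrame
    condition: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        _check_unique(self.counts.index, "gene symbols")
        _check_unique(self.counts.columns, "sample ids")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(values != np.floor(values))
                loc = [
                    (self.counts.index[i], self.counts.columns[j])
                    for i, j in bad[:5]
                ]
                raise ValueError(f"non-integer count entries at {loc}")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if self.condition is not None:
            self.condition = pd.Series(self.condition)
            missing = self.counts.columns.difference(self.condition.index)
            if len(missing):
                raise ValueError(f"samples without a condition: {list(missing)}")
            self.condition = self.condition.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def samples_in_group(self, group: str) -> list[str]:
        if self.condition is None:
            raise ValueError("count matrix has no condition table")
        return list(self.condition.index[self.condition == group])

    def restrict_genes(self, genes) -> "CountMatrix":
        """Subset to a gene universe (e.g. a coding-gene list); order kept."""
        keep = self.counts.index.intersection(pd.Index(genes), sort=False)
        return CountMatrix(self.counts.loc[keep], self.condition)
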