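"""Rank-percentile gene scoring and ADRN/MES signature scores.

Within each sample, every gene receives a score equal to its rank percentile
among all genes of the matrix (ascending, average ranks for ties, divided by
the number of genes, so the top gene scores 1.0).  A signature score is the
mean gene score over the signature's genes present in the matrix.  Because
the score depends only on within-sample ranks it is invariant to any
positive rescaling of a sample — normalization cannot change it — and lies
in (0, 1].

Adrenergic (ADRN) and mesenchymal (MES) neuroblastoma cell states are scored
with a published signature pair; a small built-in demo pair of canonical
marker genes ships with the package for tests and examples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import read_signature_list

__all__ = [
    "SignaturePair",
    "demo_signature_pair",
    "gene_rank_percentiles",
    "signature_score",
    "score_clones",
]


@dataclass
class SignaturePair:
    """Disjoint ADRN and MES signature gene lists."""

    adrn_genes: list[str]
    mes_genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.adrn_genes = list(dict.fromkeys(self.adrn_genes))
        self.mes_genes = list(dict.fromkeys(self.mes_genes))
        if not self.adrn_genes or not self.mes_genes:
            raise ValueError("signature lists must be non-empty")
        overlap = set(self.adrn_genes) & set(self.mes_genes)
        if overlap:
            raise ValueError(
                f"ADRN and MES signatures must be disjoint; shared: {sorted(overlap)[:10]}"
            )

    @classmethod
    def from_files(cls, adrn_path, mes_path, provenance: str = "") -> "SignaturePair":
        return cls(
            read_signature_list(adrn_path), read_signature_list(mes_path), provenance
        )


def demo_signature_pair() -> SignaturePair:
    """Built-in demo pair of canonical ADRN / MES marker genes."""
    data = resources.files("nbstates") / "data"

    def parse(text: str) -> list[str]:
        symbols = (line.split("#", 1)[0].strip() for line in text.splitlines())
        return [s for s in dict.fromkeys(symbols) if s]

    return SignaturePair(
        adrn_genes=parse((data / "adrn_demo.txt").read_text()),
        mes_genes=parse((data / "mes_demo.txt").read_text()),
        provenance="built-in demo marker genes",
    )


def gene_rank_percentiles(expr_column) -> pd.Series:
    """Per-gene rank percentile in (0, 1] within one sample.

    Average ranks for ties; percentile = rank / N over the gene universe of
    the matrix.  An all-identical column yields (N+1)/(2N) for every gene,
    with a warning.
    """
    col = pd.Series(expr_column)
    values = col.to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 genes to rank")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    if np.all(values == values[0]):
        warnings.warn("all expression values identical; percentiles are all (N+1)/2N")
    return pd.Series(rankdata(values) / len(values), index=col.index)


def signature_score(
    matrix: pd.DataFrame, signature, min_fraction: float = 0.5
) -> tuple[pd.Series, int]:
    """Mean rank-percentile score of a signature, per sample.

    Returns (scores indexed by sample, number of signature genes used).
    Errors if fewer than ``min_fraction`` of the signature's genes are
    present in the matrix.
    """
    signature = list(dict.fromkeys(signature))
    present = [g for g in signature if g in matrix.index]
    if len(present) < min_fraction * len(signature):
        raise ValueError(
            f"only {len(present)}/{len(signature)} signature genes present "
            f"({1 - len(present) / len(signature):.0%} missing; require >= "
            f"{min_fraction:.0%} present)"
        )
    percentiles = matrix.apply(gene_rank_percentiles, axis=0)
    return percentiles.loc[present].mean(axis=0), len(present)


def score_clones(
    matrix: pd.DataFrame,
    pair: SignaturePair,
    condition: pd.Series | None = None,
    min_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ADRN and MES scores per sample plus per-clone medians.

    Returns (per-sample table with columns clone, mes_score, adrn_score,
    n_mes_used, n_adrn_used; per-clone median table).
    """
    mes, n_mes = signature_score(matrix, pair.mes_genes, min_fraction)
    adrn, n_adrn = signature_score(matrix, pair.adrn_genes, min_fraction)
    table = pd.DataFrame(
        {
            "clone": condition.reindex(matrix.columns)
            if condition is not None
            else pd.Series(matrix.columns, index=matrix.columns),
            "mes_score": mes,
            "adrn_score": adrn,
            "n_mes_used": n_mes,
            "n_adrn_used": n_adrn,
        }
    )
    medians = table.groupby("clone")[["mes_score", "adrn_score"]].median()
    return table, medians
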