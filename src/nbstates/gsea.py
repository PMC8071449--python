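"""Pre-ranked gene-set enrichment analysis.

Genes are ranked by the differential-expression statistic — by its absolute
value by default, so that sets enriched among strongly regulated genes in
either direction score highly — and each gene set is tested with the classic
weighted Kolmogorov-Smirnov running-sum enrichment score.  Significance
comes from a gene-label permutation null: null enrichment scores are drawn
by placing a same-sized random set on the observed ranking.  The p-value
compares the observed ES with same-sign null scores,

    p = (1 + #{null |ES*| >= |ES|, same sign}) / (1 + #{same-sign null}),

and NES = ES / mean(|same-sign null ES|).  BH adjustment runs across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .de import benjamini_hochberg

__all__ = [
    "GeneSetCollection",
    "RankedList",
    "read_gmt",
    "write_gmt",
    "make_ranked_list",
    "enrichment_score",
    "gsea_preranked",
]


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member symbols)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, name TAB description TAB members..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                f"(name, description, members...), got {len(fields)}"
            )
        name, desc = fields[0].strip(), fields[1]
        members: list[str] = []
        seen = set()
        for sym in fields[2:]:
            sym = sym.strip()
            if sym and sym not in seen:
                members.append(sym)
                seen.add(sym)
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, desc] + list(members))
        for name, (desc, members) in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class RankedList:
    """Genes in descending score order with deterministic lexicographic
    tie-breaking."""

    genes: np.ndarray
    scores: np.ndarray
    transform: str = "absolute"

    def __len__(self) -> int:
        return len(self.genes)


def make_ranked_list(
    table: pd.DataFrame, transform: str = "absolute", stat_column: str = "stat"
) -> RankedList:
    """Rank genes by the DE statistic (``absolute`` or ``signed``).

    NaN statistics are dropped with a warning reporting how many.
    """
    if transform not in ("absolute", "signed"):
        raise ValueError(f"transform must be 'absolute' or 'signed', got {transform!r}")
    stat = table[stat_column]
    n_nan = int(stat.isna().sum())
    if n_nan:
        warnings.warn(f"dropping {n_nan} genes with NaN ranking statistic")
        stat = stat.dropna()
    key = stat.abs() if transform == "absolute" else stat
    order = pd.DataFrame(
        {"key": key.to_numpy(dtype=float), "gene": key.index.astype(str)}
    ).sort_values(["key", "gene"], ascending=[False, True], kind="mergesort")
    return RankedList(
        genes=order["gene"].to_numpy(),
        scores=order["key"].to_numpy(dtype=float),
        transform=transform,
    )


def _es_from_positions(
    pos: np.ndarray, weights: np.ndarray, n_total: int
) -> tuple[np.ndarray, np.ndarray]:
    """Enrichment scores from sorted hit positions.

    ``pos``: (n_instances, k) ascending 0-based hit positions;
    ``weights``: per-position hit weights |score|^p of the full ranking.
    Returns (ES, extremum_index_within_hits).  The running sum only changes
    at hit boundaries, so only values just before and just after each hit
    need inspection.
    """
    pos = np.atleast_2d(pos)
    k = pos.shape[1]
    n_miss = n_total - k
    w = weights[pos]
    w_sum = w.sum(axis=1, keepdims=True)
    # all-zero weights (e.g. p=1 with all-zero scores): fall back to equal
    # weights, the unweighted KS statistic
    flat = (w_sum == 0).ravel()
    if flat.any():
        w[flat] = 1.0
        w_sum = w.sum(axis=1, keepdims=True)
    cum_hit = np.cumsum(w, axis=1) / w_sum
    miss_before = (pos - np.arange(k)) / n_miss if n_miss > 0 else np.zeros_like(
        pos, dtype=float
    )
    after = cum_hit - miss_before  # running sum just after hit i
    before = after - w / w_sum  # running sum just before hit i
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    es = np.where(hi >= -lo, hi, lo)
    idx = np.where(hi >= -lo, after.argmax(axis=1), before.argmin(axis=1))
    return es, idx


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running profile, and leading edge for one gene set.

    The running sum increments by |score|^p / sum_hits |score|^p at hit
    positions and decrements by 1/(N - N_hits) elsewhere; ES is the signed
    maximum deviation from zero.  The leading edge contains the hits at or
    before the positive extremum (at or after it, for negative ES).
    """
    members = set(gene_set)
    hit = np.isin(ranked.genes, list(members))
    k = int(hit.sum())
    n = len(ranked)
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    if k == n:
        raise ValueError("gene set covers the entire ranked universe; ES undefined")
    weights = np.abs(ranked.scores) ** weight_p
    pos = np.flatnonzero(hit)
    es_arr, idx_arr = _es_from_positions(pos[None, :], weights, n)
    es, idx = float(es_arr[0]), int(idx_arr[0])

    w = weights[pos]
    if w.sum() == 0:
        w = np.ones_like(w)
    steps = np.full(n, -1.0 / (n - k))
    steps[pos] = w / w.sum()
    profile = np.cumsum(steps)
    if es >= 0:
        leading = [str(g) for g in ranked.genes[pos[: idx + 1]]]
    else:
        leading = [str(g) for g in ranked.genes[pos[idx:]]]
    return es, profile, leading


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> tuple[pd.DataFrame, list[str]]:
    """Permutation GSEA over a collection.

    Returns (result table indexed by set name with columns size, ES, NES,
    pvalue, padj, leading_edge; list of skipped sets).  Null scores are
    shared across sets of equal size, drawn once per size from the seeded
    generator, so results are deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    universe = set(ranked.genes.tolist())
    weights = np.abs(ranked.scores) ** weight_p

    tested: list[tuple[str, list[str], int]] = []
    skipped: list[str] = []
    for name, (_, members) in collection.sets.items():
        overlap = [g for g in members if g in universe]
        if not overlap or not (min_size <= len(overlap) <= max_size):
            skipped.append(name)
            continue
        tested.append((name, overlap, len(overlap)))

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({k for _, _, k in tested}):
        picks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :size]
        picks.sort(axis=1)
        null_by_size[size], _ = _es_from_positions(picks, weights, n)

    rows = []
    for name, overlap, size in tested:
        es, _, leading = enrichment_score(ranked, overlap, weight_p)
        null = null_by_size[size]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_sign = int(same_sign.sum())
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        pvalue = (1 + n_extreme) / (1 + n_sign)
        denom = np.abs(null[same_sign]).mean() if n_sign else np.nan
        nes = es / denom if n_sign and denom > 0 else np.nan
        rows.append((name, size, es, nes, pvalue, ",".join(leading)))

    result = pd.DataFrame(
        rows, columns=["set", "size", "ES", "NES", "pvalue", "leading_edge"]
    ).set_index("set")
    if len(result):
        result["padj"] = benjamini_hochberg(result["pvalue"].to_numpy())
    else:
        result["padj"] = pd.Series(dtype=float)
    return result[["size", "ES", "NES", "pvalue", "padj", "leading_edge"]], skipped
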