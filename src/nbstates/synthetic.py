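"""Synthetic bulk and single-cell count data with planted structure.

Emulates the study design the pipeline was built for: one parental
neuroblastoma line, five knockout (KO) clones and one overexpressing clone
with two biological replicates each, and a four-population developmental
single-cell reference (Schwann cell precursors, bridge cells, chromaffin
cells, sympathoblasts) in which the knocked-out receptor gene is depleted in
SCP-like cells while partner genes (AXL-like, YAP1-like) are enriched there.

Bulk counts are negative binomial with variance mu + alpha*mu^2, one shared
dispersion alpha per scenario, gene-wise baseline log2 means drawn uniformly
over a configurable range, and planted per-group log2 fold changes.
Single-cell counts use the same NB family; mutual-exclusivity gene pairs are
zero-inflated via explicit Bernoulli on/off states per cell type, so the
fraction of cells with a nonzero count equals the configured on-probability
exactly in expectation.

All randomness derives from one scenario seed through named sub-streams, so
bulk and single-cell matrices can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix

__all__ = [
    "PlantedProgram",
    "SyntheticScenario",
    "Population",
    "ExclusivityPair",
    "SyntheticSingleCellScenario",
    "simulate_bulk_counts",
    "simulate_single_cell_reference",
    "default_bulk_scenario",
    "default_single_cell_scenario",
    "KO_CLONES",
    "OVEREXPRESSING_CLONE",
    "PARENTAL",
    "CELL_TYPES",
]

PARENTAL = "parental"
KO_CLONES = ("C2", "C5", "C9", "C17", "C19")
OVEREXPRESSING_CLONE = "C1"
CELL_TYPES = ("SCP", "bridge", "chromaffin", "sympathoblast")


@dataclass
class PlantedProgram:
    """A set of genes with a planted log2 fold change per non-reference group.

    ``knockout=True`` forces the gene means to zero in every group listed in
    ``log2fc_by_group`` (the truth table records -inf for those entries).
    """

    name: str
    gene_ids: list[int]
    log2fc_by_group: dict[str, float]
    knockout: bool = False

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"program {self.name!r}: duplicate gene ids")


@dataclass
class SyntheticScenario:
    """Generative parameters for a bulk clone-panel count matrix."""

    n_genes: int = 2000
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [(PARENTAL, 2)]
        + [(c, 2) for c in (OVEREXPRESSING_CLONE,) + KO_CLONES]
    )
    reference_group: str = PARENTAL
    baseline_log2_mean_range: tuple[float, float] = (3.0, 11.0)
    dispersion: float = 0.05
    planted_programs: list[PlantedProgram] = field(default_factory=list)
    library_size_factors: list[float] | None = None
    gene_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ValueError("baseline_log2_mean_range must be (low, high)")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        if self.reference_group not in labels:
            raise ValueError(f"reference group {self.reference_group!r} not in groups")
        n_samples = sum(n for _, n in self.groups)
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, dtype=float)
            if len(sf) != n_samples:
                raise ValueError(
                    f"{len(sf)} library size factors for {n_samples} samples"
                )
            if (sf <= 0).any():
                raise ValueError("library size factors must be positive")
        for prog in self.planted_programs:
            ids = np.asarray(prog.gene_ids)
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_genes):
                raise ValueError(
                    f"program {prog.name!r}: gene ids outside [0, {self.n_genes})"
                )
            unknown = set(prog.log2fc_by_group) - set(labels)
            if unknown:
                raise ValueError(
                    f"program {prog.name!r}: unknown groups {sorted(unknown)}"
                )
            if self.reference_group in prog.log2fc_by_group:
                raise ValueError(
                    f"program {prog.name!r}: reference group carries implicit "
                    "log2fc 0 and cannot be assigned"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_r{i + 1}" for g, n in self.groups for i in range(n)]

    @property
    def sample_groups(self) -> pd.Series:
        return pd.Series(
            [g for g, n in self.groups for _ in range(n)],
            index=self.sample_ids,
            name="group",
        )


def _default_gene_names(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def _baseline_log2_means(
    seed: int, n_genes: int, log2_range: tuple[float, float]
) -> np.ndarray:
    """Per-gene baseline log2 means from the shared gene-universe stream.

    Bulk and single-cell scenarios built on the same seed draw the same
    per-gene quantiles (mapped onto their own ranges), emulating the
    conservation of relative expression levels between a bulk clone panel
    and a single-cell reference that Pearson correlation mapping relies on.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    lo, hi = log2_range
    return lo + (hi - lo) * rng.random(n_genes)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, var = mean + alpha*mean^2); zero mean gives zero counts."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        r = 1.0 / alpha
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def _planted_delta(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    """(delta, ko) arrays of shape (n_genes, n_groups); errors on conflicts."""
    labels = [g for g, _ in scenario.groups]
    col = {g: i for i, g in enumerate(labels)}
    delta = np.zeros((scenario.n_genes, len(labels)))
    ko = np.zeros_like(delta, dtype=bool)
    assigned: dict[tuple[int, int], tuple[str, float]] = {}
    for prog in scenario.planted_programs:
        for group, lfc in prog.log2fc_by_group.items():
            j = col[group]
            value = -np.inf if prog.knockout else float(lfc)
            for g in prog.gene_ids:
                prev = assigned.get((g, j))
                if prev is not None and prev[1] != value:
                    raise ValueError(
                        f"conflicting planted log2fc for gene {g} in group "
                        f"{group!r}: {prev[1]} (program {prev[0]!r}) vs "
                        f"{value} (program {prog.name!r})"
                    )
                assigned[(g, j)] = (prog.name, value)
                if prog.knockout:
                    ko[g, j] = True
                else:
                    delta[g, j] = value
    return delta, ko


def simulate_bulk_counts(
    scenario: SyntheticScenario,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a bulk count matrix and its truth table of planted fold changes.

    Returns (CountMatrix with condition table, truth table with columns
    gene, group, log2fc listing every planted nonzero effect; knockouts
    appear as -inf).
    """
    delta, ko = _planted_delta(scenario)
    rng_counts = np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(0,))
    )
    baseline = _baseline_log2_means(
        scenario.seed, scenario.n_genes, scenario.baseline_log2_mean_range
    )
    labels = [g for g, _ in scenario.groups]
    sf = (
        np.ones(len(scenario.sample_ids))
        if scenario.library_size_factors is None
        else np.asarray(scenario.library_size_factors, dtype=float)
    )
    names = scenario.gene_names or _default_gene_names(scenario.n_genes)
    if len(names) != scenario.n_genes:
        raise ValueError("gene_names length must equal n_genes")

    cols = {}
    j = 0
    for gi, (group, n_rep) in enumerate(scenario.groups):
        mu = 2.0 ** (baseline + delta[:, gi])
        mu[ko[:, gi]] = 0.0
        for _ in range(n_rep):
            cols[scenario.sample_ids[j]] = _nb_draw(
                rng_counts, sf[j] * mu, scenario.dispersion
            )
            j += 1
    counts = pd.DataFrame(cols, index=names)

    records = []
    for gi, group in enumerate(labels):
        planted = np.flatnonzero(ko[:, gi] | (delta[:, gi] != 0))
        for g in planted:
            records.append(
                (names[g], group, -np.inf if ko[g, gi] else delta[g, gi])
            )
    truth = pd.DataFrame(records, columns=["gene", "group", "log2fc"])
    return CountMatrix(counts, scenario.sample_groups), truth


# ---------------------------------------------------------------------------
# Single-cell reference
# ---------------------------------------------------------------------------


@dataclass
class Population:
    cell_type: str
    n_cells: int
    dev_order: int
    marker_gene_ids: list[int] = field(default_factory=list)
    marker_log2fc: float = 5.0


@dataclass
class ExclusivityPair:
    """Bernoulli on/off model for a mutually exclusive gene pair.

    Probabilities map cell type -> P(gene on | type); counts for a cell in
    the "on" state are 1 + NB, so P(count > 0) equals the on-probability.
    """

    gene_a: int
    gene_b: int
    p_a_on: dict[str, float]
    p_b_on: dict[str, float]
    on_log2_mean: float = 5.0


@dataclass
class SyntheticSingleCellScenario:
    """Generative parameters for the labeled developmental reference."""

    n_genes: int = 2000
    populations: list[Population] = field(default_factory=list)
    exclusivity_pairs: list[ExclusivityPair] = field(default_factory=list)
    baseline_log2_mean_range: tuple[float, float] = (1.0, 6.0)
    # independent per-gene log2 offset of the reference baseline relative to
    # the shared gene-universe quantiles: bulk-vs-reference expression
    # conservation is real but imperfect
    baseline_jitter_sd: float = 1.5
    dispersion: float = 0.4
    dropout: dict[str, float] = field(default_factory=dict)
    gene_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if not self.populations:
            return
        for pop in self.populations:
            if pop.cell_type not in CELL_TYPES:
                raise ValueError(
                    f"unknown cell type {pop.cell_type!r}; expected one of "
                    f"{CELL_TYPES}"
                )
            if pop.n_cells < 20:
                raise ValueError(f"{pop.cell_type}: need >= 20 cells per population")
        order = {p.cell_type: p.dev_order for p in self.populations}
        chain = [t for t in ("SCP", "bridge", "chromaffin") if t in order]
        if [order[t] for t in chain] != sorted(
            order[t] for t in chain
        ) or len({order[t] for t in chain}) != len(chain):
            raise ValueError("dev_order must strictly increase SCP < bridge < chromaffin")
        for pair in self.exclusivity_pairs:
            for probs in (pair.p_a_on, pair.p_b_on):
                for t, p in probs.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"on-probability {p} for {t!r} outside [0,1]")
        for t, d in self.dropout.items():
            if not 0.0 <= d < 1.0:
                raise ValueError(f"dropout {d} for {t!r} outside [0,1)")


def simulate_single_cell_reference(
    scenario: SyntheticSingleCellScenario,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the labeled reference: (CountMatrix, cell annotation table).

    The annotation table has columns cell_type and dev_order indexed by
    cell id.
    """
    rng_counts = np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(1,))
    )
    baseline = _baseline_log2_means(
        scenario.seed, scenario.n_genes, scenario.baseline_log2_mean_range
    )
    if scenario.baseline_jitter_sd > 0:
        rng_jitter = np.random.default_rng(
            np.random.SeedSequence(scenario.seed, spawn_key=(8,))
        )
        baseline = baseline + rng_jitter.normal(
            0.0, scenario.baseline_jitter_sd, scenario.n_genes
        )
    names = scenario.gene_names or _default_gene_names(scenario.n_genes)
    if len(names) != scenario.n_genes:
        raise ValueError("gene_names length must equal n_genes")

    excl_genes = set()
    for pair in scenario.exclusivity_pairs:
        excl_genes.update((pair.gene_a, pair.gene_b))

    blocks = []
    annot = []
    for pop in scenario.populations:
        log2_mu = baseline.copy()
        log2_mu[pop.marker_gene_ids] += pop.marker_log2fc
        mu = 2.0**log2_mu
        counts = np.empty((scenario.n_genes, pop.n_cells), dtype=np.int64)
        for c in range(pop.n_cells):
            counts[:, c] = _nb_draw(rng_counts, mu, scenario.dispersion)
        drop = scenario.dropout.get(pop.cell_type, 0.0)
        if drop > 0:
            mask = rng_counts.random((scenario.n_genes, pop.n_cells)) < drop
            counts[mask] = 0
        for pair in scenario.exclusivity_pairs:
            for gene, probs in (
                (pair.gene_a, pair.p_a_on),
                (pair.gene_b, pair.p_b_on),
            ):
                p_on = probs.get(pop.cell_type, 0.0)
                on = rng_counts.random(pop.n_cells) < p_on
                mu_on = max(2.0**pair.on_log2_mean - 1.0, 0.0)
                vals = 1 + _nb_draw(
                    rng_counts,
                    np.full(pop.n_cells, mu_on),
                    scenario.dispersion,
                )
                counts[gene] = np.where(on, vals, 0)
        blocks.append(counts)
        annot.extend(
            (f"{pop.cell_type}_{c + 1}", pop.cell_type, pop.dev_order)
            for c in range(pop.n_cells)
        )

    annot_df = pd.DataFrame(
        annot, columns=["cell_id", "cell_type", "dev_order"]
    ).set_index("cell_id")
    counts_df = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=names, columns=annot_df.index
    )
    return CountMatrix(counts_df), annot_df


# ---------------------------------------------------------------------------
# Default study-design scenarios
# ---------------------------------------------------------------------------

# Gene-universe layout shared by the default bulk and single-cell scenarios.
# Index 0 is the knocked-out receptor; 1 and 2 its exclusivity partners.
_KO_GENE = 0
_AXL_LIKE = 1
_YAP1_LIKE = 2
_N_SIG = 60  # genes per ADRN / MES signature program
_N_MARKER = 300  # marker genes per cell population


def default_gene_names(n_genes: int = 2000) -> list[str]:
    names = _default_gene_names(n_genes)
    names[_KO_GENE] = "RET"
    names[_AXL_LIKE] = "AXL"
    names[_YAP1_LIKE] = "YAP1"
    for i in range(_N_SIG):
        names[3 + i] = f"MES{i + 1:03d}"
        names[3 + _N_SIG + i] = f"ADRN{i + 1:03d}"
    return names


def default_signature_gene_sets(n_genes: int = 2000) -> tuple[list[str], list[str]]:
    """(mes_genes, adrn_genes) planted in the default bulk scenario."""
    names = default_gene_names(n_genes)
    mes = [names[3 + i] for i in range(_N_SIG)]
    adrn = [names[3 + _N_SIG + i] for i in range(_N_SIG)]
    return mes, adrn


def _marker_ids(n_genes: int) -> dict[str, list[int]]:
    """Population marker sets; overlap with the SCP set decreases along the
    developmental chain (bridge shares half, sympathoblast a third,
    chromaffin none) so bulk KO clones built on the SCP program correlate
    SCP > bridge > sympathoblast > chromaffin.  Sympathoblast-only and
    chromaffin marker ids are also returned so the adrenergic clones can
    carry the committed end of the lineage."""
    base = 3 + 2 * _N_SIG
    scp = list(range(base, base + _N_MARKER))
    extra = base + _N_MARKER
    n_shared_bridge = 3 * _N_MARKER // 5
    bridge = scp[:n_shared_bridge] + list(
        range(extra, extra + _N_MARKER - n_shared_bridge)
    )
    extra += _N_MARKER - n_shared_bridge
    n_shared_symp = 3 * _N_MARKER // 10
    symp_own = list(range(extra, extra + _N_MARKER - n_shared_symp))
    symp = scp[:n_shared_symp] + symp_own
    extra += _N_MARKER - n_shared_symp
    chromaffin = list(range(extra, extra + _N_MARKER))
    if extra + _N_MARKER > n_genes:
        raise ValueError("n_genes too small for the default marker layout")
    return {
        "SCP": scp,
        "bridge": bridge,
        "sympathoblast": symp,
        "sympathoblast_own": symp_own,
        "chromaffin": chromaffin,
    }


def default_bulk_scenario(seed: int = 0, n_genes: int = 2000) -> SyntheticScenario:
    """The study-design emulator: parental + 5 KO clones + 1 overexpressor,
    two replicates each.

    KO clones lose the receptor gene entirely, shift the mesenchymal program
    up and the adrenergic program down, and gain the SCP marker program; the
    overexpressing clone C1 moves the signature programs in the opposite
    direction.
    """
    names = default_gene_names(n_genes)
    markers = _marker_ids(n_genes)
    ko_groups = {c: 0.0 for c in KO_CLONES}
    mes_ids = list(range(3, 3 + _N_SIG))
    adrn_ids = list(range(3 + _N_SIG, 3 + 2 * _N_SIG))
    programs = [
        PlantedProgram(
            "KO-gene", [_KO_GENE], dict(ko_groups), knockout=True
        ),
        PlantedProgram(
            "KO-gene-overexpressed", [_KO_GENE], {OVEREXPRESSING_CLONE: 2.0}
        ),
        PlantedProgram(
            "AXL-like-up",
            [_AXL_LIKE, _YAP1_LIKE],
            {**{c: 3.0 for c in KO_CLONES}, OVEREXPRESSING_CLONE: -3.0},
        ),
        PlantedProgram(
            "MES-up",
            mes_ids,
            {**{c: 3.0 for c in KO_CLONES}, OVEREXPRESSING_CLONE: -3.0},
        ),
        PlantedProgram(
            "ADRN-down",
            adrn_ids,
            {**{c: -3.0 for c in KO_CLONES}, OVEREXPRESSING_CLONE: 3.0},
        ),
        PlantedProgram(
            "SCP-program-up",
            markers["SCP"],
            {c: 4.0 for c in KO_CLONES},
        ),
        # KO clones lose the committed sympathoadrenal identity that the
        # adrenergic parental line carries; the overexpressor gains it.
        PlantedProgram(
            "committed-program-down",
            markers["chromaffin"],
            {**{c: -3.0 for c in KO_CLONES}, OVEREXPRESSING_CLONE: 3.0},
        ),
        PlantedProgram(
            "sympathoblast-program-up-in-overexpressor",
            markers["sympathoblast_own"],
            {OVEREXPRESSING_CLONE: 4.0},
        ),
    ]
    return SyntheticScenario(
        n_genes=n_genes,
        planted_programs=programs,
        gene_names=names,
        seed=seed,
    )


def default_single_cell_scenario(
    seed: int = 0, n_genes: int = 2000, n_cells_per_type: int = 100
) -> SyntheticSingleCellScenario:
    """Four-population E13.5-style reference with the published on-fractions:
    in SCPs the AXL-like gene is on in 85% of cells, YAP1-like in 79%, the
    receptor in only 17%; the other populations mirror-reverse the pattern.
    """
    markers = _marker_ids(n_genes)
    pops = [
        Population("SCP", n_cells_per_type, 0, markers["SCP"]),
        Population("bridge", n_cells_per_type, 1, markers["bridge"]),
        Population("chromaffin", n_cells_per_type, 2, markers["chromaffin"]),
        Population("sympathoblast", n_cells_per_type, 3, markers["sympathoblast"]),
    ]
    mirrored = {"bridge": 0.5, "chromaffin": 0.85, "sympathoblast": 0.85}
    pairs = [
        ExclusivityPair(
            _KO_GENE,
            _AXL_LIKE,
            p_a_on={"SCP": 0.17, **mirrored},
            p_b_on={"SCP": 0.85, "bridge": 0.5, "chromaffin": 0.17, "sympathoblast": 0.17},
        ),
        ExclusivityPair(
            _KO_GENE,
            _YAP1_LIKE,
            p_a_on={"SCP": 0.17, **mirrored},
            p_b_on={"SCP": 0.79, "bridge": 0.5, "chromaffin": 0.21, "sympathoblast": 0.21},
        ),
    ]
    return SyntheticSingleCellScenario(
        n_genes=n_genes,
        populations=pops,
        exclusivity_pairs=pairs,
        dropout={t: 0.2 for t in CELL_TYPES},
        gene_names=default_gene_names(n_genes),
        seed=seed,
    )
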