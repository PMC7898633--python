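"""DEG calling, the gene x experiment log2FC matrix, and set algebra.

The meta-analysis works on one central object: a matrix whose rows are the
union of all genes called differentially expressed (DE) in at least one
experiment, whose columns are experiments, and whose cells carry log2 fold
changes.  Two boolean masks travel with it: ``de_mask`` (the gene passed the
DE thresholds in that experiment) and ``measured_mask`` (the gene was on
that experiment's platform at all).  DE calling uses strict thresholds:
adjusted p < 0.05 and |log2FC| > 1 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import DEGTable, ExperimentRecord

__all__ = [
    "DEGMatrix",
    "VennPartition",
    "call_degs",
    "assemble_matrix",
    "recurrence",
    "venn_partition",
    "time_overlap_partition",
    "species_specific_degs",
]


@dataclass
class DEGMatrix:
    genes: list[str]
    experiments: list[str]
    lfc: np.ndarray            # genes x experiments, float
    de_mask: np.ndarray        # genes x experiments, bool
    measured_mask: np.ndarray  # genes x experiments, bool

    def __post_init__(self) -> None:
        g, e = len(self.genes), len(self.experiments)
        for name in ("lfc", "de_mask", "measured_mask"):
            if getattr(self, name).shape != (g, e):
                raise ValueError(f"{name} shape mismatch: expected {(g, e)}")
        if np.any(self.de_mask & ~self.measured_mask):
            raise ValueError("de_mask set for unmeasured cells")

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def experiment_index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.experiments)}

    def row(self, gene: str) -> np.ndarray:
        return self.lfc[self.gene_index[gene]]

    def equals(self, other: "DEGMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.experiments == other.experiments
            and np.array_equal(self.lfc, other.lfc)
            and np.array_equal(self.de_mask, other.de_mask)
            and np.array_equal(self.measured_mask, other.measured_mask)
        )


@dataclass
class VennPartition:
    """Disjoint-region decomposition of named gene sets.

    Region keys are frozensets of set names; a gene's region is the exact
    subset of input sets containing it.
    """

    set_names: list[str]
    region_counts: dict[frozenset, int] = field(default_factory=dict)
    region_members: dict[frozenset, set] = field(default_factory=dict)

    def region(self, *names: str) -> set:
        """Members belonging to exactly the given sets and no others."""
        return self.region_members.get(frozenset(names), set())

    def count(self, *names: str) -> int:
        return self.region_counts.get(frozenset(names), 0)


def call_degs(
    table: DEGTable,
    padj_max: float = 0.05,
    abs_lfc_min: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Split a table into up- and down-regulated DEG sets.

    Both thresholds are strict: padj < padj_max and log2FC > abs_lfc_min
    (or < -abs_lfc_min for down-regulation).  Genes with a missing adjusted
    p-value are never called.
    """
    if padj_max <= 0 or abs_lfc_min <= 0:
        raise ValueError("thresholds must be positive")
    up, down = set(), set()
    for rec in table:
        if rec.padj is None or not (rec.padj < padj_max):
            continue
        if rec.log2fc > abs_lfc_min:
            up.add(rec.gene_id)
        elif rec.log2fc < -abs_lfc_min:
            down.add(rec.gene_id)
    return up, down


def assemble_matrix(
    tables: Iterable[DEGTable],
    manifest: Sequence[ExperimentRecord],
    fill_policy: str = "zero",
    padj_max: float = 0.05,
    abs_lfc_min: float = 1.0,
    gene_universe: str | Sequence[str] = "degs",
) -> DEGMatrix:
    """Assemble the gene x experiment log2FC matrix.

    Rows default to the union of all DEG calls (``gene_universe="degs"``);
    ``"all"`` keeps every measured gene instead, which is what variance-based
    analyses on the full expression background need.  With
    ``fill_policy="zero"`` measured-but-not-DE cells are set to 0 (the
    convention of DEG-list heatmaps, where non-significant fold changes are
    usually unavailable); ``"reported"`` keeps the reported log2FC.
    Unmeasured cells are 0 with ``measured_mask`` False.
    """
    if fill_policy not in ("zero", "reported"):
        raise ValueError(f"unknown fill_policy {fill_policy!r}")
    tables = list(tables)
    manifest_ids = [r.experiment_id for r in manifest]
    known = set(manifest_ids)
    for t in tables:
        if t.experiment_id not in known:
            raise ValueError(
                f"table {t.experiment_id!r} has no manifest entry"
            )
    order = {e: i for i, e in enumerate(manifest_ids)}
    tables.sort(key=lambda t: order[t.experiment_id])
    experiments = [t.experiment_id for t in tables]

    calls = {t.experiment_id: call_degs(t, padj_max, abs_lfc_min)
             for t in tables}
    if gene_universe == "degs":
        genes_set: set[str] = set()
        for up, down in calls.values():
            genes_set |= up | down
    elif gene_universe == "all":
        genes_set = {g for t in tables for g in t.records}
    else:
        genes_set = set(gene_universe)
    genes = sorted(genes_set)
    gidx = {g: i for i, g in enumerate(genes)}

    G, E = len(genes), len(experiments)
    lfc = np.zeros((G, E))
    de = np.zeros((G, E), dtype=bool)
    measured = np.zeros((G, E), dtype=bool)
    for j, t in enumerate(tables):
        up, down = calls[t.experiment_id]
        de_genes = up | down
        for g, rec in t.records.items():
            i = gidx.get(g)
            if i is None:
                continue
            measured[i, j] = True
            if g in de_genes:
                de[i, j] = True
                lfc[i, j] = rec.log2fc
            elif fill_policy == "reported":
                lfc[i, j] = rec.log2fc
    return DEGMatrix(genes, experiments, lfc, de, measured)


def recurrence(matrix: DEGMatrix, min_experiments: int = 10) -> set[str]:
    """Genes differentially expressed in at least ``min_experiments``."""
    if not (1 <= min_experiments <= len(matrix.experiments)):
        raise ValueError(
            f"min_experiments must be in [1, {len(matrix.experiments)}]"
        )
    counts = matrix.de_mask.sum(axis=1)
    return {g for g, c in zip(matrix.genes, counts) if c >= min_experiments}


def venn_partition(named_sets: Mapping[str, Iterable]) -> VennPartition:
    """Exact disjoint-region decomposition of named sets.

    Regions (2^n - 1 signatures) are enumerated exhaustively up to n=8 so
    empty regions appear with count 0; beyond that only occupied regions are
    stored.  Counting works for any n; classic Venn rendering is meaningful
    for 2-4 sets.
    """
    from itertools import combinations

    names = list(named_sets)
    sets = {n: set(named_sets[n]) for n in names}
    part = VennPartition(set_names=names)
    if len(names) <= 8:
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                part.region_members[frozenset(combo)] = set()
    universe = set().union(*sets.values()) if sets else set()
    for element in universe:
        sig = frozenset(n for n in names if element in sets[n])
        part.region_members.setdefault(sig, set()).add(element)
    part.region_counts = {sig: len(m) for sig, m in part.region_members.items()}
    return part


def time_overlap_partition(
    deg_calls: Mapping[object, tuple[set, set]],
) -> tuple[VennPartition, VennPartition]:
    """Venn partitions of up- and down-regulated genes across time points."""
    if len(deg_calls) < 2:
        raise ValueError("need at least 2 time points")
    ups = {str(t): up for t, (up, _) in deg_calls.items()}
    downs = {str(t): down for t, (_, down) in deg_calls.items()}
    return venn_partition(ups), venn_partition(downs)


def species_specific_degs(
    matrix: DEGMatrix,
    manifest: Sequence[ExperimentRecord],
    target_species: str,
) -> tuple[set[str], set[str]]:
    """DEGs found only in experiments of the target herbivore species.

    A gene is target-specific up-regulated when it is up-called in at least
    one target-species experiment and not DE (in either direction) in any
    experiment of another species; symmetric for down.  A gene both up- and
    down-called within the target species is reported in both sets with a
    warning.
    """
    by_id = {r.experiment_id: r for r in manifest}
    species_of = {e: by_id[e].species for e in matrix.experiments
                  if e in by_id}
    if target_species not in {r.species for r in manifest}:
        raise ValueError(f"unknown species {target_species!r}")
    is_target = np.array(
        [species_of.get(e) == target_species for e in matrix.experiments]
    )
    de, lfc = matrix.de_mask, matrix.lfc
    other_de = de[:, ~is_target].any(axis=1)
    up_target = (de & (lfc > 0))[:, is_target].any(axis=1)
    down_target = (de & (lfc < 0))[:, is_target].any(axis=1)
    up = {g for g, u, o in zip(matrix.genes, up_target, other_de) if u and not o}
    down = {g for g, d, o in zip(matrix.genes, down_target, other_de)
            if d and not o}
    both = up & down
    if both:
        warnings.warn(
            f"{len(both)} gene(s) both up- and down-regulated within "
            f"{target_species!r}: {sorted(both)[:5]}..."
        )
    return up, down
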