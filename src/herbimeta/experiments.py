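"""Planted-truth recovery benchmarks.

Each function builds a synthetic scenario with known ground truth, runs the
corresponding pipeline stage, and measures how well the planted structure
is recovered.  They are used by the test suite and the reproduction script,
and double as worked examples of the stages' calibration under controlled
conditions.
"""

from __future__ import annotations

import numpy as np

from .degmat import assemble_matrix
from .io import ExperimentRecord
from .metastats import (
    bca_interval,
    cluster_experiments,
    cluster_specificity,
    pca_contributions,
    select_dimensions,
    top_contributing_genes,
)
from .simulate import GroundTruth, ModuleSpec, SyntheticSpec, \
    simulate_meta_experiments

__all__ = [
    "four_cluster_spec",
    "clustering_recovery",
    "contribution_recovery",
    "specificity_recovery",
    "bca_coverage",
]


def four_cluster_spec(
    seed: int,
    n_genes: int = 600,
    module_size: int = 30,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    n_per_cluster: int = 7,
    platform_missing_rate: float = 0.1,
    balanced: bool = False,
) -> SyntheticSpec:
    """Four planted experiment clusters, one up-regulated module each."""
    experiments = []
    cluster_of = {}
    for k in range(4):
        for i in range(n_per_cluster):
            eid = f"e_c{k + 1}_{i}"
            platform = "microarray" if i % 2 else "rnaseq"
            experiments.append(
                ExperimentRecord(eid, f"species_{k + 1}", f"taxon_{k + 1}",
                                 float(6 * (i + 1)), platform)
            )
            cluster_of[eid] = f"c{k + 1}"
    return SyntheticSpec(
        n_genes=n_genes,
        experiments=experiments,
        cluster_of=cluster_of,
        cluster_modules={
            f"c{k + 1}": ModuleSpec(module_size, effect, balanced=balanced)
            for k in range(4)
        },
        noise_sd=noise_sd,
        platform_missing_rate=platform_missing_rate,
        seed=seed,
    )


def clustering_recovery(
    n_seeds: int = 50,
    seed: int = 0,
    effect: float = 2.0,
    noise_sd: float = 0.5,
) -> dict:
    """Fraction of seeds on which Ward clustering recovers the planted
    4-cluster partition exactly (adjusted Rand index 1), 28 experiments,
    between-cluster effect = 4 x noise sd."""
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for s in range(n_seeds):
        spec = four_cluster_spec(seed + s, effect=effect, noise_sd=noise_sd)
        tables, manifest, truth = simulate_meta_experiments(spec)
        matrix = assemble_matrix(tables, manifest)
        assignment = cluster_experiments(matrix, k=4)
        planted = [truth.cluster_of[e] for e in matrix.experiments]
        found = [assignment.labels[e] for e in matrix.experiments]
        aris.append(adjusted_rand_score(planted, found))
    aris = np.asarray(aris)
    return {
        "fraction_exact": float(np.mean(aris == 1.0)),
        "mean_ari": float(aris.mean()),
        "n_seeds": n_seeds,
    }


def contribution_recovery(
    n_seeds: int = 10,
    seed: int = 0,
    n_genes: int = 2000,
    per_cluster: int = 15,
    effect: float = 3.0,
    noise_sd: float = 0.5,
    top_n: int = 100,
) -> dict:
    """Fraction of planted discriminative genes found in the top-N
    PCA-contribution list (60 planted among ``n_genes``)."""
    fractions = []
    for s in range(n_seeds):
        spec = four_cluster_spec(seed + s, n_genes=n_genes,
                                 module_size=per_cluster, effect=effect,
                                 noise_sd=noise_sd,
                                 platform_missing_rate=0.0)
        tables, manifest, truth = simulate_meta_experiments(spec)
        matrix = assemble_matrix(tables, manifest, fill_policy="reported",
                                 gene_universe="all")
        pca = pca_contributions(matrix)
        selection = select_dimensions(pca, var_threshold=0.70)
        top = top_contributing_genes(pca, selection.dims, n=top_n)
        planted = {g for g, m in truth.module_of.items() if m != "null"}
        hits = sum(1 for g, _ in top if g in planted)
        fractions.append(hits / len(planted))
    return {
        "mean_fraction": float(np.mean(fractions)),
        "min_fraction": float(np.min(fractions)),
        "n_planted": 4 * per_cluster,
        "n_seeds": n_seeds,
    }


def specificity_recovery(
    n_seeds: int = 10,
    seed: int = 0,
    n_genes: int = 200,
    per_cluster: int = 10,
    effect: float = 3.0,
    noise_sd: float = 0.5,
    cluster_size: int = 6,
    B: int = 2000,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity/specificity of the BCa cluster-specificity call.

    Positives are (gene, cluster) pairs where the gene's planted module is
    that cluster; everything else (planted genes in foreign clusters and
    null genes everywhere) counts as negative.  Planted effects are
    balanced up/down so the global mean stays near zero.
    """
    tp = fp = fn = tn = 0
    for s in range(n_seeds):
        spec = four_cluster_spec(seed + s, n_genes=n_genes,
                                 module_size=per_cluster, effect=effect,
                                 noise_sd=noise_sd,
                                 n_per_cluster=cluster_size,
                                 platform_missing_rate=0.0, balanced=True)
        tables, manifest, truth = simulate_meta_experiments(spec)
        matrix = assemble_matrix(tables, manifest, fill_policy="reported",
                                 gene_universe="all")
        clusters = cluster_experiments(matrix, k=4)
        # map found cluster labels onto planted ones via their members
        label_of = {}
        for lab in clusters.cluster_labels:
            members = clusters.members(lab)
            planted_labels = {truth.cluster_of[e] for e in members}
            label_of[lab] = (planted_labels.pop()
                             if len(planted_labels) == 1 else None)
        calls = cluster_specificity(matrix, list(matrix.genes), clusters,
                                    B=B, alpha=alpha, seed=seed + s)
        for c in calls:
            planted_cluster = label_of[c.cluster]
            is_positive = (planted_cluster is not None and
                           truth.module_of[c.gene_id]
                           == f"cluster:{planted_cluster}")
            if is_positive and c.flagged:
                tp += 1
            elif is_positive:
                fn += 1
            elif c.flagged:
                fp += 1
            else:
                tn += 1
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_positive": tp + fn,
        "n_negative": tn + fp,
        "n_seeds": n_seeds,
    }


def bca_coverage(
    n_sims: int = 1000,
    n: int = 20,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical coverage of the true mean (0) by nominal 95% BCa intervals
    on Normal(0, 1) samples."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sims)
    covered = 0
    for child in children:
        rng = np.random.default_rng(child)
        x = rng.normal(0.0, 1.0, size=n)
        iv = bca_interval(x, B=B, alpha=alpha, seed=rng)
        covered += iv.contains(0.0)
    return {"coverage": covered / n_sims, "n_sims": n_sims, "B": B, "n": n}
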