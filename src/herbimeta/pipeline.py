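"""End-to-end orchestration of the herbivory meta-analysis.

The pipeline runs, in order: DEG calling -> matrix assembly -> time-course
Venn for the target species -> recurrence filter + correlation subnetworks
-> experiment clustering -> PCA with dimension selection and top-N
contribution genes -> BCa cluster-specificity calls -> species-specific DEG
sets -> per-time-point minimum connected PPI networks with betweenness hub
tables -> recurrent-hub intersection -> integration set algebra -> seed
expansion rounds -> optional enrichment.  Every stage draws its randomness
from a sub-seed derived from the single root seed, so a run is bitwise
reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import degmat, io, metastats, networks
from .simulate import (
    SyntheticSpec,
    default_hub_plan,
    default_meta_spec,
    simulate_meta_experiments,
    simulate_ppi,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "IntegrationSets",
    "IntegrationSelection",
    "integration_seed_selection",
    "run_full_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        self.code = f"E_{stage.upper()}"
        super().__init__(f"[{self.code}] stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    seed: int
    # inputs: either file paths or a synthetic scenario (None -> default)
    manifest_path: str | None = None
    deg_table_paths: dict[str, str] = field(default_factory=dict)
    ppi_path: str | None = None
    synthetic: SyntheticSpec | None = None
    # stage parameters
    padj_max: float = 0.05
    abs_lfc_min: float = 1.0
    min_experiments: int = 10
    r_min: float = 0.95
    k: int = 4
    var_threshold: float = 0.70
    top_n: int = 100
    B: int = 10_000
    alpha: float = 0.05
    min_combined: int = 900
    require_experimental: bool = True
    rounds: int = 6
    per_round: int = 5
    fill_policy: str = "zero"
    target_species: str = "Tetranychus urticae"
    strict_cluster_flags: bool = False
    correlated_set: str = "clique"  # or "any"
    annotation_path: str | None = None

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "synthetic":
                d[f.name] = None if v is None else _spec_summary(v)
            else:
                d[f.name] = v
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def _spec_summary(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["experiments"] = [e["experiment_id"] for e in d["experiments"]]
    return d


def _sub_seed(root: int, stage: str) -> int:
    return (zlib.crc32(stage.encode()) ^ root) & 0x7FFFFFFF


@dataclass
class IntegrationSets:
    """The four gene sets the final integration compares.

    ``basal``: nodes of the minimum network around the recurrent hubs;
    ``correlated``: the co-expression module genes; ``cluster_contributing``:
    top-contribution genes flagged cluster-specific in the target cluster;
    ``specific``: DEGs found only in the target species.
    """

    basal: set[str] = field(default_factory=set)
    correlated: set[str] = field(default_factory=set)
    cluster_contributing: set[str] = field(default_factory=set)
    specific: set[str] = field(default_factory=set)


@dataclass
class IntegrationSelection:
    specific_in_basal: set[str]
    basal_in_cluster: set[str]
    cluster_not_correlated: set[str]

    @property
    def seeds(self) -> set[str]:
        return (self.specific_in_basal | self.basal_in_cluster
                | self.cluster_not_correlated)


def integration_seed_selection(sets: IntegrationSets) -> IntegrationSelection:
    """Select the expansion seeds from the integration Venn.

    The seed set is (specific ∩ basal) ∪ (basal ∩ cluster_contributing) ∪
    (cluster_contributing \\ correlated): target-specific genes already in
    the basal network, genes shared by the basal network and the
    cluster-contributing set, and cluster-contributing genes that were not
    part of the co-expression module.
    """
    return IntegrationSelection(
        specific_in_basal=sets.specific & sets.basal,
        basal_in_cluster=sets.basal & sets.cluster_contributing,
        cluster_not_correlated=sets.cluster_contributing - sets.correlated,
    )


def _load_inputs(config: PipelineConfig):
    if config.manifest_path:
        manifest = io.read_experiment_manifest(config.manifest_path)
        tables = [
            io.read_deg_table(path, experiment_id=eid)
            for eid, path in sorted(config.deg_table_paths.items())
        ]
        truth = None
        if config.ppi_path:
            ppi = io.read_ppi_edges(
                config.ppi_path,
                min_combined=config.min_combined,
                require_experimental=config.require_experimental,
            )
        else:
            ppi = None
    else:
        spec = config.synthetic or default_meta_spec(
            seed=_sub_seed(config.seed, "simulate")
        )
        tables, manifest, truth = simulate_meta_experiments(spec)
        planted = {g for g, m in truth.module_of.items() if m != "null"}
        hub_plan = default_hub_plan(truth) if truth.module_genes("core") \
            else {}
        ppi, ppi_truth = simulate_ppi(
            n_background=800,
            seed_genes=planted,
            hub_plan=hub_plan,
            attach_m=2,
            seed=_sub_seed(config.seed, "ppi"),
        )
        truth.hub_nodes = ppi_truth.hub_nodes
    return tables, manifest, truth, ppi


def run_full_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    resume: bool = False,
) -> dict:
    """Run every stage and (optionally) write the result bundle.

    With ``resume=True`` and an ``out_dir`` holding a SUCCESS marker for the
    same config hash, the run is skipped entirely and the existing manifest
    is returned under ``{"resumed": True}`` — determinism makes the skipped
    recomputation exact.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    cfg_hash = config.content_hash()
    if resume and out_path is not None:
        marker = out_path / "SUCCESS"
        if marker.exists() and marker.read_text().strip() == cfg_hash:
            with open(out_path / "manifest.json") as fh:
                return {"resumed": True, "manifest": json.load(fh)}

    try:
        bundle = _run_stages(config)
    except PipelineError as exc:
        if out_path is not None:
            out_path.mkdir(parents=True, exist_ok=True)
            (out_path / "FAILED").write_text(
                json.dumps({"stage": exc.stage, "code": exc.code,
                            "message": str(exc)}) + "\n"
            )
        raise

    if out_path is not None:
        io.write_results(
            bundle,
            out_path,
            metadata={"config": config.to_dict(), "seed": config.seed,
                      "config_hash": cfg_hash},
        )
        failed = out_path / "FAILED"
        if failed.exists():
            failed.unlink()
        (out_path / "SUCCESS").write_text(cfg_hash + "\n")
    return bundle


def _run_stages(config: PipelineConfig) -> dict:
    bundle: dict[str, object] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Ctx()

    with stage("inputs"):
        tables, manifest, truth, ppi = _load_inputs(config)
        bundle["experiment_manifest"] = pd.DataFrame(
            [asdict(r) for r in manifest]
        ).set_index("experiment_id")

    with stage("deg_calling"):
        calls = {
            t.experiment_id: degmat.call_degs(t, config.padj_max,
                                              config.abs_lfc_min)
            for t in tables
        }
        bundle["deg_counts"] = pd.DataFrame(
            {
                "up": {e: len(u) for e, (u, d) in calls.items()},
                "down": {e: len(d) for e, (u, d) in calls.items()},
            }
        ).rename_axis("experiment_id")

    with stage("matrix_assembly"):
        matrix = degmat.assemble_matrix(
            tables, manifest, fill_policy=config.fill_policy,
            padj_max=config.padj_max, abs_lfc_min=config.abs_lfc_min,
        )
        bundle["deg_matrix"] = matrix

    target_exps = [r for r in manifest if r.species == config.target_species]
    with stage("time_venn"):
        time_points = sorted({r.time_point_h for r in target_exps})
        if len(time_points) >= 2:
            by_time = {}
            for t in time_points:
                ids = [r.experiment_id for r in target_exps
                       if r.time_point_h == t]
                up = set().union(*(calls[e][0] for e in ids))
                down = set().union(*(calls[e][1] for e in ids))
                by_time[f"{t:g}h"] = (up, down)
            venn_up, venn_down = degmat.time_overlap_partition(by_time)
            bundle["time_venn_up"] = venn_up
            bundle["time_venn_down"] = venn_down

    with stage("correlation"):
        recurrent = degmat.recurrence(matrix, config.min_experiments)
        bundle["recurrent_genes"] = recurrent
        if len(recurrent) >= 2:
            corr = metastats.correlation_graph(matrix, recurrent,
                                               r_min=config.r_min)
            any_corr, cliques = metastats.fully_connected_subnetworks(corr)
            bundle["correlation_edges"] = pd.DataFrame(
                sorted(corr.edges), columns=["gene_a", "gene_b", "r"]
            ).set_index("gene_a")
            bundle["correlated_any"] = any_corr
            clique_genes = set().union(*cliques) if cliques else set()
            bundle["correlated_clique"] = clique_genes
        else:
            any_corr, clique_genes = set(), set()
            bundle["correlated_any"] = set()
            bundle["correlated_clique"] = set()

    with stage("clustering"):
        if config.k > len(matrix.experiments):
            raise ValueError(
                f"k={config.k} exceeds the {len(matrix.experiments)} "
                "experiments"
            )
        clusters = metastats.cluster_experiments(matrix, k=config.k)
        bundle["experiment_clusters"] = clusters

    with stage("pca"):
        pca = metastats.pca_contributions(matrix)
        selection = metastats.select_dimensions(pca, config.var_threshold)
        top = metastats.top_contributing_genes(
            pca, selection.dims, n=min(config.top_n, len(matrix.genes))
        )
        bundle["pca"] = pca
        bundle["selected_dimensions"] = {
            "dims": selection.dims,
            "n_variance": selection.n_variance,
            "inflection": selection.inflection,
        }
        bundle["top_contributing_genes"] = pd.DataFrame(
            top, columns=["gene", "contribution"]
        ).set_index("gene")

    with stage("specificity"):
        top_genes = [g for g, _ in top]
        spec_calls = metastats.cluster_specificity(
            matrix, top_genes, clusters, B=config.B, alpha=config.alpha,
            seed=_sub_seed(config.seed, "specificity"),
        )
        bundle["specificity_calls"] = spec_calls

    with stage("species_specific"):
        sp_up, sp_down = degmat.species_specific_degs(
            matrix, manifest, config.target_species
        )
        bundle["species_specific_up"] = sp_up
        bundle["species_specific_down"] = sp_down

    with stage("minimum_networks"):
        hub_rankings = []
        if ppi is not None:
            expression = {}
            gidx = matrix.gene_index
            for e in target_exps:
                eid = e.experiment_id
                seeds = calls[eid][0] | calls[eid][1]
                if not (seeds & ppi.nodes):
                    continue
                sub, dropped = networks.minimum_connected_network(ppi, seeds)
                j = matrix.experiment_index[eid]
                expr = {
                    g: float(matrix.lfc[gidx[g], j])
                    for g in sub.nodes if g in gidx and matrix.de_mask[
                        gidx[g], j]
                }
                stats = networks.node_centralities(sub, seeds & sub.nodes,
                                                   expr)
                ranked = networks.top_betweenness(stats, n=15)
                hub_rankings.append(ranked)
                bundle[f"minnet_{eid}"] = sub
                bundle[f"centralities_{eid}"] = stats
                bundle[f"top_betweenness_{eid}"] = list(ranked)
        recurrent_hub_set = (
            networks.recurrent_hubs(hub_rankings)
            if len(hub_rankings) >= 2 else set()
        )
        bundle["recurrent_hubs"] = recurrent_hub_set

    with stage("integration"):
        if ppi is not None and recurrent_hub_set:
            basal_net, _ = networks.minimum_connected_network(
                ppi, recurrent_hub_set
            )
            basal = set(basal_net.nodes)
            bundle["basal_network"] = basal_net
        else:
            basal = set()
        flagged_target = _cluster_contributing(
            spec_calls, clusters, manifest, config
        )
        correlated = (clique_genes if config.correlated_set == "clique"
                      else any_corr)
        sets = IntegrationSets(
            basal=basal,
            correlated=correlated,
            cluster_contributing=flagged_target,
            specific=sp_up | sp_down,
        )
        selection_sets = integration_seed_selection(sets)
        bundle["integration_basal"] = sets.basal
        bundle["integration_correlated"] = sets.correlated
        bundle["integration_cluster_contributing"] = sets.cluster_contributing
        bundle["integration_specific"] = sets.specific
        bundle["integration_specific_in_basal"] = \
            selection_sets.specific_in_basal
        bundle["integration_basal_in_cluster"] = \
            selection_sets.basal_in_cluster
        bundle["integration_cluster_not_correlated"] = \
            selection_sets.cluster_not_correlated
        bundle["integration_seeds"] = selection_sets.seeds

    with stage("expansion"):
        if ppi is not None and selection_sets.seeds & ppi.nodes:
            trace = networks.expand_network(
                ppi, selection_sets.seeds, rounds=config.rounds,
                per_round=config.per_round,
            )
            bundle["expansion"] = trace

    with stage("enrichment"):
        if config.annotation_path:
            annotation = _read_annotation(config.annotation_path)
            universe = set(matrix.genes)
            query = (bundle["expansion"].subnetwork.nodes & universe
                     if "expansion" in bundle
                     else selection_sets.seeds & universe)
            if query:
                bundle["enrichment"] = networks.enrich_terms(
                    query, annotation, universe
                )

    if truth is not None:
        bundle["ground_truth"] = {
            "cluster_of": truth.cluster_of,
            "module_of": truth.module_of,
            "hub_nodes": sorted(truth.hub_nodes),
            "phase_of": truth.phase_of,
        }
    return bundle


def _cluster_contributing(
    spec_calls, clusters, manifest, config: PipelineConfig
) -> set[str]:
    """Top-contribution genes flagged specific (above the mean) in the
    cluster holding the target species' experiments."""
    by_id = {r.experiment_id: r for r in manifest}
    counts: dict[int, int] = {}
    for e, lab in clusters.labels.items():
        if by_id[e].species == config.target_species:
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        return set()
    target_cluster = min(sorted(counts), key=lambda c: -counts[c])
    flagged = {
        c.gene_id for c in spec_calls
        if c.cluster == target_cluster and c.flagged
        and c.direction == "above"
    }
    if config.strict_cluster_flags:
        foreign_flagged = {
            c.gene_id for c in spec_calls
            if c.cluster != target_cluster and c.flagged
        }
        flagged -= foreign_flagged
    return flagged


def _read_annotation(path: str) -> dict[str, set[str]]:
    """Two-column (term, gene) TSV -> term to gene-set mapping."""
    annotation: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            annotation.setdefault(parts[0], set()).add(parts[1])
    return annotation
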