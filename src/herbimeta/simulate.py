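"""Synthetic transcriptomic meta-experiments with planted, known structure.

The generator emits exactly what the pipeline consumes — per-experiment DEG
tables, an experiment manifest, and a PPI edge graph — while recording the
planted ground truth (experiment clusters, gene module memberships,
connector hubs) so every downstream stage can be tested for recovery.

The model is deliberately minimal: for gene g in experiment e,
``log2FC = mu(g, e) + Normal(0, sd)`` where ``mu`` is the planted module
effect when g's module is active in e's cluster/species and 0 otherwise.
Adjusted p-values are assigned, not computed from a count model: genes with
a planted effect get ``de_padj`` (default 0.001), the rest ``null_padj``
(default 0.5), because all downstream stages consume only the thresholded
DE decision.  Microarray experiments drop a fraction of genes uniformly at
random to emulate platform coverage gaps.

Modules can be given a shared per-experiment amplitude profile (a
multiplier drawn once per experiment), which models a co-regulated module
whose response strength tracks the experiment — the only way a module's
pairwise Pearson correlations can clear a 0.95 threshold in the presence of
per-gene noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import DEGRecord, DEGTable, ExperimentRecord, PPIEdge, PPINetwork

__all__ = [
    "ModuleSpec",
    "SyntheticSpec",
    "GroundTruth",
    "simulate_meta_experiments",
    "simulate_time_course",
    "simulate_ppi",
    "default_meta_spec",
    "default_hub_plan",
]


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module: size, log2 effect, and optional refinements.

    ``silent_clusters`` lists experiment clusters where the module shows no
    response (used for the core module, which is silent in the aphid-like
    cluster).  ``noise_sd`` overrides the global per-gene noise.
    ``amplitude`` (lo, hi) draws one shared multiplier per experiment from
    U(lo, hi).  ``balanced=True`` plants half the genes with +effect and
    half with -effect.
    """

    n_genes: int
    effect: float
    silent_clusters: frozenset = frozenset()
    noise_sd: float | None = None
    amplitude: tuple[float, float] | None = None
    balanced: bool = False


@dataclass
class SyntheticSpec:
    n_genes: int
    experiments: list[ExperimentRecord]
    cluster_of: dict[str, str]
    core_module: ModuleSpec | None = None
    cluster_modules: dict[str, ModuleSpec] = field(default_factory=dict)
    species_specific: dict[str, ModuleSpec] = field(default_factory=dict)
    noise_sd: float = 0.5
    de_padj: float = 0.001
    null_padj: float = 0.5
    platform_missing_rate: float = 0.1
    seed: int = 0
    # time-course generator: planted early-only / persistent / late-only sets
    time_modules: dict[str, ModuleSpec] = field(default_factory=dict)
    # split species-specific modules of multi-time-point species into
    # early-only / persistent / late-only thirds
    split_time_phases: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name, rate in (("platform_missing_rate", self.platform_missing_rate),):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        missing = [e.experiment_id for e in self.experiments
                   if e.experiment_id not in self.cluster_of]
        if missing:
            raise ValueError(f"experiments without cluster label: {missing}")
        total = sum(m.n_genes for m in self._modules().values())
        if total > self.n_genes:
            raise ValueError(
                f"module sizes ({total}) exceed n_genes ({self.n_genes})"
            )

    def _modules(self) -> dict[str, ModuleSpec]:
        mods: dict[str, ModuleSpec] = {}
        if self.core_module is not None:
            mods["core"] = self.core_module
        for label in sorted(self.cluster_modules):
            mods[f"cluster:{label}"] = self.cluster_modules[label]
        for sp in sorted(self.species_specific):
            mods[f"species:{sp}"] = self.species_specific[sp]
        return mods


@dataclass
class GroundTruth:
    cluster_of: dict[str, str] = field(default_factory=dict)
    module_of: dict[str, str] = field(default_factory=dict)
    hub_nodes: set[str] = field(default_factory=set)
    phase_of: dict[str, str] = field(default_factory=dict)

    def module_genes(self, label: str) -> set[str]:
        return {g for g, m in self.module_of.items() if m == label}


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _assign_modules(spec: SyntheticSpec) -> tuple[list[str], dict[str, str]]:
    genes = _gene_names(spec.n_genes)
    module_of = {g: "null" for g in genes}
    cursor = 0
    for label, mod in spec._modules().items():
        for g in genes[cursor:cursor + mod.n_genes]:
            module_of[g] = label
        cursor += mod.n_genes
    return genes, module_of


def _phases_for(spec: SyntheticSpec) -> dict[str, str]:
    """Early/persistent/late split of species modules with >=3 time points."""
    if not spec.split_time_phases:
        return {}
    genes, module_of = _assign_modules(spec)
    times_by_species: dict[str, set[float]] = {}
    for e in spec.experiments:
        times_by_species.setdefault(e.species, set()).add(e.time_point_h)
    phase_of: dict[str, str] = {}
    for sp in sorted(spec.species_specific):
        if len(times_by_species.get(sp, ())) < 3:
            continue
        members = [g for g in genes if module_of[g] == f"species:{sp}"]
        third = len(members) // 3
        for g in members[:third]:
            phase_of[g] = "early"
        for g in members[third:len(members) - third]:
            phase_of[g] = "persistent"
        for g in members[len(members) - third:]:
            phase_of[g] = "late"
    return phase_of


def _effect_matrix(spec: SyntheticSpec):
    """Planted mean log2FC per gene x experiment, plus per-gene noise sd."""
    genes, module_of = _assign_modules(spec)
    phase_of = _phases_for(spec)
    mods = spec._modules()
    exps = spec.experiments
    G, E = len(genes), len(exps)
    gidx = {g: i for i, g in enumerate(genes)}

    times_by_species: dict[str, list[float]] = {}
    for e in exps:
        times_by_species.setdefault(e.species, []).append(e.time_point_h)

    amp_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,))
    )
    amplitudes: dict[str, np.ndarray] = {}
    for label in mods:  # stable order: amplitude draws are label-ordered
        mod = mods[label]
        if mod.amplitude is not None:
            lo, hi = mod.amplitude
            amplitudes[label] = amp_rng.uniform(lo, hi, size=E)
        else:
            amplitudes[label] = np.ones(E)

    mu = np.zeros((G, E))
    noise_sd = np.full(G, spec.noise_sd)
    for label, mod in mods.items():
        members = [g for g in genes if module_of[g] == label]
        if mod.noise_sd is not None:
            for g in members:
                noise_sd[gidx[g]] = mod.noise_sd
        signs = {g: (1.0 if (not mod.balanced or k < (len(members) + 1) // 2)
                     else -1.0)
                 for k, g in enumerate(members)}
        for j, e in enumerate(exps):
            cluster = spec.cluster_of[e.experiment_id]
            if label == "core":
                active = cluster not in mod.silent_clusters
            elif label.startswith("cluster:"):
                active = cluster == label.split(":", 1)[1]
            else:  # species module
                sp = label.split(":", 1)[1]
                active = e.species == sp
                if active:
                    sp_times = times_by_species[sp]
                    for g in members:
                        phase = phase_of.get(g)
                        if phase == "early":
                            ok = e.time_point_h == min(sp_times)
                        elif phase == "late":
                            ok = e.time_point_h == max(sp_times)
                        else:
                            ok = True
                        if ok:
                            mu[gidx[g], j] = (mod.effect * signs[g]
                                              * amplitudes[label][j])
                    continue
            if active:
                for g in members:
                    mu[gidx[g], j] = (mod.effect * signs[g]
                                      * amplitudes[label][j])
    return genes, module_of, phase_of, mu, noise_sd


def simulate_meta_experiments(
    spec: SyntheticSpec,
) -> tuple[list[DEGTable], list[ExperimentRecord], GroundTruth]:
    """Generate one DEG table per experiment plus the planted ground truth.

    Fully reproducible from ``spec.seed``: noise and platform-dropout
    streams are derived per experiment from independent seed-sequence
    spawns, so adding or reordering experiments elsewhere does not perturb
    an experiment's draws.
    """
    genes, module_of, phase_of, mu, noise_sd = _effect_matrix(spec)
    tables: list[DEGTable] = []
    for j, exp in enumerate(spec.experiments):
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, j))
        )
        lfc = mu[:, j] + noise_rng.normal(0.0, 1.0, size=len(genes)) * noise_sd
        padj = np.where(mu[:, j] != 0.0, spec.de_padj, spec.null_padj)
        masked: set[int] = set()
        if exp.platform == "microarray" and spec.platform_missing_rate > 0:
            mask_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(2, j))
            )
            n_mask = int(round(spec.platform_missing_rate * len(genes)))
            masked = set(mask_rng.choice(len(genes), size=n_mask,
                                         replace=False).tolist())
        records = {
            genes[i]: DEGRecord(genes[i], float(lfc[i]), float(padj[i]))
            for i in range(len(genes)) if i not in masked
        }
        tables.append(DEGTable(exp.experiment_id, records))
    truth = GroundTruth(
        cluster_of=dict(spec.cluster_of),
        module_of=module_of,
        phase_of=phase_of,
    )
    return tables, list(spec.experiments), truth


def simulate_time_course(
    spec: SyntheticSpec,
    time_points: Sequence[float],
    species: str = "synthetic herbivore",
) -> tuple[list[DEGTable], list[ExperimentRecord], GroundTruth]:
    """One DEG table per time point of a single-species infestation.

    Planted sets come from ``spec.time_modules`` (labels "early",
    "persistent", "late"): early-only genes respond at the first time point
    only, late-only at the last, persistent at all of them.
    """
    if not time_points:
        raise ValueError("time_points must be non-empty")
    labels = [lab for lab in ("early", "persistent", "late")
              if lab in spec.time_modules]
    total = sum(spec.time_modules[lab].n_genes for lab in labels)
    if total > spec.n_genes:
        raise ValueError(
            f"time module sizes ({total}) exceed n_genes ({spec.n_genes})"
        )
    genes = _gene_names(spec.n_genes)
    module_of = {g: "null" for g in genes}
    cursor = 0
    for lab in labels:
        for g in genes[cursor:cursor + spec.time_modules[lab].n_genes]:
            module_of[g] = f"time:{lab}"
        cursor += spec.time_modules[lab].n_genes

    t_first, t_last = min(time_points), max(time_points)
    records_exps = [
        ExperimentRecord(f"tc_{t:g}h", species, "time-course", float(t),
                         "rnaseq")
        for t in time_points
    ]
    tables: list[DEGTable] = []
    for j, (t, exp) in enumerate(zip(time_points, records_exps)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(3, j))
        )
        mu = np.zeros(len(genes))
        for i, g in enumerate(genes):
            lab = module_of[g]
            if lab == "time:early":
                active = t == t_first
            elif lab == "time:late":
                active = t == t_last
            elif lab == "time:persistent":
                active = True
            else:
                active = False
            if active:
                mu[i] = spec.time_modules[lab.split(":", 1)[1]].effect
        lfc = mu + rng.normal(0.0, spec.noise_sd, size=len(genes))
        padj = np.where(mu != 0.0, spec.de_padj, spec.null_padj)
        tables.append(DEGTable(exp.experiment_id, {
            g: DEGRecord(g, float(lfc[i]), float(padj[i]))
            for i, g in enumerate(genes)
        }))
    truth = GroundTruth(
        cluster_of={e.experiment_id: "time-course" for e in records_exps},
        module_of=module_of,
    )
    return tables, records_exps, truth


def simulate_ppi(
    n_background: int,
    seed_genes: Iterable[str],
    hub_plan: Mapping[str, Iterable[str]],
    attach_m: int = 2,
    seed: int = 0,
    combined_score: int = 999,
    experimental_score: int = 500,
) -> tuple[PPINetwork, GroundTruth]:
    """A background interactome with planted connector hubs.

    A preferential-attachment (Barabasi-Albert) background graph of
    ``n_background`` nodes is built first; each seed gene then attaches to
    ``attach_m`` background nodes, with attachment neighborhoods disjoint
    across seed genes so that no two seed genes share a background
    neighbor.  Each planned hub is inserted with direct edges to its
    assigned seed genes, making the hub the unique length-2 connector among
    them.  All edges carry the given scores.
    """
    import networkx as nx

    seed_genes = sorted(set(seed_genes))
    hubs = sorted(hub_plan)
    if set(hubs) & set(seed_genes):
        raise ValueError("hub names must be distinct from seed genes")
    if attach_m >= n_background:
        raise ValueError(
            f"attach_m={attach_m} must be below the {n_background} "
            "background nodes"
        )
    if attach_m * len(seed_genes) > n_background:
        raise ValueError(
            "not enough background nodes for disjoint seed attachments: "
            f"need {attach_m * len(seed_genes)}, have {n_background}"
        )
    bg = nx.barabasi_albert_graph(n_background, attach_m, seed=seed)
    width = max(4, len(str(n_background)))
    name = {i: f"bg{i:0{width}d}" for i in bg.nodes}
    net = PPINetwork()
    for u, v in bg.edges:
        net.add_edge(PPIEdge(name[u], name[v], combined_score,
                             experimental_score))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(4,)))
    pool = rng.permutation(n_background)
    cursor = 0
    for g in seed_genes:
        for _ in range(attach_m):
            net.add_edge(PPIEdge(g, name[int(pool[cursor])], combined_score,
                                 experimental_score))
            cursor += 1
    for hub in hubs:
        targets = sorted(set(hub_plan[hub]))
        unknown = [t for t in targets if t not in seed_genes]
        if unknown:
            raise ValueError(f"hub {hub!r} connects unknown seeds {unknown}")
        for t in targets:
            net.add_edge(PPIEdge(hub, t, combined_score, experimental_score))
    truth = GroundTruth(hub_nodes=set(hubs))
    return net, truth


# ---------------------------------------------------------------------------
# the default study scenario


def default_meta_spec(seed: int = 0, n_genes: int = 2000) -> SyntheticSpec:
    """The default meta-analysis scenario: 28 experiments, four clusters.

    Emulates a herbivory meta-analysis: an aphid-like cluster in which the
    shared core response is silent, a broad lepidopteran cluster, a small
    late-lepidopteran cluster, and a spider-mite/leafminer cluster whose
    mite experiments form a four-time-point series.  The core module gets a
    shared per-experiment amplitude profile (tightly co-regulated), the
    mite-specific module is split early/persistent/late.
    """
    rows = [
        # id, species, taxon_group, time (h), platform, cluster
        ("mp_6h", "Myzus persicae", "aphid", 6, "microarray", "c1"),
        ("mp_24h", "Myzus persicae", "aphid", 24, "microarray", "c1"),
        ("mp_48h", "Myzus persicae", "aphid", 48, "microarray", "c1"),
        ("mp_72h", "Myzus persicae", "aphid", 72, "microarray", "c1"),
        ("bb_6h", "Brevicoryne brassicae", "aphid", 6, "microarray", "c1"),
        ("bb_24h", "Brevicoryne brassicae", "aphid", 24, "microarray", "c1"),
        ("mc_3h", "Myzus cerasi", "aphid", 3, "microarray", "c1"),
        ("bt_6h", "Bemisia tabaci", "whitefly", 6, "rnaseq", "c1"),
        ("bt_24h", "Bemisia tabaci", "whitefly", 24, "rnaseq", "c1"),
        ("fo_24h", "Frankliniella occidentalis", "thrips", 24, "microarray",
         "c1"),
        ("pb_3h", "Pieris brassicae", "lepidopteran", 3, "microarray", "c2"),
        ("pb_24h", "Pieris brassicae", "lepidopteran", 24, "microarray", "c2"),
        ("mb_6h", "Mamestra brassicae", "lepidopteran", 6, "microarray", "c2"),
        ("mb_24h", "Mamestra brassicae", "lepidopteran", 24, "microarray",
         "c2"),
        ("sl_3h", "Spodoptera littoralis", "lepidopteran", 3, "rnaseq", "c2"),
        ("sl_24h", "Spodoptera littoralis", "lepidopteran", 24, "rnaseq",
         "c2"),
        ("pr_3h", "Pieris rapae", "lepidopteran", 3, "microarray", "c2"),
        ("fo_48h", "Frankliniella occidentalis", "thrips", 48, "microarray",
         "c2"),
        ("by_48h", "Brevipalpus yothersi", "mite", 48, "microarray", "c2"),
        ("pr_6h", "Pieris rapae", "lepidopteran", 6, "rnaseq", "c3"),
        ("pr_12h", "Pieris rapae", "lepidopteran", 12, "rnaseq", "c3"),
        ("pr_24h", "Pieris rapae", "lepidopteran", 24, "rnaseq", "c3"),
        ("tu_0.5h", "Tetranychus urticae", "mite", 0.5, "rnaseq", "c4"),
        ("tu_1h", "Tetranychus urticae", "mite", 1, "rnaseq", "c4"),
        ("tu_3h", "Tetranychus urticae", "mite", 3, "rnaseq", "c4"),
        ("tu_24h", "Tetranychus urticae", "mite", 24, "rnaseq", "c4"),
        ("lh_24h", "Liriomyza huidobrensis", "leafminer", 24, "microarray",
         "c4"),
        ("lh_48h", "Liriomyza huidobrensis", "leafminer", 48, "microarray",
         "c4"),
    ]
    experiments = [ExperimentRecord(r[0], r[1], r[2], float(r[3]), r[4])
                   for r in rows]
    cluster_of = {r[0]: r[5] for r in rows}
    return SyntheticSpec(
        n_genes=n_genes,
        experiments=experiments,
        cluster_of=cluster_of,
        core_module=ModuleSpec(120, 1.0, silent_clusters=frozenset({"c1"}),
                               noise_sd=0.15, amplitude=(1.5, 4.0)),
        cluster_modules={
            "c1": ModuleSpec(15, 2.0),
            "c2": ModuleSpec(25, 2.5),
            "c3": ModuleSpec(25, 3.0),
            "c4": ModuleSpec(30, 3.0),
        },
        species_specific={"Tetranychus urticae": ModuleSpec(20, 3.0)},
        noise_sd=0.5,
        platform_missing_rate=0.1,
        seed=seed,
    )


def default_hub_plan(truth: GroundTruth, n_hubs: int = 3,
                     fan_out: int = 40) -> dict[str, list[str]]:
    """Plant hubs that each connect ``fan_out`` core-module genes.

    Core genes respond at every time point of the target species, so these
    connectors should recur in every per-time-point hub ranking.
    """
    core = sorted(truth.module_genes("core"))
    if len(core) < n_hubs * fan_out:
        raise ValueError("not enough core genes for the hub plan")
    return {
        f"hub_{chr(ord('a') + i)}": core[i * fan_out:(i + 1) * fan_out]
        for i in range(n_hubs)
    }
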