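"""Readers and writers for the pipeline's exchange formats.

Three kinds of input feed the meta-analysis: per-experiment differential
expression tables (gene id, log2 fold change, adjusted p-value), an
experiment manifest describing each transcriptomic experiment (species,
taxon group, time point, platform), and a STRING-style weighted
protein-protein interaction edge list.  Result artifacts round-trip through
plain text: gene lists, TSV matrices with companion mask matrices, edge-list
TSVs and JSON run metadata.

Identifiers are opaque, case-sensitive strings; no probe or ortholog mapping
is attempted here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FormatError",
    "ExperimentRecord",
    "DEGRecord",
    "DEGTable",
    "PPIEdge",
    "PPINetwork",
    "read_deg_table",
    "read_experiment_manifest",
    "read_ppi_edges",
    "write_results",
    "read_gene_set",
    "read_deg_matrix",
]

PLATFORMS = ("microarray", "rnaseq")


class FormatError(ValueError):
    """An input file violates the expected format."""


@dataclass(frozen=True)
class ExperimentRecord:
    """One transcriptomic experiment in the meta-analysis manifest."""

    experiment_id: str
    species: str
    taxon_group: str
    time_point_h: float
    platform: str

    def __post_init__(self) -> None:
        if self.time_point_h < 0:
            raise ValueError(
                f"time_point_h must be >= 0, got {self.time_point_h} "
                f"for {self.experiment_id!r}"
            )
        if self.platform not in PLATFORMS:
            raise FormatError(
                f"unknown platform {self.platform!r} for {self.experiment_id!r}; "
                f"expected one of {PLATFORMS}"
            )


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential-expression statistics from one experiment."""

    gene_id: str
    log2fc: float
    padj: float | None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(
                f"padj must lie in [0, 1], got {self.padj} for {self.gene_id!r}"
            )


@dataclass
class DEGTable:
    """All per-gene statistics reported by a single experiment."""

    experiment_id: str
    records: dict[str, DEGRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPIEdge:
    """Undirected interaction with STRING-style 0-1000 evidence scores."""

    node_a: str
    node_b: str
    combined_score: int
    experimental_score: int

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"self-loop on {self.node_a!r}")
        for name in ("combined_score", "experimental_score"):
            v = getattr(self, name)
            if not (0 <= v <= 1000):
                raise FormatError(f"{name}={v} outside the 0-1000 scale")

    def canonical(self) -> "PPIEdge":
        a, b = _canonical_pair(self.node_a, self.node_b)
        if (a, b) == (self.node_a, self.node_b):
            return self
        return PPIEdge(a, b, self.combined_score, self.experimental_score)


@dataclass
class PPINetwork:
    """Simple undirected weighted graph: at most one edge per node pair."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], PPIEdge] = field(default_factory=dict)

    def add_edge(self, edge: PPIEdge, keep_max: bool = True) -> None:
        edge = edge.canonical()
        key = (edge.node_a, edge.node_b)
        old = self.edges.get(key)
        if old is None or not keep_max or (
            (edge.combined_score, edge.experimental_score)
            > (old.combined_score, old.experimental_score)
        ):
            self.edges[key] = edge
        self.nodes.update(key)

    def add_node(self, node: str) -> None:
        self.nodes.add(node)

    @property
    def edge_list(self) -> list[PPIEdge]:
        return [self.edges[k] for k in sorted(self.edges)]

    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), e in sorted(self.edges.items()):
            g.add_edge(a, b, combined_score=e.combined_score,
                       experimental_score=e.experimental_score)
        return g

    def subgraph(self, keep: Iterable[str]) -> "PPINetwork":
        keep = set(keep)
        sub = PPINetwork(nodes=set(k for k in keep if k in self.nodes))
        for (a, b), e in self.edges.items():
            if a in keep and b in keep:
                sub.edges[(a, b)] = e
        return sub


# ---------------------------------------------------------------------------
# readers


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a header-bearing TSV/CSV/whitespace table, sniffing the delimiter."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        sep = "\t"
    elif "," in header:
        sep = ","
    else:
        sep = r"\s+"
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def _to_float(value, path, line_no: int, col: str, allow_missing: bool = False):
    if value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip() in ("", "NA", "NaN", "nan")
    ):
        if allow_missing:
            return None
        raise FormatError(f"{path}:{line_no}: missing value in column {col!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}:{line_no}: unparsable numeric {value!r} in column {col!r}"
        ) from None


def read_deg_table(
    path: str | Path,
    experiment_id: str,
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> DEGTable:
    """Read one experiment's DEG table.

    Duplicate gene rows collapse to the row with the smallest adjusted
    p-value (missing padj sorts last); ties go to the larger \\|log2fc\\|,
    then to the first occurrence.
    """
    df = _read_delimited(path)
    _require_columns(df, [gene_col, lfc_col, padj_col], path)
    genes_col = df[gene_col].tolist()
    lfcs_col = df[lfc_col].tolist()
    padjs_col = df[padj_col].tolist()
    best: dict[str, tuple] = {}
    records: dict[str, DEGRecord] = {}
    for i in range(len(df)):
        line_no = i + 2  # 1-based, after header
        gene = genes_col[i]
        if gene is None or (isinstance(gene, float) and math.isnan(gene)):
            raise FormatError(f"{path}:{line_no}: empty gene id")
        gene = str(gene)
        lfc = _to_float(lfcs_col[i], path, line_no, lfc_col)
        padj = _to_float(padjs_col[i], path, line_no, padj_col,
                         allow_missing=True)
        rec = DEGRecord(gene, lfc, padj)
        key = (
            padj if padj is not None else math.inf,  # smaller padj wins
            -abs(lfc),                                # then larger |lfc|
            i,                                        # then first occurrence
        )
        if gene not in best or key < best[gene]:
            best[gene] = key
            records[gene] = rec
    return DEGTable(experiment_id=experiment_id, records=records)


def read_experiment_manifest(path: str | Path) -> list[ExperimentRecord]:
    """Read the experiment manifest; experiment ids must be unique."""
    df = _read_delimited(path)
    cols = ["experiment_id", "species", "taxon_group", "time_point_h", "platform"]
    _require_columns(df, cols, path)
    records = []
    for i in range(len(df)):
        line_no = i + 2
        records.append(
            ExperimentRecord(
                experiment_id=str(df.iloc[i]["experiment_id"]),
                species=str(df.iloc[i]["species"]),
                taxon_group=str(df.iloc[i]["taxon_group"]),
                time_point_h=_to_float(df.iloc[i]["time_point_h"], path,
                                       line_no, "time_point_h"),
                platform=str(df.iloc[i]["platform"]).strip(),
            )
        )
    seen: dict[str, int] = {}
    dups = []
    for r in records:
        seen[r.experiment_id] = seen.get(r.experiment_id, 0) + 1
    dups = sorted(e for e, n in seen.items() if n > 1)
    if dups:
        raise FormatError(f"{path}: duplicate experiment_id(s): {dups}")
    return records


def read_ppi_edges(
    path: str | Path,
    min_combined: int = 900,
    require_experimental: bool = True,
    node_a_col: str = "node1",
    node_b_col: str = "node2",
    combined_col: str = "combined_score",
    experimental_col: str = "experimental",
) -> PPINetwork:
    """Read a STRING-style edge list, filter, symmetrize and deduplicate.

    Edges survive only with ``combined_score > min_combined`` (strict) and,
    when ``require_experimental``, ``experimental_score > 0``.  Reciprocal
    duplicates keep the max-score copy.  Self-loops are discarded.
    """
    df = _read_delimited(path)
    _require_columns(df, [node_a_col, node_b_col, combined_col, experimental_col],
                     path)
    net = PPINetwork()
    a_col = df[node_a_col].tolist()
    b_col = df[node_b_col].tolist()
    c_col = df[combined_col].tolist()
    e_col = df[experimental_col].tolist()
    for i in range(len(df)):
        line_no = i + 2
        a, b = str(a_col[i]), str(b_col[i])
        comb = _to_float(c_col[i], path, line_no, combined_col)
        expr = _to_float(e_col[i], path, line_no, experimental_col)
        if not (comb == int(comb) and expr == int(expr)):
            comb, expr = round(comb), round(expr)
        comb, expr = int(comb), int(expr)
        if not (0 <= comb <= 1000) or not (0 <= expr <= 1000):
            raise FormatError(
                f"{path}:{line_no}: score outside 0-1000 ({comb}, {expr})"
            )
        if a == b:
            warnings.warn(f"{path}:{line_no}: self-loop on {a!r} discarded")
            continue
        if comb > min_combined and (not require_experimental or expr > 0):
            net.add_edge(PPIEdge(a, b, comb, expr))
    return net


# ---------------------------------------------------------------------------
# writers (and the round-trip readers for each artifact)


def _write_gene_set(genes: Iterable[str], path: Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_set(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _write_network(net: PPINetwork, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcombined_score\texperimental\n")
        for e in net.edge_list:
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.combined_score}\t"
                     f"{e.experimental_score}\n")
    # isolated nodes live in a sidecar so the graph round-trips exactly
    isolated = sorted(net.nodes - {n for k in net.edges for n in k})
    if isolated:
        with open(path.with_suffix(".nodes.txt"), "w") as fh:
            for n in isolated:
                fh.write(f"{n}\n")


def read_network(path: str | Path) -> PPINetwork:
    net = read_ppi_edges(path, min_combined=-1, require_experimental=False)
    sidecar = Path(path).with_suffix(".nodes.txt")
    if sidecar.exists():
        for n in read_gene_set(sidecar):
            net.add_node(n)
    return net


def _write_deg_matrix(matrix, out_dir: Path, name: str) -> list[str]:
    import numpy as np

    files = []
    frames = {
        "lfc": pd.DataFrame(matrix.lfc, index=matrix.genes,
                            columns=matrix.experiments),
        "de_mask": pd.DataFrame(matrix.de_mask.astype(int), index=matrix.genes,
                                columns=matrix.experiments),
        "measured_mask": pd.DataFrame(matrix.measured_mask.astype(int),
                                      index=matrix.genes,
                                      columns=matrix.experiments),
    }
    for suffix, frame in frames.items():
        fn = f"{name}.{suffix}.tsv"
        frame.to_csv(out_dir / fn, sep="\t", index_label="gene")
        files.append(fn)
    return files


def read_deg_matrix(out_dir: str | Path, name: str):
    """Re-read a matrix trio written by :func:`write_results`."""
    from .degmat import DEGMatrix
    import numpy as np

    out_dir = Path(out_dir)
    lfc = pd.read_csv(out_dir / f"{name}.lfc.tsv", sep="\t", index_col="gene")
    de = pd.read_csv(out_dir / f"{name}.de_mask.tsv", sep="\t", index_col="gene")
    meas = pd.read_csv(out_dir / f"{name}.measured_mask.tsv", sep="\t",
                       index_col="gene")
    return DEGMatrix(
        genes=list(lfc.index),
        experiments=list(lfc.columns),
        lfc=lfc.to_numpy(dtype=float),
        de_mask=de.to_numpy(dtype=bool),
        measured_mask=meas.to_numpy(dtype=bool),
    )


def write_results(
    bundle: Mapping[str, object],
    out_dir: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> dict[str, list[str]]:
    """Write a dict of pipeline artifacts to ``out_dir``.

    Dispatches on type: gene sets become sorted one-id-per-line text files,
    matrices a TSV trio (values + DE mask + measured mask), networks
    edge-list TSVs, data frames TSVs, everything JSON-serializable a JSON
    file.  Returns the manifest (artifact name -> written file names), which
    is itself written as ``manifest.json`` together with ``run_metadata.json``.
    Output is deterministic: same bundle, byte-identical files.
    """
    from .degmat import DEGMatrix, VennPartition
    from .metastats import ClusterAssignment, PCAResult, SpecificityCall
    from .networks import ExpansionTrace

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}

    for name, obj in bundle.items():
        files: list[str] = []
        if isinstance(obj, DEGMatrix):
            files = _write_deg_matrix(obj, out_dir, name)
        elif isinstance(obj, PPINetwork):
            fn = f"{name}.edges.tsv"
            _write_network(obj, out_dir / fn)
            files = [fn]
        elif isinstance(obj, (set, frozenset)) or (
            isinstance(obj, list) and all(isinstance(x, str) for x in obj)
        ):
            fn = f"{name}.genes.txt"
            _write_gene_set(obj, out_dir / fn)
            files = [fn]
        elif isinstance(obj, VennPartition):
            fn = f"{name}.venn.tsv"
            with open(out_dir / fn, "w") as fh:
                fh.write("signature\tcount\tmembers\n")
                for sig in sorted(obj.region_counts,
                                  key=lambda s: (len(s), sorted(s))):
                    label = "&".join(n for n in obj.set_names if n in sig)
                    members = ",".join(sorted(obj.region_members[sig]))
                    fh.write(f"{label}\t{obj.region_counts[sig]}\t{members}\n")
            files = [fn]
        elif isinstance(obj, ClusterAssignment):
            fn = f"{name}.clusters.tsv"
            with open(out_dir / fn, "w") as fh:
                fh.write("experiment_id\tcluster\n")
                for e in obj.experiments:
                    fh.write(f"{e}\t{obj.labels[e]}\n")
            files = [fn]
        elif isinstance(obj, PCAResult):
            eig = pd.DataFrame({"eigenvalue": obj.eigenvalues})
            eig.index = [f"dim{i + 1}" for i in range(len(obj.eigenvalues))]
            eig.to_csv(out_dir / f"{name}.eigenvalues.tsv", sep="\t",
                       index_label="dimension")
            gc = pd.DataFrame(obj.gene_contrib, index=obj.genes,
                              columns=eig.index)
            gc.to_csv(out_dir / f"{name}.gene_contributions.tsv", sep="\t",
                      index_label="gene")
            ec = pd.DataFrame(obj.experiment_contrib, index=obj.experiments,
                              columns=eig.index)
            ec.to_csv(out_dir / f"{name}.experiment_contributions.tsv",
                      sep="\t", index_label="experiment_id")
            files = [f"{name}.eigenvalues.tsv",
                     f"{name}.gene_contributions.tsv",
                     f"{name}.experiment_contributions.tsv"]
        elif isinstance(obj, list) and obj and isinstance(obj[0], SpecificityCall):
            fn = f"{name}.calls.tsv"
            with open(out_dir / fn, "w") as fh:
                fh.write("gene_id\tcluster\testimate\tlower\tupper\t"
                         "z0\ta\tglobal_mean\tflagged\tdirection\n")
                for c in obj:
                    iv = c.interval
                    fh.write(
                        f"{c.gene_id}\t{c.cluster}\t{iv.estimate!r}\t"
                        f"{iv.lower!r}\t{iv.upper!r}\t{iv.z0!r}\t{iv.a!r}\t"
                        f"{c.global_mean!r}\t{int(c.flagged)}\t{c.direction}\n"
                    )
            files = [fn]
        elif isinstance(obj, ExpansionTrace):
            fn = f"{name}.rounds.tsv"
            with open(out_dir / fn, "w") as fh:
                fh.write("round\tnode\tattachment_score\n")
                for r, added in enumerate(obj.rounds, start=1):
                    for node, score in added:
                        fh.write(f"{r}\t{node}\t{score}\n")
            _write_network(obj.subnetwork, out_dir / f"{name}.edges.tsv")
            files = [fn, f"{name}.edges.tsv"]
        elif isinstance(obj, pd.DataFrame):
            fn = f"{name}.tsv"
            obj.to_csv(out_dir / fn, sep="\t")
            files = [fn]
        else:
            fn = f"{name}.json"
            with open(out_dir / fn, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)
                fh.write("\n")
            files = [fn]
        manifest[name] = files

    from . import __version__

    meta = {
        "package": "herbimeta",
        "version": __version__,
        **(dict(metadata) if metadata else {}),
    }
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"cannot serialize {type(obj)!r}")
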