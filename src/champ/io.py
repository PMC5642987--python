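"""Readers and writers for the interchange formats.

Formats are plain text throughout: tab-separated edge lists (single- and
multilayer), GML via networkx, ensemble CSV (one row per partition, one
column per node), coefficient tables, 1-D domain CSVs and 2-D domain-map
JSON.  External node labels are preserved through a label table on the
network objects; floats are serialized with 12 significant digits so writers
are deterministic and round trips are faithful.

Multilayer inputs use three files: an intralayer edge TSV with a fourth
``layer`` column, an interlayer edge TSV whose endpoints are state-node
tokens ``name@layer``, and a ``node<TAB>layer`` state-node table defining
which node-layer pairs exist.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .champ_1d import Envelope1D
from .champ_2d import Domain2D, DomainMap2D, ParameterBox
from .partition_core import (
    CoefficientRecord,
    MultilayerNetwork,
    Network,
    Partition,
    canonicalize,
)

__all__ = [
    "read_network",
    "read_multilayer",
    "read_ensemble",
    "write_ensemble",
    "read_coefficients",
    "write_coefficients",
    "write_domains_1d",
    "write_domain_map",
    "read_domain_map",
    "write_manifest",
]

FLOAT_FMT = ".12g"


def _fmt(x: float) -> str:
    return format(float(x), FLOAT_FMT)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def _parse_edge_tsv(path: Path, n_fields: tuple[int, ...]) -> list[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in n_fields:
                raise ValueError(
                    f"{path}:{lineno}: expected {' or '.join(map(str, n_fields))} "
                    f"tab-separated fields, got {len(fields)}"
                )
            rows.append((lineno, fields))
    return rows


def read_network(path: str | Path, format: str | None = None) -> Network:
    """Read a single-layer network from edge-list TSV or GML.

    TSV rows are ``src<TAB>dst[<TAB>weight]`` with weight defaulting to 1.0;
    duplicate listings of an edge are summed.  Format is inferred from the
    extension unless given.
    """
    path = Path(path)
    fmt = format or ("gml" if path.suffix.lower() == ".gml" else "tsv")
    if fmt == "gml":
        import networkx as nx

        g = nx.read_gml(path)
        labels = list(g.nodes())
        index = {lab: i for i, lab in enumerate(labels)}
        edges = [
            (index[u], index[v], float(d.get("weight", 1.0)))
            for u, v, d in g.edges(data=True)
        ]
        if not edges:
            raise ValueError(f"{path}: no edges")
        return Network(len(labels), edges, node_labels=labels)
    if fmt != "tsv":
        raise ValueError(f"unknown network format: {fmt!r}")

    labels: list[str] = []
    index: dict[str, int] = {}

    def node(tok: str) -> int:
        if tok not in index:
            index[tok] = len(labels)
            labels.append(tok)
        return index[tok]

    edges = []
    for lineno, fields in _parse_edge_tsv(path, (2, 3)):
        u, v = node(fields[0]), node(fields[1])
        w = 1.0
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}")
        edges.append((u, v, w))
    if not edges:
        raise ValueError(f"{path}: no edges")
    return Network(len(labels), edges, node_labels=labels)


def read_multilayer(
    intra_path: str | Path,
    inter_path: str | Path,
    nodes_path: str | Path,
    zero_self_loops: bool = False,
) -> MultilayerNetwork:
    """Assemble a multilayer network from its three TSV files.

    ``nodes_path`` rows ``node<TAB>layer`` enumerate the state nodes;
    ``intra_path`` rows ``src<TAB>dst<TAB>weight<TAB>layer`` give intralayer
    edges by node name within a layer; ``inter_path`` rows
    ``src<TAB>dst<TAB>weight`` give interlayer edges with ``name@layer``
    endpoints.  ``zero_self_loops`` drops intralayer self-loops on read (the
    usual preprocessing when diagonal entries encode trivial self-similarity).
    """
    nodes_path, intra_path, inter_path = map(Path, (nodes_path, intra_path, inter_path))
    state_index: dict[tuple[str, str], int] = {}
    labels: list[str] = []
    layer_names: list[str] = []
    layer_index: dict[str, int] = {}
    layer_of: list[int] = []
    for lineno, fields in _parse_edge_tsv(nodes_path, (2,)):
        key = (fields[0], fields[1])
        if key in state_index:
            raise ValueError(f"{nodes_path}:{lineno}: duplicate state node {key}")
        if fields[1] not in layer_index:
            layer_index[fields[1]] = len(layer_names)
            layer_names.append(fields[1])
        state_index[key] = len(labels)
        labels.append(f"{fields[0]}@{fields[1]}")
        layer_of.append(layer_index[fields[1]])

    def state(tok_node: str, tok_layer: str, where: str) -> int:
        key = (tok_node, tok_layer)
        if key not in state_index:
            raise ValueError(f"{where}: unknown state node {tok_node}@{tok_layer}")
        return state_index[key]

    intra = []
    for lineno, fields in _parse_edge_tsv(intra_path, (4,)):
        where = f"{intra_path}:{lineno}"
        u = state(fields[0], fields[3], where)
        v = state(fields[1], fields[3], where)
        if zero_self_loops and u == v:
            continue
        try:
            w = float(fields[2])
        except ValueError:
            raise ValueError(f"{where}: non-numeric weight {fields[2]!r}")
        intra.append((u, v, w))

    inter = []
    for lineno, fields in _parse_edge_tsv(inter_path, (3,)):
        where = f"{inter_path}:{lineno}"
        ends = []
        for tok in fields[:2]:
            if "@" not in tok:
                raise ValueError(f"{where}: interlayer endpoint {tok!r} lacks '@layer'")
            name, _, layer = tok.rpartition("@")
            ends.append(state(name, layer, where))
        try:
            w = float(fields[2])
        except ValueError:
            raise ValueError(f"{where}: non-numeric weight {fields[2]!r}")
        inter.append((ends[0], ends[1], w))

    return MultilayerNetwork(intra, inter, layer_of, node_labels=labels)


# ---------------------------------------------------------------------------
# ensembles and coefficient tables
# ---------------------------------------------------------------------------


def write_ensemble(
    partitions: Sequence[Partition],
    path: str | Path,
    node_labels: Sequence[str] | None = None,
) -> None:
    """Write partitions as CSV: header of node labels, one row per partition."""
    if partitions:
        n = len(partitions[0])
    elif node_labels is not None:
        n = len(node_labels)
    else:
        raise ValueError("cannot write an empty ensemble without node labels")
    cols = [str(c) for c in (node_labels if node_labels is not None else range(n))]
    df = pd.DataFrame(
        [list(p.membership) for p in partitions], columns=cols, dtype="int64"
    )
    df.to_csv(path, index=False)


def read_ensemble(
    path: str | Path, node_labels: Sequence[str] | None = None
) -> list[Partition]:
    """Read an ensemble CSV back into canonical partitions.

    If ``node_labels`` is given the columns are reordered to match it, and
    unknown or missing node columns are an error.
    """
    df = pd.read_csv(path)
    if node_labels is not None:
        want = [str(c) for c in node_labels]
        missing = set(want) - set(df.columns)
        extra = set(df.columns) - set(want)
        if missing or extra:
            raise ValueError(
                f"{path}: ensemble columns do not match network labels "
                f"(missing: {sorted(missing)}, unknown: {sorted(extra)})"
            )
        df = df[want]
    if df.isna().any().any():
        raise ValueError(f"{path}: ensemble contains missing values")
    return [canonicalize(row.tolist()) for _, row in df.iterrows()]


def write_coefficients(records: Sequence[CoefficientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("partition_id,a_hat,p_hat,c_hat,n_communities,n_communities_min5\n")
        for r in records:
            fh.write(
                f"{r.partition_id},{_fmt(r.a_hat)},{_fmt(r.p_hat)},{_fmt(r.c_hat)},"
                f"{r.n_communities_total},{r.n_communities_min5}\n"
            )


def read_coefficients(path: str | Path) -> list[CoefficientRecord]:
    df = pd.read_csv(path)
    required = {"partition_id", "a_hat", "p_hat", "c_hat"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        CoefficientRecord(
            a_hat=float(row.a_hat),
            p_hat=float(row.p_hat),
            c_hat=float(row.c_hat),
            partition_id=int(row.partition_id),
            n_communities_total=int(getattr(row, "n_communities", 0)),
            n_communities_min5=int(getattr(row, "n_communities_min5", 0)),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------


def write_domains_1d(env: Envelope1D, path: str | Path) -> None:
    """Write envelope domains as CSV, interval endpoints exactly as computed."""
    with open(path, "w") as fh:
        fh.write(
            "partition_id,gamma_lo,gamma_hi,a_hat,p_hat,n_communities,n_communities_min5\n"
        )
        for d in env.domains:
            r = d.record
            hi = "inf" if np.isinf(d.gamma_hi) else _fmt(d.gamma_hi)
            fh.write(
                f"{d.partition_id},{_fmt(d.gamma_lo)},{hi},{_fmt(r.a_hat)},"
                f"{_fmt(r.p_hat)},{r.n_communities_total},{r.n_communities_min5}\n"
            )


def write_domain_map(dmap: DomainMap2D, path: str | Path) -> None:
    """Serialize a 2-D domain map (polygons, adjacency, out-of-box ids) to JSON."""
    payload = {
        "box": {
            "gamma_lo": dmap.box.gamma_lo,
            "gamma_hi": dmap.box.gamma_hi,
            "omega_lo": dmap.box.omega_lo,
            "omega_hi": dmap.box.omega_hi,
        },
        "input_count": dmap.input_count,
        "pruned_count": dmap.pruned_count,
        "domains": [
            {
                "partition_id": d.partition_id,
                "vertices": [[float(g), float(o)] for g, o in d.vertices],
                "area": d.area,
                "a_hat": d.record.a_hat,
                "p_hat": d.record.p_hat,
                "c_hat": d.record.c_hat,
                "n_communities": d.record.n_communities_total,
            }
            for d in dmap.domains
        ],
        "out_of_box": list(dmap.out_of_box),
        "adjacency": [
            {"ids": [i, j], "border_length": length}
            for (i, j), length in sorted(dmap.adjacency.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_domain_map(path: str | Path) -> DomainMap2D:
    from shapely.geometry import Polygon

    with open(path) as fh:
        payload = json.load(fh)
    box = ParameterBox(**payload["box"])
    domains = []
    for d in payload["domains"]:
        rec = CoefficientRecord(
            a_hat=d["a_hat"],
            p_hat=d["p_hat"],
            c_hat=d["c_hat"],
            partition_id=d["partition_id"],
            n_communities_total=d.get("n_communities", 0),
        )
        domains.append(Domain2D(d["partition_id"], Polygon(d["vertices"]), rec))
    adjacency = {
        (e["ids"][0], e["ids"][1]): e["border_length"] for e in payload["adjacency"]
    }
    return DomainMap2D(
        domains=domains,
        box=box,
        out_of_box=list(payload.get("out_of_box", [])),
        input_count=payload.get("input_count", len(domains)),
        pruned_count=payload.get("pruned_count", 0),
        adjacency=adjacency,
    )


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    inputs: Sequence[str | Path],
    config: dict,
    seed: int | None = None,
) -> Path:
    """Write a JSON manifest (versions, input checksums, config, seed) beside an output."""
    out_path = Path(out_path)
    manifest = {
        "tool": "champ",
        "version": __version__,
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()
        },
        "config": config,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    mpath = out_path.with_name(out_path.name + ".manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    return mpath
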