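"""File I/O: NIfTI volumes, graph TSV/GraphML, feature CSV, JSON manifests."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from fcgraph.cohort import LabelVolume, SubjectVolume
from fcgraph.connectivity import ConnectivityGraph, EdgeMethodSpec
from fcgraph.parcellation import Parcellation

__all__ = [
    "write_subject_nifti",
    "read_subject_nifti",
    "write_labels_nifti",
    "read_labels_nifti",
    "write_graph_tsv",
    "read_graph_tsv",
    "write_graph_graphml",
    "read_graph_graphml",
    "write_features_csv",
    "read_features_csv",
    "write_parcellation_json",
    "write_cohort_manifest",
]


def write_subject_nifti(subject: SubjectVolume, path: str | Path) -> None:
    """4D NIfTI-1 with the TR stored in the temporal zoom."""
    img = nib.Nifti1Image(subject.data.astype(np.float64), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, subject.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_subject_nifti(
    path: str | Path, subject_id: str, condition: str
) -> SubjectVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return SubjectVolume(
        data=data,
        mask=np.ones(data.shape[:3], dtype=bool),
        tr_seconds=tr,
        subject_id=subject_id,
        condition=condition,
    )


def write_labels_nifti(labels: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int32), affine=np.eye(4))
    nib.save(img, str(path))


def read_labels_nifti(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    lab = np.asarray(img.dataobj).astype(np.int32)
    if lab.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume")
    return LabelVolume(labels=lab, n_regions=int(lab.max()))


def _spec_to_attrs(spec: EdgeMethodSpec | None) -> dict:
    return dataclasses.asdict(spec) if spec is not None else {}


def write_graph_tsv(g: ConnectivityGraph, path: str | Path) -> None:
    """Weighted edge list (node_i, node_j, weight) at full float precision.

    Header comment lines carry the node ids, directedness and method name so
    the graph round-trips losslessly.
    """
    lines = [
        f"# directed\t{g.directed}",
        "# nodes\t" + ",".join(str(i) for i in g.node_ids),
    ]
    if g.method is not None:
        lines.append(f"# method\t{g.method.name}")
    n = g.n_nodes
    for i in range(n):
        for j in range(n):
            if not g.directed and j <= i:
                continue
            if j == i or g.weights[i, j] == 0:
                continue
            lines.append(
                f"{g.node_ids[i]}\t{g.node_ids[j]}\t{float(g.weights[i, j])!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph_tsv(path: str | Path) -> ConnectivityGraph:
    directed = False
    node_ids: list[int] = []
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "directed":
                directed = parts[1] == "True"
            elif parts[0] == "nodes":
                node_ids = [int(t) for t in parts[1].split(",")]
            continue
        try:
            a, b, w = line.split("\t")
            edges.append((int(a), int(b), float(w)))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed edge line {line!r}") from exc
    if not node_ids:
        raise ValueError(f"{path}: missing '# nodes' header")
    index = {nid: i for i, nid in enumerate(node_ids)}
    weights = np.zeros((len(node_ids), len(node_ids)))
    for a, b, w in edges:
        weights[index[a], index[b]] = w
        if not directed:
            weights[index[b], index[a]] = w
    return ConnectivityGraph(weights=weights, directed=directed, node_ids=node_ids)


def write_graph_graphml(g: ConnectivityGraph, path: str | Path) -> None:
    nxg = nx.DiGraph() if g.directed else nx.Graph()
    nxg.add_nodes_from(g.node_ids)
    n = g.n_nodes
    for i in range(n):
        for j in range(n):
            if j == i or g.weights[i, j] == 0 or (not g.directed and j < i):
                continue
            nxg.add_edge(g.node_ids[i], g.node_ids[j], weight=float(g.weights[i, j]))
    for key, val in _spec_to_attrs(g.method).items():
        nxg.graph[key] = val
    nx.write_graphml(nxg, str(path))


def read_graph_graphml(path: str | Path) -> ConnectivityGraph:
    nxg = nx.read_graphml(str(path))
    directed = nxg.is_directed()
    node_ids = [int(v) for v in nxg.nodes]
    index = {v: i for i, v in enumerate(nxg.nodes)}
    weights = np.zeros((len(node_ids), len(node_ids)))
    for a, b, attrs in nxg.edges(data=True):
        weights[index[a], index[b]] = attrs["weight"]
        if not directed:
            weights[index[b], index[a]] = attrs["weight"]
    return ConnectivityGraph(weights=weights, directed=directed, node_ids=node_ids)


def write_features_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_parcellation_json(parc: Parcellation, path: str | Path) -> None:
    """JSON sidecar with per-cluster voxel lists (supports overlapping RGS
    clusters, which a label volume cannot encode)."""
    payload = {
        "method_tag": parc.method_tag,
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "center": list(c.center),
                "voxels": c.voxels.tolist(),
            }
            for c in parc.clusters
        ],
    }
    Path(path).write_text(json.dumps(payload))


def write_cohort_manifest(
    entries: list[dict], path: str | Path
) -> None:
    Path(path).write_text(json.dumps(entries, indent=2))
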