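"""File interfaces: trace tables, onset TSVs, sequence JSONL, matrices,
graphs (edge-list TSV / GraphML), partitions and YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .communities import Dendrogram, Partition
from .connectivity import FunctionalGraph
from .onsets import FluorescenceRecording, OnsetTrain
from .sequences import CoactivationMatrix, FiringSequence

__all__ = [
    "write_traces_csv", "read_traces_csv",
    "write_traces_hdf5", "read_traces_hdf5",
    "write_onsets_tsv", "read_onsets_tsv",
    "write_sequences_jsonl", "read_sequences_jsonl",
    "write_coactivation_csv", "read_coactivation_csv",
    "write_graph_tsv", "write_graph_graphml",
    "write_partition_json", "read_partition_json",
    "write_dendrogram_csv",
    "write_ground_truth_json",
    "load_config", "dump_config",
]


# -- trace tables -----------------------------------------------------------

def write_traces_csv(path, traces: np.ndarray, frame_dt: float) -> None:
    """Column 1 is `time_s`, then one column per cluster `c000`, `c001`, ..."""
    t = np.arange(traces.shape[0]) * frame_dt
    cols = {"time_s": t}
    for i in range(traces.shape[1]):
        cols[f"c{i:03d}"] = traces[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def read_traces_csv(path, **kwargs) -> FluorescenceRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    frame_dt = float(t[1] - t[0]) if len(t) > 1 else 0.02
    roi_cols = [c for c in df.columns if c != "time_s"]
    return FluorescenceRecording(
        traces=df[roi_cols].to_numpy(), frame_dt=frame_dt, roi_ids=roi_cols, **kwargs
    )


def write_traces_hdf5(path, traces: np.ndarray, frame_dt: float) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=traces)
        f.create_dataset("time", data=np.arange(traces.shape[0]) * frame_dt)
        f.attrs["frame_dt"] = frame_dt


def read_traces_hdf5(path, **kwargs) -> FluorescenceRecording:
    with h5py.File(path, "r") as f:
        traces = f["traces"][()]
        frame_dt = float(f.attrs["frame_dt"])
    return FluorescenceRecording(traces=traces, frame_dt=frame_dt, **kwargs)


# -- onsets -----------------------------------------------------------------

def write_onsets_tsv(path, trains: list[OnsetTrain]) -> None:
    with open(path, "w") as f:
        f.write("cluster_id\tonset_time_s\n")
        for train in trains:
            for t in train.onset_times:
                f.write(f"{train.cluster_id}\t{t:.6f}\n")


def read_onsets_tsv(path, cluster_ids: list | None = None) -> list[OnsetTrain]:
    """Read onset trains; ``cluster_ids`` fixes order and includes silent clusters."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str})
    groups = {cid: g["onset_time_s"].to_numpy() for cid, g in df.groupby("cluster_id")}
    if cluster_ids is None:
        cluster_ids = sorted(groups)
    return [
        OnsetTrain(cid, np.sort(groups.get(str(cid), np.empty(0))))
        for cid in cluster_ids
    ]


# -- sequences and coactivation matrix -------------------------------------

def write_sequences_jsonl(path, sequences: list[FiringSequence]) -> None:
    with open(path, "w") as f:
        for j, seq in enumerate(sequences):
            rec = {
                "seq": j,
                "members": [str(m) for m in seq.members],
                "times": [float(t) for t in seq.times],
            }
            f.write(json.dumps(rec) + "\n")


def read_sequences_jsonl(path) -> list[FiringSequence]:
    out = []
    with open(path) as f:
        for line in f:
            rec = json.loads(line)
            out.append(FiringSequence(rec["members"], np.asarray(rec["times"])))
    return out


def write_coactivation_csv(path, X: CoactivationMatrix) -> None:
    df = pd.DataFrame(
        X.X,
        index=[str(c) for c in X.cluster_ids],
        columns=[f"seq{j}" for j in range(X.n_sequences)],
    )
    df.to_csv(path, index_label="cluster_id")


def read_coactivation_csv(path) -> CoactivationMatrix:
    df = pd.read_csv(path, index_col="cluster_id")
    return CoactivationMatrix(df.to_numpy(dtype=np.uint8), list(df.index))


# -- functional graphs ------------------------------------------------------

def write_graph_tsv(path, graph: FunctionalGraph) -> None:
    """Weighted edge list: src, dst, raw weight, z-score, significance flag."""
    ids = graph.cluster_ids or tuple(range(graph.n_clusters))
    sig = graph.sig_mask if graph.sig_mask is not None else np.zeros_like(graph.w, bool)
    with open(path, "w") as f:
        f.write("src\tdst\tw\tW\tsig\n")
        for i in range(graph.n_clusters):
            for j in range(graph.n_clusters):
                if i != j and (graph.w[i, j] > 0 or sig[i, j]):
                    f.write(
                        f"{ids[i]}\t{ids[j]}\t{graph.w[i, j]:.6g}\t"
                        f"{graph.W[i, j]:.6g}\t{int(sig[i, j])}\n"
                    )


def write_graph_graphml(path, graph: FunctionalGraph) -> None:
    ids = graph.cluster_ids or tuple(range(graph.n_clusters))
    sig = graph.sig_mask if graph.sig_mask is not None else np.zeros_like(graph.w, bool)
    G = nx.DiGraph()
    G.add_nodes_from(str(c) for c in ids)
    for i in range(graph.n_clusters):
        for j in range(graph.n_clusters):
            if i != j and (graph.w[i, j] > 0 or sig[i, j]):
                G.add_edge(
                    str(ids[i]), str(ids[j]),
                    w=float(graph.w[i, j]), W=float(graph.W[i, j]),
                    sig=bool(sig[i, j]),
                )
    nx.write_graphml(G, path)


# -- partitions and dendrograms --------------------------------------------

def write_partition_json(path, partition: Partition) -> None:
    payload = {
        "labels": [int(x) for x in partition.labels],
        "d_th": partition.d,
        "n_moduli": partition.n_moduli,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_partition_json(path) -> Partition:
    payload = json.loads(Path(path).read_text())
    return Partition(labels=np.asarray(payload["labels"]), d=payload.get("d_th"))


def write_dendrogram_csv(path, dendrogram: Dendrogram) -> None:
    """Merge table: node, child1, child2, height (leaves are 0..N-1)."""
    n = dendrogram.n_leaves
    rows = [
        {"node": n + k, "child1": int(row[0]), "child2": int(row[1]), "height": row[2]}
        for k, row in enumerate(dendrogram.linkage)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ground_truth_json(path, onsets: list[np.ndarray], partition: np.ndarray) -> None:
    payload = {
        "onsets": {str(i): [float(t) for t in train] for i, train in enumerate(onsets)},
        "partition": [int(x) for x in partition],
    }
    Path(path).write_text(json.dumps(payload))


# -- configs ----------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_config(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)
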