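"""Firing-sequence detection and the coactivation matrix.

A firing sequence is the concatenated activation of two or more clusters:
onsets chain together while the gap to the previous onset does not exceed
the window (200 ms by default), and the same window acts as the cut-off
separating two sequences.  Clusters that fire in isolation are excluded by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .onsets import OnsetTrain

__all__ = [
    "FiringSequence",
    "CoactivationMatrix",
    "detect_sequences",
    "coactivation_matrix",
]


@dataclass
class FiringSequence:
    """One collective event: participating clusters and their onset times.

    ``members`` are in activation order; a cluster appearing several times
    inside one chain is counted once, at its first activation.
    """

    members: list
    times: np.ndarray  # seconds, one per member, non-decreasing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.members) != self.times.size:
            raise ValueError("one activation time per member required")
        if len(self.members) < 2:
            raise ValueError("a firing sequence needs >= 2 distinct clusters")

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CoactivationMatrix:
    """Binary N clusters x M sequences participation matrix.

    Row i is the *activity history* of cluster i across all sequences; the
    row of a cluster that never joined a sequence is all zeros.
    """

    X: np.ndarray          # (N, M) uint8
    cluster_ids: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("X must be binary")
        if len(self.cluster_ids) != self.X.shape[0]:
            raise ValueError("one row per cluster id required")

    @property
    def n_clusters(self) -> int:
        return self.X.shape[0]

    @property
    def n_sequences(self) -> int:
        return self.X.shape[1]


def detect_sequences(
    onset_trains: list[OnsetTrain], window: float = 0.2
) -> list[FiringSequence]:
    """Chain pooled onsets into firing sequences.

    All onsets are pooled and sorted; a chain grows while the gap to the
    *previous* onset is <= ``window`` seconds.  Chains involving >= 2
    distinct clusters become sequences; single-cluster chains are dropped.
    The result does not depend on the order in which trains are supplied
    (ties in time are broken by cluster id for determinism).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    ids: list = []
    times: list = []
    for train in onset_trains:
        ids.extend([train.cluster_id] * len(train))
        times.extend(train.onset_times.tolist())
    if not times:
        return []
    order = sorted(range(len(times)), key=lambda i: (times[i], repr(ids[i])))
    t = np.asarray([times[i] for i in order])
    ids_sorted = [ids[i] for i in order]

    sequences: list[FiringSequence] = []
    chain_start = 0
    breaks = list(np.flatnonzero(np.diff(t) > window) + 1) + [t.size]
    for stop in breaks:
        chunk_ids = ids_sorted[chain_start:stop]
        chunk_t = t[chain_start:stop]
        chain_start = stop
        seen: dict = {}
        for cid, ti in zip(chunk_ids, chunk_t):
            if cid not in seen:
                seen[cid] = float(ti)
        if len(seen) >= 2:
            members = list(seen.keys())
            sequences.append(FiringSequence(members, np.array([seen[m] for m in members])))
    return sequences


def coactivation_matrix(
    sequences: list[FiringSequence], cluster_ids: list
) -> CoactivationMatrix:
    """Build the binary N x M coactivation matrix X from a sequence set."""
    index = {cid: i for i, cid in enumerate(cluster_ids)}
    X = np.zeros((len(cluster_ids), len(sequences)), dtype=np.uint8)
    for j, seq in enumerate(sequences):
        for cid in seq.members:
            if cid not in index:
                raise ValueError(f"sequence member {cid!r} not in cluster_ids")
            X[index[cid], j] = 1
    return CoactivationMatrix(X, list(cluster_ids))
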