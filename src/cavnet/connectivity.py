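"""Directed weighted functional connectivity from firing-sequence delays.

Within every firing sequence, each ordered pair of participating clusters
(earlier -> later activation) contributes a weight that decays
exponentially with the activation delay, ``exp(-dt / tau)``; simultaneous
activations contribute 1 in both directions.  Raw weights ``w_ij`` are the
sum over all sequences.  Significance and cross-condition comparability
come from a firings-preserving null model: the binary cluster-by-sequence
participation structure is randomized by margin-preserving (curveball)
trades, which keep both each cluster's number of firings and each
sequence's size while destroying which clusters fire *together*; within-
sequence delays are redrawn from the pooled observed offsets.  The
z-score ``W_ij = (w_ij - <w_surr>) / sd(w_surr)`` normalizes each link
against this null.

Preserving the sequence sizes alongside the per-cluster firing counts is
what makes the null calibrated: chains are by construction conditioned on
containing at least two clusters, so a null that scatters participations
over slots independently (e.g. per-row shifts) systematically inflates
surrogate co-occurrence and biases every z-score negative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sequences import FiringSequence

__all__ = [
    "FunctionalGraph",
    "WeightDifference",
    "infer_functional_graph",
    "significant_links",
    "weight_differences",
]


@dataclass(frozen=True)
class FunctionalGraph:
    """Directed weighted functional graph over the cavity's clusters."""

    w: np.ndarray                    # (N, N) raw weights, >= 0, zero diagonal
    W: np.ndarray                    # (N, N) z-scores vs the surrogate null
    n_surrogates: int
    sig_mask: np.ndarray | None = None   # boolean, set by significant_links
    z_threshold: float | None = None
    cluster_ids: tuple | None = None

    @property
    def n_clusters(self) -> int:
        return self.w.shape[0]

    def significant_weights(self) -> np.ndarray:
        """Z-scored weights with non-significant links zeroed."""
        if self.sig_mask is None:
            raise ValueError("call significant_links() first")
        return np.where(self.sig_mask, self.W, 0.0)


@dataclass(frozen=True)
class WeightDifference:
    """After-minus-before difference of significant z-scored weights."""

    wd: np.ndarray           # (N, N); zero outside the union of significant links
    union_mask: np.ndarray   # boolean union of the two significance masks
    gamma_wd: float          # sample skewness of wd over the union links
    median_wd: float         # median of wd over the union links


def _pair_weight_matrix(
    cluster_idx: np.ndarray,
    slot: np.ndarray,
    times: np.ndarray,
    n_clusters: int,
    tau: float,
) -> np.ndarray:
    """Accumulate delay-kernel weights for all within-slot ordered pairs.

    ``cluster_idx``, ``slot`` and ``times`` describe the active cells of one
    (real or surrogate) sequence set: cluster ``cluster_idx[a]`` activates
    at ``times[a]`` inside sequence ``slot[a]``.  Fully vectorized: pairs
    within each slot are enumerated via local-position arithmetic.
    """
    w = np.zeros((n_clusters, n_clusters))
    if cluster_idx.size < 2:
        return w
    order = np.lexsort((cluster_idx, times, slot))
    c = cluster_idx[order]
    s = slot[order]
    t = times[order]

    new_group = np.r_[True, s[1:] != s[:-1]]
    group_start = np.maximum.accumulate(np.where(new_group, np.arange(s.size), 0))
    local = np.arange(s.size) - group_start          # position inside the slot
    n_pairs = int(local.sum())
    if n_pairs == 0:
        return w
    # element a at local position p pairs with its p predecessors in the slot
    idx_j = np.repeat(np.arange(s.size), local)
    offset = np.arange(n_pairs) - np.repeat(np.cumsum(local) - local, local)
    idx_i = idx_j - 1 - offset                        # earlier element of the pair

    dt = t[idx_j] - t[idx_i]
    ci, cj = c[idx_i], c[idx_j]
    distinct = ci != cj
    val = np.exp(-dt / tau)
    np.add.at(w, (ci[distinct], cj[distinct]), val[distinct])
    ties = distinct & (dt == 0.0)
    if ties.any():
        np.add.at(w, (cj[ties], ci[ties]), 1.0)
    return w


def _sequence_cells(
    sequences: list[FiringSequence], index: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a sequence set into (cluster_idx, slot, time) active cells."""
    cluster_idx, slot, times = [], [], []
    for j, seq in enumerate(sequences):
        for cid, t in zip(seq.members, seq.times):
            cluster_idx.append(index[cid])
            slot.append(j)
            times.append(t)
    return (
        np.asarray(cluster_idx, dtype=np.intp),
        np.asarray(slot, dtype=np.intp),
        np.asarray(times, dtype=float),
    )


def infer_functional_graph(
    sequences: list[FiringSequence],
    n_clusters: int,
    tau: float = 0.2,
    n_surrogates: int = 500,
    seed: int = 0,
    *,
    cluster_ids: list | None = None,
) -> FunctionalGraph:
    """Build the raw and z-scored functional graph from a sequence set.

    ``cluster_ids`` fixes the node order; by default members must be
    integers in ``range(n_clusters)``.  Deterministic for a fixed seed.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    if cluster_ids is None:
        cluster_ids = list(range(n_clusters))
    if len(cluster_ids) != n_clusters:
        raise ValueError("cluster_ids length must equal n_clusters")
    index = {cid: i for i, cid in enumerate(cluster_ids)}
    for seq in sequences:
        for cid in seq.members:
            if cid not in index:
                raise ValueError(f"sequence member {cid!r} outside the declared clusters")

    cells_c, cells_s, cells_t = _sequence_cells(sequences, index)
    w = _pair_weight_matrix(cells_c, cells_s, cells_t, n_clusters, tau)

    M = len(sequences)
    W = np.zeros_like(w)
    if M >= 2 and cells_c.size:
        starts = np.array([seq.start for seq in sequences])
        offsets = cells_t - starts[cells_s]          # pooled within-sequence delays
        rng = np.random.default_rng(seed)

        # participation sets per cluster; curveball trades randomize which
        # clusters co-occur while fixing both matrix margins
        row_slots: list[set] = [set() for _ in range(n_clusters)]
        for ci, si in zip(cells_c, cells_s):
            row_slots[ci].add(int(si))
        active_rows = [i for i in range(n_clusters) if row_slots[i]]
        n_cells = cells_c.size

        def trade_sweep(n_trades: int) -> None:
            if len(active_rows) < 2:
                return
            pairs = rng.integers(0, len(active_rows), size=(n_trades, 2))
            for a_i, b_i in pairs:
                if a_i == b_i:
                    continue
                a, b = active_rows[a_i], active_rows[b_i]
                sa, sb = row_slots[a], row_slots[b]
                shared = sa & sb
                a_only = sorted(sa - shared)
                b_only = sorted(sb - shared)
                if not a_only or not b_only:
                    continue
                pool = a_only + b_only
                take = rng.permutation(len(pool))[: len(a_only)]
                new_a = set(pool[k] for k in take)
                row_slots[a] = shared | new_a
                row_slots[b] = shared | (set(pool) - new_a)

        # observed within-sequence offsets grouped by slot; surrogates keep
        # each slot's offset multiset (column sums are preserved) and only
        # permute which cluster receives which delay
        obs_order = np.argsort(cells_s, kind="stable")
        off_by_slot = offsets[obs_order]

        sweep = 2 * max(len(active_rows), 1)
        trade_sweep(5 * sweep)  # burn-in from the observed matrix
        acc = np.zeros_like(w)
        acc2 = np.zeros_like(w)
        surr_c = np.empty(n_cells, dtype=np.intp)
        surr_s = np.empty(n_cells, dtype=np.intp)
        for _ in range(n_surrogates):
            trade_sweep(sweep)
            pos = 0
            for i in active_rows:
                slots = row_slots[i]
                k = len(slots)
                surr_c[pos : pos + k] = i
                surr_s[pos : pos + k] = sorted(slots)
                pos += k
            order = np.argsort(surr_s, kind="stable")
            sc, ss = surr_c[order], surr_s[order]
            perm = np.lexsort((rng.random(n_cells), ss))
            surr_t = np.empty(n_cells)
            surr_t[perm] = off_by_slot
            ws = _pair_weight_matrix(sc, ss, surr_t, n_clusters, tau)
            acc += ws
            acc2 += ws * ws
        mean = acc / n_surrogates
        var = (acc2 - n_surrogates * mean * mean) / (n_surrogates - 1)
        sd = np.sqrt(np.maximum(var, 0.0))
        nz = sd > 0
        W[nz] = (w[nz] - mean[nz]) / sd[nz]
    np.fill_diagonal(W, 0.0)
    return FunctionalGraph(
        w=w, W=W, n_surrogates=n_surrogates, cluster_ids=tuple(cluster_ids)
    )


def significant_links(graph: FunctionalGraph, z_threshold: float = 1.95) -> FunctionalGraph:
    """Keep links whose z-score exceeds the threshold (the ~95% one-sided
    confidence bound at the default 1.95); negative and sub-threshold
    links are disregarded."""
    mask = graph.W > z_threshold
    np.fill_diagonal(mask, False)
    return dataclasses.replace(graph, sig_mask=mask, z_threshold=z_threshold)


def weight_differences(after: FunctionalGraph, before: FunctionalGraph) -> WeightDifference:
    """Difference of z-scored weights over the union of significant links.

    Links significant in neither condition contribute nothing; a link
    present only in one condition counts the other side as zero.
    """
    if after.w.shape != before.w.shape:
        raise ValueError("graphs cover different cluster sets")
    if after.cluster_ids != before.cluster_ids:
        raise ValueError("graphs cover different cluster sets")
    if after.sig_mask is None or before.sig_mask is None:
        raise ValueError("call significant_links() on both graphs first")
    union = after.sig_mask | before.sig_mask
    wd = np.where(union, after.W - before.W, 0.0)
    vals = wd[union]
    if vals.size >= 3 and np.std(vals) > 0:
        gamma = float(stats.skew(vals, bias=False))
    else:
        gamma = 0.0
    median = float(np.median(vals)) if vals.size else 0.0
    return WeightDifference(wd=wd, union_mask=union, gamma_wd=gamma, median_wd=median)
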