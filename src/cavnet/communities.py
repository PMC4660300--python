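"""Community structure from activity-history similarity.

Clusters that repeatedly fire in the same sequences have similar rows in
the coactivation matrix X.  Pairwise Jaccard similarity of those rows,
normalized against row-shuffling surrogates (which preserve each cluster's
number of firings), gives a distance matrix whose average-linkage
dendrogram exposes the community organization.  The cut threshold is
selected by a Variation-of-Information scan: the partition after the
largest mean-VI jump that still leaves at least two communities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .sequences import CoactivationMatrix

__all__ = [
    "SimilarityMatrices",
    "Dendrogram",
    "Partition",
    "ThresholdScan",
    "jaccard_similarity",
    "normalized_jaccard_distance",
    "build_dendrogram",
    "cut_dendrogram",
    "variation_of_information",
    "select_threshold",
    "compare_partitions",
]


@dataclass
class SimilarityMatrices:
    """Jaccard similarity/distance and their surrogate-normalized versions."""

    J_S: np.ndarray             # (N, N) Jaccard similarity in [0, 1]
    J_D: np.ndarray             # 1 - J_S
    Z: np.ndarray | None = None       # z-scores vs row-shuffled surrogates
    D_norm: np.ndarray | None = None  # normalized distance in [0, 1]


@dataclass
class Dendrogram:
    """Average-linkage merge tree over the clusters."""

    linkage: np.ndarray     # scipy linkage matrix
    leaf_order: np.ndarray  # display ordering of the leaves

    @property
    def n_leaves(self) -> int:
        return self.linkage.shape[0] + 1

    @property
    def max_height(self) -> float:
        return float(self.linkage[-1, 2]) if self.linkage.size else 0.0


@dataclass
class Partition:
    """Community labels per cluster, from cutting the dendrogram at ``d``."""

    labels: np.ndarray      # (N,) integers 1..n_moduli
    d: float | None = None  # cut threshold that produced the partition

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def n_moduli(self) -> int:
        return len(np.unique(self.labels))

    @property
    def n_elements(self) -> int:
        return self.labels.size


@dataclass
class ThresholdScan:
    """MVI scan over cut thresholds (step 0.01 by default)."""

    thresholds: np.ndarray   # strictly increasing
    n_moduli: np.ndarray     # communities at each threshold
    MVI: np.ndarray          # mean VI of each partition vs all others
    dMVI: np.ndarray         # MVI(d_i) - MVI(d_{i-1}); dMVI[0] = 0
    d_th: float              # selected threshold


def jaccard_similarity(X: CoactivationMatrix | np.ndarray) -> SimilarityMatrices:
    """Pairwise Jaccard similarity of the activity-history rows.

    J(A, B) = |A and B| / |A or B|: concurrent activations relative to all
    occurrences where at least one of the two clusters fired.  Pairs with
    an empty union (two silent clusters) score 0.
    """
    rows = X.X if isinstance(X, CoactivationMatrix) else np.asarray(X)
    rows = rows.astype(np.int64)
    inter = rows @ rows.T
    counts = rows.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return SimilarityMatrices(J_S=J, J_D=1.0 - J)


def normalized_jaccard_distance(
    X: CoactivationMatrix | np.ndarray,
    n_surrogates: int = 500,
    seed: int = 0,
) -> SimilarityMatrices:
    """Surrogate-normalized Jaccard distance.

    Each surrogate independently permutes the entries within every row of X
    (preserving each cluster's number of firings) and yields a Jaccard
    distance matrix S.  The z-score ``Z = (<S> - D) / sd(S)`` is positive
    for pairs more similar than chance and maps to a bounded distance
    ``D_norm = 1 - CDF_N(0,1)(Z)``, so strongly coupled pairs sit near 0.
    Pairs with zero surrogate spread get the non-informative 0.5; silent
    clusters are forced to distance 1 from everything (they end up as
    singleton leaves).  The diagonal is 0.
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    rows = (X.X if isinstance(X, CoactivationMatrix) else np.asarray(X)).astype(np.int64)
    n, m = rows.shape
    base = jaccard_similarity(rows)
    D = base.J_D
    rng = np.random.default_rng(seed)

    counts = rows.sum(axis=1)
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    for _ in range(n_surrogates):
        # independent permutation of each row via random-key argsort
        keys = rng.random((n, m)).argsort(axis=1)
        shuffled = np.take_along_axis(rows, keys, axis=1)
        inter = shuffled @ shuffled.T
        union = counts[:, None] + counts[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            S = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        acc += S
        acc2 += S * S
    mean = acc / n_surrogates
    var = (acc2 - n_surrogates * mean * mean) / (n_surrogates - 1)
    sd = np.sqrt(np.maximum(var, 0.0))

    Z = np.zeros((n, n))
    nz = sd > 0
    Z[nz] = (mean[nz] - D[nz]) / sd[nz]
    D_norm = np.where(nz, 1.0 - norm.cdf(Z), 0.5)
    silent = counts == 0
    D_norm[silent, :] = 1.0
    D_norm[:, silent] = 1.0
    np.fill_diagonal(D_norm, 0.0)
    np.fill_diagonal(Z, 0.0)
    return SimilarityMatrices(J_S=base.J_S, J_D=base.J_D, Z=Z, D_norm=D_norm)


def build_dendrogram(D: np.ndarray) -> Dendrogram:
    """Average-linkage tree on a symmetric zero-diagonal distance matrix."""
    D = np.asarray(D, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("D must be symmetric with a zero diagonal")
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    leaf_order = np.asarray(hierarchy.leaves_list(Z))
    return Dendrogram(linkage=Z, leaf_order=leaf_order)


def _canonical(labels: np.ndarray, leaf_order: np.ndarray | None = None) -> np.ndarray:
    """Relabel communities 1..k in order of first appearance (leaf order if given)."""
    labels = np.asarray(labels)
    scan = labels[leaf_order] if leaf_order is not None else labels
    mapping: dict = {}
    for lab in scan:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[lab] for lab in labels])


def cut_dendrogram(dendrogram: Dendrogram, d: float) -> Partition:
    """Flat partition: clusters merged at height <= d share a community."""
    if d < 0:
        raise ValueError("threshold must be non-negative")
    # absolute tolerance so merges at exactly d are included despite
    # float accumulation in the linkage update
    raw = hierarchy.fcluster(dendrogram.linkage, t=d + 1e-9, criterion="distance")
    return Partition(labels=_canonical(raw, dendrogram.leaf_order), d=float(d))


def _labels_of(p) -> np.ndarray:
    return p.labels if isinstance(p, Partition) else np.asarray(p)


def variation_of_information(p1, p2) -> float:
    """VI(X, Y) = H(X|Y) + H(Y|X) in bits; 0 iff the partitions coincide
    up to relabeling.  Computed from the label contingency table."""
    x = _labels_of(p1)
    y = _labels_of(p2)
    if x.size != y.size:
        raise ValueError("partitions cover different numbers of elements")
    n = x.size
    if n == 0:
        raise ValueError("empty partitions")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(table, (xi, yi), 1.0)
    pxy = table / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    # VI = -sum p(x,y) [log p(x,y)/p(y) + log p(x,y)/p(x)]
    vi = -np.sum(pxy[nz] * (np.log2(pxy[nz] / np.broadcast_to(py, pxy.shape)[nz])
                            + np.log2(pxy[nz] / np.broadcast_to(px, pxy.shape)[nz])))
    return float(vi) if vi > 0 else 0.0


def select_threshold(
    dendrogram: Dendrogram, step: float = 0.01
) -> tuple[ThresholdScan, Partition]:
    """Scan cut thresholds and pick the most representative non-trivial partition.

    Thresholds run from 0 to just past the top merge in steps of ``step``.
    MVI_i is the mean VI between the partition at d_i and the partitions at
    every other threshold; jumps in its difference series dMVI delimit the
    basins where the community structure is stable.  The selected d_th
    minimizes MVI among partitions with at least two communities (the
    minimum yet significant structure, never the trivial single-community
    case), with ties broken toward the largest threshold.  Minimizing MVI
    is what makes the selection robust when the normalized distance
    saturates and a spurious one-or-two-step plateau appears just below
    the top merge: such ephemeral partitions have high mean VI even though
    the jump flanking them is large.
    """
    if dendrogram.n_leaves < 2:
        raise ValueError("dendrogram is trivial")
    top = dendrogram.max_height
    n_steps = int(np.ceil(top / step)) + 1 if top > 0 else 1
    # round away float accumulation so decimal grid points hit merge heights
    thresholds = np.round(np.arange(n_steps + 1) * step, 12)
    partitions = [cut_dendrogram(dendrogram, d) for d in thresholds]
    n_moduli = np.array([p.n_moduli for p in partitions])
    if np.all(n_moduli == 1):
        raise ValueError("all partitions are trivial")

    T = len(partitions)
    vi = np.zeros((T, T))
    # identical label vectors collapse to one VI evaluation per pair of plateaus
    keys = [tuple(p.labels.tolist()) for p in partitions]
    cache: dict = {}
    for i in range(T):
        for j in range(i + 1, T):
            key = (keys[i], keys[j]) if keys[i] <= keys[j] else (keys[j], keys[i])
            if key not in cache:
                cache[key] = variation_of_information(partitions[i], partitions[j])
            vi[i, j] = vi[j, i] = cache[key]
    MVI = vi.sum(axis=1) / (T - 1)
    dMVI = np.r_[0.0, np.diff(MVI)]

    eligible = np.flatnonzero(n_moduli >= 2)
    scores = MVI[eligible]
    # argmin over eligible, ties toward the largest threshold
    best = eligible[np.flatnonzero(scores == scores.min())[-1]]
    scan = ThresholdScan(
        thresholds=thresholds,
        n_moduli=n_moduli,
        MVI=MVI,
        dMVI=dMVI,
        d_th=float(thresholds[best]),
    )
    return scan, partitions[best]


def compare_partitions(before: Partition, after: Partition) -> dict:
    """Before/after community change report.

    Maps every before-community to the after-communities its members end
    up in, and counts splits (one before-community feeding >= 2
    after-communities) and merges (one after-community fed by >= 2).
    """
    b = _labels_of(before)
    a = _labels_of(after)
    if b.size != a.size:
        raise ValueError("partitions cover different cluster sets")
    mapping: dict = {}
    for lab in np.unique(b):
        targets, counts = np.unique(a[b == lab], return_counts=True)
        mapping[int(lab)] = {int(t): int(c) for t, c in zip(targets, counts)}
    splits = sum(1 for tgt in mapping.values() if len(tgt) > 1)
    sources: dict = {}
    for src, tgt in mapping.items():
        for t in tgt:
            sources.setdefault(t, set()).add(src)
    merges = sum(1 for s in sources.values() if len(s) > 1)
    return {
        "n_moduli_before": int(len(np.unique(b))),
        "n_moduli_after": int(len(np.unique(a))),
        "vi_bits": variation_of_information(b, a),
        "mapping": mapping,
        "n_splits": splits,
        "n_merges": merges,
    }
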