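"""Synthetic clustered-culture activity generator.

Clustered neuronal cultures grown in mm-sized cavities self-organize into
~30-40 neuronal aggregates ("clusters") that fire collectively: a community
of clusters ignites every few seconds and its members activate within
~100 ms of one another, while a small background of independent firings is
always present.  This module generates ground-truth networks with that
statistical structure, simulates their onset trains, renders fluorescence
traces with a calcium-indicator kernel, and applies perturbations that
emulate chemical damage (cluster silencing, weakening of inter-community
coupling, rare activity boosting).

The model is deliberately phenomenological.  Community ignitions are a
homogeneous Poisson (renewal) process; the nominal per-community rate is
modulated by the community's *excitability* - its per-member excitatory
drive (own-member participation plus the cross-participation of bridging
clusters) relative to the drive at construction time.  An unperturbed
network therefore ignites exactly at ``ignition_rate``, while silencing
members or weakening cross-community coupling lowers both the ignition
rate and, downstream, the sequence occurrence rate - the behaviour
observed in chemically perturbed cultures.

Cross-community coupling is carried by *bridge* clusters: each cluster's
cross-participation is aimed at its spatially nearest foreign community,
and a minority of clusters participate strongly there.  Concentrated
bridging (rather than diffuse, independent cross-joining) is what gives
rise to statistically significant inter-community functional links, as
seen in cultured networks where some clusters take part in several
communities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroundTruthNetwork",
    "PerturbationSpec",
    "CalciumKernel",
    "SequenceEvent",
    "SimulatedRecording",
    "generate_network",
    "simulate_activity",
    "render_traces",
    "apply_perturbation",
]

#: default cavity radius (mm); cavities are 3.5 mm in diameter
CAVITY_RADIUS_MM = 1.75


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A planted modular network of neuronal clusters.

    Rates are per minute; ``delay_scale`` is in seconds.  ``participation``
    is each cluster's probability of joining its own community's ignition
    events.  ``cross_participation`` is its probability of joining events
    of ONE specific foreign community, ``bridge_target`` (its spatially
    nearest neighbour); most clusters have a small spillover probability
    while a minority of *bridge* clusters participate strongly in their
    target community, which is what produces inter-community functional
    links in cultured networks.  ``nominal_drive`` stores each community's
    total excitatory drive at construction time and defines the reference
    against which perturbed networks are scaled.
    """

    positions: np.ndarray            # (n, 2) mm
    community_of: np.ndarray         # (n,) int labels 0..k-1
    ignition_rate: np.ndarray        # (k,) events/min, nominal
    participation: np.ndarray        # (n,) in [0, 1]
    cross_participation: np.ndarray  # (n,) in [0, 1]
    bridge_target: np.ndarray        # (n,) community index, -1 for none
    independent_rate: np.ndarray     # (n,) firings/min
    delay_scale: float               # s
    nominal_drive: np.ndarray        # (k,) drive at construction

    def __post_init__(self) -> None:
        for name in ("participation", "cross_participation"):
            p = getattr(self, name)
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.ignition_rate < 0) or np.any(self.independent_rate < 0):
            raise ValueError("rates must be non-negative")
        if len(np.unique(self.community_of)) != self.n_communities:
            raise ValueError("community labels must be contiguous 0..k-1")

    @property
    def n_clusters(self) -> int:
        return len(self.community_of)

    @property
    def n_communities(self) -> int:
        return int(self.community_of.max()) + 1

    def members(self, community: int) -> np.ndarray:
        return np.flatnonzero(self.community_of == community)

    def drive(self, community: int) -> float:
        """Total excitatory drive of a community: the summed own-member
        participation plus the summed cross-participation of the clusters
        bridging into it, per member."""
        inside = self.community_of == community
        total = float(self.participation[inside].sum())
        targeting = (self.bridge_target == community) & ~inside
        total += float(self.cross_participation[targeting].sum())
        return total / max(int(inside.sum()), 1)

    def excitability(self, community: int) -> float:
        """Drive relative to the nominal construction-time drive.

        Equals 1.0 for an unperturbed network; silencing members or
        weakening cross-community coupling lowers it, and with it the
        realized ignition rate.
        """
        nominal = float(self.nominal_drive[community])
        return self.drive(community) / nominal if nominal > 0 else 0.0


@dataclass(frozen=True)
class PerturbationSpec:
    """Chemical-perturbation knobs applied to a ground-truth network."""

    silenced_fraction: float = 0.0
    weaken_factor: float = 1.0          # multiplier on cross-community participation
    within_weaken_factor: float = 1.0   # multiplier on own-community participation
    boosted_fraction: float = 0.0
    boost_factor: float = 1.0           # multiplier on independent rate of boosted clusters

    def __post_init__(self) -> None:
        for name in ("silenced_fraction", "boosted_fraction"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("weaken_factor", "within_weaken_factor", "boost_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (
            self.silenced_fraction == 0.0
            and self.boosted_fraction == 0.0
            and self.weaken_factor == 1.0
            and self.within_weaken_factor == 1.0
        )


@dataclass(frozen=True)
class CalciumKernel:
    """Fluorescence transient: linear rise then exponential decay.

    Defaults approximate Fluo-4 kinetics on a cluster ROI.
    """

    rise_ms: float = 50.0
    decay_ms: float = 1000.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.decay_ms > self.rise_ms > 0:
            raise ValueError("require decay_ms > rise_ms > 0")


@dataclass
class SequenceEvent:
    """Ground-truth ignition event: which clusters joined, and when."""

    time: float
    community: int
    members: np.ndarray        # cluster indices, activation order
    onset_times: np.ndarray    # absolute seconds, sorted


@dataclass
class SimulatedRecording:
    """Rendered fluorescence movie at the ROI level, plus its ground truth."""

    traces: np.ndarray                     # (T, n) fluorescence, a.u.
    frame_dt: float                        # s
    true_onsets: list[np.ndarray]          # per-cluster sorted onset times (s)
    true_partition: np.ndarray             # (n,) community labels
    events: list[SequenceEvent] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.traces.shape[0] * self.frame_dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.traces.shape[0]) * self.frame_dt


def generate_network(
    n_clusters: int,
    n_communities: int,
    seed: int,
    *,
    cavity_radius_mm: float = CAVITY_RADIUS_MM,
    ignition_rate: float = 2.4,
    participation: float = 0.6,
    cross_participation: float = 0.02,
    bridge_fraction: float = 0.2,
    bridge_participation: float = 0.5,
    independent_rate: float = 0.1,
    delay_scale: float = 0.030,
) -> GroundTruthNetwork:
    """Place clusters in a cavity and assign spatially contiguous communities.

    Positions are uniform over a disc of radius ``cavity_radius_mm``.
    Communities are angular sectors about the centroid, so that members are
    spatially contiguous and community sizes are balanced to within one
    cluster.  Every cluster's cross-participation is directed at its
    spatially nearest foreign community; a ``bridge_fraction`` of clusters
    are bridges with cross-participation ``bridge_participation`` (the rest
    get the small spillover ``cross_participation``).  Deterministic for a
    fixed ``seed``.

    The rate defaults place a 3-community, ~36-cluster cavity in the regime
    observed in clustered cultures: 1-2 firings/min per cluster on average,
    ignition events separated by a few seconds, and a minority of
    inter-community functional links carried by the bridges.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if not 1 <= n_communities <= n_clusters:
        raise ValueError("need 1 <= n_communities <= n_clusters")
    rng = np.random.default_rng(seed)
    # uniform over the disc via sqrt-radius sampling
    r = cavity_radius_mm * np.sqrt(rng.uniform(size=n_clusters))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_clusters)
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    centroid = positions.mean(axis=0)
    angles = np.arctan2(positions[:, 1] - centroid[1], positions[:, 0] - centroid[0])
    order = np.argsort(angles, kind="stable")
    sizes = np.full(n_communities, n_clusters // n_communities)
    sizes[: n_clusters % n_communities] += 1
    community_of = np.empty(n_clusters, dtype=np.int64)
    start = 0
    for label, size in enumerate(sizes):
        community_of[order[start : start + size]] = label
        start += size

    # cross-participation is aimed at the nearest foreign community
    bridge_target = np.full(n_clusters, -1, dtype=np.int64)
    if n_communities > 1:
        centroids = np.array(
            [positions[community_of == c].mean(axis=0) for c in range(n_communities)]
        )
        for i in range(n_clusters):
            d = np.linalg.norm(centroids - positions[i], axis=1)
            d[community_of[i]] = np.inf
            bridge_target[i] = int(np.argmin(d))

    cross = np.full(n_clusters, float(cross_participation))
    n_bridges = int(round(bridge_fraction * n_clusters)) if n_communities > 1 else 0
    if n_bridges:
        bridges = rng.choice(n_clusters, size=n_bridges, replace=False)
        cross[bridges] = float(bridge_participation)
    if n_communities == 1:
        cross[:] = 0.0

    network = GroundTruthNetwork(
        positions=positions,
        community_of=community_of,
        ignition_rate=np.full(n_communities, float(ignition_rate)),
        participation=np.full(n_clusters, float(participation)),
        cross_participation=cross,
        bridge_target=bridge_target,
        independent_rate=np.full(n_clusters, float(independent_rate)),
        delay_scale=float(delay_scale),
        nominal_drive=np.ones(n_communities),
    )
    nominal = np.array([network.drive(c) for c in range(n_communities)])
    return dataclasses.replace(network, nominal_drive=np.maximum(nominal, 1e-12))


def _poisson_times(rng: np.random.Generator, rate_per_min: float, duration_s: float) -> np.ndarray:
    """Event times of a homogeneous Poisson process on [0, duration_s).

    Standard-exponential gaps are drawn and scaled by the rate, so two
    simulations at slightly different rates but the same generator state
    share a common prefix of events (common-random-numbers coupling).
    """
    if rate_per_min <= 0:
        return np.empty(0)
    mean_gap = 60.0 / rate_per_min
    n_guess = max(16, int(duration_s / mean_gap * 1.5) + 16)
    times: list[float] = []
    t = 0.0
    while True:
        gaps = rng.exponential(1.0, size=n_guess) * mean_gap
        cum = t + np.cumsum(gaps)
        inside = cum[cum < duration_s]
        times.extend(inside.tolist())
        if len(inside) < len(cum):
            break
        t = cum[-1]
    return np.asarray(times)


def simulate_activity(
    network: GroundTruthNetwork,
    duration: float,
    seed: int,
    *,
    min_separation: float = 0.2,
) -> tuple[list[np.ndarray], list[SequenceEvent]]:
    """Simulate onset trains and the ground-truth event log.

    Community ignitions are a Poisson process at
    ``ignition_rate * excitability``; each cluster joins an event with its
    own-community participation probability (or cross-participation for
    other communities) and activates after an exponential delay of scale
    ``delay_scale``.  Independent firings are per-cluster Poisson processes.
    Per-cluster onsets closer than ``min_separation`` are merged (a calcium
    ROI cannot resolve them), keeping the earlier one.

    Returns ``(onsets, events)`` where ``onsets[i]`` is the sorted onset
    array of cluster ``i`` and ``events`` records ground-truth sequence
    membership (events with >= 2 joining clusters).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = network.n_clusters
    k = network.n_communities
    # independent child streams per component keep conditions comparable
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = root.spawn(2 * k + n)
    time_rngs = [np.random.default_rng(children[c]) for c in range(k)]
    member_rngs = [np.random.default_rng(children[k + c]) for c in range(k)]
    indep_rngs = [np.random.default_rng(children[2 * k + i]) for i in range(n)]

    onsets: list[list[float]] = [[] for _ in range(n)]
    events: list[SequenceEvent] = []
    for c in range(k):
        rate = float(network.ignition_rate[c]) * network.excitability(c)
        t_events = _poisson_times(time_rngs[c], rate, duration)
        inside = network.community_of == c
        join_prob = np.zeros(n)
        targeting = (network.bridge_target == c) & ~inside
        join_prob[targeting] = network.cross_participation[targeting]
        join_prob[inside] = network.participation[inside]
        rng_m = member_rngs[c]
        for t0 in t_events:
            # fixed draw count per event keeps streams aligned across specs
            u = rng_m.uniform(size=n)
            delays = rng_m.exponential(network.delay_scale, size=n)
            joined = np.flatnonzero(u < join_prob)
            if joined.size == 0:
                continue
            t_on = t0 + delays[joined]
            order = np.argsort(t_on, kind="stable")
            joined, t_on = joined[order], t_on[order]
            keep = t_on < duration
            joined, t_on = joined[keep], t_on[keep]
            for i, t in zip(joined, t_on):
                onsets[i].append(float(t))
            if joined.size >= 2:
                events.append(SequenceEvent(float(t0), c, joined, t_on))
    for i in range(n):
        t_ind = _poisson_times(indep_rngs[i], float(network.independent_rate[i]), duration)
        onsets[i].extend(t_ind.tolist())

    trains: list[np.ndarray] = []
    for i in range(n):
        t = np.sort(np.asarray(onsets[i]))
        if t.size > 1 and min_separation > 0:
            keep = np.ones(t.size, dtype=bool)
            last = t[0]
            for j in range(1, t.size):
                if t[j] - last < min_separation:
                    keep[j] = False
                else:
                    last = t[j]
            t = t[keep]
        trains.append(t)
    events.sort(key=lambda e: e.time)
    return trains, events


def render_traces(
    onsets: list[np.ndarray],
    frame_dt: float = 0.02,
    kernel: CalciumKernel = CalciumKernel(),
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    duration: float | None = None,
    true_partition: np.ndarray | None = None,
    events: list[SequenceEvent] | None = None,
) -> SimulatedRecording:
    """Render onset trains into noisy fluorescence traces.

    Each onset adds a transient that rises linearly over ``kernel.rise_ms``
    to ``kernel.amplitude`` and then decays exponentially with time constant
    ``kernel.decay_ms``; transients superpose additively on a zero baseline,
    plus white Gaussian noise of s.d. ``noise_sd``.
    """
    if frame_dt <= 0:
        raise ValueError("frame_dt must be positive")
    n = len(onsets)
    if duration is None:
        last = max((float(t[-1]) for t in onsets if len(t)), default=0.0)
        duration = last + 5.0
    n_frames = int(round(duration / frame_dt))
    rng = np.random.default_rng(seed)

    rise_s = kernel.rise_ms / 1000.0
    decay_s = kernel.decay_ms / 1000.0
    # kernel support: rise + ~8 decay constants
    kernel_len = int(np.ceil((rise_s + 8.0 * decay_s) / frame_dt))
    # frames integrate to the end of their interval, so the sampled peak
    # falls within the rise window
    tk = (np.arange(kernel_len) + 1) * frame_dt
    shape = np.where(
        tk < rise_s,
        tk / rise_s,
        np.exp(-np.maximum(tk - rise_s, 0.0) / decay_s),
    ) * kernel.amplitude

    traces = np.zeros((n_frames, n))
    for i, train in enumerate(onsets):
        for t0 in np.asarray(train, dtype=float):
            f0 = int(np.floor(t0 / frame_dt))
            if f0 >= n_frames:
                continue
            stop = min(n_frames, f0 + kernel_len)
            traces[f0:stop, i] += shape[: stop - f0]
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, size=traces.shape)

    return SimulatedRecording(
        traces=traces,
        frame_dt=frame_dt,
        true_onsets=[np.asarray(t, dtype=float) for t in onsets],
        true_partition=(
            np.asarray(true_partition)
            if true_partition is not None
            else np.zeros(n, dtype=np.int64)
        ),
        events=list(events) if events is not None else [],
    )


def apply_perturbation(
    network: GroundTruthNetwork, spec: PerturbationSpec, seed: int
) -> GroundTruthNetwork:
    """Return a perturbed copy of ``network`` (the input is unchanged).

    Silenced clusters get zero participation, cross-participation and
    independent rate; cross-community participation of the remaining
    clusters is multiplied by ``weaken_factor`` and own-community
    participation by ``within_weaken_factor``; boosted clusters (drawn among
    the non-silenced ones) get their independent rate multiplied by
    ``boost_factor``.  Cluster count, positions and community labels are
    conserved.
    """
    rng = np.random.default_rng(seed)
    n = network.n_clusters
    participation = network.participation * spec.within_weaken_factor
    cross = network.cross_participation * spec.weaken_factor
    independent = network.independent_rate.copy()

    n_silenced = int(round(spec.silenced_fraction * n))
    silenced = rng.choice(n, size=n_silenced, replace=False) if n_silenced else np.empty(0, int)
    participation = participation.copy()
    participation[silenced] = 0.0
    cross = cross.copy()
    cross[silenced] = 0.0
    independent[silenced] = 0.0

    alive = np.setdiff1d(np.arange(n), silenced)
    n_boost = int(round(spec.boosted_fraction * n))
    if n_boost and alive.size:
        boosted = rng.choice(alive, size=min(n_boost, alive.size), replace=False)
        independent[boosted] = independent[boosted] * spec.boost_factor

    return dataclasses.replace(
        network,
        participation=np.clip(participation, 0.0, 1.0),
        cross_participation=np.clip(cross, 0.0, 1.0),
        independent_rate=independent,
    )
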