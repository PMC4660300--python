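# Methods

This note documents the models, conventions and numerical choices behind
`cavnet`, in the order the analysis chain runs. Parameters named here are
the package defaults; all are overridable through function arguments or
the pipeline YAML config, and every pipeline output records the config
hash and seeds that produced it.

## Synthetic clustered-culture model

The generator is phenomenological: it reproduces the *statistics* of
clustered-culture activity, not the biophysics of neurons or synapses.

**Network.** `n_clusters` positions uniform over a disc of radius
1.75 mm (cavities are 3.5 mm across). Communities are angular sectors
about the centroid: spatially contiguous, sizes balanced to within one
cluster. Defaults: 36 clusters, 3 communities.

**Dynamics.** Each community ignites as a homogeneous Poisson process at
`ignition_rate` (default 2.4 events/min) times its *excitability*. Each
cluster joins its own community's events with probability
`participation` (0.6) after an exponential delay of scale `delay_scale`
(30 ms), so a typical sequence engages 5–15 clusters over roughly
100 ms. Independent firing is a small per-cluster Poisson background
(0.1/min). Per-cluster onsets closer than 0.2 s are merged (a calcium
ROI cannot resolve them). With these defaults, per-cluster rates average
1.5–2.0/min, sequences number one per ~8 s, and all four calibration
ranges (rates, sizes, durations, intervals) hold simultaneously.

**Excitability.** A community's event rate is its nominal rate times its
per-member excitatory drive (summed member participation plus the summed
cross-participation of clusters bridging into it) relative to the drive
at construction. An unperturbed network has excitability exactly 1;
silencing members or weakening cross-coupling lowers the realized
ignition rate. This is the model's one mechanistic commitment: ignition
in these cultures is recurrent-excitation driven, so removing drive slows
the collective rhythm rather than merely shrinking event memberships.
Without it, silencing 30% of clusters would leave the sequence rate Ψ
essentially unchanged, which is not what chemically damaged cultures do.

**Bridges.** Every cluster's cross-community participation is aimed at
its spatially nearest foreign community; most clusters have a small
spillover (`cross_participation` = 0.02) while `bridge_fraction` = 0.2 of
them participate strongly (`bridge_participation` = 0.5). Concentrated
bridging matters: under the margins-preserving connectivity null (below),
*diffuse* independent cross-joining is always at or below chance — a
promiscuous cluster's inflated row margin discounts its co-occurrences
everywhere — so no inter-community link could ever reach significance.
Bridge clusters are what give the before-networks their minority
(~10%) of significant inter-community links, and they make the planted
labels deliberately ambiguous for one or two clusters per cavity, as in
real cultures where some clusters participate equally in two
communities. Validation of exact community recovery therefore uses
`bridge_fraction=0` ("well-separated" networks).

**Traces.** Each onset adds a transient rising linearly over `rise_ms`
(50 ms) to `amplitude` (1.0) and decaying exponentially with `decay_ms`
(1000 ms) — Fluo-4-like kinetics — plus white Gaussian noise
(`noise_sd` 0.05, i.e. SNR 20 at default amplitude). Frames integrate to
the end of their 20 ms interval, so the sampled peak falls inside the
rise window.

**Perturbations.** `silenced_fraction` clusters get zero participation
and background; survivors' cross-participation is multiplied by
`weaken_factor` and own-community participation by
`within_weaken_factor`; `boosted_fraction` of surviving clusters get
their background rate multiplied by `boost_factor`. Cluster count,
positions and community labels are conserved. The magnitudes are free
parameters — no quantitative dose→effect mapping exists — and the
default "M-Aβ-like" setting (30% silenced, cross ×0.3) is a direction
probe, not a fit.

**Randomness.** `simulate_activity` gives every component (per-community
event times, per-community memberships, per-cluster background) its own
child stream of the seed, and membership draws consume a fixed count per
event. Two runs with the same seed but slightly different rates then
share a common prefix of random numbers, so fixed-seed directional
comparisons (e.g. weakened vs baseline sequence counts) are coupled
rather than independent.

**What the generator does not emulate.** Photobleaching and slow
baseline drift, indicator saturation, ROI cross-talk, development or
plasticity over the recording, bursty (non-Poisson) ignition statistics,
and propagation structure beyond a single exponential delay per
activation. Tests passing on this generator show the *analysis chain* is
correct and directionally sensitive; they do not certify detector
performance on low-SNR or drifting real recordings.

## Onset detection

Per ROI: the trace is smoothed with a 3-frame moving average; the
baseline is a running 10th percentile over a 30 s window (evaluated on a
~1 s grid and interpolated); the noise level is 1.4826 × MAD of the raw
baseline-subtracted trace. A frame qualifies when the smoothed amplitude
above baseline exceeds `amp_k` (3.0) times the raw-noise s.d. **and** the
forward difference of the smoothed trace exceeds `deriv_k` (2.0) times
the raw derivative's robust s.d. The onset is the first frame of each
qualifying run; runs within `refractory` (0.5 s) of an onset merge into
it. Expressing thresholds in raw-noise units while testing the denoised
signal is what pushes the false-positive rate on transient-free traces
to effectively zero while leaving real transients (amplitude ≫ noise)
untouched. No spike inference or deconvolution is attempted; exact
reproduction of any particular laboratory's onset sets is out of scope
since thresholds are conventions.

## Sequences and the coactivation matrix

Pooled onsets are sorted (ties broken by cluster id for determinism) and
chained while the gap to the previous onset is ≤ `window` (0.2 s), the
same value separating two sequences. Chains with ≥ 2 distinct clusters
are sequences; a cluster firing twice inside one chain counts once, at
its first activation. X is the binary clusters × sequences participation
matrix; a silent cluster keeps an all-zero row. Rare accidental
participations of independent clusters are not filtered out.

## Activity statistics and drift correction

φᵢ = onsets/minute; Φ = mean over all clusters (silent ones at 0);
Ψ = sequences/minute. Drift: r = Φ_control,2nd / Φ_control,1st rescales
φ and Φ of the perturbed cavities; Ψ uses the control's own sequence-rate
ratio (falling back to r when the control produced no sequences).
Division, not subtraction: the drift is multiplicative (temperature,
evaporation). Normalized differences (φᴾ−φ⁰)/(φᴾ+φ⁰) are bounded in
[−1, 1], put silenced clusters at −1, newly active ones at +1, and
define 0/0 as 0. The summary Gaussian (μ, σ) is a least-squares fit to a
Freedman–Diaconis histogram (falling back to sample moments when the
histogram is degenerate); γ is the bias-corrected Fisher sample
skewness of the raw values. Two-sample comparisons use Student's t or
Kolmogorov–Smirnov, two-sided, with the printing convention * p < 0.05,
** p < 0.005.

## Functional connectivity

Within each sequence, every ordered pair (earlier → later) contributes
exp(−Δt/τ) with τ = 0.2 s (the sequence window; the decay form and τ are
config options). Simultaneous activations contribute 1 in both
directions. Raw weights sum over sequences, so w is additive over
sequence sets and invariant under rescaling delays and τ together.

**Null model.** 500 surrogates randomize the binary participation
structure by curveball trades — repeated exchanges of the non-shared
sequence slots of two random clusters — which preserve *both* each
cluster's number of firings and each sequence's size; within-sequence
delays are then permuted inside each slot (each slot keeps its observed
offset multiset). The chain is burned in for 10 sweeps from the observed
matrix and advanced 2 sweeps between samples (a sweep is 2N trades).
W = (w − mean)/sd over surrogates, with sd = 0 pairs set to W = 0
(never-varying pairs are not significant rather than infinite).
Preserving sequence sizes is essential for calibration: sequences are
conditioned on ≥ 2 members, so a null that scatters participations over
slots independently inflates surrogate co-occurrence and drives every
z-score negative. As implemented, fully random activity yields 3.5–5% of
links above z = 1.95, consistent with a one-sided ~95% bound.
Significant links are W > `z_threshold` (1.95); negative and
sub-threshold scores are disregarded. Weight differences between
conditions are taken on the union of the two significance masks, absent
links counting 0; the summary reports their median and skewness.

## Communities

Jaccard similarity J(A,B) = |A∧B|/|A∨B| over history rows, with empty
unions scored 0; distance D = 1 − J. Normalization against 500
surrogates that independently permute each row of X (preserving firing
counts, the classical row-shuffle null for similarity matrices):
Z = (⟨S⟩ − D)/sd(S), positive when a pair is more similar than chance,
mapped to D_norm = 1 − CDF_N(0,1)(Z) so coupled pairs sit near 0.
Zero-spread pairs get the uninformative 0.5; silent clusters are forced
to distance 1 from everything and end as singleton communities.
Average-linkage (UPGMA) dendrograms via scipy; a cut at d keeps clusters
whose cophenetic distance is ≤ d + 1e−9 together (the tolerance admits
merges lying exactly on a decimal grid point).

**Threshold selection.** Thresholds scan 0 → just past the top merge in
steps of 0.01 (grid values rounded to kill float accumulation). For each
threshold, MVI is the mean VI (base-2) between its partition and the
partitions at all other thresholds; ΔMVI jumps mark the boundaries of
stable community structure. The selected d_th *minimizes* MVI among
partitions with ≥ 2 communities, ties toward the largest threshold — the
most representative non-trivial partition, never the single-community
case. Selecting the largest ΔMVI jump directly is degenerate when the
normalized distance saturates: the two top merges can straddle one grid
step, creating an ephemeral two-community plateau whose flanking jump
dwarfs all others even though that partition is unrepresentative (high
MVI). Minimizing MVI reproduces the worked 5-cluster example (2 moduli)
and recovers planted partitions exactly. VI itself is computed from the
label contingency table; base 2 (bits) throughout — any base only
rescales.

## Network topology

Descriptors are computed on the significant-link graph with z-scored
weights, rescaled to (0, 1] by the maximum weight; geodesic edge length
is 1/weight, so efficiencies are bounded by 1. Global efficiency: mean
over all ordered node pairs (isolated nodes included) of inverse
geodesic distance. Local efficiency: mean over nodes with ≥ 2 neighbors
of the efficiency of the subgraph induced by the union of in- and
out-neighbors; isolated and degree-1 nodes are excluded from the mean
(counting them as zero would conflate node loss with neighborhood
cohesion). Clustering: Fagiolo's weighted-directed coefficient averaged
over nodes. Assortativity: Pearson correlation of total (in+out)
weighted degree across all directed links — of the several
degree-flavor pairings possible in a directed graph, the total-degree
correlation is used. After/before ratios are element-wise, with
division by zero reported as missing rather than raised.

## Homogeneous cultures

ROIs are grid elements (30 × 30 per cavity on real data; each covering
~5–10 neurons). A network burst is a sequence whose participating ROI
fraction is ≥ `min_fraction` (0.5 — the all-or-none events have no
quantitative definition, so this is a declared convention); burst time
is the first onset. The burst-rate ratio after/before is drift-corrected
by the control pair exactly as the firing-rate statistics. Community and
functional-graph analyses are not applied to homogeneous cultures, whose
all-or-none dynamics excludes community structure.

## Pipeline

One YAML config drives a whole well: exactly one control cavity, up to
three perturbed ones, per-cavity trace files or generator specs, and all
module parameters with the defaults above. Seeds for every stochastic
stage derive from the single top-level seed through named SeedSequence
children; the summary embeds the config hash and the per-stage seeds, so
a rerun is byte-identical. Validation (roles, uniqueness, file
existence) happens before any computation; a silent control aborts at
drift correction with an explicit error.

## Problem sizes used in validation

The end-to-end checks simulate the study's protocol at desk scale:
30-minute recordings per condition; rate and skewness statistics
averaged/pooled over 24 simulated wells per seed (per-cluster rates are
correlated through shared community events, so the skewness estimator's
effective sample size scales with wells × communities, not clusters);
graph statistics over 4 wells with 200 surrogates; null calibration over
20 independent-activity cavities with the full 500 surrogates; 10 seeds
per directional claim with an 80% majority rule. These sizes were fixed
by a power analysis of the renewal-process event counts before the
checks were frozen.

## Known limitations

- Onset detection assumes a stationary baseline within the percentile
  window and white noise; strong bleaching trends need detrending first.
- The surrogate nulls randomize *which* clusters co-fire but keep the
  sequence scaffold fixed; they do not model temporally structured
  (bursty) null activity.
- The excitability model couples participation and ignition rate
  linearly; real dose–response curves are unknown and likely nonlinear.
- Homogeneous-mode analysis stops at burst rates, as community structure
  is undefined there.
- VI-based threshold selection needs at least one non-trivial partition;
  degenerate dendrograms (all merges at height 0) raise an error rather
  than guessing.
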