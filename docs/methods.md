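# Methods

This note documents the models implemented in `multifreq`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations.

## Multilayer network model

A multilayer network holds the same physical entities (e.g. EEG
electrodes) in L layers (e.g. frequency bands).  Intra-layer edges connect
nodes within one layer; inter-layer edges may connect *any* node of one
layer to any node of another — unlike a multiplex graph, which couples a
node only to its own copies.  The whole object is equivalently a symmetric
N x N supra-adjacency matrix with the layers' adjacency matrices on the
block diagonal and bipartite incidence blocks off it.  All weights are
finite, nonnegative and undirected, with no self-loops within a layer.
Missing inter-layer blocks are treated as all-zero, so single-layer and
multiplex graphs are degenerate cases handled by the same machinery.

The *layer-wise strength* `s_u^{hk}` of node u in layer h toward layer k
is the total weight u sends into layer k; `m^{hk}` is the (h, k) block's
total weight, counting each intra-layer edge once.

## Multilayer modularity and the layer-strength null model

Multi-frequency brain networks have strongly heterogeneous weights across
layers: a task engages some bands much more than others.  A null model
that ignores this drives community detection toward trivial partitions by
layer label.  The null model used here preserves every layer-wise node
strength:

    P_uv^{hk} = s_u^{hk} s_v^{kh} / ((1 + delta_hk) m^{hk}),

which reduces to the familiar configuration model s_u s_v / 2m within a
layer and satisfies sum_v P_uv^{hk} = s_u^{hk} exactly.  An empty block
(m^{hk} = 0) contributes no expectation (P = 0, logged).  The quality of a
partition g is the unnormalized

    Q = sum_h sum_{i,j in h} (A - gamma_r P) delta(g_i, g_j)
      + omega sum_{h != k} sum_{i in h, j in k} (A - gamma_r P) delta(g_i, g_j),

with the resolution parameter gamma_r > 0 scaling the null term (larger
values resolve smaller communities) and the inter-layer scale omega >= 0
weighing cross-layer contributions.  Two conventions are pinned here: the
inter-layer double sum runs over ordered pairs h != k only (the intra-layer
term is already the first sum, and the delta_hk factor in P separates the
two cases), and the i = j diagonal null terms are included, which makes Q
identically zero for the all-in-one partition at gamma_r = 1 (observed and
expected totals telescope).  Q is reported unnormalized; only differences
and maximizers matter downstream.

## Optimization

Q is the quadratic form of a symmetric supra "modularity matrix"
B = A - gamma_r P with omega folded into the off-diagonal blocks, so a
Louvain-style greedy works directly on B: nodes start as singletons, are
repeatedly moved to the community with the largest gain (ties broken
uniformly at random under the run's seed), then communities are aggregated
(B -> S^T B S) and the procedure recurses until a full pass makes no
improving move.  A `maximize` call runs 10 descents by default (40 on
instances of at most 10 nodes, where the landscape is near-degenerate and
search is cheap) — the first from singletons, the rest from random
partitions — polishes each with up
to 5 Kernighan-Lin escape passes (a chain of forced best single moves,
keeping the best prefix, which reaches splits that single improving moves
cannot), keeps the best result, and finally compares against the
all-singleton and all-in-one partitions, so the reported quality is never
below either trivial partition; on networks of up to 8 layer-nodes this
matches exhaustive enumeration over all set partitions in our tests.  The
parameter-selection stage instead uses light single-descent runs without
refinement, identically for the observed network and its surrogates: there
only the *comparison* of mean detected quality matters, and the light
detector keeps the grid search fast.  Modularity maximization
is NP-hard and greedy results are local optima; ensembles of seeded runs
(`maximize_ensemble`) deliberately sample this degeneracy for the
consensus stage.  Gain comparisons use an absolute tolerance of 1e-12;
zero-gain moves are not taken, so structureless merges (e.g. across layers
at omega = 0) never occur.  Community labels are canonicalized by first
appearance.

## Surrogate-based selection of (gamma_r, omega)

Surrogate networks permute edge weights *within* each (h, k) block over
the existing edges (for the fully connected weighted networks this
pipeline produces, topology preservation and weight permutation coincide).
Per-block weight multisets — and hence the m^{hk} entering the null — are
exactly conserved, while the assignment of weights to node pairs, i.e. any
community-aligned structure, is destroyed.  Full permutation is the
limiting distribution of the pairwise weight-swap randomization; an
`n_swaps` option performs literal transpositions instead.  For each
(gamma_r, omega) on a grid, Q_obs averages the modularity of c detection
runs on the observed network and Q_surr averages one detection per
surrogate over a shared, seeded ensemble of c surrogates (one ensemble is
generated per network and reused across the grid; results are independent
of grid evaluation order).  The selected parameters maximize
Q_obs - Q_surr; exact ties resolve to the smallest omega, then smallest
gamma.  The default grids are gamma_r in 0.95..1.05 (step 0.0025) and
omega in 0..0.5 (step 0.0125); validation uses a reduced 5 x 5 grid with
gamma_r in 0.98..1.02 — a window around the regime's optimum near 1 — and
omega in 0..0.5.

A property worth knowing: on weight-sampled planted networks with i.i.d.
Gaussian edge noise and *homogeneous* inter-layer weights, the argmax over
omega is decided largely by a single frozen fluctuation of the observed
network (cross-layer community merges cost nothing intra-layer, so the
observed network exploits omega roughly as well as surrogates do, and the
surface is near-flat in omega with one random tilt).  Networks built by
the PLV/dPAC pipeline do not behave this way — their inter-layer noise
floor is correlated along phase-channel rows, which weight permutation
destroys — and the selection then cleanly separates coupled from uncoupled
regimes.  Validation of the selection stage therefore uses pipeline-built
networks.

## Group community detection (co-clustering + SC-ML)

For each subject, c seeded maximization runs are summarized in a
co-clustering matrix counting how often each node pair shares a community;
diagonals equal c, so node strengths are always positive.  The subjects'
matrices form the layers of a multiplex graph and the group structure is
found by spectral clustering on multi-layer graphs: each layer contributes
its symmetric normalized Laplacian L^h and the eigenvectors U^h of its k
smallest eigenvalues, and the final embedding comes from the k smallest
eigenvectors of

    L_mod = sum_h L^h - alpha sum_h U^h U^h^T,      alpha = 0.5,

followed by k-means (50 restarts, fixed seed) on row-normalized embedding
rows; the embedding's sign indeterminacy is irrelevant to k-means
distances, and eigenvalue ties resolve by the symmetric solver's ordering.
With alpha = 0 this reduces to spectral clustering on the summed
normalized Laplacians; the same subspace rank k is used for every layer.
The number of groups defaults to the half-up-rounded mean of the subjects'
modal community counts across their runs (minimum 2).

## Comparison metrics

NMI between partitions uses arithmetic-mean normalization of the mutual
information by default (max, min and geometric variants are exposed); it
is 1 exactly for equal partitions up to relabeling and 0 for an
all-in-one versus all-singletons pair.  The graph distance is the square
root of the Jensen-Shannon divergence between spectral density operators
rho = L / tr(L) (L the normalized Laplacian), with von Neumann entropies
in base-2 logarithms so the divergence — and the distance — is bounded by
1.  This is one pinned member of the spectral-JS family of graph
distances; it satisfies identity on equal matrices, symmetry and
boundedness, but other members of the family are not numerically
identical to it.

## Multi-frequency network construction

Inputs are trial-epoched channel x sample x trial arrays (at least two
trials; windows are given in seconds relative to the response time t0).
Defaults follow standard EEG practice: theta 4-7, alpha 8-12, beta 13-30,
gamma 31-100 Hz, analysis window 25-75 ms post-response, band and window
membership half-open.

**Time-frequency distribution.**  The reduced-interference Rihaczek
distribution is computed on the raw real signal via the ambiguity-plane
route: C0(t, f) = x(t) X*(f) e^{-j 2 pi f t}, transformed to the
(doppler, lag) plane, multiplied by a Choi-Williams kernel
exp(-(theta tau)^2 / sigma) on dimensionless grids theta, tau = fftfreq(N),
and transformed back; the positive-frequency half is returned.  Under this
normalization, doppler content at f_d Hz survives to lags of roughly
sqrt(sigma) N fs / f_d samples.  The default sigma = 1e-6 keeps theta-rate
temporal modulation intact across ~40 lags while suppressing carrier-rate
interference within a few lags; with 1-second epochs at 512 Hz the
frequency grid is 1 Hz.  The epoch length sets the frequency resolution,
so band sums count integer-Hz bins.

**Intra-layer weights (PLV).**  The phase difference between channels at
each time-frequency point is the angle of C_u C_v*; bins where either
distribution has (numerically) zero magnitude carry no phase and are
masked out of averages.  The phase-locking value is the across-trial
resultant length of these phase differences, in [0, 1]; the edge weight
averages PLV over the analysis window and the band's bins.  For K i.i.d.
trials with unrelated phases the PLV floor is ~ sqrt(pi / 4K).

**Inter-layer weights (dPAC).**  The direct phase-amplitude coupling
estimator is

    dPAC = |sum_k a_k e^{j phi_k}| / (sqrt(K) sqrt(sum_k a_k^2)),

in [0, 1] by Cauchy-Schwarz, with equality for constant amplitude and
identical phases and a ~1/sqrt(K) floor for uncoupled inputs.  The
low-frequency phase phi and high-frequency envelope a are the angle and
magnitude of *band-limited analytic components* reconstructed from the
distribution's spectral factor: the phase from the single bin at f_p, the
envelope from a band of width twice the phase band's upper edge around
f_a (wide enough to carry modulation sidebands for any phase frequency in
the band).  This interpretation of the frequency-constrained marginal is
deliberate: a bilinear distribution of a real signal is invariant under
x -> -x, so its single-channel phase is defined only modulo pi, and a
first-harmonic envelope coupling is exactly orthogonal to any phase factor
derived from it; conversely the bilinear distribution of an analytic
signal cancels the across-trial phase variation that the dPAC
normalization requires.  The band-analytic components are the standard
quantities the direct-PAC estimator is defined over, and they make the
estimator's floors, ceilings and monotonicity in coupling depth hold as
designed.  The undirected inter-layer weight averages dPAC over the
window and both bands' bins, and combines the two role assignments (phase
at u / amplitude at v and the reverse) by their mean (options: max, or
strictly phase-from-the-lower-band).

Memory scales as channels^2 x window samples x frequency bins for the
pairwise accumulators — fine for tens of channels at desk scale.

## Synthetic study conditions

Two generators make every stage testable without recordings; both are
pure functions of (spec, seed) and return ground truth.

*Planted networks* are fully connected and weighted, mirroring PLV/dPAC
networks: intra-layer means 0.6 within / 0.3 between communities,
inter-layer means 0.2 within / 0.12 between (coupling weights concentrate
well below synchrony weights, as dPAC floors do), Gaussian weight noise
sd 0.05 clipped at zero, optional per-layer scale factors for
heterogeneity.  Cross-layer communities are planted by letting labels
span layers (boosting the corresponding inter-layer entries); per-layer
regimes share no labels across layers, leaving all inter-layer weights at
the uninformative baseline.

*Planted epochs* are sums of band-limited cosines plus white noise:
locked groups share a uniformly random per-trial phase at a carrier
frequency (per-channel Gaussian phase jitter), and PAC links multiply an
amplitude carrier by 1 + depth cos(phase-channel low-frequency phase).
The canonical validation scenario (`theta_gamma_study`) has eight channels
in two modules of four, each module with its own theta (6 Hz) and gamma
(40 Hz) locked groups (jitter 0.1 rad, noise sd 0.3, 60 trials — the upper
range of usable trials in event-related designs); in the coupled regime
every channel's gamma envelope follows its module's theta phase at depth
0.9, and the two-layer analysis uses theta 4-8 and gamma 35-46 Hz, the
band around the planted carrier.  Coupling is planted in both modules so
that the ground truth is unambiguous (two cross-layer communities): with
only one module coupled, the uncoupled module's theta and gamma layers
still bind through shared dPAC-floor structure and the "correct"
partition is ill-defined.

What these fixtures do *not* emulate: volume conduction and reference
effects, 1/f broadband spectra, non-stationary oscillation bursts,
between-subject topographic variability, and artifacts.  Passing tests
demonstrate that the estimators and the detection machinery recover
planted structure under controlled conditions, not that a given EEG
dataset will yield stable communities.

## Validation problem sizes

The shipped validation suite uses 4-layer, 16-node random networks for
the algebraic identities; 8-layer-node networks (4140-partition
enumeration) for optimizer exactness; the eight-channel, 60-trial
theta/gamma scenario for construction, selection and end-to-end recovery
(10 seeds per regime, 5 x 5 parameter grid, c = 20 runs and surrogates);
and 16-node, 5-subject co-clustering stacks for group recovery.  These
sizes keep the full suite in the minutes range on one CPU while leaving
every statistical margin (floors ~ 1/sqrt(K), recovery NMIs) far from the
decision thresholds.

## Known limitations

- The greedy optimizer guarantees local optimality only; global-optimum
  agreement is verified up to 8 layer-nodes.
- The JS graph distance is one pinned member of its family; numerical
  values are not interchangeable with other definitions.
- The dPAC grid average dilutes narrowband coupling over the full band
  grid; layers much wider than the coupled carrier region lower the
  contrast between coupled and uncoupled pairs.
- Directed or negatively weighted multilayer networks, multi-aspect
  (tensor) networks, and overlapping communities are out of scope.
- EEG preprocessing (artifact rejection, source-space or current-source-
  density transforms) is expected to happen upstream.
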