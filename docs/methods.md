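# Methods

`netrep` quantifies how reproducible and how robust graph-theoretic summaries
of functional connectivity networks are, when the networks are built from
partial correlations of multi-run node time series. Because suitable
multi-subject recordings are rarely public, the package ships a synthetic
cohort generator with a fully known generating network, so every claim the
pipeline makes can be checked against ground truth.

## Network construction

For each subject, the runs under analysis are concatenated in time and the
partial correlation between every node pair is computed from the inverse of
the sample covariance, `rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)`. An
optional ridge term (`cov + reg*I`, default `reg = 0`) is available for
ill-conditioned covariances; the synthetic defaults keep `t >> p`, so the
default suffices there.

Association strengths are absolute variance-stabilized Fisher z-scores,

    z_ij = |atanh(rho_ij)| * sqrt(n - p - 1),

with `n` time points and `p` nodes: the partial correlation conditions on the
remaining `p - 2` nodes, so the familiar `n - 3` degrees of freedom for a
bivariate Fisher z lose a further `p - 2`. Two network representations are
derived from an association matrix:

* **weighted** — `w_ij = 2*Phi(z_ij) - 1`, the unique affine-in-Phi map that
  sends `z = 0` to weight 0 and `z -> inf` to weight 1. It is monotone, so
  edge rankings are preserved, and it compresses outliers.
* **binary (equi-density)** — the `round(d * p(p-1)/2)` strongest pairs
  become edges at density `d` (round-half-up; ties at the cut break by
  ascending node-pair order so results are bit-reproducible). The default
  density grid is 5–45% in steps of 5% plus 7.8%.

Group-based networks always weight/threshold the *entrywise mean* of the
per-subject association matrices. The z-to-weight map is nonlinear, so
averaging weighted networks instead would give a different (and here,
unintended) object; a regression test pins this ordering.

## Graph measures

Local measures per node: degree (binary) or strength (weighted), average
shortest-path length over reachable nodes, clustering coefficient, local
efficiency, nodal efficiency, and betweenness centrality (Brandes) normalized
by `(n-1)(n-2)/2` so it lies in [0, 1]. Weighted variants use edge lengths
`1/w`, Onnela cube-root clustering on raw weights (weights already live in
[0, 1], so no rescaling), and the cube-root weighted local efficiency with
distances confined to the neighbour subgraph. Global measures are the means
of the local ones. Isolated nodes are excluded throughout: they carry no
measure values, and `n` in every normalization counts included nodes only.
Note one deliberate asymmetry: weighted local efficiency on a 0/1-valued
weight matrix does *not* reduce to the binary local efficiency (the weighted
convention takes cube roots of inverse subgraph distances); all other
measures reduce exactly, and the test suite checks both facts.

Disconnected graphs keep a finite path length by averaging per node over
reachable partners only; efficiencies count unreachable pairs as 0.

## Reliability

Each subject's runs are split into two disjoint, equally sized halves (with 5
runs, 4 are drawn and split 2/2; the unused run is redrawn each realization;
draws are independent across subjects). Each half passes through the full
construction pipeline, giving paired measurements of every measure at every
density and for the weighted network. Reliability indices:

* **ICC** — one-way random-effects, single-measurement (ICC(1,1), k = 2):
  `ICC = (BMS - EMS) / (BMS + EMS)` from the between-subject and residual
  mean squares of the 2 x S table. Zero total variance is defined as ICC = 0
  with a warning.
* **TRT** — `|v1 - v2| / ((v1 + v2)/2) * 100` percent, computed per subject
  and averaged (subject level), or between the two half-group networks
  (group level).

Both are aggregated over seeded split realizations (default 100).
Significance follows one-sample t-tests (ICC > 0.4; TRT < 5% and < 10%), a
linear regression of log-TRT on density, and Bonferroni correction over the
number of network conditions (globals) times the number of nodes (locals).
Between-independent-groups comparisons reuse the group-level TRT plus a
two-sample t-test on subject-specific weighted global measures.

## Hubs and communities

A node's hub score adds four 0/1 criteria: top 20% by degree/strength, top
20% by betweenness, bottom 20% by clustering (restricted to nodes with
degree >= 2, where clustering is defined), bottom 20% by path length. The
cut keeps `ceil(0.2 * n_included)` nodes with boundary ties all flagged;
hubs are nodes scoring >= 2. Hub agreement between two networks is the Dice
co-occurrence `2|A∩B| / (|A| + |B|)` (1 = identical, 0 = disjoint; a Jaccard
alternative is exposed behind an option).

Community structure is summarized probabilistically: Louvain modularity
maximization runs from `n` seeded random node orders (default 100), each
yielding a 0/1 same-community matrix; the average is the co-assignment
matrix. Community consistency between networks A and B is scaled
inclusivity, per node `SI = |C_A ∩ C_B|^2 / (|C_A||C_B|)`, generalized to
co-assignment matrices as

    pSI_i = (sum_j P^A_ij P^B_ij)^2 / ((sum_j P^A_ij)(sum_j P^B_ij)),

sums including the diagonal. On binarized matrices pSI reduces exactly to SI
(the diagonal convention is what makes the reduction exact), and
Cauchy–Schwarz with entries in [0, 1] bounds it by 1. Consensus co-assignment
matrices are entrywise means; *stable groups* are connected components (of
size >= 2) of the pairs whose consensus probability is >= 0.95.

Significance of consistency values is assessed against rewired null
networks: Maslov–Sneppen double-edge swaps (10 x E attempted swaps per
realization, degree sequence preserved exactly) for binary networks; for
weighted networks the binarized support is rewired the same way and the
original weight multiset is randomly permuted onto the new edges. Empirical
p-values use the add-one form `(1 + #{null >= obs}) / (1 + N)`.

## Robustness

*Group size*: subjects are subsampled without replacement (default 100
bootstrap realizations per size), the group network rebuilt per subsample,
and each global measure expressed as relative change (%) against the
full-cohort reference; an individual-level variant averages per-subject
weighted measures over the subsample. The smallest size whose absolute
relative change is significantly below 10% is reported per measure.

*Missing nodes*: the intact network is weighted/thresholded once, then nodes
are deleted one at a time in ascending order of an externally supplied
importance score (ties break by node index), without re-thresholding — the
realized density drifts as nodes leave, by design, because the question is
what happens when nodes were never captured. Measures are recomputed on each
surviving subgraph; a from-scratch subgraph oracle pins the equality to
1e-12.

## Synthetic cohort generator

The generator emulates a task-fMRI style study: ~54 subjects, 5 runs, 57
network nodes. The generating object is a block-structured precision matrix:
off-diagonal entries of magnitude `within_strength` inside contiguous
modules, sparse weaker `between_strength` entries across modules, and hub
nodes with extra cross-module entries. Off-diagonal entries are positive
(equivalently, within-module partial correlations are negative); the
association matrix uses |z|, so downstream stages are sign-blind, and the
positive convention keeps the matrix positive definite across the whole
useful strength range — diagonal loading (`delta*I`, delta grown
geometrically from 1e-6, capped at 1) repairs any residual indefiniteness.

Between-subject variability has two knobs: white symmetric jitter on the
precision entries (`subject_jitter_sd`) and a log-normal subject factor
multiplying all off-diagonal entries (`subject_scale_sd`), representing
individual differences in overall coupling strength. Both default to
moderate/zero values; the scale factor is the mechanism of choice for
"between-subject variance much larger than within" regimes, because white
jitter largely averages out of global measures and is bounded by the
positive-definiteness repair at 57 nodes. Time samples are i.i.d. Gaussian
draws from the subject precision's inverse (prewhitened series carry little
autocorrelation; an AR(1) option with variance-preserving innovations exists
for sensitivity checks). All randomness derives from one integer seed via a
fixed (seed, subject, run) hierarchy.

`node_importance` is a generator output (hubs highest, then a descending
ramp with seeded jitter) standing in for whatever per-node statistic a real
study would rank removal by; the removal pipeline accepts any user-supplied
importance vector.

What the generator does **not** emulate: hemodynamics, image space, motion
or physiological noise, scanner/session effects, non-Gaussian signals.
Passing tests therefore demonstrate the correctness and internal consistency
of the pipeline and the behaviour of the indices under known variance
structure — not that any particular empirical dataset is reliable.

## Numerical and scale choices

* Weight saturation: `2*Phi(z) - 1` rounds to exactly 1.0 in double
  precision near `z ≈ 8.2`; saturated weights create shortest-path tie
  degeneracy that makes betweenness erratic. The default synthetic regimes
  keep z below that range.
* The weighted test-retest floor is set by the Fisher z of truly-null pairs,
  whose sampling noise (sd ~ 1 on the z scale) does not shrink with run
  length; reliability demonstrations therefore use generating networks whose
  pairs all carry (possibly weak) true coupling.
* Test and demonstration problem sizes are scaled down from the emulated
  study (e.g. 100 split realizations on 10–20 subjects; null ensembles of
  99–200 rather than 1000) — these sizes are the package's own defaults for
  its validation suite and keep every check cheap to re-run; the library
  accepts the full-size counts.
* Ties: thresholding and removal order break ties deterministically (node
  order); hub flags include boundary ties (so fully regular graphs
  degenerate to "all nodes are hubs", documented behaviour).
* Degenerate inputs: |rho| = 1, non-positive Fisher degrees of freedom,
  zero-variance series, empty graphs, all-isolated networks, and
  sub-2-subject ICC tables all raise informative errors rather than
  propagating NaNs; TRT of a zero-mean pair is reported as missing.

## Known limitations

* Only one community-detection family (Louvain-style modularity
  maximization) is wired in; the consistency machinery is detector-agnostic
  but untested against others.
* The between-independent-groups design assumes equal node sets; no
  harmonization of acquisition differences is attempted.
* Local-measure reliability tables grow as (nodes x measures x densities)
  and are computed only when requested.
* The rewiring null preserves degrees (binary) or the weight multiset
  (weighted) but not, e.g., the clustering spectrum; conclusions about
  "significance versus null" inherit that choice.
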