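# Methods

`fatepattern` simulates binary cell-fate patterns in growing 2D colonies and
3D organoids, quantifies them with spatial summary statistics, and trains two
neural models: a graph neural network that regresses the signal-dispersion
parameter `q` of a whole tissue, and a multilayer perceptron that imputes a
single cell's fate from its nearest neighbours.  This note records the model,
its assumptions, the numerical choices, and what the synthetic data do and do
not show.

## Agent-based tissue model

### Growth phase

A single founder cell of radius `r_init = 1` divides on a jittered cell-cycle
clock.  At division the two daughters inherit the radius

    r_new = 2^(-1/dim) * r_old,   dim in {2, 3},

which conserves total cell area (2D) or volume (3D): the colony stays within
a roughly unit-radius footprint while cells shrink.  Daughters are placed at
`±r_new/2` along a uniformly random direction, and all overlapping cell pairs
relax by overdamped linear repulsion (spring constant 50, mobility 1,
`dt = T/n_steps`).  Each daughter draws its cycle length uniformly from
`tau * (1 ± 0.25)`.  The mean cycle times, `tau = 3.56` (2D) and `3.00` (3D),
were calibrated once so that a growth time of `T = 25` with 6000 steps yields
mean tissue sizes of ~132 cells in 2D and ~330 cells in 3D — the mean sizes
of the discrete-q data sets.  After the last division the tissue settles for
200 extra relaxation steps.  Growth stops early the moment a target cell
count (e.g. 150) is reached.

Assumptions and limits: no adhesion, polarity or growth-rate regulation; the
packing is what soft repulsion alone produces (local density fluctuations,
mildly anisotropic outlines).  Mean contact numbers on the thresholded
Delaunay graph come out at ~6 (2D) and ~14 (3D), matching the planar and
spatial packing expectations.

### Fate phase

Cell positions are frozen.  Every cell carries two antagonistic transcription
factors `u` and `v` (read epiblast-like vs primitive-endoderm-like).  With
`d_ij` the Euclidean centroid distance in units of the mean nearest-neighbour
distance (floored at 1), the dispersion kernel is

    K_ij = q^(e_ij),   e_ij = d_ij            for Delaunay contacts,
                       e_ij = d_ij^1.4        otherwise,

so beyond the contact neighbourhood influence falls superexponentially and
the *effective* reach of the signal is set by `q`.  Cell i receives

    s_i = g_i * (Σ_j K_ij u_j) / (mass_i * mean(u)),   mass_i = Σ_j K_ij,

a row-normalized weighted mean of the neighbours' `u`, multiplied by a
geometric centrality bias

    g_i = (M_i / mean(M))^(4 q^2),   M_i = Σ_j 0.9^(d_ij).

`M_i` is a smooth interior-high/rim-low field measured with a fixed mesoscale
kernel; its exponent `4 q^2` makes the bias negligible for short-range
signalling and dominant as `q -> 1`.  The dynamics are mutual inhibition with
the signal activating `v`:

    du_i/dt = θ^h / (θ^h + v_i^h) - u_i
    dv_i/dt = s_i^m * θ^h / (θ^h + u_i^h) - v_i

with Hill coefficient `h = 4`, threshold `θ = 0.5`, signal exponent `m = 3`,
unit production and degradation, `s` clipped at 3.  Initial conditions are
`u, v = 0.5 ± 0.01` (uniform).  Forward Euler with `T = 100` over 1000 steps
(`dt = 0.1`); the stiffest local rates are O(few), so this is stable.
Integration runs in float32.  Fates: `u > v` → 0 (u+v−), `u < v` → 1 (u−v+);
`|u - v| <= 1e-3` is *unresolved* — the run is repeated once with a fresh
noise seed and then fails loudly.  In practice unresolved cells occur only in
exactly symmetric configurations (e.g. zero initial noise).

Why these choices (the design was genuinely open here):

- *Hill 4, m = 3*: linear stability of the symmetric state shows that with a
  row-stochastic coupling no graph mode can destabilize when the loop gain is
  below ~1; Hill 2 never patterns.  Hill 4 with a cubic signal bias gives a
  robust checkerboard instability on both the ~6-contact 2D and ~14-contact
  3D graphs.
- *Row normalization*: normalizing the signal by total kernel mass instead
  biases rim cells (smaller mass) systematically to one fate and skews the
  fate ratio to ~1/3 at all q; the row-normalized form keeps the ratio near
  1/2, as observed for the discrete-q data sets.
- *Distance-based weights*: making all contacts contribute equally renders
  the fate a function of the Delaunay contact *set*, which nearest-neighbour
  distance features cannot see, and caps fate imputation far below the
  observed accuracy; weighting by actual distance makes the local rule
  learnable from (fate, distance) features.
- *Explicit centrality bias*: with a row-normalized signal the engulfing
  (core–shell) pattern needs an interior/rim asymmetry; a fixed mesoscale
  centrality field with q-scaled exponent supplies it smoothly without
  adding noise at low q.

Resulting pattern regimes (150-cell 2D colony): Moran's I ≈ −0.2 to −0.3 for
q ≤ 0.2 (checkerboard), monotonically increasing through ~0 near q ≈ 0.5
(mixed blobs), ≈ +0.7 for q ≥ 0.9 (engulfing, with the rim type's pair
correlation rising sharply at the maximum pair distance).

### Data-set recipes

- **A**: 2D colonies of exactly 150 cells (growth T=30, ≤6000 steps, stop at
  the 150th cell), `q ~ U(0,1)`, colonies with more than 2/3 of one fate
  excluded (strict inequality: exactly 2/3 is kept).  Under this generator
  the filter removes mainly mid-q colonies (blob regimes are unbalanced);
  the keep rate is ~58%.
- **B**: 3D organoids, growth time uniform over a range (default
  23.09–27.06), `q ~ U(0,1)`, same filter.
- **C**/**D**: 2D/3D, growth T=25, 100 replicates per q on the grid
  0.1, …, 0.9, unfiltered.

## Cell graphs

Nodes are cells with the binary fate as the single node feature.  Edges are
Delaunay edges shorter than a threshold: 2 for simulated tissues (twice the
maximum possible radius), per-organoid `mean + 2·SD` of Delaunay edge lengths
for experimental-style tables.  Edge weights are lengths divided by the
longest retained edge (per graph), hence in (0, 1].  Batches are disjoint
unions: block-diagonal adjacency plus a per-node graph index.

## Spatial statistics

Moran's index uses the binary adjacency of the cell graph,

    I = n / ΣA · (x − x̄)ᵀ A (x − x̄) / ((x − x̄)ᵀ (x − x̄)),

and is label-swap invariant.  The pair correlation functions normalize pair
distances by the maximum pair distance, use 20 equal-width bins, and divide
the observed same-type pair fraction per bin by the hypergeometric
expectation `n_t (n_t − 1) / (n (n − 1))`, which makes ρ = 1 exact in
expectation under random labeling.  Empty bins are NaN, not 0.  Envelopes
re-assign the uncommitted classes (N+G+, N−G−) to the committed ones with
probability `p = #N+G− / (#N+G− + #N−G+)` (preserving expected proportions),
recompute the statistic R times (default 1000) and keep the min/max.

## Pattern recognition (dispersion regression)

Architecture: two graph-convolution-with-skip layers,
`Z' = D^(−1/2) A D^(−1/2) X W1 + X W2 + b`, with 450 (relu) and 150 (sigmoid)
channels on the weighted adjacency; global attention-sum pooling (per-graph
softmax over learned node scores); dense head 50 (relu) → 1 (sigmoid).  The
150→50→1 head is available as a configuration option.  Degree-0 nodes get a
zero normalization entry.  Training: MSE loss, Adam starting at 1e-4, the
rate multiplied by 0.2 after 10 epochs without validation improvement,
80/10/10 train/test/validation split, early stop with best-checkpoint
restore.  The network and its gradients are implemented in NumPy/SciPy
(float32, sparse adjacency); correctness is pinned by a dense-matrix oracle
test and numerical gradient checks.  Batch size 8 is the default for the
reproduction runs: with the 1e-4 starting rate, optimizer steps (not data
passes) limit convergence, and smaller batches converge in fewer epochs at
identical arithmetic cost.

Accuracy depends on where `q` lies: patterns for q below ~0.15 change little
with q (the kernel already couples only direct contacts), so predictions
there scatter more — the same asymmetry the human-expert comparison showed.

## Pattern reconstruction (fate imputation)

Feature rows are `label, F1, D1, …, Fk, Dk`: the fates and raw Euclidean
distances of the k nearest neighbours in ascending order (ties broken by
cell index); neighbour coordinates are deliberately excluded.  The imputer
is a 3×64 ReLU perceptron with a softmax output of width 2 or 4, Adam 1e-3,
sparse categorical cross-entropy, an 80/20 train/test split with a 10%
validation carve-out, autostop after 75 epochs without validation-loss
improvement, and best-checkpoint restore.  Neighbour sweeps train one model
per k under a shared seed; crosstraining trains on one q level and evaluates
on the held-out split of every level.

Known limitation: in 3D at low q the converged pattern retains glassy
degeneracy — the same neighbourhood can host either fate depending on
initial noise — which caps imputation accuracy near 85–88% (the full
converged signal explains ~97% of fates, but part of that information sits
in graded `u` levels and beyond-contact terms).  The accuracy-vs-k curve
rises smoothly rather than jumping at the contact number.

## Synthetic ICM-organoid tables

`synthdata` emulates the experimental schema end-to-end: Poisson cell counts
around stage means 441.73 (24 h) / 1041.24 (48 h); near-uniform positions in
a ball with unit minimum separation; four classes with P(N−G+) tilted
logistically toward the rim (slope = rim strength, stage defaults 1.0 / 4.0)
and its epiblast counterpart tilted inward; uncommitted classes placed
uniformly; lognormal NANOG/GATA6 levels with high/low log-means ln 200 /
ln 20 (SD 0.3, >5 SD separation, so 2-means clustering of committed classes
is essentially noiseless).  These tables reproduce schema and summary
structure only — no imaging noise, nuclear segmentation artifacts, batch
effects (a batch-shift knob exists, default 0) or realistic expression
covariation.  Tests passing on them validate plumbing and statistical
machinery, not biological fidelity.

## Reproduction problem sizes

`scripts/acceptance.py` re-runs the full pipeline at sizes chosen to keep a
single-CPU run practical while preserving each quantity's meaning: ~930
filtered 2D colonies for the 2D recognizer (1600 attempts); ~500 filtered 3D
organoids of ~300–600 cells (1000 attempts, growth times 24.7–26.7) for the
3D recognizer; 60 organoids at q = 0.1 for the 3D imputer sweep; 40
organoids per q in {0.6, …, 0.9} for crosstraining; 60 colonies per q in
{0.6, 0.7, 0.8} for the 2D imputer.  Recognizer training uses batch size 8
with early stopping (patience 30; epoch caps 50 in 2D, 95 in 3D); imputers
cap at 120–200 epochs under the patience-75 autostop.  Stochastic
quantities are the median of three training seeds on shared simulations.
The tissue simulations themselves always use the full physics (6000 growth
steps, 1000 fate steps).
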