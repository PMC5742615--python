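# Methods

## Model

`gphsmm` treats a continuous multivariate time series as a concatenation
of variable-length segments emitted by one of `C` latent classes. The
generative process per sequence is a hidden semi-Markov chain: the class
of segment `j` follows a smoothed Markov transition from the class of
segment `j−1` (a dedicated begin-of-sequence state provides the prior for
the opening segment), the segment length `k` follows a Poisson
distribution with mean `λ` truncated to `[min_len, K]`, and the segment's
frames follow the class's Gaussian-process regression over within-segment
time `i = 1..k`.

A candidate segment is scored as the product over its frames and
dimensions of the class GP's predictive marginal density — each frame
scored against the class data accumulated from *other* segments — rather
than as a joint GP likelihood over the candidate. This factorized
treatment keeps the lattice cost bounded (predictions depend only on the
within-segment step, so one `K`-point predictive grid per class serves
every candidate) and matches the per-dimension independence of the
emission model. The predictive follows standard GP regression with noisy
targets: mean `k^T C^{-1} x`, variance `k(i,i) − k^T C^{-1} k + 1/β`; the
`+1/β` appears because the model scores noisy observations. A class with
no data scores segments under the prior predictive `N(0, k(i,i) + 1/β)`,
which gives the sampler a well-defined cold start.

### Transition probabilities

Transitions use additively smoothed counts. The denominator counts
*outgoing transitions* of the conditioning class (plus `Cα`), not its
segments: segments that close a sequence have no successor, and counting
them in the denominator would leave each row summing to less than one.
With outgoing counts every row is an exactly normalized smoothed
categorical — the standard collapsed Dirichlet–categorical estimator.
The begin-of-sequence row is smoothed the same way from
sequence-opening counts. There is no end-of-sequence state.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| `C` | number of classes | 8 (CLI config) | must be supplied; set near the expected number of primitives |
| `K` | maximum segment length (frames) | 30 | upper bound of the duration prior and lattice depth |
| `min_len` | minimum segment length (frames) | 2 | a 1-frame segment is degenerate for GP indexing |
| `lambda_len` | Poisson mean length (frames) | 15 | set to the expected primitive length |
| `alpha_smooth` | transition smoothing | 1.0 | Laplace smoothing of the class chain |
| `theta0, theta1, theta2, theta3` | kernel amplitude, inverse squared length-scale, bias, linear weight | 1, 1, 0, 0 | `theta1` multiplies `‖i_p−i_q‖²`; 1 reproduces the classic Gaussian kernel exactly |
| `beta` | observation-noise precision | 10 | model noise sd `1/√β ≈ 0.32` in observation units; deliberately generous — see below |
| `renormalize_len` | renormalize the truncated Poisson | off | the truncated, unrenormalized pmf is what enters the lattice by default |
| `pair_cap` | max GP training pairs per class | none | uniform subsample (run-seeded) for very large corpora |
| `n_iter` | Gibbs sweeps | 10 | fixed count; the joint log-probability trace is logged for inspection |
| `n_restarts` | independent chains | 5 | best final joint log probability wins |

Durations are truncated to `[min_len, K]` without renormalization by
default; the missing mass is a constant factor per segment and does not
affect the sampled posterior for fixed segment counts, while the
renormalized variant is available by flag. Hyperparameters are never
optimized (no marginal-likelihood maximization); inputs can optionally be
per-dimension z-scored, with the inverse transform recorded in the run
manifest, which is the practical choice for coordinates with
heterogeneous scales.

## Inference

All probabilities are handled in log space with log-sum-exp
marginalization; products of hundreds of Gaussian densities underflow
catastrophically in linear space. The forward lattice `α[t][k][c]` is
filled by dynamic programming with the boundary conventions
`α[t][k][·] = 0` for `t − k < 0` and `α[0][0][·] = 1`; per-frame log
densities are accumulated along lattice diagonals so the scores for
lengths `k` and `k+1` share work, and each class's Gram matrix is
Cholesky-factorized once per sequence visit (the class data is frozen
while that sequence is held out). Factorizations add diagonal jitter only
on failure, escalating from 1e−6 by factors of 10 to 1e−2 before raising
a degeneracy error naming the class.

Backward sampling draws `(k, c)` at `t = T` proportionally to
`α[T][k][c]`; at interior `t` the weight is multiplied by
`p(c_next | c)`, the transition into the segment already drawn to the
right. Without this factor the walk does not sample the joint posterior;
a literal mode that omits it is available by flag. Correctness of the
whole pipeline is verified against a brute-force oracle that enumerates
and scores every feasible (segmentation, classes) outcome on tiny
instances: the lattice total matches the enumerated total to machine
precision and 20,000 backward draws sit within total-variation distance
0.05 of the enumerated posterior.

The blocked Gibbs sampler initializes each sequence with a random
division (lengths uniform on `[min_len, K]` with a feasible tail, classes
uniform) and then sweeps: remove a sequence's segments and counts,
rebuild caches, forward filter, backward sample, re-add. If no
segmentation of some length is feasible under `[min_len, K]` the sampler
raises rather than silently relaxing the constraints. Sequences are
visited in corpus order by default (a seeded shuffle is available), and a
fixed number of sweeps is run — there is no automatic convergence test —
with the per-iteration joint log probability logged.

### Restarts

The segmentation posterior is strongly multimodal: single chains can
settle into self-reinforcing "fragment" modes in which a class learns the
beginnings of primitives and then scores further fragments well, tens of
log-units below the dominant mode. Because a full run is cheap, the
sampler runs `n_restarts` independent chains (seeds spawned
deterministically from the run seed) and keeps the chain with the highest
final joint log probability — the same defence against multimodality as
`n_init` in k-means or Gaussian-mixture fitting. Selection uses only the
model's own joint probability. Tempered or annealed sweeps were
deliberately not used.

## Synthetic data and what it shows

The generator draws corpora from the model's own generative family:
Markov class chains, truncated-Poisson lengths, smooth per-class
templates plus i.i.d. Gaussian noise. The default template family is
per-class, per-dimension sinusoids `a sin(2π i / T + φ)` with amplitudes
in [0.8, 1.2], periods in [10, 40] frames and uniform phases, drawn once
per class from the seed — smooth, GP-representable curves loosely
analogous to cyclic exercise motions. The standard recovery benchmark
uses 3 classes, 2 dimensions, 4 sequences of 10 segments, `λ = 15`,
`min_len = 5`, `K = 40`, uniform transitions, and noise at 10 % of the
class amplitude; the model is run matched to the generating `λ`, with the
default kernel and `β = 10` (a model noise floor about 3× the generating
noise; sharper `β` makes chains greedier and more mode-prone without
improving the recovered optimum).

Passing this benchmark shows that the inference machinery recovers
recoverable structure planted by the model's own process. It does not
show robustness to what real recordings add: non-stationary primitives,
execution-speed variation (time warping), correlated sensor noise,
class counts unknown in advance, or dimensions on heterogeneous scales.

## Evaluation metrics

The normalized Hamming distance expands both segmentations to per-frame
labels, optimally matches estimated to true classes (Hungarian algorithm
on the confusion matrix; surplus estimated classes stay unmatched and
count wholly as errors), and reports the mismatched fraction. Boundary
precision/recall/F-measure extract interior boundaries (the shared
endpoints at frame 0 and T are excluded as uninformative), then match
each true boundary, left to right, to the nearest unclaimed estimated
boundary within ±tol frames, ties toward the earlier estimate; unmatched
truths are false negatives, unmatched estimates false positives, and
`F = 2PR/(P+R)` with `F = 0` when `P + R = 0`. The matching is
one-to-one, so `TP ≤ min(#true, #estimated)` and `TP` is monotone in the
tolerance. The default tolerance is 4 frames, with 5 used for
coarser-grained comparisons.

## Numerical and degenerate-input choices

* Gram matrices are built at full precision and factorized with the
  jitter ladder above; predictive variances are floored at 1e−12.
* The kernel groups `θ3 (i_p i_q)` so evaluation is bit-exactly
  symmetric.
* Removing a segment that is not stored raises a bookkeeping error
  (a sampler bug, never a data condition); counts can never go negative.
* Sequences shorter than `min_len` are rejected at input; sequence
  lengths unreachable by any composition of `[min_len, K]` raise an
  infeasibility error.
* The enumeration oracle refuses instances beyond a configurable outcome
  bound (10⁶ by default); it exists for validation, not analysis.

## Problem sizes

The bundled validation instances are sized for quick, exact checking:
the enumeration cross-check uses T = 8, C = 2, K = 4 (4212 outcomes);
sampler calibration uses 20,000 draws; the recovery benchmark (about 600
frames per corpus, 5 restarts × 10 sweeps) runs in roughly 10–15 s per
seed on one CPU. Larger corpora scale linearly in total frames and in
`K·C` per frame for the lattice, plus cubic Gram factorization in the
per-class training-set size — the `pair_cap` option bounds the latter.

## Known limitations

The number of classes is fixed in advance; too few classes merge
primitives and too many over-segment. Computation grows cubically with
per-class data (no sparse-GP approximation is included). Dimensions are
modeled independently, so cross-dimension covariance is ignored. The
duration model is a single global Poisson, not per-class. Kernel
hyperparameters are fixed, not learned.
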