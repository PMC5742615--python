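# gphsmm — unsupervised segmentation of continuous time series

`gphsmm` discovers recurring movement primitives in continuous multivariate
time series — motion-capture traces, cyclic exercise or martial-arts
motions, any behavioral recording — and finds their boundaries and classes
without supervision. It is aimed at researchers in computational ethology,
biomechanics and robot imitation learning who have trajectories but no
frame labels.

## The model

A sequence `s` of `T` frames (each a `D`-dimensional vector) is modeled as
a concatenation of segments `x_j` produced by a hidden semi-Markov model:

    c_j ~ P(c | c_{j-1})          class chain (smoothed Markov transitions)
    k_j ~ Poisson(λ)              segment length, truncated to [min_len, K]
    x_j ~ GP(x | X_{c_j})         segment emission

Each class `c` owns a Gaussian-process regression over within-segment time
`i = 1..k`: given the frames `X_c` of segments currently assigned to `c`,
the value at step `i` of a new segment is Gaussian with

    mean  k^T C^{-1} x ,   variance  k(i,i) − k^T C^{-1} k + 1/β ,

where `C(i_p, i_q) = k(i_p, i_q) + β^{-1} δ_pq` is the Gram matrix of the
kernel

    k(i_p, i_q) = θ0 exp(−θ1 ‖i_p − i_q‖² / 2) + θ2 + θ3 i_p i_q

and `β` is the observation-noise precision. Dimensions are independent GPs
sharing one set of time steps. Transition probabilities are additively
smoothed counts, `p(c | c') = (N_{c'c} + α) / (N_{c'·} + Cα)`.

Inference is a blocked Gibbs sampler: each sweep removes one sequence's
segments from the sufficient statistics, computes the exact forward
lattice

    α[t][k][c] = P(s_{t−k:t} | X_c) · P_len(k | λ) · Σ_{k',c'} p(c|c') α[t−k][k'][c'] ,

draws a fresh segmentation by backward sampling, and folds it back in.
Several independent chains are run and the one with the highest final
joint probability is kept (like `n_init` in k-means). Quality is measured
by the normalized Hamming distance after optimal (Hungarian) class
matching and by boundary precision/recall/F-measure within a ±tol frame
window.

## Worked example

`python examples/segment_synthetic.py` generates four sequences (644
frames) by chaining three sinusoid primitives with Poisson(15) lengths and
10 % observation noise, segments them, and prints:

```
joint log probability per iteration (best restart):
  -842 -276 -195 -145 -132 -133 -128 -119 -121 -114
normalized Hamming distance: 0.078   (fraction of frames mislabeled after optimal class matching; 0 = perfect)
boundary precision 0.795, recall 0.972, F-measure 0.875 at +/-3 frames
```

The rising joint log probability shows the sampler converging; a Hamming
distance of 0.078 means 92 % of frames get the right primitive label (up
to relabeling), and F = 0.875 means discovered boundaries almost always
fall within three frames of a true one. The other examples show the GP
emission mechanics (`gp_emission_basics.py`), the exact-inference
cross-check (`exact_posterior_check.py`) and the on-disk formats
(`file_workflow.py`).

A thin CLI wraps the same library calls:

```sh
gphsmm simulate --out-dir synth --seed 0
gphsmm segment --config run.yaml --out-dir out synth/synth-*.csv
gphsmm evaluate --tol 5 out/segmentation.tsv synth/truth.tsv
gphsmm oracle-check --seed 7
```

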