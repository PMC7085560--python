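# Methods

## Model

The feature learner is an autoencoder whose encoder is an ELM-style
random sigmoid layer and whose decoder is a closed-form linear
regression. Unlike a gradient-trained autoencoder only the encoder's
parameters are free: the hidden weights `W` (n bands × L features) and
biases `b` (L) are flattened into a single decision vector
`α = [w11, …, w1L, …, wn1, …, wnL, b1, …, bL]` of length `nL + L`
(weights row-major over input index, biases trailing) and evolved by
NSGA-II inside a box constraint. Two objectives are minimized
simultaneously:

- `f1(α) = Σ_{j=1..L} [ρ ln(ρ/ρ̂_j) + (1−ρ) ln((1−ρ)/(1−ρ̂_j))]`, the
  summed Bernoulli KL divergence between the desired activation `ρ` and
  the per-neuron mean activation `ρ̂_j` over the full data set. Natural
  logarithm; activations are clipped to `[1e-6, 1−1e-6]` so saturated
  neurons stay finite. `f1 = 0` exactly when every `ρ̂_j = ρ`.
- `f2(α)`: K-fold cross-validated reconstruction RMSE. The sample index
  is permuted once per run (from the fold seed) and split into K
  contiguous blocks; per fold, decoder weights `β` are solved by
  pseudoinverse least squares on the training folds' hidden outputs and
  the held-out fold is reconstructed as `h(x)β`. The per-fold RMSE
  `sqrt(Σ‖x_i − y_i‖²/(n_k n))` is averaged over folds (root inside the
  average). The inner decoder uses the pseudoinverse (no ridge penalty)
  because no inner regularization constant is part of the model.

The two objectives conflict: silencing neurons (small `ρ̂_j`) removes
capacity the decoder needs, so sparser codes reconstruct worse. The
solver returns the final non-dominated set; one member is selected and
frozen as the encoder `X̃ = g(X W_F + b_F)`.

## Solver

Canonical NSGA-II: fast non-dominated sorting, crowding distance
(boundary solutions +∞; a zero-range objective contributes 0, avoiding
0/0), binary tournament on (rank, crowding) with stable index
tie-breaks, simulated binary crossover (probability 0.9, distribution
index 15), polynomial mutation (probability 1/dim, index 20), uniform
initialization within bounds, and (μ+λ) survival truncated by front
then crowding. These operator choices are the standard suite; the
underlying model fixes only the population/generation budget, so the
operators are exposed in `EvolutionConfig`. Offspring are clipped back
into bounds. Termination is a fixed generation budget. Because the
per-objective extremes carry infinite crowding and survival is elitist,
the per-generation minimum of each objective is non-increasing — a
property the tests track.

Any optimizer with the contract `(objective, n_variables, config) →
archive` can replace `evolve`; the evaluation engine
(`ObjectiveEvaluator`) is a plain callable.

## Solution selection

`min_f1` and `min_f2` take the archive member minimizing that objective
(ties broken by the other objective, then index). The `knee` strategy
targets the best trade-off: the front is min-max normalized into the
unit square (a zero-range objective maps to 0), sorted by `f1` with
duplicate abscissae collapsed to the lower `f2`, approximated by a
parametric B-spline (degree 3, falling back for tiny fronts), resampled
at 100 evenly spaced parameter values, and the curvature
`κ = |x′y″ − y′x″|/(x′²+y′²)^{3/2}` computed from the spline
derivatives. The archive point nearest (Euclidean, normalized space) to
the maximum-curvature sample is returned; the three nearest points are
reported in diagnostics.

Smoothing: evolved fronts are noisy, so the spline is a light
approximation rather than an interpolation — FITPACK residual budget
`s = 1e-3` per front point, configurable. Near-constant-curvature
fronts (straight lines, circular arcs) have no meaningful knee; when
`max(κ)/mean(κ) < 1.5` (or the profile is numerically flat,
`max(κ) ≤ 1e-8`) the argmax point is still returned but flagged
low-confidence with a warning.

## Baselines and the classifier

- **NRP**: the unoptimized encoder — `W`, `b` drawn uniform in the same
  `[-1, 1]` box the optimizer searches, so optimized and unoptimized
  encoders share a domain.
- **ELM-AE / SELM-AE**: linear feature extractors `X β^T` with
  `β = W^T V V^T`, `V` the top-L eigenvectors (descending eigenvalue)
  of the *uncentered* Gram matrix `X^T X`; `W` orthogonal
  (`W^T W = I`, requires L ≤ n) for ELM-AE, three-valued sparse for
  SELM-AE. Taking all n eigenvectors would give `V V^T = I` and
  `β = W^T`, a pure rotation — hence the top-L restriction.
- **Sparse layer**: entries of `W` and `b` i.i.d. `+√(3/L)` w.p. 1/6,
  `0` w.p. 2/3, `−√(3/L)` w.p. 1/6 (Achlioptas-style sparse random
  projection scaled by the hidden width).
- **ELM classifier**: 500 uniform-random hidden neurons, one-hot (0/1)
  targets, ridge output weights with `λ = 1e6` (the penalty enters as
  `I/λ`, so this is nearly unregularized; `λ` is exposed). The two
  algebraically identical ridge forms — `H^T(HH^T + I/λ)^{-1}T` and
  `(H^TH + I/λ)^{-1}H^T T` — are auto-selected by whichever system is
  smaller (N ≤ L picks the first).

## Evaluation protocol

Features are scored by (a) the L2/L1 sparsity measure — mean over
samples of `‖f‖₂/‖f‖₁`, in `[1/√L, 1]`, higher = sparser; zero rows are
skipped with a warning; a whole-matrix variant is available — and (b)
repeated stratified splits: per repeat, `train_fraction` (default 10%)
of the labeled pixels train the 500-neuron ELM classifier and the rest
are predicted; overall accuracy, average (per-class mean) accuracy and
Cohen's kappa are reported as mean ± std over 10 repeats. The
three-fold cross-validation inside `f2` and the 10%-train protocol for
classification are distinct stages; the split fraction and repeat count
are parameters.

## Synthetic scenes

The generator emulates a small labeled agricultural scene: per-class
spectral signatures are smooth random low-frequency sinusoid mixtures
over bands, clipped to [0.05, 0.95]; the spatial layout is a Voronoi
patchwork (3 patches per class by default, every class guaranteed one);
pixels are the class signature plus zero-mean Gaussian noise with
inter-band covariance `σ² exp(−|i−j|/ℓ)` (defaults σ = 0.05, ℓ = 5
bands — noise visibly below the typical inter-class signature gap, so
scenes are separable but not trivially so). Defaults: 5 classes, 30
bands, 40×40 pixels, fully labeled.

What the generator does *not* emulate: mixed pixels at field
boundaries, class-dependent covariance, atmospheric absorption bands,
sensor striping, or spatially correlated noise. A green trend test on
these scenes therefore establishes that evolving the encoder improves
sparsity and preserves separability *relative to its own unoptimized
baseline under Gaussian band-correlated noise* — not performance on
real radiance data.

## Numerical choices and conventions

- Pixels flatten to samples in row-major spatial order; ground-truth
  label 0 marks unlabeled pixels and classes are 1-based. Per-band
  min-max scaling to [0, 1] is applied by default (sigmoid encoders
  need bounded inputs); constant bands map to 0.
- Pseudoinverse solves use SVD least squares with the default relative
  cutoff; `f1` uses the full data while `f2` uses held-out folds only.
- Decision-variable bounds default to `[-1, 1]`: with unit-scaled
  inputs the sigmoid then operates in its informative range rather than
  saturating.
- All randomness descends from one master seed through named
  `SeedSequence` substreams (evolution, fold assignment, per-repeat
  splits, classifier layers, scene generation); identical seeds give
  byte-identical model JSON and report CSV.
- Model files are JSON (config, seed, strategy, `α_F`, `W_F` row-major,
  `b_F`, archive objective pairs); fronts, features and reports are CSV
  written at `%.17g` so float64 values round-trip exactly.

## Limitations

- Evolution cost scales as population × generations × (hidden-output +
  K pseudoinverse solves); the reference budget (50 × 5000) on
  full-size scenes is hours of CPU. The implementation is exact, not
  approximate, about this cost — subsample pixels or lower `n_gen` for
  exploration.
- Only the sigmoid activation is wired in; other activations change the
  activation-sparsity interpretation of `f1`.
- The knee detector assumes the front is representable as a planar
  curve ordered by `f1`; heavily duplicated or two-point fronts
  degenerate to warnings and boundary choices.
- L0-penalized decoders and gradient-trained autoencoder baselines are
  out of scope.
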