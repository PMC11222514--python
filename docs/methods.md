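# Methods

## Model

The generative model is a denoising diffusion probabilistic model over the
joint state `z = [z^(x), z^(h)]` of a molecule: `z^(x)` holds Cartesian
coordinates (Å) projected onto the zero-centre-of-gravity subspace, and
`z^(h)` holds the invariant features — a one-hot element block scaled by
0.25 and an integer-charge slot scaled by 0.1.  The scalings balance the
integer-valued channels against unit-variance Gaussian noise; they are
configurable and stored with every checkpoint.

The chain is variance preserving (`α_t² + σ_t² = 1`).  Two schedule
families are provided:

* `polynomial` (default): `α_t² ∝ (1 − (t/(T+1))²)²`, with stepwise ratios
  clipped below at 0.001 and the whole table affinely squeezed into
  `[precision, 1 − 2·precision]`, `precision = 1e-4`.  This keeps
  `α_0 ≈ 1` (near-clean data end) and `α_T ≈ 0.01 ≫ 0` (numerically safe
  noisy end).
* `cosine`: the squared-cosine alternative, same clipping.

`T = 1000` is the default chain length; the toy experiments use `T = 100`,
which is ample for three-to-five-atom geometries and keeps sampling cheap.

Clean data sits in front of the chain, so the forward jump to step `t` uses
the marginal scales, `z_t = α_t z_0 + σ_t ε`; this is the `α_0 ≈ 1`
convention under which the noise-estimate inversion
`z̃_0 = z_t/α_t − ε̂ σ_t/α_t` is exact.  Between-step transitions use
`α_{t|s} = α_t/α_s` and `σ²_{t|s} = σ_t² − α²_{t|s} σ_s²` — the
squared-coefficient form, which is the unique choice satisfying the
Gaussian composition law (verified against a Monte-Carlo oracle in the
tests).  Reverse sampling is ancestral: the network's `z̃_0` enters the
exact posterior `q(z_s | z_t, z̃_0)`; coordinate noise is drawn on the
zero-CoG subspace, so the subspace is conserved exactly along the chain.
The final transition to `t = 0` takes the posterior mean without extra
noise before decoding (argmax types; charges rounded half-away-from-zero).

### Likelihood bound

`negative_log_likelihood` assembles `−log p(x, h, N)` from (i) the prior
term `KL(q(z_T|z_0) ‖ N(0, I))` with the coordinate contribution counted on
the `(N−1)×3`-dimensional subspace, (ii) per-step terms
`½ (SNR(s)/SNR(t) − 1) E‖ε − ε̂‖²` for `t = 1..T` (each estimated with a
configurable number of noise draws), (iii) a reconstruction term at `t = 0`
— Gaussian with scale `σ_0/α_0` for coordinates, and a unit-width
discretised Gaussian for the integer features, normalised across categories
for the one-hot block — and (iv) `−log p(N)` under the empirical size
distribution.  Whether published per-molecule likelihoods average per
molecule or per sampling batch is ambiguous; the function returns the
per-molecule bound and callers may average however they need.

## Denoising network

Each layer passes messages over the fully-connected graph with two feature
channels per node: invariant scalars `H` and equivariant 3-vectors `χ`.
Noisy coordinates are lifted into vector features once per forward pass:
the node channel carries the displacement to the centre of gravity, each
edge carries `x_j − x_i`, and — when frames are enabled — an additional
pseudo-vector node channel `x_i × n_i` (with `n_i` an inverse-square-
distance-weighted neighbour mean).  The pseudo channel matters: the plain
displacement channels of an edge lie in the plane of `x_i` and `x_j`, which
is orthogonal to the frame axis `b`, so without it the first layer would be
blind to chirality.

Message inputs are scalars only: sender/receiver features, embedded
distances, channel norms, and (frames on) projections of all vector
channels onto the edge frame `(a, b, c)`.  Projections onto `a` and `c` of
pseudo-vectors, and onto `b` of true vectors, are pseudo-scalars — they
flip sign under reflection, which is the entire chirality mechanism; with
`use_frames=False` every scalar is parity-even and the network is exactly
reflection-equivariant.  Messages pass through a two-layer MLP (SiLU),
optionally gated by the logistic scalar-message-attention unit, and are
mean-aggregated.  Scalar updates are residual MLPs; vector updates combine
the per-edge basis `(χ_i, χ_j, ξ_ij)` with bounded invariant coefficients
(`3·tanh` of a linear map of the message) and a per-channel logistic gate.
Edge scalars are residually updated as well (`update_edges`, on by
default; recomputation instead of update is the other defensible reading
and is available via the flag).

Output heads: `ε̂^(h)` from a scalar MLP, `ε̂^(x)` as a learned combination
of the final vector channels re-projected to zero CoG.  Both heads saturate
smoothly at scale 10 (the vector head by norm, preserving equivariance):
near-identity on the ±5σ range that standard-normal noise occupies, but it
keeps reverse chains bounded under arbitrary (e.g. untrained) parameters.
Degenerate frames (collinear or coincident atoms, cross-product norm below
1e-8) are zeroed so their projections contribute nothing and no NaNs arise;
the linear CO₂ toy template exercises this path.  Time is conditioned by
appending `t/T` to the node scalars; a conditioning property is normalised
by training-set mean and median absolute deviation and appended likewise.

The reference configuration (9 layers, 256/64 node and 32/16 edge
scalar/vector widths) is the config default; the experiments use a 2-layer
64/16/16/8 profile.  Everything runs in float64 — with a numpy backend
there is no performance reason for single precision, and it keeps the
symmetry contracts sharp (equivariance probes pass at 1e-10, asserted at
the looser 1e-4).

Training minimises the noise-matching loss with `t ~ U{1..T}`, one noise
draw per example, Adam (3e-3, linearly decayed to 3e-4 in the toy
experiments), batch mean of per-molecule summed squared residuals.  An
optional weight EMA is available in the trainer but stays off in the toy
experiments: for short overfitting runs the averaging lags the learning-
rate anneal and the raw final weights are measurably better.  The
gradient engine is a small reverse-mode tape over numpy arrays
(`diffmol.autodiff`) providing exactly the primitives graph message passing
needs; its backward rules are verified against central finite differences.

## Synthetic data

`make_toy_dataset` emulates a small-molecule dataset: a template geometry
is drawn, rigidly rotated by a Haar-uniform rotation, jittered with
isotropic Gaussian noise (default experiments: 0.02 Å), and annotated with
a scalar geometric property.  Templates were chosen to exercise specific
failure modes: a bent water-like triatomic (training target for recovery),
tetrahedral methane, linear CO₂ (degenerate frames), the chiral CHFClBr
tetrahedron, and the *bent family* — the water-like triatomic with its
bond angle drawn uniformly from 90–120° so the mean pairwise distance
(1.09–1.19 Å) varies continuously while bond lengths, and therefore
atom/molecule stability, are invariant across the family.  The family is
the conditioning testbed: a uniformly scaled chain would have been the
alternative, but scaling bonds leaves the bond-length windows and breaks
the generator's own plausibility invariant (every template must score
atom stability 1.0 at zero jitter, which the generator enforces).

What the toy data does *not* emulate: chemical diversity (few templates),
size variation within a dataset, conformational flexibility, and the
distance-geometry ambiguity of large molecules.  Passing the recovery and
steering experiments therefore demonstrates that the pipeline's mechanics
(equivariant denoising, conditioning, strided sampling, optimization entry
points) are correct at desk scale, not that the model reaches the quality
reported for real datasets at production scale.

## Experiments and their settings

* **Generative recovery** — 200 training molecules, 3000 Adam steps, batch
  8 (~2.5 min CPU); 200 full-grid samples scored by the worst sorted
  pairwise-distance deviation from the template, threshold 0.15 Å; 200
  10-step strided samples must be rougher on average.  Strided
  ("time-scaled") sampling is interpreted as ancestral sampling on `k`
  evenly spaced timesteps with the transition moments recomputed between
  visited steps; `k = T` is bitwise path-identical to standard sampling.
* **Conditional steering** — conditional and unconditional models trained
  on the bent family (4000/2000 steps); 20 seeded trials, each optimizing a
  fresh batch of 16 molecules by re-noising to `t_opt = 50` (of 100) and
  denoising; success when the conditional batch-mean property lands closer
  to the target than the unconditional refinement of the same re-noised
  states.  Targets are drawn 0.025–0.045 Å away from the family mean
  (both tails): a target that coincides with the training mean cannot
  distinguish conditional steering from the baseline's regression to the
  mean, so such trials would measure only sampling noise; batch 16 and the
  deeper re-noising likewise keep trial outcomes dominated by the
  systematic steering effect rather than batch-mean noise.  Existing
  molecules enter optimization through the exact forward marginal (decoded
  molecules live at the `t = 0` scale), and atom counts are preserved.

## Metrics

Bond inference assigns each pair the highest order whose covalent
reference length plus margin (10/5/3 pm) still bounds the observed
distance; the tables ship as a versioned JSON data file and include
charge-adjusted valences (N⁺ 4, N⁻ 2, O⁺ 3, O⁻ 1, C± 3) with a neutral
fallback.  Validity is RDKit sanitisation of the inferred bond graph;
uniqueness and novelty compare canonical heavy-atom SMILES (whole graph —
disconnected fragments are not special-cased).  A single-atom record
sanitises (implicit hydrogens) and is pinned valid by a fixture test.  The
energy ratio embeds the molecular graph `n` times with ETKDGv3 (no
force-field minimisation, seeded), divides the input conformer's UFF
energy by the ensemble mean, and flags ratios above 7; embedding failure or
a non-positive reference mean yields a metric-unavailable result that is
excluded from aggregates but counted.  Energy-ratio summaries use
Student's-t 95% confidence intervals.

## Numerical choices and edge cases

* Posterior at `σ_t = 0` raises; `predict_clean` guards `α_t` below 1e-12.
* `σ²_{t|s}` is clamped at 0 before the square root (round-off).
* Single-atom molecules: the coordinate subspace is `{0}`, the prior draw
  and `ε̂^(x)` are exactly zero, and the likelihood counts zero coordinate
  dimensions.
* Charge decoding rounds half away from zero (0.5 → 1, −0.5 → −1).
* Discretised-Gaussian probabilities are clipped at 1e-30 before logs.
* All randomness flows through explicitly seeded `numpy` generators; CLI
  runs record their seed in a provenance sidecar.

## Limitations

Pure-numpy training limits practical model sizes to the toy regime;
reproducing published large-scale results (QM9/GEOM-Drugs training) is out
of scope here, though the loaders and metric stack accept the processed
archives when present.  Protein-pocket-conditional generation, classifier-
gradient guidance, learned/continuous-time schedules and latent-space
diffusion are explicitly not implemented.
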