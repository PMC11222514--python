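# diffmol

SE(3)-equivariant denoising diffusion for 3D molecules: joint generation of
atom coordinates and atom types, chirality-aware graph denoising with local
frames, property-guided optimization of existing molecules, and the
distance-based stability metrics used to score 3D generative models.

The package is aimed at method developers in generative chemistry who want a
transparent, CPU-friendly implementation of the full pipeline — diffusion
algebra, equivariant denoiser, sampling, optimization and evaluation — that
can be exercised end-to-end on synthetic molecules without any download.

## The model

A molecule is a fully-connected 3D graph with coordinates
`X ∈ R^{N×3}` and invariant features `H` (one-hot element types and integer
formal charges).  A fixed variance-preserving Markov chain

    q(z_t | z_{t−1}) = N(z_t | α_t z_{t−1}, σ_t² I),   α_t² + σ_t² = 1

noises the joint latent `z = [z^(x), z^(h)]`, with the coordinate channel
confined to the zero-centre-of-gravity subspace `Σ_i x_i = 0` so the
likelihood is translation-invariant.  Transitions obey
`α_{t|s} = α_t/α_s`, `σ²_{t|s} = σ_t² − α²_{t|s} σ_s²`, and the true
denoising posterior `q(z_s | z_t, z_0)` is Gaussian with

    μ_{t→s} = (α_s σ²_{t|s}/σ_t²) z_0 + (α_{t|s} σ_s²/σ_t²) z_t,
    σ_{t→s} = σ_{t|s} σ_s / σ_t.

A graph network Φ predicts the noise `ε̂ = [ε̂^(x), ε̂^(h)]`; the clean-state
estimate `z̃_0 = z_t/α_t − ε̂ σ_t/α_t` plugs into the posterior for ancestral
sampling.  Training minimises `E ½ w(t) ‖ε − ε̂‖²` with `w(t) = 1`, and the
same terms assemble a variational bound on `−log p(x, h, N)`.

The denoiser keeps separate scalar and vector feature channels.  Message
scalars are rotation-invariant (vector norms plus projections onto per-edge
orthonormal frames `a = (x_i−x_j)/‖·‖`, `b = (x_i×x_j)/‖·‖`, `c = a×b`);
because `b` and `c` are pseudo-vectors the projections change sign under
reflection, making mirror images distinguishable (chirality awareness)
while rotations and translations act exactly equivariantly.  A per-edge
logistic gate on message scalars (scalar message attention) provides a
lightweight form of fully-connected graph attention.

Evaluation follows the standard distance-based conventions: bond orders are
inferred from inter-atomic distances against covalent reference lengths
(with 10/5/3 pm margins for single/double/triple), an atom is *stable* when
its summed bond orders match an allowed valence, a molecule is stable when
all its atoms are, and validity/uniqueness/novelty use sanitisation and
canonical SMILES.  The energy ratio — UFF energy of a conformer over the
mean UFF energy of 50 distance-geometry re-embeddings — flags unlikely 3D
geometries when it exceeds 7.

## Worked example

```python
import numpy as np
import diffmol as dm
from diffmol.experiments import train_toy_generative_model

model, schedule = train_toy_generative_model(seed=0)   # ~2 min on one CPU
rng = np.random.default_rng(42)
mol = dm.generate(model, schedule, 3, rng=rng, alphabet=dm.TOY_ALPHABET)
print(mol.elements, np.round(np.sort(
    mol.pairwise_distances()[np.triu_indices(3, 1)]), 3))
```

prints, for a model trained on a rigid water-like template (O–H 0.96 Å,
H–H 1.52 Å):

```
['O', 'H', 'H'] [0.934 0.943 1.452]
```

i.e. the sampled molecule reproduces the template's element types and all
three pairwise distances to within a few hundredths of an angstrom.  Across
200 samples the package measures a 100% recovery rate at the 0.15 Å
tolerance, with a mean worst-pair deviation of 0.045 Å for full-grid
sampling versus 0.139 Å for 10-step strided sampling — fewer reverse steps,
rougher molecules.

The same pipeline is available from the shell:

```bash
diffmol train --toy-template water --steps 1500 --timesteps 100 --out water.json
diffmol sample --checkpoint water.json -n 10 --out samples
diffmol evaluate --in samples.xyz
```

See `examples/` for short narrative scripts covering the diffusion algebra,
generation, property-guided optimization and the metric stack.

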