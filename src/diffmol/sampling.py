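"""Sampling, strided sampling, property-guided optimization, and training.

Unconditional generation draws z_T from the joint prior (subspace Gaussian
coordinates, standard Gaussian features) and runs the learned reverse chain
down the full timestep grid.  Strided ("time-scaled") sampling visits only k
evenly spaced timesteps, recomputing the transition moments between
consecutive visited steps — few visited steps produce deliberately rough,
"unoptimized" molecules.  Property-guided optimization re-noises existing
molecules to an intermediate step t_opt with the forward process and then
denoises them under a property-conditional model pointed at a target value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .diffusion import (
    LatentState,
    forward_noise,
    posterior_moments,
    predict_clean,
    reverse_step,
    sample_subspace_gaussian,
)
from .denoiser import GCPDenoiser, PropertyNormalizer
from .molecules import (
    CHARGE_SCALE,
    ONEHOT_SCALE,
    QM9_ALPHABET,
    MoleculeRecord,
    decode_latent,
    featurize,
)
from .schedule import NoiseSchedule

__all__ = [
    "SizeDistribution",
    "GenerationConfig",
    "TrainConfig",
    "sample_num_atoms",
    "generate",
    "generate_strided",
    "optimize_molecules",
    "train",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Empirical categorical prior p(N) over molecule sizes."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        support = np.asarray(self.support, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        if support.size == 0:
            raise ValueError("size distribution needs a non-empty support")
        if probs.shape != support.shape or abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must match support and sum to 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def from_sizes(cls, sizes) -> "SizeDistribution":
        support, counts = np.unique(np.asarray(sizes, dtype=np.int64),
                                    return_counts=True)
        return cls(support=support, probs=counts / counts.sum())

    def prob(self, n: int) -> float:
        hit = self.support == n
        return float(self.probs[hit][0]) if hit.any() else 0.0


def sample_num_atoms(dist: SizeDistribution, rng: np.random.Generator) -> int:
    """Draw an atom count from the empirical size prior."""
    return int(rng.choice(dist.support, p=dist.probs))


@dataclass
class GenerationConfig:
    """Reverse-chain controls: visited timesteps and optional conditioning."""

    n_steps: int | None = None  # None -> full grid (T steps)
    condition: tuple[str, float] | None = None
    seed: int | None = None

    def timestep_path(self, T: int) -> np.ndarray:
        k = T if self.n_steps is None else int(self.n_steps)
        if not (1 <= k <= T):
            raise ValueError(f"n_steps must lie in [1, {T}], got {k}")
        path = np.unique(np.round(np.linspace(0, T, k + 1)).astype(int))[::-1]
        if path[0] != T or path[-1] != 0:
            raise AssertionError("timestep path must run from T to 0")
        return path


def _reverse_chain(
    model: GCPDenoiser,
    schedule: NoiseSchedule,
    z: LatentState,
    path: np.ndarray,
    cond: float | None,
    rng: np.random.Generator,
) -> LatentState:
    """Run the reverse process along a strictly decreasing timestep path.

    Every intermediate transition is a stochastic ancestral step; the final
    transition to t = 0 takes the posterior mean (no extra noise before
    decoding).
    """
    for t, s in zip(path[:-1], path[1:]):
        eps = model.predict(z, int(t), cond)
        if s > 0:
            z = reverse_step(z, (eps.eps_x, eps.eps_h), int(s), schedule, rng)
        else:
            z0_tilde = predict_clean(z, (eps.eps_x, eps.eps_h), schedule)
            post = posterior_moments(z, z0_tilde, 0, schedule)
            z = LatentState(zx=post.mu_x - post.mu_x.mean(0, keepdims=True),
                            zh=post.mu_h, t=0)
    return z


def _prior_draw(N: int, n_feat: int, rng: np.random.Generator) -> LatentState:
    return LatentState(
        zx=sample_subspace_gaussian(N, rng),
        zh=rng.standard_normal((N, n_feat)),
        t=0,  # overwritten below; t is bookkeeping only
    )


def generate(
    model: GCPDenoiser,
    schedule: NoiseSchedule,
    N: int,
    config: GenerationConfig | None = None,
    rng: np.random.Generator | None = None,
    alphabet=QM9_ALPHABET,
) -> MoleculeRecord:
    """Sample one molecule with N atoms by full-grid ancestral denoising."""
    config = config or GenerationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cond = config.condition[1] if config.condition else None
    z = _prior_draw(N, model.n_feat, rng)
    z = LatentState(zx=z.zx, zh=z.zh, t=schedule.T)
    z0 = _reverse_chain(model, schedule, z, config.timestep_path(schedule.T),
                        cond, rng)
    mol = decode_latent(z0, alphabet=alphabet)
    if config.condition:
        mol.properties[config.condition[0] + "_target"] = config.condition[1]
    return mol


def generate_strided(
    model: GCPDenoiser,
    schedule: NoiseSchedule,
    N: int,
    k_steps: int,
    rng: np.random.Generator,
    condition: tuple[str, float] | None = None,
    alphabet=QM9_ALPHABET,
) -> MoleculeRecord:
    """Sample with only k evenly spaced reverse steps (time-scaled sampling)."""
    cfg = GenerationConfig(n_steps=k_steps, condition=condition)
    return generate(model, schedule, N, cfg, rng, alphabet)


def renoise_denoise(
    mols: list[MoleculeRecord],
    model: GCPDenoiser,
    schedule: NoiseSchedule,
    t_opt: int,
    rng: np.random.Generator,
    cond: float | None = None,
    alphabet=QM9_ALPHABET,
) -> list[MoleculeRecord]:
    """Forward-noise existing molecules to step t_opt and denoise them back.

    The shared mechanics behind property-guided optimization (conditional
    model + target) and its unconditional refinement baseline.  Atom counts
    are preserved; t_opt = 0 is the identity up to the featurise/decode
    round trip.
    """
    if not (0 <= t_opt <= schedule.T):
        raise ValueError(f"t_opt must lie in [0, {schedule.T}], got {t_opt}")
    out = []
    for mol in mols:
        z0, _ = featurize(mol, alphabet=alphabet)
        if t_opt == 0:
            out.append(decode_latent(z0, alphabet=alphabet))
            continue
        eps = (sample_subspace_gaussian(z0.N, rng),
               rng.standard_normal(z0.zh.shape))
        z_t = forward_noise(z0, t_opt, eps, schedule)
        path = np.arange(t_opt, -1, -1)
        z_new = _reverse_chain(model, schedule, z_t, path, cond, rng)
        out.append(decode_latent(z_new, alphabet=alphabet))
    return out


def optimize_molecules(
    mols: list[MoleculeRecord],
    cond_model: GCPDenoiser,
    schedule: NoiseSchedule,
    t_opt: int,
    target: float,
    rng: np.random.Generator,
    alphabet=QM9_ALPHABET,
) -> list[MoleculeRecord]:
    """Steer existing molecules toward a target property value.

    Each molecule is featurised, forward-noised to step t_opt via the exact
    forward marginal, then denoised back to t = 0 under the conditional
    model with the requested target value appended to its inputs.
    """
    if cond_model.config.condition_dim == 0:
        raise ValueError("optimization requires a property-conditional model")
    out = renoise_denoise(mols, cond_model, schedule, t_opt, rng,
                          cond=target, alphabet=alphabet)
    for mol in out:
        mol.properties["target"] = float(target)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    n_steps: int = 2000
    batch_size: int = 8
    lr: float = 1e-3
    lr_final: float | None = None  # linear decay target; None keeps lr constant
    ema_decay: float | None = None  # optional weight EMA (e.g. 0.999)
    val_every: int = 200
    condition_on: str | None = None  # property name for conditional training


@dataclass
class TrainResult:
    model: GCPDenoiser
    log: dict = field(default_factory=dict)


def _molecule_loss(model, z0, t, eps, cond):
    from .autodiff import Tensor

    z_t = forward_noise(z0, t, eps, model._schedule_ref)
    eps_x_hat, eps_h_hat = model.forward(z_t, t, cond)
    dx = eps_x_hat - Tensor(eps[0])
    dh = eps_h_hat - Tensor(eps[1])
    return ((dx * dx).sum() + (dh * dh).sum()) * 0.5


def train(
    model: GCPDenoiser,
    dataset,
    schedule: NoiseSchedule,
    hyperparams: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
    alphabet=QM9_ALPHABET,
    val_set=None,
) -> TrainResult:
    """Minimise the noise-matching loss with uniformly sampled timesteps.

    ``dataset``/``val_set`` are lists of MoleculeRecord.  Each gradient step
    draws a batch with replacement, a timestep t ~ U{1..T} per molecule, and
    one noise realisation; the loss is the batch mean of the per-molecule
    summed squared residuals (w(t) = 1).  ``ema_decay`` optionally keeps an
    exponential moving average of the weights and installs it at the end (a
    common stabiliser for long diffusion trainings; for short overfitting
    runs the averaging lags the anneal and the raw weights are better).
    The best-validation parameters are restored instead when a validation
    set is given.
    """
    hp = hyperparams or TrainConfig()
    rng = np.random.default_rng() if rng is None else rng
    if not dataset:
        raise ValueError("training dataset is empty")
    if hp.condition_on and model.config.condition_dim == 0:
        raise ValueError("conditional training requires condition_dim > 0")

    feats = []
    for mol in dataset:
        z0, _ = featurize(mol, alphabet=alphabet)
        cond = mol.properties[hp.condition_on] if hp.condition_on else None
        feats.append((z0, cond))
    val_feats = []
    if val_set:
        for mol in val_set:
            z0, _ = featurize(mol, alphabet=alphabet)
            cond = mol.properties[hp.condition_on] if hp.condition_on else None
            val_feats.append((z0, cond))

    model._schedule_ref = schedule  # used by _molecule_loss
    opt = Adam(model.parameters(), lr=hp.lr)
    T = schedule.T
    losses, val_losses = [], []
    best_val, best_params = np.inf, None
    ema = (None if hp.ema_decay is None or val_feats
           else {k: v.data.copy() for k, v in model.params.items()})

    def batch_loss(batch, loss_rng):
        total = None
        for z0, cond in batch:
            t = int(loss_rng.integers(1, T + 1))
            eps = (sample_subspace_gaussian(z0.N, loss_rng),
                   loss_rng.standard_normal(z0.zh.shape))
            l = _molecule_loss(model, z0, t, eps, cond)
            total = l if total is None else total + l
        return total * (1.0 / len(batch))

    for step in range(hp.n_steps):
        if hp.lr_final is not None and hp.n_steps > 1:
            frac = step / (hp.n_steps - 1)
            opt.lr = hp.lr + frac * (hp.lr_final - hp.lr)
        idx = rng.integers(0, len(feats), size=min(hp.batch_size, len(feats)))
        loss = batch_loss([feats[i] for i in idx], rng)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite training loss at step {step}: {float(loss.data)!r}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
        if ema is not None:
            d = hp.ema_decay
            for k, v in model.params.items():
                ema[k] = d * ema[k] + (1.0 - d) * v.data

        if val_feats and (step + 1) % hp.val_every == 0:
            vrng = np.random.default_rng(12345)  # fixed draws -> comparable evals
            vl = float(batch_loss(val_feats, vrng).data)
            val_losses.append(vl)
            if vl < best_val:
                best_val = vl
                best_params = {k: v.data.copy() for k, v in model.params.items()}

    if best_params is not None:
        for k, v in best_params.items():
            model.params[k].data = v
    elif ema is not None:
        for k, v in ema.items():
            model.params[k].data = v
    del model._schedule_ref
    return TrainResult(model=model, log={"train_loss": losses,
                                         "val_loss": val_losses})
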