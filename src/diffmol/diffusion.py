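"""Closed-form diffusion operations on the joint molecular latent state.

The latent state z = [z^(x), z^(h)] couples an equivariant coordinate channel
(confined to the zero-centre-of-gravity subspace, which makes the coordinate
likelihood translation-invariant) with an invariant feature channel carrying
scaled one-hot atom types and integer charges.  Everything in this module is
exact Gaussian algebra: forward noising to any step, the true denoising
posterior, the epsilon-parametrised reverse step, the training loss, and the
variational negative log-likelihood bound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm as _norm

from .schedule import NoiseSchedule, conditional_moments

__all__ = [
    "LatentState",
    "PosteriorMoments",
    "project_zero_cog",
    "sample_subspace_gaussian",
    "forward_noise",
    "posterior_moments",
    "predict_clean",
    "reverse_step",
    "diffusion_loss",
    "negative_log_likelihood",
]

#: predicted or true noise, as (eps_x, eps_h) arrays matching (zx, zh)
EpsPair = tuple[np.ndarray, np.ndarray]


@dataclass(frozen=True)
class LatentState:
    """Noisy joint variable z_t = [z^(x), z^(h)] at chain step t."""

    zx: np.ndarray  # (N, 3), zero column-mean
    zh: np.ndarray  # (N, d), scaled one-hot types + charge slot
    t: int

    @property
    def N(self) -> int:
        return self.zx.shape[0]

    def __post_init__(self):
        zx = np.asarray(self.zx, dtype=np.float64)
        zh = np.asarray(self.zh, dtype=np.float64)
        if zx.ndim != 2 or zx.shape[1] != 3:
            raise ValueError(f"zx must be (N, 3), got {zx.shape}")
        if zh.ndim != 2 or zh.shape[0] != zx.shape[0]:
            raise ValueError(f"zh must be (N, d) matching zx, got {zh.shape}")
        object.__setattr__(self, "zx", zx)
        object.__setattr__(self, "zh", zh)


@dataclass(frozen=True)
class PosteriorMoments:
    """Moments of the true denoising posterior q(z_s | z_t, z_0)."""

    mu_x: np.ndarray
    mu_h: np.ndarray
    sigma_t_to_s: float


def project_zero_cog(coords: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the subspace sum_i x_i = 0.

    Subtracting the column mean is the orthogonal projector onto the
    zero-centre-of-gravity subspace; it is idempotent and annihilates global
    translations.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError(f"coords must be (N>=1, 3), got {coords.shape}")
    return coords - coords.mean(axis=0, keepdims=True)


def sample_subspace_gaussian(N: int, rng: np.random.Generator) -> np.ndarray:
    """Standard Gaussian restricted to the zero-CoG subspace of R^{N x 3}.

    Drawing a full standard normal and projecting yields exactly the normal
    distribution on the subspace (the projector is orthogonal), with
    covariance P = I - (1/N) 11^T per spatial axis.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    eps = rng.standard_normal((N, 3))
    return eps - eps.mean(axis=0, keepdims=True)


def _check_zero_cog(x: np.ndarray, tol: float = 1e-6) -> None:
    drift = np.abs(x.mean(axis=0)).max()
    if drift > tol:
        raise ValueError(f"coordinate channel not zero-CoG (max drift {drift:.2e})")


def forward_noise(
    z0: LatentState, t: int, eps: EpsPair, schedule: NoiseSchedule
) -> LatentState:
    """Jump the clean state straight to step t: z_t = alpha_t z_0 + sigma_t eps.

    Uses the marginal scales (alpha_t, sigma_t): clean data sits in front of
    the chain, so q(z_t | data) is the marginal itself (this is the
    alpha_0 ~= 1 convention under which the transition 0 -> t coincides with
    the marginal, and it is what makes the noise-estimate inversion exact).
    ``eps`` must have a zero-CoG coordinate part so z_t stays on the
    subspace; shapes must match z0 channelwise.
    """
    eps_x, eps_h = eps
    eps_x = np.asarray(eps_x, dtype=np.float64)
    eps_h = np.asarray(eps_h, dtype=np.float64)
    if eps_x.shape != z0.zx.shape or eps_h.shape != z0.zh.shape:
        raise ValueError("eps shapes do not match the latent state")
    if not (0 <= t <= schedule.T):
        raise ValueError(f"t out of range [0, {schedule.T}]: {t}")
    _check_zero_cog(eps_x)
    alpha_t = float(schedule.alpha[t])
    sigma_t = float(schedule.sigma[t])
    zx = alpha_t * z0.zx + sigma_t * eps_x
    zh = alpha_t * z0.zh + sigma_t * eps_h
    return LatentState(zx=project_zero_cog(zx), zh=zh, t=int(t))


def posterior_moments(
    z_t: LatentState, z0: LatentState, s: int, schedule: NoiseSchedule
) -> PosteriorMoments:
    """Moments of q(z_s | z_t, z_0) for s < t (Bayes rule on the Gaussians).

    mu_{t->s} = (alpha_s sigma_{t|s}^2 / sigma_t^2) z_0
              + (alpha_{t|s} sigma_s^2 / sigma_t^2) z_t,
    sigma_{t->s} = sigma_{t|s} sigma_s / sigma_t.
    """
    t = z_t.t
    if not (0 <= s < t):
        raise ValueError(f"require 0 <= s < t, got s={s}, t={t}")
    sigma_t = float(schedule.sigma[t])
    if sigma_t == 0.0:
        raise ZeroDivisionError("posterior undefined at sigma_t = 0")
    m = conditional_moments(schedule, s, t)
    alpha_s = float(schedule.alpha[s])
    sigma_s = float(schedule.sigma[s])
    c0 = alpha_s * m.sigma_ts**2 / sigma_t**2
    ct = m.alpha_ts * sigma_s**2 / sigma_t**2
    return PosteriorMoments(
        mu_x=c0 * z0.zx + ct * z_t.zx,
        mu_h=c0 * z0.zh + ct * z_t.zh,
        sigma_t_to_s=m.sigma_ts * sigma_s / sigma_t,
    )


def predict_clean(
    z_t: LatentState, eps_hat: EpsPair, schedule: NoiseSchedule
) -> LatentState:
    """Invert the forward jump using a noise estimate:
    z~_0 = z_t / alpha_t - eps_hat * sigma_t / alpha_t (channelwise)."""
    if z_t.t < 1:
        raise ValueError("predict_clean requires t >= 1")
    alpha_t = float(schedule.alpha[z_t.t])
    sigma_t = float(schedule.sigma[z_t.t])
    if alpha_t < 1e-12:
        raise FloatingPointError(f"alpha_t={alpha_t:.3e} below numerical floor")
    eps_x, eps_h = eps_hat
    zx = z_t.zx / alpha_t - np.asarray(eps_x) * (sigma_t / alpha_t)
    zh = z_t.zh / alpha_t - np.asarray(eps_h) * (sigma_t / alpha_t)
    return LatentState(zx=project_zero_cog(zx), zh=zh, t=0)


def reverse_step(
    z_t: LatentState,
    eps_hat: EpsPair,
    s: int,
    schedule: NoiseSchedule,
    rng: np.random.Generator,
) -> LatentState:
    """One ancestral step z_t -> z_s of the learned reverse process.

    The network's noise estimate defines z~_0 (predict_clean); z_s is then a
    draw from the Gaussian posterior around mu_{t->s}(z_t, z~_0) with the
    coordinate noise drawn on the zero-CoG subspace, so the coordinate
    channel never leaves it.
    """
    z0_tilde = predict_clean(z_t, eps_hat, schedule)
    post = posterior_moments(z_t, z0_tilde, s, schedule)
    noise_x = sample_subspace_gaussian(z_t.N, rng)
    noise_h = rng.standard_normal(z_t.zh.shape)
    zx = post.mu_x + post.sigma_t_to_s * noise_x
    zh = post.mu_h + post.sigma_t_to_s * noise_h
    return LatentState(zx=project_zero_cog(zx), zh=zh, t=int(s))


def diffusion_loss(eps: EpsPair, eps_hat: EpsPair, w_t: float = 1.0) -> float:
    """Noise-matching objective 0.5 * w(t) * ||eps - eps_hat||^2.

    The squared norm runs over both channels of one molecule; batching code
    averages these per-molecule sums.  w(t) = 1 is the empirical choice used
    throughout.
    """
    (ex, eh), (exh, ehh) = eps, eps_hat
    ex, eh = np.asarray(ex), np.asarray(eh)
    exh, ehh = np.asarray(exh), np.asarray(ehh)
    if ex.shape != exh.shape or eh.shape != ehh.shape:
        raise ValueError("eps and eps_hat shapes differ")
    sq = float(np.sum((ex - exh) ** 2) + np.sum((eh - ehh) ** 2))
    return 0.5 * float(w_t) * sq


# ---------------------------------------------------------------------------
# Negative log-likelihood bound
# ---------------------------------------------------------------------------

def _gaussian_kl(mu: np.ndarray, sigma: float, d: int) -> float:
    # KL( N(mu, sigma^2 I_d) || N(0, I_d) )
    return 0.5 * (float(np.sum(mu**2)) + d * (sigma**2 - 1.0) - 2.0 * d * np.log(sigma))


def _log_discretized_gaussian(value: np.ndarray, mean: np.ndarray, sd: float) -> np.ndarray:
    # log P(value) with P the unit-width discretisation of N(mean, sd^2)
    upper = _norm.cdf((value + 0.5 - mean) / sd)
    lower = _norm.cdf((value - 0.5 - mean) / sd)
    return np.log(np.clip(upper - lower, 1e-30, None))


def negative_log_likelihood(
    molecule,
    denoiser: Callable[[LatentState, int], EpsPair],
    schedule: NoiseSchedule,
    size_dist=None,
    rng: np.random.Generator | None = None,
    *,
    alphabet: Sequence[str] | None = None,
    onehot_scale: float = 0.25,
    charge_scale: float = 0.1,
    n_draws: int = 1,
    return_terms: bool = False,
):
    """Variational bound on -log p(x, h, N) for one molecule.

    Assembled from (i) the prior term KL(q(z_T|z_0) || N(0, I)), (ii) the
    per-step terms L_t = 0.5 (SNR(s)/SNR(t) - 1) E||eps - eps_hat||^2 for
    t = 1..T with s = t-1 (estimated with ``n_draws`` noise draws each),
    (iii) the reconstruction term L_0 — Gaussian on the (N-1) x 3 coordinate
    subspace, discretised Gaussian (normalised across categories for the
    one-hot block) for the integer-valued features — and (iv) -log p(N) under
    the empirical size distribution.

    ``molecule`` may be a MoleculeRecord (featurised internally) or a
    LatentState already at t = 0; in the latter case ``alphabet`` gives the
    one-hot block width (charge slot is always last).
    """
    from .molecules import featurize  # local import avoids a cycle

    rng = np.random.default_rng() if rng is None else rng
    if isinstance(molecule, LatentState):
        z0 = molecule
        n_types = z0.zh.shape[1] - 1
    else:
        z0, _ = featurize(molecule, alphabet=alphabet,
                          onehot_scale=onehot_scale, charge_scale=charge_scale)
        n_types = len(alphabet) if alphabet is not None else z0.zh.shape[1] - 1

    N = z0.N
    d_x = (N - 1) * 3  # zero-CoG subspace dimensionality
    d_h = z0.zh.size
    T = schedule.T

    # integer-valued targets recovered from the scaled channel
    h_scaled = z0.zh
    h_int = np.empty_like(h_scaled)
    h_int[:, :n_types] = np.round(h_scaled[:, :n_types] / onehot_scale)
    h_int[:, n_types:] = np.round(h_scaled[:, n_types:] / charge_scale)

    # (iv) size prior
    if size_dist is not None:
        p_n = size_dist.prob(N)
        if p_n <= 0.0:
            raise ValueError(f"molecule size N={N} has zero probability under p(N)")
        log_p_n = float(np.log(p_n))
    else:
        log_p_n = 0.0

    # (i) prior term at t = T
    alpha_T = float(schedule.alpha[T])
    sigma_T = float(schedule.sigma[T])
    kl_prior = _gaussian_kl(alpha_T * z0.zx, sigma_T, d_x) + _gaussian_kl(
        alpha_T * z0.zh, sigma_T, d_h
    )

    # (ii) per-step terms
    snr = schedule.alpha**2 / schedule.sigma**2
    l_t = np.zeros(T + 1)
    for t in range(1, T + 1):
        w = float(snr[t - 1] / snr[t] - 1.0)
        acc = 0.0
        for _ in range(n_draws):
            eps = (sample_subspace_gaussian(N, rng), rng.standard_normal(z0.zh.shape))
            z_t = forward_noise(z0, t, eps, schedule)
            eps_hat = denoiser(z_t, t)
            acc += diffusion_loss(eps, eps_hat, w_t=w)
        l_t[t] = acc / n_draws

    # (iii) reconstruction at t = 0
    alpha_0 = float(schedule.alpha[0])
    sigma_0 = float(schedule.sigma[0])
    sd0 = sigma_0 / alpha_0
    eps0 = (sample_subspace_gaussian(N, rng), rng.standard_normal(z0.zh.shape))
    z_0 = forward_noise(z0, 0, eps0, schedule)
    eps_hat0 = denoiser(z_0, 0)
    # coordinates: Gaussian with std sigma_0/alpha_0 on the subspace
    neg_log_px = 0.5 * float(np.sum((eps0[0] - np.asarray(eps_hat0[0])) ** 2))
    neg_log_px += 0.5 * d_x * np.log(2.0 * np.pi * sd0**2)
    # features: discretised Gaussian around the unscaled estimate
    h_hat = z_0.zh / alpha_0 - np.asarray(eps_hat0[1]) * sd0
    h_hat_unscaled = np.empty_like(h_hat)
    h_hat_unscaled[:, :n_types] = h_hat[:, :n_types] / onehot_scale
    h_hat_unscaled[:, n_types:] = h_hat[:, n_types:] / charge_scale
    sd_onehot = sd0 / onehot_scale
    sd_charge = sd0 / charge_scale
    # one-hot block: probability of the interval around 1 for each class,
    # normalised across classes; score the true class
    log_pk = _log_discretized_gaussian(
        np.ones_like(h_hat_unscaled[:, :n_types]), h_hat_unscaled[:, :n_types], sd_onehot
    )
    log_norm = np.log(np.sum(np.exp(log_pk - log_pk.max(axis=1, keepdims=True)),
                             axis=1, keepdims=True)) + log_pk.max(axis=1, keepdims=True)
    log_p_onehot = float(np.sum((log_pk - log_norm) * h_int[:, :n_types]))
    log_p_charge = float(np.sum(_log_discretized_gaussian(
        h_int[:, n_types:], h_hat_unscaled[:, n_types:], sd_charge)))
    l_0 = neg_log_px - log_p_onehot - log_p_charge

    nll = kl_prior + float(l_t.sum()) + l_0 - log_p_n
    if return_terms:
        return {
            "nll": nll,
            "kl_prior": kl_prior,
            "l_t": l_t,
            "l_0": l_0,
            "log_p_n": log_p_n,
        }
    return nll
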