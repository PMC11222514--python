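"""Variance-preserving noise schedules for the joint molecular diffusion chain.

The forward chain q(z_t | z_{t-1}) = N(z_t | alpha_t z_{t-1}, sigma_t^2 I) is
fixed ahead of training.  Under the variance-preserving convention
alpha_t = sqrt(1 - sigma_t^2), so the whole chain is summarised by the tables
(alpha_t, sigma_t) for t = 0..T, and transitions between arbitrary steps
s <= t follow in closed form:

    alpha_{t|s}   = alpha_t / alpha_s
    sigma_{t|s}^2 = sigma_t^2 - alpha_{t|s}^2 sigma_s^2

The squared-coefficient form of the transition variance is the one consistent
with composing Gaussians (q(z_s|z_0) then q(z_t|z_s) must reproduce
q(z_t|z_0)); the tests verify this by Monte-Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSchedule",
    "ConditionalMoments",
    "build_noise_schedule",
    "conditional_moments",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-timestep (alpha_t, sigma_t) tables of a variance-preserving chain.

    Attributes
    ----------
    T : int
        Number of diffusion steps; tables have T + 1 entries (t = 0..T).
    alpha, sigma : ndarray, shape (T + 1,)
        Signal and noise scales, with alpha**2 + sigma**2 == 1 at each t.
    kind : str
        Schedule family identifier ("polynomial" or "cosine").
    precision : float
        Clipping parameter keeping alpha_0 near 1 and alpha_T near 0 without
        reaching the exact boundary (numerical stability).
    """

    T: int
    alpha: np.ndarray
    sigma: np.ndarray
    kind: str
    precision: float

    def snr(self, t: int | np.ndarray) -> np.ndarray:
        """Signal-to-noise ratio alpha_t^2 / sigma_t^2."""
        return self.alpha[t] ** 2 / self.sigma[t] ** 2

    def gamma(self, t: int | np.ndarray) -> np.ndarray:
        """Log-SNR parameterisation, gamma_t = -log SNR(t)."""
        return -np.log(self.snr(t))


@dataclass(frozen=True)
class ConditionalMoments:
    """Moments of the transition q(z_t | z_s) between two chain steps."""

    alpha_ts: float
    sigma_ts: float
    s: int
    t: int


def _clip_cumulative(alpha2: np.ndarray, clip_value: float = 0.001) -> np.ndarray:
    # Bound each stepwise ratio alpha2[t]/alpha2[t-1] below so the chain never
    # collapses numerically, then rebuild the cumulative product.
    ratios = alpha2[1:] / alpha2[:-1]
    ratios = np.clip(ratios, clip_value, 1.0)
    out = np.empty_like(alpha2)
    out[0] = alpha2[0]
    out[1:] = alpha2[0] * np.cumprod(ratios)
    return out


def build_noise_schedule(
    T: int, kind: str = "polynomial", precision: float = 1e-4
) -> NoiseSchedule:
    """Construct the (alpha_t, sigma_t) tables for a T-step chain.

    Parameters
    ----------
    T : int
        Number of diffusion steps (>= 1).  The published configuration uses
        T = 1000; smaller chains are useful for desk-scale models.
    kind : {"polynomial", "cosine"}
        Schedule family.  "polynomial" is the quadratic alpha^2 schedule of
        the equivariant-diffusion lineage this model extends,
        alpha_t^2 = (1 - (t/T)^2)^2 rescaled into [precision, 1 - 2*precision];
        "cosine" is the squared-cosine alternative.
    precision : float
        Small positive clipping constant in (0, 0.5).

    Returns
    -------
    NoiseSchedule
        With alpha non-increasing, sigma non-decreasing and
        alpha**2 + sigma**2 == 1 everywhere.
    """
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError(f"T must be a positive integer, got {T!r}")
    if not (0.0 < precision < 0.5):
        raise ValueError(f"precision must lie in (0, 0.5), got {precision!r}")

    t = np.arange(T + 1, dtype=np.float64)
    if kind == "polynomial":
        alpha2 = (1.0 - (t / (T + 1)) ** 2) ** 2
        alpha2 = _clip_cumulative(alpha2)
        alpha2 = (1.0 - 2.0 * precision) * alpha2 + precision
    elif kind == "cosine":
        s = precision
        f = np.cos((t / T + s) / (1 + s) * np.pi / 2) ** 2
        alpha2 = _clip_cumulative(f / f[0])
        alpha2 = (1.0 - 2.0 * precision) * alpha2 + precision
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")

    alpha = np.sqrt(alpha2)
    sigma = np.sqrt(1.0 - alpha2)
    return NoiseSchedule(T=int(T), alpha=alpha, sigma=sigma, kind=kind,
                         precision=float(precision))


def conditional_moments(schedule: NoiseSchedule, s: int, t: int) -> ConditionalMoments:
    """Closed-form moments of q(z_t | z_s) for 0 <= s <= t <= T.

    alpha_{t|s} = alpha_t/alpha_s and
    sigma_{t|s} = sqrt(sigma_t^2 - alpha_{t|s}^2 sigma_s^2), which is the
    unique choice under which forward transitions compose like Gaussians.
    """
    if s > t:
        raise ValueError(f"require s <= t, got s={s}, t={t}")
    if t > schedule.T or s < 0:
        raise ValueError(f"steps out of range [0, {schedule.T}]: s={s}, t={t}")
    alpha_ts = float(schedule.alpha[t] / schedule.alpha[s])
    var = float(schedule.sigma[t] ** 2 - alpha_ts**2 * schedule.sigma[s] ** 2)
    sigma_ts = float(np.sqrt(max(var, 0.0)))
    return ConditionalMoments(alpha_ts=alpha_ts, sigma_ts=sigma_ts, s=int(s), t=int(t))
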