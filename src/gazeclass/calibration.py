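"""Calibration of the synthetic cohort's latent attention model.

The simulator draws, for each participant and stimulus, a latent percentage of
the stimulus duration spent in each AoI: a normal draw clipped to [0, 100],
then rescaled proportionally whenever the within-stimulus sum exceeds the
participant's available share of the recording.  Clipping and rescaling shift
the moments away from the latent (mu, sigma), so the latent parameters cannot
simply be set to the published group means/SDs: doing so biases every derived
mean down by 3-6 percentage points.  Instead the latents are fitted so that
the *derived* percentages reproduce the published per-AoI means and SDs.

Fitting is joint per (group, stimulus) because the rescale step couples the
AoIs of one stimulus.  The objective is a weighted least-squares match of the
post-process means (weight 4) and SDs (weight 1) on a fixed common-random-
numbers sample.  In the saturated regime - stimuli whose published AoI means
sum to nearly the whole available recording, so rescaling is active for most
draws - the objective is invariant to scaling all latents up together; a soft
penalty on latent locations beyond 250 selects the least-saturated (least
shape-distorting) solution on that ridge.

Availability itself is modelled as a scaled Beta on [82, 100], moment-matched
in closed form to the published availability mean/SD of included participants.
A Beta (rather than a truncated normal) is required: no truncated normal on
[80, 100] has mean 95.3 with SD 5.5, and the 2-point margin above the 80%
exclusion threshold keeps per-sample binomial noise from flipping inclusion
of a nominally included participant.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .exceptions import ConfigurationError

__all__ = [
    "beta_availability_params",
    "draw_normal_availability",
    "clip_rescale",
    "calibrate_stimulus",
    "calibrate_latents",
]

AVAILABILITY_LO = 82.0
AVAILABILITY_HI = 100.0

#: Internal seed for the calibration sample; part of the definition of the
#: default cohort parameters, independent of user simulation seeds.
CALIBRATION_SEED = 12345


def beta_availability_params(mean: float, sd: float, lo: float = AVAILABILITY_LO, hi: float = AVAILABILITY_HI):
    """Closed-form (alpha, beta) for a scaled Beta on [lo, hi] with the given moments."""
    m = (mean - lo) / (hi - lo)
    v = (sd / (hi - lo)) ** 2
    if not 0 < m < 1:
        raise ConfigurationError(f"availability mean {mean} outside ({lo}, {hi})")
    if v >= m * (1 - m):
        raise ConfigurationError(f"availability sd {sd} infeasible for mean {mean} on [{lo}, {hi}]")
    s = m * (1 - m) / v - 1
    return m * s, (1 - m) * s


def draw_normal_availability(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Availability (percent) of normally tracking participants."""
    a, b = beta_availability_params(mean, sd)
    return AVAILABILITY_LO + (AVAILABILITY_HI - AVAILABILITY_LO) * rng.beta(a, b, size)


def clip_rescale(latent: np.ndarray, availability: np.ndarray) -> np.ndarray:
    """Apply the clip-to-[0,100] and sum<=availability rescale, vectorised.

    ``latent`` has shape (n_aoi, n); ``availability`` has shape (n,).
    Returns derived per-AoI target percentages of the full stimulus duration.
    """
    p = np.clip(latent, 0.0, 100.0)
    tot = p.sum(axis=0)
    factor = np.where(tot > availability, availability / np.maximum(tot, 1e-12), 1.0)
    return p * factor


def _moments(mus, sigmas, availability, z):
    q = clip_rescale(mus[:, None] + sigmas[:, None] * z, availability)
    return q.mean(axis=1), q.std(axis=1)


def calibrate_stimulus(
    target_means,
    target_sds,
    availability_mean: float,
    availability_sd: float,
    n_mc: int = 120_000,
    seed: int = CALIBRATION_SEED,
    mean_weight: float = 4.0,
    penalty_weight: float = 1e-4,
    penalty_threshold: float = 250.0,
    maxiter: int = 4000,
):
    """Fit latent (mu, sigma) per AoI of one stimulus for one group.

    Returns ``(mus, sigmas)`` such that the clip+rescale process applied to
    N(mu, sigma) draws, under the group's availability distribution,
    reproduces ``target_means``/``target_sds``.
    """
    tm = np.asarray(target_means, dtype=float)
    ts = np.asarray(target_sds, dtype=float)
    if np.any(tm < 0) or np.any(tm > 100):
        raise ConfigurationError("target means must lie in [0, 100]")
    if np.any(ts < 0):
        raise ConfigurationError("target SDs must be non-negative")
    k = len(tm)
    rng = np.random.default_rng(seed)
    av = draw_normal_availability(availability_mean, availability_sd, n_mc, rng)
    z = rng.standard_normal((k, n_mc))
    saturated = tm.sum() > 0.93 * av.mean()

    def loss(x):
        mus = x[:k]
        sigmas = np.exp(x[k:])
        m, s = _moments(mus, sigmas, av, z)
        pen = penalty_weight * np.sum(np.maximum(np.abs(mus) - penalty_threshold, 0.0) ** 2)
        return mean_weight * np.sum((m - tm) ** 2) + np.sum((s - ts) ** 2) + pen

    best = None
    scales = (1.5, 3.0) if saturated else (1.0,)
    for scale in scales:
        x0 = np.concatenate([tm * scale, np.log(np.maximum(ts, 0.5) * (2.0 if saturated else 1.2) * scale**0.5)])
        res = optimize.minimize(
            loss,
            x0,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-7, "adaptive": True},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:k], np.exp(best.x[k:])


def calibrate_latents(targets, availability, n_mc: int = 120_000, seed: int = CALIBRATION_SEED):
    """Calibrate every (group, stimulus) cell.

    Parameters
    ----------
    targets : mapping ``(group, stimulus_id) -> list of (aoi_id, mean, sd)``
    availability : mapping ``group -> (mean, sd)`` of included participants

    Returns a list of records ``(group, stimulus_id, aoi_id, mu, sigma)``.
    """
    records = []
    for (group, stim), rows in targets.items():
        av_mean, av_sd = availability[group]
        mus, sigmas = calibrate_stimulus(
            [r[1] for r in rows],
            [r[2] for r in rows],
            av_mean,
            av_sd,
            n_mc=n_mc,
            seed=seed,
        )
        for (aoi_id, _, _), mu, sigma in zip(rows, mus, sigmas):
            records.append((group, stim, aoi_id, float(mu), float(sigma)))
    return records
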