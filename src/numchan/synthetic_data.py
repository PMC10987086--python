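"""Generative model of numerosity-tuned sensorimotor channels.

The simulator produces cohorts of observers whose reproduction precision
(Weber fraction, Wf) at each target numerosity is determined by a small
bank of channels with Gaussian tuning in log-numerosity coordinates.
Each observer carries one Wf per channel, drawn around a population mean;
behaviour at a probed numerosity is the tuning-weighted average of the
channel Wfs, optionally corrupted by trial-sampling error (a finite number
of reproduction trials) and by additive measurement noise on the realized
Wf.  Trial-level responses follow Weber's law: the SD of the reproduced
count is proportional to the target.

All randomness flows from explicit seeds through numpy Generators; every
public simulation entry point accepts either an integer seed or a
``numpy.random.Generator``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .preprocessing import WfMatrix

__all__ = [
    "TARGET_SET",
    "FWHM_TO_SIGMA",
    "ChannelModelConfig",
    "ObserverProfile",
    "TrialRecord",
    "channel_sensitivity",
    "channel_peaks",
    "effective_wf",
    "simulate_cohort",
    "simulate_trials",
    "simulate_trial_table",
]

logger = logging.getLogger(__name__)

#: The eleven target numerosities of the number-matching task.
TARGET_SET: tuple[int, ...] = (8, 10, 11, 13, 14, 16, 19, 21, 24, 28, 32)

#: sigma = FWHM * FWHM_TO_SIGMA for a Gaussian (1 / (2 sqrt(2 ln 2))).
FWHM_TO_SIGMA: float = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Typical tapping rates (Hz) by condition, used to give simulated trials
#: realistic response durations.
DEFAULT_RATES_HZ: dict[str, float] = {"fast": 6.8, "slow": 3.3, "duration": 3.5}


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator from an int seed, an existing Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration and record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelModelConfig:
    """Parameters of the generative channel/observer model.

    Parameters
    ----------
    n_channels
        Number of tuned channels.  ``1`` denotes the flat (untuned) model,
        which has no peaks and infinitely broad tuning.
    peaks
        Preferred numerosity of each channel, strictly increasing.  Empty
        for the flat model.
    fwhm_octaves
        Full width at half maximum of the Gaussian tuning, in octaves
        (log2 units).  Ignored by the flat model.
    mean_wf
        Population mean Weber fraction of a channel (0.176 in the
        number-matching data the model was built for).
    observer_sd
        SD of the per-observer, per-channel Wf around ``mean_wf``.
    noise_sd
        SD of additive measurement noise applied to each realized Wf.
    n_reps
        Reproduction trials per target per observer when simulating at the
        trial level.
    target_set
        Ordered target numerosities probed in the experiment.
    shared_observer_deviate
        If True, a single Gaussian deviate per observer is shared by all
        channels (perfectly correlated channel Wfs); default draws one
        deviate per channel independently.
    lognormal_responses
        If True, trial responses are lognormal with matched coefficient of
        variation rather than (rounded) normal.
    """

    n_channels: int
    peaks: tuple[float, ...] = ()
    fwhm_octaves: float | None = None
    mean_wf: float = 0.176
    observer_sd: float = 0.08
    noise_sd: float = 0.065
    n_reps: int = 25
    target_set: tuple[float, ...] = TARGET_SET
    shared_observer_deviate: bool = False
    lognormal_responses: bool = False

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        peaks = tuple(float(p) for p in self.peaks)
        object.__setattr__(self, "peaks", peaks)
        if self.n_channels == 1:
            if peaks:
                raise ValueError("the 1-channel flat model has no peaks")
        else:
            if len(peaks) != self.n_channels:
                raise ValueError(
                    f"expected {self.n_channels} peaks, got {len(peaks)}"
                )
            if any(p <= 0 for p in peaks):
                raise ValueError("channel peaks must be positive")
            if any(b <= a for a, b in zip(peaks, peaks[1:])):
                raise ValueError("channel peaks must be strictly increasing")
            if self.fwhm_octaves is None or self.fwhm_octaves <= 0:
                raise ValueError("fwhm_octaves must be positive for tuned models")
        if self.mean_wf <= 0:
            raise ValueError("mean_wf must be positive")
        if self.observer_sd < 0 or self.noise_sd < 0:
            raise ValueError("observer_sd and noise_sd must be non-negative")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (Wf undefined otherwise)")
        targets = tuple(float(t) for t in self.target_set)
        if len(targets) < 2 or any(t <= 0 for t in targets):
            raise ValueError("target_set needs >= 2 positive targets")
        if any(b <= a for a, b in zip(targets, targets[1:])):
            raise ValueError("target_set must be strictly increasing")
        object.__setattr__(self, "target_set", targets)

    # -- constructors -------------------------------------------------------

    @classmethod
    def flat(cls, **kwargs) -> "ChannelModelConfig":
        """The untuned 1-channel model (flat tuning across all targets)."""
        return cls(n_channels=1, peaks=(), fwhm_octaves=None, **kwargs)

    @classmethod
    def two_channel(cls, fwhm_octaves: float = 1.45, lo: float = 8.0,
                    hi: float = 32.0, **kwargs) -> "ChannelModelConfig":
        """Two channels at the range extremes (defaults 8 and 32, 1.45 oct)."""
        return cls(n_channels=2, peaks=tuple(channel_peaks(2, lo, hi)),
                   fwhm_octaves=fwhm_octaves, **kwargs)

    @classmethod
    def four_channel(cls, fwhm_octaves: float = 1.10, lo: float = 8.0,
                     hi: float = 32.0, **kwargs) -> "ChannelModelConfig":
        """Four log-spaced channels (defaults 8, 12.7, 20.1, 32; 1.10 oct)."""
        return cls(n_channels=4, peaks=tuple(channel_peaks(4, lo, hi)),
                   fwhm_octaves=fwhm_octaves, **kwargs)

    @classmethod
    def tuned(cls, n_channels: int, fwhm_octaves: float, lo: float = 8.0,
              hi: float = 32.0, **kwargs) -> "ChannelModelConfig":
        return cls(n_channels=n_channels,
                   peaks=tuple(channel_peaks(n_channels, lo, hi)),
                   fwhm_octaves=fwhm_octaves, **kwargs)

    def with_(self, **kwargs) -> "ChannelModelConfig":
        """A copy with the given fields replaced."""
        return replace(self, **kwargs)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "peaks": list(self.peaks),
            "fwhm_octaves": self.fwhm_octaves,
            "mean_wf": self.mean_wf,
            "observer_sd": self.observer_sd,
            "noise_sd": self.noise_sd,
            "n_reps": self.n_reps,
            "target_set": list(self.target_set),
            "shared_observer_deviate": self.shared_observer_deviate,
            "lognormal_responses": self.lognormal_responses,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelModelConfig":
        d = dict(d)
        d["peaks"] = tuple(d.get("peaks") or ())
        d["target_set"] = tuple(d.get("target_set") or TARGET_SET)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChannelModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ObserverProfile:
    """One simulated observer: one Weber fraction per channel (all > 0)."""

    observer_id: str
    channel_wfs: tuple[float, ...]

    def __post_init__(self) -> None:
        wfs = tuple(float(w) for w in self.channel_wfs)
        if not wfs or any(w <= 0 for w in wfs):
            raise ValueError("channel_wfs must be positive and non-empty")
        object.__setattr__(self, "channel_wfs", wfs)


@dataclass(frozen=True)
class TrialRecord:
    """A single reproduction trial."""

    participant_id: str
    condition: str  # "fast" | "slow" | "duration"
    target: float  # numerosity (count) or duration (s)
    response_count: int
    response_duration: float

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError("target must be positive")
        if self.response_count < 0 or self.response_duration < 0:
            raise ValueError("responses must be non-negative")


# ---------------------------------------------------------------------------
# Tuning primitives
# ---------------------------------------------------------------------------


def channel_sensitivity(peak, fwhm_octaves, n):
    """Gaussian tuning in log2-numerosity: weight in (0, 1].

    ``weight = exp(-(log2(n/peak))^2 / (2 sigma^2))`` with
    ``sigma = fwhm_octaves / (2 sqrt(2 ln 2))``.  Maximal (1) at the peak,
    symmetric in log space, and scale-free: rescaling peak and probe by a
    common factor leaves the weight unchanged.
    """
    peak = np.asarray(peak, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(peak <= 0) or np.any(n <= 0):
        raise ValueError("peak and n must be positive")
    if not fwhm_octaves > 0:
        raise ValueError("fwhm_octaves must be positive")
    sigma = fwhm_octaves * FWHM_TO_SIGMA
    z = np.log2(n / peak) / sigma
    out = np.exp(-0.5 * z * z)
    return out if out.ndim else float(out)


def channel_peaks(n_channels: int, lo: float, hi: float) -> np.ndarray:
    """Equally log-spaced channel peaks from ``lo`` to ``hi`` inclusive.

    Defined for two or more channels; the 1-channel model is flat and has
    no peak (use :meth:`ChannelModelConfig.flat`).
    """
    if n_channels < 2:
        raise ValueError(
            "peaks are defined for n_channels >= 2; the 1-channel model is "
            "flat (ChannelModelConfig.flat)"
        )
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    return np.geomspace(lo, hi, n_channels)


def _tuning_weights(config: ChannelModelConfig) -> np.ndarray:
    """(n_channels, n_targets) normalized tuning weights at the target set."""
    targets = np.asarray(config.target_set, dtype=float)
    if config.n_channels == 1:
        return np.ones((1, targets.size))
    peaks = np.asarray(config.peaks, dtype=float)
    w = channel_sensitivity(peaks[:, None], config.fwhm_octaves, targets[None, :])
    return w / w.sum(axis=0, keepdims=True)


def effective_wf(profile, n, config: ChannelModelConfig):
    """Tuning-weighted average of an observer's channel Wfs at numerosity n.

    For the flat model this is the single channel Wf regardless of ``n``.
    Raises if every channel weight underflows to zero (probe too far from
    all channels).
    """
    wfs = np.asarray(
        profile.channel_wfs if isinstance(profile, ObserverProfile) else profile,
        dtype=float,
    )
    if wfs.shape[-1] != config.n_channels:
        raise ValueError("profile must hold one Wf per channel")
    n_arr = np.asarray(n, dtype=float)
    if config.n_channels == 1:
        out = np.broadcast_to(wfs[..., 0], np.broadcast_shapes(wfs[..., 0].shape,
                                                               n_arr.shape)).copy()
        return out if out.ndim else float(out)
    peaks = np.asarray(config.peaks, dtype=float)
    w = channel_sensitivity(peaks, config.fwhm_octaves, n_arr[..., None])
    total = w.sum(axis=-1)
    if np.any(total == 0):
        raise ValueError("all channel weights are zero: n is too far from every channel")
    out = (w * wfs).sum(axis=-1) / total
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Trial-level simulation
# ---------------------------------------------------------------------------


def simulate_trials(
    wf: float,
    target: float,
    n_reps: int,
    seed: int | np.random.Generator | None = None,
    *,
    participant_id: str = "S1",
    condition: str = "fast",
    rate_hz: float | None = None,
    lognormal: bool = False,
) -> list[TrialRecord]:
    """Simulate reproduction trials at one target for one observer.

    Responses are drawn from Normal(target, wf * target), rounded to the
    nearest count and floored at 1 — the Weber's-law scalar-noise model.
    The response duration is count / rate, with the tapping rate fixed once
    per call (defaults by condition: fast 6.8 Hz, slow 3.3 Hz).
    """
    if wf < 0:
        raise ValueError("wf must be >= 0")
    if target <= 0:
        raise ValueError("target must be positive")
    if n_reps < 2:
        raise ValueError("need n_reps >= 2 (the Wf estimator is undefined below)")
    rng = as_rng(seed)
    rate = rate_hz if rate_hz is not None else DEFAULT_RATES_HZ.get(condition, 6.8)
    counts = _draw_counts(float(target), float(wf),
                          rng.standard_normal(n_reps), lognormal=lognormal)
    return [
        TrialRecord(
            participant_id=participant_id,
            condition=condition,
            target=float(target),
            response_count=int(c),
            response_duration=float(c / rate),
        )
        for c in counts
    ]


def _draw_counts(target: float, wf, z: np.ndarray, *, lognormal: bool = False):
    """Map standard-normal deviates to integer response counts (>= 1)."""
    if lognormal:
        # matched coefficient of variation and mean: sigma^2 = ln(1 + wf^2)
        sig = np.sqrt(np.log1p(np.square(wf)))
        raw = target * np.exp(sig * z - 0.5 * sig * sig)
    else:
        raw = target * (1.0 + np.multiply(wf, z))
    return np.maximum(np.rint(raw), 1.0)


def simulate_trial_table(
    config: ChannelModelConfig,
    n_observers: int,
    seed: int | np.random.Generator | None = None,
    *,
    condition: str = "fast",
    rate_mean_hz: float | None = None,
    rate_sd_hz: float = 1.0,
) -> pd.DataFrame:
    """Simulate a full long-format trial table for a cohort.

    Each observer gets channel Wfs drawn from the config, a personal tapping
    rate (truncated normal around the condition's typical rate), and
    ``config.n_reps`` trials at every target.  The measurement noise
    ``noise_sd`` perturbs each observer x target cell's generating Wf
    (truncated positive) before trials are drawn, so cell-level precision
    fluctuates beyond pure trial sampling, as in the analytic model.
    Columns match the on-disk trial CSV: participant_id, condition,
    target, response_count, response_duration.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    rng = as_rng(seed)
    rate_mean = rate_mean_hz if rate_mean_hz is not None else \
        DEFAULT_RATES_HZ.get(condition, 6.8)
    profiles = _draw_profiles(config, (1, n_observers), rng)[0]  # (O, C)
    wf_eff = _effective_wf_profiles(profiles, config)  # (O, T)
    if config.noise_sd > 0:
        wf_eff = _truncated_normal(wf_eff, config.noise_sd,
                                   rng.random(wf_eff.shape))
    rates = _truncated_normal(rate_mean, rate_sd_hz,
                              rng.random(n_observers), lower=0.5)
    targets = np.asarray(config.target_set)
    rows = []
    width = len(str(n_observers))
    for o in range(n_observers):
        pid = f"S{o + 1:0{width}d}"
        for t_idx, target in enumerate(targets):
            counts = _draw_counts(float(target), wf_eff[o, t_idx],
                                  rng.standard_normal(config.n_reps),
                                  lognormal=config.lognormal_responses)
            for c in counts:
                rows.append((pid, condition, float(target), int(c),
                             float(c / rates[o])))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "target",
                 "response_count", "response_duration"],
    )


# ---------------------------------------------------------------------------
# Cohort simulation (vectorised core shared with the model-fitting grid)
# ---------------------------------------------------------------------------


def _truncated_normal(mean, sd, u, lower=0.0):
    """Exact truncated-normal sampling from uniforms (inverse-CDF).

    Sampling through shared uniforms keeps common random numbers valid when
    the same draws are reused across parameter-grid points.
    """
    mean = np.asarray(mean, dtype=float)
    sd_arr = np.asarray(sd, dtype=float)
    if np.all(sd_arr == 0):
        return np.broadcast_to(mean, np.asarray(u).shape).copy()
    a = ndtr((lower - mean) / np.where(sd_arr > 0, sd_arr, 1.0))
    q = np.clip(a + np.asarray(u) * (1.0 - a), 1e-300, 1 - 1e-16)
    out = mean + sd_arr * ndtri(q)
    return np.where(sd_arr > 0, out, mean + 0 * np.asarray(u))


@dataclass
class CohortDraws:
    """Pre-drawn uniform/normal deviates for cohort simulation.

    Drawing once and reusing across a parameter grid implements common
    random numbers: grid points differ only through the parameters, not
    through sampling noise.
    """

    u_obs: np.ndarray      # (E, O, C) uniforms -> observer channel Wfs
    z_trials: np.ndarray | None  # (E, O, T, R) std normals -> trial responses
    u_noise: np.ndarray    # (E, O, T) uniforms -> measurement noise

    @classmethod
    def draw(cls, n_experiments: int, n_observers: int, n_targets: int,
             n_reps: int, n_channels: int,
             rng: np.random.Generator, mode: str = "trials") -> "CohortDraws":
        E, O, T = n_experiments, n_observers, n_targets
        u_obs = rng.random((E, O, n_channels))
        z_trials = (rng.standard_normal((E, O, T, n_reps))
                    if mode == "trials" else None)
        u_noise = rng.random((E, O, T))
        return cls(u_obs=u_obs, z_trials=z_trials, u_noise=u_noise)


def _draw_profiles(config: ChannelModelConfig, shape_eo: tuple[int, int],
                   rng: np.random.Generator) -> np.ndarray:
    """(E, O, C) channel Wfs, truncated positive."""
    E, O = shape_eo
    C = config.n_channels
    u = rng.random((E, O, 1 if config.shared_observer_deviate else C))
    wfs = _truncated_normal(config.mean_wf, config.observer_sd, u)
    if config.shared_observer_deviate:
        wfs = np.broadcast_to(wfs, (E, O, C)).copy()
    return wfs


def _profiles_from_draws(config: ChannelModelConfig, u_obs: np.ndarray) -> np.ndarray:
    if config.shared_observer_deviate:
        u_obs = u_obs[..., :1]
    wfs = _truncated_normal(config.mean_wf, config.observer_sd, u_obs)
    if config.shared_observer_deviate:
        wfs = np.broadcast_to(wfs, u_obs.shape[:-1] + (config.n_channels,)).copy()
    return wfs


def _effective_wf_profiles(profiles: np.ndarray,
                           config: ChannelModelConfig) -> np.ndarray:
    """(..., C) channel Wfs -> (..., T) effective Wfs at the target set."""
    if config.n_channels == 1:
        return np.repeat(profiles[..., :1], len(config.target_set), axis=-1)
    wn = _tuning_weights(config)  # (C, T), columns sum to 1
    return profiles @ wn


def _wf_stack_from_draws(config: ChannelModelConfig, draws: CohortDraws,
                         mode: str) -> np.ndarray:
    """Realized Wf matrices for every experiment: (E, O, T).

    mode "analytic": effective Wf plus truncated measurement noise.
    mode "trials":   n_reps simulated responses -> sample SD / mean, plus
                     the same truncated measurement noise.
    """
    profiles = _profiles_from_draws(config, draws.u_obs)
    wf_eff = _effective_wf_profiles(profiles, config)  # (E, O, T)
    if mode == "analytic":
        base = wf_eff
    elif mode == "trials":
        if draws.z_trials is None:
            raise ValueError("draws lack trial deviates for mode='trials'")
        targets = np.asarray(config.target_set)  # (T,)
        counts = _draw_counts(targets[None, None, :, None],
                              wf_eff[..., None], draws.z_trials,
                              lognormal=config.lognormal_responses)
        m = counts.mean(axis=-1)
        s = counts.std(axis=-1, ddof=1)
        base = s / m
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'analytic' or 'trials'")
    if config.noise_sd == 0:
        return base
    # additive noise truncated so realized Wf stays positive
    return _truncated_normal(base, config.noise_sd, draws.u_noise)


def simulate_wf_stack(config: ChannelModelConfig, n_observers: int,
                      n_experiments: int, seed, mode: str = "trials",
                      ) -> np.ndarray:
    """Simulate ``n_experiments`` cohorts at once; returns (E, O, T) Wfs."""
    if n_observers < 2:
        raise ValueError("n_observers must be >= 2")
    rng = as_rng(seed)
    draws = CohortDraws.draw(n_experiments, n_observers,
                             len(config.target_set), config.n_reps,
                             config.n_channels, rng, mode)
    return _wf_stack_from_draws(config, draws, mode)


def simulate_cohort(config: ChannelModelConfig, n_observers: int,
                    seed: int | np.random.Generator | None = None,
                    mode: str = "trials", condition: str = "sim",
                    ) -> WfMatrix:
    """Simulate one cohort and return its participants x targets Wf matrix.

    ``mode="analytic"`` realizes each Wf as effective Wf + measurement
    noise; ``mode="trials"`` simulates ``config.n_reps`` reproduction
    trials per cell and estimates the Wf as sample SD / mean before adding
    measurement noise.  Deterministic for a fixed seed.
    """
    values = simulate_wf_stack(config, n_observers, 1, seed, mode)[0]
    width = len(str(n_observers))
    participants = [f"S{o + 1:0{width}d}" for o in range(n_observers)]
    return WfMatrix(participants=participants,
                    targets=np.asarray(config.target_set, dtype=float),
                    values=values, condition=condition)
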