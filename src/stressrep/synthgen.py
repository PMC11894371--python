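"""Seeded generator of replicated stress-response curve datasets.

Produces datasets spanning a gradient of repeatability: each individual has
a latent monotone-rise response profile, replicates are the profile plus
individual-specific Gaussian noise (noise level log-spaced across
individuals), and an optional fraction of the noisiest individuals has a
random subset of replicates reflected about their own mean to force curve
crossings without changing per-curve means.

Presets mirror three useful structures: an 11x4x4 panel, a 5x28x2 two-point
panel, and a 10x10x3 three-point panel.
"""

from __future__ import annotations

import dataclasses
import string
from typing import Sequence

import numpy as np

from .data_model import CurveMatrix, StressCurveDataset, ValidationError

PRESET_SHAPES = {
    # name: (n_individuals, n_replicates, times in minutes)
    "synthetic": (11, 4, (0.0, 10.0, 20.0, 30.0)),
    "two_point": (5, 28, (0.0, 30.0)),
    "three_point": (10, 10, (0.0, 15.0, 30.0)),
}


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset draw."""

    n_individuals: int
    n_replicates: int
    times: tuple
    seed: int
    baseline_mean: float = 5.0
    peak_mean: float = 30.0
    noise_sd_range: tuple = (0.3, 8.0)
    crossing_fraction: float = 0.2
    reflect_probability: float = 0.25
    floor: float = 0.1
    name: str = "synthetic-curves"

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("times must be strictly increasing with length >= 2")
        lo, hi = self.noise_sd_range
        if lo < 0 or lo > hi:
            raise ValidationError("noise_sd_range must satisfy 0 <= sd_min <= sd_max")
        if not 0.0 <= self.crossing_fraction <= 1.0:
            raise ValidationError("crossing_fraction must be in [0, 1]")
        if not 0.0 < self.reflect_probability <= 1.0:
            raise ValidationError("reflect_probability must be in (0, 1]")
        if self.floor <= 0:
            raise ValidationError("floor must be positive (keeps values KL-safe)")


def preset(name: str, seed: int, **overrides) -> SyntheticConfig:
    """Config with a preset's dimensions and default physiological magnitudes."""
    if name not in PRESET_SHAPES:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_SHAPES)}"
        )
    n_ind, n_rep, times = PRESET_SHAPES[name]
    fields = dict(
        n_individuals=n_ind,
        n_replicates=n_rep,
        times=times,
        seed=seed,
        name=name,
    )
    fields.update(overrides)
    return SyntheticConfig(**fields)


def _individual_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"I{i + 1:03d}" for i in range(n)]


def _noise_levels(cfg: SyntheticConfig) -> np.ndarray:
    lo, hi = cfg.noise_sd_range
    if cfg.n_individuals == 1 or lo == hi:
        return np.full(cfg.n_individuals, hi)
    if lo > 0:
        return np.geomspace(lo, hi, cfg.n_individuals)
    return np.linspace(lo, hi, cfg.n_individuals)  # log spacing undefined at 0


def _rise_shape(times: np.ndarray) -> np.ndarray:
    # Monotone rise: 0 at the first timepoint, 1 at 30 min (or at the last
    # timepoint when the grid does not reach 30).
    t0 = times[0]
    ref = 30.0 if times[-1] >= 30.0 else times[-1]
    return (times - t0) / (ref - t0)


def generate(cfg: SyntheticConfig) -> StressCurveDataset:
    """Draw a complete dataset; deterministic given the config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.times)
    profile = cfg.baseline_mean + (cfg.peak_mean - cfg.baseline_mean) * _rise_shape(times)
    sigmas = _noise_levels(cfg)
    ids = _individual_ids(cfg.n_individuals)
    n_crossing = int(round(cfg.crossing_fraction * cfg.n_individuals))
    crossing_ids = set(ids[cfg.n_individuals - n_crossing :]) if n_crossing else set()

    curves = []
    for ident, sigma in zip(ids, sigmas):
        values = profile[None, :] + rng.normal(0.0, sigma, (cfg.n_replicates, len(times)))
        if ident in crossing_ids:
            flip = rng.random(cfg.n_replicates) < cfg.reflect_probability
            if not flip.any():
                flip[0] = True
            row_means = values.mean(axis=1, keepdims=True)
            values[flip] = 2.0 * row_means[flip] - values[flip]
        values = np.maximum(cfg.floor, values)
        curves.append(CurveMatrix(individual_id=ident, times=times, values=values))
    return StressCurveDataset(name=cfg.name, curves=curves)


def noise_order(cfg: SyntheticConfig) -> list[str]:
    """Individual ids from least to most noisy (ground-truth repeatability order)."""
    return _individual_ids(cfg.n_individuals)
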