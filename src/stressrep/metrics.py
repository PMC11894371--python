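"""Discrete-individual repeatability metrics for replicated response curves.

Three metrics are provided, each collapsing one individual's replicate
curves to a single score:

``PR``
    Profile repeatability on [0, 1] (1 = perfectly repeatable), built from
    per-timepoint variances, the maximum variance, curve crossings, and an
    interpolation penalty for filled-in missing cells.
``KL``
    Generalized (unnormalized) Kullback-Leibler divergence averaged over
    successive ordered replicate pairs; 0 = perfectly repeatable, unbounded
    above.
``RMSSD``
    Root mean square of successive differences of per-replicate mean
    levels; 0 = perfectly repeatable, unbounded above.

Only ``PR`` tolerates missing cells (they are interpolated and penalized);
``KL`` and ``RMSSD`` refuse incomplete matrices.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import CurveMatrix, StressCurveDataset

METRICS = ("PR", "KL", "RMSSD")

#: Direction metadata: True if a larger score means a more repeatable individual.
HIGHER_IS_MORE_REPEATABLE = {"PR": True, "KL": False, "RMSSD": False}

#: Provenance tag for the profile-repeatability functional form in use.
PR_VARIANT = "meanmax-variance/crossing/interp-penalty-v1"


class MetricError(ValueError):
    """A metric's preconditions are not met by the given curve."""


@dataclasses.dataclass(frozen=True)
class ProfileRepeatabilityDetail:
    per_time_variance: np.ndarray
    max_variance: float
    crossings: int
    max_crossings: int
    n_interpolated: int
    raw_dispersion: float
    score: float


@dataclasses.dataclass(frozen=True)
class KlDetail:
    pairwise_divergences: np.ndarray
    score: float


@dataclasses.dataclass(frozen=True)
class RmssdDetail:
    replicate_means: np.ndarray
    score: float


def fill_missing_replicates(curve: CurveMatrix) -> tuple[CurveMatrix, int]:
    """Interpolate missing cells in replicate-index space at fixed timepoints.

    A missing cell ``(r, t)`` is filled linearly between the nearest present
    replicates below and above it in collection order, at the same
    timepoint.  When no present replicate exists below (or above) -- i.e.
    the first (or last) replicates are missing -- the gap is bridged
    cyclically between the last present and the next present replicate, so
    a single missing boundary replicate receives the mean of those two
    values.

    Returns the filled matrix (empty mask) and the number of filled cells.
    """
    if curve.is_complete:
        return curve, 0
    n_rep = curve.n_replicates
    values = curve.values.copy()
    n_filled = 0
    for t in range(curve.n_timepoints):
        col = values[:, t]
        present = np.flatnonzero(~curve.missing_mask[:, t])
        if present.size < 2:
            raise MetricError(
                f"individual {curve.individual_id!r}: timepoint {curve.times[t]} has "
                f"fewer than 2 present replicate values; cannot interpolate"
            )
        for r in np.flatnonzero(curve.missing_mask[:, t]):
            below = present[present < r]
            above = present[present > r]
            r_prev = below[-1] if below.size else present[-1]
            r_next = above[0] if above.size else present[0]
            gap = (r_next - r_prev) % n_rep
            offset = (r - r_prev) % n_rep
            col[r] = col[r_prev] + (offset / gap) * (col[r_next] - col[r_prev])
            n_filled += 1
    filled = CurveMatrix(
        individual_id=curve.individual_id,
        times=curve.times,
        values=values,
        missing_mask=np.zeros_like(curve.missing_mask),
    )
    return filled, n_filled


def _require_complete(curve: CurveMatrix, metric: str) -> None:
    if not curve.is_complete:
        raise MetricError(
            f"individual {curve.individual_id!r}: {metric} cannot handle missing datapoints"
        )


def count_crossings(curve: CurveMatrix) -> int:
    """Count strict sign reversals of pairwise replicate differences.

    For every unordered replicate pair and every adjacent time interval, a
    crossing is counted when the difference between the two curves has
    strictly opposite signs at the interval's endpoints.  A zero difference
    at an endpoint (curves touching) is not a crossing.
    """
    _require_complete(curve, "crossing count")
    values = curve.values
    n_rep = curve.n_replicates
    total = 0
    for i in range(n_rep - 1):
        d = values[i] - values[i + 1 :]  # (n_rep-1-i, T)
        total += int(np.sum(d[:, :-1] * d[:, 1:] < 0))
    return total


def max_crossings(n_replicates: int, n_timepoints: int) -> int:
    """Upper bound on crossings: every pair crosses in every interval."""
    return (n_timepoints - 1) * n_replicates * (n_replicates - 1) // 2


def profile_repeatability(curve: CurveMatrix) -> tuple[float, ProfileRepeatabilityDetail]:
    """Profile repeatability score on [0, 1]; 1 = perfectly repeatable.

    Missing cells are first interpolated (see
    :func:`fill_missing_replicates`).  With the filled matrix ``X`` and its
    grand mean ``G``, per-timepoint sample variances (``ddof=1``) are
    normalized by ``G**2`` for scale invariance.  The dispersion

    ``S = (mean_t v_t + max_t v_t) * (1 + C/C_max) * (1 + m/(R*T))``

    combines the normalized variances, the crossing count ``C`` relative to
    its maximum, and a penalty for the ``m`` interpolated cells; the score
    is ``1 / (1 + S)``.
    """
    filled, n_interpolated = fill_missing_replicates(curve)
    values = filled.values
    grand_mean = values.mean()
    if grand_mean == 0:
        raise MetricError(
            f"individual {curve.individual_id!r}: grand mean is 0, scale undefined"
        )
    n_rep, n_time = values.shape
    v = values.var(axis=0, ddof=1) / grand_mean**2
    crossings = count_crossings(filled)
    c_max = max_crossings(n_rep, n_time)
    dispersion = (
        (v.mean() + v.max())
        * (1.0 + crossings / c_max)
        * (1.0 + n_interpolated / (n_rep * n_time))
    )
    score = 1.0 / (1.0 + dispersion)
    detail = ProfileRepeatabilityDetail(
        per_time_variance=v,
        max_variance=float(v.max()),
        crossings=crossings,
        max_crossings=c_max,
        n_interpolated=n_interpolated,
        raw_dispersion=float(dispersion),
        score=float(score),
    )
    return float(score), detail


def generalized_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Generalized KL divergence sum(p*ln(p/q) - p + q) for positive vectors.

    The correction terms keep the divergence nonnegative on unnormalized
    series; it is 0 iff ``p == q`` elementwise.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.sum(p * np.log(p / q) - p + q))


def kl_divergence_score(curve: CurveMatrix) -> tuple[float, KlDetail]:
    """Mean generalized KL divergence over successive ordered replicate pairs.

    Raw (unnormalized) curves are compared directly; replicate collection
    order matters and the score is 0 iff all successive curves are
    identical.  Requires a complete matrix of strictly positive values.
    """
    _require_complete(curve, "KL divergence")
    bad = np.argwhere(curve.values <= 0)
    if bad.size:
        r, t = bad[0]
        raise MetricError(
            f"individual {curve.individual_id!r}: non-positive value "
            f"{curve.values[r, t]} at replicate {r + 1}, time {curve.times[t]}; "
            f"KL divergence requires strictly positive values"
        )
    values = curve.values
    divs = np.array(
        [generalized_kl(values[r], values[r + 1]) for r in range(curve.n_replicates - 1)]
    )
    score = float(divs.mean())
    return score, KlDetail(pairwise_divergences=divs, score=score)


def hpa_flexibility_score(curve: CurveMatrix) -> tuple[float, RmssdDetail]:
    """RMSSD of per-replicate mean levels, in collection order.

    Each replicate curve is collapsed to its unweighted mean over
    timepoints; the score is
    ``sqrt(mean(successive squared differences))`` of those means.  0 means
    all replicate means are equal (maximally repeatable / least flexible).
    """
    _require_complete(curve, "RMSSD")
    means = curve.values.mean(axis=1)
    score = float(np.sqrt(np.mean(np.diff(means) ** 2)))
    return score, RmssdDetail(replicate_means=means, score=score)


_SCORERS = {
    "PR": lambda c: profile_repeatability(c)[0],
    "KL": lambda c: kl_divergence_score(c)[0],
    "RMSSD": lambda c: hpa_flexibility_score(c)[0],
}


def score_curve(curve: CurveMatrix, metric: str) -> float:
    if metric not in _SCORERS:
        raise MetricError(f"unknown metric {metric!r}; choose from {METRICS}")
    return _SCORERS[metric](curve)


def score_dataset(
    ds: StressCurveDataset, metrics: Sequence[str] = METRICS
) -> pd.DataFrame:
    """Score every individual with every requested metric.

    Returns a tidy frame with columns ``individual``, ``metric``,
    ``score`` -- one row per (individual, metric), deterministic given the
    input.  Metric errors are re-raised annotated with the individual id.
    """
    for m in metrics:
        if m not in _SCORERS:
            raise MetricError(f"unknown metric {m!r}; choose from {METRICS}")
    rows = []
    for curve in ds:
        for metric in metrics:
            try:
                score = _SCORERS[metric](curve)
            except MetricError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise MetricError(
                    f"individual {curve.individual_id!r}: {metric} failed: {exc}"
                ) from exc
            rows.append((curve.individual_id, metric, score))
    return pd.DataFrame(rows, columns=["individual", "metric", "score"])
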