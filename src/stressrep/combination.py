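"""Replicate-subsampling ("combination") analysis against the consensus score.

For each individual, every replicate subset of size k (or a capped random
sample of distinct subsets when there are more than ``cap`` of them) is
scored with each metric and compared to the consensus score computed from
all replicates.  This quantifies how representative scores based on few
replicates are of the full-data score.
"""

from __future__ import annotations

import hashlib
import math
from itertools import combinations as _combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import StressCurveDataset, ValidationError
from .metrics import METRICS, MetricError, score_curve

DEFAULT_CAP = 100


def enumerate_or_sample_subsets(
    n: int,
    k: int,
    cap: int = DEFAULT_CAP,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[int, ...]]:
    """All k-subsets of range(n), or ``cap`` distinct ones sampled uniformly.

    When ``C(n, k) <= cap`` every subset is returned in lexicographic
    order; otherwise exactly ``cap`` distinct subsets are drawn uniformly
    without replacement (reproducible for a given ``rng`` seed).  Subsets
    are 0-based sorted index tuples, preserving original replicate order.
    """
    if k < 2 or k > n:
        raise ValidationError(f"subset size k={k} must satisfy 2 <= k <= n={n}")
    total = math.comb(n, k)
    if total <= cap:
        return list(_combinations(range(n), k))
    if rng is None:
        raise ValidationError(
            f"C({n},{k})={total} exceeds cap={cap}; a seed/rng is required to sample"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < cap:
        chosen.add(tuple(sorted(rng.choice(n, size=k, replace=False).tolist())))
    return sorted(chosen)


def subset_label(indices: Sequence[int]) -> str:
    """Serialize a 0-based index subset as '+'-joined 1-based indices."""
    return "+".join(str(i + 1) for i in indices)


def _stream(seed: int, individual_id: str, k: int) -> np.random.Generator:
    # One RNG stream per (individual, k): adding individuals to a dataset
    # must not perturb the subsets sampled for the others.
    digest = hashlib.sha256(individual_id.encode("utf-8")).digest()
    ident = int.from_bytes(digest[:8], "big")
    return np.random.default_rng([seed, ident, k])


def combination_analysis(
    ds: StressCurveDataset,
    metrics: Sequence[str] = METRICS,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
    ks: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Score replicate subsets of every size against the consensus score.

    For every individual and every subset size ``k`` from 2 up to the
    dataset's replicate count ``R`` (the single full set at ``k = R`` being
    the consensus), each subset's curve restriction is scored with each
    requested metric.  ``ks`` restricts the sizes computed; the consensus
    score is always attached.

    Returns a tidy frame with columns ``individual``, ``metric``, ``k``,
    ``subset_id``, ``score``, ``consensus_score``.
    """
    n_rep = ds.n_replicates
    if ks is None:
        ks = range(2, n_rep + 1)
    ks = sorted(set(int(k) for k in ks))
    for k in ks:
        if k < 2 or k > n_rep:
            raise ValidationError(f"subset size k={k} out of range 2..{n_rep}")
    rows = []
    for curve in ds:
        consensus = {}
        for metric in metrics:
            try:
                consensus[metric] = score_curve(curve, metric)
            except MetricError as exc:
                raise MetricError(
                    f"individual {curve.individual_id!r} (consensus): {exc}"
                ) from exc
        for k in ks:
            subsets = enumerate_or_sample_subsets(
                n_rep, k, cap=cap, rng=_stream(seed, curve.individual_id, k)
            )
            for subset in subsets:
                sub = curve.restrict(subset)
                for metric in metrics:
                    try:
                        score = score_curve(sub, metric)
                    except MetricError as exc:
                        raise MetricError(
                            f"individual {curve.individual_id!r}, k={k}, "
                            f"subset {subset_label(subset)}: {exc}"
                        ) from exc
                    rows.append(
                        (
                            curve.individual_id,
                            metric,
                            k,
                            subset_label(subset),
                            score,
                            consensus[metric],
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["individual", "metric", "k", "subset_id", "score", "consensus_score"],
    )


def summarize_combinations(result: pd.DataFrame) -> pd.DataFrame:
    """Per (individual, metric, k) summary of the subset score distribution.

    Columns: ``n_subsets``, ``median``, ``mean``, ``variance`` (sample,
    NaN for a single subset), ``iqr``, plus the consensus score.
    """
    def _agg(group: pd.DataFrame) -> pd.Series:
        s = group["score"]
        q1, q3 = s.quantile([0.25, 0.75])
        return pd.Series(
            {
                "n_subsets": len(s),
                "median": s.median(),
                "mean": s.mean(),
                "variance": s.var(ddof=1),
                "iqr": q3 - q1,
                "consensus_score": group["consensus_score"].iloc[0],
            }
        )

    out = (
        result.groupby(["individual", "metric", "k"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_subsets"] = out["n_subsets"].astype(int)
    return out
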