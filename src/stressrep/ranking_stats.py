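"""Tie-aware repeatability rankings and rank-vector correlations.

Scores on different scales (and with opposite directions) are made
comparable by ranking individuals from most to least repeatable with
competition ("min") ranking: tied individuals share the smallest applicable
rank and the next distinct value skips ahead by the size of the tie group.
Pairwise Pearson correlations are then computed on the integer rank
vectors, with two-sided p-values from the t transform and significance
codes.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ParseError, ValidationError
from .metrics import HIGHER_IS_MORE_REPEATABLE

#: (threshold, code) pairs checked in order; p below the threshold earns the code.
DEFAULT_ALPHA_CODES = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "."))


def significance_stars(p: float, alpha_codes=DEFAULT_ALPHA_CODES) -> str:
    """Map a p-value to its significance code ('' when nothing applies)."""
    if not np.isfinite(p):
        return ""
    for threshold, code in alpha_codes:
        if p < threshold:
            return code
    return ""


def competition_rank(values: Sequence[float], higher_is_better: bool) -> np.ndarray:
    """Competition ("min") ranks, 1 = best; ties share the smallest rank."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("cannot rank non-finite scores")
    keyed = -values if higher_is_better else values
    return stats.rankdata(keyed, method="min").astype(int)


def rank_scores(
    scores: pd.DataFrame,
    tie_decimals: int | None = None,
    directions: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Rank individuals per metric from most (rank 1) to least repeatable.

    Parameters
    ----------
    scores
        Tidy frame with columns ``individual``, ``metric``, ``score``.
    tie_decimals
        Optional rounding applied to scores before ranking, so near-ties at
        a given precision become exact ties.  Default: no rounding; ties
        require exact score equality.
    directions
        Map metric name -> True if higher scores are more repeatable.
        Defaults to the built-in metric directions (PR up, KL/RMSSD down).

    Returns a wide frame indexed by individual (input order preserved) with
    one integer rank column per metric.
    """
    directions = dict(HIGHER_IS_MORE_REPEATABLE if directions is None else directions)
    for col in ("individual", "metric", "score"):
        if col not in scores.columns:
            raise ValidationError(f"scores table lacks required column {col!r}")
    individuals = list(dict.fromkeys(scores["individual"]))
    out = pd.DataFrame(index=pd.Index(individuals, name="individual"))
    for metric in dict.fromkeys(scores["metric"]):
        if metric not in directions:
            raise ValidationError(f"no direction metadata for metric {metric!r}")
        sub = scores[scores["metric"] == metric].set_index("individual")["score"]
        if sub.index.duplicated().any():
            raise ValidationError(f"duplicate scores for metric {metric!r}")
        if len(sub) < 2:
            raise ValidationError(f"metric {metric!r}: need at least 2 individuals")
        vals = sub.reindex(out.index).to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError(f"metric {metric!r}: missing score for some individuals")
        if tie_decimals is not None:
            vals = np.round(vals, tie_decimals)
        out[metric] = competition_rank(vals, directions[metric])
    return out


def read_external_ranks(path, sep: str | None = None, name: str | None = None) -> pd.Series:
    """Read a two-column (individual, rank) delimited file as a rank column."""
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (individual, rank)")
    series = pd.Series(
        pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(),
        index=pd.Index(df.iloc[:, 0].astype(str), name="individual"),
        name=name or str(df.columns[1]),
    )
    if series.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate individual ids")
    return series


def attach_ranks(ranks: pd.DataFrame, external: pd.Series) -> pd.DataFrame:
    """Merge an external rank column onto a rank table by individual id."""
    missing = [i for i in ranks.index if i not in external.index]
    extra = [i for i in external.index if i not in ranks.index]
    if missing or extra:
        raise ValidationError(
            f"external rank column {external.name!r} does not cover the same "
            f"individuals (missing {missing or 'none'}, unmatched {extra or 'none'})"
        )
    out = ranks.copy()
    out[external.name] = external.reindex(ranks.index).astype(int)
    return out


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:  # snap exact linear relations hit by rounding
        r = 1.0 if r > 0 else -1.0
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_ranks(
    ranks: pd.DataFrame, alpha_codes=DEFAULT_ALPHA_CODES
) -> pd.DataFrame:
    """Pearson correlations between every unordered pair of rank columns.

    Requires at least 3 individuals and complete columns over the same
    individual set.  A zero-variance column (all individuals tied) makes r
    undefined; the pair is reported with NaN and a warning rather than an
    exception.

    Returns a tidy frame with columns ``column_a``, ``column_b``, ``n``,
    ``r``, ``p``, ``stars``.
    """
    if len(ranks) < 3:
        raise ValidationError("need at least 3 individuals to correlate ranks")
    if ranks.isna().any().any():
        raise ValidationError("rank table has missing entries")
    rows = []
    for a, b in combinations(ranks.columns, 2):
        x = ranks[a].to_numpy(dtype=float)
        y = ranks[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"rank column with zero variance in pair ({a!r}, {b!r}); "
                f"correlation undefined",
                stacklevel=2,
            )
            r, p = float("nan"), float("nan")
        else:
            r, p = _pearson_with_p(x, y)
        rows.append((a, b, len(x), r, p, significance_stars(p, alpha_codes)))
    return pd.DataFrame(rows, columns=["column_a", "column_b", "n", "r", "p", "stars"])


def correlation_matrix(ranks: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric matrix of rank correlations with unit diagonal."""
    long = correlate_ranks(ranks)
    cols = list(ranks.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for row in long.itertuples(index=False):
        mat.loc[row.column_a, row.column_b] = row.r
        mat.loc[row.column_b, row.column_a] = row.r
    return mat
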