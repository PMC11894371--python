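"""Bundled reference tables of scores, ranks, and visual rankings.

Three example panels of repeatability results ship with the package:
``synthetic`` (11 individuals, 4 replicates of 4 timepoints), ``two_point``
(5 individuals, 28 replicates of 2 timepoints), and ``three_point`` (10
individuals, 10 replicates of 3 timepoints).  For each individual the table
holds the human visual rankings (majority, and for the synthetic panel also
a minority ranking) alongside the scores and competition ranks of the three
metrics.  These serve as fixtures for the ranking and correlation
machinery; the underlying raw curves are not distributed.
"""

from __future__ import annotations

import pandas as pd

# dataset, individual, majority_rank, minority_rank,
# pr_score, pr_rank, kl_score, kl_rank, rmssd_score, rmssd_rank
_ROWS = [
    ("synthetic", "E", 1, 8, 0.99, 1, 0.61, 1, 19.13, 6),
    ("synthetic", "B", 2, 2, 0.99, 2, 2.55, 2, 14.52, 2),
    ("synthetic", "D", 3, 6, 0.99, 3, 3.50, 3, 31.54, 11),
    ("synthetic", "F", 4, 4, 0.98, 4, 30.45, 11, 18.21, 5),
    ("synthetic", "G", 5, 3, 0.96, 5, 19.27, 8, 31.06, 10),
    ("synthetic", "I", 6, 1, 0.95, 6, 15.84, 5, 16.56, 3),
    ("synthetic", "C", 7, 4, 0.89, 8, 15.45, 4, 13.67, 1),
    ("synthetic", "H", 8, 7, 0.44, 10, 24.06, 10, 20.39, 7),
    ("synthetic", "A", 9, 8, 0.20, 11, 21.67, 9, 18.08, 4),
    ("synthetic", "J", 10, 10, 0.90, 7, 15.84, 5, 21.88, 8),
    ("synthetic", "K", 11, 11, 0.76, 9, 15.84, 5, 23.93, 9),
    ("two_point", "C", 1, None, 0.96, 1, 14.10, 2, 17.33, 1),
    ("two_point", "E", 2, None, 0.94, 2, 9.42, 1, 24.31, 3),
    ("two_point", "A", 3, None, 0.70, 4, 15.31, 3, 27.21, 4),
    ("two_point", "B", 4, None, 0.53, 5, 15.89, 4, 31.05, 5),
    ("two_point", "D", 5, None, 0.81, 3, 20.57, 5, 24.27, 2),
    ("three_point", "H", 1, None, 0.63, 7, 11.80, 4, 29.63, 9),
    ("three_point", "F", 2, None, 0.87, 2, 10.44, 1, 24.46, 7),
    ("three_point", "C", 3, None, 0.86, 3, 14.84, 6, 19.02, 3),
    ("three_point", "E", 4, None, 0.71, 6, 18.84, 10, 22.26, 5),
    ("three_point", "I", 5, None, 0.85, 4, 14.18, 5, 17.08, 1),
    ("three_point", "A", 6, None, 0.84, 5, 16.61, 8, 27.78, 8),
    ("three_point", "J", 7, None, 0.89, 1, 11.60, 3, 20.09, 4),
    ("three_point", "B", 8, None, 0.34, 9, 18.01, 9, 17.64, 2),
    ("three_point", "G", 9, None, 0.05, 10, 15.03, 7, 32.60, 10),
    ("three_point", "D", 10, None, 0.50, 8, 10.57, 2, 24.44, 6),
]

_COLUMNS = [
    "dataset",
    "individual",
    "majority_rank",
    "minority_rank",
    "pr_score",
    "pr_rank",
    "kl_score",
    "kl_rank",
    "rmssd_score",
    "rmssd_rank",
]


def load_reference_table(dataset: str | None = None) -> pd.DataFrame:
    """Return the bundled reference score/rank table.

    Parameters
    ----------
    dataset
        Optional panel name (``synthetic``, ``two_point``, ``three_point``)
        to select a single panel; by default all rows are returned.
    """
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    if dataset is not None:
        if dataset not in set(df["dataset"]):
            raise KeyError(dataset)
        df = df[df["dataset"] == dataset].reset_index(drop=True)
    return df


def reference_scores(dataset: str) -> pd.DataFrame:
    """Panel scores in the tidy (individual, metric, score) layout."""
    wide = load_reference_table(dataset)
    rows = []
    for row in wide.itertuples(index=False):
        rows.append((row.individual, "PR", row.pr_score))
        rows.append((row.individual, "KL", row.kl_score))
        rows.append((row.individual, "RMSSD", row.rmssd_score))
    return pd.DataFrame(rows, columns=["individual", "metric", "score"])


def reference_ranks(dataset: str) -> pd.DataFrame:
    """Panel rank columns (metric ranks plus visual rankings), wide layout."""
    wide = load_reference_table(dataset).set_index("individual")
    out = pd.DataFrame(
        {
            "PR": wide["pr_rank"],
            "KL": wide["kl_rank"],
            "RMSSD": wide["rmssd_rank"],
            "majority": wide["majority_rank"],
        }
    )
    if wide["minority_rank"].notna().all():
        out["minority"] = wide["minority_rank"].astype(int)
    return out.astype(int, errors="ignore")
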