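"""Core data structures and long-format table I/O for replicated response curves.

A *curve* is one complete time course of a response variable (e.g. plasma
corticosterone in ng/mL over a restraint protocol).  Each individual carries
several replicate curves collected on different occasions; the collection
order of replicates is semantically meaningful and is preserved everywhere.

The on-disk exchange format is a long ("tidy") delimited table with the
header ``individual,replicate,time,value``.  An empty ``value`` field marks a
missing measurement.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("individual", "replicate", "time", "value")


class ValidationError(ValueError):
    """A dataset or table violates a structural invariant."""


class ParseError(ValueError):
    """An input file could not be interpreted."""


@dataclasses.dataclass(frozen=True)
class CurveMatrix:
    """Replicate-by-timepoint response values for one individual.

    Parameters
    ----------
    individual_id
        Label of the individual.
    times
        Strictly increasing time grid (minutes), length ``T >= 2``.
    values
        ``(R, T)`` float matrix with replicates as rows, in collection
        order (``R >= 2``).  Cells flagged missing are stored as NaN.
    missing_mask
        ``(R, T)`` boolean matrix, ``True`` where the value is absent.
        Defaults to the NaN pattern of ``values``.
    """

    individual_id: str
    times: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            mask = np.isnan(values)
        else:
            mask = np.asarray(self.missing_mask, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", np.where(mask, np.nan, values))
        object.__setattr__(self, "missing_mask", mask)
        self._validate()

    def _validate(self) -> None:
        ident = self.individual_id
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValidationError(
                f"individual {ident!r}: need at least 2 timepoints, got {self.times.size}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"individual {ident!r}: times must be strictly increasing")
        if self.values.ndim != 2:
            raise ValidationError(f"individual {ident!r}: values must be a 2-D matrix")
        n_rep, n_time = self.values.shape
        if n_time != self.times.size:
            raise ValidationError(
                f"individual {ident!r}: values have {n_time} columns but {self.times.size} times"
            )
        if n_rep < 2:
            raise ValidationError(
                f"individual {ident!r}: need at least 2 replicates, got {n_rep}"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError(f"individual {ident!r}: mask shape mismatch")
        present = ~self.missing_mask
        if not np.all(np.isfinite(self.values[present])):
            raise ValidationError(f"individual {ident!r}: non-finite value present")
        if np.any(present.sum(axis=1) < 1):
            raise ValidationError(
                f"individual {ident!r}: every replicate needs at least one present value"
            )
        if np.any(present.sum(axis=0) < 2):
            raise ValidationError(
                f"individual {ident!r}: every timepoint needs at least two present values"
            )

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def restrict(self, replicate_indices: Sequence[int]) -> "CurveMatrix":
        """Return the sub-matrix holding only the given replicates.

        Indices are 0-based and are applied in sorted order so the original
        collection order is preserved within the subset.
        """
        idx = sorted(int(i) for i in replicate_indices)
        if len(set(idx)) != len(idx):
            raise ValidationError("duplicate replicate index in subset")
        if idx and (idx[0] < 0 or idx[-1] >= self.n_replicates):
            raise ValidationError("replicate index out of range")
        return CurveMatrix(
            individual_id=self.individual_id,
            times=self.times,
            values=self.values[idx, :],
            missing_mask=self.missing_mask[idx, :],
        )


@dataclasses.dataclass(frozen=True)
class StressCurveDataset:
    """A named collection of :class:`CurveMatrix` sharing one time grid.

    All members must have identical time grids and identical replicate
    counts; scores and ranks are only comparable within such a collection.
    """

    name: str
    curves: tuple

    def __post_init__(self) -> None:
        curves = tuple(self.curves)
        object.__setattr__(self, "curves", curves)
        if not curves:
            raise ValidationError(f"dataset {self.name!r}: no curves")
        ids = [c.individual_id for c in curves]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"dataset {self.name!r}: duplicate individual ids")
        ref = curves[0]
        for c in curves[1:]:
            if not np.array_equal(c.times, ref.times):
                raise ValidationError(
                    f"dataset {self.name!r}: individual {c.individual_id!r} has a "
                    f"different time grid than {ref.individual_id!r}"
                )
            if c.n_replicates != ref.n_replicates:
                raise ValidationError(
                    f"dataset {self.name!r}: individual {c.individual_id!r} has "
                    f"{c.n_replicates} replicates but {ref.individual_id!r} has "
                    f"{ref.n_replicates}"
                )

    @property
    def shared_times(self) -> np.ndarray:
        return self.curves[0].times

    @property
    def n_replicates(self) -> int:
        return self.curves[0].n_replicates

    @property
    def individual_ids(self) -> list:
        return [c.individual_id for c in self.curves]

    def __iter__(self):
        return iter(self.curves)

    def __len__(self) -> int:
        return len(self.curves)

    def get(self, individual_id: str) -> CurveMatrix:
        for c in self.curves:
            if c.individual_id == individual_id:
                return c
        raise KeyError(individual_id)


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_curves(path, sep: str | None = None, name: str | None = None) -> StressCurveDataset:
    """Read a long-format curve table into a validated dataset.

    The file must be UTF-8 delimited text (comma by default, tab accepted)
    with the header ``individual,replicate,time,value``.  Replicate order is
    the order of first appearance of each replicate identifier within its
    individual; times are sorted ascending.  Absent cells and empty
    ``value`` fields become missing-mask entries.
    """
    if sep is None:
        sep = _sniff_sep(path)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required column(s) {missing_cols}")

    def _numeric(col: str, allow_empty: bool) -> pd.Series:
        stripped = raw[col].str.strip()
        out = pd.to_numeric(stripped.replace("", np.nan), errors="coerce")
        bad = out.isna() & (stripped != "")
        if not allow_empty:
            bad |= stripped == ""
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise ParseError(f"{path}: line {line}: bad {col!r} field {raw[col][bad.idxmax()]!r}")
        return out

    time = _numeric("time", allow_empty=False)
    value = _numeric("value", allow_empty=True)
    df = pd.DataFrame(
        {
            "individual": raw["individual"].str.strip(),
            "replicate": raw["replicate"].str.strip(),
            "time": time,
            "value": value,
        }
    )
    times = np.array(sorted(df["time"].unique()), dtype=float)
    time_pos = {t: i for i, t in enumerate(times)}

    curves = []
    for ind in df["individual"].unique():
        sub = df[df["individual"] == ind]
        ind_times = np.array(sorted(sub["time"].unique()), dtype=float)
        if not np.array_equal(ind_times, times):
            raise ValidationError(
                f"{path}: individual {ind!r} uses time grid {ind_times.tolist()} "
                f"but the file-wide grid is {times.tolist()}"
            )
        reps = list(dict.fromkeys(sub["replicate"]))  # first-appearance order
        mat = np.full((len(reps), len(times)), np.nan)
        seen = set()
        for row in sub.itertuples(index=False):
            key = (row.replicate, row.time)
            if key in seen:
                raise ParseError(
                    f"{path}: duplicate cell for individual {ind!r}, "
                    f"replicate {row.replicate!r}, time {row.time}"
                )
            seen.add(key)
            mat[reps.index(row.replicate), time_pos[row.time]] = row.value
        curves.append(CurveMatrix(individual_id=str(ind), times=times, values=mat))
    return StressCurveDataset(name=name or str(path), curves=curves)


def write_curves(ds: StressCurveDataset, path, sep: str = ",") -> None:
    """Write a dataset back to the long exchange format (missing cells omitted)."""
    rows = []
    for curve in ds:
        for r in range(curve.n_replicates):
            for t, time in enumerate(curve.times):
                if curve.missing_mask[r, t]:
                    val = ""
                else:
                    val = curve.values[r, t]
                rows.append((curve.individual_id, r + 1, time, val))
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    write_table(df, path, sep=sep)


def write_table(table: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a tidy result table as delimited text.

    Floats are rendered with 12 significant digits so a read-back
    round-trips within 1e-9 relative error.  Empty tables are rejected.
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty table")
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read back a tidy result table written by :func:`write_table`."""
    if sep is None:
        sep = _sniff_sep(path)
    return pd.read_csv(path, sep=sep)
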