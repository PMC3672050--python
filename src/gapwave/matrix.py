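"""Expression-table I/O, between-array quantile normalisation and probe collapse.

The pipeline consumes one-colour microarray intensity tables: rows are probes
(or transcripts after collapsing), columns are sampling days of a recovery
time course.  Between-array quantile normalisation equalises the per-day
intensity distributions; probes mapping to the same transcript are then
collapsed by their median, retaining the per-probe values so the downstream
reliability filter can measure probe dispersion at the most extreme time
point.  The order is fixed: normalise at probe level first, then collapse.

All downstream statistics run on ``log2(signal + 1)``; the matrices here stay
on whichever scale they were built on and carry a ``scale`` tag.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

_log = logging.getLogger(__name__)

VALID_SCALES = ("linear", "log2")


@dataclasses.dataclass
class ExpressionMatrix:
    """Features x sampling-days expression table.

    Parameters
    ----------
    values : 2-D float array, one row per feature, one column per day.
    row_ids : unique feature identifiers (probe or transcript ids).
    col_days : strictly increasing integer days post-irradiation.
    scale : ``"linear"`` (raw intensities) or ``"log2"`` (log2(x + 1)).
    """

    values: np.ndarray
    row_ids: list
    col_days: np.ndarray
    scale: str = "linear"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.col_days = np.asarray(self.col_days, dtype=int)
        self.row_ids = [str(r) for r in self.row_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.row_ids) != n:
            raise ValueError("row_ids length does not match values")
        if len(self.col_days) != m:
            raise ValueError("col_days length does not match values")
        if m < 2:
            raise ValueError("need at least 2 day columns")
        if np.any(np.diff(self.col_days) <= 0):
            raise ValueError("col_days must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    def to_log2(self) -> "ExpressionMatrix":
        """Return the matrix on log2(x + 1) scale (no-op if already log2)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(
            np.log2(self.values + 1.0), list(self.row_ids), self.col_days.copy(), scale="log2"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.row_ids, name="feature_id"),
            columns=[f"day_{d}" for d in self.col_days],
        )

    def write_tsv(self, path) -> None:
        """Write the table; values round-trip at 6 significant digits."""
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def read_expression_table(path, day_header_pattern: str = r"^day_(\d+)$",
                          scale: str = "linear") -> ExpressionMatrix:
    """Read a TSV with a feature-id first column and one column per day.

    Day columns are recognised by ``day_header_pattern`` (first capture group
    = integer day) and returned sorted by day.  Duplicate day columns, fewer
    than 3 day columns, or non-numeric cells raise ``ValueError``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate columns in {path.name}: {dupes}")

    pat = re.compile(day_header_pattern)
    day_cols, days = [], []
    for col in header[1:]:
        m = pat.match(col)
        if m:
            day_cols.append(col)
            days.append(int(m.group(1)))
    if len(set(days)) != len(days):
        raise ValueError("duplicate day columns after parsing the day pattern")
    if len(days) < 3:
        raise ValueError(f"found {len(days)} day columns; need at least 3")

    df = pd.read_csv(path, sep="\t", dtype={header[0]: str})
    values = df[day_cols].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    order = np.argsort(days)
    return ExpressionMatrix(
        values[:, order],
        df[header[0]].tolist(),
        np.asarray(days)[order],
        scale=scale,
    )


@dataclasses.dataclass
class ProbeAnnotation:
    """Many-to-one probe -> transcript mapping.

    Each probe maps to at most one transcript; probes absent from the mapping
    are dropped (with a logged count) at collapse time.
    """

    mapping: dict

    def __post_init__(self):
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    @classmethod
    def read_tsv(cls, path) -> "ProbeAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"probe_id", "transcript_id"} <= set(df.columns):
            raise ValueError("annotation needs columns probe_id, transcript_id")
        df = df.dropna(subset=["probe_id", "transcript_id"]).drop_duplicates()
        conflicts = df.groupby("probe_id")["transcript_id"].nunique()
        bad = conflicts[conflicts > 1]
        if len(bad):
            raise ValueError(f"probes mapped to several transcripts: {list(bad.index)[:5]}")
        return cls(dict(zip(df["probe_id"], df["transcript_id"])))

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"probe_id": list(self.mapping), "transcript_id": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common per-rank-mean distribution.

    The reference distribution is the across-column mean of the sorted
    columns.  Ties within a column receive the mean of the reference values
    at the ranks they occupy ("ties = average" dialect), so the output of a
    column is a function of its ranks only.
    """
    v = m.values
    n, p = v.shape
    ref = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(p):
        col = v[:, j]
        order = np.argsort(col, kind="stable")
        scol = col[order]
        starts = np.flatnonzero(np.r_[True, scol[1:] != scol[:-1]])
        counts = np.diff(np.r_[starts, n])
        means = np.add.reduceat(ref, starts) / counts
        out[order, j] = np.repeat(means, counts)
    return ExpressionMatrix(out, list(m.row_ids), m.col_days.copy(), m.scale)


@dataclasses.dataclass
class CollapsedMatrix:
    """Transcript-level matrix plus the probe-level values behind it.

    ``matrix`` has one row per transcript (median over its probes at each
    day).  ``probe_values`` keeps the retained probe rows (same scale) and
    ``probe_transcript_index`` maps each probe row to its transcript row, so
    the extreme-point SD filter can measure probe dispersion later.
    """

    matrix: ExpressionMatrix
    probe_values: np.ndarray
    probe_transcript_index: np.ndarray
    probe_ids: list

    @property
    def probes_per_transcript(self) -> np.ndarray:
        return np.bincount(self.probe_transcript_index, minlength=self.matrix.n_features)

    def probes_for(self, transcript_id: str) -> np.ndarray:
        """Probe-level sub-table (n_probes x n_days) for one transcript."""
        idx = self.matrix.row_ids.index(transcript_id)
        return self.probe_values[self.probe_transcript_index == idx]


def collapse_probes_median(m: ExpressionMatrix, ann: ProbeAnnotation) -> CollapsedMatrix:
    """Collapse probe rows to one row per transcript by the median.

    Unmapped probes are dropped with a logged count; an empty intersection of
    probes and annotation raises ``ValueError``.
    """
    tids = [ann.mapping.get(r) for r in m.row_ids]
    keep = np.array([t is not None for t in tids])
    n_dropped = int((~keep).sum())
    if n_dropped:
        _log.info("collapse: dropping %d probes without transcript annotation", n_dropped)
    if not keep.any():
        raise ValueError("no probe ids overlap the annotation")

    keep_idx = np.flatnonzero(keep)
    vals = m.values[keep_idx]
    kept_tids = np.array([tids[i] for i in keep_idx], dtype=object)
    probe_ids = [m.row_ids[i] for i in keep_idx]

    uniq, inv = np.unique(kept_tids, return_inverse=True)
    df = pd.DataFrame(vals)
    df["_t"] = inv
    collapsed = df.groupby("_t").median().to_numpy()

    cm = ExpressionMatrix(collapsed, list(uniq), m.col_days.copy(), m.scale)
    return CollapsedMatrix(cm, vals, inv, probe_ids)
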