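"""Marker-based cell-type annotation of transcript clusters.

A marker table maps gene symbols to the six testicular cell types
(spermatogonia, spermatocytes, spermatids, Leydig, peritubular myoid,
Sertoli).  Markers found among the clustered transcripts give per-cluster
evidence counts; the clusters are then assigned to the five cell
populations:

* the somatic cluster holds the majority of the somatic (Leydig + PTM +
  Sertoli) markers and its profile rises while the germ clusters dip;
* the four germ clusters are ordered by the day of their expression trough
  (the depletion gap reaches spermatogonia first, then spermatocytes
  around day 17, early spermatids around day 24 and late spermatids around
  day 27).

Marker votes that contradict the trough ordering are resolved in favour of
the ordering, with a logged warning (marker expression is often shared
between consecutive germ stages).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging

import numpy as np
import pandas as pd

_log = logging.getLogger(__name__)

CELL_TYPES = ("spermatogonia", "spermatocytes", "spermatids", "leydig", "ptm", "sertoli")
SOMATIC_TYPES = ("leydig", "ptm", "sertoli")
POPULATIONS = ("spermatogonia", "spermatocytes", "early_spermatids",
               "late_spermatids", "somatic")
GERM_ORDER = ("spermatogonia", "spermatocytes", "early_spermatids", "late_spermatids")


@dataclasses.dataclass
class MarkerTable:
    """Rows of (gene_symbol, cell_type), symbols unique within the table."""

    table: pd.DataFrame

    def __post_init__(self):
        need = {"gene_symbol", "cell_type"}
        if not need <= set(self.table.columns):
            raise ValueError(f"marker table needs columns {sorted(need)}")
        t = self.table.copy()
        t["gene_symbol"] = t["gene_symbol"].astype(str).str.strip()
        t["cell_type"] = t["cell_type"].astype(str).str.strip().str.lower()
        unknown = set(t["cell_type"]) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")
        if t["gene_symbol"].str.lower().duplicated().any():
            raise ValueError("duplicate gene symbols in marker table")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path) -> "MarkerTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def load_packaged(cls) -> "MarkerTable":
        """The packaged 39-marker testis cell-type table."""
        ref = importlib.resources.files("gapwave").joinpath("data/testis_markers.tsv")
        with ref.open() as fh:
            return cls(pd.read_csv(fh, sep="\t", dtype=str))

    def counts_by_cell_type(self) -> pd.Series:
        return self.table["cell_type"].value_counts().reindex(CELL_TYPES, fill_value=0)


def map_markers(markers: MarkerTable, labels: pd.Series):
    """Contingency table of marker counts per (cluster, cell type).

    ``labels`` maps transcript ids / gene symbols to cluster ids.  Symbols
    are matched case-insensitively with whitespace stripped.  Returns
    ``(counts, missing)`` where ``missing`` lists marker symbols absent from
    the labelled set.
    """
    key = {str(ix).strip().lower(): cl for ix, cl in labels.items()}
    clusters = sorted(set(labels.values))
    counts = pd.DataFrame(0, index=clusters, columns=list(CELL_TYPES))
    counts.index.name = "cluster"
    missing = []
    for _, row in markers.table.iterrows():
        cl = key.get(row["gene_symbol"].lower())
        if cl is None:
            missing.append(row["gene_symbol"])
        else:
            counts.loc[cl, row["cell_type"]] += 1
    return counts, missing


@dataclasses.dataclass
class CellTypeAssignment:
    """Cluster -> cell population labels with the evidence behind them."""

    labels: dict               # cluster id -> population name
    trough_day: dict           # cluster id -> argmin/argmax day of the median profile
    evidence: pd.DataFrame     # marker counts per cluster x cell type

    def cluster_for(self, population: str):
        for cl, pop in self.labels.items():
            if pop == population:
                return cl
        raise KeyError(population)

    def to_json(self, path=None) -> str:
        payload = {
            "labels": {str(k): v for k, v in self.labels.items()},
            "trough_day": {str(k): int(v) for k, v in self.trough_day.items()},
            "evidence": {str(k): v for k, v in
                         self.evidence.astype(int).T.to_dict().items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def assign_cell_types(profiles: pd.DataFrame, evidence: pd.DataFrame) -> CellTypeAssignment:
    """Assign the five cell populations to k = 5 clusters.

    ``profiles``: per-cluster median z-profiles (index = cluster id, columns
    = days).  ``evidence``: marker counts from :func:`map_markers`.

    The somatic cluster is the one holding the majority of somatic markers
    (falling back to the cluster with the highest profile peak if no somatic
    marker was found).  The remaining germ clusters are ordered by trough
    day.  For k != 5 a marker-majority labelling is returned instead.
    """
    clusters = list(profiles.index)
    days = np.asarray(profiles.columns, dtype=float)
    evidence = evidence.reindex(index=clusters, fill_value=0)

    if len(clusters) != 5:
        labels = {}
        for cl in clusters:
            row = evidence.loc[cl]
            labels[cl] = row.idxmax() if row.sum() else "unassigned"
        trough = {cl: int(days[np.argmin(profiles.loc[cl].to_numpy())]) for cl in clusters}
        return CellTypeAssignment(labels, trough, evidence)

    somatic_votes = evidence[list(SOMATIC_TYPES)].sum(axis=1)
    if somatic_votes.sum() > 0:
        somatic = somatic_votes.idxmax()
    else:
        somatic = profiles.max(axis=1).idxmax()
        _log.warning("no somatic markers found; somatic cluster chosen by profile peak")

    germ = [cl for cl in clusters if cl != somatic]
    trough = {cl: int(days[np.argmin(profiles.loc[cl].to_numpy())]) for cl in germ}
    trough[somatic] = int(days[np.argmax(profiles.loc[somatic].to_numpy())])

    germ_sorted = sorted(germ, key=lambda cl: (trough[cl], -_germ_votes(evidence, cl)))
    tdays = [trough[cl] for cl in germ_sorted]
    for a, b in zip(germ_sorted, germ_sorted[1:]):
        if trough[a] == trough[b] and _germ_votes(evidence, a) == _germ_votes(evidence, b):
            raise ValueError(
                f"clusters {a} and {b} tie on trough day {trough[a]} and marker votes"
            )
    del tdays

    labels = {somatic: "somatic"}
    for cl, pop in zip(germ_sorted, GERM_ORDER):
        labels[cl] = pop

    # flag marker-vote conflicts (resolved in favour of the trough ordering)
    vote_map = {"spermatogonia": "spermatogonia", "spermatocytes": "spermatocytes",
                "spermatids": ("early_spermatids", "late_spermatids")}
    for cl in germ:
        row = evidence.loc[cl, ["spermatogonia", "spermatocytes", "spermatids"]]
        if row.sum() == 0:
            continue
        vote = vote_map[row.idxmax()]
        ok = labels[cl] in vote if isinstance(vote, tuple) else labels[cl] == vote
        if not ok:
            _log.warning(
                "cluster %s: marker majority suggests %s but trough ordering assigns %s",
                cl, row.idxmax(), labels[cl],
            )
    return CellTypeAssignment(labels, trough, evidence)


def _germ_votes(evidence: pd.DataFrame, cl) -> int:
    return int(evidence.loc[cl, ["spermatogonia", "spermatocytes", "spermatids"]].sum())
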