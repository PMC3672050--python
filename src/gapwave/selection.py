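"""Smoothness-based transcript selection: ES, permutation FDR, SD filter.

The enrichment score (ES) of a time-course profile is

    ES = sum_i |x_i - x_{i+1}|  /  sum_i (x_i - mean(x))^2

small ES = large overall change over the series but small changes between
neighbouring time points, exactly the signature of a depletion/recovery wave
moving through the germinal epithelium.  Because the statistic is a ratio of
a first-order to a second-order quantity it is not scale-free:
ES(c*x + b) = ES(x) / |c|, so transcripts of larger amplitude score lower.

Significance comes from a permutation null: the time points are shuffled
(the same random ordering applied to every transcript within one shuffle,
preserving cross-transcript correlation) and each transcript's ES is
recorded under each ordering.  The empirical FDR at a threshold t is the
null exceedance ratio; taking the cumulative minimum from the largest
observed ES downward gives monotone q-values.

Transcripts finally pass a reliability filter: the coefficient of variation
of the probe-level values at the most extreme time point (sample SD over
probes, as a percent of the collapsed value) must stay small.  Transcripts
measured by a single probe have no measurable dispersion and return 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .matrix import CollapsedMatrix, ExpressionMatrix


@dataclasses.dataclass
class SelectionConfig:
    """Thresholds for the ES / FDR / SD selection.

    n_permutations : number of shuffled-time-point ES calculations.
    fdr_threshold : q-value cut-off, in percent.
    sd_threshold : extreme-point probe CV cut-off, in percent.
    rng_seed : seed for the permutation orderings.
    per_transcript_shuffles : if True, each transcript gets its own random
        ordering within a permutation instead of one shared ordering.
    """

    n_permutations: int = 10
    fdr_threshold: float = 30.0
    sd_threshold: float = 15.0
    rng_seed: int = 0
    per_transcript_shuffles: bool = False

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for name in ("fdr_threshold", "sd_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must lie in (0, 100]")


def enrichment_score(profile) -> float:
    """ES of one profile; +inf for a constant profile (denominator 0)."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("profile must be 1-D with at least 3 time points")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile values must be finite")
    return float(enrichment_scores(x[None, :])[0])


def enrichment_scores(values: np.ndarray) -> np.ndarray:
    """Row-wise ES for a transcripts x days matrix."""
    v = np.asarray(values, dtype=float)
    if v.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    num = np.abs(np.diff(v, axis=1)).sum(axis=1)
    den = ((v - v.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    out = np.full(len(v), np.inf)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def permutation_null(m, cfg: SelectionConfig) -> np.ndarray:
    """Null ES collection, shape (n_permutations, n_transcripts).

    One uniformly random column ordering per permutation is applied to all
    transcripts (or one ordering per transcript if
    ``cfg.per_transcript_shuffles``); seeded by ``cfg.rng_seed``.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=float)
    rng = np.random.default_rng(cfg.rng_seed)
    n_t, n_d = values.shape
    out = np.empty((cfg.n_permutations, n_t))
    for p in range(cfg.n_permutations):
        if cfg.per_transcript_shuffles:
            idx = np.argsort(rng.random((n_t, n_d)), axis=1)
            permuted = np.take_along_axis(values, idx, axis=1)
        else:
            permuted = values[:, rng.permutation(n_d)]
        out[p] = enrichment_scores(permuted)
    return out


def fdr_curve(observed_es, null_es, cfg: SelectionConfig | None = None) -> np.ndarray:
    """q-values for each observed ES against the pooled permutation null.

    raw FDR(t) = [(1/P) * #{null <= t}] / max(1, #{observed <= t}); q-values
    are the cumulative minimum of raw FDR taken from the largest observed ES
    downward, clipped to [0, 1].  Monotone non-decreasing in ES.
    """
    obs = np.asarray(observed_es, dtype=float)
    null = np.asarray(null_es, dtype=float)
    if null.size == 0:
        raise ValueError("empty permutation null")
    n_perm = null.shape[0] if null.ndim == 2 else 1
    null_sorted = np.sort(null.ravel())
    so = np.sort(obs)
    null_le = np.searchsorted(null_sorted, so, side="right")
    obs_le = np.searchsorted(so, so, side="right")
    raw = (null_le / n_perm) / np.maximum(1, obs_le)
    q_sorted = np.clip(np.minimum.accumulate(raw[::-1])[::-1], 0.0, 1.0)
    return q_sorted[np.searchsorted(so, obs, side="left")]


def extreme_sd_profile(probe_table, collapsed_profile) -> float:
    """Extreme-point SD%, for one transcript's probe table.

    Finds the day where |collapsed - mean(collapsed)| is largest, then
    returns 100 * sample SD of the probe values at that day / |collapsed|.
    Single-probe transcripts return 0; a collapsed value of 0 at the extreme
    day returns +inf (fails any threshold).
    """
    probes = np.atleast_2d(np.asarray(probe_table, dtype=float))
    prof = np.asarray(collapsed_profile, dtype=float)
    day = int(np.argmax(np.abs(prof - prof.mean())))
    centre = prof[day]
    if centre == 0:
        return float(np.inf)
    if probes.shape[0] < 2:
        return 0.0
    return float(100.0 * probes[:, day].std(ddof=1) / abs(centre))


def extreme_sd(collapsed: CollapsedMatrix) -> np.ndarray:
    """Vectorised extreme-point SD% for every transcript in a collapsed matrix."""
    tm = collapsed.matrix.values
    n_t = len(tm)
    ext_day = np.argmax(np.abs(tm - tm.mean(axis=1, keepdims=True)), axis=1)
    ext_val = tm[np.arange(n_t), ext_day]

    g = collapsed.probe_transcript_index
    pv = collapsed.probe_values[np.arange(len(g)), ext_day[g]]
    n = np.bincount(g, minlength=n_t).astype(float)
    s1 = np.bincount(g, weights=pv, minlength=n_t)
    s2 = np.bincount(g, weights=pv * pv, minlength=n_t)
    var = np.zeros(n_t)
    multi = n > 1
    var[multi] = np.maximum(s2[multi] - s1[multi] ** 2 / n[multi], 0.0) / (n[multi] - 1)

    out = np.zeros(n_t)
    nz = ext_val != 0
    out[nz] = 100.0 * np.sqrt(var[nz]) / np.abs(ext_val[nz])
    out[~nz] = np.inf
    return out


@dataclasses.dataclass
class SelectionResult:
    """Per-transcript ES, q-value, SD% and the final selection flag."""

    table: pd.DataFrame  # transcript_id, es, q_value, extreme_sd_pct, selected
    config: SelectionConfig

    @property
    def selected_ids(self) -> list:
        return self.table.loc[self.table["selected"], "transcript_id"].tolist()

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def select_transcripts(collapsed: CollapsedMatrix,
                       cfg: SelectionConfig | None = None,
                       scale: str = "log2") -> SelectionResult:
    """Full selection: ES + permutation q-value + extreme-point SD filter.

    ES and the permutation null are computed on ``log2(x + 1)`` of the
    collapsed matrix when ``scale="log2"`` (the default; pass ``"linear"``
    to run on the stored values as-is).  The SD filter always runs on the
    stored (intensity) scale, where a percent CV is meaningful.

    selected = q <= fdr_threshold AND SD% <= sd_threshold AND finite ES.
    Deterministic for a given ``cfg.rng_seed``.
    """
    cfg = cfg or SelectionConfig()
    work = collapsed.matrix.to_log2() if scale == "log2" else collapsed.matrix
    es = enrichment_scores(work.values)
    null = permutation_null(work, cfg)
    q = fdr_curve(es, null, cfg)
    sd_pct = extreme_sd(collapsed)
    selected = np.isfinite(es) & (q <= cfg.fdr_threshold / 100.0) & (sd_pct <= cfg.sd_threshold)
    table = pd.DataFrame(
        {
            "transcript_id": collapsed.matrix.row_ids,
            "es": es,
            "q_value": q,
            "extreme_sd_pct": sd_pct,
            "selected": selected,
        }
    )
    return SelectionResult(table, cfg)
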