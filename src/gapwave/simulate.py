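"""Synthetic expression matrices and section images with known ground truth.

The expression generator emulates a whole-testis recovery time course after
spermatogonia-killing irradiation, arrayed on 17 sampling days (3..59):

* five planted cell-population archetypes.  Germ-cell archetypes are
  multiplicative Gaussian-bump depletions of a per-transcript baseline
  (troughs near days 10 / 17 / 24 / 27, returning to baseline by ~day 40 as
  spermatogenesis completes a round); the somatic archetype is an apparent
  up-regulation peak — a cellularity artefact: somatic RNA occupies a larger
  share of the pool while germ cells are missing, without any per-cell
  transcriptional change.
* a large background of non-smooth transcripts whose probe-day values are
  independent draws: erratic profiles with high neighbour differences (high
  ES) and inconsistent probes (high extreme-point CV), the two properties
  the selection is designed to reject.

Every transcript is measured by several probes; planted probes replicate the
transcript profile with small log2 noise, background probes are mutually
independent.  Background transcripts are dimmer and more broadly spread than
planted ones, as unexpressed array probes are, which densely populates the
low-intensity range so that quantile normalisation does not rank-distort the
deep troughs.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .annotation import POPULATIONS, MarkerTable
from .histology import BACKGROUND, BLUE, RED, PixelClassMap, QuantConfig, SWATCH_MEANS, SWATCH_SD
from .matrix import ExpressionMatrix, ProbeAnnotation

#: the arrayed sampling schedule: days 3..59 post-irradiation (17 occasions)
DEFAULT_SAMPLING_DAYS = (3, 7, 10, 14, 17, 21, 24, 28, 31, 35, 38, 42, 45, 48, 52, 56, 59)


@dataclasses.dataclass
class ArchetypeSpec:
    """One planted cell-population profile.

    ``depth`` is the fractional depletion at the trough for germ archetypes
    (in (0, 1]), or the peak height of the apparent up-regulation for the
    somatic archetype (``direction="peak"``): the linear profile is
    baseline * (1 - depth*bump) or baseline * (1 + depth*bump) with a
    Gaussian bump of SD ``width_days`` centred on ``trough_or_peak_day``.
    ``recovery_day`` documents when the profile is expected back at
    baseline; the residual bump there is validated to be < 5% of depth.
    """

    name: str
    trough_or_peak_day: int
    depth: float
    width_days: float
    planted_count: int
    direction: str = "trough"
    recovery_day: int = 40

    def __post_init__(self):
        if self.direction not in ("trough", "peak"):
            raise ValueError("direction must be 'trough' or 'peak'")
        if self.direction == "trough" and not (0 < self.depth <= 1):
            raise ValueError("trough depth must lie in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.planted_count < 0:
            raise ValueError("planted_count must be >= 0")

    def log2_profile(self, days: np.ndarray) -> np.ndarray:
        days = np.asarray(days, dtype=float)
        bump = np.exp(-((days - self.trough_or_peak_day) ** 2) / (2 * self.width_days ** 2))
        factor = 1 + self.depth * bump if self.direction == "peak" else 1 - self.depth * bump
        return np.log2(factor)


def default_archetypes() -> list:
    """The five planted populations with their per-population counts."""
    return [
        ArchetypeSpec("spermatogonia", 10, 0.95, 4.0, 109),
        ArchetypeSpec("spermatocytes", 17, 0.95, 4.0, 164),
        ArchetypeSpec("early_spermatids", 24, 0.95, 3.0, 246),
        ArchetypeSpec("late_spermatids", 27, 0.95, 4.5, 273),
        ArchetypeSpec("somatic", 26, 3.0, 6.0, 196, direction="peak", recovery_day=45),
    ]


@dataclasses.dataclass
class SimConfig:
    """Generator settings; the defaults define the study conditions.

    noise_sd_log2 : per-probe replicate noise (log2 SD) on planted
        transcripts — probes of an expressed transcript agree closely.
    background_sd_log2 : per-probe-day SD of the erratic background draws.
    baseline_log2_mean/sd : brightness of planted transcripts.
    background_log2_mean/sd : brightness spread of the background (dimmer
        and broader, like unexpressed array probes).
    """

    sampling_days: tuple = DEFAULT_SAMPLING_DAYS
    archetypes: list = dataclasses.field(default_factory=default_archetypes)
    n_noise_transcripts: int = 10000
    probes_per_transcript: int = 4
    noise_sd_log2: float = 0.05
    background_sd_log2: float = 1.5
    baseline_log2_mean: float = 9.5
    baseline_log2_sd: float = 1.0
    background_log2_mean: float = 7.5
    background_log2_sd: float = 2.0
    rng_seed: int = 42
    embed_markers: bool = True

    def __post_init__(self):
        days = np.asarray(self.sampling_days)
        if np.any(np.diff(days) <= 0):
            raise ValueError("sampling_days must be strictly increasing")
        if self.probes_per_transcript < 1:
            raise ValueError("probes_per_transcript must be >= 1")
        for a in self.archetypes:
            if not days.min() <= a.trough_or_peak_day <= days.max():
                raise ValueError(
                    f"archetype {a.name!r} day {a.trough_or_peak_day} outside the sampling window"
                )
            residual = np.exp(-((a.recovery_day - a.trough_or_peak_day) ** 2)
                              / (2 * a.width_days ** 2))
            if a.trough_or_peak_day < a.recovery_day and residual > 0.05:
                raise ValueError(
                    f"archetype {a.name!r} has not recovered by day {a.recovery_day}"
                )


@dataclasses.dataclass
class SimulatedDataset:
    """Probe-level matrix + annotation + per-transcript ground truth."""

    probe_matrix: ExpressionMatrix     # linear scale
    annotation: ProbeAnnotation
    truth: pd.DataFrame                # transcript_id, archetype ('noise' for background)
    config: SimConfig

    @property
    def planted_ids(self) -> list:
        return self.truth.loc[self.truth["archetype"] != "noise", "transcript_id"].tolist()

    def truth_labels(self) -> pd.Series:
        t = self.truth[self.truth["archetype"] != "noise"]
        return pd.Series(t["archetype"].values, index=t["transcript_id"].values)


def _transcript_ids(cfg: SimConfig) -> dict:
    """Per-archetype transcript id lists, with marker symbols embedded.

    Marker symbols from the packaged table are used as transcript ids inside
    the cluster the marker was observed in (cluster 1..5 maps onto the five
    populations in order), so marker-based annotation has something to find.
    """
    per_cluster = {name: [] for name in POPULATIONS}
    if cfg.embed_markers:
        markers = MarkerTable.load_packaged()
        if "reported_cluster" in markers.table.columns:
            for _, row in markers.table.iterrows():
                pop = POPULATIONS[int(row["reported_cluster"]) - 1]
                per_cluster[pop].append(row["gene_symbol"])
    out = {}
    for a in cfg.archetypes:
        ids = list(per_cluster.get(a.name, []))[: a.planted_count]
        ids += [f"{a.name}_{i:04d}" for i in range(a.planted_count - len(ids))]
        out[a.name] = ids
    return out


def simulate_expression(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Generate the probe-level expression matrix with ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    days = np.asarray(cfg.sampling_days, dtype=int)
    n_days = len(days)
    n_probes = cfg.probes_per_transcript

    ids_by_arch = _transcript_ids(cfg)
    tids, archetype_of, profiles = [], [], []
    for a in cfg.archetypes:
        prof = a.log2_profile(days)
        for tid in ids_by_arch[a.name]:
            tids.append(tid)
            archetype_of.append(a.name)
            profiles.append(prof)
    n_planted = len(tids)

    values = np.empty((n_planted + cfg.n_noise_transcripts, n_probes, n_days))
    if n_planted:
        profiles = np.array(profiles)
        base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=(n_planted, 1, 1))
        noise = rng.normal(0.0, cfg.noise_sd_log2, size=(n_planted, n_probes, n_days))
        values[:n_planted] = 2.0 ** (base + profiles[:, None, :] + noise)

    if cfg.n_noise_transcripts:
        base = rng.normal(cfg.background_log2_mean, cfg.background_log2_sd,
                          size=(cfg.n_noise_transcripts, 1, 1))
        draws = rng.normal(0.0, cfg.background_sd_log2,
                           size=(cfg.n_noise_transcripts, n_probes, n_days))
        values[n_planted:] = 2.0 ** (base + draws)
        tids += [f"noise_{i:05d}" for i in range(cfg.n_noise_transcripts)]
        archetype_of += ["noise"] * cfg.n_noise_transcripts

    probe_ids = [f"{tid}:p{j + 1}" for tid in tids for j in range(n_probes)]
    probe_matrix = ExpressionMatrix(
        values.reshape(-1, n_days), probe_ids, days, scale="linear"
    )
    annotation = ProbeAnnotation(
        {pid: pid.rsplit(":p", 1)[0] for pid in probe_ids}
    )
    truth = pd.DataFrame({"transcript_id": tids, "archetype": archetype_of})
    return SimulatedDataset(probe_matrix, annotation, truth, cfg)


def simulate_ihc_image(n_blobs: int, blob_areas_um2, background_fraction: float,
                       cfg: QuantConfig, rng_seed: int = 0,
                       shape: tuple = (256, 256)):
    """Draw red disks on a blue tissue field with a white background margin.

    ``blob_areas_um2`` gives the requested disk areas; disks are placed
    without overlap, colours are sampled from the nominal class
    distributions, and the returned ground truth holds the *rasterised*
    pixel-exact areas.  Raises if the disks cannot be placed.
    """
    blob_areas_um2 = list(blob_areas_um2)
    if len(blob_areas_um2) != n_blobs:
        raise ValueError("blob_areas_um2 length must equal n_blobs")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    h, w = shape

    # white margin strip at the top, blue tissue below
    margin_rows = int(round(h * background_fraction))
    classes = np.full(shape, BLUE, dtype=np.int8)
    classes[:margin_rows] = BACKGROUND

    yy, xx = np.mgrid[0:h, 0:w]
    truth_red = 0
    for area in blob_areas_um2:
        radius = np.sqrt(area / cfg.um2_per_pixel / np.pi)
        if 2 * radius > min(h - margin_rows, w) - 2:
            raise ValueError(f"blob of {area} um^2 does not fit the tissue field")
        placed = False
        for _ in range(200):
            cy = rng.uniform(margin_rows + radius + 1, h - radius - 1)
            cx = rng.uniform(radius + 1, w - radius - 1)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
            if not np.any(classes[disk] != BLUE):
                classes[disk] = RED
                truth_red += int(disk.sum())
                placed = True
                break
        if not placed:
            raise ValueError("could not place all blobs without overlap")

    image = np.empty((h, w, 3))
    for idx, name in ((RED, "red"), (BLUE, "blue"), (BACKGROUND, "background")):
        mask = classes == idx
        image[mask] = rng.normal(SWATCH_MEANS[name], SWATCH_SD, size=(int(mask.sum()), 3))
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    counts = {name: int(np.sum(classes == i)) for i, name in
              enumerate(("red", "blue", "background"))}
    truth = {
        "red_um2": counts["red"] * cfg.um2_per_pixel,
        "blue_um2": counts["blue"] * cfg.um2_per_pixel,
        "background_um2": counts["background"] * cfg.um2_per_pixel,
        "class_map": PixelClassMap(classes, cfg.um2_per_pixel),
    }
    truth["ratio"] = (truth["red_um2"] / truth["blue_um2"]) if truth["blue_um2"] else 0.0
    return image, truth
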