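"""Area quantification of Leydig-cell staining in section images.

Stained sections carry three pixel populations: the red chromogen (AEC)
marking Hsd3b-positive Leydig cells, the blue haematoxylin counterstain
marking all other tissue, and the white background.  Pixels are classified
by a Gaussian naive-Bayes model (per-channel Gaussian class-conditionals,
equal priors) fitted to labelled colour swatches.  Red connected components
smaller than a physical area threshold (default 20 um^2) are re-assigned to
blue — isolated chromogen specks are not cells — and the red:blue area
ratio estimates the amount of Leydig cells relative to other testis cells.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from PIL import Image
from skimage import measure
from sklearn.naive_bayes import GaussianNB

CLASSES = ("red", "blue", "background")
RED, BLUE, BACKGROUND = 0, 1, 2

# nominal class colours: AEC red-brown, haematoxylin blue, white background
SWATCH_MEANS = {
    "red": (150.0, 45.0, 50.0),
    "blue": (70.0, 75.0, 150.0),
    "background": (245.0, 243.0, 240.0),
}
SWATCH_SD = 8.0


def default_swatches(n_per_class: int = 200, seed: int = 0) -> dict:
    """Labelled RGB training pixels mimicking AEC / haematoxylin / white."""
    rng = np.random.default_rng(seed)
    out = {}
    for name in CLASSES:
        mean = np.array(SWATCH_MEANS[name])
        px = rng.normal(mean, SWATCH_SD, size=(n_per_class, 3))
        out[name] = np.clip(np.round(px), 0, 255).astype(np.uint8)
    return out


@dataclasses.dataclass
class QuantConfig:
    """Calibration and filter settings for the area quantification.

    um2_per_pixel : physical area of one pixel, in um^2.
    min_red_area_um2 : red components strictly smaller than this are
        re-assigned to blue.
    connectivity : 4 or 8 (neighbourhood for connected components).
    swatches : labelled RGB training pixels per class.
    """

    um2_per_pixel: float
    min_red_area_um2: float = 20.0
    connectivity: int = 8
    swatches: dict = dataclasses.field(default_factory=default_swatches)

    def __post_init__(self):
        if self.um2_per_pixel <= 0:
            raise ValueError("um2_per_pixel must be positive")
        if self.min_red_area_um2 < 0:
            raise ValueError("min_red_area_um2 must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclasses.dataclass
class PixelClassMap:
    """Per-pixel class labels plus the physical calibration."""

    labels: np.ndarray          # 2-D int array of RED/BLUE/BACKGROUND
    um2_per_pixel: float

    def pixel_counts(self) -> dict:
        return {name: int(np.sum(self.labels == i)) for i, name in enumerate(CLASSES)}

    def area_um2(self, cls: str) -> float:
        return float(np.sum(self.labels == CLASSES.index(cls)) * self.um2_per_pixel)

    @property
    def total_area_um2(self) -> float:
        return float(self.labels.size * self.um2_per_pixel)


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF as an 8-bit RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_label_png(pcm: PixelClassMap, path) -> None:
    """Render the class map with a red/blue/white palette."""
    palette = np.array([[200, 30, 30], [40, 40, 200], [255, 255, 255]], dtype=np.uint8)
    Image.fromarray(palette[pcm.labels]).save(path)


def classify_pixels(image: np.ndarray, cfg: QuantConfig) -> PixelClassMap:
    """Maximum-posterior pixel labels under per-channel Gaussians, equal priors."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be an RGB raster (H, W, 3)")
    if img.dtype != np.uint8:
        raise ValueError("image must be 8-bit")
    missing = [c for c in CLASSES if c not in cfg.swatches]
    if missing:
        raise ValueError(f"missing swatch classes: {missing}")
    for c in CLASSES:
        if len(cfg.swatches[c]) < 10:
            raise ValueError(f"swatch class {c!r} needs >= 10 pixels")

    X = np.vstack([np.asarray(cfg.swatches[c], dtype=float) for c in CLASSES])
    y = np.concatenate([np.full(len(cfg.swatches[c]), i) for i, c in enumerate(CLASSES)])
    model = GaussianNB(priors=[1.0 / len(CLASSES)] * len(CLASSES))
    model.fit(X, y)
    labels = model.predict(img.reshape(-1, 3).astype(float)).reshape(img.shape[:2])
    return PixelClassMap(labels.astype(np.int8), cfg.um2_per_pixel)


def filter_small_components(pcm: PixelClassMap, cfg: QuantConfig) -> PixelClassMap:
    """Re-assign red components with area < min_red_area_um2 to blue.

    Strict inequality: a component of exactly the threshold area is kept.
    Blue and background pixels are never touched; the operation is
    idempotent.
    """
    labels = pcm.labels.copy()
    red_mask = labels == RED
    conn = 2 if cfg.connectivity == 8 else 1
    comp = measure.label(red_mask, connectivity=conn)
    sizes = np.bincount(comp.ravel())
    too_small = sizes * pcm.um2_per_pixel < cfg.min_red_area_um2
    too_small[0] = False  # component 0 is the non-red region
    labels[too_small[comp]] = BLUE
    return PixelClassMap(labels, pcm.um2_per_pixel)


def red_blue_ratio(pcm: PixelClassMap) -> float:
    """Red area / blue area (background excluded); error if no blue tissue."""
    red = pcm.area_um2("red")
    blue = pcm.area_um2("blue")
    if blue == 0:
        raise ValueError("no blue (tissue) area in the image")
    return red / blue


def quantify_image(image: np.ndarray, cfg: QuantConfig) -> dict:
    """Classify, filter, and measure one image; returns areas and the ratio."""
    pcm = filter_small_components(classify_pixels(image, cfg), cfg)
    return {
        "red_um2": pcm.area_um2("red"),
        "blue_um2": pcm.area_um2("blue"),
        "background_um2": pcm.area_um2("background"),
        "ratio": red_blue_ratio(pcm),
    }
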