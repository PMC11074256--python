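"""Synthetic multispectral scenes, feature tables and cover fields.

Everything downstream (feature extraction, the forest classifier, cover
estimation, accuracy assessment) is testable against known ground truth
generated here.  The defaults mirror the two-class, strongly imbalanced
study design the toolkit targets: grassland-dominated scenes with a
small forest minority (932 grassland vs 45 forest training objects;
1031 vs 23 for validation).

Segment geometry is a Voronoi tessellation of uniformly sampled seed
points: irregular object shapes with an exactly controllable count.
Band noise is independent Gaussian per pixel, clipped to [0, 1].  The
endmember spectra are plausible synthetic reflectances chosen by the
implementers; they are stand-ins and are not claimed to match any real
sensor's radiometry.

One seed governs a named substream per generator (scene / table /
cover), so adding a generator never shifts another's stream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .features import BAND_NAMES, FeatureTable

__all__ = [
    "SceneConfig",
    "RasterScene",
    "TableConfig",
    "GRASSLAND_SPECTRUM",
    "FOREST_SPECTRUM",
    "SOIL_SPECTRUM",
    "generate_scene",
    "generate_feature_table",
    "generate_cover_scene",
    "save_scene",
    "load_scene",
]

# substream ids: one fixed, documented stream per generator
_STREAM_SCENE = 11
_STREAM_TABLE = 12
_STREAM_COVER = 13

# synthetic endmember reflectances (blue, green, red, NIR)
GRASSLAND_SPECTRUM = (0.06, 0.10, 0.08, 0.30)
FOREST_SPECTRUM = (0.04, 0.07, 0.05, 0.45)
SOIL_SPECTRUM = (0.15, 0.18, 0.20, 0.25)


@dataclass(frozen=True)
class SceneConfig:
    """Stated world for a labeled two-class scene.

    Class proportions default to the 932:45 grassland:forest object
    imbalance of the target study design.
    """

    height: int = 120
    width: int = 120
    n_segments: int = 180
    class_names: tuple[str, ...] = ("grassland", "forest")
    class_proportions: tuple[float, ...] = (932 / 977, 45 / 977)
    endmember_spectra: tuple[tuple[float, float, float, float], ...] = (
        GRASSLAND_SPECTRUM,
        FOREST_SPECTRUM,
    )
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("scene dimensions must be positive")
        if self.n_segments < 1 or self.n_segments > self.height * self.width:
            raise ValueError("n_segments must be in [1, height*width]")
        if len(self.class_names) != len(self.class_proportions) or len(
            self.class_names
        ) != len(self.endmember_spectra):
            raise ValueError("class_names, proportions and spectra must align")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class proportions must be non-negative")
        for spec in self.endmember_spectra:
            if len(spec) != 4 or any(not 0.0 <= v <= 1.0 for v in spec):
                raise ValueError("endmember reflectances must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class RasterScene:
    """Multiband reflectance grids plus a segment-id grid and optional
    per-segment labels.  Segment ids are positive; 0 marks no-data."""

    bands: dict[str, np.ndarray]
    segments: np.ndarray
    labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        shape = self.segments.shape
        for name, grid in self.bands.items():
            if grid.shape != shape:
                raise ValueError(f"band {name!r} shape {grid.shape} != segments {shape}")
        if self.labels is not None:
            present = set(int(s) for s in np.unique(self.segments) if s > 0)
            missing = present - set(self.labels)
            if missing:
                raise ValueError(f"segments without a label: {sorted(missing)[:5]}...")

    @property
    def shape(self) -> tuple[int, int]:
        return self.segments.shape

    @property
    def segment_ids(self) -> np.ndarray:
        ids = np.unique(self.segments)
        return ids[ids > 0]


@dataclass(frozen=True)
class TableConfig:
    """Stated world for a pre-built feature table.

    Defaults: the 45-positive / 932-negative training imbalance, 85
    features of which 5 are informative for the positive (forest) class
    and 5 for the negative class, standardised mean shift 1.5.  Column
    names self-document their role: ``pos_inf_*``, ``neg_inf_*``,
    ``noise_*``.
    """

    n_pos: int = 45
    n_neg: int = 932
    n_feat_total: int = 85
    n_informative_pos: int = 5
    n_informative_neg: int = 5
    effect_size: float = 1.5
    pos_label: str = "forest"
    neg_label: str = "grassland"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("each class needs at least one object")
        if self.n_informative_pos < 0 or self.n_informative_neg < 0:
            raise ValueError("informative counts must be >= 0")
        if self.n_informative_pos + self.n_informative_neg > self.n_feat_total:
            raise ValueError("informative features cannot exceed the total")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _proportional_counts(proportions, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across proportions."""
    raw = np.asarray(proportions) * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def generate_scene(config: SceneConfig = SceneConfig()) -> RasterScene:
    """Voronoi-tessellated labeled scene with Gaussian band noise.

    Deterministic for a fixed seed; segment count equals
    ``config.n_segments`` (seed points are redrawn in the rare event a
    Voronoi cell captures no pixel centre).
    """
    rng = np.random.default_rng([config.seed, _STREAM_SCENE])
    h, w = config.height, config.width
    yy, xx = np.mgrid[0:h, 0:w]
    pixel_centers = np.column_stack([yy.ravel() + 0.5, xx.ravel() + 0.5])

    for _ in range(100):
        points = np.column_stack(
            [rng.uniform(0, h, config.n_segments), rng.uniform(0, w, config.n_segments)]
        )
        _, nearest = cKDTree(points).query(pixel_centers)
        if np.unique(nearest).size == config.n_segments:
            break
    else:
        raise RuntimeError("could not realise a tessellation with every cell non-empty")
    segments = (nearest + 1).reshape(h, w).astype(np.int32)

    counts = _proportional_counts(config.class_proportions, config.n_segments)
    class_of_segment = np.repeat(np.arange(len(config.class_names)), counts)
    class_of_segment = rng.permutation(class_of_segment)
    labels = {
        sid + 1: config.class_names[class_of_segment[sid]]
        for sid in range(config.n_segments)
    }

    spectra = np.asarray(config.endmember_spectra)  # classes x bands
    pixel_class = class_of_segment[segments - 1]
    bands: dict[str, np.ndarray] = {}
    for bi, bname in enumerate(BAND_NAMES):
        mean = spectra[pixel_class, bi]
        noise = rng.normal(0.0, config.noise_sd, size=(h, w)) if config.noise_sd > 0 else 0.0
        bands[bname] = np.clip(mean + noise, 0.0, 1.0)
    return RasterScene(bands=bands, segments=segments, labels=labels)


def generate_feature_table(config: TableConfig = TableConfig()) -> FeatureTable:
    """Gaussian feature table with class-specific informative columns.

    ``pos_inf`` columns are shifted by ``effect_size`` on positive rows
    only, ``neg_inf`` columns on negative rows only; everything else is
    exchangeable standard-normal noise.  Row order is a seeded shuffle.
    """
    rng = np.random.default_rng([config.seed, _STREAM_TABLE])
    n = config.n_pos + config.n_neg
    X = rng.standard_normal((n, config.n_feat_total))
    is_pos = np.zeros(n, dtype=bool)
    is_pos[: config.n_pos] = True

    kp, kn = config.n_informative_pos, config.n_informative_neg
    X[np.ix_(is_pos, np.arange(kp))] += config.effect_size
    X[np.ix_(~is_pos, np.arange(kp, kp + kn))] += config.effect_size

    names = (
        [f"pos_inf_{i+1}" for i in range(kp)]
        + [f"neg_inf_{i+1}" for i in range(kn)]
        + [f"noise_{i+1}" for i in range(config.n_feat_total - kp - kn)]
    )
    labels = np.where(is_pos, config.pos_label, config.neg_label)
    order = rng.permutation(n)
    return FeatureTable.from_arrays(X[order], names, labels=labels[order])


def generate_cover_scene(
    height: int = 120,
    width: int = 120,
    veg_spectrum=FOREST_SPECTRUM,
    soil_spectrum=SOIL_SPECTRUM,
    cover_field_smoothness: float = 8.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[RasterScene, np.ndarray]:
    """Linear soil-vegetation mixture scene with a smooth random cover
    field (Gaussian-filtered white noise rescaled to span [0, 1]).

    Returns the scene (single segment covering everything, no labels)
    and the true cover grid.  With zero noise the mixture is exactly
    invertible per band.
    """
    for spec in (veg_spectrum, soil_spectrum):
        if len(spec) != 4 or any(not 0.0 <= v <= 1.0 for v in spec):
            raise ValueError("spectra must be 4-band reflectances in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng([seed, _STREAM_COVER])
    field = rng.standard_normal((height, width))
    if cover_field_smoothness > 0:
        field = gaussian_filter(field, sigma=cover_field_smoothness, mode="nearest")
    lo, hi = field.min(), field.max()
    cover = (field - lo) / (hi - lo) if hi > lo else np.full_like(field, 0.5)

    veg = np.asarray(veg_spectrum)
    soil = np.asarray(soil_spectrum)
    bands: dict[str, np.ndarray] = {}
    for bi, bname in enumerate(BAND_NAMES):
        mean = cover * veg[bi] + (1.0 - cover) * soil[bi]
        noise = rng.normal(0.0, noise_sd, size=(height, width)) if noise_sd > 0 else 0.0
        bands[bname] = np.clip(mean + noise, 0.0, 1.0)
    segments = np.ones((height, width), dtype=np.int32)
    return RasterScene(bands=bands, segments=segments, labels=None), cover


# ---------------------------------------------------------------------------
# Scene I/O: multiband TIFF (band order blue, green, red, NIR; float32),
# int32 segment TIFF, and a segment_id,label CSV
# ---------------------------------------------------------------------------

def save_scene(scene: RasterScene, scene_path, segments_path, labels_path=None) -> None:
    stack = np.stack([scene.bands[b] for b in BAND_NAMES]).astype(np.float32)
    tifffile.imwrite(scene_path, stack, photometric="minisblack")
    tifffile.imwrite(segments_path, scene.segments.astype(np.int32))
    if labels_path is not None:
        if scene.labels is None:
            raise ValueError("scene has no labels to save")
        with open(labels_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["segment_id", "label"])
            for sid in sorted(scene.labels):
                writer.writerow([sid, scene.labels[sid]])


def load_scene(scene_path, segments_path, labels_path=None) -> RasterScene:
    stack = tifffile.imread(scene_path)
    if stack.ndim != 3 or stack.shape[0] != len(BAND_NAMES):
        raise ValueError("scene TIFF must hold 4 bands (blue, green, red, NIR)")
    bands = {b: stack[i].astype(float) for i, b in enumerate(BAND_NAMES)}
    segments = np.asarray(tifffile.imread(segments_path)).astype(np.int32)
    labels = None
    if labels_path is not None:
        labels = {}
        with open(Path(labels_path), newline="") as fh:
            for row in csv.DictReader(fh):
                labels[int(row["segment_id"])] = row["label"]
    return RasterScene(bands=bands, segments=segments, labels=labels)
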