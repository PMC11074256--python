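"""Object-level feature extraction for segmented multispectral scenes.

Each segment (image object) is summarised by spectral statistics,
geometric shape descriptors, gray-level co-occurrence / difference-vector
texture statistics, and per-segment means of standard vegetation and
land-cover indices.  The default manifest emits exactly 85 features.

Default manifest decomposition (85 columns):

* 4 bands x (mean, sd)                        =  8
* brightness, max difference                  =  2
* area, perimeter, length-width ratio,
  density, rectangular fit                    =  5
* GLCM {homogeneity, variance, dissimilarity,
  ASM, entropy} x 4 bands x 2 offset sets     = 40
* GLDV {mean, entropy, ASM} x 4 bands         = 12
* segment means of NDVI, EVI, ARVI,
  water index, built-up proxy                 =  5
* per-band min, max, median (12) + NIR range  = 13

The built-up index is a visible/NIR proxy (the standard NDBI needs a
SWIR band that 4-band imagery lacks).  Texture is computed on each
segment's bounding box masked to the segment; pixel pairs crossing the
mask are discarded.  Gray levels are a linear 16-level quantisation over
the segment's own min-max.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from . import vegmetrics

if TYPE_CHECKING:  # pragma: no cover
    from .synthdata import RasterScene

__all__ = [
    "FeatureTable",
    "GlcmSpec",
    "FeatureManifest",
    "default_manifest",
    "spectral_features",
    "geometric_features",
    "quantize_gray",
    "glcm",
    "glcm_stats",
    "gldv_stats",
    "index_features",
    "build_feature_table",
]

BAND_NAMES = ("blue", "green", "red", "nir")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

class FeatureTable:
    """Objects x features, with an optional per-object class label.

    Backed by a :class:`pandas.DataFrame` indexed by segment id; the
    label column is named ``"label"`` and is excluded from the feature
    matrix.  Feature names must be unique and values finite.
    """

    LABEL_COLUMN = "label"

    def __init__(self, df: pd.DataFrame, manifest: "FeatureManifest | None" = None):
        if df.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        self.df = df
        self.manifest = manifest

    # -- accessors ----------------------------------------------------------
    @property
    def object_ids(self) -> np.ndarray:
        return self.df.index.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c != self.LABEL_COLUMN]

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray | None:
        if self.LABEL_COLUMN in self.df.columns:
            return self.df[self.LABEL_COLUMN].to_numpy()
        return None

    @property
    def n_objects(self) -> int:
        return len(self.df)

    def select_rows(self, ids: Iterable) -> "FeatureTable":
        return FeatureTable(self.df.loc[list(ids)], self.manifest)

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="object_id")

    @classmethod
    def from_csv(cls, path, manifest: "FeatureManifest | None" = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="object_id", comment="#")
        return cls(df, manifest)

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        feature_names: Sequence[str],
        labels: Sequence | None = None,
        object_ids: Sequence | None = None,
    ) -> "FeatureTable":
        X = np.asarray(X, dtype=float)
        if object_ids is None:
            object_ids = np.arange(1, X.shape[0] + 1)
        df = pd.DataFrame(X, columns=list(feature_names), index=np.asarray(object_ids))
        if labels is not None:
            df[cls.LABEL_COLUMN] = np.asarray(labels)
        return cls(df)


@dataclass(frozen=True)
class GlcmSpec:
    """Gray-level co-occurrence setup: level count, pixel offsets, and
    whether the matrix is symmetrised and normalised."""

    levels: int = 16
    offsets: tuple[tuple[int, int], ...] = ((0, 1),)
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.offsets) < 1:
            raise ValueError("at least one offset is required")


GLCM_STAT_NAMES = ("homogeneity", "variance", "dissimilarity", "asm", "entropy")
GLDV_STAT_NAMES = ("mean", "entropy", "asm")
INDEX_NAMES = ("ndvi", "evi", "arvi", "water", "builtup")


@dataclass(frozen=True)
class FeatureManifest:
    """The feature decomposition applied to every segment.

    Serialised alongside every feature table so any other decomposition
    stays pluggable.
    """

    glcm_levels: int = 16
    glcm_offset_sets: tuple[tuple[tuple[int, int], ...], ...] = (((0, 1),), ((1, 0),))
    glcm_offset_names: tuple[str, ...] = ("h", "v")
    range_bands: tuple[str, ...] = ("nir",)  # non-NIR ranges trimmed to hit 85

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for b in BAND_NAMES:
            names += [f"mean_{b}", f"sd_{b}"]
        names += ["brightness", "max_diff"]
        names += ["area", "perimeter", "length_width_ratio", "density", "rect_fit"]
        for b in BAND_NAMES:
            for off in self.glcm_offset_names:
                for s in GLCM_STAT_NAMES:
                    names.append(f"glcm_{s}_{b}_{off}")
        for b in BAND_NAMES:
            for s in GLDV_STAT_NAMES:
                names.append(f"gldv_{s}_{b}")
        names += [f"{ix}_mean" for ix in INDEX_NAMES]
        for b in BAND_NAMES:
            names += [f"min_{b}", f"max_{b}", f"median_{b}"]
        for b in self.range_bands:
            names.append(f"range_{b}")
        return names

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "glcm_levels": self.glcm_levels,
                "glcm_offset_sets": [
                    [list(o) for o in s] for s in self.glcm_offset_sets
                ],
                "glcm_offset_names": list(self.glcm_offset_names),
                "range_bands": list(self.range_bands),
                "feature_names": self.feature_names,
            },
            **kwargs,
        )

    @classmethod
    def from_json(cls, s: str) -> "FeatureManifest":
        d = json.loads(s)
        return cls(
            glcm_levels=d["glcm_levels"],
            glcm_offset_sets=tuple(
                tuple(tuple(o) for o in sset) for sset in d["glcm_offset_sets"]
            ),
            glcm_offset_names=tuple(d["glcm_offset_names"]),
            range_bands=tuple(d["range_bands"]),
        )


def default_manifest() -> FeatureManifest:
    """The 85-feature decomposition documented in the module docstring."""
    return FeatureManifest()


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def _segment_mask(scene: "RasterScene", segment_id: int) -> np.ndarray:
    mask = scene.segments == segment_id
    if not mask.any():
        raise KeyError(f"segment id {segment_id} not present in the scene")
    return mask


def spectral_features(scene: "RasterScene", segment_id: int) -> dict[str, float]:
    """Per-band mean and sd, brightness (mean of band means) and maximum
    difference ``(max band mean - min band mean) / brightness``."""
    mask = _segment_mask(scene, segment_id)
    out: dict[str, float] = {}
    band_means = []
    for b in BAND_NAMES:
        vals = scene.bands[b][mask]
        out[f"mean_{b}"] = float(vals.mean())
        out[f"sd_{b}"] = float(vals.std())
        band_means.append(out[f"mean_{b}"])
    brightness = float(np.mean(band_means))
    out["brightness"] = brightness
    if brightness == 0:
        warnings.warn("zero brightness; max_diff set to 0", RuntimeWarning, stacklevel=2)
        out["max_diff"] = 0.0
    else:
        out["max_diff"] = float((max(band_means) - min(band_means)) / brightness)
    return out


# ---------------------------------------------------------------------------
# Geometric features
# ---------------------------------------------------------------------------

def geometric_features(mask: np.ndarray) -> dict[str, float]:
    """Shape descriptors of a binary segment mask.

    Area is the pixel count; perimeter counts exposed 4-neighbour pixel
    edges.  The length-width ratio is ``sqrt(l1/l2)`` from the
    eigenvalues of the pixel-coordinate covariance (each pixel treated as
    a unit square, i.e. 1/12 within-pixel variance added per axis, so a
    solid a x b rectangle yields exactly a/b).  Density is
    ``sqrt(area) / (1 + sqrt(l1 + l2))`` and rectangular fit is area over
    the area of the oriented minimum bounding rectangle.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    area = int(mask.sum())
    horiz = np.count_nonzero(mask[:, :-1] & mask[:, 1:])
    vert = np.count_nonzero(mask[:-1, :] & mask[1:, :])
    perimeter = 4 * area - 2 * (horiz + vert)

    rr, cc = np.nonzero(mask)
    coords = np.stack([rr, cc]).astype(float)
    cov = np.cov(coords, ddof=0) + np.eye(2) / 12.0
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    lam2, lam1 = float(eigvals[0]), float(eigvals[1])
    ratio = 1.0 if lam2 <= 1e-12 else float(np.sqrt(lam1 / lam2))
    density = float(np.sqrt(area) / (1.0 + np.sqrt(lam1 + lam2)))

    corners = np.concatenate(
        [
            np.stack([rr, cc], axis=1),
            np.stack([rr + 1, cc], axis=1),
            np.stack([rr, cc + 1], axis=1),
            np.stack([rr + 1, cc + 1], axis=1),
        ]
    )
    corners = np.unique(corners, axis=0)
    rect = MultiPoint([tuple(p) for p in corners]).convex_hull.minimum_rotated_rectangle
    rect_area = rect.area if rect.area > 0 else float(area)
    rect_fit = min(1.0, area / rect_area)

    return {
        "area": float(area),
        "perimeter": float(perimeter),
        "length_width_ratio": ratio,
        "density": density,
        "rect_fit": rect_fit,
    }


# ---------------------------------------------------------------------------
# Texture: GLCM and GLDV
# ---------------------------------------------------------------------------

def quantize_gray(values: np.ndarray, levels: int, mask: np.ndarray | None = None) -> np.ndarray:
    """Linear quantisation to ``levels`` gray levels over the masked
    min-max range.  Constant inputs map to level 0."""
    values = np.asarray(values, dtype=float)
    sel = values[mask] if mask is not None else values
    lo, hi = float(sel.min()), float(sel.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    scaled = (values - lo) / (hi - lo) * levels
    return np.clip(scaled.astype(np.int64), 0, levels - 1)


def glcm(
    gray: np.ndarray,
    spec: GlcmSpec = GlcmSpec(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gray-level co-occurrence matrix, summed over the spec's offsets.

    Pairs with either pixel outside ``mask`` are discarded.  Symmetrised
    and/or normalised (sum 1) per the spec.
    """
    gray = np.asarray(gray)
    if gray.min() < 0 or gray.max() >= spec.levels:
        raise ValueError("gray values must lie in [0, levels)")
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    P = np.zeros((spec.levels, spec.levels), dtype=float)
    h, w = gray.shape
    for dr, dc in spec.offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = gray[r0:r1, c0:c1]
        b = gray[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        np.add.at(P, (a[valid], b[valid]), 1.0)
    if spec.symmetric:
        P = P + P.T
    if spec.normalized:
        total = P.sum()
        if total > 0:
            P = P / total
    return P


def glcm_stats(P: np.ndarray) -> dict[str, float]:
    """Haralick-style statistics of a normalised co-occurrence matrix.

    homogeneity = sum P/(1+(i-j)^2); dissimilarity = sum P|i-j|;
    ASM = sum P^2; entropy = -sum P ln P; variance = sum P (i-mu)^2 with
    mu the P-weighted mean level.  Entropy uses the natural log.
    """
    P = np.asarray(P, dtype=float)
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"P must be normalised to sum 1 (got {total})")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff = i - j
    homogeneity = float((P / (1.0 + diff**2)).sum())
    dissimilarity = float((P * np.abs(diff)).sum())
    asm = float((P * P).sum())
    pos = P[P > 0]
    ent = float(-(pos * np.log(pos)).sum())
    mu = float((P * i).sum())
    variance = float((P * (i - mu) ** 2).sum())
    return {
        "homogeneity": homogeneity,
        "variance": variance,
        "dissimilarity": dissimilarity,
        "asm": asm,
        "entropy": ent,
    }


def gldv(
    gray: np.ndarray,
    offsets: Sequence[tuple[int, int]],
    levels: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Normalised histogram of absolute level differences at the offsets
    (the anti-diagonal marginal of the symmetric GLCM)."""
    spec = GlcmSpec(levels=levels, offsets=tuple(offsets), symmetric=True, normalized=True)
    P = glcm(gray, spec, mask)
    v = np.zeros(levels)
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    np.add.at(v, np.abs(i - j).ravel(), P.ravel())
    return v


def gldv_stats(
    gray: np.ndarray,
    offsets: Sequence[tuple[int, int]] = ((0, 1),),
    levels: int = 16,
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Mean, entropy (natural log) and ASM of the gray-level difference
    vector."""
    v = gldv(gray, offsets, levels, mask)
    total = v.sum()
    if total == 0:  # no valid pairs (e.g. single-pixel segment)
        return {"mean": 0.0, "entropy": 0.0, "asm": 1.0}
    v = v / total
    d = np.arange(levels)
    pos = v[v > 0]
    return {
        "mean": float((v * d).sum()),
        "entropy": float(-(pos * np.log(pos)).sum()),
        "asm": float((v * v).sum()),
    }


# degenerate (pair-less) segments take the constant-image limit
_CONSTANT_GLCM_STATS = {
    "homogeneity": 1.0,
    "variance": 0.0,
    "dissimilarity": 0.0,
    "asm": 1.0,
    "entropy": 0.0,
}


# ---------------------------------------------------------------------------
# Index features
# ---------------------------------------------------------------------------

def _safe_ratio(num: np.ndarray, den: np.ndarray, context: str) -> np.ndarray:
    bad = den == 0
    if np.any(bad):
        warnings.warn(
            f"{context}: zero denominator at {int(bad.sum())} pixel(s); returning 0",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(bad, 0.0, num / np.where(bad, 1.0, den))


def index_features(
    scene: "RasterScene",
    segment_id: int,
    evi_params: vegmetrics.EviParams = vegmetrics.EviParams(),
) -> dict[str, float]:
    """Segment means of pixelwise NDVI, EVI, ARVI, water index and the
    built-up proxy index.  Zero-denominator pixels contribute 0 with a
    warning, so every feature stays finite."""
    for b in BAND_NAMES:
        if b not in scene.bands:
            raise KeyError(f"scene is missing band {b!r}")
    mask = _segment_mask(scene, segment_id)
    blue = scene.bands["blue"][mask]
    green = scene.bands["green"][mask]
    red = scene.bands["red"][mask]
    nir = scene.bands["nir"][mask]

    ndvi_v = vegmetrics.ndvi(nir, red)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        evi_v = vegmetrics.evi(nir, red, blue, evi_params)
    n_bad = int(np.count_nonzero(~np.isfinite(evi_v)))
    if n_bad:
        warnings.warn(
            f"EVI: invalid denominator at {n_bad} pixel(s); contributing 0",
            RuntimeWarning,
            stacklevel=2,
        )
    evi_v = np.nan_to_num(np.asarray(evi_v), nan=0.0, posinf=0.0, neginf=0.0)
    rb = 2.0 * red - blue
    arvi_v = _safe_ratio(nir - rb, nir + rb, "ARVI")
    water_v = _safe_ratio(green - nir, green + nir, "water index")
    builtup_v = 0.5 * (
        _safe_ratio(red - nir, red + nir, "built-up proxy")
        + _safe_ratio(red - green, red + green, "built-up proxy")
    )
    return {
        "ndvi_mean": float(np.mean(ndvi_v)),
        "evi_mean": float(np.mean(evi_v)),
        "arvi_mean": float(np.mean(arvi_v)),
        "water_mean": float(np.mean(water_v)),
        "builtup_mean": float(np.mean(builtup_v)),
    }


# ---------------------------------------------------------------------------
# Full table
# ---------------------------------------------------------------------------

def _texture_features(
    scene: "RasterScene", mask: np.ndarray, manifest: FeatureManifest
) -> dict[str, float]:
    rr, cc = np.nonzero(mask)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    sub_mask = mask[r0:r1, c0:c1]
    out: dict[str, float] = {}
    all_offsets = tuple(o for sset in manifest.glcm_offset_sets for o in sset)
    for b in BAND_NAMES:
        band = scene.bands[b][r0:r1, c0:c1]
        gray = quantize_gray(band, manifest.glcm_levels, sub_mask)
        for offsets, off_name in zip(manifest.glcm_offset_sets, manifest.glcm_offset_names):
            spec = GlcmSpec(levels=manifest.glcm_levels, offsets=tuple(offsets))
            P = glcm(gray, spec, sub_mask)
            stats = glcm_stats(P) if P.sum() > 0 else dict(_CONSTANT_GLCM_STATS)
            for s in GLCM_STAT_NAMES:
                out[f"glcm_{s}_{b}_{off_name}"] = stats[s]
        gstats = gldv_stats(gray, all_offsets, manifest.glcm_levels, sub_mask)
        for s in GLDV_STAT_NAMES:
            out[f"gldv_{s}_{b}"] = gstats[s]
    return out


def segment_features(
    scene: "RasterScene", segment_id: int, manifest: FeatureManifest
) -> dict[str, float]:
    """All raw features of one segment (superset of the manifest)."""
    mask = _segment_mask(scene, segment_id)
    row: dict[str, float] = {}
    row.update(spectral_features(scene, segment_id))
    row.update(geometric_features(mask))
    row.update(_texture_features(scene, mask, manifest))
    row.update(index_features(scene, segment_id))
    for b in BAND_NAMES:
        vals = scene.bands[b][mask]
        row[f"min_{b}"] = float(vals.min())
        row[f"max_{b}"] = float(vals.max())
        row[f"median_{b}"] = float(np.median(vals))
        row[f"range_{b}"] = row[f"max_{b}"] - row[f"min_{b}"]
    return row


def build_feature_table(
    scene: "RasterScene", manifest: FeatureManifest | None = None
) -> FeatureTable:
    """One row per segment, columns exactly per the manifest (default 85),
    with labels copied from the scene when present."""
    if manifest is None:
        manifest = default_manifest()
    seg_ids = np.unique(scene.segments)
    seg_ids = seg_ids[seg_ids > 0]
    if seg_ids.size == 0:
        raise ValueError("scene contains no segments")
    names = manifest.feature_names
    rows = np.empty((seg_ids.size, len(names)))
    for k, sid in enumerate(seg_ids):
        row = segment_features(scene, int(sid), manifest)
        rows[k] = [row[name] for name in names]
    labels = None
    if scene.labels is not None:
        labels = [scene.labels[int(sid)] for sid in seg_ids]
    table = FeatureTable.from_arrays(rows, names, labels=labels, object_ids=seg_ids)
    table.manifest = manifest
    return table
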