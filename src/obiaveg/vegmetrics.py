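"""Vegetation formula layer.

Plant-community diversity indices (Shannon diversity, Margalef-style
richness, Simpson dominance), the enhanced vegetation index (EVI) and
NDVI, fractional vegetation cover by the dimidiate pixel model, and the
validation statistics (determination coefficient and RMSE) used to judge
cover estimates.

Diversity entropies use the natural logarithm; tree-induction entropies
elsewhere in the package use base 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "AbundanceVector",
    "EviParams",
    "CoverValidation",
    "shannon_diversity",
    "richness",
    "dominance",
    "evi",
    "ndvi",
    "estimate_cover",
    "r_squared",
    "rmse",
]

#: smallest admissible EVI denominator; pixels at or below it are invalid
DENOM_EPS = 1e-9


@dataclass(frozen=True)
class AbundanceVector:
    """Per-species importance values for one sample plot.

    Parameters
    ----------
    importance
        Importance value of each species, summing to 1.
    total_individuals
        Total number of individuals of all species in the plot; must be
        at least the species count.
    """

    importance: np.ndarray
    total_individuals: int | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.importance, dtype=float)
        object.__setattr__(self, "importance", z)
        if z.ndim != 1 or z.size < 1:
            raise ValueError("importance must be a non-empty 1-D vector")
        if np.any(z < 0) or np.any(z > 1):
            raise ValueError("importance values must lie in [0, 1]")
        if abs(float(z.sum()) - 1.0) > 1e-9:
            raise ValueError(f"importance values must sum to 1 (got {z.sum()!r})")
        if self.total_individuals is not None and self.total_individuals < z.size:
            raise ValueError("total individuals cannot be below the species count")

    @property
    def n_species(self) -> int:
        return int(self.importance.size)


@dataclass(frozen=True)
class EviParams:
    """EVI coefficients: gain ``o``, aerosol/soil terms ``v1``/``v2``,
    background offset ``d``.  Defaults are the MODIS convention."""

    o: float = 2.5
    v1: float = 6.0
    v2: float = 7.5
    d: float = 1.0


@dataclass(frozen=True)
class CoverValidation:
    """Paired observed / estimated fractional-cover samples."""

    observed: np.ndarray
    estimated: np.ndarray

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float).ravel()
        est = np.asarray(self.estimated, dtype=float).ravel()
        if obs.size != est.size:
            raise ValueError("observed and estimated must have equal length")
        if obs.size < 1:
            raise ValueError("at least one pair is required")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "estimated", est)

    @property
    def q(self) -> int:
        return int(self.observed.size)


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

def shannon_diversity(ab: AbundanceVector) -> float:
    """Shannon diversity ``-sum(Z ln Z)`` with ``0 ln 0 := 0``.

    Lies in ``[0, ln N]`` and is maximised by the uniform vector.
    """
    z = ab.importance
    pos = z[z > 0]
    return float(-(pos * np.log(pos)).sum())


def richness(n_species: int, total_individuals: int) -> float:
    """Species richness ``(N - 1) / ln X``.

    Requires ``X >= 2`` so the logarithm is positive.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if total_individuals < 2:
        raise ValueError("total_individuals must be >= 2 (ln X must be > 0)")
    return float((n_species - 1) / np.log(total_individuals))


def dominance(ab: AbundanceVector) -> float:
    """Simpson-type dominance ``1 - sum(Z^2)``; range ``[0, 1 - 1/N]``."""
    z = ab.importance
    return float(1.0 - (z * z).sum())


# ---------------------------------------------------------------------------
# Vegetation indices
# ---------------------------------------------------------------------------

def evi(
    nir: np.ndarray | float,
    red: np.ndarray | float,
    blue: np.ndarray | float,
    params: EviParams = EviParams(),
) -> np.ndarray | float:
    """Enhanced vegetation index.

    ``E = O (NIR - red) / (NIR + V1 red - V2 blue + D)`` evaluated
    elementwise.  Pixels whose denominator is ``<= DENOM_EPS`` are flagged
    invalid by returning NaN there (never silently zeroed).
    """
    nir_a = np.asarray(nir, dtype=float)
    red_a = np.asarray(red, dtype=float)
    blue_a = np.asarray(blue, dtype=float)
    denom = nir_a + params.v1 * red_a - params.v2 * blue_a + params.d
    invalid = denom <= DENOM_EPS
    if np.any(invalid):
        warnings.warn(
            f"{int(np.count_nonzero(invalid))} pixel(s) have non-positive EVI "
            "denominator; flagged NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = params.o * (nir_a - red_a) / denom
    out = np.where(invalid, np.nan, out)
    if np.isscalar(nir) and np.isscalar(red) and np.isscalar(blue):
        return float(out)
    return out


def ndvi(nir: np.ndarray | float, red: np.ndarray | float) -> np.ndarray | float:
    """Normalised difference vegetation index ``(NIR - red)/(NIR + red)``.

    Guarded: 0 where both bands are 0.  Always within ``[-1, 1]`` for
    non-negative reflectances.
    """
    nir_a = np.asarray(nir, dtype=float)
    red_a = np.asarray(red, dtype=float)
    denom = nir_a + red_a
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0, 0.0, (nir_a - red_a) / np.where(denom == 0, 1.0, denom))
    if np.isscalar(nir) and np.isscalar(red):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Fractional vegetation cover (dimidiate pixel model)
# ---------------------------------------------------------------------------

def estimate_cover(
    vi: np.ndarray,
    vi_soil: float | None = None,
    vi_veg: float | None = None,
    *,
    percentiles: tuple[float, float] = (5.0, 95.0),
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Fractional vegetation cover from a vegetation-index grid.

    Dimidiate pixel model: ``FVC = (VI - VI_soil) / (VI_veg - VI_soil)``
    clipped to [0, 1].  Endmembers are user-supplied or fall back to the
    5th/95th percentiles of the grid.

    Because band-ratio indices (EVI in particular, whose denominator
    carries coefficients 6 and 7.5) amplify per-band sensor noise
    several-fold, the grid is Gaussian-smoothed (``smooth_sigma`` pixels,
    default 1) before inversion; set ``smooth_sigma=0`` to invert the raw
    grid.  Constant grids are unaffected by smoothing.
    """
    vi = np.asarray(vi, dtype=float)
    if smooth_sigma > 0 and vi.ndim == 2 and min(vi.shape) > 1:
        vi = gaussian_filter(vi, sigma=smooth_sigma, mode="nearest")
    if vi_soil is None:
        vi_soil = float(np.nanpercentile(vi, percentiles[0]))
    if vi_veg is None:
        vi_veg = float(np.nanpercentile(vi, percentiles[1]))
    if not vi_veg > vi_soil:
        raise ValueError(
            f"vegetation endmember ({vi_veg}) must exceed soil endmember ({vi_soil})"
        )
    return np.clip((vi - vi_soil) / (vi_veg - vi_soil), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Cover-validation statistics
# ---------------------------------------------------------------------------

def r_squared(cv: CoverValidation, *, form: str = "ssr") -> float:
    """Determination coefficient of estimated vs observed cover.

    ``form="ssr"`` (default): regression sum of squares over total sum of
    squares, ``sum((est - mean(obs))^2) / sum((obs - mean(obs))^2)``.
    ``form="one_minus_sse"``: the conventional ``1 - SSE/SST``.
    Both equal 1 for a perfect fit.
    """
    if cv.q < 2:
        raise ValueError("at least two pairs are required")
    obs, est = cv.observed, cv.estimated
    obs_mean = obs.mean()
    sst = float(((obs - obs_mean) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values are all equal; R^2 undefined")
    if form == "ssr":
        return float(((est - obs_mean) ** 2).sum() / sst)
    if form == "one_minus_sse":
        return float(1.0 - ((obs - est) ** 2).sum() / sst)
    raise ValueError(f"unknown form {form!r}")


def rmse(cv: CoverValidation) -> float:
    """Root mean square error ``sqrt(sum((obs - est)^2) / q)``."""
    return float(np.sqrt(((cv.observed - cv.estimated) ** 2).mean()))
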