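"""Scene preprocessing: quality/water masking and dark-pixel subtraction.

The output of this stage is, per band, an atmosphere-and-glint-corrected
radiance raster (``L - Lsi`` with ``Lsi`` the mean deep-water radiance) and
a validity mask restricting all downstream log-domain arithmetic to usable
shallow-water pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .synthetic import QUALITY_CLOUD, QUALITY_FILL, Scene, VISIBLE_BANDS

MIN_DEEP_PIXELS = 30
#: corrected radiances at or below this are unusable for log transforms
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class DeepWaterRadiance:
    """Mean deep-water radiance for one band plus its support."""

    band: str
    value: float  # Lsi
    n_pixels: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("deep-water radiance must be >= 0")
        if self.n_pixels < MIN_DEEP_PIXELS:
            raise ValueError(
                f"deep-water estimate for {self.band!r} supported by only "
                f"{self.n_pixels} pixels (minimum {MIN_DEEP_PIXELS})"
            )


def quality_mask(quality: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """True where neither the fill/land nor the cloud bit is set."""
    quality = np.asarray(quality)
    if shape is not None and quality.shape != tuple(shape):
        raise ValueError(f"quality band shape {quality.shape} != scene shape {tuple(shape)}")
    return (quality & (QUALITY_FILL | QUALITY_CLOUD)) == 0


def water_mask_from_nir(nir: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """True where NIR radiance is below ``threshold`` (water absorbs NIR).

    Without an explicit threshold the land/water split point is found with
    Otsu's method on the NIR histogram; a constant band cannot be split and
    raises.
    """
    nir = np.asarray(nir, dtype=float)
    if threshold is None:
        if np.ptp(nir) < 1e-12:
            raise ValueError("constant NIR band: cannot derive a water threshold")
        threshold = float(threshold_otsu(nir))
    return nir < threshold


def estimate_deep_water_radiance(
    band_raster: np.ndarray,
    mask: np.ndarray,
    band: str = "",
    strategy: str = "darkest",
    percentile: float = 1.0,
    region: np.ndarray | None = None,
) -> DeepWaterRadiance:
    """Estimate the mean deep-water radiance ``Lsi`` for one band.

    ``strategy="darkest"`` averages the darkest ``percentile`` % of masked
    water pixels (dark-pixel approach, no polygon needed);
    ``strategy="region"`` averages over a supplied deep-water region mask.
    """
    band_raster = np.asarray(band_raster, dtype=float)
    if band_raster.shape != mask.shape:
        raise ValueError("band and mask dimensions differ")
    if strategy == "region":
        if region is None:
            raise ValueError('strategy "region" requires a deep-water region mask')
        values = band_raster[mask & region]
    elif strategy == "darkest":
        water = band_raster[mask]
        if water.size < MIN_DEEP_PIXELS:
            raise ValueError(f"only {water.size} water pixels available (minimum {MIN_DEEP_PIXELS})")
        k = max(MIN_DEEP_PIXELS, int(np.ceil(water.size * percentile / 100.0)))
        values = np.sort(water)[:k]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if values.size < MIN_DEEP_PIXELS:
        raise ValueError(
            f"deep-water estimate supported by only {values.size} pixels "
            f"(minimum {MIN_DEEP_PIXELS})"
        )
    return DeepWaterRadiance(band=band, value=float(values.mean()), n_pixels=int(values.size))


def dark_pixel_subtract(
    band_raster: np.ndarray,
    deep_water: DeepWaterRadiance | float,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the deep-water radiance; flag non-positive residuals.

    Returns ``(corrected, valid)`` where ``corrected = L - Lsi`` everywhere
    and ``valid`` is False for pixels with ``corrected <= epsilon`` — those
    carry no usable bottom signal and must be excluded from log-domain work,
    not clipped.
    """
    lsi = deep_water.value if isinstance(deep_water, DeepWaterRadiance) else float(deep_water)
    corrected = np.asarray(band_raster, dtype=float) - lsi
    return corrected, corrected > epsilon


def preprocess_scene(
    scene: Scene,
    nir_threshold: float | None = None,
    deep_strategy: str = "darkest",
    deep_percentile: float = 1.0,
    deep_region: np.ndarray | None = None,
) -> dict:
    """Run the full preprocessing chain on a scene.

    Returns a dict with the combined usable-pixel ``mask``, per-band
    ``deep_water`` estimates, per-band ``corrected`` radiances and the
    per-band ``valid`` flags (positive corrected signal).
    """
    qmask = quality_mask(scene.quality, scene.shape)
    if "nir" not in scene.bands:
        raise ValueError("water_mask stage requires a NIR band")
    wmask = water_mask_from_nir(scene.bands["nir"], nir_threshold)
    mask = qmask & wmask
    deep_water: dict[str, DeepWaterRadiance] = {}
    corrected: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for band in VISIBLE_BANDS:
        dw = estimate_deep_water_radiance(
            scene.bands[band],
            mask,
            band=band,
            strategy=deep_strategy,
            percentile=deep_percentile,
            region=deep_region,
        )
        deep_water[band] = dw
        corrected[band], valid[band] = dark_pixel_subtract(scene.bands[band], dw)
    return {"mask": mask, "deep_water": deep_water, "corrected": corrected, "valid": valid}
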