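"""Seeded synthetic shallow-water scene generator.

Emulates two-epoch, Landsat-like 30 m multispectral scenes of a fringing
reef with the statistical structure the downstream analysis assumes:

* bottom radiance follows the exponential water-column attenuation model
  ``Li = Lsi + ai * ri * exp(-f * ki * z)`` per band, where ``Lsi`` is the
  deep-water (atmosphere + surface) radiance, ``ai`` a surface/atmosphere
  constant, ``ri`` the bottom reflectance, ``ki`` the diffuse attenuation
  coefficient (per metre), ``z`` the depth and ``f`` a geometric path-length
  factor (2 for a two-flow model);
* a smoothed random depth field over the shelf, plus a contiguous optically
  deep strip (no bottom signal) used by dark-pixel subtraction;
* a land strip (bright NIR), optional cloud patches flagged in a quality
  band, additive Gaussian sensor noise;
* a programmed coral -> non-coral conversion between the two epochs, with
  exact bookkeeping of the converted pixels;
* percent-cover ground-truth tables in the field-survey format
  (Sand, Rock, Mud, Rubble, Coral, Seagrass, Seaweed columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .raster_io import write_raster

# ---------------------------------------------------------------- constants

VISIBLE_BANDS = ("blue", "green", "red")
ALL_BANDS = ("blue", "green", "red", "nir")

#: integer codes for bottom classes in truth maps; 0 = not sea floor (land)
CLASS_CODES = {"coral": 1, "sand": 2, "algae": 3, "rubble": 4, "seagrass": 5}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}
CORAL_CODE = CLASS_CODES["coral"]

#: quality-band bit flags
QUALITY_FILL = 1  # bit 0: fill / land
QUALITY_CLOUD = 2  # bit 1: cloud

#: ground-truth CSV benthic categories, in header order
GT_CATEGORIES = ("sand", "rock", "mud", "rubble", "coral", "seagrass", "seaweed")

#: simulated bottom class -> dominant ground-truth category
_CLASS_TO_CATEGORY = {
    "coral": "coral",
    "sand": "sand",
    "algae": "seaweed",
    "rubble": "rubble",
    "seagrass": "seagrass",
}


# ------------------------------------------------------------------- types


@dataclass(frozen=True)
class BandParams:
    """Forward-model constants for one band."""

    deep_water_radiance: float  # Lsi, radiance units
    surface_constant: float  # ai, dimensionless scale
    attenuation: float  # ki, per metre

    def __post_init__(self) -> None:
        if self.deep_water_radiance < 0:
            raise ValueError("deep_water_radiance must be >= 0")
        if self.attenuation <= 0:
            raise ValueError("attenuation must be > 0")


@dataclass(frozen=True)
class ForwardModelParams:
    """Per-band radiative constants plus shared geometry and noise."""

    bands: dict[str, BandParams]
    geometric_factor: float = 2.0  # f: two-flow model
    noise_sd: float = 0.0  # additive Gaussian sensor noise, radiance units

    def __post_init__(self) -> None:
        if self.geometric_factor <= 0:
            raise ValueError("geometric_factor must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def attenuation_ratio(self, band_i: str, band_j: str) -> float:
        """True ki/kj ratio, the quantity the water-column step estimates."""
        return self.bands[band_i].attenuation / self.bands[band_j].attenuation


@dataclass(frozen=True)
class BottomLibrary:
    """Per-class, per-band bottom reflectances (dimensionless, [0, 1])."""

    reflectance: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for cls, per_band in self.reflectance.items():
            for band in ALL_BANDS:
                if band not in per_band:
                    raise ValueError(f"class {cls!r} missing band {band!r}")
                r = per_band[band]
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"reflectance out of [0,1]: {cls}/{band}={r}")

    def array(self, band: str) -> np.ndarray:
        """Reflectance lookup indexed by class code (index 0 unused)."""
        out = np.zeros(max(CLASS_CODES.values()) + 1)
        for cls, code in CLASS_CODES.items():
            out[code] = self.reflectance[cls][band]
        return out


def default_forward_params(noise_sd: float | None = None) -> ForwardModelParams:
    """Landsat-like radiance constants for clear reef water.

    Attenuation rises steeply from blue to red (red penetrates a few metres
    only); NIR is effectively opaque to water. Default noise is 0.5 % of the
    brightest shallow-bottom signal.
    """
    bands = {
        "blue": BandParams(deep_water_radiance=52.0, surface_constant=110.0, attenuation=0.07),
        "green": BandParams(deep_water_radiance=30.0, surface_constant=100.0, attenuation=0.09),
        "red": BandParams(deep_water_radiance=12.0, surface_constant=90.0, attenuation=0.35),
        "nir": BandParams(deep_water_radiance=5.0, surface_constant=80.0, attenuation=3.0),
    }
    if noise_sd is None:
        lib = default_bottom_library()
        peak = max(
            bands[b].surface_constant * max(lib.reflectance[c][b] for c in CLASS_CODES)
            for b in VISIBLE_BANDS
        )
        noise_sd = 0.005 * peak
    return ForwardModelParams(bands=bands, noise_sd=noise_sd)


def default_bottom_library() -> BottomLibrary:
    """Typical visible-band reflectances: bright sand, dark vegetated bottoms."""
    return BottomLibrary(
        reflectance={
            "coral": {"blue": 0.10, "green": 0.14, "red": 0.12, "nir": 0.20},
            "sand": {"blue": 0.35, "green": 0.40, "red": 0.45, "nir": 0.50},
            "algae": {"blue": 0.06, "green": 0.12, "red": 0.08, "nir": 0.30},
            "rubble": {"blue": 0.20, "green": 0.24, "red": 0.26, "nir": 0.35},
            "seagrass": {"blue": 0.05, "green": 0.10, "red": 0.06, "nir": 0.25},
        }
    )


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and composition of a simulated two-epoch scene pair."""

    rows: int = 128
    cols: int = 128
    pixel_size: float = 30.0  # metres
    depth_range: tuple[float, float] = (0.5, 12.0)  # metres, shelf
    depth_smoothness: float = 8.0  # gaussian sigma, pixels
    deep_water_depth: float = 45.0  # metres, optically deep strip
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "coral": 0.35,
            "sand": 0.25,
            "algae": 0.15,
            "rubble": 0.15,
            "seagrass": 0.10,
        }
    )
    patch_granularity: int = 60  # tessellation centroids
    deep_water_fraction: float = 0.15  # of columns, right edge
    land_fraction: float = 0.08  # of columns, left edge
    cloud_fraction: float = 0.0
    change_fraction: float = 0.0  # coral pixels converted in epoch 2
    change_to: str = "algae"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 16 or self.cols < 16:
            raise ValueError("scene dimensions must be at least 16x16")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for name in ("deep_water_fraction", "land_fraction", "cloud_fraction", "change_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.change_to not in CLASS_CODES or self.change_to == "coral":
            raise ValueError(f"change_to must be a non-coral class, got {self.change_to!r}")
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"class proportions must sum to 1, got {total}")

    @property
    def geotransform(self) -> tuple[float, float, float, float, float, float]:
        return (0.0, self.pixel_size, 0.0, 0.0, 0.0, -self.pixel_size)


@dataclass
class Scene:
    """A multiband radiance raster with its quality band."""

    bands: dict[str, np.ndarray]  # band name -> (rows, cols) radiance
    quality: np.ndarray  # uint8 bit flags
    geotransform: tuple[float, ...]
    nodata: float = -9999.0
    epoch: str = ""

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()} | {self.quality.shape}
        if len(shapes) != 1:
            raise ValueError("all bands and quality must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.quality.shape

    @property
    def pixel_size(self) -> float:
        return abs(self.geotransform[1])

    def write(self, path: str | Path) -> Path:
        """Persist bands (B, G, R, NIR order) and quality as TIFFs."""
        path = Path(path)
        stack = np.stack([self.bands[b] for b in ALL_BANDS])
        write_raster(
            path,
            stack.astype(np.float32),
            geotransform=self.geotransform,
            nodata=self.nodata,
            band_names=list(ALL_BANDS),
            extra={"epoch": self.epoch},
        )
        qpath = path.with_name(path.stem + "_quality" + path.suffix)
        write_raster(qpath, self.quality, geotransform=self.geotransform)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "Scene":
        from .raster_io import read_raster

        path = Path(path)
        data, meta = read_raster(path)
        names = meta.get("band_names") or list(ALL_BANDS)
        qpath = path.with_name(path.stem + "_quality" + path.suffix)
        quality, _ = read_raster(qpath)
        return cls(
            bands={n: data[i].astype(np.float64) for i, n in enumerate(names)},
            quality=quality[0].astype(np.uint8),
            geotransform=tuple(meta["geotransform"]),
            nodata=meta.get("nodata") if meta.get("nodata") is not None else -9999.0,
            epoch=str(meta.get("epoch", "")),
        )


class ScenePair(NamedTuple):
    """Everything :func:`simulate_scene_pair` knows about a simulated site."""

    scene1: Scene
    scene2: Scene
    depth: np.ndarray  # metres; deep strip at deep_water_depth
    truth1: np.ndarray  # class codes, 0 on land
    truth2: np.ndarray
    water: np.ndarray  # bool: sea pixels (shelf + deep strip)
    shallow: np.ndarray  # bool: shelf pixels with a classified bottom
    deep_region: np.ndarray  # bool: optically deep strip
    n_converted: int  # programmed coral -> change_to conversions


# ------------------------------------------------------------- forward model


def radiance_forward(
    r: float | np.ndarray,
    z: float | np.ndarray,
    band: BandParams,
    geometric_factor: float = 2.0,
) -> np.ndarray:
    """At-sensor radiance of a bottom with reflectance ``r`` at depth ``z``.

    ``L = Lsi + ai * r * exp(-f * ki * z)``: strictly decreasing in depth
    (for a reflective bottom) and asymptoting to the deep-water radiance.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    return (
        band.deep_water_radiance
        + band.surface_constant * np.asarray(r, dtype=float)
        * np.exp(-geometric_factor * band.attenuation * z)
    )


# ------------------------------------------------------------ scene assembly


def _depth_field(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random shelf bathymetry rescaled to the configured range."""
    raw = gaussian_filter(
        rng.standard_normal((config.rows, config.cols)), sigma=config.depth_smoothness
    )
    lo, hi = raw.min(), raw.max()
    z_min, z_max = config.depth_range
    if hi - lo < 1e-12:  # pathologically smooth field
        return np.full((config.rows, config.cols), 0.5 * (z_min + z_max))
    return z_min + (raw - lo) / (hi - lo) * (z_max - z_min)


def _tessellate_bottom(
    config: SceneConfig, rng: np.random.Generator, region: np.ndarray
) -> np.ndarray:
    """Seeded nearest-centroid patchwork of bottom classes over ``region``."""
    classes = sorted(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    n = max(config.patch_granularity, len(classes))
    centroids = np.column_stack(
        [rng.uniform(0, config.rows, n), rng.uniform(0, config.cols, n)]
    )
    labels = rng.choice(len(classes), size=n, p=probs)
    # guarantee every positive-proportion class at least one centroid
    for idx, cls in enumerate(classes):
        if probs[idx] > 0 and not np.any(labels == idx):
            labels[rng.integers(n)] = idx
    tree = cKDTree(centroids)
    rr, cc = np.nonzero(region)
    _, nearest = tree.query(np.column_stack([rr, cc]))
    out = np.zeros((config.rows, config.cols), dtype=np.uint8)
    out[rr, cc] = np.array(
        [CLASS_CODES[classes[i]] for i in labels], dtype=np.uint8
    )[nearest]
    return out


def _render_scene(
    config: SceneConfig,
    params: ForwardModelParams,
    bottoms: BottomLibrary,
    truth: np.ndarray,
    depth: np.ndarray,
    land: np.ndarray,
    cloud: np.ndarray,
    rng: np.random.Generator,
    epoch: str,
) -> Scene:
    water = ~land
    bands: dict[str, np.ndarray] = {}
    for name in VISIBLE_BANDS:
        bp = params.bands[name]
        refl = bottoms.array(name)[truth]  # 0 where land / deep (code 0)
        li = radiance_forward(refl, np.maximum(depth, 0.0), bp, params.geometric_factor)
        li = np.where(land, bp.deep_water_radiance + 0.30 * bp.surface_constant, li)
        bands[name] = li
    # NIR: water absorbs fully -> deep-water value; land is bright
    nir = params.bands["nir"]
    bands["nir"] = np.where(
        land,
        nir.deep_water_radiance + 0.50 * nir.surface_constant,
        nir.deep_water_radiance,
    )
    if params.noise_sd > 0:
        for name in ALL_BANDS:
            bands[name] = bands[name] + rng.normal(0.0, params.noise_sd, truth.shape)
    # clouds: bright in every band, flagged in quality
    if cloud.any():
        for name in ALL_BANDS:
            bp = params.bands[name]
            bright = bp.deep_water_radiance + 1.2 * bp.surface_constant
            bands[name] = np.where(cloud, bright, bands[name])
    quality = np.zeros(truth.shape, dtype=np.uint8)
    quality[land] |= QUALITY_FILL
    quality[cloud] |= QUALITY_CLOUD
    return Scene(
        bands=bands, quality=quality, geotransform=config.geotransform, epoch=epoch
    )


def _cloud_mask(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Disk-shaped cloud patches covering ~cloud_fraction of the scene."""
    mask = np.zeros((config.rows, config.cols), dtype=bool)
    target = config.cloud_fraction * config.rows * config.cols
    if target < 1:
        return mask
    rr, cc = np.mgrid[0 : config.rows, 0 : config.cols]
    radius = max(2.0, 0.04 * min(config.rows, config.cols))
    while mask.sum() < target:
        cy, cx = rng.uniform(0, config.rows), rng.uniform(0, config.cols)
        mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
    return mask


def simulate_scene_pair(
    config: SceneConfig,
    params: ForwardModelParams | None = None,
    bottoms: BottomLibrary | None = None,
) -> ScenePair:
    """Simulate two co-registered epochs of one site.

    Epoch 2 differs from epoch 1 by exactly
    ``round(change_fraction * n_coral)`` coral pixels converted to the
    configured replacement class, plus independent sensor noise.
    Deterministic given ``config.seed``.
    """
    params = params or default_forward_params()
    bottoms = bottoms or default_bottom_library()
    rng = np.random.default_rng(config.seed)

    n_land = int(round(config.land_fraction * config.cols))
    n_deep = int(round(config.deep_water_fraction * config.cols))
    land = np.zeros((config.rows, config.cols), dtype=bool)
    land[:, :n_land] = True
    deep = np.zeros((config.rows, config.cols), dtype=bool)
    if n_deep:
        deep[:, config.cols - n_deep :] = True
    deep &= ~land
    water = ~land
    shelf = water & ~deep

    depth = _depth_field(config, rng)
    depth[deep] = config.deep_water_depth
    depth[land] = 0.0

    truth1 = _tessellate_bottom(config, rng, shelf)
    coral_idx = np.flatnonzero(truth1 == CORAL_CODE)
    n_convert = int(round(config.change_fraction * coral_idx.size))
    truth2 = truth1.copy()
    if n_convert:
        chosen = rng.choice(coral_idx, size=n_convert, replace=False)
        truth2.flat[chosen] = CLASS_CODES[config.change_to]

    cloud1 = _cloud_mask(config, rng)
    cloud2 = _cloud_mask(config, rng)

    scene1 = _render_scene(config, params, bottoms, truth1, depth, land, cloud1, rng, "t0")
    scene2 = _render_scene(config, params, bottoms, truth2, depth, land, cloud2, rng, "t1")
    return ScenePair(
        scene1=scene1,
        scene2=scene2,
        depth=depth,
        truth1=truth1,
        truth2=truth2,
        water=water,
        shallow=shelf,
        deep_region=deep,
        n_converted=n_convert,
    )


# ------------------------------------------------------------- ground truth


def _percent_cover_row(
    dominant: str, rng: np.random.Generator
) -> dict[str, int]:
    """Integer percent covers summing to 100 with ``dominant`` >= 55 %."""
    covers = dict.fromkeys(GT_CATEGORIES, 0)
    dom = int(rng.integers(55, 91))
    covers[dominant] = dom
    others = [c for c in GT_CATEGORIES if c != dominant]
    fill = rng.choice(len(others), size=min(3, len(others)), replace=False)
    remaining = 100 - dom
    weights = rng.dirichlet(np.ones(len(fill)))
    parts = np.floor(weights * remaining).astype(int)
    parts[0] += remaining - parts.sum()
    for k, p in zip(fill, parts):
        covers[others[k]] += int(p)
    return covers


def sample_ground_truth(
    truth_map: np.ndarray,
    n: int,
    coral_fraction: float | None = None,
    seed: int = 0,
    site: str = "site",
    valid: np.ndarray | None = None,
    allow_fewer: bool = False,
) -> pd.DataFrame:
    """Draw ``n`` survey points and emit a percent-cover table.

    Each row's dominant category reflects the true bottom class at that
    pixel. If ``coral_fraction`` is given, ``round(n * coral_fraction)``
    points fall on coral pixels and the rest on non-coral bottom; otherwise
    points are drawn uniformly over classified pixels. With ``allow_fewer``
    a request larger than the usable pool returns every usable pixel
    instead of raising.
    """
    rng = np.random.default_rng(seed)
    usable = truth_map > 0
    if valid is not None:
        usable &= valid
    pool = np.flatnonzero(usable)
    if pool.size == 0:
        raise ValueError("no usable water pixels to sample ground truth from")
    if n > pool.size:
        if not allow_fewer:
            raise ValueError(f"requested {n} points but only {pool.size} usable pixels")
        n = pool.size

    if coral_fraction is None:
        chosen = rng.choice(pool, size=n, replace=False)
    else:
        if not 0.0 <= coral_fraction <= 1.0:
            raise ValueError("coral_fraction must lie in [0, 1]")
        coral_pool = pool[truth_map.flat[pool] == CORAL_CODE]
        other_pool = pool[truth_map.flat[pool] != CORAL_CODE]
        n_coral = int(round(n * coral_fraction))
        n_other = n - n_coral
        if n_coral > coral_pool.size or n_other > other_pool.size:
            raise ValueError(
                f"cannot draw {n_coral} coral / {n_other} non-coral points "
                f"from pools of {coral_pool.size} / {other_pool.size}"
            )
        chosen = np.concatenate(
            [
                rng.choice(coral_pool, size=n_coral, replace=False),
                rng.choice(other_pool, size=n_other, replace=False),
            ]
        )
        rng.shuffle(chosen)

    rows_idx, cols_idx = np.unravel_index(chosen, truth_map.shape)
    records = []
    for r, c in zip(rows_idx.tolist(), cols_idx.tolist()):
        cls = CODE_NAMES[int(truth_map[r, c])]
        covers = _percent_cover_row(_CLASS_TO_CATEGORY[cls], rng)
        records.append({"row": r, "col": c, "site": site, **covers})
    return pd.DataFrame.from_records(records, columns=["row", "col", "site", *GT_CATEGORIES])


def write_ground_truth(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"row", "col", "site", *GT_CATEGORIES} - set(table.columns)
    if missing:
        raise ValueError(f"ground truth table missing columns: {sorted(missing)}")
    return table


def write_truth_map(truth: np.ndarray, path: str | Path, pixel_size: float = 30.0) -> Path:
    return write_raster(
        path,
        truth.astype(np.uint8),
        geotransform=(0.0, pixel_size, 0.0, 0.0, 0.0, -pixel_size),
        extra={"class_codes": CLASS_CODES},
    )


def twin_site_params(
    base: ForwardModelParams,
    turbidity_shift: float = 0.0,
    deep_water_shift: float = 0.0,
) -> ForwardModelParams:
    """Parameter-shifted variant of a site: different optical conditions.

    ``turbidity_shift`` scales every attenuation coefficient multiplicatively
    (turbid water attenuates faster); ``deep_water_shift`` offsets the
    deep-water radiances (different atmosphere / glint).
    """
    bands = {
        name: replace(
            bp,
            attenuation=bp.attenuation * (1.0 + turbidity_shift),
            deep_water_radiance=max(0.0, bp.deep_water_radiance + deep_water_shift),
        )
        for name, bp in base.bands.items()
    }
    return replace(base, bands=bands)


def jitter_bottom_library(
    base: BottomLibrary, scale: float, seed: int
) -> BottomLibrary:
    """Multiplicatively jitter reflectances (site-to-site benthic variation)."""
    rng = np.random.default_rng(seed)
    refl = {
        cls: {
            band: float(np.clip(r * (1.0 + rng.normal(0.0, scale)), 0.0, 1.0))
            for band, r in per_band.items()
        }
        for cls, per_band in base.reflectance.items()
    }
    return BottomLibrary(reflectance=refl)
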