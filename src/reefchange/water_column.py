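"""Water-column correction: attenuation ratios and depth-invariant indices.

Under the exponential attenuation model, the log of a deep-water-corrected
band radiance is linear in depth with slope ``-f * ki``. Over pixels of one
bottom type spanning a range of depths, the variances and covariance of two
log bands therefore determine the attenuation ratio ``ki/kj`` through

    a = (sigma_ii - sigma_jj) / (2 * sigma_ij),      ki/kj = a + sqrt(a^2 + 1)

and the per-pixel combination

    DII_ij = ln(Li - Lsi) - (ki/kj) * ln(Lj - Lsj)

is independent of depth — it varies with bottom type only, which is what
makes it a usable classification feature in optically shallow water.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .preprocessing import preprocess_scene
from .raster_io import write_raster
from .synthetic import Scene, VISIBLE_BANDS

MIN_CALIBRATION_PIXELS = 10


@dataclass(frozen=True)
class BandPairStats:
    """Log-domain second moments of one band pair over calibration pixels."""

    band_i: str
    band_j: str
    var_i: float  # sigma_ii
    var_j: float  # sigma_jj
    cov: float  # sigma_ij
    n: int

    def __post_init__(self) -> None:
        if self.var_i < 0 or self.var_j < 0:
            raise ValueError("variances must be non-negative")
        if self.n < MIN_CALIBRATION_PIXELS:
            raise ValueError(
                f"{self.n} calibration pixels for ({self.band_i}, {self.band_j}); "
                f"need at least {MIN_CALIBRATION_PIXELS}"
            )
        bound = np.sqrt(self.var_i * self.var_j)
        if abs(self.cov) > bound * (1 + 1e-9) + 1e-30:
            raise ValueError("covariance exceeds Cauchy-Schwarz bound")


@dataclass(frozen=True)
class AttenuationEstimate:
    """Estimated attenuation ratio for one band pair."""

    stats: BandPairStats
    a: float  # (sigma_ii - sigma_jj) / (2 sigma_ij)
    ratio: float  # ki / kj = a + sqrt(a^2 + 1)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.stats.band_i, self.stats.band_j)


@dataclass
class DIIStack:
    """Depth-invariant index layers, one per band pair, with validity."""

    layers: dict[tuple[str, str], np.ndarray]  # NaN where invalid
    valid: np.ndarray  # bool: all layers defined
    provenance: dict[tuple[str, str], AttenuationEstimate]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape

    def features(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n, n_pairs) feature matrix at pixel positions (may contain NaN)."""
        return np.column_stack([self.layers[p][rows, cols] for p in self.pairs])

    def feature_names(self) -> list[str]:
        return [f"dii_{i}_{j}" for i, j in self.pairs]

    def write(self, path: str | Path, geotransform=(0.0, 30.0, 0.0, 0.0, 0.0, -30.0)) -> Path:
        stack = np.stack([self.layers[p] for p in self.pairs]).astype(np.float32)
        return write_raster(
            path,
            stack,
            geotransform=geotransform,
            nodata=float("nan"),
            band_names=self.feature_names(),
            extra={
                "attenuation_ratios": {
                    f"{i}/{j}": est.ratio for (i, j), est in self.provenance.items()
                }
            },
        )


def read_dii_stack(path: str | Path) -> DIIStack:
    """Read a persisted DII stack; provenance carries ratios only."""
    from .raster_io import read_raster

    data, meta = read_raster(path)
    names = meta.get("band_names") or [f"dii_{i}" for i in range(data.shape[0])]
    pairs = []
    for name in names:
        parts = name.split("_")
        pairs.append((parts[1], parts[2]) if len(parts) == 3 else (name, ""))
    layers = {p: data[k].astype(np.float64) for k, p in enumerate(pairs)}
    valid = np.logical_and.reduce([np.isfinite(l) for l in layers.values()])
    return DIIStack(layers=layers, valid=valid, provenance={})


def band_pair_stats(
    corrected_i: np.ndarray,
    corrected_j: np.ndarray,
    calibration_mask: np.ndarray,
    band_i: str = "i",
    band_j: str = "j",
) -> BandPairStats:
    """Sample (n-1) variances/covariance of the log corrected radiances.

    Calibration pixels must share one bottom type while spanning a depth
    range; every selected pixel must carry positive corrected radiance in
    both bands.
    """
    xi = np.asarray(corrected_i, dtype=float)[calibration_mask]
    xj = np.asarray(corrected_j, dtype=float)[calibration_mask]
    if xi.size < MIN_CALIBRATION_PIXELS:
        raise ValueError(
            f"{xi.size} calibration pixels; need at least {MIN_CALIBRATION_PIXELS}"
        )
    if np.any(xi <= 0) or np.any(xj <= 0):
        raise ValueError("calibration pixels must have positive corrected radiance")
    li, lj = np.log(xi), np.log(xj)
    cov = np.cov(li, lj, ddof=1)
    return BandPairStats(
        band_i=band_i,
        band_j=band_j,
        var_i=float(cov[0, 0]),
        var_j=float(cov[1, 1]),
        cov=float(cov[0, 1]),
        n=int(xi.size),
    )


def attenuation_ratio(stats: BandPairStats) -> AttenuationEstimate:
    """Closed-form attenuation-ratio estimate from the pair moments."""
    if stats.cov == 0:
        raise ValueError(
            f"zero covariance for ({stats.band_i}, {stats.band_j}): ratio undefined"
        )
    a = (stats.var_i - stats.var_j) / (2.0 * stats.cov)
    return AttenuationEstimate(stats=stats, a=a, ratio=a + float(np.sqrt(a * a + 1.0)))


def depth_invariant_index(
    corrected_i: np.ndarray,
    corrected_j: np.ndarray,
    ratio: float,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel ``ln(Li - Lsi) - ratio * ln(Lj - Lsj)``; NaN where invalid."""
    ci = np.asarray(corrected_i, dtype=float)
    cj = np.asarray(corrected_j, dtype=float)
    ok = (ci > 0) & (cj > 0)
    if valid is not None:
        ok &= valid
    out = np.full(ci.shape, np.nan)
    out[ok] = np.log(ci[ok]) - ratio * np.log(cj[ok])
    return out


def build_dii_stack(
    scene: Scene,
    calibration_mask: np.ndarray,
    pairs: list[tuple[str, str]] | None = None,
    nir_threshold: float | None = None,
    deep_strategy: str = "darkest",
    deep_region: np.ndarray | None = None,
    preprocessed: dict | None = None,
    noise_sigma_factor: float = 3.0,
    min_signal_fraction: float = 0.02,
) -> DIIStack:
    """Preprocess a scene and compute one DII layer per band pair.

    Default pairs are all three combinations of the visible bands
    (blue-green, blue-red, green-red). The calibration mask selects
    uniform-bottom pixels across depths for the ratio estimate; it is
    intersected with the scene's usable mask and validity flags.

    Strongly attenuated bands (red in particular) lose their bottom signal
    into the sensor noise within a few metres of water; log-transforming
    such pixels yields meaningless values and corrupts the moment
    estimates. Each band therefore carries a detection limit below which
    its corrected radiance is treated as no-signal, for calibration and
    layer validity alike. When a deep-water region is supplied, the limit
    is ``noise_sigma_factor`` times the sensor-noise standard deviation
    estimated from that region (a conventional 3-sigma detection limit,
    zero for a noiseless scene); otherwise it falls back to
    ``min_signal_fraction`` of the band's bright (95th-percentile)
    calibration signal. Red-pair layers consequently cover only the depth
    range the red band actually penetrates.
    """
    if pairs is None:
        pairs = list(combinations(VISIBLE_BANDS, 2))
    for i, j in pairs:
        if i not in VISIBLE_BANDS or j not in VISIBLE_BANDS:
            raise ValueError(f"band pair ({i}, {j}) not drawn from visible bands")
    pre = preprocessed if preprocessed is not None else preprocess_scene(
        scene,
        nir_threshold=nir_threshold,
        deep_strategy=deep_strategy,
        deep_region=deep_region,
    )
    mask, corrected, valid = pre["mask"], pre["corrected"], pre["valid"]
    base_calib = calibration_mask & mask
    floor: dict[str, np.ndarray] = {}
    for band in {b for pair in pairs for b in pair}:
        level = 0.0
        if deep_region is not None and (deep_region & mask).sum() >= 2:
            sigma = float(np.std(corrected[band][deep_region & mask], ddof=1))
            level = noise_sigma_factor * sigma
        elif min_signal_fraction > 0 and (base_calib & valid[band]).any():
            level = min_signal_fraction * float(
                np.percentile(corrected[band][base_calib & valid[band]], 95)
            )
        floor[band] = valid[band] & (corrected[band] > level)
    layers: dict[tuple[str, str], np.ndarray] = {}
    provenance: dict[tuple[str, str], AttenuationEstimate] = {}
    for i, j in pairs:
        calib = base_calib & floor[i] & floor[j]
        est = attenuation_ratio(
            band_pair_stats(corrected[i], corrected[j], calib, band_i=i, band_j=j)
        )
        provenance[(i, j)] = est
        layers[(i, j)] = depth_invariant_index(
            corrected[i], corrected[j], est.ratio, valid=mask & floor[i] & floor[j]
        )
    all_valid = np.logical_and.reduce([np.isfinite(l) for l in layers.values()])
    return DIIStack(layers=layers, valid=all_valid, provenance=provenance)
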