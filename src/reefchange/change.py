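"""Two-epoch per-pixel change detection and area accounting.

Class rasters from two epochs are compared pixel by pixel over the shared
valid-water mask, transitions are tabulated, pixel counts convert to km^2
through the pixel footprint, and the summary mirrors the conventional
reporting: areas to 2 decimals, percentages to 1 decimal, raw counts kept
alongside.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np


class Transition(IntEnum):
    CORAL_CORAL = 0
    CORAL_NON = 1
    NON_CORAL = 2
    NON_NON = 3
    INVALID = 4


@dataclass(frozen=True)
class ChangeReport:
    """Transition counts, areas and percentages for one site pair."""

    counts: dict[str, int]  # transition name -> pixel count
    initial_coral_pixels: int
    final_coral_pixels: int
    initial_coral_km2: float  # 2 dp
    final_coral_km2: float  # 2 dp
    percent_change: float | None  # 1 dp; (initial - final) / initial * 100
    initial_coral_share_pct: float | None  # 1 dp, of valid shallow pixels
    final_coral_share_pct: float | None
    pixel_size_m: float

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload = {k: ("undefined" if v is None else v) for k, v in payload.items()}
        path.write_text(json.dumps(payload, indent=2))
        return path

    def summary_lines(self) -> list[str]:
        pc = "undefined" if self.percent_change is None else f"{self.percent_change} %"
        return [
            f"initial coral: {self.initial_coral_pixels} px = {self.initial_coral_km2} km^2",
            f"final coral:   {self.final_coral_pixels} px = {self.final_coral_km2} km^2",
            f"coral-cover change: {pc}"
            + ("" if self.percent_change is None else " reduction"
               if self.percent_change >= 0 else " gain"),
            f"coral share of shallow benthic area: "
            f"{self.initial_coral_share_pct} % -> {self.final_coral_share_pct} %",
        ]


def per_pixel_change(
    class_t0: np.ndarray,
    class_t1: np.ndarray,
    valid: np.ndarray | None = None,
    geotransform_t0: tuple | None = None,
    geotransform_t1: tuple | None = None,
) -> np.ndarray:
    """Categorical transition raster from two binary class rasters.

    Class rasters use 1 = coral, 0 = non-coral, negative = nodata. The
    valid mask (intersection of both epochs' usable masks) gates every
    pixel; anything outside it, or nodata in either epoch, is INVALID.
    """
    c0 = np.asarray(class_t0)
    c1 = np.asarray(class_t1)
    if c0.shape != c1.shape:
        raise ValueError(f"epoch rasters differ in shape: {c0.shape} vs {c1.shape}")
    if geotransform_t0 is not None and geotransform_t1 is not None:
        if not np.allclose(geotransform_t0, geotransform_t1):
            raise ValueError("epoch rasters have different geotransforms")
    ok = (c0 >= 0) & (c1 >= 0)
    if valid is not None:
        if valid.shape != c0.shape:
            raise ValueError("valid mask shape mismatch")
        ok &= valid.astype(bool)
    out = np.full(c0.shape, Transition.INVALID, dtype=np.uint8)
    coral0 = c0 == 1
    coral1 = c1 == 1
    out[ok & coral0 & coral1] = Transition.CORAL_CORAL
    out[ok & coral0 & ~coral1] = Transition.CORAL_NON
    out[ok & ~coral0 & coral1] = Transition.NON_CORAL
    out[ok & ~coral0 & ~coral1] = Transition.NON_NON
    return out


def area_from_pixels(count: int, pixel_size_m: float = 30.0) -> float:
    """Pixel count to km^2 (2-decimal report rounding)."""
    if count < 0:
        raise ValueError("pixel count must be >= 0")
    return round(count * pixel_size_m**2 / 1e6, 2)


def change_summary(change: np.ndarray, pixel_size_m: float = 30.0) -> ChangeReport:
    """Tabulate a transition raster into the full change report."""
    counts = {t.name.lower(): int(np.sum(change == t)) for t in Transition}
    initial = counts["coral_coral"] + counts["coral_non"]
    final = counts["coral_coral"] + counts["non_coral"]
    n_valid = sum(counts[t.name.lower()] for t in Transition if t != Transition.INVALID)
    percent_change = (
        round((initial - final) / initial * 100.0, 1) if initial else None
    )
    share0 = round(initial / n_valid * 100.0, 1) if n_valid else None
    share1 = round(final / n_valid * 100.0, 1) if n_valid else None
    return ChangeReport(
        counts=counts,
        initial_coral_pixels=initial,
        final_coral_pixels=final,
        initial_coral_km2=area_from_pixels(initial, pixel_size_m),
        final_coral_km2=area_from_pixels(final, pixel_size_m),
        percent_change=percent_change,
        initial_coral_share_pct=share0,
        final_coral_share_pct=share1,
        pixel_size_m=pixel_size_m,
    )
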