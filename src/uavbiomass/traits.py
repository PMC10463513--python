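"""Per-plot trait extraction from masked multispectral rasters.

Mirrors the manual image-analysis workflow used in UAV field phenotyping:
cut a rectangular region of interest (ROI) per plot out of the orthomosaic,
mask out soil pixels, then summarise the remaining plant pixels as

* canopy cover (CC) — percentage of plant pixels in the ROI,
* per-band mean digital numbers (DNs) — the input to vegetation indices,
* plant height (PH) — mean of the canopy height model (DSM − DTM) over
  plant pixels.

All grids are plain numpy arrays; digital numbers are reflectance-like
floats and elevations are in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Fixed band order for every 5-channel stack in this package.
BANDS: tuple[str, ...] = ("B", "G", "R", "RE", "NIR")


@dataclass(frozen=True)
class ChannelStack:
    """Co-registered 5-band grid of digital numbers (B, G, R, RE, NIR)."""

    data: np.ndarray  # shape (5, rows, cols)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[0] != len(BANDS):
            raise ValueError(
                f"expected shape (5, rows, cols), got {data.shape}"
            )
        if not np.all(np.isfinite(data)) or np.any(data < 0):
            raise ValueError("digital numbers must be finite and >= 0")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band(self, name: str) -> np.ndarray:
        try:
            return self.data[BANDS.index(name)]
        except ValueError:
            raise KeyError(f"unknown band {name!r}; bands are {BANDS}") from None

    @classmethod
    def from_bands(cls, bands: Mapping[str, np.ndarray]) -> "ChannelStack":
        return cls(np.stack([np.asarray(bands[b], dtype=float) for b in BANDS]))


@dataclass(frozen=True)
class ElevationPair:
    """Digital surface model (canopy top) and digital terrain model (bare
    ground), metres, same grid as the channel stack.

    ``dsm >= dtm - tol`` is enforced everywhere; small negative differences
    (elevation noise) are tolerated up to ``tol`` (default 1 cm).
    """

    dsm: np.ndarray
    dtm: np.ndarray
    tol: float = 0.01

    def __post_init__(self) -> None:
        dsm = np.asarray(self.dsm, dtype=float)
        dtm = np.asarray(self.dtm, dtype=float)
        if dsm.shape != dtm.shape:
            raise ValueError("DSM and DTM shapes differ")
        if np.any(dsm < dtm - self.tol):
            raise ValueError(f"DSM below DTM by more than {self.tol} m")
        object.__setattr__(self, "dsm", dsm)
        object.__setattr__(self, "dtm", dtm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dsm.shape


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular region of interest, 0-based, half-open."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("ROI must be non-empty")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError("ROI indices must be non-negative")

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ROI":
        return cls(0, shape[0], 0, shape[1])

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop)

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.row_stop > shape[0] or self.col_stop > shape[1]:
            raise ValueError(f"ROI {self} outside raster bounds {shape}")

    @property
    def n_pixels(self) -> int:
        return (self.row_stop - self.row_start) * (self.col_stop - self.col_start)


@dataclass(frozen=True)
class MaskRule:
    """Soil-masking rule: classify a pixel as plant when the configured
    index exceeds ``threshold``.

    Rules: ``ndvi`` — (NIR−R)/(NIR+R); ``exg`` — excess green 2G−R−B.
    Pixels with a zero NDVI denominator are soil.
    """

    name: str = "ndvi"
    threshold: float = 0.4

    _KNOWN = ("ndvi", "exg")

    def __post_init__(self) -> None:
        if self.name not in self._KNOWN:
            raise ValueError(
                f"unknown mask rule {self.name!r}; known rules: {self._KNOWN}"
            )


def mask_soil(stack: ChannelStack, rule: MaskRule = MaskRule()) -> np.ndarray:
    """Classify every pixel as plant (True) or soil (False)."""
    if rule.name == "ndvi":
        nir, r = stack.band("NIR"), stack.band("R")
        denom = nir + r
        with np.errstate(divide="ignore", invalid="ignore"):
            ndvi = np.where(denom > 0, (nir - r) / np.where(denom > 0, denom, 1.0), -np.inf)
        return ndvi > rule.threshold
    # excess green: 2G - R - B
    exg = 2.0 * stack.band("G") - stack.band("R") - stack.band("B")
    return exg > rule.threshold


def canopy_cover(mask: np.ndarray, roi: ROI) -> float:
    """Canopy cover: percentage of plant pixels filling the ROI (0–100)."""
    roi.check_within(mask.shape)
    window = mask[roi.slices()]
    return 100.0 * float(np.count_nonzero(window)) / window.size


def mean_dns(stack: ChannelStack, mask: np.ndarray, roi: ROI) -> np.ndarray:
    """Per-band mean DN over plant pixels inside the ROI.

    Returns a length-5 vector in band order; all-NaN when the ROI holds no
    plant pixel, so downstream predictors propagate as missing, never as 0.
    """
    roi.check_within(stack.shape)
    rs, cs = roi.slices()
    window_mask = mask[rs, cs]
    if not window_mask.any():
        return np.full(len(BANDS), np.nan)
    return stack.data[:, rs, cs][:, window_mask].mean(axis=1)


def plant_height(elev: ElevationPair, mask: np.ndarray, roi: ROI) -> float:
    """Mean canopy height (DSM − DTM) over plant pixels, metres.

    Per-pixel negative differences (elevation noise) are clamped to 0
    before averaging — heights are physical. NaN when no plant pixel.
    """
    roi.check_within(elev.shape)
    rs, cs = roi.slices()
    window_mask = mask[rs, cs]
    if not window_mask.any():
        return float("nan")
    chm = elev.dsm[rs, cs] - elev.dtm[rs, cs]
    return float(np.clip(chm[window_mask], 0.0, None).mean())


@dataclass
class PlotRecord:
    """One plot's extracted predictors plus its design metadata."""

    plot_id: str
    genotype: str = ""
    year: int = 0
    gdd: float = 0.0
    environment: str = "control"
    rep: int = 0
    cc: float = float("nan")            # percent of ROI
    ph: float = float("nan")            # metres
    mean_dn: np.ndarray = field(default_factory=lambda: np.full(5, np.nan))
    vi: dict[str, float] = field(default_factory=dict)
    fb_measured: float | None = None    # kg/m^2, None when not harvested

    def __post_init__(self) -> None:
        if np.isfinite(self.cc) and not 0.0 <= self.cc <= 100.0:
            raise ValueError("CC must lie in [0, 100]")
        if np.isfinite(self.ph) and self.ph < 0:
            raise ValueError("PH must be >= 0")


def extract_record(
    stack: ChannelStack,
    elev: ElevationPair,
    roi: ROI | None = None,
    rule: MaskRule = MaskRule(),
    **metadata,
) -> PlotRecord:
    """Run the full masking + summarisation chain for a single plot."""
    roi = roi or ROI.full(stack.shape)
    mask = mask_soil(stack, rule)
    return PlotRecord(
        plot_id=str(metadata.pop("plot_id", "plot")),
        cc=canopy_cover(mask, roi),
        ph=plant_height(elev, mask, roi),
        mean_dn=mean_dns(stack, mask, roi),
        **metadata,
    )


def records_to_table(records: Iterable[PlotRecord]) -> pd.DataFrame:
    """Flatten PlotRecords into the plots × predictors modelling table.

    Mean DNs appear as ``dn_B .. dn_NIR``; VI columns carry their registry
    names; measured biomass (when present) as ``fb_measured``.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "plot_id": rec.plot_id,
            "genotype": rec.genotype,
            "year": rec.year,
            "gdd": rec.gdd,
            "environment": rec.environment,
            "rep": rec.rep,
            "CC": rec.cc,
            "PH": rec.ph,
        }
        row.update({f"dn_{b}": v for b, v in zip(BANDS, rec.mean_dn)})
        row.update(rec.vi)
        if rec.fb_measured is not None:
            row["fb_measured"] = rec.fb_measured
        rows.append(row)
    return pd.DataFrame(rows)
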