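"""Quantitative maps: MTR computation, normative atlas, voxelwise z-scores.

The magnetization transfer ratio is computed voxelwise from the raw pair as
``MTR = (MT0 - MT1) / MT0 * 100`` (percent units).  A healthy-control
normative atlas stores the voxelwise mean and sample SD (n-1 denominator) of
the HC maps; an individual z-score map is
``z = (individual - HC mean) / HC SD``.  Voxels with SD below a floor are
flagged and excluded from every downstream statistic, as are invalid voxels
(e.g. MT0 <= 0), which carry NaN sentinels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantMap",
    "NormativeAtlas",
    "ZScoreMap",
    "MetricMismatchError",
    "compute_mtr_map",
    "build_normative_atlas",
    "compute_zscore_map",
    "DEFAULT_SD_FLOOR",
]

#: Default SD floor per metric: below this the atlas SD is considered too
#: small for a stable z-score and the voxel is excluded.
DEFAULT_SD_FLOOR = {"MTR": 0.5, "qT1": 50.0}


class MetricMismatchError(ValueError):
    """Raised when maps of different metrics are combined."""


@dataclass
class QuantMap:
    """A 3-D quantitative map with a validity mask.

    ``metric`` is ``'MTR'`` (percent units; lower = more demyelination) or
    ``'qT1'`` (ms; higher = more demyelination).  Invalid voxels hold NaN
    and are excluded from every statistic.
    """

    values: np.ndarray
    metric: str = "MTR"
    validity_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.validity_mask is None:
            self.validity_mask = np.isfinite(self.values)
        else:
            self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
            if self.validity_mask.shape != self.values.shape:
                raise ValueError("validity mask shape must match values")
            self.validity_mask = self.validity_mask & np.isfinite(self.values)
        self.values = np.where(self.validity_mask, self.values, np.nan)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class NormativeAtlas:
    """Voxelwise HC mean/SD maps with low-SD exclusion flags."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    n_hc: int
    metric: str
    low_sd_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    sd_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_hc < 2:
            raise ValueError("a normative atlas needs n_hc >= 2")
        if np.nanmin(self.sd_map) < 0:
            raise ValueError("sd_map must be non-negative")
        if self.low_sd_mask is None:
            self.low_sd_mask = np.zeros(self.mean_map.shape, dtype=bool)


@dataclass
class ZScoreMap:
    """Voxelwise z-scores of one subject against the normative atlas."""

    values: np.ndarray
    metric: str
    excluded_mask: np.ndarray

    def __post_init__(self) -> None:
        bad = ~self.excluded_mask & ~np.isfinite(self.values)
        if np.any(bad):
            raise ValueError("z-map contains non-finite values outside the excluded mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def compute_mtr_map(
    mt0: np.ndarray,
    mt1: np.ndarray,
    mask: np.ndarray | None = None,
) -> QuantMap:
    """Compute the MTR map ``(MT0 - MT1) / MT0 * 100`` in percent units.

    Voxels with ``MT0 <= 0`` (no signal without the MT prepulse) are marked
    invalid.  ``mask``, if given, restricts validity further.
    """
    mt0 = np.asarray(mt0, dtype=float)
    mt1 = np.asarray(mt1, dtype=float)
    if mt0.shape != mt1.shape:
        raise ValueError(f"MT0 shape {mt0.shape} != MT1 shape {mt1.shape}")
    valid = np.isfinite(mt0) & np.isfinite(mt1) & (mt0 > 0)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mt0.shape:
            raise ValueError("mask shape must match the MT pair")
        valid &= mask
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = (mt0 - mt1) / mt0 * 100.0
    mtr = np.where(valid, mtr, np.nan)
    return QuantMap(values=mtr, metric="MTR", validity_mask=valid)


def build_normative_atlas(
    hc_maps: list[QuantMap],
    sd_floor: float | None = None,
) -> NormativeAtlas:
    """Build the voxelwise HC mean/SD atlas from >= 2 healthy-control maps.

    SD uses the n-1 (sample) denominator.  Voxels whose SD falls below
    ``sd_floor`` (default per metric, 0.5 pu for MTR) are flagged in
    ``low_sd_mask`` and later excluded from z-scoring.
    """
    if len(hc_maps) < 2:
        raise ValueError("a normative atlas needs at least 2 HC maps")
    metric = hc_maps[0].metric
    shape = hc_maps[0].shape
    for m in hc_maps[1:]:
        if m.metric != metric:
            raise MetricMismatchError(f"mixed metrics {metric!r} and {m.metric!r}")
        if m.shape != shape:
            raise ValueError("HC maps must share one shape")
    if sd_floor is None:
        sd_floor = DEFAULT_SD_FLOOR.get(metric, 0.0)
    stack = np.stack([m.values for m in hc_maps])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    low_sd = np.isfinite(sd) & (sd < sd_floor)
    return NormativeAtlas(
        mean_map=mean, sd_map=sd, n_hc=len(hc_maps), metric=metric,
        low_sd_mask=low_sd, sd_floor=float(sd_floor),
    )


def compute_zscore_map(qmap: QuantMap, atlas: NormativeAtlas) -> ZScoreMap:
    """Voxelwise ``z = (individual - HC mean) / HC SD`` against the atlas.

    Excluded voxels are those invalid in the subject map, invalid in the
    atlas, or flagged low-SD.
    """
    if qmap.metric != atlas.metric:
        raise MetricMismatchError(
            f"map metric {qmap.metric!r} != atlas metric {atlas.metric!r}"
        )
    if qmap.shape != atlas.mean_map.shape:
        raise ValueError("map shape must match atlas")
    atlas_valid = np.isfinite(atlas.mean_map) & np.isfinite(atlas.sd_map) & (atlas.sd_map > 0)
    excluded = ~qmap.validity_mask | ~atlas_valid | atlas.low_sd_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (qmap.values - atlas.mean_map) / atlas.sd_map
    z = np.where(excluded, np.nan, z)
    return ZScoreMap(values=z, metric=qmap.metric, excluded_mask=excluded)
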