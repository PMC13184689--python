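"""Synthetic CST phantom cohorts.

The phantom emulates the statistical structure that the downstream analysis
assumes: two tube-shaped corticospinal tracts running through brain,
brainstem, cervical and thoracic portions of a template grid; healthy-control
(HC) quantitative maps whose tract voxels are Gaussian around per-portion
MTR means; patients with ellipsoidal lesions planted at a controlled z-score
depth; per-limb clinical/electrophysiological outcomes driven by lesion
burden on the functional side; and multiplicative/additive site effects.

Every generator carries its planted ground truth (lesion specifications,
site-free feature values) so recovery experiments can score against it.
All randomness flows through a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PORTIONS",
    "BANDS",
    "DEFAULT_HC_PARAMS",
    "DEFAULT_OUTCOME_MODEL",
    "TemplateSpace",
    "LesionSpec",
    "OutcomeModel",
    "SubjectPhantom",
    "PhantomConfigError",
    "LesionPlacementError",
    "build_phantom_space",
    "simulate_hc_cohort",
    "simulate_patient",
    "draw_lesion_specs",
    "simulate_outcomes",
    "simulate_multisite",
    "write_dataset",
]

#: Major CST portions, ordered superior -> inferior along the I-S axis.
PORTIONS = ("brain", "brainstem", "cervical_C1_C7", "thoracic_T1_T10")

#: Measurement bands as (parent portion, fractional extent within parent).
#: C4-C6 spans vertebrae 4-6 of the 7 cervical levels; T4-T6 and T9-T10 the
#: corresponding thirds/fifths of the 10 thoracic levels.
BANDS: dict[str, tuple[str, float, float]] = {
    "band_C4_C6": ("cervical_C1_C7", 3 / 7, 6 / 7),
    "band_T4_T6": ("thoracic_T1_T10", 3 / 10, 6 / 10),
    "band_T9_T10": ("thoracic_T1_T10", 8 / 10, 10 / 10),
}

#: Default HC MTR mean/SD (percent units) per generative region.  Band values
#: are healthy-control left-CST cohort statistics; portions without a direct
#: measurement band (cervical outside C4-C6, thoracic between bands) reuse or
#: interpolate the neighbouring band parameters.
DEFAULT_HC_PARAMS: dict[str, tuple[float, float]] = {
    "brain": (42.817, 0.948),
    "brainstem": (46.610, 0.826),
    "cervical_C1_C7": (42.716, 1.395),
    "band_C4_C6": (42.716, 1.395),
    "thoracic_T1_T10": (38.35, 3.5),
    "band_T4_T6": (41.164, 2.725),
    "band_T9_T10": (35.541, 4.428),
}

#: Default HC qT1 mean/SD (ms) per generative region.  qT1 rises with
#: demyelination (opposite sign to MTR); voxel SDs sit above the 50 ms
#: low-SD exclusion floor used for qT1 atlases.
DEFAULT_QT1_PARAMS: dict[str, tuple[float, float]] = {
    "brain": (850.0, 60.0),
    "brainstem": (820.0, 60.0),
    "cervical_C1_C7": (880.0, 70.0),
    "band_C4_C6": (880.0, 70.0),
    "thoracic_T1_T10": (900.0, 90.0),
    "band_T4_T6": (890.0, 80.0),
    "band_T9_T10": (920.0, 100.0),
}

#: Background (non-tract) tissue mean/SD per metric.
_BACKGROUND = {"MTR": (25.0, 2.0), "qT1": (1400.0, 80.0)}


class PhantomConfigError(ValueError):
    """Raised for inconsistent phantom geometry configuration."""


class LesionPlacementError(ValueError):
    """Raised when a lesion specification does not intersect its tract."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateSpace:
    """Template grid with CST tube masks and portion/band slice intervals.

    Slice index 0 on the inferior-superior axis is the most *superior* slice
    (top of the brain); indices increase toward the thoracic cord.

    Parameters
    ----------
    shape : grid dimensions in voxels.
    voxel_size : mm per axis.
    axis_is : index of the inferior-superior axis.
    portion_bounds : half-open ``[start, stop)`` slice interval per major
        portion; disjoint and contiguous, ordered superior to inferior.
    band_bounds : half-open slice interval per measurement band; each band
        is contained in its parent portion.
    tract_left, tract_right : boolean voxel masks; disjoint.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    axis_is: int
    portion_bounds: dict[str, tuple[int, int]]
    band_bounds: dict[str, tuple[int, int]]
    tract_left: np.ndarray = field(repr=False)
    tract_right: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.tract_left.shape != self.shape or self.tract_right.shape != self.shape:
            raise PhantomConfigError("tract masks must match the grid shape")
        if np.any(self.tract_left & self.tract_right):
            raise PhantomConfigError("left and right tract masks overlap")
        prev_stop = None
        nz = self.shape[self.axis_is]
        for name in PORTIONS:
            if name not in self.portion_bounds:
                raise PhantomConfigError(f"missing portion {name!r}")
            start, stop = self.portion_bounds[name]
            if not (0 <= start < stop <= nz):
                raise PhantomConfigError(
                    f"portion {name!r} interval [{start}, {stop}) outside grid of {nz} slices"
                )
            if prev_stop is not None and start != prev_stop:
                raise PhantomConfigError("portion bands must be contiguous and ordered")
            prev_stop = stop
        for band, (start, stop) in self.band_bounds.items():
            parent = BANDS[band][0]
            pstart, pstop = self.portion_bounds[parent]
            if not (pstart <= start < stop <= pstop):
                raise PhantomConfigError(f"band {band!r} extends outside {parent!r}")

    # -- masks ------------------------------------------------------------

    def tract_mask(self, side: str = "both") -> np.ndarray:
        """Binary tract mask for ``side`` in {'left', 'right', 'both'}."""
        if side == "left":
            return self.tract_left.copy()
        if side == "right":
            return self.tract_right.copy()
        if side == "both":
            return self.tract_left | self.tract_right
        raise ValueError(f"unknown side {side!r}")

    def region_mask(self, region: str, side: str = "both") -> np.ndarray:
        """Tract mask restricted to a portion or band slice interval."""
        start, stop = self.region_bounds(region)
        mask = self.tract_mask(side)
        sl = [slice(None)] * 3
        keep = np.zeros(self.shape, dtype=bool)
        sl[self.axis_is] = slice(start, stop)
        keep[tuple(sl)] = True
        return mask & keep

    def region_bounds(self, region: str) -> tuple[int, int]:
        if region in self.portion_bounds:
            return self.portion_bounds[region]
        if region in self.band_bounds:
            return self.band_bounds[region]
        raise KeyError(f"unknown region {region!r}")

    def portion_of_slice(self, z: int) -> str:
        """Major portion containing I-S slice ``z``."""
        for name in PORTIONS:
            start, stop = self.portion_bounds[name]
            if start <= z < stop:
                return name
        raise IndexError(f"slice {z} outside every portion")

    def generative_region_of_slice(self, z: int) -> str:
        """Most specific generative region (band overrides its portion)."""
        for band, (start, stop) in self.band_bounds.items():
            if start <= z < stop:
                return band
        return self.portion_of_slice(z)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def n_slices(self) -> int:
        return self.shape[self.axis_is]


def _default_portion_bounds(nz: int) -> dict[str, tuple[int, int]]:
    # superior -> inferior fractional extents: brain 41%, brainstem 9%,
    # cervical 23%, thoracic 27% of the grid
    fracs = {"brain": 0.41, "brainstem": 0.09, "cervical_C1_C7": 0.23,
             "thoracic_T1_T10": 0.27}
    bounds: dict[str, tuple[int, int]] = {}
    start = 0
    names = list(PORTIONS)
    for i, name in enumerate(names):
        stop = nz if i == len(names) - 1 else start + int(round(fracs[name] * nz))
        bounds[name] = (start, stop)
        start = stop
    return bounds


def _band_bounds(portion_bounds: Mapping[str, tuple[int, int]]) -> dict[str, tuple[int, int]]:
    out = {}
    for band, (parent, f0, f1) in BANDS.items():
        start, stop = portion_bounds[parent]
        n = stop - start
        out[band] = (start + int(round(f0 * n)), start + int(round(f1 * n)))
    return out


def build_phantom_space(
    shape: tuple[int, int, int] = (48, 48, 220),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    axis_is: int = 2,
    portion_bounds: Mapping[str, tuple[int, int]] | None = None,
    tract_radius: float | None = None,
    fan_radius: float | None = None,
    tract_separation: float | None = None,
) -> TemplateSpace:
    """Build a deterministic synthetic template space.

    Two parallel tube-shaped tracts of in-plane radius ``tract_radius``
    (default scales with the grid, ``max(1.5, nx/16)``) run through every
    slice; within the brain portion the radius widens linearly toward the
    top slice (up to ``fan_radius``, default twice the tube radius) to evoke
    the fanning of the corticospinal projection.  ``tract_separation`` is
    the in-plane distance of each tube centre from the grid midline
    (default ``nx // 4``).

    Raises :class:`PhantomConfigError` for overlapping, out-of-range or
    non-contiguous portion intervals.
    """
    shape = tuple(int(s) for s in shape)  # type: ignore[assignment]
    nz = shape[axis_is]
    pbounds = dict(portion_bounds) if portion_bounds is not None else _default_portion_bounds(nz)
    bbounds = _band_bounds(pbounds)

    plane_axes = [a for a in range(3) if a != axis_is]
    nx, ny = shape[plane_axes[0]], shape[plane_axes[1]]
    if tract_radius is None:
        tract_radius = max(1.5, nx / 16)
    if fan_radius is None:
        fan_radius = 2 * tract_radius
    sep = tract_separation if tract_separation is not None else nx // 4
    cx_left, cx_right = (nx - 1) / 2 - sep, (nx - 1) / 2 + sep
    cy = (ny - 1) / 2

    xx = np.arange(nx)[:, None]
    yy = np.arange(ny)[None, :]
    brain_start, brain_stop = pbounds["brain"]

    def tube(cx: float) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for z in range(nz):
            r = tract_radius
            if brain_start <= z < brain_stop:
                # widen toward the most superior slice
                t = (brain_stop - 1 - z) / max(brain_stop - 1 - brain_start, 1)
                r = tract_radius + t * (fan_radius - tract_radius)
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
            sl: list = [slice(None)] * 3
            sl[plane_axes[0]] = slice(None)
            sl[plane_axes[1]] = slice(None)
            sl[axis_is] = z
            plane = np.zeros((nx, ny), dtype=bool)
            plane |= disc
            mask[tuple(sl)] = plane
        return mask

    left = tube(cx_left)
    right = tube(cx_right)
    if np.any(left & right):
        raise PhantomConfigError(
            "tract tubes overlap; reduce fan_radius or increase tract_separation"
        )
    return TemplateSpace(
        shape=shape,
        voxel_size=tuple(float(v) for v in voxel_size),  # type: ignore[arg-type]
        axis_is=axis_is,
        portion_bounds=pbounds,
        band_bounds=bbounds,
        tract_left=left,
        tract_right=right,
    )


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

@dataclass
class LesionSpec:
    """One planted ellipsoidal lesion.

    ``severity_z`` is the target mean z-depth relative to the HC atlas
    (negative for MTR, where demyelination lowers the signal).
    """

    centre: tuple[int, int, int]
    radii: tuple[float, float, float]  # mm per axis
    severity_z: float
    side: str  # 'left' | 'right'

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"lesion radii must be positive, got {self.radii}")
        if self.side not in ("left", "right"):
            raise ValueError(f"lesion side must be 'left' or 'right', got {self.side!r}")

    @property
    def truth_severe(self) -> bool:
        """Planted-truth severity under the |z| > 1.96 criterion.

        The sign carries the metric direction (negative depths for MTR,
        positive for qT1), so the magnitude decides severity.
        """
        return abs(self.severity_z) > 1.96


@dataclass
class OutcomeModel:
    """Generative model for per-limb CMCT and mASIA outcomes.

    CMCT (ms) for a limb is ``baseline + effect_severe * n_severe_sc +
    effect_severe_brain * n_severe_brain + effect_lvf *
    log-lesion-volume-fraction + N(0, noise_sd)`` where burdens are taken on
    the limb's functional side.  Cord severe lesions carry the dominant
    conduction-delay effect; brain severe lesions a weaker one — the
    cord-driven structure the cohort emulates.  Baselines default to the HC
    cohort values (upper 7.50 +/- 1.88 ms, lower 14.89 +/- 3.07 ms); the
    baseline SDs are the normative spread used for CMCT z-scoring, not a
    noise source.  The effect sizes are free generator parameters.
    """

    cmct_baseline_mean: dict[str, float] = field(
        default_factory=lambda: {"upper": 7.50, "lower": 14.89}
    )
    cmct_baseline_sd: dict[str, float] = field(
        default_factory=lambda: {"upper": 1.88, "lower": 3.07}
    )
    effect_severe: float = 4.0  # ms per severe cord lesion on the functional side
    effect_severe_brain: float = 1.5  # ms per severe brain lesion
    effect_lvf: float = 0.3  # ms per unit log lesion-volume-fraction above floor
    noise_sd: float = 2.5  # ms
    masia_per_severe: float = 3.0  # points lost per severe lesion
    masia_rule: Callable[[int, float], float] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(m <= 0 for m in self.cmct_baseline_mean.values()):
            raise ValueError("CMCT baseline means must be positive")

    def masia(self, n_severe: int, log_lvf: float) -> float:
        if self.masia_rule is not None:
            score = self.masia_rule(n_severe, log_lvf)
        else:
            score = 25.0 - min(self.masia_per_severe * n_severe, 15.0)
        return float(np.clip(score, 0.0, 25.0))


DEFAULT_OUTCOME_MODEL = OutcomeModel()


@dataclass
class SubjectPhantom:
    """One synthetic subject: raw MT pair, quantitative maps, lesion truth."""

    subject_id: str
    group: str  # 'HC' | 'pwMS'
    site: str
    quant_maps: dict[str, np.ndarray]
    mt0: np.ndarray | None
    mt1: np.ndarray | None
    lesion_mask: np.ndarray
    covariates: dict[str, float | str]
    lesion_specs: list[LesionSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group == "HC" and self.lesion_mask.any():
            raise ValueError("healthy-control phantom must have an empty lesion mask")


def _slice_region_params(
    space: TemplateSpace, params: Mapping[str, tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice (mean, sd) arrays along the I-S axis."""
    means = np.empty(space.n_slices)
    sds = np.empty(space.n_slices)
    for z in range(space.n_slices):
        region = space.generative_region_of_slice(z)
        m, s = params[region]
        means[z] = m
        sds[z] = s
    return means, sds


def _broadcast_along(space: TemplateSpace, per_slice: np.ndarray) -> np.ndarray:
    shape = [1, 1, 1]
    shape[space.axis_is] = space.n_slices
    return per_slice.reshape(shape)


def _hc_map(space: TemplateSpace, params: Mapping[str, tuple[float, float]],
            rng: np.random.Generator, metric: str = "MTR") -> np.ndarray:
    means, sds = _slice_region_params(space, params)
    bg_mean, bg_sd = _BACKGROUND[metric]
    values = bg_mean + bg_sd * rng.standard_normal(space.shape)
    tract = space.tract_mask("both")
    mean_vol = np.broadcast_to(_broadcast_along(space, means), space.shape)
    sd_vol = np.broadcast_to(_broadcast_along(space, sds), space.shape)
    noise = rng.standard_normal(space.shape)
    values[tract] = mean_vol[tract] + sd_vol[tract] * noise[tract]
    return values


def _mt_pair_from_mtr(mtr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # MT0 fixed at 100 arbitrary units so the MTR formula inverts exactly
    mt0 = np.full_like(mtr, 100.0)
    mt1 = mt0 * (1.0 - mtr / 100.0)
    return mt0, mt1


def _draw_covariates(rng: np.random.Generator, group: str) -> dict[str, float | str]:
    age = float(np.clip(rng.normal(40.0, 11.0), 18.0, None))
    sex = "F" if rng.random() < 0.65 else "M"
    duration = float(max(rng.normal(8.73, 5.56), 0.5)) if group == "pwMS" else 0.0
    return {"age": age, "sex": sex, "disease_duration": duration}


def simulate_hc_cohort(
    space: TemplateSpace,
    n: int = 21,
    portion_means_sds: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    site: str = "A",
    metric: str = "MTR",
) -> list[SubjectPhantom]:
    """Simulate ``n`` healthy-control phantoms.

    Tract voxels are drawn as per-portion mean + Gaussian voxel noise with
    the configured SD; background tissue is a plausible non-tract signal.
    For MTR the raw MT0/MT1 pair is back-computed; qT1 phantoms are
    generated directly as maps.  At least two subjects are required because
    the normative atlas needs a voxelwise SD.
    """
    if n < 2:
        raise ValueError("an HC cohort needs n >= 2 (the normative atlas requires an SD)")
    defaults = DEFAULT_HC_PARAMS if metric == "MTR" else DEFAULT_QT1_PARAMS
    params = dict(defaults if portion_means_sds is None else portion_means_sds)
    if any(s <= 0 for _, s in params.values()):
        raise ValueError("portion SDs must be > 0")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        qmap = _hc_map(space, params, rng, metric=metric)
        mt0, mt1 = _mt_pair_from_mtr(qmap) if metric == "MTR" else (None, None)
        subjects.append(
            SubjectPhantom(
                subject_id=f"HC{i:03d}",
                group="HC",
                site=site,
                quant_maps={metric: qmap},
                mt0=mt0,
                mt1=mt1,
                lesion_mask=np.zeros(space.shape, dtype=bool),
                covariates=_draw_covariates(rng, "HC"),
            )
        )
    return subjects


def _ellipsoid_mask(space: TemplateSpace, spec: LesionSpec) -> np.ndarray:
    grids = np.ogrid[[slice(0, s) for s in space.shape]]
    d2 = sum(
        ((g - c) * v / r) ** 2
        for g, c, v, r in zip(grids, spec.centre, space.voxel_size, spec.radii)
    )
    return d2 <= 1.0


def simulate_patient(
    space: TemplateSpace,
    lesion_specs: Sequence[LesionSpec],
    hc_reference: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    subject_id: str = "MS000",
    site: str = "A",
    metric: str = "MTR",
) -> SubjectPhantom:
    """Simulate one patient phantom with planted ellipsoidal lesions.

    Inside each lesion the map is shifted by ``severity_z`` times the local
    HC portion SD, so the expected mean z-score of the lesion equals
    ``severity_z`` (negative depths for MTR, positive for qT1).  For MTR
    the MT0/MT1 raw pair is back-computed to be exactly consistent with the
    final map.

    Raises :class:`LesionPlacementError` if a lesion does not intersect its
    designated tract side.
    """
    defaults = DEFAULT_HC_PARAMS if metric == "MTR" else DEFAULT_QT1_PARAMS
    params = dict(defaults if hc_reference is None else hc_reference)
    rng = np.random.default_rng(seed)
    mtr = _hc_map(space, params, rng, metric=metric)
    lesion_mask = np.zeros(space.shape, dtype=bool)
    _, sds = _slice_region_params(space, params)
    sd_vol = np.broadcast_to(_broadcast_along(space, sds), space.shape)
    for spec in lesion_specs:
        ell = _ellipsoid_mask(space, spec)
        if not np.any(ell & space.tract_mask(spec.side)):
            raise LesionPlacementError(
                f"lesion at centre {spec.centre} (radii {spec.radii} mm) does not "
                f"intersect the {spec.side} tract"
            )
        mtr[ell] = mtr[ell] + spec.severity_z * sd_vol[ell]
        lesion_mask |= ell
    mt0, mt1 = _mt_pair_from_mtr(mtr) if metric == "MTR" else (None, None)
    return SubjectPhantom(
        subject_id=subject_id,
        group="pwMS",
        site=site,
        quant_maps={metric: mtr},
        mt0=mt0,
        mt1=mt1,
        lesion_mask=lesion_mask,
        covariates=_draw_covariates(rng, "pwMS"),
        lesion_specs=list(lesion_specs),
    )


def draw_lesion_specs(
    space: TemplateSpace,
    rng: np.random.Generator,
    mean_lesions_per_side: float = 4.1,
    p_side_unaffected: float = 0.12,
    severe_fraction: float = 0.26,
    portion_probs: Mapping[str, float] | None = None,
    severity_sign: float = -1.0,
) -> list[LesionSpec]:
    """Draw a random lesion load for one patient (both sides).

    Per side, with probability ``p_side_unaffected`` no lesion is planted;
    otherwise the count is ``1 + Poisson(mean_lesions_per_side)``.  Each
    lesion is severe with probability ``severe_fraction``; severe depths are
    Uniform(-3.5, -2.5) and non-severe Uniform(-1.5, -0.5) (multiplied by
    ``severity_sign``; use +1 for qT1).  Lesion centres
    are random tract voxels with portion probabilities defaulting to the
    cervical-dominant distribution (brain 0.30, brainstem 0.05, cervical
    0.40, thoracic 0.25).
    """
    if portion_probs is None:
        portion_probs = {"brain": 0.30, "brainstem": 0.05,
                         "cervical_C1_C7": 0.40, "thoracic_T1_T10": 0.25}
    portions = list(portion_probs)
    probs = np.asarray([portion_probs[p] for p in portions], dtype=float)
    probs = probs / probs.sum()
    specs: list[LesionSpec] = []
    for side in ("left", "right"):
        if rng.random() < p_side_unaffected:
            continue
        n_lesions = 1 + rng.poisson(mean_lesions_per_side)
        side_mask = space.tract_mask(side)
        for _ in range(n_lesions):
            portion = portions[rng.choice(len(portions), p=probs)]
            start, stop = space.portion_bounds[portion]
            sl = [slice(None)] * 3
            sl[space.axis_is] = slice(start, stop)
            sub = np.zeros(space.shape, dtype=bool)
            sub[tuple(sl)] = True
            candidates = np.argwhere(side_mask & sub)
            centre = tuple(int(c) for c in candidates[rng.integers(len(candidates))])
            severe = rng.random() < severe_fraction
            z = rng.uniform(-3.5, -2.5) if severe else rng.uniform(-1.5, -0.5)
            z = float(np.sign(severity_sign)) * abs(z)
            radii = [float(rng.uniform(1.5, 3.0)) for _ in range(3)]
            radii[space.axis_is] = float(rng.uniform(2.0, 5.0))
            specs.append(LesionSpec(centre=centre, radii=tuple(radii),
                                    severity_z=z, side=side))
    return specs


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

#: The four limbs, keyed as (girdle, body side).
LIMBS = (("upper", "left"), ("upper", "right"), ("lower", "left"), ("lower", "right"))


def simulate_outcomes(
    patient: SubjectPhantom,
    space: TemplateSpace,
    model: OutcomeModel | None = None,
    seed: int | None = None,
    severe_counts: Mapping[tuple[str, str], int] | None = None,
    log_lvfs: Mapping[tuple[str, str], float] | None = None,
) -> dict:
    """Simulate per-limb CMCT (ms) and mASIA (0-25) for a patient phantom.

    Lesion burden per limb is evaluated on the limb's *functional* side
    (contralateral brain tract, ipsilateral cord tract; C1-C7 only for upper
    limbs) from the planted lesion truth, unless explicit ``severe_counts``
    and ``log_lvfs`` per limb are supplied.  The lesion-volume term is
    measured from its lesion-free floor (``log_lvf - ln(epsilon)``), so a
    lesion-free limb with ``model.noise_sd == 0`` has CMCT exactly equal to
    the baseline mean.
    """
    from cstlesion import stats as _stats
    from cstlesion import tract as _tract

    model = model if model is not None else DEFAULT_OUTCOME_MODEL
    rng = np.random.default_rng(seed)
    record: dict = {
        "subject_id": patient.subject_id,
        "site": patient.site,
        "group": patient.group,
        **patient.covariates,
    }
    sc_portions = ("cervical_C1_C7", "thoracic_T1_T10")
    for girdle, body_side in LIMBS:
        key = (girdle, body_side)
        sel = _tract.map_functional_side(f"{body_side} {girdle}")
        if severe_counts is not None and log_lvfs is not None:
            n_severe_sc = int(severe_counts.get(key, 0))
            n_severe_brain = 0
            log_lvf = float(log_lvfs.get(key, _stats.log_transform_fraction([0.0])[0]))
        else:
            roi = _tract.functional_roi_mask(space, sel)
            n_severe_sc = n_severe_brain = 0
            for spec in patient.lesion_specs:
                if not spec.truth_severe:
                    continue
                if not (roi[spec.centre] or np.any(_ellipsoid_mask(space, spec) & roi)):
                    continue
                z = spec.centre[space.axis_is]
                if space.portion_of_slice(z) in sc_portions:
                    n_severe_sc += 1
                else:
                    n_severe_brain += 1
            lvf = _tract.lesion_volume_fraction(patient.lesion_mask, roi)
            log_lvf = float(_stats.log_transform_fraction([lvf])[0])
        noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
        lvf_floor = float(np.log(0.01))  # log-transform value of a 0% fraction
        n_severe = n_severe_sc + n_severe_brain
        cmct = (
            model.cmct_baseline_mean[girdle]
            + model.effect_severe * n_severe_sc
            + model.effect_severe_brain * n_severe_brain
            + model.effect_lvf * (log_lvf - lvf_floor)
            + noise
        )
        record[f"cmct_{girdle}_{body_side}"] = float(cmct)
        record[f"masia_{girdle}_{body_side}"] = model.masia(n_severe, log_lvf)
        record[f"n_severe_{girdle}_{body_side}"] = n_severe
        record[f"n_severe_sc_{girdle}_{body_side}"] = n_severe_sc
        record[f"log_lvf_{girdle}_{body_side}"] = log_lvf
    total_severe = sum(record[f"n_severe_{g}_{s}"] for g, s in LIMBS)
    edss = 1.0 + 0.35 * total_severe + rng.normal(0.0, 0.7)
    record["edss"] = float(np.clip(round(edss * 2) / 2, 0.0, 10.0))
    return record


def simulate_multisite(
    records: pd.DataFrame,
    feature_cols: Sequence[str],
    site_effects: Mapping[str, tuple[float, float]],
    seed: int | None = None,
) -> pd.DataFrame:
    """Apply per-site additive and multiplicative effects to feature columns.

    ``site_effects`` maps site label -> ``(additive, multiplicative)``;
    ``x -> multiplicative * x + additive``.  Original (site-free) values are
    retained in ``<col>__clean`` columns so harmonization can be scored
    against ground truth.  Sites with fewer than 2 subjects are recorded in
    ``df.attrs['small_sites']``.
    """
    if "site" not in records.columns:
        raise ValueError("records need a 'site' column")
    unknown = set(records["site"]) - set(site_effects)
    if unknown:
        raise ValueError(f"no site effect configured for sites {sorted(unknown)}")
    out = records.copy()
    small = [s for s, cnt in out["site"].value_counts().items() if cnt < 2]
    out.attrs["small_sites"] = small
    for col in feature_cols:
        out[f"{col}__clean"] = out[col]
        for site, (add, mult) in site_effects.items():
            idx = out["site"] == site
            out.loc[idx, col] = mult * out.loc[idx, col] + add
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_dataset(
    cohort: Sequence[SubjectPhantom],
    directory: str | Path,
    space: TemplateSpace | None = None,
    clinical: pd.DataFrame | None = None,
) -> dict:
    """Write a cohort as NIfTI volumes + clinical CSV + JSON manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    import nibabel as nib

    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    if space is not None:
        affine[:3, :3] = np.diag(space.voxel_size)
        for side in ("left", "right"):
            nib.save(
                nib.Nifti1Image(space.tract_mask(side).astype(np.uint8), affine),
                directory / f"tract_{side}.nii.gz",
            )
    manifest: dict = {"n_subjects": len(cohort), "subjects": []}
    for subj in cohort:
        sdir = directory / subj.subject_id
        sdir.mkdir(exist_ok=True)
        files = {}
        channels = {metric.lower(): m for metric, m in subj.quant_maps.items()}
        if subj.mt0 is not None:
            channels.update(mt0=subj.mt0, mt1=subj.mt1)
        for name, arr in channels.items():
            path = sdir / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), path)
            files[name] = str(path.relative_to(directory))
        path = sdir / "lesion_mask.nii.gz"
        nib.save(nib.Nifti1Image(subj.lesion_mask.astype(np.uint8), affine), path)
        files["lesion_mask"] = str(path.relative_to(directory))
        manifest["subjects"].append(
            {"subject_id": subj.subject_id, "group": subj.group, "site": subj.site,
             "files": files}
        )
    if clinical is not None:
        clinical.to_csv(directory / "clinical.csv", index=False)
        manifest["clinical"] = "clinical.csv"
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_dataset(directory: str | Path) -> tuple[list[SubjectPhantom], pd.DataFrame | None]:
    """Read back a dataset written by :func:`write_dataset`."""
    import nibabel as nib

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    subjects = []
    for entry in manifest["subjects"]:
        files = entry["files"]
        load = lambda key: np.asarray(nib.load(directory / files[key]).dataobj)
        quant = {}
        for key in files:
            if key in ("mtr", "qt1"):
                quant["MTR" if key == "mtr" else "qT1"] = load(key).astype(np.float64)
        subjects.append(
            SubjectPhantom(
                subject_id=entry["subject_id"],
                group=entry["group"],
                site=entry["site"],
                quant_maps=quant,
                mt0=load("mt0").astype(np.float64) if "mt0" in files else None,
                mt1=load("mt1").astype(np.float64) if "mt1" in files else None,
                lesion_mask=load("lesion_mask").astype(bool),
                covariates={},
            )
        )
    clinical = None
    if "clinical" in manifest:
        clinical = pd.read_csv(directory / manifest["clinical"])
    return subjects, clinical
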