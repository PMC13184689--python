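"""Tract-referenced lesionometry.

Everything measured *along* or *within* the corticospinal tract lives here:
connected lesion components (26-connectivity), lesion volume fractions, ROI
means, lesion severity calls against the normative z-score criterion
(mean z within lesion-and-tract below -1.96 for MTR, above +1.96 for qT1),
abnormal-area attribution, per-slice damage profiles, extra-lesional means,
the functional-side (decussation) convention and cohort severity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from cstlesion.maps import QuantMap, ZScoreMap
from cstlesion.phantom import PORTIONS, TemplateSpace

__all__ = [
    "LesionComponent",
    "SeverityCall",
    "TractProfile",
    "TractSelection",
    "map_functional_side",
    "functional_roi_mask",
    "label_lesion_components",
    "lesion_volume_fraction",
    "roi_mean",
    "classify_lesion_severity",
    "abnormal_zscore_areas",
    "tract_profile",
    "extralesional_mean",
    "severity_summary",
    "SEVERITY_THRESHOLD",
]

#: Two-sided normal criterion used throughout (z depth for severe lesions,
#: CMCT prolongation): |z| > 1.96 corresponds to P < 0.05.
SEVERITY_THRESHOLD = 1.96

#: 26-connectivity structuring element for 3-D components.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LesionComponent:
    """One 26-connected lesion component and its tract overlap."""

    component_id: int
    voxel_indices: np.ndarray = field(repr=False)  # (n, 3) int array
    size_voxels: int
    size_mm3: float
    portion: str | None  # majority portion of tract-overlapping voxels
    side: str | None  # majority tract side ('left' | 'right')
    tract_overlap_voxels: int

    @property
    def in_tract(self) -> bool:
        return self.tract_overlap_voxels > 0


@dataclass
class SeverityCall:
    """Severity classification of one lesion component."""

    component_id: int
    mean_z: float
    severe: bool
    direction: str  # 'low' (MTR) | 'high' (qT1)
    threshold: float
    classifiable: bool = True
    portion: str | None = None
    side: str | None = None


@dataclass
class TractSelection:
    """Functional-side tract selection for one limb (or whole-CST analyses).

    The corticospinal tract decussates at the brainstem-cord junction, so a
    limb is served by the *contralateral* brain tract and the *ipsilateral*
    cord tract.  Upper limbs are innervated from cervical segments, so their
    cord extent stops at the end of C7; lower limbs use the full cord.
    """

    limb: str
    brain_side: str  # 'left' | 'right' | 'both'
    sc_side: str
    sc_extent: str  # 'C1_C7' | 'full'

    def __post_init__(self) -> None:
        opposite = {"left": "right", "right": "left", "both": "both"}
        if self.brain_side != opposite[self.sc_side]:
            raise ValueError("brain side must be contralateral to the cord side")


def map_functional_side(limb: str) -> TractSelection:
    """Map a limb to its functional tract sides.

    ``limb`` is e.g. ``'right upper'``, ``'left lower'`` (order-insensitive),
    or ``'both'`` / ``'edss'`` for whole-CST analyses that pool both sides
    and the full extent.
    """
    tokens = set(limb.lower().replace("_", " ").split())
    if tokens & {"both", "edss", "global"}:
        return TractSelection(limb="both", brain_side="both", sc_side="both",
                              sc_extent="full")
    body_side = "left" if "left" in tokens else "right" if "right" in tokens else None
    girdle = "upper" if "upper" in tokens else "lower" if "lower" in tokens else None
    if body_side is None or girdle is None:
        raise ValueError(f"cannot parse limb {limb!r}")
    brain_side = "left" if body_side == "right" else "right"
    return TractSelection(
        limb=f"{body_side} {girdle}",
        brain_side=brain_side,
        sc_side=body_side,
        sc_extent="C1_C7" if girdle == "upper" else "full",
    )


def functional_roi_mask(space: TemplateSpace, selection: TractSelection) -> np.ndarray:
    """Voxel mask of the functional tract for a :class:`TractSelection`."""
    brain = space.region_mask("brain", selection.brain_side) | space.region_mask(
        "brainstem", selection.brain_side
    )
    sc = space.region_mask("cervical_C1_C7", selection.sc_side)
    if selection.sc_extent == "full":
        sc |= space.region_mask("thoracic_T1_T10", selection.sc_side)
    return brain | sc


def label_lesion_components(
    lesion_mask: np.ndarray,
    space: TemplateSpace,
) -> list[LesionComponent]:
    """Label 26-connected lesion components and their tract overlap.

    Portion is assigned by majority vote of tract-overlapping voxels (all
    lesion voxels if the component misses the tract); ties go to the more
    superior portion.  Side is the majority tract side.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    labels, n = ndimage.label(lesion_mask, structure=_CONN26)
    left = space.tract_left
    right = space.tract_right
    tract = left | right
    components: list[LesionComponent] = []
    for cid in range(1, n + 1):
        comp = labels == cid
        idx = np.argwhere(comp)
        overlap = comp & tract
        n_overlap = int(overlap.sum())
        vote_mask = overlap if n_overlap else comp
        zs = np.argwhere(vote_mask)[:, space.axis_is]
        counts = {p: 0 for p in PORTIONS}
        for z in zs:
            counts[space.portion_of_slice(int(z))] += 1
        best = max(counts.values())
        # ties resolved toward the more superior portion (PORTIONS order)
        portion = next(p for p in PORTIONS if counts[p] == best) if best else None
        n_left = int((comp & left).sum())
        n_right = int((comp & right).sum())
        side = None
        if n_left or n_right:
            side = "left" if n_left >= n_right else "right"
        components.append(
            LesionComponent(
                component_id=cid,
                voxel_indices=idx,
                size_voxels=int(comp.sum()),
                size_mm3=float(comp.sum() * space.voxel_volume_mm3),
                portion=portion,
                side=side,
                tract_overlap_voxels=n_overlap,
            )
        )
    return components


def lesion_volume_fraction(lesion_mask: np.ndarray, tract_mask: np.ndarray) -> float:
    """Lesion volume within the tract ROI over the ROI volume, x100 (%)."""
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    tract_mask = np.asarray(tract_mask, dtype=bool)
    if lesion_mask.shape != tract_mask.shape:
        raise ValueError("lesion and tract masks must share a shape")
    n_tract = int(tract_mask.sum())
    if n_tract == 0:
        raise ValueError("tract ROI is empty")
    return float((lesion_mask & tract_mask).sum() / n_tract * 100.0)


def _map_values(m) -> np.ndarray:
    if isinstance(m, (QuantMap, ZScoreMap)):
        return m.values
    return np.asarray(m, dtype=float)


def roi_mean(m, roi_mask: np.ndarray) -> float:
    """Arithmetic mean of a map over valid (finite) voxels of an ROI."""
    values = _map_values(m)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if values.shape != roi_mask.shape:
        raise ValueError("map and ROI shapes differ")
    sel = values[roi_mask]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise ValueError("ROI contains no valid voxels")
    return float(sel.mean())


def classify_lesion_severity(
    components: Sequence[LesionComponent],
    zmap: ZScoreMap,
    tract_mask: np.ndarray,
    threshold: float = SEVERITY_THRESHOLD,
    direction: str = "low",
) -> list[SeverityCall]:
    """Classify each lesion component as severe or not.

    The lesion's z-depth is the mean z over its tract-overlapping,
    non-excluded voxels.  ``direction='low'`` (MTR): severe iff
    ``mean_z < -threshold`` (strict); ``direction='high'`` (qT1): severe iff
    ``mean_z > +threshold``.  Components whose lesion-and-tract voxels are
    all excluded are flagged unclassifiable.
    """
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    tract_mask = np.asarray(tract_mask, dtype=bool)
    calls: list[SeverityCall] = []
    for comp in components:
        idx = comp.voxel_indices
        in_tract = tract_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        zvals = zmap.values[idx[in_tract, 0], idx[in_tract, 1], idx[in_tract, 2]]
        zvals = zvals[np.isfinite(zvals)]
        if zvals.size == 0:
            calls.append(
                SeverityCall(comp.component_id, float("nan"), False, direction,
                             threshold, classifiable=False,
                             portion=comp.portion, side=comp.side)
            )
            continue
        mean_z = float(zvals.mean())
        severe = mean_z < -threshold if direction == "low" else mean_z > threshold
        calls.append(
            SeverityCall(comp.component_id, mean_z, severe, direction, threshold,
                         portion=comp.portion, side=comp.side)
        )
    return calls


@dataclass
class AbnormalArea:
    """One connected abnormal-z area within the tract."""

    area_id: int
    size_voxels: int
    in_lesion: bool


def abnormal_zscore_areas(
    zmap: ZScoreMap,
    tract_mask: np.ndarray,
    lesion_mask: np.ndarray,
    threshold: float = SEVERITY_THRESHOLD,
    direction: str = "low",
) -> tuple[list[AbnormalArea], float]:
    """Connected tract areas with z beyond the signed threshold.

    Each 26-connected area is labelled in-lesion if it overlaps the lesion
    mask by at least one voxel.  Returns the areas and the percentage of
    areas located in segmented lesions (NaN when no area exists).
    """
    tract_mask = np.asarray(tract_mask, dtype=bool)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if not (zmap.shape == tract_mask.shape == lesion_mask.shape):
        raise ValueError("inputs must share one shape")
    with np.errstate(invalid="ignore"):
        beyond = zmap.values < -threshold if direction == "low" else zmap.values > threshold
    beyond = beyond & tract_mask & ~zmap.excluded_mask
    labels, n = ndimage.label(beyond, structure=_CONN26)
    areas = []
    for aid in range(1, n + 1):
        comp = labels == aid
        areas.append(
            AbnormalArea(
                area_id=aid,
                size_voxels=int(comp.sum()),
                in_lesion=bool(np.any(comp & lesion_mask)),
            )
        )
    frac = float("nan")
    if areas:
        frac = 100.0 * sum(a.in_lesion for a in areas) / len(areas)
    return areas, frac


@dataclass
class TractProfile:
    """Per-slice damage profile of one tract side along the I-S axis."""

    side: str
    records: pd.DataFrame  # columns: slice, pct_damaged, mean_z, n_tract, n_lesion
    portion_bounds: dict[str, tuple[int, int]]

    @property
    def has_records(self) -> bool:
        return len(self.records) > 0


def tract_profile(
    lesion_mask: np.ndarray,
    zmap: ZScoreMap,
    tract_mask: np.ndarray,
    space: TemplateSpace,
    side: str = "both",
) -> TractProfile:
    """Per-slice percentage of damaged tract and mean z along the I-S axis.

    One record per slice that contains tract voxels:
    ``pct_damaged = lesion-and-tract voxels / tract voxels * 100`` and the
    mean z over the slice's non-excluded tract voxels.  The per-slice lesion
    counts sum exactly to the total lesion-and-tract voxel count.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    tract_mask = np.asarray(tract_mask, dtype=bool)
    if not (lesion_mask.shape == zmap.shape == tract_mask.shape):
        raise ValueError("inputs must share one shape")
    axis = space.axis_is
    other = tuple(a for a in range(3) if a != axis)
    n_tract = tract_mask.sum(axis=other)
    n_lesion = (lesion_mask & tract_mask).sum(axis=other)
    with np.errstate(invalid="ignore"):
        z_in_tract = np.where(tract_mask & ~zmap.excluded_mask, zmap.values, np.nan)
        mean_z = np.nanmean(z_in_tract, axis=other)
    rows = []
    for z in range(space.n_slices):
        if n_tract[z] == 0:
            continue
        rows.append(
            {
                "slice": z,
                "pct_damaged": 100.0 * n_lesion[z] / n_tract[z],
                "mean_z": float(mean_z[z]),
                "n_tract": int(n_tract[z]),
                "n_lesion": int(n_lesion[z]),
            }
        )
    return TractProfile(
        side=side,
        records=pd.DataFrame(rows, columns=["slice", "pct_damaged", "mean_z",
                                            "n_tract", "n_lesion"]),
        portion_bounds=dict(space.portion_bounds),
    )


def extralesional_mean(m, tract_mask: np.ndarray, lesion_mask: np.ndarray) -> float:
    """Mean map value over tract voxels outside every lesion voxel.

    No dilation margin is applied around lesions; callers wanting a safety
    margin should dilate ``lesion_mask`` first.
    """
    tract_mask = np.asarray(tract_mask, dtype=bool)
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    extra = tract_mask & ~lesion_mask
    if not extra.any():
        raise ValueError("lesions cover the entire tract ROI")
    return roi_mean(m, extra)


def severity_summary(
    calls_per_profile: Sequence[Sequence[SeverityCall]],
) -> dict:
    """Cohort-level severity bookkeeping over tract profiles.

    ``calls_per_profile`` holds one list of :class:`SeverityCall` per tract
    profile (functional side).  Returns total lesions, severe counts and
    percentages, the percentage of profiles with at least one lesion and at
    least one severe lesion, and the severe-lesion location breakdown
    (brain vs cord, cervical vs thoracic).  An all-empty cohort reports
    zeros with ``empty=True``.
    """
    n_profiles = len(calls_per_profile)
    all_calls = [c for calls in calls_per_profile for c in calls]
    n_lesions = len(all_calls)
    severe = [c for c in all_calls if c.severe]
    n_severe = len(severe)
    summary = {
        "n_profiles": n_profiles,
        "n_lesions": n_lesions,
        "n_severe": n_severe,
        "pct_severe": 100.0 * n_severe / n_lesions if n_lesions else 0.0,
        "pct_profiles_with_lesion": (
            100.0 * sum(bool(c) for c in calls_per_profile) / n_profiles
            if n_profiles else 0.0
        ),
        "pct_profiles_with_severe": (
            100.0 * sum(any(x.severe for x in c) for c in calls_per_profile) / n_profiles
            if n_profiles else 0.0
        ),
        "empty": n_lesions == 0,
    }
    brain_portions = {"brain", "brainstem"}
    located = [c for c in severe if c.portion is not None]
    n_loc = len(located)
    n_brain = sum(c.portion in brain_portions for c in located)
    n_cerv = sum(c.portion == "cervical_C1_C7" for c in located)
    n_thor = sum(c.portion == "thoracic_T1_T10" for c in located)
    summary["severe_location"] = {
        "pct_brain": 100.0 * n_brain / n_loc if n_loc else 0.0,
        "pct_sc": 100.0 * (n_cerv + n_thor) / n_loc if n_loc else 0.0,
        "pct_cervical": 100.0 * n_cerv / n_loc if n_loc else 0.0,
        "pct_thoracic": 100.0 * n_thor / n_loc if n_loc else 0.0,
    }
    return summary
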