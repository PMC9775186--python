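"""Template tracts and lesion overlap.

Control tract masks on a shared voxel grid are collapsed into group
templates (voxels present in at least k of n controls), and each stroke
participant's lesion mask is intersected with every template to yield
percent damage and a lesioned / non-lesioned grouping per tract.

All masks must already live in the common template space; a grid mismatch
is an error, not something this module resamples away.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MaskVolume:
    """Binary voxel mask with its grid geometry."""

    data: np.ndarray  # bool, 3D
    voxel_size_mm: float = 4.0
    space: str = "study-template"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be a 3D array")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be binary")
        object.__setattr__(self, "data", arr.astype(bool))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_size_mm**3

    def same_grid(self, other: "MaskVolume") -> bool:
        return self.data.shape == other.data.shape and np.isclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, space: str = "study-template") -> "MaskVolume":
        img = nib.load(str(path))
        vox = float(img.header.get_zooms()[0])
        return cls(data=np.asarray(img.dataobj) > 0, voxel_size_mm=vox, space=space)


@dataclass(frozen=True)
class TractTemplate:
    tract: str
    hemisphere: str
    mask: MaskVolume
    agreement_k: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.agreement_k > self.n_controls:
            raise ValueError("agreement_k cannot exceed the number of controls")


@dataclass(frozen=True)
class LesionOverlapResult:
    participant: str
    tract: str
    hemisphere: str
    overlap_voxels: int
    template_voxels: int
    percent_damage: float
    lesioned: bool


def threshold_probability_map(
    prob_map: np.ndarray, threshold_fraction: float, voxel_size_mm: float = 4.0
) -> MaskVolume:
    """Keep voxels whose probability is >= the threshold (binary output)."""
    prob = np.asarray(prob_map, dtype=float)
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return MaskVolume(data=prob >= threshold_fraction, voxel_size_mm=voxel_size_mm)


def build_template(
    control_masks: list[MaskVolume] | list[np.ndarray],
    k: int,
    tract: str = "",
    hemisphere: str = "",
    voxel_size_mm: float | None = None,
) -> TractTemplate:
    """Group template: voxels present in at least k of the control masks."""
    masks = [
        m if isinstance(m, MaskVolume) else MaskVolume(m, voxel_size_mm or 4.0)
        for m in control_masks
    ]
    if len(masks) < 2:
        raise ValueError("need at least 2 control masks")
    if not 1 <= k <= len(masks):
        raise ValueError("k must lie in [1, n]")
    first = masks[0]
    for m in masks[1:]:
        if not first.same_grid(m):
            raise ValueError("control masks must share one grid")
    agreement = np.sum([m.data for m in masks], axis=0)
    return TractTemplate(
        tract=tract,
        hemisphere=hemisphere,
        mask=MaskVolume(agreement >= k, first.voxel_size_mm),
        agreement_k=k,
        n_controls=len(masks),
    )


def lesion_overlap(
    template: TractTemplate, lesion: MaskVolume, participant: str = ""
) -> LesionOverlapResult:
    """Intersect a lesion with a template tract; percent damage is the share
    of template voxels covered by the lesion."""
    if not template.mask.same_grid(lesion):
        raise ValueError("template and lesion must share one grid")
    tv = template.mask.n_voxels
    if tv == 0:
        raise ValueError("template tract is empty")
    overlap = int(np.sum(template.mask.data & lesion.data))
    pct = 100.0 * overlap / tv
    return LesionOverlapResult(
        participant=participant,
        tract=template.tract,
        hemisphere=template.hemisphere,
        overlap_voxels=overlap,
        template_voxels=tv,
        percent_damage=pct,
        lesioned=pct > 0.0,
    )


def overlaps_to_frame(results: list[LesionOverlapResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def assign_lesion_groups(overlaps: pd.DataFrame) -> pd.DataFrame:
    """Per-tract lesioned / non-lesioned partition of stroke participants.

    Input: one row per participant x tract (columns ``participant``,
    ``tract``, ``lesioned``); a participant may belong to several lesion
    groups.  Output: same rows with a ``group`` column; missing pairs are an
    error because every participant must be classifiable for every tract.
    """
    required = {"participant", "tract", "lesioned"}
    if not required.issubset(overlaps.columns):
        raise ValueError(f"overlap table needs columns {sorted(required)}")
    pivot = overlaps.pivot_table(
        index="participant", columns="tract", values="lesioned", aggfunc="first"
    )
    if pivot.isna().any().any():
        missing = pivot.isna().stack()
        pairs = list(missing[missing].index[:5])
        raise ValueError(f"missing participant-tract pairs, e.g. {pairs}")
    out = overlaps.copy()
    out["group"] = np.where(out["lesioned"], "lesioned", "non_lesioned")
    return out
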