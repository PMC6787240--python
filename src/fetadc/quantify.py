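"""Per-patient lesion metrics: SUV, TBR, ADC and their background ratios.

Background is measured on a contralateral 2-D disk ROI of similar size
to the lesion's cross-section, placed by geometric mirroring across
the mid-sagittal plane on the representative axial slice (the slice
with the highest mean uptake inside the 3D-VOI).  Ratios follow the
usual convention: TBR = lesion SUV / contralateral mean SUV and
rADC = lesion ADCmean / contralateral mean ADC.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .segmentation import LesionVOI, transfer_voi
from .volumes import ScalarVolume

__all__ = [
    "BackgroundROI",
    "LesionMetrics",
    "representative_slice",
    "mirror_background_roi",
    "roi_mean",
    "compute_metrics",
]

METRIC_COLUMNS = [
    "patient_id",
    "suv_max",
    "suv80_mean",
    "suv_bg",
    "tbr_max",
    "tbr80_mean",
    "adc_mean",
    "adc_bg",
    "radc_mean",
    "voi_volume_mm3",
]


@dataclasses.dataclass
class BackgroundROI:
    """A single-slice disk of background voxels."""

    grid_id: str
    slice_index: int
    voxels: np.ndarray  # (N, 3) int indices, all with k == slice_index
    area_mm2: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        if len(self.voxels) == 0:
            raise ValueError("background ROI is empty")
        if not np.all(self.voxels[:, 2] == self.slice_index):
            raise ValueError("background ROI voxels must lie on its slice")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def as_voi(self) -> LesionVOI:
        """View the ROI as a voxel set for grid-to-grid transfer."""
        return LesionVOI(
            grid_id=self.grid_id,
            voxels=self.voxels,
            threshold_fraction=float("nan"),
            absolute_threshold=float("nan"),
            seed_voxel=tuple(int(x) for x in self.voxels[0]),
        )


@dataclasses.dataclass
class LesionMetrics:
    """The per-patient quantitative read-out."""

    patient_id: str
    suv_max: float
    suv80_mean: float
    suv_bg: float
    tbr_max: float
    tbr80_mean: float
    adc_mean: float
    adc_bg: float
    radc_mean: float
    voi_volume_mm3: float

    def validate(self, threshold_fraction: float = 0.8) -> None:
        if self.suv_bg <= 0 or self.adc_bg <= 0:
            raise ValueError("background means must be positive")
        if not self.suv_max >= self.suv80_mean >= threshold_fraction * self.suv_max:
            raise ValueError(
                "isocontour mean must sit between the threshold fraction and the maximum"
            )

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in METRIC_COLUMNS}


def representative_slice(suv: ScalarVolume, voi: LesionVOI) -> int:
    """Axial slice with the highest mean uptake inside the VOI.

    Ties go to the inferior-most slice (lowest index).
    """
    if voi.grid_id != suv.grid_id:
        raise ValueError("VOI and volume are on different grids")
    values = suv.data[tuple(voi.voxels.T)]
    slices = voi.voxels[:, 2]
    best_slice, best_mean = -1, -np.inf
    for k in np.unique(slices):  # unique() is sorted -> first win = inferior-most
        m = values[slices == k].mean()
        if m > best_mean:
            best_slice, best_mean = int(k), float(m)
    return best_slice


def mirror_background_roi(
    vol: ScalarVolume,
    voi: LesionVOI,
    slice_index: int,
    brain_mask: np.ndarray,
    midline_world_x: float = 0.0,
    max_area_loss: float = 0.25,
) -> BackgroundROI:
    """Contralateral 2-D disk ROI of similar size on one axial slice.

    The VOI's in-slice centroid is reflected across the mid-sagittal
    plane ``x = midline_world_x``; the ROI is the set of in-slice voxel
    centres nearest the mirrored point, as many as the VOI has on that
    slice (a discrete disk of equal area), clipped to the brain mask.
    Raises if the VOI straddles the midline, if the clipped ROI loses
    more than ``max_area_loss`` of its area, or if it touches the VOI.
    """
    if voi.grid_id != vol.grid_id:
        raise ValueError("VOI and volume are on different grids")
    world_all = vol.voxel_to_world(voi.voxels.astype(float))
    side = np.sign(world_all[:, 0] - midline_world_x)
    if side.max() > 0 and side.min() < 0:
        raise ValueError("lesion VOI straddles the mid-sagittal plane; no contralateral side")
    if np.any(side == 0):
        raise ValueError("lesion VOI touches the mid-sagittal plane")

    in_slice = voi.voxels[voi.voxels[:, 2] == slice_index]
    if len(in_slice) == 0:
        raise ValueError(f"VOI has no voxels on slice {slice_index}")
    centroid = vol.voxel_to_world(in_slice.astype(float)).mean(axis=0)
    mirrored = centroid.copy()
    mirrored[0] = 2.0 * midline_world_x - centroid[0]

    nx, ny = vol.shape[0], vol.shape[1]
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    slice_idx = np.column_stack(
        [ii.ravel(), jj.ravel(), np.full(ii.size, slice_index)]
    )
    slice_world = vol.voxel_to_world(slice_idx.astype(float))
    d = np.linalg.norm(slice_world[:, :2] - mirrored[:2], axis=1)
    order = np.argsort(d, kind="stable")
    disk = slice_idx[order[: len(in_slice)]]  # ideal disk, same voxel count

    brain_mask = np.asarray(brain_mask, dtype=bool)
    kept = disk[brain_mask[tuple(disk.T)]]
    if len(kept) < (1.0 - max_area_loss) * len(disk):
        raise ValueError(
            f"mirrored background ROI lost {len(disk) - len(kept)} of {len(disk)} voxels "
            "to the brain-mask clip — lesion too medial or mask too tight"
        )
    if voi.voxel_set() & {tuple(v) for v in kept}:
        raise ValueError("mirrored background ROI overlaps the lesion VOI")

    pixel_area = float(np.prod(vol.voxel_size_mm[:2]))
    return BackgroundROI(
        grid_id=vol.grid_id,
        slice_index=int(slice_index),
        voxels=kept,
        area_mm2=len(kept) * pixel_area,
    )


def roi_mean(vol: ScalarVolume, voxels: np.ndarray) -> float:
    """Arithmetic mean of voxel values over an index set."""
    voxels = np.asarray(voxels, dtype=int).reshape(-1, 3)
    if len(voxels) == 0:
        raise ValueError("cannot average an empty region")
    if np.any(voxels < 0) or np.any(voxels >= np.asarray(vol.shape)):
        raise ValueError("region indices fall outside the grid")
    return float(vol.data[tuple(voxels.T)].mean())


def compute_metrics(
    suv: ScalarVolume,
    adc: ScalarVolume,
    voi_suv: LesionVOI,
    voi_adc: LesionVOI,
    bg_suv: BackgroundROI,
    bg_adc: BackgroundROI,
    patient_id: str = "",
) -> LesionMetrics:
    """Assemble the full metric set from VOIs and background ROIs.

    SUV statistics come from the isocontour VOI on the SUV grid; the
    ADC mean from the (margin-adapted) VOI on the ADC grid; ratios
    divide by the respective contralateral background mean.
    """
    suv_bg = roi_mean(suv, bg_suv.voxels)
    adc_bg = roi_mean(adc, bg_adc.voxels)
    if suv_bg <= 0 or adc_bg <= 0:
        raise ValueError("background means must be strictly positive")
    suv_values = suv.data[tuple(voi_suv.voxels.T)]
    suv_max = float(suv_values.max())
    suv80_mean = float(suv_values.mean())
    adc_mean = roi_mean(adc, voi_adc.voxels)
    metrics = LesionMetrics(
        patient_id=patient_id,
        suv_max=suv_max,
        suv80_mean=suv80_mean,
        suv_bg=suv_bg,
        tbr_max=suv_max / suv_bg,
        tbr80_mean=suv80_mean / suv_bg,
        adc_mean=adc_mean,
        adc_bg=adc_bg,
        radc_mean=adc_mean / adc_bg,
        voi_volume_mm3=voi_suv.n_voxels * suv.voxel_volume_mm3,
    )
    metrics.validate(voi_suv.threshold_fraction)
    return metrics


def background_roi_on(
    roi: BackgroundROI, source: ScalarVolume, target: ScalarVolume
) -> BackgroundROI:
    """Transfer a background ROI to a co-registered grid.

    The same anatomical locus measured on both modalities; on the
    target grid the ROI may span more than one slice, so the result is
    returned as a plain voxel set wrapped in a single representative
    slice (the modal one).
    """
    moved = transfer_voi(roi.as_voi(), source, target)
    slices = moved.voxels[:, 2]
    modal = int(np.bincount(slices).argmax())
    if np.all(slices == modal):
        pixel_area = float(np.prod(target.voxel_size_mm[:2]))
        return BackgroundROI(
            grid_id=target.grid_id,
            slice_index=modal,
            voxels=moved.voxels,
            area_mm2=len(moved.voxels) * pixel_area,
        )
    # multi-slice after resampling: keep the dominant slice's voxels
    kept = moved.voxels[slices == modal]
    pixel_area = float(np.prod(target.voxel_size_mm[:2]))
    return BackgroundROI(
        grid_id=target.grid_id, slice_index=modal, voxels=kept, area_mm2=len(kept) * pixel_area
    )
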