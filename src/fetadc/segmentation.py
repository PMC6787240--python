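"""Isocontour lesion segmentation on SUV volumes.

The metabolically most active lesion region is delineated by
thresholding the SUV volume at a fraction of its in-mask maximum
(isocontour 80%, "IC80", by default), labelling 26-connected
components of the supra-threshold set, picking the most prominent
component, and re-thresholding it locally at ``fraction x component
max`` so that a dimmer secondary lesion still carries a true 80%
isocontour of its own peak.  The resulting voxel set can be
transferred to a co-registered grid (e.g. the ADC map) by
nearest-neighbour affine mapping and trimmed so it does not overlap
CSF or a resection cavity.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import ScalarVolume

__all__ = [
    "HotComponent",
    "LesionVOI",
    "find_hot_components",
    "select_prominent_lesion",
    "isocontour_voi",
    "transfer_voi",
    "adapt_margins",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

DEFAULT_CSF_CUTOFF = 2400.0  # x10^-6 mm^2/s, below free water (~3000), above tumour range


def _sorted_voxels(voxels: np.ndarray) -> np.ndarray:
    voxels = np.asarray(voxels, dtype=int).reshape(-1, 3)
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    return voxels[order]


@dataclasses.dataclass
class HotComponent:
    """One 26-connected supra-threshold component of the SUV volume."""

    voxels: np.ndarray  # (N, 3) int indices
    suv_max: float
    peak_voxel: tuple[int, int, int]  # argmax; ties -> lowest index triple
    threshold: float  # global threshold that produced the component
    centroid_world: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclasses.dataclass
class LesionVOI:
    """A connected supra-threshold voxel set with its provenance."""

    grid_id: str
    voxels: np.ndarray  # (N, 3), lexicographically sorted
    threshold_fraction: float
    absolute_threshold: float
    seed_voxel: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.voxels = _sorted_voxels(self.voxels)
        if len(self.voxels) == 0:
            raise ValueError("VOI is empty")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def to_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(self.voxels.T)] = True
        return mask

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(v) for v in self.voxels}

    def volume_mm3(self, volume: ScalarVolume) -> float:
        return self.n_voxels * volume.voxel_volume_mm3

    # -- export -------------------------------------------------------------

    def to_nifti_mask(self, volume: ScalarVolume, path: str | Path) -> Path:
        mask = self.to_mask(volume.shape).astype(np.uint8)
        return ScalarVolume.to_nifti(
            dataclasses.replace(volume, data=mask.astype(float)), path, dtype=np.uint8
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "grid_id": self.grid_id,
            "threshold_fraction": self.threshold_fraction,
            "absolute_threshold": self.absolute_threshold,
            "seed_voxel": list(self.seed_voxel),
            "voxels": self.voxels.tolist(),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LesionVOI":
        payload = json.loads(Path(path).read_text())
        return cls(
            grid_id=payload["grid_id"],
            voxels=np.asarray(payload["voxels"], dtype=int),
            threshold_fraction=payload["threshold_fraction"],
            absolute_threshold=payload["absolute_threshold"],
            seed_voxel=tuple(payload["seed_voxel"]),
        )


def _component_argmax(data: np.ndarray, voxels: np.ndarray) -> tuple[int, int, int]:
    """Argmax over a voxel list; ties broken by lowest index triple.

    ``voxels`` must be lexicographically sorted so the first maximal
    entry is the tie-break winner.
    """
    values = data[tuple(voxels.T)]
    best = np.flatnonzero(values == values.max())[0]
    return tuple(int(x) for x in voxels[best])


def find_hot_components(
    suv: ScalarVolume, brain_mask: np.ndarray, fraction: float = 0.8
) -> list[HotComponent]:
    """26-connected components of the global isocontour set.

    Thresholds at ``fraction x max(SUV within brain_mask)``; the voxel
    attaining the maximum always survives, so the result is non-empty.
    Components are returned sorted by descending SUVmax.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != suv.shape:
        raise ValueError("brain mask shape does not match the volume")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    threshold = fraction * float(suv.data[brain_mask].max())
    supra = brain_mask & (suv.data >= threshold)
    labels, n = ndimage.label(supra, structure=_STRUCT_26)
    comps = []
    for lab in range(1, n + 1):
        voxels = _sorted_voxels(np.argwhere(labels == lab))
        peak = _component_argmax(suv.data, voxels)
        comps.append(
            HotComponent(
                voxels=voxels,
                suv_max=float(suv.data[peak]),
                peak_voxel=peak,
                threshold=threshold,
                centroid_world=suv.voxel_to_world(voxels).mean(axis=0),
            )
        )
    comps.sort(key=lambda c: -c.suv_max)
    return comps


def select_prominent_lesion(
    components: list[HotComponent], reference_point_world: np.ndarray | None = None
) -> HotComponent:
    """Pick the most prominent component.

    Rank by highest SUVmax, then largest voxel volume, then (if a
    reference point such as the resection-cavity centre is given)
    smallest distance to it.  Deterministic: any residual tie falls
    back to the lowest peak-voxel index triple.
    """
    if not components:
        raise ValueError("no candidate components")

    def key(c: HotComponent):
        dist = (
            float(np.linalg.norm(c.centroid_world - np.asarray(reference_point_world)))
            if reference_point_world is not None
            else 0.0
        )
        return (-c.suv_max, -c.n_voxels, dist, c.peak_voxel)

    return min(components, key=key)


def isocontour_voi(
    suv: ScalarVolume, component: HotComponent, fraction: float = 0.8
) -> LesionVOI:
    """Local isocontour VOI of one component.

    Re-thresholds at ``fraction x component SUVmax`` (so a dimmer
    secondary lesion gets its own 80% contour rather than the global
    one) and keeps the 26-connected piece containing the component
    peak.  With ``fraction = 1`` the VOI collapses to the argmax.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    local_threshold = fraction * component.suv_max
    keep = component.voxels[suv.data[tuple(component.voxels.T)] >= local_threshold]
    mask = np.zeros(suv.shape, dtype=bool)
    mask[tuple(keep.T)] = True
    labels, _ = ndimage.label(mask, structure=_STRUCT_26)
    seed = component.peak_voxel
    voxels = np.argwhere(labels == labels[seed])
    return LesionVOI(
        grid_id=suv.grid_id,
        voxels=voxels,
        threshold_fraction=fraction,
        absolute_threshold=local_threshold,
        seed_voxel=seed,
    )


def transfer_voi(voi: LesionVOI, source: ScalarVolume, target: ScalarVolume) -> LesionVOI:
    """Map a VOI between co-registered grids by nearest neighbour.

    Each target voxel centre is pushed through the target affine and
    the inverse source affine; it joins the transferred VOI when it
    lands inside a source VOI voxel.  Identical grids give an identity
    transfer.  An empty result signals mis-registration.
    """
    if voi.grid_id != source.grid_id:
        raise ValueError(f"VOI lives on grid {voi.grid_id!r}, not {source.grid_id!r}")
    src_mask = voi.to_mask(source.shape)
    tgt_idx = np.indices(target.shape).reshape(3, -1).T.astype(float)
    world = target.voxel_to_world(tgt_idx)
    src_idx = np.rint(source.world_to_voxel(world)).astype(int)
    inside = np.all((src_idx >= 0) & (src_idx < np.asarray(source.shape)), axis=1)
    hit = np.zeros(len(tgt_idx), dtype=bool)
    hit[inside] = src_mask[tuple(src_idx[inside].T)]
    if not hit.any():
        raise ValueError(
            "VOI transfer produced an empty set — grids do not overlap in world space "
            "(check co-registration)"
        )
    voxels = tgt_idx[hit].astype(int)
    # seed: target voxel nearest (in world mm) to the source seed centre
    seed_world = source.voxel_to_world(np.asarray(voi.seed_voxel, dtype=float))
    d = np.linalg.norm(target.voxel_to_world(voxels.astype(float)) - seed_world, axis=1)
    seed = tuple(int(x) for x in voxels[int(np.argmin(d))])
    return LesionVOI(
        grid_id=target.grid_id,
        voxels=voxels,
        threshold_fraction=voi.threshold_fraction,
        absolute_threshold=voi.absolute_threshold,
        seed_voxel=seed,
    )


def adapt_margins(
    voi_on_adc: LesionVOI,
    adc: ScalarVolume,
    csf_cutoff: float = DEFAULT_CSF_CUTOFF,
    exclusion_mask: np.ndarray | None = None,
) -> LesionVOI:
    """Trim VOI margins that overlap CSF or an exclusion region.

    Removes voxels whose ADC reaches ``csf_cutoff`` (free-water-like
    diffusivity) or that fall inside ``exclusion_mask`` (e.g. a
    resection cavity).  Losing more than half of the VOI — or all of
    it — signals a mis-placed VOI and raises.
    """
    if csf_cutoff <= 0:
        raise ValueError("csf_cutoff must be positive")
    if voi_on_adc.grid_id != adc.grid_id:
        raise ValueError("VOI and ADC volume are on different grids")
    values = adc.data[tuple(voi_on_adc.voxels.T)]
    keep = values < csf_cutoff
    if exclusion_mask is not None:
        keep &= ~np.asarray(exclusion_mask, dtype=bool)[tuple(voi_on_adc.voxels.T)]
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError("margin adaptation emptied the VOI — lesion placement is suspect")
    if n_kept < 0.5 * voi_on_adc.n_voxels:
        raise ValueError(
            f"margin adaptation removed {voi_on_adc.n_voxels - n_kept} of "
            f"{voi_on_adc.n_voxels} voxels (> 50%) — VOI overlaps CSF/cavity too heavily"
        )
    return dataclasses.replace(voi_on_adc, voxels=voi_on_adc.voxels[keep])
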