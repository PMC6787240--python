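"""Digital FET-PET/ADC phantom cohorts.

This module fabricates co-registered SUV and ADC volumes that stand in
for a post-treatment glioma cohort: an ellipsoidal brain-like
background, CSF-like spheres (high ADC, low SUV), and a single focal
hot lesion whose target-to-background ratio (TBR) and hot-core mean
ADC are drawn from per-group sampling distributions.

Calibration model
-----------------
Published group summaries report group means and the standard error of
the mean difference (MD +/- SE) for two diagnostic groups: recurrent
glioma (REC, n1) and post-treatment related effects (PTRE, n2).  Under
a pooled-variance two-sample model the between-patient SD implied by
the SE of the difference is::

    sd = md_se / sqrt(1/n1 + 1/n2)

Both groups share this SD; group means are taken as printed.  Lesion
TBRmax is sampled from a *mean-matched* truncated normal: the normal's
location is solved so that the mean of the distribution truncated
below at ``tbr_truncation_floor`` equals the calibration mean (a plain
truncation at these dispersions would inflate the group mean far above
the printed value).  An 80% isocontour is a compact hot spot only for
TBR > 1/0.8, hence the floor defaults to 1.4.

Lesion model
------------
The lesion adds a radial profile ``A * exp(-0.5 * (r/sigma)**p)`` to
the background, with amplitude ``A = lesion_peak_suv - bg_suv_mean``.
The exponent ``p`` controls how much of the 80% isocontour volume sits
close to the peak and therefore the SUV80mean/SUVmax ratio; the
packaged default is solved so that the continuum ratio at the REC
group-mean TBR reproduces the published TBR80mean/TBRmax ratio.  The
"hot core" — the region whose noise-free SUV is at least 80% of the
peak — is filled with an independent Gaussian ADC distribution
(``core_adc_mean``, ``core_adc_sd``), emulating the diffusion
signature of the metabolically most active tissue.
"""

from __future__ import annotations

import dataclasses
import json
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, ndimage, optimize
from scipy import stats as sps

from .volumes import ScalarVolume

__all__ = [
    "GroupCalibration",
    "PhantomSpec",
    "CohortManifest",
    "pooled_sd_from_md_se",
    "calibrate_from_summary",
    "default_calibrations",
    "default_phantom_geometry",
    "sample_patient_spec",
    "render_phantom",
    "generate_cohort",
    "ic80_mean_ratio",
    "solve_profile_exponent",
    "truncated_tbr_distribution",
]

GROUPS = ("REC", "PTRE")

MANIFEST_COLUMNS = [
    "patient_id",
    "group",
    "suv_path",
    "adc_path",
    "true_core_adc",
    "true_tbrmax",
]


# ---------------------------------------------------------------------------
# calibration


def pooled_sd_from_md_se(md_se: float, n1: int, n2: int) -> float:
    """Between-patient SD implied by the SE of a two-sample mean difference.

    ``se(diff) = sd * sqrt(1/n1 + 1/n2)`` under pooled variance, so
    ``sd = md_se / sqrt(1/n1 + 1/n2)``.
    """
    if md_se <= 0:
        raise ValueError("md_se must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return float(md_se / np.sqrt(1.0 / n1 + 1.0 / n2))


@dataclasses.dataclass(frozen=True)
class GroupCalibration:
    """Per-group sampling distribution for phantom lesions."""

    group: str
    tbrmax_mean: float
    tbrmax_sd: float
    core_adc_mean_mean: float
    core_adc_mean_sd: float
    bg_suv_mean: float
    bg_adc_mean: float
    tbr_truncation_floor: float = 1.4

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.tbrmax_sd < 0 or self.core_adc_mean_sd < 0:
            raise ValueError("SDs must be non-negative")
        if self.tbr_truncation_floor <= 1:
            raise ValueError("tbr_truncation_floor must exceed 1 (a lesion must beat background)")
        if self.bg_suv_mean <= 0 or self.bg_adc_mean <= 0:
            raise ValueError("background means must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def calibrate_from_summary(
    tbrmax_means: tuple[float, float],
    tbrmax_md_se: float,
    adc_means: tuple[float, float],
    adc_md_se: float,
    n_rec: int,
    n_ptre: int,
    bg_suv_means: tuple[float, float] = (0.94, 1.11),
    bg_adc_means: tuple[float, float] = (768.0, 755.0),
    tbr_truncation_floor: float = 1.4,
) -> tuple[GroupCalibration, GroupCalibration]:
    """Build (REC, PTRE) calibrations from printed group summaries.

    Means are passed as ``(rec, ptre)`` pairs; dispersions are derived
    from the SE of each mean difference via :func:`pooled_sd_from_md_se`
    and shared by both groups (pooled-variance assumption).
    """
    tbr_sd = pooled_sd_from_md_se(tbrmax_md_se, n_rec, n_ptre)
    adc_sd = pooled_sd_from_md_se(adc_md_se, n_rec, n_ptre)
    cals = []
    for i, group in enumerate(GROUPS):
        cals.append(
            GroupCalibration(
                group=group,
                tbrmax_mean=float(tbrmax_means[i]),
                tbrmax_sd=tbr_sd,
                core_adc_mean_mean=float(adc_means[i]),
                core_adc_mean_sd=adc_sd,
                bg_suv_mean=float(bg_suv_means[i]),
                bg_adc_mean=float(bg_adc_means[i]),
                tbr_truncation_floor=tbr_truncation_floor,
            )
        )
    return cals[0], cals[1]


def _load_defaults() -> dict:
    with resources.files("fetadc.data").joinpath("default_calibrations.json").open() as fh:
        return json.load(fh)


def default_calibrations() -> tuple[GroupCalibration, GroupCalibration]:
    """The packaged (REC, PTRE) calibrations."""
    cfg = _load_defaults()
    return tuple(GroupCalibration(**cfg["groups"][g]) for g in GROUPS)  # type: ignore[return-value]


def default_phantom_geometry() -> dict:
    """Packaged geometry / noise defaults shared by all phantoms."""
    cfg = _load_defaults()
    return cfg["phantom"]


# ---------------------------------------------------------------------------
# truncated-normal TBR sampling


@lru_cache(maxsize=64)
def _solve_truncnorm_loc(target_mean: float, sd: float, floor: float) -> float:
    """Location of a normal whose floor-truncated mean equals ``target_mean``."""
    if sd == 0:
        if target_mean < floor:
            raise ValueError("degenerate TBR distribution below the truncation floor")
        return target_mean

    def trunc_mean(mu: float) -> float:
        a = (floor - mu) / sd
        return float(sps.truncnorm.mean(a, np.inf, loc=mu, scale=sd))

    lo, hi = target_mean - 8 * sd, target_mean + sd
    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean, lo, hi, xtol=1e-12))


def truncated_tbr_distribution(calibration: GroupCalibration):
    """Frozen scipy distribution of lesion TBRmax for one group.

    Mean-matched: the truncated mean equals ``calibration.tbrmax_mean``.
    """
    mu = _solve_truncnorm_loc(
        calibration.tbrmax_mean, calibration.tbrmax_sd, calibration.tbr_truncation_floor
    )
    a = (calibration.tbr_truncation_floor - mu) / calibration.tbrmax_sd
    return sps.truncnorm(a, np.inf, loc=mu, scale=calibration.tbrmax_sd)


# ---------------------------------------------------------------------------
# lesion profile maths (continuum, noise-free)


def _profile(u: np.ndarray, p: float) -> np.ndarray:
    """Radial fall-off ``exp(-0.5 * u**p)`` with ``u = r / sigma``."""
    return np.exp(-0.5 * np.asarray(u, dtype=float) ** p)


def _core_boundary_fraction(tbr: float, fraction: float = 0.8) -> float:
    """Profile value at the edge of the hot core.

    The core is where ``bg + A*g >= fraction * peak`` with
    ``A = (tbr - 1) * bg``, i.e. ``g >= (fraction*tbr - 1)/(tbr - 1)``.
    Requires ``tbr > 1/fraction`` for a compact core.
    """
    if tbr <= 1.0 / fraction:
        raise ValueError(
            f"TBR {tbr:.3f} <= 1/{fraction} — the {fraction:.0%} isocontour is not a compact hot spot"
        )
    return (fraction * tbr - 1.0) / (tbr - 1.0)


def core_radius_mm(tbr: float, sigma_mm: float, exponent: float, fraction: float = 0.8) -> float:
    """Radius of the hot core (noise-free SUV >= fraction * peak)."""
    g80 = _core_boundary_fraction(tbr, fraction)
    return float(sigma_mm * (2.0 * np.log(1.0 / g80)) ** (1.0 / exponent))


def ic80_mean_ratio(tbr: float, exponent: float, fraction: float = 0.8) -> float:
    """Continuum SUVmean/SUVmax ratio over the isocontour core.

    Scale-free in sigma; depends only on the lesion TBR and the profile
    exponent.  Used to calibrate the exponent against a published
    TBR-mean/TBR-max ratio.
    """
    g_edge = _core_boundary_fraction(tbr, fraction)
    u_edge = (2.0 * np.log(1.0 / g_edge)) ** (1.0 / exponent)
    num = integrate.quad(lambda u: _profile(u, exponent) * u**2, 0.0, u_edge)[0]
    mean_g = num / (u_edge**3 / 3.0)
    return float((1.0 + (tbr - 1.0) * mean_g) / tbr)


def solve_profile_exponent(target_ratio: float, tbr: float, fraction: float = 0.8) -> float:
    """Profile exponent whose continuum core mean/max ratio equals ``target_ratio``."""
    if not fraction < target_ratio < 1.0:
        raise ValueError(f"target ratio must lie in ({fraction}, 1)")
    return float(
        optimize.brentq(
            lambda p: ic80_mean_ratio(tbr, p, fraction) - target_ratio, 0.5, 8.0, xtol=1e-10
        )
    )


# ---------------------------------------------------------------------------
# phantom specification


@dataclasses.dataclass
class PhantomSpec:
    """Full recipe for one co-registered SUV/ADC phantom pair.

    World frame: RAS-like, grid centred on the origin, mid-sagittal
    plane at x = 0; the lesion must sit strictly lateral to it so a
    contralateral mirrored background always exists.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    brain_semi_axes_mm: tuple[float, float, float] = (55.0, 65.0, 45.0)
    bg_suv_mean: float = 1.0
    bg_adc_mean: float = 760.0
    bg_suv_sd: float = 0.03
    bg_adc_sd: float = 40.0
    csf_structures: tuple[tuple[tuple[float, float, float], float], ...] = (
        ((14.0, -8.0, 6.0), 7.0),
        ((-14.0, -8.0, 6.0), 7.0),
    )
    csf_adc: float = 3000.0
    csf_suv: float = 0.2
    lesion_center_mm: tuple[float, float, float] = (27.0, 9.0, 8.75)
    lesion_radius_mm: float = 13.0
    lesion_peak_suv: float = 3.0
    lesion_profile_sigma_mm: float = 6.0
    lesion_profile_exponent: float = 1.6343640271696414
    core_fraction: float = 0.8
    core_dilation_voxels: int = 1
    """The ADC core extends this many voxels beyond the SUV isocontour,
    so that noise-induced jitter of the segmented boundary stays inside
    the core's diffusion signature instead of picking up background ADC."""
    core_adc_mean: float = 1300.0
    core_adc_sd: float = 100.0
    secondary_lesions: tuple[tuple[tuple[float, float, float], float, float], ...] = ()
    """Optional extra hot spots as ``((cx, cy, cz), peak_suv, sigma_mm)``;
    they carry no ADC core and exist to exercise prominent-lesion selection."""
    seed: int = 0

    # -- derived geometry ---------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.voxel_size_mm)
        return aff

    @property
    def tbr(self) -> float:
        return self.lesion_peak_suv / self.bg_suv_mean

    @property
    def hot_core_radius_mm(self) -> float:
        return core_radius_mm(
            self.tbr, self.lesion_profile_sigma_mm, self.lesion_profile_exponent, self.core_fraction
        )

    def world_grid(self) -> np.ndarray:
        """(nx, ny, nz, 3) world coordinates of all voxel centres."""
        idx = np.indices(self.grid_shape, dtype=float)
        ijk = np.stack(idx, axis=-1)
        aff = self.affine
        return ijk @ aff[:3, :3].T + aff[:3, 3]

    def brain_mask(self) -> np.ndarray:
        xyz = self.world_grid()
        semi = np.asarray(self.brain_semi_axes_mm)
        return np.sum((xyz / semi) ** 2, axis=-1) <= 1.0

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        shape = np.asarray(self.grid_shape)
        if np.any(shape < 8):
            raise ValueError("grid too small")
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise ValueError("voxel spacings must be positive")
        for sd in (self.bg_suv_sd, self.bg_adc_sd, self.core_adc_sd):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")
        if self.lesion_peak_suv <= self.bg_suv_mean:
            raise ValueError("lesion_peak_suv must exceed bg_suv_mean (hot lesion)")
        c = np.asarray(self.lesion_center_mm)
        r = self.lesion_radius_mm
        semi = np.asarray(self.brain_semi_axes_mm)
        # conservative containment: inflate the centre by r on each axis
        if np.sum(((np.abs(c) + r) / semi) ** 2) > 1.0:
            raise ValueError("lesion sphere is not fully inside the brain mask")
        if abs(c[0]) <= r:
            raise ValueError("lesion sphere intersects the mid-sagittal plane")
        for centre, radius in self.csf_structures:
            if np.linalg.norm(c - np.asarray(centre)) <= r + radius:
                raise ValueError("lesion sphere intersects a CSF structure")
        margin = self.core_dilation_voxels * max(self.voxel_size_mm)
        if self.hot_core_radius_mm + margin > r:
            raise ValueError(
                "hot core (plus its dilation margin) extends beyond the declared "
                "lesion radius; increase lesion_radius_mm or the lesion contrast"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# sampling and rendering


def sample_patient_spec(calibration: GroupCalibration, rng_seed: int, **geometry) -> PhantomSpec:
    """Draw one patient's phantom recipe from a group calibration.

    TBRmax is drawn from the mean-matched truncated normal and the
    hot-core mean ADC from an untruncated normal; the drawn values are
    the phantom's ground truth (``spec.tbr``, ``spec.core_adc_mean``).
    Deterministic given ``rng_seed``.  ``geometry`` overrides any
    :class:`PhantomSpec` field not governed by the calibration.
    """
    rng = np.random.default_rng(rng_seed)
    if calibration.tbrmax_sd > 0:
        tbr = float(truncated_tbr_distribution(calibration).ppf(rng.uniform()))
    else:
        rng.uniform()  # keep the draw order identical either way
        tbr = calibration.tbrmax_mean
    core_adc = float(
        rng.normal(calibration.core_adc_mean_mean, calibration.core_adc_mean_sd)
        if calibration.core_adc_mean_sd > 0
        else calibration.core_adc_mean_mean
    )
    spec = PhantomSpec(
        bg_suv_mean=calibration.bg_suv_mean,
        bg_adc_mean=calibration.bg_adc_mean,
        lesion_peak_suv=tbr * calibration.bg_suv_mean,
        core_adc_mean=core_adc,
        seed=int(rng.integers(2**31)),
        **geometry,
    )
    spec.validate()
    return spec


def render_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, ScalarVolume]:
    """Render a spec into co-registered (SUV, ADC) volumes.

    Outside the brain ellipsoid both volumes are zero.  Background and
    lesion voxels carry independent Gaussian noise; CSF spheres are set
    to fixed values (low SUV, free-water ADC) with no noise so their
    signature is unambiguous.  The noise-free SUV maximum sits at the
    lesion centre voxel.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    xyz = spec.world_grid()
    brain = spec.brain_mask()
    aff = spec.affine

    r = np.linalg.norm(xyz - np.asarray(spec.lesion_center_mm), axis=-1)
    g = _profile(r / spec.lesion_profile_sigma_mm, spec.lesion_profile_exponent)
    amp = spec.lesion_peak_suv - spec.bg_suv_mean
    suv0 = np.where(brain, spec.bg_suv_mean + amp * g, 0.0)

    for centre, peak, sigma in spec.secondary_lesions:
        r2 = np.linalg.norm(xyz - np.asarray(centre), axis=-1)
        g2 = _profile(r2 / sigma, spec.lesion_profile_exponent)
        suv0 = np.where(brain, suv0 + (peak - spec.bg_suv_mean) * g2, 0.0)

    # hot core: noise-free primary-lesion SUV >= core_fraction * peak,
    # dilated so the ADC signature is marginally wider than the isocontour
    core = brain & (
        spec.bg_suv_mean + amp * g >= spec.core_fraction * spec.lesion_peak_suv
    )
    if spec.core_dilation_voxels > 0:
        core = ndimage.binary_dilation(
            core, structure=np.ones((3, 3, 3), dtype=bool), iterations=spec.core_dilation_voxels
        )

    csf = np.zeros_like(brain)
    for centre, radius in spec.csf_structures:
        csf |= np.linalg.norm(xyz - np.asarray(centre), axis=-1) <= radius
    csf &= brain
    core &= brain & ~csf

    noisy = brain & ~csf
    suv = suv0.copy()
    if spec.bg_suv_sd > 0:
        suv[noisy] += rng.normal(0.0, spec.bg_suv_sd, size=int(noisy.sum()))
    suv[csf] = spec.csf_suv

    adc = np.where(brain, spec.bg_adc_mean, 0.0)
    if spec.bg_adc_sd > 0:
        adc[noisy] += rng.normal(0.0, spec.bg_adc_sd, size=int(noisy.sum()))
    core_n = int(core.sum())
    adc[core] = (
        rng.normal(spec.core_adc_mean, spec.core_adc_sd, size=core_n)
        if spec.core_adc_sd > 0
        else spec.core_adc_mean
    )
    adc[csf] = spec.csf_adc

    suv_vol = ScalarVolume(suv, aff, "SUV", grid_id="phantom")
    adc_vol = ScalarVolume(adc, aff, "ADC", grid_id="phantom")

    peak_idx = np.unravel_index(np.argmax(suv_vol.data), suv_vol.shape)
    if not core[peak_idx]:
        raise RuntimeError("rendered SUV maximum fell outside the lesion hot core")
    return suv_vol, adc_vol


# ---------------------------------------------------------------------------
# cohorts


@dataclasses.dataclass
class CohortManifest:
    """Table mapping patient IDs to volume pairs and ground truth."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.table["patient_id"].duplicated().any():
            raise ValueError("patient_id values must be unique")

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        return cls(pd.read_csv(path))


def generate_cohort(
    calibrations: tuple[GroupCalibration, GroupCalibration],
    n_rec: int,
    n_ptre: int,
    seed: int,
    out_dir: str | Path,
    **geometry,
) -> CohortManifest:
    """Write a labelled phantom cohort (NIfTI pairs + manifest CSV).

    Fully reproducible from ``seed``: per-patient seeds are derived
    from one parent generator in a fixed order.
    """
    if n_rec < 1 or n_ptre < 1:
        raise ValueError("group sizes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec_cal, ptre_cal = calibrations
    parent = np.random.default_rng(seed)
    rows = []
    plan = [(rec_cal, i) for i in range(n_rec)] + [(ptre_cal, i) for i in range(n_ptre)]
    for cal, i in plan:
        pid = f"{cal.group}{i + 1:03d}"
        spec = sample_patient_spec(cal, int(parent.integers(2**31)), **geometry)
        suv, adc = render_phantom(spec)
        suv_path = suv.to_nifti(out_dir / f"{pid}_suv.nii")
        adc_path = adc.to_nifti(out_dir / f"{pid}_adc.nii")
        rows.append(
            {
                "patient_id": pid,
                "group": cal.group,
                "suv_path": str(suv_path),
                "adc_path": str(adc_path),
                "true_core_adc": spec.core_adc_mean,
                "true_tbrmax": spec.tbr,
            }
        )
    manifest = CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
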