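"""End-to-end orchestration: volumes in, metrics and cohort report out.

``run_patient`` composes segmentation -> VOI transfer -> margin
adaptation -> mirrored background -> metrics for one SUV/ADC pair;
``run_cohort`` maps it over a manifest and adds the cohort-level
statistics (group comparisons, ROC analyses, Youden cutoffs, the
step-wise classifier's diagnostic measures).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantify, segmentation, stats
from .phantom import CohortManifest
from .volumes import ScalarVolume

__all__ = [
    "PipelineConfig",
    "CohortReport",
    "run_patient",
    "run_patient_volumes",
    "run_cohort",
    "simulate_calibration_arms",
]

logger = logging.getLogger("fetadc")

COMPARISON_METRICS = ["adc_mean", "radc_mean", "tbr80_mean", "tbr_max"]


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the per-patient and cohort pipeline."""

    isocontour_fraction: float = 0.80
    csf_cutoff: float = segmentation.DEFAULT_CSF_CUTOFF
    theta_tbr: float = 2.0
    theta_adc: float = 1254.0
    midline_world_x: float = 0.0
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.isocontour_fraction < 1:
            raise ValueError("isocontour_fraction must lie in (0, 1)")
        for name in ("csf_cutoff", "theta_tbr", "theta_adc", "midline_world_x"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def rule(self) -> stats.ClassifierRule:
        return stats.ClassifierRule(theta_tbr=self.theta_tbr, theta_adc=self.theta_adc)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def run_patient_volumes(
    config: PipelineConfig,
    suv: ScalarVolume,
    adc: ScalarVolume,
    brain_mask: np.ndarray | None = None,
    patient_id: str = "",
) -> quantify.LesionMetrics:
    """Full per-patient analysis on in-memory volumes.

    With no explicit brain mask, non-zero SUV voxels are taken as
    brain — the convention of the packaged phantoms, whose volumes are
    zero outside the brain ellipsoid.
    """
    if brain_mask is None:
        brain_mask = suv.data > 0
    comps = segmentation.find_hot_components(suv, brain_mask, config.isocontour_fraction)
    comp = segmentation.select_prominent_lesion(comps)
    voi = segmentation.isocontour_voi(suv, comp, config.isocontour_fraction)
    logger.info(
        "%s: seed voxel %s, threshold %.4g, VOI %d voxels",
        patient_id or "patient",
        voi.seed_voxel,
        voi.absolute_threshold,
        voi.n_voxels,
    )
    k = quantify.representative_slice(suv, voi)
    bg_suv = quantify.mirror_background_roi(
        suv, voi, k, brain_mask, midline_world_x=config.midline_world_x
    )
    logger.info(
        "%s: background disk on slice %d, %d voxels (%.0f mm^2)",
        patient_id or "patient",
        bg_suv.slice_index,
        bg_suv.n_voxels,
        bg_suv.area_mm2,
    )
    voi_adc = segmentation.transfer_voi(voi, suv, adc)
    voi_adc = segmentation.adapt_margins(voi_adc, adc, csf_cutoff=config.csf_cutoff)
    bg_adc = quantify.background_roi_on(bg_suv, suv, adc)
    return quantify.compute_metrics(
        suv, adc, voi, voi_adc, bg_suv, bg_adc, patient_id=patient_id
    )


def run_patient(
    config: PipelineConfig, suv_path: str | Path, adc_path: str | Path, patient_id: str = ""
) -> quantify.LesionMetrics:
    """Per-patient analysis from a NIfTI pair on disk."""
    suv = ScalarVolume.from_nifti(suv_path, "SUV")
    adc = ScalarVolume.from_nifti(adc_path, "ADC")
    if not patient_id:
        patient_id = Path(suv_path).stem
    return run_patient_volumes(config, suv, adc, patient_id=patient_id)


# ---------------------------------------------------------------------------
# cohort


def _roc_summary(roc: stats.ROCResult, youden=None) -> dict:
    out = {
        "metric": roc.metric,
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "ci95": list(roc.ci95),
        "p_value": roc.p_value,
    }
    if youden is not None:
        cutoff, sens, spec, j = youden
        out["youden"] = {"cutoff": cutoff, "sensitivity": sens, "specificity": spec, "J": j}
    return out


@dataclasses.dataclass
class CohortReport:
    metrics: pd.DataFrame
    comparisons: list[stats.GroupComparison]
    roc_summaries: list[dict]
    roc_comparisons: list[dict]
    diagnostics: dict[str, stats.DiagnosticMeasures]
    failures: list[dict]
    degenerate: bool
    notes: list[str]

    def to_dict(self) -> dict:
        return {
            "n_patients": len(self.metrics),
            "n_failures": len(self.failures),
            "degenerate": self.degenerate,
            "notes": self.notes,
            "group_comparisons": [dataclasses.asdict(c) for c in self.comparisons],
            "roc": self.roc_summaries,
            "roc_comparisons": self.roc_comparisons,
            "diagnostic_measures": {
                k: dataclasses.asdict(v) for k, v in self.diagnostics.items()
            },
            "failures": self.failures,
        }

    def save(self, metrics_csv: str | Path, report_json: str | Path) -> None:
        self.metrics.to_csv(metrics_csv, index=False)
        Path(report_json).write_text(json.dumps(self.to_dict(), indent=2))


def run_cohort(config: PipelineConfig, manifest: CohortManifest) -> CohortReport:
    """Analyse every manifest row, then compute cohort statistics.

    Individual patient failures are logged and collected, not fatal;
    statistics that need both groups with adequate sizes are skipped
    (and flagged) on degenerate cohorts.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    rows, labels, failures = [], [], []
    for rec in manifest.table.itertuples(index=False):
        try:
            m = run_patient(config, rec.suv_path, rec.adc_path, patient_id=rec.patient_id)
            rows.append(m.to_row())
            labels.append(rec.group)
        except Exception as exc:  # noqa: BLE001 — per-patient isolation is the contract
            logger.warning("patient %s failed: %s", rec.patient_id, exc)
            failures.append({"patient_id": rec.patient_id, "error": str(exc)})
    if not rows:
        raise ValueError("no patient could be analysed")
    metrics = pd.DataFrame(rows, columns=quantify.METRIC_COLUMNS)
    metrics["group"] = labels

    y = stats.as_binary_labels(labels)
    notes: list[str] = []
    degenerate = (y == 1).sum() < 2 or (y == 0).sum() < 2
    comparisons, roc_summaries, roc_comparisons = [], [], []
    diagnostics: dict[str, stats.DiagnosticMeasures] = {}

    rule = config.rule
    predictions = [
        stats.classify_biparametric(r.tbr_max, r.adc_mean, rule)
        for r in metrics.itertuples(index=False)
    ]
    metrics["predicted"] = predictions
    if (y == 1).any() and (y == 0).any():
        for comb in ("or_rule", "tbr_only", "adc_only"):
            pred = [
                stats.classify_biparametric(
                    r.tbr_max, r.adc_mean, dataclasses.replace(rule, combination=comb)
                )
                for r in metrics.itertuples(index=False)
            ]
            diagnostics[comb] = stats.diagnostic_measures(pred, labels)

    if degenerate:
        notes.append(
            "cohort degenerate for inference: fewer than 2 patients in a group — "
            "t-tests and ROC statistics skipped"
        )
    else:
        for name in COMPARISON_METRICS:
            comparisons.append(
                stats.independent_t_test(
                    metrics.loc[y == 1, name], metrics.loc[y == 0, name], metric=name
                )
            )
        roc_tbr = stats.empirical_roc(metrics["tbr_max"], y, metric="tbr_max")
        roc_adc = stats.empirical_roc(metrics["adc_mean"], y, metric="adc_mean")
        roc_bi = stats.bivariate_roc(
            metrics["tbr_max"],
            metrics["adc_mean"],
            y,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        roc_summaries = [
            _roc_summary(roc_tbr, stats.youden_cutoff(roc_tbr)),
            _roc_summary(roc_adc, stats.youden_cutoff(roc_adc)),
            _roc_summary(roc_bi),
        ]
        diff, se, p = stats.compare_roc(roc_adc, roc_tbr, paired=True)
        roc_comparisons.append(
            {"pair": "adc_mean vs tbr_max", "difference": diff, "se": se, "p_value": p}
        )

    return CohortReport(
        metrics=metrics,
        comparisons=comparisons,
        roc_summaries=roc_summaries,
        roc_comparisons=roc_comparisons,
        diagnostics=diagnostics,
        failures=failures,
        degenerate=bool(degenerate),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# calibration-recovery simulation


def simulate_calibration_arms(
    n_per_group: int, seed: int, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Run paired REC/PTRE phantom arms through the full pipeline.

    Draws ``n_per_group`` phantoms per group from the packaged
    calibrations and extracts every metric with the standard pipeline
    (IC80 segmentation, VOI transfer, margin adaptation, mirrored
    background).  The two arms share one per-patient seed stream
    (common random numbers): each group's marginal distribution is
    untouched, but between-group difference estimates lose the
    between-patient sampling noise, a standard Monte-Carlo variance
    reduction for paired contrasts.

    Returns a tidy frame with one row per phantom: group, the pipeline
    metrics, and the generator's ground truth (``true_tbrmax``,
    ``true_core_adc``).
    """
    from .phantom import default_calibrations, render_phantom, sample_patient_spec

    if config is None:
        config = PipelineConfig()
    parent = np.random.default_rng(seed)
    patient_seeds = parent.integers(2**31, size=n_per_group)
    rows = []
    for cal in default_calibrations():
        for i, s in enumerate(patient_seeds):
            spec = sample_patient_spec(cal, int(s))
            suv, adc = render_phantom(spec)
            m = run_patient_volumes(config, suv, adc, patient_id=f"{cal.group}{i + 1:03d}")
            row = m.to_row()
            row["group"] = cal.group
            row["true_tbrmax"] = spec.tbr
            row["true_core_adc"] = spec.core_adc_mean
            rows.append(row)
    return pd.DataFrame(rows)
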