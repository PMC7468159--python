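"""End-to-end measurement and group-comparison pipeline.

Ties the stages together under one :class:`~gliamorph.config.PipelineConfig`:
optional pre-threshold smoothing, intensity thresholds (automatic per-image
or fixed quantiles), soma detection with the minimum-size filter, foreground
cleanup, process tracing and the eight per-cell parameters, then per-animal
aggregation and the normality-gated genotype comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import morphometry as morpho
from . import segmentation as seg
from .config import PipelineConfig
from .stats import (GroupSample, compare_parameter, significance_stars,
                    welch_t_two_sample)
from .synthetic import FieldImage

__all__ = [
    "FieldMeasurement",
    "measure_field",
    "cells_to_frame",
    "aggregate_per_animal",
    "compare_groups",
    "CELL_PARAMETERS",
    "DENSITY_PARAMETER",
]

#: Long-format names of the per-cell parameters.
CELL_PARAMETERS = [
    "n_primary_branches",
    "n_branch_points",
    "total_branch_length_um",
    "cell_radius_um",
    "cell_area_um2",
    "soma_area_um2",
    "soma_eccentricity",
]
DENSITY_PARAMETER = "cell_density_per_mm2"


@dataclass
class FieldMeasurement:
    """Everything measured on one field, plus a stage-count audit log."""

    cells: list[morpho.CellMorphology]
    summary: morpho.FieldSummary
    thresholds: seg.QuantileThresholds
    log: dict = field(default_factory=dict)
    soma_label_image: np.ndarray | None = None
    skeleton_mask: np.ndarray | None = None
    foreground: np.ndarray | None = None

    def qc_overlay(self) -> np.ndarray:
        """Label overlay for visual QC: 1 = foreground, 2 = skeleton, 3 = soma."""
        if self.soma_label_image is None or self.skeleton_mask is None:
            raise ValueError("measurement was run without keep_masks=True")
        overlay = (self.foreground.astype(np.uint8)
                   + self.skeleton_mask.astype(np.uint8))
        overlay[self.soma_label_image > 0] = 3
        return overlay


def measure_field(image: FieldImage, config: PipelineConfig = PipelineConfig(),
                  region: str | None = None, keep_masks: bool = False,
                  ) -> FieldMeasurement:
    """Measure one field: detect somata, trace processes, compute morphology.

    The audit log records how many objects were seen and filtered at each
    stage so the density denominator is reproducible from the log alone.
    """
    work = image
    if config.smooth_sigma_px > 0:
        work = FieldImage(gaussian_filter(image.pixels, config.smooth_sigma_px),
                          image.pixel_size, image.channel)
    if config.threshold_mode == "auto":
        thresholds = seg.auto_thresholds(work)
    else:
        thresholds = seg.compute_thresholds(
            work, config.soma_quantile, config.background_quantile)
    detections = seg.detect_somata(work, thresholds, config.min_size_px)
    mask = seg.clean_mask(
        seg.foreground_mask(work, thresholds),
        min_object_px=config.clean_min_object_px,
        max_hole_px=config.clean_max_hole_px,
        opening=config.clean_opening)
    cells = morpho.measure_cells(
        mask, detections, image.pixel_size,
        prune_len_um=config.prune_len_um, radius_from=config.radius_from)

    n_border = sum(c.touches_border for c in cells)
    n_density = len(cells) if config.include_border_in_density \
        else len(cells) - n_border
    summary = morpho.FieldSummary(
        region_label=region or "", n_cells=n_density,
        field_area_mm2=image.field_area_mm2)
    log = {
        "detected_somata": len(cells),
        "border_flagged": n_border,
        "ambiguity_flagged": sum(c.ambiguous for c in cells),
        "process_free": sum(c.process_free for c in cells),
        "counted_for_density": n_density,
        "t_bg": thresholds.t_bg,
        "t_soma": thresholds.t_soma,
        "prune_len_um": config.prune_len_um,
    }
    fm = FieldMeasurement(cells, summary, thresholds, log)
    if keep_masks:
        soma_labels = np.zeros(mask.shape, dtype=np.int32)
        for det in detections:
            soma_labels[det.slices][det.mask] = det.label
        from skimage.morphology import skeletonize
        fm.soma_label_image = soma_labels
        fm.skeleton_mask = skeletonize(mask | (soma_labels > 0))
        fm.foreground = mask
    return fm


def cells_to_frame(measurement: FieldMeasurement, image_name: str = "",
                   ) -> pd.DataFrame:
    """Per-cell table with one row per retained cell and all eight parameters."""
    rows = []
    for c in measurement.cells:
        rows.append({
            "image": image_name,
            "cell_label": c.cell_label,
            "soma_x_um": c.centroid_um[0],
            "soma_y_um": c.centroid_um[1],
            "n_primary_branches": c.n_primary_branches,
            "n_branch_points": c.n_branch_points,
            "total_branch_length_um": c.total_branch_length_um,
            "cell_radius_um": c.cell_radius_um,
            "cell_area_um2": c.cell_area_um2,
            "soma_area_um2": c.soma_area_um2,
            "soma_eccentricity": c.soma_eccentricity,
            "process_free": c.process_free,
            "ambiguous": c.ambiguous,
            "touches_border": c.touches_border,
        })
    cols = ["image", "cell_label", "soma_x_um", "soma_y_um", *CELL_PARAMETERS,
            "process_free", "ambiguous", "touches_border"]
    return pd.DataFrame(rows, columns=cols)


def aggregate_per_animal(cells: pd.DataFrame, fields: pd.DataFrame,
                         config: PipelineConfig = PipelineConfig(),
                         ) -> pd.DataFrame:
    """Per-animal parameter means (the animal is the statistical unit).

    ``cells`` needs ``animal_id``, ``genotype``, ``region`` annotations plus
    the per-cell parameters; ``fields`` needs the same annotations plus
    ``density_cells_per_mm2``.  Border-touching cells are dropped from the
    morphology means when the config says so (they always keep their place in
    the density).  Returns long format: animal_id, genotype, region,
    parameter, value.
    """
    for col in ("animal_id", "genotype", "region"):
        if col not in cells.columns or col not in fields.columns:
            raise ValueError(f"missing annotation column {col!r}")
    morph = cells
    if config.exclude_border_from_morphology and "touches_border" in cells:
        morph = cells[~cells["touches_border"].astype(bool)]
    long = (morph.groupby(["animal_id", "genotype", "region"])[CELL_PARAMETERS]
            .mean().reset_index()
            .melt(id_vars=["animal_id", "genotype", "region"],
                  var_name="parameter", value_name="value"))
    dens = (fields.groupby(["animal_id", "genotype", "region"])
            ["density_cells_per_mm2"].mean().reset_index()
            .rename(columns={"density_cells_per_mm2": "value"}))
    dens["parameter"] = DENSITY_PARAMETER
    return pd.concat([long, dens], ignore_index=True)[
        ["animal_id", "genotype", "region", "parameter", "value"]]


def compare_groups(per_animal: pd.DataFrame,
                   config: PipelineConfig = PipelineConfig(),
                   wt_label: str = "WT") -> pd.DataFrame:
    """Normality-gated WT-vs-mutant comparison for every region x parameter.

    Produces the published table layout: mean +/- SEM per genotype, the test
    used, the two-tailed p and significance stars (* p < 0.05, ** p < 0.01).
    A parameter observed in only one genotype is an error.  No correction for
    testing multiple parameters is applied, matching the reconstructed
    protocol; treat the family-wise error accordingly.
    """
    genotypes = set(per_animal["genotype"].unique())
    if wt_label not in genotypes or len(genotypes) != 2:
        raise ValueError(
            f"need exactly two genotypes including {wt_label!r}, got {sorted(genotypes)}")
    (mut_label,) = genotypes - {wt_label}
    rows = []
    for (region, parameter), grp in per_animal.groupby(["region", "parameter"],
                                                       sort=True):
        wt_vals = grp.loc[grp["genotype"] == wt_label, "value"].to_numpy()
        mut_vals = grp.loc[grp["genotype"] == mut_label, "value"].to_numpy()
        if wt_vals.size == 0 or mut_vals.size == 0:
            raise ValueError(
                f"parameter {parameter!r} in region {region!r} is present in "
                "only one genotype")
        wt = GroupSample(wt_label, parameter, tuple(wt_vals))
        mut = GroupSample(mut_label, parameter, tuple(mut_vals))
        res = compare_parameter(wt, mut, alpha=config.alpha,
                                normality_alpha=config.normality_alpha)
        stat, p, used = res.statistic, res.p_two_tailed, res.test_used
        if config.use_welch and used == "student_t":
            w = welch_t_two_sample(wt_vals, mut_vals)
            stat, p, used = w.statistic, w.pvalue, "welch_t"
        rows.append({
            "region": region, "parameter": parameter,
            "wt_mean": wt_vals.mean(),
            "wt_sem": wt_vals.std(ddof=1) / np.sqrt(wt_vals.size),
            "n_wt": wt_vals.size,
            "mut_mean": mut_vals.mean(),
            "mut_sem": mut_vals.std(ddof=1) / np.sqrt(mut_vals.size),
            "n_mut": mut_vals.size,
            "test_used": used, "statistic": stat, "p_two_tailed": p,
            "significance": significance_stars(p),
        })
    return pd.DataFrame(rows)
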