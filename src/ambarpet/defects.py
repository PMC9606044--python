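"""Per-patient metabolic defect maps and their longitudinal classification.

A patient scan is compared voxel-by-voxel to the normative template: the
Z-score is (patient − template mean) / template SD. A voxel at least two
template SDs below the mean counts as a metabolic defect; defects are graded
into severity codes by SD steps. Voxels that fall outside the patient's own
gray-matter-probability mask are excluded — a low-uptake voxel explained by
tissue loss (atrophy, ventricular dilation) must not be read as
hypometabolism.

Between two visits each in-mask voxel is classified as improved, maintained
or worsened from its defect status and Z-score change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Volume
from .template import NormalTemplate

__all__ = [
    "DefectMap",
    "LongitudinalClassification",
    "compute_zmap",
    "build_correction_mask",
    "classify_defects",
    "baseline_group_pattern",
    "classify_longitudinal",
    "CLASS_OUTSIDE",
    "CLASS_IMPROVED",
    "CLASS_MAINTAINED",
    "CLASS_WORSENED",
]

log = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_SEVERITY_BINS = (-2.0, -3.0, -4.0)
DEFAULT_DELTA_THRESHOLD = 0.5

# longitudinal class codes (uint8 on disk)
CLASS_OUTSIDE = 0
CLASS_IMPROVED = 1
CLASS_MAINTAINED = 2
CLASS_WORSENED = 3


@dataclass(frozen=True)
class DefectMap:
    """Z-scores, defect mask and severity codes for one (subject, visit)."""

    z: Volume
    defect: np.ndarray
    severity: np.ndarray
    correction_mask: np.ndarray
    visit: str = ""
    z_threshold: float = DEFAULT_Z_THRESHOLD
    severity_bins: tuple[float, ...] = DEFAULT_SEVERITY_BINS


@dataclass(frozen=True)
class LongitudinalClassification:
    """Voxel-wise improved/maintained/worsened classes between two visits.

    ``n_rule_conflicts`` counts voxels where the defect-status rule and the
    Z-change rule pointed in opposite directions (status change wins).
    """

    classes: np.ndarray
    from_visit: str
    to_visit: str
    delta_threshold: float
    n_rule_conflicts: int = 0

    def fraction(self, code: int) -> float:
        """Fraction of in-mask voxels with the given class code."""
        inside = self.classes != CLASS_OUTSIDE
        n = int(inside.sum())
        if n == 0:
            return float("nan")
        return float((self.classes[inside] == code).mean())


def compute_zmap(patient_scan: Volume, template: NormalTemplate) -> Volume:
    """Voxel-wise Z-score of a preprocessed patient scan against the template.

    Z = (patient − mean) / sd inside the template brain mask; 0 outside.
    """
    template.mean.assert_compatible(patient_scan)
    brain = template.brain_mask
    z = np.zeros(patient_scan.shape, dtype=np.float64)
    z[brain] = (patient_scan.data[brain] - template.mean.data[brain]) / template.sd.data[brain]
    return patient_scan.like(z)


def build_correction_mask(gm_probability: Volume, threshold: float = 0.5) -> np.ndarray:
    """Atrophy-correction mask: gray-matter probability ≥ threshold.

    The ≥ convention keeps a voxel exactly at the threshold in the mask.
    """
    p = gm_probability.data
    if p.min() < 0 or p.max() > 1:
        raise ValueError(
            f"gray-matter probabilities must lie in [0,1], got range [{p.min():g}, {p.max():g}]"
        )
    if not 0 < threshold <= 1:
        raise ValueError(f"gm threshold must be in (0,1], got {threshold}")
    return p >= threshold


def classify_defects(
    z: Volume,
    correction_mask: np.ndarray,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    severity_bins: Sequence[float] = DEFAULT_SEVERITY_BINS,
    visit: str = "",
) -> DefectMap:
    """Threshold a Z-map into a defect mask and graded severity codes.

    A voxel is a defect when its Z-score is at least ``z_threshold`` SDs
    below the template mean (z ≤ −z_threshold; the boundary is included) and
    it lies inside the atrophy-correction mask. Severity code s means the
    voxel sits at or below the s-th cut-point: with the default bins
    (−2, −3, −4), z in (−3, −2] → 1, (−4, −3] → 2, z ≤ −4 → 3.
    """
    bins = tuple(float(b) for b in severity_bins)
    if len(bins) == 0:
        raise ValueError("severity_bins must be nonempty")
    if abs(bins[0] - (-z_threshold)) > 1e-12:
        raise ValueError(
            f"severity_bins must start at -z_threshold = {-z_threshold}, got {bins[0]}"
        )
    if any(b2 >= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError(f"severity_bins must be strictly decreasing, got {bins}")
    if correction_mask.shape != z.shape:
        raise ValueError("correction mask grid does not match Z-map grid")
    mask = correction_mask.astype(bool)
    zd = z.data
    severity = np.zeros(z.shape, dtype=np.uint8)
    for cut in bins:
        severity += (zd <= cut).astype(np.uint8)
    severity[~mask] = 0
    defect = (zd <= -z_threshold) & mask
    return DefectMap(
        z=z,
        defect=defect,
        severity=severity,
        correction_mask=mask,
        visit=visit,
        z_threshold=float(z_threshold),
        severity_bins=bins,
    )


def baseline_group_pattern(defect_maps: Sequence[DefectMap]) -> Volume:
    """Group defect pattern: voxel-wise mean of individual severity maps.

    Voxels outside a subject's correction mask contribute 0 for that
    subject, so the pattern is a plain arithmetic mean over subjects.
    """
    if len(defect_maps) == 0:
        raise ValueError("need at least one defect map")
    first = defect_maps[0].z
    acc = np.zeros(first.shape, dtype=np.float64)
    for m in defect_maps:
        first.assert_compatible(m.z)
        acc += m.severity.astype(np.float64)
    return first.like(acc / len(defect_maps))


def classify_longitudinal(
    map_t0: DefectMap,
    map_t1: DefectMap,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    mask_policy: str = "both",
) -> LongitudinalClassification:
    """Classify each voxel as improved / maintained / worsened between visits.

    Rules (status change takes precedence over the Z-change rule):

    * improved — a defect at the first visit that is no longer a defect, or
      a Z-score increase of more than ``delta_threshold``;
    * worsened — a normal voxel that became a defect, or a Z-score that
      dropped by ``delta_threshold`` or more (boundary included);
    * maintained — everything else in-mask;
    * outside — excluded by the atrophy-correction mask (``mask_policy``:
      ``"both"`` excludes voxels outside either visit's mask, ``"later"`` /
      ``"earlier"`` use a single visit's mask).

    The improvement boundary is strict (Δz must exceed +``delta_threshold``)
    while the worsening boundary is inclusive (Δz ≤ −``delta_threshold``).
    """
    if delta_threshold <= 0:
        raise ValueError(f"delta_threshold must be positive, got {delta_threshold}")
    map_t0.z.assert_compatible(map_t1.z)
    if mask_policy == "both":
        inside = map_t0.correction_mask & map_t1.correction_mask
    elif mask_policy == "later":
        inside = map_t1.correction_mask
    elif mask_policy == "earlier":
        inside = map_t0.correction_mask
    else:
        raise ValueError(f"unknown mask_policy {mask_policy!r}")

    dz = map_t1.z.data - map_t0.z.data
    d0, d1 = map_t0.defect, map_t1.defect

    improved_status = d0 & ~d1
    worsened_status = ~d0 & d1
    improved_dz = dz > delta_threshold
    worsened_dz = dz <= -delta_threshold

    classes = np.full(map_t0.z.shape, CLASS_MAINTAINED, dtype=np.uint8)
    classes[improved_dz] = CLASS_IMPROVED
    classes[worsened_dz] = CLASS_WORSENED
    # defect-status transitions override the Z-change rule where they disagree
    classes[improved_status] = CLASS_IMPROVED
    classes[worsened_status] = CLASS_WORSENED
    conflicts = int(
        (((improved_status & worsened_dz) | (worsened_status & improved_dz)) & inside).sum()
    )
    if conflicts:
        log.info("longitudinal classification: %d status/Z-change rule conflicts", conflicts)
    classes[~inside] = CLASS_OUTSIDE
    return LongitudinalClassification(
        classes=classes,
        from_visit=map_t0.visit,
        to_visit=map_t1.visit,
        delta_threshold=float(delta_threshold),
        n_rule_conflicts=conflicts,
    )
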