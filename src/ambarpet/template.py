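"""Normative reference template: voxel-wise mean and SD of control scans.

Patient scans are later expressed as Z-scores against this template. The SD
image is floored so that a zero-variance voxel can never produce an infinite
Z; the default floor is 1% of the in-brain mean signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import Volume, read_volume, write_volume

__all__ = ["NormalTemplate", "build_template", "save_template", "load_template"]


@dataclass(frozen=True)
class NormalTemplate:
    """Voxel-wise mean/SD reference built from healthy-control scans."""

    mean: Volume
    sd: Volume
    n_controls: int
    fwhm_mm: float
    sd_floor: float

    @property
    def brain_mask(self) -> np.ndarray:
        """Voxels inside the reference brain (mean signal > 0)."""
        return self.mean.data > 0


def build_template(
    controls: Sequence[Volume],
    fwhm_mm: float = 8.0,
    sd_floor: float | None = None,
) -> NormalTemplate:
    """Voxel-wise mean and sample SD (n−1) over preprocessed control scans.

    Controls must already be cerebellum-normalised and smoothed; the template
    stage does not re-check that numerically. ``sd_floor=None`` uses 1% of
    the in-brain mean of the mean image. The floor is applied everywhere
    inside the brain mask (mean > 0).
    """
    if len(controls) < 2:
        raise ValueError(f"need at least 2 controls to estimate a voxel-wise SD, got {len(controls)}")
    first = controls[0]
    for c in controls[1:]:
        first.assert_compatible(c)
    stack = np.stack([c.data for c in controls], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    brain = mean > 0
    if sd_floor is None:
        in_brain_mean = float(mean[brain].mean()) if brain.any() else 1.0
        sd_floor = 0.01 * in_brain_mean
    if sd_floor <= 0:
        raise ValueError(f"sd_floor must be positive, got {sd_floor}")
    sd = np.where(brain, np.maximum(sd, sd_floor), sd)
    return NormalTemplate(
        mean=first.like(mean),
        sd=first.like(sd),
        n_controls=len(controls),
        fwhm_mm=float(fwhm_mm),
        sd_floor=float(sd_floor),
    )


def save_template(template: NormalTemplate, out_dir: str | Path) -> Path:
    """Persist as two NIfTI volumes plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(template.mean, out_dir / "template_mean.nii.gz")
    write_volume(template.sd, out_dir / "template_sd.nii.gz")
    sidecar = {
        "n_controls": template.n_controls,
        "fwhm_mm": template.fwhm_mm,
        "sd_floor": template.sd_floor,
    }
    (out_dir / "template.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def load_template(out_dir: str | Path) -> NormalTemplate:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "template.json").read_text())
    return NormalTemplate(
        mean=read_volume(out_dir / "template_mean.nii.gz"),
        sd=read_volume(out_dir / "template_sd.nii.gz"),
        n_controls=int(meta["n_controls"]),
        fwhm_mm=float(meta["fwhm_mm"]),
        sd_floor=float(meta["sd_floor"]),
    )
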