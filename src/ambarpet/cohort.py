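"""Synthetic longitudinal cohort: controls plus a four-arm patient series.

The cohort emulates the design of a plasma-exchange trial in Alzheimer's
disease: four treatment arms (placebo, low albumin, low albumin + IVIG,
high albumin + IVIG) crossed with two severity strata (mild, moderate),
imaged at months 0, 2, 6, 9 and 14, alongside an independent pool of healthy
controls for the normative template.

Ground truth — the decline fraction seeded into each subject's
disease-affected regions — is stored next to every record so downstream
recovery checks never need to re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AtlasParcellation, Volume, read_parcellation, read_volume, write_parcellation, write_volume
from .phantom import PhantomSpec, build_phantom
from .volumetry import SUBCORTICAL_STRUCTURES, TISSUE_CLASSES

__all__ = [
    "ArmSpec",
    "StratumSpec",
    "CohortSpec",
    "SubjectRecord",
    "DEFAULT_VISITS",
    "visit_months",
    "sample_control_scans",
    "sample_patient_series",
    "write_cohort",
    "load_cohort",
]

DEFAULT_VISITS = ("M0", "M2", "M6", "M9", "M14")

#: baseline structure volumes, mm³ (typical adult magnitudes)
BASELINE_STRUCTURE_MM3: dict[str, float] = {
    "thalamus_l": 7000.0, "thalamus_r": 7000.0,
    "putamen_l": 5000.0, "putamen_r": 5000.0,
    "caudate_l": 3600.0, "caudate_r": 3600.0,
    "pallidum_l": 1800.0, "pallidum_r": 1800.0,
    "hippocampus_l": 3800.0, "hippocampus_r": 3800.0,
    "amygdala_l": 1500.0, "amygdala_r": 1500.0,
    "accumbens_l": 500.0, "accumbens_r": 500.0,
    "brainstem_4th_ventricle": 25000.0,
    "gm": 600000.0, "wm": 500000.0, "csf": 300000.0,
}

#: annual fractional volume change per structure (negative = loss)
DEFAULT_VOLUMETRY_DECLINE: dict[str, float] = {
    **{s: -0.010 for s in SUBCORTICAL_STRUCTURES},
    "hippocampus_l": -0.040, "hippocampus_r": -0.040,
    "amygdala_l": -0.030, "amygdala_r": -0.030,
    "accumbens_l": -0.030, "accumbens_r": -0.030,
    "gm": -0.010, "wm": -0.005, "csf": 0.020,
}


def visit_months(visit: str) -> float:
    """Months since baseline from a visit label like ``"M9"``."""
    if not visit.startswith("M"):
        raise ValueError(f"unknown visit label {visit!r}; expected 'M<months>'")
    try:
        return float(visit[1:])
    except ValueError as exc:
        raise ValueError(f"unknown visit label {visit!r}") from exc


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: its name, seeded decline and size.

    ``decline`` is the fraction of baseline uptake lost in the
    disease-affected regions over the full study span (severity multiplier
    1); subjects are split evenly over the severity strata.
    """

    name: str
    decline: float
    n_subjects: int = 16

    def __post_init__(self) -> None:
        if not 0 <= self.decline < 1:
            raise ValueError(f"decline fraction must be in [0,1), got {self.decline}")
        if self.n_subjects < 2:
            raise ValueError(f"arm {self.name!r} needs ≥2 subjects, got {self.n_subjects}")


@dataclass(frozen=True)
class StratumSpec:
    """Severity stratum: decline multiplier and pre-existing defect offset.

    The offset is the fraction of uptake already lost in disease regions at
    baseline (moderate patients start with deeper, more extensive defects).
    """

    multiplier: float
    baseline_defect_offset: float

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("severity multiplier must be nonnegative")
        if not 0 <= self.baseline_defect_offset < 1:
            raise ValueError("baseline defect offset must be in [0,1)")


def _default_arms() -> tuple[ArmSpec, ...]:
    # study-span decline ordered like the observed in-mask losses:
    # placebo worst, high albumin + IVIG best
    return (
        ArmSpec("placebo", 0.060),
        ArmSpec("low_albumin", 0.045),
        ArmSpec("low_albumin_ivig", 0.050),
        ArmSpec("high_albumin_ivig", 0.020),
    )


def _default_strata() -> dict[str, StratumSpec]:
    return {
        "mild": StratumSpec(multiplier=1.0, baseline_defect_offset=0.10),
        "moderate": StratumSpec(multiplier=1.6, baseline_defect_offset=0.16),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Design of the synthetic longitudinal cohort."""

    arms: tuple[ArmSpec, ...] = field(default_factory=_default_arms)
    severity_strata: dict[str, StratumSpec] = field(default_factory=_default_strata)
    visits: tuple[str, ...] = DEFAULT_VISITS
    atrophy_rate: float = 0.08
    volumetry_decline: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VOLUMETRY_DECLINE))
    volumetry_noise_frac: float = 0.02
    n_controls: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("cohort needs at least one arm")
        if not self.visits or self.visits[0] != "M0":
            raise ValueError(f"visits must start at M0, got {self.visits}")
        months = [visit_months(v) for v in self.visits]
        if sorted(months) != list(months):
            raise ValueError("visits must be in chronological order")
        if not 0 <= self.atrophy_rate < 1:
            raise ValueError("atrophy_rate must be in [0,1)")
        if self.n_controls < 2:
            raise ValueError("need ≥2 controls")

    @property
    def span_months(self) -> float:
        return visit_months(self.visits[-1])

    def progress(self, visit: str) -> float:
        """Linear visit progress: 0 at baseline, 1 at the final visit."""
        return visit_months(visit) / self.span_months


@dataclass
class SubjectRecord:
    """One synthetic patient: all visits plus the seeded ground truth."""

    subject_id: str
    arm: str
    stratum: str
    scans: dict[str, Volume]
    gm_maps: dict[str, Volume]
    volumetry: pd.DataFrame  # one row per visit
    true_decline: float  # AD-region fractional loss over the study span
    severity_multiplier: float
    baseline_defect_offset: float


def sample_control_scans(
    phantom_uptake: Volume,
    n_controls: int,
    noise_sd: float,
    seed: int,
) -> list[Volume]:
    """Healthy-control scans: phantom uptake plus i.i.d. Gaussian noise.

    Noise is added on in-brain voxels only; the background stays exactly
    zero. ``noise_sd=0`` reproduces the noise-free phantom.
    """
    if n_controls < 2:
        raise ValueError(f"need ≥2 controls, got {n_controls}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    brain = phantom_uptake.data > 0
    out = []
    for _ in range(n_controls):
        data = phantom_uptake.data.copy()
        data[brain] += rng.normal(0.0, noise_sd, size=int(brain.sum()))
        out.append(phantom_uptake.like(data))
    return out


def _volumetry_row(
    rng: np.random.Generator,
    baseline: dict[str, float],
    decline: dict[str, float],
    months: float,
    noise_frac: float,
) -> dict[str, float]:
    row = {}
    for s in SUBCORTICAL_STRUCTURES + TISSUE_CLASSES:
        base = baseline[s]
        rate = decline.get(s, 0.0)
        true = base * (1.0 + rate * months / 12.0)
        noisy = true + rng.normal(0.0, noise_frac * base)
        row[s] = max(noisy, 1e-6)
    return row


def sample_patient_series(
    phantom_spec: PhantomSpec,
    cohort: CohortSpec,
    phantom: tuple[AtlasParcellation, Volume, Volume] | None = None,
) -> tuple[list[SubjectRecord], AtlasParcellation]:
    """Generate the full longitudinal patient series.

    Per subject and visit the PET scan is the phantom uptake with
    disease-region uptake multiplied by
    ``(1 − offset) × (1 − decline × progress × multiplier)`` before additive
    Gaussian noise; the GM probability map is the phantom's scaled by
    ``(1 − atrophy_rate × progress)``; the volumetry row follows each
    structure's annual fractional change plus noise.
    """
    if phantom is None:
        phantom = build_phantom(phantom_spec)
    atlas, uptake, gm = phantom
    rng = np.random.default_rng(np.random.SeedSequence([cohort.seed, 917]))
    ad_mask = atlas.region_mask(phantom_spec.ad_region_ids)
    brain = uptake.data > 0
    n_brain = int(brain.sum())

    records: list[SubjectRecord] = []
    strata = list(cohort.severity_strata.items())
    for arm in cohort.arms:
        for i in range(arm.n_subjects):
            stratum_name, stratum = strata[i % len(strata)]
            sid = f"{arm.name}_{stratum_name}_{i:03d}"
            # per-subject baseline volumetry with mild anatomical variation
            baseline = {
                k: v * float(rng.uniform(0.93, 1.07)) for k, v in BASELINE_STRUCTURE_MM3.items()
            }
            subj_base = uptake.data.copy()
            subj_base[ad_mask] *= 1.0 - stratum.baseline_defect_offset
            scans: dict[str, Volume] = {}
            gms: dict[str, Volume] = {}
            vrows = []
            for visit in cohort.visits:
                prog = cohort.progress(visit)
                data = subj_base.copy()
                factor = 1.0 - arm.decline * prog * stratum.multiplier
                data[ad_mask] *= factor
                data[brain] += rng.normal(0.0, phantom_spec.noise_sd, size=n_brain)
                scans[visit] = uptake.like(data)
                gms[visit] = gm.like(gm.data * (1.0 - cohort.atrophy_rate * prog))
                row = _volumetry_row(
                    rng, baseline, cohort.volumetry_decline,
                    visit_months(visit), cohort.volumetry_noise_frac,
                )
                row.update({"subject": sid, "arm": arm.name, "stratum": stratum_name, "visit": visit})
                vrows.append(row)
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    arm=arm.name,
                    stratum=stratum_name,
                    scans=scans,
                    gm_maps=gms,
                    volumetry=pd.DataFrame(vrows),
                    true_decline=arm.decline * stratum.multiplier,
                    severity_multiplier=stratum.multiplier,
                    baseline_defect_offset=stratum.baseline_defect_offset,
                )
            )
    return records, atlas


def ground_truth_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Seeded per-subject truth, persisted so checks never re-derive it."""
    return pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "arm": [r.arm for r in records],
            "stratum": [r.stratum for r in records],
            "true_decline": [r.true_decline for r in records],
            "severity_multiplier": [r.severity_multiplier for r in records],
            "baseline_defect_offset": [r.baseline_defect_offset for r in records],
        }
    )


def write_cohort(
    records: list[SubjectRecord],
    atlas: AtlasParcellation,
    controls: list[Volume],
    out_dir: str | Path,
) -> Path:
    """Persist cohort to disk: NIfTI volumes, CSV tables, manifest."""
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    (out / "controls").mkdir(exist_ok=True)
    write_parcellation(atlas, out / "atlas.nii.gz", out / "regions.csv")
    for i, c in enumerate(controls):
        write_volume(c, out / "controls" / f"control_{i:03d}.nii.gz")
    manifest_rows = []
    volumetry = []
    for r in records:
        for visit in r.scans:
            pet = out / "scans" / f"{r.subject_id}_{visit}_pet.nii.gz"
            gmp = out / "scans" / f"{r.subject_id}_{visit}_gm.nii.gz"
            write_volume(r.scans[visit], pet)
            write_volume(r.gm_maps[visit], gmp)
            manifest_rows.append(
                {
                    "subject": r.subject_id, "arm": r.arm, "stratum": r.stratum,
                    "visit": visit, "pet_path": str(pet.relative_to(out)),
                    "gm_path": str(gmp.relative_to(out)),
                }
            )
        volumetry.append(r.volumetry)
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    pd.concat(volumetry, ignore_index=True).to_csv(out / "volumetry.csv", index=False)
    ground_truth_table(records).to_csv(out / "ground_truth.csv", index=False)
    return out


def load_cohort(cohort_dir: str | Path) -> tuple[list[SubjectRecord], AtlasParcellation, list[Volume]]:
    """Read back a cohort written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    atlas = read_parcellation(d / "atlas.nii.gz", d / "regions.csv")
    controls = [read_volume(p) for p in sorted((d / "controls").glob("control_*.nii.gz"))]
    manifest = pd.read_csv(d / "manifest.csv")
    volumetry = pd.read_csv(d / "volumetry.csv")
    truth = pd.read_csv(d / "ground_truth.csv").set_index("subject")
    records = []
    for sid, grp in manifest.groupby("subject", sort=True):
        scans, gms = {}, {}
        for _, row in grp.iterrows():
            scans[row["visit"]] = read_volume(d / row["pet_path"])
            gms[row["visit"]] = read_volume(d / row["gm_path"])
        t = truth.loc[sid]
        records.append(
            SubjectRecord(
                subject_id=sid,
                arm=grp["arm"].iloc[0],
                stratum=grp["stratum"].iloc[0],
                scans=scans,
                gm_maps=gms,
                volumetry=volumetry[volumetry["subject"] == sid].reset_index(drop=True),
                true_decline=float(t["true_decline"]),
                severity_multiplier=float(t["severity_multiplier"]),
                baseline_defect_offset=float(t["baseline_defect_offset"]),
            )
        )
    return records, atlas, controls
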