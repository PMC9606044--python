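"""Atlas-regional metrics and their statistics.

For each atlas region three parameters are extracted inside the patient's
atrophy-correction mask:

1. metabolism intensity — mean normalised uptake,
2. defect extension — percentage of in-mask voxels flagged as defect,
3. defect intensity — mean severity code over in-mask voxels.

Longitudinal change is assessed per region with a two-sided paired t-test on
per-subject change scores, cross-sectional group differences with a one-way
ANOVA. Counts of significant regions are reported raw (no multiple-testing
correction across regions — a deliberate faithfulness choice; an optional
Benjamini–Hochberg flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AtlasParcellation, Volume
from .defects import DefectMap

__all__ = [
    "extract_regional_metrics",
    "longitudinal_region_tests",
    "cross_sectional_group_tests",
    "RegionalChangeSummary",
    "percentage_of_regions",
]

PARAMETERS = ("metabolism_intensity", "defect_extension", "defect_intensity")


@dataclass(frozen=True)
class RegionalChangeSummary:
    """Count and percentage of regions with a significant longitudinal change."""

    parameter: str
    n_significant: int
    total_regions: int
    significant_region_ids: tuple[int, ...]
    p_values: pd.Series
    alpha: float

    @property
    def pct_of_regions(self) -> float:
        return percentage_of_regions(self.n_significant, self.total_regions)


def percentage_of_regions(n_significant: int, total: int) -> float:
    """Exact count→percentage arithmetic, rounded to one decimal.

    E.g. 21 of 116 regions → 18.1; 9 of 15 structures → 60.0.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n_significant / total, 1)


def extract_regional_metrics(
    defect_map: DefectMap,
    scan: Volume,
    atlas: AtlasParcellation,
    subject_id: str = "",
    visit: str = "",
) -> pd.DataFrame:
    """Three regional parameters over region ∩ correction-mask voxels.

    ``scan`` must be the normalised+smoothed scan matching the defect map's
    visit. A region with zero in-mask voxels carries NaN for all three
    parameters (never a silent 0).

    Returns a tidy frame with columns ``subject, visit, region_id,
    metabolism_intensity, defect_extension, defect_intensity, n_voxels``.
    """
    atlas.assert_compatible(scan)
    scan.assert_compatible(defect_map.z)
    labels = atlas.labels
    mask = defect_map.correction_mask
    rows = []
    for rid in atlas.region_ids:
        sel = (labels == rid) & mask
        n = int(sel.sum())
        if n == 0:
            rows.append((subject_id, visit, rid, np.nan, np.nan, np.nan, 0))
            continue
        intensity = float(scan.data[sel].mean())
        extension = 100.0 * float(defect_map.defect[sel].mean())
        dint = float(defect_map.severity[sel].mean())
        rows.append((subject_id, visit, rid, intensity, extension, dint, n))
    return pd.DataFrame(
        rows,
        columns=["subject", "visit", "region_id", *PARAMETERS, "n_voxels"],
    )


def _paired_frame(
    metrics_t0: pd.DataFrame, metrics_t1: pd.DataFrame, parameter: str
) -> pd.DataFrame:
    """Per-subject change scores, wide by region."""
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
    a = metrics_t0.pivot(index="subject", columns="region_id", values=parameter)
    b = metrics_t1.pivot(index="subject", columns="region_id", values=parameter)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"need ≥3 paired subjects for a t-test, got {len(common)}")
    return b.loc[common] - a.loc[common]


def longitudinal_region_tests(
    metrics_t0: pd.DataFrame,
    metrics_t1: pd.DataFrame,
    parameter: str,
    alpha: float = 0.05,
    fdr: bool = False,
) -> RegionalChangeSummary:
    """Two-sided paired t-test of a regional parameter between two visits.

    Subjects are paired by id; per region the test is on the per-subject
    change scores (later − earlier). Regions where every subject has zero
    change (or missing values leave <3 pairs) get p = 1. ``fdr=True``
    applies Benjamini–Hochberg before counting (off by default).
    """
    diff = _paired_frame(metrics_t0, metrics_t1, parameter)
    pvals = {}
    for rid in diff.columns:
        d = diff[rid].dropna().to_numpy()
        if len(d) < 3 or np.allclose(d.std(ddof=1), 0):
            pvals[int(rid)] = 1.0 if (len(d) < 3 or np.allclose(d, 0)) else 0.0
            continue
        pvals[int(rid)] = float(stats.ttest_rel(d, np.zeros_like(d)).pvalue)
    p = pd.Series(pvals).sort_index()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        reject = multipletests(p.to_numpy(), alpha=alpha, method="fdr_bh")[0]
        sig = tuple(int(r) for r in p.index[reject])
    else:
        sig = tuple(int(r) for r in p.index[p < alpha])
    return RegionalChangeSummary(
        parameter=parameter,
        n_significant=len(sig),
        total_regions=len(p),
        significant_region_ids=sig,
        p_values=p,
        alpha=alpha,
    )


def cross_sectional_group_tests(
    metrics_by_arm: dict[str, pd.DataFrame],
    parameter: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across arms per region at a single visit.

    ``metrics_by_arm`` maps arm name → tidy regional-metrics frame (one row
    per subject × region). Returns a frame with columns ``region_id, F, p,
    significant``.
    """
    if len(metrics_by_arm) < 2:
        raise ValueError("need at least two arms for a between-group ANOVA")
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    wide = {
        arm: df.pivot(index="subject", columns="region_id", values=parameter)
        for arm, df in metrics_by_arm.items()
    }
    for arm, w in wide.items():
        if len(w) < 2:
            raise ValueError(f"arm {arm!r} has fewer than 2 subjects")
    region_ids = sorted(set.intersection(*(set(w.columns) for w in wide.values())))
    rows = []
    for rid in region_ids:
        groups = [w[rid].dropna().to_numpy() for w in wide.values()]
        if any(len(g) < 2 for g in groups):
            rows.append((int(rid), np.nan, np.nan, False))
            continue
        if all(np.allclose(g, groups[0].mean()) for g in groups):
            rows.append((int(rid), 0.0, 1.0, False))
            continue
        f, p = stats.f_oneway(*groups)
        rows.append((int(rid), float(f), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["region_id", "F", "p", "significant"])
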