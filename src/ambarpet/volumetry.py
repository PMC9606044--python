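"""Longitudinal summaries of precomputed brain-structure volumes.

Segmentation itself is upstream; this module consumes tables of structure
volumes per (subject, visit): the 15 subcortical entries (left/right
thalamus, putamen, caudate, pallidum, hippocampus, amygdala, accumbens, plus
brainstem with the fourth ventricle) and total gray matter, white matter and
CSF. Total intracranial volume (TIV) is always derived as GM+WM+CSF, never
stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .regional import percentage_of_regions

__all__ = [
    "SUBCORTICAL_STRUCTURES",
    "TISSUE_CLASSES",
    "derive_tiv_fractions",
    "structure_change_tests",
    "cross_sectional_structure_anova",
]

_BILATERAL = ("thalamus", "putamen", "caudate", "pallidum", "hippocampus", "amygdala", "accumbens")
SUBCORTICAL_STRUCTURES: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _BILATERAL for side in ("l", "r")
) + ("brainstem_4th_ventricle",)
TISSUE_CLASSES: tuple[str, ...] = ("gm", "wm", "csf")


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in SUBCORTICAL_STRUCTURES + TISSUE_CLASSES if c not in records.columns]
    if missing:
        raise ValueError(f"volumetry table missing structure columns: {missing}")


def derive_tiv_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Append TIV and tissue fractions to a volumetry table.

    TIV = GM + WM + CSF (mm³); fractions are each class over TIV and sum to
    1 to machine precision. Any non-positive volume is an error.
    """
    _check_columns(records)
    vols = records[list(SUBCORTICAL_STRUCTURES + TISSUE_CLASSES)]
    if (vols <= 0).any().any():
        bad = vols.columns[(vols <= 0).any()].tolist()
        raise ValueError(f"non-positive volumes in columns: {bad}")
    out = records.copy()
    out["tiv"] = out["gm"] + out["wm"] + out["csf"]
    for t in TISSUE_CLASSES:
        out[f"{t}_fraction"] = out[t] / out["tiv"]
    return out


def structure_change_tests(
    records_t0: pd.DataFrame,
    records_t1: pd.DataFrame,
    alpha: float = 0.05,
    structures: tuple[str, ...] = SUBCORTICAL_STRUCTURES,
    tiv_normalized: bool = False,
) -> dict:
    """Per-structure two-sided paired t-test between two visits.

    Tables must carry a ``subject`` column; subjects are paired by id.
    Returns a dict with the significant-structure list, the count, the
    percentage over the structure set, and the per-structure p-values. No
    correction across the 15 structures (reported raw); set
    ``tiv_normalized=True`` to test volumes divided by each record's TIV.
    """
    _check_columns(records_t0)
    _check_columns(records_t1)
    a = records_t0.set_index("subject")
    b = records_t1.set_index("subject")
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"need ≥3 paired subjects, got {len(common)}")
    a, b = a.loc[common], b.loc[common]
    if tiv_normalized:
        a = derive_tiv_fractions(a.reset_index()).set_index("subject")
        b = derive_tiv_fractions(b.reset_index()).set_index("subject")

    pvals = {}
    for s in structures:
        x0 = a[s].to_numpy(dtype=float)
        x1 = b[s].to_numpy(dtype=float)
        if tiv_normalized:
            x0 = x0 / a["tiv"].to_numpy(dtype=float)
            x1 = x1 / b["tiv"].to_numpy(dtype=float)
        d = x1 - x0
        if np.allclose(d, 0):
            pvals[s] = 1.0
        else:
            pvals[s] = float(stats.ttest_rel(x1, x0).pvalue)
    p = pd.Series(pvals)
    significant = [s for s in structures if p[s] < alpha]
    return {
        "significant": significant,
        "n_significant": len(significant),
        "total": len(structures),
        "pct": percentage_of_regions(len(significant), len(structures)),
        "p_values": p,
        "alpha": alpha,
        "n_pairs": int(len(common)),
    }


def cross_sectional_structure_anova(
    records_by_arm: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    structures: tuple[str, ...] = SUBCORTICAL_STRUCTURES,
) -> pd.DataFrame:
    """One-way ANOVA of each structure volume across arms at a fixed visit."""
    if len(records_by_arm) < 2:
        raise ValueError("need at least two arms")
    rows = []
    for s in structures:
        groups = [df[s].to_numpy(dtype=float) for df in records_by_arm.values()]
        if any(len(g) < 2 for g in groups):
            raise ValueError("each arm needs ≥2 subjects")
        f, p = stats.f_oneway(*groups)
        rows.append((s, float(f), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["structure", "F", "p", "significant"])
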