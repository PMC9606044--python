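"""Voxel-wise paired t contrasts, cluster-extent thresholding, and MaskAD.

The group-level machinery: a paired t-test at every voxel between two visits
of one arm, thresholded at an uncorrected voxel-wise p and a minimum cluster
extent k. The surviving clusters of the placebo arm's baseline→final decline
contrast define the AD-progression mask (MaskAD); mean uptake inside MaskAD
then summarises each arm's percent metabolic loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import Volume

__all__ = [
    "TContrastMap",
    "ClusterResult",
    "MaskAD",
    "paired_t_map",
    "cluster_threshold",
    "build_mask_ad",
    "mask_ad_percent_loss",
    "connectivity_structure",
]

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.001
DEFAULT_K_MIN = 50
DEFAULT_CONNECTIVITY = 18


@dataclass(frozen=True)
class TContrastMap:
    """Voxel-wise paired t statistics and one-sided uncorrected p-values."""

    t: Volume
    p: Volume
    df: int
    from_visit: str
    to_visit: str
    direction: str  # "decline" tests uptake(from) > uptake(to)


@dataclass(frozen=True)
class ClusterResult:
    """Suprathreshold voxels partitioned into connected clusters ≥ k_min."""

    mask: np.ndarray
    clusters: pd.DataFrame  # cluster_id, k_extent, peak_t, peak_i, peak_j, peak_k
    p_threshold: float
    k_min: int
    connectivity: int

    @property
    def total_k_extent(self) -> int:
        return int(self.clusters["k_extent"].sum())


@dataclass(frozen=True)
class MaskAD:
    """Union of surviving clusters of the placebo decline contrast."""

    mask: np.ndarray
    arm: str
    from_visit: str
    to_visit: str
    p_threshold: float
    k_min: int

    @property
    def k_extent(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D neighbourhood structure: 6 (faces), 18 (faces+edges), 26 (all)."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def paired_t_map(
    scans_t0: list[Volume],
    scans_t1: list[Volume],
    direction: str = "decline",
    from_visit: str = "M0",
    to_visit: str = "M14",
) -> TContrastMap:
    """Voxel-wise paired t-test between two visits of the same subjects.

    Scans must be ordered identically in both lists (pairing by position).
    With ``direction="decline"`` the one-sided p tests uptake(t0) >
    uptake(t1); ``"increase"`` tests the reverse. Voxels with zero variance
    across pairs get p = 1 (no evidence either way).
    """
    if len(scans_t0) != len(scans_t1):
        raise ValueError(
            f"unpaired inputs: {len(scans_t0)} scans at {from_visit} vs {len(scans_t1)} at {to_visit}"
        )
    n = len(scans_t0)
    if n < 3:
        raise ValueError(f"need ≥3 pairs for a paired t-test, got {n}")
    if direction not in ("decline", "increase"):
        raise ValueError(f"direction must be 'decline' or 'increase', got {direction!r}")
    first = scans_t0[0]
    for s in scans_t0[1:] + scans_t1:
        first.assert_compatible(s)
    diff = np.stack([b.data - a.data for a, b in zip(scans_t0, scans_t1)], axis=0)
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    dfree = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    tval[zero_var] = 0.0
    if direction == "decline":  # decline: mean diff (t1-t0) < 0
        p = stats.t.cdf(tval, dfree)
    else:
        p = stats.t.sf(tval, dfree)
    p[zero_var] = 1.0
    return TContrastMap(
        t=first.like(tval),
        p=first.like(p),
        df=dfree,
        from_visit=from_visit,
        to_visit=to_visit,
        direction=direction,
    )


def cluster_threshold(
    tmap: TContrastMap,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    k_min: int = DEFAULT_K_MIN,
    connectivity: int = DEFAULT_CONNECTIVITY,
    brain_mask: np.ndarray | None = None,
) -> ClusterResult:
    """Keep connected suprathreshold clusters of at least ``k_min`` voxels.

    Suprathreshold means one-sided p < ``p_threshold`` (strict). Components
    are found under the stated neighbourhood connectivity; smaller
    components are discarded entirely. ``brain_mask`` restricts the search
    to in-brain voxels — smoothing carries signal into the off-brain shell,
    which must not enter group statistics.
    """
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must be in (0,1), got {p_threshold}")
    if k_min < 1:
        raise ValueError(f"k_min must be ≥ 1, got {k_min}")
    supra = tmap.p.data < p_threshold
    if brain_mask is not None:
        if brain_mask.shape != supra.shape:
            raise ValueError("brain mask grid does not match the contrast grid")
        supra &= brain_mask.astype(bool)
    labelled, n_comp = ndimage.label(supra, structure=connectivity_structure(connectivity))
    keep = np.zeros_like(supra)
    rows = []
    cid = 0
    tmag = np.abs(tmap.t.data)
    for comp in range(1, n_comp + 1):
        sel = labelled == comp
        k = int(sel.sum())
        if k < k_min:
            continue
        cid += 1
        keep |= sel
        idx = np.argwhere(sel)
        peak = idx[np.argmax(tmag[sel])]
        rows.append((cid, k, float(tmap.t.data[tuple(peak)]), int(peak[0]), int(peak[1]), int(peak[2])))
    clusters = pd.DataFrame(
        rows, columns=["cluster_id", "k_extent", "peak_t", "peak_i", "peak_j", "peak_k"]
    )
    return ClusterResult(
        mask=keep,
        clusters=clusters,
        p_threshold=float(p_threshold),
        k_min=int(k_min),
        connectivity=int(connectivity),
    )


def build_mask_ad(
    placebo_t0: list[Volume],
    placebo_t1: list[Volume],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    k_min: int = DEFAULT_K_MIN,
    connectivity: int = DEFAULT_CONNECTIVITY,
    arm: str = "placebo",
    from_visit: str = "M0",
    to_visit: str = "M14",
    brain_mask: np.ndarray | None = None,
) -> MaskAD:
    """MaskAD: clusters of significant placebo-arm baseline→final decline.

    Returns an empty mask (with a logged warning) when no cluster survives;
    downstream consumers must handle emptiness explicitly.
    """
    tmap = paired_t_map(placebo_t0, placebo_t1, "decline", from_visit, to_visit)
    result = cluster_threshold(tmap, p_threshold, k_min, connectivity, brain_mask)
    if not result.mask.any():
        log.warning(
            "MaskAD is empty: no cluster of ≥%d voxels survived p<%g in the %s decline contrast",
            k_min,
            p_threshold,
            arm,
        )
    return MaskAD(
        mask=result.mask,
        arm=arm,
        from_visit=from_visit,
        to_visit=to_visit,
        p_threshold=float(p_threshold),
        k_min=int(k_min),
    )


def mask_ad_percent_loss(
    subject_scans: dict[str, tuple[Volume, Volume]],
    mask: MaskAD,
) -> tuple[float, pd.DataFrame]:
    """Mean percent change of in-mask uptake between two visits, per arm input.

    ``subject_scans`` maps subject id → (scan at first visit, scan at final
    visit), both preprocessed. Per subject the change is
    100 × (mean_t1 − mean_t0) / mean_t0; the group value is the plain mean
    over subjects (negative = metabolic loss). Returns (group mean,
    per-subject frame).
    """
    if mask.is_empty:
        raise ValueError(
            "MaskAD is empty (no surviving cluster in the source contrast); "
            "percent loss is undefined — see the build_mask_ad warning"
        )
    if not subject_scans:
        raise ValueError("no subjects supplied")
    rows = []
    for sid, (s0, s1) in subject_scans.items():
        s0.assert_compatible(s1)
        if s0.shape != mask.mask.shape:
            raise ValueError(f"scan grid for subject {sid} does not match MaskAD grid")
        m0 = float(s0.data[mask.mask].mean())
        m1 = float(s1.data[mask.mask].mean())
        if m0 <= 0:
            raise ValueError(f"non-positive baseline in-mask uptake for subject {sid}")
        rows.append((sid, 100.0 * (m1 - m0) / m0))
    per_subject = pd.DataFrame(rows, columns=["subject", "percent_change"])
    return float(per_subject["percent_change"].mean()), per_subject
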