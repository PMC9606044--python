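"""Independent brute-force oracles: plain Python voxel loops.

These deliberately avoid the vectorised implementation paths (and scipy's
labelling) so that agreement is a genuine cross-check.
"""

from collections import deque

import numpy as np


def zmap_loop(patient: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Per-voxel Z-score with an explicit triple loop; 0 outside mean>0."""
    out = np.zeros_like(patient, dtype=float)
    nx, ny, nz = patient.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mean[i, j, k] > 0:
                    out[i, j, k] = (patient[i, j, k] - mean[i, j, k]) / sd[i, j, k]
    return out


def severity_loop(z: np.ndarray, mask: np.ndarray, bins) -> np.ndarray:
    out = np.zeros(z.shape, dtype=int)
    nx, ny, nz = z.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                s = 0
                for cut in bins:
                    if z[i, j, k] <= cut:
                        s += 1
                out[i, j, k] = s
    return out


def regional_loop(labels, mask, scan, defect, severity, region_ids):
    """Three regional parameters via explicit per-region voxel loops."""
    res = {}
    for rid in region_ids:
        vals, ndef, sev, n = 0.0, 0, 0.0, 0
        for idx in zip(*np.nonzero(labels == rid)):
            if not mask[idx]:
                continue
            n += 1
            vals += scan[idx]
            ndef += int(defect[idx])
            sev += severity[idx]
        if n == 0:
            res[rid] = (np.nan, np.nan, np.nan)
        else:
            res[rid] = (vals / n, 100.0 * ndef / n, sev / n)
    return res


def _neighbours(connectivity: int):
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((di, dj, dk))
    return offs


def flood_fill_clusters(mask: np.ndarray, connectivity: int = 18):
    """BFS flood fill returning a list of frozensets of voxel indices."""
    offs = _neighbours(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    clusters = []
    nx, ny, nz = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            i, j, k = q.popleft()
            comp.add((i, j, k))
            for di, dj, dk in offs:
                a, b, c = i + di, j + dj, k + dk
                if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and mask[a, b, c] and not seen[a, b, c]:
                    seen[a, b, c] = True
                    q.append((a, b, c))
        clusters.append(frozenset(comp))
    return clusters
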