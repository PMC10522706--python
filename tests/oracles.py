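"""Independent brute-force oracles used to pin the fast implementations.

Everything here is deliberately naive: explicit loops, all-pairs distance
matrices, and full enumeration of sign assignments.  These functions never
call into segnoninfer internals beyond the mask container.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_surface_voxels(voxels: np.ndarray) -> list[tuple[int, int, int]]:
    """Foreground voxels with a face-adjacent background/outside neighbour."""
    out = []
    shape = voxels.shape
    for idx in np.argwhere(voxels):
        i, j, k = (int(v) for v in idx)
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            outside = not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2])
            if outside or not voxels[ni, nj, nk]:
                out.append((i, j, k))
                break
    return out


def brute_directed_distances(
    a: list[tuple[int, int, int]], b: list[tuple[int, int, int]], spacing
) -> np.ndarray:
    """All-pairs nearest distances from each voxel of a to the set b (mm)."""
    sp = np.asarray(spacing, dtype=float)
    a_mm = np.asarray(a, dtype=float).reshape(-1, 3) * sp
    b_mm = np.asarray(b, dtype=float).reshape(-1, 3) * sp
    diff = a_mm[:, None, :] - b_mm[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def brute_hd95(pred_vox: np.ndarray, ref_vox: np.ndarray, spacing) -> float:
    sp_surf = brute_surface_voxels(pred_vox)
    sr_surf = brute_surface_voxels(ref_vox)
    d_pr = brute_directed_distances(sp_surf, sr_surf, spacing)
    d_rp = brute_directed_distances(sr_surf, sp_surf, spacing)
    return max(float(np.percentile(d_pr, 95)), float(np.percentile(d_rp, 95)))


def brute_sdt(pred_vox: np.ndarray, ref_vox: np.ndarray, spacing, tol_mm: float) -> float:
    sp_surf = brute_surface_voxels(pred_vox)
    sr_surf = brute_surface_voxels(ref_vox)
    d_pr = brute_directed_distances(sp_surf, sr_surf, spacing)
    d_rp = brute_directed_distances(sr_surf, sp_surf, spacing)
    hits = int(np.sum(d_pr <= tol_mm)) + int(np.sum(d_rp <= tol_mm))
    return hits / (len(sp_surf) + len(sr_surf))


def enumerate_wilcoxon_greater(deltas: np.ndarray) -> float:
    """Exact one-sided signed-rank p by enumerating all 2^n sign assignments.

    Assumes no zeros and no ties among |deltas| (the exact regime).
    p = P(W+ >= observed W+) under random independent signs.
    """
    d = np.asarray(deltas, dtype=float)
    assert np.all(d != 0)
    absd = np.abs(d)
    ranks = np.argsort(np.argsort(absd)) + 1.0
    w_obs = float(ranks[d > 0].sum())
    n = d.size
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(ranks[np.asarray(signs, dtype=bool)].sum())
        if w >= w_obs:
            count += 1
    return count / 2**n


def holm_by_hand(p_values: list[float]) -> list[float]:
    """Step-down Holm adjustment: literal transcription of the procedure."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_values[i]))
        adjusted[i] = running
    return adjusted
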