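"""Independent brute-force oracles used by the tests.

Deliberately naive implementations (all-pairs loops, exhaustive
enumeration) against which the package's vectorized/EDT-based code is
checked on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps


def voxel_coords(shape, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """(N, 3) world-mm coordinates of every voxel centre."""
    idx = np.indices(shape).reshape(3, -1).T
    return np.asarray(origin) + idx * np.asarray(spacing)


def brute_force_expand(vox: np.ndarray, spacing, margin_mm: float) -> np.ndarray:
    """Minkowski dilation by thresholding all pairwise centre distances."""
    shape = vox.shape
    coords = voxel_coords(shape, spacing)
    occ = coords[vox.ravel()]
    if len(occ) == 0:
        return vox.copy()
    d2 = ((coords[:, None, :] - occ[None, :, :]) ** 2).sum(axis=2)
    out = (d2.min(axis=1) <= margin_mm**2 + 1e-9).reshape(shape)
    return out


def brute_force_min_distance(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Minimum over all occupied voxel-centre pairs of the Euclidean distance."""
    coords = voxel_coords(a.shape, spacing)
    pa = coords[a.ravel()]
    pb = coords[b.ravel()]
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def whole_voxel_dxcc(doses: np.ndarray, voxel_cc: float, x_cc: float) -> float:
    """Largest dose d with volume(dose >= d) >= x_cc, scanning candidate doses."""
    best = None
    for d in np.unique(doses):
        vol = float((doses >= d).sum()) * voxel_cc
        if vol >= x_cc - 1e-12:
            best = float(d) if best is None else max(best, float(d))
    return best


def count_volume_at(doses: np.ndarray, voxel_cc: float, threshold: float) -> float:
    return float(sum(1 for d in doses if d >= threshold)) * voxel_cc


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(r, exact two-sided permutation p) using scipy's spearmanr per permutation."""
    r_obs = sps.spearmanr(x, y).statistic
    n = len(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = sps.spearmanr(x, y[list(perm)]).statistic
        if abs(r) >= abs(r_obs) - 1e-9:
            count += 1
        total += 1
    return float(r_obs), count / total


def wilcoxon_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """(W+, exact two-sided p) by full sign-pattern enumeration on tie-averaged
    ranks of |d| (zero differences must already be removed)."""
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = float(ranks[diffs > 0].sum())
    n = len(diffs)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(float(sum(r for s, r in zip(signs, ranks) if s)))
    ws = np.asarray(ws)
    n_le = int((ws <= w_obs + 1e-9).sum())
    n_ge = int((ws >= w_obs - 1e-9).sum())
    return w_obs, min(1.0, 2.0 * min(n_le, n_ge) / len(ws))
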