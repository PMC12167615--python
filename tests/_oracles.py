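"""Independent brute-force reference implementations (tests only).

Everything here recomputes pipeline quantities from first principles with a
different mechanism than the package: bounding-box scans instead of
precomputed offset kernels, pairwise distances instead of a distance
transform, sort-based ranks instead of scipy's, explicit enumeration for
permutation p-values and quartiles.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.distance import cdist

PEAK_DIAMETER_MM = 2.0 * (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def sphere_members(center, radius_mm, spacing, shape):
    """In-grid voxel coords whose centre lies within radius of the centre voxel."""
    sp = np.asarray(spacing, dtype=float)
    c = np.asarray(center, dtype=int)
    n = np.floor(radius_mm / sp).astype(int)
    lo = np.maximum(c - n, 0)
    hi = np.minimum(c + n, np.asarray(shape) - 1)
    grid = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    pts = grid.reshape(3, -1).T
    d2 = np.sum(((pts - c) * sp) ** 2, axis=1)
    return pts[d2 <= radius_mm * radius_mm]


def brute_peak_map(values, mask, spacing):
    """Per-voxel mean over the 1 cm^3 sphere, NaN outside the mask."""
    out = np.full(values.shape, np.nan)
    for p in np.argwhere(mask):
        mem = sphere_members(p, PEAK_DIAMETER_MM / 2.0, spacing, values.shape)
        out[tuple(p)] = values[mem[:, 0], mem[:, 1], mem[:, 2]].mean()
    return out


def brute_inside_distances(mask, spacing, cap_mm):
    """Min world distance from each mask voxel to any background voxel.

    Exact for all distances up to ``cap_mm`` (background search restricted to
    a correspondingly dilated bounding box); larger distances are reported as
    at least their true value, which suffices to test >= thresholds below
    ``cap_mm``.
    """
    sp = np.asarray(spacing, dtype=float)
    shape = np.asarray(mask.shape)
    inside = np.argwhere(mask)
    pad = np.ceil((cap_mm + 2 * sp.max()) / sp).astype(int)
    lo = np.maximum(inside.min(axis=0) - pad, 0)
    hi = np.minimum(inside.max(axis=0) + pad, shape - 1)
    region = np.zeros(mask.shape, dtype=bool)
    region[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = True
    bg = np.argwhere(region & ~mask)
    dists = np.empty(len(inside))
    for start in range(0, len(inside), 256):
        chunk = inside[start:start + 256]
        d = cdist(chunk * sp, bg * sp)
        dists[start:start + 256] = d.min(axis=1)
    return inside, dists


def brute_force_place(values, mask, spacing, diameter_mm, margin_mm=5.0):
    """Monolithic reference of the four placement steps.

    Returns a dict with the chosen centre, its SUVmean, the median score,
    the candidate list with distances and scores.
    """
    radius = diameter_mm / 2.0
    peak = brute_peak_map(values, mask, spacing)
    inside, dists = brute_inside_distances(mask, spacing,
                                           radius + margin_mm + 10.0)
    keep = dists >= radius + margin_mm
    cands = inside[keep]                      # argwhere order = lexicographic
    cand_dists = dists[keep]
    scores = np.empty(len(cands))
    for i, c in enumerate(cands):
        mem = sphere_members(c, radius, spacing, values.shape)
        in_mask = mask[mem[:, 0], mem[:, 1], mem[:, 2]]
        vals = peak[mem[in_mask, 0], mem[in_mask, 1], mem[in_mask, 2]]
        mean = vals.mean()
        scores[i] = vals.max() + math.sqrt(((vals - mean) ** 2).mean())
    median = float(np.median(scores))
    best = 0
    for i in range(1, len(cands)):            # first minimum = lexicographic
        if abs(scores[i] - median) < abs(scores[best] - median):
            best = i
    mem = sphere_members(cands[best], radius, spacing, values.shape)
    suv_mean = float(values[mem[:, 0], mem[:, 1], mem[:, 2]].mean())
    return {
        "center": tuple(int(v) for v in cands[best]),
        "suv_mean": suv_mean,
        "score": float(scores[best]),
        "median_score": median,
        "candidates": cands,
        "distances": cand_dists,
        "scores": scores,
    }


def average_ranks(v):
    """Sort-based average ranks (1-based), ties share the mean rank."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da, db = a - a.mean(), b - b.mean()
    return float((da * db).sum() / math.sqrt((da ** 2).sum() * (db ** 2).sum()))


def brute_spearman_rho(x, y):
    return pearson(average_ranks(x), average_ranks(y))


def brute_permutation_p(x, y):
    """Two-tailed exact permutation p for |rho|, all n! pairings."""
    obs = abs(brute_spearman_rho(x, y))
    y = np.asarray(y, dtype=float)
    count = total = 0
    for perm in itertools.permutations(range(len(y))):
        if abs(brute_spearman_rho(x, y[list(perm)])) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def sort_quartiles(v):
    """Type-7 (linear interpolation) quartiles computed by hand."""
    v = np.sort(np.asarray(v, dtype=float))
    n = len(v)

    def q(p):
        h = (n - 1) * p
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)
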