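"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the most literal algorithm
available (per-voxel loops, exhaustive searches, run merging with explicit
Python loops) so they share no code path with the implementations they
check.
"""

from __future__ import annotations

import numpy as np


def naive_otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive search over all histogram cut points for the Otsu threshold."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_var = centers[0], -1.0
    total = counts.sum()
    for cut in range(1, nbins):
        w0 = counts[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:cut] * centers[:cut]).sum() / w0
        mu1 = (counts[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = (edges[cut - 1 + 1] + edges[cut]) / 2  # boundary between bins
    return float(best_t)


def naive_cone_bins(image, geom, center_nm, axis, aperture_deg, bin_width_nm, r_max_nm):
    """Per-voxel membership test + binning, with explicit loops."""
    az, ay, ax = np.asarray(axis, dtype=float) / np.linalg.norm(axis)
    cz, cy, cx = center_nm
    cos_half = np.cos(np.radians(aperture_deg / 2))
    nbins = int(r_max_nm / bin_width_nm) + 1
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    nz, ny, nx = image.shape
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                dz = iz * geom.dz - cz
                dy = iy * geom.dy - cy
                dx = ix * geom.dx - cx
                r = np.sqrt(dz * dz + dy * dy + dx * dx)
                if r == 0 or r > r_max_nm:
                    continue
                if dz * az + dy * ay + dx * ax < cos_half * r:
                    continue
                b = int(r / bin_width_nm)
                sums[b] += image[iz, iy, ix]
                counts[b] += 1
    return sums, counts


def naive_detect_events(samples, baseline, sigma, fs, k_sigma=5.0, dmin_s=25e-6, dmax_s=2.5):
    """Literal run-scan event detector: flag, extend to re-crossing, merge, gate.

    Returns accepted (start, end) half-open index pairs.
    """
    x = np.asarray(samples, dtype=float)
    base = np.broadcast_to(np.asarray(baseline, dtype=float), x.shape)
    dev = base - x
    n = x.size
    flagged = dev > k_sigma * sigma

    runs = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1

    extended = []
    for s, e in runs:
        while s > 0 and dev[s - 1] > 0:
            s -= 1
        while e < n and dev[e] > 0:
            e += 1
        extended.append((s, e))

    merged = []
    for s, e in sorted(extended):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))

    accepted = []
    for s, e in merged:
        if s == 0 or e == n:  # unresolvable boundaries
            continue
        d = (e - s) / fs
        if dmin_s <= d <= dmax_s:
            accepted.append((s, e))
    return accepted


def intervals_overlap(a, b) -> bool:
    return not (a[1] <= b[0] or b[1] <= a[0])


def recall_precision(detected, truth):
    """Fraction of truth intervals hit / detections that hit a truth interval."""
    if not detected or not truth:
        return 0.0, 0.0
    recall = sum(any(intervals_overlap(t, d) for d in detected) for t in truth) / len(truth)
    precision = sum(any(intervals_overlap(d, t) for t in truth) for d in detected) / len(detected)
    return recall, precision
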