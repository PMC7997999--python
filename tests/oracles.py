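"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit Python loops, direct
definitions) and shares no code with the package internals.
"""

import itertools
import math

import numpy as np


def msd_bruteforce(positions, frame_interval, max_lag):
    """All-pairs time-averaged MSD by explicit double loop."""
    n = len(positions)
    lags, values, n_pairs = [], [], []
    for m in range(1, max_lag + 1):
        acc, cnt = 0.0, 0
        for t in range(n - m):
            dx = positions[t + m][0] - positions[t][0]
            dy = positions[t + m][1] - positions[t][1]
            acc += dx * dx + dy * dy
            cnt += 1
        lags.append(m * frame_interval)
        values.append(acc / cnt)
        n_pairs.append(cnt)
    return np.array(lags), np.array(values), np.array(n_pairs)


def total_distance_bruteforce(positions):
    acc = 0.0
    for i in range(1, len(positions)):
        dx = positions[i][0] - positions[i - 1][0]
        dy = positions[i][1] - positions[i - 1][1]
        acc += math.sqrt(dx * dx + dy * dy)
    return acc


def euclidean_distance_bruteforce(positions):
    dx = positions[-1][0] - positions[0][0]
    dy = positions[-1][1] - positions[0][1]
    return math.sqrt(dx * dx + dy * dy)


def pause_fraction_bruteforce(positions, pixel_size):
    """Census of identical consecutive nearest-pixel positions."""
    quantized = [
        (round(p[0] / pixel_size), round(p[1] / pixel_size)) for p in positions
    ]
    paused = sum(
        1 for i in range(1, len(quantized)) if quantized[i] == quantized[i - 1]
    )
    return paused / (len(quantized) - 1)


def in_band_bruteforce(x, y, nucleus_center, nucleus_radius, cell_center, cell_radius, band):
    """Point-in-annulus-clipped-to-cell test for analytic circles."""
    rn = math.hypot(x - nucleus_center[0], y - nucleus_center[1])
    rc = math.hypot(x - cell_center[0], y - cell_center[1])
    return nucleus_radius < rn <= nucleus_radius + band and rc <= cell_radius


def band_area_montecarlo(nucleus_center, nucleus_radius, cell_center, cell_radius,
                         band, n_samples=1_000_000, seed=0):
    """Rejection-sampling estimate of the clipped annulus area."""
    rng = np.random.default_rng(seed)
    r_out = nucleus_radius + band
    lo_x, hi_x = nucleus_center[0] - r_out, nucleus_center[0] + r_out
    lo_y, hi_y = nucleus_center[1] - r_out, nucleus_center[1] + r_out
    xs = rng.uniform(lo_x, hi_x, n_samples)
    ys = rng.uniform(lo_y, hi_y, n_samples)
    rn = np.hypot(xs - nucleus_center[0], ys - nucleus_center[1])
    rc = np.hypot(xs - cell_center[0], ys - cell_center[1])
    hit = (rn > nucleus_radius) & (rn <= r_out) & (rc <= cell_radius)
    box = (hi_x - lo_x) * (hi_y - lo_y)
    return box * hit.mean()


def rank_sum_exact_p(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments.

    Two-sided convention: twice the smaller one-sided tail probability,
    capped at 1 (tail probabilities include the observed value).
    """
    pooled = list(a) + list(b)
    n = len(pooled)
    # mid-ranks
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    n_a = len(a)
    observed = sum(ranks[:n_a])
    total = n_le = n_ge = 0
    for combo in itertools.combinations(range(n), n_a):
        stat = sum(ranks[i] for i in combo)
        total += 1
        if stat <= observed + 1e-12:
            n_le += 1
        if stat >= observed - 1e-12:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)
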