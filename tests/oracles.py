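"""Independent brute-force oracles used by the test suite.

Everything here is written as literal enumeration / textbook formula
transcription, deliberately sharing no code with the package, so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_brute_force(levels, mask, n_levels, offset, symmetric=True):
    """O(N^2)-style double loop over all pixels applying the offset and
    mask rule; returns the normalised co-occurrence matrix."""
    h, w = levels.shape
    dr, dc = offset
    counts = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total


def haralick_brute_force(p, dialect="matlab_toolbox"):
    """Literal transcription of the 18 feature formulas, scalar loops."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))

    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[(i + 1) + (j + 1)] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    def ent(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    f = {}
    f["autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng)
    )
    f["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    f["cluster_prominence"] = sum(
        ((i + 1) + (j + 1) - mu_x - mu_y) ** 4 * p[i, j]
        for i in range(ng) for j in range(ng)
    )
    f["cluster_shade"] = sum(
        ((i + 1) + (j + 1) - mu_x - mu_y) ** 3 * p[i, j]
        for i in range(ng) for j in range(ng)
    )
    f["dissimilarity"] = sum(
        abs(i - j) * p[i, j] for i in range(ng) for j in range(ng)
    )
    f["energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["entropy"] = ent(p.ravel())
    f["homogeneity"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    f["maximum_probability"] = max(p[i, j] for i in range(ng) for j in range(ng))
    f["sum_average"] = sum(k * v for k, v in p_sum.items())
    f["sum_entropy"] = ent(p_sum.values())
    f["difference_entropy"] = ent(p_diff.values())

    if var_x > 0 and var_y > 0:
        f["correlation"] = (f["autocorrelation"] - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        f["correlation"] = float("nan")

    hx, hy, hxy = ent(px), ent(py), f["entropy"]
    hxy1 = -sum(
        p[i, j] * math.log(px[i] * py[j])
        for i in range(ng) for j in range(ng)
        if px[i] * py[j] > 0 and p[i, j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log(px[i] * py[j])
        for i in range(ng) for j in range(ng)
        if px[i] * py[j] > 0
    )
    f["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else float("nan")
    f["imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    if dialect == "matlab_toolbox":
        f["difference_variance"] = sum(k**2 * v for k, v in p_diff.items())
        se = f["sum_entropy"]
        f["sum_variance"] = sum((k - se) ** 2 * v for k, v in p_sum.items())
        u = p.mean()
        f["variance"] = sum(
            ((i + 1) - u) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        )
    else:
        mu_d = sum(k * v for k, v in p_diff.items())
        f["difference_variance"] = sum((k - mu_d) ** 2 * v for k, v in p_diff.items())
        sa = f["sum_average"]
        f["sum_variance"] = sum((k - sa) ** 2 * v for k, v in p_sum.items())
        f["variance"] = sum(
            ((i + 1) - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
        )
    return f


def bh_step_up(pvalues):
    """Hand step-up enumeration of Benjamini-Hochberg adjusted values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj_sorted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvalues[i] / rank)
        adj_sorted[rank - 1] = running_min
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = min(1.0, adj_sorted[rank])
    return out


def disc_pixel_count(h, w, radius):
    """Enumerate every pixel against the inclusive distance rule."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return sum(
        1
        for r in range(h)
        for c in range(w)
        if (r - cy) ** 2 + (c - cx) ** 2 <= radius**2
    )
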