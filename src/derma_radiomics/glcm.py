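"""Grey-level co-occurrence matrices and Haralick texture features.

Co-occurrence matrices are accumulated over ordered pixel pairs
``(a, a + offset)`` with *both* pixels inside the ROI mask, at the four
standard offsets (0, 45, 90, 135 degrees; displacement d, default 1),
symmetrised by also counting the reversed pair, and normalised to sum
to one.  From each matrix the 18 classical second-order texture
statistics are computed; features are averaged over the four angles and
then over the three colour channels, giving one 18-feature vector per
capture.

Two formula dialects are provided for the three features whose
definition varies across implementations in circulation:

``matlab_toolbox`` (default)
    The conventions of the widely used MATLAB GLCM feature script
    lineage: *variance* is centred on the mean of the matrix entries
    (so it closely tracks autocorrelation), *sum variance* is centred
    on the sum entropy, and *difference variance* is the raw second
    moment of the difference distribution - making it identical to
    contrast.

``haralick_1973``
    The textbook definitions: *variance* centred on the marginal mean
    level, *sum variance* centred on the sum average, and *difference
    variance* the central variance of the difference distribution.

All entropies use the natural logarithm with 0 * ln 0 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_prep import MaskedLevelGrid, split_channels, prepare_channel

__all__ = [
    "GLCMParams",
    "GLCMMatrix",
    "FEATURE_NAMES",
    "DegenerateFeatureWarning",
    "EmptyGLCMError",
    "compute_glcm",
    "haralick_features",
    "average_feature_vectors",
    "extract_image_features",
]

FEATURE_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

ANGLES = (0, 45, 90, 135)

# (row, col) displacement per angle at d = 1; rows grow downward, so 45
# degrees pairs a pixel with its upper-right neighbour.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class EmptyGLCMError(ValueError):
    """No valid in-mask pixel pair exists for the requested offset."""


class DegenerateFeatureWarning(UserWarning):
    """A feature is undefined on a degenerate (single-level) matrix."""


@dataclass(frozen=True)
class GLCMParams:
    n_levels: int = 64
    displacement: int = 1
    angles: tuple[int, ...] = ANGLES
    symmetric: bool = True
    dialect: str = "matlab_toolbox"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.displacement < 1:
            raise ValueError("displacement must be >= 1")
        if any(a not in _OFFSETS for a in self.angles):
            raise ValueError(f"angles must be among {sorted(_OFFSETS)}")
        if self.dialect not in ("matlab_toolbox", "haralick_1973"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


@dataclass(frozen=True)
class GLCMMatrix:
    p: np.ndarray  # Ng x Ng, sums to 1
    params: GLCMParams
    angle: int
    pair_count: int


def compute_glcm(grid: MaskedLevelGrid, params: GLCMParams, angle: int) -> GLCMMatrix:
    """Accumulate the normalised co-occurrence matrix at one offset.

    Counts every ordered pair (a, a + offset) with both pixels in-mask;
    in symmetric mode the reversed pair is counted as well, so the
    matrix is exactly symmetric and 0/180 degrees coincide.
    """
    if angle not in params.angles:
        raise ValueError(f"angle {angle} not among configured angles {params.angles}")
    dr, dc = (o * params.displacement for o in _OFFSETS[angle])
    lev, mask = grid.levels, grid.mask
    h, w = lev.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    i = lev[src_r, src_c]
    j = lev[dst_r, dst_c]
    valid = mask[src_r, src_c] & mask[dst_r, dst_c]
    ii = i[valid].astype(np.int64) - 1
    jj = j[valid].astype(np.int64) - 1
    ng = grid.n_levels
    counts = np.bincount(ii * ng + jj, minlength=ng * ng).reshape(ng, ng)
    if params.symmetric:
        counts = counts + counts.T
    total = int(counts.sum())
    if total == 0:
        raise EmptyGLCMError(f"no valid pixel pair at angle {angle} (mask too small)")
    return GLCMMatrix(p=counts / total, params=params, angle=angle, pair_count=total)


def _entropy(q: np.ndarray) -> float:
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum())


def haralick_features(glcm: GLCMMatrix) -> dict[str, float]:
    """The 18 second-order texture statistics of one matrix.

    On a degenerate matrix concentrated in a single cell, correlation
    and IMC1 are undefined (zero marginal variance / zero marginal
    entropy); they are returned as NaN with a warning.
    """
    p = glcm.p
    ng = p.shape[0]
    lv = np.arange(1, ng + 1, dtype=float)
    I = lv[:, None]
    J = lv[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(lv @ px)
    mu_y = float(lv @ py)
    var_x = float(((lv - mu_x) ** 2) @ px)
    var_y = float(((lv - mu_y) ** 2) @ py)

    # sum / difference distributions: k = i + j in 2..2Ng, k = |i - j| in 0..Ng-1
    flat = p.ravel()
    ksum = (I + J).ravel().astype(int)
    kdiff = np.abs(I - J).ravel().astype(int)
    p_sum = np.bincount(ksum, weights=flat, minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(kdiff, weights=flat, minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    k_diff = np.arange(0, ng, dtype=float)

    f: dict[str, float] = {}
    f["autocorrelation"] = float((I * J * p).sum())
    f["contrast"] = float((((I - J) ** 2) * p).sum())
    f["cluster_prominence"] = float((((I + J - mu_x - mu_y) ** 4) * p).sum())
    f["cluster_shade"] = float((((I + J - mu_x - mu_y) ** 3) * p).sum())
    f["dissimilarity"] = float((np.abs(I - J) * p).sum())
    f["energy"] = float((p**2).sum())
    f["entropy"] = _entropy(flat)
    f["homogeneity"] = float((p / (1.0 + np.abs(I - J))).sum())
    f["maximum_probability"] = float(p.max())
    f["sum_average"] = float(k_sum @ p_sum)
    f["sum_entropy"] = _entropy(p_sum)
    f["difference_entropy"] = _entropy(p_diff)

    if var_x <= 0 or var_y <= 0:
        warnings.warn(
            "degenerate co-occurrence matrix: correlation undefined",
            DegenerateFeatureWarning,
            stacklevel=2,
        )
        f["correlation"] = np.nan
    else:
        f["correlation"] = (f["autocorrelation"] - mu_x * mu_y) / np.sqrt(var_x * var_y)

    # information measures of correlation
    hx = _entropy(px)
    hy = _entropy(py)
    hxy = f["entropy"]
    pxpy = np.outer(px, py)
    nz = pxpy > 0
    log_pxpy = np.zeros_like(pxpy)
    log_pxpy[nz] = np.log(pxpy[nz])
    hxy1 = float(-(p[nz] * log_pxpy[nz]).sum())
    hxy2 = float(-(pxpy[nz] * log_pxpy[nz]).sum())
    denom = max(hx, hy)
    if denom <= 0:
        warnings.warn(
            "degenerate co-occurrence matrix: IMC1 undefined",
            DegenerateFeatureWarning,
            stacklevel=2,
        )
        f["imc1"] = np.nan
    else:
        f["imc1"] = (hxy - hxy1) / denom
    f["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if glcm.params.dialect == "matlab_toolbox":
        f["difference_variance"] = float((k_diff**2) @ p_diff)  # == contrast
        f["sum_variance"] = float(((k_sum - f["sum_entropy"]) ** 2) @ p_sum)
        u = float(p.mean())
        f["variance"] = float((((I - u) ** 2) * p).sum())
    else:  # haralick_1973
        mu_diff = float(k_diff @ p_diff)
        f["difference_variance"] = float(((k_diff - mu_diff) ** 2) @ p_diff)
        f["sum_variance"] = float(((k_sum - f["sum_average"]) ** 2) @ p_sum)
        f["variance"] = float((((I - mu_x) ** 2) * p).sum())

    return {name: f[name] for name in FEATURE_NAMES}


def average_feature_vectors(vectors: list[dict[str, float]]) -> dict[str, float]:
    """Feature-wise arithmetic mean of several feature vectors.

    NaN sentinels (degenerate features) are skipped per feature; a
    feature degenerate in every vector stays NaN.
    """
    if not vectors:
        raise ValueError("cannot average an empty list of feature vectors")
    out = {}
    for name in FEATURE_NAMES:
        vals = np.array([v[name] for v in vectors], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[name] = float(finite.mean()) if finite.size else float("nan")
    return out


def extract_image_features(
    pixels: np.ndarray,
    params: GLCMParams = GLCMParams(),
    roi_radius: float = 300.0,
) -> dict[str, float]:
    """One 18-feature vector for an RGB capture.

    Per channel: ROI crop, quantize, one matrix per angle, features,
    angle average; then the three channel vectors are averaged.  When
    all channels are identical (greyscale content) a single channel is
    computed, which by the averaging identity gives the same result.
    """
    channels = split_channels(pixels)
    grey = all(
        np.array_equal(channels[0].values, ch.values) for ch in channels[1:]
    )
    per_channel = []
    for ch in channels[:1] if grey else channels:
        grid = prepare_channel(ch, radius=roi_radius, n_levels=params.n_levels)
        angle_vectors = [
            haralick_features(compute_glcm(grid, params, angle)) for angle in params.angles
        ]
        per_channel.append(average_feature_vectors(angle_vectors))
    return per_channel[0] if grey else average_feature_vectors(per_channel)
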