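"""Per-subband texture descriptor families.

Four descriptor families are computed on every directional subband of the
magnitude and relative-phase stacks:

* ``cm`` — 20 co-occurrence (Haralick-style) statistics of the orientation-
  averaged gray-level co-occurrence matrix (20 x 32 = 640 per component);
* ``lbp`` — rotation-invariant uniform local binary pattern histogram,
  P = 8, R = 2 (10 x 32 = 320);
* ``losib`` — local oriented statistic information booster: mean absolute
  centre-neighbour difference per direction, P = 8, R = 1 (8 x 32 = 256);
* ``sfta`` — segmentation-based fractal texture analysis via two-threshold
  binary decomposition, n_t = 4 (21 x 32 = 672);

plus the auxiliary ``cmdot`` family (co-occurrence matrix Hadamard-multiplied
with a size-matched reduction of the magnitude subband, summarised by
column-wise maxima).

All families are deterministic and operate on a stack shaped
(n_subbands, rows, cols) with the canonical subband ordering of
:mod:`sheartex.shearlet` (scales coarse to fine, directions ascending).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from skimage.feature import graycomatrix, local_binary_pattern

from .errors import ContractError, DataError, DimensionError

__all__ = [
    "CoocMatrix",
    "FeatureBlock",
    "HARALICK_NAMES",
    "quantize_subband",
    "cooccurrence_mean",
    "haralick20",
    "cm_features",
    "lbp_riu2",
    "lbp_features",
    "losib",
    "losib_features",
    "multiotsu_thresholds",
    "ttbd",
    "sfta_region_features",
    "sfta",
    "sfta_features",
    "cmdot_subband",
    "cmdot_features",
    "extract_feature_blocks",
]

#: The twenty co-occurrence statistics, in their fixed output order.
HARALICK_NAMES = (
    "contrast",
    "correlation",
    "energy",
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "sum_of_squares",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "information_measure_of_correlation",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

#: 8-connected neighbour offsets (row, col), counter-clockwise from East.
_NEIGHBOURS8 = (
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
)


@dataclasses.dataclass(frozen=True)
class CoocMatrix:
    """Orientation-averaged, symmetric, normalized co-occurrence matrix."""

    p: np.ndarray
    distance: int
    orientations_deg: tuple[int, ...] = (0, 45, 90, 135)

    @property
    def levels(self) -> int:
        return self.p.shape[0]


@dataclasses.dataclass(frozen=True)
class FeatureBlock:
    """Named descriptor vector for one (family, component) pair."""

    descriptor: str
    component: str
    values: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.column_names):
            raise ContractError(
                f"{len(self.values)} values but {len(self.column_names)} names"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise ContractError("column names are not unique")

    def __len__(self) -> int:
        return len(self.values)


def quantize_subband(band: np.ndarray, ng: int = 8) -> np.ndarray:
    """Min-max rescale a subband and bin uniformly into levels 1..ng.

    A constant subband maps entirely to level 1.
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    band = np.asarray(band, dtype=np.float64)
    if not np.all(np.isfinite(band)):
        raise DataError("subband contains non-finite values")
    lo, hi = band.min(), band.max()
    if hi == lo:
        return np.ones(band.shape, dtype=np.int64)
    norm = (band - lo) / (hi - lo)
    return np.minimum(np.floor(norm * ng).astype(np.int64), ng - 1) + 1


def cooccurrence_mean(levels: np.ndarray, ng: int | None = None, pd: int = 1) -> CoocMatrix:
    """Mean of the four symmetric normalized GLCMs at 0/45/90/135 degrees.

    ``levels`` holds integer levels 1..ng (see :func:`quantize_subband`).
    Each orientation's matrix is symmetrized and normalized before averaging;
    the average is renormalized to sum exactly one.
    """
    levels = np.asarray(levels)
    if levels.ndim != 2 or min(levels.shape) <= pd:
        raise DataError(
            f"subband shape {levels.shape} too small for co-occurrence offset {pd}"
        )
    if ng is None:
        ng = int(levels.max())
    if levels.min() < 1 or levels.max() > ng:
        raise DataError("quantized levels must lie in 1..ng")
    glcm = graycomatrix(
        (levels - 1).astype(np.uint8),
        distances=[pd],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=ng,
        symmetric=True,
        normed=True,
    )
    p = glcm[:, :, 0, :].mean(axis=-1)
    p = p / p.sum()
    return CoocMatrix(p=p, distance=pd)


def haralick20(cm: CoocMatrix | np.ndarray) -> np.ndarray:
    """The twenty co-occurrence statistics of :data:`HARALICK_NAMES`.

    All logarithms are natural.  Statistics with a variance in the
    denominator (correlation, information measure of correlation) return 0
    when that denominator vanishes, so the output is always finite.
    ``sum_of_squares`` is taken about the mean of the matrix entries, as in
    the widely used co-occurrence feature implementations, while
    ``variance`` is the marginal level variance.
    """
    p = cm.p if isinstance(cm, CoocMatrix) else np.asarray(cm, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ContractError(f"co-occurrence matrix must be square, got {p.shape}")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ContractError("co-occurrence matrix is not normalized (sum != 1)")
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i[:, 0] * px))
    mu_y = float(np.sum(j[0, :] * py))
    var_x = float(np.sum((i[:, 0] - mu_x) ** 2 * px))
    var_y = float(np.sum((j[0, :] - mu_y) ** 2 * py))

    # distributions of i + j (2..2Ng) and |i - j| (0..Ng-1)
    sums = (i + j).ravel()
    diffs = np.abs(i - j).ravel()
    p_flat = p.ravel()
    p_sum = np.bincount(sums, weights=p_flat, minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(diffs, weights=p_flat, minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1)
    k_diff = np.arange(ng)

    def _entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log(q)))

    contrast = float(np.sum((i - j) ** 2 * p))
    if var_x > 0 and var_y > 0:
        correlation = float(
            np.sum((i - mu_x) * (j - mu_y) * p) / np.sqrt(var_x * var_y)
        )
    else:
        correlation = 0.0
    energy = float(np.sum(p**2))
    autocorrelation = float(np.sum(i * j * p))
    cp_base = i + j - mu_x - mu_y
    cluster_prominence = float(np.sum(cp_base**4 * p))
    cluster_shade = float(np.sum(cp_base**3 * p))
    dissimilarity = float(np.sum(np.abs(i - j) * p))
    entropy = _entropy(p_flat)
    homogeneity = float(np.sum(p / (1.0 + (i - j) ** 2)))
    maximum_probability = float(p.max())
    sum_of_squares = float(np.sum((i - p.mean()) ** 2 * p))
    variance = float(np.sum((i - mu_x) ** 2 * p))
    sum_average = float(np.sum(k_sum * p_sum))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * p_sum))
    sum_entropy = _entropy(p_sum)
    mu_diff = float(np.sum(k_diff * p_diff))
    difference_variance = float(np.sum((k_diff - mu_diff) ** 2 * p_diff))
    difference_entropy = _entropy(p_diff)
    hx = _entropy(px)
    hy = _entropy(py)
    pxy = px[:, None] * py[None, :]
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-np.sum(p[mask] * np.log(pxy[mask])))
    denom = max(hx, hy)
    imc = (entropy - hxy1) / denom if denom > 0 else 0.0
    inv_diff_norm = float(np.sum(p / (1.0 + np.abs(i - j) / ng)))
    inv_diff_moment_norm = float(np.sum(p / (1.0 + (i - j) ** 2 / ng**2)))

    return np.array(
        [
            contrast,
            correlation,
            energy,
            autocorrelation,
            cluster_prominence,
            cluster_shade,
            dissimilarity,
            entropy,
            homogeneity,
            maximum_probability,
            sum_of_squares,
            variance,
            sum_average,
            sum_variance,
            sum_entropy,
            difference_variance,
            difference_entropy,
            imc,
            inv_diff_norm,
            inv_diff_moment_norm,
        ]
    )


def _block_names(
    descriptor: str,
    component: str,
    subband_index: Sequence[tuple[int, int]],
    stat_names: Sequence[str],
) -> tuple[str, ...]:
    return tuple(
        f"{descriptor}.{component}.s{s}.k{k}.{stat}"
        for (s, k) in subband_index
        for stat in stat_names
    )


def _stack_and_index(
    stack: np.ndarray, subband_index: Sequence[tuple[int, int]] | None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise DimensionError(f"expected (n_subbands, rows, cols), got {stack.shape}")
    if subband_index is None:
        subband_index = [(1, k + 1) for k in range(stack.shape[0])]
    if len(subband_index) != stack.shape[0]:
        raise DimensionError(
            f"{stack.shape[0]} subbands but {len(subband_index)} index entries"
        )
    return stack, list(subband_index)


def cm_features(
    stack: np.ndarray,
    component: str = "magnitude",
    subband_index: Sequence[tuple[int, int]] | None = None,
    ng: int = 8,
    pd: int = 1,
) -> FeatureBlock:
    """Concatenated 20 co-occurrence statistics over all subbands (20 per band)."""
    stack, index = _stack_and_index(stack, subband_index)
    values = np.concatenate(
        [haralick20(cooccurrence_mean(quantize_subband(b, ng), ng, pd)) for b in stack]
    )
    return FeatureBlock(
        "cm", component, values, _block_names("cm", component, index, HARALICK_NAMES)
    )


def lbp_riu2(band: np.ndarray, p: int = 8, r: float = 2.0) -> np.ndarray:
    """Rotation-invariant uniform LBP histogram of one subband.

    Codes use the sign rule s(x) = 1 iff x >= 0 against the centre value,
    neighbours at radius ``r`` bilinearly interpolated, mapped to the P + 2
    rotation-invariant uniform labels.  The histogram is accumulated over
    interior pixels only (a border of ``ceil(r)`` pixels is discarded) and
    normalized to sum one.
    """
    band = np.asarray(band, dtype=np.float64)
    margin = int(np.ceil(r))
    if band.ndim != 2 or min(band.shape) <= 2 * margin:
        raise DataError(
            f"subband shape {band.shape} too small for LBP radius {r}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        codes = local_binary_pattern(band, p, r, method="uniform")
    interior = codes[margin:-margin, margin:-margin]
    hist = np.bincount(interior.astype(np.int64).ravel(), minlength=p + 2)
    return hist / hist.sum()


def lbp_features(
    stack: np.ndarray,
    component: str = "magnitude",
    subband_index: Sequence[tuple[int, int]] | None = None,
    p: int = 8,
    r: float = 2.0,
) -> FeatureBlock:
    """Concatenated riu2 LBP histograms over all subbands (P + 2 per band)."""
    stack, index = _stack_and_index(stack, subband_index)
    values = np.concatenate([lbp_riu2(b, p, r) for b in stack])
    names = _block_names(
        "lbp", component, index, [f"bin{b}" for b in range(p + 2)]
    )
    return FeatureBlock("lbp", component, values, names)


def losib(band: np.ndarray, p: int = 8, r: int = 1) -> np.ndarray:
    """Mean absolute centre-neighbour difference per direction.

    With the default P = 8, R = 1 the neighbours are the eight integer-offset
    8-connected pixels; the mean runs over all centres whose neighbourhood is
    fully inside the subband (no padding).
    """
    band = np.asarray(band, dtype=np.float64)
    if band.ndim != 2 or min(band.shape) < 2 * r + 1:
        raise DataError(f"subband shape {band.shape} too small for LOSIB radius {r}")
    if p == 8 and r == 1:
        offsets = _NEIGHBOURS8
    else:
        angles = 2.0 * np.pi * np.arange(p) / p
        offsets = [
            (int(np.round(-r * np.sin(a))), int(np.round(r * np.cos(a))))
            for a in angles
        ]
    m = r
    centre = band[m:-m, m:-m]
    out = np.empty(p)
    for idx, (dy, dx) in enumerate(offsets):
        neighbour = band[
            m + dy : band.shape[0] - m + dy, m + dx : band.shape[1] - m + dx
        ]
        out[idx] = np.abs(centre - neighbour).mean()
    return out


def losib_features(
    stack: np.ndarray,
    component: str = "magnitude",
    subband_index: Sequence[tuple[int, int]] | None = None,
    p: int = 8,
    r: int = 1,
) -> FeatureBlock:
    """Concatenated LOSIB vectors over all subbands (P per band)."""
    stack, index = _stack_and_index(stack, subband_index)
    values = np.concatenate([losib(b, p, r) for b in stack])
    names = _block_names("losib", component, index, [f"p{q}" for q in range(p)])
    return FeatureBlock("losib", component, values, names)


# ---------------------------------------------------------------------------
# SFTA
# ---------------------------------------------------------------------------


def multiotsu_thresholds(levels: np.ndarray, n_thresholds: int, nbins: int = 256) -> np.ndarray:
    """Multi-level Otsu thresholds by exact dynamic programming.

    Maximizes the between-class variance of a split of ``levels`` (integers
    in 0..nbins-1) into ``n_thresholds + 1`` classes.  Returns the
    ``n_thresholds`` class boundaries as half-integer thresholds t such that
    the classes are ``levels <= t`` bands.  O(n_thresholds * nbins^2).
    """
    flat = np.asarray(levels).ravel()
    if flat.min() < 0 or flat.max() >= nbins:
        raise DataError(f"levels must lie in 0..{nbins - 1}")
    hist = np.bincount(flat, minlength=nbins).astype(np.float64)
    csum = np.concatenate([[0.0], np.cumsum(hist)])
    cmom = np.concatenate([[0.0], np.cumsum(hist * np.arange(nbins))])
    # q[a, b]: contribution w * mu^2 of a class covering bins [a, b)
    w = csum[None, :] - csum[:, None]
    m = cmom[None, :] - cmom[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(w > 0, m**2 / np.where(w > 0, w, 1.0), 0.0)
    n_classes = n_thresholds + 1
    edges = np.arange(nbins + 1)
    best = q[0].copy()  # one class over bins [0, b)
    split = np.zeros((n_classes, nbins + 1), dtype=np.int64)
    valid = edges[:, None] <= edges[None, :]  # a <= b
    for c in range(2, n_classes + 1):
        scores = np.where(valid, best[:, None] + q, -np.inf)
        split[c - 1] = np.argmax(scores, axis=0)
        best = np.max(scores, axis=0)
    cuts = []
    b = nbins
    for c in range(n_classes, 1, -1):
        b = int(split[c - 1, b])
        cuts.append(b)
    return np.array(sorted(cuts), dtype=np.float64) - 0.5


def _rescale_levels(band: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Min-max rescale a subband to integer levels 0..nbins-1."""
    band = np.asarray(band, dtype=np.float64)
    lo, hi = band.min(), band.max()
    if hi == lo:
        return np.zeros(band.shape, dtype=np.int64)
    return np.minimum(
        ((band - lo) / (hi - lo) * nbins).astype(np.int64), nbins - 1
    )


def ttbd(band: np.ndarray, nt: int = 4, nbins: int = 256) -> list[np.ndarray]:
    """Two-threshold binary decomposition of a subband.

    The subband is min-max rescaled to ``nbins`` integer levels and
    thresholded with ``nt``-level Otsu thresholds t_1 < ... < t_nt.  The
    binary set consists of the ``nt`` upper sets {band > t_i} followed by
    the ``nt - 1`` band-pass sets {t_i < band <= t_{i+1}}, i.e. 2 nt - 1
    binary images.  A constant (or otherwise degenerate) subband yields
    all-zero binaries rather than an error.
    """
    if nt < 2:
        raise ValueError("nt must be >= 2")
    levels = _rescale_levels(band, nbins)
    n_binaries = 2 * nt - 1
    if len(np.unique(levels)) <= nt:
        return [np.zeros(levels.shape, dtype=bool) for _ in range(n_binaries)]
    t = multiotsu_thresholds(levels, nt, nbins)
    binaries = [levels > ti for ti in t]
    binaries += [(levels > t[i]) & (levels <= t[i + 1]) for i in range(nt - 1)]
    return binaries


def _border_pixels(binary: np.ndarray) -> np.ndarray:
    """Set pixels with at least one unset 4-neighbour (outside counts unset)."""
    padded = np.pad(binary, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return binary & ~interior


def box_counting_dimension(binary: np.ndarray) -> float:
    """Box-counting dimension of a binary image.

    Dyadic box sizes 1, 2, 4, ... up to half the minimum dimension; the
    dimension is the least-squares slope of log(count) against log(1/size).
    Returns 0.0 for an empty image.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return 0.0
    sizes = []
    s = 1
    while s <= min(binary.shape) // 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 0.0
    counts = []
    for s in sizes:
        pr = (-binary.shape[0]) % s
        pc = (-binary.shape[1]) % s
        padded = np.pad(binary, ((0, pr), (0, pc)), constant_values=False)
        blocks = padded.reshape(
            padded.shape[0] // s, s, padded.shape[1] // s, s
        ).any(axis=(1, 3))
        counts.append(blocks.sum())
    xs = np.log(1.0 / np.asarray(sizes, dtype=np.float64))
    ys = np.log(np.asarray(counts, dtype=np.float64))
    return float(np.polyfit(xs, ys, 1)[0])


def sfta_region_features(binary: np.ndarray, band: np.ndarray) -> np.ndarray:
    """(boundary fractal dimension, mean gray level, pixel count) of a region.

    ``band`` supplies the gray levels averaged over the region's set pixels;
    an empty region yields (0, 0, 0).
    """
    binary = np.asarray(binary, dtype=bool)
    band = np.asarray(band, dtype=np.float64)
    if binary.shape != band.shape:
        raise DimensionError(
            f"binary shape {binary.shape} does not match band shape {band.shape}"
        )
    count = int(binary.sum())
    if count == 0:
        return np.zeros(3)
    border = _border_pixels(binary)
    dim = box_counting_dimension(border)
    mean_level = float(band[binary].mean())
    return np.array([dim, mean_level, float(count)])


def sfta(band: np.ndarray, nt: int = 4, nbins: int = 256) -> np.ndarray:
    """SFTA vector of one subband: 3 features per TTBD binary image.

    With the default ``nt = 4`` this yields 7 binary images x 3 features
    = 21 attributes, ordered [fractal dim, mean level, count] per binary.
    Gray levels for the mean are the ``nbins``-level rescaled subband, so
    the vector is invariant to affine rescaling of the input.
    """
    levels = _rescale_levels(band, nbins).astype(np.float64)
    return np.concatenate(
        [sfta_region_features(b, levels) for b in ttbd(band, nt, nbins)]
    )


def sfta_features(
    stack: np.ndarray,
    component: str = "magnitude",
    subband_index: Sequence[tuple[int, int]] | None = None,
    nt: int = 4,
    nbins: int = 256,
) -> FeatureBlock:
    """Concatenated SFTA vectors over all subbands (3 (2 nt - 1) per band)."""
    stack, index = _stack_and_index(stack, subband_index)
    values = np.concatenate([sfta(b, nt, nbins) for b in stack])
    stat_names = [
        f"b{j}.{stat}"
        for j in range(2 * nt - 1)
        for stat in ("fractal_dim", "mean_level", "count")
    ]
    return FeatureBlock(
        "sfta", component, values, _block_names("sfta", component, index, stat_names)
    )


# ---------------------------------------------------------------------------
# CM-dot
# ---------------------------------------------------------------------------


def _block_mean_reduce(band: np.ndarray, ng: int) -> np.ndarray:
    """Reduce a subband to an ng x ng matrix of block means."""
    rows = np.array_split(np.asarray(band, dtype=np.float64), ng, axis=0)
    return np.array(
        [[blk.mean() for blk in np.array_split(row, ng, axis=1)] for row in rows]
    )


def cmdot_subband(band: np.ndarray, ng: int = 8, pd: int = 1) -> np.ndarray:
    """CM-dot vector of one magnitude subband (length ng).

    The subband's orientation-averaged co-occurrence matrix is multiplied
    entrywise (Hadamard product) with the ng x ng block-mean reduction of
    the magnitude coefficients; the product is summarised by its
    column-wise maxima.
    """
    cm = cooccurrence_mean(quantize_subband(band, ng), ng, pd)
    reduced = _block_mean_reduce(band, ng)
    return (cm.p * reduced).max(axis=0)


def cmdot_features(
    stack: np.ndarray,
    component: str = "magnitude",
    subband_index: Sequence[tuple[int, int]] | None = None,
    ng: int = 8,
    pd: int = 1,
) -> FeatureBlock:
    """Concatenated CM-dot vectors over all magnitude subbands (ng per band)."""
    if component != "magnitude":
        raise ContractError("cmdot is defined on the magnitude component only")
    stack, index = _stack_and_index(stack, subband_index)
    values = np.concatenate([cmdot_subband(b, ng, pd) for b in stack])
    names = _block_names("cmdot", component, index, [f"col{c}" for c in range(ng)])
    return FeatureBlock("cmdot", component, values, names)


_FAMILY_FUNCS = {
    "cm": cm_features,
    "lbp": lbp_features,
    "losib": losib_features,
    "sfta": sfta_features,
    "cmdot": cmdot_features,
}


def extract_feature_blocks(
    coeff_stack,
    descriptors: Sequence[str] = ("cm", "lbp", "losib", "sfta"),
    components: Sequence[str] = ("magnitude", "rp"),
    ng: int = 8,
    nt: int = 4,
) -> dict[tuple[str, str], FeatureBlock]:
    """Compute the requested descriptor families on a coefficient stack.

    Returns blocks keyed by (descriptor, component).  ``cmdot`` is computed
    on the magnitude component only regardless of ``components``.
    """
    blocks: dict[tuple[str, str], FeatureBlock] = {}
    index = coeff_stack.subband_index
    for descriptor in descriptors:
        if descriptor not in _FAMILY_FUNCS:
            raise ValueError(f"unknown descriptor family {descriptor!r}")
        targets = ("magnitude",) if descriptor == "cmdot" else components
        for comp in targets:
            stack = coeff_stack.component(comp)
            if descriptor == "cm":
                block = cm_features(stack, comp, index, ng=ng)
            elif descriptor == "lbp":
                block = lbp_features(stack, comp, index)
            elif descriptor == "losib":
                block = losib_features(stack, comp, index)
            elif descriptor == "sfta":
                block = sfta_features(stack, comp, index, nt=nt)
            else:
                block = cmdot_features(stack, comp, index, ng=ng)
            blocks[(descriptor, comp)] = block
    return blocks
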