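"""Descriptor fusion, standardization and varimax-rotated PCA reduction.

Fusion is pure concatenation of per-sample :class:`FeatureBlock` vectors in
a fixed order: relative-phase blocks first, then magnitude blocks, each in
the canonical family order (cm, lbp, losib, sfta, cmdot).  The three named
recipes match the combinations evaluated in the package's experiments:

* ``fusion1`` — cm + lbp + losib + sfta on both components (3776 columns
  under S = 4, K = 8);
* ``fusion2`` — cm + losib on both components (1792 columns);
* ``fusion3`` — cm + lbp + losib on RP and cm + lbp + sfta + cmdot on
  magnitude.

Reduction standardizes features to zero mean / unit variance (training
statistics only), fits PCA on the training data and rotates the leading
loadings to maximize the varimax (orthomax, gamma = 1) criterion.  The
rotated basis stays orthonormal, so projecting with all components is an
isometry.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .descriptors import FeatureBlock
from .errors import AssemblyError, DimensionError

__all__ = [
    "BLOCK_ORDER",
    "COMPONENT_ORDER",
    "FusionSpec",
    "FUSION_1",
    "FUSION_2",
    "FUSION_3",
    "FUSION_PRESETS",
    "FeatureMatrix",
    "fuse",
    "Standardizer",
    "standardize_fit",
    "standardize_apply",
    "varimax",
    "PCAModel",
    "pca_fit",
    "pca_project",
    "pc_sweep",
]

logger = logging.getLogger(__name__)

BLOCK_ORDER = ("cm", "lbp", "losib", "sfta", "cmdot")
COMPONENT_ORDER = ("rp", "magnitude")


@dataclasses.dataclass(frozen=True)
class FusionSpec:
    """Declarative recipe naming the blocks concatenated per component."""

    name: str
    rp_blocks: tuple[str, ...]
    mag_blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rp_blocks and not self.mag_blocks:
            raise ValueError("a fusion spec must select at least one block")
        for tag in self.rp_blocks + self.mag_blocks:
            if tag not in BLOCK_ORDER:
                raise ValueError(f"unknown descriptor tag {tag!r}")

    def ordered_keys(self) -> list[tuple[str, str]]:
        """(descriptor, component) pairs in canonical concatenation order."""
        keys = []
        for comp in COMPONENT_ORDER:
            tags = self.rp_blocks if comp == "rp" else self.mag_blocks
            keys.extend(
                (tag, comp) for tag in BLOCK_ORDER if tag in tags
            )
        return keys


FUSION_1 = FusionSpec("fusion1", ("cm", "lbp", "losib", "sfta"), ("cm", "lbp", "losib", "sfta"))
FUSION_2 = FusionSpec("fusion2", ("cm", "losib"), ("cm", "losib"))
FUSION_3 = FusionSpec("fusion3", ("cm", "lbp", "losib"), ("cm", "lbp", "sfta", "cmdot"))
FUSION_PRESETS = {spec.name: spec for spec in (FUSION_1, FUSION_2, FUSION_3)}


@dataclasses.dataclass
class FeatureMatrix:
    """Sample-by-feature matrix with aligned names, ids and labels."""

    X: np.ndarray
    column_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise DimensionError(f"expected a 2-D matrix, got shape {self.X.shape}")
        if self.X.shape[1] != len(self.column_names):
            raise DimensionError(
                f"{self.X.shape[1]} columns but {len(self.column_names)} names"
            )
        if self.X.shape[0] != len(self.sample_ids):
            raise DimensionError(
                f"{self.X.shape[0]} rows but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise DimensionError("column names are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.X.shape[0]:
                raise DimensionError("labels do not align with rows")
        if not np.all(np.isfinite(self.X)):
            raise DimensionError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.X, index=list(self.sample_ids), columns=list(self.column_names))
        if self.labels is not None:
            frame.insert(0, "label", self.labels)
        return frame


def fuse(
    samples: Sequence[Mapping[tuple[str, str], FeatureBlock]],
    spec: FusionSpec,
    labels: Sequence | None = None,
    sample_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Concatenate the blocks selected by ``spec`` for every sample.

    ``samples`` maps (descriptor, component) to a :class:`FeatureBlock` per
    sample.  Raises :class:`AssemblyError` naming the sample and block if a
    requested block is missing.
    """
    keys = spec.ordered_keys()
    if not samples:
        raise ValueError("no samples to fuse")
    rows = []
    names: tuple[str, ...] | None = None
    for pos, blocks in enumerate(samples):
        parts = []
        part_names = []
        for key in keys:
            if key not in blocks:
                raise AssemblyError(
                    f"sample {pos}: missing feature block {key[0]!r} "
                    f"for component {key[1]!r}"
                )
            block = blocks[key]
            parts.append(np.asarray(block.values, dtype=np.float64))
            part_names.extend(block.column_names)
        row = np.concatenate(parts)
        if names is None:
            names = tuple(part_names)
        elif tuple(part_names) != names:
            raise AssemblyError(f"sample {pos}: block columns differ from sample 0")
        rows.append(row)
    ids = tuple(sample_ids) if sample_ids is not None else tuple(
        str(i) for i in range(len(rows))
    )
    return FeatureMatrix(
        np.vstack(rows), names, ids,
        None if labels is None else np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Standardizer:
    """Per-feature centering/scaling fitted on a training split.

    Zero-variance training columns are dropped (their indices are recorded
    in ``dropped``) so every retained standard deviation is positive.
    """

    mean: np.ndarray
    std: np.ndarray
    kept: np.ndarray
    dropped: np.ndarray


def _as_array(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.X
    return np.asarray(x, dtype=np.float64)


def standardize_fit(train) -> Standardizer:
    """Estimate per-feature mean and standard deviation from training data."""
    X = _as_array(train)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    # a constant column can show a tiny spurious std from cancellation;
    # detect zero variance by the exact value range
    constant = X.max(axis=0) == X.min(axis=0)
    kept = np.flatnonzero(~constant & (std > 0))
    dropped = np.flatnonzero(constant | (std == 0))
    if dropped.size:
        logger.warning(
            "standardize_fit: dropping %d zero-variance feature(s)", dropped.size
        )
    return Standardizer(mean=mean[kept], std=std[kept], kept=kept, dropped=dropped)


def standardize_apply(x, s: Standardizer) -> np.ndarray:
    """Transform data with training statistics only."""
    X = _as_array(x)
    if X.shape[1] != s.kept.size + s.dropped.size:
        raise DimensionError(
            f"data has {X.shape[1]} columns, standardizer was fitted on "
            f"{s.kept.size + s.dropped.size}"
        )
    return (X[:, s.kept] - s.mean) / s.std


# ---------------------------------------------------------------------------
# PCA with varimax rotation
# ---------------------------------------------------------------------------


def varimax(
    loadings: np.ndarray,
    gamma: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Orthomax rotation of a loading matrix (gamma = 1: varimax).

    Returns the k x k orthogonal rotation matrix maximizing the orthomax
    criterion for the p x k ``loadings``.
    """
    p, k = loadings.shape
    if k < 2:
        return np.eye(k)
    rotation = np.eye(k)
    obj = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        grad = rotated**3 - (gamma / p) * rotated * np.sum(rotated**2, axis=0)
        u, s, vt = np.linalg.svd(loadings.T @ grad)
        rotation = u @ vt
        new_obj = float(np.sum(s))
        if new_obj <= obj * (1.0 + tol):
            break
        obj = new_obj
    return rotation


@dataclasses.dataclass(frozen=True)
class PCAModel:
    """Varimax-rotated principal-component basis fitted on training data."""

    training_mean: np.ndarray
    rotated_basis: np.ndarray  # (n_features, n_components), orthonormal
    n_components: int


def pca_fit(train, n_components: int, rotate: bool = True) -> PCAModel:
    """Fit PCA on training data and varimax-rotate the leading loadings.

    ``n_components`` must not exceed min(n_features, n_train - 1).  The
    returned basis is orthonormal; each column's largest-magnitude loading
    is made positive for a deterministic sign convention.
    """
    X = _as_array(train)
    n, p = X.shape
    limit = min(p, n - 1)
    if not 1 <= n_components <= limit:
        raise DimensionError(
            f"n_components={n_components} outside 1..{limit} "
            f"(min(n_features, n_train - 1))"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    basis = pca.components_.T  # (p, k), orthonormal columns
    if rotate:
        basis = basis @ varimax(basis)
    # deterministic sign: largest-|loading| entry positive per column
    signs = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    basis = basis * signs
    return PCAModel(
        training_mean=pca.mean_, rotated_basis=basis, n_components=n_components
    )


def pca_project(x, model: PCAModel) -> np.ndarray:
    """Center by the training mean and project onto the rotated basis."""
    X = _as_array(x)
    if X.shape[1] != model.rotated_basis.shape[0]:
        raise DimensionError(
            f"data has {X.shape[1]} columns, model expects "
            f"{model.rotated_basis.shape[0]}"
        )
    return (X - model.training_mean) @ model.rotated_basis


def pc_sweep(
    X,
    y,
    folds,
    classifier_config,
    step: int = 50,
    max_components: int | None = None,
    positive_label=None,
):
    """Cross-validated performance at step, 2*step, ... principal components.

    Evaluates :func:`sheartex.classify.cross_validate` with per-fold PCA at
    each grid point (the last point is the maximum usable component count)
    and returns ``(curve, best)`` where ``curve`` is a list of
    ``(n_components, MetricsReport)`` and ``best`` the argmax-accuracy entry.
    """
    from .classify import cross_validate

    Xa = _as_array(X)
    y = np.asarray(y)
    if max_components is None:
        fold_sizes = np.bincount(folds.assignments)
        min_train = len(y) - fold_sizes.max()
        max_components = min(Xa.shape[1], min_train - 1)
    grid = list(range(step, max_components + 1, step))
    if not grid or grid[-1] != max_components:
        grid.append(max_components)
    curve = []
    for n in grid:
        report = cross_validate(
            Xa, y, folds, classifier_config, n_components=n,
            positive_label=positive_label,
        )
        curve.append((n, report))
    best = max(curve, key=lambda item: item[1].acc_mean)
    return curve, best
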