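"""End-to-end convenience layer: images -> blocks -> fused feature matrix."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .descriptors import FeatureBlock, extract_feature_blocks
from .fusion import FeatureMatrix, FusionSpec, fuse
from .shearlet import ShearletSystem, build_shearlet_system, shearlet_transform

__all__ = ["extract_dataset_blocks", "extract_fused_features"]


def _needed_descriptors(spec: FusionSpec) -> tuple[list[str], list[str]]:
    tags = sorted(set(spec.rp_blocks) | set(spec.mag_blocks))
    components = []
    if spec.mag_blocks:
        components.append("magnitude")
    if spec.rp_blocks:
        components.append("rp")
    return tags, components


def extract_dataset_blocks(
    images: Sequence[np.ndarray],
    descriptors: Sequence[str] = ("cm", "lbp", "losib", "sfta"),
    components: Sequence[str] = ("magnitude", "rp"),
    system: ShearletSystem | None = None,
    scales: int = 4,
    directions_per_scale: int = 8,
    ng: int = 8,
    nt: int = 4,
) -> list[dict[tuple[str, str], FeatureBlock]]:
    """Descriptor blocks for every image, building one system per shape."""
    systems: dict[tuple[int, int], ShearletSystem] = {}
    if system is not None:
        systems[system.shape] = system
    out = []
    for img in images:
        arr = np.asarray(img, dtype=np.float64)
        if arr.shape not in systems:
            systems[arr.shape] = build_shearlet_system(
                arr.shape[0], arr.shape[1], scales, directions_per_scale
            )
        stack = shearlet_transform(arr, systems[arr.shape])
        out.append(
            extract_feature_blocks(stack, descriptors, components, ng=ng, nt=nt)
        )
    return out


def extract_fused_features(
    images: Sequence[np.ndarray],
    spec: FusionSpec,
    labels: Sequence | None = None,
    sample_ids: Sequence[str] | None = None,
    **kwargs,
) -> FeatureMatrix:
    """Extract exactly the blocks a fusion recipe needs and concatenate."""
    descriptors, components = _needed_descriptors(spec)
    blocks = extract_dataset_blocks(
        images, descriptors=descriptors, components=components, **kwargs
    )
    return fuse(blocks, spec, labels=labels, sample_ids=sample_ids)
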