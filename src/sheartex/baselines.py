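"""Comparison descriptor sets computed on the same shearlet stacks.

Four previously published shearlet-domain feature recipes are provided so
they can be evaluated through the identical fusion/cross-validation
machinery as the package's own descriptors:

* ``vo`` — circular mean and circular variance of the relative phase plus
  the mean magnitude, per subband (3 x 32 = 96 values);
* ``meshkini`` — the co-occurrence-matrix/magnitude Hadamard-product
  summary (shared construction with the ``cmdot`` family);
* ``zhou`` — co-occurrence statistics of the first horizontal-cone layer,
  mean/variance/energy of layers 1 and 3 in both cones, and per-column
  maxima of the finest-scale subbands;
* ``dong`` — mean and standard deviation per magnitude subband (64 values).

Cone membership follows the package convention: directions k <= K/2 form
the horizontal cone, k > K/2 the vertical cone; "layers" count scales
coarse to fine.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import circmean, circvar

from .descriptors import (
    HARALICK_NAMES,
    cmdot_subband,
    cooccurrence_mean,
    haralick20,
    quantize_subband,
)
from .errors import ContractError
from .shearlet import CoefficientStack

__all__ = [
    "BaselineBlock",
    "vo_features",
    "meshkini_features",
    "zhou_features",
    "dong_features",
    "BASELINES",
]


@dataclasses.dataclass(frozen=True)
class BaselineBlock:
    method: str
    values: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.column_names):
            raise ContractError("values and names differ in length")

    def __len__(self) -> int:
        return len(self.values)


def vo_features(stack: CoefficientStack) -> BaselineBlock:
    """Circular mean/variance of RP and mean magnitude, per subband."""
    values = []
    names = []
    for pos, (s, k) in enumerate(stack.subband_index):
        rp = stack.rp[pos].ravel()
        values.extend(
            [
                float(circmean(rp, high=np.pi, low=-np.pi)),
                float(circvar(rp, high=np.pi, low=-np.pi)),
                float(stack.magnitude[pos].mean()),
            ]
        )
        names.extend(
            [f"vo.s{s}.k{k}.circ_mean", f"vo.s{s}.k{k}.circ_var", f"vo.s{s}.k{k}.mag_mean"]
        )
    return BaselineBlock("vo", np.array(values), tuple(names))


def meshkini_features(stack: CoefficientStack, ng: int = 8) -> BaselineBlock:
    """Hadamard product of each subband's CM with reduced magnitude."""
    values = []
    names = []
    for pos, (s, k) in enumerate(stack.subband_index):
        vec = cmdot_subband(stack.magnitude[pos], ng)
        values.append(vec)
        names.extend(f"meshkini.s{s}.k{k}.col{c}" for c in range(len(vec)))
    return BaselineBlock("meshkini", np.concatenate(values), tuple(names))


_ZHOU_CM_STATS = ("entropy", "correlation", "contrast", "energy")


def zhou_features(stack: CoefficientStack, ng: int = 8) -> BaselineBlock:
    """Three concatenated parts from selected magnitude subbands.

    (1) entropy/correlation/contrast/energy of the co-occurrence matrix of
    every first-layer horizontal-cone subband; (2) mean, variance and energy
    (sum of squares) of every subband in layers 1 and 3, both cones; (3)
    column-wise maxima of every finest-scale subband.
    """
    k_half = stack.directions_per_scale // 2
    n_scales = max(s for s, _ in stack.subband_index)
    idx = {name: HARALICK_NAMES.index(name) for name in _ZHOU_CM_STATS}
    values = []
    names = []
    # part 1: CM statistics, first layer, horizontal cone
    for pos, (s, k) in enumerate(stack.subband_index):
        if s == 1 and k <= k_half:
            stats = haralick20(
                cooccurrence_mean(quantize_subband(stack.magnitude[pos], ng), ng)
            )
            for name in _ZHOU_CM_STATS:
                values.append(stats[idx[name]])
                names.append(f"zhou.cm.s{s}.k{k}.{name}")
    # part 2: mean / variance / energy, layers 1 and 3, both cones
    for pos, (s, k) in enumerate(stack.subband_index):
        if s in (1, 3):
            band = stack.magnitude[pos]
            values.extend([band.mean(), band.var(), float(np.sum(band**2))])
            names.extend(
                f"zhou.stat.s{s}.k{k}.{stat}" for stat in ("mean", "variance", "energy")
            )
    # part 3: column maxima of the finest scale
    for pos, (s, k) in enumerate(stack.subband_index):
        if s == n_scales:
            maxima = stack.magnitude[pos].max(axis=0)
            values.extend(maxima.tolist())
            names.extend(
                f"zhou.colmax.s{s}.k{k}.c{c}" for c in range(len(maxima))
            )
    return BaselineBlock("zhou", np.array(values), tuple(names))


def dong_features(stack: CoefficientStack) -> BaselineBlock:
    """Mean and standard deviation of each magnitude subband."""
    values = []
    names = []
    for pos, (s, k) in enumerate(stack.subband_index):
        band = stack.magnitude[pos]
        values.extend([band.mean(), band.std()])
        names.extend([f"dong.s{s}.k{k}.mean", f"dong.s{s}.k{k}.std"])
    return BaselineBlock("dong", np.array(values), tuple(names))


BASELINES = {
    "vo": vo_features,
    "meshkini": meshkini_features,
    "zhou": zhou_features,
    "dong": dong_features,
}
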