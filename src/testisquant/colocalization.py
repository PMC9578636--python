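"""Voxel-wise Pearson colocalization between two fluorescence channels.

The coefficient is the sample Pearson correlation of paired voxel
intensities,

    r = sum((a_i - a_bar)(b_i - b_bar))
        / sqrt(sum((a_i - a_bar)^2) * sum((b_i - b_bar)^2)),

computed over the whole volume by default or over an optional mask (for
example a tissue-foreground mask). The computation runs in double
precision with an explicit two-pass mean so 16-bit data cannot suffer
catastrophic cancellation. A channel that is constant within the mask has
no defined correlation and raises, rather than returning NaN.

Per-image r values are aggregated per genotype by arithmetic mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedCorrelationError
from .imaging_io import ImageStack

__all__ = ["ColocResult", "pearson_coefficient", "coloc_scatter"]


@dataclass(frozen=True)
class ColocResult:
    """One Pearson colocalization measurement."""

    r: float
    n_voxels: int
    channels: tuple[str, str]
    mask_description: str = "whole volume"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")
        if self.n_voxels < 2:
            raise ValueError("Pearson r needs at least 2 voxels")


def _masked_pair(stack, channel_a, channel_b, mask):
    a = stack.channel(channel_a)
    b = stack.channel(channel_b)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != tuple(stack.shape):
            raise ValueError("mask shape must match the stack's spatial shape")
        a, b = a[mask], b[mask]
        desc = f"mask ({int(mask.sum())} voxels)"
    else:
        a, b = a.ravel(), b.ravel()
        desc = "whole volume"
    if a.size < 2:
        raise ValueError("need at least 2 voxels to correlate")
    return a.astype(np.float64), b.astype(np.float64), desc


def pearson_coefficient(
    stack: ImageStack,
    channel_a: str,
    channel_b: str,
    mask: np.ndarray | None = None,
) -> ColocResult:
    """Pearson colocalization coefficient between two channels.

    Raises :class:`UndefinedCorrelationError` if either channel is
    constant within the mask.
    """
    a, b, desc = _masked_pair(stack, channel_a, channel_b, mask)
    ac = a - a.mean()
    bc = b - b.mean()
    ssa = float(ac @ ac)
    ssb = float(bc @ bc)
    if ssa == 0.0 or ssb == 0.0:
        const = channel_a if ssa == 0.0 else channel_b
        raise UndefinedCorrelationError(
            f"undefined correlation: channel {const!r} is constant "
            f"within the {desc}")
    r = float(ac @ bc) / np.sqrt(ssa * ssb)
    r = float(np.clip(r, -1.0, 1.0))
    return ColocResult(r, int(a.size), (channel_a, channel_b), desc)


def coloc_scatter(
    stack: ImageStack,
    channel_a: str,
    channel_b: str,
    mask: np.ndarray | None = None,
    bins: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint intensity histogram of two channels (figure-ready scatter).

    Returns ``(hist, a_edges, b_edges)``; the histogram total equals the
    number of voxels used, and each marginal sums to the same count.
    """
    a, b, _ = _masked_pair(stack, channel_a, channel_b, mask)
    hist, a_edges, b_edges = np.histogram2d(a, b, bins=bins)
    return hist, a_edges, b_edges
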