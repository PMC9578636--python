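"""Individualization-complex geometry: the actin-nucleus association angle.

During sperm individualization, a cone of F-actin travels along each
elongated spermatid nucleus. In an organized (wildtype-like) complex the
actin cone and the nucleus form a straight line — a 180 degree vertex
angle — while disorganization bends the pair to smaller angles. The angle
is measured at the actin-nucleus junction between the ray to the distal
actin landmark and the ray to the distal nucleus landmark, in physical
(micrometre) coordinates so voxel anisotropy cannot bias it, and reported
in (0, 180] (undirected rays).

Landmark extraction from image stacks is automated: each actin component
is paired with its nearest nuclear component, each cluster's principal
axis supplies distal endpoints, and the vertex is the point of closest
approach between the two clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imaging_io import ImageStack

__all__ = ["ICMeasurement", "association_angle", "extract_ic_landmarks",
           "ic_summary"]


@dataclass(frozen=True)
class ICMeasurement:
    """Three landmarks of one complex and the vertex angle they subtend."""

    p_actin: tuple[float, float, float]
    p_vertex: tuple[float, float, float]
    p_nucleus: tuple[float, float, float]
    angle_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_deg <= 180.0:
            raise ValueError(f"angle out of (0, 180]: {self.angle_deg}")


def association_angle(
    p_actin: Sequence[float],
    p_vertex: Sequence[float],
    p_nucleus: Sequence[float],
) -> float:
    """Vertex angle (degrees) between rays vertex->actin and vertex->nucleus.

    Points are (z, y, x) positions in micrometres. The angle lies in
    (0, 180]; 180 means the actin cone and nucleus are collinear
    (linear alignment), smaller angles mean disorganization. Coincident
    points leave the rays undefined and raise ``ValueError``.
    """
    u = np.asarray(p_actin, dtype=float) - np.asarray(p_vertex, dtype=float)
    v = np.asarray(p_nucleus, dtype=float) - np.asarray(p_vertex, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("coincident points: vertex angle undefined")
    cosang = np.clip(float(u @ v) / (nu * nv), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    return angle if angle > 0.0 else 0.0  # exactly-0 never occurs for distinct rays


def _component_axis(coords_um: np.ndarray, weights: np.ndarray):
    """Weighted principal axis of a voxel cluster: (centroid, end1, end2)."""
    w = weights / weights.sum()
    centroid = w @ coords_um
    centered = coords_um - centroid
    cov = (centered * w[:, None]).T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    proj = centered @ axis
    return centroid, centroid + proj.min() * axis, centroid + proj.max() * axis


def _labelled_clusters(img, voxel_size, min_voxels=30, smooth_um=0.4):
    """Threshold a channel and return per-component (coords_um, weights).

    A light pre-threshold blur bridges sub-voxel gaps so one arm stays one
    component; fragments below ``min_voxels`` are discarded.
    """
    img = img.astype(np.float64)
    if np.ptp(img) == 0:
        return []
    smoothed = ndimage.gaussian_filter(
        img, sigma=[smooth_um / v for v in voxel_size])
    mask = smoothed > threshold_otsu(smoothed)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    vs = np.asarray(voxel_size)
    out = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if len(idx) < min_voxels:
            continue
        out.append((idx * vs, img[labels == lab]))
    return out


def extract_ic_landmarks(
    stack: ImageStack,
    actin_channel: str = "actin",
    nuclear_channel: str = "nuclear",
) -> list[ICMeasurement]:
    """Detect complexes and measure their actin-nucleus angles.

    Each actin component is paired with the nearest nuclear component (by
    centroid). For each pair, the endpoints of both principal axes are
    computed; the vertex is the midpoint of the two mutually closest
    endpoints, and the distal endpoints become the actin and nucleus
    landmarks. Returns an empty list when nothing is detected.
    """
    actin_clusters = _labelled_clusters(stack.channel(actin_channel),
                                        stack.voxel_size)
    nuc_clusters = _labelled_clusters(stack.channel(nuclear_channel),
                                      stack.voxel_size)
    if not actin_clusters or not nuc_clusters:
        return []
    actin_axes = [_component_axis(c, w) for c, w in actin_clusters]
    nuc_axes = [_component_axis(c, w) for c, w in nuc_clusters]
    measurements = []
    for _, a_end1, a_end2 in actin_axes:
        a_ends = [a_end1, a_end2]
        # pair with the nuclear cluster whose endpoint approaches closest
        best = None
        for j, (_, n_end1, n_end2) in enumerate(nuc_axes):
            n_ends = [n_end1, n_end2]
            for ai in (0, 1):
                for ni in (0, 1):
                    d = float(np.linalg.norm(a_ends[ai] - n_ends[ni]))
                    if best is None or d < best[0]:
                        best = (d, j, ai, ni)
        _, j, ai, ni = best
        n_ends = [nuc_axes[j][1], nuc_axes[j][2]]
        vertex = (a_ends[ai] + n_ends[ni]) / 2.0
        p_actin = a_ends[1 - ai]
        p_nucleus = n_ends[1 - ni]
        # the angle comes from the fitted arm axes (distal minus proximal
        # endpoint), which is robust to vertex-localization error; the
        # vertex itself is reported as the closest-approach midpoint
        d_actin = p_actin - a_ends[ai]
        d_nuc = p_nucleus - n_ends[ni]
        angle = association_angle(vertex + d_actin, vertex, vertex + d_nuc)
        measurements.append(ICMeasurement(tuple(p_actin), tuple(vertex),
                                          tuple(p_nucleus), angle))
    return measurements


def ic_summary(
    measurements: Sequence[ICMeasurement | float],
    genotype: str = "",
) -> dict:
    """Mean angle +/- SEM over a genotype's measured complexes."""
    if len(measurements) == 0:
        raise ValueError("ic_summary needs at least one measurement")
    angles = np.asarray([
        m.angle_deg if isinstance(m, ICMeasurement) else float(m)
        for m in measurements])
    n = len(angles)
    sem = float(angles.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {"genotype": genotype, "mean_angle_deg": float(angles.mean()),
            "sem_deg": sem, "n": n}
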