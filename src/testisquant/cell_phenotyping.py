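"""Marker-based cell classification with spatial gating to the hub.

The rules implemented here are the operational definitions used for testis
niche quantification:

* **GSC** (germline stem cell): a Vasa-positive *single* cell contacting
  the hub — operationally, hub surface-to-surface distance at most
  ``contact_tol_um`` and no other Vasa-positive centroid within the
  singleness distance (a proxy for not sitting inside a multi-cell cyst).
* **CySC** (cyst stem cell): a Zfh-1-positive cell in direct proximity to
  the hub, strictly closer than 10 um (surface-to-surface).
* **Spermatid bundle**: a cluster of 64 syncytial spermatid nuclei;
  counted by single-linkage clustering of nuclear centroids, keeping
  clusters of at least ``min_bundle_nuclei`` members so a few segmentation
  misses do not drop a bundle.

Marker positivity itself is threshold-based (mean cell intensity above a
per-channel cutoff); the default helper derives the cutoff as background
mean + 3 x background SD, since visual scoring is not reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu

from .errors import ChannelRoleError, HubNotFoundError
from .imaging_io import CellTable, ImageStack

__all__ = ["HubRegion", "detect_hub", "flag_markers", "hub_distances",
           "classify_gsc", "classify_cysc", "count_bundles",
           "measure_intensity", "marker_threshold_from_background"]

DEFAULT_CONTACT_TOL_UM = 0.5
DEFAULT_CYSC_MAX_DIST_UM = 10.0
DEFAULT_BUNDLE_LINKAGE_UM = 3.0
DEFAULT_MIN_BUNDLE_NUCLEI = 48  # 3/4 of the canonical 64
DEFAULT_MIN_HUB_VOLUME_UM3 = 50.0


@dataclass
class HubRegion:
    """The detected hub: a single connected somatic-cell cluster."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    centroid_um: tuple[float, float, float]
    equivalent_radius_um: float

    def surface_distance_map(self) -> np.ndarray:
        """Distance (um) from every voxel to the hub surface (0 inside)."""
        return ndimage.distance_transform_edt(~self.mask,
                                              sampling=self.voxel_size)


def detect_hub(
    stack: ImageStack,
    hub_channel: str = "hub",
    sigma_um: float = 1.0,
    min_volume_um3: float = DEFAULT_MIN_HUB_VOLUME_UM3,
) -> HubRegion:
    """Locate the hub as the largest bright blob in the hub-marker channel.

    The channel is smoothed, Otsu-thresholded, and the largest connected
    component above ``min_volume_um3`` returned. Raises
    :class:`HubNotFoundError` when nothing qualifies.
    """
    img = stack.channel(hub_channel).astype(np.float64)
    vs = stack.voxel_size
    if sigma_um > 0:
        img = ndimage.gaussian_filter(img, sigma=[sigma_um / v for v in vs])
    if np.ptp(img) == 0:
        raise HubNotFoundError("hub not found: hub channel is constant")
    mask = img > threshold_otsu(img)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise HubNotFoundError("hub not found: no foreground component")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))
    voxel_volume = float(np.prod(vs))
    if counts[best] * voxel_volume < min_volume_um3:
        raise HubNotFoundError(
            f"hub not found: largest component is "
            f"{counts[best] * voxel_volume:.1f} um^3 < {min_volume_um3} um^3")
    hub_mask = labels == best
    com = ndimage.center_of_mass(hub_mask)
    centroid = tuple(float(c) * v for c, v in zip(com, vs))
    eq_radius = (3.0 * counts[best] * voxel_volume / (4.0 * np.pi)) ** (1 / 3)
    return HubRegion(hub_mask, vs, centroid, float(eq_radius))


def marker_threshold_from_background(
    stack: ImageStack, channel: str, background_mask: np.ndarray,
    k: float = 3.0,
) -> float:
    """Positivity cutoff = background mean + k x background SD."""
    vals = stack.channel(channel)[background_mask].astype(np.float64)
    if vals.size == 0:
        raise ValueError("background mask is empty")
    return float(vals.mean() + k * vals.std())


def flag_markers(
    table: CellTable,
    rules: Mapping[str, float],
) -> CellTable:
    """Set per-marker positivity flags from mean-intensity thresholds.

    ``rules`` maps a marker channel name to an absolute intensity cutoff;
    a cell is positive when its mean intensity in that channel exceeds the
    cutoff. Adds a ``<marker>_pos`` column per rule.
    """
    df = table.df.copy()
    for marker, thr in rules.items():
        col = f"mean_{marker}"
        if col not in df.columns:
            raise ChannelRoleError(
                f"marker rule for {marker!r} needs column {col!r}; "
                "measure that channel in count_cells first")
        df[f"{marker}_pos"] = df[col] > float(thr)
    return CellTable(df, genotype=table.genotype, source=table.source)


def hub_distances(table: CellTable, hub: HubRegion) -> CellTable:
    """Add surface-to-surface hub distance (um) for every cell.

    Distance from the cell centroid to the hub surface (via the distance
    transform of the hub mask) minus the cell's equivalent spherical
    radius. Slightly negative values mean cell and hub overlap.
    """
    df = table.df.copy()
    if len(df) == 0:
        df["hub_distance_um"] = np.array([], dtype=float)
        return CellTable(df, genotype=table.genotype, source=table.source)
    dist_map = hub.surface_distance_map()
    vs = np.asarray(hub.voxel_size)
    idx = np.rint(df[["z_um", "y_um", "x_um"]].to_numpy() / vs).astype(int)
    idx = np.clip(idx, 0, np.asarray(dist_map.shape) - 1)
    centroid_dist = dist_map[idx[:, 0], idx[:, 1], idx[:, 2]]
    eq_radius = (3.0 * df["volume_um3"].to_numpy() / (4.0 * np.pi)) ** (1 / 3)
    df["hub_distance_um"] = centroid_dist - eq_radius
    return CellTable(df, genotype=table.genotype, source=table.source)


def classify_gsc(
    table: CellTable,
    hub: HubRegion,
    contact_tol_um: float = DEFAULT_CONTACT_TOL_UM,
    singleness_dist_um: float = 8.0,
) -> CellTable:
    """Flag GSCs: Vasa-positive single cells contacting the hub.

    A cell qualifies when it is Vasa-positive, its surface-to-surface hub
    distance is at most ``contact_tol_um``, and no other Vasa-positive
    centroid lies within ``singleness_dist_um`` (default twice the nominal
    4 um nuclear diameter).
    """
    df = table.df.copy()
    if "vasa_pos" not in df.columns:
        raise ChannelRoleError("classify_gsc requires vasa_pos flags")
    if "hub_distance_um" not in df.columns:
        table = hub_distances(CellTable(df, table.genotype, table.source), hub)
        df = table.df.copy()
    is_gsc = np.zeros(len(df), dtype=bool)
    vasa = df["vasa_pos"].to_numpy(dtype=bool)
    pts = df[["z_um", "y_um", "x_um"]].to_numpy()
    near_hub = df["hub_distance_um"].to_numpy() <= contact_tol_um
    for i in np.flatnonzero(vasa & near_hub):
        others = vasa.copy()
        others[i] = False
        if others.any():
            d = np.linalg.norm(pts[others] - pts[i], axis=1)
            if d.min() < singleness_dist_um:
                continue
        is_gsc[i] = True
    df["cell_class"] = df.get("cell_class", "other")
    df.loc[is_gsc, "cell_class"] = "GSC"
    return CellTable(df, genotype=table.genotype, source=table.source)


def classify_cysc(
    table: CellTable,
    hub: HubRegion,
    max_dist_um: float = DEFAULT_CYSC_MAX_DIST_UM,
) -> CellTable:
    """Flag CySCs: Zfh-1-positive cells strictly within 10 um of the hub."""
    df = table.df.copy()
    if "zfh1_pos" not in df.columns:
        raise ChannelRoleError("classify_cysc requires zfh1_pos flags")
    if "hub_distance_um" not in df.columns:
        table = hub_distances(CellTable(df, table.genotype, table.source), hub)
        df = table.df.copy()
    is_cysc = (df["zfh1_pos"].to_numpy(dtype=bool)
               & (df["hub_distance_um"].to_numpy() < max_dist_um))
    if "cell_class" not in df.columns:
        df["cell_class"] = "other"
    # a cell already called GSC keeps that call; CySC fills the rest
    assignable = df["cell_class"].to_numpy() != "GSC"
    df.loc[is_cysc & assignable, "cell_class"] = "CySC"
    return CellTable(df, genotype=table.genotype, source=table.source)


def count_bundles(
    nuclei: CellTable,
    linkage_dist_um: float = DEFAULT_BUNDLE_LINKAGE_UM,
    min_bundle_nuclei: int = DEFAULT_MIN_BUNDLE_NUCLEI,
) -> tuple[int, list[int]]:
    """Count spermatid bundles by single-linkage clustering of centroids.

    Nuclei whose centroids chain together within ``linkage_dist_um`` form
    one cluster; clusters with at least ``min_bundle_nuclei`` members count
    as bundles (the canonical bundle holds 64 syncytial nuclei).

    Returns ``(bundle_count, sorted per-bundle sizes)``.
    """
    if linkage_dist_um <= 0 or min_bundle_nuclei <= 0:
        raise ValueError("bundle parameters must be > 0")
    df = nuclei.df
    if len(df) == 0:
        return 0, []
    pts = df[["z_um", "y_um", "x_um"]].to_numpy()
    if len(pts) == 1:
        sizes = [1]
    else:
        z = linkage(pdist(pts), method="single")
        assignment = fcluster(z, t=linkage_dist_um, criterion="distance")
        sizes = np.bincount(assignment)[1:]
        sizes = sizes[sizes > 0].tolist()
    bundle_sizes = sorted(int(s) for s in sizes if s >= min_bundle_nuclei)
    return len(bundle_sizes), bundle_sizes


def measure_intensity(
    stack: ImageStack, channel: str, region: np.ndarray,
) -> float:
    """Mean fluorescence intensity (AU) of one channel within a region."""
    region = np.asarray(region).astype(bool)
    if region.shape != tuple(stack.shape):
        raise ValueError("region mask must match the stack's spatial shape")
    if not region.any():
        raise ValueError("region is empty")
    return float(stack.channel(channel)[region].astype(np.float64).mean())
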