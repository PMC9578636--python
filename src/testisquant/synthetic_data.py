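"""Synthetic confocal volumes with known ground truth.

The generator emulates the statistical structure the analysis stages
assume: Gaussian-blurred spherical nuclei at controlled density and
separation, a bright hub blob marking the stem-cell niche, marker channels
that light up a controlled subset of cells, 64-nucleus syncytial spermatid
bundles, two-channel images with a target Pearson correlation, and
individualization complexes (an actin-cone arm and a nucleus arm meeting at
a vertex with a set angle). Every scene is reproducible: identical spec and
seed give bit-identical voxel arrays and ground truth.

Intensities are rendered as expected photon counts, optionally corrupted by
Poisson shot noise or additive Gaussian read noise, and stored as 16-bit
unsigned integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SceneInfeasibleError
from .imaging_io import DEFAULT_VOXEL_SIZE, ImageStack

__all__ = [
    "SceneSpec", "CellTruth", "GroundTruth",
    "make_nuclei_scene", "make_coloc_pair", "make_ic_scene",
    "make_fertility_table",
]

_MAX_REJECTION_FACTOR = 500  # placement attempts allowed per cell


@dataclass(frozen=True)
class CellTruth:
    """One true cell: where it is, how bright, and what it expresses."""

    centroid_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float
    intensity: float
    flags: dict[str, bool] = field(default_factory=dict)
    bundle_id: int | None = None


@dataclass
class GroundTruth:
    """The generator's record of what a scene truly contains."""

    cells: list[CellTruth] = field(default_factory=list)
    hub_centroid_um: tuple[float, float, float] | None = None
    hub_radius_um: float | None = None
    target_rho: float | None = None
    ic_angles_deg: list[float] = field(default_factory=list)
    ic_landmarks: list[tuple] = field(default_factory=list)  # (p_actin, p_vertex, p_nucleus)
    seed: int = 0

    def cell_frame(self) -> pd.DataFrame:
        """Ground-truth cells as a table (one row per cell), for CSV export."""
        rows = []
        markers = sorted({m for c in self.cells for m in c.flags})
        for i, c in enumerate(self.cells):
            row = {
                "cell_id": i,
                "z_um": c.centroid_um[0],
                "y_um": c.centroid_um[1],
                "x_um": c.centroid_um[2],
                "radius_um": c.radius_um,
                "intensity": c.intensity,
                "bundle_id": -1 if c.bundle_id is None else c.bundle_id,
            }
            for m in markers:
                row[f"{m}_pos"] = bool(c.flags.get(m, False))
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic nuclei scene.

    The defaults describe a small anterior-tip field of view: ~2 um-radius
    nuclei sampled at 1.0 x 0.31 x 0.31 um (a typical confocal z-step and
    in-plane pixel size), moderate blur, Poisson shot noise on a dim
    autofluorescent background.
    """

    shape: tuple[int, int, int] = (24, 160, 160)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    n_cells: int = 20
    nucleus_radius_um: float = 2.0
    min_separation_um: float = 0.0
    blur_sigma_um: float = 0.5
    noise: str = "poisson"  # "poisson" | "gaussian" | "none"
    gaussian_sigma: float = 10.0
    background: float = 10.0
    base_intensity: float = 300.0
    marker_fractions: Mapping[str, float] = field(default_factory=dict)
    marker_contrast: float = 10.0  # positive/negative intensity ratio
    include_hub: bool = False
    hub_radius_um: float = 8.0
    n_gsc: int = 0   # Vasa+ singles placed touching the hub surface
    n_cysc: int = 0  # Zfh-1+ cells placed <10 um from the hub surface
    n_bundles: int = 0
    bundle_size: int = 64
    bundle_nucleus_radius_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("shape must be three positive voxel counts")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.n_cells < 0 or self.n_gsc < 0 or self.n_cysc < 0:
            raise ValueError("cell counts must be non-negative")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")
        if self.nucleus_radius_um <= 0:
            raise ValueError("nucleus_radius_um must be > 0")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise ValueError("noise must be poisson | gaussian | none")
        for m, f in self.marker_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"marker fraction for {m!r} outside [0,1]")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical position of the last voxel centre along each axis."""
        return tuple((s - 1) * v for s, v in zip(self.shape, self.voxel_size))


# ---------------------------------------------------------------------------
# rendering primitives

def _paint_sphere(img: np.ndarray, centre_um, radius_um, value,
                  voxel_size) -> None:
    """Add `value` inside a sphere; anisotropy-aware, bounding-box local."""
    centre = np.asarray(centre_um, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    lo = np.maximum(np.floor((centre - radius_um) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((centre + radius_um) / vs).astype(int) + 1,
                    np.asarray(img.shape))
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = ((zz * vs[0] - centre[0]) ** 2
          + (yy * vs[1] - centre[1]) ** 2
          + (xx * vs[2] - centre[2]) ** 2)
    img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][d2 <= radius_um ** 2] += value


def _finalize(expected: np.ndarray, spec_noise: str, gaussian_sigma: float,
              rng: np.random.Generator) -> np.ndarray:
    """Apply the noise model and quantize to uint16."""
    if spec_noise == "poisson":
        out = rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
    elif spec_noise == "gaussian":
        out = expected + rng.normal(0.0, gaussian_sigma, expected.shape)
    else:
        out = expected
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)


def _blur(expected: np.ndarray, sigma_um: float, voxel_size) -> np.ndarray:
    if sigma_um <= 0:
        return expected
    sigma_vox = [sigma_um / v for v in voxel_size]
    return ndimage.gaussian_filter(expected, sigma=sigma_vox)


# ---------------------------------------------------------------------------
# placement

def _place_points(rng, n, bounds_lo, bounds_hi, min_sep, existing,
                  max_attempts, what="cells"):
    """Rejection-sample n points with pairwise separation >= min_sep."""
    placed = []
    all_pts = list(existing)
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise SceneInfeasibleError(
                f"scene infeasible: could not place {n} {what} with "
                f"min separation {min_sep} um after {max_attempts} attempts")
        attempts += 1
        p = rng.uniform(bounds_lo, bounds_hi)
        if min_sep > 0 and all_pts:
            d = np.linalg.norm(np.asarray(all_pts) - p, axis=1)
            if d.min() < min_sep:
                continue
        placed.append(p)
        all_pts.append(p)
    return placed


def _unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _fibonacci_directions(n: int) -> np.ndarray:
    """n near-evenly spaced unit vectors (Fibonacci sphere lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    return np.stack([z, r * np.sin(phi), r * np.cos(phi)], axis=1)


# ---------------------------------------------------------------------------
# nuclei / niche scenes

def make_nuclei_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a nuclei scene (optionally with hub, markers and bundles).

    The nuclear channel contains every cell; each marker channel renders
    flagged cells at full intensity and unflagged cells dimmed by
    ``marker_contrast``; the hub channel, if present, contains a single
    bright blob near one end of the volume (the apical tip).

    Returns the stack and a :class:`GroundTruth` listing every cell.
    """
    rng = np.random.default_rng(spec.seed)
    extent = np.asarray(spec.extent_um)
    r = spec.nucleus_radius_um
    lo, hi = np.full(3, r), extent - r
    if np.any(hi < lo) and (spec.n_cells or spec.n_gsc or spec.n_cysc):
        raise SceneInfeasibleError("volume too small for one nucleus")

    truth = GroundTruth(seed=spec.seed)
    markers = sorted(spec.marker_fractions)
    if spec.n_gsc and "vasa" not in markers:
        markers.append("vasa")
    if spec.n_cysc and "zfh1" not in markers:
        markers.append("zfh1")
    markers.sort()

    hub_c = None
    protected: list[np.ndarray] = []  # points bulk cells must keep away from
    if spec.include_hub:
        # apical tip: hub sits at mid z/y, a quarter of the way along x
        hub_c = np.array([extent[0] / 2, extent[1] / 2, extent[2] / 4])
        truth.hub_centroid_um = tuple(hub_c)
        truth.hub_radius_um = spec.hub_radius_um

    def in_bounds(p):
        return np.all(p >= lo) and np.all(p <= hi)

    max_attempts = _MAX_REJECTION_FACTOR * max(
        spec.n_cells + spec.n_gsc + spec.n_cysc, 1)

    # --- niche cells pinned to the hub surface -----------------------------
    gsc_pts, cysc_pts = [], []
    if spec.include_hub:
        if spec.n_gsc:
            # Fibonacci lattice on the contact sphere guarantees near-even
            # spacing (so GSCs stay mutually "single"); retry rotations
            # until every point fits the volume bounds.
            ring = spec.hub_radius_um + r - 0.3  # slight inward press: touching
            dirs = _fibonacci_directions(spec.n_gsc)
            for attempt in range(200):
                q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
                pts = hub_c + ring * (dirs @ q.T)
                if all(in_bounds(p) for p in pts):
                    break
            else:
                raise SceneInfeasibleError(
                    "scene infeasible: cannot place GSCs on the hub surface "
                    "within the volume bounds")
            gsc_pts = [p for p in pts]
        attempts = 0
        while len(cysc_pts) < spec.n_cysc:
            if attempts > max_attempts:
                raise SceneInfeasibleError(
                    "scene infeasible: cannot place CySCs near the hub")
            attempts += 1
            d = _unit_vector(rng)
            d[0] *= 0.3
            d /= np.linalg.norm(d)
            gap = rng.uniform(1.0, 7.0)  # surface-to-surface, safely <10 um
            p = hub_c + d * (spec.hub_radius_um + r + gap)
            if not in_bounds(p):
                continue
            near = gsc_pts + cysc_pts
            if near and min(np.linalg.norm(np.asarray(near) - p,
                                           axis=1)) < max(spec.min_separation_um,
                                                          2 * r):
                continue
            cysc_pts.append(p)
        protected = [hub_c] + gsc_pts + cysc_pts

    # --- bulk cells --------------------------------------------------------
    def far_from_hub(p):
        if hub_c is None:
            return True
        # stay >12 um from the hub surface so bulk cells never gate as niche
        return np.linalg.norm(p - hub_c) > spec.hub_radius_um + r + 12.0

    bulk_pts = []
    attempts = 0
    existing = list(protected)
    while len(bulk_pts) < spec.n_cells:
        if attempts >= max_attempts:
            raise SceneInfeasibleError(
                f"scene infeasible: could not place {spec.n_cells} cells with "
                f"min separation {spec.min_separation_um} um")
        attempts += 1
        p = rng.uniform(lo, hi)
        if not far_from_hub(p):
            continue
        sep = spec.min_separation_um
        if sep > 0 and existing:
            if min(np.linalg.norm(np.asarray(existing) - p, axis=1)) < sep:
                continue
        bulk_pts.append(p)
        existing.append(p)

    # marker flags: exact counts over the bulk population
    n_bulk = len(bulk_pts)
    flag_sets: dict[str, set[int]] = {}
    for m in markers:
        frac = spec.marker_fractions.get(m, 0.0)
        n_pos = int(round(frac * n_bulk))
        flag_sets[m] = set(rng.permutation(n_bulk)[:n_pos].tolist())

    for p in gsc_pts:
        truth.cells.append(CellTruth(tuple(p), r, spec.base_intensity,
                                     {m: (m == "vasa") for m in markers}))
    for p in cysc_pts:
        truth.cells.append(CellTruth(tuple(p), r, spec.base_intensity,
                                     {m: (m == "zfh1") for m in markers}))
    for i, p in enumerate(bulk_pts):
        truth.cells.append(CellTruth(
            tuple(p), r, spec.base_intensity,
            {m: (i in flag_sets[m]) for m in markers}))

    # --- spermatid bundles (tight 4x4x4 grids of small nuclei) -------------
    if spec.n_bundles:
        half = 4.0  # bundle half-extent, um
        b_lo = np.full(3, half + 1.0)
        b_hi = extent - (half + 1.0)
        if np.any(b_hi < b_lo):
            raise SceneInfeasibleError("volume too small for spermatid bundles")
        keep_away = [np.asarray(c.centroid_um) for c in truth.cells]
        if hub_c is not None:
            keep_away.append(hub_c)
        centers = _place_points(rng, spec.n_bundles, b_lo, b_hi,
                                min_sep=2 * half + 12.0,
                                existing=keep_away,
                                max_attempts=_MAX_REJECTION_FACTOR
                                * max(spec.n_bundles, 1),
                                what="bundles")
        side = int(round(spec.bundle_size ** (1 / 3)))
        if side ** 3 != spec.bundle_size:
            side = int(np.ceil(spec.bundle_size ** (1 / 3)))
        grid = np.stack(np.meshgrid(*([np.arange(side)] * 3),
                                    indexing="ij"), -1).reshape(-1, 3)
        grid = (grid - (side - 1) / 2) * 2.0  # 2 um lattice spacing
        for b_id, c in enumerate(centers):
            # random rotation (QR of a Gaussian matrix) + small jitter:
            # lattice spacing 2 um and jitter <=0.3 um keeps every
            # nearest-neighbour pair under the 3 um single-linkage default
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            pts = grid[:spec.bundle_size] @ q.T + c
            pts = pts + rng.uniform(-0.3, 0.3, pts.shape)
            for p in pts:
                truth.cells.append(CellTruth(
                    tuple(np.clip(p, lo, hi)), spec.bundle_nucleus_radius_um,
                    spec.base_intensity, {m: False for m in markers},
                    bundle_id=b_id))

    # --- render ------------------------------------------------------------
    channel_names = ["nuclear"] + markers + (["hub"] if spec.include_hub else [])
    chans = []
    for name in channel_names:
        img = np.zeros(spec.shape, dtype=np.float64)
        if name == "nuclear":
            for c in truth.cells:
                _paint_sphere(img, c.centroid_um, c.radius_um, c.intensity,
                              spec.voxel_size)
        elif name == "hub":
            _paint_sphere(img, hub_c, spec.hub_radius_um,
                          spec.base_intensity, spec.voxel_size)
        else:
            for c in truth.cells:
                val = c.intensity if c.flags.get(name, False) \
                    else c.intensity / spec.marker_contrast
                _paint_sphere(img, c.centroid_um, c.radius_um, val,
                              spec.voxel_size)
        img = _blur(img, spec.blur_sigma_um, spec.voxel_size) + spec.background
        chans.append(_finalize(img, spec.noise, spec.gaussian_sigma, rng))

    stack = ImageStack(np.stack(chans), spec.voxel_size, channel_names,
                       source="synthetic")
    return stack, truth


# ---------------------------------------------------------------------------
# correlated channel pairs

def make_coloc_pair(
    shape: Sequence[int],
    rho: float,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> tuple[ImageStack, GroundTruth]:
    """Two channels whose voxel-wise Pearson correlation targets ``rho``.

    Channel B is built as ``rho * A + sqrt(1 - rho^2) * noise`` from
    standard-normal fields, then each channel is affinely rescaled to the
    16-bit range — a transform that leaves Pearson r invariant — so the
    sample correlation converges to ``rho`` as the voxel count grows.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    shape = tuple(int(s) for s in shape)
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(shape)
    if abs(rho) == 1.0:
        b = np.copysign(1.0, rho) * a
    else:
        b = rho * a + np.sqrt(1.0 - rho * rho) * rng.standard_normal(shape)

    def rescale(x):
        x = x - x.min()
        peak = x.max()
        if peak > 0:
            x = x * (65535.0 / peak)
        return np.rint(x).astype(np.uint16)

    voxels = np.stack([rescale(a), rescale(b)])
    stack = ImageStack(voxels, voxel_size, ["zpg", "gfp"], source="synthetic")
    truth = GroundTruth(target_rho=float(rho), seed=seed)
    return stack, truth


# ---------------------------------------------------------------------------
# individualization complexes

def make_ic_scene(
    angle_deg: float,
    n_complexes: int,
    seed: int = 0,
    shape: tuple[int, int, int] = (48, 288, 288),
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    arm_length_um: float = 8.0,
    noise: str = "none",
) -> tuple[ImageStack, GroundTruth]:
    """Render individualization complexes with a set actin-nucleus angle.

    Each complex is a chain of bright beads along the actin-cone axis (actin
    channel) and another along the nuclear-bundle axis (nuclear channel);
    the two rays meet at a vertex with the requested angle. A wildtype
    complex is linear (180 deg); disorganized complexes bend. Ground truth
    stores the three landmark points per complex.
    """
    if not 0.0 < angle_deg <= 180.0:
        raise ValueError(f"angle_deg must lie in (0, 180], got {angle_deg}")
    if n_complexes < 0:
        raise ValueError("n_complexes must be >= 0")
    rng = np.random.default_rng(seed)
    extent = np.asarray([(s - 1) * v for s, v in zip(shape, voxel_size)])
    margin = arm_length_um + 2.0
    lo, hi = np.full(3, margin), extent - margin
    truth = GroundTruth(seed=seed)
    actin = np.zeros(shape, dtype=np.float64)
    nuclear = np.zeros(shape, dtype=np.float64)
    if n_complexes:
        if np.any(hi < lo):
            raise SceneInfeasibleError("volume too small for one complex")
        vertices = _place_points(
            rng, n_complexes, lo, hi, min_sep=2 * arm_length_um + 8.0,
            existing=[], max_attempts=_MAX_REJECTION_FACTOR * n_complexes,
            what="complexes")
        theta = np.deg2rad(angle_deg)
        for v in vertices:
            d1 = _unit_vector(rng)
            # perpendicular direction for the second ray
            u = np.cross(d1, _unit_vector(rng))
            while np.linalg.norm(u) < 1e-8:
                u = np.cross(d1, _unit_vector(rng))
            u /= np.linalg.norm(u)
            d2 = np.cos(theta) * d1 + np.sin(theta) * u
            p_actin = v + arm_length_um * d1
            p_nucleus = v + arm_length_um * d2
            # clamp-free by construction: |arm| + margin fits the volume;
            # bead spacing well under the bead radius keeps each arm one
            # connected component after thresholding
            # bead radius 1.0 um: the structure must span the z-step or an
            # oblique arm dashes into fragments across slices
            for t in np.arange(1.2, arm_length_um + 1e-9, 0.2):
                _paint_sphere(actin, v + t * d1, 1.0, 400.0, voxel_size)
                _paint_sphere(nuclear, v + t * d2, 1.0, 400.0, voxel_size)
            truth.ic_angles_deg.append(float(angle_deg))
            truth.ic_landmarks.append(
                (tuple(p_actin), tuple(v), tuple(p_nucleus)))
    chans = []
    for img in (actin, nuclear):
        img = _blur(img, 0.3, voxel_size) + 2.0
        chans.append(_finalize(img, noise, 5.0, rng))
    stack = ImageStack(np.stack(chans), voxel_size, ["actin", "nuclear"],
                       source="synthetic")
    return stack, truth


# ---------------------------------------------------------------------------
# fertility tables

def make_fertility_table(
    genotypes: Sequence[str],
    counts_per_genotype: Mapping[str, object],
    seed: int = 0,
) -> pd.DataFrame:
    """Build a per-male offspring table, one row per male.

    ``counts_per_genotype`` maps each genotype either to an explicit
    sequence of non-negative integer daily offspring counts, or to a
    sampling rule ``{"dist": "poisson", "mean": m, "n": k}``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in genotypes:
        try:
            spec = counts_per_genotype[g]
        except KeyError:
            raise ValueError(f"no counts given for genotype {g!r}") from None
        if isinstance(spec, Mapping):
            if spec.get("dist") != "poisson":
                raise ValueError(f"unknown sampling rule for {g!r}: {spec}")
            counts = rng.poisson(float(spec["mean"]), int(spec["n"]))
        else:
            counts = np.asarray(list(spec))
            if counts.size and (np.any(counts < 0)
                                or not np.issubdtype(counts.dtype, np.integer)):
                raise ValueError(
                    f"offspring counts for {g!r} must be non-negative integers")
        for i, c in enumerate(counts):
            rows.append({"male_id": f"{g}_{i:03d}", "genotype": g,
                         "offspring_per_day": int(c)})
    return pd.DataFrame(rows, columns=["male_id", "genotype",
                                       "offspring_per_day"])
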