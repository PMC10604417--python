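"""Virtual-spike morphometry: clustering, surfaces, boxes, traits.

The segmented binary volume is converted to a point cloud (one point per
foreground voxel center), individual grains are isolated with DBSCAN
density clustering (neighbourhood radius ``eps`` in voxels, working range
3-7), and per-grain traits are computed:

* volume  V = n * P^3 / 1e9  mm^3  (n = voxel count, P = pixel size in um)
* surface S = m * P^2 / 1e6  mm^2  (m = alpha-shape mesh area in voxel^2,
  reconstructed over the grain's 6-connectivity contour shell)
* length / width / thickness from the principal-axes oriented bounding
  box, extent = (max - min projection + 1 voxel) * P / 1e3, sorted
  descending

Grains are ordered bottom-up along the spike axis (largest principal axis
of the whole cloud), spike-level traits aggregate the grains, and
positional profiles average a trait per grain position across spikes
within each germplasm group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay
from sklearn.cluster import DBSCAN

from .volume_io import BinaryVolume

log = logging.getLogger("spikect")

GROUPS = ("wild", "landrace", "cultivar")


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters for grain isolation and surface reconstruction.

    ``eps`` is the DBSCAN neighbourhood radius in voxels (3-7 works across
    scan resolutions; default 4).  ``min_points`` is the neighbourhood size
    (including the point itself) required for a core point.  Clusters
    smaller than ``min_cluster_voxels`` are discarded as debris (dust, awn
    fragments surviving segmentation).  ``alpha`` is the alpha-shape
    parameter in voxels; it must exceed half the grain thickness or the
    reconstruction adds an inner surface over the hollow contour shell.
    """

    eps: float = 4.0
    min_points: int = 10
    min_cluster_voxels: int = 50
    alpha: float = 12.0

    def __post_init__(self):
        if self.eps <= 0 or self.alpha <= 0:
            raise ValueError("eps and alpha must be positive")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")


@dataclass
class GrainRecord:
    """Measurements of one virtual grain."""

    grain_id: int
    position_index: int          # 1 = bottom-most grain
    centroid: tuple[float, float, float]  # (z, y, x) voxel coords
    n: int                       # voxel count
    volume_mm3: float
    mesh_area_voxel2: float
    surface_mm2: float
    length_mm: float
    width_mm: float
    thickness_mm: float


@dataclass
class SpikeRecord:
    """Spike-level traits plus the per-grain records."""

    spike_id: str
    group: str
    spike_length_mm: float
    grain_count: int
    total_grain_volume_mm3: float
    total_grain_surface_mm2: float
    grains: list[GrainRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------

def volume_to_pointcloud(vol: BinaryVolume) -> np.ndarray:
    """One point per foreground voxel at its center, (z, y, x) order.

    Points come out in lexicographic (z, y, x) order, which fixes the
    processing order of everything downstream (clustering is deterministic
    given point order).
    """
    pts = np.argwhere(np.asarray(vol.voxels) > 0).astype(np.float64)
    if pts.shape[0] == 0:
        raise ValueError("no spike detected: binary volume has empty foreground")
    return pts


def extract_surface_points(vol_voxels: np.ndarray, grain_points: np.ndarray) -> np.ndarray:
    """Contour shell of a grain: voxels with a 6-connected background neighbour.

    ``vol_voxels`` is the full binary occupancy grid and ``grain_points``
    the (z, y, x) integer coordinates of one grain's voxels.  Voxels on the
    volume boundary count as having a background neighbour.  The shell is
    the input to alpha-shape surface reconstruction.
    """
    pts = np.asarray(grain_points)
    if pts.shape[0] == 0:
        raise ValueError("grain_points must be nonempty")
    occ = np.asarray(vol_voxels) > 0
    ipts = np.rint(pts).astype(int)
    dims = np.asarray(occ.shape)
    on_surface = np.zeros(ipts.shape[0], dtype=bool)
    for axis in range(3):
        for step in (-1, 1):
            nb = ipts.copy()
            nb[:, axis] += step
            outside = (nb[:, axis] < 0) | (nb[:, axis] >= dims[axis])
            inside = ~outside
            covered = np.zeros(ipts.shape[0], dtype=bool)
            covered[inside] = occ[nb[inside, 0], nb[inside, 1], nb[inside, 2]]
            on_surface |= outside | ~covered
    return pts[on_surface]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_grains(points: np.ndarray, cfg: ClusterConfig):
    """Isolate grains by DBSCAN; returns (list of point arrays, debris array).

    Core points have >= ``min_points`` neighbours within ``eps`` (counting
    themselves); clusters are maximal density-connected sets; noise points
    and clusters below ``min_cluster_voxels`` go to debris.  Cluster order
    follows first appearance in point order.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.shape[0] == 0:
        raise ValueError("empty point cloud")
    labels = DBSCAN(eps=cfg.eps, min_samples=cfg.min_points).fit(points).labels_
    clusters, debris_parts = [], []
    for lab in range(labels.max() + 1):
        members = points[labels == lab]
        if members.shape[0] >= cfg.min_cluster_voxels:
            clusters.append(members)
        else:
            debris_parts.append(members)
    noise = points[labels == -1]
    if noise.size:
        debris_parts.append(noise)
    debris = (np.concatenate(debris_parts) if debris_parts
              else np.empty((0, 3)))
    if debris.shape[0]:
        log.info("clustering: %d debris points discarded", debris.shape[0])
    if not clusters:
        raise ValueError("clustering produced no grains; adjust eps")
    return clusters, debris


# ---------------------------------------------------------------------------
# Per-grain measurements
# ---------------------------------------------------------------------------

def grain_volume(n: int, pixel_size_um: float) -> float:
    """V = n * P^3 / 1e9 in mm^3."""
    if n < 0 or pixel_size_um <= 0:
        raise ValueError("need n >= 0 and P > 0")
    return n * pixel_size_um ** 3 / 1e9


def _tet_circumradius(tets_pts: np.ndarray) -> np.ndarray:
    """Circumsphere radii for an array of tetrahedra, shape (m, 4, 3).

    Degenerate (near-zero-volume) tetrahedra get radius 0 so they are
    always retained: they arise from exactly co-planar/co-spherical lattice
    points inside the solid and removing them would punch spurious faces
    into the mesh.
    """
    a = tets_pts[:, 0]
    rows = tets_pts[:, 1:] - a[:, None, :]          # (m, 3, 3)
    rhs = 0.5 * np.einsum("mij,mij->mi", rows, rows)
    det = np.linalg.det(rows)
    ok = np.abs(det) > 1e-9
    radii = np.zeros(tets_pts.shape[0])
    if ok.any():
        centers = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers, axis=1)
    return radii


def alpha_shape_mesh(points: np.ndarray, alpha: float):
    """Alpha-shape surface of a 3D point set.

    Delaunay-tetrahedralizes the points, keeps tetrahedra whose
    circumradius is below ``alpha``, and returns the boundary: the
    triangles belonging to exactly one kept tetrahedron.  For convex point
    sets with alpha >= the set diameter this equals the convex hull.

    Returns (vertices, faces, area) with area in squared input units.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise ValueError("degenerate grain geometry: need >= 4 non-coplanar points")
    tri = Delaunay(pts)
    tets = tri.simplices
    radii = _tet_circumradius(pts[tets])
    keep = tets[radii < alpha]
    if keep.shape[0] == 0:
        raise ValueError("alpha too small: no tetrahedra retained")
    faces = np.sort(
        np.concatenate([keep[:, [0, 1, 2]], keep[:, [0, 1, 3]],
                        keep[:, [0, 2, 3]], keep[:, [1, 2, 3]]]),
        axis=1,
    )
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    v0 = pts[boundary[:, 0]]
    e1 = pts[boundary[:, 1]] - v0
    e2 = pts[boundary[:, 2]] - v0
    area = float(0.5 * np.linalg.norm(np.cross(e1, e2), axis=1).sum())
    return pts, boundary, area


def grain_surface(surface_points: np.ndarray, alpha: float,
                  pixel_size_um: float):
    """Alpha-shape mesh and surface area of one grain.

    ``m`` is the total triangle area in voxel^2; S = m * P^2 / 1e6 mm^2.
    Returns ((vertices, faces), m, S).
    """
    verts, faces, m = alpha_shape_mesh(surface_points, alpha)
    return (verts, faces), m, m * pixel_size_um ** 2 / 1e6


def convex_hull_area(points: np.ndarray) -> float:
    """Convex-hull surface area in squared input units (cross-check oracle)."""
    return float(ConvexHull(np.asarray(points, dtype=np.float64)).area)


def grain_obb(points: np.ndarray, pixel_size_um: float) -> tuple[float, float, float]:
    """Oriented-bounding-box dims (length >= width >= thickness) in mm.

    Box axes are the covariance eigenvectors of the points (principal
    axes); the extent along each axis is (max - min projection + 1 voxel)
    * P / 1e3 — the +1 accounts for the width of the voxels whose centers
    the points are.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 2:
        raise ValueError("need >= 2 points for an oriented bounding box")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    extents = (proj.max(axis=0) - proj.min(axis=0) + 1.0) * pixel_size_um / 1e3
    l, w, t = sorted(extents, reverse=True)
    return float(l), float(w), float(t)


# ---------------------------------------------------------------------------
# Spike assembly
# ---------------------------------------------------------------------------

def spike_axis(points: np.ndarray, invert: bool = False) -> np.ndarray:
    """Unit spike axis: principal eigenvector of the cloud, bottom-first.

    Oriented so the z-component is positive ("bottom" is the small-z end,
    where the scanner holder grips the spike base); ``invert`` flips it for
    scans mounted the other way.  Deterministic sign for degenerate
    orientations via (z, y, x) lexicographic rule.
    """
    pts = np.asarray(points, dtype=np.float64)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / max(pts.shape[0], 1)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    for comp in axis:  # first nonzero component decides the sign
        if abs(comp) > 1e-12:
            if comp < 0:
                axis = -axis
            break
    return -axis if invert else axis


def order_grains(centroids: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Bottom-up position indices (1..G) along the spike axis.

    Grains sort by ascending centroid projection onto the axis; exact ties
    break by (y, x) centroid lexicographic order, so the ordering is stable
    across runs.
    """
    cents = np.asarray(centroids, dtype=np.float64)
    proj = cents @ np.asarray(axis, dtype=np.float64)
    order = np.lexsort((cents[:, 2], cents[:, 1], proj))
    indices = np.empty(len(cents), dtype=int)
    indices[order] = np.arange(1, len(cents) + 1)
    return indices


def measure_grains(clusters: list[np.ndarray], vol_voxels: np.ndarray,
                   pixel_size_um: float, cfg: ClusterConfig) -> list[GrainRecord]:
    """Per-grain records (position indices assigned by the caller)."""
    records = []
    for i, pts in enumerate(clusters):
        shell = extract_surface_points(vol_voxels, pts)
        _, m, s = grain_surface(shell, cfg.alpha, pixel_size_um)
        l, w, t = grain_obb(pts, pixel_size_um)
        records.append(GrainRecord(
            grain_id=i + 1, position_index=0,
            centroid=tuple(pts.mean(axis=0)),
            n=pts.shape[0],
            volume_mm3=grain_volume(pts.shape[0], pixel_size_um),
            mesh_area_voxel2=m, surface_mm2=s,
            length_mm=l, width_mm=w, thickness_mm=t,
        ))
    return records


def spike_traits(grains: list[GrainRecord], full_cloud: np.ndarray,
                 pixel_size_um: float, spike_id: str = "spike",
                 group: str = "cultivar") -> SpikeRecord:
    """Aggregate grain records into spike-level traits.

    Spike length is the longest oriented-bounding-box extent of the full
    grain cloud (awn/stalk remnants are excluded upstream by segmentation
    and debris filtering).
    """
    if not grains:
        raise ValueError("need >= 1 grain")
    length, _, _ = grain_obb(full_cloud, pixel_size_um)
    return SpikeRecord(
        spike_id=spike_id, group=group,
        spike_length_mm=length,
        grain_count=len(grains),
        total_grain_volume_mm3=float(sum(g.volume_mm3 for g in grains)),
        total_grain_surface_mm2=float(sum(g.surface_mm2 for g in grains)),
        grains=grains,
    )


def analyze_spike(vol: BinaryVolume, cfg: ClusterConfig | None = None,
                  spike_id: str = "spike", group: str = "cultivar",
                  invert_axis: bool = False) -> SpikeRecord:
    """Full morphometry pass on one segmented binary volume.

    Point cloud -> DBSCAN grains -> per-grain measures -> bottom-up
    ordering -> spike aggregation.
    """
    cfg = cfg or ClusterConfig()
    cloud = volume_to_pointcloud(vol)
    clusters, _ = cluster_grains(cloud, cfg)
    grains = measure_grains(clusters, vol.voxels, vol.pixel_size_um, cfg)
    grain_cloud = np.concatenate(clusters)
    axis = spike_axis(grain_cloud, invert=invert_axis)
    indices = order_grains(np.array([g.centroid for g in grains]), axis)
    for g, pos in zip(grains, indices):
        g.position_index = int(pos)
    grains.sort(key=lambda g: g.position_index)
    for new_id, g in enumerate(grains, start=1):
        g.grain_id = new_id
    return spike_traits(grains, grain_cloud, vol.pixel_size_um,
                        spike_id=spike_id, group=group)


# ---------------------------------------------------------------------------
# Tables, profiles, export
# ---------------------------------------------------------------------------

_TRAIT_FIELDS = ("n", "volume_mm3", "surface_mm2", "length_mm", "width_mm",
                 "thickness_mm")


def grains_table(spike: SpikeRecord) -> pd.DataFrame:
    """Per-grain CSV-ready table for one spike."""
    return pd.DataFrame([{
        "spike_id": spike.spike_id, "grain_id": g.grain_id,
        "position_index": g.position_index,
        "cz": g.centroid[0], "cy": g.centroid[1], "cx": g.centroid[2],
        "n": g.n, "volume_mm3": g.volume_mm3,
        "mesh_area_voxel2": g.mesh_area_voxel2, "surface_mm2": g.surface_mm2,
        "length_mm": g.length_mm, "width_mm": g.width_mm,
        "thickness_mm": g.thickness_mm,
    } for g in spike.grains])


def spikes_table(spikes: list[SpikeRecord]) -> pd.DataFrame:
    """Per-spike summary table."""
    return pd.DataFrame([{
        "spike_id": s.spike_id, "group": s.group,
        "spike_length_mm": s.spike_length_mm, "grain_count": s.grain_count,
        "total_grain_volume_mm3": s.total_grain_volume_mm3,
        "total_grain_surface_mm2": s.total_grain_surface_mm2,
    } for s in spikes])


def positional_profile(spikes: list[SpikeRecord], trait: str) -> pd.DataFrame:
    """Mean trait value per grain position per group.

    For each group and each bottom-up position index present in at least
    one spike, averages ``trait`` over the spikes having a grain at that
    position; reports the contributing spike count.  Positions no spike
    reaches are simply absent.
    """
    if trait not in _TRAIT_FIELDS:
        raise ValueError(f"unknown trait {trait!r}; choose from {_TRAIT_FIELDS}")
    rows = [{"group": s.group, "position": g.position_index,
             "value": getattr(g, trait)}
            for s in spikes for g in s.grains]
    if not rows:
        raise ValueError("no grains to profile")
    df = pd.DataFrame(rows)
    out = (df.groupby(["group", "position"])["value"]
             .agg(mean="mean", n_spikes="size").reset_index())
    return out.sort_values(["group", "position"]).reset_index(drop=True)


def export_labeled_cloud(clusters: list[np.ndarray], path: str | Path,
                         seed: int = 0) -> Path:
    """Write a PLY point cloud with one random color per grain."""
    import trimesh

    rng = np.random.default_rng(seed)
    pts = np.concatenate(clusters)
    colors = np.concatenate([
        np.tile(np.append(rng.integers(40, 256, size=3), 255), (c.shape[0], 1))
        for c in clusters
    ]).astype(np.uint8)
    cloud = trimesh.PointCloud(pts[:, ::-1], colors=colors)  # (x, y, z) order
    cloud.export(str(path))
    return Path(path)
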