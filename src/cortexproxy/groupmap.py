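"""Group weight maps and recursive volumetric subdivision of their clusters.

Per-subject SVR weight maps for one target are combined with a voxelwise
one-sample t-test against zero; the map is thresholded at FDR-corrected
p < 0.05, organized into connected clusters of at least five voxels (one
grid cell in any direction, i.e. 26-connectivity), and every cluster larger
than 40 voxels is recursively bisected by a plane normal to the vector
between its two farthest points and passing through their midpoint. The
resulting disjoint subdivisions (each <= 40 voxels, 2,560 mm^3 at 4 mm
isotropic) define a sparse, target-specific surface feature set: one feature
per subdivision, the mean series of its member voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import InputError, VolumeGrid
from .wavestrap import fdr_correct

__all__ = [
    "GroupMap",
    "Cluster",
    "SubdivisionSet",
    "Subdivision",
    "group_ttest",
    "find_clusters",
    "farthest_pair",
    "subdivide",
    "subdivision_features",
]


@dataclass
class GroupMap:
    """Voxelwise one-sample t-test of subject weight maps against zero."""

    t: np.ndarray
    p: np.ndarray
    sig_mask: VolumeGrid
    defined_mask: np.ndarray  # voxels with nonzero between-subject variance
    n_subjects: int


@dataclass
class Cluster:
    """A connected set of voxel coordinates (0-based, N x 3 int array)."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        if self.voxels.shape[0] == 0:
            raise InputError("empty cluster")

    @property
    def size(self) -> int:
        return self.voxels.shape[0]

    def centers_mm(self) -> np.ndarray:
        return self.voxels * np.asarray(self.voxel_size_mm)


@dataclass
class Subdivision:
    voxels: np.ndarray
    cluster_id: int
    history: str  # split path, e.g. "1.L.R"


@dataclass
class SubdivisionSet:
    """Disjoint voxel sets partitioning the significant clusters of one target."""

    subdivisions: list[Subdivision]
    voxel_size_mm: tuple[float, float, float]
    target_name: str = ""

    def centroids_mm(self) -> np.ndarray:
        vs = np.asarray(self.voxel_size_mm)
        return np.array([(s.voxels * vs).mean(axis=0) for s in self.subdivisions])

    def volumes_mm3(self) -> np.ndarray:
        unit = float(np.prod(self.voxel_size_mm))
        return np.array([s.voxels.shape[0] * unit for s in self.subdivisions])

    def to_label_volume(self, shape: tuple[int, int, int]) -> VolumeGrid:
        """Integer label volume: subdivision i gets label i + 1; 0 = background."""
        out = np.zeros(shape, dtype=np.int32)
        for i, s in enumerate(self.subdivisions):
            out[s.voxels[:, 0], s.voxels[:, 1], s.voxels[:, 2]] = i + 1
        return VolumeGrid(out, self.voxel_size_mm)

    def to_table(self) -> pd.DataFrame:
        cen = self.centroids_mm()
        return pd.DataFrame(
            {
                "id": np.arange(1, len(self.subdivisions) + 1),
                "n_voxels": [s.voxels.shape[0] for s in self.subdivisions],
                "volume_mm3": self.volumes_mm3(),
                "centroid_x_mm": cen[:, 0],
                "centroid_y_mm": cen[:, 1],
                "centroid_z_mm": cen[:, 2],
                "cluster_id": [s.cluster_id for s in self.subdivisions],
                "history": [s.history for s in self.subdivisions],
            }
        )


def group_ttest(weight_maps: list[VolumeGrid], fdr_q: float = 0.05) -> GroupMap:
    """Voxelwise one-sample t-test across subjects, BH-FDR thresholded.

    Voxels with zero between-subject variance (including all-zero voxels
    outside every subject's support) are flagged undefined and excluded from
    both the test and the FDR family.
    """
    if len(weight_maps) < 2:
        raise InputError("need at least 2 subject maps")
    shapes = {m.shape for m in weight_maps}
    if len(shapes) != 1:
        raise InputError("subject maps must share one grid")
    vs = weight_maps[0].voxel_size_mm
    stack = np.stack([np.asarray(m.data, dtype=np.float64) for m in weight_maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    defined = sd > 0
    t = np.full(mean.shape, np.nan)
    p = np.full(mean.shape, np.nan)
    t[defined] = mean[defined] / (sd[defined] / np.sqrt(n))
    p[defined] = 2.0 * stats.t.sf(np.abs(t[defined]), df=n - 1)
    sig = np.zeros(mean.shape, dtype=bool)
    if defined.any():
        p_def = np.clip(p[defined], np.finfo(float).tiny, 1.0)
        sig[defined] = fdr_correct(p_def) < fdr_q
    return GroupMap(t, p, VolumeGrid(sig, vs), defined, n)


def find_clusters(
    sig_mask: VolumeGrid, min_size: int = 5, connectivity: int = 26
) -> list[Cluster]:
    """Connected components of the significance mask.

    26-connectivity by default (every neighbor within one grid cell,
    including diagonals); components smaller than ``min_size`` voxels are
    discarded. Clusters are ordered by descending size, ties broken by the
    lexicographically smallest member coordinate.
    """
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise InputError("connectivity must be 6 or 26")
    mask = np.asarray(sig_mask.data, dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if coords.shape[0] >= min_size:
            clusters.append(Cluster(coords, sig_mask.voxel_size_mm))
    clusters.sort(key=lambda c: (-c.size, tuple(map(int, c.voxels.min(axis=0))), tuple(map(int, c.voxels[0]))))
    return clusters


def farthest_pair(cluster: Cluster):
    """Exact farthest pair of voxel centers (mm), by brute-force O(n^2) scan.

    Returns ``(p1, p2, v, midpoint)`` with p1/p2 in mm, ``v = p2 - p1`` and
    the arithmetic midpoint. Ties are broken by the lexicographically
    smallest ordered coordinate pair, so the result is deterministic.
    """
    if cluster.size < 2:
        raise InputError("farthest_pair needs at least 2 voxels")
    # lexicographic ordering of voxel coordinates fixes the tie-break
    order = np.lexsort(cluster.voxels.T[::-1])
    pts = cluster.centers_mm()[order]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    best = float(d2.max())
    ii, jj = np.nonzero(d2 == best)
    # keep i < j; np.nonzero scans rows then columns = lexicographic (i, j)
    keep = ii < jj
    i, j = int(ii[keep][0]), int(jj[keep][0])
    p1, p2 = pts[i], pts[j]
    v = p2 - p1
    return p1, p2, v, (p1 + p2) / 2.0


def _split_once(voxels: np.ndarray, voxel_size: tuple) -> tuple[np.ndarray, np.ndarray]:
    """One plane bisection; falls back to a stable median split when the
    plane leaves a side empty (all projections equal up to ties)."""
    cl = Cluster(voxels, voxel_size)
    _, _, v, mid = farthest_pair(cl)
    pts = cl.centers_mm()
    proj = pts @ v
    b = float(mid @ v)
    side1 = proj <= b
    if side1.all() or not side1.any():
        order = np.argsort(proj, kind="stable")
        half = voxels.shape[0] // 2
        side1 = np.zeros(voxels.shape[0], dtype=bool)
        side1[order[:half]] = True
    return voxels[side1], voxels[~side1]


def subdivide(
    clusters: list[Cluster], max_voxels: int = 40, target_name: str = ""
) -> SubdivisionSet:
    """Recursively bisect clusters until every piece has <= ``max_voxels``.

    Each oversized piece is cut by the plane normal to its farthest-pair
    vector v through the pair midpoint x (v . p <= b goes to side 1).
    Degenerate cuts fall back to a stable median split of the projections, so
    every split strictly shrinks the largest piece and termination is
    guaranteed. Entirely deterministic.
    """
    if max_voxels < 1:
        raise InputError("max_voxels must be >= 1")
    if not clusters:
        return SubdivisionSet([], (1.0, 1.0, 1.0), target_name)
    vs = clusters[0].voxel_size_mm
    out: list[Subdivision] = []
    for ci, cluster in enumerate(clusters, start=1):
        stack: list[tuple[np.ndarray, str]] = [(cluster.voxels, str(ci))]
        pieces: list[Subdivision] = []
        while stack:
            voxels, history = stack.pop()
            if voxels.shape[0] <= max_voxels:
                pieces.append(Subdivision(voxels, ci, history))
                continue
            left, right = _split_once(voxels, vs)
            # push right first so the left side is processed first (DFS order)
            stack.append((right, history + ".R"))
            stack.append((left, history + ".L"))
        # deterministic ordering within a cluster: by split history
        pieces.sort(key=lambda s: s.history)
        out.extend(pieces)
    return SubdivisionSet(out, vs, target_name)


def subdivision_features(run, subs: SubdivisionSet):
    """Feature matrix with one column per subdivision (mean member series)."""
    from .decoder import extract_features

    return extract_features(run, subs)
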