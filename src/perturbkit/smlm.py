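"""Voronoi-tessellation cluster analysis of single-molecule localizations.

Reproduces the dSTORM cluster workflow: tessellate the localizations of a
region of interest (ROI), select points whose local density (inverse
Voronoi cell area) exceeds a multiple of the average density, group
adjacent selected cells into clusters, discard small clusters, and report
the fraction of clustered localizations and the localization density.
Coordinates are nanometres; areas are nm^2 (also reported in um^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

logger = logging.getLogger("perturbkit.smlm")


@dataclass
class LocalizationSet:
    """2-D localization coordinates (nm) with an ROI polygon."""

    points: np.ndarray  # (n, 2) float, nm
    roi: Polygon

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not self.roi.is_valid or self.roi.area <= 0:
            raise ValueError("ROI polygon is invalid or degenerate")
        if len(self.points):
            inside = shapely.covers(self.roi, shapely.points(self.points))
            if not inside.all():
                n_out = int((~inside).sum())
                raise ValueError(f"{n_out} localization(s) outside the ROI")

    @classmethod
    def from_rectangle(
        cls, points: np.ndarray, xmin: float, ymin: float, xmax: float, ymax: float
    ) -> "LocalizationSet":
        return cls(points, box(xmin, ymin, xmax, ymax))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VoronoiDiagram:
    """Per-point ROI-clipped Voronoi cells with areas, densities and adjacency."""

    points: np.ndarray
    roi: Polygon
    polygons: list[Polygon]
    areas: np.ndarray  # nm^2
    densities: np.ndarray  # nm^-2
    adjacency: list[tuple[int, int]]  # i < j, cells sharing a boundary segment
    clipped: np.ndarray  # bool, cell altered by ROI clipping

    @property
    def roi_area(self) -> float:
        return float(self.roi.area)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class VoronoiClusterResult:
    """Retained clusters of adjacent high-density Voronoi cells."""

    clusters: list[dict]  # {"members": array, "n": int, "area_nm2": float}
    fraction_clustered: float
    localization_density: float  # localizations per nm^2
    n_points: int
    roi_area: float


_ADJ_TOL = 1e-9  # nm; minimum shared-boundary length to count as adjacency


def tessellate(locs: LocalizationSet, jitter_seed: int = 0) -> VoronoiDiagram:
    """Voronoi tessellation clipped to the ROI.

    Infinite cells are closed by surrounding the field with 8 distant ghost
    points (100x the ROI extent) whose bisectors lie far outside the ROI,
    so the clipped cells are exact.  Duplicate coordinates are jittered by
    1e-6 nm with a deterministic seed; an all-collinear point set is an
    error.  Adjacency connects points whose clipped cells share a boundary
    segment of positive length.
    """
    pts = np.array(locs.points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 localizations to tessellate")

    _, inv, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if (counts > 1).any():
        n_dup = int(counts[counts > 1].sum() - (counts > 1).sum())
        warnings.warn(f"jittering {n_dup} duplicate localization(s) by 1e-6 nm")
        rng = np.random.default_rng(jitter_seed)
        dup_mask = counts[inv] > 1
        pts[dup_mask] += rng.uniform(-1e-6, 1e-6, size=(int(dup_mask.sum()), 2))

    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("all localizations are collinear; tessellation undefined")

    minx, miny, maxx, maxy = locs.roi.bounds
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    radius = 100.0 * max(maxx - minx, maxy - miny, 1.0)
    angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    ghosts = np.column_stack([cx + radius * np.cos(angles), cy + radius * np.sin(angles)])
    vor = Voronoi(np.vstack([pts, ghosts]))

    polygons: list[Polygon] = []
    clipped = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:  # cannot happen with ghosts, guard anyway
            raise RuntimeError("unbounded Voronoi cell survived ghost closure")
        cell = Polygon(vor.vertices[region])
        inside = shapely.covers(locs.roi, shapely.points(vor.vertices[region]))
        if bool(inside.all()):
            polygons.append(cell)
        else:
            clipped[i] = True
            inter = cell.intersection(locs.roi)
            if inter.geom_type == "MultiPolygon":
                inter = max(inter.geoms, key=lambda g: g.area)
            polygons.append(inter)

    areas = np.array([p.area for p in polygons])
    if (areas <= 0).any():
        raise RuntimeError("clipped Voronoi cell with nonpositive area")
    densities = 1.0 / areas

    adjacency: list[tuple[int, int]] = []
    for a, b in vor.ridge_points:
        if a >= n or b >= n:
            continue  # ridge to a ghost point
        i, j = (int(a), int(b)) if a < b else (int(b), int(a))
        if not (clipped[i] or clipped[j]):
            adjacency.append((i, j))
        else:
            shared = polygons[i].intersection(polygons[j])
            if shared.length > _ADJ_TOL:
                adjacency.append((i, j))
    adjacency.sort()

    return VoronoiDiagram(pts, locs.roi, polygons, areas, densities, adjacency, clipped)


def select_dense(
    diag: VoronoiDiagram,
    factor: float = 3.0,
    average: str = "global",
    exclude_boundary: bool = False,
) -> np.ndarray:
    """Boolean mask of points denser than ``factor`` x the average density.

    ``average='global'`` (default) uses N / ROI area; ``average='per_point'``
    uses the mean of per-point densities (biased upward by small cells,
    available for comparison).  ``exclude_boundary`` drops points whose
    cells were altered by ROI clipping.
    """
    if average == "global":
        avg = diag.n_points / diag.roi_area
    elif average == "per_point":
        avg = float(diag.densities.mean())
    else:
        raise ValueError(f"unknown average mode {average!r}")
    selected = diag.densities > factor * avg
    if exclude_boundary:
        selected = selected & ~diag.clipped
    return selected


def group_clusters(
    diag: VoronoiDiagram, selected: np.ndarray, min_cluster_size: int = 10
) -> VoronoiClusterResult:
    """Group adjacent selected cells; retain clusters with more than
    ``min_cluster_size`` localizations (strict).

    fraction_clustered = retained clustered points / total points;
    localization_density = total points / ROI area.
    """
    selected = np.asarray(selected, dtype=bool)
    idx = np.flatnonzero(selected)
    clusters: list[dict] = []
    if idx.size:
        remap = -np.ones(diag.n_points, dtype=int)
        remap[idx] = np.arange(idx.size)
        edges = [
            (remap[i], remap[j]) for i, j in diag.adjacency if selected[i] and selected[j]
        ]
        if edges:
            rows, cols = zip(*edges)
            graph = coo_matrix(
                (np.ones(len(edges)), (rows, cols)), shape=(idx.size, idx.size)
            )
        else:
            graph = coo_matrix((idx.size, idx.size))
        n_comp, labels = connected_components(graph, directed=False)
        for k in range(n_comp):
            members = idx[labels == k]
            if len(members) > min_cluster_size:
                clusters.append(
                    {
                        "members": members,
                        "n": int(len(members)),
                        "area_nm2": float(diag.areas[members].sum()),
                    }
                )
    clusters.sort(key=lambda c: -c["n"])
    n_clustered = sum(c["n"] for c in clusters)
    frac = n_clustered / diag.n_points if diag.n_points else 0.0
    return VoronoiClusterResult(
        clusters=clusters,
        fraction_clustered=float(frac),
        localization_density=diag.n_points / diag.roi_area,
        n_points=diag.n_points,
        roi_area=diag.roi_area,
    )


def summarize_roi(result: VoronoiClusterResult) -> dict:
    """Per-ROI summary of the cluster analysis.

    Reports the conventional clustered/total fraction (primary) and, for
    fidelity, the literal mean per-cluster fraction mean_k(n_k)/sum_k(n_k),
    which is 1/K by construction whenever K clusters are retained and
    therefore degenerate as a comparison metric.  Densities are given per
    nm^2 and per um^2; the per-cluster table lists counts and areas.
    """
    k = len(result.clusters)
    counts = np.array([c["n"] for c in result.clusters], dtype=float)
    mean_per_cluster = float((counts.mean() / counts.sum())) if k else 0.0
    table = pd.DataFrame(
        {
            "cluster_id": np.arange(k),
            "n_localizations": [c["n"] for c in result.clusters],
            "area_nm2": [c["area_nm2"] for c in result.clusters],
            "area_um2": [c["area_nm2"] / 1e6 for c in result.clusters],
        }
    )
    if k:
        table["density_per_nm2"] = table["n_localizations"] / table["area_nm2"]
    else:
        table["density_per_nm2"] = pd.Series(dtype=float)
    return {
        "n_localizations": result.n_points,
        "roi_area_nm2": result.roi_area,
        "roi_area_um2": result.roi_area / 1e6,
        "n_clusters": k,
        "fraction_clustered": result.fraction_clustered,
        "mean_per_cluster_fraction": mean_per_cluster,
        "localization_density_per_nm2": result.localization_density,
        "localization_density_per_um2": result.localization_density * 1e6,
        "cluster_table": table,
    }


def analyze_roi(
    locs: LocalizationSet,
    factor: float = 3.0,
    min_cluster_size: int = 10,
    average: str = "global",
    exclude_boundary: bool = False,
) -> dict:
    """Full pipeline on one ROI: tessellate, select, group, summarize."""
    diag = tessellate(locs)
    selected = select_dense(diag, factor, average=average, exclude_boundary=exclude_boundary)
    result = group_clusters(diag, selected, min_cluster_size)
    return summarize_roi(result)
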