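"""Cell-level features: counts/densities, proportions/proximity, and
Birch spatial-cluster statistics.

Cells are points in μm; a cell belongs to a region iff the raster pixel
containing it is in the region mask. Proximity uses Euclidean distance
with the canonical 80 μm interaction radius. Spatial clusters come from
CF-tree (Birch) construction with threshold 100 μm and branching factor
10, with leaf subclusters taken as the final clusters and their centroids
as exemplars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import Birch
from sklearn.metrics import calinski_harabasz_score

from .slides import CELL_CLASSES, SlideMap
from .tissue import SlideRegions

DEFAULT_PROXIMITY_RADIUS_UM = 80.0
DEFAULT_BIRCH_THRESHOLD_UM = 100.0
DEFAULT_BIRCH_BRANCHING = 10

#: Regions used for cell counts and densities.
COUNT_REGIONS = ("CT", "CAS", "CT+CAS", "CSI", "NECROSIS")
#: Regions used for proportions and spatial-cluster features.
CLUSTER_REGIONS = ("CT", "CAS", "CT+CAS", "CSI")

CLUSTER_METRICS = (
    "n_clusters", "size_mean", "size_sd", "dispersion_mean", "dispersion_sd",
    "extent_mean", "extent_sd", "ball_hall", "calinski_harabasz",
)

ORDERED_PAIRS = [(a, b) for a in CELL_CLASSES for b in CELL_CLASSES if a != b]
UNORDERED_PAIRS = [(CELL_CLASSES[i], CELL_CLASSES[j])
                   for i in range(len(CELL_CLASSES))
                   for j in range(i + 1, len(CELL_CLASSES))]


# ---------------------------------------------------------------------------
# cell / region bookkeeping

def cells_in_region(slide: SlideMap, ctx: SlideRegions, kind: str,
                    cell_class: str | None = None) -> np.ndarray:
    """(n, 2) μm coordinates of cells of a class inside a region, in cell
    table order (class None = all cells); cached on the context."""
    key = (cell_class, kind)
    cached = ctx._cells_xy.get(key)
    if cached is not None:
        return cached
    cells = slide.cells
    sel = np.ones(len(cells), bool)
    if cell_class is not None:
        sel &= (cells["cell_class"] == cell_class).to_numpy()
    r, c = slide.cell_pixel_indices()
    mask = ctx.region(kind).mask
    if len(cells):
        sel &= mask[r, c]
    out = cells.loc[sel, ["x_um", "y_um"]].to_numpy(float)
    ctx._cells_xy[key] = out
    return out


def proximity_pair_count(cells_a: np.ndarray, cells_b: np.ndarray,
                         radius: float = DEFAULT_PROXIMITY_RADIUS_UM) -> int:
    """Number of a-cells whose nearest b-cell is within ``radius`` μm.

    Each a-cell counts at most once; implemented with a k-d tree but
    contractually identical to an all-pairs search (boundary inclusive).
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if len(cells_a) == 0 or len(cells_b) == 0:
        return 0
    tree = cKDTree(np.asarray(cells_b, float))
    d, _ = tree.query(np.asarray(cells_a, float), k=1)
    return int((d <= radius).sum())


# ---------------------------------------------------------------------------
# 56 counts and densities

def count_density_features(slide: SlideMap,
                           regions: SlideRegions | None = None) -> dict[str, float]:
    """5 classes × {count, density/mm²} × 5 regions, plus total-cell count
    and density in CT, CAS, CT+CAS (56 features). Densities are NaN when
    the region has zero area."""
    ctx = regions or SlideRegions(slide)
    out: dict[str, float] = {}
    for kind in COUNT_REGIONS:
        area = ctx.region(kind).area_mm2
        total = 0
        for cls in CELL_CLASSES:
            n = len(cells_in_region(slide, ctx, kind, cls))
            total += n
            out[f"cells.{cls}.{kind}.count"] = float(n)
            out[f"cells.{cls}.{kind}.density"] = n / area if area > 0 else float("nan")
        if kind in ("CT", "CAS", "CT+CAS"):
            out[f"cells.all.{kind}.count"] = float(total)
            out[f"cells.all.{kind}.density"] = total / area if area > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# 208 proportions / proximity

def proportion_proximity_features(
        slide: SlideMap, regions: SlideRegions | None = None,
        radius: float = DEFAULT_PROXIMITY_RADIUS_UM) -> dict[str, float]:
    """The 208-feature proportion/proximity family (see the manifest for
    the full pinned list). Zero denominators yield NaN."""
    ctx = regions or SlideRegions(slide)
    out: dict[str, float] = {}
    pts = {(cls, kind): cells_in_region(slide, ctx, kind, cls)
           for cls in CELL_CLASSES for kind in CLUSTER_REGIONS}

    # (i) per-region class proportions: 5 × 4 = 20
    for kind in CLUSTER_REGIONS:
        total = sum(len(pts[(cls, kind)]) for cls in CELL_CLASSES)
        for cls in CELL_CLASSES:
            out[f"prop.{cls}.{kind}.fraction_of_cells"] = (
                len(pts[(cls, kind)]) / total if total > 0 else float("nan"))

    # (ii) ordered-pair proximity count and proportion in CT+CAS and CSI: 80
    for kind in ("CT+CAS", "CSI"):
        for a, b in ORDERED_PAIRS:
            n_a = len(pts[(a, kind)])
            cnt = proximity_pair_count(pts[(a, kind)], pts[(b, kind)], radius)
            out[f"prox80.{a}.near.{b}.{kind}.count"] = float(cnt)
            out[f"prox80.{a}.near.{b}.{kind}.proportion"] = (
                cnt / n_a if n_a > 0 else float("nan"))

    # (iii) cross-region density log-ratios: 5 × 3 = 15
    dens = {}
    for kind in ("CT", "CAS", "CT+CAS"):
        area = ctx.region(kind).area_mm2
        for cls in CELL_CLASSES:
            n = len(cells_in_region(slide, ctx, kind, cls))
            dens[(cls, kind)] = n / area if area > 0 else float("nan")
    for cls in CELL_CLASSES:
        for k1, k2 in (("CT", "CAS"), ("CT", "CT+CAS"), ("CAS", "CT+CAS")):
            d1, d2 = dens[(cls, k1)], dens[(cls, k2)]
            out[f"contrast.{cls}.log_density_{k1}_vs_{k2}"] = (
                float(np.log(d1 / d2)) if d1 and d2 and np.isfinite(d1) and
                np.isfinite(d2) and d1 > 0 and d2 > 0 else float("nan"))

    # (iv) cells within the proximity radius of the CSI boundary curve: 15
    mids = ctx.interface_midpoints_um
    band_pts = {}
    band_area = _interface_band_area_mm2(ctx, radius)
    for cls in CELL_CLASSES:
        xy = slide.cells.loc[slide.cells["cell_class"] == cls,
                             ["x_um", "y_um"]].to_numpy(float)
        near = _near_curve(xy, mids, radius)
        band_pts[cls] = near
        n = len(near)
        n_all = len(xy)
        out[f"csiband.{cls}.count"] = float(n)
        out[f"csiband.{cls}.density"] = (
            n / band_area if band_area > 0 else float("nan"))
        out[f"csiband.{cls}.proportion"] = n / n_all if n_all > 0 else float("nan")

    # (v) pairwise proportional counts a/(a+b): 10 pairs × 4 regions = 40
    for kind in CLUSTER_REGIONS:
        for a, b in UNORDERED_PAIRS:
            na, nb = len(pts[(a, kind)]), len(pts[(b, kind)])
            out[f"pairprop.{a}_vs_{b}.{kind}"] = (
                na / (na + nb) if na + nb > 0 else float("nan"))

    # (vi) 38 interface-centric contrasts:
    #      pairwise proportional counts among interface-proximal cells (10),
    #      ordered-pair proximity counts among interface-proximal cells (20),
    #      total-cell count/density/proportion in the interface band (3),
    #      per-class density log-ratio CSI region vs CT+CAS (5)
    for a, b in UNORDERED_PAIRS:
        na, nb = len(band_pts[a]), len(band_pts[b])
        out[f"csiprox.pairprop.{a}_vs_{b}"] = (
            na / (na + nb) if na + nb > 0 else float("nan"))
    for a, b in ORDERED_PAIRS:
        out[f"csiprox.{a}.near.{b}.count"] = float(
            proximity_pair_count(band_pts[a], band_pts[b], radius))
    n_band = sum(len(band_pts[cls]) for cls in CELL_CLASSES)
    n_slide = len(slide.cells)
    out["csiband.all.count"] = float(n_band)
    out["csiband.all.density"] = n_band / band_area if band_area > 0 else float("nan")
    out["csiband.all.proportion"] = n_band / n_slide if n_slide > 0 else float("nan")
    area_csi = ctx.region("CSI").area_mm2
    area_tumor = ctx.region("CT+CAS").area_mm2
    for cls in CELL_CLASSES:
        n_csi = len(pts[(cls, "CSI")])
        n_tum = len(cells_in_region(slide, ctx, "CT+CAS", cls))
        d1 = n_csi / area_csi if area_csi > 0 else float("nan")
        d2 = n_tum / area_tumor if area_tumor > 0 else float("nan")
        out[f"contrast.{cls}.log_density_CSI_vs_CT+CAS"] = (
            float(np.log(d1 / d2)) if np.isfinite(d1) and np.isfinite(d2)
            and d1 > 0 and d2 > 0 else float("nan"))
    return out


def _near_curve(xy: np.ndarray, curve_pts_um: np.ndarray,
                radius: float) -> np.ndarray:
    """Subset of points within ``radius`` of the interface point set."""
    if len(xy) == 0 or len(curve_pts_um) == 0:
        return np.empty((0, 2))
    tree = cKDTree(curve_pts_um)
    d, _ = tree.query(xy, k=1)
    return xy[d <= radius]


def _interface_band_area_mm2(ctx: SlideRegions, radius: float) -> float:
    """Area (mm²) of the raster within ``radius`` μm of the CT|CAS
    interface, irrespective of tissue class."""
    from .slides import _distance_to_interface_px  # shared half-pixel EDT

    dist = _distance_to_interface_px(ctx.slide.tissue_raster)
    mpp = ctx.slide.tissue_mpp
    n = int((dist * mpp <= radius + 1e-9).sum())
    return n * (mpp / 1000.0) ** 2


# ---------------------------------------------------------------------------
# Birch spatial clusters

@dataclass
class CellCluster:
    exemplar_um: np.ndarray     # subcluster centroid (x, y)
    member_idx: np.ndarray      # indices into the clustered point array
    size: int
    dispersion_um: float        # mean member–exemplar distance
    extent_um: float            # max member–exemplar distance


@dataclass
class CellClusterSet:
    """Birch leaf-subcluster partition of one cell point set."""

    points_um: np.ndarray
    labels: np.ndarray
    clusters: list[CellCluster]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def birch_clusters(points_um: np.ndarray,
                   threshold: float = DEFAULT_BIRCH_THRESHOLD_UM,
                   branching: int = DEFAULT_BIRCH_BRANCHING) -> CellClusterSet:
    """CF-tree clustering of a nonempty point set; leaf subclusters are the
    final clusters (no global reclustering step) and their centroids the
    exemplars. Deterministic given point order."""
    pts = np.asarray(points_um, float)
    if len(pts) == 0:
        raise ValueError("birch_clusters requires a nonempty point set")
    if len(pts) == 1:
        cl = CellCluster(exemplar_um=pts[0].copy(), member_idx=np.array([0]),
                         size=1, dispersion_um=0.0, extent_um=0.0)
        return CellClusterSet(points_um=pts, labels=np.zeros(1, int), clusters=[cl])
    model = Birch(threshold=threshold, branching_factor=branching, n_clusters=None)
    labels = model.fit_predict(pts)
    centers = model.subcluster_centers_
    clusters = []
    new_labels = np.empty(len(pts), int)
    for k, lab in enumerate(np.unique(labels)):
        idx = np.flatnonzero(labels == lab)
        new_labels[idx] = k
        d = np.linalg.norm(pts[idx] - centers[lab], axis=1)
        clusters.append(CellCluster(
            exemplar_um=centers[lab].copy(), member_idx=idx, size=len(idx),
            dispersion_um=float(d.mean()), extent_um=float(d.max())))
    return CellClusterSet(points_um=pts, labels=new_labels, clusters=clusters)


def ball_hall_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the mean squared member–centroid distance."""
    vals = []
    for lab in np.unique(labels):
        p = points[labels == lab]
        c = p.mean(axis=0)
        vals.append(float(((p - c) ** 2).sum(axis=1).mean()))
    return float(np.mean(vals))


def cluster_metrics(cs: CellClusterSet) -> dict[str, float]:
    """The nine per-partition spatial-cluster statistics."""
    sizes = np.array([c.size for c in cs.clusters], float)
    disp = np.array([c.dispersion_um for c in cs.clusters], float)
    ext = np.array([c.extent_um for c in cs.clusters], float)
    n, k = len(cs.points_um), cs.n_clusters
    ch = float("nan")
    if 1 < k < n:
        ch = float(calinski_harabasz_score(cs.points_um, cs.labels))
    return {
        "n_clusters": float(k),
        "size_mean": float(sizes.mean()),
        "size_sd": float(sizes.std(ddof=0)),
        "dispersion_mean": float(disp.mean()),
        "dispersion_sd": float(disp.std(ddof=0)),
        "extent_mean": float(ext.mean()),
        "extent_sd": float(ext.std(ddof=0)),
        "ball_hall": ball_hall_index(cs.points_um, cs.labels),
        "calinski_harabasz": ch,
    }


def cluster_features(slide: SlideMap, regions: SlideRegions | None = None,
                     threshold: float = DEFAULT_BIRCH_THRESHOLD_UM,
                     branching: int = DEFAULT_BIRCH_BRANCHING) -> dict[str, float]:
    """180 features: 9 cluster metrics × 5 cell classes × 4 regions.

    Regions with fewer than 2 cells of a class report only the cluster
    count and size statistics; the remaining metrics are NaN.
    """
    ctx = regions or SlideRegions(slide)
    out: dict[str, float] = {}
    for cls in CELL_CLASSES:
        for kind in CLUSTER_REGIONS:
            key = f"cluster.{cls}.{kind}"
            pts = cells_in_region(slide, ctx, kind, cls)
            vals = {m: float("nan") for m in CLUSTER_METRICS}
            if len(pts) == 0:
                vals["n_clusters"] = 0.0
            elif len(pts) == 1:
                vals.update({"n_clusters": 1.0, "size_mean": 1.0, "size_sd": 0.0})
            else:
                vals = cluster_metrics(birch_clusters(pts, threshold, branching))
            for m in CLUSTER_METRICS:
                out[f"{key}.{m}"] = vals[m]
    return out
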