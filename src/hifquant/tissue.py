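"""Tissue-level features: areas/multiplicity, morphology, architecture.

All features are computed per analysis region (CT, CAS, CT+CAS, necrosis,
and the cancer–stroma interface band) from 8-connected components of the
region mask. Component-level metrics are aggregated over three scopes:
the largest component, and the mean and standard deviation across the
"significant" components (≥ 10% of the largest component's pixel count).
Features that are undefined on a slide (empty region, degenerate
component) are reported as NaN, the catalog-wide missing sentinel.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .contours import mask_perimeter_px
from .slides import (
    ComponentSet,
    RegionMask,
    SlideMap,
    connected_components,
    csi_interface_edges,
    region_mask,
    significant_components,
)

#: Regions over which component-level tissue features are aggregated.
COMPONENT_REGIONS = ("CT", "CAS", "CT+CAS", "NECROSIS")

#: The ten per-component morphology metrics.
MORPHOLOGY_METRICS = (
    "major_axis_um", "minor_axis_um", "convex_area_mm2", "filled_area_mm2",
    "euler_number", "lacunarity", "eccentricity", "perimeter_um",
    "shape_roughness", "extent_bbox",
)

#: Morphology metrics also reported for the largest CSI-band component.
CSI_MORPHOLOGY_METRICS = (
    "major_axis_um", "minor_axis_um", "eccentricity", "perimeter_um",
    "shape_roughness",
)

ARCHITECTURE_METRICS = ("fractal_dimension", "solidity")

SCOPES = ("largest", "sig_mean", "sig_sd")

DEFAULT_LACUNARITY_BOX_PX = 32
DEFAULT_SIGNIFICANT_FRACTION = 0.10


class SlideRegions:
    """Cached region masks and component sets for one slide.

    Feature families share this context so the (fairly expensive) region
    derivation and component labeling happen once per slide.
    """

    def __init__(self, slide: SlideMap, csi_halfwidth_um: float = 40.0,
                 significant_fraction: float = DEFAULT_SIGNIFICANT_FRACTION):
        self.slide = slide
        self.csi_halfwidth_um = csi_halfwidth_um
        self.significant_fraction = significant_fraction
        self._regions: dict[str, RegionMask] = {}
        self._components: dict[str, ComponentSet] = {}
        self._significant: dict[str, ComponentSet] = {}
        self._metric_rows: dict[str, list[dict[str, float]]] = {}
        self._cells_xy: dict[tuple[str | None, str], np.ndarray] = {}
        self._interface = None

    def region(self, kind: str) -> RegionMask:
        if kind not in self._regions:
            self._regions[kind] = region_mask(self.slide, kind, self.csi_halfwidth_um)
        return self._regions[kind]

    def components(self, kind: str) -> ComponentSet:
        if kind not in self._components:
            self._components[kind] = connected_components(self.region(kind))
        return self._components[kind]

    def significant(self, kind: str) -> ComponentSet:
        if kind not in self._significant:
            self._significant[kind] = significant_components(
                self.components(kind), self.significant_fraction)
        return self._significant[kind]

    def metric_rows(self, kind: str,
                    lac_box: int = DEFAULT_LACUNARITY_BOX_PX) -> list[dict[str, float]]:
        """All per-component metrics for the significant components of a
        region, cached (largest component is row 0)."""
        key = f"{kind}:{lac_box}"
        if key not in self._metric_rows:
            comps = self.significant(kind)
            self._metric_rows[key] = [
                _component_metrics(_crop(comps.labels, c), comps.mpp, lac_box)
                for c in comps.components]
        return self._metric_rows[key]

    @property
    def interface_midpoints_um(self) -> np.ndarray:
        """Midpoints of CT|CAS shared pixel edges, in μm (x, y)."""
        if self._interface is None:
            mids, incident = csi_interface_edges(self.slide.tissue_raster)
            self._interface = (mids * self.slide.tissue_mpp, incident)
        return self._interface[0]

    @property
    def interface_incident_pixels(self) -> np.ndarray:
        if self._interface is None:
            _ = self.interface_midpoints_um
        return self._interface[1]


# ---------------------------------------------------------------------------
# scalar metrics

def perimeter(component_mask: np.ndarray, mpp: float) -> float:
    """Perimeter of a component's pixel set in μm (contour estimator)."""
    if not component_mask.any():
        raise ValueError("perimeter of an empty component is undefined")
    return mask_perimeter_px(component_mask) * mpp


def fractal_dimension(boundary: np.ndarray,
                      box_sizes: list[int] | None = None) -> float:
    """Box-counting dimension of a pixel point set.

    ``boundary`` is an (n, 2) array of integer pixel coordinates (or a
    boolean mask). D is the least-squares slope of log N(ε) against
    log(1/ε) where N(ε) counts occupied grid-aligned ε-boxes. Box sizes
    default to the dyadic ladder 2..256 clipped to half the extent of the
    point set; a degenerate set (< 2 usable sizes) returns NaN.
    """
    if boundary.ndim == 2 and boundary.dtype == bool:
        pts = np.argwhere(boundary)
    else:
        pts = np.asarray(boundary, int)
    if len(pts) < 2:
        return float("nan")
    pts = pts - pts.min(axis=0)
    extent = int(pts.max()) + 1
    if box_sizes is None:
        box_sizes = [s for s in (2, 4, 8, 16, 32, 64, 128, 256)
                     if s <= max(2, extent / 2)]
    sizes, counts = [], []
    for s in box_sizes:
        boxes = pts // s
        n = len(np.unique(boxes[:, 0].astype(np.int64) * (extent // s + 2)
                          + boxes[:, 1], axis=0))
        if n > 0:
            sizes.append(s)
            counts.append(n)
    if len(sizes) < 2:
        return float("nan")
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, float)),
                       np.log(np.asarray(counts, float)), 1)[0]
    return float(slope)


def lacunarity(mask: np.ndarray, box_size: int = DEFAULT_LACUNARITY_BOX_PX) -> float:
    """Gliding-box lacunarity Λ(r) = E[M²]/E[M]² at window size ``box_size``.

    M is the mask pixel count in each r×r window fully inside the array.
    A fully occupied mask gives Λ = 1; an empty mask gives NaN.
    """
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    r = int(box_size)
    if r > h or r > w:
        raise ValueError(f"box size {r} exceeds raster shape {mask.shape}")
    if r < 1:
        raise ValueError("box size must be >= 1")
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    m = (ii[r:, r:] - ii[:-r, r:] - ii[r:, :-r] + ii[:-r, :-r]).astype(float)
    em = m.mean()
    if em == 0:
        return float("nan")
    return float((m ** 2).mean() / em ** 2)


def component_boundary_pixels(component_mask: np.ndarray) -> np.ndarray:
    """Pixels of the component with at least one 4-neighbor outside it."""
    m = np.pad(component_mask, 1)
    interior = m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1] & m[1:-1, :-2] & m[1:-1, 2:]
    return np.argwhere(component_mask & ~interior)


# ---------------------------------------------------------------------------
# per-component metric table

def _component_metrics(comp_mask: np.ndarray, mpp: float,
                       lac_box: int = DEFAULT_LACUNARITY_BOX_PX) -> dict[str, float]:
    """All morphology + architecture metrics for one component (cropped mask)."""
    props = measure.regionprops(comp_mask.astype(np.uint8))[0]
    area_px = float(props.area)
    mm = mpp / 1000.0
    perim_px = mask_perimeter_px(comp_mask)
    h, w = comp_mask.shape
    bs = min(lac_box, min(h, w) // 2)
    lac = lacunarity(comp_mask, bs) if bs >= 2 else float("nan")
    boundary = component_boundary_pixels(comp_mask)
    fd = fractal_dimension(boundary) if len(boundary) > 1 else float("nan")
    return {
        "major_axis_um": float(props.axis_major_length) * mpp,
        "minor_axis_um": float(props.axis_minor_length) * mpp,
        "convex_area_mm2": float(props.area_convex) * mm ** 2,
        "filled_area_mm2": float(props.area_filled) * mm ** 2,
        "euler_number": float(props.euler_number),
        "lacunarity": lac,
        "eccentricity": float(props.eccentricity),
        "perimeter_um": perim_px * mpp,
        "shape_roughness": perim_px ** 2 / area_px,
        "extent_bbox": float(props.extent),
        "fractal_dimension": fd,
        "solidity": float(props.solidity),
    }


def _crop(labels: np.ndarray, comp) -> np.ndarray:
    r0, c0, r1, c1 = comp.bbox
    return labels[r0:r1, c0:c1] == comp.component_id


def _scope_aggregate(ctx: "SlideRegions", kind: str, metrics: tuple[str, ...],
                     lac_box: int = DEFAULT_LACUNARITY_BOX_PX) -> dict[str, float]:
    """largest / significant-mean / significant-sd for each metric."""
    out = {f"{m}.{s}": float("nan") for m in metrics for s in SCOPES}
    rows = ctx.metric_rows(kind, lac_box)
    if not rows:
        return out
    for m in metrics:
        vals = np.array([r[m] for r in rows], float)
        out[f"{m}.largest"] = vals[0]  # components sorted by descending size
        finite = vals[np.isfinite(vals)]
        if finite.size:
            out[f"{m}.sig_mean"] = float(finite.mean())
            out[f"{m}.sig_sd"] = float(finite.std(ddof=0))
    return out


# ---------------------------------------------------------------------------
# the three tissue feature families

def area_multiplicity_features(slide: SlideMap,
                               regions: SlideRegions | None = None) -> dict[str, float]:
    """13 area / multiplicity / relative-area features (areas in mm²)."""
    ctx = regions or SlideRegions(slide)
    areas = {k: ctx.region(k).area_mm2 for k in ("CT", "CAS", "CT+CAS", "CSI", "NECROSIS")}
    out = {f"area.{k}.mm2": areas[k] for k in ("CT", "CAS", "CT+CAS", "CSI", "NECROSIS")}
    for k in COMPONENT_REGIONS:
        out[f"multiplicity.{k}.significant"] = float(len(ctx.significant(k)))
    tumor = areas["CT+CAS"]
    out["relarea.CAS_over_CT+CAS"] = areas["CAS"] / tumor if tumor > 0 else float("nan")
    out["relarea.CT_over_CT+CAS"] = areas["CT"] / tumor if tumor > 0 else float("nan")
    denom = tumor + areas["NECROSIS"]
    out["relarea.NECROSIS_over_CT+CAS+NECROSIS"] = (
        areas["NECROSIS"] / denom if denom > 0 else float("nan"))
    out["relarea.CSI_over_CT+CAS"] = areas["CSI"] / tumor if tumor > 0 else float("nan")
    return out


def morphology_features(slide: SlideMap,
                        regions: SlideRegions | None = None,
                        lacunarity_box_px: int = DEFAULT_LACUNARITY_BOX_PX) -> dict[str, float]:
    """125 morphology features: 10 metrics × 3 scopes × 4 regions, plus
    5 metrics of the largest CSI-band component."""
    ctx = regions or SlideRegions(slide)
    out: dict[str, float] = {}
    for kind in COMPONENT_REGIONS:
        agg = _scope_aggregate(ctx, kind, MORPHOLOGY_METRICS, lacunarity_box_px)
        for m in MORPHOLOGY_METRICS:
            for s in SCOPES:
                out[f"morph.{kind}.{m}.{s}"] = agg[f"{m}.{s}"]
    csi_rows = ctx.metric_rows("CSI", lacunarity_box_px)
    vals = {m: float("nan") for m in CSI_MORPHOLOGY_METRICS}
    if csi_rows:
        vals = {m: csi_rows[0][m] for m in CSI_MORPHOLOGY_METRICS}
    for m in CSI_MORPHOLOGY_METRICS:
        out[f"morph.CSI.{m}.largest"] = vals[m]
    return out


def architecture_features(slide: SlideMap,
                          regions: SlideRegions | None = None) -> dict[str, float]:
    """25 architecture features: {fractal dimension, solidity} × 3 scopes
    × 4 regions, plus the fractal dimension of the CT|CAS interface curve."""
    ctx = regions or SlideRegions(slide)
    out: dict[str, float] = {}
    for kind in COMPONENT_REGIONS:
        agg = _scope_aggregate(ctx, kind, ARCHITECTURE_METRICS)
        for m in ARCHITECTURE_METRICS:
            for s in SCOPES:
                out[f"arch.{kind}.{m}.{s}"] = agg[f"{m}.{s}"]
    incident = ctx.interface_incident_pixels
    pts = np.argwhere(incident)
    out["arch.CSI.fractal_dimension.interface"] = (
        fractal_dimension(pts) if len(pts) > 1 else float("nan"))
    return out
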