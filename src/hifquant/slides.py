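"""Slide-level data model: tissue rasters, cell tables, analysis regions.

A slide is represented by a dense tissue-type raster (integer codes at a
fixed resolution, typically 4 μm per pixel) plus a table of cell centroids
in micron coordinates. Analysis regions are derived from the raster:
cancer tissue (CT), cancer-associated stroma (CAS), their union, necrosis,
and the cancer–stroma interface (CSI) band.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure

#: Tissue raster codes.
TISSUE_BACKGROUND = 0
TISSUE_CT = 1
TISSUE_CAS = 2
TISSUE_NECROSIS = 3
TISSUE_CODES = (TISSUE_BACKGROUND, TISSUE_CT, TISSUE_CAS, TISSUE_NECROSIS)

#: The five cell classes scored on every slide.
CELL_CLASSES = ("lymphocyte", "plasma", "fibroblast", "macrophage", "cancer")

#: Analysis region kinds.
REGION_KINDS = ("CT", "CAS", "CT+CAS", "NECROSIS", "CSI")

#: Default half-width of the cancer–stroma interface band, in μm.
DEFAULT_CSI_HALFWIDTH_UM = 40.0


class SlideValidationError(ValueError):
    """Raised when a slide map violates its contract."""


@dataclass
class SlideMap:
    """One slide: tissue raster, cell point table, resolution, metadata.

    Parameters
    ----------
    tissue_raster
        2-D integer array with codes 0 (background/normal), 1 (cancer
        tissue), 2 (cancer-associated stroma), 3 (necrosis).
    tissue_mpp
        Microns per raster pixel (> 0).
    cells
        DataFrame with columns ``x_um``, ``y_um``, ``cell_class``. The
        origin is the raster's top-left corner; pixel (r, c) covers the
        half-open square [c·mpp, (c+1)·mpp) × [r·mpp, (r+1)·mpp).
    """

    slide_id: str
    patient_id: str
    site_id: str
    cancer_type: str
    tissue_raster: np.ndarray
    tissue_mpp: float = 4.0
    cells: pd.DataFrame = field(default_factory=lambda: _empty_cell_table())

    def __post_init__(self) -> None:
        self.tissue_raster = np.asarray(self.tissue_raster)
        if self.tissue_raster.ndim != 2:
            raise SlideValidationError(
                f"tissue raster must be 2-D, got shape {self.tissue_raster.shape}"
            )
        if self.tissue_mpp <= 0:
            raise SlideValidationError(f"tissue_mpp must be > 0, got {self.tissue_mpp}")
        bad = ~np.isin(self.tissue_raster, TISSUE_CODES)
        if bad.any():
            code = int(self.tissue_raster[bad][0])
            raise SlideValidationError(
                f"slide {self.slide_id}: unknown tissue code {code}"
            )
        self.cells = self.cells.reset_index(drop=True)
        missing = {"x_um", "y_um", "cell_class"} - set(self.cells.columns)
        if missing:
            raise SlideValidationError(f"cell table missing columns {sorted(missing)}")
        unknown = ~self.cells["cell_class"].isin(CELL_CLASSES)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise SlideValidationError(
                f"slide {self.slide_id}: unknown cell class "
                f"{self.cells['cell_class'].iloc[row]!r} at row {row}"
            )
        h, w = self.tissue_raster.shape
        x = self.cells["x_um"].to_numpy(float)
        y = self.cells["y_um"].to_numpy(float)
        oob = (x < 0) | (y < 0) | (x >= w * self.tissue_mpp) | (y >= h * self.tissue_mpp)
        if oob.any():
            row = int(np.flatnonzero(oob)[0])
            raise SlideValidationError(
                f"slide {self.slide_id}: cell at row {row} "
                f"({x[row]}, {y[row]}) μm lies outside the "
                f"{w * self.tissue_mpp} × {h * self.tissue_mpp} μm raster extent"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue_raster.shape

    def cell_pixel_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Raster (row, col) index of the pixel containing each cell."""
        r = np.floor(self.cells["y_um"].to_numpy(float) / self.tissue_mpp).astype(int)
        c = np.floor(self.cells["x_um"].to_numpy(float) / self.tissue_mpp).astype(int)
        return r, c


def _empty_cell_table() -> pd.DataFrame:
    return pd.DataFrame({"x_um": pd.Series(dtype=float),
                         "y_um": pd.Series(dtype=float),
                         "cell_class": pd.Series(dtype=str)})


@dataclass
class RegionMask:
    """A boolean analysis region derived from a slide raster."""

    region_kind: str
    mask: np.ndarray
    mpp: float

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.mpp / 1000.0) ** 2


@dataclass
class ComponentInfo:
    component_id: int
    pixel_count: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) exclusive


@dataclass
class ComponentSet:
    """8-connected components of a region mask, sorted by descending size."""

    labels: np.ndarray
    components: list[ComponentInfo]
    mpp: float

    def __len__(self) -> int:
        return len(self.components)

    def component_mask(self, component_id: int) -> np.ndarray:
        return self.labels == component_id


# ---------------------------------------------------------------------------
# readers / writers

def load_slide_map(raster_path: str | os.PathLike, cells_path: str | os.PathLike | None,
                   meta: dict) -> SlideMap:
    """Read a slide from a single-channel PNG/TIFF raster plus a cell CSV.

    ``meta`` must provide ``slide_id``, ``patient_id``, ``site_id``,
    ``cancer_type`` and may provide ``tissue_mpp`` (default 4 μm/px).
    """
    raster_path = os.fspath(raster_path)
    if not os.path.exists(raster_path):
        raise FileNotFoundError(raster_path)
    if raster_path.lower().endswith((".tif", ".tiff")):
        raster = tifffile.imread(raster_path)
    else:
        raster = iio.imread(raster_path)
    raster = np.asarray(raster)
    if raster.ndim == 3:  # single-channel image stored with trailing axis
        if raster.shape[2] != 1:
            raise SlideValidationError(
                f"{raster_path}: expected a single-channel raster, got shape {raster.shape}"
            )
        raster = raster[:, :, 0]
    if cells_path is None:
        cells = _empty_cell_table()
    else:
        if not os.path.exists(os.fspath(cells_path)):
            raise FileNotFoundError(os.fspath(cells_path))
        cells = pd.read_csv(cells_path, dtype={"cell_class": str})
        if cells.empty:
            cells = _empty_cell_table()
    return SlideMap(
        slide_id=str(meta["slide_id"]),
        patient_id=str(meta["patient_id"]),
        site_id=str(meta["site_id"]),
        cancer_type=str(meta.get("cancer_type", "NA")),
        tissue_raster=raster.astype(np.uint8),
        tissue_mpp=float(meta.get("tissue_mpp", 4.0)),
        cells=cells,
    )


def save_slide_map(slide: SlideMap, raster_path: str | os.PathLike,
                   cells_path: str | os.PathLike) -> None:
    """Write the raster (PNG or TIFF by extension) and the cell CSV."""
    raster_path = os.fspath(raster_path)
    raster = slide.tissue_raster.astype(np.uint8)
    if raster_path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(raster_path, raster)
    else:
        iio.imwrite(raster_path, raster)
    slide.cells.to_csv(cells_path, index=False,
                       columns=["x_um", "y_um", "cell_class"])


def slide_meta(slide: SlideMap) -> dict:
    return {
        "slide_id": slide.slide_id,
        "patient_id": slide.patient_id,
        "site_id": slide.site_id,
        "cancer_type": slide.cancer_type,
        "tissue_mpp": slide.tissue_mpp,
    }


# ---------------------------------------------------------------------------
# regions

def csi_interface_edges(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midpoints (in pixel units, x=col, y=row) of pixel edges shared
    between a CT pixel and a CAS pixel, and the set of pixels incident to
    such an edge (boolean mask)."""
    mids_v, mids_h, incident = _interface_edge_midpoints(raster)
    if len(mids_v) or len(mids_h):
        midpoints = np.concatenate([m for m in (mids_v, mids_h) if len(m)])
    else:
        midpoints = np.empty((0, 2))
    return midpoints, incident


def _interface_edge_midpoints(raster: np.ndarray):
    ct = raster == TISSUE_CT
    cas = raster == TISSUE_CAS
    incident = np.zeros(raster.shape, bool)
    # vertical edges between columns c-1 | c (the edge is the segment
    # x = c, y in [r, r+1])
    pair = (ct[:, :-1] & cas[:, 1:]) | (cas[:, :-1] & ct[:, 1:])
    rr, cc = np.nonzero(pair)
    mids_v = np.column_stack([cc + 1.0, rr + 0.5]) if rr.size else np.empty((0, 2))
    incident[rr, cc] = True
    incident[rr, cc + 1] = True
    # horizontal edges between rows r-1 / r (segment y = r, x in [c, c+1])
    pair = (ct[:-1, :] & cas[1:, :]) | (cas[:-1, :] & ct[1:, :])
    rr, cc = np.nonzero(pair)
    mids_h = np.column_stack([cc + 0.5, rr + 1.0]) if rr.size else np.empty((0, 2))
    incident[rr, cc] = True
    incident[rr + 1, cc] = True
    return mids_v, mids_h, incident


def interface_sample_points(raster: np.ndarray) -> np.ndarray:
    """The CT|CAS shared boundary sampled at each edge's endpoints and
    midpoint (half-pixel lattice, pixel units). Distance to this point set
    approximates distance to the boundary curve to within a quarter pixel."""
    mids_v, mids_h, _ = _interface_edge_midpoints(raster)
    pts = []
    for mids, along in ((mids_v, (0.0, 0.5)), (mids_h, (0.5, 0.0))):
        if len(mids):
            pts.extend([mids, mids + along, mids - along])
    if not pts:
        return np.empty((0, 2))
    return np.unique(np.concatenate(pts), axis=0)


def _distance_to_interface_px(raster: np.ndarray) -> np.ndarray:
    """Distance (in pixel units) from each pixel center to the nearest
    sampled point of the CT|CAS shared boundary, via an exact Euclidean
    distance transform on a half-pixel grid."""
    h, w = raster.shape
    pts = interface_sample_points(raster)
    if len(pts) == 0:
        return np.full((h, w), np.inf)
    grid = np.ones((2 * h + 1, 2 * w + 1), bool)
    xs = np.round(pts[:, 0] * 2).astype(int)
    ys = np.round(pts[:, 1] * 2).astype(int)
    grid[ys, xs] = False
    dist = ndimage.distance_transform_edt(grid, sampling=0.5)
    return dist[1::2, 1::2]


def region_mask(slide: SlideMap, kind: str,
                csi_halfwidth_um: float = DEFAULT_CSI_HALFWIDTH_UM) -> RegionMask:
    """Derive an analysis region from a slide raster.

    CT, CAS and NECROSIS are code-equality masks; CT+CAS is their union.
    CSI is the subset of CT∪CAS within ``csi_halfwidth_um`` (Euclidean
    distance in μm) of any pixel edge shared between a CT and a CAS pixel.
    """
    raster = slide.tissue_raster
    if kind == "CT":
        mask = raster == TISSUE_CT
    elif kind == "CAS":
        mask = raster == TISSUE_CAS
    elif kind == "CT+CAS":
        mask = (raster == TISSUE_CT) | (raster == TISSUE_CAS)
    elif kind == "NECROSIS":
        mask = raster == TISSUE_NECROSIS
    elif kind == "CSI":
        union = (raster == TISSUE_CT) | (raster == TISSUE_CAS)
        dist = _distance_to_interface_px(raster)
        mask = union & (dist * slide.tissue_mpp <= csi_halfwidth_um + 1e-9)
    else:
        raise ValueError(f"unknown region kind {kind!r}; expected one of {REGION_KINDS}")
    return RegionMask(region_kind=kind, mask=mask, mpp=slide.tissue_mpp)


# ---------------------------------------------------------------------------
# connected components

def connected_components(region: RegionMask) -> ComponentSet:
    """8-connectivity labeling, components sorted by descending pixel count."""
    labels = measure.label(region.mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return ComponentSet(labels=labels, components=[], mpp=region.mpp)
    counts = np.bincount(labels.ravel())[1:]
    order = np.argsort(-counts, kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[labels]
    objects = ndimage.find_objects(labels)
    comps = []
    for new_id in range(1, n + 1):
        sl = objects[new_id - 1]
        comps.append(ComponentInfo(
            component_id=new_id,
            pixel_count=int(counts[order[new_id - 1]]),
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
        ))
    return ComponentSet(labels=labels, components=comps, mpp=region.mpp)


def significant_components(comps: ComponentSet, fraction: float = 0.10) -> ComponentSet:
    """Keep components whose size is at least ``fraction`` of the largest."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not comps.components:
        return comps
    cutoff = fraction * comps.components[0].pixel_count
    keep = [c for c in comps.components if c.pixel_count >= cutoff]
    keep_ids = {c.component_id for c in keep}
    labels = np.where(np.isin(comps.labels, list(keep_ids)), comps.labels, 0)
    # ids stay contiguous because components are sorted by descending size
    return ComponentSet(labels=labels, components=keep, mpp=comps.mpp)
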