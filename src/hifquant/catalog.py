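"""The 607-feature HIF catalog: manifest, per-slide extraction, patient
aggregation, normalization, and feature clustering.

The catalog has six categories with fixed sizes — count/density 56,
spatial cluster 180, proportion/proximity 208, area/multiplicity 13,
architecture 25, morphology 125 — for 607 features in total (163
tissue-derived, 444 cell-derived). The decomposition of each category
into named features is pinned here and written out as a manifest;
editing the configuration in a way that breaks the totals is a hard
error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import cells as cellmod
from . import tissue as tissmod
from .cells import CELL_CLASSES, CLUSTER_METRICS, CLUSTER_REGIONS, COUNT_REGIONS
from .slides import SlideMap
from .tissue import (
    ARCHITECTURE_METRICS,
    COMPONENT_REGIONS,
    CSI_MORPHOLOGY_METRICS,
    MORPHOLOGY_METRICS,
    SCOPES,
    SlideRegions,
)

logger = logging.getLogger(__name__)

CATEGORY_SIZES = {
    "count_density": 56,
    "cluster": 180,
    "proportion_proximity": 208,
    "area_multiplicity": 13,
    "architecture": 25,
    "morphology": 125,
}
TOTAL_FEATURES = 607
TISSUE_FEATURES_TOTAL = 163
CELL_FEATURES_TOTAL = 444

#: The CT+CAS area feature used for patient-level slide selection.
TUMOR_AREA_FEATURE = "area.CT+CAS.mm2"


@dataclass(frozen=True)
class HifEntry:
    feature_id: str
    category: str
    cell_class: str | None
    region: str | None
    metric: str
    scope: str | None = None


@dataclass
class HifManifest:
    entries: list[HifEntry]

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.category] = counts.get(e.category, 0) + 1
        return counts

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(e) for e in self.entries], fh, indent=1)


class ManifestError(ValueError):
    """Raised when a catalog configuration breaks the printed totals."""


def enumerate_catalog(config: dict | None = None) -> HifManifest:
    """Build the deterministic 607-entry manifest and verify its totals."""
    entries: list[HifEntry] = []

    def add(fid, cat, cls, region, metric, scope=None):
        entries.append(HifEntry(fid, cat, cls, region, metric, scope))

    # --- area / multiplicity (13) -------------------------------------
    for kind in ("CT", "CAS", "CT+CAS", "CSI", "NECROSIS"):
        add(f"area.{kind}.mm2", "area_multiplicity", None, kind, "area_mm2")
    for kind in COMPONENT_REGIONS:
        add(f"multiplicity.{kind}.significant", "area_multiplicity", None, kind,
            "n_significant_components")
    for fid, kind in (("relarea.CAS_over_CT+CAS", "CAS"),
                      ("relarea.CT_over_CT+CAS", "CT"),
                      ("relarea.NECROSIS_over_CT+CAS+NECROSIS", "NECROSIS"),
                      ("relarea.CSI_over_CT+CAS", "CSI")):
        add(fid, "area_multiplicity", None, kind, "relative_area")

    # --- morphology (125) ---------------------------------------------
    for kind in COMPONENT_REGIONS:
        for m in MORPHOLOGY_METRICS:
            for s in SCOPES:
                add(f"morph.{kind}.{m}.{s}", "morphology", None, kind, m, s)
    for m in CSI_MORPHOLOGY_METRICS:
        add(f"morph.CSI.{m}.largest", "morphology", None, "CSI", m, "largest")

    # --- architecture (25) --------------------------------------------
    for kind in COMPONENT_REGIONS:
        for m in ARCHITECTURE_METRICS:
            for s in SCOPES:
                add(f"arch.{kind}.{m}.{s}", "architecture", None, kind, m, s)
    add("arch.CSI.fractal_dimension.interface", "architecture", None, "CSI",
        "fractal_dimension", "interface")

    # --- counts / densities (56) --------------------------------------
    for kind in COUNT_REGIONS:
        for cls in CELL_CLASSES:
            add(f"cells.{cls}.{kind}.count", "count_density", cls, kind, "count")
            add(f"cells.{cls}.{kind}.density", "count_density", cls, kind, "density")
        if kind in ("CT", "CAS", "CT+CAS"):
            add(f"cells.all.{kind}.count", "count_density", "all", kind, "count")
            add(f"cells.all.{kind}.density", "count_density", "all", kind, "density")

    # --- proportions / proximity (208) --------------------------------
    for kind in CLUSTER_REGIONS:
        for cls in CELL_CLASSES:
            add(f"prop.{cls}.{kind}.fraction_of_cells", "proportion_proximity",
                cls, kind, "fraction_of_cells")
    for kind in ("CT+CAS", "CSI"):
        for a, b in cellmod.ORDERED_PAIRS:
            add(f"prox80.{a}.near.{b}.{kind}.count", "proportion_proximity",
                a, kind, f"proximity_count_near_{b}")
            add(f"prox80.{a}.near.{b}.{kind}.proportion", "proportion_proximity",
                a, kind, f"proximity_proportion_near_{b}")
    for cls in CELL_CLASSES:
        for k1, k2 in (("CT", "CAS"), ("CT", "CT+CAS"), ("CAS", "CT+CAS")):
            add(f"contrast.{cls}.log_density_{k1}_vs_{k2}", "proportion_proximity",
                cls, k1, f"log_density_vs_{k2}")
    for cls in CELL_CLASSES:
        for m in ("count", "density", "proportion"):
            add(f"csiband.{cls}.{m}", "proportion_proximity", cls, "CSI",
                f"interface_band_{m}")
    for kind in CLUSTER_REGIONS:
        for a, b in cellmod.UNORDERED_PAIRS:
            add(f"pairprop.{a}_vs_{b}.{kind}", "proportion_proximity", a, kind,
                f"proportional_count_vs_{b}")
    for a, b in cellmod.UNORDERED_PAIRS:
        add(f"csiprox.pairprop.{a}_vs_{b}", "proportion_proximity", a, "CSI",
            f"interface_proportional_count_vs_{b}")
    for a, b in cellmod.ORDERED_PAIRS:
        add(f"csiprox.{a}.near.{b}.count", "proportion_proximity", a, "CSI",
            f"interface_proximity_count_near_{b}")
    for m in ("count", "density", "proportion"):
        add(f"csiband.all.{m}", "proportion_proximity", "all", "CSI",
            f"interface_band_{m}")
    for cls in CELL_CLASSES:
        add(f"contrast.{cls}.log_density_CSI_vs_CT+CAS", "proportion_proximity",
            cls, "CSI", "log_density_vs_CT+CAS")

    # --- spatial clusters (180) ---------------------------------------
    for cls in CELL_CLASSES:
        for kind in CLUSTER_REGIONS:
            for m in CLUSTER_METRICS:
                add(f"cluster.{cls}.{kind}.{m}", "cluster", cls, kind, m)

    manifest = HifManifest(entries)
    counts = manifest.category_counts()
    for cat, expected in CATEGORY_SIZES.items():
        if counts.get(cat, 0) != expected:
            raise ManifestError(
                f"category {cat!r} has {counts.get(cat, 0)} entries, expected {expected}")
    if len(entries) != TOTAL_FEATURES:
        raise ManifestError(f"manifest has {len(entries)} entries, expected {TOTAL_FEATURES}")
    tissue_n = sum(counts[c] for c in ("area_multiplicity", "morphology", "architecture"))
    if tissue_n != TISSUE_FEATURES_TOTAL:
        raise ManifestError(f"tissue-derived total {tissue_n} != {TISSUE_FEATURES_TOTAL}")
    if len(set(manifest.feature_ids)) != TOTAL_FEATURES:
        raise ManifestError("duplicate feature ids in manifest")
    return manifest


# ---------------------------------------------------------------------------
# extraction

def extract_slide(slide: SlideMap, manifest: HifManifest | None = None,
                  csi_halfwidth_um: float = 40.0,
                  proximity_radius_um: float = cellmod.DEFAULT_PROXIMITY_RADIUS_UM,
                  birch_threshold_um: float = cellmod.DEFAULT_BIRCH_THRESHOLD_UM,
                  birch_branching: int = cellmod.DEFAULT_BIRCH_BRANCHING) -> pd.Series:
    """One value (or NaN) per manifest entry, in manifest order."""
    manifest = manifest or enumerate_catalog()
    ctx = SlideRegions(slide, csi_halfwidth_um=csi_halfwidth_um)
    values: dict[str, float] = {}
    values.update(tissmod.area_multiplicity_features(slide, ctx))
    values.update(tissmod.morphology_features(slide, ctx))
    values.update(tissmod.architecture_features(slide, ctx))
    values.update(cellmod.count_density_features(slide, ctx))
    values.update(cellmod.proportion_proximity_features(slide, ctx,
                                                        radius=proximity_radius_um))
    values.update(cellmod.cluster_features(slide, ctx, threshold=birch_threshold_um,
                                           branching=birch_branching))
    row = pd.Series([values.get(fid, np.nan) for fid in manifest.feature_ids],
                    index=manifest.feature_ids, name=slide.slide_id, dtype=float)
    return row


def extract_cohort(slides: list[SlideMap],
                   manifest: HifManifest | None = None, **kwargs) -> pd.DataFrame:
    """Slide-level feature matrix (rows keyed by slide_id, manifest order)."""
    manifest = manifest or enumerate_catalog()
    rows = [extract_slide(s, manifest, **kwargs) for s in slides]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient aggregation and normalization

def aggregate_patients(slide_matrix: pd.DataFrame,
                       metadata: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: the slide with the largest CT+CAS area.

    ``metadata`` maps slide_id → patient_id. Ties are broken by
    lexicographically smaller slide_id; patients with no slides are absent.
    """
    meta = metadata.set_index("slide_id")["patient_id"]
    rows = {}
    for patient, group in meta.groupby(meta):
        slide_ids = sorted(sid for sid in group.index if sid in slide_matrix.index)
        if not slide_ids:
            continue
        areas = slide_matrix.loc[slide_ids, TUMOR_AREA_FEATURE]
        best = areas.index[np.argmax(areas.to_numpy())]  # first max = smaller id
        rows[patient] = slide_matrix.loc[best]
    out = pd.DataFrame(rows).T
    out.index.name = "patient_id"
    return out.sort_index()


@dataclass
class HifMatrix:
    """A patients × features matrix with its normalization state."""

    values: pd.DataFrame
    z_scored: bool = False
    means: pd.Series | None = None
    sds: pd.Series | None = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


def zscore(matrix: HifMatrix | pd.DataFrame) -> HifMatrix:
    """Column-wise (x − mean)/SD over non-missing entries (population SD).

    Constant columns become 0; missing entries are imputed as 0 (the
    column mean) after scaling. Z-scoring an already z-scored matrix is
    the identity.
    """
    if isinstance(matrix, HifMatrix):
        if matrix.z_scored:
            return matrix
        df = matrix.values
    else:
        df = matrix
    if len(df) < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    vals = df.to_numpy(float)
    means = np.nanmean(vals, axis=0)
    sds = np.nanstd(vals, axis=0, ddof=0)
    means = np.where(np.isfinite(means), means, 0.0)
    with np.errstate(invalid="ignore"):
        z = (vals - means) / np.where(sds > 0, sds, 1.0)
    z[:, ~(sds > 0)] = 0.0
    n_missing = int(np.isnan(z).sum())
    if n_missing:
        logger.info("z-score: imputing %d missing entries (%.2f%%) with 0",
                    n_missing, 100.0 * n_missing / z.size)
    z = np.nan_to_num(z, nan=0.0)
    out = pd.DataFrame(z, index=df.index, columns=df.columns)
    return HifMatrix(values=out, z_scored=True,
                     means=pd.Series(means, index=df.columns),
                     sds=pd.Series(sds, index=df.columns))


# ---------------------------------------------------------------------------
# feature clustering

@dataclass
class HifClusterAssignment:
    """feature_id → cluster id from complete-linkage clustering at
    distance 1 − |Spearman ρ| with a dendrogram cutoff (default 0.95)."""

    assignment: pd.Series
    cutoff: float = 0.95

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.nunique())

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])

    def groups_array(self, feature_ids: list[str]) -> np.ndarray:
        return self.assignment.loc[feature_ids].to_numpy(int)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: int(v) for k, v in self.assignment.items()}, fh, indent=0)


def cluster_hifs(matrix: HifMatrix | pd.DataFrame,
                 cutoff: float = 0.95) -> HifClusterAssignment:
    """Agglomerative complete-linkage clustering of features.

    Distance is 1 − |Spearman ρ| (mid-rank ties); pairs with undefined
    correlation (constant columns) get distance 1. Cutting the complete-
    linkage dendrogram at ``cutoff`` guarantees every within-cluster pair
    has |ρ| ≥ 1 − cutoff.
    """
    df = matrix.values if isinstance(matrix, HifMatrix) else matrix
    if len(df) < 3:
        raise ValueError("feature clustering requires at least 3 rows")
    rho = df.corr(method="spearman").to_numpy()
    dist = 1.0 - np.abs(rho)
    dist[~np.isfinite(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="complete")
    flat = fcluster(z, t=cutoff, criterion="distance")
    return HifClusterAssignment(
        assignment=pd.Series(flat, index=df.columns, name="cluster"), cutoff=cutoff)
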