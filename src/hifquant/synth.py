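"""Synthetic slide maps and cohorts with known ground truth.

Tissue geometry is a thresholded smoothed Gaussian random field: the top
quantiles of the field become cancer tissue (CT) with necrosis nested in
the field's peaks (i.e., inside CT cores), the band below CT becomes
cancer-associated stroma (CAS), and the rest is background. This yields
blob-like regions with a genuine CT|CAS interface and necrotic holes.

Cells are drawn per (class × region) either as a homogeneous Poisson
process at a stated intensity (cells/mm²) or as a Thomas cluster process
(Poisson parents, Gaussian-displaced offspring, truncated to the region).
Cohorts add multi-site structure (per-site intensity perturbations),
one or two slides per patient, and a continuous phenotype generated from
a known group-sparse linear dependence on the extracted, z-scored HIFs —
so a defect anywhere in the extraction pipeline breaks phenotype
recovery, by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import spearmanr

from . import catalog
from .slides import CELL_CLASSES, SlideMap, TISSUE_CAS, TISSUE_CT, TISSUE_NECROSIS

logger = logging.getLogger(__name__)

#: Regions that receive cells in the generator (background stays empty).
CELL_REGIONS = ("CT", "CAS", "NECROSIS")

#: Default per-class cell intensities λ (cells per mm²) by region,
#: order-of-magnitude realistic for H&E tumor microenvironments:
#: cancer cells dominate CT, fibroblasts dominate stroma, lymphocytes and
#: plasma cells are enriched in stroma, necrosis is cell-poor.
DEFAULT_INTENSITIES: dict[tuple[str, str], float] = {
    ("lymphocyte", "CT"): 400.0, ("lymphocyte", "CAS"): 700.0, ("lymphocyte", "NECROSIS"): 30.0,
    ("plasma", "CT"): 80.0, ("plasma", "CAS"): 200.0, ("plasma", "NECROSIS"): 10.0,
    ("fibroblast", "CT"): 150.0, ("fibroblast", "CAS"): 900.0, ("fibroblast", "NECROSIS"): 20.0,
    ("macrophage", "CT"): 150.0, ("macrophage", "CAS"): 250.0, ("macrophage", "NECROSIS"): 60.0,
    ("cancer", "CT"): 2500.0, ("cancer", "CAS"): 60.0, ("cancer", "NECROSIS"): 40.0,
}


@dataclass
class ThomasParams:
    """Thomas cluster process: Poisson(κ·area) parents uniform in the
    region, Poisson(μ_off) offspring per parent displaced by an isotropic
    Gaussian of scale σ_off μm; offspring outside the region are dropped."""

    kappa_per_mm2: float
    mu_offspring: float
    sigma_um: float


@dataclass
class SceneParams:
    shape: tuple[int, int] = (160, 160)
    mpp: float = 4.0
    geometry_seed: int = 0
    point_seed: int = 0
    smooth_sigma_px: float = 10.0
    q_cas: float = 0.55       # field quantile where CAS starts
    q_ct: float = 0.75        # field quantile where CT starts
    q_necrosis: float = 0.97  # field quantile where necrosis starts (inside CT)
    intensities: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    cluster_process: dict[str, ThomasParams] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.q_cas < self.q_ct < self.q_necrosis <= 1:
            raise ValueError("threshold quantiles must satisfy 0 < q_cas < q_ct "
                             f"< q_necrosis <= 1, got {self.q_cas}, {self.q_ct}, "
                             f"{self.q_necrosis}")
        if any(lam < 0 for lam in self.intensities.values()):
            raise ValueError("cell intensities must be >= 0")
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")


def generate_scene(params: SceneParams, slide_id: str = "S0",
                   patient_id: str = "P0", site_id: str = "site0",
                   cancer_type: str = "SYN") -> SlideMap:
    """Generate one synthetic slide, fully determined by the two seeds."""
    params.validate()
    h, w = params.shape
    rng_geo = np.random.default_rng(params.geometry_seed)
    fld = gaussian_filter(rng_geo.normal(size=(h, w)), params.smooth_sigma_px)
    t_cas, t_ct, t_nec = np.quantile(fld, [params.q_cas, params.q_ct,
                                           params.q_necrosis])
    raster = np.zeros((h, w), np.uint8)
    raster[fld >= t_cas] = TISSUE_CAS
    raster[fld >= t_ct] = TISSUE_CT
    raster[fld >= t_nec] = TISSUE_NECROSIS
    rng_pts = np.random.default_rng(params.point_seed)
    region_masks = {"CT": raster == TISSUE_CT, "CAS": raster == TISSUE_CAS,
                    "NECROSIS": raster == TISSUE_NECROSIS}
    frames = []
    for cls in CELL_CLASSES:
        for region in CELL_REGIONS:
            lam = params.intensities.get((cls, region), 0.0)
            if lam == 0:
                continue
            mask = region_masks[region]
            area_mm2 = mask.sum() * (params.mpp / 1000.0) ** 2
            if area_mm2 == 0:
                logger.warning("scene %s: region %s empty but λ(%s)=%s > 0",
                               slide_id, region, cls, lam)
                continue
            tp = params.cluster_process.get(cls)
            if tp is None:
                n = rng_pts.poisson(lam * area_mm2)
                xy = _uniform_in_mask(rng_pts, mask, params.mpp, n)
            else:
                xy = _thomas_in_mask(rng_pts, mask, params.mpp, tp, area_mm2)
            if len(xy):
                frames.append(pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1],
                                            "cell_class": cls}))
    if frames:
        cells = pd.concat(frames, ignore_index=True)
    else:
        cells = pd.DataFrame({"x_um": pd.Series(dtype=float),
                              "y_um": pd.Series(dtype=float),
                              "cell_class": pd.Series(dtype=str)})
    return SlideMap(slide_id=slide_id, patient_id=patient_id, site_id=site_id,
                    cancer_type=cancer_type, tissue_raster=raster,
                    tissue_mpp=params.mpp, cells=cells)


def _uniform_in_mask(rng, mask: np.ndarray, mpp: float, n: int) -> np.ndarray:
    """n points uniform over the union of mask pixels, in μm."""
    if n == 0:
        return np.empty((0, 2))
    rr, cc = np.nonzero(mask)
    pick = rng.integers(0, len(rr), n)
    u = rng.random((n, 2))
    x = (cc[pick] + u[:, 0]) * mpp
    y = (rr[pick] + u[:, 1]) * mpp
    return np.column_stack([x, y])


def _thomas_in_mask(rng, mask: np.ndarray, mpp: float, tp: ThomasParams,
                    area_mm2: float) -> np.ndarray:
    n_parents = rng.poisson(tp.kappa_per_mm2 * area_mm2)
    parents = _uniform_in_mask(rng, mask, mpp, n_parents)
    if len(parents) == 0:
        return np.empty((0, 2))
    counts = rng.poisson(tp.mu_offspring, len(parents))
    centers = np.repeat(parents, counts, axis=0)
    if len(centers) == 0:
        return np.empty((0, 2))
    xy = centers + rng.normal(scale=tp.sigma_um, size=centers.shape)
    h, w = mask.shape
    c = np.floor(xy[:, 0] / mpp).astype(int)
    r = np.floor(xy[:, 1] / mpp).astype(int)
    ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
    ok[ok] &= mask[r[ok], c[ok]]
    return xy[ok]


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortSpec:
    n_patients: int = 300
    n_sites: int = 10
    base_scene: SceneParams = field(default_factory=SceneParams)
    two_slide_prob: float = 0.30
    site_sigma: float = 0.15      # lognormal σ of per-site intensity multipliers
    slide_sigma: float = 0.10     # lognormal σ of per-slide intensity jitter
    n_active_clusters: int = 2
    signal_sd: float = 2.5        # SD of xᵀβ across patients
    noise_sd: float = 1.0
    intercept: float = 0.0
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 4:
            raise ValueError("need n_sites >= 4 so a 20–30% site hold-out exists")
        if self.n_sites > self.n_patients:
            raise ValueError("more sites than patients is infeasible")


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort: the generating coefficients,
    the active feature clusters, and the extracted z-scored HIF matrix
    the phenotype was computed from."""

    beta: pd.Series
    active_clusters: list[int]
    cluster_assignment: pd.Series
    hif_z: pd.DataFrame
    linear_predictor: pd.Series
    signal_sd: float
    noise_sd: float


def simulate_cohort_maps(spec: CohortSpec) -> tuple[list[SlideMap], pd.DataFrame]:
    """Generate the slide maps and the sample metadata table for a cohort."""
    spec.validate()
    rng = np.random.default_rng(spec.master_seed)
    site_ids = [f"site{j:02d}" for j in range(spec.n_sites)]
    site_mult = {
        s: {key: float(m) for key, m in zip(
            spec.base_scene.intensities,
            np.exp(rng.normal(0.0, spec.site_sigma,
                              len(spec.base_scene.intensities))))}
        for s in site_ids
    }
    slides: list[SlideMap] = []
    meta_rows = []
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        site = site_ids[i % spec.n_sites]
        n_slides = 2 if rng.random() < spec.two_slide_prob else 1
        for k in range(n_slides):
            sid = f"{pid}-s{k}"
            jitter = np.exp(rng.normal(0.0, spec.slide_sigma,
                                       len(spec.base_scene.intensities)))
            intens = {key: lam * site_mult[site][key] * float(j)
                      for (key, lam), j in zip(
                          spec.base_scene.intensities.items(), jitter)}
            params = replace(
                spec.base_scene,
                geometry_seed=int(rng.integers(0, 2 ** 31 - 1)),
                point_seed=int(rng.integers(0, 2 ** 31 - 1)),
                intensities=intens)
            slides.append(generate_scene(params, slide_id=sid, patient_id=pid,
                                         site_id=site))
            meta_rows.append({"slide_id": sid, "patient_id": pid,
                              "site_id": site, "cancer_type": "SYN",
                              "tissue_mpp": spec.base_scene.mpp})
    return slides, pd.DataFrame(meta_rows)


def attach_phenotype(hif_z: pd.DataFrame, clusters, spec: CohortSpec,
                     seed: int) -> tuple[pd.Series, pd.Series, list[int]]:
    """Draw a continuous phenotype y = xᵀβ + intercept + ε from a known
    group-sparse β supported on ``n_active_clusters`` feature clusters.

    Within an active cluster, coefficient signs are aligned with each
    member's Spearman correlation to the cluster's first member so that
    correlated features reinforce rather than cancel; β is scaled so the
    linear predictor has SD ``signal_sd`` across patients.
    """
    rng = np.random.default_rng(seed)
    assignment = clusters.assignment if hasattr(clusters, "assignment") else clusters
    sizes = assignment.value_counts()
    # informative clusters: enough members to exercise group sparsity and
    # non-degenerate columns
    col_sd = hif_z.std(ddof=0)
    candidates = []
    for cid, size in sizes.items():
        members = list(assignment.index[assignment == cid])
        if 4 <= size <= 60 and (col_sd[members] > 1e-8).sum() >= 3:
            candidates.append(cid)
    if len(candidates) < spec.n_active_clusters:
        raise ValueError("not enough informative feature clusters for the "
                         "requested active set")
    active = sorted(rng.choice(candidates, spec.n_active_clusters,
                               replace=False).tolist())
    beta = pd.Series(0.0, index=hif_z.columns)
    for cid in active:
        members = [m for m in assignment.index[assignment == cid]
                   if col_sd[m] > 1e-8]
        rep = hif_z[members[0]]
        for m in members:
            r = spearmanr(hif_z[m], rep).statistic
            sign = 1.0 if (not np.isfinite(r) or r >= 0) else -1.0
            beta[m] = sign / np.sqrt(len(members))
    lin = hif_z.to_numpy() @ beta.to_numpy()
    sd = lin.std()
    if sd > 0:
        beta *= spec.signal_sd / sd
        lin = lin * (spec.signal_sd / sd)
    y = lin + spec.intercept + rng.normal(0.0, spec.noise_sd, len(hif_z))
    return (pd.Series(y, index=hif_z.index, name="phenotype"), beta, active)


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[SlideMap], pd.DataFrame, CohortTruth]:
    """Full cohort: slide maps, per-patient outcome table, truth record.

    The phenotype is computed from the *extracted* z-scored HIF matrix
    (not a stored formula), so downstream recovery tests exercise the
    whole extraction path.
    """
    slides, metadata = simulate_cohort_maps(spec)
    slide_matrix = catalog.extract_cohort(slides)
    patient_matrix = catalog.aggregate_patients(slide_matrix, metadata)
    hif_z = catalog.zscore(patient_matrix).values
    clusters = catalog.cluster_hifs(hif_z)
    y, beta, active = attach_phenotype(hif_z, clusters, spec,
                                       seed=spec.master_seed + 1)
    outcomes = pd.DataFrame({"patient_id": y.index, "phenotype": y.to_numpy()})
    lin = pd.Series(hif_z.to_numpy() @ beta.to_numpy(), index=hif_z.index)
    truth = CohortTruth(beta=beta, active_clusters=active,
                        cluster_assignment=clusters.assignment, hif_z=hif_z,
                        linear_predictor=lin, signal_sd=spec.signal_sd,
                        noise_sd=spec.noise_sd)
    return slides, outcomes, truth
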