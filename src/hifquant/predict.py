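"""Molecular-phenotype prediction: GMM binarization of continuous
outcomes, tissue-source-site hold-out splits, a logistic sparse group
lasso (SGL) tuned by nested cross-validation with ensembling, bootstrap
evaluation, and permutation inference on ensemble coefficients.

The SGL objective for z-scored features X (n × p), binary labels y and a
partition of features into groups g with sizes p_g is

    (1/n) Σ log(1 + exp(−ỹ_i (x_iᵀβ + β₀)))
        + λ [ (1−α) Σ_g √p_g ‖β_g‖₂ + α ‖β‖₁ ],   ỹ = ±1,

minimized by proximal gradient descent with backtracking line search; the
proximal operator is an elementwise soft-threshold followed by groupwise
shrinkage, which induces sparsity both across and within groups. The
intercept is unpenalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold

from .stats import bh_correct, empirical_browns

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.95
LAMBDA_GRID_POINTS = 30
LAMBDA_GRID_DECADES = 3.0
CONVERGENCE_TOL = 1e-6
MAX_ITER = 5000


# ---------------------------------------------------------------------------
# GMM binarization

@dataclass
class BinarizationModel:
    """Two-component 1-D Gaussian mixture (unequal variances) with the
    high/low threshold at the weighted-density intersection between the
    component means."""

    weights: tuple[float, float]
    means: tuple[float, float]         # μ1 < μ2
    variances: tuple[float, float]
    threshold: float

    def __post_init__(self) -> None:
        assert self.means[0] <= self.threshold <= self.means[1]


def gmm_binarize(values: np.ndarray, seed: int = 0
                 ) -> tuple[BinarizationModel, np.ndarray]:
    """Fit a 2-component unequal-variance GMM and binarize at the density
    intersection between the means (high: value ≥ threshold)."""
    x = np.asarray(values, float)
    if len(x) < 20:
        raise ValueError(f"need at least 20 values, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: no mixture to fit")
    var_floor = 1e-6 * float(np.var(x))
    gm = GaussianMixture(n_components=2, covariance_type="full", n_init=10,
                         max_iter=500, reg_covar=max(var_floor, 1e-12),
                         random_state=seed)
    gm.fit(x[:, None])
    if not gm.converged_:
        raise RuntimeError("GMM EM failed to converge within 500 iterations")
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_[order]
    mu = gm.means_.ravel()[order]
    var = np.maximum(gm.covariances_.ravel()[order], var_floor)

    def logdiff(t: float) -> float:
        return (np.log(w[0]) + norm.logpdf(t, mu[0], np.sqrt(var[0]))
                - np.log(w[1]) - norm.logpdf(t, mu[1], np.sqrt(var[1])))

    lo, hi = float(mu[0]), float(mu[1])
    if hi - lo < 1e-12:
        thr = lo
    elif logdiff(lo) * logdiff(hi) < 0:
        thr = float(brentq(logdiff, lo, hi))
    else:
        # no sign change between the means (heavily overlapping fit):
        # take the point of closest weighted densities on a grid
        grid = np.linspace(lo, hi, 512)
        thr = float(grid[np.argmin(np.abs([logdiff(t) for t in grid]))])
    model = BinarizationModel(weights=(float(w[0]), float(w[1])),
                              means=(float(mu[0]), float(mu[1])),
                              variances=(float(var[0]), float(var[1])),
                              threshold=thr)
    return model, (x >= thr).astype(int)


# ---------------------------------------------------------------------------
# site-held-out split

def site_holdout_split(metadata: pd.DataFrame,
                       frac_range: tuple[float, float] = (0.20, 0.30),
                       seed: int = 0) -> tuple[list[str], list[str]]:
    """Split patients into train and hold-out so that hold-out sites are
    disjoint from training sites and hold roughly 20–30% of patients.

    Sites are shuffled by seed and added greedily; a site that would
    overshoot the range is skipped. If no subset lands inside the range
    the closest achievable fraction is used with a warning.
    """
    meta = metadata.drop_duplicates("patient_id")
    sites = sorted(meta["site_id"].unique())
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for a site-held-out split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(sites))
    n_total = len(meta)
    by_site = meta.groupby("site_id")["patient_id"].apply(list)
    chosen: list[str] = []
    n_held = 0
    best: tuple[float, list[str]] | None = None
    for site in order:
        cand = n_held + len(by_site[site])
        frac = cand / n_total
        if frac <= frac_range[1] + 1e-12:
            chosen.append(site)
            n_held = cand
            if frac >= frac_range[0]:
                break
        gap = min(abs(cand / n_total - f) for f in frac_range)
        if best is None or gap < best[0]:
            best = (gap, chosen + [site])
    frac = n_held / n_total
    if not frac_range[0] <= frac <= frac_range[1]:
        if best is not None and chosen == []:
            chosen = best[1]
        logger.warning(
            "no site subset lands in hold-out range %s; using fraction %.3f",
            frac_range, sum(len(by_site[s]) for s in chosen) / n_total)
    holdout_sites = set(chosen)
    holdout = [p for s in sorted(holdout_sites) for p in by_site[s]]
    train = [p for s in sites if s not in holdout_sites for p in by_site[s]]
    assert not (holdout_sites & (set(sites) - holdout_sites))
    return train, holdout


# ---------------------------------------------------------------------------
# sparse group lasso

@dataclass
class SglModel:
    beta: np.ndarray
    intercept: float
    lam: float
    alpha: float
    groups: np.ndarray
    n_iter: int = 0
    objective: float = float("nan")

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision(X))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _logloss(z: np.ndarray, y: np.ndarray) -> float:
    # mean logistic deviance; stable log(1+exp(-yz))
    yz = (2.0 * y - 1.0) * z
    return float(np.mean(np.logaddexp(0.0, -yz)))


def _penalty(beta: np.ndarray, lam: float, alpha: float,
             group_slices: list[np.ndarray], group_w: np.ndarray) -> float:
    gn = np.array([np.linalg.norm(beta[idx]) for idx in group_slices])
    return lam * ((1.0 - alpha) * float(group_w @ gn)
                  + alpha * float(np.abs(beta).sum()))


def _prox(b: np.ndarray, t: float, lam: float, alpha: float,
          group_ids: np.ndarray, group_w_per_feat: np.ndarray) -> np.ndarray:
    """Proximal operator of the SGL penalty: elementwise soft-threshold,
    then groupwise shrinkage."""
    s = np.sign(b) * np.maximum(np.abs(b) - t * lam * alpha, 0.0)
    gn = np.sqrt(np.bincount(group_ids, weights=s * s))
    shrink = np.zeros_like(gn)
    nz = gn > 0
    # group weights √p_g are constant within a group
    gw = np.zeros_like(gn)
    np.maximum.at(gw, group_ids, group_w_per_feat)
    shrink[nz] = np.maximum(0.0, 1.0 - t * lam * (1.0 - alpha) * gw[nz] / gn[nz])
    return s * shrink[group_ids]


def _prepare_groups(groups: np.ndarray) -> tuple[np.ndarray, list[np.ndarray],
                                                 np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    uniq, ids = np.unique(groups, return_inverse=True)
    slices = [np.flatnonzero(ids == k) for k in range(len(uniq))]
    sizes = np.array([len(s) for s in slices], float)
    group_w = np.sqrt(sizes)
    return ids, slices, group_w, group_w[ids]


def fit_sgl_logistic(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                     lam: float, alpha: float = DEFAULT_ALPHA,
                     tol: float = CONVERGENCE_TOL, max_iter: int = MAX_ITER,
                     beta0: np.ndarray | None = None,
                     intercept0: float | None = None) -> SglModel:
    """Minimize the SGL-penalized logistic objective by proximal gradient
    descent with backtracking; converged when the largest coefficient
    change in a step is below ``tol``. The objective is checked to be
    monotonically non-increasing."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if np.isnan(X).any():
        raise ValueError("X must not contain missing values")
    n, p = X.shape
    ids, slices, group_w, gw_feat = _prepare_groups(groups)
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    b0 = float(np.log(ybar / (1 - ybar))) if intercept0 is None else float(intercept0)

    def objective(b, b0_):
        return _logloss(X @ b + b0_, y) + _penalty(b, lam, alpha, slices, group_w)

    # step size from a cheap Lipschitz bound, refined by backtracking
    lip = (np.linalg.norm(X, ord="fro") ** 2) / (4.0 * n) + 0.25
    t = 1.0 / lip
    obj = objective(beta, b0)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = X @ beta + b0
        r = _sigmoid(z) - y
        grad = X.T @ r / n
        grad0 = float(r.mean())
        loss_old = _logloss(z, y)
        while True:
            beta_new = _prox(beta - t * grad, t, lam, alpha, ids, gw_feat)
            b0_new = b0 - t * grad0
            d = beta_new - beta
            d0 = b0_new - b0
            loss_new = _logloss(X @ beta_new + b0_new, y)
            quad = (loss_old + float(grad @ d) + grad0 * d0
                    + (float(d @ d) + d0 * d0) / (2.0 * t))
            if loss_new <= quad + 1e-12:
                break
            t *= 0.5
        step = max(float(np.max(np.abs(d))) if p else 0.0, abs(d0))
        beta, b0 = beta_new, b0_new
        new_obj = objective(beta, b0)
        if new_obj > obj + 1e-8:
            raise RuntimeError("SGL objective increased — solver defect")
        obj = new_obj
        if step < tol:
            break
        t = min(t * 2.0, 1.0 / lip * 64.0)  # allow the step to grow back
    return SglModel(beta=beta, intercept=b0, lam=lam, alpha=alpha,
                    groups=np.asarray(groups), n_iter=n_iter, objective=obj)


def lambda_max(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
               alpha: float = DEFAULT_ALPHA) -> float:
    """Smallest λ at which β = 0 is optimal (from the group-threshold
    condition at the null model with fitted intercept)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    grad = X.T @ (ybar - y) / n
    ids, slices, group_w, _ = _prepare_groups(groups)

    def group_active(lam: float, idx: np.ndarray, w: float) -> bool:
        s = np.sign(grad[idx]) * np.maximum(np.abs(grad[idx]) - lam * alpha, 0.0)
        return np.linalg.norm(s) > lam * (1.0 - alpha) * w

    lam_hi = float(np.abs(grad).max()) / max(alpha, 1e-12) + 1e-12
    out = 0.0
    for idx, w in zip(slices, group_w):
        lo, hi = 0.0, lam_hi
        for _ in range(60):
            mid = (lo + hi) / 2
            if group_active(mid, idx, w):
                lo = mid
            else:
                hi = mid
        out = max(out, hi)
    return out


def lambda_grid(lam_max: float, n_points: int = LAMBDA_GRID_POINTS,
                decades: float = LAMBDA_GRID_DECADES) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_points)


# ---------------------------------------------------------------------------
# nested cross-validation and ensembling

@dataclass
class SglEnsemble:
    """Three outer-fold SGL fits with averaged probabilities and betas."""

    models: list[SglModel]
    feature_ids: list[str] = field(default_factory=list)

    @property
    def beta(self) -> np.ndarray:
        return np.mean([m.beta for m in self.models], axis=0)

    @property
    def intercept(self) -> float:
        return float(np.mean([m.intercept for m in self.models]))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.models], axis=0)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the Mann–Whitney identity (mid-ranks for ties)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision–recall curve by the step-wise integral
    (average precision)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    # evaluate at distinct thresholds only (ties grouped)
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    drecall = np.diff(np.r_[0.0, recall])
    return float((precision * drecall).sum())


def _stratified_folds(y: np.ndarray, n_splits: int, seed: int,
                      max_attempts: int = 10):
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
               for tr, te in folds):
            return folds
    raise RuntimeError("could not stratify folds with both classes present")


def nested_cv_ensemble(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                       seed: int = 0, alpha: float = DEFAULT_ALPHA,
                       n_outer: int = 3, n_inner: int = 5,
                       n_lambda: int = LAMBDA_GRID_POINTS,
                       tol: float = 1e-4,
                       feature_ids: list[str] | None = None) -> SglEnsemble:
    """Nested CV: stratified outer folds; per outer-training set, inner CV
    selects λ over a log grid (3 decades below λ_max) by mean inner-fold
    AUROC; each tuned model is refit on its outer-training set and the
    three are ensembled by averaging probabilities and betas."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if min((y == 0).sum(), (y == 1).sum()) < max(n_outer, 3):
        raise ValueError("too few samples per class for nested CV")
    outer = _stratified_folds(y, n_outer, seed)
    models = []
    for fold_i, (tr, _te) in enumerate(outer):
        Xtr, ytr = X[tr], y[tr]
        lmax = lambda_max(Xtr, ytr, groups, alpha)
        grid = lambda_grid(lmax, n_lambda)
        inner = _stratified_folds(ytr, n_inner,
                                  (seed * 1009 + fold_i + 1) % (2 ** 31 - 1))
        scores = np.zeros(len(grid))
        counts = np.zeros(len(grid))
        for itr, ite in inner:
            beta_ws, b0_ws = None, None
            for li, lam in enumerate(grid):
                m = fit_sgl_logistic(Xtr[itr], ytr[itr], groups, lam, alpha,
                                     tol=tol, beta0=beta_ws, intercept0=b0_ws)
                beta_ws, b0_ws = m.beta, m.intercept
                s = m.decision(Xtr[ite])
                if len(np.unique(ytr[ite])) == 2:
                    scores[li] += auroc(s, ytr[ite])
                    counts[li] += 1
        mean_auc = scores / np.maximum(counts, 1)
        best = int(np.argmax(mean_auc))  # ties → first = largest λ (sparsest)
        # refit on the full outer-training set, warm-started down the path
        beta_ws, b0_ws = None, None
        final = None
        for lam in grid[:best + 1]:
            final = fit_sgl_logistic(Xtr, ytr, groups, lam, alpha, tol=tol,
                                     beta0=beta_ws, intercept0=b0_ws)
            beta_ws, b0_ws = final.beta, final.intercept
        models.append(final)
    return SglEnsemble(models=models, feature_ids=feature_ids or [])


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvaluationReport:
    auroc: float
    auprc: float
    auroc_ci: tuple[float, float]
    auprc_ci: tuple[float, float]
    p_auroc: float
    p_auprc: float
    n_boot: int


def evaluate(probs: np.ndarray, labels: np.ndarray, n_boot: int = 1000,
             seed: int = 0) -> EvaluationReport:
    """AUROC/AUPRC with 1000-resample paired-bootstrap percentile CIs and
    p = fraction of bootstrap metrics below 0.5 (chance). Resamples
    missing a class are redrawn."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    a_roc = auroc(probs, labels)
    a_prc = auprc(probs, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    boot_roc = np.empty(n_boot)
    boot_prc = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            if len(np.unique(labels[idx])) == 2:
                break
        boot_roc[b] = auroc(probs[idx], labels[idx])
        boot_prc[b] = auprc(probs[idx], labels[idx])
    return EvaluationReport(
        auroc=a_roc, auprc=a_prc,
        auroc_ci=(float(np.percentile(boot_roc, 2.5)),
                  float(np.percentile(boot_roc, 97.5))),
        auprc_ci=(float(np.percentile(boot_prc, 2.5)),
                  float(np.percentile(boot_prc, 97.5))),
        p_auroc=float((boot_roc < 0.5).mean()),
        p_auprc=float((boot_prc < 0.5).mean()),
        n_boot=n_boot)


def permutation_beta_inference(X: np.ndarray, y: np.ndarray,
                               groups: np.ndarray, ensemble: SglEnsemble,
                               B: int = 1000, seed: int = 0,
                               clusters=None, matrix: pd.DataFrame | None = None,
                               **cv_kwargs) -> dict:
    """Permutation p-values for ensemble betas.

    Training labels are permuted B times and the full nested-CV ensemble
    refit; per-feature p = (1 + #{|β_null| ≥ |β_obs|})/(B + 1) (two-sided
    via absolute values, add-one smoothed). If a cluster assignment and
    the feature matrix are given, cluster-level p-values are combined with
    the Empirical Brown's method and BH-corrected."""
    if B < 50:
        warnings.warn(f"B={B} permutations gives an unstable p-value tail",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    obs = np.abs(ensemble.beta)
    exceed = np.zeros_like(obs)
    for b in range(B):
        yp = rng.permutation(y)
        perm_seed = int(rng.integers(0, 2 ** 31 - 1))
        ens = nested_cv_ensemble(X, yp, groups, seed=perm_seed, **cv_kwargs)
        exceed += np.abs(ens.beta) >= obs
    p_feat = (1.0 + exceed) / (B + 1.0)
    out = {"p_feature": p_feat, "B": B}
    if clusters is not None and matrix is not None:
        assignment = clusters.assignment if hasattr(clusters, "assignment") else clusters
        fid = list(matrix.columns)
        p_ser = pd.Series(p_feat, index=fid)
        rows = []
        for cid in sorted(assignment.unique()):
            members = [f for f in assignment.index[assignment == cid] if f in fid]
            if not members:
                continue
            if len(members) == 1:
                p_comb = float(p_ser[members[0]])
            else:
                p_comb = empirical_browns(matrix[members].to_numpy().T,
                                          p_ser[members].to_numpy()).p_combined
            rows.append({"cluster": cid, "p_combined": p_comb})
        cl = pd.DataFrame(rows).set_index("cluster")
        cl["q"] = bh_correct(cl["p_combined"].to_numpy())
        out["clusters"] = cl
    return out
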