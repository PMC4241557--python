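"""Hierarchical clustering and covariance PCA of the spontaneous phenotype.

The multivariate stages operate on the 8 spontaneous-activity parameters
only (ISI_avg, CV_ISI, AP threshold, amplitude, rise slope, decay slope,
half-width, AHP amplitude) so that a neuron's phenotype is defined without
any current injection.

Conventions (fixed for reproducibility):

* mean normalization — each column divided by the absolute value of its
  population mean — is applied before both the clustering and the PCA, which
  makes the mixed-unit columns commensurable (also ``none`` and ``zscore``
  are available);
* agglomeration: Ward's method on Euclidean dissimilarities;
* the automatic dendrogram cut sits in the largest gap between consecutive
  merge dissimilarities among the top min(n-1, 10) merges;
* PCA diagonalizes the divisor-n (population) covariance matrix of the
  normalized table; each component's largest-magnitude entry is made
  positive; perturbed/supplementary cohorts are projected with the training
  divisors and means and never alter the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .features import SPONTANEOUS_FEATURES

__all__ = [
    "SpontaneousMatrix",
    "ClusterClasses",
    "PCAModel",
    "normalize_features",
    "ahc_ward",
    "dendrogram_to_newick",
    "auto_cut",
    "pca_covariance",
    "project_supplementary",
    "stage_trajectory",
    "variability_ellipse",
    "sd_age_correlation",
]


@dataclass
class SpontaneousMatrix:
    """Normalized neurons x 8 matrix plus the normalization record."""

    data: pd.DataFrame              # normalized values, canonical column order
    divisors: pd.Series             # per-column divisor (|population mean|)
    ages: pd.Series | None = None   # age (days) per row
    stages: pd.Series | None = None

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def normalize_features(
    table: pd.DataFrame,
    mode: str = "mean",
    columns: tuple[str, ...] = SPONTANEOUS_FEATURES,
) -> SpontaneousMatrix:
    """Build the spontaneous-parameter matrix from a cohort feature table.

    ``mode='mean'`` divides each column by |population mean| (sign
    preserved, so the mostly-negative threshold column keeps its sign);
    ``'zscore'`` centers and scales by the SD; ``'none'`` passes raw values.
    Rows with any null among the 8 columns are rejected.
    """
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = table.loc[:, list(columns)].astype(float)
    if X.isna().any().any():
        bad = int(X.isna().any(axis=1).sum())
        raise ValueError(
            f"{bad} rows have nulls among the spontaneous parameters; "
            "the multivariate stages need complete rows"
        )
    if mode == "mean":
        div = X.mean(axis=0).abs()
        tol = 1e-9 * X.abs().max(axis=0)
        if (div <= tol).any():
            zero = list(div.index[div <= tol])
            raise ValueError(f"zero population mean in columns {zero}")
        Xn = X / div
    elif mode == "zscore":
        div = X.std(axis=0, ddof=1)
        if (div == 0).any():
            raise ValueError("zero-variance column under zscore normalization")
        Xn = (X - X.mean(axis=0)) / div
    elif mode == "none":
        div = pd.Series(1.0, index=X.columns)
        Xn = X
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    ages = table["age_days"] if "age_days" in table.columns else None
    stages = table["stage"] if "stage" in table.columns else None
    return SpontaneousMatrix(data=Xn, divisors=div, ages=ages, stages=stages)


# ---------------------------------------------------------------------------
# Agglomerative hierarchical clustering


def ahc_ward(m: SpontaneousMatrix | np.ndarray) -> np.ndarray:
    """Ward linkage matrix (scipy format) on Euclidean dissimilarities."""
    X = m.values if isinstance(m, SpontaneousMatrix) else np.asarray(m, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d matrix with >= 2 rows")
    return hierarchy.linkage(X, method="ward")


def dendrogram_to_newick(Z: np.ndarray, labels: list[str] | None = None) -> str:
    """Newick export with branch lengths derived from merge dissimilarities.

    Each node sits at its merge height; a child's branch length is the height
    difference to its parent (leaves sit at height 0).
    """
    n = Z.shape[0] + 1
    labels = labels or [f"n{i}" for i in range(n)]
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + Z.shape[0] - 1] + ";"


@dataclass
class ClusterClasses:
    labels: np.ndarray              # class id (1..k) per neuron
    centroids: pd.DataFrame         # class x 8 centroid table
    central_objects: dict[int, int]  # class id -> row index of central object
    mean_ages: dict[int, tuple[float, float]]  # class id -> (mean, SD) age
    cut_height: float


def auto_cut(
    Z: np.ndarray,
    m: SpontaneousMatrix,
    k: int | None = None,
    top: int = 10,
) -> ClusterClasses:
    """Cut the dendrogram and describe the resulting classes.

    With ``k=None`` the dissimilarity threshold is placed automatically in
    the largest gap between consecutive merge heights among the top
    min(n-1, ``top``) merges.  Per class: centroid (in normalized units),
    central object (member closest to the centroid; ties to the lowest row
    index) and mean +- SD age when ages are known.
    """
    n = Z.shape[0] + 1
    if n < 3:
        raise ValueError("need >= 3 leaves to cut")
    heights = Z[:, 2]
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        cut_h = float(heights[n - k - 1]) if k < n else 0.0
    else:
        w = min(n - 1, top)
        idx0 = (n - 1) - w
        gaps = np.diff(heights[idx0:])
        if gaps.size == 0 or np.allclose(gaps, 0.0):
            warnings.warn("merge heights indistinguishable; falling back to "
                          "2 classes")
            labels = hierarchy.cut_tree(Z, n_clusters=2).ravel() + 1
            cut_h = float(heights[-1])
        else:
            j = idx0 + int(np.argmax(gaps))  # largest gap: after merge j
            cut_h = float((heights[j] + heights[j + 1]) / 2.0)
            labels = hierarchy.fcluster(Z, t=cut_h, criterion="distance")

    X = m.values
    # renumber classes in order of first appearance for determinism
    order = list(dict.fromkeys(labels))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.asarray([remap[v] for v in labels])

    cents = {}
    centrals = {}
    ages = {}
    for cid in sorted(set(labels)):
        rows = np.flatnonzero(labels == cid)
        c = X[rows].mean(axis=0)
        cents[cid] = c
        d = np.linalg.norm(X[rows] - c, axis=1)
        centrals[cid] = int(rows[int(np.argmin(d))])
        if m.ages is not None:
            a = m.ages.to_numpy(dtype=float)[rows]
            ages[cid] = (float(a.mean()),
                         float(a.std(ddof=1)) if a.size > 1 else 0.0)
    centroids = pd.DataFrame.from_dict(cents, orient="index",
                                       columns=m.data.columns)
    return ClusterClasses(labels=labels, centroids=centroids,
                          central_objects=centrals, mean_ages=ages,
                          cut_height=cut_h)


# ---------------------------------------------------------------------------
# Covariance PCA


@dataclass
class PCAModel:
    means: np.ndarray          # per-column means of the normalized table
    components: np.ndarray     # rows = PC1, PC2, ... (orthonormal)
    eigenvalues: np.ndarray    # descending, divisor-n convention
    variance_fractions: np.ndarray
    scores: np.ndarray         # training factor loadings (F1, F2, ...)
    columns: list[str]
    divisors: pd.Series | None = None  # training normalization record


def pca_covariance(m: SpontaneousMatrix, divisor_n: bool = True) -> PCAModel:
    """PCA of the divisor-n covariance matrix of the normalized table.

    The divisor convention only scales the eigenvalues (component directions
    are unaffected); ``divisor_n=False`` switches to the sample (n-1)
    covariance.
    """
    X = m.values
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("PCA needs >= 3 rows and >= 2 columns")
    means = X.mean(axis=0)
    Xc = X - means
    denom = n if divisor_n else n - 1
    cov = Xc.T @ Xc / denom
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    comps = evecs[:, order].T
    # sign convention: largest-magnitude entry of each component positive
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    total = evals.sum()
    if total == 0:
        raise ValueError("zero-variance table")
    frac = evals / total
    if np.linalg.matrix_rank(cov) < 2:
        warnings.warn("matrix rank < 2; PC2 carries no variance")
    scores = Xc @ comps.T
    return PCAModel(means=means, components=comps, eigenvalues=evals,
                    variance_fractions=frac, scores=scores,
                    columns=list(m.data.columns), divisors=m.divisors)


def project_supplementary(
    model: PCAModel,
    observations: pd.DataFrame,
) -> np.ndarray:
    """Project raw-unit supplementary observations into the trained space.

    The rows are normalized with the *training* divisors, centered with the
    training means, and projected on the training components; the model is
    never refit.
    """
    missing = [c for c in model.columns if c not in observations.columns]
    if missing:
        raise ValueError(f"supplementary observations lack columns {missing}")
    X = observations.loc[:, model.columns].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("supplementary observations contain nulls")
    if model.divisors is not None:
        X = X / model.divisors.to_numpy(dtype=float)
    return (X - model.means) @ model.components.T


# ---------------------------------------------------------------------------
# Developmental trajectory and variability


def stage_trajectory(
    scores: np.ndarray,
    stages: pd.Series,
    ages: pd.Series,
) -> pd.DataFrame:
    """Per-stage mean/SD/SEM of the first two factor loadings.

    Output rows are ordered by mean age; singleton stages get null SDs with
    a warning.
    """
    df = pd.DataFrame({
        "stage": np.asarray(stages), "age": np.asarray(ages, dtype=float),
        "f1": scores[:, 0], "f2": scores[:, 1],
    })
    rows = []
    for stage, g in df.groupby("stage", sort=False):
        n = len(g)
        if n < 2:
            warnings.warn(f"stage {stage}: single observation, SD undefined")
        rows.append({
            "stage": stage,
            "mean_age": g["age"].mean(),
            "n": n,
            "mean_f1": g["f1"].mean(), "mean_f2": g["f2"].mean(),
            "sd_f1": g["f1"].std(ddof=1) if n > 1 else np.nan,
            "sd_f2": g["f2"].std(ddof=1) if n > 1 else np.nan,
        })
    out = pd.DataFrame(rows).sort_values("mean_age").reset_index(drop=True)
    out["sem_f1"] = out["sd_f1"] / np.sqrt(out["n"])
    out["sem_f2"] = out["sd_f2"] / np.sqrt(out["n"])
    return out


def variability_ellipse(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Phenotype-variability ellipse per stage: A = pi * SD(F1) * SD(F2)."""
    rows = []
    for r in trajectory.itertuples(index=False):
        if np.isnan(r.sd_f1) or np.isnan(r.sd_f2):
            warnings.warn(f"stage {r.stage}: missing SD, skipped")
            continue
        rows.append({"stage": r.stage, "mean_age": r.mean_age,
                     "a": r.sd_f1, "b": r.sd_f2,
                     "area": np.pi * r.sd_f1 * r.sd_f2})
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def sd_age_correlation(trajectory: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation between SD(F1) and stage mean age (signed r)."""
    t = trajectory.dropna(subset=["sd_f1"])
    if len(t) < 3:
        raise ValueError("need >= 3 stages with defined SD(F1)")
    x = t["mean_age"].to_numpy(dtype=float)
    y = t["sd_f1"].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=len(t))
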