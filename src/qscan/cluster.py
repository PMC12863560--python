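"""Standardized PCA and Gaussian-mixture clustering of subject profiles.

The phenotyping question — are there distinct groups of drug takers? —
is answered here by (1) projecting the standardized per-subject variables
onto principal components and (2) fitting Gaussian mixtures to the
component scores, selecting the number of clusters by BIC (lower is
better), then (3) applying explicit distinction criteria: cluster centers
separated along PC1, and convex hulls disjoint in the (PC1, PC2) plane
and in (PC1, PC2, PC3) space.

Small-sample regime
-------------------
These cohorts are tiny (a dozen subjects), which shapes two defaults.
The mixture uses a single pooled ("tied") covariance matrix shared by
all components: per-component covariances are unidentifiable at this n
and let EM collapse onto near-singleton components whose vanishing
variance produces arbitrarily low, meaningless BIC.  For the same reason
candidate solutions in which any component captures fewer than
``min_count`` subjects (default 3) are rejected as degenerate outlier
pockets rather than clusters.  EM is started from a Ward-linkage
hierarchical partition — the classic mclust recipe — plus seeded random
restarts, and clustering runs on all principal components by default,
which preserves the full standardized feature space (the likelihood is
rotation-invariant, so this equals clustering the z-scored variables).
Both choices are arguments, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .cohort import VariableTable
from .stats import welch_t

__all__ = [
    "PCAResult",
    "ClusterResult",
    "DistinctionVerdict",
    "run_pca",
    "gmm_cluster",
    "check_distinction",
    "convex_hulls_disjoint",
]


# ---------------------------------------------------------------------------
# PCA on the correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigendecomposition of the variable correlation matrix.

    ``loadings`` columns are unit-norm eigenvectors (signs oriented so the
    largest-magnitude loading in each column is positive, making results
    reproducible across LAPACK builds); ``scores = Z @ loadings`` with Z
    the z-scored data; ``variance_fraction`` sums to 1.
    """

    subjects: list[str]
    variables: list[str]
    loadings: np.ndarray           # variables x components, unit-norm columns
    scores: np.ndarray             # subjects x components
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray

    @property
    def correlation_loadings(self) -> np.ndarray:
        """Loadings scaled to variable-component correlations
        (eigenvector × √eigenvalue) — the strengths shown on biplots."""
        return self.loadings * np.sqrt(np.clip(self.eigenvalues, 0, None))

    def to_dict(self):
        return {"subjects": self.subjects, "variables": self.variables,
                "variance_fraction": self.variance_fraction,
                "scores": self.scores, "loadings": self.loadings}


def run_pca(table: VariableTable) -> PCAResult:
    """PCA of z-scored variables via the correlation matrix.

    Columns are standardized to mean 0, sd 1 (denominator n−1); the
    correlation matrix is eigendecomposed; components are ordered by
    decreasing eigenvalue.
    """
    if table.n_subjects < 3:
        raise ValueError("need >= 3 subjects")
    X = table.values
    sds = X.std(axis=0, ddof=1)
    constant = [v for v, s in zip(table.variables, sds) if s == 0]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    Z = (X - X.mean(axis=0)) / sds
    R = (Z.T @ Z) / (table.n_subjects - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        if eigvecs[np.argmax(np.abs(eigvecs[:, j])), j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return PCAResult(
        subjects=list(table.subjects),
        variables=list(table.variables),
        loadings=eigvecs,
        scores=Z @ eigvecs,
        eigenvalues=eigvals,
        variance_fraction=eigvals / eigvals.sum(),
    )


# ---------------------------------------------------------------------------
# Gaussian-mixture clustering with BIC selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: dict[str, int]          # subject -> cluster id (0-based)
    k: int
    bic_by_k: dict[int, float]
    means: np.ndarray               # cluster x component
    covariances: np.ndarray
    posteriors: np.ndarray          # subject x cluster membership probs
    seed: int
    covariance_type: str
    n_components_used: int

    @property
    def sizes(self) -> list[int]:
        counts = np.bincount(list(self.labels.values()), minlength=self.k)
        return counts.tolist()

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == cluster]

    def to_dict(self):
        return {"labels": self.labels, "k": self.k,
                "bic_by_k": self.bic_by_k, "sizes": self.sizes,
                "seed": self.seed, "covariance_type": self.covariance_type,
                "n_components_used": self.n_components_used}


def _em_candidates(S, k, restarts, rng, covariance_type, reg_covar):
    """Ward-initialized EM plus seeded k-means/random restarts."""
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.mixture import GaussianMixture

    fits = []
    common = dict(n_components=k, covariance_type=covariance_type,
                  reg_covar=reg_covar, max_iter=500, n_init=1)
    if k == 1:
        ward = np.zeros(len(S), dtype=int)
    else:
        ward = AgglomerativeClustering(n_clusters=k).fit(S).labels_
    means = np.array([S[ward == j].mean(axis=0) for j in range(k)])
    weights = np.bincount(ward, minlength=k) / len(S)
    try:
        fits.append(GaussianMixture(means_init=means, weights_init=weights,
                                    random_state=0, **common).fit(S))
    except ValueError:
        pass
    for r in range(restarts):
        sub = int(rng.integers(0, 2**31 - 1))
        init = "kmeans" if r % 2 == 0 else "random_from_data"
        try:
            fits.append(GaussianMixture(init_params=init, random_state=sub,
                                        **common).fit(S))
        except ValueError:
            continue
    return fits


def gmm_cluster(scores, subjects=None, n_components_used: int | None = None,
                k_candidates=range(1, 6), restarts: int = 10, seed: int = 0,
                covariance_type: str = "tied", min_count: int = 3,
                reg_covar: float = 1e-6) -> ClusterResult:
    """EM-fitted Gaussian mixtures on PC scores, k selected by lowest BIC.

    Parameters
    ----------
    scores : ndarray or PCAResult
        Subject × component score matrix.
    n_components_used : int, optional
        Leading components to cluster on; default all.
    k_candidates : iterable of int
        Candidate numbers of clusters (must stay below n_subjects).
    restarts : int
        Random EM restarts per k, in addition to the deterministic
        Ward-linkage start.
    min_count : int
        Solutions with any component capturing fewer subjects than this
        are rejected as degenerate (see module docstring).

    Cluster ids are relabelled by ascending mean PC1 score, so label 0 is
    always the low-PC1 cluster.
    """
    if hasattr(scores, "scores"):
        if subjects is None:
            subjects = scores.subjects
        scores = scores.scores
    S = np.asarray(scores, dtype=float)
    n = S.shape[0]
    if subjects is None:
        subjects = [str(i) for i in range(n)]
    if n_components_used is not None:
        S = S[:, :n_components_used]
    n_used = S.shape[1]
    k_candidates = [int(k) for k in k_candidates]
    if not k_candidates or min(k_candidates) < 1 or max(k_candidates) > n - 1:
        raise ValueError("k_candidates must lie within [1, n_subjects - 1]")

    rng = np.random.default_rng(seed)
    best_by_k: dict[int, tuple[float, object]] = {}
    for k in sorted(k_candidates):
        for gm in _em_candidates(S, k, restarts, rng, covariance_type, reg_covar):
            lab = gm.predict(S)
            if np.bincount(lab, minlength=k).min() < min_count:
                continue
            bic = float(gm.bic(S))
            if k not in best_by_k or bic < best_by_k[k][0]:
                best_by_k[k] = (bic, gm)
    if not best_by_k:
        raise RuntimeError("no non-degenerate mixture fit for any candidate k")

    bic_by_k = {k: v[0] for k, v in best_by_k.items()}
    k_best = min(bic_by_k, key=bic_by_k.get)
    gm = best_by_k[k_best][1]
    raw_labels = gm.predict(S)
    post = gm.predict_proba(S)

    # stable relabelling: ascending mean PC1
    order = np.argsort([S[raw_labels == j, 0].mean() for j in range(k_best)])
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = {s: relabel[int(l)] for s, l in zip(subjects, raw_labels)}
    means = gm.means_[order]
    if covariance_type == "full":
        covs = gm.covariances_[order]
    else:
        covs = np.asarray(gm.covariances_)
    return ClusterResult(labels=labels, k=int(k_best), bic_by_k=bic_by_k,
                         means=means, covariances=covs,
                         posteriors=post[:, order], seed=int(seed),
                         covariance_type=covariance_type,
                         n_components_used=int(n_used))


# ---------------------------------------------------------------------------
# Distinction criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistinctionVerdict:
    pc1_separated: bool       # cluster centers distinct along PC1
    nonoverlapping_2d: bool   # convex hulls disjoint in (PC1, PC2)
    nonoverlapping_3d: bool   # convex hulls disjoint in (PC1, PC2, PC3)
    pc1_p_value: float

    @property
    def distinct(self) -> bool:
        return bool(self.pc1_separated and self.nonoverlapping_2d
                    and self.nonoverlapping_3d)

    def to_dict(self):
        d = self.__dict__.copy()
        d["distinct"] = self.distinct
        return d


def convex_hulls_disjoint(points_a, points_b) -> bool:
    """True iff the convex hulls of two point sets do not intersect.

    Solved as a linear feasibility problem: the hulls intersect iff some
    convex combination of A equals a convex combination of B.  Works in
    any dimension and for degenerate (collinear, single-point) sets,
    which trips the QHull-based route at these sample sizes.
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if A.size == 0 or B.size == 0:
        raise ValueError("each cluster needs at least one point")
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    nA, d = A.shape
    nB = B.shape[0]
    A_eq = np.zeros((d + 2, nA + nB))
    A_eq[:d, :nA] = A.T
    A_eq[:d, nA:] = -B.T
    A_eq[d, :nA] = 1.0
    A_eq[d + 1, nA:] = 1.0
    b_eq = np.concatenate([np.zeros(d), [1.0, 1.0]])
    res = linprog(np.zeros(nA + nB), A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * (nA + nB), method="highs")
    return not res.success


def check_distinction(scores, labels, alpha: float = 0.05) -> DistinctionVerdict:
    """Apply the cluster-distinction criteria to a two-group labelling.

    PC1 separation tests whether the cluster *centers* differ along the
    first principal component (Welch's t on PC1 scores at ``alpha``);
    overlap is convex-hull intersection in the leading two and three
    component dimensions.  Invariant under label permutation.
    """
    S = np.asarray(scores.scores if hasattr(scores, "scores") else scores,
                   dtype=float)
    if isinstance(labels, dict):
        lab = np.asarray(list(labels.values()))
    elif hasattr(labels, "labels"):
        lab = np.asarray(list(labels.labels.values()))
    else:
        lab = np.asarray(labels)
    uniq = np.unique(lab)
    if uniq.size != 2:
        raise ValueError("distinction criteria require exactly 2 clusters")
    a, b = (S[lab == u] for u in uniq)
    if min(len(a), len(b)) < 2:
        pc1_sep = False
        p = float("nan")
    else:
        res = welch_t(a[:, 0], b[:, 0])
        pc1_sep = res.p < alpha
        p = res.p
    d2 = convex_hulls_disjoint(a[:, :2], b[:, :2])
    d3 = convex_hulls_disjoint(a[:, :3], b[:, :3]) if S.shape[1] >= 3 else d2
    return DistinctionVerdict(bool(pc1_sep), bool(d2), bool(d3), p)
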