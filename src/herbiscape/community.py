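"""Community synthesis: biomass surfaces, functional dispersion and the
clustering of grid cells into landscape-scale herbivory regimes
("herbiscapes").

Functional dispersion (FDis) is the abundance-weighted mean distance of
species to the abundance-weighted community centroid in a trait space
built from Gower dissimilarities (range-normalized quantitative traits,
0/1 categorical mismatches, equal trait weights) embedded by principal
coordinates.  Herbiscapes are obtained by hierarchical clustering on
principal components (HCPC): standardize features, PCA, Ward agglomeration
on the component scores, cut to k clusters, then optional k-means
consolidation seeded from the cluster centroids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "biomass_surfaces",
    "gower_distance",
    "trait_space",
    "compute_fdis",
    "fdis_map",
    "pairwise_overlap",
    "HCPC",
    "hcpc_cluster",
]


# ---------------------------------------------------------------------------
# biomass
# ---------------------------------------------------------------------------

def biomass_surfaces(
    density_surfaces: dict[str, np.ndarray], weights: dict[str, float]
) -> pd.DataFrame:
    """Per-species and total biomass per cell: biomass_sj = w_s * lambda_sj.

    ``weights`` are species body masses in kg; the returned frame has one
    biomass column per species plus ``total_biomass``.
    """
    if not density_surfaces:
        raise ValueError("no density surfaces given")
    sizes = {np.asarray(v).size for v in density_surfaces.values()}
    if len(sizes) != 1:
        raise ValueError("density surfaces must share one grid")
    out = {}
    for name, surface in density_surfaces.items():
        if name not in weights:
            raise KeyError(f"missing biomass weight for species {name!r}")
        if weights[name] <= 0:
            raise ValueError(f"biomass weight for {name!r} must be positive")
        out[f"biomass_{name}"] = weights[name] * np.asarray(surface, dtype=float).ravel()
    frame = pd.DataFrame(out)
    frame["total_biomass"] = frame.sum(axis=1)
    frame.index.name = "cell"
    return frame


# ---------------------------------------------------------------------------
# Gower + PCoA trait space
# ---------------------------------------------------------------------------

def gower_distance(traits: pd.DataFrame) -> np.ndarray:
    """Gower dissimilarity matrix for a mixed-type trait table.

    Numeric columns contribute |x_i - x_j| / range, categorical columns a
    0/1 mismatch; traits are weighted equally.  Missing values are not
    allowed.
    """
    if traits.isna().any().any():
        raise ValueError("trait table contains missing values")
    n = len(traits)
    parts = []
    for col in traits.columns:
        s = traits[col]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(dtype=float)
            rng = x.max() - x.min()
            if rng == 0:
                parts.append(np.zeros((n, n)))
            else:
                parts.append(np.abs(x[:, None] - x[None, :]) / rng)
        else:
            x = s.to_numpy()
            parts.append((x[:, None] != x[None, :]).astype(float))
    return np.mean(parts, axis=0)


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest constant c so that d_ij + c (i != j) is Euclidean
    (Cailliez 1983: largest real eigenvalue of a 2n x 2n block matrix)."""
    n = d.shape[0]
    delta1 = -0.5 * d**2
    delta2 = -0.5 * d
    zero = np.zeros((n, n))
    eye = np.eye(n)
    block = np.block([[zero, 2 * delta1], [-eye, -4 * delta2]])
    eigs = np.linalg.eigvals(block)
    real = eigs[np.abs(eigs.imag) < 1e-8].real
    return float(max(real.max(), 0.0))


def trait_space(traits: pd.DataFrame) -> np.ndarray:
    """Principal-coordinate embedding of the Gower dissimilarities.

    If the Gower matrix is not Euclidean (negative PCoA eigenvalues below
    -1e-8), a Cailliez correction is applied first, so centroid geometry in
    the returned coordinates is exact.
    """
    d = gower_distance(traits)
    coords = _pcoa(d)
    return coords


def _pcoa(d: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, 1))

    def embed(dist: np.ndarray):
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dist**2) @ j
        b = 0.5 * (b + b.T)
        vals, vecs = np.linalg.eigh(b)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = embed(d)
    if vals.min() < -tol:
        c = _cailliez_constant(d)
        d = d + c * (1 - np.eye(n))
        vals, vecs = embed(d)
    keep = vals > tol
    if not np.any(keep):
        return np.zeros((n, 1))
    return vecs[:, keep] * np.sqrt(vals[keep])


def compute_fdis(traits: pd.DataFrame, abundances: np.ndarray) -> float:
    """Abundance-weighted functional dispersion of one community.

    FDis = sum_k a_k z_k / sum_k a_k with z_k the distance of species k to
    the abundance-weighted centroid c = sum_k a_k x_k / sum_k a_k in the
    PCoA trait space.  A single-species community has FDis 0.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size != len(traits):
        raise ValueError("abundance vector length must match the trait table")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    if a.sum() == 0:
        raise ValueError("all-zero abundance vector")
    if len(traits) == 1:
        return 0.0
    coords = trait_space(traits)
    return _fdis_from_coords(coords, a[None, :])[0]


def _fdis_from_coords(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized FDis for many communities sharing one trait space.

    ``weights`` is (n_communities, n_species).
    """
    w = weights / weights.sum(axis=1, keepdims=True)
    centroids = w @ coords  # (n_comm, n_dim)
    # distances of every species to every community centroid
    diff = coords[None, :, :] - centroids[:, None, :]
    z = np.sqrt((diff**2).sum(axis=2))  # (n_comm, n_species)
    return (w * z).sum(axis=1)


def fdis_map(traits: pd.DataFrame, abundance_matrix: pd.DataFrame) -> pd.Series:
    """Per-cell FDis for an abundance matrix (cells x species).

    Column order must match the trait table's species index.
    """
    cols = list(abundance_matrix.columns)
    if cols != list(traits.index):
        abundance_matrix = abundance_matrix[list(traits.index)]
    w = abundance_matrix.to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("abundances must be non-negative")
    if np.any(w.sum(axis=1) == 0):
        raise ValueError("some cells have all-zero abundances")
    coords = trait_space(traits)
    if len(traits) == 1:
        return pd.Series(np.zeros(len(abundance_matrix)), index=abundance_matrix.index)
    return pd.Series(
        _fdis_from_coords(coords, w), index=abundance_matrix.index, name="fdis"
    )


# ---------------------------------------------------------------------------
# spatial overlap
# ---------------------------------------------------------------------------

def pairwise_overlap(surfaces: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlations of relative-density surfaces.

    A constant surface has no defined correlation; its entries are NaN
    (flagged) rather than an error.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least two surfaces")
    names = list(surfaces)
    mat = np.column_stack([np.asarray(surfaces[n], float).ravel() for n in names])
    if len({np.asarray(v).size for v in surfaces.values()}) != 1:
        raise ValueError("surfaces must share one grid")
    sd = mat.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    corr[np.ix_(sd == 0, np.arange(len(names)))] = np.nan
    corr[np.ix_(np.arange(len(names)), sd == 0)] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=names, columns=names)


# ---------------------------------------------------------------------------
# HCPC
# ---------------------------------------------------------------------------

class HCPC(BaseEstimator, ClusterMixin):
    """Hierarchical clustering on principal components.

    Standardizes the feature table, projects onto principal components
    (all of them by default), builds a Ward tree with Euclidean distances
    on the scores, cuts it into ``n_clusters`` groups and, if
    ``consolidate``, refines the partition with k-means seeded from the
    cluster centroids (turn off for exact-tree reproducibility).

    Fitted attributes: ``labels_`` (1-based, contiguous), ``linkage_``,
    ``inertia_gain_`` (within-inertia drop per candidate cut, for choosing
    k), ``scores_`` and ``profiles_`` (per-cluster feature means).
    """

    def __init__(
        self,
        n_clusters: int = 5,
        consolidate: bool = True,
        standardize: bool = True,
        n_components: int | None = None,
        max_cut: int = 10,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.consolidate = consolidate
        self.standardize = standardize
        self.n_components = n_components
        self.max_cut = max_cut
        self.random_state = random_state

    def fit(self, features: pd.DataFrame, y=None) -> "HCPC":
        features = pd.DataFrame(features)
        if self.n_clusters < 2:
            raise ValueError("need at least two clusters")
        n_distinct = len(np.unique(features.to_numpy(float), axis=0))
        if self.n_clusters > n_distinct:
            raise ValueError(
                f"k={self.n_clusters} exceeds the {n_distinct} distinct rows"
            )
        x = features.to_numpy(dtype=float)
        if self.standardize:
            mean = x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            x = (x - mean) / sd
        pca = PCA(n_components=self.n_components, random_state=self.random_state)
        scores = pca.fit_transform(x)
        self.pca_ = pca
        self.scores_ = scores
        self.linkage_ = sch.linkage(scores, method="ward")
        labels = sch.fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        if self.consolidate:
            centroids = np.vstack(
                [scores[labels == c].mean(axis=0) for c in np.unique(labels)]
            )
            km = KMeans(
                n_clusters=centroids.shape[0],
                init=centroids,
                n_init=1,
                random_state=self.random_state,
            ).fit(scores)
            labels = km.labels_ + 1
        self.labels_ = _contiguous(labels)
        self.inertia_gain_ = self._inertia_gains(scores)
        self.profiles_ = (
            features.assign(cluster=self.labels_).groupby("cluster").mean()
        )
        return self

    def fit_predict(self, features: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(features).labels_

    def _inertia_gains(self, scores: np.ndarray) -> pd.Series:
        """Within-cluster inertia released by each candidate cut k-1 -> k
        on the (unconsolidated) tree; large gains justify finer cuts."""
        kmax = min(self.max_cut, scores.shape[0])
        inertia = {}
        for k in range(1, kmax + 1):
            lab = sch.fcluster(self.linkage_, t=k, criterion="maxclust")
            w = 0.0
            for c in np.unique(lab):
                pts = scores[lab == c]
                w += float(((pts - pts.mean(axis=0)) ** 2).sum())
            inertia[k] = w
        gains = {k: inertia[k - 1] - inertia[k] for k in range(2, kmax + 1)}
        return pd.Series(gains, name="inertia_gain")


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters to 1..k in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def hcpc_cluster(
    features: pd.DataFrame,
    k: int = 5,
    consolidate: bool = True,
    seed: int | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Functional wrapper over :class:`HCPC`: returns (labels 1..k,
    inertia-gain curve)."""
    est = HCPC(n_clusters=k, consolidate=consolidate, random_state=seed).fit(features)
    return est.labels_, est.inertia_gain_
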