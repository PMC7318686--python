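"""Structural context of side-chain dynamics.

Two questions about where the dynamics live in the structure:

* does O²_axis correlate with the distance from the methyl carbon to the
  nearest lipid/detergent atom (a "surface molten" protein would show a
  positive trend)?
* do the motional classes cluster spatially, or are they heterogeneously
  scattered through the fold?

Both are answered with permutation tests: labels (or O² values) are
shuffled over the fixed coordinates, so the null distribution carries the
exact spatial geometry of the probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .exceptions import InsufficientDataError, MethylDynError

__all__ = [
    "SpatialDataset",
    "distance_to_cloud",
    "dynamics_distance_correlation",
    "spatial_class_clustering_test",
    "spatial_kmeans_ari_test",
    "slab_pseudo_cloud",
]


@dataclass
class SpatialDataset:
    """Methyl probes with 3-D coordinates, O² values, and class labels."""

    probes: list  #: MethylProbe (or any hashable id) per row
    coords: np.ndarray  #: (n, 3) methyl-carbon positions, Å
    o2_values: np.ndarray
    class_labels: np.ndarray  #: integer or string label per probe
    cloud: np.ndarray | None = None  #: optional lipid/detergent atoms, Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.o2_values = np.asarray(self.o2_values, dtype=float)
        self.class_labels = np.asarray(self.class_labels)
        n = len(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise MethylDynError("coords must be (n, 3)")
        if len(self.o2_values) != n or len(self.class_labels) != n:
            raise MethylDynError("coords, o2_values and class_labels must align")
        if not np.all(np.isfinite(self.coords)):
            raise MethylDynError("coordinates must be finite")
        if self.cloud is not None:
            self.cloud = np.asarray(self.cloud, dtype=float)


def distance_to_cloud(coords, cloud) -> np.ndarray:
    """Minimum Euclidean distance from each probe to any cloud point, Å."""
    cloud = np.asarray(cloud, dtype=float)
    if cloud.size == 0:
        raise MethylDynError("reference cloud is empty")
    dists, _ = cKDTree(cloud).query(np.asarray(coords, dtype=float))
    return np.asarray(dists, dtype=float)


def dynamics_distance_correlation(
    distances, o2_values, n_perm: int = 1999, seed: int = 0
):
    """OLS R² of O² on distance, with a permutation p-value.

    The p-value is the +1-smoothed fraction of ``n_perm`` seeded shuffles
    of the O² values whose squared correlation reaches the observed one.
    Returns ``(r_squared, slope, p_perm)``.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(o2_values, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise InsufficientDataError("need >= 5 aligned (distance, O2) pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MethylDynError("zero variance in distances or O2 values: R2 undefined")
    fit = stats.linregress(x, y)
    r2_obs = float(fit.rvalue**2)

    # canonical row order: permutation p-values do not depend on input order
    order = np.lexsort((y, x))
    x, y = x[order], y[order]

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom_x = np.sqrt((xc**2).sum())
    perm_r2 = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        r = (xc @ yc) / (denom_x * np.sqrt((yc**2).sum()))
        perm_r2[i] = r * r
    p_perm = (1 + np.count_nonzero(perm_r2 >= r2_obs)) / (n_perm + 1)
    return r2_obs, float(fit.slope), float(p_perm)


def _clustering_statistic(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-class pairwise distance minus overall mean pairwise
    distance. Negative values mean classes are spatially compact."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    overall = D[iu].mean()
    same = labels[iu[0]] == labels[iu[1]]
    if not np.any(same):
        return 0.0
    return float(D[iu][same].mean() - overall)


def spatial_class_clustering_test(
    dataset: SpatialDataset, n_perm: int = 1999, seed: int = 0
):
    """Permutation test for spatial clustering of motional classes.

    Statistic: mean within-class pairwise 3-D distance minus the overall
    mean pairwise distance (negative = clustered). Class labels are
    permuted over the fixed coordinates; the one-sided p-value (toward
    clustering) uses +1 smoothing. Classes with fewer than 2 members
    contribute no within-class pairs and are effectively excluded (with a
    warning). With a single class the statistic is 0 by convention and
    p = 1. Returns ``(statistic, p_value)``.
    """
    labels = dataset.class_labels
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        return 0.0, 1.0
    small = uniq[counts < 2]
    if small.size:
        warnings.warn(
            f"classes {list(small)} have < 2 members and contribute no "
            "within-class pairs",
            stacklevel=2,
        )
    # canonical row order: permutation p-values do not depend on input order
    coords = dataset.coords
    order = np.lexsort((labels.astype(str), coords[:, 2], coords[:, 1], coords[:, 0]))
    coords, labels = coords[order], labels[order]
    D = squareform(pdist(coords))
    obs = _clustering_statistic(D, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _clustering_statistic(D, perm) <= obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return obs, float(p)


def spatial_kmeans_ari_test(
    dataset: SpatialDataset, n_perm: int = 1999, seed: int = 0
):
    """Alternative spatial statistic: agreement between motional classes
    and a spatial k-means partition of the coordinates.

    The coordinates are partitioned into as many spatial clusters as
    there are motional classes; the statistic is the adjusted Rand index
    between that partition and the class labels (positive = classes track
    spatial regions). Null from label permutations; one-sided toward
    agreement, +1 smoothing. Returns ``(ari, p_value)``.
    """
    labels = dataset.class_labels
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return 0.0, 1.0
    km = KMeans(n_clusters=len(uniq), n_init=10, random_state=seed).fit(dataset.coords)
    obs = adjusted_rand_score(labels, km.labels_)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if adjusted_rand_score(perm, km.labels_) >= obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(obs), float(p)


def slab_pseudo_cloud(coords, z_min: float, z_max: float, spacing: float = 4.0) -> np.ndarray:
    """Pseudo-lipid cloud on the two surfaces of a bilayer z-slab.

    For structures without explicit lipid coordinates, a user-supplied
    z-slab (the approximate bilayer-spanning region) is turned into two
    planes of grid points covering the xy extent of the probes.
    """
    coords = np.asarray(coords, dtype=float)
    if z_max <= z_min:
        raise MethylDynError("z_max must exceed z_min")
    x0, x1 = coords[:, 0].min() - spacing, coords[:, 0].max() + spacing
    y0, y1 = coords[:, 1].min() - spacing, coords[:, 1].max() + spacing
    xs = np.arange(x0, x1 + spacing, spacing)
    ys = np.arange(y0, y1 + spacing, spacing)
    gx, gy = np.meshgrid(xs, ys)
    plane = np.column_stack([gx.ravel(), gy.ravel()])
    lower = np.column_stack([plane, np.full(len(plane), z_min)])
    upper = np.column_stack([plane, np.full(len(plane), z_max)])
    return np.vstack([lower, upper])
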