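"""Motional-class decomposition of an order-parameter distribution.

Methyl order-parameter histograms of well-folded proteins segregate into
bands that correspond to distinct modes of side-chain motion:

* ω — highly restricted motion within a single rotamer (high O²),
* α — large intra-rotamer excursions with occasional rotameric jumps,
* J — two-state rotamer interconversion (O² around 0.3–0.45),
* J′ — extensive multi-torsion rotameric sampling (O² ≈ 0.21), a band so
  far seen only in membrane proteins.

The class count is chosen by BIC over 1-D Gaussian mixtures with a
tie-break toward the larger count; band centers and boundaries come from
1-D k-means on the error-filtered values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .exceptions import InsufficientDataError, MethylDynError
from .probes import MethylProbe, OrderParameterSet

__all__ = [
    "ClassModel",
    "filter_by_error",
    "select_class_count",
    "kmeans_classes",
    "classify_set",
    "class_composition",
]

#: residue types grouped as "multi-torsion" for composition statistics
MLI_TYPES = frozenset({"MET", "LEU", "ILE"})


def filter_by_error(
    opset: OrderParameterSet, max_error: float = 0.1
) -> tuple[OrderParameterSet, int]:
    """Retain entries with error ≤ max_error (boundary inclusive).

    Returns the filtered set and the number of removed entries. Order is
    preserved.
    """
    kept = [e for e in opset.entries if e.error <= max_error]
    removed = len(opset) - len(kept)
    return OrderParameterSet(kept, tau_m_ns=opset.tau_m_ns), removed


def select_class_count(
    values,
    k_candidates=(1, 2, 3, 4, 5),
    tie_margin: float = 2.0,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, dict]:
    """Choose the number of motional classes by BIC over Gaussian mixtures.

    Fits a 1-D Gaussian mixture for each candidate k (seeded EM with
    ``n_init`` restarts) and scores by BIC. The best k minimizes BIC,
    except that when a larger candidate is within ``tie_margin`` of the
    minimum, the larger one is chosen: near-equal evidence for two counts
    is resolved toward the richer taxonomy, since a band that matches a
    known motional class is more interpretable than a merged one.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise InsufficientDataError("class-count selection needs >= 10 values")
    scores: dict[int, float] = {}
    for k in sorted(k_candidates):
        if k >= len(x):
            scores[k] = float("inf")
            continue
        try:
            gm = GaussianMixture(
                n_components=k, n_init=n_init, random_state=seed, covariance_type="full"
            ).fit(x)
            scores[k] = float(gm.bic(x))
        except Exception as exc:  # EM failure on a degenerate candidate
            warnings.warn(f"mixture fit failed for k={k}: {exc}", stacklevel=2)
            scores[k] = float("inf")
    finite = {k: s for k, s in scores.items() if np.isfinite(s)}
    if not finite:
        raise MethylDynError("no mixture converged for any candidate k")
    best_score = min(finite.values())
    tied = [k for k, s in finite.items() if s - best_score <= tie_margin]
    return max(tied), scores


def _labels_for(k: int, centers: np.ndarray) -> list[str]:
    """Class names low→high O².

    With three bands all below the rigid region the ω class is absent and
    the bands are J′/J/α; a third band reaching into O² ≥ 0.75 is read as
    the soluble-protein J/α/ω pattern instead. Two bands are taxonomically
    ambiguous and get generic names with a warning.
    """
    if k == 3:
        if centers[-1] < 0.75:
            return ["J'", "J", "alpha"]
        return ["J", "alpha", "omega"]
    if k == 4:
        return ["J'", "J", "alpha", "omega"]
    if k == 2:
        warnings.warn(
            "two-class model: band taxonomy is ambiguous; using generic labels",
            stacklevel=3,
        )
        return ["J-like", "alpha-like"]
    if k == 1:
        return ["single"]
    return [f"band{i + 1}" for i in range(k)]


@dataclass
class ClassModel:
    """Fitted motional-class model for a set of O²_axis values."""

    k: int
    centers: np.ndarray  #: strictly increasing class centers
    boundaries: np.ndarray  #: k−1 midpoints between adjacent centers
    labels: list  #: class names, low→high O²
    assignments: np.ndarray  #: class index per input value
    values: np.ndarray  #: the (clipped-for-classification) values used
    clipped: np.ndarray  #: flags: value was outside [0,1] and clipped
    selection_scores: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.diff(self.centers) > 0):
            raise MethylDynError("class centers must be strictly increasing")

    def label_of(self, index: int) -> str:
        return self.labels[index]

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def kmeans_classes(values, k: int, seed: int = 0, n_restarts: int = 50) -> ClassModel:
    """1-D k-means decomposition into k motional classes.

    k-means++ initialization with ``n_restarts`` restarts at a fixed seed;
    the lowest-inertia solution is kept. Values outside [0, 1] are clipped
    into [0, 1] for classification only (flagged in the result). Class
    boundaries are midpoints between adjacent sorted centers.
    """
    raw = np.asarray(values, dtype=float)
    clipped_flags = (raw < 0.0) | (raw > 1.0)
    x = np.clip(raw, 0.0, 1.0)
    if k < 1:
        raise MethylDynError("k must be >= 1")
    if k > len(np.unique(x)):
        raise MethylDynError(
            f"k={k} exceeds the number of distinct values ({len(np.unique(x))})"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(x.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    centers_sorted = centers[order]
    # remap raw cluster ids to ascending-center class indices
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    assignments = remap[km.labels_]
    boundaries = 0.5 * (centers_sorted[:-1] + centers_sorted[1:])
    return ClassModel(
        k=k,
        centers=centers_sorted,
        boundaries=boundaries,
        labels=_labels_for(k, centers_sorted),
        assignments=assignments,
        values=x,
        clipped=clipped_flags,
    )


def classify_set(
    opset: OrderParameterSet,
    k: int | None = None,
    max_error: float = 0.1,
    seed: int = 0,
) -> tuple[ClassModel, OrderParameterSet]:
    """Filter a set by error, pick k if not given, and run k-means.

    Returns the fitted model and the filtered set (aligned with the
    model's assignments).
    """
    filtered, removed = filter_by_error(opset, max_error=max_error)
    if removed:
        warnings.warn(f"{removed} entries removed by error filter", stacklevel=2)
    if len(filtered) == 0:
        raise InsufficientDataError("no entries survive the error filter")
    scores: dict = {}
    if k is None:
        k, scores = select_class_count(filtered.values, seed=seed)
    model = kmeans_classes(filtered.values, k, seed=seed)
    model.selection_scores = scores
    return model, filtered


def class_composition(model: ClassModel, probes) -> pd.DataFrame:
    """Residue-type composition per class versus the overall composition.

    Residue types are grouped as MLI (Met/Leu/Ile — side chains with two
    or more torsions) against V (Val). Returns a DataFrame indexed by
    class label with columns ``n``, ``frac_MLI``, ``frac_V``,
    ``enrich_MLI``, ``enrich_V``; empty classes are reported with NaN
    fractions.
    """
    probes = list(probes)
    if len(probes) != len(model.assignments):
        raise MethylDynError(
            f"got {len(probes)} probes for {len(model.assignments)} assignments"
        )
    is_mli = np.array([p.residue_type in MLI_TYPES for p in probes])
    overall_mli = float(is_mli.mean())
    rows = []
    for ci, label in enumerate(model.labels):
        mask = model.assignments == ci
        n = int(mask.sum())
        if n == 0:
            rows.append((label, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        f_mli = float(is_mli[mask].mean())
        rows.append(
            (label, n, f_mli, 1.0 - f_mli, f_mli - overall_mli, (1.0 - f_mli) - (1.0 - overall_mli))
        )
    df = pd.DataFrame(
        rows, columns=["class", "n", "frac_MLI", "frac_V", "enrich_MLI", "enrich_V"]
    ).set_index("class")
    df.attrs["overall_frac_MLI"] = overall_mli
    df.attrs["overall_frac_V"] = 1.0 - overall_mli
    return df
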