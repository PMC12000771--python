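"""Comorbidity phenotyping: k-means over condition profiles, elbow selection,
cluster characterisation and per-cluster outcome risk.

Records are embedded as binary condition-flag vectors by default (count and
TF-IDF modes are available for the text-vectorizer route), clustered with
k-means (k-means++ initialisation, best of ``n_init`` restarts), with the
number of clusters chosen by the elbow criterion formalised as maximum
perpendicular distance of the inertia-vs-k polyline from the chord joining
its endpoints. A manual override is supported since published analyses
often fix k by inspection. Per-cluster outcome risk is compared pairwise
with the same continuity-corrected chi-square used for association
screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.feature_extraction.text import TfidfTransformer

from .association import (
    ContingencyTable2x2,
    chi2_pvalue_1df,
    chi_square_corrected,
)

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "ElbowCurve",
    "ClusterRiskTable",
    "build_feature_matrix",
    "kmeans_fit",
    "elbow_select_k",
    "characterize_clusters",
    "cluster_outcome_risk",
]


@dataclass(frozen=True)
class FeatureMatrix:
    record_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    X: np.ndarray
    mode: str


@dataclass(frozen=True)
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    seed: int
    n_init: int
    converged: bool
    record_ids: tuple[str, ...]


@dataclass(frozen=True)
class ElbowCurve:
    ks: tuple[int, ...]
    inertias: tuple[float, ...]
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "inertia": self.inertias})


@dataclass(frozen=True)
class ClusterRiskTable:
    cluster_ids: tuple[int, ...]
    n: dict[int, int]
    outcome_count: dict[int, int]
    risk: dict[int, float]
    pairwise_p: pd.DataFrame  # symmetric, indexed by cluster id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": list(self.cluster_ids),
                "n": [self.n[c] for c in self.cluster_ids],
                "outcome_count": [self.outcome_count[c] for c in self.cluster_ids],
                "risk": [self.risk[c] for c in self.cluster_ids],
            }
        )


def build_feature_matrix(
    profiles: pd.DataFrame,
    mode: str = "binary",
    condition_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Embed morbidity profiles as a numeric matrix.

    ``binary`` uses the 0/1 flags as-is; ``count`` treats them as
    occurrence counts (identical for single-mention fields but kept
    distinct for pre-counted inputs); ``tfidf`` reweights counts by smooth
    inverse document frequency ``ln((1+N)/(1+df)) + 1`` and normalises each
    row to unit Euclidean norm (all-zero rows stay zero).
    """
    if profiles.empty:
        raise ValueError("profiles table is empty")
    if condition_ids is None:
        reserved = {"record_id", "morbidity_count", "burden_class"}
        condition_ids = [c for c in profiles.columns if c not in reserved]
    raw = profiles[list(condition_ids)].to_numpy(dtype=float)
    if mode in ("binary", "count"):
        X = raw
        if mode == "binary" and not np.isin(X, (0.0, 1.0)).all():
            raise ValueError("binary mode requires 0/1 flags")
    elif mode == "tfidf":
        X = TfidfTransformer(norm="l2", smooth_idf=True).fit_transform(raw).toarray()
    else:
        raise ValueError(f"unknown feature mode: {mode!r}")
    return FeatureMatrix(
        record_ids=tuple(profiles["record_id"].astype(str)),
        condition_ids=tuple(condition_ids),
        X=X,
        mode=mode,
    )


def kmeans_fit(
    fm: FeatureMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterModel:
    """Lloyd's k-means with k-means++ init, best of ``n_init`` restarts.

    Deterministic given (seed, n_init). Raises when k exceeds the number of
    distinct rows (some centroids could never separate).
    """
    n_distinct = len(np.unique(fm.X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatter on duplicate points
        labels = km.fit_predict(fm.X)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=labels,
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
        converged=bool(km.n_iter_ < max_iter),
        record_ids=fm.record_ids,
    )


def recompute_inertia(model: ClusterModel, fm: FeatureMatrix) -> float:
    """Within-cluster sum of squared distances, recomputed from scratch."""
    diffs = fm.X - model.centroids[model.assignments]
    return float(np.sum(diffs * diffs))


def elbow_select_k(
    fm: FeatureMatrix,
    k_min: int = 1,
    k_max: int = 8,
    seed: int = 0,
    n_init: int = 10,
    override_k: int | None = None,
) -> ElbowCurve:
    """Scan k in [k_min, k_max] and pick the elbow by maximum chord distance.

    The chosen k maximises the perpendicular distance of (k, inertia) from
    the straight line joining the curve's endpoints; ties break toward
    smaller k. A flat (linear) curve has no elbow: k_min is returned with a
    warning. ``override_k`` bypasses the criterion while still reporting
    the scanned curve.
    """
    if not (1 <= k_min < k_max):
        raise ValueError("need 1 <= k_min < k_max")
    ks = list(range(k_min, k_max + 1))
    inertias = [kmeans_fit(fm, k, seed=seed, n_init=n_init).inertia for k in ks]

    if override_k is not None:
        if override_k not in ks:
            raise ValueError(f"override_k={override_k} outside scanned range")
        return ElbowCurve(tuple(ks), tuple(inertias), override_k)

    x0, y0 = ks[0], inertias[0]
    x1, y1 = ks[-1], inertias[-1]
    chord = np.hypot(x1 - x0, y1 - y0)
    if chord == 0:
        warnings.warn("flat inertia curve: no elbow, falling back to k_min")
        return ElbowCurve(tuple(ks), tuple(inertias), k_min)
    dists = [
        abs((y1 - y0) * k - (x1 - x0) * inertia + x1 * y0 - y1 * x0) / chord
        for k, inertia in zip(ks, inertias)
    ]
    best = max(dists)
    if best <= 1e-12 * max(1.0, abs(y0)):
        warnings.warn("inertia declines linearly: no elbow, falling back to k_min")
        return ElbowCurve(tuple(ks), tuple(inertias), k_min)
    chosen = ks[int(np.argmax(dists))]  # argmax returns first max -> smaller k on ties
    return ElbowCurve(tuple(ks), tuple(inertias), chosen)


def characterize_clusters(
    model: ClusterModel, profiles: pd.DataFrame, top_m: int = 10,
    condition_ids: Sequence[str] | None = None,
) -> dict[int, list[tuple[str, float]]]:
    """Top conditions per cluster by within-cluster prevalence.

    Returns, for each cluster, up to ``top_m`` (condition, prevalence)
    pairs ordered by descending prevalence, lexicographic ties.
    """
    if condition_ids is None:
        reserved = {"record_id", "morbidity_count", "burden_class"}
        condition_ids = [c for c in profiles.columns if c not in reserved]
    out: dict[int, list[tuple[str, float]]] = {}
    flags = profiles[list(condition_ids)].to_numpy(dtype=float)
    for cl in range(model.k):
        mask = model.assignments == cl
        prev = flags[mask].mean(axis=0)
        ranked = sorted(zip(condition_ids, prev), key=lambda cp: (-cp[1], cp[0]))
        out[cl] = [(c, float(p)) for c, p in ranked[:top_m] if p > 0]
    return out


def cluster_outcome_risk(
    model: ClusterModel, outcome_flags: Sequence[int] | np.ndarray
) -> ClusterRiskTable:
    """Per-cluster outcome risk with pairwise corrected chi-square p-values.

    Each pairwise test compares membership in cluster A vs cluster B
    against the outcome in a 2×2 table (records outside the pair are
    excluded).
    """
    y = np.asarray(outcome_flags)
    if len(y) != len(model.assignments):
        raise ValueError("need one outcome flag per assigned record")
    clusters = [c for c in range(model.k) if np.sum(model.assignments == c) > 0]
    dropped = model.k - len(clusters)
    if dropped:
        warnings.warn(f"excluding {dropped} empty cluster(s) from the risk table")
    n = {c: int(np.sum(model.assignments == c)) for c in clusters}
    cnt = {c: int(y[model.assignments == c].sum()) for c in clusters}
    risk = {c: cnt[c] / n[c] for c in clusters}

    p = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    for i, a in enumerate(clusters):
        p.loc[a, a] = 1.0
        for b in clusters[i + 1 :]:
            t = ContingencyTable2x2(
                a=n[a] - cnt[a], b=cnt[a], c=n[b] - cnt[b], d=cnt[b]
            )
            pv = np.nan if t.degenerate else chi2_pvalue_1df(chi_square_corrected(t))
            p.loc[a, b] = pv
            p.loc[b, a] = pv
    return ClusterRiskTable(tuple(clusters), n, cnt, risk, p)
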