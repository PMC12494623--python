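"""Patient stratification and antigen co-reactivity clustering.

Patients are stratified by complete-linkage agglomeration on Euclidean
distances between reactivity profiles, cut into k=3 groups labelled
high / intermediate / low by descending mean reactivity.  Antigens are
clustered on patient-scaled (row z-scored) co-reactivity, with the cut
height chosen deterministically to maximize the number of clusters whose
size falls in the eligible [3, 20] window used for network seeding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .associate import bh_adjust, spearman_screen
from .preprocess import zero_variance_filter

TIER_NAMES = ("high", "intermediate", "low")


@dataclass
class ClusterAssignment:
    """Patient (or antigen) cluster labels plus linkage metadata."""

    entity_kind: str
    labels: pd.Series
    linkage_matrix: np.ndarray
    method: str = "complete"
    metric: str = "euclidean"
    tier: pd.Series | None = None
    k: int | None = None
    cut_height: float | None = None

    def tier_members(self, name: str) -> pd.Index:
        if self.tier is None:
            raise ValueError("no tier labels on this assignment")
        return self.tier.index[self.tier == name]


@dataclass
class AntigenCluster:
    cluster_id: int
    members: tuple
    eligible: bool
    reason: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AntigenClusterSet:
    clusters: list
    cut_height: float
    linkage_matrix: np.ndarray
    size_bounds: tuple = (3, 20)

    @property
    def eligible(self) -> list:
        return [c for c in self.clusters if c.eligible]


def cluster_patients(
    matrix: pd.DataFrame,
    k: int = 3,
    method: str = "complete",
    metric: str = "euclidean",
    scale_columns: bool = True,
) -> ClusterAssignment:
    """Stratify patients into k reactivity groups.

    Complete-linkage agglomeration on Euclidean row distances, cut to
    exactly ``k`` clusters.  ``scale_columns`` (default) z-scores each
    antigen first: per-antigen Box-Cox transforms leave columns on
    incommensurable scales, and standardization keeps any one antigen from
    dominating the distances.  For k=3 the clusters are named high /
    intermediate / low by descending mean (standardized) reactivity; other
    k get ``tier_1`` (highest mean) .. ``tier_k``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if matrix.shape[0] < k:
        raise ValueError(f"need at least {k} patients")
    X = matrix.to_numpy(dtype=float)
    if scale_columns:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    work = pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
    Z = linkage(pdist(X, metric=metric), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=matrix.index, name="cluster")
    means = work.mean(axis=1).groupby(labels).mean()
    order = means.sort_values(ascending=False, kind="mergesort").index
    if k == 3:
        names = dict(zip(order, TIER_NAMES))
    else:
        names = {c: f"tier_{i + 1}" for i, c in enumerate(order)}
    tier = labels.map(names).rename("tier")
    return ClusterAssignment(
        entity_kind="patient",
        labels=labels,
        linkage_matrix=Z,
        method=method,
        metric=metric,
        tier=tier,
        k=k,
    )


def stratify_patients(result, k: int = 3) -> ClusterAssignment:
    """Reactivity-tier stratification from a preprocessing result.

    Overall-reactivity tiers are a between-patient *level* structure, which
    between-sample normalization deliberately suppresses; stratification
    therefore clusters the log2 background-corrected matrix (kept on
    ``result.corrected``) rather than the normalized one.  Antigen columns
    are left unscaled so reactive antigens carry their natural weight.
    """
    if result.corrected is None:
        raise ValueError("preprocessing result lacks the corrected matrix")
    logc = pd.DataFrame(
        np.log2(result.corrected.to_numpy(dtype=float)),
        index=result.corrected.index,
        columns=result.corrected.columns,
    )
    return cluster_patients(logc, k=k, scale_columns=False)


def subgroup_screen(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    assignment: ClusterAssignment,
    tiers=("high", "low"),
    params=None,
    min_patients: int = 5,
) -> dict:
    """Re-run the Spearman screen inside reactivity tiers.

    Per tier: antigens with zero variance within the tier are removed, then
    ``spearman_screen`` runs on the tier's patients with BH within that
    tier's family.  Tiers with fewer than ``min_patients`` patients are
    skipped with a warning.  Returns ``{tier: {"table", "removed", "n"}}``.
    """
    out = {}
    for tier_name in tiers:
        members = assignment.tier_members(tier_name)
        if len(members) == 0:
            raise ValueError(f"tier {tier_name!r} is empty")
        if len(members) < min_patients:
            warnings.warn(
                f"tier {tier_name!r} has {len(members)} patients (<{min_patients}); skipped",
                stacklevel=2,
            )
            continue
        sub = matrix.loc[members]
        filtered, removed = zero_variance_filter(sub, scope=None)
        table = spearman_screen(filtered, clinical.loc[members], params=params)
        out[tier_name] = {"table": table, "removed": removed, "n": len(members)}
    return out


def patient_scale(matrix: pd.DataFrame):
    """Row z-score: per patient, subtract the row mean and divide by the
    row SD (ddof=1).  Zero-SD rows become all zeros and are flagged."""
    if matrix.shape[1] < 2:
        raise ValueError("patient scaling needs at least 2 antigens")
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = sd.ravel() == 0
    sd[flat.reshape(-1, 1)] = 1.0
    scaled = (X - mean) / sd
    scaled[flat] = 0.0
    out = pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
    return out, tuple(matrix.index[flat])


@dataclass
class AntigenCorrelation:
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    excluded: tuple = ()


def antigen_correlation(scaled: pd.DataFrame) -> AntigenCorrelation:
    """Pairwise antigen Spearman correlation across patients.

    All-zero (flagged degenerate) antigen columns are excluded with a
    report; BH adjusts over the C(m, 2) unordered pairs.  The returned rho
    matrix is symmetric with unit diagonal.
    """
    if scaled.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    keep = scaled.columns[(scaled != 0).any(axis=0)]
    excluded = tuple(c for c in scaled.columns if c not in set(keep))
    X = scaled[keep]
    m = X.shape[1]
    if m < 2:
        raise ValueError("fewer than 2 non-degenerate antigens")
    if m == 2:
        r, pv = stats.spearmanr(X.iloc[:, 0], X.iloc[:, 1])
        rho = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, pv], [pv, 0.0]])
    else:
        rho, p = stats.spearmanr(X.to_numpy())
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    iu = np.triu_indices(m, 1)
    q_flat = bh_adjust(p[iu])
    q = np.ones_like(p)
    q[iu] = q_flat
    q.T[iu] = q_flat
    np.fill_diagonal(q, 0.0)
    cols = list(keep)
    return AntigenCorrelation(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        q=pd.DataFrame(q, index=cols, columns=cols),
        excluded=excluded,
    )


def cut_antigen_clusters(
    rho: pd.DataFrame,
    size_bounds=(3, 20),
    method: str = "complete",
) -> AntigenClusterSet:
    """Complete-linkage antigen clustering on correlation distance 1 - rho.

    The cut height is chosen among all distinct merge heights to maximize
    the number of clusters with size inside ``size_bounds`` (ties: fewest
    out-of-range clusters, then lowest height); out-of-range clusters are
    kept but flagged ineligible for network seeding.
    """
    m = rho.shape[0]
    if m < 3:
        raise ValueError("need at least 3 antigens to cluster")
    dist = 1.0 - rho.to_numpy(dtype=float)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    lo, hi = size_bounds
    best = None
    for h in np.unique(Z[:, 2]):
        labels = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labels)[1:]
        n_ok = int(((sizes >= lo) & (sizes <= hi)).sum())
        n_bad = int((sizes > 0).sum()) - n_ok
        key = (-n_ok, n_bad, h)
        if best is None or key < best[0]:
            best = (key, h, labels)
    _, cut_height, labels = best
    clusters = []
    for cid in np.unique(labels):
        members = tuple(rho.index[labels == cid])
        size = len(members)
        if size < lo:
            clusters.append(AntigenCluster(int(cid), members, False, f"size {size} < {lo}"))
        elif size > hi:
            clusters.append(AntigenCluster(int(cid), members, False, f"size {size} > {hi}"))
        else:
            clusters.append(AntigenCluster(int(cid), members, True))
    return AntigenClusterSet(
        clusters=clusters,
        cut_height=float(cut_height),
        linkage_matrix=Z,
        size_bounds=tuple(size_bounds),
    )
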