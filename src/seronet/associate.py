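"""Antigen-reactivity vs clinical-parameter screening.

Numeric parameters: Spearman rank correlation per (antigen, parameter) pair
with Benjamini-Hochberg control over the whole family.  Categorical
parameters: distance-based PERMANOVA of the full multivariate reactivity
profile with a permutation null, followed (for significant categories) by
per-antigen permutation Welch t-tests.

Clinical conventions: VFI is converted to VFI loss (100 - VFI) and the mean
deviation MD to |MD| so that larger values of every screened parameter mean
worse disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

#: numeric parameters screened by default (after the worse-is-larger transforms)
NUMERIC_PARAMS = (
    "age",
    "IOP",
    "CCT",
    "SE",
    "VA",
    "MD_abs",
    "MD_3_abs",
    "VFI_loss_diagnosis",
    "VFI_loss_3",
    "ROP",
    "CD",
    "OCT",
    "medications",
)

CATEGORICAL_PARAMS = (
    "sex",
    "diabetes",
    "hypertension",
    "migraine",
    "smoking",
    "SLT",
    "GPA",
)


@dataclass
class PermanovaResult:
    parameter: str
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict

    def __post_init__(self):
        if self.n_permutations > 0:
            assert self.p_value >= 1.0 / (self.n_permutations + 1)


def transform_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add worse-is-larger derived columns; originals are retained.

    ``VFI_loss_* = 100 - VFI`` and ``MD*_abs = |MD*|``.
    """
    out = clinical.copy()
    for src, dst in (("VFI Diagnosis", "VFI_loss_diagnosis"), ("VFI 3", "VFI_loss_3")):
        if src in out.columns:
            vfi = out[src].astype(float)
            if ((vfi < 0) | (vfi > 100)).any():
                raise ValueError(f"{src} outside [0, 100]")
            out[dst] = 100.0 - vfi
    for src, dst in (("MD", "MD_abs"), ("MD 3", "MD_3_abs")):
        if src in out.columns:
            out[dst] = out[src].astype(float).abs()
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m * p_(j) / j, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def spearman_screen(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    params=None,
    family: str = "global",
) -> pd.DataFrame:
    """Spearman rho/p/q for every (antigen, numeric parameter) pair.

    Missing clinical values are dropped pairwise (``n_used`` recorded);
    constant inputs yield NA rho with q excluded from the BH family.
    ``family='global'`` adjusts over all pairs at once, ``'per_parameter'``
    within each clinical parameter.
    """
    if params is None:
        params = [p for p in NUMERIC_PARAMS if p in clinical.columns]
    common = matrix.index.intersection(clinical.index)
    X = matrix.loc[common]
    C = clinical.loc[common]
    rows = []
    for param in params:
        y = C[param].astype(float).to_numpy()
        for antigen in X.columns:
            x = X[antigen].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n_used = int(ok.sum())
            if n_used < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rows.append((antigen, param, np.nan, np.nan, n_used))
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            if abs(rho) >= 1.0:
                p = 0.0
            rows.append((antigen, param, float(rho), float(p), n_used))
    table = pd.DataFrame(rows, columns=["antigen", "parameter", "rho", "p", "n_used"])
    table["q"] = np.nan
    if family == "global":
        mask = table["p"].notna()
        if mask.any():
            table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    elif family == "per_parameter":
        for param in params:
            mask = (table["parameter"] == param) & table["p"].notna()
            if mask.any():
                table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    else:
        raise ValueError(f"unknown BH family {family!r}")
    return table[["antigen", "parameter", "rho", "p", "q", "n_used"]]


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from a squared-distance matrix and group codes.

    SS_total = sum_{i<j} d2_ij / N; SS_within = sum_g sum_{i<j in g} d2_ij / n_g.
    """
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        block = d2[np.ix_(idx, idx)]
        ss_within += block[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    matrix: pd.DataFrame,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
    metric: str = "euclidean",
    parameter: str = "",
    exact: bool = False,
) -> PermanovaResult:
    """Distance-based multivariate group test with a permutation null.

    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1) under uniform label
    permutation.  ``exact=True`` (two groups only) enumerates all distinct
    label partitions instead and reports p = k / n_partitions with the
    observed partition included.
    """
    labels = pd.Series(labels)
    if labels.isna().any():
        keep = ~labels.isna().to_numpy()
        matrix = matrix.iloc[keep]
        labels = labels[~labels.isna()]
    codes, uniques = pd.factorize(labels.to_numpy())
    n_groups = len(uniques)
    sizes = {str(u): int((codes == i).sum()) for i, u in enumerate(uniques)}
    if n_groups < 2 or min(sizes.values()) < 2:
        raise ValueError(f"need >=2 groups of >=2 members, got {sizes}")
    X = matrix.to_numpy(dtype=float)
    d2 = squareform(pdist(X, metric=metric) ** 2)
    f_obs = _pseudo_f(d2, codes, n_groups)
    if exact:
        if n_groups != 2:
            raise ValueError("exact enumeration implemented for two groups only")
        n = len(codes)
        n1 = int((codes == 0).sum())
        count = 0
        total = 0
        for members in combinations(range(n), n1):
            perm = np.ones(n, dtype=int)
            perm[list(members)] = 0
            total += 1
            if _pseudo_f(d2, perm, 2) >= f_obs:
                count += 1
        return PermanovaResult(parameter, float(f_obs), count / total, 0, sizes)
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(codes), n_groups) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(parameter, float(f_obs), p, n_perm, sizes)


def permanova_screen(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    params=None,
    n_perm: int = 1000,
    seed: int | None = None,
    metric: str = "euclidean",
    standardize: bool = True,
) -> pd.DataFrame:
    """PERMANOVA for each categorical clinical parameter (mirrors a results
    table with Parameter / Test statistic / P-value columns).

    ``standardize`` (default) z-scores antigen columns before computing
    distances: per-antigen variance stabilization leaves columns on
    incommensurable scales, and without standardization a handful of
    large-scale antigens dominate the multivariate distance.
    """
    if params is None:
        params = [p for p in CATEGORICAL_PARAMS if p in clinical.columns]
    common = matrix.index.intersection(clinical.index)
    work = matrix.loc[common]
    if standardize:
        sd = work.std(ddof=1).replace(0.0, 1.0)
        work = (work - work.mean()) / sd
    rows = []
    rng = np.random.default_rng(seed)
    for param in params:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = permanova(
            work,
            clinical.loc[common, param],
            n_perm=n_perm,
            seed=sub_seed,
            metric=metric,
            parameter=param,
        )
        rows.append((param, res.pseudo_f, res.p_value))
    out = pd.DataFrame(rows, columns=["parameter", "test_statistic", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def _welch_t(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = len(x1), len(x2)
    v1 = x1.var(ddof=1) if n1 > 1 else 0.0
    v2 = x2.var(ddof=1) if n2 > 1 else 0.0
    num = x1.mean() - x2.mean()
    den = np.sqrt(v1 / n1 + v2 / n2)
    if den == 0:
        return 0.0 if num == 0 else np.copysign(np.inf, num)
    return num / den


def permutation_t_test(
    values,
    labels,
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool = False,
) -> float:
    """Two-sided permutation p-value for a Welch t statistic (two groups).

    Sampled null: p = (#{|t_perm| >= |t_obs|} + 1) / (n_perm + 1).
    ``exact=True`` enumerates all distinct group splits (p = k / C(n, n1)).
    Degenerate zero-variance, equal-mean groups give t = 0.
    """
    x = np.asarray(values, dtype=float)
    codes, uniques = pd.factorize(np.asarray(labels))
    if len(uniques) != 2:
        raise ValueError("permutation t-test needs exactly two groups")
    n1 = int((codes == 0).sum())
    n2 = int((codes == 1).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 members")
    x_sorted = np.concatenate([x[codes == 0], x[codes == 1]])
    t_obs = abs(_welch_t(x_sorted[:n1], x_sorted[n1:]))
    n = n1 + n2
    if exact:
        count = 0
        total = 0
        idx_all = frozenset(range(n))
        for members in combinations(range(n), n1):
            rest = list(idx_all - set(members))
            total += 1
            if abs(_welch_t(x_sorted[list(members)], x_sorted[rest])) >= t_obs:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: permute values, first n1 columns form group 1
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    xp = x_sorted[perm_idx]
    g1, g2 = xp[:, :n1], xp[:, n1:]
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    num = g1.mean(axis=1) - g2.mean(axis=1)
    den = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.abs(num / den)
    t_perm[np.isnan(t_perm)] = 0.0  # 0/0 -> degenerate equal groups
    count = int((t_perm >= t_obs).sum())
    return (count + 1) / (n_perm + 1)


def permutation_t_screen(
    matrix: pd.DataFrame,
    labels,
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-antigen permutation Welch t-tests against a binary grouping,
    BH-adjusted across antigens."""
    labels = pd.Series(labels, index=matrix.index)
    rng = np.random.default_rng(seed)
    rows = []
    for antigen in matrix.columns:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p = permutation_t_test(
            matrix[antigen].to_numpy(), labels.to_numpy(), n_perm=n_perm, seed=sub_seed
        )
        rows.append((antigen, p))
    out = pd.DataFrame(rows, columns=["antigen", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
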