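"""Raw MFI plates to the analysis-ready patient x antigen matrix.

Pipeline: (1) background = mean + 1 SD of the pooled empty-well readings
across non-control analytes; (2) subtract, floor negatives at zero, add 1;
(3) join to the clinical table, excluding plate samples without clinical
rows; (4) robust spline normalization (RSN) against a virtual median
reference on the log2 scale; (5) per-antigen Box-Cox variance stabilization;
(6) optional zero-variance filtering within a patient scope.

RSN here fits, for each patient, a monotone map from the patient's log2
values onto the reference on a rank-invariant antigen subset (pool-adjacent-
violators followed by a monotone PCHIP spline through the fitted knots).
The map is anchored at (0, 0): a corrected value of exactly 1 marks
"at or below assay background" and is preserved as-is, so antigens that are
background-flat within a patient subset stay exactly constant there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

CONTROL_ROLES = frozenset(
    {"control_tag", "control_blank", "control_loading", "control_positive"}
)


@dataclass
class RawPlate:
    """Samples x analytes MFI with well and analyte roles.

    ``well_role`` is ``sample`` or ``empty`` per plate row; ``analyte_role``
    is ``antigen`` or one of the control roles per column.
    """

    mfi: pd.DataFrame
    well_role: pd.Series
    analyte_role: pd.Series

    def __post_init__(self):
        self.well_role = self.well_role.reindex(self.mfi.index)
        self.analyte_role = self.analyte_role.reindex(self.mfi.columns)
        if (self.mfi.to_numpy() < 0).any():
            raise ValueError("negative MFI values in plate")
        if not (self.well_role == "empty").any():
            raise ValueError("plate has no empty wells")
        if not (self.analyte_role == "antigen").any():
            raise ValueError("plate has no antigen analytes")

    @property
    def antigen_ids(self) -> pd.Index:
        return self.mfi.columns[self.analyte_role == "antigen"]

    @property
    def sample_ids(self) -> pd.Index:
        return self.mfi.index[self.well_role == "sample"]


@dataclass
class ExclusionReport:
    dropped_samples: tuple
    dropped_clinical: tuple

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_samples)


@dataclass
class NormalizedMatrix:
    """Final patients x antigens reactivity matrix with provenance."""

    values: pd.DataFrame
    lambdas: pd.Series
    offset: float = 0.0
    flagged_constant: tuple = ()
    exclusions: ExclusionReport | None = None
    steps: list = field(default_factory=list)
    #: background-corrected, clinically aligned matrix before between-sample
    #: normalization — the substrate for overall-reactivity stratification
    corrected: pd.DataFrame | None = None


def estimate_background(plate: RawPlate, per_analyte: bool = False):
    """Mean + 1 sample SD of empty-well MFI over non-control analytes.

    With ``per_analyte=True`` returns a per-antigen Series instead of the
    pooled scalar; a single pooled value yields SD = 0.
    """
    empty = plate.mfi.loc[plate.well_role == "empty", plate.antigen_ids]
    if empty.shape[0] == 0:
        raise ValueError("no empty wells: background cannot be estimated")
    if empty.shape[1] == 0:
        raise ValueError("all analytes are controls: background cannot be estimated")
    if per_analyte:
        mean = empty.mean(axis=0)
        sd = empty.std(axis=0, ddof=1).fillna(0.0) if empty.shape[0] > 1 else 0.0
        return mean + sd
    pooled = empty.to_numpy().ravel()
    sd = pooled.std(ddof=1) if pooled.size > 1 else 0.0
    return float(pooled.mean() + sd)


def subtract_and_floor(plate: RawPlate, background) -> pd.DataFrame:
    """``max(MFI - background, 0) + 1`` on sample wells x antigen analytes."""
    sub = plate.mfi.loc[plate.sample_ids, plate.antigen_ids].astype(float)
    corrected = (sub - background).clip(lower=0.0) + 1.0
    return corrected


def join_clinical(matrix: pd.DataFrame, clinical: pd.DataFrame):
    """Align the reactivity matrix to the clinical table.

    Retains the intersection of plate sample IDs and clinical patient IDs in
    clinical row order; returns the aligned matrix plus an exclusion report
    listing plate samples without clinical rows (the study's enrollment
    dropouts) and clinical rows without plate samples.
    """
    if matrix.index.has_duplicates or clinical.index.has_duplicates:
        raise ValueError("duplicate sample/patient identifiers")
    keep = clinical.index[clinical.index.isin(matrix.index)]
    if len(keep) == 0:
        raise ValueError("no overlap between plate samples and clinical patients")
    dropped_samples = tuple(matrix.index.difference(keep))
    dropped_clinical = tuple(clinical.index.difference(matrix.index))
    return matrix.loc[keep], ExclusionReport(dropped_samples, dropped_clinical)


def _pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators: nondecreasing least-squares fit."""
    means, weights, sizes = [], [], []
    for yi, wi in zip(y, w):
        means.append(yi)
        weights.append(wi)
        sizes.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, n2 = means.pop(), weights.pop(), sizes.pop()
            m1, w1, n1 = means.pop(), weights.pop(), sizes.pop()
            means.append((m1 * w1 + m2 * w2) / (w1 + w2))
            weights.append(w1 + w2)
            sizes.append(n1 + n2)
    out = np.empty_like(np.asarray(y, dtype=float))
    pos = 0
    for m, n in zip(means, sizes):
        out[pos : pos + n] = m
        pos += n
    return out


def _monotone_map(x: np.ndarray, y: np.ndarray, n_knots: int = 1):
    """Stiff robust monotone nondecreasing map fit to the cloud (x, y).

    The normalization offsets y - x are centred on their median and points
    far from it (differentially reactive antigens, not technical bias) are
    iteratively trimmed; the surviving cloud is summarized by ``n_knots``
    equal-count bin medians joined by a monotone (PAVA + PCHIP) curve with
    unit-slope linear extensions beyond the outer knots.  ``n_knots=1`` is
    the stiffest member of the family, a pure median-offset shift.  The
    curve must stay this stiff: with ~10^2 analytes a flexible fit chases
    noise and antigen-specific biology rather than sample-level bias.

    The assay floor is special-cased: an input of exactly 0 (log2 of a
    background-floored value) returns 0, and outputs are clipped at 0, so
    "no reactivity above background" is preserved by normalization.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    for _ in range(3):
        resid = ys - xs
        med = np.median(resid)
        mad = np.median(np.abs(resid - med))
        keep = np.abs(resid - med) <= max(2.0 * 1.4826 * mad, 1e-9)
        if keep.sum() < max(4, n_knots) or keep.all():
            break
        xs, ys = xs[keep], ys[keep]
    if n_knots == 1 or len(xs) <= n_knots:
        shift = np.median(ys - xs)

        def f_shift(q):
            q = np.asarray(q, dtype=float)
            out = np.maximum(q + shift, 0.0)
            return np.where(q == 0.0, 0.0, out)

        return f_shift
    edges = np.linspace(0, len(xs), n_knots + 1).astype(int)
    bx, by, bw = [], [], []
    for a, b in zip(edges, edges[1:]):
        if b > a:
            bx.append(np.median(xs[a:b]))
            by.append(np.median(ys[a:b]))
            bw.append(float(b - a))
    ux, inverse = np.unique(np.asarray(bx), return_inverse=True)
    w = np.asarray(bw)
    uy = np.bincount(inverse, weights=np.asarray(by) * w) / np.bincount(inverse, weights=w)
    uw = np.bincount(inverse, weights=w)
    fitted = _pava(uy, uw)
    if len(ux) == 1:
        shift = float(fitted[0] - ux[0])
        return _monotone_map(np.array([0.0, 1.0]), np.array([shift, 1 + shift]), n_knots=1)
    interp = PchipInterpolator(ux, fitted, extrapolate=False)
    x_lo, y_lo = ux[0], fitted[0]
    x_hi, y_hi = ux[-1], fitted[-1]

    def f(q):
        q = np.asarray(q, dtype=float)
        out = interp(np.clip(q, x_lo, x_hi))
        out = np.where(q > x_hi, y_hi + (q - x_hi), out)
        out = np.where(q < x_lo, y_lo + (q - x_lo), out)
        out = np.maximum(out, 0.0)
        return np.where(q == 0.0, 0.0, out)

    return f


def robust_spline_normalize(
    matrix: pd.DataFrame,
    mode: str = "rsn",
    selection: str = "trim",
    rank_window: float = 0.05,
    min_invariant: int = 8,
    n_knots: int = 1,
) -> pd.DataFrame:
    """Between-patient normalization on the log2 scale.

    ``mode='rsn'``: per patient, fit a stiff monotone map onto the virtual
    reference (per-antigen median across patients).  With
    ``selection='trim'`` (default) the fit uses all antigens with iterative
    median/MAD trimming of the normalization offsets, so the curve tracks
    the quiet (non-differentially-reactive) majority; ``selection='rank'``
    restricts the fit to the rank-invariant antigen set instead
    (within-patient rank within ``ceil(rank_window * m)`` of the reference
    rank, falling back to all antigens below ``min_invariant`` points).
    ``mode='quantile'`` substitutes full quantile normalization.
    Within-patient rank order is preserved in every variant.
    """
    values = matrix.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("normalization requires strictly positive values")
    n, m = values.shape
    if m < 8:
        raise ValueError("need at least 8 antigens to normalize")
    logx = np.log2(values)
    if mode == "quantile":
        target = np.sort(logx, axis=1).mean(axis=0)
        out = np.empty_like(logx)
        positions = np.arange(1, m + 1, dtype=float)
        for i in range(n):
            ranks = stats.rankdata(logx[i], method="average")
            out[i] = np.interp(ranks, positions, target)
        return pd.DataFrame(2.0 ** out, index=matrix.index, columns=matrix.columns)
    if mode != "rsn":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if selection not in ("trim", "rank"):
        raise ValueError(f"unknown selection {selection!r}")
    ref = np.median(logx, axis=0)
    ref_rank = stats.rankdata(ref, method="average")
    window = math.ceil(rank_window * m)
    out = np.empty_like(logx)
    for i in range(n):
        row = logx[i]
        if selection == "rank":
            invariant = np.abs(stats.rankdata(row, method="average") - ref_rank) <= window
            if invariant.sum() < min_invariant:
                invariant = np.ones(m, dtype=bool)
        else:
            invariant = np.ones(m, dtype=bool)
        f = _monotone_map(row[invariant], ref[invariant], n_knots=n_knots)
        out[i] = f(row)
    return pd.DataFrame(2.0 ** out, index=matrix.index, columns=matrix.columns)


def _boxcox_profile_llf(lam: float, x: np.ndarray, logx: np.ndarray) -> float:
    """Box-Cox profile log-likelihood (sigma^2 profiled out):
    (lam - 1) sum(ln x) - n/2 ln(var(y(lam)))."""
    n = x.size
    if abs(lam) < 1e-8:
        y = logx
    else:
        y = (np.power(x, lam) - 1.0) / lam
    var = y.var()
    if var <= 0 or not np.isfinite(var):
        return -np.inf
    return float((lam - 1.0) * logx.sum() - 0.5 * n * np.log(var))


def boxcox_lambda(x: np.ndarray, bounds=(-5.0, 5.0), tol: float = 1e-4) -> float:
    """Profile-likelihood Box-Cox lambda: coarse grid + bounded refinement."""
    x = np.asarray(x, dtype=float)
    logx = np.log(x)
    grid = np.linspace(bounds[0], bounds[1], 101)
    llf = np.array([_boxcox_profile_llf(l, x, logx) for l in grid])
    best = int(np.argmax(llf))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda l: -_boxcox_profile_llf(l, x, logx),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def _boxcox_apply(x: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-3:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def boxcox_transform(
    matrix: pd.DataFrame,
    per_antigen: bool = True,
    bounds=(-5.0, 5.0),
    tol: float = 1e-4,
) -> NormalizedMatrix:
    """Per-antigen Box-Cox variance stabilization.

    A global offset of ``1 - min`` is applied first if the matrix minimum is
    not strictly positive.  Constant antigen columns get lambda = 1 (flagged)
    since their profile likelihood is undefined.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    mmin = values.min()
    offset = float(1.0 - mmin) if mmin <= 0 else 0.0
    values = values + offset
    lambdas = pd.Series(index=matrix.columns, dtype=float)
    flagged = []
    out = np.empty_like(values)
    if per_antigen:
        for j, col in enumerate(matrix.columns):
            x = values[:, j]
            if np.ptp(x) < 1e-12:
                lam = 1.0
                flagged.append(col)
            else:
                lam = boxcox_lambda(x, bounds=bounds, tol=tol)
            if abs(lam) < 1e-3:
                lam = 0.0
            lambdas[col] = lam
            out[:, j] = _boxcox_apply(x, lam)
    else:
        lam = boxcox_lambda(values.ravel(), bounds=bounds, tol=tol)
        if abs(lam) < 1e-3:
            lam = 0.0
        lambdas[:] = lam
        out = _boxcox_apply(values, lam)
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
        lambdas=lambdas,
        offset=offset,
        flagged_constant=tuple(flagged),
        steps=["boxcox"],
    )


def zero_variance_filter(matrix: pd.DataFrame, scope=None, tol: float = 1e-12):
    """Drop antigen columns with (near-)zero variance within ``scope``.

    ``scope`` is an optional patient-id subset; returns the filtered matrix
    (all patients, surviving columns) and the list of removed antigens.
    """
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        raise ValueError("empty matrix")
    sub = matrix.loc[scope] if scope is not None else matrix
    variances = sub.var(axis=0, ddof=1).fillna(0.0)
    removed = list(matrix.columns[variances.to_numpy() < tol])
    if len(removed) == matrix.shape[1]:
        raise ValueError("zero-variance filter would remove every antigen")
    return matrix.drop(columns=removed), removed


def preprocess_pipeline(
    plate: RawPlate,
    clinical: pd.DataFrame,
    mode: str = "rsn",
    per_analyte_background: bool = False,
) -> NormalizedMatrix:
    """Background correction -> clinical join -> RSN -> Box-Cox."""
    background = estimate_background(plate, per_analyte=per_analyte_background)
    corrected = subtract_and_floor(plate, background)
    aligned, exclusions = join_clinical(corrected, clinical)
    normalized = robust_spline_normalize(aligned, mode=mode)
    result = boxcox_transform(normalized)
    result.exclusions = exclusions
    result.corrected = aligned
    bg_desc = "per-analyte" if per_analyte_background else f"{background:.6g}"
    result.steps = [
        f"background={bg_desc}",
        f"excluded={exclusions.n_dropped}",
        f"normalize={mode}",
        "boxcox",
    ]
    return result
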