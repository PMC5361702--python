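"""Sample normalization, QC-anchored drift correction and batch correction.

Two families of method are provided, mirroring common practice in
large-scale untargeted metabolomics:

* sample-based normalization for differing sample concentration — total
  sum, probabilistic quotient (PQN) and quantile normalization (VSN is a
  reserved name);
* peak-based correction of run-order drift and batch structure — QC-robust
  spline correction (QC-RSC), support-vector-regression (SVR) drift
  correction, and empirical-Bayes location/scale batch adjustment (ComBat).

Both drift corrections model the pooled-QC log intensity as a function of
injection order (per feature, per batch), subtract the fitted drift on the
log scale and re-anchor to the feature's QC median, so biological fold
changes are untouched.  After any correction, features whose QC
coefficient of variation exceeds a threshold (30% by default) can be
dropped with :func:`cv_filter`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .core_io import PeakTable, SampleMeta

__all__ = [
    "normalize_samples",
    "qcrsc_correct",
    "svr_correct",
    "combat_correct",
    "cv_filter",
    "compare_normalizations",
    "apply_normalization",
    "NormalizationComparison",
    "NORMALIZATION_METHODS",
]

NORMALIZATION_METHODS = ("none", "sum", "pqn", "quantile", "qcrsc", "svr", "combat", "vsn")


# ---------------------------------------------------------------------------
# sample-based normalization
# ---------------------------------------------------------------------------

def normalize_samples(pt: PeakTable, meta: SampleMeta | None = None, method: str = "pqn") -> PeakTable:
    """Sample-based normalization: ``sum``, ``pqn``, ``quantile`` (``vsn`` reserved).

    sum      : each sample divided by its observed total, rescaled by the
               median of all sample totals (so the output keeps intensity
               units).
    pqn      : reference spectrum = feature-wise median over QC samples
               (falling back to all samples when no QCs); each sample is
               divided by the median of its per-feature quotients against
               the reference.
    quantile : classic rank/mean substitution; ties receive the mean of the
               tied rank values.
    """
    if method == "vsn":
        raise NotImplementedError("VSN is a reserved method name and is not implemented")
    if method == "none":
        return pt.copy()
    if method not in ("sum", "pqn", "quantile"):
        raise ValueError(f"unknown sample normalization {method!r}")
    X = pt.values
    obs = pt.observed
    empty = ~obs.any(axis=0)
    if empty.any():
        raise ValueError(f"samples with no observed values: {list(pt.sample_ids[empty])}")

    if method == "sum":
        totals = np.nansum(np.where(obs, X, np.nan), axis=0)
        target = np.median(totals)
        out = X / totals[None, :] * target
    elif method == "pqn":
        if meta is not None:
            is_qc = meta.qc_mask(pt.sample_ids)
        else:
            is_qc = np.zeros(pt.n_samples, dtype=bool)
        ref_cols = np.where(is_qc)[0] if is_qc.any() else np.arange(pt.n_samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            reference = np.nanmedian(X[:, ref_cols], axis=1)
        usable = np.isfinite(reference) & (reference > 0)
        if not usable.any():
            raise ValueError("PQN reference spectrum is empty")
        quotients = X[usable] / reference[usable, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            factors = np.nanmedian(quotients, axis=0)
        if np.any(~np.isfinite(factors) | (factors <= 0)):
            raise ValueError("PQN dilution factor undefined for some sample")
        out = X / factors[None, :]
    else:  # quantile
        out = _quantile_normalize(X)
    return pt.with_values(out)


def _quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Rank/mean quantile normalization, NaN-aware.

    Complete samples get the classic sorted-mean substitution (average of
    the k-th order statistics across samples, mean-of-tied-ranks for ties).
    Samples with missing cells are mapped through interpolation of the
    reference distribution at their observed quantiles.
    """
    from scipy.stats import rankdata

    F, S = X.shape
    counts = np.sum(np.isfinite(X), axis=0)
    grid = np.linspace(0.0, 1.0, F)
    # reference distribution: average of per-sample sorted values on a common grid
    stack = np.empty((S, F))
    for j in range(S):
        v = np.sort(X[np.isfinite(X[:, j]), j])
        if v.size == F:
            stack[j] = v
        elif v.size == 1:
            stack[j] = v[0]
        else:
            q = np.linspace(0.0, 1.0, v.size)
            stack[j] = np.interp(grid, q, v)
    reference = stack.mean(axis=0)

    out = np.full_like(X, np.nan)
    for j in range(S):
        fin = np.isfinite(X[:, j])
        n = int(fin.sum())
        ranks = rankdata(X[fin, j], method="average")  # 1..n, ties averaged
        if n == F:
            # fractional ranks interpolate between adjacent sorted means =
            # mean of tied rank values
            out[fin, j] = np.interp(ranks, np.arange(1, F + 1), reference)
        else:
            q = (ranks - 1.0) / max(n - 1, 1)
            out[fin, j] = np.interp(q, grid, reference)
    return out


# ---------------------------------------------------------------------------
# QC-anchored drift correction
# ---------------------------------------------------------------------------

def _check_positive_observed(pt: PeakTable) -> None:
    if np.any(pt.values[pt.observed] <= 0):
        raise ValueError("drift correction requires positive intensities (zeros should be missing)")


def _fit_drift_curve(x: np.ndarray, y: np.ndarray, lam: float):
    """Cubic smoothing spline; degrades to a straight line below 5 points
    (the most a handful of QC injections can support)."""
    if x.size >= 5:
        return make_smoothing_spline(x, y, lam=lam)
    coeff = np.polyfit(x, y, 1)
    return np.poly1d(coeff)


def _loocv_spline(x: np.ndarray, y: np.ndarray, lam_grid: np.ndarray):
    """Pick the smoothing-spline penalty by leave-one-out CV; ties -> smoother."""
    best_lam = lam_grid[0]
    best_err = np.inf
    for lam in lam_grid:
        err = 0.0
        ok = True
        for i in range(x.size):
            xi = np.delete(x, i)
            yi = np.delete(y, i)
            try:
                f = _fit_drift_curve(xi, yi, lam=lam)
            except Exception:
                ok = False
                break
            err += float(y[i] - f(x[i])) ** 2
        if not ok:
            continue
        # strict improvement required: on ties keep the larger (smoother) lam,
        # grid is scanned from smooth to wiggly
        if err < best_err - 1e-12 * max(1.0, best_err):
            best_err = err
            best_lam = lam
    return _fit_drift_curve(x, y, lam=best_lam), best_lam


def qcrsc_correct(pt: PeakTable, meta: SampleMeta, min_qc: int = 4, n_lambda: int = 20) -> PeakTable:
    """QC-robust spline correction of injection-order signal drift.

    Per feature and per batch, a cubic smoothing spline is fitted to the
    log intensities of the QC samples versus injection order, with the
    smoothing penalty chosen by leave-one-out cross validation over a
    log-spaced grid (ties resolved toward the smoother fit).  The fitted
    drift (clamped to the QC order range) is subtracted on the log scale
    and the feature is re-anchored to its overall QC median:
    ``corrected = exp(log x − fit(order) + median(log QC))``.

    Batches with fewer than ``min_qc`` usable QC points fall back to
    QC-median scaling.  Missing cells stay missing.
    """
    is_qc = meta.qc_mask(pt.sample_ids)
    if not is_qc.any():
        raise ValueError("QC-RSC needs QC samples; use sum/pqn/quantile normalization instead")
    _check_positive_observed(pt)
    order = meta.orders(pt.sample_ids).astype(float)
    batches = meta.batches(pt.sample_ids)
    L = np.where(pt.observed, np.log(pt.values), np.nan)
    out = np.full_like(L, np.nan)
    # grid scanned smoothest-first so CV ties keep the smoother fit
    lam_grid = np.logspace(6, -2, n_lambda)
    n_fallback = 0
    for b in pd.unique(batches):
        cols = np.where(batches == b)[0]
        qc_cols = cols[is_qc[cols]]
        for i in range(pt.n_features):
            row = L[i, cols]
            fin = np.isfinite(row)
            if not fin.any():
                continue
            qy = L[i, qc_cols]
            qfin = np.isfinite(qy)
            anchor = np.nanmedian(L[i, is_qc]) if np.isfinite(L[i, is_qc]).any() else np.nan
            if qfin.sum() < min_qc or not np.isfinite(anchor):
                n_fallback += 1
                batch_med = np.nanmedian(qy) if qfin.any() else np.nanmedian(row)
                out[i, cols] = row - batch_med + (anchor if np.isfinite(anchor) else batch_med)
                continue
            qx = order[qc_cols][qfin]
            qv = qy[qfin]
            srt = np.argsort(qx)
            qx, qv = qx[srt], qv[srt]
            if np.ptp(qv) < 1e-12:  # flat QC signal: no drift to remove
                out[i, cols] = row - qv.mean() + anchor
                continue
            spline, _ = _loocv_spline(qx, qv, lam_grid)
            fit = spline(np.clip(order[cols], qx[0], qx[-1]))
            out[i, cols] = row - fit + anchor
    if n_fallback:
        warnings.warn(f"QC-median fallback used for {n_fallback} feature/batch fits (QC count < {min_qc})")
    values = np.where(pt.observed, np.exp(out), np.nan)
    return pt.with_values(values)


def svr_correct(
    pt: PeakTable,
    meta: SampleMeta,
    kernel_width: float | None = None,
    epsilon: float = 0.1,
    C: float = 1.0,
    min_qc: int = 4,
) -> PeakTable:
    """Support-vector-regression drift correction (RBF kernel).

    Per feature and per batch an RBF SVR of QC log intensity on injection
    order is trained; the prediction (clamped to the QC order range) is
    subtracted on the log scale and the feature re-anchored to its QC
    median.  ``kernel_width`` defaults to half the QC order span, entering
    the kernel as gamma = 1/(2·width²).  Features whose QC signal is
    constant are returned unchanged (no drift to remove); batches with too
    few QCs fall back to QC-median scaling.
    """
    from sklearn.svm import SVR

    is_qc = meta.qc_mask(pt.sample_ids)
    if not is_qc.any():
        raise ValueError("SVR correction needs QC samples; use sum/pqn/quantile normalization instead")
    _check_positive_observed(pt)
    order = meta.orders(pt.sample_ids).astype(float)
    batches = meta.batches(pt.sample_ids)
    L = np.where(pt.observed, np.log(pt.values), np.nan)
    out = np.full_like(L, np.nan)
    n_fallback = 0
    for b in pd.unique(batches):
        cols = np.where(batches == b)[0]
        qc_cols = cols[is_qc[cols]]
        for i in range(pt.n_features):
            row = L[i, cols]
            if not np.isfinite(row).any():
                continue
            qy = L[i, qc_cols]
            qfin = np.isfinite(qy)
            anchor = np.nanmedian(L[i, is_qc]) if np.isfinite(L[i, is_qc]).any() else np.nan
            if qfin.sum() < min_qc or not np.isfinite(anchor):
                n_fallback += 1
                batch_med = np.nanmedian(qy) if qfin.any() else np.nanmedian(row)
                out[i, cols] = row - batch_med + (anchor if np.isfinite(anchor) else batch_med)
                continue
            qx = order[qc_cols][qfin]
            qv = qy[qfin]
            if np.ptp(qv) < 1e-12:
                out[i, cols] = row - qv.mean() + anchor
                continue
            width = kernel_width if kernel_width is not None else max(np.ptp(qx) / 2.0, 1.0)
            gamma = 1.0 / (2.0 * width**2)
            model = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
            model.fit(qx[:, None], qv)
            fit = model.predict(np.clip(order[cols], qx.min(), qx.max())[:, None])
            out[i, cols] = row - fit + anchor
    if n_fallback:
        warnings.warn(f"QC-median fallback used for {n_fallback} feature/batch fits (QC count < {min_qc})")
    values = np.where(pt.observed, np.exp(out), np.nan)
    return pt.with_values(values)


# ---------------------------------------------------------------------------
# ComBat empirical-Bayes batch correction
# ---------------------------------------------------------------------------

def combat_correct(pt: PeakTable, meta: SampleMeta, parametric: bool = True, max_iter: int = 100) -> PeakTable:
    """Empirical-Bayes location/scale batch adjustment on the log scale.

    Each feature is standardized against its grand mean and pooled
    variance; per-batch location (gamma) and scale (delta²) parameters are
    estimated and shrunk toward parametric priors (normal for gamma,
    inverse-gamma for delta²) by the standard iterative posterior update,
    then removed.  A single batch is returned unchanged with a warning.
    Only the parametric prior family is implemented.
    """
    if not parametric:
        raise NotImplementedError("only the parametric ComBat priors are implemented")
    batches = meta.batches(pt.sample_ids)
    labels = pd.unique(batches)
    if len(labels) < 2:
        warnings.warn("single batch: ComBat returns the input unchanged")
        return pt.copy()
    _check_positive_observed(pt)
    obs = pt.observed
    for b in labels:
        cols = batches == b
        if cols.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        if (~obs[:, cols]).all(axis=1).any():
            raise ValueError(f"some feature entirely missing within batch {b!r}")

    L = np.where(obs, np.log(pt.values), np.nan)
    F = pt.n_features
    B = len(labels)
    cols_of = {b: np.where(batches == b)[0] for b in labels}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        batch_mean = np.stack([np.nanmean(L[:, cols_of[b]], axis=1) for b in labels], axis=1)  # F x B
        n_obs = np.stack([np.isfinite(L[:, cols_of[b]]).sum(axis=1) for b in labels], axis=1).astype(float)
        n_tot = n_obs.sum(axis=1)
        grand = (batch_mean * n_obs).sum(axis=1) / n_tot
        fitted = np.empty_like(L)
        for k, b in enumerate(labels):
            fitted[:, cols_of[b]] = batch_mean[:, [k]]
        pooled_var = np.nansum((L - fitted) ** 2, axis=1) / n_tot
    pooled_var = np.maximum(pooled_var, 1e-12)
    sd = np.sqrt(pooled_var)

    Z = (L - grand[:, None]) / sd[:, None]

    adjusted = Z.copy()
    for k, b in enumerate(labels):
        cols = cols_of[b]
        Zb = Z[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            gamma_hat = np.nanmean(Zb, axis=1)
            delta_hat = np.nanvar(Zb, axis=1, ddof=1)
        delta_hat = np.where(np.isfinite(delta_hat) & (delta_hat > 0), delta_hat, 1e-8)
        # parametric priors across features
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1) if F > 1 else 1.0
        tau2 = max(tau2, 1e-12)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1) if F > 1 else 1.0
        s2 = max(s2, 1e-12)
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        nb = np.isfinite(Zb).sum(axis=1).astype(float)

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (nb * tau2 + delta_star)
            ssq = np.nansum((Zb - g_new[:, None]) ** 2, axis=1)
            d_new = (0.5 * ssq + b_prior) / (nb / 2.0 + a_prior - 1.0)
            change = max(
                np.max(np.abs(g_new - gamma_star) / np.maximum(np.abs(gamma_star), 1e-8)),
                np.max(np.abs(d_new - delta_star) / np.maximum(np.abs(delta_star), 1e-8)),
            )
            gamma_star, delta_star = g_new, d_new
            if change < 1e-4:
                break
        adjusted[:, cols] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    corrected = adjusted * sd[:, None] + grand[:, None]
    values = np.where(obs, np.exp(corrected), np.nan)
    return pt.with_values(values)


# ---------------------------------------------------------------------------
# QC CV filtering and method comparison
# ---------------------------------------------------------------------------

def _qc_cv(pt: PeakTable, is_qc: np.ndarray) -> np.ndarray:
    """Per-feature CV (sd/mean, n-1) over observed QC intensities."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        Q = pt.values[:, is_qc]
        mean = np.nanmean(Q, axis=1)
        sd = np.nanstd(Q, axis=1, ddof=1)
        return np.where(mean != 0, sd / mean, np.nan)


def cv_filter(pt: PeakTable, meta: SampleMeta, cv_max: float = 0.30) -> PeakTable:
    """Drop features whose QC coefficient of variation exceeds ``cv_max``."""
    is_qc = meta.qc_mask(pt.sample_ids)
    if not is_qc.any():
        raise ValueError("CV filtering needs QC samples")
    cv = _qc_cv(pt, is_qc)
    keep = np.where(~(cv > cv_max))[0]  # NaN CV (undefined) is kept
    return pt.select_features(keep)


def apply_normalization(pt: PeakTable, meta: SampleMeta, method: str) -> PeakTable:
    """Dispatch a normalization/correction method by name."""
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(NORMALIZATION_METHODS)}")
    if method == "none":
        return pt.copy()
    if method in ("sum", "pqn", "quantile", "vsn"):
        return normalize_samples(pt, meta, method=method)
    if method == "qcrsc":
        return qcrsc_correct(pt, meta)
    if method == "svr":
        return svr_correct(pt, meta)
    return combat_correct(pt, meta)


@dataclasses.dataclass
class NormalizationComparison:
    """Per-method comparison metrics (peak counts, QC-CV retention, DEF)."""

    table: pd.DataFrame  # method, n_peaks, n_peaks_cv_le, n_def, mean_cv_<group>...


def compare_normalizations(
    pt: PeakTable,
    meta: SampleMeta,
    methods: list[str],
    def_q: float = 0.05,
    def_fc: float = 1.5,
    def_vip: float = 1.0,
    cv_max: float = 0.30,
    seed: int = 0,
) -> NormalizationComparison:
    """Compare normalization methods on CV retention and DEF counts.

    For each method (a "none" baseline is always included) the table
    reports: total peak count, peaks with QC CV <= ``cv_max``, mean CV per
    group, and the number of differentially expressed features (DEF):
    q <= ``def_q`` (Mann-Whitney + BH) AND fold change >= ``def_fc`` or
    <= 1/``def_fc`` AND VIP >= ``def_vip`` from a two-component PLS-DA on
    glog + Pareto processed data.
    """
    from . import preprocess, stats as mstats

    groups = meta.groups()
    if len(groups) != 2:
        raise ValueError(f"DEF counting needs exactly two non-QC groups, found {groups}")
    case, control = groups
    is_qc = meta.qc_mask(pt.sample_ids)
    wanted = list(dict.fromkeys(["none"] + list(methods)))
    bad = [m for m in wanted if m not in NORMALIZATION_METHODS]
    if bad:
        raise ValueError(f"unknown methods {bad}; valid: {', '.join(NORMALIZATION_METHODS)}")

    rows = []
    for method in wanted:
        npt = apply_normalization(pt, meta, method)
        cv_qc = _qc_cv(npt, is_qc)
        row = {
            "method": method,
            "n_peaks": npt.n_features,
            "n_peaks_cv_le": int(np.sum(cv_qc <= cv_max)),
        }
        klass = meta.classes(npt.sample_ids)
        for g in (case, control):
            cols = np.array([k == g for k in klass], dtype=bool)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                V = npt.values[:, cols]
                cv_g = np.nanstd(V, axis=1, ddof=1) / np.nanmean(V, axis=1)
            row[f"mean_cv_{g}"] = float(np.nanmean(cv_g))
        row["mean_cv_qc"] = float(np.nanmean(cv_qc))

        imputed = preprocess.impute_missing(npt, method="min_half") if npt.mask.any() else npt
        res = mstats.univariate_tests(imputed, meta, case=case, control=control, seed=seed)
        selected = mstats.select_def(res, q_max=def_q, fc_min=def_fc, vip_min=def_vip, test="wilcox")
        row["n_def"] = len(selected)
        rows.append(row)
    return NormalizationComparison(pd.DataFrame(rows))
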