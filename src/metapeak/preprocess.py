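"""Feature filtering, missing-value imputation, transformation/scaling and
PCA-based outlier removal.

Filtering follows the detection-rate rule: a feature must be seen in at
least half of the pooled-QC injections and at least 20% of the biological
samples (both thresholds configurable, strict-inequality removal).
Imputation offers k-nearest-neighbour (across features), iterative
low-rank SVD reconstruction, missForest-style random-forest regression and
the simple half-minimum substitution; Bayesian-PCA imputation is a
reserved method name.  Outlier removal iteratively fits a two-component
PCA and drops samples outside the Hotelling T² confidence ellipse.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sps

from .core_io import PeakTable, SampleMeta

__all__ = [
    "filter_features",
    "impute_missing",
    "transform_intensities",
    "scale_features",
    "remove_outliers",
    "OutlierResult",
]


def filter_features(
    pt: PeakTable,
    meta: SampleMeta,
    qc_frac: float = 0.5,
    sample_frac: float = 0.2,
) -> PeakTable:
    """Drop features under-detected in QCs or in biological samples.

    A feature is removed iff its detected fraction among QC samples is
    strictly below ``qc_frac`` OR its detected fraction among non-QC
    samples is strictly below ``sample_frac``.  With no QC samples only
    the biological-sample rule applies.
    """
    for name, f in (("qc_frac", qc_frac), ("sample_frac", sample_frac)):
        if not 0 < f <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    is_qc = meta.qc_mask(pt.sample_ids)
    obs = pt.observed
    keep = np.ones(pt.n_features, dtype=bool)
    if is_qc.any():
        qc_rate = obs[:, is_qc].mean(axis=1)
        keep &= qc_rate >= qc_frac
    if (~is_qc).any():
        bio_rate = obs[:, ~is_qc].mean(axis=1)
        keep &= bio_rate >= sample_frac
    if not keep.any():
        warnings.warn("all features removed by detection-rate filter")
    return pt.select_features(np.where(keep)[0])


def impute_missing(
    pt: PeakTable,
    method: str = "knn",
    k: int = 10,
    rank: int = 3,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PeakTable:
    """Fill missing cells; observed cells are never altered.

    methods
    -------
    ``knn``  : each missing cell is the mean over the k nearest features
               (Euclidean distance over co-observed samples) of their value
               in that sample.
    ``svd``  : iterative rank-``rank`` SVD reconstruction, run to relative
               change < ``tol`` (max ``max_iter`` sweeps).
    ``rf``   : missForest-style iterative random-forest regression per
               feature, stopped when the imputed values stop improving.
    ``min_half`` : half the feature's observed minimum.
    ``bpca`` : reserved name, raises NotImplementedError.
    """
    if method == "bpca":
        raise NotImplementedError("BPCA imputation is a reserved method name and is not implemented")
    if method not in ("knn", "svd", "rf", "min_half"):
        raise ValueError(f"unknown imputation method {method!r}")
    dead = np.where(pt.mask.all(axis=1))[0]
    if dead.size:
        raise ValueError(f"features fully missing, cannot impute: {list(pt.feature_ids[dead])}")
    if not pt.mask.any():
        return pt.copy()

    X = pt.values.copy()  # NaN at missing cells
    if method == "min_half":
        fill = np.nanmin(X, axis=1) / 2.0
        out = X.copy()
        for i in range(X.shape[0]):
            out[i, np.isnan(out[i])] = fill[i]
    elif method == "knn":
        from sklearn.impute import KNNImputer

        imputer = KNNImputer(n_neighbors=min(k, X.shape[0] - 1), weights="uniform")
        # features as rows: neighbours are features, imputation is per sample column
        out = imputer.fit_transform(X)
        if out.shape != X.shape:  # KNNImputer drops all-NaN columns; guarded above per feature
            raise ValueError("imputation dropped samples with no observed values")
    elif method == "svd":
        out = _svd_impute(X, rank=rank, max_iter=max_iter, tol=tol)
    else:  # rf
        out = _rf_impute(X, seed=seed)

    return pt.with_values(out, mask=np.zeros_like(pt.mask))


def _svd_impute(X: np.ndarray, rank: int, max_iter: int, tol: float) -> np.ndarray:
    miss = np.isnan(X)
    filled = X.copy()
    row_means = np.nanmean(X, axis=1)
    for i in range(X.shape[0]):
        filled[i, miss[i]] = row_means[i]
    rank = min(rank, min(X.shape) - 1) if min(X.shape) > 1 else 1
    prev = filled[miss].copy()
    for _ in range(max_iter):
        center = filled.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(filled - center, full_matrices=False)
        recon = center + (U[:, :rank] * s[:rank]) @ Vt[:rank]
        filled[miss] = recon[miss]
        cur = filled[miss]
        denom = np.linalg.norm(prev) or 1.0
        if np.linalg.norm(cur - prev) / denom < tol:
            break
        prev = cur.copy()
    return filled


def _rf_impute(X: np.ndarray, seed: int, n_estimators: int = 100, max_sweeps: int = 10) -> np.ndarray:
    from sklearn.ensemble import RandomForestRegressor

    miss = np.isnan(X)
    filled = X.copy()
    row_means = np.nanmean(X, axis=1)
    for i in range(X.shape[0]):
        filled[i, miss[i]] = row_means[i]
    # features with missing values, least-missing first (missForest ordering)
    targets = np.where(miss.any(axis=1))[0]
    targets = targets[np.argsort(miss[targets].sum(axis=1), kind="mergesort")]
    prev_delta = np.inf
    best = filled.copy()
    for sweep in range(max_sweeps):
        before = filled[miss].copy()
        for t, i in enumerate(targets):
            obs_cols = ~miss[i]
            predictors = np.delete(filled, i, axis=0).T  # samples x other features
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=seed + 1009 * sweep + t,
                n_jobs=1,
            )
            rf.fit(predictors[obs_cols], filled[i, obs_cols])
            filled[i, miss[i]] = rf.predict(predictors[miss[i]])
        delta = float(np.sum((filled[miss] - before) ** 2) / (np.sum(filled[miss] ** 2) or 1.0))
        if delta >= prev_delta:  # stopped improving: keep previous sweep
            return best
        best = filled.copy()
        prev_delta = delta
    return best


def transform_intensities(
    pt: PeakTable,
    method: str = "glog",
    base: float = 2.0,
    lam: float | None = None,
    offset: float = 0.0,
) -> PeakTable:
    """Variance-stabilising elementwise transforms.

    ``log``       : log_base(x + offset); requires all observed values > 0
                    after the offset.
    ``glog``      : log_base((x + sqrt(x^2 + lam)) / 2); ``lam`` defaults to
                    the square of the smallest positive observed intensity.
    ``cube_root`` : sign-preserving |x|^(1/3) * sign(x).
    """
    X = pt.values.copy()
    obs = pt.observed
    if method == "log":
        shifted = X + offset
        if np.any(shifted[obs] <= 0):
            raise ValueError("log transform requires positive values; configure an offset")
        out = np.log(shifted) / np.log(base)
    elif method == "glog":
        if lam is None:
            positive = X[obs & (X > 0)]
            if positive.size == 0:
                raise ValueError("glog auto-lambda needs at least one positive intensity")
            lam = float(positive.min()) ** 2
        out = np.log((X + np.sqrt(X**2 + lam)) / 2.0) / np.log(base)
    elif method == "cube_root":
        out = np.cbrt(X)
    else:
        raise ValueError(f"unknown transform {method!r}")
    return pt.with_values(out)


def scale_features(pt: PeakTable, method: str = "pareto", on_zero: str = "drop") -> PeakTable:
    """Per-feature scaling: auto, pareto, range, vast, level, center, none.

    With mean m, sample sd s (n-1) and range r per feature:
    auto=(x-m)/s, pareto=(x-m)/sqrt(s), range=(x-m)/r, vast=((x-m)/s)*(m/s),
    level=(x-m)/m, center=x-m.  Features whose required divisor is zero are
    dropped with a warning (``on_zero="error"`` raises instead).
    """
    if method == "none":
        return pt.copy()
    if method not in ("auto", "pareto", "range", "vast", "level", "center"):
        raise ValueError(f"unknown scaling method {method!r}")
    X = pt.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(X, axis=1)
        s = np.nanstd(X, axis=1, ddof=1)
        r = np.nanmax(X, axis=1) - np.nanmin(X, axis=1)

    if method in ("auto", "vast"):
        divisor_ok = s > 0
    elif method == "pareto":
        divisor_ok = s > 0
    elif method == "range":
        divisor_ok = r > 0
    elif method == "level":
        divisor_ok = m != 0
    else:  # center
        divisor_ok = np.ones(pt.n_features, dtype=bool)

    if not divisor_ok.all():
        bad = list(pt.feature_ids[~divisor_ok])
        if on_zero == "error":
            raise ValueError(f"zero divisor in {method} scaling for features: {bad}")
        warnings.warn(f"dropping {len(bad)} features with zero divisor in {method} scaling")
    idx = np.where(divisor_ok)[0]
    X = X[idx]
    m, s, r = m[idx], s[idx], r[idx]
    centered = X - m[:, None]
    if method == "auto":
        out = centered / s[:, None]
    elif method == "pareto":
        out = centered / np.sqrt(s)[:, None]
    elif method == "range":
        out = centered / r[:, None]
    elif method == "vast":
        out = centered / s[:, None] * (m / s)[:, None]
    elif method == "level":
        out = centered / m[:, None]
    else:
        out = centered
    sub = pt.select_features(idx)
    return sub.with_values(out)


@dataclasses.dataclass
class OutlierResult:
    """Record of iterative Hotelling-T² outlier removal."""

    removed_samples: list[tuple[int, str, float]]  # (round, sample id, T²)
    rounds_run: int
    final_table: PeakTable


def remove_outliers(
    pt: PeakTable,
    meta: SampleMeta | None = None,
    max_rounds: int = 3,
    conf: float = 0.95,
    expand: float = 1.0,
) -> OutlierResult:
    """Iteratively remove samples outside the 2-component PCA T² ellipse.

    Each round fits a two-component PCA on the (complete) intensity matrix;
    sample i is outlying iff T²_i = t_i1²/s1² + t_i2²/s2² exceeds
    ``expand² · 2(n−1)/(n−2) · F(conf; 2, n−2)`` where s_k² is the score
    variance of component k.  Removal stops early on a clean round, after
    ``max_rounds`` rounds, or when fewer than 4 samples would remain.
    """
    if pt.mask.any():
        raise ValueError("outlier removal requires a complete matrix; impute first")
    if pt.n_samples < 4:
        raise ValueError("outlier removal needs at least 4 samples")
    current = pt.copy()
    removed: list[tuple[int, str, float]] = []
    rounds = 0
    for rnd in range(1, max_rounds + 1):
        n = current.n_samples
        if n < 4:
            warnings.warn("fewer than 4 samples remain; stopping outlier removal")
            break
        rounds = rnd
        X = current.values.T  # samples x features
        Xc = X - X.mean(axis=0)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        scores = U[:, :2] * s[:2]
        var = scores.var(axis=0, ddof=1)
        var[var == 0] = np.inf  # degenerate direction cannot flag anyone
        t2 = (scores**2 / var).sum(axis=1)
        limit = expand**2 * 2.0 * (n - 1) / (n - 2) * sps.f.ppf(conf, 2, n - 2)
        out = np.where(t2 > limit)[0]
        if out.size == 0:
            break
        keep = np.setdiff1d(np.arange(n), out)
        if keep.size < 4:
            warnings.warn("removal would leave fewer than 4 samples; stopping")
            break
        for i in out:
            removed.append((rnd, str(current.sample_ids[i]), float(t2[i])))
        current = current.select_samples(keep)
    return OutlierResult(removed_samples=removed, rounds_run=rounds, final_table=current)
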