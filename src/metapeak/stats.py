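"""Univariate and multivariate statistics for two-group peak tables.

Univariate: Welch (or pooled) t-test and Mann-Whitney U per feature,
Benjamini-Hochberg q-values, case/control fold change and the univariate
ROC AUC; the DEF rule (q <= 0.05, fold change >= 1.5 or <= 1/1.5, VIP >= 1)
selects differentially expressed features.

Multivariate: PCA by SVD; PLS-DA and OPLS-DA fitted with the NIPALS
deflation scheme on a -1/+1 dummy response, reporting R²Y (fitted), Q²Y
(stratified k-fold cross-validated) and VIP scores, with model validity
assessed by a label-permutation test on Q²Y.

Power: a simplified pilot-data surrogate — estimate the null fraction pi0,
convert the apparent non-null t statistics to standardized effect sizes
and average noncentral-t power over them for each candidate group size.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import PeakTable, SampleMeta

__all__ = [
    "bh_adjust",
    "univariate_tests",
    "univariate_auc",
    "pca_fit",
    "plsda_fit",
    "oplsda_fit",
    "permutation_test",
    "select_def",
    "estimate_power",
    "UnivariateResult",
    "MultivariateModel",
    "PowerCurve",
]


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j>=i} p_(j) * m / j over the sorted p-values, mapped back
    to input order.  NaN entries (untestable features) stay NaN and do not
    count toward m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    fin = np.isfinite(p)
    pf = p[fin]
    if ((pf < 0) | (pf > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    buf = np.empty(m)
    buf[order] = q
    out[fin] = buf
    return out


def univariate_auc(scores_case, scores_control) -> float:
    """ROC AUC of case vs control scores: U-statistic / (n1*n2), ties ½."""
    a = np.asarray(scores_case, dtype=float)
    b = np.asarray(scores_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


@dataclasses.dataclass
class UnivariateResult:
    """Per-feature two-group test results (QC samples excluded)."""

    table: pd.DataFrame  # feature, p_t, p_wilcox, q_t, q_wilcox, fold_change, auc, vip
    case: str
    control: str


def univariate_tests(
    pt: PeakTable,
    meta: SampleMeta,
    case: str,
    control: str,
    welch: bool = True,
    compute_vip: bool = True,
    n_components: int = 2,
    seed: int = 0,
) -> UnivariateResult:
    """Welch/pooled t-test, Mann-Whitney U, BH q, fold change and AUC per feature.

    QC samples are removed before testing.  A feature needs >= 2 observed
    values in each group to be testable; untestable features carry NaN.
    Fold change is mean(case)/mean(control) on the (normalized, raw-scale)
    intensities.  When ``compute_vip`` is on, VIP scores come from a
    two-component PLS-DA fitted on glog + Pareto processed data.
    """
    klass = meta.classes(pt.sample_ids)
    for g in (case, control):
        if g not in set(k for k in klass if k is not None):
            raise ValueError(f"group {g!r} not present in sample list")
    ia = np.array([k == case for k in klass], dtype=bool)
    ib = np.array([k == control for k in klass], dtype=bool)
    X = pt.values

    F = pt.n_features
    p_t = np.full(F, np.nan)
    p_w = np.full(F, np.nan)
    fc = np.full(F, np.nan)
    auc = np.full(F, np.nan)
    for i in range(F):
        a = X[i, ia]
        b = X[i, ib]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            continue
        fc[i] = a.mean() / b.mean() if b.mean() != 0 else np.nan
        auc[i] = univariate_auc(a, b)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            p_t[i] = 1.0
            p_w[i] = 1.0
            continue
        t_res = sps.ttest_ind(a, b, equal_var=not welch)
        p_t[i] = float(t_res.pvalue)
        method = "exact" if (a.size + b.size <= 12 and np.unique(np.concatenate([a, b])).size == a.size + b.size) else "asymptotic"
        w_res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        p_w[i] = float(w_res.pvalue)

    vip = np.full(F, np.nan)
    if compute_vip:
        vip = _default_vip(pt, meta, case, control, n_components=n_components, seed=seed)

    table = pd.DataFrame(
        {
            "feature": pt.feature_ids,
            "p_t": p_t,
            "p_wilcox": p_w,
            "q_t": bh_adjust(p_t),
            "q_wilcox": bh_adjust(p_w),
            "fold_change": fc,
            "auc": auc,
            "vip": vip,
        }
    )
    return UnivariateResult(table=table, case=case, control=control)


def _default_vip(pt, meta, case, control, n_components=2, seed=0) -> np.ndarray:
    """VIP from a 2-component PLS-DA on glog + Pareto processed intensities."""
    from . import preprocess

    work = pt
    if work.mask.any():
        work = preprocess.impute_missing(work, method="min_half")
    work = preprocess.transform_intensities(work, method="glog")
    work = preprocess.scale_features(work, method="pareto")
    if work.n_features == 0:
        return np.full(pt.n_features, np.nan)
    model = plsda_fit(work, meta, case=case, control=control, n_components=n_components, seed=seed)
    vip = np.full(pt.n_features, np.nan)
    vip[pt.feature_index(work.feature_ids)] = model.vip
    return vip


def select_def(
    res: UnivariateResult,
    q_max: float = 0.05,
    fc_min: float = 1.5,
    vip_min: float = 1.0,
    test: str = "wilcox",
) -> list[str]:
    """Differentially expressed features: q <= q_max AND (FC >= fc_min OR
    FC <= 1/fc_min) AND VIP >= vip_min."""
    t = res.table
    q = t["q_wilcox"] if test == "wilcox" else t["q_t"]
    fc = t["fold_change"]
    vip = t["vip"]
    hit = (q <= q_max) & ((fc >= fc_min) | (fc <= 1.0 / fc_min)) & (vip >= vip_min)
    return t.loc[hit.fillna(False), "feature"].tolist()


# ---------------------------------------------------------------------------
# multivariate
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MultivariateModel:
    """Fitted PCA / PLS-DA / OPLS-DA model."""

    kind: str
    scores: np.ndarray                  # samples x components
    loadings: np.ndarray                # features x components
    r2y: float | None
    q2y: float | None
    vip: np.ndarray | None
    n_components: int
    n_orthogonal: int = 0
    permutation_p: float | None = None
    explained_variance_ratio: np.ndarray | None = None
    sample_ids: np.ndarray | None = None
    feature_ids: np.ndarray | None = None
    orthogonal_scores: np.ndarray | None = None


def pca_fit(pt: PeakTable, n_components: int = 2) -> MultivariateModel:
    """PCA of the samples by SVD of the column-centered matrix."""
    if pt.mask.any():
        raise ValueError("PCA requires a complete matrix; impute first")
    X = pt.values.T  # samples x features
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min(dims)={min(X.shape)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    total = float((s**2).sum()) or 1.0
    evr = s[:n_components] ** 2 / total
    return MultivariateModel(
        kind="pca",
        scores=scores,
        loadings=loadings,
        r2y=None,
        q2y=None,
        vip=None,
        n_components=n_components,
        explained_variance_ratio=evr,
        sample_ids=pt.sample_ids.copy(),
        feature_ids=pt.feature_ids.copy(),
    )


def _two_group_response(pt: PeakTable, meta: SampleMeta, case: str | None, control: str | None):
    klass = meta.classes(pt.sample_ids)
    keep = np.array([k is not None for k in klass], dtype=bool)
    labels = [k for k in klass if k is not None]
    groups = list(dict.fromkeys(labels))
    if case is None or control is None:
        if len(groups) != 2:
            raise ValueError(f"expected exactly two non-QC groups, found {groups}")
        case, control = groups
    else:
        extra = set(groups) - {case, control}
        if extra:
            raise ValueError(f"more than two groups present: {sorted(extra)} beyond {case}/{control}")
    cols = np.where(keep)[0]
    y = np.array([1.0 if klass[j] == case else -1.0 for j in cols])
    return cols, y, case, control


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """PLS1 via NIPALS on centered X (n x p) and centered y.

    Returns scores T, normalized weight vectors W, X-loadings P and
    y-loadings q (one per component).
    """
    n, p = Xc.shape
    A = min(n_components, n - 1, p)
    T = np.zeros((n, A))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    Xk = Xc.copy()
    yk = yc.copy()
    for a in range(A):
        w = Xk.T @ yk
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            A = a
            break
        w /= norm
        t = Xk @ w
        tt = float(t @ t)
        if tt < 1e-14:
            A = a
            break
        pvec = Xk.T @ t / tt
        qa = float(yk @ t) / tt
        Xk = Xk - np.outer(t, pvec)
        yk = yk - qa * t
        T[:, a], W[:, a], P[:, a], q[a] = t, w, pvec, qa
    return T[:, :A], W[:, :A], P[:, :A], q[:A]


def _pls_vip(T: np.ndarray, W: np.ndarray, q: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a), SSY_a = q_a^2 t_a't_a."""
    p = W.shape[0]
    ssy = q**2 * (T**2).sum(axis=0)
    denom = ssy.sum() or 1.0
    return np.sqrt(p * (W**2 @ ssy) / denom)


def _pls1_predict(Xc_new: np.ndarray, W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Predict centered y for centered new X using the deflation weights."""
    n = Xc_new.shape[0]
    yhat = np.zeros(n)
    Xk = Xc_new.copy()
    for a in range(W.shape[1]):
        t = Xk @ W[:, a]
        yhat += q[a] * t
        Xk = Xk - np.outer(t, P[:, a])
    return yhat


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified k-fold test-index sets for a binary response."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for value in np.unique(y):
        idx = np.where(y == value)[0]
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds if len(f)]


def _opls_split(Xc, yc, n_orthogonal):
    """Remove y-orthogonal variation from centered X (O-PLS deflation).

    Returns (filtered X, orthogonal scores, orthogonal weights/loadings).
    """
    w = Xc.T @ yc
    w /= np.linalg.norm(w)
    Xk = Xc.copy()
    T_o, W_o, P_o = [], [], []
    for _ in range(n_orthogonal):
        t = Xk @ w
        tt = float(t @ t)
        p = Xk.T @ t / tt
        w_o = p - float(w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break
        w_o /= n_wo
        t_o = Xk @ w_o
        p_o = Xk.T @ t_o / float(t_o @ t_o)
        Xk = Xk - np.outer(t_o, p_o)
        T_o.append(t_o)
        W_o.append(w_o)
        P_o.append(p_o)
    T_o = np.column_stack(T_o) if T_o else np.zeros((Xc.shape[0], 0))
    W_o = np.column_stack(W_o) if W_o else np.zeros((Xc.shape[1], 0))
    P_o = np.column_stack(P_o) if P_o else np.zeros((Xc.shape[1], 0))
    return Xk, T_o, W_o, P_o


def _opls_filter_new(Xc_new, W_o, P_o):
    Xk = Xc_new.copy()
    for a in range(W_o.shape[1]):
        t_o = Xk @ W_o[:, a]
        Xk = Xk - np.outer(t_o, P_o[:, a])
    return Xk


def plsda_fit(
    pt: PeakTable,
    meta: SampleMeta,
    case: str | None = None,
    control: str | None = None,
    n_components: int = 2,
    cv_folds: int = 7,
    seed: int = 0,
) -> MultivariateModel:
    """NIPALS PLS-DA on a -1/+1 response; QC samples are excluded.

    R²Y is computed on the fitted response, Q²Y from stratified
    ``cv_folds``-fold cross-validated predictions, and VIP by the
    SSY-weighted formula (so the mean squared VIP is always 1).
    """
    if pt.mask.any():
        raise ValueError("PLS-DA requires a complete matrix; impute first")
    cols, y, case, control = _two_group_response(pt, meta, case, control)
    X = pt.values[:, cols].T
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    T, W, P, q = _nipals_pls1(Xc, yc, n_components)
    yhat = _pls1_predict(Xc, W, P, q)
    ss_tot = float(yc @ yc)
    r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / ss_tot
    q2y = _q2_cv(X, y, cv_folds, seed, lambda Xtr, ytr: _plsda_cv_fit(Xtr, ytr, n_components))
    vip = _pls_vip(T, W, q)
    return MultivariateModel(
        kind="plsda",
        scores=T,
        loadings=P,
        r2y=r2y,
        q2y=q2y,
        vip=vip,
        n_components=T.shape[1],
        sample_ids=pt.sample_ids[cols].copy(),
        feature_ids=pt.feature_ids.copy(),
    )


def _plsda_cv_fit(Xtr, ytr, n_components):
    mx = Xtr.mean(axis=0)
    my = ytr.mean()
    _, W, P, q = _nipals_pls1(Xtr - mx, ytr - my, n_components)
    return lambda Xte: _pls1_predict(Xte - mx, W, P, q) + my


def _q2_cv(X, y, cv_folds, seed, fit_fn) -> float:
    """Q²Y = 1 - PRESS/SS_tot from stratified k-fold CV predictions."""
    folds = _stratified_folds(y, cv_folds, seed)
    press = 0.0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        predict = fit_fn(X[train_idx], y[train_idx])
        press += float(np.sum((y[test_idx] - predict(X[test_idx])) ** 2))
    yc = y - y.mean()
    return 1.0 - press / float(yc @ yc)


def oplsda_fit(
    pt: PeakTable,
    meta: SampleMeta,
    case: str | None = None,
    control: str | None = None,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
) -> MultivariateModel:
    """OPLS-DA: remove ``n_orthogonal`` y-orthogonal components, then fit a
    single predictive PLS component on the filtered matrix."""
    if pt.mask.any():
        raise ValueError("OPLS-DA requires a complete matrix; impute first")
    cols, y, case, control = _two_group_response(pt, meta, case, control)
    X = pt.values[:, cols].T
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    Xf, T_o, W_o, P_o = _opls_split(Xc, yc, n_orthogonal)
    T, W, P, q = _nipals_pls1(Xf, yc, 1)
    yhat = _pls1_predict(Xf, W, P, q)
    ss_tot = float(yc @ yc)
    r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / ss_tot
    q2y = _q2_cv(X, y, cv_folds, seed, lambda Xtr, ytr: _oplsda_cv_fit(Xtr, ytr, n_orthogonal))
    vip = _pls_vip(T, W, q)
    return MultivariateModel(
        kind="oplsda",
        scores=T,
        loadings=P,
        r2y=r2y,
        q2y=q2y,
        vip=vip,
        n_components=1 + T_o.shape[1],
        n_orthogonal=T_o.shape[1],
        sample_ids=pt.sample_ids[cols].copy(),
        feature_ids=pt.feature_ids.copy(),
        orthogonal_scores=T_o,
    )


def _oplsda_cv_fit(Xtr, ytr, n_orthogonal):
    mx = Xtr.mean(axis=0)
    my = ytr.mean()
    Xf, _, W_o, P_o = _opls_split(Xtr - mx, ytr - my, n_orthogonal)
    _, W, P, q = _nipals_pls1(Xf, ytr - my, 1)

    def predict(Xte):
        Xte_f = _opls_filter_new(Xte - mx, W_o, P_o)
        return _pls1_predict(Xte_f, W, P, q) + my

    return predict


def permutation_test(
    pt: PeakTable,
    meta: SampleMeta,
    model_kind: str = "plsda",
    n_perm: int = 200,
    case: str | None = None,
    control: str | None = None,
    cv_folds: int = 7,
    seed: int = 0,
    n_components: int = 2,
    n_orthogonal: int = 1,
) -> float:
    """Label-permutation validity test on Q²Y.

    p = (1 + #{Q²Y_perm >= Q²Y_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if model_kind not in ("plsda", "oplsda"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    if pt.mask.any():
        raise ValueError("permutation test requires a complete matrix; impute first")
    cols, y, case, control = _two_group_response(pt, meta, case, control)
    X = pt.values[:, cols].T
    if model_kind == "plsda":
        fit_fn = lambda Xtr, ytr: _plsda_cv_fit(Xtr, ytr, n_components)
    else:
        fit_fn = lambda Xtr, ytr: _oplsda_cv_fit(Xtr, ytr, n_orthogonal)
    q2_obs = _q2_cv(X, y, cv_folds, seed, fit_fn)
    rng = np.random.default_rng(seed)
    hits = 0
    for b in range(n_perm):
        yp = rng.permutation(y)
        q2_perm = _q2_cv(X, yp, cv_folds, seed + b + 1, fit_fn)
        if q2_perm >= q2_obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PowerCurve:
    """Average power over the pilot effect-size set per candidate group size."""

    table: pd.DataFrame  # n_per_group, estimated_power
    alpha: float
    pi0: float


def _t_power(d: float, n_per_group: int, alpha: float) -> float:
    """Two-sided two-sample t-test power at effect size d, equal n."""
    df = 2 * n_per_group - 2
    if df < 1:
        return np.nan
    ncp = d * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    power = 1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    if not np.isfinite(power):  # noncentral-t tails overflow at huge ncp
        power = sps.norm.sf(tcrit - ncp) + sps.norm.cdf(-tcrit - ncp)
    return float(min(max(power, 0.0), 1.0))


def estimate_power(
    pilot_stats,
    n_grid,
    alpha: float = 0.05,
    pilot_n1: int = 20,
    pilot_n2: int = 20,
) -> PowerCurve:
    """Power curve from pilot two-group t statistics.

    The fraction of null features pi0 is estimated by the Storey method at
    lambda = 0.5; the (1-pi0) fraction of statistics largest in magnitude
    is converted to standardized effect sizes d = t * sqrt(1/n1 + 1/n2);
    estimated power at each candidate per-group size n is the average
    two-sided noncentral-t power over that effect-size set (alpha when the
    set is empty).
    """
    t = np.asarray(pilot_stats, dtype=float)
    t = t[np.isfinite(t)]
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("n_grid must be nonempty")
    if t.size == 0:
        raise ValueError("no finite pilot statistics")
    df = pilot_n1 + pilot_n2 - 2
    p = 2 * sps.t.sf(np.abs(t), df)
    pi0 = min(1.0, float(np.mean(p > 0.5) / 0.5))
    n_alt = int(round((1.0 - pi0) * t.size))
    if n_alt == 0:
        effects = np.array([])
    else:
        top = np.argsort(-np.abs(t), kind="mergesort")[:n_alt]
        effects = np.abs(t[top]) * np.sqrt(1.0 / pilot_n1 + 1.0 / pilot_n2)
    rows = []
    for n in sorted(set(int(x) for x in n_grid)):
        if effects.size == 0:
            power = alpha
        else:
            power = float(np.mean([_t_power(d, n, alpha) for d in effects]))
        rows.append({"n_per_group": n, "estimated_power": power})
    return PowerCurve(pd.DataFrame(rows), alpha=alpha, pi0=pi0)
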