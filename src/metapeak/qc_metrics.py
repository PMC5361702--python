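"""Quality-assessment data series, pre- and post-normalization.

These are the numbers behind the eight standard QC charts of an
untargeted metabolomics run: per-sample peak counts, missing-value
counts and total intensity along injection order; feature m/z and
retention-time distributions (and m/z vs RT); the QC-sample correlation
heatmap; per-group CV distributions; and two-component PCA scores.
All series are pure functions of the peak table and sample list, so
recomputation is deterministic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import PeakTable, SampleMeta

__all__ = ["compute_cv", "sample_summaries", "qc_correlation", "cv_distribution", "QASummary"]


def compute_cv(values) -> float:
    """Coefficient of variation sd(n-1)/mean; NaN when undefined (<2 values
    or zero mean)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


@dataclasses.dataclass
class QASummary:
    """Chart-ready quality-assessment series."""

    samples: pd.DataFrame        # sample, batch, class, order, is_qc, detected, missing, total_intensity
    features: pd.DataFrame       # feature, mz, rt, cv_<group> columns
    qc_correlation: pd.DataFrame  # QC x QC correlation matrix
    pca_scores: pd.DataFrame | None  # sample, pc1, pc2 (complete-feature PCA)


def sample_summaries(pt: PeakTable, meta: SampleMeta) -> QASummary:
    """Per-sample counts/totals ordered by injection order, per-feature CVs,
    QC correlations and a 2-component PCA score overview."""
    aligned = meta.for_samples(pt.sample_ids)
    obs = pt.observed
    detected = obs.sum(axis=0)
    missing = (~obs).sum(axis=0)
    totals = np.nansum(np.where(obs, pt.values, 0.0), axis=0)
    samples = aligned.assign(
        detected=detected, missing=missing, total_intensity=totals
    ).sort_values("order", kind="mergesort").reset_index(drop=True)

    feat = {"feature": pt.feature_ids}
    if pt.mz is not None:
        feat["mz"] = pt.mz
    if pt.rt is not None:
        feat["rt"] = pt.rt
    klass = meta.classes(pt.sample_ids)
    is_qc = meta.qc_mask(pt.sample_ids)
    group_cols: dict[str, np.ndarray] = {}
    for g in meta.groups():
        group_cols[f"cv_{g}"] = np.array([k == g for k in klass], dtype=bool)
    if is_qc.any():
        group_cols["cv_QC"] = is_qc
    for name, colmask in group_cols.items():
        if colmask.sum() < 2:
            continue
        feat[name] = np.array([compute_cv(pt.values[i, colmask]) for i in range(pt.n_features)])
    features = pd.DataFrame(feat)

    qc_corr = (
        qc_correlation(pt, meta) if is_qc.sum() >= 2 else pd.DataFrame()
    )

    pca_scores = None
    complete = ~pt.mask.any(axis=1)
    if complete.sum() >= 2 and pt.n_samples >= 3:
        from .stats import pca_fit

        model = pca_fit(pt.select_features(np.where(complete)[0]), n_components=2)
        pca_scores = pd.DataFrame(
            {"sample": pt.sample_ids, "pc1": model.scores[:, 0], "pc2": model.scores[:, 1]}
        )
    return QASummary(samples=samples, features=features, qc_correlation=qc_corr, pca_scores=pca_scores)


def qc_correlation(pt: PeakTable, meta: SampleMeta, method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlation of QC samples over co-observed features."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    is_qc = meta.qc_mask(pt.sample_ids)
    qc_cols = np.where(is_qc)[0]
    if qc_cols.size < 2:
        raise ValueError("QC correlation needs at least 2 QC samples")
    k = qc_cols.size
    out = np.eye(k)
    V = pt.values[:, qc_cols]
    for a in range(k):
        for b in range(a + 1, k):
            both = np.isfinite(V[:, a]) & np.isfinite(V[:, b])
            if both.sum() < 3:
                r = np.nan
            elif method == "pearson":
                r = sps.pearsonr(V[both, a], V[both, b]).statistic
            else:
                r = sps.spearmanr(V[both, a], V[both, b]).statistic
            out[a, b] = out[b, a] = r
    ids = [str(s) for s in pt.sample_ids[qc_cols]]
    return pd.DataFrame(out, index=ids, columns=ids)


def cv_distribution(pt_pre: PeakTable, pt_post: PeakTable, meta: SampleMeta) -> pd.DataFrame:
    """Per-feature, per-group CV before and after normalization.

    Features are intersected by id; groups with fewer than 2 samples are
    excluded.  Returns tidy rows (feature, group, cv_pre, cv_post).
    """
    common = [f for f in pt_pre.feature_ids if f in set(pt_post.feature_ids)]
    pre = pt_pre.select_features(pt_pre.feature_index(common))
    post = pt_post.select_features(pt_post.feature_index(common))
    klass_pre = meta.classes(pre.sample_ids)
    is_qc_pre = meta.qc_mask(pre.sample_ids)
    klass_post = meta.classes(post.sample_ids)
    is_qc_post = meta.qc_mask(post.sample_ids)

    groups = meta.groups()
    rows = []
    for g in groups + ["QC"]:
        if g == "QC":
            pre_mask, post_mask = is_qc_pre, is_qc_post
        else:
            pre_mask = np.array([k == g for k in klass_pre], dtype=bool)
            post_mask = np.array([k == g for k in klass_post], dtype=bool)
        if pre_mask.sum() < 2 or post_mask.sum() < 2:
            continue
        for i, f in enumerate(common):
            rows.append(
                {
                    "feature": f,
                    "group": g,
                    "cv_pre": compute_cv(pre.values[i, pre_mask]),
                    "cv_post": compute_cv(post.values[i, post_mask]),
                }
            )
    return pd.DataFrame(rows)
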