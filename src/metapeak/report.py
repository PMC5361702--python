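"""Self-contained HTML report assembly.

The report gathers the outputs of whichever pipeline stages were run —
the eight quality-assessment charts, the normalization-method comparison
table, a univariate excerpt, multivariate model summaries (R²Y, Q²Y,
permutation p), the network summary, the identification table and the
biomarker ROC — into one HTML file with every chart inlined as a base64
PNG, so it renders without network access.  A provenance block records
the package version, configuration, seed and SHA-256 hashes of the input
files; timestamps are deliberately excluded so two runs on the same
inputs produce byte-identical output.
"""

from __future__ import annotations

import base64
import hashlib
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .qc_metrics import QASummary

__all__ = ["generate_report", "file_sha256"]

_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }
h1 { border-bottom: 2px solid #444; }
h2 { border-bottom: 1px solid #bbb; margin-top: 2em; }
table { border-collapse: collapse; font-size: 0.9em; }
th, td { border: 1px solid #ccc; padding: 0.25em 0.6em; text-align: right; }
th { background: #f0f0f0; }
img { max-width: 100%; }
.provenance { font-size: 0.8em; color: #666; background: #f8f8f8; padding: 1em; }
"""


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fig_to_img(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, metadata={"Software": None})
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img src="data:image/png;base64,{data}"/>'


def _table_html(df: pd.DataFrame, max_rows: int = 30) -> str:
    shown = df.head(max_rows)
    note = "" if len(df) <= max_rows else f"<p><em>first {max_rows} of {len(df)} rows</em></p>"
    return shown.to_html(index=False, float_format=lambda v: f"{v:.4g}") + note


def _qa_charts(qa: QASummary) -> list[tuple[str, str]]:
    """The eight quality-assessment chart sections."""
    charts: list[tuple[str, str]] = []
    s = qa.samples
    color = ["#d62728" if q else "#1f77b4" for q in s["is_qc"]]

    def bar(series, title, ylabel):
        fig, ax = plt.subplots(figsize=(7, 2.6))
        ax.bar(s["order"], series, color=color)
        ax.set_xlabel("injection order")
        ax.set_ylabel(ylabel)
        ax.set_title(title)
        fig.tight_layout()
        return _fig_to_img(fig)

    charts.append(("Peak number distribution", bar(s["detected"], "Detected features per sample", "peaks")))
    charts.append(("Missing value distribution", bar(s["missing"], "Missing values per sample", "missing")))

    fig, ax = plt.subplots(figsize=(7, 2.6))
    ax.plot(s["order"], np.log10(s["total_intensity"].where(s["total_intensity"] > 0)), "o", ms=3)
    ax.set_xlabel("injection order")
    ax.set_ylabel("log10 total intensity")
    ax.set_title("Total peak intensity over injection order")
    fig.tight_layout()
    charts.append(("Total peak intensity distribution", _fig_to_img(fig)))

    fig, ax = plt.subplots(figsize=(7, 2.6))
    ax.boxplot(
        [np.log10(v) for v in (s["total_intensity"][~s["is_qc"]], s["total_intensity"][s["is_qc"]]) if len(v)],
        tick_labels=["samples", "QC"][: 2 if s["is_qc"].any() else 1],
    )
    ax.set_ylabel("log10 total intensity")
    ax.set_title("Peak intensity boxplot")
    fig.tight_layout()
    charts.append(("Peak intensity boxplot", _fig_to_img(fig)))

    if not qa.qc_correlation.empty:
        fig, ax = plt.subplots(figsize=(4.2, 3.6))
        im = ax.imshow(qa.qc_correlation.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(qa.qc_correlation)), qa.qc_correlation.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(qa.qc_correlation)), qa.qc_correlation.index, fontsize=6)
        fig.colorbar(im)
        ax.set_title("QC sample correlation")
        fig.tight_layout()
        charts.append(("Correlation heatmap of QC samples", _fig_to_img(fig)))
    else:
        charts.append(("Correlation heatmap of QC samples", "<p>fewer than 2 QC samples</p>"))

    f = qa.features
    if "mz" in f:
        fig, ax = plt.subplots(figsize=(7, 2.6))
        ax.hist(f["mz"].dropna(), bins=40)
        ax.set_xlabel("m/z")
        ax.set_title("Feature m/z distribution")
        fig.tight_layout()
        charts.append(("m/z distribution", _fig_to_img(fig)))
    else:
        charts.append(("m/z distribution", "<p>no m/z metadata</p>"))

    if "mz" in f and "rt" in f:
        fig, ax = plt.subplots(figsize=(7, 2.8))
        ax.plot(f["rt"], f["mz"], ".", ms=2)
        ax.set_xlabel("retention time (min)")
        ax.set_ylabel("m/z")
        ax.set_title("m/z versus retention time")
        fig.tight_layout()
        charts.append(("m/z versus retention time", _fig_to_img(fig)))
    else:
        charts.append(("m/z versus retention time", "<p>no m/z or RT metadata</p>"))

    if qa.pca_scores is not None:
        p = qa.pca_scores.merge(s[["sample", "is_qc", "class"]], on="sample")
        fig, ax = plt.subplots(figsize=(4.5, 3.8))
        for label, sub in p.groupby(p["class"].fillna("QC")):
            ax.plot(sub["pc1"], sub["pc2"], "o", ms=4, label=str(label))
        ax.legend(fontsize=7)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title("PCA score plot")
        fig.tight_layout()
        charts.append(("PCA score plot", _fig_to_img(fig)))
    else:
        charts.append(("PCA score plot", "<p>too few complete features for PCA</p>"))
    return charts


def generate_report(
    results: dict,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    input_files: list[str | Path] | None = None,
    title: str = "metapeak analysis report",
) -> None:
    """Assemble the HTML report from stage outputs.

    ``results`` maps stage names to their outputs; recognized keys:
    ``qa`` (QASummary, mandatory when quality assessment ran),
    ``normalization`` (NormalizationComparison), ``univariate``
    (UnivariateResult), ``multivariate`` (list of MultivariateModel),
    ``network`` (CorrelationGraph), ``identification`` (hit DataFrame),
    ``biomarker`` (RFEResult).  Unknown keys are an error, as is an empty
    ``results``.
    """
    known = {"qa", "normalization", "univariate", "multivariate", "network", "identification", "biomarker"}
    if not results:
        raise ValueError("no stage results to report")
    unknown = set(results) - known
    if unknown:
        raise ValueError(f"unknown report sections: {sorted(unknown)}")

    sections: list[str] = []

    if "qa" in results:
        qa = results["qa"]
        if qa is None:
            raise ValueError("quality assessment ran but produced no summary")
        parts = [f"<h3>{name}</h3>{img}" for name, img in _qa_charts(qa)]
        sections.append("<h2>Quality assessment</h2>" + "".join(parts))

    if "normalization" in results:
        sections.append(
            "<h2>Normalization comparison</h2>" + _table_html(results["normalization"].table)
        )

    if "univariate" in results:
        uni = results["univariate"]
        t = uni.table.sort_values("q_wilcox", na_position="last")
        sections.append(
            f"<h2>Univariate statistics ({uni.case} vs {uni.control})</h2>" + _table_html(t)
        )

    if "multivariate" in results:
        rows = []
        for m in results["multivariate"]:
            rows.append(
                {
                    "model": m.kind,
                    "components": m.n_components,
                    "orthogonal": m.n_orthogonal,
                    "R2Y": m.r2y,
                    "Q2Y": m.q2y,
                    "permutation_p": m.permutation_p,
                }
            )
        sections.append("<h2>Multivariate models</h2>" + _table_html(pd.DataFrame(rows)))

    if "network" in results:
        cg = results["network"]
        n_comm = len(set(cg.communities.values())) if cg.communities else None
        info = pd.DataFrame(
            [
                {
                    "type": cg.kind,
                    "nodes": cg.n_nodes,
                    "edges": cg.n_edges,
                    "communities": n_comm,
                    "modularity": cg.modularity,
                }
            ]
        )
        sections.append("<h2>Correlation network</h2>" + _table_html(info))

    if "identification" in results:
        sections.append("<h2>Metabolite identification</h2>" + _table_html(results["identification"]))

    if "biomarker" in results:
        r = results["biomarker"]
        html = f"<p>estimator: {r.estimator}; selected panel: {', '.join(r.selected_features)}</p>"
        if r.profile:
            html += _table_html(pd.DataFrame(r.profile, columns=["panel size", "CV ROC AUC"]))
        if r.roc_points:
            fig, ax = plt.subplots(figsize=(3.8, 3.5))
            fpr, tpr = zip(*r.roc_points)
            ax.plot(fpr, tpr, "-o", ms=3)
            ax.plot([0, 1], [0, 1], "--", color="#999")
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.set_title(f"ROC (AUROC = {r.auroc:.3f})")
            fig.tight_layout()
            html += _fig_to_img(fig)
        sections.append("<h2>Biomarker analysis</h2>" + html)

    provenance = {
        "version": __version__,
        "config": config or {},
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in (input_files or [])},
    }
    prov_html = (
        '<h2>Provenance</h2><pre class="provenance">'
        + json.dumps(provenance, indent=2, sort_keys=True)
        + "</pre>"
    )

    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{title}</title><style>{_CSS}</style></head><body>"
        f"<h1>{title}</h1>" + "".join(sections) + prov_html + "</body></html>"
    )
    Path(path).write_text(html)
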