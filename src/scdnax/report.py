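"""Static HTML report: the figure set of the four workflow steps, rendered
from the exported tables so the figure data stays independently checkable.
"""

from __future__ import annotations

import base64
import datetime
import io
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dataset import ScdnaDataset
from .explore import ClusteringResult, VafMatrix

_GT_COLORS = {"WT": "#4878cf", "Het": "#eec35f", "Hom": "#d1605e", "Missing": "#cccccc"}


def _embed(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def fig_amplicon_distribution(summary: pd.DataFrame) -> str:
    """Mean reads per amplicon, ordered by genomic position, uniformity line."""
    df = summary.sort_values(["chrom", "start"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(max(6, len(df) * 0.08), 3.2))
    colors = ["#4878cf" if u else "#d1605e" for u in df["uniform"]]
    ax.bar(range(len(df)), df["mean_reads"], color=colors, width=0.9)
    ax.axhline(0.2 * df["mean_reads"].mean(), color="k", ls="--", lw=0.8,
               label="20% of panel mean")
    ax.set_xlabel("amplicon (by genomic position)")
    ax.set_ylabel("mean reads per cell")
    ax.legend(frameon=False, fontsize=8)
    return _embed(fig)


def fig_vaf_heatmap(
    vaf: VafMatrix, ngt: np.ndarray, labels: Optional[np.ndarray] = None
) -> str:
    """VAF heatmap over cells x variants with a genotype annotation strip.

    Cell order: cluster label, then descending mean VAF within cluster.
    """
    x = vaf.values
    if labels is None:
        order = np.argsort(-x.mean(axis=1), kind="stable")
    else:
        order = np.lexsort((-x.mean(axis=1), labels))
    fig, axes = plt.subplots(
        1, 2, figsize=(2 + x.shape[1] * 0.6, 4.5),
        gridspec_kw={"width_ratios": [x.shape[1], 1]}, sharey=True,
    )
    im = axes[0].imshow(x[order], aspect="auto", cmap="viridis", vmin=0, vmax=100)
    axes[0].set_xticks(range(len(vaf.variant_keys)))
    axes[0].set_xticklabels(
        [f"{k[0]}:{k[1]}" for k in vaf.variant_keys], rotation=90, fontsize=7
    )
    axes[0].set_ylabel("cells")
    fig.colorbar(im, ax=axes[0], label="VAF (%)", shrink=0.8)
    strip = ngt[order].mean(axis=1, keepdims=True)
    axes[1].imshow(strip, aspect="auto", cmap="coolwarm", vmin=0, vmax=3)
    axes[1].set_xticks([0])
    axes[1].set_xticklabels(["mean NGT"], rotation=90, fontsize=7)
    return _embed(fig)


def fig_elbow(curve: Sequence[tuple[int, float]]) -> str:
    ks, wss = zip(*curve)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(ks, wss, "o-")
    ax.set_xlabel("k")
    ax.set_ylabel("within-cluster sum of squares")
    return _embed(fig)


def fig_pca_clusters(result: ClusteringResult, vaf: VafMatrix) -> list[str]:
    """PCA colored by cluster label, then by each variant's VAF."""
    if result.pca is None:
        return []
    proj, evr = result.pca
    out = []
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    for cl in sorted(set(result.labels.tolist())):
        m = result.labels == cl
        ax.scatter(proj[m, 0], proj[m, 1] if proj.shape[1] > 1 else np.zeros(m.sum()),
                   s=6, label=f"c{cl + 1}" if cl >= 0 else "noise")
    ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
    if proj.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
    ax.legend(frameon=False, fontsize=8, markerscale=2)
    out.append(_embed(fig))
    for j, key in enumerate(vaf.variant_keys):
        fig, ax = plt.subplots(figsize=(4.2, 3.6))
        sc = ax.scatter(
            proj[:, 0], proj[:, 1] if proj.shape[1] > 1 else np.zeros(len(proj)),
            c=vaf.values[:, j], s=6, cmap="viridis", vmin=0, vmax=100,
        )
        fig.colorbar(sc, label="VAF (%)")
        ax.set_title(f"{key[0]}:{key[1]}:{key[2]}/{key[3]}", fontsize=9)
        ax.set_xlabel("PC1")
        out.append(_embed(fig))
    return out


def fig_violin_vaf(vaf: VafMatrix, labels: np.ndarray) -> str:
    """Per-cluster VAF distributions: violins with jittered points."""
    clusters = sorted(set(labels.tolist()))
    nv = len(vaf.variant_keys)
    fig, axes = plt.subplots(1, nv, figsize=(3 * nv, 3.2), sharey=True, squeeze=False)
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for j, key in enumerate(vaf.variant_keys):
        ax = axes[0, j]
        data = [vaf.values[labels == cl, j] for cl in clusters]
        nonempty = [d for d in data if len(d)]
        if nonempty:
            ax.violinplot([d if len(d) else [0] for d in data],
                          positions=range(len(clusters)), showextrema=False)
        for i, d in enumerate(data):
            ax.scatter(i + rng.uniform(-0.08, 0.08, len(d)), d, s=3, alpha=0.4, color="k")
        ax.set_xticks(range(len(clusters)))
        ax.set_xticklabels([f"c{c + 1}" for c in clusters])
        ax.set_title(f"{key[0]}:{key[1]}", fontsize=9)
    axes[0, 0].set_ylabel("VAF (%)")
    return _embed(fig)


def fig_genotype_barplots(abundance: pd.DataFrame) -> str:
    """Stacked genotype-count barplots per variant and cluster."""
    variants = abundance["variant"].unique()
    fig, axes = plt.subplots(
        1, len(variants), figsize=(3 * len(variants), 3.2), sharey=True, squeeze=False
    )
    for j, var in enumerate(variants):
        ax = axes[0, j]
        sub = abundance[abundance["variant"] == var]
        clusters = sorted(sub["cluster"].unique())
        bottom = np.zeros(len(clusters))
        for gt in ("WT", "Het", "Hom", "Missing"):
            counts = np.array(
                [int(sub[(sub["cluster"] == c) & (sub["genotype"] == gt)]["count"].sum())
                 for c in clusters]
            )
            ax.bar(range(len(clusters)), counts, bottom=bottom,
                   color=_GT_COLORS[gt], label=gt if j == 0 else None)
            bottom += counts
        ax.set_xticks(range(len(clusters)))
        ax.set_xticklabels([f"c{c + 1}" for c in clusters])
        ax.set_title(var, fontsize=9)
    axes[0, 0].set_ylabel("cells")
    fig.legend(frameon=False, fontsize=8, loc="upper right")
    return _embed(fig)


def assemble_html(
    title: str,
    sections: list[tuple[str, str, list[str]]],
    out_path,
    seed: Optional[int] = None,
) -> None:
    """Write a self-contained HTML report.

    ``sections`` is a list of (heading, html body, list of base64 PNGs).
    The timestamp is confined to one marked line so everything else is
    byte-reproducible.
    """
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{title}</title>",
        "<style>body{font-family:sans-serif;max-width:1100px;margin:auto}"
        "img{max-width:100%;margin:4px}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:3px 8px;font-size:13px}</style>",
        "</head><body>",
        f"<h1>{title}</h1>",
        f"<!-- timestamp: {datetime.datetime.now().isoformat()} -->",
    ]
    if seed is not None:
        parts.append(f"<p>seed: {seed}</p>")
    for heading, body, images in sections:
        parts.append(f"<h2>{heading}</h2>")
        if body:
            parts.append(body)
        for img in images:
            parts.append(f"<img src='data:image/png;base64,{img}'>")
    parts.append("</body></html>")
    with open(out_path, "w") as fh:
        fh.write("\n".join(parts))


def dict_to_html_table(d: dict) -> str:
    rows = "".join(f"<tr><th>{k}</th><td>{v}</td></tr>" for k, v in d.items())
    return f"<table>{rows}</table>"
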