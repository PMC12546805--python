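"""Superplots, embedding plots, and the Analysis output folder.

A superplot shows every cilium as a jittered point per condition while
encoding replicate identity by color, overlays the per-replicate means
as large markers, and a violin of the pooled distribution with median
and quartile lines — so both cell-to-cell variability and experiment-
to-experiment reproducibility are visible in one panel.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ciliametry.explorer import GroupedDataset, QCReport, embed, select_features
from ciliametry.stats import StatsResult, statistics_text

logger = logging.getLogger(__name__)

_REPLICATE_CMAP = "tab10"


def replicate_means(dataset: GroupedDataset, measurement: str) -> pd.DataFrame:
    """Per-replicate means of one measurement (the superplot overlay)."""
    rows = []
    for group, reps in dataset.groups.items():
        for rep_id, table in reps.items():
            if measurement in table.data:
                vals = table.data[measurement].astype(float)
                rows.append({"group": group, "replicate": rep_id,
                             "mean": float(np.nanmean(vals))})
    return pd.DataFrame(rows)


def make_superplot(dataset: GroupedDataset, measurement: str,
                   stats_result: StatsResult | None = None,
                   seed: int = 42, ax=None):
    """Build a superplot figure for one measurement; returns the figure."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(1.6 + 1.4 * len(dataset.groups), 4.0))
    else:
        fig = ax.figure
    rng = np.random.default_rng(seed)
    groups = dataset.group_labels
    cmap = plt.get_cmap(_REPLICATE_CMAP)

    pooled_per_group = []
    for gi, group in enumerate(groups):
        reps = dataset.groups[group]
        vals_all = []
        for ri, (rep_id, table) in enumerate(reps.items()):
            if measurement not in table.data:
                continue
            vals = table.data[measurement].astype(float).to_numpy()
            vals = vals[~np.isnan(vals)]
            vals_all.append(vals)
            jitter = rng.uniform(-0.18, 0.18, size=len(vals))
            ax.scatter(gi + jitter, vals, s=12, alpha=0.45,
                       color=cmap(ri % 10), label=rep_id if gi == 0 else None)
        pooled = np.concatenate(vals_all) if vals_all else np.array([])
        pooled_per_group.append(pooled)
        if pooled.size:
            parts = ax.violinplot([pooled], positions=[gi], widths=0.7,
                                  showextrema=False)
            for body in parts["bodies"]:
                body.set_alpha(0.15)
                body.set_facecolor("gray")
            q1, med, q3 = np.percentile(pooled, [25, 50, 75])
            ax.hlines(med, gi - 0.3, gi + 0.3, color="black", lw=1.6)
            ax.hlines([q1, q3], gi - 0.22, gi + 0.22, color="black",
                      lw=1.0, linestyles="dashed")
        for ri, (rep_id, table) in enumerate(reps.items()):
            if measurement not in table.data:
                continue
            m = float(np.nanmean(table.data[measurement].astype(float)))
            ax.scatter([gi], [m], s=120, marker="D", color=cmap(ri % 10),
                       edgecolor="black", zorder=5)

    if (stats_result is not None and stats_result.decision.runnable
            and len(groups) == 2):
        top = max((p.max() if p.size else 0) for p in pooled_per_group)
        y = top * 1.08 if top else 1.0
        ax.plot([0, 0, 1, 1], [y, y * 1.02, y * 1.02, y], color="black", lw=1)
        ax.text(0.5, y * 1.03, stats_result.stars, ha="center", va="bottom")

    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(groups, rotation=20, ha="right")
    ax.set_ylabel(measurement)
    if any(len(reps) > 1 for reps in dataset.groups.values()):
        ax.legend(title="replicate", fontsize=7, loc="best")
    fig.tight_layout()
    return fig


def make_embedding_plot(coords: np.ndarray, pooled: pd.DataFrame,
                        info: dict, ax=None):
    """Scatter an embedding, coloring by group and marking replicates."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4.2))
    else:
        fig = ax.figure
    groups = pooled["group"].unique()
    markers = ["o", "s", "^", "v", "D", "P", "X", "*"]
    cmap = plt.get_cmap("tab10")
    for gi, group in enumerate(groups):
        sel_g = pooled["group"] == group
        for ri, rep in enumerate(pooled.loc[sel_g, "replicate"].unique()):
            sel = sel_g & (pooled["replicate"] == rep)
            ax.scatter(coords[sel.to_numpy(), 0], coords[sel.to_numpy(), 1],
                       s=14, alpha=0.6, color=cmap(gi % 10),
                       marker=markers[ri % len(markers)],
                       label=f"{group} / {rep}")
    method = info.get("method", "embedding")
    if method == "PCA":
        evr = info.get("explained_variance_ratio", [0, 0])
        ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
        ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    else:
        ax.set_xlabel(f"{method} 1")
        ax.set_ylabel(f"{method} 2")
    ax.legend(fontsize=6, loc="best")
    fig.tight_layout()
    return fig


def _save(fig, path_stem: Path, plot_format: str) -> list[Path]:
    """Save a figure; always also in vector form."""
    written = []
    formats = {"png": ["png", "svg"], "svg": ["svg"], "both": ["png", "svg"]}[plot_format]
    for ext in formats:
        p = path_stem.with_suffix(f".{ext}")
        fig.savefig(p, dpi=120)
        written.append(p)
    plt.close(fig)
    return written


def write_outputs(dataset: GroupedDataset,
                  results: dict[str, StatsResult],
                  qc_report: QCReport,
                  measurements: list[str],
                  first_group_path: str | Path,
                  metafile_annotations: dict[str, str] | None = None,
                  seed: int = 42,
                  plot_format: str = "both",
                  run_umap: bool = True) -> Path:
    """Write the Analysis folder tree next to the first group folder.

    Layout: ``Analysis/Data`` holds summary CSV tables, ``Analysis/Plots``
    every figure (raster + vector), and ``qc.txt`` / ``statistics.txt`` /
    ``summary.txt`` sit at the top level of ``Analysis``.
    """
    root = Path(first_group_path).parent / "Analysis"
    data_dir = root / "Data"
    plot_dir = root / "Plots"
    for d in (data_dir, plot_dir):
        d.mkdir(parents=True, exist_ok=True)

    pooled = dataset.pooled()
    pooled.to_csv(data_dir / "pooled_records.csv", index=False)

    summary_rows = []
    for meas in measurements:
        for group in dataset.group_labels:
            vals = dataset.values(meas, group)
            vals = vals[~np.isnan(vals)]
            if not vals.size:
                continue
            summary_rows.append({
                "measurement": meas, "group": group, "n": len(vals),
                "mean": vals.mean(), "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
            })
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(data_dir / "summary_statistics.csv", index=False)
    for meas in measurements:
        replicate_means(dataset, meas).to_csv(
            data_dir / f"replicate_means_{meas}.csv", index=False)

    (root / "qc.txt").write_text(qc_report.to_text(), encoding="utf-8")
    (root / "statistics.txt").write_text(statistics_text(results), encoding="utf-8")

    summary_lines = ["# analysis summary",
                     f"groups: {', '.join(dataset.group_labels)}",
                     f"records: {dataset.n_records()}",
                     f"tool versions seen: {sorted(v or '(unknown)' for v in dataset.versions_seen)}"]
    if metafile_annotations:
        summary_lines.append("# experimental metadata")
        for key, value in metafile_annotations.items():
            summary_lines.append(f"{key}: {value}")
    summary_lines.append("# per-group record counts")
    for group, count in qc_report.per_group_counts.items():
        summary_lines.append(f"{group}: {count}")
    (root / "summary.txt").write_text("\n".join(summary_lines) + "\n",
                                      encoding="utf-8")

    for meas in measurements:
        fig = make_superplot(dataset, meas, results.get(meas), seed=seed)
        _save(fig, plot_dir / f"superplot_{meas}", plot_format)

    try:
        features, excluded = select_features(
            pooled.drop(columns=["group", "replicate"], errors="ignore"))
        (data_dir / "excluded_features.csv").write_text(
            "\n".join(["column"] + excluded) + "\n", encoding="utf-8")
        coords, info = embed(features, "pca", seed=seed)
        pd.DataFrame(coords, columns=["PC1", "PC2"]).assign(
            group=pooled["group"], replicate=pooled["replicate"]).to_csv(
            data_dir / "pca_coordinates.csv", index=False)
        fig = make_embedding_plot(coords, pooled, info)
        _save(fig, plot_dir / "pca", plot_format)
        if run_umap:
            coords, info = embed(features, "umap", seed=seed)
            pd.DataFrame(coords, columns=["UMAP1", "UMAP2"]).assign(
                group=pooled["group"], replicate=pooled["replicate"]).to_csv(
                data_dir / "umap_coordinates.csv", index=False)
            fig = make_embedding_plot(coords, pooled, info)
            _save(fig, plot_dir / "umap", plot_format)
    except ValueError as exc:
        logger.warning("dimensionality reduction skipped: %s", exc)

    logger.info("analysis outputs written to %s", root)
    return root
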