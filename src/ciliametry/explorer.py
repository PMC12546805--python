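"""Pooling, quality control and exploratory analysis of grouped tables.

One folder per experimental condition ("group"), one measurement table
per replicate.  The folder name becomes the group label in every output.
Pooled data is screened for suspicious cilia (advisory flags only — QC
never silently drops records), checked for tool-version consistency,
reduced to 2D embeddings (PCA / UMAP) after excluding non-morphological
columns, and scanned for group-discriminating measurements with LDA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ciliametry.io_formats import CiliaTable, read_cilia_table

logger = logging.getLogger(__name__)

#: Measurements screened by the outlier QC (where present in the data).
QC_MEASUREMENTS = (
    "cilia_length_um",
    "volume_um3",
    "max_span_um",
    "recon_intensity_mean",
    "recon_intensity_sd",
)


@dataclass
class GroupedDataset:
    """condition -> replicate -> table, with provenance."""

    groups: dict[str, dict[str, CiliaTable]]
    provenance: dict[str, Path] = field(default_factory=dict)

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups)

    @property
    def versions_seen(self) -> set[str]:
        return {t.metadata.tool_version
                for reps in self.groups.values() for t in reps.values()}

    def n_records(self) -> int:
        return sum(len(t) for reps in self.groups.values() for t in reps.values())

    def pooled(self) -> pd.DataFrame:
        """All records in one frame with ``group`` and ``replicate`` columns."""
        frames = []
        for group, reps in self.groups.items():
            for rep_id, table in reps.items():
                df = table.data.copy()
                df.insert(0, "group", group)
                df.insert(1, "replicate", rep_id)
                frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def values(self, measurement: str, group: str) -> np.ndarray:
        vals = [t.data[measurement].to_numpy()
                for t in self.groups[group].values() if measurement in t.data]
        return np.concatenate(vals) if vals else np.array([])


@dataclass
class QCFlag:
    group: str
    replicate: str
    cilium_id: int
    measurement: str
    reason: str


@dataclass
class QCReport:
    """Advisory quality-control findings over a pooled dataset."""

    flags: list[QCFlag] = field(default_factory=list)
    notices: list[str] = field(default_factory=list)
    version_consistent: bool = True
    per_group_counts: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["# quality control report"]
        lines.append(f"version_consistent\t{self.version_consistent}")
        for group, count in self.per_group_counts.items():
            lines.append(f"group\t{group}\t{count} cilia")
        for notice in self.notices:
            lines.append(f"notice\t{notice}")
        lines.append(f"{len(self.flags)} flagged cilia "
                     "(flags are advisory: scrutinize segmentation, do not auto-delete)")
        for fl in self.flags:
            lines.append(
                f"flag\t{fl.group}\t{fl.replicate}\tid={fl.cilium_id}\t"
                f"{fl.measurement}\t{fl.reason}"
            )
        return "\n".join(lines) + "\n"


def pool_groups(folders: list[str | Path]) -> GroupedDataset:
    """Pool per-condition folders of replicate tables.

    Every ``*.tsv`` in a folder is one replicate; the folder name is the
    group label.  Empty folders and unreadable tables are hard errors —
    silently skipping data would corrupt downstream counts.
    """
    if not folders:
        raise ValueError("need at least one group folder")
    groups: dict[str, dict[str, CiliaTable]] = {}
    provenance: dict[str, Path] = {}
    for folder in folders:
        folder = Path(folder)
        label = folder.name
        if label in groups:
            raise ValueError(f"group folder {label!r} listed twice")
        if not folder.is_dir():
            raise FileNotFoundError(f"group folder not found: {folder}")
        tables = {}
        for path in sorted(folder.glob("*.tsv")):
            if path.name.endswith("_truth.tsv"):
                continue
            table = read_cilia_table(path)
            table.group_label = label
            tables[table.replicate_id] = table
        if not tables:
            raise ValueError(f"group folder {folder} contains no readable tables")
        groups[label] = tables
        provenance[label] = folder
    return GroupedDataset(groups=groups, provenance=provenance)


def check_version_consistency(dataset: GroupedDataset) -> tuple[bool, str]:
    """True iff all known tool versions agree; mismatches get a warning.

    Measurements from different tool versions can carry a batch-dependent
    bias, so pooled analyses should come from a single version.
    """
    versions = dataset.versions_seen
    known = sorted(v for v in versions if v)
    unknown = sum(1 for reps in dataset.groups.values()
                  for t in reps.values() if not t.metadata.tool_version)
    if len(known) > 1:
        msg = (
            f"tool versions differ across pooled tables: {known}. Comparing "
            "data from different tool versions can introduce a batch-"
            "dependent bias; re-analyze all data with one version."
        )
        warnings.warn(msg)
        return False, msg
    msg = f"all tables from tool version {known[0]}" if known else "no version information"
    if unknown:
        msg += f" ({unknown} table(s) with unknown version)"
        warnings.warn(f"{unknown} table(s) have no tool version recorded")
    return True, msg


def qc_screen(dataset: GroupedDataset, fence_multiplier: float = 1.5,
              branch_limit: int = 1) -> QCReport:
    """Advisory outlier screen over the pooled dataset.

    Per group and per QC measurement, values outside the Tukey fences
    ``[Q1 - k*IQR, Q3 + k*IQR]`` are flagged.  Cilia with more than
    ``branch_limit`` skeleton branches are flagged as highly branched (a
    clean cilium skeleton has a single branch), and zero-length cilia are
    flagged informationally (often spherical stubs or a wrong channel).
    Flags never remove records.
    """
    if dataset.n_records() == 0:
        raise ValueError("dataset is empty")
    report = QCReport()
    consistent, _ = check_version_consistency(dataset)
    report.version_consistent = consistent
    for group, reps in dataset.groups.items():
        report.per_group_counts[group] = sum(len(t) for t in reps.values())
        group_n = report.per_group_counts[group]
        fences = {}
        if group_n < 4:
            report.notices.append(
                f"group {group!r}: only {group_n} records, outlier fences skipped"
            )
        else:
            for meas in QC_MEASUREMENTS:
                vals = dataset.values(meas, group)
                vals = vals[~np.isnan(vals)] if vals.size else vals
                if vals.size >= 4:
                    q1, q3 = np.percentile(vals, [25, 75])
                    iqr = q3 - q1
                    fences[meas] = (q1 - fence_multiplier * iqr,
                                    q3 + fence_multiplier * iqr)
        for rep_id, table in reps.items():
            df = table.data
            for meas, (lo, hi) in fences.items():
                if meas not in df.columns:
                    continue
                for _, row in df[(df[meas] < lo) | (df[meas] > hi)].iterrows():
                    report.flags.append(QCFlag(
                        group, rep_id, int(row["id"]), meas,
                        f"outside [{lo:.3f}, {hi:.3f}] ({fence_multiplier}x IQR fence)",
                    ))
            if "n_branches" in df.columns:
                for _, row in df[df["n_branches"] > branch_limit].iterrows():
                    report.flags.append(QCFlag(
                        group, rep_id, int(row["id"]), "n_branches",
                        f"highly branched ({int(row['n_branches'])} > {branch_limit})",
                    ))
            if "cilia_length_um" in df.columns:
                for _, row in df[df["cilia_length_um"] == 0].iterrows():
                    report.flags.append(QCFlag(
                        group, rep_id, int(row["id"]), "cilia_length_um",
                        "zero length (often a spherical stub; check channel and segmentation)",
                    ))
    return report


# Feature-exclusion rules for dimensionality reduction: these columns
# encode identity, position or segmentation settings, not ciliary
# properties; voxel-unit columns duplicate micrometer-unit columns and
# would double-weight the same property.
_EXCLUDE_EXACT = {"id", "group", "replicate", "excluded_reason"}
_COORDINATE_NAMES = {"x", "y", "z", "x_um", "y_um", "z_um",
                     "x_coord", "y_coord", "z_coord"}
_UM_SUFFIXES = ("_um", "_um2", "_um3")


def _voxel_duplicate(col: str, columns) -> bool:
    for suffix in ("_voxels", "_vox", "_voxel"):
        if col.endswith(suffix):
            stem = col[: -len(suffix)]
            if any(c.startswith(stem) and c.endswith(_UM_SUFFIXES) and c != col
                   for c in columns):
                return True
    return False


def select_features(data: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Select and standardize the morphometric feature matrix.

    Excluded: ids, spatial coordinates, threshold columns, voxel-unit
    duplicates of micrometer-unit columns, non-numeric columns, and
    zero-variance columns.  Retained columns are standardized to zero
    mean and unit variance.  Returns the feature matrix and the list of
    excluded column names.
    """
    excluded = []
    retained = []
    for col in data.columns:
        if (col in _EXCLUDE_EXACT
                or col.lower() in _COORDINATE_NAMES
                or "threshold" in col.lower()
                or _voxel_duplicate(col, data.columns)):
            excluded.append(col)
        elif not pd.api.types.is_numeric_dtype(data[col]):
            excluded.append(col)
        else:
            retained.append(col)
    matrix = data[retained].astype(float)
    keep = []
    for col in retained:
        vals = matrix[col].to_numpy()
        if np.isnan(vals).any() or np.nanstd(vals) == 0:
            excluded.append(col)
        else:
            keep.append(col)
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 usable features remain after exclusion "
            f"(excluded: {excluded})"
        )
    matrix = matrix[keep]
    standardized = (matrix - matrix.mean()) / matrix.std(ddof=0)
    return standardized, excluded


def embed(features: pd.DataFrame, method: str = "pca", seed: int = 42,
          n_neighbors: int = 15, min_dist: float = 0.1):
    """2D embedding of the standardized feature matrix.

    PCA is deterministic up to sign; the sign convention makes the
    largest-magnitude loading of each component positive.  UMAP is seeded
    and reproducible for a fixed seed; ``n_neighbors`` is auto-reduced
    with a warning when it exceeds the record count.

    Returns ``(coordinates, info)`` where coordinates is an (n, 2) array
    and info holds method details (explained variance for PCA).
    """
    X = np.asarray(features, dtype=float)
    if len(X) <= 2:
        raise ValueError("need more than 2 records to embed")
    if method.lower() == "pca":
        if np.allclose(X.std(axis=0), 0):
            raise ValueError("all records identical: explained variance undefined")
        pca = PCA(n_components=2, random_state=seed)
        coords = pca.fit_transform(X)
        components = pca.components_.copy()
        for i in range(2):
            j = np.argmax(np.abs(components[i]))
            if components[i, j] < 0:
                components[i] *= -1
                coords[:, i] *= -1
        return coords, {
            "method": "PCA",
            "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
            "components": components,
        }
    if method.lower() == "umap":
        import umap  # deferred: heavy import

        if n_neighbors >= len(X):
            warnings.warn(
                f"n_neighbors={n_neighbors} >= n records ({len(X)}); reducing"
            )
            n_neighbors = max(2, len(X) - 1)
        reducer = umap.UMAP(n_components=2, random_state=seed,
                            n_neighbors=n_neighbors, min_dist=min_dist)
        coords = reducer.fit_transform(X)
        return np.asarray(coords), {"method": "UMAP", "seed": seed,
                                    "n_neighbors": n_neighbors,
                                    "min_dist": min_dist}
    raise ValueError(f"unknown embedding method {method!r}")


def discriminate(features: pd.DataFrame, group_labels) -> pd.DataFrame:
    """Per-feature discrimination weights from Linear Discriminant Analysis.

    Fits an LDA of the standardized features against the group labels and
    returns a table of discriminant coefficients per measurement, ranked
    by the largest absolute coefficient across discriminant axes — the
    top-ranked measurement separates the groups best.  With fewer records
    than features per group, shrinkage regularization is used.
    """
    y = np.asarray(group_labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 groups")
    X = np.asarray(features, dtype=float)
    min_class = min((y == c).sum() for c in classes)
    n_axes = min(len(classes) - 1, X.shape[1])
    if min_class > X.shape[1]:
        lda = LinearDiscriminantAnalysis(solver="eigen")
    else:
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear-feature warnings
        lda.fit(X, y)
    axes = lda.scalings_[:, :n_axes].T  # (n_axes, n_features)
    table = pd.DataFrame(
        axes.T,
        index=list(features.columns),
        columns=[f"LD{i + 1}" for i in range(axes.shape[0])],
    )
    table["max_abs_coefficient"] = table.abs().max(axis=1)
    table = table.sort_values("max_abs_coefficient", ascending=False)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
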