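"""Reading and writing image stacks, per-cilium tables, and run metadata.

On-disk conventions
-------------------
Images travel as multi-page TIFF with ImageJ-style metadata carrying the
voxel size; in memory a stack is a ``(channel, z, y, x)`` array plus
physical voxel sizes in micrometers.

Per-cilium measurement tables are UTF-8 TSV with a single header row,
``.`` as the decimal separator (the "US" number format) and fixed
3-decimal formatting for micrometer-scale quantities.  Each table has a
plain-text metadata sidecar (``<stem>.meta.txt``) recording the tool
version and the segmentation settings that produced it, so that pooled
analyses can verify that every replicate was produced by the same tool
version.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Suffix of the plain-text metadata sidecar accompanying each table.
META_SUFFIX = ".meta.txt"

#: Decimal places used for physical (micrometer-scale) quantities on disk.
DECIMALS = 3

_NUMERIC_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$|^nan$|^[+-]?inf$", re.IGNORECASE)
_COMMA_DECIMAL_RE = re.compile(r"^[+-]?\d+,\d+$")


class DialectError(ValueError):
    """A table does not follow the expected TSV / US-decimal dialect."""


@dataclass
class ImageStack:
    """A multi-channel 3D image with physical voxel sizes.

    Parameters
    ----------
    voxels : ndarray
        Intensities indexed ``(channel, z, y, x)``.
    voxel_size_um : tuple of float
        Physical voxel size ``(dx, dy, dz)`` in micrometers.
    bit_depth : int
        8, 12 or 16; intensities must fit the corresponding range.
    channel_labels : list of str, optional
        One label per channel.
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    bit_depth: int = 16
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (channel, z, y, x); got shape {self.voxels.shape}"
            )
        if self.voxels.shape[0] < 1 or self.voxels.shape[1] < 1:
            raise ValueError("stack needs at least one channel and one z-slice")
        dx, dy, dz = self.voxel_size_um
        if not (dx > 0 and dy > 0 and dz > 0):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_um}")
        self.voxel_size_um = (float(dx), float(dy), float(dz))
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if self.voxels.size and float(self.voxels.max()) > self.intensity_max:
            raise ValueError(
                f"intensities exceed {self.bit_depth}-bit range "
                f"(max {float(self.voxels.max())} > {self.intensity_max})"
            )
        if self.channel_labels is not None and len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1

    def channel(self, index: int) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` array."""
        if not 0 <= index < self.n_channels:
            raise IndexError(
                f"channel {index} out of range for {self.n_channels}-channel stack"
            )
        return self.voxels[index]

    def with_voxels(self, voxels: np.ndarray, channel_labels: list[str] | None = None) -> "ImageStack":
        """A copy of this stack carrying new voxel data, same geometry."""
        return ImageStack(
            voxels=voxels,
            voxel_size_um=self.voxel_size_um,
            bit_depth=self.bit_depth,
            channel_labels=channel_labels if channel_labels is not None else self.channel_labels,
        )


@dataclass
class RunMetadata:
    """Provenance of a segmentation / quantification run.

    ``settings`` is a flat mapping of setting name to value; values are
    stringified on disk and round-trip unchanged.  ``edit_log`` records
    programmatic mask edits (add/remove region operations).
    """

    tool_version: str = ""
    settings: dict[str, str] = field(default_factory=dict)
    number_format: str = "US"
    edit_log: list[str] = field(default_factory=list)

    @property
    def version_known(self) -> bool:
        return bool(self.tool_version)

    def to_text(self) -> str:
        lines = [f"tool_version\t{self.tool_version}", f"number_format\t{self.number_format}"]
        for key in sorted(self.settings):
            lines.append(f"setting.{key}\t{self.settings[key]}")
        for entry in self.edit_log:
            lines.append(f"edit\t{entry}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunMetadata":
        meta = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition("\t")
            if key == "tool_version":
                meta.tool_version = value
            elif key == "number_format":
                meta.number_format = value
            elif key.startswith("setting."):
                meta.settings[key[len("setting."):]] = value
            elif key == "edit":
                meta.edit_log.append(value)
        return meta


# Canonical measurement columns of a per-cilium record.  The id column and
# the excluded_reason column are bookkeeping; everything else is numeric.
RECORD_COLUMNS = [
    "id",
    "x_um", "y_um", "z_um",
    "volume_voxels", "volume_um3",
    "surface_um2", "max_span_um",
    "n_branches", "tree_length_um", "cilia_length_um", "bending_ratio",
    "orientation_x", "orientation_y", "orientation_z",
    "recon_intensity_mean", "recon_intensity_sd",
    "recon_intensity_min", "recon_intensity_max",
    "touches_x_border", "touches_y_border", "touches_z_border",
    "excluded_reason",
]


@dataclass
class CiliumRecord:
    """Morphometric and intensity measurements of one cilium.

    Lengths and coordinates are in micrometers; ``bending_ratio`` is the
    straight-line end-to-end distance divided by the skeleton-path cilium
    length (1 for a perfectly straight cilium).  Intensity statistics are
    computed over the original (unsegmented) channel within the mask.
    """

    id: int
    x_um: float = np.nan
    y_um: float = np.nan
    z_um: float = np.nan
    volume_voxels: int = 0
    volume_um3: float = np.nan
    surface_um2: float = np.nan
    max_span_um: float = np.nan
    n_branches: int = 0
    tree_length_um: float = np.nan
    cilia_length_um: float = np.nan
    bending_ratio: float = np.nan
    orientation_x: float = np.nan
    orientation_y: float = np.nan
    orientation_z: float = np.nan
    recon_intensity_mean: float = np.nan
    recon_intensity_sd: float = np.nan
    recon_intensity_min: float = np.nan
    recon_intensity_max: float = np.nan
    touches_x_border: int = 0
    touches_y_border: int = 0
    touches_z_border: int = 0
    excluded_reason: str = "none"
    extra: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {col: getattr(self, col) for col in RECORD_COLUMNS}
        row.update(self.extra)
        return row


@dataclass
class CiliaTable:
    """A table of :class:`CiliumRecord` rows plus provenance.

    ``data`` is the canonical in-memory container (a pandas DataFrame with
    one row per cilium); ``records`` offers dataclass access for canonical
    columns.
    """

    data: pd.DataFrame
    source_image: str = ""
    metadata: RunMetadata = field(default_factory=RunMetadata)
    replicate_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        if "id" not in self.data.columns:
            raise ValueError("cilia table requires an 'id' column")
        ids = self.data["id"].tolist()
        if len(ids) != len(set(ids)):
            raise ValueError("cilium ids must be unique within a table")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_records(cls, records: list[CiliumRecord], **kwargs) -> "CiliaTable":
        rows = [r.as_row() for r in records]
        columns = RECORD_COLUMNS + sorted(
            {k for r in rows for k in r} - set(RECORD_COLUMNS)
        )
        data = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
        return cls(data=data, **kwargs)

    @property
    def records(self) -> list[CiliumRecord]:
        out = []
        known = set(RECORD_COLUMNS)
        for _, row in self.data.iterrows():
            kwargs = {c: row[c] for c in RECORD_COLUMNS if c in row.index}
            extra = {c: row[c] for c in row.index if c not in known}
            kwargs["id"] = int(kwargs["id"])
            out.append(CiliumRecord(extra=extra, **kwargs))
        return out


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF with voxel-size metadata.

    Voxel sizes are stored in the ImageJ convention: x/y via the TIFF
    resolution tags (pixels per micrometer) and z via the ``spacing``
    entry, all in micrometers.
    """
    path = Path(path)
    dx, dy, dz = stack.voxel_size_um
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    data = np.asarray(np.rint(stack.voxels), dtype=dtype)
    # ImageJ hyperstack axis order is (z, channel, y, x)
    tifffile.imwrite(
        path,
        np.moveaxis(data, 0, 1),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={
            "spacing": dz,
            "unit": "um",
            "axes": "ZCYX",
            "ciliametry_bit_depth": stack.bit_depth,
        },
    )
    return path


def read_image_stack(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    bit_depth: int | None = None,
) -> ImageStack:
    """Read a TIFF z-stack into the canonical ``(channel, z, y, x)`` layout.

    The voxel size is taken from the file's ImageJ/resolution metadata; if
    absent it must be supplied via ``voxel_size_um``, because all
    measurements are reported in micrometers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "ZCYX", "CZYX", "ZYX", "YX"
        meta_voxel = _voxel_size_from_tiff(tif)
        ij = tif.imagej_metadata or {}
    # Normalize axes to (C, Z, Y, X)
    axes = axes.replace("S", "C")  # sample axis treated as channel
    for ax in axes:
        if ax not in "CZYX":
            raise ValueError(f"unsupported TIFF axis {ax!r} in {path.name}")
    for missing in set("CZYX") - set(axes):
        data = data[np.newaxis]
        axes = missing + axes
    order = [axes.index(ax) for ax in "CZYX"]
    data = np.transpose(data, order)

    if voxel_size_um is None:
        voxel_size_um = meta_voxel
    if voxel_size_um is None:
        raise ValueError(
            f"{path.name} carries no voxel-size metadata; pass voxel_size_um "
            "explicitly (measurements are in micrometers and cannot be "
            "computed without it)"
        )
    if bit_depth is None:
        bit_depth = int(ij.get("ciliametry_bit_depth", 0)) or (
            8 if data.dtype == np.uint8 else 16
        )
    return ImageStack(voxels=data, voxel_size_um=voxel_size_um, bit_depth=bit_depth)


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Recover (dx, dy, dz) in micrometers from ImageJ-style TIFF metadata."""
    ij = tif.imagej_metadata or {}
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    dz = ij.get("spacing")
    if xres is None or yres is None or dz is None:
        return None
    xr = xres.value[0] / xres.value[1]
    yr = yres.value[0] / yres.value[1]
    if xr <= 0 or yr <= 0:
        return None
    return (1.0 / xr, 1.0 / yr, float(dz))


def _format_cell(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "nan"
        return f"{value:.{DECIMALS}f}"
    return str(value)


def write_cilia_table(table: CiliaTable, path: str | Path) -> Path:
    """Write a cilia table as TSV plus its metadata sidecar.

    Numeric cells use the US decimal point at fixed 3-decimal precision so
    that write -> read -> write is byte-stable.
    """
    path = Path(path)
    df = table.data
    lines = ["\t".join(map(str, df.columns))]
    for _, row in df.iterrows():
        lines.append("\t".join(_format_cell(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    meta_path = path.parent / (path.stem + META_SUFFIX)
    meta_text = table.metadata.to_text()
    if table.source_image:
        meta_text += f"source_image\t{table.source_image}\n"
    meta_path.write_text(meta_text, encoding="utf-8")
    return path


def read_cilia_table(path: str | Path) -> CiliaTable:
    """Read a TSV cilia table; never silently coerce malformed numbers.

    A column is parsed as numeric only if every cell in it parses as a
    US-decimal number; a column where no cell parses is kept as text; a
    mixed column raises.  Comma-decimal cells raise :class:`DialectError`.
    If the metadata sidecar is missing the table loads with an unknown
    tool version (downstream pooling will warn).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    parsed = {}
    for col in raw.columns:
        cells = raw[col].tolist()
        n_numeric = 0
        for cell in cells:
            if _COMMA_DECIMAL_RE.match(cell.strip()):
                raise DialectError(
                    f"{path.name}, column {col!r}: comma-decimal value "
                    f"{cell!r}; tables must use the US '.' decimal format"
                )
            if _NUMERIC_RE.match(cell.strip()):
                n_numeric += 1
        if cells and n_numeric == len(cells):
            if all(re.fullmatch(r"[+-]?\d+", c.strip()) for c in cells):
                parsed[col] = [int(c) for c in cells]
            else:
                parsed[col] = [float(c) for c in cells]
        elif n_numeric == 0 or not cells:
            parsed[col] = cells
        else:
            bad = next(c for c in cells if not _NUMERIC_RE.match(c.strip()))
            raise DialectError(
                f"{path.name}, column {col!r}: non-numeric cell {bad!r} in a "
                "numeric column"
            )
    df = pd.DataFrame(parsed, columns=list(raw.columns))
    if "id" in df.columns and pd.api.types.is_numeric_dtype(df["id"]):
        df["id"] = df["id"].astype(int)

    meta_path = path.parent / (path.stem + META_SUFFIX)
    source_image = ""
    if meta_path.exists():
        text = meta_path.read_text(encoding="utf-8")
        metadata = RunMetadata.from_text(text)
        for line in text.splitlines():
            if line.startswith("source_image\t"):
                source_image = line.split("\t", 1)[1]
    else:
        metadata = RunMetadata(tool_version="")
        logger.warning("%s: no metadata sidecar; tool version unknown", path.name)
    return CiliaTable(
        data=df,
        source_image=source_image,
        metadata=metadata,
        replicate_id=path.stem,
    )


def read_metafile(path: str | Path) -> dict[str, str]:
    """Read an experimental metafile of key/value annotations.

    Accepts CSV or TSV with (at least) two columns; the first is the key,
    the second the value.  Duplicate keys: last value wins with a warning.
    An unreadable file yields an empty annotation set with a warning so
    that the analysis proceeds without metadata.
    """
    path = Path(path)
    annotations: dict[str, str] = {}
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        warnings.warn(f"metafile {path} unreadable ({exc}); proceeding without metadata")
        return annotations
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return annotations
    sep = "\t" if "\t" in lines[0] else ","
    if lines[0].lower().replace(" ", "").split(sep)[:2] == ["key", "value"]:
        lines = lines[1:]
    for line in lines:
        parts = line.split(sep)
        if len(parts) < 2:
            continue
        key, value = parts[0].strip(), parts[1].strip()
        if key in annotations:
            warnings.warn(f"metafile {path.name}: duplicate key {key!r}; last value wins")
        annotations[key] = value
    return annotations
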