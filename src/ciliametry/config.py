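"""Flat key=value pipeline configuration with lossless round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run.

    Every run writes its resolved configuration next to its outputs so
    runs are self-describing and reproducible.
    """

    seed: int = 42
    output_root: str = "."
    # phantom stage
    n_phantoms: int = 5
    length_min_um: float = 2.0
    length_max_um: float = 10.0
    radius_um: float = 0.25
    snr: float = 5.0
    voxel_dx_um: float = 0.08
    voxel_dy_um: float = 0.08
    voxel_dz_um: float = 0.5
    # preparator stage
    channel_index: int = 0
    bg_radius_px: float = -1.0        # <= 0 disables
    blur_sigma_px: float = 1.5
    method: str = "hysteresis:yen:otsu"
    style: str = "keep-intensities"
    histogram_source: str = "max-projection"
    # quantifier stage
    min_size_voxels: int = -1         # <= 0 means suggest from pixel size
    exclude_borders: str = "xyz"
    increase_range: bool = True
    gauss_xy_sigma: float = 0.5
    # explorer stage
    alpha: float = 0.05
    no_stats: bool = False
    plot_format: str = "both"
    run_umap: bool = True

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        values = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = raw.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values.pop(f.name)
            if f.type == "bool" or isinstance(getattr(cls, f.name, None), bool):
                kwargs[f.name] = raw.lower() in ("true", "1", "yes")
            elif f.type == "int":
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        if values:
            raise ValueError(f"unknown config keys: {sorted(values)}")
        return cls(**kwargs)

    def parsed_method(self):
        """Parse the method string: 'otsu', '123', or 'hysteresis:low:high'."""
        m = self.method
        if m.startswith("hysteresis:"):
            _, low, high = m.split(":")
            return ("hysteresis", _maybe_int(low), _maybe_int(high))
        return _maybe_int(m)

    def parsed_borders(self) -> tuple[bool, bool, bool]:
        s = self.exclude_borders.lower()
        return ("x" in s, "y" in s, "z" in s)


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s
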