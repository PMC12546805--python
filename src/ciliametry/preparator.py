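"""Segmentation preparation: preprocessing, thresholding, mask editing.

Turns a raw multi-channel z-stack into a segmentation-ready stack.  The
marker channel is optionally background-subtracted (slice-wise rolling
ball) and Gaussian-smoothed, a threshold is selected on a histogram —
by default of the maximum-intensity projection, mirroring how thresholds
are tested manually on a projection — and applied voxel-wise to the full
3D stack.  Two segmentation styles are supported: ``keep-intensities``
zeroes sub-threshold voxels and preserves intensities above (a
background-removed image), ``binary`` sets supra-threshold voxels to the
maximum representable intensity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.restoration import rolling_ball

from ciliametry.io_formats import ImageStack, RunMetadata
from ciliametry.thresholds import METHOD_NAMES, auto_threshold
from ciliametry._version import __version__

logger = logging.getLogger(__name__)

#: 26-connectivity structuring element used for 3D component linking.
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationSettings:
    """Settings controlling :func:`segment_stack`.

    ``method`` is a threshold method name, a manual integer threshold, or
    a ``("hysteresis", low, high)`` tuple where low/high are themselves
    method names or manual values.  ``histogram_source`` selects whether
    the threshold histogram is built from the maximum-intensity
    projection (default) or the full stack.
    """

    channel_index: int = 0
    include_unsegmented_copy: bool = True
    bg_radius_px: float | None = None
    blur_sigma_px: float | None = None
    method: object = "otsu"
    style: str = "keep-intensities"
    histogram_source: str = "max-projection"

    def __post_init__(self) -> None:
        if self.style not in ("keep-intensities", "binary"):
            raise ValueError(f"unknown segmentation style {self.style!r}")
        if self.histogram_source not in ("max-projection", "full-stack"):
            raise ValueError(f"unknown histogram source {self.histogram_source!r}")

    def as_settings_dict(self) -> dict[str, str]:
        return {
            "channel_index": str(self.channel_index),
            "include_unsegmented_copy": str(self.include_unsegmented_copy),
            "bg_radius_px": str(self.bg_radius_px),
            "blur_sigma_px": str(self.blur_sigma_px),
            "method": str(self.method),
            "style": self.style,
            "histogram_source": self.histogram_source,
        }


def subtract_background(stack: ImageStack, radius_px: float) -> ImageStack:
    """Remove smooth background slice-wise with a rolling-ball estimate.

    The rolling ball of the given pixel radius is applied independently to
    every (channel, z) slice; the estimated background is subtracted and
    the result clipped at zero.  A constant image maps to all zeros.
    """
    if radius_px <= 0:
        raise ValueError(f"radius must be positive, got {radius_px}")
    ny, nx = stack.voxels.shape[-2:]
    if radius_px > max(ny, nx):
        raise ValueError(
            f"rolling-ball radius {radius_px} exceeds image extent ({ny}x{nx})"
        )
    out = np.empty_like(stack.voxels, dtype=float)
    for c in range(stack.voxels.shape[0]):
        for z in range(stack.voxels.shape[1]):
            sl = stack.voxels[c, z].astype(float)
            bg = rolling_ball(sl, radius=radius_px)
            out[c, z] = np.clip(sl - bg, 0, None)
    return stack.with_voxels(out.astype(stack.voxels.dtype))


def gaussian_blur(stack: ImageStack, sigma_px: float) -> ImageStack:
    """Smooth every slice with a 2D Gaussian of the given pixel sigma.

    ``sigma_px = 0`` is the identity.  Total intensity is conserved (up
    to boundary effects) because the kernel is normalized.
    """
    if sigma_px < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma_px}")
    if sigma_px == 0:
        return stack.with_voxels(stack.voxels.copy())
    blurred = ndi.gaussian_filter(
        stack.voxels.astype(float), sigma=(0, 0, sigma_px, sigma_px)
    )
    return stack.with_voxels(blurred)


def _to_int_image(volume: np.ndarray, bit_depth: int) -> np.ndarray:
    """Round/clip a possibly-float volume into integer bins for histograms."""
    upper = (1 << bit_depth) - 1
    return np.clip(np.rint(volume), 0, upper).astype(np.int64)


def _histogram(volume: np.ndarray, bit_depth: int) -> np.ndarray:
    n_bins = 1 << bit_depth
    ints = _to_int_image(volume, bit_depth)
    return np.bincount(ints.ravel(), minlength=n_bins)


def _evaluate_threshold(volume: np.ndarray, method_or_value, bit_depth: int,
                        histogram_source: str) -> int:
    if isinstance(method_or_value, (int, np.integer)):
        value = int(method_or_value)
        if not 0 <= value <= (1 << bit_depth) - 1:
            raise ValueError(
                f"manual threshold {value} outside {bit_depth}-bit range"
            )
        return value
    if histogram_source == "max-projection":
        source = volume.max(axis=0)
    else:
        source = volume
    hist = _histogram(source, bit_depth)
    return auto_threshold(hist, str(method_or_value))


def hysteresis_segment(volume: np.ndarray, low: int, high: int) -> np.ndarray:
    """Two-level hysteresis segmentation with 26-connected linking.

    Foreground is the union of those 26-connected components of the
    low-threshold mask (``volume > low``) that contain at least one voxel
    above the high threshold; a dim object exceeding only the low
    threshold is discarded even though all its voxels pass ``low``.
    The result always satisfies ``mask(high) ⊆ result ⊆ mask(low)``.
    """
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")
    volume = np.asarray(volume)
    mask_low = volume > low
    mask_high = volume > high
    labels, n = ndi.label(mask_low, structure=np.ones((3,) * volume.ndim, bool))
    if n == 0:
        return np.zeros_like(mask_low)
    seeded = np.unique(labels[mask_high])
    seeded = seeded[seeded > 0]
    keep = np.zeros(n + 1, dtype=bool)
    keep[seeded] = True
    return keep[labels]


def segment_stack(stack: ImageStack, settings: SegmentationSettings
                  ) -> tuple[ImageStack, RunMetadata]:
    """Segment the marker channel of a stack.

    Returns the output stack — segmented channel first, followed by an
    unsegmented copy when requested — together with the run metadata
    recording the tool version, the settings, and the evaluated
    threshold(s).
    """
    channel = stack.channel(settings.channel_index).astype(float)
    work = stack.with_voxels(channel[np.newaxis])
    if settings.bg_radius_px is not None:
        work = subtract_background(work, settings.bg_radius_px)
    if settings.blur_sigma_px is not None:
        work = gaussian_blur(work, settings.blur_sigma_px)
    volume = work.voxels[0]

    meta = RunMetadata(tool_version=f"v{__version__}",
                       settings=settings.as_settings_dict())

    method = settings.method
    if isinstance(method, tuple) and len(method) == 3 and method[0] == "hysteresis":
        low = _evaluate_threshold(volume, method[1], stack.bit_depth,
                                  settings.histogram_source)
        high = _evaluate_threshold(volume, method[2], stack.bit_depth,
                                   settings.histogram_source)
        if low > high:
            raise ValueError(
                f"hysteresis low threshold ({low}) exceeds high ({high}) "
                "after evaluation"
            )
        mask = hysteresis_segment(volume, low, high)
        meta.settings["threshold_low"] = str(low)
        meta.settings["threshold_high"] = str(high)
    else:
        t = _evaluate_threshold(volume, method, stack.bit_depth,
                                settings.histogram_source)
        mask = volume > t
        meta.settings["threshold"] = str(t)

    if not mask.any():
        warnings.warn("segmentation produced an empty mask (no voxel above threshold)")

    original = stack.channel(settings.channel_index)
    if settings.style == "binary":
        segmented = np.where(mask, stack.intensity_max, 0)
    else:
        # keep-intensities: background-removed image; intensities are those
        # of the (preprocessed) volume the threshold was applied to
        segmented = np.where(mask, np.rint(volume), 0)

    channels = [segmented]
    labels = ["segmented"]
    if settings.include_unsegmented_copy:
        channels.append(original)
        labels.append("unsegmented")
    out = ImageStack(
        voxels=np.stack(channels).astype(stack.voxels.dtype),
        voxel_size_um=stack.voxel_size_um,
        bit_depth=stack.bit_depth,
        channel_labels=labels,
    )
    return out, meta


def apply_mask_edit(mask: np.ndarray, region, mode: str,
                    metadata: RunMetadata | None = None) -> np.ndarray:
    """Add or remove a set of ``(z, y, x)`` voxels from a binary mask.

    Mirrors interactive mask refinement: ``add`` sets the region voxels to
    foreground, ``remove`` clears them; all other voxels are untouched.
    The edit is appended to ``metadata.edit_log`` when metadata is given.
    """
    if mode not in ("add", "remove"):
        raise ValueError(f"mode must be 'add' or 'remove', got {mode!r}")
    mask = np.asarray(mask).astype(bool)
    region = [tuple(int(c) for c in v) for v in region]
    out_of_bounds = [v for v in region
                     if any(c < 0 or c >= s for c, s in zip(v, mask.shape))]
    if out_of_bounds:
        raise IndexError(f"voxels outside image bounds: {out_of_bounds}")
    edited = mask.copy()
    if region:
        idx = tuple(np.array(region).T)
        edited[idx] = mode == "add"
    if metadata is not None:
        metadata.edit_log.append(f"{mode} {len(region)} voxels")
    return edited


def compute_sampling_limits(emission_wavelength_nm: float,
                            numerical_aperture: float) -> tuple[float, float]:
    """Rayleigh lateral resolution and the Nyquist sampling interval.

    Resolution is ``0.61·λ/NA`` (nm); the Nyquist interval is half of it
    (the voxel size should be no larger than half the optical
    resolution).  Raw values are returned; rounding is left to the
    caller.
    """
    if emission_wavelength_nm <= 0:
        raise ValueError("emission wavelength must be positive")
    if not 0 < numerical_aperture <= 1.7:
        raise ValueError("numerical aperture must be in (0, 1.7]")
    resolution = 0.61 * emission_wavelength_nm / numerical_aperture
    return resolution, resolution / 2.0
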