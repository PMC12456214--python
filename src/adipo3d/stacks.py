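"""In-memory containers for 3D image and label stacks, with TIFF I/O.

Axis convention throughout the package: arrays are ``(Z, Y, X)`` for label
stacks and ``(C, Z, Y, X)`` for multi-channel intensity stacks, matching the
acquisition order of a confocal z-series. All physical quantities are in
micrometres; ``spacing`` is the per-axis voxel pitch ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Default isotropic confocal voxel pitch in µm.
DEFAULT_SPACING: tuple[float, float, float] = (1.15, 1.15, 1.15)


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing!r}")
    return spacing


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence stack.

    Parameters
    ----------
    intensities:
        Non-negative array of shape ``(C, Z, Y, X)``. Channel 0 is the
        extracellular-matrix (ECM, "green") channel and channel 1 the lipid
        ("red") channel for two-channel tissue stacks; extracted-cell stacks
        carry a single (lipid) channel.
    spacing:
        Voxel pitch ``(z, y, x)`` in µm.
    channel_names:
        One name per channel.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be a (C, Z, Y, X) array")
        if self.intensities.size and self.intensities.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.spacing = _validate_spacing(self.spacing)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("one channel name required per channel")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    def channel(self, index_or_name) -> np.ndarray:
        if isinstance(index_or_name, str):
            index_or_name = self.channel_names.index(index_or_name)
        return self.intensities[index_or_name]

    def save(self, path) -> None:
        save_image(path, self)


@dataclass
class LabelStack:
    """A 3D instance segmentation: 0 is background, each positive integer
    marks one cell."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a (Z, Y, X) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the stack."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.ids.size)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def save(self, path) -> None:
        save_labels(path, self)


def _imagej_metadata(spacing):
    # ImageJ-style calibration: XY resolution in pixels/µm, Z as 'spacing'.
    return dict(
        resolution=(1.0 / spacing[2], 1.0 / spacing[1]),
        metadata={"spacing": spacing[0], "unit": "um"},
        imagej=True,
    )


def save_image(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as an unsigned 16-bit multi-page TIFF."""
    data = np.clip(np.rint(stack.intensities), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16), **_imagej_metadata(stack.spacing))


def load_image(path, spacing=DEFAULT_SPACING, channel_names=None) -> ImageStack:
    """Read an intensity TIFF written by :func:`save_image` (or any CZYX/ZYX
    TIFF); single-volume files become one-channel stacks."""
    data = np.asarray(tifffile.imread(path))
    if data.ndim == 3:
        data = data[None]
    return ImageStack(data.astype(np.float64), spacing, list(channel_names or []))


def save_labels(path, stack: LabelStack) -> None:
    """Write a :class:`LabelStack` as an unsigned 32-bit multi-page TIFF.

    Plain TIFF (not ImageJ-flavoured: ImageJ files cannot carry uint32);
    the spacing lives in the cohort manifest and must be supplied on load.
    """
    tifffile.imwrite(
        path,
        stack.labels.astype(np.uint32),
        resolution=(1.0 / stack.spacing[2], 1.0 / stack.spacing[1]),
    )


def load_labels(path, spacing=DEFAULT_SPACING) -> LabelStack:
    """Read an integer label TIFF (e.g. external ``*_masks`` output).

    Label values are preserved verbatim; ``spacing`` must be supplied by the
    caller because mask files rarely carry trustworthy calibration.
    """
    labels = np.asarray(tifffile.imread(path))
    if labels.ndim == 2:
        labels = labels[None]
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.allclose(labels, rounded):
            raise ValueError(f"{path}: label TIFF contains non-integer values")
        labels = rounded
    return LabelStack(labels.astype(np.int64), spacing)
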