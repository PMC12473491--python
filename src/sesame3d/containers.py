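"""Core in-memory containers shared by every pipeline stage.

Coordinates live in arbitrary reconstruction units (whatever the multi-view
reconstruction emitted); real-world units only enter through the calibration
scale factor ``r`` (cm per reconstruction unit) when traits are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Semantic label scheme used throughout: 0 = stem, 1 = petiole, 2 = leaf.
STEM, PETIOLE, LEAF = 0, 1, 2
SEMANTIC_CLASSES = (STEM, PETIOLE, LEAF)
NOISE_INSTANCE = -1


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


@dataclass
class PointCloud:
    """N x 3 coordinates plus optional per-point 8-bit RGB.

    Parameters
    ----------
    coords
        ``(N, 3)`` float array, reconstruction units. Stored as float64.
    colors
        Optional ``(N, 3)`` integer array with values in ``[0, 255]``.
        Either every point has a color or none does.
    """

    coords: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.isfinite(self.coords).all():
            raise ValueError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if self.colors.shape != self.coords.shape:
                raise ValueError(
                    f"colors shape {self.colors.shape} does not match "
                    f"coords shape {self.coords.shape}"
                )
            if self.colors.size and (
                self.colors.min() < 0 or self.colors.max() > 255
            ):
                raise ValueError("colors must lie in [0, 255]")
            self.colors = self.colors.astype(np.uint8)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset / reorder by an index or boolean mask, colors carried along."""
        colors = self.colors[index] if self.colors is not None else None
        return PointCloud(self.coords[index], colors)

    def copy(self) -> "PointCloud":
        colors = None if self.colors is None else self.colors.copy()
        return PointCloud(self.coords.copy(), colors)


@dataclass
class LabeledCloud:
    """A :class:`PointCloud` with per-point semantic and instance labels.

    ``semantic`` holds organ classes (0 stem / 1 petiole / 2 leaf);
    ``instance`` holds leaf-instance ids with ``-1`` meaning noise or
    not-yet-assigned.
    """

    cloud: PointCloud
    semantic: np.ndarray
    instance: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.cloud)
        self.semantic = np.asarray(self.semantic, dtype=np.int64).reshape(-1)
        if self.semantic.shape[0] != n:
            raise ValueError("semantic labels must match point count")
        if self.semantic.size and not np.isin(self.semantic, SEMANTIC_CLASSES).all():
            bad = np.setdiff1d(np.unique(self.semantic), SEMANTIC_CLASSES)
            raise ValueError(f"semantic labels outside {{0,1,2}}: {bad.tolist()}")
        if self.instance is None:
            self.instance = np.full(n, NOISE_INSTANCE, dtype=np.int64)
        else:
            self.instance = np.asarray(self.instance, dtype=np.int64).reshape(-1)
            if self.instance.shape[0] != n:
                raise ValueError("instance labels must match point count")
            if self.instance.size and self.instance.min() < NOISE_INSTANCE:
                raise ValueError("instance ids must be >= -1")

    def __len__(self) -> int:
        return len(self.cloud)

    def select(self, index: np.ndarray) -> "LabeledCloud":
        return LabeledCloud(
            self.cloud.select(index), self.semantic[index], self.instance[index]
        )

    def organ(self, label: int) -> PointCloud:
        """Sub-cloud of one semantic class."""
        return self.cloud.select(self.semantic == label)


@dataclass
class ScaleCalibration:
    """Scale factor turning reconstruction units into centimetres.

    ``r = h_real / h_reconstructed`` where ``h_real`` is the physical edge
    length of the calibration cube (2 cm by default) and ``h_reconstructed``
    its edge length measured in the point-cloud model.
    """

    r: float
    h_real: float = 2.0
    h_reconstructed: float | None = None

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("scale factor r must be positive")


@dataclass
class LeafTraits:
    """Per-leaf geometric traits in real units."""

    instance_id: int
    length_cm: float
    width_cm: float
    angle_deg: float
    area_cm2: float

    def __post_init__(self) -> None:
        for name in ("length_cm", "width_cm", "area_cm2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError("leaf angle must lie in [0, 180] degrees")


@dataclass
class TraitReport:
    """Plant-level and per-leaf phenotypic parameters in real units."""

    plant_height_cm: float
    stem_diameter_mm: float
    leaves: list[LeafTraits] = field(default_factory=list)
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.plant_height_cm < 0 or self.stem_diameter_mm < 0:
            raise ValueError("plant-level traits must be >= 0")
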