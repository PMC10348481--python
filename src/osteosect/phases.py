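"""Integer-coded section phases and the labelled-section container.

Label codes follow the staining-derived tissue classes of an
undecalcified section: 0 marrow, 1 mineralized bone, 2 osteoid,
3 adipocyte, 4 mineralized cartilage, 5 calibration-standard patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import tifffile
from scipy import ndimage

MARROW = 0
BONE = 1
OSTEOID = 2
ADIPOCYTE = 3
CARTILAGE = 4
STANDARD = 5

PHASE_NAMES = {
    MARROW: "marrow",
    BONE: "mineralized_bone",
    OSTEOID: "osteoid",
    ADIPOCYTE: "adipocyte",
    CARTILAGE: "mineralized_cartilage",
    STANDARD: "standard_patch",
}

#: phases counted as mineralized matrix (bone proper plus calcified cartilage)
MINERALIZED_LABELS = (BONE, CARTILAGE)

ANNOTATION_KEYS = ("osteoblast_covered", "osteoclast_covered", "eroded")

_EIGHT = np.ones((3, 3), dtype=bool)


def mineralized_from_labels(labels: np.ndarray) -> np.ndarray:
    """Boolean mask of mineralized-matrix pixels."""
    return np.isin(labels, MINERALIZED_LABELS)


def bone_boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Mineralized pixels with a non-mineralized 8-neighbour inside the image.

    The image border itself does not create surface: a mineralized pixel
    at the edge is boundary only if one of its in-image neighbours is
    soft tissue.
    """
    bone = mineralized_from_labels(labels)
    interior = ndimage.binary_erosion(bone, structure=_EIGHT, border_value=1)
    return bone & ~interior


@dataclass(frozen=True)
class PhaseLabelMap:
    """Phase labels of a stained section plus optional surface annotations.

    ``surface_annotations`` maps each of ``osteoblast_covered``,
    ``osteoclast_covered`` and ``eroded`` to a boolean mask of
    bone-surface pixels; None means the layers were not recorded (e.g.
    no usable stained section) and surface indices are not evaluable.
    """

    labels: np.ndarray
    pixel_size_um: float = 1.8
    surface_annotations: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        codes = np.unique(labels)
        if not np.isin(codes, list(PHASE_NAMES)).all():
            raise ValueError(f"unknown label codes: {sorted(set(codes) - set(PHASE_NAMES))}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))
        if self.surface_annotations is not None:
            bone = mineralized_from_labels(labels)
            near_bone = ndimage.binary_dilation(bone, structure=_EIGHT)
            ann = {}
            for key in ANNOTATION_KEYS:
                mask = np.asarray(
                    self.surface_annotations.get(key, np.zeros_like(bone)), dtype=bool
                )
                if mask.shape != labels.shape:
                    raise ValueError(f"annotation {key!r} shape mismatch")
                if (mask & ~near_bone).any():
                    raise ValueError(
                        f"annotation {key!r} has pixels not adjacent to bone"
                    )
                ann[key] = mask
            object.__setattr__(self, "surface_annotations", ann)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def phase_area_um2(self) -> dict[str, float]:
        """Area of every phase in µm², including zero-area phases."""
        px2 = self.pixel_size_um**2
        return {
            name: float(np.count_nonzero(self.labels == code) * px2)
            for code, name in PHASE_NAMES.items()
        }

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.labels)

    @classmethod
    def from_tiff(
        cls, path, pixel_size_um: float = 1.8, surface_annotations=None
    ) -> "PhaseLabelMap":
        return cls(
            labels=tifffile.imread(path),
            pixel_size_um=pixel_size_um,
            surface_annotations=surface_annotations,
        )
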