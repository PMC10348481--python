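"""Bone-marrow adipocyte detection and marrow area-fraction analysis.

Adipocytes appear as roundish voids in the marrow space.  Candidate
regions come either from the adipocyte phase of a label map or from
thresholding bright regions of a grayscale field; candidates are kept
when they pass a minimum area (default 525 µm²) and a minimum
circularity (4*pi*A/P^2, default 0.4).  Unlike the semiautomatic
routine it replaces, the procedure is fully parameterized and
deterministic; manual curation is emulated by an optional explicit
include/exclude region-id override.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage import filters, measure

from osteosect.phases import ADIPOCYTE, PhaseLabelMap


@dataclass(frozen=True)
class AdipocyteParams:
    min_area_um2: float = 525.0
    min_circularity: float = 0.4
    field_area_um2: float = 1.5e6
    n_fields: int = 3
    exclude_border_regions: bool = False

    def __post_init__(self) -> None:
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be positive")
        if not 0 <= self.min_circularity <= 1:
            raise ValueError("min_circularity must be in [0, 1]")


@dataclass(frozen=True)
class AdipocyteResult:
    count: int
    areas_um2: list[float]
    adipocyte_area_um2: float
    marrow_area_um2: float
    fraction_pct: float
    regions: Optional[pd.DataFrame] = None

    def as_dict(self) -> dict:
        return {
            "count": self.count,
            "areas_um2": list(self.areas_um2),
            "adipocyte_area_um2": self.adipocyte_area_um2,
            "marrow_area_um2": self.marrow_area_um2,
            "fraction_pct": self.fraction_pct,
        }


def _circularity(area_px: float, perimeter_px: float) -> float:
    if perimeter_px <= 0:
        return 1.0  # single pixels / degenerate regions are maximally compact
    return float(min(1.0, 4.0 * np.pi * area_px / perimeter_px**2))


def detect_adipocytes(
    section: Union[PhaseLabelMap, np.ndarray],
    marrow_mask: np.ndarray,
    params: AdipocyteParams = AdipocyteParams(),
    pixel_size_um: Optional[float] = None,
    include_ids: Optional[Sequence[int]] = None,
    exclude_ids: Optional[Sequence[int]] = None,
) -> AdipocyteResult:
    """Detect adipocytes inside the marrow and quantify their area share.

    Parameters
    ----------
    section
        Either a :class:`PhaseLabelMap` (candidates are the adipocyte
        phase) or a raw grayscale array (candidates are Otsu-bright
        regions inside the marrow; ``pixel_size_um`` is then required).
    marrow_mask
        The full marrow space, including the area occupied by the
        adipocytes themselves; the denominator of the fraction.
    include_ids, exclude_ids
        Region labels (as emitted in the per-region table) to force-keep
        or force-drop, standing in for manual curation.
    """
    marrow_mask = np.asarray(marrow_mask, dtype=bool)
    if not marrow_mask.any():
        raise ValueError("marrow mask is empty")

    if isinstance(section, PhaseLabelMap):
        candidates = (section.labels == ADIPOCYTE) & marrow_mask
        px = section.pixel_size_um
    else:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um is required for grayscale input")
        px = pixel_size_um
        gray = np.asarray(section, dtype=np.float64)
        if gray.shape != marrow_mask.shape:
            raise ValueError("image and marrow mask shapes differ")
        vals = gray[marrow_mask]
        if np.ptp(vals) == 0:
            candidates = marrow_mask.copy()
        else:
            candidates = marrow_mask & (gray > filters.threshold_otsu(vals))

    px2 = px**2
    marrow_area = float(marrow_mask.sum()) * px2

    labelled = measure.label(candidates, connectivity=2)
    include = set(include_ids or ())
    exclude = set(exclude_ids or ())
    rows = []
    kept_areas: list[float] = []
    h, w = candidates.shape
    for region in measure.regionprops(labelled):
        area_um2 = region.area * px2
        circ = _circularity(region.area, region.perimeter)
        r0, c0, r1, c1 = region.bbox
        on_border = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        keep = area_um2 >= params.min_area_um2 and circ >= params.min_circularity
        if params.exclude_border_regions and on_border:
            keep = False
        if region.label in include:
            keep = True
        if region.label in exclude:
            keep = False
        rows.append(
            {
                "id": region.label,
                "area_um2": area_um2,
                "circularity": circ,
                "on_border": on_border,
                "kept": keep,
            }
        )
        if keep:
            kept_areas.append(float(area_um2))

    table = pd.DataFrame(
        rows, columns=["id", "area_um2", "circularity", "on_border", "kept"]
    )
    adipo_area = float(sum(kept_areas))
    return AdipocyteResult(
        count=len(kept_areas),
        areas_um2=kept_areas,
        adipocyte_area_um2=adipo_area,
        marrow_area_um2=marrow_area,
        fraction_pct=100.0 * adipo_area / marrow_area,
        regions=table,
    )


def aggregate_fields(results: Sequence[AdipocyteResult]) -> dict:
    """Pool several measurement fields into a single adiposity fraction.

    The headline value pools areas (total adipocyte area over total
    marrow area); the per-field fractions and their plain mean are also
    returned.
    """
    if not results:
        raise ValueError("no fields to aggregate")
    adipo = sum(r.adipocyte_area_um2 for r in results)
    marrow = sum(r.marrow_area_um2 for r in results)
    fractions = [r.fraction_pct for r in results]
    return {
        "pooled_fraction_pct": 100.0 * adipo / marrow,
        "per_field_fraction_pct": fractions,
        "mean_field_fraction_pct": float(np.mean(fractions)),
        "total_adipocyte_area_um2": float(adipo),
        "total_marrow_area_um2": float(marrow),
        "total_count": int(sum(r.count for r in results)),
    }
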