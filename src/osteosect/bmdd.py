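"""Bone mineralization density distribution (BMDD) statistics.

The BMDD is the area-fraction histogram of calcium weight percent over
mineralized bone.  Five canonical parameters summarize it: CaMean
(area-weighted mean), CaPeak (modal concentration), CaWidth (full width
at half maximum), and CaLow/CaHigh (percent of bone area below 17.68
resp. above 25.30 wt% Ca, the 5th/95th percentiles of the adult
trabecular reference distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from osteosect.calibration import CalciumMap

#: reference thresholds (wt% Ca) defining the low/high mineralization tails
T_LOW_WTPCT = 17.68
T_HIGH_WTPCT = 25.30

#: default cut separating mineralized matrix from osteoid/soft tissue
DEFAULT_MINERALIZED_T0 = 5.2

#: default histogram bin width in wt% Ca
DEFAULT_BIN_WIDTH = 0.17


class EmptyCompartmentError(ValueError):
    """Raised when a statistic is requested over an empty pixel set."""


@dataclass(frozen=True)
class CompartmentMasks:
    """Pixel masks delimiting the skeletal compartments of a section.

    ``cortex2`` may be None when only one cortical plate is available.
    The trabecular and cortical compartment masks must be pairwise
    disjoint; ``marrow`` (the soft-tissue space, used by the adiposity
    analysis) lies inside the trabecular/cortical tissue area and is
    exempt from the disjointness requirement.
    """

    trabecular: np.ndarray
    cortex1: np.ndarray
    cortex2: Optional[np.ndarray] = None
    marrow: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        named = [("trabecular", self.trabecular), ("cortex1", self.cortex1)]
        if self.cortex2 is not None:
            named.append(("cortex2", self.cortex2))
        if self.marrow is not None:
            named.append(("marrow", self.marrow))
        shape = None
        arrays = {}
        for name, mask in named:
            mask = np.asarray(mask, dtype=bool)
            if shape is None:
                shape = mask.shape
            elif mask.shape != shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            arrays[name] = mask
        stack = np.stack([arrays[n] for n in arrays if n != "marrow"])
        if (stack.sum(axis=0) > 1).any():
            raise ValueError("compartment masks must be pairwise disjoint")
        for name, mask in arrays.items():
            object.__setattr__(self, name, mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.trabecular.shape

    def items(self):
        yield "trabecular", self.trabecular
        yield "cortex1", self.cortex1
        if self.cortex2 is not None:
            yield "cortex2", self.cortex2


@dataclass(frozen=True)
class BmddHistogram:
    """Normalized area-fraction histogram over uniform wt% Ca bins."""

    bin_edges: np.ndarray
    area_pct: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        pct = np.asarray(self.area_pct, dtype=np.float64)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1D array of at least 2 edges")
        if pct.size != edges.size - 1:
            raise ValueError("area_pct length must be len(bin_edges) - 1")
        widths = np.diff(edges)
        if widths.min() <= 0:
            raise ValueError("bin_edges must be strictly ascending")
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
            raise ValueError("bin width must be uniform")
        if abs(pct.sum() - 100.0) > 1e-6:
            raise ValueError("area_pct must sum to 100")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "area_pct", pct)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class BmddParameters:
    """The five canonical BMDD summary statistics."""

    ca_mean_wtpct: float
    ca_peak_wtpct: float
    ca_width_wtpct: float
    ca_low_pct_area: float
    ca_high_pct_area: float
    thresholds: tuple[float, float] = (T_LOW_WTPCT, T_HIGH_WTPCT)

    def as_dict(self) -> dict:
        """Keys follow the conventional report-row naming."""
        return {
            "CaMean": self.ca_mean_wtpct,
            "CaPeak": self.ca_peak_wtpct,
            "CaWidth": self.ca_width_wtpct,
            "CaLow": self.ca_low_pct_area,
            "CaHigh": self.ca_high_pct_area,
        }


def mineralized_mask(
    ca_map: CalciumMap, t0: float = DEFAULT_MINERALIZED_T0
) -> np.ndarray:
    """Valid pixels with wt% Ca strictly above the mineralization cut."""
    if not 0 < t0 < np.inf:
        raise ValueError("t0 must be positive")
    return ca_map.valid_mask & (ca_map.wtpct_ca > t0)


def compute_bmdd(
    ca_map: CalciumMap,
    mask: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_origin: float = 0.0,
) -> BmddHistogram:
    """Area-fraction histogram of wt% Ca over the masked pixels.

    Bins are uniform, ``bin_width`` wide and aligned to ``bin_origin``
    (an edge sits at the origin); the histogram is normalized so the
    area percentages sum to 100 over the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ca_map.shape:
        raise ValueError("mask shape does not match map shape")
    values = ca_map.wtpct_ca[mask & ca_map.valid_mask]
    if values.size == 0:
        raise EmptyCompartmentError("no valid pixels under the mask")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    k0 = math.floor((values.min() - bin_origin) / bin_width)
    k1 = math.floor((values.max() - bin_origin) / bin_width) + 1
    edges = bin_origin + np.arange(k0, k1 + 1, dtype=np.float64) * bin_width
    counts, edges = np.histogram(values, bins=edges)
    area_pct = counts * (100.0 / counts.sum())
    return BmddHistogram(bin_edges=edges, area_pct=area_pct, n_pixels=int(values.size))


def _fwhm(
    centers: np.ndarray, heights: np.ndarray, peak_idx: int, step: float
) -> float:
    """Full width at half maximum around a peak, linearly interpolated.

    On multimodal profiles the crossings nearest the given peak are
    used.  When a flank never drops below half maximum the histogram
    support edge (half a bin beyond the end bin center) is used.
    """
    half = heights[peak_idx] / 2.0

    left = centers[0] - step / 2.0
    for i in range(peak_idx, 0, -1):
        if heights[i - 1] < half:
            frac = (half - heights[i - 1]) / (heights[i] - heights[i - 1])
            left = centers[i - 1] + frac * (centers[i] - centers[i - 1])
            break

    right = centers[-1] + step / 2.0
    for i in range(peak_idx, len(heights) - 1):
        if heights[i + 1] < half:
            frac = (heights[i] - half) / (heights[i] - heights[i + 1])
            right = centers[i] + frac * (centers[i + 1] - centers[i])
            break
    return float(right - left)


def _tail_percent(
    edges: np.ndarray, area_pct: np.ndarray, threshold: float, side: str
) -> float:
    """Percent of area below/above a threshold with linear sub-bin overlap."""
    lo = edges[:-1]
    width = edges[1] - edges[0]
    frac_below = np.clip((threshold - lo) / width, 0.0, 1.0)
    below = float(np.sum(area_pct * frac_below))
    if side == "below":
        return below
    return float(area_pct.sum() - below)


def bmdd_parameters(hist: BmddHistogram, smooth: bool = False) -> BmddParameters:
    """Extract the five summary statistics from a BMDD histogram.

    CaPeak is the center of the maximal bin; with ``smooth=True`` a
    3-bin moving average is applied before locating the peak (ties break
    toward the lowest bin center either way).  CaWidth is the FWHM of
    the unsmoothed histogram measured at the crossings nearest the
    global peak.  CaLow/CaHigh apportion the threshold-straddling bin by
    linear overlap so they are insensitive to bin placement.
    """
    pct = hist.area_pct
    if not (pct > 0).any():
        raise EmptyCompartmentError("histogram has no mass")
    centers = hist.bin_centers

    ca_mean = float(np.sum(pct * centers) / 100.0)

    if smooth and pct.size >= 3:
        kernel = np.ones(3) / 3.0
        peak_profile = np.convolve(pct, kernel, mode="same")
    else:
        peak_profile = pct
    peak_idx = int(np.argmax(peak_profile))  # argmax takes the lowest tie
    ca_peak = float(centers[peak_idx])

    raw_peak_idx = int(np.argmax(pct))
    ca_width = _fwhm(centers, pct, raw_peak_idx, hist.bin_width)

    ca_low = _tail_percent(hist.bin_edges, pct, T_LOW_WTPCT, "below")
    ca_high = _tail_percent(hist.bin_edges, pct, T_HIGH_WTPCT, "above")

    return BmddParameters(
        ca_mean_wtpct=ca_mean,
        ca_peak_wtpct=ca_peak,
        ca_width_wtpct=ca_width,
        ca_low_pct_area=ca_low,
        ca_high_pct_area=ca_high,
    )


def average_parameters(params: list[BmddParameters]) -> BmddParameters:
    """Field-wise arithmetic mean of BMDD parameter sets."""
    if not params:
        raise ValueError("nothing to average")
    return BmddParameters(
        ca_mean_wtpct=float(np.mean([p.ca_mean_wtpct for p in params])),
        ca_peak_wtpct=float(np.mean([p.ca_peak_wtpct for p in params])),
        ca_width_wtpct=float(np.mean([p.ca_width_wtpct for p in params])),
        ca_low_pct_area=float(np.mean([p.ca_low_pct_area for p in params])),
        ca_high_pct_area=float(np.mean([p.ca_high_pct_area for p in params])),
        thresholds=params[0].thresholds,
    )


def compartment_bmdd(
    ca_map: CalciumMap,
    masks: CompartmentMasks,
    t0: float = DEFAULT_MINERALIZED_T0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    smooth: bool = False,
) -> dict[str, Optional[BmddParameters]]:
    """BMDD parameters per compartment, plus the cortical summary.

    Returns a mapping with keys ``trabecular``, ``cortex1``, ``cortex2``
    (when present) and ``cortical``; the cortical summary is the
    arithmetic mean of both cortices, or the single cortex when only one
    is available.  A compartment that is empty after mineralized masking
    yields None (reported downstream as "Not evaluable") rather than a
    hard failure.
    """
    mineral = mineralized_mask(ca_map, t0)
    out: dict[str, Optional[BmddParameters]] = {}
    for name, comp_mask in masks.items():
        pixels = comp_mask & mineral
        if not pixels.any():
            out[name] = None
            continue
        hist = compute_bmdd(ca_map, pixels, bin_width=bin_width)
        out[name] = bmdd_parameters(hist, smooth=smooth)

    cortices = [out.get(k) for k in ("cortex1", "cortex2") if out.get(k) is not None]
    out["cortical"] = average_parameters(cortices) if cortices else None
    return out
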