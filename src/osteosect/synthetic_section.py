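"""Seeded generator of synthetic transiliac bone-section data.

Produces matched triples — a backscatter-style grayscale image, a
stained-section phase label map, and the noiseless ground truth — for a
cross-section with two cortical plates flanking a trabecular
compartment.  Trabecular bone is laid down as randomly oriented strips
trimmed toward a target area fraction; the mineralized matrix carries
calcium values drawn from a configurable mixture (plus an optional
highly mineralized cartilage component); osteoid seams, roundish marrow
adipocytes, carbon/aluminum standard patches and additive Gaussian
detector noise complete the scene.

Gray levels are produced by inverting the same two-anchor linear
calibration model used by :mod:`osteosect.calibration`, so a noiseless
image round-trips exactly through fit/apply back to the ground-truth
calcium map.  The ground truth stores the calcium map *after* gray
quantization: it is the exact map a perfect analysis of the noiseless
image can recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml
from scipy import ndimage
from skimage import draw

from osteosect import phases as ph
from osteosect.bmdd import (
    BmddParameters,
    CompartmentMasks,
    DEFAULT_MINERALIZED_T0,
    EmptyCompartmentError,
    average_parameters,
)
from osteosect.calibration import (
    SATURATION_WTPCT_CA,
    CalibrationCurve,
    QbeiImage,
)
from osteosect.phases import PhaseLabelMap

#: nominal calcium-equivalent signal of the soft-tissue phases (wt% Ca);
#: all far below the mineralized cut so thresholding separates them.
SOFT_TISSUE_WTPCT = {ph.MARROW: 1.2, ph.OSTEOID: 3.5, ph.ADIPOCYTE: 0.4}

_EIGHT = np.ones((3, 3), dtype=bool)
_CROSS = ndimage.generate_binary_structure(2, 1)


class InvalidSectionSpecError(ValueError):
    """Raised when a section specification cannot be realized."""


@dataclass(frozen=True)
class SectionSpec:
    """Full parameterization of a synthetic section.

    ``cortical_width_um`` gives the two plate widths; the second may be
    0 to emulate a sample with only one cortex.  Mixture components are
    ``(mean_wtpct_ca, sd_wtpct_ca, weight)`` with weights summing to 1;
    ``cartilage_peak`` is an optional extra component whose weight is
    the fraction of mineralized area converted to calcified cartilage.
    """

    image_height_px: int = 700
    image_width_px: int = 600
    pixel_size_um: float = 1.8
    cortical_width_um: tuple[float, float] = (250.0, 250.0)
    trabecular_target_bvtv_pct: float = 20.0
    trabecular_thickness_um: float = 100.0
    osteoid_seam_thickness_um: float = 5.4
    osteoid_surface_fraction: float = 0.25
    mineralization_mixture: tuple[tuple[float, float, float], ...] = (
        (20.5, 1.6, 0.65),
        (23.5, 1.9, 0.35),
    )
    cartilage_peak: Optional[tuple[float, float, float]] = None
    adipocyte_count: int = 25
    adipocyte_area_um2_range: tuple[float, float] = (600.0, 2500.0)
    gray_noise_sd: float = 150.0
    standards_patch_gray: tuple[float, float] = (2500.0, 22500.0)
    osteoblast_surface_fraction: float = 0.15
    osteoclast_surface_fraction: float = 0.03
    eroded_surface_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise InvalidSectionSpecError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise InvalidSectionSpecError("pixel_size_um must be positive")
        weights = [w for _, _, w in self.mineralization_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise InvalidSectionSpecError("mixture weights must sum to 1")
        components = list(self.mineralization_mixture)
        if self.cartilage_peak is not None:
            components.append(self.cartilage_peak)
        for mean, sd, w in components:
            if not 0 <= mean <= SATURATION_WTPCT_CA:
                raise InvalidSectionSpecError(
                    f"component mean {mean} outside [0, {SATURATION_WTPCT_CA}]"
                )
            if sd < 0 or w < 0:
                raise InvalidSectionSpecError("component sd/weight must be nonnegative")
        if not 0 < self.trabecular_target_bvtv_pct < 100:
            raise InvalidSectionSpecError("trabecular_target_bvtv_pct must be in (0,100)")
        if self.trabecular_thickness_um <= 0:
            raise InvalidSectionSpecError("trabecular_thickness_um must be positive")
        if not 0 <= self.osteoid_surface_fraction <= 1:
            raise InvalidSectionSpecError("osteoid_surface_fraction must be in [0,1]")
        if self.osteoid_seam_thickness_um < 0:
            raise InvalidSectionSpecError("osteoid_seam_thickness_um must be >= 0")
        if self.adipocyte_count < 0:
            raise InvalidSectionSpecError("adipocyte_count must be nonnegative")
        lo, hi = self.adipocyte_area_um2_range
        if not 0 < lo <= hi:
            raise InvalidSectionSpecError("bad adipocyte_area_um2_range")
        if self.gray_noise_sd < 0:
            raise InvalidSectionSpecError("gray_noise_sd must be nonnegative")
        gl_c, gl_al = self.standards_patch_gray
        if not gl_al > gl_c >= 0:
            raise InvalidSectionSpecError("standards_patch_gray must be ascending")
        cw1, cw2 = self.cortical_width_um
        if cw1 <= 0 or cw2 < 0:
            raise InvalidSectionSpecError("cortical widths must be positive (cortex2 may be 0)")
        if self._cortex_rows()[0] + self._cortex_rows()[1] >= self.image_height_px:
            raise InvalidSectionSpecError("cortices do not fit inside the image height")
        if self.image_height_px < 48 or self.image_width_px < 24:
            raise InvalidSectionSpecError(
                "image too small to embed the calibration standard patches"
            )

    def _cortex_rows(self) -> tuple[int, int]:
        px = self.pixel_size_um
        return (
            int(round(self.cortical_width_um[0] / px)),
            int(round(self.cortical_width_um[1] / px)),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SectionSpec":
        kwargs = dict(d)
        for key in (
            "cortical_width_um",
            "adipocyte_area_um2_range",
            "standards_patch_gray",
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("mineralization_mixture") is not None:
            kwargs["mineralization_mixture"] = tuple(
                tuple(c) for c in kwargs["mineralization_mixture"]
            )
        if kwargs.get("cartilage_peak") is not None:
            kwargs["cartilage_peak"] = tuple(kwargs["cartilage_peak"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SectionSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SectionGroundTruth:
    """Noiseless truth paired with a simulated section (test oracle)."""

    true_calcium_map: np.ndarray
    true_phase_area_um2: dict[str, float]
    true_bmdd_params: dict[str, Optional[BmddParameters]]
    true_adipocyte_areas_um2: list[float]
    compartments: CompartmentMasks
    standard_rois: dict[str, tuple[int, int, int, int]]
    realized: dict[str, float]
    spec_echo: SectionSpec


# ----------------------------------------------------------------- geometry


def _stamp_strip(bone, trab_mask, rng, half_th, length, H, W, row_lo, row_hi):
    r = rng.uniform(row_lo, row_hi)
    c = rng.uniform(0, W)
    theta = rng.uniform(0, np.pi)
    dr, dc = np.sin(theta), np.cos(theta)
    half_len = length / 2.0
    margin = int(np.ceil(half_len + half_th + 2))
    r0, r1 = max(0, int(r - margin)), min(H, int(r + margin) + 1)
    c0, c1 = max(0, int(c - margin)), min(W, int(c + margin) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pr, pc = rr - r, cc - c
    t = np.clip(pr * dr + pc * dc, -half_len, half_len)
    dist2 = (pr - t * dr) ** 2 + (pc - t * dc) ** 2
    strip = dist2 <= half_th**2
    bone[r0:r1, c0:c1] |= strip & trab_mask[r0:r1, c0:c1]


def _grow_trabeculae(rng, trab_mask, spec) -> np.ndarray:
    """Random strips unioned until the target area fraction, then trimmed."""
    H, W = trab_mask.shape
    px = spec.pixel_size_um
    target = spec.trabecular_target_bvtv_pct / 100.0
    th_px = max(1.0, spec.trabecular_thickness_um / px)
    trab_area = trab_mask.sum()
    rows = np.nonzero(trab_mask.any(axis=1))[0]
    row_lo, row_hi = rows[0], rows[-1] + 1

    bone = np.zeros_like(trab_mask)
    for _ in range(5000):
        if bone.sum() / trab_area >= target:
            break
        length = rng.uniform(2.0, 5.0) * th_px
        _stamp_strip(bone, trab_mask, rng, th_px / 2.0, length, H, W, row_lo, row_hi)

    # trim overshoot by erosion while it brings the fraction closer
    realized = bone.sum() / trab_area
    for _ in range(20):
        if realized <= target:
            break
        eroded = ndimage.binary_erosion(bone, structure=_CROSS)
        new = eroded.sum() / trab_area
        if abs(new - target) < abs(realized - target):
            bone, realized = eroded, new
        else:
            break
    return bone


def _select_arcs(rng, candidates: np.ndarray, n_target: float, radius_px: float):
    """Mark random boundary arcs (disk neighbourhoods) until ~n_target pixels."""
    selected = np.zeros_like(candidates)
    coords = np.argwhere(candidates)
    if len(coords) == 0 or n_target <= 0:
        return selected
    chosen = np.zeros(len(coords), dtype=bool)
    r2 = radius_px**2
    for _ in range(4 * len(coords)):
        if chosen.sum() >= n_target:
            break
        i = rng.integers(len(coords))
        d2 = ((coords - coords[i]) ** 2).sum(axis=1)
        chosen |= d2 <= r2
    selected[tuple(coords[chosen].T)] = True
    return selected


def _place_adipocytes(rng, labels, spec) -> list[float]:
    """Non-overlapping roundish ellipses rejection-sampled into the marrow."""
    px2 = spec.pixel_size_um**2
    areas: list[float] = []
    H, W = labels.shape
    for _ in range(spec.adipocyte_count):
        marrow_coords = np.argwhere(labels == ph.MARROW)
        if len(marrow_coords) == 0:
            return areas
        for _attempt in range(200):
            r, c = marrow_coords[rng.integers(len(marrow_coords))]
            area_um2 = rng.uniform(*spec.adipocyte_area_um2_range)
            q = rng.uniform(0.6, 1.0)
            a = np.sqrt(area_um2 / px2 / (np.pi * q))
            b = q * a
            rot = rng.uniform(0, np.pi)
            rr, cc = draw.ellipse(r, c, a, b, rotation=rot)
            if len(rr) == 0:
                continue
            if rr.min() < 0 or cc.min() < 0 or rr.max() >= H or cc.max() >= W:
                continue
            if not (labels[rr, cc] == ph.MARROW).all():
                continue
            labels[rr, cc] = ph.ADIPOCYTE
            areas.append(float(len(rr)) * px2)
            break
    return areas


# ---------------------------------------------------------------- synthesis


def simulate_section(
    spec: SectionSpec, seed: Optional[int] = None
) -> tuple[QbeiImage, PhaseLabelMap, SectionGroundTruth]:
    """Generate a (image, label map, ground truth) triple from a spec.

    Identical ``(spec, seed)`` always yields a bit-identical triple.
    When ``seed`` is None the spec's own seed field is used.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    H, W = spec.image_height_px, spec.image_width_px
    px = spec.pixel_size_um
    c1, c2 = spec._cortex_rows()

    labels = np.full((H, W), ph.MARROW, dtype=np.uint8)
    labels[:c1, :] = ph.BONE
    if c2 > 0:
        labels[H - c2 :, :] = ph.BONE

    trab_region = np.zeros((H, W), dtype=bool)
    trab_region[c1 : H - c2 if c2 > 0 else H, :] = True

    bone_trab = _grow_trabeculae(rng, trab_region, spec)
    labels[bone_trab] = ph.BONE

    # optional highly mineralized cartilage blobs carved out of bone
    if spec.cartilage_peak is not None and spec.cartilage_peak[2] > 0:
        w_cart = spec.cartilage_peak[2]
        bone_idx = np.argwhere(labels == ph.BONE)
        n_target = int(round(w_cart * len(bone_idx)))
        n_done = 0
        for _ in range(2000):
            if n_done >= n_target:
                break
            r, c = bone_idx[rng.integers(len(bone_idx))]
            radius = rng.integers(3, 8)
            rr, cc = draw.disk((r, c), radius, shape=(H, W))
            hit = labels[rr, cc] == ph.BONE
            labels[rr[hit], cc[hit]] = ph.CARTILAGE
            n_done += int(hit.sum())

    # calibration standard patches at mid-height near the left edge
    r_mid = H // 2
    roi_c = (r_mid - 20, r_mid - 4, 4, 20)
    roi_al = (r_mid + 4, r_mid + 20, 4, 20)
    for r0, r1, col0, col1 in (roi_c, roi_al):
        labels[r0:r1, col0:col1] = ph.STANDARD

    # osteoid seams along randomly chosen surface arcs
    boundary = ph.bone_boundary_pixels(labels)
    n_boundary = int(boundary.sum())
    seam_px = int(round(spec.osteoid_seam_thickness_um / px))
    if seam_px > 0 and spec.osteoid_surface_fraction > 0 and n_boundary > 0:
        covered = _select_arcs(
            rng, boundary, spec.osteoid_surface_fraction * n_boundary, radius_px=6
        )
        seam = ndimage.binary_dilation(
            covered, structure=_CROSS, iterations=seam_px
        ) & (labels == ph.MARROW)
        labels[seam] = ph.OSTEOID
        realized_osteoid_frac = covered.sum() / n_boundary
    else:
        realized_osteoid_frac = 0.0

    # surface annotations on disjoint arcs of the (final) bone boundary
    boundary = ph.bone_boundary_pixels(labels)
    n_boundary = int(boundary.sum())
    annotations: dict[str, np.ndarray] = {}
    realized_fracs: dict[str, float] = {}
    free = boundary.copy()
    for key, frac in (
        ("osteoblast_covered", spec.osteoblast_surface_fraction),
        ("osteoclast_covered", spec.osteoclast_surface_fraction),
        ("eroded", spec.eroded_surface_fraction),
    ):
        ann = _select_arcs(rng, free, frac * n_boundary, radius_px=5)
        free &= ~ann
        annotations[key] = ann
        realized_fracs[key] = float(ann.sum() / n_boundary) if n_boundary else 0.0

    adipocyte_areas = _place_adipocytes(rng, labels, spec)

    # per-pixel calcium values
    ca = np.zeros((H, W), dtype=np.float64)
    for code, value in SOFT_TISSUE_WTPCT.items():
        ca[labels == code] = value
    bone_mask = labels == ph.BONE
    n_bone = int(bone_mask.sum())
    if n_bone:
        means = np.array([m for m, _, _ in spec.mineralization_mixture])
        sds = np.array([s for _, s, _ in spec.mineralization_mixture])
        weights = np.array([w for _, _, w in spec.mineralization_mixture])
        comp = rng.choice(len(means), size=n_bone, p=weights / weights.sum())
        ca[bone_mask] = np.clip(
            rng.normal(means[comp], sds[comp]), 0.0, SATURATION_WTPCT_CA
        )
    cart_mask = labels == ph.CARTILAGE
    if cart_mask.any():
        m, s, _ = spec.cartilage_peak
        ca[cart_mask] = np.clip(
            rng.normal(m, s, size=int(cart_mask.sum())), 0.0, SATURATION_WTPCT_CA
        )

    # invert the calibration convention to gray levels, then quantize
    gl_c, gl_al = spec.standards_patch_gray
    curve = CalibrationCurve(gl_carbon=gl_c, gl_aluminum=gl_al)
    span = gl_al - gl_c
    gray_f = gl_c + span * (ca / curve.ca_equiv_aluminum_wtpct)
    gray_f[labels == ph.STANDARD] = gl_c
    gray_f[roi_al[0] : roi_al[1], roi_al[2] : roi_al[3]] = gl_al
    gray0 = np.clip(np.rint(gray_f), 0, 65535).astype(np.uint16)

    true_ca = curve(gray0)  # exact target of a perfect noiseless analysis

    if spec.gray_noise_sd > 0:
        noisy = gray0.astype(np.float64) + rng.normal(
            0.0, spec.gray_noise_sd, size=(H, W)
        )
        gray = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)
    else:
        gray = gray0

    image = QbeiImage(gray=gray, pixel_size_um=px)
    phase_map = PhaseLabelMap(
        labels=labels, pixel_size_um=px, surface_annotations=annotations
    )

    not_patch = labels != ph.STANDARD
    cortex1 = np.zeros((H, W), dtype=bool)
    cortex1[:c1, :] = True
    cortex1 &= not_patch
    cortex2 = None
    if c2 > 0:
        cortex2 = np.zeros((H, W), dtype=bool)
        cortex2[H - c2 :, :] = True
        cortex2 &= not_patch
    trabecular = trab_region & not_patch
    marrow = np.isin(labels, (ph.MARROW, ph.ADIPOCYTE))
    compartments = CompartmentMasks(
        trabecular=trabecular, cortex1=cortex1, cortex2=cortex2, marrow=marrow
    )

    trab_area = int(trabecular.sum())
    realized = {
        "bvtv_pct": 100.0
        * int((np.isin(labels, ph.MINERALIZED_LABELS) & trabecular).sum())
        / trab_area,
        "osteoid_surface_fraction": float(realized_osteoid_frac),
        "osteoblast_surface_fraction": realized_fracs["osteoblast_covered"],
        "osteoclast_surface_fraction": realized_fracs["osteoclast_covered"],
        "eroded_surface_fraction": realized_fracs["eroded"],
    }

    truth = SectionGroundTruth(
        true_calcium_map=true_ca,
        true_phase_area_um2=phase_map.phase_area_um2(),
        true_bmdd_params={},
        true_adipocyte_areas_um2=adipocyte_areas,
        compartments=compartments,
        standard_rois={"carbon": roi_c, "aluminum": roi_al},
        realized=realized,
        spec_echo=spec,
    )
    object.__setattr__(truth, "true_bmdd_params", true_parameters(truth))
    return image, phase_map, truth


# ------------------------------------------------------------------ oracle


def _exhaustive_params(values: np.ndarray) -> BmddParameters:
    """Summary statistics by direct per-pixel enumeration (no binning).

    Values coming out of the simulator are quantized at the gray-level
    resolution, so the mode and an FWHM over the discrete value
    frequencies are well defined.
    """
    from osteosect.bmdd import T_HIGH_WTPCT, T_LOW_WTPCT, _fwhm

    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size == 1:
        step = 0.0
        profile = counts.astype(float)
        positions = uniq
    else:
        step = float(np.diff(uniq).min())
        k = np.rint((uniq - uniq[0]) / step).astype(int)
        profile = np.zeros(k[-1] + 1)
        profile[k] = counts
        positions = uniq[0] + np.arange(k[-1] + 1) * step
    peak_idx = int(np.argmax(profile))
    return BmddParameters(
        ca_mean_wtpct=float(values.mean()),
        ca_peak_wtpct=float(positions[peak_idx]),
        ca_width_wtpct=_fwhm(positions, profile, peak_idx, step),
        ca_low_pct_area=100.0 * float(np.mean(values < T_LOW_WTPCT)),
        ca_high_pct_area=100.0 * float(np.mean(values > T_HIGH_WTPCT)),
    )


def true_parameters(
    truth: SectionGroundTruth,
    compartments: Optional[CompartmentMasks] = None,
    t0: float = DEFAULT_MINERALIZED_T0,
) -> dict[str, Optional[BmddParameters]]:
    """Per-compartment BMDD parameters straight from the noiseless map.

    This is the brute-force oracle the histogram pipeline is checked
    against: statistics are computed by exhaustive pixel enumeration
    over the noiseless calcium map, with no histogram binning.
    """
    masks = compartments if compartments is not None else truth.compartments
    ca = truth.true_calcium_map
    if masks.shape != ca.shape:
        raise ValueError("compartment masks do not match the calcium map")
    out: dict[str, Optional[BmddParameters]] = {}
    for name, mask in masks.items():
        if not mask.any():
            raise EmptyCompartmentError(f"compartment {name!r} mask is empty")
        values = ca[mask & (ca > t0)]
        out[name] = _exhaustive_params(values) if values.size else None
    cortices = [out.get(k) for k in ("cortex1", "cortex2") if out.get(k) is not None]
    out["cortical"] = average_parameters(cortices) if cortices else None
    return out


# --------------------------------------------------------------------- I/O


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_section(
    outdir,
    image: QbeiImage,
    phase_map: PhaseLabelMap,
    truth: SectionGroundTruth,
) -> None:
    """Write a simulated section to disk.

    Layout: ``image.tif`` (16-bit gray), ``labels.tif`` (8-bit phases),
    ``compartments.tif`` (0 none / 1 trabecular / 2 cortex1 / 3 cortex2),
    ``annotations.tif`` (bitmask: 1 osteoblast, 2 osteoclast, 4 eroded),
    ``true_calcium.tif`` (float32), ``ground_truth.json`` and
    ``spec.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image.to_tiff(outdir / "image.tif")
    phase_map.to_tiff(outdir / "labels.tif")
    tifffile.imwrite(
        outdir / "true_calcium.tif", truth.true_calcium_map.astype(np.float32)
    )

    comp = np.zeros(phase_map.shape, dtype=np.uint8)
    comp[truth.compartments.trabecular] = 1
    comp[truth.compartments.cortex1] = 2
    if truth.compartments.cortex2 is not None:
        comp[truth.compartments.cortex2] = 3
    tifffile.imwrite(outdir / "compartments.tif", comp)

    ann = np.zeros(phase_map.shape, dtype=np.uint8)
    if phase_map.surface_annotations is not None:
        for bit, key in enumerate(ph.ANNOTATION_KEYS):
            ann |= phase_map.surface_annotations[key].astype(np.uint8) << bit
    tifffile.imwrite(outdir / "annotations.tif", ann)

    payload = {
        "pixel_size_um": image.pixel_size_um,
        "true_phase_area_um2": truth.true_phase_area_um2,
        "true_bmdd_params": {
            name: (p.as_dict() if p is not None else None)
            for name, p in truth.true_bmdd_params.items()
        },
        "true_adipocyte_areas_um2": truth.true_adipocyte_areas_um2,
        "standard_rois": truth.standard_rois,
        "realized": truth.realized,
        "spec": truth.spec_echo.to_dict(),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(_jsonify(payload), fh, indent=2, sort_keys=True)
    truth.spec_echo.to_yaml(outdir / "spec.yaml")
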