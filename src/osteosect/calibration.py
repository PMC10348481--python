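"""Two-point material calibration of backscattered-electron gray levels.

Backscatter signal is modelled as linear in mean atomic number, so two
pure-material standards fix the whole gray-to-mineral scale: carbon
(Z=6) anchors 0 wt% calcium and aluminum (Z=13) anchors the
calcium-equivalent concentration at which fully mineralized bone matrix
would produce the same backscatter contrast.

The aluminum anchor constant is derived once from the linear-in-Z model:
hydroxyapatite (Ca10(PO4)6(OH)2) contains 39.86 wt% Ca and has a
mass-fraction-weighted mean atomic number of 14.068, so aluminum sits at
39.86 * (13 - 6) / (14.068 - 6) = 34.583 wt% Ca equivalent.  Both
constants are module-level and overridable per standards object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: wt% Ca of stoichiometric hydroxyapatite; upper bound for bone matrix.
SATURATION_WTPCT_CA = 39.86

#: wt% Ca equivalent assigned to the aluminum standard (see module docstring).
CA_EQUIV_ALUMINUM_WTPCT = 34.583


class CalibrationError(ValueError):
    """Raised when standards cannot define a valid calibration curve."""


@dataclass(frozen=True)
class QbeiImage:
    """Raw backscattered-electron image with acquisition metadata."""

    gray: np.ndarray
    pixel_size_um: float = 1.8
    accelerating_voltage_kv: float = 20.0

    def __post_init__(self) -> None:
        gray = np.asarray(self.gray)
        if gray.ndim != 2:
            raise ValueError("gray must be a 2D array")
        if np.issubdtype(gray.dtype, np.signedinteger) and gray.min() < 0:
            raise ValueError("gray levels must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "gray", gray)

    @property
    def shape(self) -> tuple[int, int]:
        return self.gray.shape

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float = 1.8, **meta) -> "QbeiImage":
        return cls(tifffile.imread(path), pixel_size_um=pixel_size_um, **meta)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, np.asarray(self.gray, dtype=np.uint16))


@dataclass(frozen=True)
class CalciumMap:
    """Calibrated calcium-concentration image (wt% Ca) with validity mask.

    ``valid_mask`` is False where the gray level exceeded the calibrated
    range (above hydroxyapatite stoichiometry); sub-carbon gray levels
    are clamped to 0 wt% and remain valid.
    """

    wtpct_ca: np.ndarray
    valid_mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        wt = np.asarray(self.wtpct_ca, dtype=np.float64)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if wt.shape != mask.shape:
            raise ValueError("wtpct_ca and valid_mask shapes differ")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "wtpct_ca", wt)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.wtpct_ca.shape


@dataclass(frozen=True)
class CalibrationStandards:
    """Mean gray levels measured on the carbon and aluminum patches."""

    gl_carbon: float
    gl_aluminum: float
    ca_equiv_aluminum_wtpct: float = CA_EQUIV_ALUMINUM_WTPCT

    def __post_init__(self) -> None:
        if not self.gl_aluminum > self.gl_carbon:
            raise CalibrationError(
                f"aluminum gray ({self.gl_aluminum}) must exceed carbon "
                f"gray ({self.gl_carbon})"
            )
        if self.ca_equiv_aluminum_wtpct <= 0:
            raise CalibrationError("ca_equiv_aluminum_wtpct must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear gray-level -> wt% Ca transform anchored at the two standards.

    Evaluation uses the normalized two-anchor form
    ``wtpct = ca_al * (gl - gl_carbon) / (gl_aluminum - gl_carbon)``
    so both anchors are reproduced exactly in floating point.
    """

    gl_carbon: float
    gl_aluminum: float
    ca_equiv_aluminum_wtpct: float = CA_EQUIV_ALUMINUM_WTPCT
    saturation_wtpct: float = SATURATION_WTPCT_CA
    valid_range: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.gl_aluminum > self.gl_carbon:
            raise CalibrationError("gl_aluminum must exceed gl_carbon")
        gl_sat = self.gl_carbon + (
            (self.gl_aluminum - self.gl_carbon)
            * self.saturation_wtpct
            / self.ca_equiv_aluminum_wtpct
        )
        object.__setattr__(self, "valid_range", (float(self.gl_carbon), float(gl_sat)))

    @property
    def slope(self) -> float:
        """wt% Ca per gray unit."""
        return self.ca_equiv_aluminum_wtpct / (self.gl_aluminum - self.gl_carbon)

    @property
    def intercept(self) -> float:
        """wt% Ca at gray level 0."""
        return -self.slope * self.gl_carbon

    def __call__(self, gray) -> np.ndarray:
        """Evaluate the curve (with sub-carbon clamping, no validity mask)."""
        gl = np.asarray(gray, dtype=np.float64)
        span = self.gl_aluminum - self.gl_carbon
        wt = self.ca_equiv_aluminum_wtpct * ((gl - self.gl_carbon) / span)
        return np.maximum(wt, 0.0)

    def to_dict(self) -> dict:
        return {
            "gl_carbon": self.gl_carbon,
            "gl_aluminum": self.gl_aluminum,
            "ca_equiv_aluminum_wtpct": self.ca_equiv_aluminum_wtpct,
            "saturation_wtpct": self.saturation_wtpct,
            "slope": self.slope,
            "intercept": self.intercept,
            "valid_range": list(self.valid_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            gl_carbon=d["gl_carbon"],
            gl_aluminum=d["gl_aluminum"],
            ca_equiv_aluminum_wtpct=d.get(
                "ca_equiv_aluminum_wtpct", CA_EQUIV_ALUMINUM_WTPCT
            ),
            saturation_wtpct=d.get("saturation_wtpct", SATURATION_WTPCT_CA),
        )


def measure_standard_gray(image: QbeiImage, roi: np.ndarray) -> float:
    """Arithmetic mean gray level over a standard-patch ROI mask.

    Parameters
    ----------
    image
        Raw image containing the embedded standard.
    roi
        Boolean mask of the same shape as the image, True on the patch.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError(
            f"roi shape {roi.shape} does not match image shape {image.shape}"
        )
    if not roi.any():
        raise ValueError("standard ROI is empty")
    return float(np.asarray(image.gray, dtype=np.float64)[roi].mean())


def fit_calibration(standards: CalibrationStandards) -> CalibrationCurve:
    """Fit the two-anchor linear curve: carbon -> 0 wt%, aluminum -> anchor."""
    return CalibrationCurve(
        gl_carbon=standards.gl_carbon,
        gl_aluminum=standards.gl_aluminum,
        ca_equiv_aluminum_wtpct=standards.ca_equiv_aluminum_wtpct,
    )


def apply_calibration(image: QbeiImage, curve: CalibrationCurve) -> CalciumMap:
    """Transform every pixel of a raw image into wt% Ca.

    Sub-carbon gray levels (detector noise) clamp to 0 wt% and stay
    valid; gray levels mapping above the hydroxyapatite saturation are
    flagged invalid in the mask.  Pixel size is propagated unchanged.
    """
    wt = curve(image.gray)
    valid = wt <= curve.saturation_wtpct
    return CalciumMap(
        wtpct_ca=wt, valid_mask=valid, pixel_size_um=image.pixel_size_um
    )


def rect_roi_mask(shape: tuple[int, int], rect: tuple[int, int, int, int]) -> np.ndarray:
    """Boolean mask for a half-open rectangle (r0, r1, c0, c1) in pixel coords."""
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"rectangle {rect} outside image bounds {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask
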