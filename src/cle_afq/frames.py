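"""Core frame container and device geometry constants.

The Convivo-class endomicroscope scans a 267 x 475 µm field of view and
delivers 16-bit single-channel frames of 1080 x 1920 pixels, so one pixel
covers 475/1920 ≈ 0.2474 µm.  The two nominal axis ratios (267/1080 and
475/1920) agree to better than 0.1%, so square pixels are assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: frame shape (rows, cols)
IMAGE_SHAPE: tuple[int, int] = (1080, 1920)

#: physical field of view in µm as (height, width)
FOV_UM: tuple[float, float] = (267.0, 475.0)

#: square pixel pitch in µm, derived from the long axis (475 µm over 1920 px)
PIXEL_SIZE_UM: float = FOV_UM[1] / IMAGE_SHAPE[1]

#: emission filter identifiers: green bandpass (518-573 nm) and longpass (>515 nm)
FILTERS = ("BP", "LP")

ACQUISITIONS = ("ex_vivo", "in_situ")

DTYPE_MAX = 65535


class DimensionError(ValueError):
    """Raised when a frame does not match the expected single-channel geometry."""


@dataclass
class FieldImage:
    """One endomicroscopy frame with calibration and acquisition metadata.

    Parameters
    ----------
    pixels:
        ``(1080, 1920)`` array of integer gray values in ``[0, 65535]``.
    pixel_size_um:
        Square pixel pitch; must lie within 1% of 475/1920 µm unless the
        frame was loaded with an explicit size override.
    filter:
        ``"BP"`` or ``"LP"`` emission filter.
    """

    pixels: np.ndarray
    pixel_size_um: float = PIXEL_SIZE_UM
    filter: str = "BP"
    case_id: str = ""
    image_id: str = ""
    acquisition: str = "ex_vivo"
    #: free-form extras (artifact labels, generator seed, ...) round-tripped via sidecar
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError(
                f"expected a single-channel 2-D frame, got ndim={self.pixels.ndim}"
            )
        if self.pixels.shape != IMAGE_SHAPE and not self.meta.get("size_override"):
            raise DimensionError(
                f"expected shape {IMAGE_SHAPE}, got {self.pixels.shape} "
                "(pass meta={'size_override': True} with the true pixel_size_um to accept)"
            )
        if not self.meta.get("size_override"):
            if abs(self.pixel_size_um - PIXEL_SIZE_UM) > 0.01 * PIXEL_SIZE_UM:
                raise DimensionError(
                    f"pixel_size_um {self.pixel_size_um} deviates >1% from {PIXEL_SIZE_UM:.4f}"
                )
        if self.filter not in FILTERS:
            raise ValueError(f"filter must be one of {FILTERS}, got {self.filter!r}")
        if self.acquisition not in ACQUISITIONS:
            raise ValueError(
                f"acquisition must be one of {ACQUISITIONS}, got {self.acquisition!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def um_to_px(self, value_um: float) -> float:
        return value_um / self.pixel_size_um

    def px_to_um(self, value_px: float) -> float:
        return value_px * self.pixel_size_um


def robust_background(pixels: np.ndarray) -> tuple[float, float]:
    """Median / MAD-based background level and scale of a frame.

    Returns ``(median, 1.4826 * MAD)``.  Bright objects occupy a small
    fraction of the field of view, so the median and MAD are essentially
    unaffected by them, unlike the mean and standard deviation.
    """
    med = float(np.median(pixels))
    mad = float(np.median(np.abs(pixels.astype(np.float64) - med)))
    return med, 1.4826 * mad
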