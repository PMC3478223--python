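"""Core record types shared by the feature-extraction modules.

A nucleus is represented as an 8-bit luminance matrix plus a binary mask;
only pixels inside the mask ever contribute to features.  The coordinate
convention is row-major with the origin at the top-left pixel center, and
the calibration is an isotropic edge length in micrometres per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Minimum number of foreground pixels for a nucleus accepted by the
#: validated loading path (tiny masks make texture/shape features
#: meaningless).  Low-level feature functions do not re-check this, so unit
#: tests may build smaller synthetic inputs directly.
MIN_FOREGROUND_PIXELS = 50


@dataclass
class NucleusImage:
    """One segmented nucleus: gray matrix, mask, calibration and identity."""

    gray: np.ndarray
    mask: np.ndarray
    calibration: float = 0.1
    patient_id: str = ""
    nucleus_id: str = ""

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.gray.ndim != 2:
            raise ValidationError("gray must be a 2-D matrix")
        if self.gray.shape != self.mask.shape:
            raise ValidationError(
                f"gray shape {self.gray.shape} != mask shape {self.mask.shape}"
            )
        if self.gray.size and (self.gray.min() < 0 or self.gray.max() > 255):
            raise ValidationError("gray values must lie in [0, 255]")
        if self.calibration <= 0:
            raise ValidationError("calibration must be > 0 um/pixel")
        self.gray = self.gray.astype(np.uint8)

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())

    def validate_size(self, min_pixels: int = MIN_FOREGROUND_PIXELS) -> "NucleusImage":
        """Enforce the minimum-mask-size invariant (used by the I/O path)."""
        if self.foreground_count < min_pixels:
            raise ValidationError(
                f"mask has {self.foreground_count} foreground pixels, "
                f"need >= {min_pixels}"
            )
        return self


@dataclass
class PatientRecord:
    """Per-patient covariates, survival outcome and feature medians."""

    patient_id: str
    covariates: dict[str, float] = field(default_factory=dict)
    time: float = 0.0
    event: int = 0
    feature_medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError("survival time must be >= 0")
        if self.event not in (0, 1):
            raise ValidationError("event must be 0 or 1")

    def value_of(self, name: str) -> float:
        """Look a variable up among covariates first, then feature medians."""
        if name in self.covariates:
            return float(self.covariates[name])
        if name in self.feature_medians:
            return float(self.feature_medians[name])
        raise KeyError(f"patient {self.patient_id}: unknown variable {name!r}")
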