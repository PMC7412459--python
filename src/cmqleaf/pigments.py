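"""Pigment meter units and their model-scale transforms.

Chlorophyll content is read in SPAD units (transmittance meter) and
anthocyanin content in ACI units.  Both are transformed before any modeling
to improve normality: SR-S = sqrt(SPAD) for chlorophylls and
Lb-A = log2(ACI) for anthocyanins.  Readings are taken at antipodal points
on the two leaf surfaces and averaged per pigment; averaging is done on the
transformed scale, the scale every downstream model works on.

The calibrated domain of the quasi-color model is SR-S in [0, 9.7] and
Lb-A in [0, 8.0] (the pigment ranges seen across all tested species).
Inputs outside it are accepted — the model is deliberately applied beyond
the lettuce training range — but carry a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "PigmentLevel",
    "CalibrationWarning",
    "SRS_MAX",
    "LBA_MIN",
    "LBA_MAX",
    "spad_to_srs",
    "srs_to_spad",
    "aci_to_lba",
    "lba_to_aci",
    "average_antipodal",
]

#: calibrated pigment domain (all tested species)
SRS_MAX = 9.7
LBA_MIN = 0.0
LBA_MAX = 8.0


class CalibrationWarning(UserWarning):
    """Pigment level outside the range the quasi-color model was built on."""


@dataclass(frozen=True)
class PigmentLevel:
    """Transformed pigment pair: srs = sqrt(SPAD), lba = log2(ACI)."""

    srs: float
    lba: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.srs) and math.isfinite(self.lba)):
            raise ValueError("pigment levels must be finite")
        if self.srs < 0.0:
            raise ValueError(f"srs = {self.srs} must be non-negative")

    @property
    def out_of_calibration(self) -> bool:
        return self.srs > SRS_MAX or not LBA_MIN <= self.lba <= LBA_MAX

    def warn_if_uncalibrated(self) -> None:
        if self.out_of_calibration:
            warnings.warn(
                f"pigment level (srs={self.srs}, lba={self.lba}) outside the "
                f"calibrated range srs <= {SRS_MAX}, {LBA_MIN} <= lba <= {LBA_MAX}",
                CalibrationWarning,
                stacklevel=3,
            )


def spad_to_srs(spad: float) -> float:
    """sqrt transform of a SPAD chlorophyll reading."""
    if spad < 0.0:
        raise ValueError(f"SPAD = {spad} must be non-negative")
    return math.sqrt(spad)


def srs_to_spad(srs: float) -> float:
    if srs < 0.0:
        raise ValueError(f"SR-S = {srs} must be non-negative")
    return srs * srs


def aci_to_lba(aci: float) -> float:
    """log2 transform of an ACI anthocyanin reading.

    ACI below 1 gives a negative Lb-A, below the calibrated range; this is
    accepted with a :class:`CalibrationWarning` rather than rejected.
    """
    if aci <= 0.0:
        raise ValueError(f"ACI = {aci} must be positive")
    lba = math.log2(aci)
    if lba < LBA_MIN or lba > LBA_MAX:
        warnings.warn(
            f"Lb-A = {lba:.3f} outside the calibrated range [{LBA_MIN}, {LBA_MAX}]",
            CalibrationWarning,
            stacklevel=2,
        )
    return lba


def lba_to_aci(lba: float) -> float:
    return 2.0**lba


def average_antipodal(adaxial: PigmentLevel, abaxial: PigmentLevel) -> PigmentLevel:
    """Per-pigment mean of the two surface readings, on the transformed scale."""
    return PigmentLevel(
        srs=(adaxial.srs + abaxial.srs) / 2.0,
        lba=(adaxial.lba + abaxial.lba) / 2.0,
    )
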