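"""Echocardiographic and histologic quantification formulas.

Pure functions.  Left-ventricular volumes come from the Teichholz
formula on M-mode diameters, V(D) = 7.0/(2.4 + D) * D^3, with the
ejection fraction LVEF = 100 * (EDV - ESV) / EDV.  Fibrosis is
quantified either perivascularly (fibrotic area over the vessel ellipse
area, A_F / (a*b*pi) with a, b the semi-axes) or interstitially
(fibrotic area over the field of view, A_F / A_FoV).  Non-physiologic
inputs are flagged with a warning rather than clamped, preserving
auditability of raw measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from lrxtalk._errors import DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EchoMeasurement:
    """M-mode LV diameters: end-diastolic (LVDd) and end-systolic (LVDs), mm."""

    LVDd: float
    LVDs: float

    def __post_init__(self) -> None:
        if self.LVDd <= 0:
            raise DataError("LVDd must be positive")
        if self.LVDs < 0:
            raise DataError("LVDs must be non-negative")
        if self.LVDs > self.LVDd:
            logger.warning(
                "non-physiologic measurement: LVDs %.3g > LVDd %.3g", self.LVDs, self.LVDd
            )


@dataclass(frozen=True)
class FibrosisMeasurement:
    """Histology inputs: fibrotic area, vessel semi-axes, field-of-view area.

    All lengths share one unit and all areas its square; both ratios are
    dimensionless and invariant under a common unit change.
    ``full_axis=True`` accepts full axis lengths and halves them.
    """

    A_F: float
    a: float | None = None
    b: float | None = None
    A_FoV: float | None = None
    full_axis: bool = False

    def __post_init__(self) -> None:
        if self.A_F < 0:
            raise DataError("fibrotic area A_F must be non-negative")

    def semi_axes(self) -> tuple[float, float]:
        if self.a is None or self.b is None:
            raise DataError("vessel axes a and b required for perivascular mode")
        a, b = (self.a / 2, self.b / 2) if self.full_axis else (self.a, self.b)
        if a <= 0 or b <= 0:
            raise DataError("vessel semi-axes must be positive")
        return a, b


def teichholz_volume(D: float) -> float:
    """LV volume from an M-mode diameter: 7.0/(2.4 + D) * D^3.

    Units follow D cubed (mm -> microliters).
    """
    if D < 0:
        raise DataError("diameter must be non-negative")
    return 7.0 / (2.4 + D) * D**3


def lvef(m: EchoMeasurement) -> float:
    """Left-ventricular ejection fraction in percent.

    100 * (EDV - ESV) / EDV with EDV = V(LVDd), ESV = V(LVDs).  Lies in
    [0, 100] whenever 0 <= LVDs <= LVDd; non-physiologic inputs yield
    out-of-range values (warned at construction, never clamped).
    """
    edv = teichholz_volume(m.LVDd)
    esv = teichholz_volume(m.LVDs)
    return 100.0 * (edv - esv) / edv


def perivascular_fibrosis_ratio(m: FibrosisMeasurement) -> float:
    """Fibrotic area normalized by the vessel ellipse area: A_F / (a*b*pi)."""
    a, b = m.semi_axes()
    return m.A_F / (a * b * math.pi)


def interstitial_fibrosis_ratio(m: FibrosisMeasurement) -> float:
    """Fibrotic area fraction of the field of view: A_F / A_FoV, in [0, 1]."""
    if m.A_FoV is None or m.A_FoV <= 0:
        raise DataError("A_FoV must be positive for interstitial mode")
    if m.A_F > m.A_FoV:
        raise DataError("fibrotic area exceeds field-of-view area")
    return m.A_F / m.A_FoV
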