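"""DTNB (Ellman) signal model: absorbance at 412 nm <-> thiol concentration.

The DTNB assay reports free CoA released by the acetyltransfer reaction: each
CoA thiol reduces one DTNB molecule, releasing one TNB chromophore (1:1
stoichiometry), so the TNB concentration read at 412 nm equals the CoA (and
hence product) concentration.  Plate readers measure through a variable
liquid column, so the per-well pathlength is derived from the near-infrared
water absorption band (A975 - A900, divided by 0.18 per cm) before applying
Beer-Lambert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalCalibration",
    "WellOptics",
    "InvalidOpticalRead",
    "pathlength_from_water_band",
    "absorbance_to_concentration",
    "concentration_to_absorbance",
    "EPSILON_ENDPOINT",
    "EPSILON_KINETIC",
    "WATER_BAND_DIVISOR",
]

# Molar extinction coefficients of TNB at 412 nm (M^-1 cm^-1).  Endpoint
# screens and continuous kinetic reads use slightly different literature
# calibrations; both are kept and selected by assay type.
EPSILON_ENDPOINT = 13700.0
EPSILON_KINETIC = 13800.0

# Water near-IR band absorbance per cm of pathlength (A975 - A900).
WATER_BAND_DIVISOR = 0.18


class InvalidOpticalRead(ValueError):
    """Raised when the water-band read implies a non-positive pathlength."""


@dataclass
class OpticalCalibration:
    """Calibration constants for converting A412 to thiol concentration.

    Parameters
    ----------
    epsilon : float
        Molar extinction coefficient of TNB at 412 nm (M^-1 cm^-1).
    pathlength_divisor : float
        Water-band absorbance per cm (A975 - A900 divided by this gives the
        pathlength in cm).
    blank_a412 : float
        Background absorbance subtracted before conversion (AU).
    clamp_sigma : float
        Negative concentrations within ``clamp_sigma`` blank standard
        deviations of zero are clamped to zero (counted, warned); more
        negative values raise, flagging miscalibration.
    blank_sd : float
        Standard deviation of the blank absorbance, used by the clamp rule.
    """

    epsilon: float = EPSILON_KINETIC
    pathlength_divisor: float = WATER_BAND_DIVISOR
    blank_a412: float = 0.0
    clamp_sigma: float = 3.0
    blank_sd: float = 0.0
    n_clamped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.pathlength_divisor <= 0:
            raise ValueError(
                f"pathlength_divisor must be positive, got {self.pathlength_divisor}"
            )
        if self.blank_a412 < 0:
            raise ValueError(f"blank_a412 must be >= 0, got {self.blank_a412}")

    @classmethod
    def for_assay(cls, assay: str, **kwargs) -> "OpticalCalibration":
        """Calibration with the conventional epsilon for ``assay``.

        ``assay`` is ``"endpoint"`` (13700) or ``"kinetic"`` (13800); an
        explicit ``epsilon=`` keyword overrides.
        """
        eps = kwargs.pop("epsilon", None)
        if eps is None:
            try:
                eps = {"endpoint": EPSILON_ENDPOINT, "kinetic": EPSILON_KINETIC}[assay]
            except KeyError:
                raise ValueError(f"unknown assay type {assay!r}") from None
        return cls(epsilon=eps, **kwargs)


@dataclass(frozen=True)
class WellOptics:
    """Per-well near-IR reads and the pathlength derived from them."""

    a975: float
    a900: float
    pathlength_cm: float

    @classmethod
    def from_water_band(
        cls, a975: float, a900: float, divisor: float = WATER_BAND_DIVISOR
    ) -> "WellOptics":
        return cls(a975, a900, pathlength_from_water_band(a975, a900, divisor))


def pathlength_from_water_band(
    a975: float, a900: float, divisor: float = WATER_BAND_DIVISOR
) -> float:
    """Pathlength in cm from the water near-IR band: (A975 - A900) / divisor.

    Raises :class:`InvalidOpticalRead` when A975 - A900 <= 0 (an empty or
    mis-read well); wells are flagged, never silently passed through.
    """
    if divisor <= 0:
        raise ValueError(f"divisor must be positive, got {divisor}")
    diff = a975 - a900
    if np.any(np.asarray(diff) <= 0):
        raise InvalidOpticalRead(
            f"non-positive water-band difference (a975={a975}, a900={a900}); "
            "cannot derive pathlength"
        )
    return diff / divisor


def absorbance_to_concentration(
    a412, pathlength_cm, cal: OpticalCalibration | None = None
):
    """Convert A412 to TNB/CoA concentration in µM via Beer-Lambert.

    conc_uM = (A412 - blank) / (epsilon * pathlength) * 1e6.  Accepts scalars
    or arrays.  Slightly negative results (within ``cal.clamp_sigma`` blank
    SDs) are clamped to 0 with a counted warning; larger negatives raise.
    """
    if cal is None:
        cal = OpticalCalibration()
    pathlength_cm = np.asarray(pathlength_cm, dtype=float)
    if np.any(pathlength_cm <= 0):
        raise ValueError("pathlength must be positive")
    conc = (np.asarray(a412, dtype=float) - cal.blank_a412) / (
        cal.epsilon * pathlength_cm
    ) * 1e6
    if cal.blank_sd > 0:
        # floor: -clamp_sigma blank SDs expressed in concentration units
        floor_uM = -cal.clamp_sigma * cal.blank_sd / (
            cal.epsilon * pathlength_cm
        ) * 1e6
        if np.any(conc < floor_uM):
            raise ValueError(
                "negative concentration beyond blank noise tolerance: "
                "probable miscalibration"
            )
        neg = conc < 0
        if np.any(neg):
            n = int(np.count_nonzero(neg))
            cal.n_clamped += n
            warnings.warn(f"clamped {n} negative concentration(s) to 0", stacklevel=2)
            conc = np.where(neg, 0.0, conc)
    return conc if np.ndim(conc) else float(conc)


def concentration_to_absorbance(
    conc_uM, pathlength_cm, cal: OpticalCalibration | None = None
):
    """Forward Beer-Lambert model: µM concentration to A412 (AU).

    Exact inverse of :func:`absorbance_to_concentration` (round-trips to
    machine precision); used by the simulator.
    """
    if cal is None:
        cal = OpticalCalibration()
    conc_uM = np.asarray(conc_uM, dtype=float)
    if np.any(conc_uM < 0):
        raise ValueError("concentration must be >= 0")
    a = conc_uM * 1e-6 * cal.epsilon * np.asarray(pathlength_cm, dtype=float) \
        + cal.blank_a412
    return a if np.ndim(a) else float(a)
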