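"""Closed-form radiobiology and spherical-geometry calculators.

Biologically effective dose (BED) quantifies the biological impact of a
fractionation scheme of ``n`` fractions of ``d`` Gy each.  Two models are
provided:

* the conventional linear-quadratic (LQ) model,

  .. math:: \\mathrm{BED} = n\\,d\\,\\left[1 + \\frac{d}{\\alpha/\\beta}\\right]

* the linear-quadratic-cubic (LQC) model, which adds a cubic correction
  that reduces the predicted effect of large fraction sizes,

  .. math:: \\mathrm{BED} = n\\,d\\,\\left[1 + \\frac{d}{\\alpha/\\beta}
            - \\frac{d^2}{\\alpha/\\gamma}\\right]

Brain metastases behave as early-reacting tissue with a high
fractionation-insensitivity (``α/β ≈ 12`` Gy, LQC model), while the
surrounding normal brain is a classical late-reacting tissue
(``α/β ≈ 2`` Gy, LQ model).  The defaults below encode exactly that
parameterisation; both are overridable for sensitivity analyses.

The geometric helpers convert between the longest diameter of a sphere
(mm) and its volume (cm³).  They are the single source of every
volumetric response threshold used elsewhere in the package: a 20 %
diameter increase of a sphere is a 72.8 % volume increase, a 30 %
diameter reduction is a 65 % volume reduction, a 5 mm sphere measures
0.065 cm³, and a 5 mm sphere growing by 3 mm gains 0.2 cm³.

Units are fixed package-wide: diameters in mm, volumes in cm³, doses in
Gy.  All conversions are centralised here so no other module multiplies
by 10³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import InvalidInputError, ModelValidityError

#: Default fractionation-sensitivity ratio for brain metastases (Gy).
TUMOR_ALPHA_BETA = 12.0
#: Default fractionation-sensitivity ratio for normal brain (Gy).
NORMAL_BRAIN_ALPHA_BETA = 2.0
#: Default cubic-term coefficient of the LQC model (Gy²).
DEFAULT_ALPHA_GAMMA = 648.0

_MM3_PER_CM3 = 1000.0


class BEDModel(str, Enum):
    """Which dose-effect model produced a :class:`BEDResult`."""

    LQ = "LQ"
    LQC = "LQC"


@dataclass(frozen=True)
class FractionationScheme:
    """A radiotherapy fractionation scheme.

    Parameters
    ----------
    n_fractions
        Number of fractions delivered (positive integer).
    dose_per_fraction
        Physical dose per fraction in Gy (> 0).
    alpha_beta
        α/β ratio in Gy; 12 Gy (tumor) by default.
    alpha_gamma
        α/γ coefficient in Gy², used by the LQC model only; 648 Gy²
        by default.
    """

    n_fractions: int
    dose_per_fraction: float
    alpha_beta: float = TUMOR_ALPHA_BETA
    alpha_gamma: float = DEFAULT_ALPHA_GAMMA

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions <= 0:
            raise InvalidInputError(
                f"n_fractions must be a positive integer, got {self.n_fractions!r}"
            )
        if not (self.dose_per_fraction > 0) or not math.isfinite(self.dose_per_fraction):
            raise InvalidInputError(
                f"dose_per_fraction must be > 0 Gy, got {self.dose_per_fraction!r}"
            )
        if not (self.alpha_beta > 0):
            raise InvalidInputError(f"alpha_beta must be > 0 Gy, got {self.alpha_beta!r}")
        if not (self.alpha_gamma > 0):
            raise InvalidInputError(f"alpha_gamma must be > 0 Gy², got {self.alpha_gamma!r}")

    @property
    def total_dose(self) -> float:
        """Total physical dose in Gy."""
        return self.n_fractions * self.dose_per_fraction


@dataclass(frozen=True)
class BEDResult:
    """A biologically effective dose together with its provenance."""

    bed: float
    model: BEDModel
    scheme: FractionationScheme


def bed_lq(scheme: FractionationScheme) -> BEDResult:
    """BED under the linear-quadratic model, ``n d (1 + d/(α/β))``.

    Examples
    --------
    >>> round(bed_lq(FractionationScheme(1, 20.0, alpha_beta=2.0)).bed, 1)
    220.0
    """
    d = scheme.dose_per_fraction
    bed = scheme.n_fractions * d * (1.0 + d / scheme.alpha_beta)
    return BEDResult(bed=bed, model=BEDModel.LQ, scheme=scheme)


def bed_lqc(scheme: FractionationScheme) -> BEDResult:
    """BED under the linear-quadratic-cubic model.

    ``n d [1 + d/(α/β) − d²/(α/γ)]``.  The cubic term caps the predicted
    effect of large single fractions; outside the model's validity range
    the bracket turns non-positive and the call is rejected rather than
    returning a negative dose.

    Examples
    --------
    >>> round(bed_lqc(FractionationScheme(1, 20.0)).bed, 1)
    41.0
    >>> round(bed_lqc(FractionationScheme(10, 4.0)).bed, 1)
    52.4
    """
    d = scheme.dose_per_fraction
    bracket = 1.0 + d / scheme.alpha_beta - d * d / scheme.alpha_gamma
    if bracket <= 0:
        raise ModelValidityError(
            f"LQC bracket is non-positive at dose {d} Gy per fraction "
            f"(α/β={scheme.alpha_beta}, α/γ={scheme.alpha_gamma}); "
            "the dose is outside the model's validity range"
        )
    bed = scheme.n_fractions * d * bracket
    return BEDResult(bed=bed, model=BEDModel.LQC, scheme=scheme)


def sphere_volume(diameter_mm: float) -> float:
    """Volume (cm³) of a sphere with the given diameter (mm).

    >>> round(sphere_volume(5.0), 4)
    0.0654
    """
    if diameter_mm < 0 or not math.isfinite(diameter_mm):
        raise InvalidInputError(f"diameter must be ≥ 0 mm, got {diameter_mm!r}")
    return (math.pi / 6.0) * diameter_mm**3 / _MM3_PER_CM3


def sphere_diameter(volume_cm3: float) -> float:
    """Diameter (mm) of a sphere with the given volume (cm³); inverse of
    :func:`sphere_volume`."""
    if volume_cm3 < 0 or not math.isfinite(volume_cm3):
        raise InvalidInputError(f"volume must be ≥ 0 cm³, got {volume_cm3!r}")
    return (6.0 * volume_cm3 * _MM3_PER_CM3 / math.pi) ** (1.0 / 3.0)


def diameter_change_to_volume_change(relative_diameter_change: float) -> float:
    """Relative volume change of a sphere given a relative diameter change.

    A fractional diameter change ``x`` maps to ``(1+x)³ − 1``:

    >>> round(diameter_change_to_volume_change(0.20), 3)
    0.728
    >>> round(diameter_change_to_volume_change(-0.30), 3)
    -0.657
    """
    x = relative_diameter_change
    if x <= -1:
        raise InvalidInputError(f"relative diameter change must be > −1, got {x!r}")
    return (1.0 + x) ** 3 - 1.0


def volume_change_to_diameter_change(relative_volume_change: float) -> float:
    """Inverse of :func:`diameter_change_to_volume_change`."""
    y = relative_volume_change
    if y <= -1:
        raise InvalidInputError(f"relative volume change must be > −1, got {y!r}")
    return (1.0 + y) ** (1.0 / 3.0) - 1.0


def absolute_volume_increment(base_diameter_mm: float, diameter_increment_mm: float) -> float:
    """Absolute volume gain (cm³) when a sphere of ``base_diameter_mm``
    grows by ``diameter_increment_mm``.

    >>> round(absolute_volume_increment(5.0, 3.0), 4)
    0.2026
    """
    if base_diameter_mm < 0 or diameter_increment_mm < 0:
        raise InvalidInputError(
            "base diameter and increment must be ≥ 0 mm, got "
            f"({base_diameter_mm!r}, {diameter_increment_mm!r})"
        )
    return sphere_volume(base_diameter_mm + diameter_increment_mm) - sphere_volume(
        base_diameter_mm
    )
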