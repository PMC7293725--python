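"""Oxidative-stress assay calculators.

Two readouts are supported:

* **MDA + 4-HDA** (lipid peroxidation): the chromophore formed with
  N-methyl-2-phenylindole absorbs at 586 nm; concentrations are
  back-calculated from a linear standard curve fitted to calibrators.
* **Protein carbonyls** (protein oxidation): the DNPH derivative absorbs
  at 360-390 nm; concentration follows directly from the Beer-Lambert
  law A = epsilon * l * c with the DNPH molar absorptivity
  epsilon = 22,000 / (M * cm), normalised per mg of total protein.

Blank subtraction happens inside the calculators, not at I/O, so raw
plate readings stay auditable.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats

from .errors import DegenerateInputError, InvalidSampleError

#: Molar absorptivity of the DNPH-carbonyl derivative, 1/(M*cm).
DNPH_EPSILON_M_CM = 22_000.0

#: Tolerance below which a negative back-calculated concentration is
#: treated as rounding noise and clamped to zero (with a warning flag).
_NEGATIVE_TOL = 1e-9


@dataclasses.dataclass
class StandardCurve:
    """A fitted calibration line: absorbance = slope * concentration + intercept."""

    calibrators: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float


@dataclasses.dataclass(frozen=True)
class AssaySample:
    """One absorbance reading with its calibration context.

    ``protein_mg_per_ml`` is required only when per-mg-protein
    normalisation is requested (carbonyls).
    """

    absorbance: float
    blank_absorbance: float = 0.0
    dilution_factor: float = 1.0
    path_length_cm: float = 1.0
    protein_mg_per_ml: float | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.absorbance < 0 or self.blank_absorbance < 0:
            raise ValueError("absorbances must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if not self.path_length_cm > 0:
            raise ValueError("path_length_cm must be > 0")

    @property
    def net_absorbance(self) -> float:
        return self.absorbance - self.blank_absorbance


def fit_standard_curve(
    calibrators: Sequence[tuple[float, float]]
) -> StandardCurve:
    """Ordinary least squares of absorbance on known concentration.

    Needs at least two calibrators at two distinct concentrations.
    """
    if len(calibrators) < 2:
        raise DegenerateInputError("need at least 2 calibrators")
    conc = np.array([c for c, _ in calibrators], dtype=float)
    absorb = np.array([a for _, a in calibrators], dtype=float)
    if np.ptp(conc) == 0:
        raise DegenerateInputError(
            "all calibrator concentrations identical: cannot fit a line"
        )
    res = sp_stats.linregress(conc, absorb)
    return StandardCurve(
        calibrators=[(float(c), float(a)) for c, a in calibrators],
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def mda_concentration(
    sample: AssaySample, curve: StandardCurve
) -> tuple[float, bool]:
    """Back-calculate MDA + 4-HDA concentration from a 586 nm reading.

    Returns ``(concentration, clamped)`` in the calibrators' units scaled
    by the sample's dilution factor; ``clamped`` flags a tiny negative
    back-calculation that was rounded up to zero.
    """
    net = sample.net_absorbance
    if net < 0:
        raise InvalidSampleError(
            f"net absorbance {net:.4g} < 0 (blank exceeds reading)"
        )
    if curve.slope == 0:
        raise DegenerateInputError("standard curve slope is zero")
    conc = sample.dilution_factor * (net - curve.intercept) / curve.slope
    if conc < 0:
        if conc > -_NEGATIVE_TOL:
            return 0.0, True
        raise InvalidSampleError(
            f"back-calculated concentration {conc:.4g} is negative; "
            "reading lies below the curve intercept"
        )
    return conc, False


def carbonyl_content(
    sample: AssaySample, epsilon_M_cm: float = DNPH_EPSILON_M_CM
) -> float:
    """Protein carbonyls in nmol per mg protein via the Beer-Lambert law.

    c = A_net / (epsilon * l) gives mol/L; one mol/L is 1e6 nmol/mL, so
    the result is ``c * 1e6 / protein_mg_per_ml * dilution_factor``.
    """
    net = sample.net_absorbance
    if net < 0:
        raise InvalidSampleError(
            f"net absorbance {net:.4g} < 0 (blank exceeds reading)"
        )
    if sample.protein_mg_per_ml is None or sample.protein_mg_per_ml <= 0:
        raise InvalidSampleError(
            "carbonyl normalisation requires protein_mg_per_ml > 0"
        )
    if epsilon_M_cm <= 0:
        raise ValueError("molar absorptivity must be > 0")
    molar = net / (epsilon_M_cm * sample.path_length_cm)  # mol/L
    nmol_per_ml = molar * 1e6
    return nmol_per_ml / sample.protein_mg_per_ml * sample.dilution_factor
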