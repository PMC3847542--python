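"""Baseline correction and classical EPR parameter extraction.

The large-scale background under a narrow EPR line is removed with a cubic
polynomial fitted only on the smooth tails of the sweep (by default the first
and last 10% of points), where intensity variations are noise.  From the
baseline-corrected derivative line the three classical parameters are read off:

* ``App``  — peak-to-peak amplitude, ordinate difference between the global
  maximum and minimum;
* ``DeltaBpp`` — peak-to-peak linewidth, field separation of the two extrema;
* ``Bres`` — resonance field, where the derivative crosses zero between the
  extrema (the maximum of the underlying absorption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from numpy.polynomial import Polynomial

from .errors import BaselineError, DataQualityWarning, ExtractionError
from .spectra_io import Spectrum

__all__ = [
    "BaselineModel",
    "ClassicalParams",
    "fit_baseline",
    "correct_baseline",
    "extract_classical_params",
]

DEFAULT_TAIL_FRACTION = 0.10
_MIN_TAIL_POINTS = 4


@dataclass(frozen=True)
class BaselineModel:
    """Cubic background model ``b(B) = c0 + c1 B + c2 B^2 + c3 B^3``.

    ``coefficients`` are in ascending order, in intensity units per
    field-unit powers.  ``fit_range`` records the field span the tails
    covered, for extrapolation warnings.
    """

    coefficients: Tuple[float, float, float, float]
    tail_fraction: float = DEFAULT_TAIL_FRACTION
    fit_range: Tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self):
        if len(self.coefficients) != 4:
            raise BaselineError(
                f"cubic baseline needs exactly 4 coefficients, "
                f"got {len(self.coefficients)}"
            )
        if not 0.0 < self.tail_fraction <= 0.25:
            raise BaselineError(
                f"tail_fraction must be in (0, 0.25], got {self.tail_fraction}"
            )
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )

    def __call__(self, field: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(field, float),
                                                np.asarray(self.coefficients))


@dataclass(frozen=True)
class ClassicalParams:
    """The classical triple (App, DeltaBpp, Bres) of a single derivative line."""

    App: float
    DeltaBpp: float
    Bres: float

    def __post_init__(self):
        if not self.App > 0:
            raise ExtractionError(f"App must be > 0, got {self.App}")
        if not self.DeltaBpp > 0:
            raise ExtractionError(f"DeltaBpp must be > 0, got {self.DeltaBpp}")


def _tail_indices(n: int, tail_fraction: float) -> np.ndarray:
    k = int(np.floor(tail_fraction * n))
    if k < _MIN_TAIL_POINTS:
        raise BaselineError(
            f"each tail must hold >= {_MIN_TAIL_POINTS} points; "
            f"tail_fraction={tail_fraction} of n={n} gives only {k}"
        )
    return np.concatenate([np.arange(k), np.arange(n - k, n)])


def fit_baseline(
    spectrum: Spectrum, tail_fraction: float = DEFAULT_TAIL_FRACTION
) -> BaselineModel:
    """Least-squares cubic fitted only on the first and last tail points.

    The fit runs in a scaled variable (numpy's Polynomial window) for
    conditioning and the coefficients are converted back to the raw field
    basis.
    """
    if not 0.0 < tail_fraction <= 0.25:
        raise BaselineError(
            f"tail_fraction must be in (0, 0.25], got {tail_fraction}"
        )
    idx = _tail_indices(len(spectrum), tail_fraction)
    b = spectrum.field[idx]
    y = spectrum.intensity[idx]
    poly = Polynomial.fit(b, y, deg=3).convert()
    coef = np.zeros(4)
    coef[: poly.coef.size] = poly.coef
    return BaselineModel(
        coefficients=tuple(coef),
        tail_fraction=tail_fraction,
        fit_range=(float(spectrum.field[0]), float(spectrum.field[-1])),
    )


def correct_baseline(spectrum: Spectrum, model: BaselineModel) -> Spectrum:
    """Subtract the cubic background; the field axis is untouched."""
    lo, hi = model.fit_range
    if np.isfinite(lo) and np.isfinite(hi):
        span = hi - lo
        if spectrum.field[0] < lo - 0.01 * span or spectrum.field[-1] > hi + 0.01 * span:
            warnings.warn(
                "correcting outside the field range the baseline was fitted on",
                DataQualityWarning,
                stacklevel=2,
            )
    return replace(
        spectrum,
        intensity=spectrum.intensity - model(spectrum.field),
        baseline_corrected=True,
    )


def _zero_crossing_field(field: np.ndarray, intensity: np.ndarray,
                         i_max: int, i_min: int) -> float:
    """Resonance field between the extrema.

    Candidates are exact-zero samples (their own field) and sign changes
    between consecutive samples (midpoint of the two bracketing fields).  With
    noise several crossings can occur; the one nearest the midpoint of the two
    extrema fields wins, ties going to the lower field.  Deterministic.
    """
    seg = slice(i_max, i_min + 1)
    y = intensity[seg]
    b = field[seg]
    candidates = []
    zero = np.flatnonzero(y == 0.0)
    candidates.extend(float(b[i]) for i in zero)
    s = np.sign(y)
    flips = np.flatnonzero(s[:-1] * s[1:] < 0)
    candidates.extend(0.5 * (float(b[i]) + float(b[i + 1])) for i in flips)
    if not candidates:
        raise ExtractionError(
            "no zero crossing between the extrema: cannot locate Bres"
        )
    mid = 0.5 * (field[i_max] + field[i_min])
    candidates.sort()
    return min(candidates, key=lambda c: (abs(c - mid), c))


def extract_classical_params(spectrum: Spectrum) -> ClassicalParams:
    """Read (App, DeltaBpp, Bres) off a baseline-corrected derivative line.

    The peaks are the global extrema of the ordinates, with no smoothing
    (mirroring the manual method; noisy spectra are handled by the Monte Carlo
    distribution, not by filtering).  A standard derivative line has its
    maximum at lower field than its minimum; anything else is an error.
    """
    if not spectrum.baseline_corrected:
        raise ExtractionError(
            "spectrum must be baseline-corrected before parameter extraction"
        )
    y = spectrum.intensity
    b = spectrum.field
    i_max = int(np.argmax(y))  # first occurrence wins on ties
    i_min = int(np.argmin(y))
    if i_max >= i_min:
        raise ExtractionError(
            "not a standard derivative line: the maximum must occur at lower "
            "field than the minimum"
        )
    app = float(y[i_max] - y[i_min])
    dbpp = float(abs(b[i_min] - b[i_max]))
    bres = _zero_crossing_field(b, y, i_max, i_min)
    if not (b[i_max] < bres < b[i_min]):
        raise ExtractionError(
            f"resonance field {bres} not strictly between the extrema fields"
        )
    return ClassicalParams(App=app, DeltaBpp=dbpp, Bres=bres)
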