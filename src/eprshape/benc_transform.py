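"""The Benc coordinate system, in which a Lorentzian derivative is a line.

Each side of a baseline-corrected derivative line is mapped to

    x = ((B - Bres) / DeltaBpp)**2          (reduced squared field offset)
    y = sqrt( -App * u / F )   with  u = (B - Bres) / DeltaBpp

which sends the ideal Lorentzian derivative onto the straight line
``y = x + 3/4`` and the Gaussian onto ``y = exp(x - 1/4)``; stretched
Lorentzians (d < 3) fall below the line, Gaussians above.  Both x and y are
dimensionless, so the transform is invariant under intensity rescaling and
field affine maps — the basis of the R10 statistic's unit independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TransformError
from .preprocessing import ClassicalParams
from .spectra_io import Spectrum

__all__ = ["TransformedCurve", "transform_side", "f_lorentz_line", "f_gauss_curve"]

#: points with |F| below this fraction of App are dropped (division blow-up)
INTENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class TransformedCurve:
    """One side of a spectrum in Benc coordinates, ascending in x.

    ``n_dropped`` counts points on this side (plus any sample exactly at
    Bres) excluded because F vanished, fell below the intensity floor, or
    noise flipped its sign making the radicand negative.
    """

    x: np.ndarray
    y: np.ndarray
    side: str
    n_dropped: int = 0

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.side not in ("left", "right"):
            raise TransformError(f"side must be 'left' or 'right', got {self.side!r}")
        if x.size != y.size or x.size < 2:
            raise TransformError("a transformed curve needs >= 2 (x, y) pairs")
        if not (np.diff(x) > 0).all():
            raise TransformError("x must be strictly increasing")
        if not (np.isfinite(y).all() and (y >= 0).all()):
            raise TransformError("y must be finite and >= 0")


def f_lorentz_line(x):
    """Benc image of the ideal Lorentzian derivative: the line x + 3/4."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("the Benc abscissa is a squared quantity: x >= 0")
    return x + 0.75


def f_gauss_curve(x):
    """Benc image of the Gaussian derivative: exp(x - 1/4), above the line."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("the Benc abscissa is a squared quantity: x >= 0")
    return np.exp(x - 0.25)


def transform_side(
    spectrum: Spectrum, params: ClassicalParams, side: str
) -> TransformedCurve:
    """Map one side of a baseline-corrected spectrum into Benc coordinates.

    Points on the other side of ``Bres`` are excluded outright; points where
    the transform is undefined (F = 0 or below the intensity floor, or a
    negative radicand from wing noise) are dropped and counted in
    ``n_dropped`` — dropped, not clipped, mirroring the manual practice of
    working where the signal is clean.  Left-side points are reversed so x
    ascends.  No interpolation onto a uniform x grid is done: the rectangle
    widths downstream use the actual, non-uniform spacing.
    """
    if side not in ("left", "right"):
        raise TransformError(f"side must be 'left' or 'right', got {side!r}")
    if not spectrum.baseline_corrected:
        raise TransformError("spectrum must be baseline-corrected before transforming")
    u = (spectrum.field - params.Bres) / params.DeltaBpp
    F = spectrum.intensity
    n_center = int(np.count_nonzero(u == 0.0))
    on_side = u < 0 if side == "left" else u > 0
    u_s = u[on_side]
    F_s = F[on_side]
    floor = INTENSITY_FLOOR * params.App
    safe = np.abs(F_s) > floor
    radicand = np.full(u_s.size, -1.0)
    radicand[safe] = -params.App * u_s[safe] / F_s[safe]
    keep = radicand > 0
    n_dropped = int(u_s.size - np.count_nonzero(keep)) + n_center
    x = u_s[keep] ** 2
    y = np.sqrt(radicand[keep])
    if x.size < 2:
        raise TransformError(
            f"fewer than 2 transformable points on the {side} side "
            f"({n_dropped} dropped)"
        )
    order = np.argsort(x, kind="stable")
    return TransformedCurve(x=x[order], y=y[order], side=side, n_dropped=n_dropped)
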