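"""Synthetic EPR spectra with known ground truth.

Real spectra of kerogen-bearing rocks are not shippable as test fixtures, so
every test input is generated: a model derivative line (any of the three
families), a cubic instrumental baseline, and i.i.d. constant-sd Gaussian
noise, sampled on a uniform field grid and optionally written in the
plain-text dialect with a metadata-conforming filename.

The noise here is deliberately constant-sd — not the sqrt(|y|) model the
Monte Carlo stage assumes — so that the noise model can be exercised as a
model, separately from data generation.  Ground truth travels with the
:class:`FixtureSpec` itself, so tests never hard-code expected values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .lineshape_models import LineshapeSpec, evaluate_lineshape
from .spectra_io import AcquisitionMeta, Spectrum, format_filename, write_spectrum

__all__ = ["FixtureSpec", "generate_spectrum", "emit_fixture_file", "default_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic spectrum; the ground truth is its fields."""

    shape: LineshapeSpec
    n_points: int = 4096
    field_min: float | None = None
    field_max: float | None = None
    noise_sd: float = 0.0
    baseline_coeffs: tuple = (0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 64:
            raise ValueError(f"n_points must be >= 64, got {self.n_points}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if len(self.baseline_coeffs) != 4:
            raise ValueError("baseline_coeffs must hold 4 cubic coefficients")
        object.__setattr__(
            self, "baseline_coeffs", tuple(float(c) for c in self.baseline_coeffs)
        )

    def grid(self) -> np.ndarray:
        """Uniform field grid; defaults to |u| <= 4 so x = 10 is reachable."""
        lo = self.field_min
        hi = self.field_max
        if lo is None:
            lo = self.shape.Bres - 4.0 * self.shape.DeltaBpp
        if hi is None:
            hi = self.shape.Bres + 4.0 * self.shape.DeltaBpp
        if not hi > lo:
            raise ValueError(f"field_max ({hi}) must exceed field_min ({lo})")
        return np.linspace(lo, hi, self.n_points)


_FAMILY_SAMPLE = {"gaussian": "synthGauss", "lorentzian": "synthLor",
                  "stretched": "synthStretched"}


def _fixture_meta(fix: FixtureSpec) -> AcquisitionMeta:
    sample = _FAMILY_SAMPLE[fix.shape.family]
    if fix.shape.family == "stretched":
        sample += f"{fix.shape.d}d"
    return AcquisitionMeta(
        sample_name=sample, temperature="ambient", microwave_power="2mW", n_scans=1
    )


def generate_spectrum(fix: FixtureSpec) -> Spectrum:
    """Model line + cubic baseline + constant-sd noise, deterministic in seed."""
    b = fix.grid()
    intensity = evaluate_lineshape(b, fix.shape)
    intensity = intensity + np.polynomial.polynomial.polyval(
        b, np.asarray(fix.baseline_coeffs)
    )
    if fix.noise_sd > 0:
        rng = np.random.default_rng(fix.seed)
        intensity = intensity + rng.normal(0.0, fix.noise_sd, size=b.size)
    return Spectrum(
        field=b, intensity=intensity, meta=_fixture_meta(fix), baseline_corrected=False
    )


def emit_fixture_file(fix: FixtureSpec, path) -> Spectrum:
    """Write the fixture in the text dialect under a parseable filename.

    ``path`` may be a directory (the canonical metadata filename is appended)
    or a full file path.  Returns the spectrum that was written.
    """
    spectrum = generate_spectrum(fix)
    path = str(path)
    if os.path.isdir(path):
        path = os.path.join(path, format_filename(spectrum.meta))
    write_spectrum(spectrum, path)
    return spectrum


def default_fixture(family: str, d: int | None = None, *, noise_sd: float = 0.0,
                    seed: int = 0) -> FixtureSpec:
    """A ready-made fixture per family in realistic instrument units.

    The line sits at Bres = 3480 G with DeltaBpp = 4 G and App = 2 (arbitrary
    intensity units) on a 4096-point grid spanning |u| <= 4 — wide enough for
    the Benc abscissa to pass x = 10 with margin, narrow enough that the
    sweep looks like a routine single-line acquisition.
    """
    shape = LineshapeSpec(
        family=family, App=2.0, DeltaBpp=4.0, Bres=3480.0, d=d
    )
    return FixtureSpec(shape=shape, noise_sd=noise_sd, seed=seed)
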