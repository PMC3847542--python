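"""Reading and writing the plain-text EPR spectrum dialect.

A spectrum file carries two free-text header lines (acquisition parameters and a
file description) followed by three whitespace-separated columns: the 1-based
point index, the magnetic field ``B`` (instrument units, e.g. G or mT) and the
signal intensity (arbitrary units, first derivative of the microwave
absorption).  Acquisition metadata is encoded in the file name as
``<sample>_<temperature>_<power>_<N>scan[s].txt``, e.g.
``gunflint_ambient_2mW_1scan.txt``.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DataQualityWarning, MetadataWarning, SpectrumFormatError

__all__ = [
    "AcquisitionMeta",
    "Spectrum",
    "read_spectrum",
    "write_spectrum",
    "parse_filename",
    "format_filename",
]

# Rightmost-anchored: the greedy sample group lets sample names contain
# underscores as long as the trailing three fields still parse.
_FILENAME_RE = re.compile(
    r"^(?P<sample>.+)_(?P<temperature>[^_]+)_(?P<power>[^_]+)_(?P<nscans>\d+)scans?\.txt$"
)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata carried by the spectrum file name.

    ``temperature`` and ``microwave_power`` are kept as opaque text (e.g.
    ``"ambient"``, ``"100K"``, ``"2mW"``): the lineshape analysis never uses
    them numerically.
    """

    sample_name: str
    temperature: str
    microwave_power: str
    n_scans: int

    def __post_init__(self):
        if self.n_scans < 1:
            raise ValueError(f"n_scans must be >= 1, got {self.n_scans}")


@dataclass(frozen=True)
class Spectrum:
    """An ordered (field, intensity) sampling of one EPR derivative line.

    Field units are carried opaquely (no G/mT conversion): every downstream
    formula uses differences and ratios of fields, so units cancel.
    """

    field: np.ndarray
    intensity: np.ndarray
    meta: Optional[AcquisitionMeta] = None
    baseline_corrected: bool = False

    def __post_init__(self):
        f = np.asarray(self.field, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "field", f)
        object.__setattr__(self, "intensity", i)
        if f.ndim != 1 or i.ndim != 1:
            raise SpectrumFormatError("field and intensity must be 1-D")
        if f.size != i.size:
            raise SpectrumFormatError(
                f"field ({f.size}) and intensity ({i.size}) lengths differ"
            )
        if f.size < 1:
            raise SpectrumFormatError("a spectrum needs at least one point")
        if not (np.isfinite(f).all() and np.isfinite(i).all()):
            raise SpectrumFormatError("field and intensity must be finite")
        if f.size > 1 and not (np.diff(f) > 0).all():
            raise SpectrumFormatError(
                "magnetic field values must be strictly increasing "
                "(spectra are never silently re-sorted)"
            )

    def __len__(self) -> int:
        return int(self.field.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.field, other.field)
            and np.array_equal(self.intensity, other.intensity)
            and self.meta == other.meta
            and self.baseline_corrected == other.baseline_corrected
        )


def parse_filename(name: str) -> Optional[AcquisitionMeta]:
    """Parse acquisition metadata out of a spectrum file name.

    Returns ``None`` (with a :class:`MetadataWarning`) when the basename does
    not match ``<sample>_<temperature>_<power>_<N>scan[s].txt``; reading the
    file itself still succeeds in that case.
    """
    base = os.path.basename(str(name))
    m = _FILENAME_RE.match(base)
    if m is None:
        warnings.warn(
            f"file name {base!r} does not encode acquisition metadata "
            "(expected <sample>_<temperature>_<power>_<N>scan[s].txt)",
            MetadataWarning,
            stacklevel=2,
        )
        return None
    n_scans = int(m.group("nscans"))
    if n_scans < 1:
        warnings.warn(
            f"file name {base!r} declares {n_scans} scans; metadata ignored",
            MetadataWarning,
            stacklevel=2,
        )
        return None
    return AcquisitionMeta(
        sample_name=m.group("sample"),
        temperature=m.group("temperature"),
        microwave_power=m.group("power"),
        n_scans=n_scans,
    )


def format_filename(meta: AcquisitionMeta) -> str:
    """Inverse of :func:`parse_filename` for canonical names."""
    suffix = "scan" if meta.n_scans == 1 else "scans"
    return (
        f"{meta.sample_name}_{meta.temperature}_{meta.microwave_power}_"
        f"{meta.n_scans}{suffix}.txt"
    )


def _parse_rows(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Line-by-line parse used both as the loader and for error localization."""
    idx, fields, intens = [], [], []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 2:  # header: acquisition parameters + file description
                continue
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) < 3:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: expected at least 3 columns, "
                    f"got {len(cols)}"
                )
            try:
                vals = [float(c) for c in cols[:3]]
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: non-numeric value ({exc})"
                ) from None
            idx.append(vals[0])
            fields.append(vals[1])
            intens.append(vals[2])
    if not fields:
        raise SpectrumFormatError(f"{path}: no data rows after the 2 header lines")
    return np.array(idx), np.array(fields), np.array(intens)


def read_spectrum(path) -> Spectrum:
    """Load a spectrum file, skipping the two header lines.

    Column 2 becomes the field axis and column 3 the intensity.  Column 1 is
    checked against the 1..n convention when it is integer-valued and otherwise
    ignored with a warning.  A non-monotonic field axis is an error: sorting is
    never applied silently.
    """
    idx, fields, intens = _parse_rows(path)
    n = fields.size
    if np.allclose(idx, np.round(idx)):
        if not np.array_equal(np.round(idx), np.arange(1, n + 1)):
            warnings.warn(
                f"{path}: index column is not 1..{n}; ignoring it",
                DataQualityWarning,
                stacklevel=2,
            )
    else:
        warnings.warn(
            f"{path}: index column is not integer-valued; ignoring it",
            DataQualityWarning,
            stacklevel=2,
        )
    if n > 1 and not (np.diff(fields) > 0).all():
        raise SpectrumFormatError(
            f"{path}: magnetic field column is not strictly increasing"
        )
    meta = parse_filename(os.path.basename(str(path)))
    return Spectrum(field=fields, intensity=intens, meta=meta, baseline_corrected=False)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write the file dialect read by :func:`read_spectrum`.

    Values are printed at full double precision (``%.17g``): the R10 statistic
    is sensitive to the wings, where the intensity is small.
    """
    meta = spectrum.meta
    header1 = (
        f"# acquisition: sample={meta.sample_name} T={meta.temperature} "
        f"P={meta.microwave_power} scans={meta.n_scans}"
        if meta is not None
        else "# acquisition: unknown"
    )
    header2 = (
        f"# EPR derivative spectrum, {len(spectrum)} points: "
        "index  field  intensity"
    )
    with open(path, "w") as fh:
        fh.write(header1 + "\n")
        fh.write(header2 + "\n")
        for i, (b, y) in enumerate(zip(spectrum.field, spectrum.intensity), start=1):
            fh.write(f"{i} {b:.17g} {y:.17g}\n")
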