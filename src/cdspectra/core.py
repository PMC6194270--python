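"""Core domain types for circular-dichroism spectra.

A :class:`Spectrum` mirrors the five-channel ``.gen`` record in memory:
wavelength grid, raw CD, detector high-tension (HT) voltage, smoothed CD
and the per-point standard deviation between averaged replicate scans.
Wavelengths are stored descending (high to low), the convention of CD
scans; readers reorder ascending files on ingest and note the original
order in ``meta``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Recognised signal units: raw instrument millidegrees, mean residue
#: ellipticity (deg cm^2 dmol^-1), and delta epsilon (M^-1 cm^-1).
UNITS = ("mdeg", "MRE", "delta_epsilon")

#: Conversion constant between mean residue ellipticity and delta epsilon:
#: MRE = 3298 * delta_epsilon.
MRE_PER_DELTA_EPSILON = 3298.0

#: Two wavelengths are considered the same grid point when they differ by
#: less than this (nm).  Files print fixed decimals, so exact-after-parse
#: matching suffices; the tolerance only guards float parsing.
WAVELENGTH_TOL = 1e-6


def _as_float_array(x) -> np.ndarray:
    return np.array(x, dtype=float, copy=True)


@dataclass
class Spectrum:
    """One CD measurement: the ``.gen`` record in memory.

    Parameters
    ----------
    wavelengths:
        Strictly monotonic grid in nm.  Stored descending; ascending input
        is flipped (all channels together) and the original order recorded
        in ``meta["original_order"]``.
    cd:
        Signal per wavelength, in ``units``.
    ht:
        Detector high-tension (photomultiplier) voltage per wavelength, in
        volts.  Optional; rises where little light reaches the detector and
        marks the low-wavelength validity cutoff.
    cd_smoothed:
        Savitzky-Golay smoothed CD, same units as ``cd``.  Optional.
    sd:
        Per-point standard deviation between averaged replicate scans,
        same units as ``cd``.  All zeros when the spectrum is not an
        average (``n_averaged == 1``).
    units:
        One of :data:`UNITS`.
    meta:
        Free-form key -> text metadata (sample name, instrument, the
        processing log under ``"processing"``).
    n_averaged:
        Number of replicate scans merged into this spectrum (1 if raw).
    """

    wavelengths: np.ndarray
    cd: np.ndarray
    ht: np.ndarray | None = None
    cd_smoothed: np.ndarray | None = None
    sd: np.ndarray | None = None
    units: str = "mdeg"
    meta: dict[str, str] = field(default_factory=dict)
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.wavelengths = _as_float_array(self.wavelengths)
        self.cd = _as_float_array(self.cd)
        if self.ht is not None:
            self.ht = _as_float_array(self.ht)
        if self.cd_smoothed is not None:
            self.cd_smoothed = _as_float_array(self.cd_smoothed)
        if self.sd is None:
            self.sd = np.zeros_like(self.cd)
        else:
            self.sd = _as_float_array(self.sd)
        self.meta = dict(self.meta)
        if self.wavelengths.size >= 2 and np.all(np.diff(self.wavelengths) > 0):
            # ascending input: normalise to the descending convention
            self.wavelengths = self.wavelengths[::-1].copy()
            self.cd = self.cd[::-1].copy()
            if self.ht is not None:
                self.ht = self.ht[::-1].copy()
            if self.cd_smoothed is not None:
                self.cd_smoothed = self.cd_smoothed[::-1].copy()
            self.sd = self.sd[::-1].copy()
            self.meta.setdefault("original_order", "ascending")

    # -- convenience ----------------------------------------------------

    @property
    def n_points(self) -> int:
        return int(self.wavelengths.size)

    def copy(self) -> "Spectrum":
        return Spectrum(
            wavelengths=self.wavelengths,
            cd=self.cd,
            ht=None if self.ht is None else self.ht,
            cd_smoothed=None if self.cd_smoothed is None else self.cd_smoothed,
            sd=self.sd,
            units=self.units,
            meta=dict(self.meta),
            n_averaged=self.n_averaged,
        )

    def replace(self, **changes) -> "Spectrum":
        """Return a copy with the given fields replaced."""
        out = self.copy()
        for name, value in changes.items():
            if name not in {f.name for f in dataclasses.fields(Spectrum)}:
                raise TypeError(f"Spectrum has no field {name!r}")
            setattr(out, name, value)
        return Spectrum(**{f.name: getattr(out, f.name) for f in dataclasses.fields(Spectrum)})

    def log(self, line: str) -> None:
        """Append one line to the processing log in ``meta``."""
        existing = self.meta.get("processing", "")
        self.meta["processing"] = (existing + "\n" + line) if existing else line

    def index_of(self, wavelength: float) -> int:
        """Index of a grid point, matched within :data:`WAVELENGTH_TOL`."""
        hits = np.nonzero(np.abs(self.wavelengths - wavelength) < WAVELENGTH_TOL)[0]
        if hits.size == 0:
            raise ValueError(f"wavelength {wavelength} nm is not on the grid")
        return int(hits[0])

    def value_at(self, wavelength: float) -> float:
        return float(self.cd[self.index_of(wavelength)])

    def label(self) -> str:
        return self.meta.get("sample", self.meta.get("file", "<unnamed>"))


@dataclass
class SampleInfo:
    """Sample parameters needed for unit conversion.

    ``mean_residue_weight`` follows the CD convention MW / (N - 1): the
    chromophore being counted is the peptide bond, of which an N-residue
    chain has N - 1.  Set ``count_convention="residues"`` to use MW / N
    instead.
    """

    concentration: float  # mg/mL
    molecular_weight: float  # Da
    n_residues: int
    pathlength: float  # cm
    count_convention: str = "bonds"  # "bonds" -> MW/(N-1), "residues" -> MW/N

    def __post_init__(self) -> None:
        for name in ("concentration", "molecular_weight", "n_residues", "pathlength"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SampleInfo.{name} must be strictly positive")
        if self.count_convention not in ("bonds", "residues"):
            raise ValueError("count_convention must be 'bonds' or 'residues'")
        if self.count_convention == "bonds" and self.n_residues < 2:
            raise ValueError("n_residues must be >= 2 for the peptide-bond convention")

    @property
    def mean_residue_weight(self) -> float:
        divisor = self.n_residues - 1 if self.count_convention == "bonds" else self.n_residues
        return self.molecular_weight / divisor


@dataclass
class WavelengthWindow:
    """A closed wavelength interval [low, high] in nm."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"window low ({self.low}) must be < high ({self.high})")

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.low - WAVELENGTH_TOL) & (
            wavelengths <= self.high + WAVELENGTH_TOL
        )


def validate_spectrum(s: Spectrum) -> list[str]:
    """Check a spectrum against the type invariants.

    Returns a list of human-readable violation descriptions; an empty list
    means the spectrum is well formed.  Never raises on bad data.
    """
    violations: list[str] = []
    try:
        n = s.wavelengths.size
        if n == 0:
            violations.append("wavelengths: empty grid")
        diffs = np.diff(s.wavelengths)
        if n >= 2 and not (np.all(diffs < 0) or np.all(diffs > 0)):
            violations.append("wavelengths: not strictly monotonic")
        for name in ("cd", "ht", "cd_smoothed", "sd"):
            arr = getattr(s, name)
            if arr is not None and arr.size != n:
                violations.append(
                    f"{name}: length {arr.size} does not match wavelengths length {n}"
                )
        if s.sd is not None and s.sd.size == n:
            if np.any(s.sd < 0):
                violations.append("sd: contains negative values")
            all_zero = bool(np.all(s.sd == 0))
            if s.n_averaged == 1 and not all_zero:
                violations.append("sd: nonzero but n_averaged == 1")
            if s.n_averaged > 1 and all_zero:
                violations.append(f"sd: all zero but n_averaged == {s.n_averaged}")
        if s.units not in UNITS:
            violations.append(f"units: {s.units!r} not one of {UNITS}")
        if not isinstance(s.n_averaged, (int, np.integer)) or s.n_averaged < 1:
            violations.append(f"n_averaged: {s.n_averaged!r} is not a positive integer")
    except Exception as exc:  # pragma: no cover - defensive
        violations.append(f"unvalidatable spectrum: {exc}")
    return violations


def _grid_keys(wavelengths: np.ndarray) -> np.ndarray:
    """Integer keys identifying grid points within :data:`WAVELENGTH_TOL`."""
    return np.round(wavelengths / WAVELENGTH_TOL).astype(np.int64)


def align_wavelengths(spectra: list[Spectrum]) -> list[Spectrum]:
    """Restrict a set of spectra to their common wavelength grid.

    Only exact grid intersection is performed (matching within
    :data:`WAVELENGTH_TOL`); no interpolation.  The output order of
    wavelengths follows the first spectrum.  Raises ``ValueError`` naming
    the first incompatible pair when the intersection is empty.
    """
    if len(spectra) == 0:
        raise ValueError("align_wavelengths requires at least one spectrum")
    keysets = [set(_grid_keys(s.wavelengths).tolist()) for s in spectra]
    common = set(keysets[0])
    for ks in keysets[1:]:
        common &= ks
    if not common:
        # name the first pairwise-incompatible files for the error message
        for i in range(len(spectra)):
            for j in range(i + 1, len(spectra)):
                if not (keysets[i] & keysets[j]):
                    raise ValueError(
                        "no common wavelengths between "
                        f"{spectra[i].label()!r} and {spectra[j].label()!r}"
                    )
        raise ValueError("no wavelength common to all spectra")

    out: list[Spectrum] = []
    for s in spectra:
        keys = _grid_keys(s.wavelengths)
        keep = np.array([k in common for k in keys.tolist()], dtype=bool)
        if np.all(keep):
            out.append(s.copy())
            continue
        t = s.replace(
            wavelengths=s.wavelengths[keep],
            cd=s.cd[keep],
            ht=None if s.ht is None else s.ht[keep],
            cd_smoothed=None if s.cd_smoothed is None else s.cd_smoothed[keep],
            sd=s.sd[keep],
        )
        t.log(
            f"aligned to common grid ({int(keep.sum())} of {s.n_points} points kept)"
        )
        out.append(t)
    return out
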