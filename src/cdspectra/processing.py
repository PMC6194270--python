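"""Single- and multi-spectrum processing operations.

Replicate averaging with between-scan standard deviations, baseline
subtraction, zeroing over a signal-free window, Savitzky-Golay smoothing,
unit conversion (mdeg -> mean residue ellipticity -> delta epsilon),
magnitude scaling and calibration, and HT-based low-wavelength truncation.

All operations return new :class:`~cdspectra.core.Spectrum` objects and
append one line to the processing log; inputs are never mutated.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    MRE_PER_DELTA_EPSILON,
    SampleInfo,
    Spectrum,
    WavelengthWindow,
    WAVELENGTH_TOL,
)

#: Default Savitzky-Golay parameters: a 7-point quadratic window, a mild
#: smoothing suitable for 1-nm far-UV scans.
DEFAULT_SG_WINDOW = 7
DEFAULT_SG_ORDER = 2

#: Default zeroing window (nm): the 263-270 nm region, conventionally
#: signal-free for protein far-UV CD.
DEFAULT_ZERO_WINDOW = WavelengthWindow(263.0, 270.0)


def _require_same_units(spectra: list[Spectrum]) -> str:
    units = {s.units for s in spectra}
    if len(units) != 1:
        raise ValueError(f"spectra have mixed units: {sorted(units)}")
    return units.pop()


def _require_same_grid(spectra: list[Spectrum]) -> None:
    ref = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.size != ref.size or np.any(
            np.abs(s.wavelengths - ref) > WAVELENGTH_TOL
        ):
            raise ValueError(
                "spectra are not on the same wavelength grid; "
                "apply align_wavelengths first"
            )


def average_spectra(spectra: list[Spectrum]) -> Spectrum:
    """Average replicate scans pointwise.

    The fifth ``.gen`` channel of the result is the sample standard
    deviation (n-1 denominator) between the replicates at each wavelength.
    HT is the pointwise mean over the spectra that carry an HT channel.
    """
    if len(spectra) < 2:
        raise ValueError("averaging requires at least 2 spectra")
    units = _require_same_units(spectra)
    _require_same_grid(spectra)
    cds = np.stack([s.cd for s in spectra])
    cd = cds.mean(axis=0)
    sd = cds.std(axis=0, ddof=1)
    hts = [s.ht for s in spectra if s.ht is not None]
    ht = np.stack(hts).mean(axis=0) if hts else None
    out = Spectrum(
        wavelengths=spectra[0].wavelengths,
        cd=cd,
        ht=ht,
        cd_smoothed=None,
        sd=sd,
        units=units,
        meta=dict(spectra[0].meta),
        n_averaged=len(spectra),
    )
    names = ", ".join(s.label() for s in spectra)
    out.log(f"averaged {len(spectra)} spectra: {names}")
    return out


def subtract_baseline(sample: Spectrum, baseline: Spectrum) -> Spectrum:
    """Subtract a baseline scan pointwise; SDs propagate in quadrature."""
    _require_same_units([sample, baseline])
    _require_same_grid([sample, baseline])
    out = sample.replace(
        cd=sample.cd - baseline.cd,
        cd_smoothed=None
        if sample.cd_smoothed is None or baseline.cd_smoothed is None
        else sample.cd_smoothed - baseline.cd_smoothed,
        sd=np.sqrt(sample.sd**2 + baseline.sd**2),
    )
    out.log(f"subtracted baseline {baseline.label()!r}")
    return out


def subtract_baseline_multi(
    samples: list[Spectrum], baseline: Spectrum
) -> list[Spectrum]:
    """Subtract a single baseline from multiple sample spectra."""
    if len(samples) == 0:
        raise ValueError("no sample spectra given")
    return [subtract_baseline(s, baseline) for s in samples]


def zero_spectrum(s: Spectrum, window: WavelengthWindow = DEFAULT_ZERO_WINDOW) -> Spectrum:
    """Shift the spectrum so its mean over ``window`` is zero.

    Removes instrument baseline offsets using a region where the sample has
    no genuine CD signal.
    """
    mask = window.mask(s.wavelengths)
    if not np.any(mask):
        raise ValueError(
            f"zeroing window {window.low}-{window.high} nm is outside the grid "
            f"({s.wavelengths.max():g}-{s.wavelengths.min():g} nm)"
        )
    offset = float(s.cd[mask].mean())
    out = s.replace(
        cd=s.cd - offset,
        cd_smoothed=None if s.cd_smoothed is None else s.cd_smoothed - offset,
    )
    out.log(f"zeroed over {window.low}-{window.high} nm (offset {offset:.6g})")
    return out


def smooth_sg(
    s: Spectrum,
    window_pts: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_ORDER,
) -> Spectrum:
    """Fill the smoothed-CD channel with a Savitzky-Golay filter.

    The raw CD channel is preserved untouched, matching the five-column
    file convention of keeping raw and smoothed data side by side.
    Requires an evenly spaced grid and an odd window of at least
    ``poly_order + 2`` points.
    """
    if window_pts % 2 == 0:
        raise ValueError(f"window_pts must be odd, got {window_pts}")
    if window_pts < poly_order + 2:
        raise ValueError(
            f"window_pts ({window_pts}) must be >= poly_order + 2 ({poly_order + 2})"
        )
    if window_pts > s.n_points:
        raise ValueError(
            f"window_pts ({window_pts}) exceeds grid length ({s.n_points})"
        )
    steps = np.diff(s.wavelengths)
    if np.any(np.abs(steps - steps[0]) > WAVELENGTH_TOL):
        raise ValueError("Savitzky-Golay smoothing requires an evenly spaced grid")
    smoothed = savgol_filter(s.cd, window_length=window_pts, polyorder=poly_order)
    out = s.replace(cd_smoothed=smoothed)
    out.log(f"Savitzky-Golay smoothed (window {window_pts} pts, order {poly_order})")
    return out


def _apply_linear(s: Spectrum, factor: float) -> Spectrum:
    return s.replace(
        cd=s.cd * factor,
        cd_smoothed=None if s.cd_smoothed is None else s.cd_smoothed * factor,
        sd=s.sd * abs(factor),
    )


def to_mre(s: Spectrum, info: SampleInfo) -> Spectrum:
    """Convert millidegrees to mean residue ellipticity.

    MRE(lambda) = theta_mdeg(lambda) * MRW / (10 * c * l) with the
    concentration c in mg/mL and the pathlength l in cm, giving
    deg cm^2 dmol^-1.  MRW is the mean residue weight from ``info``.
    """
    if s.units != "mdeg":
        raise ValueError(f"to_mre expects mdeg input, got {s.units!r}")
    factor = info.mean_residue_weight / (10.0 * info.concentration * info.pathlength)
    out = _apply_linear(s, factor)
    out.units = "MRE"
    out.log(
        "converted mdeg -> MRE "
        f"(MRW {info.mean_residue_weight:.6g} Da, c {info.concentration:g} mg/mL, "
        f"l {info.pathlength:g} cm)"
    )
    return out


def to_delta_epsilon(s: Spectrum, info: SampleInfo | None = None) -> Spectrum:
    """Convert to delta epsilon (M^-1 cm^-1): delta_eps = MRE / 3298.

    Accepts mdeg input (converted via :func:`to_mre` first, requiring
    ``info``) or MRE input directly.
    """
    if s.units == "mdeg":
        if info is None:
            raise ValueError("converting mdeg -> delta_epsilon requires SampleInfo")
        s = to_mre(s, info)
    if s.units != "MRE":
        raise ValueError(f"to_delta_epsilon expects mdeg or MRE input, got {s.units!r}")
    out = _apply_linear(s, 1.0 / MRE_PER_DELTA_EPSILON)
    out.units = "delta_epsilon"
    out.log(f"converted MRE -> delta epsilon (/{MRE_PER_DELTA_EPSILON:g})")
    return out


def scale_to_value(s: Spectrum, at: float, target: float) -> Spectrum:
    """Rescale the whole spectrum so that cd(at) == target.

    Enables direct shape comparison of spectra whose magnitudes differ,
    e.g. through concentration errors.
    """
    value = s.value_at(at)
    if value == 0:
        raise ValueError(f"cd({at} nm) is zero; scale factor undefined")
    factor = target / value
    out = _apply_linear(s, factor)
    out.log(f"scaled to {target:g} at {at:g} nm (factor {factor:.6g})")
    return out


def compute_calibration_factor(measured: float, expected: float) -> float:
    """Multiplicative calibration factor expected/measured for a standard.

    E.g. the ratio of the literature band magnitude of a camphorsulfonic
    acid (CSA) standard to the magnitude measured on the instrument.
    """
    if measured == 0:
        raise ValueError("measured standard value is zero; factor undefined")
    return expected / measured


def apply_calibration(s: Spectrum, factor: float, note: str = "") -> Spectrum:
    """Apply a post-collection multiplicative magnitude calibration."""
    if not factor > 0:
        raise ValueError(f"calibration factor must be > 0, got {factor}")
    out = _apply_linear(s, factor)
    line = f"calibrated (factor {factor:.6g})"
    if note:
        line += f": {note}"
    out.log(line)
    return out


def truncate_by_ht(s: Spectrum, ht_max: float) -> tuple[Spectrum, float | None]:
    """Drop low-wavelength points where the detector HT exceeds ``ht_max``.

    The cutoff is the lowest wavelength lambda_c such that
    ht(lambda) <= ht_max for every lambda >= lambda_c: the retained range
    is the contiguous high-wavelength run entirely below the cutoff
    voltage, so an isolated high-wavelength spike also truncates.

    Returns ``(truncated_spectrum, cutoff_wavelength)``; the cutoff is
    ``None`` (and the spectrum unchanged) when HT never exceeds ``ht_max``.
    """
    if s.ht is None:
        raise ValueError("spectrum has no HT channel")
    exceed = np.nonzero(s.ht > ht_max)[0]
    if exceed.size == 0:
        return s.copy(), None
    first_bad = int(exceed[0])  # grid is descending: index 0 = highest wavelength
    if first_bad == 0:
        raise ValueError(
            f"HT exceeds {ht_max:g} V at the highest wavelength; no data retained"
        )
    keep = slice(0, first_bad)
    cutoff = float(s.wavelengths[first_bad - 1])
    out = s.replace(
        wavelengths=s.wavelengths[keep],
        cd=s.cd[keep],
        ht=s.ht[keep],
        cd_smoothed=None if s.cd_smoothed is None else s.cd_smoothed[keep],
        sd=s.sd[keep],
    )
    out.log(f"truncated at HT > {ht_max:g} V (cutoff {cutoff:g} nm)")
    return out, cutoff


def error_band(
    s: Spectrum, k_sigma: float = 1.0, interval: float = 1.0
) -> list[tuple[float, float, float]]:
    """Error-bar intervals cd +/- k_sigma * sd at wavelengths spaced >= ``interval`` nm.

    Only defined for averaged spectra, whose SD channel holds the spread
    between replicate scans.
    """
    if s.n_averaged < 2:
        raise ValueError("no replicate SD available (spectrum is not an average)")
    bands: list[tuple[float, float, float]] = []
    next_at = np.inf
    for lam, cd, sd in zip(s.wavelengths, s.cd, s.sd):
        if lam <= next_at + WAVELENGTH_TOL:
            half = k_sigma * sd
            bands.append((float(lam), float(cd - half), float(cd + half)))
            next_at = lam - interval
    return bands
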