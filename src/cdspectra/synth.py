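"""Synthetic CD spectra, HT profiles, replicate sets and thermal melts.

Every generator is a pure function of its arguments and seed, so the whole
pipeline — file parsing, averaging, HT truncation, SVD of melt series —
is exercisable offline with analytically known ground truth.

Band shapes are sums of Gaussians, which reproduce the qualitative far-UV
appearance of protein CD (e.g. the alpha-helical double minimum at 222 and
208 nm with a positive band near 193 nm) without any claim to
spectroscopic fidelity.  Thermal melts follow a two-state model: the
fraction folded f(T) = 1 / (1 + exp((T - Tm) / w)) mixes a folded and an
unfolded basis spectrum, so the noise-free series matrix has rank exactly
2 and a known melting temperature Tm (f(Tm) = 1/2 by construction).
"""

from __future__ import annotations

import json
import os

import numpy as np

from .core import Spectrum

#: Gaussian bands (center nm, width nm, amplitude mdeg) giving an
#: alpha-helix-like far-UV CD shape.
HELIX_BANDS = [(222.0, 7.0, -10.0), (208.0, 6.0, -11.0), (193.0, 5.0, 16.0)]

#: Bands giving a beta-sheet-like shape.
SHEET_BANDS = [(218.0, 8.0, -6.0), (195.0, 6.0, 9.0)]

DEFAULT_GRID = (260.0, 180.0, 1.0)


def make_grid(high: float = 260.0, low: float = 180.0, step: float = 1.0) -> np.ndarray:
    """Descending wavelength grid from ``high`` to ``low`` inclusive."""
    n = int(round((high - low) / step)) + 1
    return high - step * np.arange(n)


def make_band_spectrum(
    bands,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    seed: int = 0,
    name: str = "synthetic",
    units: str = "mdeg",
) -> Spectrum:
    """Sum-of-Gaussians spectrum: cd = sum A * exp(-(l - c)^2 / (2 w^2))."""
    wl = make_grid(*grid)
    cd = np.zeros_like(wl)
    for center, width, amplitude in bands:
        cd += amplitude * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    return Spectrum(
        wavelengths=wl,
        cd=cd,
        units=units,
        meta={"sample": name, "instrument": "fixtureCD", "seed": str(seed)},
    )


def preset_spectrum(kind: str, name: str | None = None, grid=DEFAULT_GRID) -> Spectrum:
    """A named band preset: ``"helix"`` or ``"sheet"``."""
    presets = {"helix": HELIX_BANDS, "sheet": SHEET_BANDS}
    if kind not in presets:
        raise ValueError(f"unknown preset {kind!r}; known: {sorted(presets)}")
    return make_band_spectrum(presets[kind], grid=grid, name=name or f"{kind}-like")


def make_ht_profile(
    s: Spectrum, base: float = 300.0, knee: float = 200.0, slope: float = 40.0
) -> Spectrum:
    """Attach a detector HT profile: flat at ``base`` V above ``knee`` nm,
    rising linearly at ``slope`` V/nm below it.

    The wavelength at which any threshold voltage is crossed is the closed
    form of :func:`ht_crossing`, making truncation tests exact.
    """
    wl = s.wavelengths
    ht = base + slope * np.clip(knee - wl, 0.0, None)
    out = s.copy()
    out.ht = ht
    out.meta["ht_model"] = f"base={base:g}V knee={knee:g}nm slope={slope:g}V/nm"
    return out


def ht_crossing(base: float, knee: float, slope: float, threshold: float) -> float | None:
    """Wavelength where the linear-ramp HT model first exceeds ``threshold``
    (scanning down); ``None`` when it never does."""
    if threshold < base:
        return knee  # already above threshold at the knee itself
    if slope <= 0:
        return None
    return knee - (threshold - base) / slope


def make_replicates(
    s: Spectrum, n: int, noise_sd: float, seed: int = 0
) -> list[Spectrum]:
    """``n`` copies of a spectrum with i.i.d. Gaussian noise on the CD."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    reps = []
    for i in range(n):
        rep = s.copy()
        rep.cd = s.cd + rng.normal(0.0, noise_sd, size=s.cd.shape)
        rep.meta["sample"] = f"{s.label()} scan {i + 1}"
        reps.append(rep)
    return reps


def fraction_folded(temps, tm: float, width: float) -> np.ndarray:
    """Two-state folded fraction f(T) = 1 / (1 + exp((T - Tm) / width))."""
    t = np.asarray(temps, dtype=float)
    return 1.0 / (1.0 + np.exp((t - tm) / width))


def make_melt_series(
    folded: Spectrum,
    unfolded: Spectrum,
    temps,
    tm: float = 55.0,
    width: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, Spectrum]]:
    """Two-state thermal melt: spectrum(T) = f(T)*folded + (1-f(T))*unfolded + noise.

    Both input spectra must share a wavelength grid.  Each output spectrum
    records its temperature in ``meta["temperature"]``; HT channels, when
    both inputs carry one, are mixed with the same fractions.
    """
    if folded.wavelengths.size != unfolded.wavelengths.size or np.any(
        np.abs(folded.wavelengths - unfolded.wavelengths) > 1e-9
    ):
        raise ValueError("folded and unfolded spectra must share a grid")
    rng = np.random.default_rng(seed)
    fracs = fraction_folded(temps, tm, width)
    series: list[tuple[float, Spectrum]] = []
    for t, f in zip(temps, fracs):
        cd = f * folded.cd + (1.0 - f) * unfolded.cd
        if noise_sd > 0:
            cd = cd + rng.normal(0.0, noise_sd, size=cd.shape)
        ht = None
        if folded.ht is not None and unfolded.ht is not None:
            ht = f * folded.ht + (1.0 - f) * unfolded.ht
        spec = Spectrum(
            wavelengths=folded.wavelengths,
            cd=cd,
            ht=ht,
            units=folded.units,
            meta={
                "sample": f"melt {t:g}C",
                "temperature": f"{t:g}",
                "instrument": "fixtureCD",
            },
        )
        series.append((float(t), spec))
    return series


def demo_melt_series(
    temps=None,
    tm: float = 55.0,
    width: float = 3.0,
    noise_fraction: float = 0.01,
    seed: int = 0,
    with_ht: bool = False,
) -> list[tuple[float, Spectrum]]:
    """The standard study melt: helix-like folded state unfolding to a
    flattened sheet-like state over 30-70 deg C.

    ``noise_fraction`` sets the Gaussian noise SD as a fraction of the
    maximum absolute signal of the folded state (default 1%).
    """
    if temps is None:
        temps = np.linspace(30.0, 70.0, 17)
    folded = preset_spectrum("helix", name="folded")
    unfolded = make_band_spectrum(
        [(218.0, 9.0, -3.0), (198.0, 7.0, 4.0)], name="unfolded"
    )
    if with_ht:
        folded = make_ht_profile(folded, base=300.0, knee=200.0, slope=40.0)
        unfolded = make_ht_profile(unfolded, base=320.0, knee=202.0, slope=44.0)
    noise_sd = noise_fraction * float(np.max(np.abs(folded.cd)))
    return make_melt_series(
        folded, unfolded, temps, tm=tm, width=width, noise_sd=noise_sd, seed=seed
    )


def write_dialect_fixtures(directory: str | os.PathLike, seed: int = 0) -> dict:
    """Write one sample file per registered instrument dialect plus a JSON
    manifest of the true numeric content of each.

    The layouts are synthetic stand-ins for the instrument families they
    exercise; the manifest is the parsing ground truth.
    """
    from .io_formats import DIALECTS

    os.makedirs(directory, exist_ok=True)
    base = preset_spectrum("helix", grid=(250.0, 190.0, 2.0))
    base = make_ht_profile(base, base=280.0, knee=205.0, slope=30.0)
    wl, cd, ht = base.wavelengths, base.cd, base.ht

    manifest: dict = {"seed": seed, "dialects": {}}
    for name in DIALECTS:
        path = os.path.join(os.fspath(directory), f"sample_{name}.txt")
        with open(path, "w", encoding="utf-8") as fh:
            if name == "aviv":
                fh.write("experiment_type Wavelength\n")
                fh.write("sample synthetic helix standard\n")
                fh.write("_data_\n")
                for l, c, h in zip(wl, cd, ht):
                    fh.write(f"{l:.1f} {c:.5f} {h:.2f}\n")
            elif name == "jasco":
                fh.write("TITLE\tsynthetic helix standard\n")
                fh.write("DATA TYPE\tCD\n")
                fh.write("UNITS\tmdeg\n")
                fh.write("XYDATA\n")
                for l, c, h in zip(wl, cd, ht):
                    fh.write(f"{l:.1f}\t{c:.5f}\t{h:.2f}\n")
            elif name == "chirascan":
                fh.write("Chirascan-style synthetic export\n")
                fh.write("Sample,synthetic helix standard\n")
                fh.write("Wavelength,CD,HT\n")
                for l, c, h in zip(wl, cd, ht):
                    fh.write(f"{l:.1f},{c:.5f},{h:.2f}\n")
            else:  # pragma: no cover - future dialects need explicit writers
                raise NotImplementedError(f"no fixture writer for dialect {name!r}")
        manifest["dialects"][name] = {
            "path": os.path.basename(path),
            "wavelengths": [round(float(v), 1) for v in wl],
            "cd": [round(float(v), 5) for v in cd],
            "ht": [round(float(v), 2) for v in ht],
        }
    manifest_path = os.path.join(os.fspath(directory), "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
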