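"""Component analysis of spectral series by singular value decomposition.

A series of spectra recorded under a changing condition (typically a
thermal melt) is assembled into a wavelengths x spectra matrix D of raw
(unsmoothed) CD values, optionally edited to remove wavelengths with
compromised data (high detector HT), and decomposed as D = U S V^T.  The
reported component-contribution table has eight rows; entry (i, j) is
sigma_i * v_ij, the weight of basis spectrum i in measured spectrum j, so
that summing sigma_i * u_i * v_ij over the significant components
reconstructs spectrum j.  For a two-state melt the matrix has rank 2 and
the component-2 contribution curve traces the unfolding transition; its
midpoint locates the melting temperature.

How many components are physically significant is left to the user; the
singular-value spectrum and variance fractions sigma_i^2 / sum sigma^2
are reported as guidance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Spectrum, WAVELENGTH_TOL, align_wavelengths

#: Number of component rows in the reported contributions table.
N_COMPONENTS_REPORTED = 8

#: Default significance threshold on the variance fraction
#: sigma_i^2 / sum sigma^2 used by :func:`estimate_rank`.
RANK_VARIANCE_THRESHOLD = 1e-3


@dataclass
class SpectraMatrix:
    """Aligned wavelengths x spectra data matrix for SVD.

    ``values[i, j]`` is the raw CD of spectrum ``labels[j]`` at
    ``wavelengths[i]``; ``ht`` has the same shape when every input carried
    an HT channel.  Labels are free-form but are usually the numeric
    condition values of the series (e.g. temperatures in deg C).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    labels: list = field(default_factory=list)
    ht: np.ndarray | None = None
    units: str = "mdeg"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ht is not None:
            self.ht = np.asarray(self.ht, dtype=float)
        if not self.labels:
            self.labels = list(range(self.values.shape[1]))
        if self.values.shape != (self.wavelengths.size, len(self.labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.wavelengths.size} wavelengths x {len(self.labels)} labels"
            )
        if self.ht is not None and self.ht.shape != self.values.shape:
            raise ValueError("ht shape does not match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def label_values(self) -> np.ndarray:
        """Numeric condition values of the columns (e.g. temperatures)."""
        try:
            return np.array([float(l) for l in self.labels])
        except (TypeError, ValueError):
            raise ValueError("column labels are not numeric") from None

    def row_index(self, wavelength: float) -> int:
        hits = np.nonzero(np.abs(self.wavelengths - wavelength) < WAVELENGTH_TOL)[0]
        if hits.size == 0:
            raise ValueError(f"wavelength {wavelength} nm is not in the matrix")
        return int(hits[0])


@dataclass
class SvdResult:
    """SVD of a spectral series, reported as a fixed eight-component table.

    ``singular_values``, ``basis_spectra`` (columns = left singular
    vectors over wavelengths) and ``contributions`` (row i =
    sigma_i * v_i) are zero-padded to eight components when the matrix
    supports fewer; ``variance_fraction[i]`` is sigma_i^2 / sum sigma^2.
    The full factors are kept so the input matrix can be reconstructed
    exactly.
    """

    singular_values: np.ndarray  # (8,)
    basis_spectra: np.ndarray  # (n_wavelengths, 8)
    contributions: np.ndarray  # (8, n_spectra)
    variance_fraction: np.ndarray  # (8,)
    wavelengths: np.ndarray
    labels: list
    _u: np.ndarray = field(repr=False, default=None)
    _s: np.ndarray = field(repr=False, default=None)
    _vt: np.ndarray = field(repr=False, default=None)

    def reconstruct(self) -> np.ndarray:
        """Rebuild the input matrix from the full decomposition."""
        return (self._u * self._s) @ self._vt


def build_matrix(spectra: list[Spectrum], labels: list | None = None) -> SpectraMatrix:
    """Assemble a spectral series into a :class:`SpectraMatrix`.

    Spectra are restricted to their common wavelength grid; the raw
    (unsmoothed) CD channel is used.  Columns keep the input order.
    """
    if len(spectra) < 2:
        raise ValueError("a dataset needs at least 2 spectra")
    units = {s.units for s in spectra}
    if len(units) != 1:
        raise ValueError(f"spectra have mixed units: {sorted(units)}")
    aligned = align_wavelengths(spectra)
    values = np.column_stack([s.cd for s in aligned])
    ht = None
    if all(s.ht is not None for s in aligned):
        ht = np.column_stack([s.ht for s in aligned])
    if labels is None:
        labels = [s.meta.get("temperature", s.label()) for s in aligned]
    if len(labels) != len(spectra):
        raise ValueError("one label per spectrum required")
    return SpectraMatrix(
        wavelengths=aligned[0].wavelengths,
        values=values,
        labels=list(labels),
        ht=ht,
        units=units.pop(),
    )


def remove_wavelengths(m: SpectraMatrix, rows: list[float]) -> SpectraMatrix:
    """Drop the listed wavelength rows (e.g. compromised data points)."""
    drop = {m.row_index(w) for w in rows}
    keep = np.array([i not in drop for i in range(m.wavelengths.size)], dtype=bool)
    return SpectraMatrix(
        wavelengths=m.wavelengths[keep],
        values=m.values[keep],
        labels=list(m.labels),
        ht=None if m.ht is None else m.ht[keep],
        units=m.units,
    )


def apply_ht_cutoff(m: SpectraMatrix, ht_max: float) -> SpectraMatrix:
    """Drop all wavelengths at and below the dataset's HT exceedance.

    A wavelength row is compromised when the HT of *any* spectrum in the
    series exceeds ``ht_max`` there (the hottest scan of a melt is the
    worst case); that row and every row at lower wavelength are removed,
    leaving a contiguous high-wavelength block that is clean in every
    column.
    """
    if m.ht is None:
        raise ValueError("matrix has no HT data")
    worst = m.ht.max(axis=1)
    exceed = np.nonzero(worst > ht_max)[0]
    if exceed.size == 0:
        return SpectraMatrix(
            wavelengths=m.wavelengths,
            values=m.values,
            labels=list(m.labels),
            ht=m.ht,
            units=m.units,
        )
    first_bad = int(exceed[0])  # rows descending in wavelength
    if first_bad == 0:
        raise ValueError(
            f"HT exceeds {ht_max:g} V at the highest wavelength; empty matrix"
        )
    keep = slice(0, first_bad)
    return SpectraMatrix(
        wavelengths=m.wavelengths[keep],
        values=m.values[keep],
        labels=list(m.labels),
        ht=m.ht[keep],
        units=m.units,
    )


def melt_curve(m: SpectraMatrix, at: float) -> list[tuple[float, float]]:
    """The single-wavelength row of the series vs its condition values.

    E.g. the CD signal at 222 nm against temperature: the classical
    single-wavelength melt curve.
    """
    row = m.values[m.row_index(at)]
    return list(zip((float(v) for v in m.label_values()), (float(v) for v in row)))


def normalize_series(series) -> list[float]:
    """Divide every point of a series by its first point (first point -> 1)."""
    values = [float(v) for v in series]
    if not values:
        raise ValueError("empty series")
    if values[0] == 0:
        raise ValueError("first value is zero; normalization undefined")
    first = values[0]
    return [v / first for v in values]


def compute_svd(m: SpectraMatrix) -> SvdResult:
    """Decompose the series matrix and tabulate component contributions.

    The sign ambiguity of each singular pair is fixed by making the
    largest-magnitude element of each basis spectrum positive, which makes
    results deterministic across runs and platforms.
    """
    n_rows, n_cols = m.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError(f"matrix {n_rows}x{n_cols} too small for SVD analysis")
    u, s, vt = np.linalg.svd(m.values, full_matrices=False)
    for i in range(s.size):
        j = int(np.argmax(np.abs(u[:, i])))
        if u[j, i] < 0:
            u[:, i] = -u[:, i]
            vt[i, :] = -vt[i, :]

    k = min(N_COMPONENTS_REPORTED, n_rows, n_cols)
    nrep = N_COMPONENTS_REPORTED
    singular = np.zeros(nrep)
    singular[:k] = s[:k]
    basis = np.zeros((n_rows, nrep))
    basis[:, :k] = u[:, :k]
    contributions = np.zeros((nrep, n_cols))
    contributions[:k] = s[:k, None] * vt[:k]
    total = float(np.sum(s**2))
    variance = np.zeros(nrep)
    if total > 0:
        variance[:k] = s[:k] ** 2 / total
    return SvdResult(
        singular_values=singular,
        basis_spectra=basis,
        contributions=contributions,
        variance_fraction=variance,
        wavelengths=m.wavelengths,
        labels=list(m.labels),
        _u=u,
        _s=s,
        _vt=vt,
    )


def component_curve(r: SvdResult, i: int) -> list[tuple[float, float]]:
    """Contribution of component ``i`` (1-based, 1..8) to each spectrum."""
    if not 1 <= i <= N_COMPONENTS_REPORTED:
        raise ValueError(f"component index must be 1..{N_COMPONENTS_REPORTED}, got {i}")
    row = r.contributions[i - 1]
    try:
        xs = [float(l) for l in r.labels]
    except (TypeError, ValueError):
        xs = list(range(len(r.labels)))
    return list(zip(xs, (float(v) for v in row)))


def estimate_rank(r: SvdResult, variance_threshold: float = RANK_VARIANCE_THRESHOLD) -> int:
    """Number of components whose variance fraction exceeds the threshold.

    A guidance heuristic only — the user remains responsible for the final
    significance call.
    """
    return int(np.sum(r.variance_fraction > variance_threshold))


def transition_midpoint(curve: list[tuple[float, float]]) -> float:
    """Locate the midpoint of a sigmoidal transition curve.

    The midpoint level is halfway between the curve's extreme values; the
    crossing is found by linear interpolation between the neighbouring
    points.  Intended for component-contribution or single-wavelength melt
    curves of a two-state transition.
    """
    if len(curve) < 2:
        raise ValueError("need at least 2 points")
    xs = np.array([p[0] for p in curve], dtype=float)
    ys = np.array([p[1] for p in curve], dtype=float)
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    mid = 0.5 * (ys.max() + ys.min())
    shifted = ys - mid
    for i in range(len(xs) - 1):
        a, b = shifted[i], shifted[i + 1]
        if a == 0:
            return float(xs[i])
        if a * b < 0:
            return float(xs[i] + (xs[i + 1] - xs[i]) * a / (a - b))
    if shifted[-1] == 0:
        return float(xs[-1])
    raise ValueError("curve does not cross its midpoint level")
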