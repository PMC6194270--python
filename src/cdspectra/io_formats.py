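"""Readers and writers for ASCII CD spectral formats.

The central interchange format is ``.gen``: an editable metadata header
followed by data lines of exactly five whitespace-separated columns —
wavelength, raw CD, HT voltage, smoothed CD, and the standard deviation
between averaged scans (all zeros for a single scan).  Files in this
layout are accepted by DichroWeb-style secondary-structure servers and by
the PCDDB.

Also provided: a simple two-column (wavelength, CD) reader, data-driven
readers for representative instrument dialects (Aviv-, Jasco- and
Chirascan-style text exports), and RFC 4180 CSV export/import for
spectral matrices and SVD result tables.  Vendor dialects are defined
against repository-authored synthetic fixture layouts, since the real
instrument exports vary by software version; each
:class:`DialectSpec` is plain data, so correcting a layout for a
real-world file is a configuration change.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np

from .core import Spectrum

#: Header terminator accepted in legacy .gen files; always written so that
#: free-form header text can never be mistaken for data.
GEN_DATA_SENTINEL = "$MDCDATA"

_HEADER_ONLY_KEYS = ("units", "n_averaged", "ht_channel", "smoothed_channel")


def _open_text(source, mode: str = "r"):
    """Open path-like sources as UTF-8 text with a Latin-1 fallback."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    if "r" in mode:
        raw = open(source, "rb").read()
        try:
            text = raw.decode("utf-8")
        except UnicodeDecodeError:
            text = raw.decode("latin-1")
        return io.StringIO(text), True
    return open(source, mode, encoding="utf-8", newline=""), True


def _fmt(value: float) -> str:
    return f"{value:.6g}"


def _is_numeric_row(tokens: list[str]) -> bool:
    if len(tokens) < 2:
        return False
    try:
        for t in tokens:
            float(t)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# .gen
# ---------------------------------------------------------------------------


class GenHeader(dict):
    """Ordered key -> text header block of a ``.gen`` file.

    Multi-line values (the processing log) serialise as one repeated
    ``key: line`` entry per line and are re-joined on read, so a header
    this class wrote round-trips byte-identically.
    """

    @classmethod
    def from_spectrum(cls, s: Spectrum) -> "GenHeader":
        h = cls()
        h["units"] = s.units
        h["n_averaged"] = str(s.n_averaged)
        if s.ht is None:
            h["ht_channel"] = "absent (column written as 0)"
        if s.cd_smoothed is None:
            h["smoothed_channel"] = "absent (column copies raw CD)"
        for key, value in s.meta.items():
            h[str(key)] = str(value)
        return h

    def serialize(self) -> str:
        lines = []
        for key, value in self.items():
            for part in str(value).split("\n"):
                lines.append(f"{key}: {part}")
        lines.append(GEN_DATA_SENTINEL)
        return "\n".join(lines) + "\n"


def write_gen(s: Spectrum, destination) -> None:
    """Write a spectrum as a five-column ``.gen`` file.

    Missing HT is written as 0 and missing smoothed CD as a copy of the
    raw CD, each flagged in the header.  The SD column is all zeros for a
    non-averaged spectrum by the type invariant.
    """
    header = GenHeader.from_spectrum(s)
    ht = s.ht if s.ht is not None else np.zeros_like(s.cd)
    smoothed = s.cd_smoothed if s.cd_smoothed is not None else s.cd
    fh, should_close = _open_text(destination, "w")
    try:
        fh.write(header.serialize())
        for lam, cd, h, sm, sd in zip(s.wavelengths, s.cd, ht, smoothed, s.sd):
            fh.write(f"{lam:.1f} {_fmt(cd)} {_fmt(h)} {_fmt(sm)} {_fmt(sd)}\n")
    finally:
        if should_close:
            fh.close()


def read_gen(source) -> Spectrum:
    """Read a ``.gen`` file back into a :class:`Spectrum`.

    The header block ends at a ``$MDCDATA`` sentinel if present, otherwise
    at the first line whose tokens are all numeric.  Header keys are
    captured into ``meta`` (multi-line values re-joined); ``n_averaged``
    comes from the header when present, otherwise it is inferred as >1
    exactly when the SD column is not all zero.
    """
    fh, should_close = _open_text(source, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if should_close:
            fh.close()

    header: dict[str, str] = {}
    remarks: list[str] = []
    data_start = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped == GEN_DATA_SENTINEL:
            data_start = i + 1
            break
        tokens = stripped.split()
        if _is_numeric_row(tokens):
            data_start = i
            break
        if ":" in stripped:
            key, _, value = stripped.partition(":")
            key, value = key.strip(), value.strip()
            if key in header:
                header[key] += "\n" + value
            else:
                header[key] = value
        else:
            remarks.append(stripped)
    if data_start is None:
        raise ValueError("no data section found (.gen file has no numeric lines)")

    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        stripped = line.strip()
        if not stripped:
            continue
        tokens = stripped.split()
        if len(tokens) != 5:
            raise ValueError(
                f"line {lineno}: expected 5 columns, found {len(tokens)}: {stripped!r}"
            )
        try:
            rows.append([float(t) for t in tokens])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric data: {stripped!r}") from None
    if not rows:
        raise ValueError("no data rows after the header")

    data = np.array(rows)
    units = header.pop("units", "mdeg")
    ht_absent = "ht_channel" in header and header.pop("ht_channel").startswith("absent")
    sm_absent = "smoothed_channel" in header and header.pop(
        "smoothed_channel"
    ).startswith("absent")
    sd = data[:, 4]
    if "n_averaged" in header:
        n_averaged = int(header.pop("n_averaged"))
    else:
        n_averaged = 2 if np.any(sd != 0) else 1
    meta = dict(header)
    if remarks:
        meta["remarks"] = "\n".join(remarks)
    return Spectrum(
        wavelengths=data[:, 0],
        cd=data[:, 1],
        ht=None if ht_absent else data[:, 2],
        cd_smoothed=None if sm_absent else data[:, 3],
        sd=sd,
        units=units,
        meta=meta,
        n_averaged=n_averaged,
    )


# ---------------------------------------------------------------------------
# two-column ASCII
# ---------------------------------------------------------------------------


def read_two_column(source) -> Spectrum:
    """Read a simple two-column (wavelength, CD) ASCII file.

    Lines starting with ``#`` and blank lines are ignored.  Units default
    to mdeg; HT and SD are recorded as absent in ``meta``.
    """
    fh, should_close = _open_text(source, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if should_close:
            fh.close()
    wl: list[float] = []
    cd: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.replace(",", " ").split()
        if len(tokens) != 2:
            raise ValueError(
                f"line {lineno}: expected 2 columns, found {len(tokens)} — "
                "use read_gen or a dialect reader for multi-column files"
            )
        try:
            wl.append(float(tokens[0]))
            cd.append(float(tokens[1]))
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric data: {stripped!r}") from None
    if len(wl) < 2:
        raise ValueError("fewer than 2 data lines")
    return Spectrum(
        wavelengths=np.array(wl),
        cd=np.array(cd),
        units="mdeg",
        meta={"format": "two-column", "ht": "absent", "sd": "absent"},
    )


# ---------------------------------------------------------------------------
# instrument dialects
# ---------------------------------------------------------------------------


@dataclass
class DialectSpec:
    """Data-driven description of an instrument text export layout."""

    name: str
    description: str
    header_sentinel: str | None = None  # line whose prefix ends the header
    skip_lines: int = 0
    delimiter: str | None = None  # None = any whitespace
    wavelength_col: int = 0
    cd_col: int = 1
    ht_col: int | None = None
    comment_prefix: str = "#"


#: Registered dialects.  Layouts are representative synthetic stand-ins
#: for the instrument families they are named after, not verified vendor
#: byte layouts.
DIALECTS: dict[str, DialectSpec] = {
    "aviv": DialectSpec(
        name="aviv",
        description="Aviv-style export: 'key value' header, '_data_' sentinel, "
        "whitespace columns wavelength / CD / dynode voltage",
        header_sentinel="_data_",
        wavelength_col=0,
        cd_col=1,
        ht_col=2,
    ),
    "jasco": DialectSpec(
        name="jasco",
        description="Jasco-style .txt export: 'KEY\\tvalue' header ending at "
        "'XYDATA', whitespace columns wavelength / CD / HT",
        header_sentinel="XYDATA",
        wavelength_col=0,
        cd_col=1,
        ht_col=2,
    ),
    "chirascan": DialectSpec(
        name="chirascan",
        description="Chirascan-style CSV: prose header ending at a "
        "'Wavelength,...' column-title line, comma columns "
        "wavelength / CD / HT",
        header_sentinel="Wavelength",
        delimiter=",",
        wavelength_col=0,
        cd_col=1,
        ht_col=2,
    ),
}


def read_dialect(source, dialect: str | DialectSpec) -> Spectrum:
    """Read an instrument text export described by a :class:`DialectSpec`.

    Raises on an unregistered dialect name and on files that do not match
    the dialect (missing sentinel, too few data rows), so feeding the
    wrong reader fails loudly instead of misparsing.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(
                f"unregistered dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None

    fh, should_close = _open_text(source, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if should_close:
            fh.close()

    lines = lines[dialect.skip_lines :]
    if dialect.header_sentinel is not None:
        start = None
        for i, line in enumerate(lines):
            if line.strip().startswith(dialect.header_sentinel):
                start = i + 1
                break
        if start is None:
            raise ValueError(
                f"dialect {dialect.name!r}: header sentinel "
                f"{dialect.header_sentinel!r} not found — wrong dialect?"
            )
        lines = lines[start:]

    needed = max(
        dialect.wavelength_col,
        dialect.cd_col,
        dialect.ht_col if dialect.ht_col is not None else 0,
    )
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(dialect.comment_prefix):
            continue
        tokens = (
            stripped.split()
            if dialect.delimiter is None
            else [t.strip() for t in stripped.split(dialect.delimiter)]
        )
        if not _is_numeric_row(tokens):
            if rows:
                break  # trailing footer after the data block
            raise ValueError(
                f"dialect {dialect.name!r}: line {lineno} is not numeric: {stripped!r}"
            )
        if len(tokens) <= needed:
            raise ValueError(
                f"dialect {dialect.name!r}: line {lineno} has {len(tokens)} "
                f"columns, needs at least {needed + 1}"
            )
        rows.append([float(t) for t in tokens])
    if len(rows) < 2:
        raise ValueError(f"dialect {dialect.name!r}: fewer than 2 data rows")

    data = np.array(rows)
    return Spectrum(
        wavelengths=data[:, dialect.wavelength_col],
        cd=data[:, dialect.cd_col],
        ht=None if dialect.ht_col is None else data[:, dialect.ht_col],
        units="mdeg",
        meta={"format": dialect.name},
    )


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------


def export_csv(table, destination) -> None:
    """Export a SpectraMatrix or SvdResult as RFC 4180 CSV.

    A matrix exports as ``wavelength,<label>,...`` rows; an SVD result as
    ``component,<label>,...`` with the eight component-contribution rows.
    """
    from .svd_analysis import SpectraMatrix, SvdResult  # local: avoid cycle

    fh, should_close = _open_text(destination, "w")
    try:
        writer = csv.writer(fh, lineterminator="\n")
        if isinstance(table, SpectraMatrix):
            if table.values.size == 0:
                raise ValueError("empty matrix")
            writer.writerow(["wavelength"] + [str(l) for l in table.labels])
            for lam, row in zip(table.wavelengths, table.values):
                # repr floats: shortest exact representation, lossless re-import
                writer.writerow([repr(float(lam))] + [repr(float(v)) for v in row])
        elif isinstance(table, SvdResult):
            writer.writerow(["component"] + [str(l) for l in table.labels])
            for i, row in enumerate(table.contributions, start=1):
                writer.writerow([str(i)] + [repr(float(v)) for v in row])
        else:
            raise TypeError(f"cannot export {type(table).__name__} as CSV")
    finally:
        if should_close:
            fh.close()


def read_matrix_csv(source):
    """Re-import a matrix CSV written by :func:`export_csv`."""
    from .svd_analysis import SpectraMatrix  # local: avoid cycle

    fh, should_close = _open_text(source, "r")
    try:
        reader = csv.reader(fh)
        rows = [r for r in reader if r]
    finally:
        if should_close:
            fh.close()
    if len(rows) < 2:
        raise ValueError("CSV has no data rows")
    labels = rows[0][1:]
    data = np.array([[float(v) for v in r] for r in rows[1:]])
    return SpectraMatrix(
        wavelengths=data[:, 0], values=data[:, 1:], labels=list(labels)
    )
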