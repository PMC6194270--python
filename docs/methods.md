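# Methods

## Scope and data model

`cdspectra` processes circular dichroism (CD) and synchrotron-radiation CD
spectra. The in-memory unit is the `Spectrum`: a strictly monotonic
wavelength grid (stored descending, the convention of CD scans), the raw CD
signal, the detector high-tension (HT) voltage, a Savitzky–Golay smoothed
copy of the CD, and the per-point standard deviation between averaged
replicate scans. This mirrors the five-column `.gen` interchange file:

    wavelength  raw-CD  HT  smoothed-CD  SD

preceded by an editable `key: value` header carrying sample metadata, the
units and the processing log. The SD column is identically zero for a
single (non-averaged) scan. Files in this layout are accepted by
secondary-structure servers in the DichroWeb family and by the PCDDB.

Readers normalise ascending files to descending order (recording the
original order in the metadata) and match wavelengths with a 1e-6 nm
tolerance — input files print fixed decimals, so this is exact matching
with a float-parsing guard. Spectra on different grids are reconciled only
by exact grid intersection (`align_wavelengths`); no interpolation is
performed, because inventing values between measured points would silently
manufacture data for the averaging, subtraction and SVD steps downstream.

## Processing operations

- **Averaging** is the pointwise arithmetic mean of replicate scans; the SD
  channel is the sample standard deviation (n−1 denominator, appropriate
  for the small replicate counts typical of CD, usually 3–5 scans). HT is
  averaged over the scans that carry it.
- **Baseline subtraction** is pointwise; SDs propagate in quadrature
  (sqrt(sd_s² + sd_b²)), treating sample and baseline noise as independent.
- **Zeroing** subtracts the mean CD over a signal-free window, by default
  263–270 nm, the conventional offset region for protein far-UV spectra.
  The window is configurable because instruments and samples differ.
- **Smoothing** is Savitzky–Golay (scipy implementation), default 7-point
  window, order 2 — a mild setting for 1-nm steps. The raw channel is never
  overwritten; smoothed values live in their own column, so smoothing is
  always reversible by ignoring that column.
- **Unit conversion.** With θ the ellipticity in mdeg, c the protein
  concentration in mg/mL, l the pathlength in cm and MRW the mean residue
  weight in Da,

      MRE(λ) = θ(λ) · MRW / (10 · c · l)      [deg·cm²·dmol⁻¹]
      Δε(λ)  = MRE(λ) / 3298                  [M⁻¹·cm⁻¹]

  MRW defaults to MW/(N−1): the absorbing chromophore is the peptide bond,
  of which an N-residue chain has N−1. MW/N is available as an option
  (`count_convention="residues"`), since both conventions appear in the
  literature. All conversions are linear and apply identically to the raw,
  smoothed and SD channels.
- **Scaling and calibration** are multiplicative. `scale_to_value` anchors
  the spectrum at a chosen wavelength for shape comparison;
  `apply_calibration` applies a user-supplied magnitude factor, with
  `compute_calibration_factor(measured, expected) = expected/measured` as
  the helper for standards such as camphorsulfonic acid. The full CSA
  calibration protocol (band ratios at two wavelengths, etc.) is out of
  scope; the correction it yields is a single factor, which is what is
  implemented.
- **HT truncation.** The HT voltage rises where too little light reaches
  the detector; data below that point are invalid. The cutoff λc is the
  lowest wavelength such that HT ≤ HT_max for *every* λ ≥ λc — a suffix
  criterion, so an isolated high-wavelength spike (bubble, scattering
  artifact) also truncates rather than being skipped over. The retained
  range is always a contiguous block including the highest wavelength. At
  dataset level (`apply_ht_cutoff`) the worst column governs: a row is
  compromised if any spectrum in the series exceeds the cutoff there,
  which for thermal melts means the hottest, noisiest scan sets the limit
  for the whole matrix.

## SVD component analysis

A series of spectra (e.g. a thermal melt) is assembled column-wise into a
wavelengths × spectra matrix D from the **raw** CD channel — smoothing
before decomposition would correlate the noise and bias the small singular
values. D = UΣVᵀ; the reported table has a fixed eight component rows,
entry (i, j) = σᵢ·v_ij (the reconstruction-weighted convention: summing
σᵢ·uᵢ·v_ij over accepted components rebuilds spectrum j). When the matrix
supports fewer than eight components the extra rows are zero-padded so the
table shape is stable; the full factors are retained internally so exact
reconstruction is available regardless.

The SVD sign ambiguity is fixed by flipping each (uᵢ, vᵢ) pair so the
largest-magnitude element of the basis spectrum uᵢ is positive; this makes
results deterministic across BLAS implementations.

How many components are physically meaningful is the user's call. As
guidance, `estimate_rank` counts components whose variance fraction
σᵢ²/Σσ² exceeds 1e-3, a threshold sitting well above the noise floor of
the study conditions below (where the third singular value carries ~1e-4
of the variance) and well below genuine transition components (~1e-2).

For a two-state melt the component-2 contribution curve is sigmoidal in
temperature; `transition_midpoint` locates the melting temperature as the
linear-interpolated crossing of the halfway level between the curve's
extremes.

## Synthetic data generator

The generator (`cdspectra.synth`) produces the study conditions used by
the tests and the acceptance script; every function is a pure function of
its seed.

- **Band spectra** are sums of Gaussians. The "helix" preset places
  negative bands at 222 and 208 nm and a positive band at 193 nm; "sheet"
  a negative band at 218 nm and positive at 195 nm. This reproduces the
  qualitative shape, magnitudes (~±10–16 mdeg) and band positions of
  protein far-UV CD without claiming spectroscopic fidelity — adequacy is
  judged by whether downstream operations are exercised.
- **HT profiles** are flat at a base voltage above a knee wavelength and
  rise linearly below it, so every threshold crossing has a closed form
  and truncation tests are exact.
- **Replicates** add i.i.d. Gaussian noise; real instrument noise is
  wavelength-dependent (it grows with HT), which this model omits.
- **Thermal melts** follow a two-state model: fraction folded
  f(T) = 1/(1+exp((T−Tm)/w)), spectrum(T) = f·folded + (1−f)·unfolded +
  noise. The noise-free matrix has rank exactly 2 and f(Tm) = 1/2 by
  construction. The standard study melt uses Tm = 55 °C, width = 3 °C,
  17 temperatures from 30 to 70 °C (2.5 °C steps) and Gaussian noise with
  SD equal to 1% of the folded signal maximum. Under these conditions the
  inferred rank is 2 and the component-2 midpoint recovers Tm to well
  within one temperature step.

What passing these tests does *not* show: real melts have sloping
baselines, temperature-dependent folded/unfolded spectra, and non-two-state
intermediates; real instrument files have vendor quirks beyond the
representative dialect layouts shipped here.

## File formats and numerics

- `.gen` numbers are written as fixed 1-decimal wavelengths and
  6-significant-digit values for the other four columns; round-trips are
  therefore exact to the printed precision (relative ~1e-6), which the
  tests assert at rtol 1e-5. CSV export writes `repr` floats (shortest
  exact form), so CSV round-trips are lossless.
- Vendor dialects (Aviv-, Jasco- and Chirascan-style) are data-driven
  `DialectSpec` records — column mapping, header sentinel, delimiter —
  parsed against repository-authored fixture layouts, because the real
  byte layouts vary by instrument software version. Correcting a layout
  for a real file is a configuration change, not code.
- Every reader fails loudly on the wrong format (missing sentinel, wrong
  column count, non-numeric line with its line number) rather than
  misparsing.

## Archive

The archive is an embedded SQLite file: one `spectra` table with
searchable metadata columns (sample name, instrument, operator, date,
processing log) plus the full spectrum serialized as JSON arrays of
repr-exact floats — retrieval is bit-identical, never re-parsed text.
Text search is a case-insensitive substring over all metadata fields;
structured queries are conjunctions of equality / substring / range
predicates, with a SELECT-only raw-SQL passthrough. A MySQL-dialect schema
dump (`archive.schema_sql("mysql")`) supports migrating the archive to a
server; multi-user serving is out of scope.

## Known limitations

- No interpolation between wavelength grids; spectra must share grid
  points to be combined.
- Savitzky–Golay requires an evenly spaced grid.
- Thermodynamic fitting (van't Hoff ΔH, baseline-corrected Tm fits) is
  deliberately absent: the analysis stops at SVD components and their
  midpoints.
- Secondary-structure estimation is delegated to external services; this
  package only guarantees `.gen` output they accept.
- The dialect layouts are representative, not vendor-verified.
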