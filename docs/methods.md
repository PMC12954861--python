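# Methods

## Dose bookkeeping

The per-dataset dose unit is the ADER (average dose over the exposed
region), in kGy, computed by external dose-simulation software and supplied
as input — no absorption physics is reimplemented here. For a series of
datasets indexed 1…N:

* cumulative dose after dataset *n* is the plain sum of ADERs 1…*n*
  (*n* = 0 gives the empty sum 0);
* the *effective absorbed dose* of dataset *n* — the dose label attached to
  a structure refined against it — is the cumulative dose through dataset
  *n* − 1 plus **half** of dataset *n*'s own ADER, because that dose accrues
  progressively while the dataset is being measured.

Arithmetic is carried at full double precision; rounding happens only in the
reporting helpers (`report_kgy`: one decimal, ties half-up, so 32.5/2 prints
16.3; `report_percent`: nearest integer). A `dose_fraction_of_constant`
helper expresses an effective dose as a percentage of any dose constant;
which constant is the relevant comparator is left to the caller, since a
"fraction of the fastest constant" depends on which series (temperature,
band) defines "fastest".

Data note: in the source experiment the room-temperature nitrite-reductase
series is variously described with 14.4 or 15 kGy per dataset while its
19-dataset total is 283.1 kGy; the presets here use 14.9 kGy per dataset,
the value consistent with the series total.

For continuously recorded spectra, a constant dose rate after shutter
opening maps timestamps to dose: *D*(*t*) = max(0, (*t* − *t*₀) · rate).

## Band traces and kinetics fits

Spectra are resampled onto the first spectrum's wavelength grid by linear
interpolation on load (rows sorted by wavelength first). Band absorbance is
the mean over a ± half-window around the band centre (default ±2 nm; the
averaging window used in published analyses is not stated anywhere, so this
is an explicit choice) or, with a zero half-window, linear interpolation at
the centre. Baseline correction, when requested, subtracts the mean over a
user-chosen feature-free window — a constant-offset model only; no
polynomial or scattering models are attempted because no such model is
specified for the source data.

The kinetics model is the three-parameter single exponential
A(D) = A∞ + (A₀ − A∞)·exp(−D/τ), covering rises and decays in one family;
the reported direction is the sign of the fitted net change. τ is the 1/e
dose constant in both readings. Fitting is unweighted least squares
(lmfit/Levenberg–Marquardt) initialised with A₀ = first point, A∞ = last
point, τ = dose range/3; two additional τ starts (range/10 and range) guard
against a degenerate local minimum in which the exponential collapses onto
the first data point (τ → 0), which otherwise captures a few percent of
long, noisy traces. The lowest-RSS start wins. Standard errors come from
the fit covariance. A trace with zero amplitude change, or a fit that ends
non-converged, is returned flagged `converged=False` rather than silently
replaced. Whether the published dose constants came from 2- or 3-parameter
fits is unknown; the 3-parameter form is the least committal.

Peak detection is a local-maximum search with a prominence threshold
(scipy.signal.find_peaks); band ratios divide two band absorbances and
refuse near-zero denominators.

## Difference-density integration

Maps are voxel grids over one unit cell with grid point (i, j, k) at
fractional (i/nx, j/ny, k/nz); CCP4/MRC files are read and written through
gemmi with axis order normalised to X,Y,Z on load. The map σ is the
population standard deviation over the full grid (the whole map file, not an
asymmetric unit — synthetic maps are P1 anyway).

Site integration considers every voxel whose **centre** lies within the
integration radius (default 1.0 Å) of the atom, using minimum-image distances so
sites near cell edges wrap correctly; values above +mσ are summed into the
positive sum, values below −mσ into the negative sum (default m = 3).
Voxel membership by centre rather than partial-volume overlap keeps the
operation exactly reproducible by a brute-force triple loop, which the test
suite exploits. Both the raw value sums (e⁻ Å⁻³ summed over voxels) and
volume-weighted sums (× voxel volume, in electrons) are reported, since the
fitted dose constant is invariant to the choice; the σ used for thresholding
can also be supplied explicitly (e.g. a pre-resampling σ) instead of the
map's own.

Fo−Fo synthesis is deliberately minimal: common reflections of the two
amplitude sets are scaled by the closed-form least-squares factor
k = Σ(F_ref·F_n)/Σ(F_n²), combined as (k·F_n − F_1)·exp(iφ_ref) with phases
from a reference set (default: the first dataset's), and Fourier-synthesised
by FFT in P1 onto a grid defaulting to d_min/3 spacing. No σ_A weighting,
solvent model or symmetry expansion is applied — externally produced maps
from full-featured suites can be consumed directly instead. Identical
amplitude sets therefore give the exactly-zero map, and synthesis is linear
in the coefficients; both properties are asserted in the tests.

`series_site_kinetics` resamples a map series onto the first map's grid
(trilinear, periodic), reuses one sphere mask, integrates per dose, and fits
|negative sum| (or the positive sum) with the same exponential model. A
series shorter than 5 dose points skips the fit with a warning.

Because the 3σ threshold admits a growing shell of the feature as its
amplitude grows, the thresholded sum is not exactly proportional to
1 − exp(−D/τ): recovered dose constants carry a small upward bias (a few
percent at the default synthetic conditions: feature amplitude 20× the voxel
noise, 0.5 Å feature width, ~0.31 Å voxels). This is a property of the
thresholded integral itself, not of the fit.

## Beam profile

Pinhole-scan readings are dark-subtracted, clipped at zero and reshaped onto
the rectangular scan grid. FWHM per axis is measured on the marginal
(axis-summed) profile with linear interpolation at the half-maximum
crossings — marginals are robust to pixel noise and, for a separable
top-hat, share the central slice's width. The plateau is the pixel set at or
above 90% of the 2-D maximum; flatness is sd/mean there. Edge width is the
10%→90% distance averaged over the two edges of the marginal (for an
error-function edge of width σ this is 2·1.2816·σ). The thresholds (90%
plateau, 10–90% edges) are conventions chosen here; no published numeric
flatness or edge values exist to compare against, so these metrics are
validated purely by round-trip against the generator. No pinhole
deconvolution is applied (the ~5 µm pinhole is small against beams of
50–250 µm). Flux calibration rescales the map so its trapezoidal integral
over the scan area equals a calibrated-diode total, giving photons s⁻¹ µm⁻².

## Synthetic data: what it does and does not emulate

The generators produce exactly the statistical structure the analyses
assume: Gaussian bands with exponential amplitude kinetics on a linear
(optionally dose-drifting) baseline plus i.i.d. Gaussian noise per
wavelength point; localised Gaussian density features with exponential
growth/decay plus i.i.d. Gaussian voxel noise in a cubic P1 cell (default
20 Å cell, 64³ grid ⇒ ~0.31 Å voxels, so a 1.0 Å sphere holds ~130 voxels);
erf-edged rectangular beams plus readout noise. All are bit-reproducible
given a seed.

They deliberately do **not** emulate: band-shape changes or peak shifts with
temperature/redox state (only amplitudes evolve), correlated or
wavelength-dependent noise, crystal absorption/birefringence or saturation
effects, diffraction-quality decay with dose, non-P1 symmetry, or detector
nonlinearity. Passing round-trip tests therefore shows the estimators are
correct and well-calibrated *under the assumed model*, not that real data
meet those assumptions.

Preset band positions and dose constants follow the published haem and T1Cu
photoreduction series (rise 30/19 kGy and decays 80/48 kGy for the haem
bands at cryo/room temperature; decays 279/271/283/177 kGy for the copper
charge-transfer bands); preset band **amplitudes and widths** are plausible
placeholders (Soret-like widths ~10 nm, Q-band-like 15–25 nm), since the
experimental values are not printed. The copper presets fix the zero-dose
amplitude ratios of the two charge-transfer bands at 1.28 (cryo, green
site) and 1.05 (room temperature, greenish-blue site).

## Problem sizes and tolerances

The verification suite uses: 50-replicate trace ensembles (101–147 dose
points each) for dose-constant recovery, asserting the ensemble mean within
5% of truth; one 20-map 64³ series for the integration pipeline (64³ keeps
the sphere well resolved while a full series simulates in about a second);
100+ random ≤ 12³ maps for brute-force oracle equivalence (exact, voxel for
voxel); hemisphere resolutions of 8–12 indices for synthesis tests. Fit
agreement on noiseless model data is asserted to 1e−6 relative; exact
identities (scaling covariance, negation antisymmetry, linearity of
synthesis) to floating-point round-off.
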