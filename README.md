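# dosekin

Dose-resolved radiation-damage analysis for sequential ("multiple structures
from one crystal", MSOX) macromolecular crystallography experiments with
on-line in crystallo UV-Vis absorption spectroscopy.

When complete datasets are collected back-to-back from one crystal, specific
radiation damage — above all the photoreduction of metal centres — develops
progressively with absorbed dose. Two orthogonal, quantitative readouts of
that process are

1. the absorbance of characteristic bands (haem Soret/Q bands, the
   ligand-to-metal charge-transfer bands of a type-1 copper site) tracked
   across a dose-tagged spectra series, and
2. the isomorphous difference electron density Fo(*n*) − Fo(1) integrated
   around the affected atom across the dataset series.

Both signals follow single-exponential dose kinetics

&nbsp;&nbsp;&nbsp;&nbsp;*A*(*D*) = *A*<sub>∞</sub> + (*A*<sub>0</sub> − *A*<sub>∞</sub>) · exp(−*D*/τ)

whose **dose constant** τ is the dose at which a decay has fallen to 1/e of
its initial excess over the asymptote (a rise: covered 1 − 1/e of its total
amplitude). `dosekin` implements the full chain around this model:

* **`dosekin.dose`** — ADER (average dose over the exposed region,
  per-dataset, from external dose simulation) bookkeeping: cumulative dose,
  the *effective absorbed dose* of dataset *n* (all prior doses plus half of
  its own), dose axes for continuously recorded spectra;
* **`dosekin.spectra`** — spectra loading/resampling, baseline correction,
  band-trace extraction, peak detection, band ratios, and the exponential
  dose-constant fit (lmfit/least squares, with standard errors);
* **`dosekin.density`** — CCP4/MRC map I/O (gemmi), least-squares amplitude
  scaling, Fo−Fo difference-map Fourier synthesis in P1, σ-thresholded
  integration of density within a radius of an atom (all values beyond
  ±*m*σ from voxels whose centres lie within *r* Å, minimum-image), and
  dose-kinetics fitting of the integrated signal;
* **`dosekin.beam`** — top-hat beam-profile reconstruction from pinhole
  scans: FWHM from marginal profiles, plateau flatness, 10–90% edge widths,
  flux calibration against a calibrated-diode total;
* **`dosekin.simulate`** — seeded synthetic generators for every input
  (multi-band spectra series, difference-map series, pinhole scans, dose
  schedules) with known ground truth, including presets for haem and T1Cu
  photoreduction series.

## Worked example

Dose bookkeeping for a paired cryo (47 × 14.4 kGy) / room-temperature
(18 × 32.5 kGy) myoglobin experiment (`examples/dose_bookkeeping.py`):

```text
CT series: 47 datasets x 14.4 kGy
  effective dose of dataset 1 : 7.2 kGy
  cumulative dose, dataset 6  : 86.4 kGy
  cumulative dose, dataset 47 : 676.8 kGy
RT series: 18 datasets x 32.5 kGy
  effective dose of dataset 1 : 16.3 kGy
  as % of the 19 kGy rise constant: 86%
```

The first room-temperature structure already carries 86% of the fastest
spectroscopic reduction dose constant — its iron is substantially reduced —
whereas the first cryo structure (7.2 kGy effective) is still essentially
oxidized.

Band kinetics on a simulated cryo haem series (`examples/band_kinetics.py`):

```text
band 568 nm: rise  tau =  28.8 +/- 0.4 kGy (true 30 kGy, converged=True)
band 630 nm: decay tau =  84.8 +/- 1.3 kGy (true 80 kGy, converged=True)
```

The ferrous 568 nm band rises roughly 2.7× faster than the ferric 630 nm
band decays: the iron is reduced before its coordination environment relaxes.

Integrated difference density at a metal site, from a simulated 20-map
series (`examples/difference_density_kinetics.py`):

```text
negative density at the site builds up with tau = 81.2 kGy (true 79.5 kGy)
```

Other examples: `examples/fo_fo_difference_map.py` (toy displaced-atom Fo−Fo
map with its paired negative/positive peaks) and `examples/beam_profile.py`
(pinhole-scan round trip: FWHM 199.7 × 99.9 µm for a true 200 × 100 µm
top-hat, flux normalised to 2.25 × 10¹¹ ph/s).

## Command line

A thin CLI wraps the same functions for shell pipelines:

```sh
dosekin simulate  --config sim.yaml  --out data/ --seed 7   # synthetic inputs
dosekin dose      --config dose.yaml --out out/             # dose table
dosekin kinetics  --config kin.yaml  --out out/             # band traces + fits
dosekin integrate --config int.yaml  --out out/             # map-series integration
dosekin beam      --config beam.yaml --out out/             # beam metrics
```

All outputs are plain CSV/JSON; exit codes: 0 success, 2 config error,
3 a fit did not converge. Config examples are in the test suite
(`tests/test_cli.py`).

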