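"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates the statistical structure the corresponding analysis
assumes, so that generator -> consumer round-trips recover the true
parameters:

* spectra series — sums of Gaussian bands whose amplitudes follow
  single-exponential dose kinetics, on a linear baseline with optional
  per-kGy drift, plus i.i.d. Gaussian noise per wavelength point;
* difference-map series — localised Gaussian density features whose
  amplitudes grow (or decay) exponentially with dose, plus i.i.d. Gaussian
  voxel noise, in a cubic P1 cell;
* pinhole scans — a rectangular top-hat beam with error-function edges
  (per-axis erf-profile product) plus Gaussian readout noise;
* dose schedules — uniform or explicit per-dataset doses.

All generators are bit-reproducible given a seed. The presets use band
positions and dose constants reported for haem and T1Cu photoreduction
series; their band *amplitudes and widths* are plausible placeholders, since
true experimental values are not published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import erf

from .beam import PinholeScan
from .density import DensityMap, _orth_matrix
from .dose import DoseSchedule
from .spectra import SpectraSeries, Spectrum

__all__ = [
    "BandKineticsSpec",
    "SpectraSimConfig",
    "MapFeature",
    "MapSimConfig",
    "ScanSimConfig",
    "simulate_spectra_series",
    "simulate_map_series",
    "simulate_pinhole_scan",
    "make_schedule",
    "get_preset",
    "PRESETS",
]


def _exp_kinetics(dose: np.ndarray, start: float, end: float, tau: float) -> np.ndarray:
    return end + (start - end) * np.exp(-np.asarray(dose, dtype=float) / tau)


@dataclass(frozen=True)
class BandKineticsSpec:
    """One Gaussian band with exponential amplitude kinetics.

    The direction (rise or decay) is implied by the sign of
    ``a_end_au - a_start_au``.
    """

    center_nm: float
    width_nm: float
    a_start_au: float
    a_end_au: float
    tau_kgy: float

    def __post_init__(self) -> None:
        if not self.width_nm > 0:
            raise ValueError("width_nm must be > 0")
        if not self.tau_kgy > 0:
            raise ValueError("tau_kgy must be > 0")

    def amplitude(self, dose) -> np.ndarray:
        return _exp_kinetics(dose, self.a_start_au, self.a_end_au, self.tau_kgy)


@dataclass(frozen=True)
class SpectraSimConfig:
    wavelengths_nm: np.ndarray
    bands: tuple[BandKineticsSpec, ...]
    doses_kgy: np.ndarray
    noise_sd_au: float = 0.0
    baseline_offset_au: float = 0.0
    baseline_slope_au_per_nm: float = 0.0
    baseline_drift_au_per_kgy: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        doses = np.asarray(self.doses_kgy, dtype=float)
        if self.noise_sd_au < 0:
            raise ValueError("noise_sd_au must be >= 0")
        if np.any(np.diff(doses) < 0):
            raise ValueError("doses must be non-decreasing")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "doses_kgy", doses)
        object.__setattr__(self, "bands", tuple(self.bands))

    def baseline(self, dose: float) -> np.ndarray:
        wl = self.wavelengths_nm
        return (
            self.baseline_offset_au
            + self.baseline_slope_au_per_nm * (wl - wl[0])
            + self.baseline_drift_au_per_kgy * dose
        )


def simulate_spectra_series(config: SpectraSimConfig) -> SpectraSeries:
    """A(lambda, D) = sum_b a_b(D) G(lambda; c_b, w_b) + baseline + noise."""
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths_nm
    spectra = []
    for dose in config.doses_kgy:
        signal = config.baseline(float(dose)).copy()
        for band in config.bands:
            signal += band.amplitude(dose) * np.exp(
                -((wl - band.center_nm) ** 2) / (2.0 * band.width_nm**2)
            )
        if config.noise_sd_au > 0:
            signal = signal + rng.normal(0.0, config.noise_sd_au, wl.size)
        spectra.append(Spectrum(wl, signal, float(dose)))
    return SpectraSeries(tuple(spectra), metadata={"label": config.label})


# ---------------------------------------------------------------------------
# map series


@dataclass(frozen=True)
class MapFeature:
    """A localised Gaussian density feature with exponential dose kinetics.

    ``amplitude`` carries the sign (negative for a density-loss feature);
    ``direction="grow"`` follows amplitude * (1 - exp(-D/tau)),
    ``direction="decay"`` follows amplitude * exp(-D/tau).
    """

    position_a: tuple[float, float, float]
    amplitude: float
    width_a: float
    tau_kgy: float
    direction: str = "grow"

    def __post_init__(self) -> None:
        if not self.width_a > 0:
            raise ValueError("width_a must be > 0")
        if not self.tau_kgy > 0:
            raise ValueError("tau_kgy must be > 0")
        if self.direction not in ("grow", "decay"):
            raise ValueError("direction must be 'grow' or 'decay'")

    def scale(self, dose: float) -> float:
        x = np.exp(-dose / self.tau_kgy)
        return self.amplitude * ((1.0 - x) if self.direction == "grow" else x)


@dataclass(frozen=True)
class MapSimConfig:
    grid: tuple[int, int, int] = (64, 64, 64)
    cell_a: float = 20.0
    features: tuple[MapFeature, ...] = ()
    noise_sd: float = 0.0
    doses_kgy: np.ndarray = field(default_factory=lambda: np.arange(0.0, 10.0))
    seed: int = 0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses_kgy, dtype=float)
        object.__setattr__(self, "doses_kgy", doses)
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "grid", tuple(int(n) for n in self.grid))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.cell_a > 0:
            raise ValueError("cell_a must be > 0")

    @property
    def cell(self) -> tuple[float, float, float, float, float, float]:
        return (self.cell_a, self.cell_a, self.cell_a, 90.0, 90.0, 90.0)


def _feature_field(config: MapSimConfig, feature: MapFeature) -> np.ndarray:
    """Unit-amplitude periodic Gaussian field of one feature on the grid."""
    orth = _orth_matrix(config.cell)
    frac0 = np.linalg.solve(orth, np.asarray(feature.position_a, dtype=float))
    nx, ny, nz = config.grid
    di = (np.arange(nx) / nx - frac0[0] + 0.5) % 1.0 - 0.5
    dj = (np.arange(ny) / ny - frac0[1] + 0.5) % 1.0 - 0.5
    dk = (np.arange(nz) / nz - frac0[2] + 0.5) % 1.0 - 0.5
    dfrac = np.stack(np.meshgrid(di, dj, dk, indexing="ij"), axis=-1)
    dist2 = np.sum((dfrac @ orth.T) ** 2, axis=-1)
    return np.exp(-dist2 / (2.0 * feature.width_a**2))


def simulate_map_series(
    config: MapSimConfig,
) -> tuple[list[DensityMap], np.ndarray]:
    """Per-dose maps rho_D = sum_f scale_f(D) G_f(r) + voxel noise."""
    rng = np.random.default_rng(config.seed)
    fields = [_feature_field(config, f) for f in config.features]
    maps = []
    for dose in config.doses_kgy:
        rho = np.zeros(config.grid)
        for feature, fld in zip(config.features, fields):
            rho += feature.scale(float(dose)) * fld
        if config.noise_sd > 0:
            rho = rho + rng.normal(0.0, config.noise_sd, config.grid)
        maps.append(DensityMap(rho, config.cell, "P1"))
    return maps, config.doses_kgy.copy()


def features_to_pdb(config: MapSimConfig, path: str | Path) -> None:
    """Write feature positions as a minimal PDB so site files can be round-tripped."""
    import gemmi

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*config.cell)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, feat in enumerate(config.features, start=1):
        res = gemmi.Residue()
        res.name = "SIT"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "X"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*feat.position_a)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# pinhole scan


@dataclass(frozen=True)
class ScanSimConfig:
    beam_width_um: float = 200.0
    beam_height_um: float = 100.0
    edge_sd_um: float = 5.0
    extent_x_um: float = 300.0
    extent_y_um: float = 200.0
    nx: int = 50
    ny: int = 50
    amplitude: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beam_width_um <= 0 or self.beam_height_um <= 0:
            raise ValueError("beam dimensions must be > 0")
        if self.edge_sd_um < 0 or self.noise_sd < 0:
            raise ValueError("edge_sd_um and noise_sd must be >= 0")


def _edge_profile(x: np.ndarray, half_width: float, sd: float) -> np.ndarray:
    if sd == 0:
        return (np.abs(x) <= half_width).astype(float)
    s = np.sqrt(2.0) * sd
    return 0.5 * (erf((x + half_width) / s) - erf((x - half_width) / s))


def simulate_pinhole_scan(config: ScanSimConfig) -> PinholeScan:
    """Raster scan of a soft-edged rectangular beam centred on the scan area."""
    rng = np.random.default_rng(config.seed)
    x = np.linspace(-config.extent_x_um / 2, config.extent_x_um / 2, config.nx)
    y = np.linspace(-config.extent_y_um / 2, config.extent_y_um / 2, config.ny)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    field = (
        config.amplitude
        * _edge_profile(xx, config.beam_width_um / 2, config.edge_sd_um)
        * _edge_profile(yy, config.beam_height_um / 2, config.edge_sd_um)
    )
    if config.noise_sd > 0:
        field = field + rng.normal(0.0, config.noise_sd, field.shape)
    return PinholeScan(xx.ravel(), yy.ravel(), field.ravel())


# ---------------------------------------------------------------------------
# dose schedules


def make_schedule(
    n_datasets: int | None = None,
    ader_kgy: float | Sequence[float] | None = None,
) -> DoseSchedule:
    """Uniform schedule from (n_datasets, ader_kgy) or explicit per-dataset list."""
    if isinstance(ader_kgy, (list, tuple, np.ndarray)):
        return DoseSchedule.from_aders([float(d) for d in ader_kgy])
    if n_datasets is None or ader_kgy is None:
        raise ValueError("need n_datasets and ader_kgy (or an explicit dose list)")
    return DoseSchedule.uniform(int(n_datasets), float(ader_kgy))


# ---------------------------------------------------------------------------
# presets
#
# Band positions and dose constants follow published haem (metMb) and T1Cu
# photoreduction series; amplitudes/widths are plausible placeholders (the
# experimental values are not printed anywhere) and are flagged as such.


def _metmb_ct(seed: int) -> SpectraSimConfig:
    return SpectraSimConfig(
        wavelengths_nm=np.arange(350.0, 800.0, 1.0),
        bands=(
            BandKineticsSpec(410.0, 10.0, 1.00, 1.00, 1.0),   # Soret, static here
            BandKineticsSpec(500.0, 20.0, 0.20, 0.05, 80.0),  # Q_v of metMb, decays
            BandKineticsSpec(568.0, 8.0, 0.02, 0.22, 30.0),   # ferrous Q_v, rises
            BandKineticsSpec(630.0, 25.0, 0.15, 0.02, 80.0),  # Q_0 of metMb, decays
        ),
        doses_kgy=np.arange(0.0, 500.1, 5.0),
        noise_sd_au=0.005,
        seed=seed,
        label="metMb_CT",
    )


def _metmb_rt(seed: int) -> SpectraSimConfig:
    return SpectraSimConfig(
        wavelengths_nm=np.arange(350.0, 800.0, 1.0),
        bands=(
            BandKineticsSpec(410.0, 10.0, 1.00, 1.00, 1.0),
            BandKineticsSpec(525.0, 18.0, 0.02, 0.20, 19.0),  # deoxy Q_v, rises
            BandKineticsSpec(580.0, 18.0, 0.02, 0.22, 19.0),  # deoxy Q_v, rises
            BandKineticsSpec(630.0, 25.0, 0.15, 0.02, 48.0),  # Q_0, decays
        ),
        doses_kgy=np.arange(0.0, 240.1, 2.5),
        noise_sd_au=0.005,
        seed=seed,
        label="metMb_RT",
    )


def _acnir_ct(seed: int) -> SpectraSimConfig:
    # amplitude ratio 454/566 = 0.32/0.25 = 1.28 at zero dose (green T1Cu)
    return SpectraSimConfig(
        wavelengths_nm=np.arange(330.0, 850.0, 1.0),
        bands=(
            BandKineticsSpec(385.0, 20.0, 0.30, 0.05, 280.0),  # S(Met)->Cu LMCT
            BandKineticsSpec(454.0, 20.0, 0.32, 0.02, 279.0),  # S(Cys)->Cu sigma
            BandKineticsSpec(566.0, 25.0, 0.25, 0.02, 271.0),  # S(Cys)->Cu pi
            BandKineticsSpec(700.0, 60.0, 0.08, 0.02, 280.0),  # d-d envelope
        ),
        doses_kgy=np.arange(0.0, 1460.1, 10.0),
        noise_sd_au=0.004,
        baseline_drift_au_per_kgy=2e-5,
        seed=seed,
        label="AcNiR_CT",
    )


def _acnir_rt(seed: int) -> SpectraSimConfig:
    # amplitude ratio 457/585 = 0.21/0.20 = 1.05 at zero dose (greenish-blue)
    return SpectraSimConfig(
        wavelengths_nm=np.arange(330.0, 850.0, 1.0),
        bands=(
            BandKineticsSpec(390.0, 20.0, 0.25, 0.05, 280.0),
            BandKineticsSpec(457.0, 20.0, 0.21, 0.02, 283.0),
            BandKineticsSpec(585.0, 25.0, 0.20, 0.02, 177.0),
        ),
        doses_kgy=np.arange(0.0, 1460.1, 10.0),
        noise_sd_au=0.004,
        baseline_drift_au_per_kgy=2e-5,
        seed=seed,
        label="AcNiR_RT",
    )


PRESETS = {
    "metMb_CT": _metmb_ct,
    "metMb_RT": _metmb_rt,
    "AcNiR_CT": _acnir_ct,
    "AcNiR_RT": _acnir_rt,
}


def get_preset(name: str, seed: int = 0) -> SpectraSimConfig:
    """Spectra-simulation config for a named preset (seeded)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory(seed)
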