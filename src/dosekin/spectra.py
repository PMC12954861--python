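"""In crystallo UV-Vis spectra: band traces and exponential dose kinetics.

A series of absorption spectra recorded on a still crystal during X-ray
exposure is tagged with absorbed dose. Characteristic bands (the haem Soret
and Q bands, the T1Cu charge-transfer bands, ...) rise or decay as metal
centres are photoreduced; each band's absorbance-versus-dose trace is fitted
with a single exponential

    A(D) = A_inf + (A_0 - A_inf) * exp(-D / tau)

whose *dose constant* tau is the dose at which a decay has fallen to 1/e of
its initial excess over the asymptote, and a rise has covered 1 - 1/e of its
total amplitude. The same three-parameter family covers both directions;
"rise" vs "decay" is just the sign of A_inf - A_0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.signal import find_peaks

__all__ = [
    "Spectrum",
    "SpectraSeries",
    "BandDefinition",
    "BandTrace",
    "KineticsFitResult",
    "load_spectra_series",
    "baseline_correct",
    "band_absorbance",
    "extract_trace",
    "fit_kinetics",
    "detect_peaks",
    "band_ratio",
]


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    dose_kgy: float = 0.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or ab.ndim != 1 or wl.size != ab.size:
            raise ValueError("wavelengths and absorbance must be 1-D of equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.dose_kgy < 0:
            raise ValueError("dose_kgy must be >= 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class SpectraSeries:
    """Dose-sorted spectra sharing one wavelength grid."""

    spectra: tuple[Spectrum, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sp = tuple(self.spectra)
        object.__setattr__(self, "spectra", sp)
        doses = [s.dose_kgy for s in sp]
        if any(b < a for a, b in zip(doses, doses[1:])):
            raise ValueError("spectra must be sorted by non-decreasing dose")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def doses(self) -> np.ndarray:
        return np.array([s.dose_kgy for s in self.spectra])

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide table: wavelength_nm column + one absorbance column per dose."""
        data = {"wavelength_nm": self.wavelengths}
        for s in self.spectra:
            data[f"{s.dose_kgy:g}"] = s.absorbance
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_wide_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class BandDefinition:
    """A band position with an averaging half-window (default +/- 2 nm)."""

    center_nm: float
    half_window_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.half_window_nm < 0:
            raise ValueError("half_window_nm must be >= 0")


@dataclass(frozen=True)
class BandTrace:
    """Absorbance of one band as a function of dose."""

    doses_kgy: np.ndarray
    absorbances_au: np.ndarray
    band: BandDefinition

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_kgy, dtype=float)
        a = np.asarray(self.absorbances_au, dtype=float)
        if d.shape != a.shape or d.ndim != 1:
            raise ValueError("doses and absorbances must be 1-D of equal length")
        if d.size >= 2 and np.any(np.diff(d) < 0):
            raise ValueError("doses must be non-decreasing")
        object.__setattr__(self, "doses_kgy", d)
        object.__setattr__(self, "absorbances_au", a)

    def __len__(self) -> int:
        return self.doses_kgy.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_kgy": self.doses_kgy, "absorbance_au": self.absorbances_au}
        )


@dataclass(frozen=True)
class KineticsFitResult:
    """Parameters of a single-exponential dose-kinetics fit."""

    direction: str  # "rise" | "decay"
    a0_au: float
    ainf_au: float
    tau_kgy: float
    tau_se_kgy: float
    rss: float
    converged: bool

    def model(self, dose):
        """Evaluate the fitted curve A(D)."""
        dose = np.asarray(dose, dtype=float)
        return _exp_model(dose, self.a0_au, self.ainf_au, self.tau_kgy)

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "a0_au": self.a0_au,
            "ainf_au": self.ainf_au,
            "tau_kgy": self.tau_kgy,
            "tau_se_kgy": self.tau_se_kgy,
            "rss": self.rss,
            "converged": self.converged,
        }


def _exp_model(dose, a0, ainf, tau):
    return ainf + (a0 - ainf) * np.exp(-dose / tau)


# ---------------------------------------------------------------------------
# loading


def load_spectra_series(
    source: str | Path | Sequence[str | Path],
    *,
    doses: Sequence[float] | None = None,
    dose_sidecar: str | Path | None = None,
    dose_pattern: str | None = None,
    metadata: dict | None = None,
) -> SpectraSeries:
    """Load a dose-tagged spectra series.

    ``source`` is either a single *wide* CSV (``wavelength_nm`` column plus one
    absorbance column per spectrum, headed by its dose in kGy) or a sequence of
    two-column files (``wavelength_nm,absorbance_au``). Dose tags for per-file
    input come from, in order of precedence: the ``doses`` sequence, a sidecar
    CSV with columns ``dose_kgy,file``, or a ``dose_pattern`` regex with one
    numeric group applied to each file name.

    All spectra are linearly resampled onto the first spectrum's grid;
    wavelength rows are sorted on load.
    """
    if isinstance(source, (str, Path)):
        spectra = _load_wide_csv(Path(source))
    else:
        paths = [Path(p) for p in source]
        if doses is not None:
            if len(doses) != len(paths):
                raise ValueError("doses must match the number of files")
            tags = [float(d) for d in doses]
        elif dose_sidecar is not None:
            side = pd.read_csv(dose_sidecar)
            if not {"dose_kgy", "file"}.issubset(side.columns):
                raise ValueError("sidecar CSV must have columns dose_kgy,file")
            lookup = {str(f): float(d) for f, d in zip(side["file"], side["dose_kgy"])}
            tags = [lookup[p.name] for p in paths]
        elif dose_pattern is not None:
            rx = re.compile(dose_pattern)
            tags = []
            for p in paths:
                m = rx.search(p.name)
                if m is None:
                    raise ValueError(f"dose_pattern does not match file name {p.name!r}")
                tags.append(float(m.group(1)))
        else:
            raise ValueError("per-file input needs doses, dose_sidecar or dose_pattern")
        spectra = [_load_two_column(p, d) for p, d in zip(paths, tags)]

    if len(spectra) < 2:
        raise ValueError("a spectra series needs at least 2 spectra")

    spectra.sort(key=lambda s: s.dose_kgy)
    grid = spectra[0].wavelengths
    resampled = [
        s
        if np.array_equal(s.wavelengths, grid)
        else Spectrum(grid, np.interp(grid, s.wavelengths, s.absorbance), s.dose_kgy)
        for s in spectra
    ]
    return SpectraSeries(tuple(resampled), metadata=dict(metadata or {}))


def _sorted_arrays(wl: np.ndarray, ab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(wl, kind="stable")
    wl, ab = wl[order], ab[order]
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid has duplicate values")
    return wl, ab


def _load_two_column(path: Path, dose: float) -> Spectrum:
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns wavelength_nm,absorbance_au")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    ab = df.iloc[:, 1].to_numpy(dtype=float)
    wl, ab = _sorted_arrays(wl, ab)
    return Spectrum(wl, ab, dose)


def _load_wide_csv(path: Path) -> list[Spectrum]:
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: a wide series CSV needs >= 2 absorbance columns")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    spectra = []
    for col in df.columns[1:]:
        try:
            dose = float(col)
        except ValueError as exc:
            raise ValueError(
                f"{path}: absorbance column header {col!r} is not a dose in kGy"
            ) from exc
        w, a = _sorted_arrays(wl.copy(), df[col].to_numpy(dtype=float))
        spectra.append(Spectrum(w, a, dose))
    return spectra


# ---------------------------------------------------------------------------
# band extraction


def baseline_correct(
    spectrum: Spectrum, quiet_window: tuple[float, float]
) -> Spectrum:
    """Subtract the mean absorbance over a feature-free wavelength window.

    A constant-offset correction: the corrected spectrum averages to zero over
    ``quiet_window``. The window must contain at least 3 grid points.
    """
    lo, hi = sorted(quiet_window)
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"quiet window ({lo}, {hi}) nm contains {int(mask.sum())} grid points; need >= 3"
        )
    offset = float(spectrum.absorbance[mask].mean())
    return Spectrum(spectrum.wavelengths, spectrum.absorbance - offset, spectrum.dose_kgy)


def band_absorbance(spectrum: Spectrum, band: BandDefinition) -> float:
    """Mean absorbance over [center - hw, center + hw] nm.

    With ``half_window_nm == 0`` the absorbance is linearly interpolated at the
    band centre instead.
    """
    wl = spectrum.wavelengths
    lo = band.center_nm - band.half_window_nm
    hi = band.center_nm + band.half_window_nm
    if hi < wl[0] or lo > wl[-1]:
        raise ValueError(
            f"band window ({lo}, {hi}) nm lies outside the grid "
            f"({wl[0]:g}, {wl[-1]:g}) nm"
        )
    if band.half_window_nm == 0:
        return float(np.interp(band.center_nm, wl, spectrum.absorbance))
    mask = (wl >= lo) & (wl <= hi)
    if not mask.any():
        # window overlaps the grid range but falls between grid points
        return float(np.interp(band.center_nm, wl, spectrum.absorbance))
    return float(spectrum.absorbance[mask].mean())


def extract_trace(
    series: SpectraSeries,
    band: BandDefinition,
    quiet_window: tuple[float, float] | None = None,
) -> BandTrace:
    """Band absorbance versus dose, optionally baseline-corrected per spectrum."""
    if len(series) == 0:
        raise ValueError("series is empty")
    doses, values = [], []
    for s in series.spectra:
        if quiet_window is not None:
            s = baseline_correct(s, quiet_window)
        doses.append(s.dose_kgy)
        values.append(band_absorbance(s, band))
    return BandTrace(np.array(doses), np.array(values), band)


def band_ratio(
    spectrum: Spectrum, band_a: BandDefinition, band_b: BandDefinition
) -> float:
    """Ratio of band absorbances A(band_a)/A(band_b)."""
    num = band_absorbance(spectrum, band_a)
    den = band_absorbance(spectrum, band_b)
    if abs(den) < 1e-12:
        raise ValueError("band_b absorbance is ~0; ratio undefined")
    return num / den


def detect_peaks(spectrum: Spectrum, min_prominence: float) -> list[float]:
    """Wavelengths of local maxima with prominence >= ``min_prominence`` AU."""
    if spectrum.wavelengths.size < 5:
        raise ValueError("need at least 5 grid points for peak detection")
    idx, _ = find_peaks(spectrum.absorbance, prominence=min_prominence)
    return [float(w) for w in spectrum.wavelengths[idx]]


# ---------------------------------------------------------------------------
# kinetics fitting


def fit_kinetics(trace: BandTrace, direction: str = "auto") -> KineticsFitResult:
    """Fit A(D) = A_inf + (A_0 - A_inf) exp(-D/tau) to a band trace.

    ``direction`` may be ``"rise"``, ``"decay"`` or ``"auto"``; the model
    family is identical in all cases and the reported direction comes from the
    sign of the fitted net change. Initialisation: A_0 from the first point,
    A_inf from the last, tau = dose range / 3. Standard errors come from the
    fit covariance. A trace with no amplitude change, or a fit that fails to
    converge, is returned with ``converged=False`` — never a silent fallback.
    """
    if direction not in ("rise", "decay", "auto"):
        raise ValueError(f"direction must be rise|decay|auto, got {direction!r}")
    d = trace.doses_kgy
    y = trace.absorbances_au
    if d.size < 5:
        raise ValueError(f"kinetics fit needs >= 5 points, got {d.size}")
    span = float(d.max() - d.min())
    if span <= 0:
        raise ValueError("kinetics fit needs a positive dose range")

    if np.ptp(y) == 0:
        return KineticsFitResult(
            direction="rise" if direction == "auto" else direction,
            a0_au=float(y[0]), ainf_au=float(y[0]),
            tau_kgy=float("nan"), tau_se_kgy=float("nan"),
            rss=0.0, converged=False,
        )

    # primary start: A0 = first point, A_inf = last, tau = span/3; the extra
    # tau starts guard against the degenerate local minimum at tau -> 0 (the
    # curve collapsing onto the first point) on long, noisy traces
    model = Model(_exp_model)
    result = None
    for tau0 in (span / 3.0, span / 10.0, span):
        params = model.make_params(a0=float(y[0]), ainf=float(y[-1]), tau=tau0)
        params["tau"].set(min=1e-12)
        try:
            candidate = model.fit(y, params, dose=d)
        except Exception:
            continue
        if result is None or candidate.chisqr < result.chisqr:
            result = candidate
    if result is None:
        return _failed_fit(direction, y)

    tau = float(result.params["tau"].value)
    a0 = float(result.params["a0"].value)
    ainf = float(result.params["ainf"].value)
    stderr = result.params["tau"].stderr
    tau_se = float(stderr) if stderr is not None else float("nan")
    converged = bool(result.success) and np.isfinite(tau) and tau > 0
    if ainf == a0:
        converged = False
    fitted_direction = "rise" if ainf > a0 else "decay"
    if direction == "auto":
        direction_out = fitted_direction
    else:
        direction_out = direction
        if direction != fitted_direction:
            converged = False
    return KineticsFitResult(
        direction=direction_out,
        a0_au=a0,
        ainf_au=ainf,
        tau_kgy=tau,
        tau_se_kgy=tau_se,
        rss=float(np.sum(result.residual**2)),
        converged=converged,
    )


def _failed_fit(direction: str, y: np.ndarray) -> KineticsFitResult:
    return KineticsFitResult(
        direction="rise" if direction == "auto" else direction,
        a0_au=float(y[0]),
        ainf_au=float(y[-1]),
        tau_kgy=float("nan"),
        tau_se_kgy=float("nan"),
        rss=float("nan"),
        converged=False,
    )
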