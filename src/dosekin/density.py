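"""Difference electron-density maps: synthesis, sigma thresholds, integration.

The quantitative readout of specific radiation damage in a sequential dataset
series is the isomorphous difference map Fo(n) - Fo(1): amplitudes of dataset
``n`` are least-squares scaled to the reference set, differenced, combined
with reference phases and Fourier-synthesised. Around an atom of interest,
all density values beyond ``sigma_mult`` map standard deviations — positive
and negative separately — from voxels whose centres lie within ``radius_a``
angstroms of the atom are summed, giving a signed integrated-density trace
that can be fitted with the same exponential dose-kinetics model used for
spectroscopic band traces.

Maps are plain voxel grids with unit-cell metadata; grid point (0,0,0) sits
at fractional (0,0,0) and voxel (i,j,k) at fractional (i/nx, j/ny, k/nz).
Synthesis is limited to P1; externally produced CCP4/MRC maps are consumed
as-is (axis order normalised to X,Y,Z on load) without symmetry expansion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .spectra import BandTrace, BandDefinition, KineticsFitResult, fit_kinetics

__all__ = [
    "DensityMap",
    "AtomSite",
    "IntegrationSpec",
    "IntegrationResult",
    "StructureFactorSet",
    "map_sigma",
    "resample_to_grid",
    "integrate_site",
    "scale_amplitudes",
    "difference_map",
    "series_site_kinetics",
    "gaussian_structure_factors",
    "read_sites",
]

logger = logging.getLogger(__name__)


def _orth_matrix(cell: Sequence[float]) -> np.ndarray:
    """Orthogonalisation matrix M with cartesian = M @ fractional."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.radians([al, be, ga])
    ca, cb, cg, sg = np.cos(al), np.cos(be), np.cos(ga), np.sin(ga)
    v = np.sqrt(1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg)
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ]
    )


@dataclass(frozen=True)
class DensityMap:
    """A 3-D density grid (e-/A^3) over one unit cell.

    ``values[i, j, k]`` is the density at fractional (i/nx, j/ny, k/nz).
    """

    values: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    spacegroup: str = "P1"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or min(v.shape) < 2:
            raise ValueError("map grid must be 3-D with >= 2 points per axis")
        cell = tuple(float(x) for x in self.cell)
        if len(cell) != 6 or any(x <= 0 for x in cell[:3]):
            raise ValueError("cell must be (a, b, c, alpha, beta, gamma) with positive lengths")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "cell", cell)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def cell_volume(self) -> float:
        return float(np.linalg.det(_orth_matrix(self.cell)))

    @property
    def voxel_volume(self) -> float:
        return self.cell_volume / self.values.size

    @property
    def orth(self) -> np.ndarray:
        return _orth_matrix(self.cell)

    # -- CCP4/MRC I/O ------------------------------------------------------
    @classmethod
    def from_ccp4(cls, path: str | Path) -> "DensityMap":
        """Read a CCP4/MRC map; axis order is normalised to X,Y,Z."""
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
        grid = m.grid
        values = np.array(grid, copy=True, dtype=np.float64)
        cell = grid.unit_cell
        sg = grid.spacegroup.hm if grid.spacegroup else "P1"
        return cls(
            values,
            (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
            spacegroup=sg,
        )

    def to_ccp4(self, path: str | Path) -> None:
        grid = gemmi.FloatGrid(*self.shape)
        grid.set_unit_cell(gemmi.UnitCell(*self.cell))
        grid.spacegroup = gemmi.find_spacegroup_by_name(self.spacegroup)
        np.array(grid, copy=False)[...] = self.values.astype(np.float32)
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header(2, True)  # mode 2: 4-byte reals
        ccp4.write_ccp4_map(str(path))


@dataclass(frozen=True)
class AtomSite:
    """A named atom position in orthogonal angstrom coordinates."""

    label: str
    position: np.ndarray
    element: str = "X"

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,):
            raise ValueError("position must be a 3-vector (orthogonal A)")
        object.__setattr__(self, "position", p)


@dataclass(frozen=True)
class IntegrationSpec:
    """Sphere radius and sigma threshold for site integration."""

    radius_a: float = 1.0
    sigma_mult: float = 3.0

    def __post_init__(self) -> None:
        if not self.radius_a > 0:
            raise ValueError("radius_a must be > 0")
        if self.sigma_mult < 0:
            raise ValueError("sigma_mult must be >= 0")


@dataclass(frozen=True)
class IntegrationResult:
    """Signed above-threshold density sums around one site.

    ``positive_sum``/``negative_sum`` are raw voxel-value sums (e-/A^3 summed
    over voxels); ``positive_e``/``negative_e`` are the volume-weighted
    variants (multiplied by the voxel volume, in electrons).
    """

    positive_sum: float
    negative_sum: float
    n_pos: int
    n_neg: int
    map_sigma: float
    voxel_volume: float

    @property
    def positive_e(self) -> float:
        return self.positive_sum * self.voxel_volume

    @property
    def negative_e(self) -> float:
        return self.negative_sum * self.voxel_volume


def map_sigma(density: DensityMap) -> float:
    """Population standard deviation over all grid voxels."""
    return float(np.std(density.values))


def resample_to_grid(density: DensityMap, reference: DensityMap) -> DensityMap:
    """Trilinear, periodic resampling onto the reference map's grid.

    Cells must agree to 1 part in 1e6; the output inherits the reference
    grid dimensions and the input's cell.
    """
    if not np.allclose(density.cell, reference.cell, rtol=1e-6, atol=1e-6):
        raise ValueError(
            f"incompatible cells: {density.cell} vs {reference.cell}"
        )
    if density.shape == reference.shape:
        return DensityMap(density.values.copy(), density.cell, density.spacegroup)
    src_shape = np.array(density.shape, dtype=float)
    coords = [
        idx * (src_shape[ax] / reference.shape[ax])
        for ax, idx in enumerate(
            np.indices(reference.shape, dtype=float)
        )
    ]
    values = map_coordinates(
        density.values, np.stack(coords), order=1, mode="grid-wrap"
    )
    return DensityMap(values, density.cell, density.spacegroup)


def sphere_mask(
    shape: tuple[int, int, int],
    cell: Sequence[float],
    site: AtomSite,
    radius_a: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within ``radius_a`` of the site.

    Distances use the minimum-image convention, so sites near cell edges (or
    outside the cell — they are wrapped in) integrate over the full sphere.
    """
    orth = _orth_matrix(cell)
    frac_site = np.linalg.solve(orth, site.position)
    nx, ny, nz = shape
    fi = np.arange(nx) / nx
    fj = np.arange(ny) / ny
    fk = np.arange(nz) / nz
    di = (fi - frac_site[0] + 0.5) % 1.0 - 0.5
    dj = (fj - frac_site[1] + 0.5) % 1.0 - 0.5
    dk = (fk - frac_site[2] + 0.5) % 1.0 - 0.5
    dfrac = np.stack(np.meshgrid(di, dj, dk, indexing="ij"), axis=-1)
    dcart = dfrac @ orth.T
    dist2 = np.sum(dcart**2, axis=-1)
    return dist2 <= radius_a**2


def integrate_site(
    density: DensityMap,
    site: AtomSite,
    spec: IntegrationSpec = IntegrationSpec(),
    *,
    sigma: float | None = None,
    mask: np.ndarray | None = None,
) -> IntegrationResult:
    """Sum density beyond +/- sigma_mult*sigma within a sphere around the site.

    ``sigma`` defaults to the standard deviation of the full input map (the
    conventional choice for difference maps); pass a pre-resampling sigma
    explicitly if preferred. ``mask`` lets callers reuse a precomputed sphere
    mask across a map series on a shared grid.
    """
    if sigma is None:
        sigma = map_sigma(density)
    if mask is None:
        mask = sphere_mask(density.shape, density.cell, site, spec.radius_a)
    vals = density.values[mask]
    if vals.size == 0:
        warnings.warn(
            f"no voxel centres within {spec.radius_a} A of site {site.label!r}; "
            "returning zero sums",
            stacklevel=2,
        )
    threshold = spec.sigma_mult * sigma
    pos = vals[vals > threshold]
    neg = vals[vals < -threshold]
    return IntegrationResult(
        positive_sum=float(pos.sum()),
        negative_sum=float(neg.sum()),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        map_sigma=float(sigma),
        voxel_volume=density.voxel_volume,
    )


# ---------------------------------------------------------------------------
# structure factors and Fo-Fo synthesis


@dataclass(frozen=True)
class StructureFactorSet:
    """Unique Miller indices with amplitudes (e-) and optional phases (deg)."""

    hkl: np.ndarray
    amplitude: np.ndarray
    phase_deg: np.ndarray | None
    cell: tuple[float, float, float, float, float, float]
    spacegroup: str = "P1"

    def __post_init__(self) -> None:
        hkl = np.asarray(self.hkl, dtype=int)
        amp = np.asarray(self.amplitude, dtype=float)
        if hkl.ndim != 2 or hkl.shape[1] != 3 or amp.shape != (hkl.shape[0],):
            raise ValueError("hkl must be (N, 3) and amplitude (N,)")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be >= 0")
        if len({tuple(h) for h in hkl}) != hkl.shape[0]:
            raise ValueError("Miller indices must be unique")
        ph = self.phase_deg
        if ph is not None:
            ph = np.asarray(ph, dtype=float)
            if ph.shape != amp.shape:
                raise ValueError("phase_deg must match amplitude length")
        object.__setattr__(self, "hkl", hkl)
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "phase_deg", ph)
        object.__setattr__(self, "cell", tuple(float(x) for x in self.cell))

    def __len__(self) -> int:
        return self.hkl.shape[0]

    @property
    def d_min(self) -> float:
        """Highest resolution (smallest d-spacing) in the set, in angstroms."""
        s2 = self._s2()
        s2 = s2[s2 > 0]
        if s2.size == 0:
            raise ValueError("d_min undefined: only the (000) reflection present")
        return float(1.0 / np.sqrt(s2.max()))

    def _s2(self) -> np.ndarray:
        orth = _orth_matrix(self.cell)
        recip = np.linalg.inv(orth)  # rows are reciprocal basis vectors
        svec = self.hkl @ recip
        return np.sum(svec**2, axis=1)

    @classmethod
    def from_csv(
        cls, path: str | Path, cell: Sequence[float], spacegroup: str = "P1"
    ) -> "StructureFactorSet":
        """Read the documented CSV dialect ``h,k,l,F,phi`` (phi optional)."""
        df = pd.read_csv(path)
        if not {"h", "k", "l", "F"}.issubset(df.columns):
            raise ValueError("structure-factor CSV must have columns h,k,l,F[,phi]")
        phases = df["phi"].to_numpy(dtype=float) if "phi" in df.columns else None
        return cls(
            df[["h", "k", "l"]].to_numpy(dtype=int),
            df["F"].to_numpy(dtype=float),
            phases,
            tuple(cell),
            spacegroup,
        )

    def to_csv(self, path: str | Path) -> None:
        data = {
            "h": self.hkl[:, 0],
            "k": self.hkl[:, 1],
            "l": self.hkl[:, 2],
            "F": self.amplitude,
        }
        if self.phase_deg is not None:
            data["phi"] = self.phase_deg
        pd.DataFrame(data).to_csv(path, index=False)


def _common_indices(
    a: StructureFactorSet, b: StructureFactorSet
) -> tuple[np.ndarray, np.ndarray]:
    pos_b = {tuple(h): i for i, h in enumerate(b.hkl)}
    ia, ib = [], []
    for i, h in enumerate(a.hkl):
        j = pos_b.get(tuple(h))
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def scale_amplitudes(f_n: StructureFactorSet, f_ref: StructureFactorSet) -> float:
    """Least-squares scale k minimising sum (F_ref - k*F_n)^2 over common hkl."""
    ia, ib = _common_indices(f_n, f_ref)
    if ia.size < 10:
        raise ValueError(
            f"need >= 10 common reflections for scaling, found {ia.size}"
        )
    fn = f_n.amplitude[ia]
    fr = f_ref.amplitude[ib]
    denom = float(np.sum(fn**2))
    if denom == 0:
        raise ValueError("cannot scale: all common F_n amplitudes are zero")
    return float(np.sum(fr * fn) / denom)


def synthesize_map(
    hkl: np.ndarray,
    coefficients: np.ndarray,
    cell: Sequence[float],
    shape: tuple[int, int, int],
    spacegroup: str = "P1",
) -> DensityMap:
    """P1 Fourier synthesis rho(x) = (1/V) sum_h F_h exp(-2 pi i h.x).

    ``hkl`` should contain one hemisphere (Friedel mates are generated by
    Hermitian symmetry); a supplied (000) term contributes its real part once.
    """
    hkl = np.asarray(hkl, dtype=int)
    shape = tuple(int(n) for n in shape)
    for ax in range(3):
        if shape[ax] < 2 * int(np.abs(hkl[:, ax]).max()) + 1:
            raise ValueError(
                f"grid dim {shape[ax]} on axis {ax} cannot represent "
                f"|index| up to {int(np.abs(hkl[:, ax]).max())}"
            )
    grid = np.zeros(shape, dtype=np.complex128)
    for h, f in zip(hkl, coefficients):
        idx = tuple(h % np.array(shape))
        if np.all(h == 0):
            grid[idx] += f.real
            continue
        grid[idx] += f
        grid[tuple((-h) % np.array(shape))] += np.conj(f)
    volume = float(np.linalg.det(_orth_matrix(cell)))
    # fftn carries the e^{-2 pi i h.x} kernel of the crystallographic convention
    rho = np.fft.fftn(grid).real / volume
    return DensityMap(rho, tuple(cell), spacegroup)


def default_synthesis_shape(
    sf: StructureFactorSet, spacing_fraction: float = 3.0
) -> tuple[int, int, int]:
    """Grid dims giving a spacing of d_min / ``spacing_fraction`` per axis."""
    spacing = sf.d_min / spacing_fraction
    dims = []
    for ax in range(3):
        n = int(np.ceil(sf.cell[ax] / spacing))
        n = max(n, 2 * int(np.abs(sf.hkl[:, ax]).max()) + 1, 2)
        dims.append(n)
    return tuple(dims)


def difference_map(
    f_n: StructureFactorSet,
    f_1: StructureFactorSet,
    phases_from: StructureFactorSet | None = None,
    *,
    shape: tuple[int, int, int] | None = None,
    scale: float | None = None,
) -> DensityMap:
    """Isomorphous Fo(n) - Fo(1) difference map with reference phases.

    Coefficients (k*F_n - F_1) exp(i phi_ref) on the common reflection set,
    where k is the least-squares scale of F_n onto F_1 (or ``scale`` if
    given). ``phases_from`` defaults to ``f_1``; every common reflection must
    carry a phase. The grid defaults to a spacing of d_min/3.
    """
    if phases_from is None:
        phases_from = f_1
    if phases_from.phase_deg is None:
        raise ValueError("phases_from carries no phases")
    i_n, i_1 = _common_indices(f_n, f_1)
    if i_n.size == 0:
        raise ValueError("no common reflections between f_n and f_1")
    phase_of = {tuple(h): p for h, p in zip(phases_from.hkl, phases_from.phase_deg)}
    hkl = f_n.hkl[i_n]
    missing = [tuple(h) for h in hkl if tuple(h) not in phase_of]
    if missing:
        raise ValueError(f"missing phases for {len(missing)} common reflections")
    if scale is None:
        scale = scale_amplitudes(f_n, f_1)
    dF = scale * f_n.amplitude[i_n] - f_1.amplitude[i_1]
    phi = np.radians([phase_of[tuple(h)] for h in hkl])
    coeffs = dF * np.exp(1j * phi)
    if shape is None:
        shape = default_synthesis_shape(f_1)
    return DensityMap(
        synthesize_map(hkl, coeffs, f_1.cell, shape).values, f_1.cell, "P1"
    )


def gaussian_structure_factors(
    hkl: np.ndarray,
    cell: Sequence[float],
    center: Sequence[float],
    amplitude: float,
    width_a: float,
    spacegroup: str = "P1",
) -> StructureFactorSet:
    """Analytic structure factors of an isotropic Gaussian density blob.

    For rho(r) = amplitude * exp(-|r - r0|^2 / (2 w^2)) in a P1 cell,
    F(h) = amplitude (2 pi)^(3/2) w^3 exp(-2 pi^2 w^2 |s|^2) exp(2 pi i h.x0)
    with s the reciprocal-lattice vector of h. Used to build toy models whose
    maps have a known closed form.
    """
    hkl = np.asarray(hkl, dtype=int)
    orth = _orth_matrix(cell)
    recip = np.linalg.inv(orth)
    s2 = np.sum((hkl @ recip) ** 2, axis=1)
    frac0 = np.linalg.solve(orth, np.asarray(center, dtype=float))
    f = (
        amplitude
        * (2.0 * np.pi) ** 1.5
        * width_a**3
        * np.exp(-2.0 * np.pi**2 * width_a**2 * s2)
        * np.exp(2j * np.pi * (hkl @ frac0))
    )
    return StructureFactorSet(
        hkl, np.abs(f), np.degrees(np.angle(f)), tuple(cell), spacegroup
    )


def gaussian_model_structure_factors(
    hkl: np.ndarray,
    cell: Sequence[float],
    atoms: Sequence[tuple[Sequence[float], float, float]],
    spacegroup: str = "P1",
) -> StructureFactorSet:
    """Structure factors of a model of several Gaussian blobs.

    ``atoms`` is a sequence of ``(center_cart, amplitude, width_a)``; the
    complex structure factors of the blobs are summed before conversion to
    amplitude/phase. Note that a *single* translated blob changes only the
    phases, never the amplitudes — an observable Fo-Fo amplitude difference
    needs at least one stationary reference atom alongside the moving one.
    """
    hkl = np.asarray(hkl, dtype=int)
    total = np.zeros(hkl.shape[0], dtype=complex)
    for center, amplitude, width in atoms:
        sf = gaussian_structure_factors(hkl, cell, center, amplitude, width)
        total += sf.amplitude * np.exp(1j * np.radians(sf.phase_deg))
    return StructureFactorSet(
        hkl, np.abs(total), np.degrees(np.angle(total)), tuple(cell), spacegroup
    )


# ---------------------------------------------------------------------------
# dose-kinetics of integrated density


def series_site_kinetics(
    maps: Sequence[DensityMap],
    doses_kgy: Sequence[float],
    site: AtomSite,
    spec: IntegrationSpec = IntegrationSpec(),
    *,
    use: str = "negative",
) -> tuple[pd.DataFrame, KineticsFitResult | None]:
    """Integrate a map series at one site and fit the dose kinetics.

    Maps are resampled onto the first map's grid if needed; the integration
    sphere mask is computed once on that grid. The fitted quantity is
    ``|negative_sum|`` (``use="negative"``, mirroring a growing negative
    difference-density feature) or ``positive_sum``. Returns the per-dose
    table (``dose_kgy, positive_sum, negative_sum, n_pos, n_neg, map_sigma``)
    and the fit result (``None`` with a warning if fewer than 5 dose points).
    """
    if use not in ("negative", "positive"):
        raise ValueError("use must be 'negative' or 'positive'")
    maps = list(maps)
    doses = [float(d) for d in doses_kgy]
    if len(maps) != len(doses):
        raise ValueError(f"{len(maps)} maps but {len(doses)} doses")
    if not maps:
        raise ValueError("empty map series")
    ref = maps[0]
    mask = sphere_mask(ref.shape, ref.cell, site, spec.radius_a)
    rows = []
    for m, d in sorted(zip(maps, doses), key=lambda t: t[1]):
        if m.shape != ref.shape:
            m = resample_to_grid(m, ref)
        res = integrate_site(m, site, spec, mask=mask)
        rows.append(
            {
                "dose_kgy": d,
                "positive_sum": res.positive_sum,
                "negative_sum": res.negative_sum,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
                "map_sigma": res.map_sigma,
            }
        )
    table = pd.DataFrame(rows)
    signal = (
        table["negative_sum"].abs() if use == "negative" else table["positive_sum"]
    )
    if len(table) < 5:
        warnings.warn(
            f"only {len(table)} dose points; skipping kinetics fit", stacklevel=2
        )
        return table, None
    trace = BandTrace(
        table["dose_kgy"].to_numpy(),
        signal.to_numpy(),
        BandDefinition(center_nm=0.0, half_window_nm=0.0),
    )
    fit = fit_kinetics(trace, direction="auto")
    if not fit.converged:
        logger.warning("site %r kinetics fit did not converge", site.label)
    return table, fit


def read_sites(
    path: str | Path, labels: Sequence[str] | None = None
) -> list[AtomSite]:
    """Read atom sites from a PDB or mmCIF file.

    ``labels`` selects atoms as ``"chain/resnum/atomname"`` (e.g. ``"A/154/FE"``)
    or plain atom names; omitted, every atom is returned.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    wanted = set(labels) if labels is not None else None
    sites = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    full = f"{chain.name}/{res.seqid.num}/{atom.name}"
                    if wanted is not None and full not in wanted and atom.name not in wanted:
                        continue
                    sites.append(
                        AtomSite(
                            label=full,
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            element=atom.element.name,
                        )
                    )
        break  # first model only
    return sites
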