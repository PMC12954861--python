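"""Absorbed-dose bookkeeping for sequential (MSOX) dataset series.

Doses are expressed in kGy throughout. The per-dataset unit is the average
dose over the exposed region (ADER), computed externally by dose-simulation
software and supplied as input — this module only does the arithmetic on top
of it: cumulative dose along a series, the *effective absorbed dose* label for
a structure refined against dataset ``n`` (all prior doses plus half of
dataset ``n``'s own dose, since that dose accrues progressively during the
sweep), and a linear dose axis for continuously recorded spectra.

Rounding happens only at the reporting layer (one decimal for kGy, nearest
integer for percentages); all arithmetic is carried at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "DatasetDoseRecord",
    "DoseSchedule",
    "ExposureTimeline",
    "cumulative_dose",
    "effective_dose",
    "dose_fraction_of_constant",
    "dose_at_time",
    "report_kgy",
    "report_percent",
]


@dataclass(frozen=True)
class DatasetDoseRecord:
    """One dataset's dose record.

    Parameters
    ----------
    index
        1-based ordinal of the dataset within the series.
    ader_kgy
        Average dose over the exposed region for this dataset (kGy).
    n_images
        Number of images in the dataset.
    exposure_s
        Per-image exposure time (s), optional metadata.
    flux_ph_s
        Photon flux (photons/s), optional metadata.
    """

    index: int
    ader_kgy: float
    n_images: int = 1
    exposure_s: float | None = None
    flux_ph_s: float | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"dataset index must be >= 1, got {self.index}")
        if not self.ader_kgy > 0:
            raise ValueError(f"ader_kgy must be > 0, got {self.ader_kgy}")
        if self.n_images < 1:
            raise ValueError(f"n_images must be >= 1, got {self.n_images}")


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered per-dataset dose records with consecutive 1-based indices."""

    records: tuple[DatasetDoseRecord, ...]

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        for pos, rec in enumerate(recs, start=1):
            if rec.index != pos:
                raise ValueError(
                    f"record at position {pos} has index {rec.index}; "
                    "indices must be consecutive starting at 1"
                )

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def uniform(
        cls,
        n_datasets: int,
        ader_kgy: float,
        *,
        n_images: int = 1,
        exposure_s: float | None = None,
        flux_ph_s: float | None = None,
    ) -> "DoseSchedule":
        """Schedule of ``n_datasets`` datasets, each depositing ``ader_kgy``."""
        if n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        return cls(
            tuple(
                DatasetDoseRecord(i, ader_kgy, n_images, exposure_s, flux_ph_s)
                for i in range(1, n_datasets + 1)
            )
        )

    @classmethod
    def from_aders(cls, aders_kgy: Iterable[float]) -> "DoseSchedule":
        return cls(
            tuple(DatasetDoseRecord(i, d) for i, d in enumerate(aders_kgy, start=1))
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseSchedule":
        """Read a schedule from CSV (``index,ader_kgy,n_images,exposure_s,flux_ph_s``).

        Only ``index`` and ``ader_kgy`` are required columns.
        """
        df = pd.read_csv(path)
        required = {"index", "ader_kgy"}
        if not required.issubset(df.columns):
            raise ValueError(f"schedule CSV must have columns {sorted(required)}")
        df = df.sort_values("index")
        recs = []
        for row in df.to_dict("records"):
            n_images = row.get("n_images", 1)
            recs.append(
                DatasetDoseRecord(
                    index=int(row["index"]),
                    ader_kgy=float(row["ader_kgy"]),
                    n_images=1 if pd.isna(n_images) else int(n_images),
                    exposure_s=_opt_float(row.get("exposure_s")),
                    flux_ph_s=_opt_float(row.get("flux_ph_s")),
                )
            )
        return cls(tuple(recs))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [r.index for r in self.records],
                "ader_kgy": [r.ader_kgy for r in self.records],
                "n_images": [r.n_images for r in self.records],
                "exposure_s": [r.exposure_s for r in self.records],
                "flux_ph_s": [r.flux_ph_s for r in self.records],
            }
        )

    # convenience wrappers
    def cumulative(self, n: int) -> float:
        return cumulative_dose(self, n)

    def effective(self, n: int) -> float:
        return effective_dose(self, n)

    def dose_table(self) -> pd.DataFrame:
        """Per-dataset ADER, cumulative and effective dose (full precision)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "index": r.index,
                    "ader_kgy": r.ader_kgy,
                    "cumulative_kgy": cumulative_dose(self, r.index),
                    "effective_kgy": effective_dose(self, r.index),
                }
            )
        return pd.DataFrame(rows)


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return None
    return float(x)


@dataclass(frozen=True)
class ExposureTimeline:
    """Constant-rate dose accrual after shutter opening.

    Maps the wall-clock timestamps of continuously recorded spectra onto a
    dose axis: dose is zero before the shutter opens at ``t0_s`` and accrues
    at ``dose_rate_kgy_s`` afterwards.
    """

    dose_rate_kgy_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_rate_kgy_s < 0:
            raise ValueError("dose_rate_kgy_s must be >= 0")

    def dose_at(self, t_s: float) -> float:
        return dose_at_time(self, t_s)


def cumulative_dose(schedule: DoseSchedule, n: int) -> float:
    """Total dose absorbed through the end of dataset ``n`` (kGy).

    ``n = 0`` returns 0 (empty sum).
    """
    if not 0 <= n <= len(schedule):
        raise IndexError(f"n must be in [0, {len(schedule)}], got {n}")
    return float(sum(r.ader_kgy for r in schedule.records[:n]))


def effective_dose(schedule: DoseSchedule, n: int) -> float:
    """Effective absorbed dose for dataset ``n`` (kGy).

    The sum of the dose absorbed during all previous datasets plus half of
    dataset ``n``'s own dose — the dose label for a structure refined against
    dataset ``n``, accounting for the progressive accumulation of dose during
    the sweep itself.
    """
    if not 1 <= n <= len(schedule):
        raise IndexError(
            f"effective dose is per-dataset: n must be in [1, {len(schedule)}], got {n}"
        )
    return cumulative_dose(schedule, n - 1) + schedule.records[n - 1].ader_kgy / 2.0


def dose_fraction_of_constant(effective_kgy: float, tau_kgy: float) -> float:
    """Effective dose as a percentage of a dose constant (full precision).

    Round to the nearest integer for reporting.
    """
    if not tau_kgy > 0:
        raise ValueError(f"tau_kgy must be > 0, got {tau_kgy}")
    return 100.0 * effective_kgy / tau_kgy


def dose_at_time(timeline: ExposureTimeline, t_s: float) -> float:
    """Dose accrued by wall-clock time ``t_s`` (kGy); 0 before shutter opening."""
    return max(0.0, (t_s - timeline.t0_s) * timeline.dose_rate_kgy_s)


def report_kgy(x: float) -> float:
    """Reporting convention for doses: one decimal in kGy, ties rounded half-up."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def report_percent(x: float) -> int:
    """Reporting convention for dose-constant fractions: nearest integer percent."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
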