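"""Idealized 28-day reference cycle, noisy replicates, and CSV round-trip.

The reference series is surge-centered: day 0 carries the LH maximum, the
cycle runs from day -14 to day +13.  The three LH anchors (follicular
plateau 7.02, surge 41.19, post-surge 14.92 IU/L) are published medians;
every other magnitude is a smooth implementer-chosen value that realizes
only qualitative shape constraints (estradiol rise over days -6..-1,
progesterone peak at day +7, luteal LH minimum at day +11, FSH surge
smaller in fold-change than LH's) and must not be read as measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidConfigError, HormoneLookupError

__all__ = [
    "HORMONES",
    "CSV_COLUMNS",
    "HormoneSeries",
    "NoiseConfig",
    "generate_reference_cycle",
    "add_noise",
    "read_series",
    "write_series",
]

#: Canonical hormone field names, in CSV column order.
HORMONES = ("fsh", "lh", "estradiol", "progesterone")

#: Exact CSV header (units encoded in the column names).
CSV_COLUMNS = ("day", "fsh_iu_l", "lh_iu_l", "estradiol_pmol_l", "progesterone_nmol_l")

_FIELD_TO_COLUMN = dict(zip(HORMONES, CSV_COLUMNS[1:]))


@dataclass(frozen=True, eq=False)
class HormoneSeries:
    """Day-indexed concentrations of FSH, LH, estradiol and progesterone.

    Units: gonadotropins IU/L, estradiol pmol/L, progesterone nmol/L.
    Days are consecutive integers; the surge-centered convention labels
    one idealized cycle -14..+13.
    """

    days: np.ndarray
    fsh: np.ndarray
    lh: np.ndarray
    estradiol: np.ndarray
    progesterone: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        object.__setattr__(self, "days", days)
        if days.ndim != 1 or days.size == 0:
            raise FormatError("days must be a non-empty 1-D integer array")
        if days.size > 1 and not np.all(np.diff(days) == 1):
            raise FormatError("days must be strictly increasing consecutive integers")
        for name in HORMONES:
            values = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, values)
            if values.shape != days.shape:
                raise FormatError(f"{name} must have the same length as days")
            if not np.all(np.isfinite(values)):
                raise FormatError(f"{name} contains non-finite values")
            if np.any(values < 0):
                raise FormatError(f"{name} contains negative concentrations")

    def __len__(self) -> int:
        return int(self.days.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HormoneSeries):
            return NotImplemented
        return np.array_equal(self.days, other.days) and all(
            np.array_equal(getattr(self, h), getattr(other, h)) for h in HORMONES
        )

    def hormone(self, name: str) -> np.ndarray:
        """Return the concentration vector for a hormone by canonical name."""
        if name not in HORMONES:
            raise HormoneLookupError(name)
        return getattr(self, name)

    def value_at(self, name: str, day: int) -> float:
        """Concentration of ``name`` on day label ``day``."""
        idx = np.flatnonzero(self.days == day)
        if idx.size == 0:
            raise KeyError(f"day {day} not in series")
        return float(self.hormone(name)[idx[0]])

    def shifted(self, offset: int) -> "HormoneSeries":
        """Same concentrations with every day label translated by ``offset``."""
        return HormoneSeries(
            self.days + int(offset), self.fsh, self.lh, self.estradiol, self.progesterone
        )

    def window(self, first_day: int, last_day: int) -> "HormoneSeries":
        """Sub-series covering day labels ``first_day..last_day`` inclusive."""
        mask = (self.days >= first_day) & (self.days <= last_day)
        if mask.sum() != last_day - first_day + 1:
            raise KeyError(f"series does not cover days {first_day}..{last_day}")
        return HormoneSeries(
            self.days[mask],
            self.fsh[mask],
            self.lh[mask],
            self.estradiol[mask],
            self.progesterone[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        """Represent the series as a DataFrame in the package CSV dialect."""
        data = {"day": self.days}
        for name in HORMONES:
            data[_FIELD_TO_COLUMN[name]] = getattr(self, name)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class NoiseConfig:
    """Multiplicative lognormal noise settings for synthetic replicates."""

    cv: float
    seed: int
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.cv) or self.cv < 0:
            raise InvalidConfigError(f"cv must be >= 0, got {self.cv}")
        if self.n_replicates < 1:
            raise InvalidConfigError(f"n_replicates must be >= 1, got {self.n_replicates}")


# Versioned fixture table for the idealized cycle (v1).
# Columns: day, FSH IU/L, LH IU/L, estradiol pmol/L, progesterone nmol/L.
# LH values on days -14..-5, 0 and +1 are the published medians; everything
# else is a smooth synthetic profile satisfying the qualitative constraints.
_REFERENCE_TABLE = (
    (-14, 6.00, 7.02, 110.0, 0.52),
    (-13, 6.50, 7.02, 115.0, 0.54),
    (-12, 7.00, 7.02, 122.0, 0.56),
    (-11, 7.40, 7.02, 130.0, 0.58),
    (-10, 7.60, 7.02, 140.0, 0.60),
    (-9, 7.70, 7.02, 152.0, 0.62),
    (-8, 7.60, 7.02, 165.0, 0.64),
    (-7, 7.40, 7.02, 180.0, 0.66),
    (-6, 7.10, 7.02, 210.0, 0.68),
    (-5, 7.00, 7.02, 260.0, 0.70),
    (-4, 6.90, 7.30, 340.0, 0.72),
    (-3, 6.85, 7.80, 460.0, 0.74),
    (-2, 6.70, 9.10, 630.0, 0.77),
    (-1, 7.80, 16.50, 870.0, 0.80),
    (0, 15.80, 41.19, 780.0, 0.92),
    (1, 8.90, 14.92, 480.0, 2.80),
    (2, 5.30, 12.60, 380.0, 5.50),
    (3, 4.90, 11.20, 340.0, 9.50),
    (4, 4.70, 10.10, 380.0, 14.00),
    (5, 4.50, 9.20, 430.0, 18.00),
    (6, 4.40, 8.40, 510.0, 21.00),
    (7, 4.30, 7.60, 570.0, 23.10),
    (8, 4.20, 6.90, 600.0, 22.00),
    (9, 4.10, 6.20, 580.0, 19.00),
    (10, 4.00, 5.50, 520.0, 14.50),
    (11, 4.30, 4.70, 260.0, 8.00),
    (12, 5.00, 5.10, 150.0, 3.00),
    (13, 5.60, 5.80, 120.0, 0.90),
)


def generate_reference_cycle() -> HormoneSeries:
    """Return the packaged idealized 28-day cycle (days -14..+13).

    Deterministic: always the same series.  Anchors: LH plateau 7.02 on
    days -14..-5, LH maximum 41.19 at day 0, LH 14.92 at day +1,
    progesterone maximum at day +7, luteal LH minimum at day +11.
    """
    table = np.asarray(_REFERENCE_TABLE, dtype=float)
    return HormoneSeries(
        days=table[:, 0].astype(int),
        fsh=table[:, 1],
        lh=table[:, 2],
        estradiol=table[:, 3],
        progesterone=table[:, 4],
    )


def add_noise(series: HormoneSeries, config: NoiseConfig) -> list[HormoneSeries]:
    """Draw seeded lognormal replicates around ``series``.

    Each concentration is sampled from a lognormal whose *median* equals
    the reference value and whose coefficient of variation is ``config.cv``
    (hormone concentrations are positive and right-skewed, so the noise is
    multiplicative).  Zero reference values stay exactly zero.
    """
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.cv**2)))
    replicates = []
    for _ in range(config.n_replicates):
        fields = {}
        for name in HORMONES:
            ref = series.hormone(name)
            factors = rng.lognormal(mean=0.0, sigma=sigma, size=ref.size) if sigma > 0 else 1.0
            fields[name] = ref * factors
        replicates.append(HormoneSeries(days=series.days, **fields))
    return replicates


def write_series(series: HormoneSeries, path) -> None:
    """Write a series to CSV in the package dialect."""
    series.to_frame().to_csv(path, index=False)


def read_series(path) -> HormoneSeries:
    """Read a series from CSV, validating the dialect and all invariants."""
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise FormatError(f"cannot parse CSV at {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    for column in CSV_COLUMNS:
        numeric = pd.to_numeric(frame[column], errors="coerce")
        bad = frame.index[numeric.isna()]
        if len(bad) > 0:
            raise FormatError(
                f"non-numeric cell in column {column!r}, row {int(bad[0])} of {path}"
            )
        frame[column] = numeric
    days = frame["day"].to_numpy()
    if np.any(days != days.astype(int)):
        raise FormatError(f"column 'day' must hold integers in {path}")
    days = days.astype(int)
    if days.size > 1 and not np.all(np.diff(days) == 1):
        step = np.flatnonzero(np.diff(days) != 1)[0]
        raise FormatError(
            f"days must be consecutive integers; offending rows {step}..{step + 1} "
            f"(days {days[step]}, {days[step + 1]}) in {path}"
        )
    return HormoneSeries(
        days=days,
        fsh=frame["fsh_iu_l"].to_numpy(float),
        lh=frame["lh_iu_l"].to_numpy(float),
        estradiol=frame["estradiol_pmol_l"].to_numpy(float),
        progesterone=frame["progesterone_nmol_l"].to_numpy(float),
    )
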