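"""Nuclear-periphery zone assay.

A fluorescent locus is scored by its distance to the nuclear envelope,
normalized by the nuclear radius, into n concentric shells of equal
volume (default three).  Modeling the nucleus as a sphere of radius R,
the shell boundaries in normalized distance-to-periphery d = dist/R are
d_k = 1 - ((n-k)/n)^(1/3): each shell encloses 1/n of the sphere volume.
Zone 1 is the outermost (peripheral) shell; boundaries belong to the
more peripheral zone.  Strains are compared with a two-sided Pearson
chi-square test on the strain x zone contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class SpotMeasurement:
    """One scored nucleus: radius and spot-to-envelope distance in microns."""

    cell_id: str
    strain: str
    radius_um: float
    distance_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValidationError(f"cell {self.cell_id!r}: radius must be positive")
        if not (0 <= self.distance_um <= self.radius_um):
            raise ValidationError(
                f"cell {self.cell_id!r}: distance {self.distance_um} outside "
                f"[0, radius={self.radius_um}]"
            )

    @property
    def normalized_distance(self) -> float:
        return self.distance_um / self.radius_um


def zone_boundaries(n_zones: int) -> np.ndarray:
    """Normalized-distance cutoffs for n equal-volume concentric zones.

    d_k = 1 - ((n-k)/n)^(1/3) for k = 1..n-1.  For n=3 the cutoffs are
    1-(2/3)^(1/3) and 1-(1/3)^(1/3).
    """
    if n_zones < 1:
        raise ValidationError(f"n_zones must be >= 1, got {n_zones}")
    k = np.arange(1, n_zones)
    return 1.0 - ((n_zones - k) / n_zones) ** (1.0 / 3.0)


def assign_zone(measurement: SpotMeasurement | float, n_zones: int = 3) -> int:
    """Zone index (1 = peripheral ... n = central) for a measurement or a
    normalized distance.  A spot exactly on a boundary goes to the outer
    (lower-index) zone."""
    if isinstance(measurement, SpotMeasurement):
        d = measurement.normalized_distance
    else:
        d = float(measurement)
    if not (0 <= d <= 1):
        raise ValidationError(f"normalized distance {d} outside [0, 1]")
    cutoffs = zone_boundaries(n_zones)
    for k, cut in enumerate(cutoffs, start=1):
        if d <= cut:
            return k
    return n_zones


@dataclass
class ZoneTable:
    """Spot counts per strain per zone (zone 1 = peripheral)."""

    strains: list[str]
    counts: np.ndarray  # shape (n_strains, n_zones), non-negative ints
    n_zones: int = 3

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.strains), self.n_zones):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.strains)}, {self.n_zones})"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative zone counts")

    def row(self, strain: str) -> np.ndarray:
        try:
            return self.counts[self.strains.index(strain)]
        except ValueError:
            raise ValidationError(
                f"strain {strain!r} not in table (have {self.strains})"
            ) from None

    def percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1, keepdims=True)
        pct = 100.0 * self.counts / np.where(totals == 0, 1, totals)
        df = pd.DataFrame(pct, index=self.strains,
                          columns=[f"zone{k}" for k in range(1, self.n_zones + 1)])
        df.insert(0, "n_cells", self.counts.sum(axis=1))
        return df.rename_axis("strain").reset_index()


def zone_table(measurements: list[SpotMeasurement], n_zones: int = 3) -> ZoneTable:
    """Count spots per strain per zone; invariant to measurement order."""
    strains = sorted({m.strain for m in measurements})
    if not strains:
        raise ValidationError("no measurements")
    counts = np.zeros((len(strains), n_zones), dtype=np.int64)
    index = {s: i for i, s in enumerate(strains)}
    for m in measurements:
        counts[index[m.strain], assign_zone(m, n_zones) - 1] += 1
    return ZoneTable(strains, counts, n_zones)


def chi_square_test(table: ZoneTable, strain_a: str,
                    strain_b: str) -> tuple[float, int, float]:
    """Two-sided Pearson chi-square comparing two strains' zone counts.

    2 x n_zones contingency table, df = n_zones - 1, no continuity
    correction; all expected counts must be positive.
    """
    obs = np.vstack([table.row(strain_a), table.row(strain_b)])
    row_tot = obs.sum(axis=1, keepdims=True)
    col_tot = obs.sum(axis=0, keepdims=True)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise ValidationError(
            "zero expected count in chi-square table; pool adjacent zones "
            "or collect more cells"
        )
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


# ---------------------------------------------------------------------------
# Spot table I/O

SPOT_COLUMNS = ("cell_id", "strain", "radius_um", "distance_um")


def read_spots(path: str | Path) -> list[SpotMeasurement]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"spot table missing columns {sorted(missing)}")
    return [
        SpotMeasurement(str(r.cell_id), str(r.strain), float(r.radius_um),
                        float(r.distance_um))
        for r in df.itertuples()
    ]


def write_spots(measurements: list[SpotMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in measurements],
            "strain": [m.strain for m in measurements],
            "radius_um": [m.radius_um for m in measurements],
            "distance_um": [m.distance_um for m in measurements],
        }
    ).to_csv(path, sep="\t", index=False)
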