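"""Per-feature nucleosome occupancy between two conditions.

Occupancy per feature is the mean per-base coverage over the feature
interval (length-normalized, so features of different sizes are
comparable); a raw read-count mode is available.  Genotype comparison uses
the Wilcoxon signed-rank test on per-feature paired differences — the
standard paired rank test — with an exact tie-aware null distribution for
small feature classes and a tie-corrected normal approximation otherwise.
An unpaired Mann-Whitney U alternative is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genome import FeatureSet
from .tracks import ProbeTrack

EXACT_THRESHOLD = 25  # pairs at or below this use the exact distribution


class OccupancyTable:
    """Paired per-feature mean occupancy for two conditions (A, B)."""

    COLUMNS = ("feature_id", "feature_class", "mean_a", "mean_b")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"occupancy table missing columns {sorted(missing)}")
        if df["feature_id"].duplicated().any():
            raise ValidationError("duplicate feature ids in occupancy table")
        if (df["mean_a"] < 0).any() or (df["mean_b"] < 0).any():
            raise ValidationError("negative occupancy values")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def by_class(self, class_label: str) -> "OccupancyTable":
        sub = self.df[self.df["feature_class"] == class_label]
        if sub.empty:
            avail = sorted(self.df["feature_class"].unique())
            raise ValidationError(
                f"no features of class {class_label!r}; available: {avail}"
            )
        return OccupancyTable(sub)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OccupancyTable":
        return cls(pd.read_csv(path, sep="\t"))


def mean_occupancy(coverage: ProbeTrack, fs: FeatureSet,
                   class_label: str | None = None,
                   mode: str = "per_base") -> pd.DataFrame:
    """Per-feature occupancy from a per-base coverage track.

    mode="per_base": mean per-base coverage over the feature (bases not
    covered by any track interval count as zero).
    mode="reads": the track intervals are read fragments; the value column
    is ignored and the count of overlapping fragments is reported.
    """
    if mode not in ("per_base", "reads"):
        raise ValidationError(f"unknown mode {mode!r}")
    if coverage.layout.names != fs.layout.names:
        raise ValidationError("coverage and feature set use different layouts")
    feats = fs.by_class(class_label).features if class_label else fs.features
    # sorted interval arrays per chromosome for binary-search overlap lookup
    per_chrom: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for ci, sl in coverage.chrom_slices():
        per_chrom[ci] = (coverage.start[sl], coverage.end[sl], coverage.value[sl])
    rows = []
    names = fs.layout.names
    for f in feats:
        iv = f.interval
        if len(iv) == 0:
            raise ValidationError(f"zero-length feature {f.id!r}")
        ci = names.index(iv.chrom)
        occ = 0.0
        if ci in per_chrom:
            starts, ends, vals = per_chrom[ci]
            lo = int(np.searchsorted(ends, iv.start, side="right"))
            hi = int(np.searchsorted(starts, iv.end, side="left"))
            s = starts[lo:hi]
            e = ends[lo:hi]
            overlap = np.minimum(e, iv.end) - np.maximum(s, iv.start)
            overlap = np.clip(overlap, 0, None)
            if mode == "per_base":
                occ = float((vals[lo:hi] * overlap).sum()) / len(iv)
            else:
                occ = float((overlap > 0).sum())
        rows.append({"feature_id": f.id, "feature_class": f.feature_class,
                     "occupancy": occ})
    return pd.DataFrame(rows)


def occupancy_table(coverage_a: ProbeTrack, coverage_b: ProbeTrack,
                    fs: FeatureSet, class_label: str | None = None,
                    mode: str = "per_base") -> OccupancyTable:
    """Build the paired A/B table from two coverage tracks."""
    a = mean_occupancy(coverage_a, fs, class_label, mode)
    b = mean_occupancy(coverage_b, fs, class_label, mode)
    df = a.rename(columns={"occupancy": "mean_a"})
    df["mean_b"] = b["occupancy"].to_numpy()
    return OccupancyTable(df)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # W+: rank sum of positive differences (B - A)
    n_pairs: int      # pairs remaining after dropping zero differences
    p_value: float
    method: str       # "exact" or "normal_approximation" (or "mannwhitney")

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ = sum of ranks with positive sign.

    Under the null every sign pattern is equally likely; the distribution is
    built by dynamic programming over the 2n-scaled ranks (midranks are
    half-integers at worst).  Returns (support of 2*W+, probabilities).
    """
    r2 = np.round(2 * np.asarray(ranks, dtype=float)).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    probs = counts / counts.sum()
    return np.arange(total + 1), probs


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    support2, probs = signed_rank_distribution(ranks)
    w2 = int(round(2 * w_plus))
    p_low = probs[support2 <= w2].sum()
    p_high = probs[support2 >= w2].sum()
    return float(min(1.0, 2 * min(p_low, p_high)))


def _approx_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    n = ranks.size
    mean = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts.astype(float) ** 3 - tie_counts).sum() / 48
    if var <= 0:
        raise ValidationError("zero variance in signed-rank approximation")
    # continuity correction: the support of W+ is a lattice of spacing >= 1/2
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2 * stats.norm.sf(max(z, 0.0))))


def paired_rank_test(table: OccupancyTable, method: str = "auto",
                     exact_threshold: int = EXACT_THRESHOLD) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on per-feature differences B - A.

    Zero differences are dropped; ties in |difference| are mid-ranked.
    method="auto" uses the exact distribution for n_pairs <= exact_threshold
    and the tie-corrected normal approximation above; "exact", "approx" and
    "mannwhitney" (unpaired two-sided Mann-Whitney U, for comparison) force
    a particular computation.
    """
    a = table.df["mean_a"].to_numpy(dtype=float)
    b = table.df["mean_b"].to_numpy(dtype=float)
    if method == "mannwhitney":
        u, p = stats.mannwhitneyu(b, a, alternative="two-sided")
        return PairedTestResult(float(u), len(a), float(p), "mannwhitney")
    d = b - a
    d = d[d != 0]
    if d.size < 2:
        raise ValidationError(
            "no paired signal: fewer than two non-zero paired differences"
        )
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if d.size <= exact_threshold else "approx"
    if method == "exact":
        p = _exact_two_sided_p(w_plus, ranks)
        return PairedTestResult(w_plus, int(d.size), p, "exact")
    if method == "approx":
        p = _approx_two_sided_p(w_plus, ranks)
        return PairedTestResult(w_plus, int(d.size), p, "normal_approximation")
    raise ValidationError(f"unknown method {method!r}")


def fold_change_summary(table: OccupancyTable,
                        pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-class median fold change B/A and fraction of features with B < A."""
    df = table.df
    a = df["mean_a"].to_numpy(dtype=float) + pseudocount
    b = df["mean_b"].to_numpy(dtype=float) + pseudocount
    if np.any(a <= 0):
        raise ValidationError(
            "zero occupancy in condition A; set a positive pseudocount"
        )
    work = pd.DataFrame({
        "feature_class": df["feature_class"],
        "fold": b / a,
        "decreased": df["mean_b"].to_numpy() < df["mean_a"].to_numpy(),
    })
    out = work.groupby("feature_class", sort=True).agg(
        n_features=("fold", "size"),
        median_fold=("fold", "median"),
        fraction_decreased=("decreased", "mean"),
    ).reset_index()
    return out
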