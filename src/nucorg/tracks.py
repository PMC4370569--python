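"""Probe-level signal tracks: bedGraph I/O, log2 ratios, uniqueness
filtering, fold-threshold target calls and per-class boxplot summaries.

A ProbeTrack stores the ordered tiling-array (or coverage) grid as numpy
arrays; `value` is either a raw signal or a log2 ratio depending on how the
track was produced.  Only probes with a unique genomic match enter
statistics; the full track is kept for visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .genome import GenomeLayout

logger = logging.getLogger(__name__)


@dataclass
class ProbeTrack:
    """Ordered per-probe signal values on a genome.

    chrom holds indices into layout.names; probes are sorted by
    (chromosome order, start).
    """

    layout: GenomeLayout
    chrom: np.ndarray  # int32 indices into layout.names
    start: np.ndarray  # int64, 0-based inclusive
    end: np.ndarray    # int64, exclusive
    value: np.ndarray  # float64
    unique: np.ndarray = field(default=None)  # bool; default all True

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=np.float64)
        if self.unique is None:
            self.unique = np.ones(len(self.start), dtype=bool)
        self.unique = np.asarray(self.unique, dtype=bool)
        n = len(self.start)
        for name, arr in (("chrom", self.chrom), ("end", self.end),
                          ("value", self.value), ("unique", self.unique)):
            if len(arr) != n:
                raise ValidationError(f"array {name} has length {len(arr)} != {n}")
        if np.any(self.end <= self.start):
            raise ValidationError("probe with non-positive width")
        if self.chrom.size and (self.chrom.min() < 0
                                or self.chrom.max() >= len(self.layout.names)):
            raise ValidationError("probe chromosome index outside layout")
        order = np.lexsort((self.start, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            logger.info("probe track not in genome order; sorting %d probes", n)
            for attr in ("chrom", "start", "end", "value", "unique"):
                setattr(self, attr, getattr(self, attr)[order])

    @property
    def n_probes(self) -> int:
        return len(self.start)

    def __len__(self) -> int:
        return self.n_probes

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """(chromosome index, contiguous slice) per chromosome with probes."""
        out = []
        if self.n_probes == 0:
            return out
        boundaries = np.flatnonzero(np.diff(self.chrom)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [self.n_probes]))
        for s, e in zip(starts, ends):
            out.append((int(self.chrom[s]), slice(int(s), int(e))))
        return out

    def same_grid(self, other: "ProbeTrack") -> bool:
        return (
            self.layout.names == other.layout.names
            and self.n_probes == other.n_probes
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        )

    def to_dataframe(self) -> pd.DataFrame:
        names = self.layout.names
        return pd.DataFrame(
            {
                "chrom": [names[c] for c in self.chrom],
                "start": self.start,
                "end": self.end,
                "value": self.value,
                "unique": self.unique,
            }
        )


def read_bedgraph(path: str | Path, layout: GenomeLayout) -> ProbeTrack:
    """Read a four-column bedGraph into a ProbeTrack (unique flag true).

    Unsorted input is sorted with a logged notice; probe overlap is allowed.
    """
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from None
            ci = layout.index(cols[0])
            if end > layout.chromosomes[ci][1]:
                raise ValidationError(
                    f"{path}:{lineno}: interval end {end} exceeds chromosome "
                    f"{cols[0]} length {layout.chromosomes[ci][1]}"
                )
            chroms.append(ci)
            starts.append(start)
            ends.append(end)
            values.append(value)
    return ProbeTrack(layout, np.array(chroms, dtype=np.int32),
                      np.array(starts), np.array(ends), np.array(values))


def write_bedgraph(track: ProbeTrack, path: str | Path) -> None:
    names = track.layout.names
    with open(path, "w") as fh:
        for i in range(track.n_probes):
            fh.write(
                f"{names[track.chrom[i]]}\t{track.start[i]}\t{track.end[i]}"
                f"\t{track.value[i]:.10g}\n"
            )


def log2_ratio(numerator: ProbeTrack, denominator: ProbeTrack,
               pseudocount: float = 0.0) -> ProbeTrack:
    """Per-probe log2((num + pc) / (den + pc)); requires identical grids.

    The unique flag of the ratio is the AND of the input flags.
    """
    if not numerator.same_grid(denominator):
        n = min(numerator.n_probes, denominator.n_probes)
        idx = None
        if numerator.n_probes == denominator.n_probes:
            diff = (
                (numerator.chrom != denominator.chrom)
                | (numerator.start != denominator.start)
                | (numerator.end != denominator.end)
            )
            where = np.flatnonzero(diff)
            idx = int(where[0]) if where.size else None
        detail = (f"; first discordant probe index {idx}" if idx is not None
                  else f"; probe counts {numerator.n_probes} vs {denominator.n_probes}")
        raise ValidationError("probe grids differ" + detail)
    num = numerator.value + pseudocount
    den = denominator.value + pseudocount
    if np.any(num <= 0) or np.any(den <= 0):
        raise ValidationError(
            "non-positive values after pseudocount; increase pseudocount"
        )
    return ProbeTrack(
        numerator.layout,
        numerator.chrom.copy(),
        numerator.start.copy(),
        numerator.end.copy(),
        np.log2(num / den),
        numerator.unique & denominator.unique,
    )


def filter_unique(track: ProbeTrack) -> ProbeTrack:
    """Keep only probes flagged as having a single genomic match."""
    keep = track.unique
    if not keep.any():
        raise ValidationError(
            "no probes left after uniqueness filtering; check the unique flags "
            "or load the track with all probes marked unique"
        )
    return ProbeTrack(track.layout, track.chrom[keep], track.start[keep],
                      track.end[keep], track.value[keep], track.unique[keep])


def threshold_targets(track: ProbeTrack, fold: float) -> np.ndarray:
    """Target mask: probes with more than `fold`-fold enrichment.

    Values are log2 ratios, so the cut is value > log2(fold), strictly.
    """
    if fold <= 0:
        raise ValidationError(f"fold threshold must be positive, got {fold}")
    return track.value > np.log2(fold)


@dataclass(frozen=True)
class ClassSummary:
    """Tukey boxplot statistics for one probe group."""

    class_label: str
    n_probes: int
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    mean: float

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValidationError("summary of an empty group")
        if not (self.q1 <= self.median <= self.q3):
            raise ValidationError("quartiles out of order")


def summarize_values(values: np.ndarray, class_label: str) -> ClassSummary:
    """Boxplot statistics: linearly interpolated quartiles, whiskers at the
    most extreme data point within 1.5 IQR of the box."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError(f"empty group for class {class_label!r}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return ClassSummary(class_label, int(values.size), float(q1), float(med),
                        float(q3), float(lo), float(hi), float(values.mean()))


def class_summary(track: ProbeTrack, mask: np.ndarray,
                  class_label: str = "members") -> tuple[ClassSummary, ClassSummary]:
    """Boxplot summaries for member probes and for the rest of the genome."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size != track.n_probes:
        raise ValidationError("mask length does not match probe count")
    if not mask.any() or mask.all():
        raise ValidationError("need at least one member and one non-member probe")
    return (
        summarize_values(track.value[mask], class_label),
        summarize_values(track.value[~mask], "rest"),
    )
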