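"""Genome coordinate space, annotation handling and interval queries.

Coordinates are 0-based half-open internally.  GFF3 input/output converts
at the boundary (GFF3 records are 1-based closed); BED is native.  The
module also carries the annotation post-processing used throughout the
analysis: reclassifying Pombase-style records into the working feature
classes (LTR, Tf2, replication origin, intron) and defining the four
S. pombe subtelomeric domains from their published chromosome coordinates.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ParseError, ValidationError

# S. pombe subtelomeric domains of chromosomes I and II, as 1-based closed
# intervals (chromosome, start, end).  These four regions delimit the
# low-expression chromatin domains adjacent to the telomeres.
SUBTELOMERE_REGIONS_1BASED: tuple[tuple[str, int, int], ...] = (
    ("I", 1, 98950),
    ("I", 5496300, 5579133),
    ("II", 1, 96400),
    ("II", 4437300, 4539804),
)

# Chromosome sizes of the S. pombe reference assembly (bp).
POMBE_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("I", 5579133),
    ("II", 4539804),
    ("III", 2452883),
)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate space."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate chromosome names in layout: {names}")
        for name, length in self.chromosomes:
            if int(length) < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")
        object.__setattr__(
            self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes)
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def index(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise ValidationError(
                f"chromosome {chrom!r} not in layout (have {list(self.names)})"
            ) from None

    def length(self, chrom: str) -> int:
        return self.lengths[self.names[self.index(chrom)]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{i}: expected 'name<TAB>length'")
                rows.append((parts[0], int(parts[1])))
        return cls(tuple(rows))


def pombe_layout() -> GenomeLayout:
    """The default S. pombe three-chromosome layout."""
    return GenomeLayout(POMBE_CHROMOSOMES)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval: start inclusive, end exclusive, 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def validate(self, layout: GenomeLayout) -> None:
        length = layout.length(self.chrom)
        if self.end > length:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {length}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Feature:
    """A classified genomic interval (tRNA, LTR, subtelomere, ...)."""

    interval: GenomicInterval
    feature_class: str
    id: str
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.feature_class:
            raise ValidationError(f"feature {self.id!r} has empty class")

    @property
    def attr(self) -> dict[str, str]:
        return dict(self.attributes)


class FeatureSet:
    """A collection of classified features validated against a genome layout."""

    def __init__(self, features: Sequence[Feature], layout: GenomeLayout):
        ids = [f.id for f in features]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate feature ids: {dup[:5]}")
        for f in features:
            f.interval.validate(layout)
        self.features: tuple[Feature, ...] = tuple(features)
        self.layout = layout

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def classes(self) -> set[str]:
        return {f.feature_class for f in self.features}

    def by_class(self, *class_labels: str) -> "FeatureSet":
        missing = set(class_labels) - self.classes
        if missing:
            raise ValidationError(
                f"unknown feature class(es) {sorted(missing)}; "
                f"available: {sorted(self.classes)}"
            )
        keep = [f for f in self.features if f.feature_class in class_labels]
        return FeatureSet(keep, self.layout)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [f.id for f in self.features],
                "feature_class": [f.feature_class for f in self.features],
                "chrom": [f.interval.chrom for f in self.features],
                "start": [f.interval.start for f in self.features],
                "end": [f.interval.end for f in self.features],
                "strand": [f.interval.strand for f in self.features],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, layout: GenomeLayout) -> "FeatureSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
        feats = [
            Feature(
                GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
                r.feature_class,
                r.id,
            )
            for r in df.itertuples()
        ]
        return cls(feats, layout)


# ---------------------------------------------------------------------------
# GFF3 I/O


def _parse_gff3_attributes(text: str) -> tuple[tuple[str, str], ...]:
    pairs = []
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
        else:
            k, v = chunk, ""
        pairs.append((k.strip(), v.strip()))
    return tuple(pairs)


def read_gff3(path: str | Path, layout: GenomeLayout) -> FeatureSet:
    """Read a GFF3 file into a FeatureSet.

    The GFF type column becomes the feature class; coordinates convert
    from 1-based closed to 0-based half-open.  Attributes are retained
    for later reclassification.  Records lacking an ID get a positional
    one so that ids stay unique.
    """
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            try:
                start = int(start1) - 1  # 1-based closed -> 0-based half-open
                end = int(end1)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {start1!r}/{end1!r}"
                ) from None
            attributes = _parse_gff3_attributes(attrs)
            fid = dict(attributes).get("ID", f"feature_{lineno}")
            strand = strand if strand in ("+", "-") else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
                iv.validate(layout)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: record {fid!r}: {exc}") from None
            features.append(Feature(iv, ftype, fid, attributes))
    return FeatureSet(features, layout)


def write_gff3(fs: FeatureSet, path: str | Path, source: str = "nucorg") -> None:
    """Write a FeatureSet as GFF3, converting back to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in fs.layout.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for f in fs.features:
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f.id)
            attr_text = ";".join(f"{k}={v}" if v else k for k, v in attrs.items())
            iv = f.interval
            fh.write(
                f"{iv.chrom}\t{source}\t{f.feature_class}\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\t{attr_text}\n"
            )


# ---------------------------------------------------------------------------
# Reclassification


@dataclass(frozen=True)
class ReclassRule:
    """Substring rule turning matching features into a new working class.

    pattern        substring looked for (case-sensitive)
    new_class      class assigned on match
    require_class  if set, only features of this class are eligible
    attribute      if set, match only this attribute's value; otherwise the
                   feature id, class and every attribute value are searched
    """

    pattern: str
    new_class: str
    require_class: str | None = None
    attribute: str | None = None

    def matches(self, feature: Feature) -> bool:
        if self.require_class is not None and feature.feature_class != self.require_class:
            return False
        if self.attribute is not None:
            return self.pattern in feature.attr.get(self.attribute, "")
        if self.pattern in feature.id or self.pattern in feature.feature_class:
            return True
        return any(self.pattern in v for _, v in feature.attributes)


# Working-class reclassification applied to Pombase-style annotation:
# LTRTF2 records become LTRs, Tf2 protein-coding genes become Tf2s,
# replication origins and introns get their own classes.
DEFAULT_RECLASS_RULES: tuple[ReclassRule, ...] = (
    ReclassRule("LTRTF2", "LTR"),
    ReclassRule("Tf2", "Tf2", require_class="protein_coding_gene"),
    ReclassRule("origin_of_replication", "origin"),
    ReclassRule("intron", "intron", attribute="external_name"),
)


def reclassify_features(
    fs: FeatureSet, rules: Iterable[ReclassRule] = DEFAULT_RECLASS_RULES
) -> FeatureSet:
    """Apply the reclassification rules in order; first matching rule wins.

    Returns a new FeatureSet; idempotent (a reclassified feature matches the
    same rule again and keeps its class).
    """
    rules = tuple(rules)
    out = []
    for f in fs.features:
        new_class = f.feature_class
        for rule in rules:
            if rule.matches(f) or f.feature_class == rule.new_class:
                new_class = rule.new_class
                break
        out.append(dataclasses.replace(f, feature_class=new_class))
    return FeatureSet(out, fs.layout)


# ---------------------------------------------------------------------------
# Subtelomeres


def default_subtelomere_intervals() -> list[GenomicInterval]:
    """The four published S. pombe subtelomeric regions, converted to the
    internal 0-based half-open convention (endpoints read as 1-based closed)."""
    return [
        GenomicInterval(chrom, start1 - 1, end1)
        for chrom, start1, end1 in SUBTELOMERE_REGIONS_1BASED
    ]


def define_subtelomeres(
    layout: GenomeLayout, regions: Sequence[GenomicInterval] | None = None
) -> FeatureSet:
    """Build a FeatureSet of class 'subtelomere', one feature per region.

    With regions=None the packaged S. pombe chromosome I/II end-domain
    coordinates are used.  Overlapping regions are rejected.
    """
    if regions is None:
        regions = default_subtelomere_intervals()
    for iv in regions:
        iv.validate(layout)
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            if a.overlaps(b):
                raise ValidationError(
                    f"subtelomere regions overlap: {a.chrom}:{a.start}-{a.end} "
                    f"and {b.chrom}:{b.start}-{b.end}"
                )
    features = [
        Feature(iv, "subtelomere", f"subtel_{iv.chrom}_{iv.start}_{iv.end}")
        for iv in regions
    ]
    return FeatureSet(features, layout)


def read_bed(path: str | Path, layout: GenomeLayout) -> list[GenomicInterval]:
    """Read BED3/BED4+ intervals (native 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
            iv.validate(layout)
            out.append(iv)
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Probe/feature overlap


def feature_trees(fs: FeatureSet, classes: set[str] | None = None
                  ) -> dict[str, IntervalTree]:
    """One interval tree per chromosome over the selected feature classes."""
    trees: dict[str, IntervalTree] = {}
    for f in fs.features:
        if classes is not None and f.feature_class not in classes:
            continue
        trees.setdefault(f.interval.chrom, IntervalTree()).addi(
            f.interval.start, f.interval.end, f.id
        )
    return trees


def probes_overlapping(fs: FeatureSet, track, classes: set[str]) -> np.ndarray:
    """Boolean membership mask: probe i overlaps (>= 1 bp) a feature whose
    class is in `classes`.  Half-open abutment does not count as overlap."""
    classes = set(classes)
    missing = classes - fs.classes
    if missing:
        raise ValidationError(
            f"unknown feature class(es) {sorted(missing)}; "
            f"available: {sorted(fs.classes)}"
        )
    if track.layout.names != fs.layout.names:
        raise ValidationError("track and feature set use different layouts")
    trees = feature_trees(fs, classes)
    mask = np.zeros(track.n_probes, dtype=bool)
    chrom_names = track.layout.names
    for i in range(track.n_probes):
        tree = trees.get(chrom_names[track.chrom[i]])
        if tree is not None and tree.overlap(int(track.start[i]), int(track.end[i])):
            mask[i] = True
    return mask
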