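"""Pipeline orchestration: run the three analyses from files to reports.

Each stage reads its inputs, runs the corresponding model, and writes a
TSV table plus a JSON report.  Reports embed the seed, a hash of the
configuration and checksums of every input file, so identical inputs and
seed reproduce byte-identical outputs; timing goes to the log only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .errors import ValidationError
from .genome import (FeatureSet, GenomeLayout, define_subtelomeres, read_bed,
                     read_gff3, reclassify_features)
from .models import ClassEnrichment, PairedOccupancy, ZoneAssay
from .occupancy import OccupancyTable
from .tracks import log2_ratio, read_bedgraph
from .zones import read_spots

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths and test parameters for a pipeline run."""

    genome: str | None = None          # layout TSV (name, length)
    features: str | None = None        # features TSV or GFF3
    subtelomeres: str | None = None    # BED of subtelomere regions
    numerator: str | None = None       # bedGraph (e.g. ChIP)
    denominator: str | None = None     # bedGraph (e.g. control)
    ratio: str | None = None           # precomputed log2-ratio bedGraph
    coverage_a: str | None = None      # occupancy condition A
    coverage_b: str | None = None      # occupancy condition B
    occupancy_table: str | None = None # precomputed paired table
    spots: str | None = None           # spot measurement TSV
    classes: list[str] = field(default_factory=list)
    compare_strains: list[list[str]] = field(default_factory=list)
    n_permutations: int = 1000
    alternative: str = "two_sided"
    seed: int = 0
    n_zones: int = 3
    pseudocount: float = 0.5
    out_dir: str = "nucorg_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def input_checksums(self) -> dict[str, str]:
        sums = {}
        for name in ("genome", "features", "subtelomeres", "numerator",
                     "denominator", "ratio", "coverage_a", "coverage_b",
                     "occupancy_table", "spots"):
            path = getattr(self, name)
            if path is None:
                continue
            p = Path(path)
            if not p.exists():
                raise ValidationError(f"input file for {name!r} missing: {path}")
            sums[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        return sums


def _report_meta(cfg: PipelineConfig) -> dict:
    return {
        "nucorg_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "inputs": cfg.input_checksums(),
    }


def _write_report(report: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")


def load_features(cfg: PipelineConfig, layout: GenomeLayout) -> FeatureSet:
    if cfg.features is None:
        raise ValidationError("config needs a 'features' file")
    path = Path(cfg.features)
    if path.suffix in (".gff", ".gff3"):
        fs = reclassify_features(read_gff3(path, layout))
    else:
        fs = FeatureSet.from_tsv(path, layout)
    if cfg.subtelomeres is not None:
        regions = read_bed(cfg.subtelomeres, layout)
        subs = define_subtelomeres(layout, regions)
        fs = FeatureSet(list(fs.features) + list(subs.features), layout)
    return fs


def _load_layout(cfg: PipelineConfig) -> GenomeLayout:
    if cfg.genome is None:
        raise ValidationError("config needs a 'genome' layout file")
    return GenomeLayout.from_tsv(cfg.genome)


def run_enrichment(cfg: PipelineConfig) -> dict:
    """Per-class enrichment with circular-permutation p-values."""
    t0 = time.perf_counter()
    layout = _load_layout(cfg)
    fs = load_features(cfg, layout)
    if cfg.ratio is not None:
        track = read_bedgraph(cfg.ratio, layout)
    elif cfg.numerator is not None and cfg.denominator is not None:
        track = log2_ratio(read_bedgraph(cfg.numerator, layout),
                           read_bedgraph(cfg.denominator, layout))
    else:
        raise ValidationError(
            "enrichment needs either 'ratio' or 'numerator'+'denominator'"
        )
    classes = cfg.classes or None
    results = ClassEnrichment(track, fs, classes).fit(
        n_permutations=cfg.n_permutations, alternative=cfg.alternative,
        seed=cfg.seed,
    )
    report = {
        "stage": "enrichment",
        "meta": _report_meta(cfg),
        "n_permutations": cfg.n_permutations,
        "alternative": cfg.alternative,
        "classes": results.to_records(),
        "skipped": results.errors,
    }
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    _write_report(report, out / "enrichment.json")
    logger.info("enrichment: %d classes in %.2fs", len(results.table),
                time.perf_counter() - t0)
    return report


def run_occupancy(cfg: PipelineConfig) -> dict:
    """Paired occupancy comparison with signed-rank p-values."""
    t0 = time.perf_counter()
    if cfg.occupancy_table is not None:
        table = OccupancyTable.from_tsv(cfg.occupancy_table)
        model = PairedOccupancy(table, cfg.classes or None)
    else:
        layout = _load_layout(cfg)
        fs = load_features(cfg, layout)
        if cfg.coverage_a is None or cfg.coverage_b is None:
            raise ValidationError(
                "occupancy needs 'occupancy_table' or 'coverage_a'+'coverage_b'"
            )
        model = PairedOccupancy.from_tracks(
            read_bedgraph(cfg.coverage_a, layout),
            read_bedgraph(cfg.coverage_b, layout),
            fs, cfg.classes or None,
        )
    results = model.fit(pseudocount=cfg.pseudocount)
    report = {
        "stage": "occupancy",
        "meta": _report_meta(cfg),
        "classes": results.to_records(),
        "skipped": results.errors,
    }
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.table.to_csv(out / "occupancy.tsv", sep="\t", index=False)
    _write_report(report, out / "occupancy.json")
    logger.info("occupancy: %d classes in %.2fs", len(results.table),
                time.perf_counter() - t0)
    return report


def run_zones(cfg: PipelineConfig) -> dict:
    """Zone assay: per-strain zone percentages and chi-square comparisons."""
    t0 = time.perf_counter()
    if cfg.spots is None:
        raise ValidationError("zones needs a 'spots' file")
    measurements = read_spots(cfg.spots)
    model = ZoneAssay(measurements, cfg.n_zones)
    compare = [tuple(pair) for pair in cfg.compare_strains] or None
    strains = sorted({m.strain for m in measurements})
    if len(strains) < 2:
        logger.warning("only one strain (%s): zone table only, no test",
                       strains[0] if strains else "none")
        compare = []
    results = model.fit(compare=compare)
    report = {
        "stage": "zones",
        "meta": _report_meta(cfg),
        "n_zones": cfg.n_zones,
        "percentages": results.percentages().to_dict(orient="records"),
        "tests": results.tests.to_dict(orient="records"),
    }
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.percentages().to_csv(out / "zones.tsv", sep="\t", index=False)
    _write_report(report, out / "zones.json")
    logger.info("zones: %d strains in %.2fs", len(strains),
                time.perf_counter() - t0)
    return report
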