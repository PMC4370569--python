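"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates, at toy scale, the inputs of a fission-yeast
chromatin-organization study: an annotated genome with subtelomeric
end-domains, tRNA/LTR-style feature classes; tiling-probe signal tracks
with lag-1 autoregressive spatial autocorrelation and additive per-class
log2 effects; paired negative-binomial occupancy counts with a fold
change between genotypes; and nuclear spot measurements with a tunable
peripheral bias.  Every generator is deterministic under a seed and its
output satisfies the invariants of the downstream containers.

Defaults: AR(1) autocorrelation rho = 0.7 (the phenomenon the circular
permutation null exists to respect), marginal signal sd 0.5 log2 units,
negative-binomial dispersion 10 (overdispersed counts, Poisson in the
dispersion -> infinity limit), wild-type spot preset (0.75, 0.15, 0.10)
matching the peripheral bias of telomeres in wild-type cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .genome import (Feature, FeatureSet, GenomeLayout, GenomicInterval,
                     write_bed, write_gff3)
from .occupancy import OccupancyTable
from .tracks import ProbeTrack
from .zones import SpotMeasurement, assign_zone

import pandas as pd

# Spot-model presets: probability of zones (1=peripheral, 2, 3=central).
SPOT_PRESETS: dict[str, tuple[float, float, float]] = {
    # peripheral anchoring as seen for wild-type telomeres
    "wildtype": (0.75, 0.15, 0.10),
    # no anchoring: uniform in the nuclear volume = equal zone occupancy
    "uniform": (1 / 3, 1 / 3, 1 / 3),
    # released from the envelope, shifted to the interior
    "released": (0.45, 0.25, 0.30),
}


@dataclass
class FeaturePlan:
    """How many features of a class to place, and how.

    placement: "random" (uniform non-overlapping), "ends" (subtelomere-style
    end-domains of `length` bp on both ends of every chromosome), or
    "subtelomere_border" (immediately inside each end-domain boundary,
    LTR-style)."""

    feature_class: str
    count: int = 0
    length: int = 80
    placement: str = "random"


@dataclass
class SignalModel:
    baseline: float = 0.0      # mean log2 level of the null track
    sd: float = 0.5            # marginal standard deviation, log2 units
    rho: float = 0.7           # lag-1 autocorrelation along the probe index
    effects: dict[str, float] = field(default_factory=dict)  # class -> delta

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValidationError(f"rho must be in [0, 1), got {self.rho}")
        if self.sd <= 0:
            raise ValidationError("sd must be positive")


@dataclass
class OccupancyModel:
    mean: float = 100.0        # per-feature mean occupancy, condition A
    dispersion: float = 10.0   # NB size parameter; inf = Poisson
    fold: float = 1.0          # condition B mean = fold * mean

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValidationError("mean must be positive")
        if self.fold <= 0:
            raise ValidationError("fold must be positive")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")


@dataclass
class SimulationConfig:
    seed: int = 0
    chromosomes: tuple[int, ...] = (300_000, 240_000, 150_000)
    probe_step: int = 60
    features: tuple[FeaturePlan, ...] = (
        FeaturePlan("subtelomere", length=20_000, placement="ends"),
        FeaturePlan("LTR", count=8, length=350, placement="subtelomere_border"),
        FeaturePlan("tRNA", count=40, length=80),
        FeaturePlan("LTR", count=30, length=350),
        FeaturePlan("5S_rRNA", count=10, length=120),
    )
    signal: SignalModel = field(default_factory=SignalModel)
    occupancy: OccupancyModel = field(default_factory=OccupancyModel)
    spot_presets: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(SPOT_PRESETS)
    )
    radius_range_um: tuple[float, float] = (0.8, 1.2)


def _chrom_names(n: int) -> list[str]:
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    if n <= len(roman):
        return roman[:n]
    return [f"chr{i + 1}" for i in range(n)]


def make_genome_and_features(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[GenomeLayout, FeatureSet]:
    """Build a toy annotated genome.

    Subtelomere plans occupy chromosome ends; "subtelomere_border" features
    sit immediately inside the end-domain boundaries; other classes are
    placed uniformly at random without overlap.  Writes genome.tsv,
    features.gff3, features.tsv and subtelomeres.bed when out_dir is given.
    Deterministic under cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = GenomeLayout(tuple(zip(_chrom_names(len(cfg.chromosomes)),
                                    cfg.chromosomes)))
    features: list[Feature] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in layout.names}
    subtel_bounds: list[tuple[str, int, int, bool]] = []  # chrom, start, end, left?

    def place(chrom: str, start: int, end: int, cls: str, fid: str) -> None:
        for s, e in occupied[chrom]:
            if start < e and s < end:
                raise ValidationError(
                    f"feature placement infeasible: {cls} at {chrom}:{start}-{end} "
                    f"collides with existing feature at {chrom}:{s}-{e}; "
                    f"{len(occupied[chrom])} features on {chrom}"
                )
        occupied[chrom].append((start, end))
        features.append(Feature(GenomicInterval(chrom, start, end), cls, fid))

    counter = 0
    for plan in cfg.features:
        if plan.placement == "ends":
            for chrom, length in layout.chromosomes:
                L = min(plan.length, length // 3)
                place(chrom, 0, L, plan.feature_class,
                      f"{plan.feature_class}_{chrom}_L")
                place(chrom, length - L, length, plan.feature_class,
                      f"{plan.feature_class}_{chrom}_R")
                subtel_bounds.append((chrom, 0, L, True))
                subtel_bounds.append((chrom, length - L, length, False))
        elif plan.placement == "subtelomere_border":
            if not subtel_bounds:
                raise ValidationError(
                    "subtelomere_border placement requires an 'ends' plan first"
                )
            for i in range(plan.count):
                chrom, s, e, left = subtel_bounds[i % len(subtel_bounds)]
                # just inside the domain boundary, offset per reuse round
                gap = (i // len(subtel_bounds) + 1) * (plan.length + 50)
                if left:
                    start = e + gap - plan.length
                else:
                    start = s - gap
                counter += 1
                place(chrom, start, start + plan.length, plan.feature_class,
                      f"{plan.feature_class}_border_{counter}")
        elif plan.placement == "random":
            for _ in range(plan.count):
                counter += 1
                for _attempt in range(1000):
                    ci = int(rng.integers(0, len(layout.chromosomes)))
                    chrom, length = layout.chromosomes[ci]
                    start = int(rng.integers(0, length - plan.length))
                    end = start + plan.length
                    if all(not (start < e and s < end)
                           for s, e in occupied[chrom]):
                        place(chrom, start, end, plan.feature_class,
                              f"{plan.feature_class}_{counter}")
                        break
                else:
                    raise ValidationError(
                        f"could not place {plan.feature_class} feature after "
                        f"1000 attempts; genome too crowded "
                        f"({sum(len(v) for v in occupied.values())} features)"
                    )
        else:
            raise ValidationError(f"unknown placement {plan.placement!r}")

    fs = FeatureSet(features, layout)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        layout.to_tsv(out / "genome.tsv")
        write_gff3(fs, out / "features.gff3")
        fs.to_tsv(out / "features.tsv")
        subs = [f for f in features if f.feature_class == "subtelomere"]
        write_bed([f.interval for f in subs], out / "subtelomeres.bed",
                  [f.id for f in subs])
    return layout, fs


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary lag-1 autoregressive series with marginal sd `sd`."""
    x = np.empty(n)
    innov_sd = sd * np.sqrt(1 - rho**2)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def tile_probes(layout: GenomeLayout, probe_step: int) -> ProbeTrack:
    """One probe per `probe_step` bp across every chromosome, value 0."""
    if probe_step < 1:
        raise ValidationError("probe_step must be >= 1")
    chroms, starts, ends = [], [], []
    for ci, (_name, length) in enumerate(layout.chromosomes):
        s = np.arange(0, length, probe_step, dtype=np.int64)
        e = np.minimum(s + probe_step, length)
        chroms.append(np.full(s.size, ci, dtype=np.int32))
        starts.append(s)
        ends.append(e)
    return ProbeTrack(layout, np.concatenate(chroms), np.concatenate(starts),
                      np.concatenate(ends), np.zeros(sum(len(s) for s in starts)))


def simulate_probe_signal(
    layout: GenomeLayout, fs: FeatureSet, cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ProbeTrack, ProbeTrack, ProbeTrack]:
    """Simulate (condition, control, log2-ratio) probe tracks.

    The log2 ratio is AR(1) noise (per chromosome) plus the per-class
    additive effects on probes overlapping those classes; the control is an
    independent AR(1) baseline on the linear scale, and the condition is
    control * 2^ratio so that log2(condition/control) returns the ratio.
    """
    from .genome import probes_overlapping  # local import avoids cycle at load

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    grid = tile_probes(layout, cfg.probe_step)
    sig = cfg.signal
    ratio = np.empty(grid.n_probes)
    baseline = np.empty(grid.n_probes)
    for _ci, sl in grid.chrom_slices():
        n = sl.stop - sl.start
        ratio[sl] = sig.baseline + _ar1(rng, n, sig.sd, sig.rho)
        baseline[sl] = _ar1(rng, n, sig.sd, sig.rho)
    for cls, delta in sig.effects.items():
        if delta == 0:
            continue
        mask = probes_overlapping(fs, grid, {cls})
        ratio[mask] += delta
    control_vals = 2.0 ** baseline
    condition_vals = control_vals * 2.0 ** ratio

    def mk(vals: np.ndarray) -> ProbeTrack:
        return ProbeTrack(layout, grid.chrom.copy(), grid.start.copy(),
                          grid.end.copy(), vals)

    return mk(condition_vals), mk(control_vals), mk(ratio)


def _negbin(rng: np.random.Generator, mean: float, dispersion: float,
            size: int) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mean, size=size).astype(float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def simulate_occupancy(fs: FeatureSet, cfg: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       class_label: str | None = None) -> OccupancyTable:
    """Paired per-feature occupancy counts: A ~ NB(mean, dispersion),
    B ~ NB(fold * mean, dispersion), independently per feature."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    feats = fs.by_class(class_label).features if class_label else fs.features
    occ = cfg.occupancy
    n = len(feats)
    a = _negbin(rng, occ.mean, occ.dispersion, n)
    b = _negbin(rng, occ.fold * occ.mean, occ.dispersion, n)
    df = pd.DataFrame({
        "feature_id": [f.id for f in feats],
        "feature_class": [f.feature_class for f in feats],
        "mean_a": a,
        "mean_b": b,
    })
    return OccupancyTable(df)


def simulate_spots(cfg: SimulationConfig, strain: str, n_cells: int,
                   rng: np.random.Generator | None = None,
                   n_zones: int = 3) -> list[SpotMeasurement]:
    """Nuclear spot measurements for one strain.

    The zone is drawn from the strain's preset probabilities; within the
    zone the radial position is volume-uniform (inverse CDF of the r^2
    density on the shell), so the "uniform" preset is exactly uniform in
    the ball.  The nuclear radius is uniform over cfg.radius_range_um.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if strain not in cfg.spot_presets:
        raise ValidationError(
            f"no spot preset for strain {strain!r}; "
            f"have {sorted(cfg.spot_presets)}"
        )
    probs = np.asarray(cfg.spot_presets[strain], dtype=float)
    if probs.size != n_zones or probs.min() < 0 or abs(probs.sum() - 1) > 1e-9:
        raise ValidationError(
            f"preset for {strain!r} must be {n_zones} probabilities summing to 1"
        )
    zones = rng.choice(np.arange(1, n_zones + 1), size=n_cells, p=probs)
    # zone k covers center-distance r with r^3 in [(n-k)/n, (n-k+1)/n]
    lo3 = (n_zones - zones) / n_zones
    hi3 = (n_zones - zones + 1) / n_zones
    r = (rng.uniform(lo3, hi3)) ** (1.0 / 3.0)
    d_norm = 1.0 - r
    radius = rng.uniform(*cfg.radius_range_um, size=n_cells)
    out = [
        SpotMeasurement(f"{strain}_{i + 1}", strain, float(radius[i]),
                        float(d_norm[i] * radius[i]))
        for i in range(n_cells)
    ]
    # generator/assigner consistency is structural: d in zone k's shell
    assert all(assign_zone(m, n_zones) == int(z) for m, z in zip(out, zones))
    return out


def write_simulation(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full fixture directory (genome, features, tracks, tables)."""
    from .tracks import log2_ratio, write_bedgraph
    from .zones import write_spots

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout, fs = make_genome_and_features(cfg, out)
    rng = np.random.default_rng(cfg.seed + 1)
    cond, ctrl, ratio = simulate_probe_signal(layout, fs, cfg, rng)
    write_bedgraph(cond, out / "condition.bedgraph")
    write_bedgraph(ctrl, out / "control.bedgraph")
    write_bedgraph(ratio, out / "log2_ratio.bedgraph")
    table = simulate_occupancy(fs, cfg, rng)
    table.to_tsv(out / "occupancy.tsv")
    spots = []
    for strain in cfg.spot_presets:
        spots.extend(simulate_spots(cfg, strain, 150, rng))
    write_spots(spots, out / "spots.tsv")
    return {
        "genome": out / "genome.tsv",
        "gff3": out / "features.gff3",
        "features": out / "features.tsv",
        "subtelomeres": out / "subtelomeres.bed",
        "condition": out / "condition.bedgraph",
        "control": out / "control.bedgraph",
        "ratio": out / "log2_ratio.bedgraph",
        "occupancy": out / "occupancy.tsv",
        "spots": out / "spots.tsv",
    }
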