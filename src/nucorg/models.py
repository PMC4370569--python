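"""Model/Results interface over the three analyses.

Each analysis is exposed the way statistical modelling packages expose an
estimator: a model object is built from data, `fit()` runs the estimation
and testing, and the returned Results object carries the estimates, their
uncertainty, diagnostics and a `summary()` table.

ClassEnrichment   per-class signal enrichment against the rest of the
                  genome, circular-permutation p-values.
PairedOccupancy   per-feature paired occupancy comparison between two
                  conditions, Wilcoxon signed-rank p-values and fold
                  summaries.
ZoneAssay         nuclear-zone scoring of spot measurements and pairwise
                  chi-square strain comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import occupancy as occ
from . import zones as zn
from .errors import ValidationError
from .genome import FeatureSet, probes_overlapping
from .permutation import PermutationResult, class_permutation_test
from .tracks import ClassSummary, ProbeTrack, filter_unique, summarize_values


def _format_table(df: pd.DataFrame, title: str) -> str:
    body = df.to_string(index=False, float_format=lambda v: f"{v:.4g}")
    rule = "=" * max(len(title), len(body.split("\n")[0]))
    return f"{title}\n{rule}\n{body}\n"


# ---------------------------------------------------------------------------
# Class enrichment


class ClassEnrichment:
    """Per-class enrichment of a probe-level signal vs the rest of the genome.

    Parameters
    ----------
    track : ProbeTrack
        Signal track, typically a log2 enrichment ratio.
    features : FeatureSet
        Annotated features sharing the track's layout.
    classes : sequence of str, optional
        Feature classes to test; defaults to every class in `features`.
    filter_nonunique : bool
        Drop probes without a unique genomic match before statistics
        (the full track is only for visualization).
    """

    def __init__(self, track: ProbeTrack, features: FeatureSet,
                 classes=None, filter_nonunique: bool = True):
        self.track = filter_unique(track) if filter_nonunique else track
        self.features = features
        self.classes = tuple(classes) if classes is not None else tuple(
            sorted(features.classes)
        )

    def fit(self, n_permutations: int = 1000, alternative: str = "two_sided",
            seed: int | None = None) -> "ClassEnrichmentResults":
        rows = []
        per_class: dict[str, PermutationResult] = {}
        summaries: dict[str, tuple[ClassSummary, ClassSummary]] = {}
        errors: dict[str, str] = {}
        for i, cls in enumerate(self.classes):
            try:
                mask = probes_overlapping(self.features, self.track, {cls})
                cls_seed = None if seed is None else seed + i
                res = class_permutation_test(
                    self.track, mask, n_permutations, alternative, cls_seed
                )
                member = summarize_values(self.track.value[mask], cls)
                rest = summarize_values(self.track.value[~mask], "rest")
            except ValidationError as exc:
                errors[cls] = str(exc)
                continue
            per_class[cls] = res
            summaries[cls] = (member, rest)
            rows.append({
                "feature_class": cls,
                "n_probes": member.n_probes,
                "median_member": member.median,
                "median_rest": rest.median,
                "mean_diff": res.observed_stat,
                "p_value": res.p_value,
            })
        if not rows:
            raise ValidationError(
                f"no testable class; per-class errors: {errors}"
            )
        table = pd.DataFrame(rows)
        table["p_adj_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
        return ClassEnrichmentResults(self, table, per_class, summaries,
                                      errors, n_permutations, alternative, seed)


@dataclass
class ClassEnrichmentResults:
    model: ClassEnrichment
    table: pd.DataFrame
    permutations: dict[str, PermutationResult]
    summaries: dict[str, tuple[ClassSummary, ClassSummary]]
    errors: dict[str, str]
    n_permutations: int
    alternative: str
    seed: int | None

    def significant(self, alpha: float = 0.01, adjusted: bool = False) -> list[str]:
        col = "p_adj_bh" if adjusted else "p_value"
        sel = self.table[self.table[col] <= alpha]
        return list(sel["feature_class"])

    def summary(self) -> str:
        title = (f"Class enrichment (circular permutation, "
                 f"n={self.n_permutations}, alternative={self.alternative}, "
                 f"seed={self.seed})")
        text = _format_table(self.table, title)
        if self.errors:
            text += "skipped classes: " + ", ".join(
                f"{c} ({m})" for c, m in self.errors.items()
            ) + "\n"
        return text

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")


# ---------------------------------------------------------------------------
# Paired occupancy


class PairedOccupancy:
    """Paired per-feature occupancy comparison between conditions A and B."""

    def __init__(self, table: occ.OccupancyTable, classes=None):
        self.table = table
        self.classes = tuple(classes) if classes is not None else tuple(
            sorted(table.df["feature_class"].unique())
        )

    @classmethod
    def from_tracks(cls, coverage_a: ProbeTrack, coverage_b: ProbeTrack,
                    features: FeatureSet, classes=None,
                    mode: str = "per_base") -> "PairedOccupancy":
        table = occ.occupancy_table(coverage_a, coverage_b, features, mode=mode)
        return cls(table, classes)

    def fit(self, method: str = "auto",
            pseudocount: float = 0.5) -> "PairedOccupancyResults":
        folds = occ.fold_change_summary(self.table, pseudocount=pseudocount)
        folds = folds[folds["feature_class"].isin(self.classes)]
        rows = []
        tests: dict[str, occ.PairedTestResult] = {}
        errors: dict[str, str] = {}
        for cls in self.classes:
            try:
                sub = self.table.by_class(cls)
                res = occ.paired_rank_test(sub, method=method)
            except ValidationError as exc:
                errors[cls] = str(exc)
                continue
            tests[cls] = res
            frow = folds[folds["feature_class"] == cls].iloc[0]
            rows.append({
                "feature_class": cls,
                "n_features": int(frow["n_features"]),
                "median_fold": float(frow["median_fold"]),
                "fraction_decreased": float(frow["fraction_decreased"]),
                "statistic": res.statistic,
                "n_pairs": res.n_pairs,
                "p_value": res.p_value,
                "method": res.method,
            })
        if not rows:
            raise ValidationError(f"no testable class; errors: {errors}")
        return PairedOccupancyResults(self, pd.DataFrame(rows), tests, errors)


@dataclass
class PairedOccupancyResults:
    model: PairedOccupancy
    table: pd.DataFrame
    tests: dict[str, occ.PairedTestResult]
    errors: dict[str, str]

    def summary(self) -> str:
        title = "Paired occupancy comparison (Wilcoxon signed-rank, two-sided)"
        text = _format_table(self.table, title)
        if self.errors:
            text += "skipped classes: " + ", ".join(
                f"{c} ({m})" for c, m in self.errors.items()
            ) + "\n"
        return text

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")


# ---------------------------------------------------------------------------
# Zone assay


class ZoneAssay:
    """Nuclear-zone scoring of spot measurements across strains."""

    def __init__(self, measurements: list[zn.SpotMeasurement], n_zones: int = 3):
        if not measurements:
            raise ValidationError("no spot measurements")
        self.measurements = list(measurements)
        self.n_zones = n_zones

    def fit(self, compare: list[tuple[str, str]] | None = None
            ) -> "ZoneAssayResults":
        table = zn.zone_table(self.measurements, self.n_zones)
        if compare is None:
            compare = [
                (a, b)
                for i, a in enumerate(table.strains)
                for b in table.strains[i + 1:]
            ]
        tests = []
        for a, b in compare:
            stat, df, p = zn.chi_square_test(table, a, b)
            tests.append({"strain_a": a, "strain_b": b, "chi2": stat,
                          "df": df, "p_value": p})
        return ZoneAssayResults(self, table, pd.DataFrame(
            tests, columns=["strain_a", "strain_b", "chi2", "df", "p_value"]
        ))


@dataclass
class ZoneAssayResults:
    model: ZoneAssay
    zone_table: zn.ZoneTable
    tests: pd.DataFrame

    def percentages(self) -> pd.DataFrame:
        return self.zone_table.percentages()

    def summary(self) -> str:
        text = _format_table(
            self.percentages(),
            f"Zone occupancy (% of cells, {self.zone_table.n_zones} "
            "equal-volume zones, zone1 = peripheral)",
        )
        if len(self.tests):
            text += "\n" + _format_table(self.tests,
                                         "Pairwise chi-square comparisons")
        return text
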