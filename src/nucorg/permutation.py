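"""Circular permutation test for feature-class enrichment.

Tiling-array signals are strongly autocorrelated along the chromosome, so
comparing "probes in a feature class" against "the rest of the genome" with
an i.i.d. resampling null badly overstates significance.  The circular
permutation null instead rotates the class-membership labels along each
chromosome's probe index by a random offset: within-chromosome spatial
structure of both the signal and the feature geometry is preserved while
the alignment between the two is destroyed.

The test statistic is the difference of means, mean(members) −
mean(non-members).  Per-chromosome offsets are drawn independently by
default; a joint single-offset mode over the concatenated genome is
available.  `exhaustive_test` enumerates every offset combination and
serves as the oracle for the sampled test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

_ALTERNATIVES = ("greater", "less", "two_sided")
# absolute slack when counting null statistics "at least as extreme":
# null stats are the same numbers summed in a different order, so only
# float round-off separates genuine ties.
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    n_permutations: int
    p_value: float
    alternative: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")
        if len(self.null_stats) != self.n_permutations:
            raise ValidationError("null_stats length != n_permutations")


def _as_mask(mask) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or mask.all():
        raise ValidationError(
            "degenerate mask: need at least one member and one non-member"
        )
    return mask


def mean_diff_statistic(values, mask) -> float:
    """mean(values[mask]) - mean(values[~mask])."""
    values = np.asarray(values, dtype=float)
    mask = _as_mask(mask)
    if values.size != mask.size:
        raise ValidationError("values and mask lengths differ")
    return float(values[mask].mean() - values[~mask].mean())


def _chrom_groups(n: int, chrom) -> list[np.ndarray]:
    """Probe indices per chromosome, in order. chrom=None means one group."""
    if chrom is None:
        return [np.arange(n)]
    chrom = np.asarray(chrom)
    if chrom.size != n:
        raise ValidationError("chrom labels length != number of probes")
    groups = []
    for c in pd_unique_stable(chrom):
        groups.append(np.flatnonzero(chrom == c))
    return groups


def pd_unique_stable(arr: np.ndarray) -> np.ndarray:
    _, idx = np.unique(arr, return_index=True)
    return arr[np.sort(idx)]


def circular_shift(mask, offsets, chrom=None) -> np.ndarray:
    """Rotate membership labels by one offset per chromosome.

    Label i moves to position (i + offset) mod n within its chromosome;
    values stay fixed, membership cardinality per chromosome is conserved.
    """
    mask = np.asarray(mask, dtype=bool)
    groups = _chrom_groups(mask.size, chrom)
    offsets = np.atleast_1d(np.asarray(offsets, dtype=np.int64))
    if offsets.size != len(groups):
        raise ValidationError(
            f"need one offset per chromosome ({len(groups)}), got {offsets.size}"
        )
    out = mask.copy()
    for grp, off in zip(groups, offsets):
        n = grp.size
        if not (0 <= off < n):
            raise ValidationError(f"offset {off} outside [0, {n})")
        out[grp] = np.roll(mask[grp], int(off))
    return out


def _member_sums_per_offset(values: np.ndarray, member_idx: np.ndarray,
                            n: int) -> np.ndarray:
    """s[o] = sum of values at the rotated member positions, all offsets o."""
    if member_idx.size == 0:
        return np.zeros(n)
    pos = (member_idx[:, None] + np.arange(n)[None, :]) % n
    return values[pos].sum(axis=0)


def _stat_from_member_sum(member_sum, total_sum, n_members, n_total):
    rest = total_sum - member_sum
    return member_sum / n_members - rest / (n_total - n_members)


def _tail_count(null_stats: np.ndarray, observed: float, alternative: str) -> int:
    scale = max(1.0, abs(observed))
    eps = _TIE_EPS * scale
    if alternative == "greater":
        return int(np.sum(null_stats >= observed - eps))
    if alternative == "less":
        return int(np.sum(null_stats <= observed + eps))
    if alternative == "two_sided":
        return int(np.sum(np.abs(null_stats) >= abs(observed) - eps))
    raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")


def permutation_test(values, mask, n_permutations: int = 1000,
                     alternative: str = "two_sided", seed: int | None = None,
                     chrom=None, joint: bool = False) -> PermutationResult:
    """Sampled circular permutation test.

    One uniform offset per chromosome per permutation (or a single joint
    offset over the concatenated probe index with joint=True).  The p-value
    uses +1 smoothing: p = (1 + #{null at least as extreme}) /
    (n_permutations + 1), so p is never zero and never smaller than
    1/(n_permutations + 1).
    """
    if alternative not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    values = np.asarray(values, dtype=float)
    mask = _as_mask(mask)
    if values.size != mask.size:
        raise ValidationError("values and mask lengths differ")
    observed = mean_diff_statistic(values, mask)
    groups = [np.arange(values.size)] if joint else _chrom_groups(values.size, chrom)
    rng = np.random.default_rng(seed)

    n_members = int(mask.sum())
    total_sum = float(values.sum())
    # per-chromosome member sums for every possible offset, so a permutation
    # is just a table lookup per chromosome
    tables = []
    for grp in groups:
        v = values[grp]
        midx = np.flatnonzero(mask[grp])
        tables.append(_member_sums_per_offset(v, midx, grp.size))
    sizes = [grp.size for grp in groups]
    offsets = np.column_stack(
        [rng.integers(0, n, size=n_permutations) for n in sizes]
    )
    member_sums = np.zeros(n_permutations)
    for j, table in enumerate(tables):
        member_sums += table[offsets[:, j]]
    null_stats = _stat_from_member_sum(member_sums, total_sum, n_members,
                                       values.size)
    k = _tail_count(null_stats, observed, alternative)
    p = (1 + k) / (n_permutations + 1)
    return PermutationResult(observed, null_stats, n_permutations, p,
                             alternative, seed)


def exhaustive_test(values, mask, alternative: str = "two_sided", chrom=None,
                    max_combinations: int = 10**6) -> PermutationResult:
    """Exact circular permutation test by full offset enumeration.

    Every combination of per-chromosome offsets is visited exactly once,
    including the identity; p = #{null stats at least as extreme}/total,
    so p >= 1/total because the identity attains the observed statistic.
    """
    if alternative not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")
    values = np.asarray(values, dtype=float)
    mask = _as_mask(mask)
    if values.size != mask.size:
        raise ValidationError("values and mask lengths differ")
    groups = _chrom_groups(values.size, chrom)
    sizes = [grp.size for grp in groups]
    total = int(np.prod(sizes))
    if total > max_combinations:
        raise ValidationError(
            f"{total} offset combinations exceed the enumeration bound "
            f"{max_combinations}; use the sampled permutation_test instead"
        )
    observed = mean_diff_statistic(values, mask)
    n_members = int(mask.sum())
    total_sum = float(values.sum())
    tables = []
    for grp in groups:
        v = values[grp]
        midx = np.flatnonzero(mask[grp])
        tables.append(_member_sums_per_offset(v, midx, grp.size))
    # combine per-chromosome tables over the cartesian product of offsets
    member_sums = tables[0]
    for table in tables[1:]:
        member_sums = np.add.outer(member_sums, table).ravel()
    null_stats = _stat_from_member_sum(member_sums, total_sum, n_members,
                                       values.size)
    k = _tail_count(null_stats, observed, alternative)
    p = k / total
    return PermutationResult(observed, null_stats, total, p, alternative, None)


def class_permutation_test(track, mask, n_permutations: int = 1000,
                           alternative: str = "two_sided",
                           seed: int | None = None,
                           joint: bool = False) -> PermutationResult:
    """Convenience wrapper taking a ProbeTrack; rotates within chromosomes."""
    return permutation_test(track.value, mask, n_permutations, alternative,
                            seed, chrom=track.chrom, joint=joint)
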