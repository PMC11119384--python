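"""Lesion probability maps and voxel-wise nonparametric group comparison.

A probability map is the voxel-wise mean of a population of binary WMH
masks on a common lattice. Groups are compared voxel by voxel with a
two-sided Wilcoxon rank-sum test (tie-corrected normal approximation;
Kruskal–Wallis when more than two groups are supplied), restricted to an
analysis mask (default: the union of all masks, so voxels lesioned in
nobody do not inflate the multiple-testing burden), and corrected with
Benjamini–Hochberg FDR.

On 0/1 data the rank statistics have closed forms in the per-group lesion
counts, so the tests are evaluated for all voxels at once with array
arithmetic; an exhaustive permutation oracle in the test-suite checks the
reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    BinaryMask,
    DegenerateInputError,
    InvalidSpecError,
    ProbabilityMap,
    check_same_lattice,
)

__all__ = [
    "MatchSpec",
    "MatchResult",
    "VoxelTestResult",
    "build_probability_map",
    "match_samples",
    "standardized_mean_difference",
    "voxelwise_rank_test",
    "voxel_test_with_fdr",
    "fdr_correct",
    "threshold_difference_map",
    "percent_voxels_different",
    "LABEL_BACKGROUND",
    "LABEL_A",
    "LABEL_B",
]

LABEL_BACKGROUND, LABEL_A, LABEL_B = 0, 1, 2


# ----------------------------------------------------------------------------
# Probability maps
# ----------------------------------------------------------------------------

def build_probability_map(masks: Sequence[BinaryMask]) -> ProbabilityMap:
    """Voxel-wise mean of the binary masks; n = number of masks."""
    masks = list(masks)
    if not masks:
        raise InvalidSpecError("need at least one mask")
    check_same_lattice(*masks)
    stacked = np.stack([m.values for m in masks]).astype(np.float64)
    return ProbabilityMap(
        stacked.mean(axis=0), len(masks), masks[0].voxel_size_mm, masks[0].affine
    )


# ----------------------------------------------------------------------------
# Matched samples
# ----------------------------------------------------------------------------

_DEFAULT_EXACT = [
    "sex", "hypertension", "diabetes", "hyperlipidemia", "cad", "ckd",
    "prior_is", "prior_ich", "smoking", "alcohol",
]


@dataclass(frozen=True)
class MatchSpec:
    """Matching recipe: exact agreement on categorical variables, nearest
    neighbour within a caliper on continuous ones (default: age within
    5 years)."""

    exact_vars: tuple[str, ...] = tuple(_DEFAULT_EXACT)
    continuous_vars: tuple[tuple[str, float], ...] = (("age", 5.0),)
    seed: int = 0

    def validate(self) -> None:
        for name, caliper in self.continuous_vars:
            if caliper <= 0:
                raise InvalidSpecError(f"caliper for {name!r} must be positive")


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns: index_a, index_b, plus distance
    unmatched_a: list
    unmatched_b: list

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def match_samples(
    cohort: pd.DataFrame, group_var: str, spec: MatchSpec = MatchSpec()
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Subjects of the smaller group, visited in a seeded random order, each
    claim the unclaimed subject of the other group that agrees exactly on
    every exact_var and minimizes the (summed) absolute difference of the
    continuous variables, subject to each caliper. Ties go to the earlier
    row; infeasible subjects are reported unmatched (a fully infeasible
    problem yields an empty result with a warning, not an error).
    """
    spec.validate()
    levels = list(pd.unique(cohort[group_var]))
    if len(levels) != 2:
        raise InvalidSpecError(f"{group_var!r} must have exactly two levels")
    ga = cohort[cohort[group_var] == levels[0]]
    gb = cohort[cohort[group_var] == levels[1]]
    if ga.empty or gb.empty:
        raise InvalidSpecError("both groups must be non-empty")
    swap = len(gb) < len(ga)
    if swap:
        ga, gb = gb, ga

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ga))
    taken = np.zeros(len(gb), dtype=bool)
    rows = []
    unmatched_a = []
    b_index = gb.index.to_numpy()
    for i in order:
        row = ga.iloc[i]
        ok = ~taken
        for var in spec.exact_vars:
            ok &= (gb[var].to_numpy() == row[var])
        dist = np.zeros(len(gb))
        for var, caliper in spec.continuous_vars:
            d = np.abs(gb[var].to_numpy(dtype=float) - float(row[var]))
            ok &= d <= caliper
            dist += d
        if not ok.any():
            unmatched_a.append(ga.index[i])
            continue
        dist[~ok] = np.inf
        j = int(np.argmin(dist))
        taken[j] = True
        rows.append((ga.index[i], b_index[j], float(dist[j])))

    pairs = pd.DataFrame(rows, columns=["index_a", "index_b", "distance"])
    if swap:
        pairs = pairs.rename(columns={"index_a": "index_b", "index_b": "index_a"})
        pairs = pairs[["index_a", "index_b", "distance"]]
    unmatched_b = [ix for ix, t in zip(b_index, taken) if not t]
    if swap:
        unmatched_a, unmatched_b = unmatched_b, unmatched_a
    if pairs.empty:
        warnings.warn("no feasible matched pair", stacklevel=2)
    return MatchResult(pairs, list(unmatched_a), list(unmatched_b))


def standardized_mean_difference(
    cohort: pd.DataFrame, result: MatchResult, var: str
) -> float:
    """Absolute SMD of one covariate across the matched pairs
    (difference of means over the pooled SD of the matched sample)."""
    a = cohort.loc[result.pairs["index_a"], var].to_numpy(dtype=float)
    b = cohort.loc[result.pairs["index_b"], var].to_numpy(dtype=float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


# ----------------------------------------------------------------------------
# Voxel-wise rank tests
# ----------------------------------------------------------------------------

def _binary_rank_p(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Two-sided rank-test p-values at every voxel for k groups of 0/1 data.

    counts: (k, V) number of lesioned subjects per group per voxel;
    sizes: (k,) group sizes. For k = 2 this is the tie-corrected Wilcoxon
    rank-sum normal approximation; for k > 2 the tie-corrected
    Kruskal–Wallis chi-square. Voxels with zero variance get p = 1.
    """
    counts = np.asarray(counts, dtype=np.float64)
    sizes = np.asarray(sizes, dtype=np.float64)
    N = sizes.sum()
    ones = counts.sum(axis=0)
    zeros = N - ones
    # midranks of the two value classes
    rank0 = (zeros + 1.0) / 2.0
    rank1 = zeros + (ones + 1.0) / 2.0
    tie_sum = (zeros**3 - zeros) + (ones**3 - ones)
    degenerate = (ones == 0) | (zeros == 0)

    if counts.shape[0] == 2:
        nA, nB = sizes
        w = (nA - counts[0]) * rank0 + counts[0] * rank1
        ew = nA * (N + 1.0) / 2.0
        var = nA * nB / 12.0 * ((N + 1.0) - tie_sum / (N * (N - 1.0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (w - ew) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        rank_sums = (sizes[:, None] - counts) * rank0 + counts * rank1
        h = (12.0 / (N * (N + 1.0))) * np.sum(
            rank_sums**2 / sizes[:, None], axis=0
        ) - 3.0 * (N + 1.0)
        correction = 1.0 - tie_sum / (N**3 - N)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = h / correction
        p = stats.chi2.sf(h, df=counts.shape[0] - 1)

    p = np.where(degenerate, 1.0, p)
    return np.minimum(np.nan_to_num(p, nan=1.0), 1.0)


def voxelwise_rank_test(
    groupA: Sequence[BinaryMask],
    groupB: Sequence[BinaryMask],
    *more_groups: Sequence[BinaryMask],
    analysis_mask: BinaryMask | None = None,
) -> tuple[np.ndarray, BinaryMask]:
    """Per-voxel two-sided rank test of lesion presence between groups.

    Returns (p_map, analysis_mask): p_map is a full-grid array with p = 1
    outside the analysis mask and at zero-variance voxels. The default
    analysis mask is the union of all masks across groups.
    """
    groups = [list(groupA), list(groupB), *[list(g) for g in more_groups]]
    for g in groups:
        if len(g) < 2:
            raise InvalidSpecError("each group needs at least 2 masks")
    flat = [m for g in groups for m in g]
    check_same_lattice(*flat)
    ref = flat[0]
    if analysis_mask is None:
        union = np.zeros(ref.shape, dtype=bool)
        for m in flat:
            union |= m.values
        analysis_mask = ref.with_values(union)
    else:
        check_same_lattice(ref, analysis_mask)

    sel = analysis_mask.values
    counts = np.stack(
        [np.sum([m.values[sel] for m in g], axis=0) for g in groups]
    )
    sizes = np.array([len(g) for g in groups])
    p_flat = _binary_rank_p(counts, sizes)
    p_map = np.ones(ref.shape, dtype=np.float64)
    p_map[sel] = p_flat
    return p_map, analysis_mask


# ----------------------------------------------------------------------------
# FDR
# ----------------------------------------------------------------------------

def fdr_correct(
    p_values: Sequence[float] | np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up.

    Adjusted value for the i-th smallest p is min over j >= i of
    m·p(j)/j, capped at 1; a test is flagged when its adjusted value
    is <= q. Returns (adjusted, flags) in the input order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise InvalidSpecError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out, out <= q


@dataclass
class VoxelTestResult:
    """Voxel-wise comparison with FDR control."""

    p_map: np.ndarray
    q_map: np.ndarray
    significant: BinaryMask
    analysis_mask: BinaryMask
    q: float = 0.05


def voxel_test_with_fdr(
    groupA: Sequence[BinaryMask],
    groupB: Sequence[BinaryMask],
    *more_groups: Sequence[BinaryMask],
    analysis_mask: BinaryMask | None = None,
    q: float = 0.05,
) -> VoxelTestResult:
    """Rank tests at every analysis voxel, then BH correction over exactly
    the tested voxels. q_map is 1 outside the analysis mask."""
    p_map, amask = voxelwise_rank_test(
        groupA, groupB, *more_groups, analysis_mask=analysis_mask
    )
    sel = amask.values
    q_map = np.ones_like(p_map)
    sig = np.zeros(p_map.shape, dtype=bool)
    if sel.any():
        adj, flags = fdr_correct(p_map[sel], q=q)
        q_map[sel] = adj
        sig[sel] = flags
    return VoxelTestResult(p_map, q_map, amask.with_values(sig), amask, q)


# ----------------------------------------------------------------------------
# Difference maps and summaries
# ----------------------------------------------------------------------------

def threshold_difference_map(
    mapA: ProbabilityMap,
    mapB: ProbabilityMap,
    thrA: float = 0.75,
    thrB: float = 0.60,
) -> np.ndarray:
    """Three-valued label map: LABEL_A where mapA >= thrA and exceeds mapB,
    LABEL_B where mapB >= thrB and exceeds mapA, background elsewhere.

    The asymmetric defaults (0.75 / 0.60) display the top of each group's
    lesion-frequency distribution: the highest quartile for group A and a
    60% cut for group B.
    """
    if not (0 <= thrA <= 1 and 0 <= thrB <= 1):
        raise InvalidSpecError("thresholds must lie in [0, 1]")
    check_same_lattice(mapA, mapB)
    labels = np.full(mapA.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[(mapA.values >= thrA) & (mapA.values > mapB.values)] = LABEL_A
    labels[(mapB.values >= thrB) & (mapB.values > mapA.values)] = LABEL_B
    return labels


def percent_voxels_different(
    significant: BinaryMask, wmh_union: BinaryMask
) -> float:
    """Share of the union WMH footprint flagged as different, in percent."""
    check_same_lattice(significant, wmh_union)
    denom = wmh_union.n_voxels
    if denom == 0:
        raise DegenerateInputError("empty WMH union")
    inter = int((significant.values & wmh_union.values).sum())
    return 100.0 * inter / denom
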