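"""Data-stream permutation inference for pre/post network comparisons.

The null model randomizes the observation stream itself: checkerboard swaps
exchange two individuals between two groups, preserving every group size and
every individual's sighting count, so the null keeps the sampling structure
and breaks only the identity of who was with whom.  The test statistic is
the slope of metric ~ period (a 0/1 indicator), which for a binary predictor
is exactly mean(post) - mean(pre).  One-tailed P-values compare the observed
slope to the slopes refit on each permuted stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator, Literal, Sequence

import numpy as np

from .network_core import (
    GBIMatrix,
    mean_group_size,
    simple_ratio_index,
    weighted_degree,
)

log = logging.getLogger(__name__)

Metric = Literal["weighted_degree", "mean_group_size"]
Tail = Literal["greater", "less"]

MAX_SWAP_ATTEMPTS = 1000  # bounded search for a swappable checkerboard


@dataclass(frozen=True)
class SwapConstraint:
    """Partition of individuals into blocks; swaps never cross a block.

    Each scenario GBI is permuted separately, so in the usual per-arm layout
    a single block covering all columns suffices; the explicit partition
    exists so a pooled matrix cannot silently mix treatment arms.
    """

    blocks: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for block in self.blocks:
            if seen & block:
                raise ValueError("swap blocks overlap")
            seen |= block

    @classmethod
    def single_block(cls, labels: Sequence[str]) -> "SwapConstraint":
        return cls(blocks=(frozenset(labels),))

    def block_of(self, label: str) -> int:
        for k, block in enumerate(self.blocks):
            if label in block:
                return k
        raise KeyError(f"{label!r} not covered by any swap block")

    def column_blocks(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.block_of(lbl) for lbl in labels])


@dataclass(frozen=True)
class PermutationResult:
    label: str
    metric: Metric
    observed_coef: float
    null_coefs: np.ndarray
    p_one_tailed: float
    tail: Tail
    n_permutations: int
    swaps_per_permutation: int
    seed: int
    n_degenerate_swaps: int = 0


@dataclass(frozen=True)
class ScenarioComparison:
    """Per-individual metric values in the two periods of one treatment arm."""

    label: str
    metric: Metric
    pre_values: tuple[float, ...]
    post_values: tuple[float, ...]

    @property
    def n_pre(self) -> int:
        return len(self.pre_values)

    @property
    def n_post(self) -> int:
        return len(self.post_values)


def _swap_inplace(
    entries: np.ndarray, col_blocks: np.ndarray, rng: np.random.Generator
) -> bool:
    """Attempt one checkerboard swap in place; True if a flip happened.

    Draws two 1-cells with distinct rows and columns, both columns in the
    same block, and flips the 2x2 checkerboard if the cross cells are 0.
    After :data:`MAX_SWAP_ATTEMPTS` failed draws the matrix is left
    unchanged (degenerate matrices such as all-ones have no checkerboard).
    """
    ones_r, ones_c = np.nonzero(entries)
    n_ones = len(ones_r)
    if n_ones < 2:
        return False
    for _ in range(MAX_SWAP_ATTEMPTS):
        a, b = rng.integers(0, n_ones, size=2)
        r1, c1 = ones_r[a], ones_c[a]
        r2, c2 = ones_r[b], ones_c[b]
        if r1 == r2 or c1 == c2:
            continue
        if col_blocks[c1] != col_blocks[c2]:
            continue
        if entries[r1, c2] or entries[r2, c1]:
            continue
        entries[r1, c1] = entries[r2, c2] = 0
        entries[r1, c2] = entries[r2, c1] = 1
        return True
    return False


def checkerboard_swap(
    gbi: GBIMatrix,
    rng: np.random.Generator,
    constraint: SwapConstraint | None = None,
) -> GBIMatrix:
    """Return a copy of *gbi* with one checkerboard 2x2 flip applied.

    The flip turns [[1,0],[0,1]] into [[0,1],[1,0]] (or back), exchanging two
    individuals between two groups; all row and column sums are preserved
    exactly.  If no valid flip is found within the attempt bound the matrix
    is returned unchanged and the degenerate event is logged.
    """
    constraint = constraint or SwapConstraint.single_block(gbi.col_labels)
    col_blocks = constraint.column_blocks(gbi.col_labels)
    entries = gbi.entries.copy()
    if not _swap_inplace(entries, col_blocks, rng):
        log.debug("degenerate swap: no checkerboard found in %s", gbi.row_labels[:3])
    return GBIMatrix(entries=entries, row_labels=gbi.row_labels, col_labels=gbi.col_labels)


def permute_stream(
    gbi: GBIMatrix,
    n_permutations: int = 1000,
    swaps_per_permutation: int = 1,
    constraint: SwapConstraint | None = None,
    seed: int | np.random.SeedSequence = 0,
    burn_in: int = 0,
) -> Iterator[GBIMatrix]:
    """Yield a sequential chain of margin-preserving permutations.

    Permutation k applies ``swaps_per_permutation`` swaps to the state left
    by permutation k-1 (the chain starts from the observed matrix, after an
    optional ``burn_in`` of unsampled swaps).  Fully reproducible from the
    seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    constraint = constraint or SwapConstraint.single_block(gbi.col_labels)
    col_blocks = constraint.column_blocks(gbi.col_labels)
    rng = np.random.default_rng(seed)
    entries = gbi.entries.copy()
    for _ in range(burn_in):
        _swap_inplace(entries, col_blocks, rng)
    for _ in range(n_permutations):
        for _ in range(swaps_per_permutation):
            _swap_inplace(entries, col_blocks, rng)
        yield GBIMatrix(
            entries=entries.copy(),
            row_labels=gbi.row_labels,
            col_labels=gbi.col_labels,
        )


def period_coefficient(
    pre_values: Sequence[float], post_values: Sequence[float]
) -> float:
    """OLS slope of metric on a 0/1 period indicator (pre=0, post=1).

    With a binary predictor this equals mean(post) - mean(pre); computed that
    way for speed and exactness.
    """
    if len(pre_values) == 0 or len(post_values) == 0:
        raise ValueError("both periods need at least one value")
    return float(np.mean(post_values) - np.mean(pre_values))


def permutation_pvalue(
    observed: float, nulls: Sequence[float], tail: Tail = "greater"
) -> float:
    """One-tailed permutation P with the add-one rule: (1 + k) / (1 + n).

    k counts null coefficients at least as extreme as the observed one in the
    direction of *tail*; the add-one correction keeps p > 0 (the smallest
    attainable p at n permutations is 1/(n+1))."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if tail == "greater":
        k = int(np.sum(nulls >= observed))
    elif tail == "less":
        k = int(np.sum(nulls <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + k) / (1 + nulls.size)


def _metric_values(gbi: GBIMatrix, metric: Metric) -> np.ndarray:
    if metric == "weighted_degree":
        return simple_ratio_index(gbi).weights.sum(axis=1)
    if metric == "mean_group_size":
        sizes = gbi.group_sizes().astype(float)
        counts = gbi.sighting_counts().astype(float)
        return (gbi.entries * sizes[:, None]).sum(axis=0) / counts
    raise ValueError(f"unknown metric {metric!r}")


def run_scenario_test(
    pre_gbi: GBIMatrix,
    post_gbi: GBIMatrix,
    metric: Metric = "weighted_degree",
    n_permutations: int = 1000,
    swaps_per_permutation: int = 1,
    tail: Tail = "greater",
    seed: int = 0,
    burn_in: int = 0,
    label: str = "",
) -> PermutationResult:
    """Permutation test of a pre/post metric shift within one treatment arm.

    The observed coefficient comes from the observed matrices.  Each period's
    stream is permuted in its own chain (child seeds split from the master
    seed), the metric is recomputed for every retained individual, and the
    slope refit, building the null coefficient distribution.
    """
    if metric not in ("weighted_degree", "mean_group_size"):
        raise ValueError(f"unknown metric {metric!r}")
    observed = period_coefficient(
        _metric_values(pre_gbi, metric), _metric_values(post_gbi, metric)
    )
    # spawn keys 101/102 keep these streams disjoint from the synthetic
    # generator's streams (keys 1-3) even when one seed drives both
    pre_seed = np.random.SeedSequence(entropy=seed, spawn_key=(101,))
    post_seed = np.random.SeedSequence(entropy=seed, spawn_key=(102,))
    pre_chain = permute_stream(
        pre_gbi, n_permutations, swaps_per_permutation, seed=pre_seed, burn_in=burn_in
    )
    post_chain = permute_stream(
        post_gbi, n_permutations, swaps_per_permutation, seed=post_seed, burn_in=burn_in
    )
    null_coefs = np.empty(n_permutations)
    for k, (pre_perm, post_perm) in enumerate(zip(pre_chain, post_chain)):
        null_coefs[k] = period_coefficient(
            _metric_values(pre_perm, metric), _metric_values(post_perm, metric)
        )
    p = permutation_pvalue(observed, null_coefs, tail)
    return PermutationResult(
        label=label,
        metric=metric,
        observed_coef=observed,
        null_coefs=null_coefs,
        p_one_tailed=p,
        tail=tail,
        n_permutations=n_permutations,
        swaps_per_permutation=swaps_per_permutation,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# BACI driver


@dataclass(frozen=True)
class BaciConfig:
    """Knobs for the before-after-control-impact analysis.

    ``tails`` give the expected direction of the degree shift per arm: the
    impact (affected) arm is predicted to gain connectivity after the fire,
    the control (unaffected) arm is not.
    """

    arms: tuple[str, ...] = ("affected", "unaffected")
    affected_radius_m: float = 100.0
    unaffected_radius_m: float = 500.0
    min_sightings: int = 2
    n_permutations: int = 1000
    swaps_per_permutation: int = 1
    burn_in: int = 0
    tails: tuple[tuple[str, Tail], ...] = (("affected", "greater"), ("unaffected", "less"))
    metrics: tuple[Metric, ...] = ("weighted_degree", "mean_group_size")
    seed: int = 0

    def tail_for(self, arm: str) -> Tail:
        return dict(self.tails).get(arm, "greater")


@dataclass(frozen=True)
class BaciResult:
    comparisons: tuple[ScenarioComparison, ...]
    tests: tuple[PermutationResult, ...]
    summary: tuple[dict, ...]  # Table-1-style cells: scenario, period, n, mean, sd
    missing: tuple[str, ...]
    gbis: dict = field(default_factory=dict)  # (arm, period) -> GBIMatrix


def child_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and an index key."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _restrict_members(observations, members: set[str]):
    from .data_io import GroupObservation

    out = []
    for obs in observations:
        kept = obs.members & members
        if kept:
            out.append(
                GroupObservation(
                    group_id=obs.group_id,
                    obs_date=obs.obs_date,
                    location=obs.location,
                    members=frozenset(kept),
                    source=obs.source,
                )
            )
    return out


def run_baci(observations, scar, windows, config: BaciConfig = BaciConfig()) -> BaciResult:
    """Run the full BACI analysis on a season of group sightings.

    Individuals are classified affected / unaffected / excluded from their
    sighting locations relative to the fire scar; one network is built per
    (arm, period) cell from the window's observations restricted to that
    arm's individuals; each arm then gets a data-stream permutation test per
    metric.  Empty cells are reported as missing and the run continues.

    Parameters
    ----------
    windows
        Mapping ``{"pre": StudyWindow, "post": StudyWindow}``.
    """
    from .data_io import Treatment, classify_population
    from .network_core import EmptyNetworkError, build_gbi

    assignments = classify_population(
        observations, scar, config.affected_radius_m, config.unaffected_radius_m
    )
    arm_members = {
        "affected": {i for i, a in assignments.items() if a.treatment is Treatment.AFFECTED},
        "unaffected": {i for i, a in assignments.items() if a.treatment is Treatment.UNAFFECTED},
    }

    gbis: dict[tuple[str, str], GBIMatrix] = {}
    missing: list[str] = []
    for arm in config.arms:
        for period in ("pre", "post"):
            if period not in windows:
                missing.append(f"{arm}-{period}")
                continue
            from .data_io import slice_window

            obs = slice_window(observations, windows[period])
            obs = _restrict_members(obs, arm_members[arm])
            if not obs:
                missing.append(f"{arm}-{period}")
                continue
            try:
                gbis[(arm, period)] = build_gbi(obs, min_sightings=config.min_sightings)
            except EmptyNetworkError:
                missing.append(f"{arm}-{period}")

    comparisons: list[ScenarioComparison] = []
    tests: list[PermutationResult] = []
    summary: list[dict] = []
    for arm_idx, arm in enumerate(config.arms):
        pre = gbis.get((arm, "pre"))
        post = gbis.get((arm, "post"))
        for period, gbi in (("pre", pre), ("post", post)):
            if gbi is None:
                continue
            deg = _metric_values(gbi, "weighted_degree")
            summary.append(
                {
                    "scenario": arm,
                    "period": period,
                    "n": int(gbi.n_individuals),
                    "mean_weighted_degree": float(np.mean(deg)),
                    "sd_weighted_degree": float(np.std(deg, ddof=1)) if len(deg) > 1 else 0.0,
                }
            )
        if pre is None or post is None:
            continue
        for metric_idx, metric in enumerate(config.metrics):
            comparisons.append(
                ScenarioComparison(
                    label=arm,
                    metric=metric,
                    pre_values=tuple(float(v) for v in _metric_values(pre, metric)),
                    post_values=tuple(float(v) for v in _metric_values(post, metric)),
                )
            )
            tests.append(
                run_scenario_test(
                    pre,
                    post,
                    metric=metric,
                    n_permutations=config.n_permutations,
                    swaps_per_permutation=config.swaps_per_permutation,
                    tail=config.tail_for(arm),
                    seed=child_seed(config.seed, arm_idx, metric_idx),
                    burn_in=config.burn_in,
                    label=arm,
                )
            )
    return BaciResult(
        comparisons=tuple(comparisons),
        tests=tuple(tests),
        summary=tuple(summary),
        missing=tuple(missing),
        gbis=gbis,
    )
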