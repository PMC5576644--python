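"""Synthetic group-sighting, fire-scar and vegetation data.

The generator emulates a color-banded songbird population on a savanna study
site through one fire season: individuals hold static home-range centers on
a ~700 ha site, a fire scar burns a configurable fraction of the site, and
on each observation day the individuals of each treatment arm are
partitioned into foraging groups by a companion-preference process.  A
post-fire response is injected in the affected arm as a group-size
multiplier (birds congregating in remaining habitat) and a sharpening of
companion reuse; the control arm can be given a small drift.  Vegetation
plots draw grass cover from beta distributions snapped to the 5% field
grain, with a post-fire reduction and a configurable used-over-random shift.

All randomness flows from ``config.seed`` through named child streams, so
every artefact is byte-reproducible; generated data round-trip exactly
through the readers in :mod:`firenet.data_io`.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import Polygon, box

from .data_io import (
    FireScar,
    GroupObservation,
    SightingSource,
    StudyWindow,
    VegPlot,
)

#: 2013-season study windows: ~6 weeks each side of the fire.
DEFAULT_WINDOWS = {
    "pre": StudyWindow("pre", dt.date(2013, 5, 15), dt.date(2013, 6, 28)),
    "post": StudyWindow("post", dt.date(2013, 7, 13), dt.date(2013, 8, 24)),
}
DEFAULT_BURN_DATE = dt.date(2013, 7, 5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic fire season.

    Defaults echo the field setting: ~60 banded individuals split evenly
    across a burn boundary on a 700 ha site of which 30% burns, 32
    observation days per ~6-week period, baseline foraging groups of mean
    size 3, and a post-fire response in the affected arm only.
    """

    n_individuals: int = 60
    frac_affected: float = 0.5
    n_obs_days_pre: int = 32
    n_obs_days_post: int = 32
    groups_per_day: int = 3  # recorded groups per arm per day (survey effort)
    baseline_mean_group_size: float = 3.0
    post_group_size_multiplier_affected: float = 1.6
    post_association_concentration: float = 2.0
    unaffected_post_drift: float = 1.0  # control-arm post group-size multiplier
    companion_strength: float = 1.0  # baseline preferred-companion sharpness
    site_area_ha: float = 700.0
    scar_fraction: float = 0.3
    grass_pre_mean: float = 60.0
    grass_post_mean: float = 30.0
    used_vs_random_post_shift: float = 20.0
    grass_concentration: float = 8.0  # beta distribution concentration
    n_used_plots: int = 106
    n_random_plots: int = 152
    mistnet_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if not 0 <= self.frac_affected <= 1:
            raise ValueError("frac_affected outside [0, 1]")
        for name in ("n_obs_days_pre", "n_obs_days_post", "groups_per_day",
                     "n_used_plots", "n_random_plots"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.baseline_mean_group_size < 1:
            raise ValueError("baseline_mean_group_size must be >= 1")
        if self.post_group_size_multiplier_affected <= 0:
            raise ValueError("post_group_size_multiplier_affected must be > 0")
        if self.post_association_concentration < 0:
            raise ValueError("post_association_concentration must be >= 0")
        for name in ("grass_pre_mean", "grass_post_mean"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} outside [0, 100]")

    @classmethod
    def neutral(cls, **overrides) -> "SyntheticConfig":
        """A null configuration: exchangeable group membership, no period
        effect anywhere (for type-I-error calibration)."""
        base = dict(
            post_group_size_multiplier_affected=1.0,
            post_association_concentration=0.0,
            unaffected_post_drift=1.0,
            companion_strength=0.0,
            used_vs_random_post_shift=0.0,
            grass_post_mean=overrides.get("grass_pre_mean", cls.grass_pre_mean),
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class Individual:
    individual_id: str
    arm: str  # "affected" or "unaffected"
    center: tuple[float, float]


@dataclass(frozen=True)
class Population:
    individuals: tuple[Individual, ...]
    scar: FireScar
    site_side_m: float

    def arm_members(self, arm: str) -> list[Individual]:
        return [ind for ind in self.individuals if ind.arm == arm]


@dataclass(frozen=True)
class SyntheticTruth:
    """What the generator actually injected, for parameter-recovery checks."""

    arm_of: dict
    expected_degree_direction: dict  # arm -> -1 / 0 / +1
    expected_group_size_direction: dict
    grass_pre_mean: float
    grass_post_mean: float
    used_vs_random_post_shift: float

    def to_dict(self) -> dict:
        return {
            "arm_of": dict(sorted(self.arm_of.items())),
            "expected_degree_direction": self.expected_degree_direction,
            "expected_group_size_direction": self.expected_group_size_direction,
            "grass_pre_mean": self.grass_pre_mean,
            "grass_post_mean": self.grass_post_mean,
            "used_vs_random_post_shift": self.used_vs_random_post_shift,
        }


def _stream(config: SyntheticConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


# spawn keys for the independent random streams
_POPULATION, _SIGHTINGS, _VEG = 1, 2, 3

# home-range centers stay this far inside their zone so that sighting jitter
# (clipped below) cannot cross the 100 m / 500 m classification buffers
_CENTER_MARGIN = 60.0
_JITTER_SD = 20.0
_JITTER_CLIP = 50.0
_UNAFFECTED_GAP = 600.0  # centers at least this far from the scar


def generate_population(config: SyntheticConfig) -> Population:
    """Lay out the site, the fire scar, and individual home-range centers.

    The scar is a rectangle covering ``scar_fraction`` of the square site.
    Affected centers fall inside the scar with a safety margin; unaffected
    centers sit beyond the 500 m buffer, so the distance-rule classifier
    recovers the arms exactly.
    """
    rng = _stream(config, _POPULATION)
    side = math.sqrt(config.site_area_ha * 10_000.0)
    scar_width = config.scar_fraction * side
    scar_poly = box(0.0, 0.0, scar_width, side)
    scar = FireScar(polygons=(scar_poly,), burn_date=DEFAULT_BURN_DATE)

    n_affected = int(round(config.n_individuals * config.frac_affected))
    n_unaffected = config.n_individuals - n_affected
    if 0 < config.frac_affected < 1 and (n_affected < 2 or n_unaffected < 2):
        raise ValueError(
            "frac_affected leaves an arm with fewer than 2 individuals"
        )
    if scar_width <= 2 * _CENTER_MARGIN:
        raise ValueError("scar too narrow for home-range placement margins")
    width = max(2, 1 + int(math.log10(max(config.n_individuals, 1))))
    individuals: list[Individual] = []
    for i in range(n_affected):
        x = rng.uniform(_CENTER_MARGIN, scar_width - _CENTER_MARGIN)
        y = rng.uniform(_CENTER_MARGIN, side - _CENTER_MARGIN)
        individuals.append(Individual(f"A{i:0{width}d}", "affected", (x, y)))
    for i in range(n_unaffected):
        x = rng.uniform(scar_width + _UNAFFECTED_GAP + _CENTER_MARGIN, side - _CENTER_MARGIN)
        y = rng.uniform(_CENTER_MARGIN, side - _CENTER_MARGIN)
        individuals.append(Individual(f"U{i:0{width}d}", "unaffected", (x, y)))
    return Population(individuals=tuple(individuals), scar=scar, site_side_m=side)


def _truncated_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (>= 1)."""
    if mean <= 1.0 + 1e-9:
        return 1e-9
    return brentq(
        lambda lam: lam / (1.0 - math.exp(-lam)) - mean, 1e-9, 10.0 * mean
    )


def _sample_group_size(mean: float, cap: int, rng: np.random.Generator) -> int:
    lam = _truncated_poisson_lambda(mean)
    for _ in range(1000):
        k = rng.poisson(lam)
        if 1 <= k <= cap:
            return int(k)
    return 1


def _partition_into_groups(
    members: list[int],
    affinity: np.ndarray,
    mean_size: float,
    strength: float,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Partition a day's individuals into groups by companion preference.

    A seed individual starts each group; further members join with
    probability proportional to exp(strength x mean affinity to the current
    group).  strength 0 gives uniformly random (exchangeable) groups.
    """
    pool = list(members)
    rng.shuffle(pool)
    groups: list[list[int]] = []
    while pool:
        seed_ind = pool.pop()
        size = _sample_group_size(mean_size, cap=len(pool) + 1, rng=rng)
        group = [seed_ind]
        while len(group) < size and pool:
            if strength == 0.0:
                pick = int(rng.integers(len(pool)))
            else:
                scores = affinity[np.ix_(group, pool)].mean(axis=0)
                logits = strength * scores
                logits -= logits.max()
                probs = np.exp(logits)
                probs /= probs.sum()
                pick = int(rng.choice(len(pool), p=probs))
            group.append(pool.pop(pick))
        groups.append(group)
    return groups


def _window_days(
    window: StudyWindow, n_days: int, rng: np.random.Generator
) -> list[dt.date]:
    all_days = [
        window.start_date + dt.timedelta(days=k)
        for k in range((window.end_date - window.start_date).days + 1)
    ]
    if n_days > len(all_days):
        raise ValueError(
            f"{n_days} observation days requested but window holds {len(all_days)}"
        )
    chosen = rng.choice(len(all_days), size=n_days, replace=False)
    return [all_days[k] for k in sorted(chosen)]


def generate_sightings(
    population: Population,
    config: SyntheticConfig,
    windows: dict[str, StudyWindow] | None = None,
) -> list[GroupObservation]:
    """Simulate the season's group observations.

    Per observation day and arm, every individual joins a group via the
    companion-preference partition; survey effort records at most
    ``groups_per_day`` randomly chosen groups per arm, so each individual is
    sighted on a random subset of days (and some can fail the two-sighting
    inclusion filter).  Post-fire, the affected arm's group-size mean is
    scaled by ``post_group_size_multiplier_affected`` and its companion
    reuse sharpened by ``post_association_concentration``.
    """
    windows = windows or DEFAULT_WINDOWS
    rng = _stream(config, _SIGHTINGS)
    arms = sorted({ind.arm for ind in population.individuals})
    # latent pairwise affinities, one symmetric matrix per arm, fixed all season
    affinities: dict[str, np.ndarray] = {}
    arm_inds: dict[str, list[Individual]] = {}
    for arm in arms:
        inds = population.arm_members(arm)
        arm_inds[arm] = inds
        z = rng.standard_normal((len(inds), len(inds)))
        affinities[arm] = (z + z.T) / math.sqrt(2.0)

    day_plan = [
        ("pre", d)
        for d in _window_days(windows["pre"], config.n_obs_days_pre, rng)
    ] + [
        ("post", d)
        for d in _window_days(windows["post"], config.n_obs_days_post, rng)
    ]

    observations: list[GroupObservation] = []
    counter = 0
    for period, day in day_plan:
        for arm in arms:
            inds = arm_inds[arm]
            if not inds:
                continue
            mean_size = config.baseline_mean_group_size
            strength = config.companion_strength
            if period == "post":
                if arm == "affected":
                    mean_size *= config.post_group_size_multiplier_affected
                    strength += config.post_association_concentration
                else:
                    mean_size *= config.unaffected_post_drift
            mean_size = max(1.0, min(mean_size, float(len(inds))))
            groups = _partition_into_groups(
                list(range(len(inds))), affinities[arm], mean_size, strength, rng
            )
            n_record = min(config.groups_per_day, len(groups))
            recorded = rng.choice(len(groups), size=n_record, replace=False)
            for gi in sorted(recorded):
                members = [inds[k] for k in groups[gi]]
                cx = float(np.mean([m.center[0] for m in members]))
                cy = float(np.mean([m.center[1] for m in members]))
                jx, jy = np.clip(
                    rng.normal(0.0, _JITTER_SD, size=2), -_JITTER_CLIP, _JITTER_CLIP
                )
                counter += 1
                source = (
                    SightingSource.MISTNET
                    if rng.random() < config.mistnet_fraction
                    else SightingSource.RESIGHT
                )
                observations.append(
                    GroupObservation(
                        group_id=f"g{counter:05d}",
                        obs_date=day,
                        location=(cx + float(jx), cy + float(jy)),
                        members=frozenset(m.individual_id for m in members),
                        source=source,
                    )
                )
    return observations


def generate_veg_plots(config: SyntheticConfig) -> list[VegPlot]:
    """Simulate grass-cover surveys on used and random plots.

    Cover is beta-distributed (rescaled to percent, snapped to the 5% field
    grain).  Pre-fire, used and random plots share one distribution; the
    post-fire mean drops to ``grass_post_mean`` for random plots while used
    plots sit ``used_vs_random_post_shift`` above them (habitat selection
    for remaining grass).
    """
    rng = _stream(config, _VEG)
    kappa = config.grass_concentration

    def draw(mean_pct: float, n: int) -> list[float]:
        mu = min(max(mean_pct / 100.0, 0.02), 0.98)
        vals = rng.beta(mu * kappa, (1 - mu) * kappa, size=n) * 100.0
        snapped = np.clip(np.round(vals / 5.0) * 5.0, 0.0, 100.0)
        return [float(v) for v in snapped]

    n_used_pre = config.n_used_plots // 2
    n_used_post = config.n_used_plots - n_used_pre
    n_rand_pre = config.n_random_plots // 2
    n_rand_post = config.n_random_plots - n_rand_pre

    plots: list[VegPlot] = []
    for cover in draw(config.grass_pre_mean, n_used_pre):
        plots.append(VegPlot("used", "pre", cover))
    for cover in draw(config.grass_pre_mean, n_rand_pre):
        plots.append(VegPlot("random", "pre", cover))
    post_used_mean = min(config.grass_post_mean + config.used_vs_random_post_shift, 100.0)
    for cover in draw(post_used_mean, n_used_post):
        plots.append(VegPlot("used", "post", cover))
    for cover in draw(config.grass_post_mean, n_rand_post):
        plots.append(VegPlot("random", "post", cover))
    return plots


def _direction(multiplier: float, concentration: float) -> int:
    if multiplier > 1 or concentration > 0:
        return 1
    if multiplier < 1:
        return -1
    return 0


def make_truth(population: Population, config: SyntheticConfig) -> SyntheticTruth:
    return SyntheticTruth(
        arm_of={ind.individual_id: ind.arm for ind in population.individuals},
        expected_degree_direction={
            "affected": _direction(
                config.post_group_size_multiplier_affected,
                config.post_association_concentration,
            ),
            "unaffected": _direction(config.unaffected_post_drift, 0.0),
        },
        expected_group_size_direction={
            "affected": _direction(config.post_group_size_multiplier_affected, 0.0),
            "unaffected": _direction(config.unaffected_post_drift, 0.0),
        },
        grass_pre_mean=config.grass_pre_mean,
        grass_post_mean=config.grass_post_mean,
        used_vs_random_post_shift=config.used_vs_random_post_shift,
    )


def generate_dataset(
    config: SyntheticConfig, windows: dict[str, StudyWindow] | None = None
):
    """Generate the full bundle: population, sightings, vegetation, truth."""
    windows = windows or DEFAULT_WINDOWS
    population = generate_population(config)
    observations = generate_sightings(population, config, windows)
    veg = generate_veg_plots(config)
    truth = make_truth(population, config)
    return population, observations, veg, truth
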