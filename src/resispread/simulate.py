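"""Spatially explicit individual-based gene-flow simulation with selection.

The simulator follows the CDPOP design: a fixed set of point locations on a
landscape, each either vacant or holding one individual; mating and offspring
dispersal are probabilistic functions of the pairwise cost distance between
locations (an inverse-square kernel truncated at a maximum dispersal
threshold d_max).  Selection acts on offspring viability at a single
biallelic locus (adaptive allele A, neutral allele a): relative survival is
1 for aa, 1 + h*s for Aa and 1 + s for AA.

Annual cycle (one call to :func:`step_year`):

1. ageing — every individual's age increases; individuals beyond the last
   age class die;
2. mortality — each individual dies with its age-class mortality rate,
   vacating its location;
3. mating — each surviving female mates with probability equal to her
   age-class fecundity; her mate is drawn among males within d_max with
   inverse-square cost-distance weights (males may mate repeatedly,
   females once); each mating yields a single offspring with Mendelian
   inheritance at every locus and 1:1 offspring sex ratio;
4. offspring viability selection — each offspring survives with probability
   min(1, v_base * w(genotype));
5. settlement — surviving offspring are assigned, in random order, to vacant
   locations drawn with inverse-square weights from the mother's location;
   offspring with no reachable vacancy (or arriving after vacancies fill)
   are discarded.

Generations overlap; population size can never exceed the number of
locations and locations never move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    CapacityError,
    ConfigurationError,
    ExtinctionSignal,
    PairwiseMatrix,
    RasterGrid,
)

__all__ = [
    "SimConfig",
    "SimState",
    "SimResult",
    "default_mortality",
    "default_fecundity",
    "stable_age_distribution",
    "auto_v_base",
    "place_individuals",
    "place_individuals_n",
    "init_state",
    "init_novel_allele",
    "init_preexisting_allele",
    "dispersal_weights",
    "viability_weights",
    "step_year",
    "run_years",
    "run_experiment",
]


def bracket_dispersal_thresholds(base: float) -> tuple[int, float, int]:
    """Low/medium/high dispersal thresholds bracketing a base estimate.

    Low is half the base (truncated toward zero to integer cost units),
    high is double; e.g. 534861 -> (267430, 534861, 1069722).
    """
    if base <= 0:
        raise ConfigurationError("base dispersal threshold must be > 0")
    return int(base / 2), base, int(base * 2)


def default_mortality(n_age_classes: int = 17) -> np.ndarray:
    """Age-class mortality rates (placeholder literature-style schedule).

    First-year survival 0.60; survival 0.90 for ages 1-9 declining linearly
    to 0.50 at the last age class.  Fully config-overridable.
    """
    surv = np.empty(n_age_classes)
    surv[0] = 0.60
    surv[1:10] = 0.90
    last = n_age_classes - 1
    for a in range(10, n_age_classes):
        surv[a] = 0.90 - (0.90 - 0.50) * (a - 9) / (last - 9)
    return 1.0 - surv


def default_fecundity(n_age_classes: int = 17) -> np.ndarray:
    """Female per-year mating probability by age class (placeholder)."""
    f = np.zeros(n_age_classes)
    f[2:14] = 0.9
    f[14:] = 0.5
    return f


@dataclass
class SimConfig:
    """Parameters of one simulation experiment.

    ``s`` is the selection differential (AA offspring-survival increase over
    aa; 0.1 weak, 0.2 moderate, 0.3 strong), ``h`` the dominance coefficient
    (0.5 = additive).  ``d_max`` is the maximum mating/dispersal threshold in
    accumulated-cost units and ``d_floor`` the cost of one cell traversal,
    used in place of zero for same-location distances.
    """

    d_max: float
    d_floor: float
    s: float = 0.0
    h: float = 0.5
    scenario: str = "novel"  # novel | preexisting
    p0: float | None = None  # default: 0.01 novel, 0.05 preexisting
    cluster_fraction: float = 0.02
    dispersal_exponent: float = 2.0
    years: int = 100
    n_replicates: int = 50
    density: float = 0.2  # individuals per km^2
    n_age_classes: int = 17
    mortality: np.ndarray | None = None
    fecundity: np.ndarray | None = None
    male_with_replacement: bool = True
    offspring_per_mating: int = 1
    mutation_rate: float = 0.0
    v_base: float | None = None  # None -> balanced automatically
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ConfigurationError("selection differential s must be >= 0")
        if not 0 <= self.h <= 1:
            raise ConfigurationError("dominance h must lie in [0, 1]")
        if self.scenario not in ("novel", "preexisting"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.p0 is None:
            self.p0 = 0.01 if self.scenario == "novel" else 0.05
        if not 0 <= self.p0 < 1:
            raise ConfigurationError("p0 must lie in [0, 1)")
        if self.d_max <= 0 or self.d_floor <= 0:
            raise ConfigurationError("d_max and d_floor must be > 0")
        if self.mutation_rate != 0:
            raise ConfigurationError("only mutation_rate = 0 is supported")
        if self.mortality is None:
            self.mortality = default_mortality(self.n_age_classes)
        else:
            self.mortality = np.asarray(self.mortality, dtype=float)
        if self.fecundity is None:
            self.fecundity = default_fecundity(self.n_age_classes)
        else:
            self.fecundity = np.asarray(self.fecundity, dtype=float)
        if len(self.mortality) != self.n_age_classes or len(self.fecundity) != self.n_age_classes:
            raise ConfigurationError("schedules must have length n_age_classes")


def stable_age_distribution(mortality: np.ndarray) -> np.ndarray:
    """Age distribution proportional to survivorship l_x under the schedule."""
    surv = 1.0 - np.asarray(mortality, dtype=float)
    lx = np.concatenate([[1.0], np.cumprod(surv[:-1])])
    return lx / lx.sum()


_OVERPRODUCTION = 1.4  # surplus births; settlement (vacancy filling) regulates


def auto_v_base(config: SimConfig) -> float:
    """Baseline offspring viability balancing recruits against deaths.

    At the stable age distribution, per-capita annual deaths are matched by
    per-capita surviving offspring, times a modest surplus so that offspring
    lost to unreachable or already-filled vacancies do not drive a decline;
    settlement then acts as the density regulator, keeping the population
    near capacity.
    """
    pi = stable_age_distribution(config.mortality)
    n = config.n_age_classes
    # death prob for an individual entering the year at age x: it ages to
    # x + 1, dying if that exceeds the last class, else with m[x + 1]
    death = np.array(
        [1.0 if x + 1 >= n else config.mortality[x + 1] for x in range(n)]
    )
    d = float(pi @ death)
    b = 0.5 * float(pi @ config.fecundity)  # half the population is female
    if b <= 0:
        raise ConfigurationError("fecundity schedule produces no offspring")
    return min(1.0, _OVERPRODUCTION * d / b)


@dataclass
class SimState:
    """Occupancy and genotypes at a fixed set of locations."""

    locations: np.ndarray  # (M, 2), never changes
    occupied: np.ndarray  # (M,) bool
    sex: np.ndarray  # (M,) 0 = male, 1 = female
    age: np.ndarray  # (M,)
    sel: np.ndarray  # (M, 2) alleles at selected locus, 1 = A
    neutral: np.ndarray | None = None  # (M, L, 2) allele states
    year: int = 0

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def pop_size(self) -> int:
        return int(self.occupied.sum())

    def allele_count_A(self) -> int:
        return int(self.sel[self.occupied].sum())


# ---------------------------------------------------------------------------
# initialisation


def place_individuals(habitat_mask: RasterGrid, density: float, seed) -> np.ndarray:
    """Uniform random locations in habitat at a constant density (per km^2).

    Returns an (n, 2) array of cell-centre coordinates, at most one
    individual per habitat cell.
    """
    cells = np.argwhere(habitat_mask.values == 1)
    if len(cells) == 0:
        raise CapacityError("habitat mask is empty")
    area_km2 = len(cells) * habitat_mask.cell_area_km2()
    n = int(round(density * area_km2))
    return _sample_cells(habitat_mask, cells, n, seed)


def place_individuals_n(habitat_mask: RasterGrid, n: int, seed) -> np.ndarray:
    """Place exactly ``n`` individuals uniformly on habitat cells."""
    cells = np.argwhere(habitat_mask.values == 1)
    return _sample_cells(habitat_mask, cells, n, seed)


def _sample_cells(mask: RasterGrid, cells: np.ndarray, n: int, seed) -> np.ndarray:
    if n > len(cells):
        raise CapacityError(f"requested {n} individuals but habitat has {len(cells)} cells")
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, 2))
    pick = cells[rng.choice(len(cells), size=n, replace=False)]
    return mask.cell_centers(pick[:, 0], pick[:, 1])


def init_state(
    locations: np.ndarray,
    config: SimConfig,
    seed,
    neutral_freqs: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> SimState:
    """Fully occupied starting state: random 1:1 sexes, stable-age ages,
    all-aa selected locus, optional neutral genotypes drawn i.i.d. from
    per-locus (states, frequencies)."""
    rng = np.random.default_rng(seed)
    locations = np.asarray(locations, dtype=float)
    m = len(locations)
    sex = rng.integers(0, 2, size=m).astype(np.int8)
    pi = stable_age_distribution(config.mortality)
    age = rng.choice(config.n_age_classes, size=m, p=pi).astype(np.int16)
    sel = np.zeros((m, 2), dtype=np.int8)
    neutral = None
    if neutral_freqs is not None:
        neutral = np.empty((m, len(neutral_freqs), 2), dtype=np.int32)
        for l, (states, freqs) in enumerate(neutral_freqs):
            neutral[:, l, :] = rng.choice(states, size=(m, 2), p=freqs)
    return SimState(
        locations=locations,
        occupied=np.ones(m, dtype=bool),
        sex=sex,
        age=age,
        sel=sel,
        neutral=neutral,
        year=0,
    )


def init_novel_allele(
    state: SimState,
    cost: PairwiseMatrix | np.ndarray,
    cluster_fraction: float = 0.02,
    seed=0,
    centroid: tuple[float, float] | None = None,
) -> SimState:
    """Seed a localized cluster of adaptive alleles near the region centre.

    The seed individual is the occupied location nearest the habitat
    centroid; the cluster is the seed plus its ceil(f*N) - 1 nearest occupied
    neighbours by cost distance.  Exactly half the cluster's allele copies
    are set to A, arranged as the rounded Hardy-Weinberg genotype counts for
    p = 0.5 (1/4 AA, 1/2 Aa, 1/4 aa); everyone else is aa.
    """
    rng = np.random.default_rng(seed)
    cost_values = cost.values if isinstance(cost, PairwiseMatrix) else np.asarray(cost)
    occ = np.flatnonzero(state.occupied)
    n = len(occ)
    k = int(math.ceil(cluster_fraction * n))
    if k > n:
        raise ConfigurationError("cluster larger than population")
    if centroid is None:
        centroid = state.locations[occ].mean(axis=0)
    d_centroid = np.linalg.norm(state.locations[occ] - np.asarray(centroid), axis=1)
    seed_local = int(np.argmin(d_centroid))
    order = np.argsort(cost_values[occ[seed_local]][occ], kind="stable")
    order = order[order != seed_local]
    cluster_local = np.concatenate([[seed_local], order[: k - 1]])
    cluster = occ[cluster_local.astype(int)]

    n_aa = int(round(k / 4))
    n_AA = int(round(k / 4))
    n_Aa = k - n_AA - n_aa
    genos = np.array([2] * n_AA + [1] * n_Aa + [0] * n_aa)
    rng.shuffle(genos)
    state.sel[:, :] = 0
    for idx, g in zip(cluster, genos):
        if g == 2:
            state.sel[idx] = (1, 1)
        elif g == 1:
            state.sel[idx] = (1, 0)
    return state


def init_preexisting_allele(state: SimState, p0: float = 0.05, seed=0) -> SimState:
    """Distribute round(2*N*p0) adaptive-allele copies uniformly at random
    over the population's 2N allele slots (standing variation)."""
    rng = np.random.default_rng(seed)
    occ = np.flatnonzero(state.occupied)
    n = len(occ)
    n_copies = int(round(2 * n * p0))
    slots = np.zeros(2 * n, dtype=np.int8)
    slots[:n_copies] = 1
    rng.shuffle(slots)
    state.sel[:, :] = 0
    state.sel[occ] = slots.reshape(n, 2)
    return state


# ---------------------------------------------------------------------------
# annual cycle


def dispersal_weights(
    cost_row: np.ndarray,
    d_max: float,
    d_floor: float,
    exponent: float = 2.0,
) -> np.ndarray | None:
    """Normalised inverse-power dispersal kernel over candidate distances.

    weight(d) = 1 / max(d, d_floor)**exponent for d <= d_max, else 0.
    Returns ``None`` when no candidate has positive weight.
    """
    d = np.asarray(cost_row, dtype=float)
    if np.any(d < 0):
        raise ConfigurationError("cost distances must be >= 0")
    w = 1.0 / np.maximum(d, d_floor) ** exponent
    w[d > d_max] = 0.0
    total = w.sum()
    if total == 0:
        return None
    return w / total


def _raw_weights(d: np.ndarray, config: SimConfig) -> np.ndarray:
    w = 1.0 / np.maximum(d, config.d_floor) ** config.dispersal_exponent
    w[d > config.d_max] = 0.0
    return w


def viability_weights(genotype, s: float, h: float = 0.5):
    """Relative offspring survival by count of A alleles (0, 1, 2)."""
    count = np.asarray(genotype)
    if np.any((count < 0) | (count > 2)):
        raise ConfigurationError("genotype must be the A-allele count (0, 1 or 2)")
    return 1.0 + s * np.where(count == 2, 1.0, np.where(count == 1, h, 0.0))


def _mendelian_pick(geno: np.ndarray, rng) -> np.ndarray:
    """One uniformly chosen allele per row of an (n, 2) genotype array."""
    pick = rng.integers(0, 2, size=len(geno))
    return geno[np.arange(len(geno)), pick]


def step_year(state: SimState, cost, config: SimConfig, rng) -> SimState:
    """Advance the state by one annual cycle (in place; returns the state)."""
    cost_values = cost.values if isinstance(cost, PairwiseMatrix) else np.asarray(cost)
    rng = np.random.default_rng(rng)
    if not state.occupied.any():
        raise ExtinctionSignal(f"population extinct at year {state.year}")
    v_base = config.v_base if config.v_base is not None else auto_v_base(config)

    # 1. ageing
    state.age[state.occupied] += 1
    too_old = state.occupied & (state.age >= config.n_age_classes)
    state.occupied[too_old] = False

    # 2. mortality
    occ = np.flatnonzero(state.occupied)
    dies = rng.random(len(occ)) < config.mortality[state.age[occ]]
    state.occupied[occ[dies]] = False

    # 3. mating
    occ = np.flatnonzero(state.occupied)
    females = occ[state.sex[occ] == 1]
    males = occ[state.sex[occ] == 0]
    offspring: dict | None = None
    if len(females) and len(males):
        mates = rng.random(len(females)) < config.fecundity[state.age[females]]
        mothers = females[mates]
        if len(mothers):
            w = _raw_weights(cost_values[np.ix_(mothers, males)], config)
            totals = w.sum(axis=1)
            ok = totals > 0
            mothers = mothers[ok]
            w = w[ok]
            totals = totals[ok]
        if len(mothers):
            probs = w / totals[:, None]
            if config.male_with_replacement:
                cum = np.cumsum(probs, axis=1)
                draws = rng.random(len(mothers))
                father_idx = (draws[:, None] > cum).sum(axis=1)
                fathers = males[father_idx]
            else:
                fathers = np.empty(len(mothers), dtype=np.int64)
                available = np.ones(len(males), dtype=bool)
                for i in range(len(mothers)):
                    wi = w[i] * available
                    t = wi.sum()
                    if t == 0:
                        fathers[i] = -1
                        continue
                    j = rng.choice(len(males), p=wi / t)
                    fathers[i] = males[j]
                    available[j] = False
                keep = fathers >= 0
                mothers, fathers = mothers[keep], fathers[keep]
        if len(mothers):
            n_off = len(mothers)
            off_sel = np.column_stack(
                [
                    _mendelian_pick(state.sel[mothers], rng),
                    _mendelian_pick(state.sel[fathers], rng),
                ]
            ).astype(np.int8)
            off_neutral = None
            if state.neutral is not None:
                n_loci = state.neutral.shape[1]
                pick_m = rng.integers(0, 2, size=(n_off, n_loci, 1))
                pick_f = rng.integers(0, 2, size=(n_off, n_loci, 1))
                from_m = np.take_along_axis(state.neutral[mothers], pick_m, axis=2)
                from_f = np.take_along_axis(state.neutral[fathers], pick_f, axis=2)
                off_neutral = np.concatenate([from_m, from_f], axis=2)
            offspring = {
                "sel": off_sel,
                "neutral": off_neutral,
                "sex": rng.integers(0, 2, size=n_off).astype(np.int8),
                "natal": mothers.copy(),
            }

    # 4. offspring viability selection
    if offspring is not None:
        w_via = viability_weights(offspring["sel"].sum(axis=1), config.s, config.h)
        p_surv = np.minimum(1.0, v_base * w_via)
        keep = rng.random(len(p_surv)) < p_surv
        for key in ("sel", "sex", "natal"):
            offspring[key] = offspring[key][keep]
        if offspring["neutral"] is not None:
            offspring["neutral"] = offspring["neutral"][keep]

    # 5. settlement
    if offspring is not None and len(offspring["natal"]):
        vacant = ~state.occupied
        order = rng.permutation(len(offspring["natal"]))
        for k in order:
            cand = np.flatnonzero(vacant)
            if len(cand) == 0:
                break
            d = cost_values[offspring["natal"][k], cand]
            w = _raw_weights(d.copy(), config)
            total = w.sum()
            if total == 0:
                continue  # no reachable vacancy: offspring discarded
            target = cand[rng.choice(len(cand), p=w / total)]
            vacant[target] = False
            state.occupied[target] = True
            state.sex[target] = offspring["sex"][k]
            state.age[target] = 0
            state.sel[target] = offspring["sel"][k]
            if state.neutral is not None and offspring["neutral"] is not None:
                state.neutral[target] = offspring["neutral"][k]

    state.year += 1
    return state


def run_years(state: SimState, cost, config: SimConfig, rng, years: int) -> SimState:
    """Run ``years`` annual cycles on one state (used for neutral burn-in)."""
    rng = np.random.default_rng(rng)
    for _ in range(years):
        step_year(state, cost, config, rng)
    return state


# ---------------------------------------------------------------------------
# experiments


@dataclass
class SimResult:
    """Per-replicate yearly records of one simulation experiment."""

    years: np.ndarray  # 0 .. config.years
    fA: np.ndarray  # (n_replicates, years + 1); NaN after extinction
    pop_size: np.ndarray  # (n_replicates, years + 1)
    presence: np.ndarray  # (n_replicates, years + 1, M) bool, >= 1 A copy
    extinct: np.ndarray  # (n_replicates,) bool
    locations: np.ndarray
    config: SimConfig


def run_experiment(
    locations: np.ndarray,
    cost,
    config: SimConfig,
    centroid: tuple[float, float] | None = None,
) -> SimResult:
    """Monte Carlo replicates of adaptive-allele spread on fixed locations.

    Replicate ``r`` is seeded with ``config.seed + r``; every record is
    deterministic given the base seed.  The initial genotypes follow
    ``config.scenario`` (novel localized cluster or pre-existing standing
    variation at frequency p0).
    """
    locations = np.asarray(locations, dtype=float)
    cost_values = cost.values if isinstance(cost, PairwiseMatrix) else np.asarray(cost)
    m = len(locations)
    ny = config.years + 1
    fA = np.full((config.n_replicates, ny), np.nan)
    pop = np.zeros((config.n_replicates, ny), dtype=np.int64)
    presence = np.zeros((config.n_replicates, ny, m), dtype=bool)
    extinct = np.zeros(config.n_replicates, dtype=bool)

    for r in range(config.n_replicates):
        seed_r = config.seed + r
        rng = np.random.default_rng(seed_r)
        state = init_state(locations, config, rng)
        if config.scenario == "novel":
            init_novel_allele(
                state, cost_values, config.cluster_fraction, rng, centroid=centroid
            )
        else:
            init_preexisting_allele(state, config.p0, rng)
        for y in range(ny):
            if y > 0:
                try:
                    step_year(state, cost_values, config, rng)
                except ExtinctionSignal:
                    extinct[r] = True
                    break
            n = state.pop_size
            pop[r, y] = n
            if n:
                fA[r, y] = state.allele_count_A() / (2.0 * n)
            carrier = state.occupied & (state.sel.sum(axis=1) > 0)
            presence[r, y] = carrier
    return SimResult(
        years=np.arange(ny),
        fA=fA,
        pop_size=pop,
        presence=presence,
        extinct=extinct,
        locations=locations,
        config=config,
    )
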