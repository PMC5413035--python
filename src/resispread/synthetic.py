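"""Synthetic landscapes and genotype datasets.

The generators emulate the three study-region archetypes — a single
continuous linear habitat band (canyon-like), a few elongated semi-discrete
patches, and many small discrete patches in a resistant matrix — as slope
rasters in degrees.  Slope fields are a deterministic ridge/blob template on
top of a smoothed Gaussian random field, so the continuity class is
controllable while the texture stays realistic.  Habitat is steep escape
terrain: cells at or above a slope threshold.

Genotype datasets are produced by running the neutral gene-flow simulator
(s = 0) on the landscape for a burn-in period, which guarantees that the
generated isolation-by-resistance structure matches the process the
optimization stage assumes.  Allele states are integers mimicking
dinucleotide microsatellite sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    BoundsError,
    CapacityError,
    ConfigurationError,
    ExtinctionSignal,
    GenotypeTable,
    RasterGrid,
)
from .costs import least_cost_distance
from .resistance import ResistanceSurface
from .simulate import SimConfig, init_state, run_years

CONTINUITY_CLASSES = ("continuous_linear", "elongated_patches", "discrete_patches")

__all__ = [
    "CONTINUITY_CLASSES",
    "LandscapeScenario",
    "make_slope_field",
    "make_barrier",
    "make_habitat_mask",
    "make_scenario",
    "generate_genotype_dataset",
]


@dataclass
class LandscapeScenario:
    """A synthetic landscape: slope raster, habitat mask, optional barrier."""

    continuity_class: str
    slope_raster: RasterGrid
    habitat_mask: RasterGrid
    barrier_raster: RasterGrid | None = None
    seed: int = 0


def _smooth_noise(shape: tuple[int, int], rng, smoothness: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness, mode="reflect")
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _separated_centers(rng, n_pts: int, n_rows: int, n_cols: int, min_sep: float, margin: float):
    """Rejection-sample blob centres with a minimum pairwise separation."""
    centers: list[tuple[float, float]] = []
    for _ in range(4000):
        if len(centers) == n_pts:
            break
        r = rng.uniform(margin * n_rows, (1 - margin) * n_rows)
        c = rng.uniform(margin * n_cols, (1 - margin) * n_cols)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    while len(centers) < n_pts:  # relax separation rather than fail
        centers.append(
            (
                rng.uniform(margin * n_rows, (1 - margin) * n_rows),
                rng.uniform(margin * n_cols, (1 - margin) * n_cols),
            )
        )
    return centers


def _template(continuity_class: str, n_rows: int, n_cols: int, rng) -> np.ndarray:
    """Ridge/blob template in [0, 1]; 1 at patch cores."""
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    scale = min(n_rows, n_cols)
    if continuity_class == "continuous_linear":
        # one sinuous steep band crossing the grid top to bottom
        phase = rng.uniform(0, 2 * np.pi)
        center = n_cols / 2 + 0.12 * n_cols * np.sin(2 * np.pi * rr / n_rows + phase)
        width = max(4.0, n_cols / 12.0)
        return np.exp(-((cc - center) / width) ** 2)
    if continuity_class == "elongated_patches":
        # the continuous band broken into collinear segments with real gaps:
        # elongated patches strung along one axis, the intermediate archetype
        n_b = int(rng.integers(3, 7))
        phase = rng.uniform(0, 2 * np.pi)
        half = n_rows / (2.0 * n_b)
        sigma1 = 0.52 * half  # threshold extent ~0.72 * half: ~28% gaps
        sigma2 = 0.06 * scale
        t = np.zeros((n_rows, n_cols))
        for i in range(n_b):
            r0 = (i + 0.5) / n_b * n_rows + rng.uniform(-0.2, 0.2) * half
            c0 = n_cols / 2 + 0.12 * n_cols * np.sin(2 * np.pi * r0 / n_rows + phase)
            t = np.maximum(
                t, np.exp(-0.5 * (((rr - r0) / sigma1) ** 2 + ((cc - c0) / sigma2) ** 2))
            )
        return t
    if continuity_class == "discrete_patches":
        n_b = int(rng.integers(8, 16))
        sigma = 0.05 * scale
        centers = _separated_centers(rng, n_b, n_rows, n_cols, min_sep=5.5 * sigma, margin=0.08)
        t = np.zeros((n_rows, n_cols))
        for r0, c0 in centers:
            t = np.maximum(
                t, np.exp(-0.5 * (((rr - r0) / sigma) ** 2 + ((cc - c0) / sigma) ** 2))
            )
        return t
    raise ConfigurationError(f"unknown continuity_class {continuity_class!r}")


def make_slope_field(
    n_rows: int,
    n_cols: int,
    cell_size: float,
    continuity_class: str,
    seed: int,
    smoothness: float = 3.0,
) -> RasterGrid:
    """Synthetic slope raster (degrees, [0, 90]) for one continuity class.

    The matrix is gently sloped (< ~16 deg); patch flanks pass through the
    30-60 degree escape-terrain range and patch cores reach ~84 degrees, so
    steepness is informative in both directions.  Deterministic given seed.
    """
    if n_rows < 32 or n_cols < 32:
        raise ConfigurationError("slope field requires dimensions >= 32x32")
    if continuity_class not in CONTINUITY_CLASSES:
        raise ConfigurationError(f"unknown continuity_class {continuity_class!r}")
    rng = np.random.default_rng(seed)
    noise = _smooth_noise((n_rows, n_cols), rng, smoothness)
    template = _template(continuity_class, n_rows, n_cols, rng)
    slope = 4.0 + 12.0 * noise + 68.0 * template
    return RasterGrid(np.clip(slope, 0.0, 90.0), cell_size)


def make_barrier(grid_template: RasterGrid, polyline) -> RasterGrid:
    """Rasterize a polyline into a binary barrier grid.

    The footprint is a 4-connected (supercover) chain of cells, so an
    edge-to-edge polyline splits the remaining cells into two or more
    regions even under 8-connected movement.
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[1] != 2 or len(polyline) < 2:
        raise ConfigurationError("polyline must be a list of >= 2 (x, y) points")
    cells: list[tuple[int, int]] = []
    for (x0, y0), (x1, y1) in zip(polyline[:-1], polyline[1:]):
        seg_len = math.hypot(x1 - x0, y1 - y0)
        n_steps = max(2, int(math.ceil(4 * seg_len / grid_template.cell_size)))
        for t in np.linspace(0, 1, n_steps):
            x = x0 + t * (x1 - x0)
            y = y0 + t * (y1 - y0)
            rc = grid_template.point_to_cell(x, y)  # raises BoundsError outside
            if not cells or cells[-1] != rc:
                cells.append(rc)
    values = np.zeros(grid_template.shape)
    prev = None
    for r, c in cells:
        if prev is not None:
            dr, dc = r - prev[0], c - prev[1]
            if dr != 0 and dc != 0:  # diagonal step: insert orthogonal bridge
                values[prev[0] + dr, prev[1]] = 1.0
        values[r, c] = 1.0
        prev = (r, c)
    return RasterGrid(values, grid_template.cell_size, grid_template.origin, grid_template.nodata)


def make_habitat_mask(slope_raster: RasterGrid, slope_threshold: float) -> RasterGrid:
    """Binary habitat mask: 1 where slope >= threshold (escape terrain)."""
    if not 0 < slope_threshold < 90:
        raise ConfigurationError("slope threshold must lie in (0, 90) degrees")
    values = (slope_raster.values >= slope_threshold).astype(float)
    return RasterGrid(
        values, slope_raster.cell_size, slope_raster.origin, slope_raster.nodata
    )


def make_scenario(
    continuity_class: str,
    n_rows: int = 64,
    n_cols: int = 64,
    cell_size: float = 100.0,
    seed: int = 0,
    slope_threshold: float = 30.0,
    with_barrier: bool = False,
    smoothness: float = 3.0,
) -> LandscapeScenario:
    """Build a complete landscape scenario (slope + habitat + optional barrier).

    With ``with_barrier`` a straight vertical barrier bisects the grid, the
    canyon-river archetype for the continuous linear landscape.
    """
    slope = make_slope_field(n_rows, n_cols, cell_size, continuity_class, seed, smoothness)
    mask = make_habitat_mask(slope, slope_threshold)
    barrier = None
    if with_barrier:
        x = slope.origin[0] + (n_cols // 2 + 0.5) * cell_size
        y0 = slope.origin[1] + 0.5 * cell_size
        y1 = slope.origin[1] + (n_rows - 0.5) * cell_size
        barrier = make_barrier(slope, [(x, y0), (x, y1)])
    return LandscapeScenario(
        continuity_class=continuity_class,
        slope_raster=slope,
        habitat_mask=mask,
        barrier_raster=barrier,
        seed=seed,
    )


def generate_genotype_dataset(
    scenario: LandscapeScenario,
    true_resistance: ResistanceSurface,
    n_individuals: int,
    n_loci: int = 15,
    alleles_per_locus: int = 8,
    burn_in_years: int = 150,
    seed: int = 0,
    d_max: float | None = None,
    d_max_quantile: float = 0.10,
) -> GenotypeTable:
    """Neutral microsatellite genotypes with isolation-by-resistance structure.

    Individuals are placed uniformly on habitat cells (one per cell), given
    i.i.d. genotypes from uniform-Dirichlet per-locus allele frequencies, and
    evolved neutrally (s = 0) for ``burn_in_years`` over ``true_resistance``
    with dispersal truncated at ``d_max`` (default: the ``d_max_quantile``
    quantile of the off-diagonal pairwise cost distances, which localises
    dispersal enough to build spatial genetic structure).  With
    ``burn_in_years = 0`` the initial genotypes are returned unevolved.
    """
    if n_loci < 10:
        raise ConfigurationError("n_loci must be >= 10")
    if alleles_per_locus < 4:
        raise ConfigurationError("alleles_per_locus must be >= 4")
    if burn_in_years != 0 and burn_in_years < 100:
        raise ConfigurationError("burn_in_years must be 0 (no evolution) or >= 100")
    rng = np.random.default_rng(seed)
    mask = scenario.habitat_mask
    cells = np.argwhere(mask.values == 1)
    if n_individuals > len(cells):
        raise CapacityError(
            f"habitat has {len(cells)} cells; cannot hold {n_individuals} individuals"
        )
    pick = cells[rng.choice(len(cells), size=n_individuals, replace=False)]
    coords = mask.cell_centers(pick[:, 0], pick[:, 1])

    cost = least_cost_distance(true_resistance, coords)
    if d_max is None:
        d_max = float(np.quantile(cost.condensed(), d_max_quantile))
    d_floor = float(true_resistance.raster.cell_size * true_resistance.raster.values.min())

    # pseudo-microsatellite allele states: dinucleotide ladder per locus
    neutral_freqs = []
    for l in range(n_loci):
        states = 100 + 2 * np.arange(alleles_per_locus) + 50 * l
        freqs = rng.dirichlet(np.ones(alleles_per_locus))
        neutral_freqs.append((states, freqs))

    config = SimConfig(
        d_max=max(d_max, d_floor), d_floor=d_floor, s=0.0, years=burn_in_years, seed=seed
    )
    state = init_state(coords, config, rng, neutral_freqs=neutral_freqs)
    if burn_in_years > 0:
        try:
            run_years(state, cost.values, config, rng, burn_in_years)
        except ExtinctionSignal as e:
            raise CapacityError(
                "neutral burn-in population went extinct; the placement is too "
                "sparse for the dispersal threshold — increase n_individuals "
                f"or d_max ({e})"
            ) from None

    occ = np.flatnonzero(state.occupied)
    ids = [f"ind{k:04d}" for k in range(len(occ))]
    return GenotypeTable(
        ids=ids,
        coordinates=state.locations[occ],
        genotypes=state.neutral[occ],
        locus_names=[f"L{l + 1}" for l in range(n_loci)],
        sex=state.sex[occ].copy(),
    )
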