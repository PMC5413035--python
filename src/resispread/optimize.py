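"""Pseudo-bootstrap independent-pairs AIC resistance-surface optimization.

Pairwise genetic and cost distances are not statistically independent: each
individual appears in N - 1 pairs.  The procedure restores independence by
repeatedly drawing a random *disjoint* pair subset (each individual in at
most one pair, so at most floor(N/2) pairs), fitting an ordinary least
squares regression of genetic distance on (optionally log-transformed) cost
distance for every candidate resistance surface on the same subset, and
ranking candidates by the median Akaike weight across iterations.

Two phases: univariate (per-variable candidate curves; variables whose best
curve does not beat the null isolation-by-distance model are dropped) and
multivariate (cell-wise sums of the supported univariate winners plus
rescaled variants).  AIC uses the Gaussian-likelihood OLS form
``n ln(RSS/n) + 2k`` with k = 3 (intercept, slope, error variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    DegenerateFitError,
    GenotypeTable,
    PairwiseMatrix,
    RasterGrid,
)
from .costs import euclidean_distance, least_cost_distance
from .gendist import correlogram_cutoff, pairwise_genetic_matrix
from .resistance import (
    CandidateLadder,
    ResistanceCurve,
    ResistanceSurface,
    build_surface,
    combine_surfaces,
    enumerate_multivariate_candidates,
    enumerate_univariate_candidates,
)

__all__ = [
    "PairSample",
    "CandidateModelResult",
    "UnivariateResult",
    "MultivariateResult",
    "sample_independent_pairs",
    "fit_linear_aic",
    "akaike_weights",
    "optimize_univariate",
    "optimize_multivariate",
    "results_to_dataframe",
]

_AIC_K = 3  # intercept, slope, error variance


@dataclass
class PairSample:
    """A disjoint set of individual pairs (each id appears at most once)."""

    pairs: list[tuple]  # (i, j) index pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        arr = np.asarray(self.pairs, dtype=np.int64)
        return arr[:, 0], arr[:, 1]


def _eligible_matrix(n: int, eligible) -> np.ndarray:
    if eligible is None:
        mat = np.ones((n, n), dtype=bool)
    elif callable(eligible):
        mat = np.empty((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                mat[i, j] = bool(eligible(i, j))
    else:
        mat = np.asarray(eligible, dtype=bool).copy()
    np.fill_diagonal(mat, False)
    return mat


def sample_independent_pairs(ids, eligible, rng) -> PairSample:
    """Greedy maximal random matching over the eligibility graph.

    Ids are shuffled; the first unpaired id is paired with a uniformly chosen
    unpaired eligible partner; ids with no remaining eligible partner are
    skipped.  With an unrestricted eligibility graph the sample attains the
    maximum floor(N/2) pairs.
    """
    ids = list(ids)
    n = len(ids)
    if n == 0:
        raise ConfigurationError("no ids to sample pairs from")
    rng = np.random.default_rng(rng)
    mat = _eligible_matrix(n, eligible)
    order = rng.permutation(n)
    unpaired = np.ones(n, dtype=bool)
    pairs: list[tuple] = []
    for i in order:
        if not unpaired[i]:
            continue
        candidates = np.flatnonzero(mat[i] & unpaired)
        candidates = candidates[candidates != i]
        if candidates.size == 0:
            unpaired[i] = False  # skipped: no eligible partner remains
            continue
        j = int(candidates[rng.integers(candidates.size)])
        unpaired[i] = False
        unpaired[j] = False
        pairs.append((int(i), j))
    return PairSample(pairs=pairs)


def _ols_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(AIC, R^2) of OLS y ~ x with the n ln(RSS/n) + 2k criterion."""
    n = len(x)
    if n < 4:
        raise DegenerateFitError("need at least 4 pairs to fit")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise DegenerateFitError("zero variance in predictor")
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    rss = max(syy - sxy * sxy / sxx, 0.0)
    r2 = 1.0 - rss / syy if syy > 0 else 0.0
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * _AIC_K
    return float(aic), float(r2)


def fit_linear_aic(
    gen: PairwiseMatrix,
    cost: PairwiseMatrix,
    pairs: PairSample,
    transform: str = "raw",
) -> tuple[float, float]:
    """OLS of genetic distance on cost distance over one independent-pair
    sample; returns (AIC, R^2)."""
    gen.require_ids(cost)
    if transform not in ("raw", "log"):
        raise ConfigurationError(f"unknown transform {transform!r}")
    ii, jj = pairs.index_arrays()
    x = cost.values[ii, jj]
    y = gen.values[ii, jj]
    if transform == "log":
        if np.any(x <= 0):
            raise ConfigurationError("log transform requires all cost values > 0")
        x = np.log(x)
    return _ols_stats(x, y)


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights exp(-dAIC/2) / sum exp(-dAIC/2)."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0 or not np.all(np.isfinite(aics) | np.isposinf(aics)):
        raise ConfigurationError("AIC list must be non-empty and not contain NaN/-inf")
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()


@dataclass
class CandidateModelResult:
    """Per-iteration and aggregated records for one candidate surface."""

    candidate_id: str
    variables: dict[str, ResistanceCurve] | None  # None for the null model
    transform_used: str
    aic: np.ndarray  # per iteration, chosen transform
    weight: np.ndarray
    r2: np.ndarray
    median_w: float = field(init=False)
    median_r2: float = field(init=False)
    median_aic: float = field(init=False)

    def __post_init__(self) -> None:
        self.median_w = float(np.median(self.weight))
        self.median_r2 = float(np.median(self.r2))
        self.median_aic = float(np.median(self.aic))

    @property
    def is_null(self) -> bool:
        return self.variables is None


def _vectorised_fits(x_stack: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS AIC/R^2 for many candidates sharing one response.

    ``x_stack``: (C, n) predictors; returns (aic, r2) each of shape (C,).
    Candidates with a degenerate predictor (zero variance, or nonpositive
    values under a log transform marked as NaN rows) get AIC = +inf.
    """
    n = x_stack.shape[1]
    yc = y - y.mean()
    syy = float(yc @ yc)
    xm = x_stack.mean(axis=1, keepdims=True)
    xc = x_stack - xm
    sxx = np.einsum("cn,cn->c", xc, xc)
    sxy = xc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = syy - np.where(sxx > 0, sxy**2 / sxx, np.nan)
    rss = np.clip(rss, 0.0, None)
    bad = ~np.isfinite(rss)
    r2 = np.where(syy > 0, 1.0 - rss / max(syy, 1e-300), 0.0)
    aic = n * np.log(np.clip(rss, 1e-300, None) / n) + 2 * _AIC_K
    aic[bad] = np.inf
    r2[bad] = -np.inf
    return aic, r2


def _bootstrap_phase(
    gen_values: np.ndarray,
    cost_stack: np.ndarray,
    eligible: np.ndarray,
    candidate_ids: list[str],
    candidate_vars: list[dict | None],
    n_iter: int,
    rng,
) -> list[CandidateModelResult]:
    """Shared engine: pair resampling, dual-transform OLS, Akaike weights."""
    n_cand = cost_stack.shape[0]
    n = gen_values.shape[0]
    aic = np.full((n_cand, 2, n_iter), np.inf)  # transform axis: 0 raw, 1 log
    r2 = np.full((n_cand, 2, n_iter), -np.inf)

    for it in range(n_iter):
        sample = sample_independent_pairs(range(n), eligible, rng)
        ii, jj = sample.index_arrays()
        if len(ii) < 4:
            raise DegenerateFitError(
                f"iteration {it}: only {len(ii)} eligible pairs; need >= 4"
            )
        y = gen_values[ii, jj]
        x = cost_stack[:, ii, jj]
        aic[:, 0, it], r2[:, 0, it] = _vectorised_fits(x, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xl = np.where(x > 0, np.log(np.clip(x, 1e-300, None)), np.nan)
        ok = ~np.isnan(xl).any(axis=1)
        if ok.any():
            a_log, r_log = _vectorised_fits(xl[ok], y)
            aic[ok, 1, it] = a_log
            r2[ok, 1, it] = r_log

    # per candidate, retain the transform with the higher median R^2
    med_r2 = np.median(r2, axis=2)
    use_log = med_r2[:, 1] > med_r2[:, 0]
    chosen_aic = np.where(use_log[:, None], aic[:, 1, :], aic[:, 0, :])
    chosen_r2 = np.where(use_log[:, None], r2[:, 1, :], r2[:, 0, :])

    # per-iteration Akaike weights across the whole candidate set
    weights = np.empty_like(chosen_aic)
    for it in range(n_iter):
        weights[:, it] = akaike_weights(chosen_aic[:, it])

    results = []
    for c in range(n_cand):
        results.append(
            CandidateModelResult(
                candidate_id=candidate_ids[c],
                variables=candidate_vars[c],
                transform_used="log" if use_log[c] else "raw",
                aic=chosen_aic[c],
                weight=weights[c],
                r2=chosen_r2[c],
            )
        )
    return results


def _rank_key(r: CandidateModelResult):
    # ties: higher median R^2, then lower median AIC
    return (-r.median_w, -r.median_r2, r.median_aic)


@dataclass
class UnivariateResult:
    """Outcome of the univariate phase."""

    candidates: list[CandidateModelResult]
    best: dict[str, CandidateModelResult]  # per variable
    supported: dict[str, ResistanceCurve]  # variables beating the null
    null: CandidateModelResult
    cutoff: float
    n_candidates: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_candidates = len(self.candidates)


def _null_surface(template: RasterGrid) -> ResistanceSurface:
    ones = RasterGrid(
        np.ones(template.shape), template.cell_size, template.origin, template.nodata
    )
    return ResistanceSurface(ones, provenance=[])


def _prepare(table, cutoff, n_perm, alpha, seed):
    gen = pairwise_genetic_matrix(table)
    euc = euclidean_distance(table.coordinates, ids=list(table.ids))
    if cutoff is None:
        cutoff = correlogram_cutoff(
            gen, euc, n_perm=n_perm, alpha=alpha, seed=seed
        ).cutoff
    eligible = euc.values <= cutoff
    np.fill_diagonal(eligible, False)
    return gen, float(cutoff), eligible


def optimize_univariate(
    table: GenotypeTable,
    rasters: dict[str, RasterGrid],
    ladder: CandidateLadder,
    n_iter: int = 10000,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    connectivity: int = 8,
    cutoff: float | None = None,
) -> UnivariateResult:
    """Phase 1: rank per-variable candidate curves against the null model.

    The pair-eligibility cutoff is estimated from a Mantel correlogram of
    genetic versus Euclidean distance unless ``cutoff`` is given (use
    ``numpy.inf`` to disable the restriction).  One null
    isolation-by-distance candidate competes in the global weight set.
    A variable is *supported* when its best candidate's median Akaike weight
    exceeds the null model's.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    gen, cutoff, eligible = _prepare(table, cutoff, n_perm, alpha, seed)
    template = next(iter(rasters.values()))

    candidate_ids: list[str] = ["null_ibd"]
    candidate_vars: list[dict | None] = [None]
    surfaces = [_null_surface(template)]
    for var, raster in rasters.items():
        template.require_template(raster)
        for curve in enumerate_univariate_candidates(var, ladder):
            candidate_ids.append(f"{var}:{curve.label()}")
            candidate_vars.append({var: curve})
            surfaces.append(build_surface(raster, curve, variable=var))

    cost_stack = np.stack(
        [
            least_cost_distance(s, table.coordinates, connectivity=connectivity).values
            for s in surfaces
        ]
    )
    results = _bootstrap_phase(
        gen.values, cost_stack, eligible, candidate_ids, candidate_vars, n_iter, rng
    )
    null = results[0]
    best: dict[str, CandidateModelResult] = {}
    for r in results[1:]:
        var = next(iter(r.variables))
        if var not in best or _rank_key(r) < _rank_key(best[var]):
            best[var] = r
    supported = {
        var: next(iter(r.variables.values()))
        for var, r in best.items()
        if r.median_w > null.median_w
    }
    return UnivariateResult(
        candidates=results, best=best, supported=supported, null=null, cutoff=cutoff
    )


@dataclass
class MultivariateResult:
    """Outcome of the multivariate phase."""

    candidates: list[CandidateModelResult]
    winner: CandidateModelResult
    winner_surface: ResistanceSurface
    cutoff: float


def optimize_multivariate(
    supported: dict[str, ResistanceCurve],
    table: GenotypeTable,
    rasters: dict[str, RasterGrid],
    ladder: CandidateLadder,
    n_iter: int = 10000,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    connectivity: int = 8,
    cutoff: float | None = None,
) -> MultivariateResult:
    """Phase 2: compare summed multivariate surfaces, the supported
    univariate winners and the null model; the winner has the highest
    median Akaike weight."""
    rng = np.random.default_rng(seed)
    gen, cutoff, eligible = _prepare(table, cutoff, n_perm, alpha, seed)
    template = next(iter(rasters.values()))

    def make_combo(assignment: dict[str, ResistanceCurve]) -> ResistanceSurface:
        parts = [
            build_surface(rasters[v], c, variable=v) for v, c in sorted(assignment.items())
        ]
        return combine_surfaces(parts) if len(parts) > 1 else parts[0]

    candidate_ids: list[str] = ["null_ibd"]
    candidate_vars: list[dict | None] = [None]
    surfaces = [_null_surface(template)]
    for var, curve in sorted(supported.items()):
        candidate_ids.append(f"{var}:{curve.label()}")
        candidate_vars.append({var: curve})
        surfaces.append(make_combo({var: curve}))
    for assignment in enumerate_multivariate_candidates(supported, ladder):
        label = " + ".join(f"{v}:{c.label()}" for v, c in sorted(assignment.items()))
        candidate_ids.append(label)
        candidate_vars.append(assignment)
        surfaces.append(make_combo(assignment))

    cost_stack = np.stack(
        [
            least_cost_distance(s, table.coordinates, connectivity=connectivity).values
            for s in surfaces
        ]
    )
    results = _bootstrap_phase(
        gen.values, cost_stack, eligible, candidate_ids, candidate_vars, n_iter, rng
    )
    winner = min(results, key=_rank_key)
    winner_surface = surfaces[results.index(winner)]
    return MultivariateResult(
        candidates=results, winner=winner, winner_surface=winner_surface, cutoff=cutoff
    )


def results_to_dataframe(results: list[CandidateModelResult]) -> pd.DataFrame:
    """Tidy summary table (one row per candidate), sorted by rank."""
    rows = []
    for r in sorted(results, key=_rank_key):
        rows.append(
            {
                "candidate": r.candidate_id,
                "n_variables": 0 if r.is_null else len(r.variables),
                "transform": r.transform_used,
                "median_weight": r.median_w,
                "median_r2": r.median_r2,
                "median_aic": r.median_aic,
            }
        )
    return pd.DataFrame(rows)
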