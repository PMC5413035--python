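"""Candidate resistance-curve families and resistance surfaces.

A resistance curve maps a landscape-variable value to a per-cell movement
resistance >= 1.  Six families are supported:

``monotonic_positive``  1 + (r_max - 1) * x_norm ** r_exp
``monotonic_negative``  1 + (r_max - 1) * (1 - x_norm) ** r_exp
``gaussian``            r_max - (r_max - 1) * exp(-(x - x_opt)^2 / (2 x_sd^2))
``breakpoint``          1 inside [break_lo, break_hi], ``outside_value`` outside
``binary_ratio``        1 where x == 0, ``ratio`` elsewhere
``null_ibd``            1 everywhere (isolation by distance)

Monotonic families operate on min-max normalised variable values (x_norm in
[0, 1] over the raster's observed range), which makes the shape exponent
scale-free.  The Gaussian family operates on raw variable units (x_opt = 50
means a slope of 50 degrees), matching the magnitude of its parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import AlignmentError, ConfigurationError, RasterGrid

MONOTONIC_FAMILIES = ("monotonic_positive", "monotonic_negative")
FAMILIES = MONOTONIC_FAMILIES + ("gaussian", "breakpoint", "binary_ratio", "null_ibd")

__all__ = [
    "ResistanceCurve",
    "ResistanceSurface",
    "VariableSpec",
    "CandidateLadder",
    "evaluate_curve",
    "build_surface",
    "combine_surfaces",
    "offset_surface",
    "enumerate_univariate_candidates",
    "enumerate_multivariate_candidates",
    "rescale_curve",
]


@dataclass(frozen=True)
class ResistanceCurve:
    """One parameterised member of a resistance-curve family."""

    family: str
    r_max: float | None = None
    r_exp: float | None = None
    x_opt: float | None = None
    x_sd: float | None = None
    break_lo: float | None = None
    break_hi: float | None = None
    outside_value: float | None = None
    ratio: float | None = None

    def __post_init__(self) -> None:
        f = self.family
        if f not in FAMILIES:
            raise ConfigurationError(f"unknown curve family {f!r}")
        if f in MONOTONIC_FAMILIES:
            if self.r_max is None or self.r_max < 1:
                raise ConfigurationError("monotonic families require r_max >= 1")
            if self.r_exp is None or self.r_exp <= 0:
                raise ConfigurationError("monotonic families require r_exp > 0")
        elif f == "gaussian":
            if self.r_max is None or self.r_max < 1:
                raise ConfigurationError("gaussian family requires r_max >= 1")
            if self.x_opt is None or self.x_sd is None or self.x_sd <= 0:
                raise ConfigurationError("gaussian family requires x_opt and x_sd > 0")
        elif f == "breakpoint":
            if self.break_lo is None or self.break_hi is None or self.break_lo > self.break_hi:
                raise ConfigurationError("breakpoint family requires break_lo <= break_hi")
            if self.outside_value is None or self.outside_value < 1:
                raise ConfigurationError("breakpoint family requires outside_value >= 1")
        elif f == "binary_ratio":
            if self.ratio is None or self.ratio < 1:
                raise ConfigurationError("binary_ratio family requires ratio >= 1")

    def label(self) -> str:
        f = self.family
        if f in MONOTONIC_FAMILIES:
            return f"{f}(r_max={self.r_max:g},r_exp={self.r_exp:g})"
        if f == "gaussian":
            return f"gaussian(r_max={self.r_max:g},x_opt={self.x_opt:g},x_sd={self.x_sd:g})"
        if f == "breakpoint":
            return (
                f"breakpoint([{self.break_lo:g},{self.break_hi:g}],"
                f"outside={self.outside_value:g})"
            )
        if f == "binary_ratio":
            return f"ratio({self.ratio:g})"
        return "null_ibd"

    @property
    def scale_value(self) -> float | None:
        """The family's maximum-resistance parameter, whatever it is called."""
        if self.family in MONOTONIC_FAMILIES or self.family == "gaussian":
            return self.r_max
        if self.family == "binary_ratio":
            return self.ratio
        if self.family == "breakpoint":
            return self.outside_value
        return None


def rescale_curve(curve: ResistanceCurve, scale: float) -> ResistanceCurve:
    """Same curve shape with a different maximum-resistance value."""
    if curve.family in MONOTONIC_FAMILIES or curve.family == "gaussian":
        return replace(curve, r_max=scale)
    if curve.family == "binary_ratio":
        return replace(curve, ratio=scale)
    if curve.family == "breakpoint":
        return replace(curve, outside_value=scale)
    raise ConfigurationError(f"{curve.family} has no maximum-resistance parameter")


def evaluate_curve(curve: ResistanceCurve, x, x_range: tuple[float, float] = (0.0, 1.0)):
    """Evaluate a resistance curve at variable value(s) ``x``.

    For monotonic families ``x`` is first min-max normalised over ``x_range``
    (pass the raster's observed (min, max); the default (0, 1) means ``x`` is
    already normalised).  Other families use raw units.
    """
    x = np.asarray(x, dtype=float)
    f = curve.family
    if f == "null_ibd":
        return np.ones_like(x)
    if f in MONOTONIC_FAMILIES:
        lo, hi = x_range
        if hi <= lo:
            raise ConfigurationError("x_range must satisfy max > min for monotonic families")
        xn = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        if f == "monotonic_negative":
            xn = 1.0 - xn
        return 1.0 + (curve.r_max - 1.0) * xn**curve.r_exp
    if f == "gaussian":
        z = (x - curve.x_opt) / curve.x_sd
        return curve.r_max - (curve.r_max - 1.0) * np.exp(-0.5 * z**2)
    if f == "breakpoint":
        inside = (x >= curve.break_lo) & (x <= curve.break_hi)
        return np.where(inside, 1.0, curve.outside_value)
    if f == "binary_ratio":
        return np.where(x == 0, 1.0, curve.ratio)
    raise ConfigurationError(f"unknown family {f!r}")


@dataclass
class ResistanceSurface:
    """A raster of per-cell resistance values with its provenance."""

    raster: RasterGrid
    provenance: list = field(default_factory=list)  # [(variable, ResistanceCurve), ...]
    offset: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.raster.values < 1.0 + self.offset - 1e-12):
            raise ConfigurationError("resistance surface has cells below 1 + offset")

    def label(self) -> str:
        parts = [f"{var}:{curve.label()}" for var, curve in self.provenance]
        s = " + ".join(parts) if parts else "null_ibd"
        if self.offset:
            s += f" + {self.offset:g}"
        return s


def build_surface(raster: RasterGrid, curve: ResistanceCurve, variable: str = "x") -> ResistanceSurface:
    """Apply a resistance curve cell-wise to a landscape-variable raster."""
    if np.any(raster.values == raster.nodata):
        raise ConfigurationError("raster has nodata cells inside the analysis extent")
    vmin = float(raster.values.min())
    vmax = float(raster.values.max())
    if curve.family in MONOTONIC_FAMILIES and vmax <= vmin:
        # constant raster: normalised value is taken as 0 everywhere
        values = np.full(raster.shape, 1.0)
    else:
        values = evaluate_curve(curve, raster.values, x_range=(vmin, vmax))
    out = RasterGrid(values, raster.cell_size, raster.origin, raster.nodata)
    return ResistanceSurface(out, provenance=[(variable, curve)])


def combine_surfaces(surfaces: list[ResistanceSurface]) -> ResistanceSurface:
    """Cell-wise sum of resistance surfaces sharing one grid template."""
    if not surfaces:
        raise ConfigurationError("no surfaces to combine")
    template = surfaces[0].raster
    total = np.zeros(template.shape)
    provenance: list = []
    for s in surfaces:
        template.require_template(s.raster)
        total = total + s.raster.values
        provenance.extend(s.provenance)
    out = RasterGrid(total, template.cell_size, template.origin, template.nodata)
    return ResistanceSurface(out, provenance=provenance)


def offset_surface(surface: ResistanceSurface, c: float) -> ResistanceSurface:
    """Add a nonnegative constant to every cell (cost standardisation)."""
    if c < 0:
        raise ConfigurationError("offset must be nonnegative")
    r = surface.raster
    out = RasterGrid(r.values + c, r.cell_size, r.origin, r.nodata)
    return ResistanceSurface(out, provenance=list(surface.provenance), offset=surface.offset + c)


# ---------------------------------------------------------------------------
# candidate enumeration


@dataclass(frozen=True)
class VariableSpec:
    """Which curve families and parameter grids to test for one variable."""

    name: str
    kind: str  # continuous | binary
    families: tuple[str, ...]
    r_max: tuple[float, ...] = (10, 50, 100, 500, 1000)
    r_exp: tuple[float, ...] = (0.25, 0.5, 1, 2, 4)
    x_opt: tuple[float, ...] = ()
    x_sd: tuple[float, ...] = ()
    breakpoints: tuple[tuple[float, float], ...] = ()
    outside_value: tuple[float, ...] = ()
    ratio: tuple[float, ...] = (10, 100, 1000, 5000, 10000)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown variable kind {self.kind!r}")
        for f in self.families:
            if f not in FAMILIES or f == "null_ibd":
                raise ConfigurationError(f"invalid family {f!r} in ladder")


@dataclass
class CandidateLadder:
    """Per-variable candidate curve grids for one optimization run."""

    variables: dict[str, VariableSpec]

    def spec(self, variable: str) -> VariableSpec:
        try:
            return self.variables[variable]
        except KeyError:
            raise ConfigurationError(f"variable {variable!r} not declared in ladder") from None


def enumerate_univariate_candidates(variable: str, ladder: CandidateLadder) -> list[ResistanceCurve]:
    """Cross-product of the declared parameter grids for one variable.

    The shared null-IBD model is *not* included here; the optimizer adds one
    null candidate per phase.
    """
    spec = ladder.spec(variable)
    curves: list[ResistanceCurve] = []
    for fam in spec.families:
        if fam in MONOTONIC_FAMILIES:
            if not spec.r_max or not spec.r_exp:
                raise ConfigurationError(f"empty parameter grid for {fam} on {variable}")
            for r_max, r_exp in itertools.product(spec.r_max, spec.r_exp):
                curves.append(ResistanceCurve(fam, r_max=r_max, r_exp=r_exp))
        elif fam == "gaussian":
            if not (spec.r_max and spec.x_opt and spec.x_sd):
                raise ConfigurationError(f"empty parameter grid for gaussian on {variable}")
            for r_max, x_opt, x_sd in itertools.product(spec.r_max, spec.x_opt, spec.x_sd):
                curves.append(ResistanceCurve(fam, r_max=r_max, x_opt=x_opt, x_sd=x_sd))
        elif fam == "breakpoint":
            if not (spec.breakpoints and spec.outside_value):
                raise ConfigurationError(f"empty parameter grid for breakpoint on {variable}")
            for (lo, hi), out in itertools.product(spec.breakpoints, spec.outside_value):
                curves.append(
                    ResistanceCurve(fam, break_lo=lo, break_hi=hi, outside_value=out)
                )
        elif fam == "binary_ratio":
            if not spec.ratio:
                raise ConfigurationError(f"empty ratio ladder for {variable}")
            for ratio in spec.ratio:
                curves.append(ResistanceCurve(fam, ratio=ratio))
    if not curves:
        raise ConfigurationError(f"no candidates enumerated for {variable}")
    return curves


def _scale_ladder(curve: ResistanceCurve, spec: VariableSpec) -> tuple[float, ...]:
    if curve.family == "binary_ratio":
        return spec.ratio
    if curve.family == "breakpoint":
        return spec.outside_value
    return spec.r_max


def _scale_options(curve: ResistanceCurve, spec: VariableSpec) -> list[ResistanceCurve]:
    """The optimal curve plus variants at the neighbouring ladder scales."""
    ladder_values = sorted(_scale_ladder(curve, spec))
    opt = curve.scale_value
    options = [curve]
    if opt in ladder_values:
        i = ladder_values.index(opt)
        neighbours = []
        if i > 0:
            neighbours.append(ladder_values[i - 1])
        if i < len(ladder_values) - 1:
            neighbours.append(ladder_values[i + 1])
    else:
        neighbours = [v for v in ladder_values if v != opt][:2]
    for v in neighbours:
        options.append(rescale_curve(curve, v))
    return options


def enumerate_multivariate_candidates(
    best_univariate: dict[str, ResistanceCurve], ladder: CandidateLadder
) -> list[dict[str, ResistanceCurve]]:
    """Multivariate candidate assignments from the supported univariate winners.

    For every subset of >= 2 supported variables, one candidate per assignment
    in which each variable takes its optimal curve or a variant rescaled to a
    neighbouring maximum-resistance ladder value.
    """
    names = sorted(best_univariate)
    if len(names) < 2:
        return []
    options = {
        v: _scale_options(best_univariate[v], ladder.spec(v)) for v in names
    }
    out: list[dict[str, ResistanceCurve]] = []
    for size in range(2, len(names) + 1):
        for subset in itertools.combinations(names, size):
            for assignment in itertools.product(*(options[v] for v in subset)):
                out.append(dict(zip(subset, assignment)))
    return out
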