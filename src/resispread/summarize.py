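"""Aggregation of replicate simulation output: f_A trajectories with 95%
bands and per-location adaptive-allele presence maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BoundsError, ConfigurationError
from .simulate import SimResult, SimState

__all__ = [
    "allele_frequency",
    "TrajectorySummary",
    "summarize_trajectories",
    "PresenceMap",
    "presence_map",
    "plot_trajectories",
]


def allele_frequency(state: SimState) -> float:
    """Adaptive-allele frequency f_A = A copies / (2 * population size)."""
    n = state.pop_size
    if n == 0:
        raise ConfigurationError("allele frequency undefined for an empty population")
    return state.allele_count_A() / (2.0 * n)


@dataclass
class TrajectorySummary:
    """Per-year mean f_A and 95% band across Monte Carlo replicates."""

    years: np.ndarray
    mean_fA: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "mean_fA": self.mean_fA,
                "lo95": self.lo95,
                "hi95": self.hi95,
            }
        )


def summarize_trajectories(result: SimResult, band_method: str = "percentile") -> TrajectorySummary:
    """Mean f_A per year with a 95% band across replicates.

    ``percentile`` (default): 2.5th/97.5th percentiles across replicates,
    robust for frequencies near 0; ``normal``: mean +/- 1.96 SE.  Years in
    which a replicate is extinct contribute nothing (NaN-aware).
    """
    fA = result.fA
    if fA.shape[0] < 2:
        raise ConfigurationError("need at least 2 replicates to summarize")
    mean = np.nanmean(fA, axis=0)
    if band_method == "percentile":
        lo = np.nanpercentile(fA, 2.5, axis=0)
        hi = np.nanpercentile(fA, 97.5, axis=0)
    elif band_method == "normal":
        n_eff = np.sum(~np.isnan(fA), axis=0)
        se = np.nanstd(fA, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
        lo = mean - 1.96 * se
        hi = mean + 1.96 * se
    else:
        raise ConfigurationError(f"unknown band_method {band_method!r}")
    return TrajectorySummary(
        years=result.years.copy(),
        mean_fA=mean,
        lo95=np.clip(lo, 0.0, 1.0),
        hi95=np.clip(hi, 0.0, 1.0),
        n_replicates=fA.shape[0],
    )


@dataclass
class PresenceMap:
    """Per-location proportion of replicates carrying >= 1 adaptive copy."""

    locations: np.ndarray  # (M, 2)
    proportion: np.ndarray  # (M,), in [0, 1]
    year: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location": np.arange(len(self.proportion)),
                "x": self.locations[:, 0],
                "y": self.locations[:, 1],
                "proportion": self.proportion,
            }
        )


def presence_map(result: SimResult, year: int) -> PresenceMap:
    """Fraction of replicates in which each location holds an adaptive-allele
    carrier at ``year`` (vacancy counts as absence)."""
    if not 0 <= year < result.presence.shape[1]:
        raise BoundsError(f"year {year} outside the simulated range")
    prop = result.presence[:, year, :].mean(axis=0)
    return PresenceMap(locations=result.locations.copy(), proportion=prop, year=year)


def plot_trajectories(summaries: dict[str, TrajectorySummary], path=None, title: str = ""):
    """Line plot of mean f_A with shaded 95% bands, one series per label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, s in summaries.items():
        (line,) = ax.plot(s.years, s.mean_fA, label=label)
        ax.fill_between(s.years, s.lo95, s.hi95, alpha=0.2, color=line.get_color())
    ax.set_xlabel("year")
    ax.set_ylabel("adaptive allele frequency $f_A$")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
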