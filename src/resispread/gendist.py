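"""Inter-individual genetic dissimilarity and the correlogram distance cutoff.

Genetic distance is the Bray-Curtis dissimilarity between two diploid
multilocus genotypes: one minus the proportion of allele copies shared,
counting shared copies per locus as the multiset intersection of the two
genotypes.  Loci untyped in either individual are dropped pair-wise
(pairwise deletion), standard practice for allele-sharing measures with
non-invasive samples.

The Mantel correlogram estimates the spatial distance beyond which genetic
and geographic distance are no longer positively correlated; pairs separated
by more than this cutoff are excluded from resistance-model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import (
    ConfigurationError,
    GenotypeTable,
    MISSING,
    MissingDataError,
    PairwiseMatrix,
)

__all__ = ["bray_curtis", "pairwise_genetic_matrix", "CorrelogramResult", "correlogram_cutoff"]


def bray_curtis(genotype_i: np.ndarray, genotype_j: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two (L, 2) diploid genotypes.

    Over loci typed in both individuals, ``shared(l)`` is the multiset
    intersection size of the two allele pairs; BC = 1 - sum shared / (2 L).
    """
    gi = np.asarray(genotype_i)
    gj = np.asarray(genotype_j)
    if gi.shape != gj.shape or gi.ndim != 2 or gi.shape[1] != 2:
        raise ConfigurationError("genotypes must both have shape (L, 2)")
    typed = np.all(gi != MISSING, axis=1) & np.all(gj != MISSING, axis=1)
    n_typed = int(typed.sum())
    if n_typed == 0:
        raise MissingDataError("no jointly typed loci for this pair")
    shared = 0
    for l in np.flatnonzero(typed):
        a = sorted(gi[l])
        b = list(gj[l])
        for allele in a:
            if allele in b:
                shared += 1
                b.remove(allele)
    return 1.0 - shared / (2.0 * n_typed)


def _allele_counts(table: GenotypeTable):
    """Per-locus allele-count matrices and typed masks.

    Returns a list of (counts, typed) per locus where counts has shape
    (N, n_states) over the allele states observed at that locus.
    """
    out = []
    for l in range(table.n_loci):
        g = table.genotypes[:, l, :]
        typed = np.all(g != MISSING, axis=1)
        states = np.unique(g[typed])
        counts = np.zeros((table.n, len(states)), dtype=np.int32)
        if len(states):
            lookup = {s: k for k, s in enumerate(states)}
            for slot in range(2):
                for i in np.flatnonzero(typed):
                    counts[i, lookup[g[i, slot]]] += 1
        out.append((counts, typed))
    return out


def pairwise_genetic_matrix(table: GenotypeTable) -> PairwiseMatrix:
    """Full N x N Bray-Curtis matrix.

    Uses the identity ``|A ∩ B| = (|A| + |B| - |A Δ B|) / 2`` on per-locus
    allele-count vectors, so each locus costs one Manhattan-distance pass.
    """
    n = table.n
    shared = np.zeros((n, n))
    joint = np.zeros((n, n))
    for counts, typed in _allele_counts(table):
        if counts.shape[1] == 0:
            continue
        l1 = cdist(counts, counts, metric="cityblock")
        s = (4.0 - l1) / 2.0  # diploid: |A| = |B| = 2
        both = np.outer(typed, typed)
        shared += np.where(both, s, 0.0)
        joint += both
    if np.any(joint[np.triu_indices(n, k=1)] == 0):
        raise MissingDataError("some pair has zero jointly typed loci")
    values = 1.0 - shared / (2.0 * joint)
    np.fill_diagonal(values, 0.0)
    return PairwiseMatrix(ids=list(table.ids), values=values, metric_kind="genetic")


@dataclass
class CorrelogramResult:
    """Per-distance-class Mantel statistics and the derived cutoff."""

    class_edges: np.ndarray  # len n_classes + 1, strictly increasing
    r_per_class: np.ndarray
    p_per_class: np.ndarray
    cutoff: float

    @property
    def n_classes(self) -> int:
        return len(self.r_per_class)


def correlogram_cutoff(
    gen: PairwiseMatrix,
    dist: PairwiseMatrix,
    n_classes: int = 10,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> CorrelogramResult:
    """Mantel correlogram of genetic distance against distance classes.

    Distance classes are equal-count (quantile) bins of the off-diagonal
    distances.  The per-class statistic is minus the Pearson correlation
    between the genetic matrix and the class-membership indicator over
    off-diagonal pairs, so a *positive* value means pairs in the class are
    genetically more similar than average.  Significance is one-tailed by
    permuting individual labels ``n_perm`` times.  The cutoff is the lower
    edge of the first class whose statistic is not significantly positive at
    ``alpha``; if every class is significant, the maximum observed distance.
    """
    gen.require_ids(dist)
    if n_perm < 99:
        raise ConfigurationError("n_perm must be >= 99")
    n = gen.n
    iu = np.triu_indices(n, k=1)
    g = gen.values[iu]
    d = dist.values[iu]
    if np.ptp(g) == 0 or np.ptp(d) == 0:
        raise ConfigurationError("constant matrix: correlogram statistic undefined")

    qs = np.linspace(0, 1, n_classes + 1)
    edges = np.unique(np.quantile(d, qs))
    if len(edges) < 3:
        raise ConfigurationError("too few distinct distances for the requested classes")
    edges[0] = d.min()
    edges[-1] = d.max()
    n_cls = len(edges) - 1

    # class membership of every off-diagonal pair
    cls = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_cls - 1)
    indicators = np.stack([(cls == k) for k in range(n_cls)])  # (n_cls, n_pairs)

    gc = g - g.mean()
    g_ss = float(gc @ gc)
    ind_c = indicators - indicators.mean(axis=1, keepdims=True)
    ind_ss = np.einsum("kp,kp->k", ind_c, ind_c)

    def stats_for(vec_c: np.ndarray) -> np.ndarray:
        # minus correlation: positive = within-class similarity
        num = ind_c @ vec_c
        return -num / np.sqrt(ind_ss * g_ss)

    r_obs = stats_for(gc)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_cls, dtype=np.int64)
    full = gen.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = full[np.ix_(perm, perm)][iu]
        exceed += stats_for(gp - gp.mean()) >= r_obs
    p = (1.0 + exceed) / (n_perm + 1.0)

    significant = p <= alpha
    cutoff = float(edges[-1])
    for k in range(n_cls):
        if not significant[k]:
            cutoff = float(edges[k])
            break
    return CorrelogramResult(
        class_edges=edges, r_per_class=r_obs, p_per_class=p, cutoff=cutoff
    )
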