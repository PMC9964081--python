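"""Pairwise F_ST, geographic distance and the Mantel isolation-by-distance test.

Pairwise divergence uses the Weir & Cockerham (1984) theta estimator:
per locus the among-population (a), among-individual (b) and
within-individual (c) variance components are formed from the two
populations' sample sizes, allele frequencies and observed heterozygote
frequencies, and theta is the ratio of sums a / (a+b+c) over loci.
Negative estimates are legitimate small-sample outcomes and are reported
as computed, not clamped.

Geographic separation is the great-circle distance between population
centroids (mean longitude/latitude of member samples). Isolation by
distance is assessed with a one-sided Mantel permutation test of the
Pearson correlation between the two distance matrices, permuting rows
and columns of the second matrix jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    SampleCoordinates,
)

__all__ = [
    "FstMatrix",
    "MantelResult",
    "pairwise_fst",
    "wc_theta",
    "geo_distance",
    "mantel_test",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class FstMatrix:
    """Symmetric matrix of pairwise Weir-Cockerham theta values."""

    populations: list[str]
    theta: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=float)
        if t.shape != (len(self.populations),) * 2:
            raise ValueError("theta shape does not match population count")
        if not np.allclose(t, t.T, equal_nan=True):
            raise ValueError("theta matrix must be symmetric")
        if not np.allclose(np.diag(t), 0.0):
            raise ValueError("theta diagonal must be zero")
        self.theta = t

    def mean_vs_others(self, population: str) -> float:
        i = self.populations.index(population)
        mask = np.ones(len(self.populations), dtype=bool)
        mask[i] = False
        return float(self.theta[i, mask].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.populations, columns=self.populations)


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p: float
    n_perm: int
    seed: int


def _wc_components(
    calls_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components a, b, c for r populations.

    Loci where any population has fewer than one call, or where the mean
    sample size is 1 (the b component is undefined), contribute NaN.
    """
    r = len(calls_by_pop)
    n_i = np.stack([(c != MISSING).sum(axis=0) for c in calls_by_pop]).astype(float)
    alt_i = np.stack(
        [np.where(c == MISSING, 0, c).sum(axis=0) for c in calls_by_pop]
    ).astype(float)
    het_i = np.stack([(c == 1).sum(axis=0) for c in calls_by_pop]).astype(float)

    valid = (n_i >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2.0 * n_i)
        h_i = het_i / n_i
        nbar = n_i.mean(axis=0)
        valid &= nbar > 1.0
        n_c = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

        a = (nbar / n_c) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    nan = ~valid
    for comp in (a, b, c):
        comp[nan] = np.nan
    return a, b, c


def wc_theta(calls_by_pop: list[np.ndarray]) -> float:
    """Multi-locus Weir-Cockerham theta as a ratio of summed components.

    Loci uninformative in every population (a+b+c = 0, e.g. globally
    monomorphic) drop out of both sums.
    """
    a, b, c = _wc_components(calls_by_pop)
    tot = a + b + c
    use = np.isfinite(tot) & (tot != 0.0)
    if not use.any():
        raise ValueError("no informative loci for theta estimation")
    return float(a[use].sum() / tot[use].sum())


def wc_theta_per_locus(calls_by_pop: list[np.ndarray]) -> np.ndarray:
    """Per-locus a and a+b+c pairs, for jackknife/uncertainty work."""
    a, b, c = _wc_components(calls_by_pop)
    return np.stack([a, a + b + c])


def pairwise_fst(gm: GenotypeMatrix, popmap: PopulationMap) -> FstMatrix:
    """Weir-Cockerham theta for every pair of populations."""
    popmap.validate(gm)
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    calls = {p: gm.calls[popmap.samples_of(p, gm.sample_ids)] for p in pops}
    for p, c in calls.items():
        if c.shape[0] < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
    k = len(pops)
    theta = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            t = wc_theta([calls[pops[i]], calls[pops[j]]])
            theta[i, j] = theta[j, i] = t
    return FstMatrix(list(pops), theta)


def geo_distance(
    coords: SampleCoordinates, popmap: PopulationMap
) -> tuple[list[str], np.ndarray]:
    """Great-circle distances (km) between population coordinate centroids."""
    pops = popmap.populations
    centroids = []
    for pop in pops:
        members = [s for s, p in popmap.assignments.items() if p == pop]
        missing = [s for s in members if s not in coords]
        if missing:
            raise KeyError(f"samples without coordinates: {', '.join(missing)}")
        if not members:
            raise ValueError(f"population {pop!r} has no georeferenced samples")
        xy = np.array([coords[s] for s in members], dtype=float)
        centroids.append(xy.mean(axis=0))
    cent = np.array(centroids)
    latlon_rad = np.radians(cent[:, ::-1])  # haversine wants (lat, lon)
    km = haversine_distances(latlon_rad) * EARTH_RADIUS_KM
    return list(pops), km


def mantel_test(
    m1: np.ndarray, m2: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> MantelResult:
    """One-sided Mantel test for positive association between two matrices.

    r is the Pearson correlation of the upper-triangle entries; the null
    is built by jointly permuting rows and columns of ``m2``; the
    add-one p-value (1 + #{r_perm >= r_obs}) / (n_perm + 1) tests for a
    positive relationship. Bit-reproducible for a fixed seed.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    k = m1.shape[0]
    if k < 3:
        raise ValueError("Mantel test needs at least a 3x3 matrix")
    iu = np.triu_indices(k, 1)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        av, bv = a[iu], b[iu]
        av = av - av.mean()
        bv = bv - bv.mean()
        denom = np.sqrt((av**2).sum() * (bv**2).sum())
        if denom == 0.0:
            raise ValueError("degenerate (constant) distance matrix")
        return float((av * bv).sum() / denom)

    r_obs = corr(m1, m2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        if corr(m1, m2[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=r_obs, r_squared=r_obs**2, p=p, n_perm=n_perm, seed=seed)
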