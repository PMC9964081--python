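"""Clone delimitation: genetic distance, threshold detection, UPGMA, clonal richness.

Clonally propagating plants present a sampling problem: stems (ramets)
of one genetic individual (genet) are genetically identical up to
genotyping error, so distinct stems are not independent individuals.
The procedure implemented here delimits genets from SNP data:

1. pairwise Prevosti genetic distance between samples — the mean
   absolute allele-count difference per locus over mutually non-missing
   loci, d in [0, 1];
2. a threshold d* separating "same genet" from "different genet" pairs,
   found as the largest gap in the low end of the pairwise-distance
   distribution (or supplied manually);
3. average-linkage (UPGMA) clustering of the distance matrix, cut at
   height d*: each subtree below the cut is one genet;
4. clonal richness CR = (G - 1)/(N - 1), where G is the number of
   genets among the N samples analysed: 0 = monoclonal, 1 = all unique.

When the distance histogram shows no gap (all samples clearly distinct),
no threshold exists and every sample is its own genet (CR = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .genotype_io import MISSING, GenotypeMatrix, SampleCoordinates

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "CloneAssignment",
    "CloneDelimiter",
    "genetic_distance",
    "detect_threshold",
    "upgma",
    "assign_clones",
    "clonal_map",
    "clonal_richness",
]


@dataclass
class DistanceMatrix:
    """Pairwise Prevosti distances with per-pair comparable-locus counts."""

    sample_ids: list[str]
    d: np.ndarray
    comparable_loci: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance diagonal must be zero")

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), 1)
        return self.d[iu]


@dataclass
class CloneAssignment:
    """Sample-to-genet labels with the summary statistics of the analysis."""

    genet_of: dict[str, str]
    d_star: float | None
    G: int
    N: int
    ramets_per_genet: dict[str, int]
    CR: float

    def __post_init__(self) -> None:
        if sum(self.ramets_per_genet.values()) != self.N:
            raise ValueError("ramet counts do not sum to N")
        if not (1 <= self.G <= self.N):
            raise ValueError("G must lie in [1, N]")


def clonal_richness(G: int, N: int) -> float:
    """CR = (G - 1)/(N - 1); defined as 1 for a single sample."""
    if N < 1 or G < 1 or G > N:
        raise ValueError("need 1 <= G <= N")
    if N == 1:
        return 1.0
    return (G - 1) / (N - 1)


def genetic_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Prevosti distance: sum |g_i - g_j| / (2 * comparable loci).

    Loci missing in either sample of a pair are excluded; a pair with no
    mutually non-missing locus is an error (its distance is undefined).
    """
    if gm.n < 2:
        raise ValueError("need at least 2 samples")
    calls = gm.calls.astype(np.int16)
    obs = (calls != MISSING).astype(np.int16)
    vals = np.where(calls == MISSING, 0, calls)
    comp = obs @ obs.T
    if (comp[np.triu_indices(gm.n, 1)] == 0).any():
        i, j = np.argwhere(np.triu(comp == 0, 1))[0]
        raise ValueError(
            f"no mutually genotyped loci for pair ({gm.sample_ids[i]}, {gm.sample_ids[j]})"
        )
    # |g_i - g_j| summed over comparable loci, via a 1-locus-at-a-time free identity:
    # sum|a-b| = sum over the three code indicators of pairwise |difference|
    n, m = calls.shape
    diff = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs
        diff[i] = (np.abs(calls[i] - calls) * both).sum(axis=1)
    d = diff / (2.0 * comp)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(gm.sample_ids), d, comp)


def detect_threshold(
    dist: DistanceMatrix,
    bin_width: float = 0.005,
    search_ceiling: float = 0.10,
    min_distance_floor: float = 0.04,
) -> float | None:
    """Locate a clone/non-clone threshold from the distance distribution.

    The intuition is the bimodality of pairwise distances in a clonal
    sample: within-genet pairs (error only) sit near zero, between-genet
    pairs well above. The threshold is the midpoint of the largest gap
    between consecutive unique distances whose left edge lies below
    ``search_ceiling`` (a clone threshold is by definition a small
    distance; the far mode may sit anywhere above). The gap must be at
    least ``bin_width`` wide and have values on both sides; the reported
    d* is capped at ``search_ceiling``, which is always still inside the
    gap. If the minimum pairwise distance already exceeds
    ``min_distance_floor`` the sample contains no clonal pairs and None
    is returned (every sample its own genet).
    """
    vals = np.unique(dist.offdiag())
    if vals.size < 2:
        return None
    if vals.min() >= min_distance_floor:
        return None
    gaps = np.diff(vals)
    candidates = np.nonzero(vals[:-1] < search_ceiling)[0]
    if candidates.size == 0:
        return None
    k = int(candidates[np.argmax(gaps[candidates])])
    if gaps[k] < bin_width:
        return None
    return float(min((vals[k] + vals[k + 1]) / 2.0, search_ceiling))


def upgma(dist: DistanceMatrix) -> np.ndarray:
    """Average-linkage (UPGMA) tree as a scipy linkage matrix.

    Node heights are the linkage distances; scipy's agglomeration order
    breaks ties deterministically by index.
    """
    return linkage(squareform(dist.d, checks=False), method="average")


def assign_clones(
    tree: np.ndarray,
    d_star: float | None,
    sample_ids: list[str],
) -> CloneAssignment:
    """Cut the UPGMA tree at height ``d_star``; each subtree is one genet.

    ``d_star = None`` (no histogram gap) makes every sample its own
    genet. Genet labels are ``genet_01`` ... in order of first member.
    """
    n = len(sample_ids)
    if d_star is None:
        flat = np.arange(1, n + 1)
    elif n == 1:
        flat = np.array([1])
    else:
        flat = fcluster(tree, t=d_star, criterion="distance")
    # relabel clusters in order of first appearance
    order: dict[int, int] = {}
    for c in flat:
        order.setdefault(int(c), len(order) + 1)
    width = max(2, len(str(len(order))))
    genet_of = {
        sid: f"genet_{order[int(c)]:0{width}d}" for sid, c in zip(sample_ids, flat)
    }
    ramets: dict[str, int] = {}
    for g in genet_of.values():
        ramets[g] = ramets.get(g, 0) + 1
    G = len(ramets)
    return CloneAssignment(
        genet_of=genet_of,
        d_star=d_star,
        G=G,
        N=n,
        ramets_per_genet=ramets,
        CR=clonal_richness(G, n),
    )


class CloneDelimiter(BaseEstimator, ClusterMixin):
    """Distance-threshold + UPGMA clone delimitation as a clusterer.

    Parameters
    ----------
    threshold : float or None, default None
        Manual clone threshold d*. When None it is detected from the
        distance histogram (and may legitimately come back None, meaning
        every sample is unique).
    bin_width, search_ceiling, min_distance_floor : float
        Gap-detection knobs, see :func:`detect_threshold`.
    max_missing : float, default 0.25
        Samples missing more than this fraction of loci are excluded
        before the analysis (label -1), because near-empty genotypes
        drift toward everything.

    Attributes
    ----------
    labels_ : ndarray of int
        Genet index per input sample; -1 marks samples excluded by the
        missingness cap.
    assignment_ : CloneAssignment
    distance_ : DistanceMatrix
    tree_ : linkage matrix
    d_star_ : float or None
    """

    def __init__(
        self,
        threshold: float | None = None,
        bin_width: float = 0.005,
        search_ceiling: float = 0.10,
        min_distance_floor: float = 0.04,
        max_missing: float = 0.25,
    ) -> None:
        self.threshold = threshold
        self.bin_width = bin_width
        self.search_ceiling = search_ceiling
        self.min_distance_floor = min_distance_floor
        self.max_missing = max_missing

    def fit(self, X: GenotypeMatrix, y: object = None) -> "CloneDelimiter":
        if not isinstance(X, GenotypeMatrix):
            raise TypeError("CloneDelimiter operates on a GenotypeMatrix")
        keep = np.nonzero(X.sample_missingness() <= self.max_missing)[0]
        if keep.size < X.n:
            logger.info(
                "excluded %d samples above %.0f%% missingness",
                X.n - keep.size,
                100 * self.max_missing,
            )
        if keep.size < 2:
            raise ValueError("fewer than 2 samples pass the missingness cap")
        sub = X.take_samples(keep)
        self.kept_samples_ = list(sub.sample_ids)
        self.distance_ = genetic_distance(sub)
        if self.threshold is not None:
            self.d_star_ = float(self.threshold)
        else:
            self.d_star_ = detect_threshold(
                self.distance_,
                bin_width=self.bin_width,
                search_ceiling=self.search_ceiling,
                min_distance_floor=self.min_distance_floor,
            )
        self.tree_ = upgma(self.distance_)
        self.assignment_ = assign_clones(self.tree_, self.d_star_, self.kept_samples_)
        genet_index = {g: i for i, g in enumerate(sorted(set(self.assignment_.genet_of.values())))}
        labels = np.full(X.n, -1, dtype=int)
        for i, sid in zip(keep, self.kept_samples_):
            labels[i] = genet_index[self.assignment_.genet_of[sid]]
        self.labels_ = labels
        return self

    def fit_predict(self, X: GenotypeMatrix, y: object = None) -> np.ndarray:
        return self.fit(X).labels_


def clonal_map(
    assignment: CloneAssignment, coords: SampleCoordinates
) -> tuple[pd.DataFrame, float]:
    """Plot-ready table of sample positions by genet, plus an intermixing index.

    The intermixing index is the fraction of samples whose nearest
    spatial neighbour belongs to a different genet: near 1 for guerrilla
    (interleaved) clonal growth, near 0 for phalanx (clumped) growth.
    Samples without coordinates are omitted with a warning.
    """
    rows = []
    skipped = []
    for sid, genet in assignment.genet_of.items():
        if sid in coords:
            lon, lat = coords[sid]
            rows.append({"sample": sid, "longitude": lon, "latitude": lat, "genet": genet})
        else:
            skipped.append(sid)
    if skipped:
        warnings.warn(f"samples without coordinates omitted from map: {', '.join(skipped)}")
    df = pd.DataFrame(rows)
    if len(df) < 2:
        return df, float("nan")
    xy = df[["longitude", "latitude"]].to_numpy()
    tree = cKDTree(xy)
    _, nn = tree.query(xy, k=2)
    neighbour = nn[:, 1]
    genets = df["genet"].to_numpy()
    index = float((genets[neighbour] != genets).mean())
    return df, index


def plot_clone_map(df: pd.DataFrame, path: str, title: str = "") -> None:
    """Scatter samples by position, one marker colour per genet (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for genet, grp in df.groupby("genet"):
        ax.scatter(grp["longitude"], grp["latitude"], label=genet, s=30)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if title:
        ax.set_title(title)
    if df["genet"].nunique() <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
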