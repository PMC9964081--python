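"""Synthetic clonal SNP datasets with known truth.

The generator emulates the sampling regime of a rangewide conservation
survey of a rhizomatous plant: a dozen or so populations of 10-35 stems,
thousands of biallelic ddRAD loci with substantial missingness, moderate
hierarchical structure, inbreeding, and clonal groups (genets) whose
sampled stems (ramets) differ only by genotyping error.

Model
-----
Ancestral allele frequencies are drawn Uniform(0.05, 0.95). Population
frequencies follow the Balding-Nichols construction: for target
divergence ``theta`` > 0,

    q_pop ~ Beta(q (1-theta)/theta, (1-q)(1-theta)/theta),

which has mean ``q`` and variance ``theta * q(1-q)`` — exactly the
variance component the Weir-Cockerham F_ST estimator targets. Genet
genotypes are drawn with heterozygote probability ``2q(1-q)(1-F_IS)``
and the inbreeding excess split equally between the homozygote classes.
Each ramet copies its genet's genotype, then each of its two alleles
flips (ref <-> alt) independently with probability ``error_rate`` and
each call is masked with probability ``missing_rate``.

Spatial layouts mirror the two classical clonal growth strategies:
``guerrilla`` scatters ramet positions i.i.d. over the population extent
regardless of genet (widely spaced, intermixed ramets), ``phalanx``
clusters each genet's ramets tightly around a genet centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    SampleCoordinates,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate", "expected_summaries"]


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults state the regime the package is aimed at: 12 populations,
    2000 biallelic loci, F_ST 0.15, F_IS 0.2, ~8 genets per population
    with geometric ramet counts (mean ~1.7 stems per genet), 0.5%
    per-allele genotyping error, 20% missing calls, guerrilla layout.
    """

    n_pops: int = 12
    loci: int = 2000
    fst_target: float = 0.15
    fis: float | Sequence[float] = 0.2
    genets_per_pop: int | Sequence[int] = 8
    ramet_counts: Sequence[Sequence[int]] | None = None
    mean_ramets: float = 1.7
    max_ramets: int = 23
    error_rate: float = 0.005
    missing_rate: float = 0.2
    layout: str = "guerrilla"
    pop_extent_deg: float = 0.002
    phalanx_sigma_deg: float = 0.0001
    region_extent_deg: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must be in [0, 1)")
        for f in np.atleast_1d(np.asarray(self.fis, dtype=float)):
            if not (-1.0 <= f <= 1.0):
                raise ValueError("fis must be in [-1, 1]")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.layout not in ("guerrilla", "phalanx"):
            raise ValueError("layout must be 'guerrilla' or 'phalanx'")
        if self.n_pops < 1 or self.loci < 1:
            raise ValueError("n_pops and loci must be positive")


@dataclass
class SyntheticTruth:
    """Generating parameters and true memberships behind a simulated set."""

    config: SimulationConfig
    ancestral_freqs: np.ndarray                 # (m,) alt-allele freqs
    pop_freqs: np.ndarray                       # (n_pops, m)
    pop_fis: np.ndarray                         # (n_pops,)
    genet_of: dict[str, str]                    # sample -> genet label
    genet_genotypes: dict[str, np.ndarray]      # genet -> (m,) codes
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)


def _fis_per_pop(config: SimulationConfig) -> np.ndarray:
    fis = np.atleast_1d(np.asarray(config.fis, dtype=float))
    if fis.size == 1:
        return np.full(config.n_pops, fis[0])
    if fis.size != config.n_pops:
        raise ValueError("fis sequence length must equal n_pops")
    return fis


def _genets_per_pop(config: SimulationConfig) -> list[int]:
    g = config.genets_per_pop
    if np.isscalar(g):
        return [int(g)] * config.n_pops
    g = list(g)
    if len(g) != config.n_pops:
        raise ValueError("genets_per_pop sequence length must equal n_pops")
    return [int(x) for x in g]


def _draw_ramet_counts(config: SimulationConfig, rng: np.random.Generator) -> list[list[int]]:
    if config.ramet_counts is not None:
        counts = [list(map(int, pop)) for pop in config.ramet_counts]
        if len(counts) != config.n_pops:
            raise ValueError("ramet_counts must have one sequence per population")
        return counts
    # geometric on {1, 2, ...} with mean mean_ramets, truncated at max_ramets
    p = 1.0 / config.mean_ramets
    out = []
    for g in _genets_per_pop(config):
        draws = np.minimum(rng.geometric(p, size=g), config.max_ramets)
        out.append([int(x) for x in draws])
    return out


def _genotype_probs(q: np.ndarray, fis: float) -> np.ndarray:
    """(m, 3) probabilities of codes 0/1/2 under inbreeding coefficient fis."""
    het = 2.0 * q * (1.0 - q) * (1.0 - fis)
    excess = q * (1.0 - q) * fis
    hom_ref = (1.0 - q) ** 2 + excess
    hom_alt = q ** 2 + excess
    probs = np.stack([hom_ref, het, hom_alt], axis=1)
    if (probs < -1e-12).any():
        raise ValueError("fis incompatible with allele frequencies (negative class)")
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum(axis=1, keepdims=True)


def _apply_allele_errors(codes: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each of the two alleles of every call independently with prob error_rate."""
    if error_rate == 0.0:
        return codes.copy()
    flips = rng.random(codes.shape + (2,)) < error_rate
    # genotype code g is the count of alt alleles; a het call has one of each
    alt1 = np.where(codes == 2, 1, 0)           # first allele is alt?
    alt2 = np.where(codes >= 1, 1, 0)           # second allele is alt?
    alt1 = np.where(flips[..., 0], 1 - alt1, alt1)
    alt2 = np.where(flips[..., 1], 1 - alt2, alt2)
    return (alt1 + alt2).astype(np.int8)


def simulate(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SampleCoordinates, SyntheticTruth]:
    """Generate a clonal SNP dataset with full ground truth.

    Returns the genotype matrix, population map, sample coordinates and a
    :class:`SyntheticTruth` carrying the generating frequencies and the
    true genet of every sample. Fixing ``config.seed`` makes the output
    fully reproducible.
    """
    rng = np.random.default_rng(config.seed)
    m = config.loci
    theta = config.fst_target
    fis = _fis_per_pop(config)

    q_anc = rng.uniform(0.05, 0.95, size=m)
    if theta > 0.0:
        a = q_anc * (1.0 - theta) / theta
        b = (1.0 - q_anc) * (1.0 - theta) / theta
        pop_freqs = rng.beta(a, b, size=(config.n_pops, m))
    else:
        pop_freqs = np.tile(q_anc, (config.n_pops, 1))

    ramet_counts = _draw_ramet_counts(config, rng)

    sample_ids: list[str] = []
    pop_of: dict[str, str] = {}
    genet_of: dict[str, str] = {}
    genet_genotypes: dict[str, np.ndarray] = {}
    coords: dict[str, tuple[float, float]] = {}
    call_rows: list[np.ndarray] = []

    # population centres laid out on a grid across the region
    n_side = int(np.ceil(np.sqrt(config.n_pops)))
    centres = [
        (
            (i % n_side) * config.region_extent_deg / max(n_side - 1, 1),
            (i // n_side) * config.region_extent_deg / max(n_side - 1, 1),
        )
        for i in range(config.n_pops)
    ]

    for p in range(config.n_pops):
        pop = f"pop{p + 1:02d}"
        probs = _genotype_probs(pop_freqs[p], float(fis[p]))
        cx, cy = centres[p]
        half = config.pop_extent_deg / 2.0
        for g, n_ramets in enumerate(ramet_counts[p]):
            genet = f"{pop}_g{g + 1:02d}"
            u = rng.random((m, 1))
            cum = np.cumsum(probs, axis=1)
            geno = (u > cum[:, :2]).sum(axis=1).astype(np.int8)
            genet_genotypes[genet] = geno
            if config.layout == "phalanx":
                gx = cx + rng.uniform(-half, half)
                gy = cy + rng.uniform(-half, half)
            for r in range(n_ramets):
                sid = f"{pop}_g{g + 1:02d}_r{r + 1:02d}"
                sample_ids.append(sid)
                pop_of[sid] = pop
                genet_of[sid] = genet
                calls = _apply_allele_errors(geno, config.error_rate, rng)
                if config.missing_rate > 0.0:
                    mask = rng.random(m) < config.missing_rate
                    calls = np.where(mask, MISSING, calls).astype(np.int8)
                call_rows.append(calls)
                if config.layout == "guerrilla":
                    x = cx + rng.uniform(-half, half)
                    y = cy + rng.uniform(-half, half)
                else:
                    x = gx + rng.normal(0.0, config.phalanx_sigma_deg)
                    y = gy + rng.normal(0.0, config.phalanx_sigma_deg)
                coords[sid] = (float(x), float(y))

    gm = GenotypeMatrix(sample_ids, [f"1:{1000 + j}" for j in range(m)], np.vstack(call_rows))
    popmap = PopulationMap(pop_of)
    truth = SyntheticTruth(
        config=config,
        ancestral_freqs=q_anc,
        pop_freqs=pop_freqs,
        pop_fis=fis,
        genet_of=genet_of,
        genet_genotypes=genet_genotypes,
        coordinates=dict(coords),
    )
    return gm, popmap, SampleCoordinates(coords), truth


def expected_summaries(truth: SyntheticTruth) -> dict:
    """Closed-form expectations implied by the generating frequencies.

    Per population: expected observed heterozygosity is the mean of
    ``2q(1-q)(1-F_IS)`` over loci, expected gene diversity the mean of
    ``2q(1-q)``; the configured F_IS and theta pass through. These are
    the oracles parameter-recovery tests compare estimates against.
    """
    pops = [f"pop{p + 1:02d}" for p in range(truth.config.n_pops)]
    out: dict = {"theta": truth.config.fst_target, "per_population": {}}
    for p, pop in enumerate(pops):
        q = truth.pop_freqs[p]
        het = 2.0 * q * (1.0 - q)
        fis = float(truth.pop_fis[p])
        out["per_population"][pop] = {
            "H_E": float(np.mean(het)),
            "H_O": float(np.mean(het * (1.0 - fis))),
            "F_IS": fis,
        }
    return out
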