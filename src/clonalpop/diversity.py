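"""Per-population heterozygosity, inbreeding coefficient and heterozygosity deficit.

Observed heterozygosity H_O at a locus is the fraction of heterozygous
calls among non-missing calls within the population. Expected
heterozygosity H_E is Nei's small-sample-corrected gene diversity,

    H_E = (2 n_c / (2 n_c - 1)) * (1 - q^2 - (1-q)^2),

with n_c the number of non-missing diploids at the locus and q the
within-population alternate-allele frequency. Population-level values
are unweighted means over loci; F_IS = 1 - mean(H_O)/mean(H_E) is a
ratio of averages, which is robust to near-monomorphic loci. The
heterozygosity deficit delta_H = H_E - H_O summarises how far a
population falls short of Hardy-Weinberg heterozygosity, a signature of
inbreeding or dominant clonal reproduction followed by selfing-like
mating. Loci monomorphic within a population still contribute 0 to its
means so that populations stay comparable; loci with zero calls in a
population are excluded from that population's means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "observed_het",
    "expected_het",
    "inbreeding_fis",
    "delta_h",
    "diversity_table",
]


def _pop_calls(gm: GenotypeMatrix, popmap: PopulationMap, population: str) -> np.ndarray:
    idx = popmap.samples_of(population, gm.sample_ids)
    if idx.size == 0:
        raise ValueError(f"population {population!r} has no samples in the matrix")
    return gm.calls[idx]


def _per_locus_ho(calls: np.ndarray) -> np.ndarray:
    """Per-locus observed heterozygosity; NaN where a locus has no calls."""
    nonmiss = (calls != MISSING).sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nonmiss > 0, het / nonmiss, np.nan)


def _per_locus_he(calls: np.ndarray) -> np.ndarray:
    """Per-locus unbiased gene diversity; NaN where a locus has no calls."""
    nonmiss = (calls != MISSING).sum(axis=0)
    alt = np.where(calls == MISSING, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = alt / (2.0 * nonmiss)
        raw = 1.0 - q**2 - (1.0 - q) ** 2
        corr = 2.0 * nonmiss / np.maximum(2.0 * nonmiss - 1.0, 1.0)
        return np.where(nonmiss > 0, corr * raw, np.nan)


def observed_het(
    gm: GenotypeMatrix, popmap: PopulationMap
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Mean and per-locus observed heterozygosity for each population."""
    popmap.validate(gm)
    means: dict[str, float] = {}
    per_locus: dict[str, np.ndarray] = {}
    for pop in popmap.populations:
        ho = _per_locus_ho(_pop_calls(gm, popmap, pop))
        if np.isnan(ho).all():
            raise ValueError(f"population {pop!r} has no callable loci")
        per_locus[pop] = ho
        means[pop] = float(np.nanmean(ho))
    return means, per_locus


def expected_het(
    gm: GenotypeMatrix, popmap: PopulationMap
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Mean and per-locus unbiased gene diversity for each population."""
    popmap.validate(gm)
    means: dict[str, float] = {}
    per_locus: dict[str, np.ndarray] = {}
    for pop in popmap.populations:
        he = _per_locus_he(_pop_calls(gm, popmap, pop))
        if np.isnan(he).all():
            raise ValueError(f"population {pop!r} has no callable loci")
        per_locus[pop] = he
        means[pop] = float(np.nanmean(he))
    return means, per_locus


def inbreeding_fis(h_o: dict[str, float], h_e: dict[str, float]) -> dict[str, float]:
    """F_IS = 1 - H_O/H_E per population (NaN where H_E = 0)."""
    out: dict[str, float] = {}
    for pop, he in h_e.items():
        out[pop] = 1.0 - h_o[pop] / he if he > 0.0 else float("nan")
    return out


def delta_h(h_e: dict[str, float], h_o: dict[str, float]) -> dict[str, float]:
    """Heterozygosity deficit delta_H = H_E - H_O per population."""
    return {pop: h_e[pop] - h_o[pop] for pop in h_e}


def diversity_table(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-population N, H_E, H_O, F_IS and delta_H as a DataFrame.

    Rows follow the population order of ``popmap``; this is the table a
    conservation assessment reads population genetic health from.
    """
    ho, _ = observed_het(gm, popmap)
    he, _ = expected_het(gm, popmap)
    fis = inbreeding_fis(ho, he)
    dh = delta_h(he, ho)
    rows = []
    for pop in popmap.populations:
        n = popmap.samples_of(pop, gm.sample_ids).size
        rows.append(
            {
                "population": pop,
                "N": n,
                "H_E": he[pop],
                "H_O": ho[pop],
                "F_IS": fis[pop],
                "delta_H": dh[pop],
            }
        )
    return pd.DataFrame(rows).set_index("population")
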