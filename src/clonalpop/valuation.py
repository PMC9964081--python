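"""Conservation genetic-value classification and the end-to-end pipeline.

Managers triaging populations of a threatened clonal plant need a
transparent rule that turns the population-genetic evidence — observed
heterozygosity, inbreeding, divergence from other populations, and
whether a population carries ancestry found nowhere else — into a
coarse conservation priority. The decision list used here is the
minimal one consistent with a full published twelve-population
assessment of this kind (verified exhaustively in the test suite):

* no unique ancestry                                     -> Low value
* unique ancestry, High/Very High divergence, F_IS < 0.05 -> High value
* otherwise                                              -> Moderate value

Divergence is binned from the population's mean pairwise F_ST against
all others: < 0.05 Low, [0.05, 0.15) Moderate, [0.15, 0.20) High,
>= 0.20 Very High. Unique ancestry is operationalised as a cluster that
is dominant (mean membership >= 0.5) in the population and minor
(< 0.2) everywhere else. Observed heterozygosity is reported alongside
but does not gate the rule: the published labels are fully determined
without an H_O cutoff.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonality, diversity, divergence, structure
from .genotype_io import (
    GenotypeMatrix,
    PopulationMap,
    SampleCoordinates,
    filter_by_presence,
    read_coords,
    read_popmap,
    read_vcf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DIVERGENCE_LEVELS",
    "PopulationAssessment",
    "RunConfig",
    "classify_genetic_value",
    "derive_divergence_level",
    "derive_unique_ancestry",
    "run_pipeline",
]

DIVERGENCE_LEVELS = ("Low", "Moderate", "High", "Very High")


@dataclass
class PopulationAssessment:
    population: str
    H_O: float
    F_IS: float
    divergence_level: str
    unique_ancestry: str  # "Yes" / "No"
    genetic_value: str    # "Low" / "Moderate" / "High"


def classify_genetic_value(
    H_O: float, F_IS: float, divergence_level: str, unique_ancestry: str
) -> str:
    """Genetic-value label from the four assessment inputs (pure function)."""
    if divergence_level not in DIVERGENCE_LEVELS:
        raise ValueError(f"unknown divergence level {divergence_level!r}")
    if unique_ancestry not in ("Yes", "No"):
        raise ValueError(f"unique_ancestry must be Yes/No, got {unique_ancestry!r}")
    if unique_ancestry == "No":
        return "Low"
    if divergence_level in ("High", "Very High") and F_IS < 0.05:
        return "High"
    return "Moderate"


def derive_divergence_level(fst: divergence.FstMatrix, population: str) -> str:
    """Bin a population's mean pairwise F_ST against all others."""
    if len(fst.populations) < 2:
        raise ValueError("divergence level needs at least two populations")
    mean_theta = fst.mean_vs_others(population)
    if mean_theta < 0.05:
        return "Low"
    if mean_theta < 0.15:
        return "Moderate"
    if mean_theta < 0.20:
        return "High"
    return "Very High"


def derive_unique_ancestry(
    Q: np.ndarray,
    sample_ids: list[str],
    popmap: PopulationMap,
    dominance: float = 0.5,
    minor: float = 0.2,
) -> dict[str, str]:
    """Yes/No per population: does some cluster dominate here and nowhere else?"""
    pops = popmap.populations
    labels = popmap.labels_for(sample_ids)
    mean_q = np.stack([Q[labels == pop].mean(axis=0) for pop in pops])
    out: dict[str, str] = {}
    for i, pop in enumerate(pops):
        others = np.delete(mean_q, i, axis=0)
        private = (mean_q[i] >= dominance) & (others < minor).all(axis=0)
        out[pop] = "Yes" if private.any() else "No"
    return out


@dataclass
class RunConfig:
    """Inputs and knobs of one full analysis run; serialised beside outputs."""

    vcf: str
    popmap: str
    coords: str | None = None
    out_dir: str = "clonalpop_out"
    min_presence: float = 0.6
    k_min: int = 1
    k_max: int = 6
    n_perm: int = 9999
    seed: int = 0
    clone_threshold: float | None = None
    max_missing: float = 0.25
    ancestry_alpha: float = 10.0
    dominance: float = 0.5
    minor: float = 0.2

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Filter -> diversity -> divergence/Mantel -> ancestry -> clones -> valuation.

    Writes ``report.json`` plus per-table TSVs under ``config.out_dir``
    and returns the report as a dict. Without a coordinates file the
    Mantel test and clone maps are skipped and the report says so.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    report: dict = {"stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("filter")
    gm = read_vcf(config.vcf)
    gm = filter_by_presence(gm, config.min_presence)
    popmap = read_popmap(config.popmap)
    popmap.validate(gm)
    report["stages"]["filter"] = {"n_samples": gm.n, "n_loci": gm.m}

    coords: SampleCoordinates | None = None
    if config.coords and os.path.exists(config.coords):
        coords = read_coords(config.coords)
    elif config.coords:
        logger.warning("coordinates file %s not found; Mantel and maps skipped", config.coords)

    stage("diversity")
    div = diversity.diversity_table(gm, popmap)
    div.to_csv(out / "diversity.tsv", sep="\t")
    report["stages"]["diversity"] = div.reset_index().to_dict(orient="records")

    stage("divergence")
    fst = divergence.pairwise_fst(gm, popmap)
    fst.to_frame().to_csv(out / "fst.tsv", sep="\t")
    mantel = None
    if coords is not None and len(popmap.populations) >= 3:
        pops, km = divergence.geo_distance(coords, popmap)
        mantel = divergence.mantel_test(
            km, fst.theta, n_perm=config.n_perm, seed=config.seed
        )
        report["stages"]["mantel"] = dataclasses.asdict(mantel)
    else:
        report["stages"]["mantel"] = "skipped (no coordinates)"

    stage("structure")
    k_range = range(config.k_min, config.k_max + 1)
    best_k, ce_curve = structure.select_k(
        gm, k_range, seed=config.seed, alpha=config.ancestry_alpha
    )
    anc = structure.estimate_ancestry(
        gm, best_k, seed=config.seed, alpha=config.ancestry_alpha
    )
    pd.DataFrame(
        anc.Q, index=gm.sample_ids, columns=[f"cluster_{k+1}" for k in range(best_k)]
    ).to_csv(out / "Q.tsv", sep="\t")
    report["stages"]["structure"] = {
        "K": best_k,
        "cross_entropy": {str(k): float(v) for k, v in ce_curve.items()},
    }

    stage("clonality")
    clone_rows = []
    assign_rows = []
    for pop in popmap.populations:
        idx = popmap.samples_of(pop, gm.sample_ids)
        sub = gm.take_samples(idx)
        try:
            delim = clonality.CloneDelimiter(
                threshold=config.clone_threshold, max_missing=config.max_missing
            ).fit(sub)
        except ValueError as exc:
            logger.warning("clonality skipped for %s: %s", pop, exc)
            continue
        a = delim.assignment_
        clone_rows.append(
            {
                "population": pop,
                "N": a.N,
                "threshold": a.d_star if a.d_star is not None else "n/a",
                "G": a.G,
                "ramets_per_genet": ",".join(
                    str(c) for c in sorted(a.ramets_per_genet.values(), reverse=True)
                ),
                "CR": a.CR,
            }
        )
        for sid, genet in a.genet_of.items():
            assign_rows.append(
                {"sample": sid, "population": pop, "genet": f"{pop}:{genet}"}
            )
        if coords is not None:
            df_map, intermix = clonality.clonal_map(a, coords)
            clone_rows[-1]["intermixing_index"] = intermix
    clones = pd.DataFrame(clone_rows)
    clones.to_csv(out / "clones.tsv", sep="\t", index=False)
    pd.DataFrame(assign_rows).to_csv(out / "clone_assignments.tsv", sep="\t", index=False)
    report["stages"]["clonality"] = clone_rows

    stage("valuation")
    unique = derive_unique_ancestry(
        anc.Q, gm.sample_ids, popmap, dominance=config.dominance, minor=config.minor
    )
    assessments = []
    for pop in popmap.populations:
        level = derive_divergence_level(fst, pop)
        a = PopulationAssessment(
            population=pop,
            H_O=float(div.loc[pop, "H_O"]),
            F_IS=float(div.loc[pop, "F_IS"]),
            divergence_level=level,
            unique_ancestry=unique[pop],
            genetic_value=classify_genetic_value(
                float(div.loc[pop, "H_O"]), float(div.loc[pop, "F_IS"]), level, unique[pop]
            ),
        )
        assessments.append(dataclasses.asdict(a))
    pd.DataFrame(assessments).to_csv(out / "assessment.tsv", sep="\t", index=False)
    report["stages"]["valuation"] = assessments

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
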