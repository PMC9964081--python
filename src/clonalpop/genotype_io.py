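"""Genotype matrices, VCF and tabular I/O, and locus presence filtering.

The in-memory substrate for every statistic in this package is a samples
x loci matrix of diploid genotype codes: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, ``MISSING`` (-1) = no call.
Codes are unphased counts of the alternate allele; phase is discarded on
read. Only biallelic SNPs are retained — multiallelic and non-SNP records
are dropped, matching reduced-representation (ddRAD) SNP panels where
statistics are computed on biallelic sites.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1


class EmptyDataError(ValueError):
    """Raised when an input or filter leaves no usable loci."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for ``n`` samples at ``m`` biallelic loci.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``calls``.
    locus_ids : list of str
        Unique locus identifiers in ``CHROM:POS`` form, one per column.
    calls : ndarray of shape (n, m), integer
        Genotype codes in ``{0, 1, 2, MISSING}``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x loci array")
        n, m = self.calls.shape
        if n < 1 or m < 1:
            raise EmptyDataError(f"empty genotype matrix ({n} samples, {m} loci)")
        if len(self.sample_ids) != n or len(self.locus_ids) != m:
            raise ValueError("id lengths do not match calls shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.calls[bad])}")

    @property
    def n(self) -> int:
        return self.calls.shape[0]

    @property
    def m(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, m) mask, True where the call is missing."""
        return self.calls == MISSING

    def locus_presence(self) -> np.ndarray:
        """Fraction of samples with a non-missing call, per locus."""
        return (self.calls != MISSING).sum(axis=0) / self.n

    def sample_missingness(self) -> np.ndarray:
        """Fraction of loci missing, per sample."""
        return (self.calls == MISSING).sum(axis=1) / self.m

    def take_samples(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], list(self.locus_ids), self.calls[idx]
        )

    def take_loci(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.sample_ids), [self.locus_ids[j] for j in idx], self.calls[:, idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationMap:
    """Sample -> population assignment.

    ``populations`` preserves first-appearance order of the labels, which
    fixes row/column order in every downstream per-population table.
    """

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.populations:
            seen: dict[str, None] = {}
            for pop in self.assignments.values():
                seen.setdefault(pop, None)
            self.populations = list(seen)

    def validate(self, gm: GenotypeMatrix) -> None:
        """Raise if any matrix sample lacks a population label."""
        missing = [s for s in gm.sample_ids if s not in self.assignments]
        if missing:
            raise KeyError(
                f"samples absent from population map: {', '.join(missing)}"
            )

    def labels_for(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.assignments[s] for s in sample_ids])

    def samples_of(self, population: str, sample_ids: list[str]) -> np.ndarray:
        """Indices (into sample_ids) of the members of ``population``."""
        return np.array(
            [i for i, s in enumerate(sample_ids) if self.assignments.get(s) == population],
            dtype=int,
        )


@dataclass
class SampleCoordinates:
    """Per-sample longitude/latitude in decimal degrees (WGS84)."""

    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for sid, (lon, lat) in self.coords.items():
            if not (-180.0 <= lon <= 180.0):
                raise ValueError(f"{sid}: longitude {lon} outside [-180, 180]")
            if not (-90.0 <= lat <= 90.0):
                raise ValueError(f"{sid}: latitude {lat} outside [-90, 90]")

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.coords

    def __getitem__(self, sample_id: str) -> tuple[float, float]:
        return self.coords[sample_id]

    def array_for(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.coords]
        if missing:
            raise KeyError(f"samples without coordinates: {', '.join(missing)}")
        return np.array([self.coords[s] for s in sample_ids], dtype=float)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF (v4.2, diploid GT) into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (with a logged count);
    ``./.`` and half-missing genotypes map to :data:`MISSING`; phased and
    unphased separators are treated identically.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_dropped = 0
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        rows.append(remap[v.gt_types])
        locus_ids.append(f"{v.CHROM}:{v.POS}")
    vcf.close()
    if n_dropped:
        logger.info("dropped %d multiallelic/non-SNP records from %s", n_dropped, path)
    if not locus_ids:
        raise EmptyDataError(f"no biallelic SNP records in {path}")
    return GenotypeMatrix(samples, locus_ids, np.column_stack(rows))


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 readable by :func:`read_vcf`.

    Locus ids must be in ``CHROM:POS`` form. Alleles are written as the
    placeholder pair A/T: genotype codes, not nucleotides, are the data
    this package round-trips.
    """
    records = []
    chroms: dict[str, None] = {}
    for lid in gm.locus_ids:
        chrom, _, pos = lid.rpartition(":")
        if not chrom or not pos.isdigit():
            raise ValueError(f"locus id {lid!r} is not CHROM:POS")
        chroms.setdefault(chrom, None)
        records.append((chrom, pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonalpop\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, (chrom, pos) in enumerate(records):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.calls[:, j])
            fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def filter_by_presence(gm: GenotypeMatrix, min_presence: float) -> GenotypeMatrix:
    """Keep loci genotyped in at least ``min_presence`` of samples.

    The threshold is inclusive: a locus with presence exactly equal to
    ``min_presence`` is kept. Sample set and locus order are unchanged.
    """
    if not (0.0 < min_presence <= 1.0):
        raise ValueError("min_presence must be in (0, 1]")
    counts = (gm.calls != MISSING).sum(axis=0)
    # integer-count comparison avoids float boundary surprises at e.g. 3/5 vs 0.6
    keep = np.nonzero(counts >= min_presence * gm.n - 1e-9)[0]
    if keep.size == 0:
        raise EmptyDataError(
            f"presence filter at min_presence={min_presence} removed all {gm.m} loci"
        )
    return gm.take_loci(keep)


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a two-column TSV ``sample_id<TAB>population``."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated fields")
            sid, pop = parts
            if sid in assignments:
                raise ValueError(f"{path}:{line_no}: duplicate sample {sid}")
            assignments[sid] = pop
    return PopulationMap(assignments)


def read_coords(path: str | os.PathLike) -> SampleCoordinates:
    """Read a three-column TSV ``sample_id<TAB>longitude<TAB>latitude``."""
    coords: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated fields")
            sid, lon, lat = parts
            coords[sid] = (float(lon), float(lat))
    return SampleCoordinates(coords)


def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid, pop in popmap.assignments.items():
            fh.write(f"{sid}\t{pop}\n")


def write_coords(coords: SampleCoordinates, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid, (lon, lat) in coords.coords.items():
            fh.write(f"{sid}\t{lon:.8f}\t{lat:.8f}\n")
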