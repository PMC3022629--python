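"""Read and subset PLINK-text genotype data (PED/MAP pairs).

The PED dialect is the classic whitespace-delimited text format: six leading
metadata columns (family ID, individual ID, paternal ID, maternal ID, sex,
phenotype) followed by two allele columns per SNP in MAP order.  The MAP file
has four columns: chromosome, SNP ID, genetic distance (parsed and discarded)
and 1-based bp position.  Missing genotypes use the code "0" for both alleles;
half-missing calls such as "A 0" are rejected because silently dropping one
allele would shift allele frequencies.

Population membership is not part of PED, so it is supplied either as a
single default label or via a sidecar table mapping individual ID to
population (see :func:`read_sample_info`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np

from .errors import DataError, ParseError, SelectionError

logger = logging.getLogger(__name__)

MISSING_ALLELE = "0"

#: Chromosome sort order: autosomes numerically, then X, Y, XY, MT.
_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "XY": 25, "MT": 26})

Source = Union[str, Path, TextIO]


def _chrom_key(chrom: str) -> int:
    return _CHROM_ORDER.get(chrom, 99)


@dataclass(frozen=True)
class SampleRecord:
    """One individual's pedigree metadata.

    A sample is a *founder* when both parental IDs equal the null code "0";
    trio children therefore are non-founders.
    """

    family_id: str
    individual_id: str
    paternal_id: str = "0"
    maternal_id: str = "0"
    sex: int = 0
    population: str = "NA"

    def __post_init__(self):
        if not self.individual_id:
            raise DataError("individual_id must be non-empty")

    @property
    def is_founder(self) -> bool:
        return self.paternal_id == "0" and self.maternal_id == "0"


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's map entry: identifier, chromosome label and 1-based position."""

    snp_id: str
    chromosome: str
    position_bp: int
    alleles_observed: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.position_bp < 1:
            raise DataError(f"{self.snp_id}: position_bp must be >= 1")


@dataclass
class GenotypeDataset:
    """Samples x SNPs allele-call matrix with pedigree and map metadata.

    ``calls`` has shape (n_samples, n_snps, 2) with single-character allele
    symbols; a call is missing iff both alleles are "0".
    """

    samples: list
    snps: list
    calls: np.ndarray

    def __post_init__(self):
        n, m = len(self.samples), len(self.snps)
        if self.calls.shape != (n, m, 2):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} samples x {m} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list:
        return [s.individual_id for s in self.samples]

    @property
    def snp_ids(self) -> list:
        return [s.snp_id for s in self.snps]

    def snp_calls(self, j: int) -> np.ndarray:
        """Allele pairs for SNP column ``j``, shape (n_samples, 2)."""
        return self.calls[:, j, :]

    def subset_samples(self, index: Sequence[int]) -> "GenotypeDataset":
        index = list(index)
        return GenotypeDataset(
            samples=[self.samples[i] for i in index],
            snps=list(self.snps),
            calls=self.calls[index, :, :].copy(),
        )

    def subset_snps(self, index: Sequence[int]) -> "GenotypeDataset":
        index = list(index)
        return GenotypeDataset(
            samples=list(self.samples),
            snps=[self.snps[j] for j in index],
            calls=self.calls[:, index, :].copy(),
        )


def _open(source: Source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r"), True


def _observed_alleles(column: np.ndarray, snp_id: str) -> frozenset:
    alleles = set(np.unique(column)) - {MISSING_ALLELE}
    if len(alleles) > 2:
        raise ParseError(
            f"SNP {snp_id}: {len(alleles)} distinct alleles observed "
            f"({sorted(alleles)}); at most 2 expected — malformed file?"
        )
    return frozenset(alleles)


def read_map(source: Source) -> list:
    """Parse a MAP file into a list of :class:`SnpRecord`.

    Rows with a negative bp position (PLINK's exclusion convention) are
    dropped with a warning.
    """
    records = []
    fh, close = _open(source)
    try:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ParseError(
                    f"MAP line {lineno}: expected 4 columns "
                    f"(chrom, snp_id, cM, bp), got {len(fields)}"
                )
            chrom, snp_id, _cm, bp = fields
            try:
                pos = int(bp)
            except ValueError as exc:
                raise ParseError(f"MAP line {lineno}: bad bp '{bp}'") from exc
            if pos < 0:
                warnings.warn(
                    f"MAP line {lineno}: SNP {snp_id} has negative bp "
                    f"({pos}); dropped (PLINK exclusion convention)"
                )
                continue
            if pos == 0:
                raise ParseError(f"MAP line {lineno}: bp must be >= 1")
            records.append(SnpRecord(snp_id=snp_id, chromosome=chrom, position_bp=pos))
    finally:
        if close:
            fh.close()
    return records


def read_sample_info(source: Source) -> dict:
    """Read the two-column (individual_id, population) sidecar table.

    An optional header line "IID<TAB>POP" is skipped.
    """
    mapping = {}
    fh, close = _open(source)
    try:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and [f.upper() for f in fields] == ["IID", "POP"]:
                continue
            if len(fields) != 2:
                raise ParseError(
                    f"sample-info line {lineno}: expected 2 columns, got {len(fields)}"
                )
            mapping[fields[0]] = fields[1]
    finally:
        if close:
            fh.close()
    return mapping


def read_ped_map(
    ped_source: Source,
    map_source: Source,
    population_labels: Union[str, Mapping[str, str], None] = None,
) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Parameters
    ----------
    ped_source, map_source
        Paths or open text handles for the PED and MAP files.
    population_labels
        Either a single label applied to every sample, a mapping from
        family ID or individual ID to population label, or None ("NA").

    The PED phenotype column is ignored on read.  Raises :class:`ParseError`
    naming the offending line for column-count mismatches, half-missing
    genotype calls and duplicate individual IDs.
    """
    snps = read_map(map_source)
    n_snps = len(snps)
    expected = 6 + 2 * n_snps

    samples = []
    rows = []
    seen_ids = set()
    fh, close = _open(ped_source)
    try:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != expected:
                raise ParseError(
                    f"PED line {lineno}: expected {expected} columns "
                    f"(6 metadata + 2 x {n_snps} alleles), got {len(fields)}"
                )
            fid, iid, pat, mat, sex, _pheno = fields[:6]
            if iid in seen_ids:
                raise ParseError(f"PED line {lineno}: duplicate individual_id '{iid}'")
            seen_ids.add(iid)
            try:
                sex_code = int(sex)
            except ValueError:
                sex_code = 0
            alleles = fields[6:]
            row = np.array(alleles, dtype="U8").reshape(n_snps, 2)
            half = (row == MISSING_ALLELE).sum(axis=1) == 1
            if half.any():
                j = int(np.nonzero(half)[0][0])
                raise ParseError(
                    f"PED line {lineno}: half-missing genotype "
                    f"'{row[j, 0]} {row[j, 1]}' at SNP {snps[j].snp_id}"
                )
            rows.append(row)
            samples.append(
                SampleRecord(
                    family_id=fid,
                    individual_id=iid,
                    paternal_id=pat,
                    maternal_id=mat,
                    sex=sex_code,
                )
            )
    finally:
        if close:
            fh.close()

    calls = (
        np.stack(rows, axis=0)
        if rows
        else np.empty((0, n_snps, 2), dtype="U8")
    )

    # attach observed alleles per SNP (also validates <=2 alleles)
    snps = [
        replace(s, alleles_observed=_observed_alleles(calls[:, j, :], s.snp_id))
        for j, s in enumerate(snps)
    ]

    # assign populations
    if population_labels is None:
        pops = ["NA"] * len(samples)
    elif isinstance(population_labels, str):
        pops = [population_labels] * len(samples)
    else:
        pops = [
            population_labels.get(
                s.individual_id, population_labels.get(s.family_id, "NA")
            )
            for s in samples
        ]
    samples = [replace(s, population=p) for s, p in zip(samples, pops)]

    sex_chroms = {s.chromosome for s in snps} & {"X", "Y"}
    if sex_chroms:
        warnings.warn(
            f"chromosome(s) {sorted(sex_chroms)} present: sex chromosomes are "
            "treated as diploid autosomes (no haploid male X/Y handling)"
        )

    logger.info("read %d samples x %d SNPs", len(samples), n_snps)
    return GenotypeDataset(samples=samples, snps=snps, calls=calls)


def extract_region(
    ds: GenotypeDataset, chromosome: str, start_bp: int, end_bp: int
) -> GenotypeDataset:
    """Keep SNPs on ``chromosome`` with start_bp <= position <= end_bp.

    Both endpoints are inclusive.  The retained SNPs are sorted by
    (chromosome, position); the sample list is unchanged.  Raises
    :class:`SelectionError` if the window contains no SNPs.
    """
    if start_bp > end_bp:
        raise SelectionError(f"start_bp {start_bp} > end_bp {end_bp}")
    chromosome = str(chromosome)
    idx = [
        j
        for j, s in enumerate(ds.snps)
        if s.chromosome == chromosome and start_bp <= s.position_bp <= end_bp
    ]
    if not idx:
        raise SelectionError(
            f"no SNPs on chromosome {chromosome} in [{start_bp}, {end_bp}]; "
            "widen the window or check the chromosome label"
        )
    idx.sort(key=lambda j: (_chrom_key(ds.snps[j].chromosome), ds.snps[j].position_bp))
    logger.info(
        "region chr%s:%d-%d retained %d of %d SNPs",
        chromosome, start_bp, end_bp, len(idx), ds.n_snps,
    )
    return ds.subset_snps(idx)


def extract_snps(ds: GenotypeDataset, snp_ids: Iterable[str]) -> GenotypeDataset:
    """Keep the listed SNPs, in map order.

    Unknown IDs are collected: if *all* are missing a :class:`SelectionError`
    lists them; partial misses produce a warning naming each miss.
    """
    wanted = list(snp_ids)
    if not wanted:
        raise SelectionError("empty SNP-ID list")
    wanted_set = set(wanted)
    present = {s.snp_id for s in ds.snps}
    misses = [sid for sid in wanted if sid not in present]
    if len(misses) == len(wanted_set):
        raise SelectionError(f"none of the requested SNPs found: {sorted(set(misses))}")
    if misses:
        warnings.warn(f"requested SNPs not in MAP: {sorted(set(misses))}")
    idx = [j for j, s in enumerate(ds.snps) if s.snp_id in wanted_set]
    return ds.subset_snps(idx)


def filter_founders(ds: GenotypeDataset) -> GenotypeDataset:
    """Keep exactly the samples with both parental IDs equal to "0"."""
    idx = [i for i, s in enumerate(ds.samples) if s.is_founder]
    logger.info("founder filter: %d of %d samples retained", len(idx), ds.n_samples)
    return ds.subset_samples(idx)


def filter_population(ds: GenotypeDataset, selection: str) -> GenotypeDataset:
    """Keep samples of one population, or all of them when ``selection="pooled"``."""
    if selection == "pooled":
        return ds
    available = sorted({s.population for s in ds.samples})
    if selection not in available:
        raise SelectionError(
            f"unknown population '{selection}'; available: {available} or 'pooled'"
        )
    idx = [i for i, s in enumerate(ds.samples) if s.population == selection]
    logger.info(
        "population filter %s: %d of %d samples retained",
        selection, len(idx), ds.n_samples,
    )
    return ds.subset_samples(idx)
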