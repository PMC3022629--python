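"""Synthetic genotype + expression fixtures with known ground truth.

The generator emulates the HapMap phase II sampling design: four
populations, two of which (CEU, YRI) are collected as parent-parent-child
trios and two (CHB, JPT) as unrelated individuals — 270 individuals in
total, of whom 210 are founders.  Founder genotypes are drawn independently
per SNP under Hardy-Weinberg equilibrium at the configured minor-allele
frequency; trio children receive one uniformly chosen allele from each
parent (Mendelian transmission).  Expression phenotypes are a linear
genetic effect at an optional causal SNP plus Gaussian noise; a gene may be
represented by several probes which share the genetic effect but carry
independent noise, mimicking multi-probe arrays.

SNPs are independent by default (no linkage disequilibrium).  An optional
block-copy helper duplicates a SNP's genotypes with flip noise to create
correlated proxies — a visualization aid for LD-driven association
plateaus, not a coalescent model.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .assoc import GeneticModel, code_genotypes
from .errors import DataError, OutputError
from .expression_io import ExpressionProfile
from .genotype_io import GenotypeDataset, SampleRecord, SnpRecord

_ALLELES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PopulationSpec:
    """One population: unrelated singletons plus parent-parent-child trios."""

    label: str
    n_unrelated: int = 0
    n_trios: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_unrelated + 3 * self.n_trios

    @property
    def n_founders(self) -> int:
        return self.n_unrelated + 2 * self.n_trios


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    chromosome: str
    position_bp: int
    maf: float
    alleles: Optional[Tuple[str, str]] = None  # (minor, major); random if None

    def __post_init__(self):
        if not (0 < self.maf <= 0.5):
            raise DataError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class CausalSpec:
    snp_id: str
    model: GeneticModel = GeneticModel.ADDITIVE
    beta: float = 0.5
    noise_sd: float = 1.0


@dataclass
class SimConfig:
    populations: List[PopulationSpec]
    snps: List[SnpSpec]
    causal: Optional[CausalSpec] = None
    gene_symbol: str = "GENE1"
    probe_prefix: str = "ILMN_"
    n_probes_per_gene: int = 1
    noise_sd: float = 1.0  # used when causal is None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_rate < 1):
            raise DataError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        for chrom in {s.chromosome for s in self.snps}:
            pos = [s.position_bp for s in self.snps if s.chromosome == chrom]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise DataError(
                    f"positions on chromosome {chrom} must be strictly increasing"
                )


def hapmap_populations() -> List[PopulationSpec]:
    """The HapMap phase II sampling design: 270 individuals, 210 founders."""
    return [
        PopulationSpec("CEU", n_unrelated=0, n_trios=30),
        PopulationSpec("CHB", n_unrelated=45, n_trios=0),
        PopulationSpec("JPT", n_unrelated=45, n_trios=0),
        PopulationSpec("YRI", n_unrelated=0, n_trios=30),
    ]


def snp_grid(
    n: int,
    chromosome: str = "4",
    start_bp: int = 8_168_000,
    spacing: int = 5_000,
    maf: float = 0.3,
    prefix: str = "rs",
) -> List[SnpSpec]:
    """Evenly spaced SNPs with a common MAF, convenient for fixtures."""
    return [
        SnpSpec(f"{prefix}{i + 1}", chromosome, start_bp + i * spacing, maf)
        for i in range(n)
    ]


def _draw_founder_calls(rng, maf: float, minor: str, major: str, n: int) -> np.ndarray:
    # per-chromosome Bernoulli(maf) draws => HWE genotype frequencies
    picks = rng.random((n, 2)) < maf
    out = np.where(picks, minor, major)
    return out.astype("U8")


def simulate_genotypes(cfg: SimConfig) -> GenotypeDataset:
    """Generate a pedigree-structured genotype dataset from a SimConfig."""
    rng = np.random.default_rng(cfg.seed)

    samples: List[SampleRecord] = []
    parent_of: List[Tuple[int, int]] = []  # child row -> (father row, mother row)
    founder_rows: List[int] = []
    for pop in cfg.populations:
        for u in range(pop.n_unrelated):
            iid = f"{pop.label}_U{u + 1:03d}"
            founder_rows.append(len(samples))
            samples.append(
                SampleRecord(
                    family_id=iid, individual_id=iid,
                    sex=int(rng.integers(1, 3)), population=pop.label,
                )
            )
        for t in range(pop.n_trios):
            fam = f"{pop.label}_F{t + 1:03d}"
            father_row = len(samples)
            samples.append(
                SampleRecord(
                    family_id=fam, individual_id=f"{fam}_dad",
                    sex=1, population=pop.label,
                )
            )
            mother_row = len(samples)
            samples.append(
                SampleRecord(
                    family_id=fam, individual_id=f"{fam}_mom",
                    sex=2, population=pop.label,
                )
            )
            founder_rows.extend([father_row, mother_row])
            child_row = len(samples)
            samples.append(
                SampleRecord(
                    family_id=fam, individual_id=f"{fam}_kid",
                    paternal_id=f"{fam}_dad", maternal_id=f"{fam}_mom",
                    sex=int(rng.integers(1, 3)), population=pop.label,
                )
            )
            parent_of.append((father_row, mother_row))

    n = len(samples)
    m = len(cfg.snps)
    calls = np.empty((n, m, 2), dtype="U8")
    snps: List[SnpRecord] = []
    child_rows = [i for i, s in enumerate(samples) if not s.is_founder]

    for j, spec in enumerate(cfg.snps):
        if spec.alleles is not None:
            minor, major = spec.alleles
        else:
            minor, major = rng.choice(len(_ALLELES), size=2, replace=False)
            minor, major = _ALLELES[minor], _ALLELES[major]
        calls[founder_rows, j, :] = _draw_founder_calls(
            rng, spec.maf, minor, major, len(founder_rows)
        )
        for child, (dad, mom) in zip(child_rows, parent_of):
            calls[child, j, 0] = calls[dad, j, int(rng.integers(2))]
            calls[child, j, 1] = calls[mom, j, int(rng.integers(2))]
        snps.append(
            SnpRecord(
                snp_id=spec.snp_id,
                chromosome=spec.chromosome,
                position_bp=spec.position_bp,
                alleles_observed=frozenset({minor, major}),
            )
        )

    if cfg.missing_rate > 0:
        drop = rng.random((n, m)) < cfg.missing_rate
        calls[drop] = "0"

    return GenotypeDataset(samples=samples, snps=snps, calls=calls)


def simulate_expression(ds: GenotypeDataset, cfg: SimConfig) -> List[ExpressionProfile]:
    """Phenotype = beta * coded(causal SNP) + Normal(0, noise_sd), per probe.

    All probes of the gene share the genetic effect; each gets an
    independent noise draw.  Without a causal spec the phenotype is pure
    noise (the null).
    """
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from genotypes
    n = ds.n_samples
    genetic = np.zeros(n)
    noise_sd = cfg.noise_sd
    if cfg.causal is not None:
        noise_sd = cfg.causal.noise_sd
        try:
            j = ds.snp_ids.index(cfg.causal.snp_id)
        except ValueError:
            raise DataError(f"causal SNP {cfg.causal.snp_id} not in dataset")
        design = code_genotypes(
            ds.snp_calls(j), cfg.causal.model, snp_id=cfg.causal.snp_id
        )
        if not design.degenerate:
            genetic[design.kept_index] = cfg.causal.beta * design.columns[0]

    profiles = []
    ids = ds.sample_ids
    for k in range(cfg.n_probes_per_gene):
        values = genetic + rng.normal(0.0, noise_sd, size=n)
        profiles.append(
            ExpressionProfile(
                probe_id=f"{cfg.probe_prefix}{k + 1:06d}",
                gene_symbol=cfg.gene_symbol,
                values=dict(zip(ids, values.tolist())),
            )
        )
    return profiles


def add_ld_proxies(
    ds: GenotypeDataset,
    snp_id: str,
    n_proxies: int,
    flip_rate: float = 0.05,
    spacing: int = 500,
    seed: int = 0,
) -> GenotypeDataset:
    """Block-copy LD mode: duplicate a SNP's genotypes with flip noise.

    Each proxy is placed ``spacing`` bp after the previous SNP copy and has
    each of its calls replaced by a random HWE draw with probability
    ``flip_rate``, yielding correlated but not identical columns.
    """
    rng = np.random.default_rng(seed)
    j = ds.snp_ids.index(snp_id)
    src = ds.snps[j]
    alleles = sorted(src.alleles_observed)
    if len(alleles) != 2:
        raise DataError(f"{snp_id} is monomorphic; cannot build proxies")
    snps = list(ds.snps)
    cols = [ds.calls]
    for k in range(n_proxies):
        col = ds.calls[:, j : j + 1, :].copy()
        flip = rng.random(ds.n_samples) < flip_rate
        col[flip, 0, :] = rng.choice(alleles, size=(int(flip.sum()), 2))
        cols.append(col)
        snps.append(
            replace(
                src,
                snp_id=f"{snp_id}_proxy{k + 1}",
                position_bp=src.position_bp + (k + 1) * spacing,
            )
        )
    calls = np.concatenate(cols, axis=1)
    order = np.argsort([s.position_bp for s in snps], kind="stable")
    return GenotypeDataset(
        samples=list(ds.samples),
        snps=[snps[i] for i in order],
        calls=calls[:, order, :],
    )


def write_fixture(
    ds: GenotypeDataset,
    profiles: Sequence[ExpressionProfile],
    out_dir,
    basename: str = "sim",
) -> dict:
    """Write PED/MAP, the sample-info sidecar and the expression TSV.

    Returns a dict of the paths written.  The dialects match exactly what
    the genotype_io / expression_io readers accept, so a write -> read
    round trip reproduces the dataset.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OutputError(f"cannot create {out}: {exc}") from exc

    ped = out / f"{basename}.ped"
    map_ = out / f"{basename}.map"
    info = out / f"{basename}.sample_info.tsv"
    expr = out / f"{basename}.expression.tsv"

    with ped.open("w") as fh:
        for i, s in enumerate(ds.samples):
            fields = [s.family_id, s.individual_id, s.paternal_id, s.maternal_id,
                      str(s.sex), "-9"]
            fields.extend(ds.calls[i].ravel().tolist())
            fh.write("\t".join(fields) + "\n")

    with map_.open("w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")

    with info.open("w") as fh:
        fh.write("IID\tPOP\n")
        for s in ds.samples:
            fh.write(f"{s.individual_id}\t{s.population}\n")

    ids = ds.sample_ids
    with expr.open("w") as fh:
        fh.write("ProbeID\tGeneSymbol\t" + "\t".join(ids) + "\n")
        for p in profiles:
            vals = "\t".join(repr(p.values[i]) for i in ids)
            fh.write(f"{p.probe_id}\t{p.gene_symbol}\t{vals}\n")

    return {"ped": ped, "map": map_, "sample_info": info, "expression": expr}
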