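"""End-to-end orchestration: extract -> filter -> merge -> regress -> adjust -> write.

One run analyzes one gene against one genomic region (or an explicit SNP
list, which may sit on a different chromosome than the gene — trans scans
impose no positional coupling).  If the gene is represented by several
probes, each probe gets a complete, independently corrected output set.

Stage failures abort the run with the stage name; partially written output
files for the run are removed so a failed run leaves no half-results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import expression_io, genotype_io, report
from .adjust import METHODS, adjust_all
from .assoc import AssociationResult, GeneticModel, run_association
from .errors import EqtlScanError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; exactly one of region / snp_ids is set."""

    gene_symbol: str
    ped_path: str
    map_path: str
    expression_path: str
    out_dir: str
    chromosome: Optional[str] = None
    region: Optional[Tuple[int, int]] = None
    snp_ids: Optional[List[str]] = None
    sample_info_path: Optional[str] = None
    population: str = "pooled"
    founders_only: bool = True
    model: GeneticModel = GeneticModel.ADDITIVE
    adjustments: Sequence[str] = tuple(METHODS)
    cap: float = report.DEFAULT_CAP
    overwrite: bool = False
    seed: int = 0

    def __post_init__(self):
        self.model = GeneticModel(self.model)
        if (self.region is None) == (self.snp_ids is None):
            raise PipelineError(
                "config", "exactly one of region / snp_ids must be provided"
            )
        if self.region is not None and self.chromosome is None:
            raise PipelineError("config", "a region requires a chromosome")
        bad = set(self.adjustments) - set(METHODS)
        if bad:
            raise PipelineError("config", f"unknown adjustment method(s): {sorted(bad)}")


@dataclass
class ProbeResult:
    probe_id: str
    results: List[AssociationResult]
    adjusted: pd.DataFrame
    n_merged: int
    files: Dict[str, Path] = field(default_factory=dict)


@dataclass
class RunResult:
    config: RunConfig
    probes: List[ProbeResult]
    track_file: Path
    log_file: Path


def _stage(name: str):
    """Re-raise stage errors as PipelineError carrying the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, EqtlScanError) and not isinstance(
                exc, PipelineError
            ):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run(config: RunConfig) -> RunResult:
    """Execute the whole workflow for one gene; returns per-probe results."""
    events: List[str] = []
    written: List[Path] = []
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        with _stage("read_genotypes"):
            pop_labels = None
            if config.sample_info_path:
                pop_labels = genotype_io.read_sample_info(config.sample_info_path)
            elif config.population != "pooled":
                pop_labels = config.population
            ds = genotype_io.read_ped_map(config.ped_path, config.map_path, pop_labels)
            events.append(f"read genotypes: {ds.n_samples} samples x {ds.n_snps} SNPs")

        with _stage("read_expression"):
            table = expression_io.read_expression_table(config.expression_path)
            probes = expression_io.probes_for_gene(table, config.gene_symbol)
            by_id = {p.probe_id: p for p in table}
            events.append(
                f"gene {config.gene_symbol}: {len(probes)} probe(s): {probes}"
            )

        with _stage("extract_snps"):
            if config.region is not None:
                ds = genotype_io.extract_region(
                    ds, config.chromosome, config.region[0], config.region[1]
                )
            else:
                ds = genotype_io.extract_snps(ds, config.snp_ids)
            events.append(f"SNP extraction: {ds.n_snps} SNPs retained")

        with _stage("filter_samples"):
            ds = genotype_io.filter_population(ds, config.population)
            events.append(
                f"population={config.population}: {ds.n_samples} samples retained"
            )
            if config.founders_only:
                ds = genotype_io.filter_founders(ds)
                events.append(f"founder filter: {ds.n_samples} founders retained")

        probe_results: List[ProbeResult] = []
        all_tracks = report.TrackSet()
        for probe_id in probes:
            profile = by_id[probe_id]
            with _stage(f"merge[{probe_id}]"):
                merged_ds, merged = expression_io.merge_samples(ds, profile)
                events.append(
                    f"probe {probe_id}: merged n={merged_ds.n_samples} "
                    f"(dropped {ds.n_samples - merged_ds.n_samples} genotyped-only)"
                )
            with _stage(f"associate[{probe_id}]"):
                results = run_association(merged_ds, merged, config.model)
                n_degen = sum(r.is_degenerate for r in results)
                if n_degen:
                    events.append(
                        f"probe {probe_id}: {n_degen} degenerate SNP(s) reported as NA"
                    )
            with _stage(f"adjust[{probe_id}]"):
                adjusted = adjust_all(
                    [r.p for r in results], methods=config.adjustments
                )
            with _stage(f"write[{probe_id}]"):
                files = {
                    "assoc": report.write_assoc_table(
                        results, probe_id, out_dir, config.overwrite
                    ),
                    "adjusted": report.write_adjusted_table(
                        results, adjusted, probe_id, out_dir, config.overwrite
                    ),
                    "means": report.write_means_table(
                        results, probe_id, out_dir, config.overwrite
                    ),
                    "ped": report.write_ped_with_phenotype(
                        merged_ds, merged, probe_id, out_dir, config.overwrite
                    ),
                }
                written.extend(files.values())
            ts = report.make_tracks(
                probe_id, results, adjusted, methods=config.adjustments, cap=config.cap
            )
            all_tracks.tracks.extend(ts.tracks)
            probe_results.append(
                ProbeResult(
                    probe_id=probe_id,
                    results=results,
                    adjusted=adjusted,
                    n_merged=merged_ds.n_samples,
                    files=files,
                )
            )

        with _stage("write_tracks"):
            track_file = out_dir / "customtrack.txt"
            if track_file.exists() and not config.overwrite:
                raise PipelineError(
                    "write_tracks", f"{track_file} exists; use overwrite"
                )
            report.write_custom_track(all_tracks, track_file)
            written.append(track_file)

        log_file = out_dir / "eqtlscan.log"
        meta = {
            "gene": config.gene_symbol,
            "chromosome": config.chromosome,
            "region": config.region,
            "snp_ids": config.snp_ids,
            "population": config.population,
            "founders_only": config.founders_only,
            "model": config.model.value,
            "adjustments": list(config.adjustments),
            "cap": config.cap,
            "seed": config.seed,
        }
        report.write_log(meta, events, log_file)
        return RunResult(
            config=config, probes=probe_results, track_file=track_file,
            log_file=log_file,
        )
    except PipelineError:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise
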